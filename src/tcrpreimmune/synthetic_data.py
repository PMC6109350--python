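"""Synthetic fixtures with known ground truth.

Everything downstream is exercised against data generated here: toy
recombination models small enough for exact enumeration, simulated donor
cohorts with planted HLA-restricted expansions and group effects, synthetic
specificity databases stratified by true generation probability, and
labelled epitope panels whose immunogenicity is a (noisy) function of a
planted Kidera-factor rule.  Every generator is deterministic given its
seed, and each returns a truth record sufficient to score recovery.

The named toy models are fixed points used throughout the tests:

* ``toy_model_a`` - one V/D/J, no deletions or insertions; a single
  scenario producing ``TGTGGGTTC`` (CGF) with probability 1.
* ``toy_model_b`` - as A with two D segments GCT / GAT at probability 0.5
  each (two scenarios, amino-acid variants CAF and CDF).
* ``toy_model_c`` - two synonymous D segments GCT / GCC (both encode A),
  with configurable probabilities; the canonical convergent-recombination
  example.
* ``toy_model_d`` - as A plus a VD insertion of length 0 or 1 with equal
  probability, so exactly half of all products are out of frame.
* ``cohort_model`` - a mid-diversity random model (about 4.5 million
  scenarios, still exactly enumerable) whose nucleotide-level generation
  probabilities stay below ~1e-4, used for cohort-scale simulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .generative_model import (
    DEFAULT_ENUMERATION_GUARD,
    GenerativeModel,
    InsertionModel,
    ModelError,
    ModelTables,
    SegmentLibrary,
    coding_status,
    pgen_nt_table,
    sample_repertoire,
    scenario_count,
    translate_nt,
)
from .repertoire_io import (
    ClonotypeRecord,
    ClonotypeTable,
    SpecificityIndex,
    SpecificityRecord,
)
from .cohort_stats import DonorMetadata
from .epitope_features import EpitopeFeatureVector, kidera_sum

__all__ = [
    "toy_model_a",
    "toy_model_b",
    "toy_model_c",
    "toy_model_d",
    "cohort_model",
    "ToyModelSpec",
    "make_toy_model",
    "CohortSpec",
    "simulate_cohort",
    "make_synthetic_db",
    "make_epitope_panels",
    "aa_pgen_table",
    "coding_conditioned_aa_pgen",
]

_NT = "ACGT"
_POINT_INS = lambda: InsertionModel(  # noqa: E731 - no insertions, point mass at 0
    length_probs=np.array([1.0]),
    initial=np.full(4, 0.25),
    transition=np.full((4, 4), 0.25),
)


def toy_model_a() -> GenerativeModel:
    lib = SegmentLibrary({"V1": "TGT"}, {"D1": "GGG"}, {"J1": "TTC"})
    tables = ModelTables(
        p_v={"V1": 1.0},
        p_dj={("D1", "J1"): 1.0},
        p_delv={"V1": np.array([1.0])},
        p_delj={"J1": np.array([1.0])},
        p_deld={"D1": np.array([[1.0]])},
        ins_vd=_POINT_INS(),
        ins_dj=InsertionModel(np.array([1.0]), np.full(4, 0.25), np.full((4, 4), 0.25), reverse=True),
    )
    return GenerativeModel(lib, tables)


def toy_model_b() -> GenerativeModel:
    lib = SegmentLibrary({"V1": "TGT"}, {"D1": "GCT", "D2": "GAT"}, {"J1": "TTC"})
    tables = ModelTables(
        p_v={"V1": 1.0},
        p_dj={("D1", "J1"): 0.5, ("D2", "J1"): 0.5},
        p_delv={"V1": np.array([1.0])},
        p_delj={"J1": np.array([1.0])},
        p_deld={"D1": np.array([[1.0]]), "D2": np.array([[1.0]])},
        ins_vd=_POINT_INS(),
        ins_dj=InsertionModel(np.array([1.0]), np.full(4, 0.25), np.full((4, 4), 0.25), reverse=True),
    )
    return GenerativeModel(lib, tables)


def toy_model_c(p_gct: float = 0.5, p_gcc: float = 0.5) -> GenerativeModel:
    """Two synonymous D segments (GCT and GCC both encode Ala)."""
    lib = SegmentLibrary({"V1": "TGT"}, {"D1": "GCT", "D2": "GCC"}, {"J1": "TTC"})
    tables = ModelTables(
        p_v={"V1": 1.0},
        p_dj={("D1", "J1"): p_gct, ("D2", "J1"): p_gcc},
        p_delv={"V1": np.array([1.0])},
        p_delj={"J1": np.array([1.0])},
        p_deld={"D1": np.array([[1.0]]), "D2": np.array([[1.0]])},
        ins_vd=_POINT_INS(),
        ins_dj=InsertionModel(np.array([1.0]), np.full(4, 0.25), np.full((4, 4), 0.25), reverse=True),
    )
    return GenerativeModel(lib, tables)


def toy_model_d() -> GenerativeModel:
    """As A but with a VD insertion of length 0 or 1 (uniform nucleotide)."""
    lib = SegmentLibrary({"V1": "TGT"}, {"D1": "GGG"}, {"J1": "TTC"})
    tables = ModelTables(
        p_v={"V1": 1.0},
        p_dj={("D1", "J1"): 1.0},
        p_delv={"V1": np.array([1.0])},
        p_delj={"J1": np.array([1.0])},
        p_deld={"D1": np.array([[1.0]])},
        ins_vd=InsertionModel(np.array([0.5, 0.5]), np.full(4, 0.25), np.full((4, 4), 0.25)),
        ins_dj=InsertionModel(np.array([1.0]), np.full(4, 0.25), np.full((4, 4), 0.25), reverse=True),
    )
    return GenerativeModel(lib, tables)


# ---------------------------------------------------------------------------
# Random toy models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyModelSpec:
    """Shape parameters for a random, exactly enumerable model."""

    n_v: int = 2
    n_d: int = 2
    n_j: int = 2
    v_len: int = 6
    d_len: int = 4
    j_len: int = 6
    max_del_v: int = 1
    max_del_j: int = 1
    max_del_d: int = 1
    ins_lengths: tuple[int, ...] = (0, 1)
    ins_lengths_dj: tuple[int, ...] | None = None  # defaults to ins_lengths
    dirichlet_alpha: float = 5.0


def _random_markov(rng: np.random.Generator, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    initial = rng.dirichlet(np.full(4, alpha))
    transition = np.vstack([rng.dirichlet(np.full(4, alpha)) for _ in range(4)])
    return initial, transition


def _random_insertion(
    rng: np.random.Generator, lengths: tuple[int, ...], alpha: float, reverse: bool
) -> InsertionModel:
    probs = np.zeros(max(lengths) + 1)
    probs[list(lengths)] = rng.dirichlet(np.full(len(lengths), alpha))
    initial, transition = _random_markov(rng, alpha)
    return InsertionModel(probs, initial, transition, reverse=reverse)


def make_toy_model(
    spec: ToyModelSpec = ToyModelSpec(),
    seed: int = 0,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> GenerativeModel:
    """Random normalized model with an enumerable scenario space."""
    rng = np.random.default_rng(seed)
    stop = {"TAA", "TAG", "TGA"}

    def _rand_nt(n: int) -> str:
        return "".join(rng.choice(list(_NT), size=n))

    def _stop_free(n: int, end_aligned: bool) -> str:
        # germline V/J CDR3 regions carry no stop codons in their own frame
        while True:
            s = _rand_nt(n)
            codons = (
                [s[len(s) - 3 * k - 3 : len(s) - 3 * k] for k in range(n // 3)]
                if end_aligned
                else [s[3 * k : 3 * k + 3] for k in range(n // 3)]
            )
            if not stop & set(codons):
                return s

    v_segs = {f"V{i+1}": "TGT" + _stop_free(spec.v_len - 3, False) for i in range(spec.n_v)}
    d_segs = {f"D{i+1}": _rand_nt(spec.d_len) for i in range(spec.n_d)}
    j_segs = {f"J{i+1}": _stop_free(spec.j_len - 3, True) + "TTC" for i in range(spec.n_j)}

    alpha = spec.dirichlet_alpha
    p_v = dict(zip(v_segs, rng.dirichlet(np.full(spec.n_v, alpha))))
    dj_pairs = list(itertools.product(d_segs, j_segs))
    p_dj = dict(zip(dj_pairs, rng.dirichlet(np.full(len(dj_pairs), alpha))))
    p_delv = {v: rng.dirichlet(np.full(spec.max_del_v + 1, alpha)) for v in v_segs}
    p_delj = {j: rng.dirichlet(np.full(spec.max_del_j + 1, alpha)) for j in j_segs}
    p_deld = {}
    for d in d_segs:
        k = spec.max_del_d + 1
        mat = rng.dirichlet(np.full(k * k, alpha)).reshape(k, k)
        for dl in range(k):
            for dr in range(k):
                if dl + dr > spec.d_len:
                    mat[dl, dr] = 0.0
        p_deld[d] = mat / mat.sum()
    tables = ModelTables(
        p_v=p_v,
        p_dj=p_dj,
        p_delv=p_delv,
        p_delj=p_delj,
        p_deld=p_deld,
        ins_vd=_random_insertion(rng, spec.ins_lengths, alpha, reverse=False),
        ins_dj=_random_insertion(
            rng, spec.ins_lengths_dj or spec.ins_lengths, alpha, reverse=True
        ),
    )
    model = GenerativeModel(SegmentLibrary(v_segs, d_segs, j_segs), tables)
    n = scenario_count(model)
    if n > guard:
        raise ModelError(f"requested scenario space {n} exceeds the enumeration guard {guard}")
    return model


def cohort_model(seed: int = 7) -> GenerativeModel:
    """Mid-diversity model for cohort simulation.

    Three V, two D, three J segments, up to four nucleotides trimmed per
    side and one-to-three random insertions per junction: about 6.8
    million scenarios, enumerable for exact ground truth, with individual
    nucleotide-sequence probabilities low enough that a 10^4-cell sample
    rarely sees the same rearrangement twice.
    """
    return make_toy_model(
        ToyModelSpec(
            n_v=3,
            n_d=2,
            n_j=3,
            v_len=12,
            d_len=6,
            j_len=12,
            max_del_v=4,
            max_del_j=4,
            max_del_d=2,
            ins_lengths=(1, 2, 3),
            ins_lengths_dj=(1, 2),
            dirichlet_alpha=10.0,
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Exact amino-acid Pgen tables (ground truth helpers)
# ---------------------------------------------------------------------------


def aa_pgen_table(model: GenerativeModel, nt_table: Mapping[str, float] | None = None) -> dict[str, float]:
    """Exact amino-acid Pgen (exact translation) for every coding product."""
    if nt_table is None:
        nt_table = pgen_nt_table(model)
    out: dict[str, float] = {}
    for nt, p in nt_table.items():
        if len(nt) % 3 == 0 and coding_status(nt) == "coding":
            aa = translate_nt(nt)
            out[aa] = out.get(aa, 0.0) + p
    return out


def coding_conditioned_aa_pgen(
    targets: Sequence[str],
    model: GenerativeModel,
    max_subst: int = 1,
    nt_table: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Exact coding-conditioned fuzzy Pgen for each target amino-acid CDR3.

    P(translation within ``max_subst`` of target | product is coding),
    the quantity that observed pooled unique-variant frequencies estimate.
    """
    if nt_table is None:
        nt_table = pgen_nt_table(model)
    aa_table = aa_pgen_table(model, nt_table)
    p_coding = sum(aa_table.values())
    index = SpecificityIndex(aa_table, max_subst=max(1, max_subst))
    out = {}
    for t in targets:
        out[t] = sum(aa_table[a] for a in index.query(t, max_subst)) / p_coding
    return out


# ---------------------------------------------------------------------------
# Synthetic specificity database
# ---------------------------------------------------------------------------

_DEFAULT_ALLELES = (
    "HLA-A*01", "HLA-A*02", "HLA-B*07", "HLA-B*08", "HLA-C*04", "HLA-C*07",
)
_DEFAULT_SPECIES = ("CMV", "EBV", "InfluenzaA", "HIV-1")


def make_synthetic_db(
    model: GenerativeModel,
    n_epitopes: int = 10,
    tcrs_per_epitope: int = 30,
    pgen_strata: Sequence[tuple[float, float]] | None = None,
    hla_alleles: Sequence[str] = _DEFAULT_ALLELES,
    seed: int = 0,
    species: Sequence[str] = _DEFAULT_SPECIES,
    nt_table: Mapping[str, float] | None = None,
) -> tuple[list[SpecificityRecord], dict[str, object]]:
    """Database of model-generated TCRs stratified by exact Pgen.

    Each epitope receives ``tcrs_per_epitope`` distinct CDR3 amino-acid
    sequences whose exact (enumerated) Pgen lies in that epitope's stratum;
    strata default to log-spaced ranges across the model's Pgen spectrum.
    Restriction alleles and source species are assigned round-robin.  The
    truth record stores the exact Pgen of every sequence.
    """
    rng = np.random.default_rng(seed)
    aa_table = aa_pgen_table(model, nt_table)
    aas = np.array(list(aa_table))
    pgens = np.array([aa_table[a] for a in aas])

    if pgen_strata is None:
        # quantile strata over the model's Pgen spectrum: every stratum holds
        # an equal share of the candidate sequences
        edges = np.quantile(pgens, np.linspace(0.0, 1.0, n_epitopes + 1))
        edges[-1] *= 1.0 + 1e-9
        pgen_strata = [(float(edges[i]), float(edges[i + 1])) for i in range(n_epitopes)]

    records: list[SpecificityRecord] = []
    truth_rows = []
    used: set[str] = set()
    for e_idx in range(n_epitopes):
        lo, hi = pgen_strata[e_idx % len(pgen_strata)]
        candidates = [a for a, p in zip(aas, pgens) if lo <= p < hi and a not in used]
        if len(candidates) < tcrs_per_epitope:
            raise ModelError(
                f"stratum unreachable: [{lo:g}, {hi:g}) holds only "
                f"{len(candidates)} unused sequences (< {tcrs_per_epitope})"
            )
        chosen = rng.choice(candidates, size=tcrs_per_epitope, replace=False)
        used.update(chosen)
        epitope_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9))
        allele = hla_alleles[e_idx % len(hla_alleles)]
        sp = species[e_idx % len(species)]
        for aa in chosen:
            records.append(
                SpecificityRecord(
                    chain="TRB",
                    cdr3_aa=str(aa),
                    epitope_seq=epitope_seq,
                    epitope_species=sp,
                    hla_restriction=allele,
                )
            )
            truth_rows.append(
                {"epitope_seq": epitope_seq, "cdr3_aa": str(aa),
                 "exact_pgen": float(aa_table[str(aa)]), "hla_restriction": allele,
                 "epitope_species": sp}
            )
    truth = {
        "records": truth_rows,
        "strata": list(pgen_strata),
        "median_pgen_per_epitope": {
            e: float(np.median([r["exact_pgen"] for r in truth_rows if r["epitope_seq"] == e]))
            for e in {r["epitope_seq"] for r in truth_rows}
        },
    }
    return records, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study-design parameters for a simulated donor cohort."""

    n_donors: int = 20
    cells_per_donor: int = 2000
    hla_allele_frequencies: Mapping[str, float] = field(
        default_factory=lambda: {
            "HLA-A*01": 0.3, "HLA-A*02": 0.5, "HLA-A*03": 0.2,
            "HLA-B*07": 0.25, "HLA-B*08": 0.35, "HLA-B*44": 0.4,
            "HLA-C*04": 0.4, "HLA-C*07": 0.6,
        }
    )
    expansion_effect: float = 1.0  # read-count multiplier in matched seropositive donors
    hla_presence_effect: float = 1.0  # unique-match multiplier for genotype-matched restrictions
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    ucb_fraction: float = 0.0
    ancestry_labels: Mapping[str, float] = field(
        default_factory=lambda: {"Caucasian": 0.6, "African": 0.25, "Asian": 0.15}
    )
    seropositive_fraction: float = 0.5
    reads_per_cell: float = 10.0
    nb_dispersion: float = 2.0  # negative-binomial shape; smaller = noisier


def _codon_options() -> dict[str, list[str]]:
    from .generative_model import CODON_TABLE

    opts: dict[str, list[str]] = {}
    for codon, aa in CODON_TABLE.items():
        opts.setdefault(aa, []).append(codon)
    return opts


_CODONS_BY_AA = _codon_options()


def _random_encoding(aa: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_BY_AA[c][rng.integers(len(_CODONS_BY_AA[c]))] for c in aa)


def _aa_for_nt(nt: str, cache: dict[str, tuple[str, bool]]) -> tuple[str, bool]:
    """(display amino-acid string, is_coding); '_' marks a frameshift."""
    hit = cache.get(nt)
    if hit is None:
        status = coding_status(nt)
        if status == "out_of_frame":
            hit = (translate_nt(nt[: 3 * (len(nt) // 3)]) + "_", False)
        else:
            hit = (translate_nt(nt), status == "coding")
        cache[nt] = hit
    return hit


def simulate_cohort(
    model: GenerativeModel,
    spec: CohortSpec,
    db: Sequence[SpecificityRecord] = (),
    max_subst: int = 1,
) -> tuple[list[ClonotypeTable], list[DonorMetadata], dict[str, object]]:
    """Simulate per-donor repertoires with planted effects.

    Each donor's ``cells_per_donor`` rearrangements are drawn i.i.d. from
    the model (coding and non-coding retained).  Genotypes draw two alleles
    per locus from the population allele frequencies; serostatus is
    independent.  Planted effects:

    * ``expansion_effect`` multiplies the expected read count of clonotypes
      matching the database (within ``max_subst``) in donors that are
      seropositive and carry a matched restriction allele;
    * ``group_effects[(label, "match_burden")] = m`` spikes extra unique
      database-matching clonotypes into donors with that sample-type or
      ancestry label, scaling their expected match count by m;
    * ``hla_presence_effect = m`` spikes extra unique clonotypes matching
      allele-a-restricted records into donors carrying a, scaling their
      expected a-restricted match count by m (a positive-selection excess).

    Read counts are negative-binomial around the per-clonotype mean, so
    frequency ratios show realistic overdispersion.  The returned truth
    record stores every planted effect and per-donor assignment.
    """
    if spec.cells_per_donor < 1:
        raise ValueError("cells_per_donor must be >= 1")
    rng = np.random.default_rng(spec.seed)

    db_by_aa: dict[str, set[str]] = {}
    for r in db:
        db_by_aa.setdefault(r.cdr3_aa, set()).add(r.hla_restriction)
    db_index = SpecificityIndex(db_by_aa, max_subst=max(1, max_subst)) if db else None
    db_aa_list = list(db_by_aa)

    loci: dict[str, list[str]] = {}
    for allele in spec.hla_allele_frequencies:
        locus = allele.split("*")[0]
        loci.setdefault(locus, []).append(allele)

    aa_cache: dict[str, tuple[str, bool]] = {}
    match_cache: dict[str, frozenset[str]] = {}

    def _matched_alleles(aa: str) -> frozenset[str]:
        hit = match_cache.get(aa)
        if hit is None:
            alleles: set[str] = set()
            if db_index is not None:
                for db_aa in db_index.query(aa, max_subst):
                    alleles |= db_by_aa[db_aa]
            hit = frozenset(alleles)
            match_cache[aa] = hit
        return hit

    tables: list[ClonotypeTable] = []
    metadata: list[DonorMetadata] = []
    truth_donors = []
    spike_totals = {}

    ancestry_labels = list(spec.ancestry_labels)
    ancestry_probs = np.array(list(spec.ancestry_labels.values()), dtype=float)
    ancestry_probs = ancestry_probs / ancestry_probs.sum()

    for d_idx in range(spec.n_donors):
        sample_id = f"donor{d_idx:04d}"
        donor_seed = int(rng.integers(2**31 - 1))
        # genotype: two alleles per locus
        genotype: set[str] = set()
        for locus, alleles in loci.items():
            freqs = np.array([spec.hla_allele_frequencies[a] for a in alleles])
            freqs = freqs / freqs.sum()
            genotype |= set(rng.choice(alleles, size=2, p=freqs))
        serostatus = "positive" if rng.random() < spec.seropositive_fraction else "negative"
        sample_type = "UCB" if rng.random() < spec.ucb_fraction else "PBMC"
        ancestry = str(rng.choice(ancestry_labels, p=ancestry_probs))

        cells = sample_repertoire(model, spec.cells_per_donor, donor_seed)
        counts: dict[str, int] = {}
        for nt in cells:
            counts[nt] = counts.get(nt, 0) + 1

        # planted positive-selection excess for genotype-matched restrictions
        spiked = 0
        if spec.hla_presence_effect > 1.0 and db_aa_list:
            for allele in sorted(genotype):
                pool = [aa for aa in db_aa_list if allele in db_by_aa[aa]]
                if not pool:
                    continue
                baseline = sum(
                    1
                    for nt in counts
                    if _aa_for_nt(nt, aa_cache)[1]
                    and allele in _matched_alleles(_aa_for_nt(nt, aa_cache)[0])
                )
                n_extra = int(np.round((spec.hla_presence_effect - 1.0) * baseline))
                for _ in range(n_extra):
                    aa = pool[rng.integers(len(pool))]
                    for _attempt in range(20):
                        nt = _random_encoding(aa, rng)
                        if nt not in counts:
                            counts[nt] = 1
                            spiked += 1
                            break

        # group effect: spike extra unique db-matching clonotypes
        for label in (sample_type, ancestry):
            mult = spec.group_effects.get((label, "match_burden"), 1.0)
            if mult <= 1.0 or not db_aa_list:
                continue
            baseline = sum(
                1
                for nt in counts
                if _aa_for_nt(nt, aa_cache)[1] and _matched_alleles(_aa_for_nt(nt, aa_cache)[0])
            )
            n_extra = int(np.round((mult - 1.0) * baseline))
            for _ in range(n_extra):
                aa = db_aa_list[rng.integers(len(db_aa_list))]
                for _attempt in range(20):
                    nt = _random_encoding(aa, rng)
                    if nt not in counts:
                        counts[nt] = 1
                        spiked += 1
                        break
        spike_totals[sample_id] = spiked

        # read counts with planted expansion
        nts = list(counts)
        means = np.empty(len(nts))
        for i, nt in enumerate(nts):
            aa, is_coding = _aa_for_nt(nt, aa_cache)
            mult = 1.0
            if (
                spec.expansion_effect != 1.0
                and is_coding
                and serostatus == "positive"
                and _matched_alleles(aa) & genotype
            ):
                mult = spec.expansion_effect
            means[i] = counts[nt] * spec.reads_per_cell * mult
        r_shape = spec.nb_dispersion
        reads = rng.negative_binomial(r_shape, r_shape / (r_shape + means))
        reads = np.maximum(reads, 1)
        total_reads = int(reads.sum())

        records = []
        for i, nt in enumerate(nts):
            aa, _ = _aa_for_nt(nt, aa_cache)
            records.append(
                ClonotypeRecord(
                    count=int(reads[i]),
                    freq=float(reads[i] / total_reads),
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    v_call="V?",
                    d_call=".",
                    j_call="J?",
                )
            )
        tables.append(ClonotypeTable(sample_id=sample_id, records=records))
        metadata.append(
            DonorMetadata(
                sample_id=sample_id,
                hla_alleles=frozenset(genotype),
                cmv_serostatus=serostatus,
                ancestry=ancestry,
                sample_type=sample_type,
            )
        )
        truth_donors.append(
            {
                "sample_id": sample_id,
                "genotype": sorted(genotype),
                "serostatus": serostatus,
                "sample_type": sample_type,
                "ancestry": ancestry,
                "n_spiked": spiked,
            }
        )

    truth = {
        "expansion_effect": spec.expansion_effect,
        "group_effects": dict(spec.group_effects),
        "donors": truth_donors,
        "spike_totals": spike_totals,
        "seed": spec.seed,
    }
    return tables, metadata, truth


# ---------------------------------------------------------------------------
# Labelled epitope panels
# ---------------------------------------------------------------------------


def make_epitope_panels(
    n_per_class: int = 50,
    planted_rule: Callable[[np.ndarray], float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    peptide_length: int = 9,
    margin_sd: float = 1.0,
) -> tuple[list[EpitopeFeatureVector], dict[str, object]]:
    """Random peptides labelled immunogenic by a noisy planted feature rule.

    The default rule scores a peptide by its tenth Kidera-factor sum
    (surrounding hydrophobicity); peptides scoring above a population
    threshold are immunogenic.  The two classes are separated by a gap of
    ``margin_sd`` population standard deviations around the threshold, so
    that with ``noise_sd = 0`` they are perfectly separable clusters in the
    planted feature (the labelled immunogenicity panels this emulates are
    separated sets, not a continuum split in half).  ``noise_sd`` perturbs
    the score before labelling, blurring the link between the label and the
    true features.  The truth record stores the rule, threshold and scores.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rule = planted_rule if planted_rule is not None else (lambda ks: float(ks[9]))
    aa = list("ACDEFGHIKLMNPQRSTVWY")

    # population threshold and scale from a fixed-size presample
    pre = [rule(kidera_sum("".join(rng.choice(aa, size=peptide_length)))) for _ in range(500)]
    threshold = float(np.median(pre))
    scale = float(np.std(pre))
    gap = margin_sd * scale / 2.0

    peptides, scores, labels = [], [], []
    n_pos = n_neg = 0
    seen: set[str] = set()
    while n_pos < n_per_class or n_neg < n_per_class:
        pep = "".join(rng.choice(aa, size=peptide_length))
        if pep in seen:
            continue
        seen.add(pep)
        score = rule(kidera_sum(pep)) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        if score >= threshold + gap and n_pos < n_per_class:
            label = "immunogenic"
            n_pos += 1
        elif score <= threshold - gap and n_neg < n_per_class:
            label = "non_immunogenic"
            n_neg += 1
        else:
            continue
        peptides.append(pep)
        scores.append(score)
        labels.append(label)
    panel = [
        EpitopeFeatureVector.from_sequence(p, label=lab) for p, lab in zip(peptides, labels)
    ]
    truth = {
        "rule": "kidera factor 10 sum" if planted_rule is None else "custom",
        "threshold": threshold,
        "margin_sd": margin_sd,
        "noise_sd": noise_sd,
        "scores": dict(zip(peptides, map(float, scores))),
    }
    return panel, truth
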