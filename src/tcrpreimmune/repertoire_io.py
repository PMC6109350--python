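"""Clonotype tables, specificity databases, pooling and fuzzy annotation.

Reads VDJtools-dialect clonotype TSVs (count, freq, cdr3nt, cdr3aa, v, d, j)
and VDJdb-like specificity tables, splits clonotypes into functional and
non-functional, derives the dataset V/J usage from non-functional
clonotypes, pools unique nucleotide variants across donors keyed by CDR3
amino-acid sequence, and annotates repertoires against the specificity
database allowing at most a fixed number of amino-acid substitutions and no
indels (V/J gene identity is deliberately not required).

Baseline frequency is measured by counting unique rearrangements: the same
nucleotide variant seen in k different donors contributes k to the pool.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .generative_model import coding_status, hamming, translate_nt

__all__ = [
    "RepertoireError",
    "ClonotypeRecord",
    "ClonotypeTable",
    "PooledRepertoire",
    "SpecificityRecord",
    "SpecificityIndex",
    "VDJTOOLS_DIALECT",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_specificity_table",
    "write_specificity_table",
    "partition_functional",
    "vj_usage_from_nonfunctional",
    "pool_by_cdr3aa",
    "fuzzy_match",
    "observed_frequency_and_incidence",
    "annotate_cohort",
    "normalize_allele",
    "incidence_bin",
    "INCIDENCE_BINS",
]


class RepertoireError(ValueError):
    pass


# Default column mapping follows the VDJtools convention; a custom dialect
# maps the same logical names onto other layouts (e.g. immuneACCESS exports).
VDJTOOLS_DIALECT: Mapping[str, str] = {
    "count": "count",
    "freq": "freq",
    "cdr3_nt": "cdr3nt",
    "cdr3_aa": "cdr3aa",
    "v_call": "v",
    "d_call": "d",
    "j_call": "j",
}


@dataclass(slots=True)
class ClonotypeRecord:
    count: int
    freq: float
    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    d_call: str
    j_call: str

    @property
    def is_coding(self) -> bool:
        return coding_status(self.cdr3_nt) == "coding"


@dataclass
class ClonotypeTable:
    sample_id: str
    records: list[ClonotypeRecord]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(r.freq for r in self.records)
        if total > 1.0 + 1e-6:
            raise RepertoireError(f"sample {self.sample_id}: frequencies sum to {total} > 1")
        nts = [r.cdr3_nt for r in self.records]
        if len(set(nts)) != len(nts):
            raise RepertoireError(f"sample {self.sample_id}: duplicate CDR3 nucleotide sequences")

    def __len__(self) -> int:
        return len(self.records)


def read_clonotype_table(
    path: str | Path,
    dialect: Mapping[str, str] = VDJTOOLS_DIALECT,
    sample_id: str | None = None,
) -> ClonotypeTable:
    """Parse a clonotype TSV; malformed rows are rejected with row numbers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [col for col in dialect.values() if col not in df.columns]
    if missing:
        raise RepertoireError(f"bad header: missing column(s) {missing} in {path.name}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            count = int(row[dialect["count"]])
            freq = float(row[dialect["freq"]])
        except (TypeError, ValueError) as exc:
            raise RepertoireError(f"bad row {i} in {path.name}: non-numeric count/freq") from exc
        if count < 1 or not (0.0 <= freq <= 1.0):
            raise RepertoireError(f"bad row {i} in {path.name}: count={count}, freq={freq}")
        records.append(
            ClonotypeRecord(
                count=count,
                freq=freq,
                cdr3_nt=str(row[dialect["cdr3_nt"]]).upper(),
                cdr3_aa=str(row[dialect["cdr3_aa"]]),
                v_call=str(row[dialect["v_call"]]),
                d_call=str(row[dialect["d_call"]]),
                j_call=str(row[dialect["j_call"]]),
            )
        )
    return ClonotypeTable(sample_id=sample_id or path.stem, records=records)


def write_clonotype_table(
    table: ClonotypeTable, path: str | Path, dialect: Mapping[str, str] = VDJTOOLS_DIALECT
) -> None:
    df = pd.DataFrame(
        {
            dialect["count"]: [r.count for r in table.records],
            dialect["freq"]: [repr(r.freq) for r in table.records],
            dialect["cdr3_nt"]: [r.cdr3_nt for r in table.records],
            dialect["cdr3_aa"]: [r.cdr3_aa for r in table.records],
            dialect["v_call"]: [r.v_call for r in table.records],
            dialect["d_call"]: [r.d_call for r in table.records],
            dialect["j_call"]: [r.j_call for r in table.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Functional split, VJ usage, pooling
# ---------------------------------------------------------------------------


def partition_functional(table: ClonotypeTable) -> tuple[ClonotypeTable, ClonotypeTable]:
    """Split into coding and non-coding clonotypes (exhaustive, disjoint).

    The authoritative check is :func:`coding_status` on the nucleotide
    sequence; amino-acid markers ('*', '_') are only a convention for
    display.
    """
    coding = [r for r in table.records if r.is_coding]
    noncoding = [r for r in table.records if not r.is_coding]
    return (
        ClonotypeTable(table.sample_id, coding, table.metadata),
        ClonotypeTable(table.sample_id, noncoding, table.metadata),
    )


def vj_usage_from_nonfunctional(tables: Iterable[ClonotypeTable]) -> dict[tuple[str, str], float]:
    """Relative (V, J) frequencies among unique non-functional clonotypes.

    Non-functional rearrangements never passed selection, so their segment
    usage reflects the raw recombination + amplification process, making
    them the appropriate weights for rescaling Pgen estimates to a dataset.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for table in tables:
        for r in table.records:
            if not r.is_coding:
                counts[(r.v_call, r.j_call)] += 1
    total = sum(counts.values())
    if total == 0:
        raise RepertoireError("cannot estimate usage: no non-functional clonotypes")
    return {vj: c / total for vj, c in counts.items()}


@dataclass
class PooledRepertoire:
    """Cross-donor pool of unique nucleotide variants keyed by CDR3 amino acid.

    The same nucleotide sequence observed in k donors contributes k unique
    rearrangements: sharing across individuals is evidence of convergent
    recombination, not redundancy.
    """

    variants: dict[str, set[tuple[str, str]]]  # cdr3_aa -> {(cdr3_nt, donor_id)}

    @property
    def total_unique(self) -> int:
        return sum(len(s) for s in self.variants.values())

    def aa_sequences(self) -> list[str]:
        return list(self.variants)


def pool_by_cdr3aa(tables: Iterable[ClonotypeTable]) -> PooledRepertoire:
    """Pool coding clonotypes across donors into unique (nt, donor) pairs."""
    variants: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for table in tables:
        for r in table.records:
            if not r.is_coding:
                continue
            aa = r.cdr3_aa if r.cdr3_aa else translate_nt(r.cdr3_nt)
            variants[aa].add((r.cdr3_nt, table.sample_id))
    return PooledRepertoire(variants=dict(variants))


# ---------------------------------------------------------------------------
# Specificity database and fuzzy matching
# ---------------------------------------------------------------------------


def normalize_allele(allele: str) -> str:
    """Normalize an HLA allele string to the gene + first field (e.g. HLA-A*02)."""
    allele = allele.strip()
    if not allele:
        return allele
    if not allele.upper().startswith("HLA-"):
        allele = "HLA-" + allele
    return allele.split(":")[0]


@dataclass(frozen=True)
class SpecificityRecord:
    """One database row linking a CDR3 to an epitope and its HLA restriction."""

    chain: str  # TRA or TRB
    cdr3_aa: str
    epitope_seq: str
    epitope_species: str
    hla_restriction: str
    v_call: str = ""
    j_call: str = ""


_VDJDB_COLUMNS = {
    "gene": "chain",
    "cdr3": "cdr3_aa",
    "v.segm": "v_call",
    "j.segm": "j_call",
    "antigen.epitope": "epitope_seq",
    "antigen.species": "epitope_species",
    "mhc.a": "hla_restriction",
}


def read_specificity_table(path: str | Path) -> list[SpecificityRecord]:
    """Read a VDJdb-like TSV of annotated TCR specificities."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _VDJDB_COLUMNS if c not in df.columns]
    if missing:
        raise RepertoireError(f"bad header: missing column(s) {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SpecificityRecord(
                chain=row["gene"],
                cdr3_aa=row["cdr3"],
                v_call=row["v.segm"],
                j_call=row["j.segm"],
                epitope_seq=row["antigen.epitope"],
                epitope_species=row["antigen.species"],
                hla_restriction=normalize_allele(row["mhc.a"]),
            )
        )
    return out


def write_specificity_table(records: Sequence[SpecificityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "complex.id": range(len(records)),
            "gene": [r.chain for r in records],
            "cdr3": [r.cdr3_aa for r in records],
            "v.segm": [r.v_call for r in records],
            "j.segm": [r.j_call for r in records],
            "species": ["HomoSapiens"] * len(records),
            "antigen.epitope": [r.epitope_seq for r in records],
            "antigen.species": [r.epitope_species for r in records],
            "mhc.a": [r.hla_restriction for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


class SpecificityIndex:
    """Length-bucketed masked-position hash for <=1-substitution lookup.

    Each length-L sequence is indexed under its L single-position masks plus
    the unmasked sequence, so a query retrieves all Hamming-distance-<=1
    records in O(L) dictionary probes.  For larger substitution allowances
    the index falls back to a Hamming scan over the query's length bucket;
    both paths return exactly the brute-force result.
    """

    def __init__(self, sequences: Iterable[str], max_subst: int = 1) -> None:
        self.max_subst = max_subst
        self._by_length: dict[int, list[str]] = defaultdict(list)
        self._masked: dict[tuple[int, int, str], set[str]] = defaultdict(set)
        seen = set()
        for s in sequences:
            if s in seen:
                continue
            seen.add(s)
            self._by_length[len(s)].append(s)
            if max_subst == 1:
                for pos in range(len(s)):
                    self._masked[(len(s), pos, s[:pos] + s[pos + 1 :])].add(s)

    def query(self, seq: str, max_subst: int | None = None) -> set[str]:
        """All indexed sequences within ``max_subst`` substitutions of ``seq``."""
        m = self.max_subst if max_subst is None else max_subst
        if m > self.max_subst:
            raise ValueError("index built for a smaller substitution allowance")
        bucket = self._by_length.get(len(seq))
        if not bucket:
            return set()
        if m == 0:
            return {seq} if seq in set(bucket) else set()
        if m == 1 and self.max_subst == 1:
            hits: set[str] = set()
            for pos in range(len(seq)):
                key = (len(seq), pos, seq[:pos] + seq[pos + 1 :])
                hits |= self._masked.get(key, set())
            return hits
        return {s for s in bucket if hamming(s, seq) <= m}


def fuzzy_match(
    cdr3_aa: str, db: Sequence[SpecificityRecord], max_subst: int = 1
) -> list[SpecificityRecord]:
    """Database records whose CDR3 is within ``max_subst`` substitutions.

    Matching is equal-length only (no indels) and ignores V/J calls: exact
    segment matching discards too many genuine hits, while the CDR3 itself
    implicitly pins down J and narrows V.
    """
    if max_subst < 0:
        raise ValueError("max_subst must be >= 0")
    return [
        r
        for r in db
        if len(r.cdr3_aa) == len(cdr3_aa) and hamming(r.cdr3_aa, cdr3_aa) <= max_subst
    ]


# ---------------------------------------------------------------------------
# Frequencies, incidence, cohort annotation
# ---------------------------------------------------------------------------

# Population-incidence bins used to stratify how widely a variant is shared.
INCIDENCE_BINS = ("<5%", "5–9%", "10–14%", "15–19%", "20%+")
PUBLIC_THRESHOLD = 0.05  # "5%+" of samples, inclusive


def incidence_bin(incidence: float) -> str:
    if incidence < 0.05:
        return INCIDENCE_BINS[0]
    if incidence < 0.10:
        return INCIDENCE_BINS[1]
    if incidence < 0.15:
        return INCIDENCE_BINS[2]
    if incidence < 0.20:
        return INCIDENCE_BINS[3]
    return INCIDENCE_BINS[4]


def observed_frequency_and_incidence(
    cdr3_aa: str,
    pooled: PooledRepertoire,
    tables: Sequence[ClonotypeTable],
    max_subst: int = 1,
    index: SpecificityIndex | None = None,
) -> tuple[float, float, str, bool]:
    """Observed baseline frequency and population incidence of a variant.

    Frequency = unique pooled rearrangements whose amino-acid sequence is
    within ``max_subst`` of ``cdr3_aa``, divided by the total unique pool
    size.  Incidence = fraction of samples carrying at least one matching
    coding clonotype.  Returns ``(frequency, incidence, bin, public_flag)``.

    Pass a prebuilt ``SpecificityIndex`` over the pool's amino-acid keys to
    amortize repeated queries.
    """
    if pooled.total_unique == 0:
        raise RepertoireError("empty pool")
    if index is None:
        index = SpecificityIndex(pooled.variants, max_subst=max(1, max_subst))
    matching_aa = index.query(cdr3_aa, max_subst)
    n_match = sum(len(pooled.variants[aa]) for aa in matching_aa)
    frequency = n_match / pooled.total_unique

    n_with = 0
    for table in tables:
        donors_aa = {
            (r.cdr3_aa if r.cdr3_aa else translate_nt(r.cdr3_nt))
            for r in table.records
            if r.is_coding
        }
        if donors_aa & matching_aa:
            n_with += 1
    incidence = n_with / len(tables) if tables else 0.0
    return frequency, incidence, incidence_bin(incidence), incidence >= PUBLIC_THRESHOLD


def annotate_cohort(
    tables: Sequence[ClonotypeTable],
    db: Sequence[SpecificityRecord],
    max_subst: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Annotate every coding clonotype in a cohort against the database.

    Returns a tidy DataFrame with one row per (sample, clonotype, matched
    record) and a per-sample Series of total unique coding rearrangements
    (the denominator for match-burden statistics).
    """
    db_by_aa: dict[str, list[SpecificityRecord]] = defaultdict(list)
    for r in db:
        db_by_aa[r.cdr3_aa].append(r)
    index = SpecificityIndex(db_by_aa, max_subst=max(1, max_subst))

    rows = []
    totals = {}
    for table in tables:
        n_coding = 0
        for rec in table.records:
            if not rec.is_coding:
                continue
            n_coding += 1
            aa = rec.cdr3_aa if rec.cdr3_aa else translate_nt(rec.cdr3_nt)
            for db_aa in index.query(aa, max_subst):
                for sr in db_by_aa[db_aa]:
                    rows.append(
                        {
                            "sample_id": table.sample_id,
                            "cdr3_nt": rec.cdr3_nt,
                            "cdr3_aa": aa,
                            "count": rec.count,
                            "freq": rec.freq,
                            "db_cdr3_aa": sr.cdr3_aa,
                            "chain": sr.chain,
                            "epitope_seq": sr.epitope_seq,
                            "epitope_species": sr.epitope_species,
                            "hla_restriction": sr.hla_restriction,
                        }
                    )
        totals[table.sample_id] = n_coding
    columns = [
        "sample_id", "cdr3_nt", "cdr3_aa", "count", "freq",
        "db_cdr3_aa", "chain", "epitope_seq", "epitope_species", "hla_restriction",
    ]
    annotations = pd.DataFrame(rows, columns=columns)
    return annotations, pd.Series(totals, name="unique_coding")
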