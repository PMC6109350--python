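"""Probabilistic model of TRB V(D)J recombination and CDR3 generation probability.

The recombination scenario probability factorizes as

    P(r) = P(V) * P(D,J) * P(delV|V) * P(insVD) * P(delDl,delDr|D)
           * P(insDJ) * P(delJ|J)

where deletions trim the CDR3-proximal ends of the germline segments and the
two junctions receive random nucleotide insertions drawn from a
length-distribution plus first-order Markov chain.  The generation
probability of a nucleotide CDR3 is the sum of P(r) over all scenarios that
assemble it; the generation probability of an amino-acid CDR3 additionally
sums over all nucleotide encodings, optionally tolerating a fixed number of
amino-acid substitutions ("fuzzy" Pgen).

Amino-acid Pgen is computed in two steps so that a dataset-specific V/J
usage profile (estimated from non-functional clonotypes) can replace the
model's own segment-choice probabilities: (i) estimate P(match | V, J) by
Monte-Carlo simulation of rearrangements with the V and J fixed, then (ii)
average over (V, J) with the supplied usage weights.

All sequences are stored 5'->3' on the coding strand.  The CDR3 spans the
conserved V-gene cysteine codon through the conserved J-gene
phenylalanine/tryptophan codon inclusive.  Palindromic nucleotides are not
modelled; deletion counts are non-negative.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ModelError",
    "SegmentLibrary",
    "InsertionModel",
    "ModelTables",
    "GenerativeModel",
    "RecombinationScenario",
    "PgenEstimate",
    "load_model",
    "save_model",
    "evaluate_scenario",
    "enumerate_scenarios",
    "scenario_count",
    "pgen_nt_exact",
    "pgen_nt_table",
    "pgen_aa_exact",
    "sample_rearrangements",
    "sample_repertoire",
    "pgen_aa",
    "coding_status",
    "coding_fraction",
    "convergence_probability",
    "translate_nt",
    "hamming",
]

NT_ALPHABET = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NT_ALPHABET)}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code, written out so the hot translation loop is a dict
# lookup; agreement with Bio.Seq.translate is asserted in the tests.
CODON_TABLE = {
    "".join(c): str(Seq("".join(c)).translate()) for c in itertools.product(NT_ALPHABET, repeat=3)
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)


class ModelError(ValueError):
    """Raised for structurally invalid or unnormalized model tables."""


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string ('*' marks stop codons)."""
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def coding_status(cdr3_nt: str) -> str:
    """Classify a CDR3 nucleotide sequence as coding / out_of_frame / stop."""
    for c in cdr3_nt:
        if c not in _NT_INDEX:
            raise ValueError(f"non-ACGT character {c!r} in CDR3 sequence")
    if len(cdr3_nt) % 3 != 0:
        return "out_of_frame"
    for i in range(0, len(cdr3_nt), 3):
        if cdr3_nt[i : i + 3] in STOP_CODONS:
            return "stop"
    return "coding"


# ---------------------------------------------------------------------------
# Model data structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentLibrary:
    """Germline segment sequences contributing to the CDR3.

    ``v_segments`` maps V names to the CDR3-proximal suffix starting at the
    conserved Cys codon; ``j_segments`` maps J names to the CDR3-proximal
    prefix ending at the conserved Phe/Trp codon; ``d_segments`` holds the
    full D sequences.
    """

    v_segments: Mapping[str, str]
    d_segments: Mapping[str, str]
    j_segments: Mapping[str, str]

    def validate(self) -> None:
        for cls, segs in (
            ("V", self.v_segments),
            ("D", self.d_segments),
            ("J", self.j_segments),
        ):
            if not segs:
                raise ModelError(f"incomplete model: no {cls} segments")
            for name, seq in segs.items():
                if not seq or any(c not in _NT_INDEX for c in seq):
                    raise ModelError(f"{cls} segment {name!r} is not an ACGT string")
        for name, seq in self.v_segments.items():
            if seq[:3] not in ("TGT", "TGC"):
                raise ModelError(f"V segment {name!r} does not begin with a Cys codon")
        for name, seq in self.j_segments.items():
            if CODON_TABLE.get(seq[-3:]) not in ("F", "W"):
                raise ModelError(f"J segment {name!r} does not end with a Phe/Trp codon")


@dataclass(frozen=True)
class InsertionModel:
    """Junctional insertions: length distribution x first-order Markov chain.

    ``reverse=True`` generates (and evaluates) the insert 3'->5', the
    convention used for the DJ junction.
    """

    length_probs: np.ndarray  # index = insert length
    initial: np.ndarray  # size 4, P(first nucleotide)
    transition: np.ndarray  # 4x4, rows P(next | prev)
    reverse: bool = False

    def validate(self, tol: float = 1e-6) -> None:
        if abs(self.length_probs.sum() - 1.0) > tol:
            raise ModelError("unnormalized table: insertion length distribution")
        if (self.length_probs[1:] > 0).any():
            if abs(self.initial.sum() - 1.0) > tol:
                raise ModelError("unnormalized table: insertion initial nucleotide distribution")
            if np.abs(self.transition.sum(axis=1) - 1.0).max() > tol:
                raise ModelError("unnormalized table: insertion transition matrix")
        if (self.length_probs < 0).any() or (self.initial < 0).any() or (self.transition < 0).any():
            raise ModelError("unnormalized table: negative insertion probability")

    @property
    def max_length(self) -> int:
        nz = np.nonzero(self.length_probs)[0]
        return int(nz[-1]) if nz.size else 0

    def sequence_probability(self, seq: str) -> float:
        """Probability of generating exactly ``seq`` at this junction."""
        L = len(seq)
        if L >= len(self.length_probs) or self.length_probs[L] == 0.0:
            return 0.0
        p = float(self.length_probs[L])
        if L == 0:
            return p
        s = seq[::-1] if self.reverse else seq
        idx = [_NT_INDEX[c] for c in s]
        p *= float(self.initial[idx[0]])
        for a, b in zip(idx, idx[1:]):
            p *= float(self.transition[a, b])
        return p

    def enumerate_sequences(self) -> Iterator[tuple[str, float]]:
        """Yield every insert with nonzero probability (5'->3') and its probability."""
        for L, pL in enumerate(self.length_probs):
            if pL == 0.0:
                continue
            if L == 0:
                yield "", float(pL)
                continue
            for tup in itertools.product(range(4), repeat=L):
                p = float(self.initial[tup[0]])
                for a, b in zip(tup, tup[1:]):
                    p *= float(self.transition[a, b])
                if p == 0.0:
                    continue
                s = "".join(NT_ALPHABET[i] for i in tup)
                yield (s[::-1] if self.reverse else s), float(pL) * p

    def n_sequences(self) -> int:
        return int(sum(4**L for L, p in enumerate(self.length_probs) if p > 0))

    def sample(self, n: int, rng: np.random.Generator) -> list[str]:
        """Draw ``n`` insert sequences (returned 5'->3')."""
        lengths = rng.choice(len(self.length_probs), size=n, p=self.length_probs)
        max_len = int(lengths.max()) if n else 0
        chars = np.zeros((n, max_len), dtype=np.int8)
        active = lengths > 0
        if active.any():
            k = int(active.sum())
            chars[active, 0] = rng.choice(4, size=k, p=self.initial)
            cum = np.cumsum(self.transition, axis=1)
            for pos in range(1, max_len):
                act = lengths > pos
                if not act.any():
                    break
                prev = chars[act, pos - 1]
                u = rng.random(int(act.sum()))
                chars[act, pos] = (u[:, None] > cum[prev]).sum(axis=1)
        out = []
        for i in range(n):
            s = "".join(NT_ALPHABET[c] for c in chars[i, : lengths[i]])
            out.append(s[::-1] if self.reverse else s)
        return out


@dataclass(frozen=True)
class ModelTables:
    """Probability tables for every factor of the scenario probability."""

    p_v: Mapping[str, float]
    p_dj: Mapping[tuple[str, str], float]
    p_delv: Mapping[str, np.ndarray]  # per V: index = #3' deletions
    p_delj: Mapping[str, np.ndarray]  # per J: index = #5' deletions
    p_deld: Mapping[str, np.ndarray]  # per D: [delDl, delDr] joint matrix
    ins_vd: InsertionModel
    ins_dj: InsertionModel

    def validate(self, library: SegmentLibrary, tol: float = 1e-6) -> None:
        def _check_dist(name: str, vals: Sequence[float]) -> None:
            arr = np.asarray(list(vals), dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > tol:
                raise ModelError(f"unnormalized table: {name}")

        if set(self.p_v) != set(library.v_segments):
            raise ModelError("incomplete model: P(V) does not cover the V segment library")
        _check_dist("P(V)", self.p_v.values())
        for d, j in self.p_dj:
            if d not in library.d_segments or j not in library.j_segments:
                raise ModelError(f"incomplete model: P(D,J) names unknown segment ({d},{j})")
        _check_dist("P(D,J)", self.p_dj.values())
        for v in library.v_segments:
            if v not in self.p_delv:
                raise ModelError(f"incomplete model: no deletion table for V {v!r}")
            _check_dist(f"P(delV|{v})", self.p_delv[v])
            support = np.nonzero(self.p_delv[v])[0]
            if support.size and support[-1] > len(library.v_segments[v]):
                raise ModelError(f"inconsistent deletions: V {v!r}")
        for j in library.j_segments:
            if j not in self.p_delj:
                raise ModelError(f"incomplete model: no deletion table for J {j!r}")
            _check_dist(f"P(delJ|{j})", self.p_delj[j])
            support = np.nonzero(self.p_delj[j])[0]
            if support.size and support[-1] > len(library.j_segments[j]):
                raise ModelError(f"inconsistent deletions: J {j!r}")
        for d in library.d_segments:
            if d not in self.p_deld:
                raise ModelError(f"incomplete model: no deletion table for D {d!r}")
            mat = self.p_deld[d]
            _check_dist(f"P(delDl,delDr|{d})", mat.ravel())
            for dl, dr in zip(*np.nonzero(mat)):
                if dl + dr > len(library.d_segments[d]):
                    raise ModelError(f"inconsistent deletions: D {d!r}")
        self.ins_vd.validate(tol)
        self.ins_dj.validate(tol)


@dataclass(frozen=True)
class GenerativeModel:
    library: SegmentLibrary
    tables: ModelTables

    def __post_init__(self) -> None:
        self.library.validate()
        self.tables.validate(self.library)

    # -- conditional helpers ------------------------------------------------

    def p_j(self, j_name: str) -> float:
        return sum(p for (d, j), p in self.tables.p_dj.items() if j == j_name)

    def p_d_given_j(self, j_name: str) -> dict[str, float]:
        """P(D | J): the J segment constrains which D segments are reachable."""
        cond = {d: p for (d, j), p in self.tables.p_dj.items() if j == j_name and p > 0}
        total = sum(cond.values())
        if total == 0:
            raise ModelError(f"empty conditional: no D compatible with J {j_name!r}")
        return {d: p / total for d, p in cond.items()}

    def model_vj_usage(self) -> dict[tuple[str, str], float]:
        """The model's own P(V,J) = P(V) * P(J)."""
        pj = {j: 0.0 for j in self.library.j_segments}
        for (d, j), p in self.tables.p_dj.items():
            pj[j] += p
        return {
            (v, j): pv * pjj
            for v, pv in self.tables.p_v.items()
            for j, pjj in pj.items()
            if pv * pjj > 0
        }


@dataclass(frozen=True)
class RecombinationScenario:
    """One fully specified recombination event."""

    v_name: str
    d_name: str
    j_name: str
    del_v: int
    del_j: int
    del_dl: int
    del_dr: int
    ins_vd_seq: str
    ins_dj_seq: str

    def assemble(self, library: SegmentLibrary) -> str:
        v = library.v_segments[self.v_name]
        d = library.d_segments[self.d_name]
        j = library.j_segments[self.j_name]
        return (
            v[: len(v) - self.del_v]
            + self.ins_vd_seq
            + d[self.del_dl : len(d) - self.del_dr]
            + self.ins_dj_seq
            + j[self.del_j :]
        )


@dataclass(frozen=True)
class PgenEstimate:
    """A generation-probability value with its Monte-Carlo uncertainty.

    ``stderr`` is zero only for exact (enumerated) or degenerate estimates.
    """

    value: float
    stderr: float
    n_samples: int
    max_mismatch: int = 0
    coding_corrected: bool = False
    per_vj_breakdown: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"Pgen value {self.value} outside [0, 1]")
        if self.stderr < 0:
            raise ValueError("negative standard error")


# ---------------------------------------------------------------------------
# Model file I/O
# ---------------------------------------------------------------------------

_SEGMENT_FILES = {"V": "v_segments.fasta", "D": "d_segments.fasta", "J": "j_segments.fasta"}


def _read_simple_table(path: Path, ncols: int) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != ncols:
                raise ModelError(f"bad row in {path.name}: {line!r}")
            rows.append(parts)
    return rows


def _read_insertion_table(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    section = None
    lengths: dict[int, float] = {}
    initial = np.zeros(4)
    transition = np.zeros((4, 4))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            parts = line.split("\t")
            if section == "lengths":
                if parts[0] == "length":
                    continue
                lengths[int(parts[0])] = float(parts[1])
            elif section == "initial":
                if parts[0] == "base":
                    continue
                initial[_NT_INDEX[parts[0]]] = float(parts[1])
            elif section == "transition":
                if parts[0] == "from":
                    continue
                transition[_NT_INDEX[parts[0]]] = [float(x) for x in parts[1:5]]
            else:
                raise ModelError(f"unrecognized section in {path.name}")
    if not lengths:
        raise ModelError(f"incomplete model: no length section in {path.name}")
    arr = np.zeros(max(lengths) + 1)
    for L, p in lengths.items():
        arr[L] = p
    return arr, initial, transition


def load_model(segment_library_path: str | Path, tables_path: str | Path) -> GenerativeModel:
    """Load a generative model from FASTA segment files and TSV factor tables.

    ``segment_library_path`` holds ``v_segments.fasta`` / ``d_segments.fasta``
    / ``j_segments.fasta``; ``tables_path`` holds one TSV per probability
    factor (``p_v.tsv``, ``p_dj.tsv``, ``p_delv.tsv``, ``p_delj.tsv``,
    ``p_deld.tsv``, ``ins_vd.tsv``, ``ins_dj.tsv``).  The two paths may be
    the same directory.
    """
    seg_dir, tab_dir = Path(segment_library_path), Path(tables_path)
    segs: dict[str, dict[str, str]] = {}
    for cls, fname in _SEGMENT_FILES.items():
        fpath = seg_dir / fname
        if not fpath.exists():
            raise ModelError(f"incomplete model: missing {fname}")
        segs[cls] = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fpath), "fasta")}
    library = SegmentLibrary(segs["V"], segs["D"], segs["J"])

    for fname in ("p_v.tsv", "p_dj.tsv", "p_delv.tsv", "p_delj.tsv", "p_deld.tsv", "ins_vd.tsv", "ins_dj.tsv"):
        if not (tab_dir / fname).exists():
            raise ModelError(f"incomplete model: missing {fname}")

    p_v = {name: float(p) for name, p in _read_simple_table(tab_dir / "p_v.tsv", 2)}
    p_dj = {(d, j): float(p) for d, j, p in _read_simple_table(tab_dir / "p_dj.tsv", 3)}

    def _del_table(fname: str, names: Mapping[str, str]) -> dict[str, np.ndarray]:
        raw: dict[str, dict[int, float]] = {}
        for name, n_del, p in _read_simple_table(tab_dir / fname, 3):
            raw.setdefault(name, {})[int(n_del)] = float(p)
        out = {}
        for name, dist in raw.items():
            arr = np.zeros(max(dist) + 1)
            for k, p in dist.items():
                arr[k] = p
            out[name] = arr
        return out

    p_delv = _del_table("p_delv.tsv", library.v_segments)
    p_delj = _del_table("p_delj.tsv", library.j_segments)

    raw_dd: dict[str, dict[tuple[int, int], float]] = {}
    for name, dl, dr, p in _read_simple_table(tab_dir / "p_deld.tsv", 4):
        raw_dd.setdefault(name, {})[(int(dl), int(dr))] = float(p)
    p_deld = {}
    for name, dist in raw_dd.items():
        mdl = max(k[0] for k in dist)
        mdr = max(k[1] for k in dist)
        mat = np.zeros((mdl + 1, mdr + 1))
        for (dl, dr), p in dist.items():
            mat[dl, dr] = p
        p_deld[name] = mat

    ins_vd = InsertionModel(*_read_insertion_table(tab_dir / "ins_vd.tsv"), reverse=False)
    ins_dj = InsertionModel(*_read_insertion_table(tab_dir / "ins_dj.tsv"), reverse=True)

    tables = ModelTables(p_v, p_dj, p_delv, p_delj, p_deld, ins_vd, ins_dj)
    return GenerativeModel(library, tables)


def save_model(model: GenerativeModel, out_dir: str | Path) -> None:
    """Write a model back to the plain-text format read by :func:`load_model`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cls, fname in _SEGMENT_FILES.items():
        segs = {"V": model.library.v_segments, "D": model.library.d_segments, "J": model.library.j_segments}[cls]
        recs = [SeqRecord(Seq(s), id=n, description="") for n, s in segs.items()]
        SeqIO.write(recs, str(out / fname), "fasta")
    with open(out / "p_v.tsv", "w") as fh:
        fh.write("v_name\tprob\n")
        for n, p in model.tables.p_v.items():
            fh.write(f"{n}\t{float(p)!r}\n")
    with open(out / "p_dj.tsv", "w") as fh:
        fh.write("d_name\tj_name\tprob\n")
        for (d, j), p in model.tables.p_dj.items():
            fh.write(f"{d}\t{j}\t{float(p)!r}\n")
    with open(out / "p_delv.tsv", "w") as fh:
        fh.write("v_name\tn_del\tprob\n")
        for n, arr in model.tables.p_delv.items():
            for k, p in enumerate(arr):
                fh.write(f"{n}\t{k}\t{float(p)!r}\n")
    with open(out / "p_delj.tsv", "w") as fh:
        fh.write("j_name\tn_del\tprob\n")
        for n, arr in model.tables.p_delj.items():
            for k, p in enumerate(arr):
                fh.write(f"{n}\t{k}\t{float(p)!r}\n")
    with open(out / "p_deld.tsv", "w") as fh:
        fh.write("d_name\tn_del_left\tn_del_right\tprob\n")
        for n, mat in model.tables.p_deld.items():
            for dl in range(mat.shape[0]):
                for dr in range(mat.shape[1]):
                    fh.write(f"{n}\t{dl}\t{dr}\t{float(mat[dl, dr])!r}\n")
    for ins, fname in ((model.tables.ins_vd, "ins_vd.tsv"), (model.tables.ins_dj, "ins_dj.tsv")):
        with open(out / fname, "w") as fh:
            fh.write("[lengths]\nlength\tprob\n")
            for L, p in enumerate(ins.length_probs):
                fh.write(f"{L}\t{float(p)!r}\n")
            fh.write("[initial]\nbase\tprob\n")
            for i, c in enumerate(NT_ALPHABET):
                fh.write(f"{c}\t{float(ins.initial[i])!r}\n")
            fh.write("[transition]\nfrom\tA\tC\tG\tT\n")
            for i, c in enumerate(NT_ALPHABET):
                fh.write(c + "\t" + "\t".join(repr(float(x)) for x in ins.transition[i]) + "\n")


# ---------------------------------------------------------------------------
# Scenario probability, enumeration, exact Pgen
# ---------------------------------------------------------------------------


def evaluate_scenario(scenario: RecombinationScenario, model: GenerativeModel) -> tuple[str, float]:
    """Assemble a scenario's CDR3 and return it with its probability."""
    lib, tab = model.library, model.tables
    for name, segs, cls in (
        (scenario.v_name, lib.v_segments, "V"),
        (scenario.d_name, lib.d_segments, "D"),
        (scenario.j_name, lib.j_segments, "J"),
    ):
        if name not in segs:
            raise ModelError(f"unknown segment: {cls} {name!r}")
    p = tab.p_v.get(scenario.v_name, 0.0)
    p *= tab.p_dj.get((scenario.d_name, scenario.j_name), 0.0)
    delv = tab.p_delv[scenario.v_name]
    p *= float(delv[scenario.del_v]) if scenario.del_v < len(delv) else 0.0
    delj = tab.p_delj[scenario.j_name]
    p *= float(delj[scenario.del_j]) if scenario.del_j < len(delj) else 0.0
    deld = tab.p_deld[scenario.d_name]
    in_support = scenario.del_dl < deld.shape[0] and scenario.del_dr < deld.shape[1]
    p *= float(deld[scenario.del_dl, scenario.del_dr]) if in_support else 0.0
    p *= tab.ins_vd.sequence_probability(scenario.ins_vd_seq)
    p *= tab.ins_dj.sequence_probability(scenario.ins_dj_seq)
    return scenario.assemble(lib), p


def scenario_count(model: GenerativeModel) -> int:
    """Number of nonzero-probability scenarios, computed without enumerating."""
    tab = model.tables
    n_ins = tab.ins_vd.n_sequences() * tab.ins_dj.n_sequences()
    n_v = sum(
        int((tab.p_delv[v] > 0).sum()) for v, p in tab.p_v.items() if p > 0
    )
    total = 0
    for (d, j), p in tab.p_dj.items():
        if p <= 0:
            continue
        total += int((tab.p_deld[d] > 0).sum()) * int((tab.p_delj[j] > 0).sum())
    return n_v * total * n_ins if n_v else 0


DEFAULT_ENUMERATION_GUARD = 10_000_000


def enumerate_scenarios(
    model: GenerativeModel, guard: int = DEFAULT_ENUMERATION_GUARD
) -> Iterator[tuple[RecombinationScenario, str, float]]:
    """Yield every nonzero-probability scenario with its CDR3 and probability.

    Refuses models whose scenario space exceeds ``guard``: exhaustive
    enumeration is an oracle for small models, not a production path.
    """
    n = scenario_count(model)
    if n > guard:
        raise ModelError(
            f"enumeration infeasible; use Monte-Carlo ({n} scenarios > guard {guard})"
        )
    tab, lib = model.tables, model.library
    ins_vd = list(tab.ins_vd.enumerate_sequences())
    ins_dj = list(tab.ins_dj.enumerate_sequences())
    for v, pv in tab.p_v.items():
        if pv <= 0:
            continue
        vseq = lib.v_segments[v]
        for delv in np.nonzero(tab.p_delv[v])[0]:
            p1 = pv * float(tab.p_delv[v][delv])
            vtrim = vseq[: len(vseq) - delv]
            for (d, j), pdj in tab.p_dj.items():
                if pdj <= 0:
                    continue
                dseq, jseq = lib.d_segments[d], lib.j_segments[j]
                deld = tab.p_deld[d]
                for delj in np.nonzero(tab.p_delj[j])[0]:
                    p2 = p1 * pdj * float(tab.p_delj[j][delj])
                    jtrim = jseq[delj:]
                    for dl, dr in zip(*np.nonzero(deld)):
                        p3 = p2 * float(deld[dl, dr])
                        dtrim = dseq[dl : len(dseq) - dr]
                        for s_vd, p_vd in ins_vd:
                            p4 = p3 * p_vd
                            left = vtrim + s_vd + dtrim
                            for s_dj, p_dj_seq in ins_dj:
                                scen = RecombinationScenario(
                                    v, d, j, int(delv), int(delj), int(dl), int(dr), s_vd, s_dj
                                )
                                yield scen, left + s_dj + jtrim, p4 * p_dj_seq


def pgen_nt_table(
    model: GenerativeModel, guard: int = DEFAULT_ENUMERATION_GUARD
) -> dict[str, float]:
    """Exact Pgen for every reachable nucleotide CDR3, by full enumeration."""
    table: dict[str, float] = {}
    for _, nt, p in enumerate_scenarios(model, guard):
        table[nt] = table.get(nt, 0.0) + p
    return table


def pgen_nt_exact(
    cdr3_nt: str, model: GenerativeModel, guard: int = DEFAULT_ENUMERATION_GUARD
) -> PgenEstimate:
    """Exact nucleotide-level Pgen: sum scenario probabilities assembling ``cdr3_nt``."""
    for c in cdr3_nt:
        if c not in _NT_INDEX:
            raise ValueError(f"non-ACGT character {c!r}")
    total = 0.0
    for _, nt, p in enumerate_scenarios(model, guard):
        if nt == cdr3_nt:
            total += p
    return PgenEstimate(value=total, stderr=0.0, n_samples=0, max_mismatch=0)


def pgen_aa_exact(
    cdr3_aa: str,
    model: GenerativeModel,
    vj_usage: Mapping[tuple[str, str], float] | None = None,
    max_mismatch: int = 0,
    coding_conditioned: bool = False,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> float:
    """Exact amino-acid Pgen by enumeration (test oracle for small models).

    Sums, over (V, J) weighted by ``vj_usage`` (the model's own P(V,J) when
    omitted), the conditional probability of assembling a coding CDR3 whose
    translation is within ``max_mismatch`` substitutions of ``cdr3_aa``.
    With ``coding_conditioned`` the result is divided by the probability of
    producing any coding sequence under the same weights.
    """
    usage = dict(vj_usage) if vj_usage is not None else model.model_vj_usage()
    cond_match: dict[tuple[str, str], float] = {}
    cond_coding: dict[tuple[str, str], float] = {}
    cond_by_j: dict[str, float] = {}
    for j in model.library.j_segments:
        cond_by_j[j] = sum(p for (d, jj), p in model.tables.p_dj.items() if jj == j)
    target_len = 3 * len(cdr3_aa)
    for scen, nt, p in enumerate_scenarios(model, guard):
        pdj = model.tables.p_dj[(scen.d_name, scen.j_name)]
        pv = model.tables.p_v[scen.v_name]
        pj = cond_by_j[scen.j_name]
        if pv <= 0 or pj <= 0:
            continue
        # conditional on (V, J): divide out P(V) and replace P(D,J) by P(D|J)
        p_cond = p / pv / pj
        key = (scen.v_name, scen.j_name)
        if coding_status(nt) == "coding":
            cond_coding[key] = cond_coding.get(key, 0.0) + p_cond
            if len(nt) == target_len and hamming(translate_nt(nt), cdr3_aa) <= max_mismatch:
                cond_match[key] = cond_match.get(key, 0.0) + p_cond
    value = sum(usage.get(k, 0.0) * v for k, v in cond_match.items())
    if coding_conditioned:
        denom = sum(usage.get(k, 0.0) * v for k, v in cond_coding.items())
        if denom == 0.0:
            raise ModelError("variant unreachable: model produces no coding sequence")
        value /= denom
    return value


# ---------------------------------------------------------------------------
# Monte-Carlo sampling
# ---------------------------------------------------------------------------


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Deterministic per-(V, J) substream derived from (seed, names)."""
    keys = [seed & 0x7FFFFFFF] + [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(keys)


def _draw_conditional_deletions(
    names: np.ndarray, tables: Mapping[str, np.ndarray], uniq: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Vectorized per-segment deletion draws grouped by segment identity."""
    out = np.zeros(len(names), dtype=np.int64)
    for name in uniq:
        mask = names == name
        k = int(mask.sum())
        if k:
            dist = tables[name]
            out[mask] = rng.choice(len(dist), size=k, p=dist / dist.sum())
    return out


def _sample_components(
    model: GenerativeModel,
    v_names: np.ndarray,
    d_names: np.ndarray,
    j_names: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    tab = model.tables
    delv = _draw_conditional_deletions(v_names, tab.p_delv, list(dict.fromkeys(v_names.tolist())), rng)
    delj = _draw_conditional_deletions(j_names, tab.p_delj, list(dict.fromkeys(j_names.tolist())), rng)
    n = len(v_names)
    dl = np.zeros(n, dtype=np.int64)
    dr = np.zeros(n, dtype=np.int64)
    for d in dict.fromkeys(d_names.tolist()):
        mask = d_names == d
        k = int(mask.sum())
        mat = tab.p_deld[d]
        flat = mat.ravel() / mat.sum()
        idx = rng.choice(mat.size, size=k, p=flat)
        dl[mask], dr[mask] = np.unravel_index(idx, mat.shape)
    ins_vd = tab.ins_vd.sample(n, rng)
    ins_dj = tab.ins_dj.sample(n, rng)
    return delv, delj, dl, dr, ins_vd, ins_dj


def _assemble_many(
    model: GenerativeModel,
    v_names: np.ndarray,
    d_names: np.ndarray,
    j_names: np.ndarray,
    delv: np.ndarray,
    delj: np.ndarray,
    dl: np.ndarray,
    dr: np.ndarray,
    ins_vd: list[str],
    ins_dj: list[str],
) -> list[str]:
    vs = model.library.v_segments
    ds = model.library.d_segments
    js = model.library.j_segments
    out = []
    for i in range(len(v_names)):
        v, d, j = vs[v_names[i]], ds[d_names[i]], js[j_names[i]]
        out.append(
            v[: len(v) - delv[i]]
            + ins_vd[i]
            + d[dl[i] : len(d) - dr[i]]
            + ins_dj[i]
            + j[delj[i] :]
        )
    return out


def sample_rearrangements(
    model: GenerativeModel, v_name: str, j_name: str, n: int, seed: int
) -> list[tuple[str, RecombinationScenario]]:
    """Sample ``n`` rearrangements with V and J fixed (D drawn from P(D | J))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if v_name not in model.library.v_segments:
        raise ModelError(f"unknown segment: V {v_name!r}")
    if j_name not in model.library.j_segments:
        raise ModelError(f"unknown segment: J {j_name!r}")
    rng = _substream(seed, v_name, j_name)
    cond = model.p_d_given_j(j_name)  # raises "empty conditional" if needed
    d_pool = list(cond)
    d_idx = rng.choice(len(d_pool), size=n, p=np.array([cond[d] for d in d_pool]))
    d_names = np.array([d_pool[i] for i in d_idx], dtype=object)
    v_names = np.full(n, v_name, dtype=object)
    j_names = np.full(n, j_name, dtype=object)
    delv, delj, dl, dr, ins_vd, ins_dj = _sample_components(model, v_names, d_names, j_names, rng)
    seqs = _assemble_many(model, v_names, d_names, j_names, delv, delj, dl, dr, ins_vd, ins_dj)
    return [
        (
            seqs[i],
            RecombinationScenario(
                v_name, d_names[i], j_name, int(delv[i]), int(delj[i]), int(dl[i]), int(dr[i]), ins_vd[i], ins_dj[i]
            ),
        )
        for i in range(n)
    ]


def _sample_cdr3_vj(
    model: GenerativeModel, v_name: str, j_name: str, n: int, rng: np.random.Generator
) -> list[str]:
    """Hot path behind :func:`pgen_aa`: sequences only, no scenario objects."""
    cond = model.p_d_given_j(j_name)
    d_pool = list(cond)
    d_idx = rng.choice(len(d_pool), size=n, p=np.array([cond[d] for d in d_pool]))
    d_names = np.array([d_pool[i] for i in d_idx], dtype=object)
    v_names = np.full(n, v_name, dtype=object)
    j_names = np.full(n, j_name, dtype=object)
    delv, delj, dl, dr, ins_vd, ins_dj = _sample_components(model, v_names, d_names, j_names, rng)
    return _assemble_many(model, v_names, d_names, j_names, delv, delj, dl, dr, ins_vd, ins_dj)


def sample_repertoire(model: GenerativeModel, n: int, seed: int) -> list[str]:
    """Sample ``n`` CDR3 nucleotide sequences from the unconditional model.

    V is drawn from P(V) and (D, J) jointly from P(D,J); used for cohort
    simulation and for the non-coding fraction estimate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _substream(seed, "repertoire")
    tab = model.tables
    v_pool = [v for v, p in tab.p_v.items() if p > 0]
    pv = np.array([tab.p_v[v] for v in v_pool])
    dj_pool = [k for k, p in tab.p_dj.items() if p > 0]
    pdj = np.array([tab.p_dj[k] for k in dj_pool])
    v_idx = rng.choice(len(v_pool), size=n, p=pv / pv.sum())
    dj_idx = rng.choice(len(dj_pool), size=n, p=pdj / pdj.sum())
    v_names = np.array([v_pool[i] for i in v_idx], dtype=object)
    d_names = np.array([dj_pool[i][0] for i in dj_idx], dtype=object)
    j_names = np.array([dj_pool[i][1] for i in dj_idx], dtype=object)
    delv, delj, dl, dr, ins_vd, ins_dj = _sample_components(model, v_names, d_names, j_names, rng)
    return _assemble_many(model, v_names, d_names, j_names, delv, delj, dl, dr, ins_vd, ins_dj)


def coding_fraction(model: GenerativeModel, n: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo estimate of the non-coding fraction (out-of-frame or stop).

    Returns ``(fraction_noncoding, stderr)`` with a binomial standard error.
    """
    seqs = sample_repertoire(model, n, seed)
    bad = sum(1 for s in seqs if len(s) % 3 != 0 or coding_status(s) != "coding")
    frac = bad / n
    return frac, float(np.sqrt(frac * (1 - frac) / n))


def pgen_aa(
    cdr3_aa: str,
    model: GenerativeModel,
    vj_usage: Mapping[tuple[str, str], float],
    n_per_vj: int = 100_000,
    max_mismatch: int = 1,
    seed: int = 0,
    coding_correct: bool = False,
    noncoding_fraction: float | None = None,
) -> PgenEstimate:
    """Monte-Carlo amino-acid Pgen with mismatch tolerance and VJ rescaling.

    For every (V, J) in ``vj_usage``, ``n_per_vj`` rearrangements are
    simulated with that V and J fixed; the match fraction (translation equal
    to ``cdr3_aa`` up to ``max_mismatch`` substitutions, same length, no
    indels; non-coding draws count as non-matches) is then averaged with the
    usage weights.  ``vj_usage`` is typically estimated from non-functional
    clonotypes of the dataset under study, not taken from the model.

    With ``coding_correct`` the value is divided by one minus the non-coding
    fraction (supplied, or estimated from the model with a derived seed).
    """
    if any(c not in _AA_SET for c in cdr3_aa):
        raise ValueError("CDR3 amino-acid sequence contains a non-standard residue")
    if n_per_vj < 1:
        raise ValueError("n_per_vj must be >= 1")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    weights = np.array(list(vj_usage.values()), dtype=float)
    if (weights < 0).any() or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("vj_usage is not a normalized distribution")

    target_len = 3 * len(cdr3_aa)
    value = 0.0
    var = 0.0
    breakdown: dict[tuple[str, str], float] = {}
    for (v, j), w in vj_usage.items():
        if w <= 0:
            continue
        rng = _substream(seed, v, j)
        seqs = _sample_cdr3_vj(model, v, j, n_per_vj, rng)
        matches = 0
        for s in seqs:
            if len(s) != target_len:
                continue
            aa = translate_nt(s)
            if "*" in aa:
                continue
            if hamming(aa, cdr3_aa) <= max_mismatch:
                matches += 1
        p_hat = matches / n_per_vj
        breakdown[(v, j)] = p_hat
        value += w * p_hat
        var += w * w * p_hat * (1 - p_hat) / n_per_vj
    if coding_correct:
        if noncoding_fraction is None:
            noncoding_fraction, _ = coding_fraction(model, n_per_vj, seed + 1)
        scale = 1.0 - noncoding_fraction
        if scale <= 0:
            raise ModelError("model produces no coding sequences; cannot correct")
        value /= scale
        var /= scale * scale
    return PgenEstimate(
        value=min(value, 1.0),
        stderr=float(np.sqrt(var)),
        n_samples=n_per_vj * sum(1 for w in vj_usage.values() if w > 0),
        max_mismatch=max_mismatch,
        coding_corrected=coding_correct,
        per_vj_breakdown=breakdown,
    )


# ---------------------------------------------------------------------------
# Convergent recombination
# ---------------------------------------------------------------------------


def convergence_probability(
    cdr3_aa: str,
    model: GenerativeModel,
    mode: str = "exact",
    n_samples: int = 100_000,
    seed: int = 0,
    guard: int = DEFAULT_ENUMERATION_GUARD,
) -> float:
    """Probability that two independent rearrangements producing ``cdr3_aa``
    yield the identical nucleotide sequence.

    Equals sum(p_n^2) / (sum(p_n))^2 over nucleotide encodings n translating
    exactly to ``cdr3_aa``; 1 iff a single encoding carries all the mass.
    High values mark convergent-recombination-prone (typically public)
    variants.
    """
    if mode == "exact":
        probs = [
            p
            for nt, p in pgen_nt_table(model, guard).items()
            if len(nt) == 3 * len(cdr3_aa)
            and coding_status(nt) == "coding"
            and translate_nt(nt) == cdr3_aa
        ]
        total = sum(probs)
        if total == 0.0:
            raise ModelError(f"variant unreachable: {cdr3_aa!r}")
        return float(sum(p * p for p in probs) / (total * total))
    if mode == "mc":
        seqs = sample_repertoire(model, n_samples, seed)
        counts: dict[str, int] = {}
        for s in seqs:
            if len(s) == 3 * len(cdr3_aa) and coding_status(s) == "coding" and translate_nt(s) == cdr3_aa:
                counts[s] = counts.get(s, 0) + 1
        m = sum(counts.values())
        if m < 2:
            raise ModelError(f"variant unreachable: {cdr3_aa!r} (insufficient matches)")
        # unbiased estimator of the collision probability
        return float(sum(c * (c - 1) for c in counts.values()) / (m * (m - 1)))
    raise ValueError(f"unknown mode {mode!r}")
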