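"""Paired-chain frequency analysis.

Tests whether epitope-specific paired alpha/beta TCR frequencies are
approximated by the product of the single-chain marginal frequencies, i.e.
whether chain pairing is effectively independent at the level of
antigen-specific rearrangement frequencies.  Marginal frequencies follow
the normalization (number of matching rearrangements) / (number of
database records for the epitope and chain) / (total number of paired
records); the paired frequency is normalized by the product of the two
per-chain database record counts so that, under independent pairing, it
equals the product of the marginals in expectation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire_io import RepertoireError, SpecificityIndex, SpecificityRecord

__all__ = [
    "PairedRecord",
    "PairedRepertoire",
    "read_paired_table",
    "write_paired_table",
    "chain_marginal_frequency",
    "independence_check",
]


@dataclass(frozen=True)
class PairedRecord:
    cdr3_aa_alpha: str
    cdr3_aa_beta: str
    count: int = 1
    v_alpha: str = ""
    j_alpha: str = ""
    v_beta: str = ""
    j_beta: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_aa_alpha or not self.cdr3_aa_beta:
            raise RepertoireError("paired record must have both chains")


@dataclass
class PairedRepertoire:
    records: list[PairedRecord]

    @property
    def total_rearrangements(self) -> int:
        return len(self.records)


def read_paired_table(path: str | Path) -> PairedRepertoire:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("alpha_cdr3aa", "beta_cdr3aa"):
        if col not in df.columns:
            raise RepertoireError(f"bad header: missing column {col!r}")
    records = [
        PairedRecord(
            cdr3_aa_alpha=row.alpha_cdr3aa,
            cdr3_aa_beta=row.beta_cdr3aa,
            count=int(getattr(row, "count", 1) or 1),
        )
        for row in df.itertuples(index=False)
    ]
    return PairedRepertoire(records)


def write_paired_table(paired: PairedRepertoire, path: str | Path) -> None:
    pd.DataFrame(
        {
            "alpha_cdr3aa": [r.cdr3_aa_alpha for r in paired.records],
            "beta_cdr3aa": [r.cdr3_aa_beta for r in paired.records],
            "count": [r.count for r in paired.records],
        }
    ).to_csv(path, sep="\t", index=False)


def _chain_records(
    db: Sequence[SpecificityRecord], epitope: str, chain: str
) -> list[SpecificityRecord]:
    return [r for r in db if r.epitope_seq == epitope and r.chain == chain]


def _match_mask(
    sequences: Sequence[str], db_aa: set[str], max_subst: int
) -> np.ndarray:
    index = SpecificityIndex(db_aa, max_subst=max(1, max_subst))
    cache: dict[str, bool] = {}
    out = np.zeros(len(sequences), dtype=bool)
    for i, s in enumerate(sequences):
        hit = cache.get(s)
        if hit is None:
            hit = bool(index.query(s, max_subst))
            cache[s] = hit
        out[i] = hit
    return out


def chain_marginal_frequency(
    paired: PairedRepertoire,
    db: Sequence[SpecificityRecord],
    epitope: str,
    chain: str,
    max_subst: int = 1,
) -> float:
    """Mean per-database-record frequency of one chain matching an epitope.

    (number of matching rearrangements) / (number of database records for
    the epitope and chain) / (total number of paired records).  Matching
    allows ``max_subst`` substitutions and no indels.
    """
    recs = _chain_records(db, epitope, chain)
    if not recs:
        raise RepertoireError(f"epitope not covered: {epitope!r} for chain {chain!r}")
    seqs = [
        r.cdr3_aa_alpha if chain == "TRA" else r.cdr3_aa_beta for r in paired.records
    ]
    n_match = int(_match_mask(seqs, {r.cdr3_aa for r in recs}, max_subst).sum())
    return n_match / len(recs) / paired.total_rearrangements


def independence_check(
    paired: PairedRepertoire,
    db: Sequence[SpecificityRecord],
    epitopes: Sequence[str] | None = None,
    max_subst: int = 1,
    min_records_per_chain: int = 30,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Compare paired-match frequencies with the product of chain marginals.

    Per epitope (covered by >= ``min_records_per_chain`` database records
    on each chain): the alpha and beta marginals, their product, and the
    paired-match frequency (both chains of one record matching the same
    epitope, normalized by the product of per-chain record counts and the
    total).  Returns the table plus the Pearson correlation of the
    log-transformed product vs paired frequencies (zero-frequency epitopes
    dropped with a notice).
    """
    by_epitope_chain: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in db:
        by_epitope_chain[(r.epitope_seq, r.chain)].add(r.cdr3_aa)
    if epitopes is None:
        epitopes = sorted({e for e, _ in by_epitope_chain})
    usable = [
        e
        for e in epitopes
        if len(by_epitope_chain.get((e, "TRA"), ())) >= min_records_per_chain
        and len(by_epitope_chain.get((e, "TRB"), ())) >= min_records_per_chain
    ]
    if len(usable) < 3:
        raise RepertoireError("insufficient coverage: fewer than 3 usable epitopes")

    alpha_seqs = [r.cdr3_aa_alpha for r in paired.records]
    beta_seqs = [r.cdr3_aa_beta for r in paired.records]
    N = paired.total_rearrangements
    rows = []
    for e in usable:
        a_db = by_epitope_chain[(e, "TRA")]
        b_db = by_epitope_chain[(e, "TRB")]
        a_mask = _match_mask(alpha_seqs, a_db, max_subst)
        b_mask = _match_mask(beta_seqs, b_db, max_subst)
        f_alpha = a_mask.sum() / len(a_db) / N
        f_beta = b_mask.sum() / len(b_db) / N
        f_paired = (a_mask & b_mask).sum() / (len(a_db) * len(b_db)) / N
        rows.append(
            {
                "epitope_seq": e,
                "f_alpha": f_alpha,
                "f_beta": f_beta,
                "f_product": f_alpha * f_beta,
                "f_paired": f_paired,
            }
        )
    table = pd.DataFrame(rows)
    ok = (table["f_product"] > 0) & (table["f_paired"] > 0)
    if (~ok).any():
        import warnings

        warnings.warn(f"dropped {(~ok).sum()} zero-frequency epitopes from the correlation")
    if ok.sum() < 3:
        raise RepertoireError("insufficient coverage: fewer than 3 nonzero epitopes")
    r, p = stats.pearsonr(
        np.log10(table.loc[ok, "f_product"]), np.log10(table.loc[ok, "f_paired"])
    )
    return table, (float(r), float(p))
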