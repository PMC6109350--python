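"""Cohort-level statistics over annotated repertoires.

Per-epitope generation-probability summaries and ANOVA, the correlation of
Pgen with population incidence, observed/expected HLA selection ratios,
per-TCR hypergeometric HLA enrichment with Benjamini-Hochberg correction,
HLA-restricted clonal-expansion read-frequency ratios, and donor-group
comparisons (cord blood vs adult PBMC match burden, ancestry).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .repertoire_io import (
    SpecificityRecord,
    incidence_bin,
    normalize_allele,
)

__all__ = [
    "CohortStatsError",
    "DonorMetadata",
    "EpitopeSummary",
    "epitope_pgen_summary",
    "pgen_incidence_correlation",
    "pgen_vs_ntcrs_correlation",
    "hla_observed_expected",
    "tcr_hla_enrichment",
    "expansion_analysis",
    "group_comparisons",
    "metadata_frame",
]


class CohortStatsError(ValueError):
    pass


@dataclass(frozen=True)
class DonorMetadata:
    sample_id: str
    hla_alleles: frozenset[str] = frozenset()
    cmv_serostatus: str = "unknown"  # positive | negative | unknown
    ancestry: str = ""
    sample_type: str = "PBMC"  # PBMC | UCB
    sex: str = ""

    def carries(self, allele: str) -> bool:
        return normalize_allele(allele) in {normalize_allele(a) for a in self.hla_alleles}


def metadata_frame(metadata: Sequence[DonorMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "cmv_serostatus": [m.cmv_serostatus for m in metadata],
            "ancestry": [m.ancestry for m in metadata],
            "sample_type": [m.sample_type for m in metadata],
            "sex": [m.sex for m in metadata],
        }
    ).set_index("sample_id")


@dataclass
class EpitopeSummary:
    epitope_seq: str
    species: str
    n_tcrs: int
    median_pgen: float
    log10_pgens: np.ndarray = field(repr=False)
    public_fraction: float | None = None
    bin_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-epitope Pgen summaries
# ---------------------------------------------------------------------------


def epitope_pgen_summary(
    db: Sequence[SpecificityRecord],
    pgen_fn: Callable[[str], float],
    min_tcrs: int = 30,
    incidence_fn: Callable[[str], float] | None = None,
    public_threshold: float = 0.05,
) -> tuple[list[EpitopeSummary], dict[str, tuple[float, float]]]:
    """Summarize generation probabilities per epitope and test for differences.

    Epitopes with fewer than ``min_tcrs`` distinct specific CDR3 amino-acid
    sequences are excluded.  Zero-probability TCRs are dropped with a
    warning (they cannot enter the log scale).  Returns the summaries plus
    one-way ANOVA results (F, p) on log10 Pgen across epitopes and across
    epitope source species.

    If ``incidence_fn`` maps a CDR3 to its population incidence, each
    summary also carries the fraction of its TCRs that are public
    (incidence >= ``public_threshold``) and the incidence-bin counts.
    """
    by_epitope: dict[str, dict[str, SpecificityRecord]] = defaultdict(dict)
    for r in db:
        by_epitope[r.epitope_seq][r.cdr3_aa] = r

    summaries: list[EpitopeSummary] = []
    n_dropped = 0
    for epitope, tcrs in by_epitope.items():
        if len(tcrs) < min_tcrs:
            continue
        pgens = {}
        for aa in tcrs:
            p = pgen_fn(aa)
            if p <= 0:
                n_dropped += 1
                continue
            pgens[aa] = p
        if not pgens:
            continue
        values = np.array(list(pgens.values()))
        species = next(iter(tcrs.values())).epitope_species
        summary = EpitopeSummary(
            epitope_seq=epitope,
            species=species,
            n_tcrs=len(pgens),
            median_pgen=float(np.median(values)),
            log10_pgens=np.log10(values),
        )
        if incidence_fn is not None:
            incidences = [incidence_fn(aa) for aa in pgens]
            summary.public_fraction = float(
                np.mean([i >= public_threshold for i in incidences])
            )
            counts: dict[str, int] = defaultdict(int)
            for i in incidences:
                counts[incidence_bin(i)] += 1
            summary.bin_counts = dict(counts)
        summaries.append(summary)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} zero-probability TCRs from summaries")

    anova: dict[str, tuple[float, float]] = {}
    groups = [s.log10_pgens for s in summaries]
    if len(groups) < 2:
        raise CohortStatsError("ANOVA undefined: fewer than 2 epitopes after filtering")
    f, p = stats.f_oneway(*groups)
    anova["epitope"] = (float(f), float(p))
    by_species: dict[str, list[np.ndarray]] = defaultdict(list)
    for s in summaries:
        by_species[s.species].append(s.log10_pgens)
    if len(by_species) >= 2:
        f, p = stats.f_oneway(*[np.concatenate(v) for v in by_species.values()])
        anova["species"] = (float(f), float(p))
    return summaries, anova


def pgen_incidence_correlation(summaries: Sequence[EpitopeSummary]) -> tuple[float, float]:
    """Spearman correlation of per-epitope median Pgen with public fraction."""
    usable = [s for s in summaries if s.public_fraction is not None]
    if len(usable) < 3:
        raise CohortStatsError("correlation undefined: fewer than 3 epitopes")
    x = np.array([s.median_pgen for s in usable])
    y = np.array([s.public_fraction for s in usable])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CohortStatsError("correlation undefined: constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pgen_vs_ntcrs_correlation(summaries: Sequence[EpitopeSummary]) -> tuple[float, float]:
    """Spearman correlation of median Pgen with the number of database TCRs.

    A robustness check: a strong correlation here would mean median
    frequency estimates are driven by database coverage rather than biology.
    """
    if len(summaries) < 3:
        raise CohortStatsError("correlation undefined: fewer than 3 epitopes")
    x = np.array([s.median_pgen for s in summaries])
    y = np.array([s.n_tcrs for s in summaries], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise CohortStatsError("correlation undefined: constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# HLA observed / expected selection ratios
# ---------------------------------------------------------------------------


def hla_observed_expected(
    annotations: pd.DataFrame,
    metadata: Sequence[DonorMetadata],
    db: Sequence[SpecificityRecord],
    min_samples: int = 30,
    min_tcrs: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[float, float]]:
    """Observed vs expected specific rearrangements per (donor allele, restriction).

    For donor allele a and restriction allele r, O(a, r) is the number of
    unique annotated rearrangements carried by donors with a that match
    r-restricted records; E(a, r) assumes independence between restriction
    and genotype: (total matches to r) x (fraction of donors carrying a).
    Donor alleles present in fewer than ``min_samples`` samples and
    restriction alleles with fewer than ``min_tcrs`` database sequences are
    dropped.  Returns the O/E ratio matrix, a tidy cell table, and a
    one-sided Mann-Whitney U comparing matched (a == r) against mismatched
    cells.
    """
    meta = {m.sample_id: m for m in metadata}
    donor_alleles: dict[str, set[str]] = {
        sid: {normalize_allele(a) for a in m.hla_alleles} for sid, m in meta.items()
    }
    n_donors = len(meta)
    allele_counts: dict[str, int] = defaultdict(int)
    for alleles in donor_alleles.values():
        for a in alleles:
            allele_counts[a] += 1
    tested_alleles = sorted(a for a, c in allele_counts.items() if c >= min_samples)

    db_tcrs_per_allele: dict[str, set[str]] = defaultdict(set)
    for r in db:
        db_tcrs_per_allele[normalize_allele(r.hla_restriction)].add(r.cdr3_aa)
    tested_restrictions = sorted(
        a for a, s in db_tcrs_per_allele.items() if len(s) >= min_tcrs
    )
    if not tested_alleles or not tested_restrictions:
        raise CohortStatsError("no matched pairs: thresholds removed every allele")

    # unique rearrangement = one (sample, cdr3_nt, restriction allele) triple
    ann = annotations.copy()
    ann["restriction"] = ann["hla_restriction"].map(normalize_allele)
    ann = ann.drop_duplicates(["sample_id", "cdr3_nt", "restriction"])
    per_donor_r = (
        ann.groupby(["sample_id", "restriction"]).size().unstack(fill_value=0)
    )

    rows = []
    for r in tested_restrictions:
        if r not in per_donor_r.columns:
            continue
        m_d = per_donor_r[r]
        total_r = float(m_d.sum())
        for a in tested_alleles:
            carriers = [sid for sid in meta if a in donor_alleles[sid]]
            observed = float(m_d.reindex(carriers).fillna(0).sum())
            expected = total_r * len(carriers) / n_donors
            rows.append(
                {
                    "donor_allele": a,
                    "restriction_allele": r,
                    "observed": observed,
                    "expected": expected,
                    "ratio": observed / expected if expected > 0 else np.nan,
                    "matched": a == r,
                }
            )
    cells = pd.DataFrame(rows)
    if cells.empty or not cells["matched"].any():
        raise CohortStatsError("no matched pairs")
    matrix = cells.pivot(index="donor_allele", columns="restriction_allele", values="ratio")
    diag = cells.loc[cells["matched"], "ratio"].dropna()
    off = cells.loc[~cells["matched"], "ratio"].dropna()
    if len(off) == 0:
        raise CohortStatsError("no matched pairs: no off-diagonal cells")
    u, p = stats.mannwhitneyu(diag, off, alternative="greater")
    return matrix, cells, (float(u), float(p))


# ---------------------------------------------------------------------------
# Per-TCR hypergeometric HLA enrichment
# ---------------------------------------------------------------------------


def tcr_hla_enrichment(
    annotations: pd.DataFrame,
    metadata: Sequence[DonorMetadata],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each database TCR in allele-carrier samples.

    For a TCR present in m of S samples, of which x carry allele a (K
    carriers overall), the upper-tail hypergeometric probability P(X >= x)
    tests whether the TCR concentrates in carriers.  P-values are
    Benjamini-Hochberg adjusted across all (TCR, allele) pairs; pairs with
    adjusted p > ``alpha`` are flagged as non-significant.
    """
    meta = list(metadata)
    S = len(meta)
    carriers: dict[str, set[str]] = defaultdict(set)
    for m in meta:
        for a in m.hla_alleles:
            carriers[normalize_allele(a)].add(m.sample_id)
    presence = (
        annotations.drop_duplicates(["db_cdr3_aa", "sample_id"])
        .groupby("db_cdr3_aa")["sample_id"]
        .apply(set)
    )
    rows = []
    for allele, carrier_set in sorted(carriers.items()):
        K = len(carrier_set)
        if K == 0 or K == S:
            raise CohortStatsError(f"degenerate allele {allele!r}: carried by {K} of {S}")
        for tcr, samples in presence.items():
            m = len(samples)
            x = len(samples & carrier_set)
            p = float(stats.hypergeom.sf(x - 1, S, K, m)) if m > 0 else 1.0
            rows.append({"db_cdr3_aa": tcr, "allele": allele, "m": m, "x": x, "K": K, "p": p})
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    reject, p_adj, _, _ = multipletests(result["p"], alpha=alpha, method="fdr_bh")
    result["p_adjusted"] = p_adj
    result["significant"] = reject
    return result


# ---------------------------------------------------------------------------
# HLA-restricted clonal expansion
# ---------------------------------------------------------------------------


def expansion_analysis(
    annotations: pd.DataFrame,
    metadata: Sequence[DonorMetadata],
    pathogen: str,
    min_clonotypes_per_allele: int = 4,
    serostatus_groups: bool = True,
) -> dict[str, object]:
    """Read-frequency expansion of pathogen-specific clonotypes in HLA-matched samples.

    For each database TCR specific to ``pathogen``, samples are split into
    HLA-matched (donor carries >= 1 restriction allele of the TCR's matched
    records) and HLA-mismatched; the clonotype's log2 ratio of mean read
    frequency (over samples where it is present; absence is not zero) in
    matched vs mismatched samples measures antigen-driven expansion.
    Distributions of ratios are compared across serostatus groups with
    two-sample Kolmogorov-Smirnov tests, and per restriction allele the
    counts of clonotypes with higher vs lower matched-sample frequency are
    reported with exact (Clopper-Pearson) binomial 95% confidence intervals.
    Alleles backed by fewer than ``min_clonotypes_per_allele`` clonotypes
    are excluded from the directional table.
    """
    meta = {m.sample_id: m for m in metadata}
    ann = annotations[annotations["epitope_species"] == pathogen].copy()
    if ann.empty:
        raise CohortStatsError(f"no annotations for pathogen {pathogen!r}")
    ann["restriction"] = ann["hla_restriction"].map(normalize_allele)

    restr_per_tcr = ann.groupby("db_cdr3_aa")["restriction"].apply(set)
    donor_alleles = {
        sid: {normalize_allele(a) for a in m.hla_alleles} for sid, m in meta.items()
    }
    sero = {sid: m.cmv_serostatus for sid, m in meta.items()}

    freq = (
        ann.drop_duplicates(["db_cdr3_aa", "sample_id", "cdr3_nt"])
        .groupby(["db_cdr3_aa", "sample_id"])["freq"]
        .sum()
    )

    groups = sorted({s for s in sero.values()}) if serostatus_groups else ["all"]
    ratio_rows = []
    n_excluded = 0
    for tcr, restr in restr_per_tcr.items():
        if tcr not in freq.index.get_level_values(0):
            continue
        f_t = freq.loc[tcr]
        for group in groups:
            matched, mismatched = [], []
            for sid, f in f_t.items():
                if group != "all" and sero.get(sid) != group:
                    continue
                if donor_alleles.get(sid, set()) & restr:
                    matched.append(f)
                else:
                    mismatched.append(f)
            if not matched or not mismatched:
                n_excluded += 1
                continue
            ratio = float(np.log2(np.mean(matched) / np.mean(mismatched)))
            ratio_rows.append(
                {
                    "db_cdr3_aa": tcr,
                    "group": group,
                    "log2_ratio": ratio,
                    "restriction": ",".join(sorted(restr)),
                    "n_matched": len(matched),
                    "n_mismatched": len(mismatched),
                }
            )
    ratios = pd.DataFrame(
        ratio_rows,
        columns=["db_cdr3_aa", "group", "log2_ratio", "restriction", "n_matched", "n_mismatched"],
    )

    ks_tests: dict[tuple[str, str], tuple[float, float]] = {}
    if serostatus_groups and not ratios.empty:
        present = [g for g in groups if (ratios["group"] == g).any()]
        for i, g1 in enumerate(present):
            for g2 in present[i + 1 :]:
                a = ratios.loc[ratios["group"] == g1, "log2_ratio"]
                b = ratios.loc[ratios["group"] == g2, "log2_ratio"]
                if len(a) >= 2 and len(b) >= 2:
                    d, p = stats.ks_2samp(a, b)
                    ks_tests[(g1, g2)] = (float(d), float(p))

    directional_rows = []
    if not ratios.empty:
        overall = ratios.drop_duplicates("db_cdr3_aa") if serostatus_groups else ratios
        per_allele: dict[str, list[float]] = defaultdict(list)
        for _, row in overall.iterrows():
            for a in row["restriction"].split(","):
                per_allele[a].append(row["log2_ratio"])
        for allele, vals in sorted(per_allele.items()):
            if len(vals) < min_clonotypes_per_allele:
                continue
            higher = sum(v > 0 for v in vals)
            ci = stats.binomtest(higher, len(vals)).proportion_ci(0.95, method="exact")
            directional_rows.append(
                {
                    "allele": allele,
                    "n_higher": higher,
                    "n_lower": len(vals) - higher,
                    "prop_higher": higher / len(vals),
                    "ci_low": float(ci.low),
                    "ci_high": float(ci.high),
                }
            )
    return {
        "ratios": ratios,
        "ks_tests": ks_tests,
        "directional": pd.DataFrame(directional_rows),
        "n_excluded": n_excluded,
    }


# ---------------------------------------------------------------------------
# Group comparisons (UCB vs PBMC, ancestry)
# ---------------------------------------------------------------------------


def _per_sample_burden(annotations: pd.DataFrame, sample_totals: pd.Series) -> pd.Series:
    matched = (
        annotations.drop_duplicates(["sample_id", "cdr3_nt"])
        .groupby("sample_id")
        .size()
        .reindex(sample_totals.index, fill_value=0)
    )
    return matched / sample_totals


def group_comparisons(
    annotations: pd.DataFrame,
    sample_totals: pd.Series,
    metadata: Sequence[DonorMetadata],
    class_ii_prefixes: tuple[str, ...] = ("HLA-DR", "HLA-DQ", "HLA-DP"),
) -> dict[str, object]:
    """Match-burden and per-epitope abundance comparisons across donor groups.

    Per-sample burden is the fraction of unique coding rearrangements that
    match the database.  UCB vs PBMC burdens are compared with a two-tailed
    t-test (overall and restricted to class II-restricted records); per
    epitope, relative abundances are compared with a t-test (two groups) or
    one-way ANOVA (ancestry, >= 3 groups), Benjamini-Hochberg adjusted.
    Groups with fewer than 2 samples are skipped with a warning.
    """
    meta = metadata_frame(list(metadata))
    burden = _per_sample_burden(annotations, sample_totals)
    out: dict[str, object] = {"burden": burden}

    def _two_group_test(values: pd.Series, labels: pd.Series, g1: str, g2: str):
        a = values[labels == g1].dropna()
        b = values[labels == g2].dropna()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"group comparison {g1} vs {g2} skipped: fewer than 2 samples")
            return None
        t, p = stats.ttest_ind(a, b)
        fold = float(a.mean() / b.mean()) if b.mean() > 0 else np.nan
        return {"t": float(t), "p": float(p), "fold_change": fold, "n": (len(a), len(b))}

    labels = meta["sample_type"].reindex(burden.index)
    out["ucb_vs_pbmc"] = _two_group_test(burden, labels, "UCB", "PBMC")

    if not annotations.empty:
        class_ii = annotations[
            annotations["hla_restriction"].str.startswith(class_ii_prefixes)
        ]
        if not class_ii.empty:
            burden2 = _per_sample_burden(class_ii, sample_totals)
            out["ucb_vs_pbmc_class_ii"] = _two_group_test(burden2, labels, "UCB", "PBMC")

    # per-epitope relative abundance: unique matched rearrangements / total
    per_epitope = (
        annotations.drop_duplicates(["sample_id", "cdr3_nt", "epitope_seq"])
        .groupby(["epitope_seq", "sample_id"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=sample_totals.index, fill_value=0)
        .div(sample_totals, axis=1)
    )

    def _per_epitope_tests(group_labels: pd.Series, kind: str) -> pd.DataFrame | None:
        valid_groups = [
            g for g, cnt in group_labels.value_counts().items() if cnt >= 2 and g != ""
        ]
        if len(valid_groups) < 2:
            warnings.warn(f"{kind} per-epitope tests skipped: fewer than 2 usable groups")
            return None
        rows = []
        for epitope, values in per_epitope.iterrows():
            samples_by_group = [
                values[group_labels == g].to_numpy() for g in valid_groups
            ]
            if len(valid_groups) == 2:
                t, p = stats.ttest_ind(*samples_by_group)
            else:
                t, p = stats.f_oneway(*samples_by_group)
            rows.append({"epitope_seq": epitope, "stat": float(t), "p": float(p)})
        df = pd.DataFrame(rows)
        if df.empty:
            return df
        df["p"] = df["p"].fillna(1.0)
        reject, p_adj, _, _ = multipletests(df["p"], method="fdr_bh")
        df["p_adjusted"] = p_adj
        df["significant"] = reject
        return df

    out["per_epitope_sample_type"] = _per_epitope_tests(labels, "sample_type")
    out["per_epitope_ancestry"] = _per_epitope_tests(
        meta["ancestry"].reindex(burden.index), "ancestry"
    )
    return out
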