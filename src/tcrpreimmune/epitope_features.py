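"""Epitope physicochemistry and immunogenicity analysis.

Peptides are embedded in a 10-dimensional space of Kidera factor sums:
the ten orthogonal descriptors of Kidera et al. (principal components of
a large panel of residue properties, standardized over the twenty amino
acids) summed across the peptide's residues.  Factor 6 is dominated by
partial specific volume and factor 10 by surrounding hydrophobicity.

On top of that embedding this module provides feature-frequency association
tests (Pearson correlation and quantile ANOVA with Benjamini-Hochberg
correction), a distance-based immunogenicity T-score against a labelled
panel, a semi-supervised two-component Gaussian-mixture EM classifier that
turns binary immunogenicity labels into posterior probabilities, a linear
model predicting log TCR frequency from the factor sums, and a 2-d PCA
projection of epitope space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureError",
    "kidera_table",
    "kidera_sum",
    "EpitopeFeatureVector",
    "feature_table",
    "quantile_bins",
    "feature_association",
    "cdr3_length_profiles",
    "immunogenicity_tscore",
    "em_immunogenicity_classifier",
    "EMFit",
    "pgen_feature_lm",
    "project_pca",
]

N_FACTORS = 10
FACTOR_NAMES = [f"kf{i}" for i in range(1, N_FACTORS + 1)]


class FeatureError(ValueError):
    pass


_KIDERA: pd.DataFrame | None = None


def kidera_table() -> pd.DataFrame:
    """The 20x10 Kidera factor table (rows: amino acids, columns: kf1..kf10)."""
    global _KIDERA
    if _KIDERA is None:
        with resources.files("tcrpreimmune.data").joinpath("kidera.tsv").open() as fh:
            _KIDERA = pd.read_csv(fh, sep="\t", index_col=0)
        assert _KIDERA.shape == (20, N_FACTORS)
    return _KIDERA


def kidera_sum(peptide: str) -> np.ndarray:
    """Sum of the ten Kidera factors across all residues of ``peptide``."""
    if not peptide:
        raise FeatureError("empty peptide")
    table = kidera_table()
    try:
        return table.loc[list(peptide)].to_numpy().sum(axis=0)
    except KeyError as exc:
        raise FeatureError(f"unknown residue in {peptide!r}") from exc


@dataclass
class EpitopeFeatureVector:
    epitope_seq: str
    length: int
    kidera_sums: np.ndarray
    label: str = "unknown"  # immunogenic | non_immunogenic | unknown

    @classmethod
    def from_sequence(cls, epitope_seq: str, label: str = "unknown") -> "EpitopeFeatureVector":
        return cls(
            epitope_seq=epitope_seq,
            length=len(epitope_seq),
            kidera_sums=kidera_sum(epitope_seq),
            label=label,
        )


def feature_table(epitopes: Sequence[EpitopeFeatureVector]) -> pd.DataFrame:
    """Tidy feature frame: one row per epitope, columns length + kf1..kf10."""
    return pd.DataFrame(
        {
            "epitope_seq": [e.epitope_seq for e in epitopes],
            "length": [e.length for e in epitopes],
            "label": [e.label for e in epitopes],
            **{
                name: [float(e.kidera_sums[i]) for e in epitopes]
                for i, name in enumerate(FACTOR_NAMES)
            },
        }
    ).set_index("epitope_seq")


# ---------------------------------------------------------------------------
# Feature-frequency association
# ---------------------------------------------------------------------------


def quantile_bins(values: np.ndarray, n_quantiles: int = 4, q1_highest: bool = False) -> np.ndarray:
    """Assign each value to a quantile bin over the whole observed spectrum.

    By default Q1..Qn run from smallest to largest value; ``q1_highest``
    flips the labelling.  The partition is a disjoint cover whose bin
    populations differ by at most one for distinct-valued inputs.
    """
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(len(values))
    bins = (ranks * n_quantiles) // len(values)
    if q1_highest:
        bins = n_quantiles - 1 - bins
    return bins + 1  # 1-based: Q1..Qn


def feature_association(
    features: pd.DataFrame,
    per_epitope_freqs: Mapping[str, float],
    n_quantiles: int = 4,
    q1_highest: bool = False,
    fixed_length: int | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Associate epitope length and Kidera sums with log10 specific-TCR frequency.

    Per variable (length + ten factor sums): Pearson correlation of the raw
    value against log10 frequency, and a one-way ANOVA of log10 frequency
    across ``n_quantiles`` bins of the variable computed over the whole
    feature spectrum.  Both p-value families are Benjamini-Hochberg adjusted
    over the 11 tests.  ``fixed_length`` restricts the test to epitopes of
    one length (the usual robustness re-test at 9-mers); constant variables
    are skipped with a notice.
    """
    df = features.copy()
    df["log10_freq"] = [np.log10(per_epitope_freqs[e]) for e in df.index]
    if fixed_length is not None:
        df = df[df["length"] == fixed_length]
        if len(df) < n_quantiles:
            raise FeatureError("too few epitopes at the fixed length")
    variables = ["length"] + FACTOR_NAMES
    rows = []
    for var in variables:
        x = df[var].to_numpy(dtype=float)
        y = df["log10_freq"].to_numpy()
        if np.all(x == x[0]):
            warnings.warn(f"feature {var!r} is constant; skipped")
            rows.append({"variable": var, "pearson_r": np.nan, "p_corr": np.nan,
                         "anova_F": np.nan, "p_anova": np.nan})
            continue
        r, p_corr = stats.pearsonr(x, y)
        bins = quantile_bins(x, n_quantiles, q1_highest)
        groups = [y[bins == b] for b in range(1, n_quantiles + 1) if (bins == b).any()]
        if len(groups) >= 2:
            f, p_anova = stats.f_oneway(*groups)
        else:
            f, p_anova = np.nan, np.nan
        rows.append({"variable": var, "pearson_r": float(r), "p_corr": float(p_corr),
                     "anova_F": float(f), "p_anova": float(p_anova)})
    result = pd.DataFrame(rows).set_index("variable")
    for col in ("p_corr", "p_anova"):
        mask = result[col].notna()
        adj = np.full(len(result), np.nan)
        if mask.any():
            _, adj_vals, _, _ = multipletests(result.loc[mask, col], method="fdr_bh")
            adj[mask.to_numpy()] = adj_vals
        result[col + "_adjusted"] = adj
    result["significant"] = (
        (result["p_corr_adjusted"] < alpha) & (result["p_anova_adjusted"] < alpha)
    )
    return result


def cdr3_length_profiles(
    db_records: pd.DataFrame,
    pgen_fn=None,
    epitope_lengths: tuple[int, ...] = (8, 9, 10, 11),
) -> dict[str, pd.DataFrame]:
    """CDR3-length distributions stratified by epitope length, and the
    Pgen-by-CDR3-length profile.

    ``db_records`` needs columns ``cdr3_aa`` and ``epitope_seq``.  Longer
    epitopes tend to be recognized by shorter CDR3 loops, and shorter CDR3s
    are easier to assemble, linking epitope length to baseline frequency.
    """
    df = db_records.drop_duplicates(["cdr3_aa", "epitope_seq"]).copy()
    df["epitope_length"] = df["epitope_seq"].str.len()
    df["cdr3_length"] = df["cdr3_aa"].str.len()
    sub = df[df["epitope_length"].isin(epitope_lengths)]
    length_dist = (
        sub.groupby(["epitope_length", "cdr3_length"]).size().unstack(fill_value=0)
    )
    length_dist = length_dist.div(length_dist.sum(axis=1), axis=0)
    out = {"cdr3_length_by_epitope_length": length_dist}
    if pgen_fn is not None:
        uniq = df.drop_duplicates("cdr3_aa")
        prof = pd.DataFrame(
            {
                "cdr3_length": uniq["cdr3_aa"].str.len().to_numpy(),
                "log10_pgen": [np.log10(max(pgen_fn(a), 1e-300)) for a in uniq["cdr3_aa"]],
            }
        )
        out["pgen_by_cdr3_length"] = (
            prof.groupby("cdr3_length")["log10_pgen"].agg(["median", "mean", "count"])
        )
    return out


# ---------------------------------------------------------------------------
# Immunogenicity T-score
# ---------------------------------------------------------------------------


def immunogenicity_tscore(
    epitope: EpitopeFeatureVector | np.ndarray,
    labeled_panel: Sequence[EpitopeFeatureVector],
) -> float:
    """Distance-based immunogenicity score against a labelled panel.

    Welch two-sample t statistic comparing the epitope's Euclidean distances
    (in Kidera-sum space) to the non-immunogenic panel members against its
    distances to the immunogenic members, signed so that positive means
    closer to the immunogenic set.  Invariant under rigid motions of the
    feature space.
    """
    x = epitope.kidera_sums if isinstance(epitope, EpitopeFeatureVector) else np.asarray(epitope)
    imm = np.array([e.kidera_sums for e in labeled_panel if e.label == "immunogenic"])
    non = np.array([e.kidera_sums for e in labeled_panel if e.label == "non_immunogenic"])
    if len(imm) < 2 or len(non) < 2:
        raise FeatureError("panel needs at least 2 epitopes per label")
    d_imm = np.linalg.norm(imm - x, axis=1)
    d_non = np.linalg.norm(non - x, axis=1)
    diff = d_non.mean() - d_imm.mean()
    se = np.sqrt(d_non.var(ddof=1) / len(d_non) + d_imm.var(ddof=1) / len(d_imm))
    if diff == 0.0:
        return 0.0  # exactly equidistant, regardless of spread
    return float(diff / se)


# ---------------------------------------------------------------------------
# Semi-supervised EM immunogenicity classifier
# ---------------------------------------------------------------------------


@dataclass
class EMFit:
    posteriors: np.ndarray  # P(immunogenic) for each unlabeled epitope
    log_likelihoods: list[float] = field(default_factory=list)
    means: np.ndarray | None = None
    priors: np.ndarray | None = None
    diagonal_fallback: bool = False


def _gauss_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    return stats.multivariate_normal.logpdf(X, mean=mean, cov=cov, allow_singular=False)


def em_immunogenicity_classifier(
    labeled_panel: Sequence[EpitopeFeatureVector],
    unlabeled: Sequence[EpitopeFeatureVector] | np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
    reg: float = 1e-6,
) -> EMFit:
    """Posterior immunogenicity probabilities from a two-component Gaussian mixture.

    The mixture over Kidera-sum space is initialized from the labelled class
    moments and refined by EM over the pooled labelled + unlabelled data
    with the labelled responsibilities held fixed at their one-hot labels
    (so the labels anchor the components).  Component 1 is the immunogenic
    class.  If a class covariance is singular the fit falls back to
    diagonal covariances with a notice.  Deterministic given the inputs;
    ``seed`` is accepted for interface uniformity.
    """
    del seed  # EM from moment-based initialization is deterministic
    X_lab = np.array([e.kidera_sums for e in labeled_panel], dtype=float)
    y_lab = np.array([1 if e.label == "immunogenic" else 0 for e in labeled_panel])
    labels_present = {e.label for e in labeled_panel}
    if not {"immunogenic", "non_immunogenic"} <= labels_present:
        raise FeatureError("labelled panel must contain both classes")
    if isinstance(unlabeled, np.ndarray):
        X_unl = np.asarray(unlabeled, dtype=float)
    else:
        X_unl = np.array([e.kidera_sums for e in unlabeled], dtype=float)
    n_lab, dim = X_lab.shape
    n_unl = len(X_unl)
    X = np.vstack([X_lab, X_unl]) if n_unl else X_lab

    resp_lab = np.zeros((n_lab, 2))
    resp_lab[np.arange(n_lab), y_lab] = 1.0

    def _moments(resp: np.ndarray, data: np.ndarray, diagonal: bool):
        nk = resp.sum(axis=0)
        means = (resp.T @ data) / nk[:, None]
        covs = []
        for k in range(2):
            diff = data - means[k]
            cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            if diagonal:
                cov = np.diag(np.diag(cov))
            covs.append(cov + reg * np.eye(dim))
        priors = nk / nk.sum()
        return means, covs, priors

    diagonal = False
    for attempt in range(2):
        try:
            # initialize from the labelled class moments alone
            means, covs, priors = _moments(resp_lab, X_lab, diagonal)
            log_liks: list[float] = []
            for _ in range(max_iter):
                logp = np.column_stack(
                    [np.log(priors[k]) + _gauss_logpdf(X, means[k], covs[k]) for k in range(2)]
                )
                norm = np.logaddexp(logp[:, 0], logp[:, 1])
                post = np.exp(logp - norm[:, None])
                # labelled points contribute their known component directly
                ll = float(
                    logp[np.arange(n_lab), y_lab].sum() + norm[n_lab:].sum()
                )
                if log_liks and ll < log_liks[-1] - 1e-6:
                    raise AssertionError("EM log-likelihood decreased")
                converged = bool(log_liks) and abs(ll - log_liks[-1]) < tol
                log_liks.append(ll)
                if converged:
                    break
                resp = np.vstack([resp_lab, post[n_lab:]]) if n_unl else resp_lab
                means, covs, priors = _moments(resp, X, diagonal)
            posteriors = post[n_lab:, 1] if n_unl else np.empty(0)
            return EMFit(
                posteriors=posteriors,
                log_likelihoods=log_liks,
                means=means,
                priors=priors,
                diagonal_fallback=diagonal,
            )
        except (np.linalg.LinAlgError, ValueError):
            if diagonal:
                raise
            warnings.warn("singular class covariance; falling back to diagonal covariance")
            diagonal = True
    raise RuntimeError("unreachable")


# ---------------------------------------------------------------------------
# Linear model of log TCR frequency
# ---------------------------------------------------------------------------


def pgen_feature_lm(
    train_features: pd.DataFrame,
    train_log10_freqs: Mapping[str, float],
    target_panel: Sequence[EpitopeFeatureVector],
) -> dict[str, object]:
    """Least-squares fit of log10 specific-TCR frequency on the ten Kidera sums.

    Returns the coefficients (intercept + one per factor), predictions for
    the target panel, and a two-sample Kolmogorov-Smirnov test comparing
    predicted frequencies of the panel's immunogenic vs non-immunogenic
    epitopes.
    """
    if len(train_features) < 12:
        raise FeatureError("need at least 12 training epitopes for a 10-feature fit")
    X = np.column_stack(
        [np.ones(len(train_features))] + [train_features[c].to_numpy() for c in FACTOR_NAMES]
    )
    y = np.array([train_log10_freqs[e] for e in train_features.index])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which factor columns are linearly dependent
        bad = []
        for i, name in enumerate(["intercept"] + FACTOR_NAMES):
            reduced = np.delete(X, i, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(name)
        raise FeatureError(f"rank-deficient design; collinear factors: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    target_X = np.column_stack(
        [np.ones(len(target_panel))] + [
            np.array([e.kidera_sums[i] for e in target_panel]) for i in range(N_FACTORS)
        ]
    )
    preds = target_X @ coef
    pred_imm = preds[[e.label == "immunogenic" for e in target_panel]]
    pred_non = preds[[e.label == "non_immunogenic" for e in target_panel]]
    ks = None
    if len(pred_imm) >= 2 and len(pred_non) >= 2:
        d, p = stats.ks_2samp(pred_imm, pred_non)
        ks = (float(d), float(p))
    return {
        "coefficients": dict(zip(["intercept"] + FACTOR_NAMES, coef)),
        "predictions": preds,
        "ks_immunogenic_vs_non": ks,
    }


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------


def project_pca(
    epitopes: Sequence[EpitopeFeatureVector] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of Kidera-sum space; 2-d scores + explained-variance fractions."""
    if isinstance(epitopes, np.ndarray):
        X = np.asarray(epitopes, dtype=float)
    else:
        X = np.array([e.kidera_sums for e in epitopes], dtype=float)
    if len(X) < 3:
        raise FeatureError("PCA requires at least 3 epitopes")
    if np.allclose(X.var(axis=0), 0):
        raise FeatureError("PCA undefined: zero variance (duplicate points)")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
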