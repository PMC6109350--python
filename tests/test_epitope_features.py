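"""Tests for Kidera-factor features, T-scores, the EM classifier, and the linear model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tcrpreimmune import epitope_features as ef
from tcrpreimmune import synthetic_data as sd

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Kidera sums
# ---------------------------------------------------------------------------


def test_kidera_table_is_standardized():
    """The published factors are principal components standardized over the 20 residues."""
    table = ef.kidera_table()
    assert table.shape == (20, 10)
    np.testing.assert_allclose(table.mean(axis=0), 0.0, atol=0.01)
    np.testing.assert_allclose(table.std(axis=0, ddof=0), 1.0, atol=0.01)


def test_kidera_sum_single_and_double():
    row_a = ef.kidera_table().loc["A"].to_numpy()
    np.testing.assert_allclose(ef.kidera_sum("A"), row_a)
    np.testing.assert_allclose(ef.kidera_sum("AA"), 2 * row_a)


def test_kidera_sum_errors():
    with pytest.raises(ef.FeatureError, match="unknown residue"):
        ef.kidera_sum("AXA")
    with pytest.raises(ef.FeatureError, match="empty"):
        ef.kidera_sum("")


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet=AA, min_size=1, max_size=12), st.text(alphabet=AA, min_size=1, max_size=12))
def test_kidera_sum_additive_under_concatenation(p, q):
    np.testing.assert_allclose(ef.kidera_sum(p + q), ef.kidera_sum(p) + ef.kidera_sum(q), atol=1e-12)


# ---------------------------------------------------------------------------
# Quantile bins and feature association
# ---------------------------------------------------------------------------


def test_quantile_bins_balanced():
    values = np.arange(8, dtype=float)
    bins = ef.quantile_bins(values, 4)
    assert sorted(np.bincount(bins)[1:]) == [2, 2, 2, 2]
    assert bins[0] == 1 and bins[-1] == 4  # Q1 smallest by default
    flipped = ef.quantile_bins(values, 4, q1_highest=True)
    assert flipped[0] == 4 and flipped[-1] == 1


def test_quantile_bins_disjoint_cover(rng):
    values = rng.normal(size=103)
    bins = ef.quantile_bins(values, 4)
    assert set(bins) == {1, 2, 3, 4}
    counts = np.bincount(bins)[1:]
    assert counts.max() - counts.min() <= 1


def _panel_features(rng, n=60, length=9):
    eps = ["".join(rng.choice(list(AA), size=length)) for _ in range(n)]
    vecs = [ef.EpitopeFeatureVector.from_sequence(e) for e in eps]
    return ef.feature_table(vecs), vecs


def test_feature_association_perfect_linear(rng):
    features, _ = _panel_features(rng)
    # frequency exactly linear in factor 6 on the log scale
    freqs = {e: 10 ** (-6 + 0.2 * features.loc[e, "kf6"]) for e in features.index}
    result = ef.feature_association(features, freqs)
    assert result.loc["kf6", "pearson_r"] == pytest.approx(1.0)
    assert result.loc["kf6", "p_anova"] < 1e-6
    assert result.loc["kf6", "significant"]


def test_feature_association_null_calibration(rng):
    """With frequency independent of all features, few factors reach significance."""
    n_sig = 0
    n_rep = 30
    for _ in range(n_rep):
        features, _ = _panel_features(rng, n=100)
        freqs = {e: 10 ** rng.normal(-6, 1) for e in features.index}
        result = ef.feature_association(features, freqs, alpha=0.05)
        n_sig += int(result["significant"].sum())
    assert n_sig / (n_rep * 11) <= 0.05 + 0.03


def test_feature_association_constant_feature_warns(rng):
    features, _ = _panel_features(rng, n=20)
    features["kf3"] = 1.0
    freqs = {e: 1e-6 for e in features.index}
    freqs = {e: 10 ** rng.normal(-6, 1) for e in features.index}
    with pytest.warns(UserWarning, match="constant"):
        result = ef.feature_association(features, freqs)
    assert np.isnan(result.loc["kf3", "pearson_r"])


def test_cdr3_length_profiles():
    df = pd.DataFrame(
        {
            "cdr3_aa": ["CASF", "CASSF", "CASSLF", "CAF"],
            "epitope_seq": ["E" * 8, "E" * 9, "E" * 10, "E" * 11],
        }
    )
    out = ef.cdr3_length_profiles(df, pgen_fn=lambda a: 10.0 ** -len(a))
    dist = out["cdr3_length_by_epitope_length"]
    assert set(dist.index) == {8, 9, 10, 11}
    np.testing.assert_allclose(dist.sum(axis=1), 1.0)
    prof = out["pgen_by_cdr3_length"]
    assert (np.diff(prof["median"].to_numpy()) < 0).all()  # longer CDR3, lower Pgen here


# ---------------------------------------------------------------------------
# T-score
# ---------------------------------------------------------------------------


def _cluster(rng, center, n, sd=0.5):
    return [
        ef.EpitopeFeatureVector("X" * 9, 9, center + rng.normal(0, sd, 10), label=lab)
        for lab in [None] * 0 or []
    ]


def _labelled_cluster(rng, center, n, label, sd=0.5):
    return [
        ef.EpitopeFeatureVector("X" * 9, 9, center + rng.normal(0, sd, 10), label=label)
        for _ in range(n)
    ]


def test_tscore_symmetric_configuration():
    """An epitope equidistant from mirror-image panels scores exactly zero."""
    imm = [ef.EpitopeFeatureVector("A" * 9, 9, np.eye(10)[i], "immunogenic") for i in range(4)]
    non = [ef.EpitopeFeatureVector("C" * 9, 9, -np.eye(10)[i], "non_immunogenic") for i in range(4)]
    t = ef.immunogenicity_tscore(np.zeros(10), imm + non)
    assert t == pytest.approx(0.0, abs=1e-12)


def test_tscore_sign(rng):
    imm = _labelled_cluster(rng, np.full(10, 3.0), 10, "immunogenic")
    non = _labelled_cluster(rng, np.full(10, -3.0), 10, "non_immunogenic")
    t = ef.immunogenicity_tscore(np.full(10, 3.0), imm + non)
    assert t > 0
    t2 = ef.immunogenicity_tscore(np.full(10, -3.0), imm + non)
    assert t2 < 0


def test_tscore_rigid_motion_invariant(rng):
    panel = _labelled_cluster(rng, np.full(10, 2.0), 8, "immunogenic") + _labelled_cluster(
        rng, np.zeros(10), 8, "non_immunogenic"
    )
    x = rng.normal(size=10)
    t0 = ef.immunogenicity_tscore(x, panel)
    Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
    shift = rng.normal(size=10)
    moved = [
        ef.EpitopeFeatureVector(e.epitope_seq, e.length, Q @ e.kidera_sums + shift, e.label)
        for e in panel
    ]
    t1 = ef.immunogenicity_tscore(Q @ x + shift, moved)
    assert t1 == pytest.approx(t0, rel=1e-9)


def test_tscore_tracks_centroid_distance(rng):
    """Rank order of T-scores follows distance to the immunogenic centroid."""
    imm_c, non_c = np.full(10, 4.0), np.full(10, -4.0)
    panel = _labelled_cluster(rng, imm_c, 20, "immunogenic") + _labelled_cluster(
        rng, non_c, 20, "non_immunogenic"
    )
    tests = [rng.uniform(-4, 4) * np.ones(10) + rng.normal(0, 0.3, 10) for _ in range(100)]
    t_scores = [ef.immunogenicity_tscore(x, panel) for x in tests]
    d_imm = [np.linalg.norm(x - imm_c) for x in tests]
    rho = stats.spearmanr(t_scores, d_imm).statistic
    assert rho <= -0.9  # closer to the immunogenic centroid => larger score


def test_tscore_needs_two_per_label(rng):
    panel = _labelled_cluster(rng, np.zeros(10), 1, "immunogenic") + _labelled_cluster(
        rng, np.ones(10), 5, "non_immunogenic"
    )
    with pytest.raises(ef.FeatureError):
        ef.immunogenicity_tscore(np.zeros(10), panel)


# ---------------------------------------------------------------------------
# EM classifier
# ---------------------------------------------------------------------------


def test_em_midpoint_is_half(rng):
    """A point exactly between two mirror-image equal-prior classes scores 0.5."""
    pts = np.full(10, 3.0) + rng.normal(0, 1.0, size=(200, 10))
    imm = [ef.EpitopeFeatureVector("X" * 9, 9, p, "immunogenic") for p in pts]
    non = [ef.EpitopeFeatureVector("X" * 9, 9, -p, "non_immunogenic") for p in pts]
    fit = ef.em_immunogenicity_classifier(imm + non, np.zeros((1, 10)), seed=0)
    assert fit.posteriors[0] == pytest.approx(0.5, abs=0.01)


def test_em_separated_means_match_bayes(rng):
    """At the immunogenic class mean of well-separated spherical classes,
    the posterior matches the (essentially 1) exact Bayes value."""
    mu = np.zeros(10)
    mu[0] = 6.0  # 6 SD separation along one axis
    imm = _labelled_cluster(rng, mu, 300, "immunogenic", sd=1.0)
    non = _labelled_cluster(rng, np.zeros(10), 300, "non_immunogenic", sd=1.0)
    fit = ef.em_immunogenicity_classifier(imm + non, mu.reshape(1, -1), seed=0)
    # exact Bayes posterior under the generating gaussians
    log_num = stats.multivariate_normal.logpdf(mu, mu, np.eye(10))
    log_den = np.logaddexp(log_num, stats.multivariate_normal.logpdf(mu, np.zeros(10), np.eye(10)))
    bayes = np.exp(log_num - log_den)
    assert bayes > 0.99
    assert fit.posteriors[0] > 0.99


def test_em_loglik_nondecreasing(rng):
    imm = _labelled_cluster(rng, np.full(10, 1.0), 50, "immunogenic", sd=1.5)
    non = _labelled_cluster(rng, np.full(10, -1.0), 50, "non_immunogenic", sd=1.5)
    unl = rng.normal(size=(80, 10))
    fit = ef.em_immunogenicity_classifier(imm + non, unl, seed=0)
    assert len(fit.log_likelihoods) > 1
    assert (np.diff(fit.log_likelihoods) >= -1e-6).all()


def test_em_shuffled_labels_recover_prior(rng):
    """With labels carrying no information, posteriors settle near the class prior."""
    X = rng.normal(size=(300, 10))
    labels = ["immunogenic" if i % 2 else "non_immunogenic" for i in range(300)]
    panel = [ef.EpitopeFeatureVector("X" * 9, 9, X[i], labels[i]) for i in range(300)]
    unl = rng.normal(size=(200, 10))
    fit = ef.em_immunogenicity_classifier(panel, unl, seed=0)
    assert abs(fit.posteriors.mean() - 0.5) <= 0.05


def test_em_requires_both_classes(rng):
    imm = _labelled_cluster(rng, np.zeros(10), 5, "immunogenic")
    with pytest.raises(ef.FeatureError, match="both classes"):
        ef.em_immunogenicity_classifier(imm, np.zeros((1, 10)), seed=0)


# ---------------------------------------------------------------------------
# Linear model
# ---------------------------------------------------------------------------


def test_lm_recovers_noise_free_coefficients(rng):
    features, vecs = _panel_features(rng, n=40)
    true = rng.normal(size=11)
    freqs = {
        e: float(true[0] + features.loc[e, ef.FACTOR_NAMES].to_numpy() @ true[1:])
        for e in features.index
    }
    out = ef.pgen_feature_lm(features, freqs, vecs)
    fitted = np.array([out["coefficients"]["intercept"]] + [out["coefficients"][f] for f in ef.FACTOR_NAMES])
    np.testing.assert_allclose(fitted, true, rtol=1e-8)


def test_lm_identical_classes_ks_zero(rng):
    features, _ = _panel_features(rng, n=30)
    freqs = {e: float(rng.normal(-6, 1)) for e in features.index}
    shared = [
        ef.EpitopeFeatureVector("Y" * 9, 9, rng.normal(size=10), label)
        for label in ("immunogenic", "non_immunogenic")
        for _ in range(5)
    ]
    # identical feature vectors across classes
    base = [rng.normal(size=10) for _ in range(5)]
    shared = [
        ef.EpitopeFeatureVector("Y" * 9, 9, b, lab)
        for b in base
        for lab in ("immunogenic", "non_immunogenic")
    ]
    out = ef.pgen_feature_lm(features, freqs, shared)
    assert out["ks_immunogenic_vs_non"][0] == pytest.approx(0.0)


def test_lm_coefficient_error_scales_with_noise(rng):
    """Gaussian noise of scale sigma gives coefficient RMSE ~ sigma/sqrt(n)."""
    true = rng.normal(size=11)
    rmses = []
    for n in (50, 800):
        features, vecs = _panel_features(rng, n=n)
        X = features[ef.FACTOR_NAMES].to_numpy()
        y = true[0] + X @ true[1:] + rng.normal(0, 0.5, size=n)
        freqs = dict(zip(features.index, map(float, y)))
        out = ef.pgen_feature_lm(features, freqs, vecs[:15])
        fitted = np.array([out["coefficients"][f] for f in ef.FACTOR_NAMES])
        rmses.append(np.sqrt(np.mean((fitted - true[1:]) ** 2)))
    assert rmses[1] < rmses[0] / 2  # 16x the data, ~4x smaller error


def test_lm_rank_deficient_names_collinear(rng):
    features, vecs = _panel_features(rng, n=20)
    features["kf10"] = features["kf9"]
    freqs = {e: -6.0 for e in features.index}
    with pytest.raises(ef.FeatureError, match="collinear"):
        ef.pgen_feature_lm(features, freqs, vecs)


def test_lm_needs_enough_epitopes(rng):
    features, vecs = _panel_features(rng, n=10)
    with pytest.raises(ef.FeatureError, match="12"):
        ef.pgen_feature_lm(features, {e: -6.0 for e in features.index}, vecs)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_planar_data_fully_explained(rng):
    basis = rng.normal(size=(2, 10))
    coords = rng.normal(size=(50, 2))
    X = coords @ basis + rng.normal(size=10)  # 2-d affine subspace
    scores, evr = ef.project_pca(X)
    assert scores.shape == (50, 2)
    assert evr.sum() == pytest.approx(1.0)


def test_pca_isotropic_cloud(rng):
    X = rng.normal(size=(1000, 10))
    _, evr = ef.project_pca(X)
    assert np.all(np.abs(evr - 0.1) < 0.02)


def test_pca_degenerate_inputs():
    with pytest.raises(ef.FeatureError, match="3 epitopes"):
        ef.project_pca(np.zeros((2, 10)))
    with pytest.raises(ef.FeatureError, match="zero variance"):
        ef.project_pca(np.ones((5, 10)))
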