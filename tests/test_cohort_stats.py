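"""Tests for cohort-level statistics: summaries, enrichment, expansion, groups."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrpreimmune import cohort_stats as cs
from tcrpreimmune import repertoire_io as rio


def _record(cdr3, epitope, species="CMV", hla="HLA-A*02"):
    return rio.SpecificityRecord("TRB", cdr3, epitope, species, hla)


def _random_aa(rng, n, length=8):
    return ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)) for _ in range(n)]


# ---------------------------------------------------------------------------
# Epitope Pgen summaries
# ---------------------------------------------------------------------------


def test_summary_excludes_small_epitopes(rng):
    seqs_a = _random_aa(rng, 30)
    seqs_b = _random_aa(rng, 29)
    db = [_record(s, "EPITOPEAA") for s in seqs_a] + [_record(s, "EPITOPEBB", "EBV") for s in seqs_b]
    pgens = {s: 1e-6 for s in seqs_a}
    pgens.update({s: 1e-5 for s in seqs_b})
    with pytest.raises(cs.CohortStatsError, match="ANOVA undefined"):
        # only one epitope survives the >= 30 filter
        cs.epitope_pgen_summary(db, pgens.get, min_tcrs=30)
    summaries, anova = cs.epitope_pgen_summary(db, pgens.get, min_tcrs=29)
    assert {s.epitope_seq for s in summaries} == {"EPITOPEAA", "EPITOPEBB"}


def test_summary_identical_groups_give_f_zero(rng):
    seqs_a = _random_aa(rng, 30)
    seqs_b = _random_aa(rng, 30)
    db = [_record(s, "EPITOPEAA") for s in seqs_a] + [_record(s, "EPITOPEBB", "EBV") for s in seqs_b]
    values = 10.0 ** (-6 + 0.01 * np.arange(30))
    pgens = dict(zip(seqs_a, values)) | dict(zip(seqs_b, values))
    summaries, anova = cs.epitope_pgen_summary(db, pgens.get, min_tcrs=30)
    f, p = anova["epitope"]
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_summary_detects_planted_gap(rng):
    """A 10x median Pgen gap between epitopes is highly significant."""
    seqs_a = _random_aa(rng, 50)
    seqs_b = _random_aa(rng, 50)
    db = [_record(s, "EPITOPEAA") for s in seqs_a] + [_record(s, "EPITOPEBB", "EBV") for s in seqs_b]
    pgens = {s: 10 ** rng.normal(-6, 0.2) for s in seqs_a}
    pgens.update({s: 10 ** rng.normal(-5, 0.2) for s in seqs_b})
    summaries, anova = cs.epitope_pgen_summary(db, pgens.get, min_tcrs=30)
    assert anova["epitope"][1] < 0.01
    assert anova["species"][1] < 0.01
    med = {s.epitope_seq: s.median_pgen for s in summaries}
    assert 5 <= med["EPITOPEBB"] / med["EPITOPEAA"] <= 20


def test_summary_drops_zero_pgen_with_warning(rng):
    seqs = _random_aa(rng, 31) + _random_aa(rng, 30, length=9)
    db = [_record(s, "EPITOPEAA") for s in seqs[:31]] + [_record(s, "EPITOPEBB") for s in seqs[31:]]
    pgens = {s: 1e-6 for s in seqs}
    pgens[seqs[0]] = 0.0
    with pytest.warns(UserWarning, match="zero-probability"):
        summaries, _ = cs.epitope_pgen_summary(db, pgens.get, min_tcrs=30)
    by_e = {s.epitope_seq: s.n_tcrs for s in summaries}
    assert by_e["EPITOPEAA"] == 30


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def _summary(epitope, median_pgen, public_fraction, n_tcrs=30):
    return cs.EpitopeSummary(
        epitope_seq=epitope, species="CMV", n_tcrs=n_tcrs,
        median_pgen=median_pgen, log10_pgens=np.array([np.log10(median_pgen)]),
        public_fraction=public_fraction,
    )


def test_pgen_incidence_correlation_monotone():
    summaries = [_summary(f"E{i}", 10 ** (-8 + i), 0.1 * i) for i in range(5)]
    rho, p = cs.pgen_incidence_correlation(summaries)
    assert rho == pytest.approx(1.0)


def test_pgen_incidence_correlation_errors():
    with pytest.raises(cs.CohortStatsError, match="fewer than 3"):
        cs.pgen_incidence_correlation([_summary("A", 1e-6, 0.1), _summary("B", 1e-5, 0.2)])
    constant = [_summary(f"E{i}", 1e-6, 0.1 * i) for i in range(4)]
    with pytest.raises(cs.CohortStatsError, match="constant"):
        cs.pgen_incidence_correlation(constant)


def test_pgen_incidence_correlation_null(rng):
    """Shuffled public fractions stay below the permutation-null envelope."""
    x = 10 ** rng.uniform(-8, -4, size=33)
    y = rng.uniform(0, 1, size=33)
    summaries = [_summary(f"E{i}", x[i], y[i]) for i in range(33)]
    rho, _ = cs.pgen_incidence_correlation(summaries)
    null = []
    for _ in range(1000):
        perm = rng.permutation(y)
        null.append(abs(stats.spearmanr(x, perm).statistic))
    assert abs(rho) <= np.quantile(null, 0.95) + 1e-12


def test_pgen_vs_ntcrs_correlation():
    summaries = [_summary(f"E{i}", 10 ** (-8 + i), 0.1, n_tcrs=30 + i) for i in range(5)]
    rho, _ = cs.pgen_vs_ntcrs_correlation(summaries)
    assert rho == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# HLA observed / expected
# ---------------------------------------------------------------------------


def _meta(sample_id, alleles, sero="unknown", ancestry="", stype="PBMC"):
    return cs.DonorMetadata(sample_id, frozenset(alleles), sero, ancestry, stype)


def _ann_rows(sample_id, n, allele, epitope="EPITOPEAA", species="CMV", freq=1e-4, tag=""):
    return [
        {
            "sample_id": sample_id, "cdr3_nt": f"NT{tag}{sample_id}{i}", "cdr3_aa": f"AA{tag}{i}",
            "count": 1, "freq": freq, "db_cdr3_aa": f"AA{tag}{i}", "chain": "TRB",
            "epitope_seq": epitope, "epitope_species": species, "hla_restriction": allele,
        }
        for i in range(n)
    ]


def test_hla_observed_expected_trivial():
    """Two donors, genotype-independent matching: every ratio is 1."""
    ann = pd.DataFrame(_ann_rows("d1", 10, "HLA-A*02") + _ann_rows("d2", 10, "HLA-A*02"))
    meta = [_meta("d1", {"HLA-A*02", "HLA-B*07"}), _meta("d2", {"HLA-A*01", "HLA-B*07"})]
    db = [_record(f"AA{i}", "EPITOPEAA", hla="HLA-A*02") for i in range(10)]
    matrix, cells, (u, p) = cs.hla_observed_expected(ann, meta, db, min_samples=1, min_tcrs=1)
    a02 = cells[(cells.donor_allele == "HLA-A*02") & (cells.restriction_allele == "HLA-A*02")]
    assert a02["expected"].iloc[0] == pytest.approx(10.0)
    assert a02["observed"].iloc[0] == pytest.approx(10.0)
    assert a02["ratio"].iloc[0] == pytest.approx(1.0)


def test_hla_observed_expected_conserves_totals():
    """With a fixed number of tested alleles per donor, sum(E) = sum(O) per restriction."""
    rng = np.random.default_rng(0)
    alleles = ["HLA-A*01", "HLA-A*02", "HLA-B*07", "HLA-B*08"]
    meta, rows = [], []
    for i in range(12):
        pair = list(rng.choice(["HLA-A*01", "HLA-A*02"], 1)) + list(rng.choice(["HLA-B*07", "HLA-B*08"], 1))
        meta.append(_meta(f"d{i}", set(pair)))
        for a in alleles:
            rows += _ann_rows(f"d{i}", int(rng.integers(1, 6)), a, tag=a[-2:])
    ann = pd.DataFrame(rows)
    db = [_record(f"AA{a[-2:]}{i}", "EPITOPEAA", hla=a) for a in alleles for i in range(6)]
    _, cells, _ = cs.hla_observed_expected(ann, meta, db, min_samples=1, min_tcrs=1)
    sums = cells.groupby("restriction_allele")[["observed", "expected"]].sum()
    np.testing.assert_allclose(sums["observed"], sums["expected"], rtol=1e-9)


def test_hla_observed_expected_thresholds_error():
    ann = pd.DataFrame(_ann_rows("d1", 2, "HLA-A*02"))
    meta = [_meta("d1", {"HLA-A*02"}), _meta("d2", set())]
    db = [_record("AA0", "EPITOPEAA", hla="HLA-A*02")]
    with pytest.raises(cs.CohortStatsError, match="no matched pairs"):
        cs.hla_observed_expected(ann, meta, db, min_samples=30, min_tcrs=100)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


def _enrichment_frame(presence, carriers, S):
    """Build annotations + metadata for an explicit presence/carrier layout."""
    rows = []
    for tcr, samples in presence.items():
        for s in samples:
            rows.append(
                {
                    "sample_id": f"d{s}", "cdr3_nt": f"NT{tcr}{s}", "cdr3_aa": tcr, "count": 1,
                    "freq": 1e-4, "db_cdr3_aa": tcr, "chain": "TRB", "epitope_seq": "EPITOPEAA",
                    "epitope_species": "CMV", "hla_restriction": "HLA-A*02",
                }
            )
    meta = [
        _meta(f"d{i}", {"HLA-A*02"} if i in carriers else {"HLA-A*01"}) for i in range(S)
    ]
    return pd.DataFrame(rows), meta


def test_hypergeometric_example():
    """S=10, K=5, m=4, x=4: p = C(5,4)/C(10,4) = 5/210."""
    ann, meta = _enrichment_frame({"T1": [0, 1, 2, 3]}, carriers={0, 1, 2, 3, 4}, S=10)
    result = cs.tcr_hla_enrichment(ann, meta)
    p = result.loc[result.allele == "HLA-A*02", "p"].iloc[0]
    assert p == pytest.approx(5 / 210)


def test_hypergeometric_matches_subset_enumeration():
    """Sampled (S, K, m, x) instances agree with exhaustive subset enumeration."""
    rng = np.random.default_rng(1)
    for _ in range(25):
        S = int(rng.integers(3, 13))
        K = int(rng.integers(1, S))
        m = int(rng.integers(0, S + 1))
        x = int(rng.integers(max(0, m - (S - K)), min(m, K) + 1))
        ours = float(stats.hypergeom.sf(x - 1, S, K, m))
        carriers = set(range(K))
        count = 0
        total = 0
        for subset in itertools.combinations(range(S), m):
            total += 1
            if len(carriers & set(subset)) >= x:
                count += 1
        assert ours == pytest.approx(count / total if total else 1.0, abs=1e-12)


def test_enrichment_edge_cases():
    ann, meta = _enrichment_frame({"T1": []}, carriers={0, 1}, S=6)
    # TCR absent everywhere -> no annotation rows at all
    assert ann.empty
    ann2, meta2 = _enrichment_frame({"T1": [0]}, carriers=set(range(6)), S=6)
    with pytest.raises(cs.CohortStatsError, match="degenerate allele"):
        cs.tcr_hla_enrichment(ann2, meta2)


def test_bh_adjustment_properties():
    ann, meta = _enrichment_frame(
        {"T1": [0, 1, 2], "T2": [0, 5, 6], "T3": [7]}, carriers={0, 1, 2, 3}, S=8
    )
    result = cs.tcr_hla_enrichment(ann, meta)
    assert (result["p_adjusted"] >= result["p"] - 1e-12).all()
    # BH adjustment is monotone in the raw p-values
    sorted_r = result.sort_values("p")
    assert (np.diff(sorted_r["p_adjusted"].to_numpy()) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Expansion analysis
# ---------------------------------------------------------------------------


def test_expansion_log2_ratio_value():
    """Mean matched frequency 4e-4 vs mismatched 1e-4 gives a log2 ratio of 2."""
    rows = []
    for sid, freq in (("d1", 4e-4), ("d2", 1e-4)):
        rows += [
            {
                "sample_id": sid, "cdr3_nt": f"NT{sid}", "cdr3_aa": "AAA", "count": 1,
                "freq": freq, "db_cdr3_aa": "AAA", "chain": "TRB", "epitope_seq": "EPITOPEAA",
                "epitope_species": "CMV", "hla_restriction": "HLA-A*02",
            }
        ]
    ann = pd.DataFrame(rows)
    meta = [_meta("d1", {"HLA-A*02"}, "positive"), _meta("d2", {"HLA-A*01"}, "positive")]
    res = cs.expansion_analysis(ann, meta, "CMV", min_clonotypes_per_allele=1)
    assert res["ratios"]["log2_ratio"].iloc[0] == pytest.approx(2.0)


def test_expansion_identical_distributions_ks_zero(rng):
    rows = []
    meta = []
    for i in range(8):
        sero = "positive" if i % 2 else "negative"
        alleles = {"HLA-A*02"} if i < 4 else {"HLA-A*01"}
        meta.append(_meta(f"d{i}", alleles, sero))
        for t in range(6):
            rows.append(
                {
                    "sample_id": f"d{i}", "cdr3_nt": f"NT{t}{i}", "cdr3_aa": f"T{t}", "count": 1,
                    "freq": 1e-4 * (t + 1), "db_cdr3_aa": f"T{t}", "chain": "TRB",
                    "epitope_seq": "EPITOPEAA", "epitope_species": "CMV",
                    "hla_restriction": "HLA-A*02",
                }
            )
    res = cs.expansion_analysis(pd.DataFrame(rows), meta, "CMV", min_clonotypes_per_allele=1)
    d, p = res["ks_tests"][("negative", "positive")]
    assert d == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_expansion_directional_clopper_pearson():
    """3 of 3 higher gives a Clopper-Pearson lower bound of 0.025^(1/3)."""
    rows = []
    for t in range(3):
        for sid, freq in (("d1", 4e-4), ("d2", 1e-4)):
            rows.append(
                {
                    "sample_id": sid, "cdr3_nt": f"NT{t}{sid}", "cdr3_aa": f"T{t}", "count": 1,
                    "freq": freq, "db_cdr3_aa": f"T{t}", "chain": "TRB",
                    "epitope_seq": "EPITOPEAA", "epitope_species": "EBV",
                    "hla_restriction": "HLA-B*08",
                }
            )
    ann = pd.DataFrame(rows)
    meta = [_meta("d1", {"HLA-B*08"}), _meta("d2", {"HLA-A*01"})]
    res = cs.expansion_analysis(ann, meta, "EBV", min_clonotypes_per_allele=3, serostatus_groups=False)
    row = res["directional"].iloc[0]
    assert row["n_higher"] == 3 and row["n_lower"] == 0
    assert row["ci_low"] == pytest.approx(0.025 ** (1 / 3), abs=1e-9)
    assert row["ci_high"] == pytest.approx(1.0)


def test_expansion_small_alleles_excluded():
    rows = []
    for sid, freq in (("d1", 4e-4), ("d2", 1e-4)):
        rows.append(
            {
                "sample_id": sid, "cdr3_nt": f"NT{sid}", "cdr3_aa": "T0", "count": 1,
                "freq": freq, "db_cdr3_aa": "T0", "chain": "TRB", "epitope_seq": "EPITOPEAA",
                "epitope_species": "EBV", "hla_restriction": "HLA-B*44",
            }
        )
    meta = [_meta("d1", {"HLA-B*44"}), _meta("d2", {"HLA-A*01"})]
    res = cs.expansion_analysis(pd.DataFrame(rows), meta, "EBV", min_clonotypes_per_allele=4, serostatus_groups=False)
    assert res["directional"].empty  # one sequence < threshold, like a 3-sequence allele


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def test_group_comparisons_identical_groups():
    rows = []
    meta = []
    totals = {}
    for i in range(8):
        stype = "UCB" if i < 4 else "PBMC"
        meta.append(_meta(f"d{i}", {"HLA-A*02"}, stype=stype))
        totals[f"d{i}"] = 100
        for t in range(10):
            rows.append(
                {
                    "sample_id": f"d{i}", "cdr3_nt": f"NT{t}{i}", "cdr3_aa": f"T{t}", "count": 1,
                    "freq": 1e-4, "db_cdr3_aa": f"T{t}", "chain": "TRB",
                    "epitope_seq": "EPITOPEAA", "epitope_species": "CMV",
                    "hla_restriction": "HLA-A*02",
                }
            )
    res = cs.group_comparisons(pd.DataFrame(rows), pd.Series(totals), meta)
    assert res["ucb_vs_pbmc"]["fold_change"] == pytest.approx(1.0)
    assert (res["burden"] == 0.1).all()


def test_group_comparisons_small_group_skipped():
    rows = _ann_rows("d1", 3, "HLA-A*02") + _ann_rows("d2", 3, "HLA-A*02")
    meta = [_meta("d1", set(), stype="UCB"), _meta("d2", set(), stype="PBMC")]
    totals = pd.Series({"d1": 10, "d2": 10})
    with pytest.warns(UserWarning, match="skipped"):
        res = cs.group_comparisons(pd.DataFrame(rows), totals, meta)
    assert res["ucb_vs_pbmc"] is None
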