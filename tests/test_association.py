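"""Alteration flags, cohort prep, Fisher/logistic tests, adjustment, summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelancestry import (ALTERATIONS, EffectModel, bin_pack_years,
                           bonferroni_adjust, build_fixture_cohort, compare_tmb,
                           extract_alteration_flags, first_sample_selection,
                           fisher_exact, logistic_fit, simulate_admixed_cohort,
                           simulate_clinical_and_somatic, summarize_cohort)

from oracles import (fisher_p_enumeration, logistic_loglik_optimum,
                     ranksum_p_enumeration)


def _call(sample, gene, cls, hgvs=None, exon=None, cna=None, partner=None):
    return {"sample": sample, "gene": gene, "class": cls, "hgvs_p": hgvs,
            "exon": exon, "cna_type": cna, "fusion_partner": partner}


class TestExtractFlags:
    @pytest.mark.parametrize("call,flag", [
        (_call("s1", "EGFR", "SNV", "p.L858R"), "EGFR_sens"),
        (_call("s1", "EGFR", "indel", "p.E746_A750del", exon=19), "EGFR_sens"),
        (_call("s1", "EGFR", "indel", "p.A767_V769dup_ins", exon=20), "EGFR_sens"),
        (_call("s1", "KRAS", "SNV", "p.G12C"), "KRAS_G12C"),
        (_call("s1", "MET", "CNA", cna="amplification"), "MET_alt"),
        (_call("s1", "MET", "SNV", "p.X1010_splice", exon=14), "MET_alt"),
        (_call("s1", "BRAF", "SNV", "p.V600E"), "BRAF_V600E"),
        (_call("s1", "ALK", "fusion", partner="EML4"), "ALK_fus"),
        (_call("s1", "ROS1", "fusion", partner="CD74"), "ROS1_fus"),
        (_call("s1", "NTRK1", "fusion", partner="TPM3"), "NTRK_fus"),
        (_call("s1", "LMNA", "fusion", partner="NTRK1"), "NTRK_fus"),
    ])
    def test_positive_rules(self, call, flag):
        flags = extract_alteration_flags(pd.DataFrame([call]))
        assert flags.loc["s1", flag]
        assert flags.loc["s1"].sum() == 1

    @pytest.mark.parametrize("call", [
        _call("s1", "KRAS", "SNV", "p.G12D"),
        _call("s1", "BRAF", "SNV", "p.V600K"),
        _call("s1", "EGFR", "SNV", "p.T790M"),
        _call("s1", "MET", "SNV", "p.D1010N", exon=13),
        _call("s1", "MET", "CNA", cna="deletion"),
        _call("s1", "FGFR1", "fusion", partner="TACC1"),
    ])
    def test_negative_rules(self, call):
        flags = extract_alteration_flags(pd.DataFrame([call]))
        assert flags.loc["s1"].sum() == 0

    def test_met_amp_and_nontarget_braf(self):
        calls = pd.DataFrame([
            _call("s1", "MET", "CNA", cna="amplification"),
            _call("s1", "BRAF", "SNV", "p.V600K"),
        ])
        flags = extract_alteration_flags(calls)
        assert flags.loc["s1", "MET_alt"]
        assert not flags.loc["s1", "BRAF_V600E"]

    def test_unknown_class_skipped_with_warning(self, caplog):
        calls = pd.DataFrame([_call("s1", "EGFR", "weird", "p.L858R")])
        with caplog.at_level("WARNING"):
            flags = extract_alteration_flags(calls, samples=["s1"])
        assert flags.loc["s1"].sum() == 0
        assert "unknown variant class" in caplog.text


class TestFirstSample:
    def test_youngest_kept_and_ties_lexicographic(self):
        df = pd.DataFrame({
            "patient_id": ["p1", "p1", "p2", "p3", "p3"],
            "sample_id": ["s2", "s1", "s9", "sB", "sA"],
            "sample_age": [62.0, 60.0, 70.0, 55.0, 55.0],
        })
        out = first_sample_selection(df)
        assert dict(zip(out["patient_id"], out["sample_id"])) == \
            {"p1": "s1", "p2": "s9", "p3": "sA"}

    def test_all_missing_age_dropped(self, caplog):
        df = pd.DataFrame({"patient_id": ["p1", "p2"],
                           "sample_id": ["s1", "s2"],
                           "sample_age": [np.nan, 50.0]})
        with caplog.at_level("WARNING"):
            out = first_sample_selection(df)
        assert list(out["patient_id"]) == ["p2"]
        assert "p1" in caplog.text


class TestPackYearBins:
    @pytest.mark.parametrize("py,bin_", [
        (0, "never"), (0.5, "1-15"), (15, "1-15"), (16, "16-30"), (30, "16-30"),
        (31, "31-45"), (45, "31-45"), (45.5, "46-59"), (59.5, "46-59"),
        (60, "60+"), (120, "60+"), (None, None), (np.nan, None),
    ])
    def test_bin_edges(self, py, bin_):
        assert bin_pack_years(py) == bin_ or (bin_ is None and bin_pack_years(py) is None)

    def test_vectorised(self):
        out = bin_pack_years(pd.Series([0.0, 10.0, np.nan, 60.0]))
        assert list(out) == ["never", "1-15", None, "60+"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bin_pack_years(-1.0)

    @given(st.floats(min_value=0, max_value=200, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bins_partition_nonnegative_reals(self, py):
        assert bin_pack_years(py) in ("never", "1-15", "16-30", "31-45",
                                      "46-59", "60+")


class TestFisherExact:
    def test_exchangeable_table(self):
        r = fisher_exact([[5, 5], [5, 5]])
        assert r.estimate == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_aj_met_enrichment_table(self):
        # 20/215 vs 97/2622 altered: prints as a 2.7-fold enrichment
        r = fisher_exact([[20, 195], [97, 2525]])
        assert r.estimate == pytest.approx(2.67, abs=0.005)
        assert round(r.estimate, 1) == 2.7
        assert r.p < 0.001
        assert r.ci_low <= r.estimate_cmle <= r.ci_high

    def test_never_smoker_lusc_table(self):
        # 6/32 never smokers vs 12/305 smokers altered; the exact two-sided
        # p is 0.00373 (frozen from the hypergeometric enumeration oracle)
        r = fisher_exact([[6, 26], [12, 293]])
        assert r.p == pytest.approx(fisher_p_enumeration(6, 26, 12, 293), abs=1e-10)
        assert r.p == pytest.approx(0.00373, abs=1e-4)
        assert r.p < 0.005

    def test_zero_cell_or_and_ci(self):
        r = fisher_exact([[0, 24], [429, 1966]])
        assert r.estimate == 0.0
        assert r.ci_low == 0.0
        assert 0 < r.ci_high < 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_p_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 9, size=4)
            if t.sum() <= 30 and t.reshape(2, 2).sum(0).all() and \
               t.reshape(2, 2).sum(1).all():
                break
        a, b, c, d = (int(v) for v in t)
        r = fisher_exact([[a, b], [c, d]])
        assert r.p == pytest.approx(fisher_p_enumeration(a, b, c, d), abs=1e-10)

    @given(st.integers(1, 20), st.integers(1, 20), st.integers(1, 20),
           st.integers(1, 20))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        r1 = fisher_exact([[a, b], [c, d]])
        r2 = fisher_exact([[d, c], [b, a]])  # swap both rows and columns
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert r1.estimate == pytest.approx(r2.estimate, rel=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])


class TestLogisticFit:
    def test_two_by_two_identity_with_sample_or(self):
        # single binary covariate: logistic MLE OR equals ad/bc
        a, b, c, d = 20, 195, 97, 2525
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        res = logistic_fit(y, pd.DataFrame({"x": x}))["x"]
        assert res.estimate == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_matches_independent_optimizer(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(80, 3))
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.3 + X @ [0.5, -1.0, 0.2])))).astype(float)
        res = logistic_fit(y, pd.DataFrame(X, columns=list("abc")))
        beta = np.array([res["const"].extra["coef"]] +
                        [res[c].extra["coef"] for c in "abc"])
        ll_opt, _ = logistic_loglik_optimum(y, X)
        eta = np.column_stack([np.ones(80), X]) @ beta
        ll_fit = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        assert abs(ll_fit - ll_opt) < 1e-6

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 0.2).astype(float)
        res = logistic_fit(y, pd.DataFrame({"x": x}))["x"]
        assert res.ci_low < 1.0 < res.ci_high
        assert abs(res.extra["z"]) < 3

    def test_separation_triggers_firth(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        res = logistic_fit(y, pd.DataFrame({"x": x}))["x"]
        assert res.method == "logistic_firth"
        assert np.isfinite(res.estimate)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.array([1.0, 0.0]),
                         pd.DataFrame({"a": [1, 2], "b": [3, 4]}))


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.5], 1), [0.5])
        q = bonferroni_adjust([0.01], 8)
        assert q[0] == pytest.approx(0.08)
        assert q[0] < 0.1
        assert bonferroni_adjust([0.3], 8)[0] == 1.0

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, ps):
        q = bonferroni_adjust(ps)
        assert (q <= 1.0).all() and (q >= np.asarray(ps)).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5], 0)


class TestSummarize:
    def test_lusc_any_targetable_pct(self):
        cohort = build_fixture_cohort([
            {"histology": "LUSC", "n": 337,
             "alterations": {"KRAS_G12C": 7, "EGFR_sens": 3, "MET_alt": 5,
                             "ALK_fus": 3}}])
        tab = summarize_cohort(cohort, strata=["histology"])
        row = tab[(tab["histology"] == "LUSC")
                  & (tab["alteration"] == "any_targetable")].iloc[0]
        assert (row["count"], row["denom"]) == (18, 337)
        assert round(row["pct"], 1) == 5.3

    def test_never_light_luad_by_ancestry(self):
        cohort = build_fixture_cohort([
            {"ancestry_group": "Asian", "n": 102,
             "alterations": {"EGFR_sens": 65, "KRAS_G12C": 2, "ALK_fus": 15}},
            {"ancestry_group": "African", "n": 59,
             "alterations": {"EGFR_sens": 18, "KRAS_G12C": 6, "MET_alt": 5}},
        ])
        tab = summarize_cohort(cohort, strata=["ancestry_group"])
        any_ = tab[tab["alteration"] == "any_targetable"].set_index("ancestry_group")
        assert round(any_.loc["Asian", "pct"]) == 80
        assert round(any_.loc["African", "pct"]) == 49

    def test_counts_recoverable_from_pct(self):
        cohort = build_fixture_cohort([
            {"n": 337, "alterations": {"EGFR_sens": 18}}])
        tab = summarize_cohort(cohort)
        for _, r in tab.iterrows():
            assert round(r["pct"] * r["denom"] / 100) == r["count"]

    def test_empty_cohort(self):
        tab = summarize_cohort(build_fixture_cohort([]))
        assert len(tab) == 0 or tab["denom"].eq(0).all()


class TestCompareTmb:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = compare_tmb(a, a)
        assert r.median_a == r.median_b
        assert r.p == pytest.approx(1.0)

    def test_all_tied_warns(self):
        with pytest.warns(UserWarning, match="tied"):
            r = compare_tmb(np.ones(5), np.ones(5))
        assert r.p == 1.0

    def test_shifted_lognormal_power(self):
        rng = np.random.default_rng(30)
        a = np.exp(rng.normal(np.log(6.1), 0.8, 215))
        b = np.exp(rng.normal(np.log(9.6), 0.8, 2622))
        r = compare_tmb(a, b)
        assert r.median_a < r.median_b
        assert r.p < 1e-4

    def test_small_n_matches_permutation_enumeration(self):
        rng = np.random.default_rng(31)
        a = rng.normal(size=4)
        b = rng.normal(size=4) + 0.5
        r = compare_tmb(a, b)
        assert r.p == pytest.approx(ranksum_p_enumeration(a, b), abs=1e-9)

    def test_packyear_adjusted_p(self):
        rng = np.random.default_rng(32)
        py_a = rng.uniform(0, 40, 100)
        py_b = rng.uniform(0, 40, 100)
        a = np.exp(rng.normal(np.log(6.0) + 0.01 * py_a, 0.4))
        b = np.exp(rng.normal(np.log(9.0) + 0.01 * py_b, 0.4))
        r = compare_tmb(a, b, py_a, py_b)
        assert r.p_adjusted is not None and r.p_adjusted < 0.01
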