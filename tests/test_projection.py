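"""SNP-weight training, projection, rescaling, thresholds, group calls."""
import numpy as np
import pandas as pd
import pytest

from panelancestry import (ReferencePanel, assign_groups, binary_auc,
                           four_sd_thresholds, project_scores, rescale_scores,
                           score_concordance, simulate_admixed_cohort,
                           simulate_reference_panel, train_snp_weights)


def _two_pop_panel_with_marker(m=40, n_hap=20, seed=0):
    """Two populations sharing noise sites plus one fully differentiated site."""
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.3, 0.7, m)
    hapA = (rng.random((n_hap, m)) < freq).astype(np.uint8)
    hapB = (rng.random((n_hap, m)) < freq).astype(np.uint8)
    hap = np.vstack([hapA, hapB])
    hap[:n_hap, 0] = 0   # marker site: fixed difference
    hap[n_hap:, 0] = 1
    sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1) * 10,
                          "ref": "A", "alt": "C"})
    labels = np.array(["EUR"] * n_hap + ["AFR"] * n_hap)
    return ReferencePanel(sites=sites, haplotypes=hap, pop_label=labels)


class TestTrainWeights:
    def test_fixed_difference_site_gets_top_weight(self):
        panel = _two_pop_panel_with_marker(seed=1)
        ws = train_snp_weights(panel, axes_spec={"african": ("AFR", "EUR")})
        w = ws.weights["african"].to_numpy()
        assert np.abs(w).argmax() == 0

    def test_self_projection_separates_reference_pops(self):
        panel = simulate_reference_panel(fst=0.1, m_sites=2000,
                                         n_hap_per_pop=40, subpop=None, seed=2)
        ws = train_snp_weights(panel)
        G, pops = panel.diploid_genotypes()
        raw = project_scores(G.astype(float)[:, ws.site_index], ws)
        for axis, pop in (("african", "AFR"), ("asian", "EAS")):
            auc = binary_auc(raw[axis], pops == pop)
            assert auc == 1.0

    def test_weights_invariant_to_site_permutation(self, small_panel):
        ws = train_snp_weights(small_panel)
        m = small_panel.n_sites
        perm = np.random.default_rng(3).permutation(m)
        sites2 = small_panel.sites.iloc[perm].reset_index(drop=True)
        sites2["pos"] = np.arange(1, m + 1) * 10
        panel2 = ReferencePanel(sites=sites2,
                                haplotypes=small_panel.haplotypes[:, perm],
                                pop_label=small_panel.pop_label,
                                subpop=small_panel.subpop,
                                subpop_parent=small_panel.subpop_parent)
        ws2 = train_snp_weights(panel2)
        orig = perm[ws2.site_index]          # permuted -> original coordinates
        order = np.argsort(orig)
        np.testing.assert_array_equal(orig[order], ws.site_index)
        for axis in ws.axes:
            a = ws.weights[axis].to_numpy()
            b = ws2.weights[axis].to_numpy()[order]
            sign = np.sign(np.dot(a, b))
            np.testing.assert_allclose(a, sign * b, atol=1e-8)

    def test_degenerate_panel_rejected(self):
        # every individual heterozygous everywhere: p = 0.5 but zero
        # genotypic variance across individuals
        sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 13) * 10,
                              "ref": "A", "alt": "C"})
        hap = np.zeros((8, 12), dtype=np.uint8)
        hap[1::2, :] = 1
        panel = ReferencePanel(sites=sites, haplotypes=hap,
                               pop_label=np.array(["A"] * 4 + ["B"] * 4))
        with pytest.raises(ValueError, match="degenerate"):
            train_snp_weights(panel, axes_spec={"x": ("A", "B")})

    def test_too_few_sites_rejected(self, small_panel):
        mask = np.zeros(small_panel.n_sites, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="retained sites"):
            train_snp_weights(small_panel, site_mask=mask)


class TestProjection:
    def test_dosage_at_2p_scores_zero(self, small_panel):
        ws = train_snp_weights(small_panel)
        D = np.tile(2 * ws.p, (3, 1))
        raw = project_scores(D, ws)
        np.testing.assert_allclose(raw.to_numpy(), 0.0, atol=1e-12)

    def test_admixed_individual_scores_at_midpoint(self):
        panel = simulate_reference_panel(fst=0.15, m_sites=3000,
                                         n_hap_per_pop=40, subpop=None, seed=4)
        ws = train_snp_weights(panel, axes_spec={"african": ("AFR", "EUR")})
        rng = np.random.default_rng(5)
        pa = panel.pop_af.loc["AFR"].to_numpy()[ws.site_index]
        pe = panel.pop_af.loc["EUR"].to_numpy()[ws.site_index]
        n = 40
        g_afr = rng.binomial(2, pa, (n, ws.n_sites)).astype(float)
        g_eur = rng.binomial(2, pe, (n, ws.n_sites)).astype(float)
        g_mix = (rng.binomial(1, pa, (n, ws.n_sites))
                 + rng.binomial(1, pe, (n, ws.n_sites))).astype(float)
        s_afr = project_scores(g_afr, ws)["african"].mean()
        s_eur = project_scores(g_eur, ws)["african"].mean()
        s_mix = project_scores(g_mix, ws)["african"].mean()
        mid = 0.5 * (s_afr + s_eur)
        assert abs(s_mix - mid) < 0.1 * abs(s_afr - s_eur)

    def test_half_site_subsample_stability(self, small_panel):
        truth = simulate_admixed_cohort(small_panel, 30, 0.1, seed=6)
        ws = train_snp_weights(small_panel)
        G = truth.genotypes.astype(float)[:, ws.site_index]
        full = project_scores(G, ws)["african"].to_numpy()
        rng = np.random.default_rng(7)
        keep = rng.random(ws.n_sites) < 0.5
        Gh = G.copy()
        Gh[:, ~keep] = np.nan
        half = project_scores(Gh, ws)["african"].to_numpy()
        # induced per-individual standard error from site-level spread
        w = ws.weights["african"].to_numpy()
        Z = (G - 2 * ws.p) / np.sqrt(2 * ws.p * (1 - ws.p))
        contrib = Z * w
        se = contrib[:, keep].std(axis=1) / np.sqrt(keep.sum())
        rms_delta = np.sqrt(np.mean((half - full) ** 2))
        assert rms_delta < 3 * np.sqrt(np.mean(se ** 2))

    def test_rescaled_score_linear_in_admixture(self):
        # regression of the rescaled continental score on the true
        # ancestry fraction: slope 100 +/- 5 and R^2 >= 0.95
        panel = simulate_reference_panel(m_sites=1500, n_hap_per_pop=40,
                                         subpop=None, seed=11)
        truth = simulate_admixed_cohort(panel, 150, 0.1, seed=12)
        ws = train_snp_weights(panel, axes_spec={"african": ("AFR", "EUR")})
        raw = project_scores(truth.genotypes.astype(float)[:, ws.site_index], ws)
        # near-pure anchors isolate the linearity property from anchor
        # impurity (anchoring on 80 %-pure groups inflates the slope)
        anchors = {"african": (truth.fraction("EUR") >= 0.95,
                               truth.fraction("AFR") >= 0.95)}
        scaled, _ = rescale_scores(raw, anchors)
        x = truth.fraction("AFR")
        y = scaled["african_pct"].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(100.0, abs=5.0)
        assert r2 >= 0.95

    def test_empty_intersection_rejected(self, small_panel):
        ws = train_snp_weights(small_panel)
        with pytest.raises(ValueError):
            project_scores(np.zeros((2, 3)), ws)


class TestRescaling:
    def _raw(self):
        rng = np.random.default_rng(8)
        raw = pd.DataFrame({"african": rng.normal(0, 1, 100)})
        zero = np.zeros(100, bool)
        high = np.zeros(100, bool)
        zero[:40] = True
        high[40:80] = True
        return raw, {"african": (zero, high)}

    def test_anchor_means_exact(self):
        raw, anchors = self._raw()
        scaled, params = rescale_scores(raw, anchors)
        zero, high = anchors["african"]
        assert scaled["african_pct"][zero].mean() == pytest.approx(0.0, abs=1e-12)
        assert scaled["african_pct"][high].mean() == pytest.approx(100.0, abs=1e-10)

    def test_affine_invariance(self):
        raw, anchors = self._raw()
        a, _ = rescale_scores(raw, anchors)
        b, _ = rescale_scores(raw * -3.7 + 42.0, anchors)
        pd.testing.assert_frame_equal(a, b)

    def test_identity_when_anchors_already_calibrated(self):
        raw, anchors = self._raw()
        scaled, _ = rescale_scores(raw, anchors)
        again, params = rescale_scores(
            scaled.rename(columns={"african_pct": "african"}), anchors)
        pd.testing.assert_frame_equal(scaled, again)
        assert params["african"]["slope"] == pytest.approx(1.0)

    def test_aj_axis_targets_unity(self):
        rng = np.random.default_rng(9)
        raw = pd.DataFrame({"aj": rng.normal(0, 1, 50)})
        zero = np.arange(50) < 25
        scaled, _ = rescale_scores(raw, {"aj": (zero, ~zero)})
        assert scaled["aj_score"][~zero].mean() == pytest.approx(1.0)

    def test_coincident_anchor_means_rejected(self):
        raw = pd.DataFrame({"african": np.ones(10)})
        zero = np.arange(10) < 5
        with pytest.raises(ValueError, match="slope"):
            rescale_scores(raw, {"african": (zero, ~zero)})


class TestThresholdsAndGroups:
    def test_four_sd_thresholds(self):
        scores = pd.DataFrame({"african_pct": [-5.0, 5.0, -5.0, 5.0, 50.0],
                               "asian_pct": [-3.75, 3.75, -3.75, 3.75, 60.0]})
        anchor = np.array([True, True, True, True, False])
        thr = four_sd_thresholds(scores, anchor)
        assert thr["african_pct"] == pytest.approx(20.0)
        assert thr["asian_pct"] == pytest.approx(15.0)

    def test_four_sd_degenerate_warns(self):
        scores = pd.DataFrame({"african_pct": np.zeros(4)})
        with pytest.warns(UserWarning, match="degenerate"):
            thr = four_sd_thresholds(scores, np.ones(4, bool))
        assert thr["african_pct"] == 0.0

    @pytest.mark.parametrize("afr,asn,aj,expect_eur,expect_aj", [
        (10, 5, 0.2, True, False),
        (50, 5, 0.2, False, False),
        (5, 5, 0.8, True, True),
        (20, 5, 0.9, False, False),   # boundary: strict african < 20
        (5, 15, 0.9, False, False),   # boundary: strict asian < 15
        (5, 5, 0.75, True, False),    # boundary: strict aj > 0.75
        (30, 5, 0.9, False, False),   # AJ only evaluated within Europeans
    ])
    def test_group_assignment(self, afr, asn, aj, expect_eur, expect_aj):
        scores = pd.DataFrame({"african_pct": [afr], "asian_pct": [asn],
                               "aj_score": [aj]})
        g = assign_groups(scores)
        assert bool(g["is_european"][0]) is expect_eur
        assert bool(g["is_aj"][0]) is expect_aj


class TestConcordanceAndAuc:
    def test_pearson_identity_and_sign(self):
        x = np.arange(10.0)
        assert score_concordance(x, x) == pytest.approx(1.0)
        assert score_concordance(x, -x) == pytest.approx(-1.0)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            score_concordance(np.ones(5), np.arange(5.0))

    def test_auc_perfect_separation(self):
        score = np.r_[np.zeros(5), np.ones(5)]
        label = score > 0.5
        assert binary_auc(score, label) == 1.0

    def test_auc_null_near_half(self):
        rng = np.random.default_rng(10)
        score = rng.normal(size=1000)
        label = rng.random(1000) < 0.5
        assert binary_auc(score, label) == pytest.approx(0.5, abs=0.05)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_auc(np.arange(4.0), np.ones(4, bool))
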