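"""Cluster-robust screens, mixed models, trends, residualization."""

import numpy as np
import pandas as pd
import pytest

from ppbc import (GeneratorConfig, bonferroni_flag, fit_marker_tslb,
                  fit_mixed_marker, generate_cohort, generate_roi_markers,
                  ordinal_trend, residual_correlations, residualize)
from ppbc.regression import MarkerScreenResult, marker_columns

CONF = ["age_dx", "n_children", "breastfed", "menopause", "fam_hx", "bmi"]


def _toy_cohort_rois():
    """4 parous women, 1 ROI each, one binary 'confounder' x."""
    cohort = pd.DataFrame({
        "woman_id": list("abcd"),
        "age_dx": [35.0] * 4,
        "parous": [True] * 4,
        "tslb": [1.0, 2.0, 3.0, 4.0],
        "tslb_cat": pd.Categorical(["0-3", "0-3", "0-3", "3-5"]),
        "subtype": ["luminal A"] * 4,
        "x": [0.0, 0.0, 1.0, 1.0],
    })
    rois = pd.DataFrame({
        "roi_id": [f"r{i}" for i in range(4)],
        "woman_id": list("abcd"),
        "segment": ["keratin_rich"] * 4,
        "y": [1.0, 2.0, 3.0, 4.0],
    })
    return cohort, rois


class TestResidualize:
    def test_four_point_worked_example(self):
        cohort, rois = _toy_cohort_rois()
        res = residualize(rois, cohort, ["x"])
        # OLS of (1,2,3,4) on intercept + (0,0,1,1): fitted (1.5,1.5,3.5,3.5)
        assert res["y"].tolist() == pytest.approx([-0.5, 0.5, -0.5, 0.5])

    def test_no_confounders_gives_centered_values(self):
        cohort, rois = _toy_cohort_rois()
        res = residualize(rois, cohort, [])
        assert res["y"].tolist() == pytest.approx([-1.5, -0.5, 0.5, 1.5])

    def test_orthogonality_and_zero_mean(self, small_dataset):
        cfg, cohort, rois = small_dataset
        res = residualize(rois, cohort, CONF)
        merged = res.merge(cohort, on="woman_id")
        markers = marker_columns(rois)
        assert np.abs(res[markers].mean()).max() < 1e-10
        scale = res[markers].abs().to_numpy().max() * len(res)
        for col in ("age_dx", "bmi", "n_children"):
            dots = res[markers].to_numpy().T @ merged[col].to_numpy()
            assert np.abs(dots).max() < 1e-8 * scale
        # orthogonal to categorical blocks: residual means per level vanish
        for lev, grp in merged.groupby("menopause", observed=True):
            assert np.abs(grp[markers].sum()).max() < 1e-8 * scale

    def test_singular_design_names_columns(self):
        cohort, rois = _toy_cohort_rois()
        cohort = cohort.assign(x2=cohort["x"])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            residualize(rois, cohort, ["x", "x2"])


class TestClusterRobustScreen:
    def test_singleton_clusters_cr0_equals_hc0(self):
        import statsmodels.api as sm

        cfg = GeneratorConfig(seed=13, n_parous=100, n_nulliparous=0,
                              p_markers=2, marker_names=["a", "b"],
                              roi_count_probs=(1.0, 0.0, 0.0, 0.0),
                              tslb_effects={}, woman_sd=0.0,
                              factor_loadings=np.zeros((2, 1)))
        cohort = generate_cohort(cfg)
        rois = generate_roi_markers(cohort, cfg)
        [res_a, _] = fit_marker_tslb(rois, cohort, [], robust="CR0")
        merged = rois.merge(cohort[["woman_id", "tslb"]], on="woman_id")
        X = sm.add_constant(merged["tslb"].to_numpy())
        hc0 = sm.OLS(merged["a"].to_numpy(), X).fit(cov_type="HC0")
        assert res_a.se_robust == pytest.approx(float(hc0.bse[1]), rel=1e-10)

    def test_matches_hand_rolled_cr1_sandwich(self, small_dataset):
        cfg, cohort, rois = small_dataset
        [res] = [r for r in fit_marker_tslb(rois, cohort, ["age_dx"])
                 if r.marker == "PR"]
        merged = rois.merge(cohort[["woman_id", "tslb", "age_dx", "parous"]],
                            on="woman_id")
        merged = merged[merged["parous"]]
        X = np.column_stack([np.ones(len(merged)), merged["tslb"],
                             merged["age_dx"]])
        y = merged["PR"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        u = y - X @ beta
        xtx_inv = np.linalg.inv(X.T @ X)
        meat = np.zeros((3, 3))
        for _, idx in merged.groupby("woman_id").indices.items():
            s = (X[idx] * u[idx, None]).sum(axis=0)
            meat += np.outer(s, s)
        g, n, k = merged["woman_id"].nunique(), len(merged), 3
        V = g / (g - 1) * (n - 1) / (n - k) * xtx_inv @ meat @ xtx_inv
        assert res.slope == pytest.approx(beta[1], rel=1e-10)
        assert res.se_robust == pytest.approx(np.sqrt(V[1, 1]), rel=1e-8)
        from scipy import stats
        p_oracle = 2 * stats.t.sf(abs(beta[1] / np.sqrt(V[1, 1])), g - 1)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-8)

    def test_requires_two_clusters(self):
        cohort, rois = _toy_cohort_rois()
        one = cohort.iloc[:1]
        with pytest.raises(ValueError, match="clusters"):
            fit_marker_tslb(rois[rois.woman_id == "a"], one, [])

    def test_subtype_adjusted_tag_and_counts(self, small_dataset):
        cfg, cohort, rois = small_dataset
        results = fit_marker_tslb(rois, cohort, CONF, adjust_subtype=True)
        assert all(r.model_tag == "subtype_adjusted" for r in results)
        assert all(r.n_roi >= r.n_women for r in results)


class TestMixedModel:
    def test_zero_variance_component_matches_ols(self):
        cfg = GeneratorConfig(seed=14, n_parous=150, n_nulliparous=0,
                              p_markers=2, marker_names=["a", "b"],
                              tslb_effects={}, woman_sd=0.0,
                              factor_loadings=np.zeros((2, 1)))
        cohort = generate_cohort(cfg)
        rois = generate_roi_markers(cohort, cfg)
        mixed = fit_mixed_marker(rois, cohort, "breastfed")
        assert all(r.icc == pytest.approx(0.0, abs=0.05) for r in mixed)
        import statsmodels.formula.api as smf
        merged = rois.merge(cohort, on="woman_id")
        ols = smf.ols("a ~ C(breastfed) + age_dx", data=merged).fit()
        [ra] = [r for r in mixed if r.marker == "a"]
        assert ra.slope == pytest.approx(
            ols.params["C(breastfed)[T.True]"], abs=0.02)

    def test_icc_recovery(self):
        cfg = GeneratorConfig(seed=15, n_parous=250, n_nulliparous=0,
                              p_markers=2, marker_names=["a", "b"],
                              tslb_effects={}, woman_sd=0.5, noise_sd=0.5,
                              factor_loadings=np.zeros((2, 1)),
                              roi_count_probs=(0.0, 0.3, 0.4, 0.3))
        cohort = generate_cohort(cfg)
        rois = generate_roi_markers(cohort, cfg)
        mixed = fit_mixed_marker(rois, cohort, "breastfed")
        for r in mixed:  # ICC oracle: 0.25/(0.25+0.25)
            assert r.icc == pytest.approx(0.5, abs=0.12)

    def test_roi_order_permutation_invariance(self, small_dataset):
        cfg, cohort, rois = small_dataset
        shuffled = rois.sample(frac=1.0, random_state=3)
        a = fit_mixed_marker(rois, cohort, "breastfed")
        b = fit_mixed_marker(shuffled, cohort, "breastfed")
        for ra, rb in zip(a, b):
            assert ra.slope == pytest.approx(rb.slope, rel=1e-6)
            assert ra.p_value == pytest.approx(rb.p_value, rel=1e-5)


class TestOrdinalTrend:
    def test_nulliparas_take_highest_score_and_signs_agree(self):
        cfg = GeneratorConfig(seed=16, n_parous=250, n_nulliparous=150,
                              p_markers=3,
                              marker_names=["up", "down", "flat"],
                              tslb_effects={"up": 0.08, "down": -0.08},
                              factor_loadings=np.zeros((3, 1)))
        cohort = generate_cohort(cfg)
        rois = generate_roi_markers(cohort, cfg)
        trend = ordinal_trend(rois, cohort, ["age_dx"],
                              include_nulliparous=False)
        cont = fit_marker_tslb(rois, cohort, ["age_dx"])
        for t, c in zip(trend, cont):
            if t.marker != "flat":
                assert np.sign(t.slope) == np.sign(c.slope)
        # nulliparas have zero slope contribution: folding them in as the
        # longest-TSLB category attenuates but keeps a detectable trend row
        all_women = ordinal_trend(rois, cohort, ["age_dx"],
                                  include_nulliparous=True)
        assert all(r.n_roi > t.n_roi for r, t in zip(all_women, trend))
        assert all(r.ci_low is not None and r.ci_high is not None
                   for r in all_women)

    def test_stratified_fits_label_strata(self, small_dataset):
        cfg, cohort, rois = small_dataset
        rows = ordinal_trend(rois, cohort, ["age_dx"],
                             stratify_by_subtype=True)
        assert {r.stratum for r in rows} <= set(
            cohort["subtype"].cat.categories)
        assert all(r.stratum is not None for r in rows)


class TestResidualCorrelations:
    def test_unit_diagonal_and_symmetry(self, small_dataset):
        cfg, cohort, rois = small_dataset
        res = residualize(rois, cohort, CONF)
        corr = residual_correlations(res)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)
        assert -1 <= corr.attrs["min_offdiag"] <= corr.attrs["max_offdiag"] <= 1

    def test_sign_flip_negates_row_and_column(self, small_dataset):
        cfg, cohort, rois = small_dataset
        res = residualize(rois, cohort, CONF)
        corr = residual_correlations(res)
        m = marker_columns(rois)[0]
        flipped = res.assign(**{m: -res[m]})
        corr_f = residual_correlations(flipped)
        others = [c for c in marker_columns(rois) if c != m]
        assert np.allclose(corr_f.loc[m, others], -corr.loc[m, others])

    def test_one_factor_model_matches_analytic_correlation(self):
        # two markers with loadings l1, l2 on one factor, noise s:
        # r = l1*l2 / sqrt((l1^2+s^2)(l2^2+s^2))
        l1, l2, s = 1.2, 0.8, 0.5
        cfg = GeneratorConfig(seed=17, n_parous=3000, n_nulliparous=0,
                              p_markers=2, marker_names=["a", "b"],
                              tslb_effects={}, woman_sd=0.0, noise_sd=s,
                              factor_loadings=np.array([[l1], [l2]]),
                              roi_count_probs=(1.0, 0.0, 0.0, 0.0))
        cohort = generate_cohort(cfg)
        rois = generate_roi_markers(cohort, cfg)
        res = residualize(rois, cohort, [])
        r = residual_correlations(res).loc["a", "b"]
        expected = l1 * l2 / np.sqrt((l1**2 + s**2) * (l2**2 + s**2))
        assert r == pytest.approx(expected, abs=0.03)


class TestBonferroni:
    def _mk(self, p):
        return MarkerScreenResult(marker="m", slope=0.0, se_robust=1.0,
                                  t_stat=0.0, p_value=p, n_roi=10, n_women=5)

    def test_printed_threshold_for_48_markers(self):
        results = [self._mk(3.00e-4)] + [self._mk(0.5)] * 46 + [self._mk(3.00e-3)]
        flagged = bonferroni_flag(results, alpha=0.05)
        assert flagged[0].m_tests == 48
        assert flagged[0].bonferroni_sig  # 3e-4 <= 0.05/48 ~ 1.0417e-3
        assert not flagged[-1].bonferroni_sig  # 3e-3 > threshold

    def test_single_test_uses_raw_alpha(self):
        [r] = bonferroni_flag([self._mk(0.04)], alpha=0.05)
        assert r.bonferroni_sig

    def test_threshold_monotone_in_m(self):
        thresholds = []
        for m in (1, 10, 48, 53):
            rs = bonferroni_flag([self._mk(0.5) for _ in range(m)], 0.05)
            thresholds.append(0.05 / rs[0].m_tests)
        assert thresholds == sorted(thresholds, reverse=True)
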