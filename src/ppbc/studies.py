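"""Reproducible simulation studies validating the pipeline's inference.

Each study generates data from a known truth, runs the corresponding
pipeline stage, and reports operating characteristics: type-I error of the
cluster-robust marker screen (and of the naive OLS variance it replaces),
bias of recovered TSLB slopes, calibration of the SIR marginal dimension
test, and calibration/power of the bootstrap coordinate test. They are used
by the test suite and the reproduction script; all take explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .config import GeneratorConfig
from .sir import _sir_core, coordinate_test, fit_sir, marginal_dimension_test
from .synthetic import generate_cohort, generate_roi_markers

__all__ = [
    "slope_recovery_study",
    "dimension_null_study",
    "dimension_two_index_study",
    "coordinate_test_study",
]

#: Marker panel of the slope-recovery study: the two published effect
#: magnitudes (log2 per year) plus null markers for calibration.
_STUDY_MARKERS = ["PR", "CD20", "null_1", "null_2", "null_3"]
_STUDY_EFFECTS = {"PR": 0.06, "CD20": -0.04}


def slope_recovery_study(n_rep: int = 200, seed: int = 0, n_parous: int = 336,
                         alpha: float = 0.05) -> dict:
    """Recover generator slopes with the cluster-robust screen.

    Each replicate draws a cohort of ``n_parous`` parous women with repeated
    ROIs, a per-woman random intercept (so naive OLS variance is wrong), and
    TSLB effects of +0.06 (PR) and -0.04 (CD20) log2/yr; the screen model is
    OLS of each marker on TSLB adjusted for the preset confounders with CR1
    cluster-robust variance on G-1 df. Reports mean/SD of the slope
    estimates and the type-I error of null markers under both the sandwich
    and the naive (model-based) variance.
    """
    p = len(_STUDY_MARKERS)
    slopes = {m: [] for m in _STUDY_MARKERS}
    robust_reject, naive_reject = [], []
    conf = ["age_dx", "n_children", "breastfed", "menopause", "fam_hx", "bmi"]
    null_markers = [m for m in _STUDY_MARKERS if m not in _STUDY_EFFECTS]
    for r in range(n_rep):
        cfg = GeneratorConfig(
            seed=seed + 10_000 + r, n_parous=n_parous, n_nulliparous=0,
            p_markers=p, marker_names=list(_STUDY_MARKERS),
            tslb_effects=dict(_STUDY_EFFECTS),
            factor_loadings=np.zeros((p, 1)), woman_sd=0.3, noise_sd=0.5,
        )
        cohort = generate_cohort(cfg)
        rois = generate_roi_markers(cohort, cfg)
        merged = rois.merge(cohort.drop(columns=["tslb_cat", "subtype"]),
                            on="woman_id")
        rhs = "Q('tslb') + " + " + ".join(
            f"C(Q('{c}'))" if merged[c].dtype == object
            or merged[c].dtype == bool
            or isinstance(merged[c].dtype, pd.CategoricalDtype) else f"Q('{c}')"
            for c in conf)
        X = patsy.dmatrix(rhs, merged, return_type="dataframe")
        groups, _ = pd.factorize(merged["woman_id"])
        j = list(X.columns).index("Q('tslb')")
        for m in _STUDY_MARKERS:
            fit = sm.OLS(merged[m].to_numpy(), np.asarray(X)).fit()
            rob = fit.get_robustcov_results(
                cov_type="cluster", groups=groups, use_correction=True,
                use_t=True)
            slopes[m].append(float(np.asarray(rob.params)[j]))
            if m in null_markers:
                robust_reject.append(float(np.asarray(rob.pvalues)[j]) < alpha)
                naive_reject.append(float(np.asarray(fit.pvalues)[j]) < alpha)
    return {
        "mean_slope": {m: float(np.mean(v)) for m, v in slopes.items()},
        "sd_slope": {m: float(np.std(v, ddof=1)) for m, v in slopes.items()},
        "n_rep": n_rep,
        "robust_type1": float(np.mean(robust_reject)),
        "naive_type1": float(np.mean(naive_reject)),
        "true_slopes": dict(_STUDY_EFFECTS),
    }


def dimension_null_study(n_rep: int = 500, n: int = 790, p: int = 10,
                         h: int = 4, alpha: float = 0.05, seed: int = 0
                         ) -> dict:
    """Fraction of pure-noise replicates for which dimension 0 is selected."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        X = rng.standard_normal((n, p))
        codes = rng.integers(0, h, size=n)
        sir = marginal_dimension_test(fit_sir(X, codes), alpha)
        hits += sir.dimension == 0
    return {"rate_d0": hits / n_rep, "n_rep": n_rep, "n": n, "p": p, "h": h}


def dimension_two_index_study(n_rep: int = 100, n: int = 2000, p: int = 10,
                              alpha: float = 0.05, seed: int = 0) -> dict:
    """Planted two-index model: slices are quadrants of two linear indices.

    The response depends on x only through (b1'x, b2'x) with orthonormal b1,
    b2; the four slices are the quadrants of that pair, so both directions
    carry slice-mean signal and the true SIR dimension is 2.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        X = rng.standard_normal((n, p))
        u1, u2 = X[:, 0], X[:, 1]
        codes = (2 * (u1 > 0) + (u2 > 0)).astype(int)
        sir = marginal_dimension_test(fit_sir(X, codes), alpha)
        hits += sir.dimension == 2
    return {"rate_d2": hits / n_rep, "n_rep": n_rep, "n": n, "p": p}


def _coordinate_replicate(rng: np.random.Generator, n_women: int, p: int,
                          rois_per_woman: int, index_noise_sd: float):
    """One clustered single-index dataset: slices from a woman-level index on
    marker 1; markers 2..p are null."""
    w = rng.standard_normal((n_women, p))
    index = w[:, 0] + index_noise_sd * rng.standard_normal(n_women)
    slices_w = np.searchsorted(np.quantile(index, [0.25, 0.5, 0.75]), index)
    rows = np.repeat(np.arange(n_women), rois_per_woman)
    X = w[rows] + 0.5 * rng.standard_normal((len(rows), p))
    return X, slices_w[rows], rows


def coordinate_test_study(n_rep: int = 200, n_women: int = 300, p: int = 6,
                          n_boot: int = 300, alpha: float = 0.05,
                          seed: int = 0) -> dict:
    """Calibration and power of the cluster-bootstrap coordinate Wald test.

    Marker 1 carries the single index that defines the four slices (planted);
    markers 2..p are pure noise (null). Rejections at ``alpha`` are tallied
    per replicate; the returned null rate averages per-replicate null-marker
    rejection fractions so within-replicate correlation cannot masquerade as
    precision.
    """
    rng = np.random.default_rng(seed)
    null_rates, planted_hits = [], []
    for r in range(n_rep):
        X, slices, rows = _coordinate_replicate(rng, n_women, p, 2, 0.3)
        results = coordinate_test(X, slices, d=1, n_boot=n_boot,
                                  seed=seed + 20_000 + r, clusters=rows,
                                  alpha=alpha, min_boot=min(200, n_boot))
        pvals = np.array([t.p_value for t in results])
        null_rates.append(float(np.mean(pvals[1:] < alpha)))
        planted_hits.append(bool(pvals[0] < alpha))
    return {
        "null_rejection": float(np.mean(null_rates)),
        "null_rejection_se": float(np.std(null_rates, ddof=1)
                                   / np.sqrt(len(null_rates))),
        "planted_power": float(np.mean(planted_hits)),
        "n_rep": n_rep, "n_women": n_women, "n_boot": n_boot,
    }
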