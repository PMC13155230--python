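"""Per-marker association models for TSLB and reproductive factors.

The screening model is ordinary least squares of each log2 marker on
continuous time since last birth (TSLB) plus the selected confounders over
all regions of interest (ROIs), with the coefficient covariance replaced by a
cluster-robust sandwich estimator clustered on woman — ROIs repeat within
women, and the sandwich keeps the TSLB test honest under that within-woman
correlation. The default flavor is CR1 (cluster-count small-sample factor)
with t reference on G-1 degrees of freedom, where G is the number of women;
CR0 is available. Positive slopes mean higher expression with longer TSLB.

Also here: random-intercept mixed models for reproductive factors, ordinal
trend models (optionally folding nulliparas in as the longest-TSLB category
and/or stratifying by molecular subtype), residualization of markers on the
confounders (input to sliced inverse regression), residual correlation
matrices, and Bonferroni flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .config import NULLIPAROUS_CATEGORY, TSLB_CATEGORIES

__all__ = [
    "MarkerScreenResult", "fit_marker_tslb", "fit_mixed_marker",
    "ordinal_trend", "residualize", "residual_correlations",
    "bonferroni_flag", "results_to_frame", "OPAL_ADJUSTERS",
]

logger = logging.getLogger(__name__)

#: Adjustment set of the immunofluorescence replication models: family
#: history of ovarian/breast cancer, age at diagnosis, menopausal status.
OPAL_ADJUSTERS = ["fam_hx", "age_dx", "menopause"]

ID_COLUMNS = ("roi_id", "woman_id", "segment")


@dataclass
class MarkerScreenResult:
    marker: str
    slope: float
    se_robust: float
    t_stat: float
    p_value: float
    n_roi: int
    n_women: int
    model_tag: str = "continuous_tslb"
    bonferroni_sig: bool | None = None
    m_tests: int | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    icc: float | None = None
    stratum: str | None = None
    note: str | None = None

    def __post_init__(self):
        if self.n_roi < self.n_women:
            raise ValueError("n_roi must be >= n_women")


def results_to_frame(results: list[MarkerScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def marker_columns(rois: pd.DataFrame) -> list[str]:
    return [c for c in rois.columns if c not in ID_COLUMNS]


def _merged(rois: pd.DataFrame, cohort: pd.DataFrame,
            covariates: list[str], parous_only: bool = True) -> pd.DataFrame:
    cols = ["woman_id", "parous", "tslb", "tslb_cat", "subtype"] + [
        c for c in covariates if c not in ("tslb", "tslb_cat", "subtype")
    ]
    cols = list(dict.fromkeys(cols))
    merged = rois.merge(cohort[cols], on="woman_id", how="left", validate="m:1")
    if parous_only:
        merged = merged[merged["parous"] & merged["tslb"].notna()]
    need = [c for c in covariates if c in merged.columns]
    merged = merged.dropna(subset=need)
    return merged


def _confounder_terms(cohort: pd.DataFrame, names: list[str]) -> str:
    terms = []
    for c in names:
        s = cohort[c]
        cat = (isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object
               or s.dtype == bool)
        terms.append(f"C(Q('{c}'))" if cat else f"Q('{c}')")
    return " + ".join(terms)


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # identify columns not adding rank, scanning left to right
        bad, kept = [], np.empty((arr.shape[0], 0))
        for j, name in enumerate(X.columns):
            cand = np.column_stack([kept, arr[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(str(name))
            else:
                kept = cand
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {bad}")


def _cluster_fit(y, X, groups, robust: str, df_gminus1: bool = True):
    """OLS with cluster-robust (CR0/CR1) covariance, t on G-1 df."""
    model = sm.OLS(y, X)
    res = model.fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": robust == "CR1",
                  "df_correction": df_gminus1},
        use_t=True,
    )
    return res


def fit_marker_tslb(rois: pd.DataFrame, cohort: pd.DataFrame, confounders,
                    robust: str = "CR1", adjust_subtype: bool = False
                    ) -> list[MarkerScreenResult]:
    """Cluster-robust screen of every marker against continuous TSLB.

    Per marker: OLS of the log2 marker on TSLB + confounders over all ROIs of
    parous women with known TSLB (complete cases), sandwich covariance
    clustered on woman, t-test of the TSLB coefficient with G-1 degrees of
    freedom. ``adjust_subtype`` adds molecular-subtype indicators
    (sensitivity model, tag ``subtype_adjusted``).
    """
    if robust not in ("CR0", "CR1"):
        raise ValueError("robust must be 'CR0' or 'CR1'")
    conf = list(getattr(confounders, "selected", confounders) or [])
    covs = conf + (["subtype"] if adjust_subtype else [])
    merged = _merged(rois, cohort, covs)
    groups = merged["woman_id"].to_numpy()
    n_women = int(pd.unique(groups).size)
    if n_women < 2:
        raise ValueError("need at least 2 clusters (women)")
    rhs = "Q('tslb')"
    if conf:
        rhs += " + " + _confounder_terms(cohort, conf)
    if adjust_subtype:
        rhs += " + C(Q('subtype'))"
    X = patsy.dmatrix(rhs, merged, return_type="dataframe")
    _check_rank(X)
    tag = "subtype_adjusted" if adjust_subtype else "continuous_tslb"

    out: list[MarkerScreenResult] = []
    for m in marker_columns(rois):
        y = merged[m].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("marker %s constant; skipped", m)
            continue
        res = _cluster_fit(y, X, groups, robust)
        j = list(X.columns).index("Q('tslb')")
        ci = res.conf_int()
        out.append(MarkerScreenResult(
            marker=m, slope=float(res.params.iloc[j]),
            se_robust=float(res.bse.iloc[j]), t_stat=float(res.tvalues.iloc[j]),
            p_value=float(res.pvalues.iloc[j]), n_roi=int(len(merged)),
            n_women=n_women, model_tag=tag,
            ci_low=float(ci.iloc[j, 0]), ci_high=float(ci.iloc[j, 1]),
        ))
    return out


def fit_mixed_marker(rois: pd.DataFrame, cohort: pd.DataFrame, factor: str,
                     parous_only: bool = True) -> list[MarkerScreenResult]:
    """Random-intercept mixed model of each marker on a reproductive factor.

    Exchangeable within-woman correlation via a per-woman random intercept;
    the factor's fixed effect is adjusted for age at diagnosis and tested with
    a Wald test (joint, for multi-level factors). The estimated intraclass
    correlation sigma_b^2/(sigma_b^2+sigma_e^2) is reported. Non-convergence
    falls back to OLS with cluster-robust variance (tagged in ``note``).
    """
    merged = _merged(rois, cohort, [factor, "age_dx"], parous_only=parous_only)
    groups = merged["woman_id"].to_numpy()
    n_women = int(pd.unique(groups).size)
    rhs = f"{_confounder_terms(cohort, [factor])} + Q('age_dx')"
    X = patsy.dmatrix(rhs, merged, return_type="dataframe")
    _check_rank(X)
    fac_cols = [i for i, c in enumerate(X.columns) if factor in c]

    out: list[MarkerScreenResult] = []
    for m in marker_columns(rois):
        y = merged[m].to_numpy(dtype=float)
        note = None
        try:
            res = sm.MixedLM(y, np.asarray(X), groups=groups).fit(reml=True)
            if not res.converged:
                raise RuntimeError("no convergence")
            var_b = float(np.asarray(res.cov_re)[0, 0])
            icc = var_b / (var_b + float(res.scale))
            params = np.asarray(res.params)[: X.shape[1]]
            bse = np.asarray(res.bse)[: X.shape[1]]
            contrast = np.zeros((len(fac_cols), len(res.params)))
            for r, c in enumerate(fac_cols):
                contrast[r, c] = 1.0
            wald_p = float(res.wald_test(contrast, scalar=True).pvalue)
        except Exception as exc:
            logger.warning("mixed model for %s failed (%s); OLS fallback", m, exc)
            note = "mixed_fallback_ols"
            res = _cluster_fit(y, X, groups, "CR1")
            icc = float("nan")
            params, bse = np.asarray(res.params), np.asarray(res.bse)
            wald_p = float(res.f_test(np.eye(X.shape[1])[fac_cols]).pvalue)
        j = fac_cols[0]
        out.append(MarkerScreenResult(
            marker=m, slope=float(params[j]), se_robust=float(bse[j]),
            t_stat=float(params[j] / bse[j]) if bse[j] else float("nan"),
            p_value=wald_p, n_roi=int(len(merged)), n_women=n_women,
            model_tag="mixed", icc=icc, note=note,
        ))
    return out


def _ordinal_scores(merged: pd.DataFrame, include_nulliparous: bool) -> np.ndarray:
    mapping = {c: i + 1 for i, c in enumerate(TSLB_CATEGORIES)}
    if include_nulliparous:
        mapping[NULLIPAROUS_CATEGORY] = len(TSLB_CATEGORIES) + 1
    return merged["tslb_cat"].astype(str).map(mapping).to_numpy(dtype=float)


def ordinal_trend(rois: pd.DataFrame, cohort: pd.DataFrame, confounders,
                  include_nulliparous: bool = False,
                  stratify_by_subtype: bool = False,
                  robust: str = "CR1", model_tag: str = "ordinal_trend"
                  ) -> list[MarkerScreenResult]:
    """Linear trend of each marker over the ordered TSLB categories.

    Categories are integer-scored 1..4 (parous) with nulliparas, when
    included, assigned the next (longest-TSLB) score of 5; OLS with the
    confounder adjustment and cluster-robust variance, with 95% confidence
    intervals on the per-category trend slope. With
    ``stratify_by_subtype``, separate fits per molecular subtype (empty or
    single-woman strata are skipped with a log entry). Use with
    ``confounders`` holding :data:`OPAL_ADJUSTERS` and ``model_tag=
    "opal_replication"`` for the replication-style model.
    """
    conf = list(getattr(confounders, "selected", confounders) or [])
    merged = _merged(rois, cohort, conf, parous_only=not include_nulliparous)
    if include_nulliparous:
        merged = merged.dropna(subset=[c for c in conf if c in merged.columns])

    strata = ([(s, merged[merged["subtype"] == s])
               for s in merged["subtype"].dropna().unique()]
              if stratify_by_subtype else [(None, merged)])
    out: list[MarkerScreenResult] = []
    for label, sub in strata:
        if sub["woman_id"].nunique() < 3:
            logger.warning("stratum %s too small; skipped", label)
            continue
        score = _ordinal_scores(sub, include_nulliparous)
        data = sub.assign(_tslb_score=score)
        rhs = "Q('_tslb_score')"
        if conf:
            rhs += " + " + _confounder_terms(cohort, conf)
        X = patsy.dmatrix(rhs, data, return_type="dataframe")
        _check_rank(X)
        groups = data["woman_id"].to_numpy()
        j = list(X.columns).index("Q('_tslb_score')")
        for m in marker_columns(rois):
            y = data[m].to_numpy(dtype=float)
            res = _cluster_fit(y, X, groups, robust)
            ci = res.conf_int()
            out.append(MarkerScreenResult(
                marker=m, slope=float(res.params.iloc[j]),
                se_robust=float(res.bse.iloc[j]),
                t_stat=float(res.tvalues.iloc[j]),
                p_value=float(res.pvalues.iloc[j]),
                n_roi=int(len(data)), n_women=int(pd.unique(groups).size),
                model_tag=model_tag, stratum=None if label is None else str(label),
                ci_low=float(ci.iloc[j, 0]), ci_high=float(ci.iloc[j, 1]),
            ))
    return out


def residualize(rois: pd.DataFrame, cohort: pd.DataFrame, confounders,
                parous_only: bool = True) -> pd.DataFrame:
    """Residuals of every log2 marker on the confounders (TSLB excluded).

    The returned frame keeps the identifier columns of the ROI matrix;
    residuals are exactly orthogonal to every design column (OLS normal
    equations) and mean zero (intercept included).
    """
    conf = list(getattr(confounders, "selected", confounders) or [])
    merged = _merged(rois, cohort, conf, parous_only=parous_only)
    rhs = _confounder_terms(cohort, conf) if conf else "1"
    X = patsy.dmatrix(rhs, merged, return_type="dataframe")
    _check_rank(X)
    markers = marker_columns(rois)
    Y = merged[markers].to_numpy(dtype=float)
    Xa = np.asarray(X, dtype=float)
    beta, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
    resid = Y - Xa @ beta
    out = merged[list(ID_COLUMNS)].reset_index(drop=True)
    return pd.concat(
        [out, pd.DataFrame(resid, columns=markers)], axis=1
    )


def residual_correlations(res: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of marker residuals.

    Zero-variance markers get NaN rows/columns (logged); the diagonal is 1
    elsewhere. The off-diagonal minimum and maximum are attached as
    ``DataFrame.attrs['min_offdiag' / 'max_offdiag']``.
    """
    markers = marker_columns(res)
    vals = res[markers]
    if len(vals) < 3:
        raise ValueError("need at least 3 rows")
    sd = vals.std()
    dead = list(sd.index[sd == 0])
    if dead:
        logger.warning("zero-variance markers, correlation undefined: %s", dead)
    corr = vals.corr()
    for m in dead:
        corr.loc[m, :] = np.nan
        corr.loc[:, m] = np.nan
    off = corr.to_numpy()[~np.eye(len(markers), dtype=bool)]
    off = off[~np.isnan(off)]
    corr.attrs["min_offdiag"] = float(off.min()) if off.size else float("nan")
    corr.attrs["max_offdiag"] = float(off.max()) if off.size else float("nan")
    return corr


def bonferroni_flag(results: list[MarkerScreenResult], alpha: float = 0.05
                    ) -> list[MarkerScreenResult]:
    """Flag results significant at the Bonferroni level alpha/m.

    ``m`` is the number of tested markers in the list (recorded on each
    result); the threshold is monotone decreasing in m.
    """
    m = len(results)
    threshold = alpha / m if m else float("nan")
    for r in results:
        r.m_tests = m
        r.bonferroni_sig = bool(r.p_value <= threshold)
    return results
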