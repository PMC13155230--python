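"""Sliced inverse regression (SIR) for joint marker-TSLB association.

SIR finds linear combinations of the (confounder-residualized) markers that
separate the ordered time-since-last-birth (TSLB) categories, without
assuming a forward regression model. With response slices s = 1..h of weight
p_s = n_s/n and standardized predictors z (centered, whitened by the inverse
square root of the sample covariance), the kernel

    M = sum_s p_s zbar_s zbar_s'

is eigen-decomposed; eigenvalues lie in [0, 1] (they are between-slice
variance fractions of whitened data) and eigenvectors mapped back through the
whitening give the SIR directions in original predictor scale.

Inference:

* marginal dimension test — T_d = n * sum_{j>d} lambda_j referred to a
  chi-square with (p-d)(h-1-d) degrees of freedom, for d = 0, 1, ...; the
  estimated dimension is the smallest non-rejected d.
* coordinate hypothesis test — per-marker Wald test of whether the marker's
  row of the direction matrix (restricted to the retained d components) is
  zero, with the row covariance estimated by a nonparametric bootstrap that
  resamples women (clusters), re-fitting SIR per resample and aligning the
  resampled directions onto the point estimate with an orthogonal Procrustes
  rotation followed by sign fixing.

Slices here are the TSLB categories themselves; an h-quantile mode is
available for continuous responses. Repeated ROIs are treated as independent
observations in the SIR fit itself; the bootstrap respects the within-woman
structure by resampling whole women.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression import ID_COLUMNS, marker_columns

__all__ = [
    "SIRResult", "CoordinateTestResult", "fit_sir", "marginal_dimension_test",
    "coordinate_test", "quantile_slices", "slice_assignments",
]

logger = logging.getLogger(__name__)


@dataclass
class SIRResult:
    slice_labels: list
    slice_weights: np.ndarray  # p_s = n_s / n
    slice_means: np.ndarray  # h x p standardized-predictor means
    kernel_eigenvalues: np.ndarray  # descending, in [0, 1]
    directions: np.ndarray  # p x p, columns in original predictor scale
    n_obs: int
    marker_names: list[str] = field(default_factory=list)
    dimension: int | None = None
    dimension_pvalues: list[float] | None = None
    ridge_eps: float = 0.0

    @property
    def p(self) -> int:
        return self.directions.shape[0]

    @property
    def h(self) -> int:
        return len(self.slice_labels)


@dataclass
class CoordinateTestResult:
    marker: str
    wald_stat: float
    df: int
    p_value: float
    bonferroni_sig: bool = False
    note: str | None = None


def quantile_slices(y: np.ndarray, h: int) -> np.ndarray:
    """h-quantile slice labels for a continuous response."""
    ranks = stats.rankdata(y, method="ordinal") - 1
    return (ranks * h // len(y)).astype(int)


def slice_assignments(res: pd.DataFrame, cohort: pd.DataFrame) -> np.ndarray:
    """TSLB-category slice labels aligned to the rows of a residual matrix."""
    cat = res[["woman_id"]].merge(
        cohort[["woman_id", "tslb_cat"]], on="woman_id", how="left",
        validate="m:1",
    )["tslb_cat"]
    if cat.isna().any():
        raise ValueError("rows with woman_id missing from cohort")
    return cat.astype(str).to_numpy()


def _as_matrix(res) -> tuple[np.ndarray, list[str]]:
    if isinstance(res, pd.DataFrame):
        names = marker_columns(res)
        return res[names].to_numpy(dtype=float), names
    arr = np.asarray(res, dtype=float)
    return arr, [f"x{i + 1}" for i in range(arr.shape[1])]


def _sir_core(X: np.ndarray, codes: np.ndarray, h: int,
              ridge_eps: float = 0.0):
    """Eigenvalues, directions, weights and slice means; the hot path."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / n
    if ridge_eps:
        cov = cov + ridge_eps * np.eye(p)
    w, V = np.linalg.eigh(cov)
    tol = max(w[-1], 1.0) * 1e-12
    if w[0] <= tol:
        bad = [i for i, wi in enumerate(w) if wi <= tol]
        raise np.linalg.LinAlgError(
            f"singular predictor covariance ({len(bad)} null directions); "
            "enable ridge regularization or drop near-collinear markers"
        )
    inv_sqrt = (V / np.sqrt(w)) @ V.T
    Z = Xc @ inv_sqrt
    counts = np.bincount(codes, minlength=h).astype(float)
    present = counts > 0
    weights = counts / n
    means = np.zeros((h, p))
    np.add.at(means, codes, Z)
    means[present] /= counts[present, None]
    M = (means * weights[:, None]).T @ means
    lam, U = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    B = inv_sqrt @ U
    # sign convention: each column's largest-magnitude entry is positive
    signs = np.sign(B[np.abs(B).argmax(axis=0), np.arange(p)])
    signs[signs == 0] = 1.0
    # slice means are reported in whitened coordinates; sign fixing applies
    # to direction columns only
    return lam, B * signs, weights, means


def fit_sir(res, slices, ridge_eps: float | None = None) -> SIRResult:
    """Fit SIR of the residual matrix on the given slice assignment.

    ``res`` is a residual matrix (frame with identifier columns plus one
    column per marker) or a plain array; ``slices`` an aligned label vector
    with at least two non-empty levels. Standardization requires n > p; when
    the sample covariance is singular, pass ``ridge_eps`` to whiten with
    ``cov + ridge_eps * I`` (logged).
    """
    X, names = _as_matrix(res)
    labels_arr = np.asarray(slices)
    if len(labels_arr) != len(X):
        raise ValueError("slices length does not match rows")
    labels, codes = np.unique(labels_arr, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 non-empty slices")
    n, p = X.shape
    eps = float(ridge_eps or 0.0)
    if n <= p and not eps:
        eps = 1e-6
        logger.warning("n_obs=%d <= p=%d: ridge-regularized standardization "
                       "with eps=%g", n, p, eps)
    lam, B, weights, means = _sir_core(X, codes, len(labels), eps)
    lam = np.clip(lam, 0.0, None)
    return SIRResult(
        slice_labels=list(labels), slice_weights=weights, slice_means=means,
        kernel_eigenvalues=lam, directions=B, n_obs=n, marker_names=names,
        ridge_eps=eps,
    )


def marginal_dimension_test(sir: SIRResult, alpha: float = 0.05,
                            d_max: int | None = None) -> SIRResult:
    """Sequential chi-square test on trailing eigenvalues; sets the dimension.

    For candidate dimension d, T_d = n * sum_{j>d} lambda_j is referred to a
    chi-square with (p-d)(h-1-d) degrees of freedom (classical normal-theory
    weights). The estimated dimension is the smallest d whose test is NOT
    rejected at ``alpha``; if every candidate is rejected the dimension is
    min(p, h-1).
    """
    p, h, n = sir.p, sir.h, sir.n_obs
    limit = min(p, h - 1)
    if d_max is None:
        d_max = limit - 1
    if d_max >= limit:
        logger.warning("d_max=%d truncated to %d (= min(p, h-1) - 1)",
                       d_max, limit - 1)
        d_max = limit - 1
    lam = sir.kernel_eigenvalues
    pvals = []
    dimension = None
    for d in range(d_max + 1):
        stat = n * float(lam[d:].sum())
        df = (p - d) * (h - 1 - d)
        pv = float(stats.chi2.sf(stat, df))
        pvals.append(pv)
        if dimension is None and pv > alpha:
            dimension = d
    sir.dimension_pvalues = pvals
    sir.dimension = dimension if dimension is not None else limit
    return sir


def coordinate_test(res, slices, d: int, n_boot: int = 500,
                    seed: int | None = None, clusters=None,
                    alpha: float = 0.05, min_boot: int = 200
                    ) -> list[CoordinateTestResult]:
    """Bootstrap Wald test of each marker's contribution to the SIR subspace.

    For marker k, H0: the k-th row of the direction matrix restricted to the
    first ``d`` components is zero. The row covariance is estimated from
    ``n_boot`` nonparametric bootstrap resamples; ``clusters`` (usually the
    woman identifiers) makes the resampling respect repeated ROIs by drawing
    whole women — pass ``None`` for a naive iid-row bootstrap (sensitivity
    mode). If the residual matrix carries a ``woman_id`` column it is used
    automatically. Each resampled direction matrix is rotated onto the point
    estimate (orthogonal Procrustes) before covariances are formed. Wald
    statistics are referred to chi-square with d degrees of freedom;
    Bonferroni flags use alpha / p_markers.
    """
    if d < 1:
        raise ValueError("coordinate test needs d >= 1")
    if n_boot < min_boot:
        raise ValueError(f"n_boot={n_boot} too small; need >= {min_boot}")
    X, names = _as_matrix(res)
    if clusters is None and isinstance(res, pd.DataFrame) and "woman_id" in res:
        clusters = res["woman_id"].to_numpy()
    labels_arr = np.asarray(slices)
    labels, codes = np.unique(labels_arr, return_inverse=True)
    h = len(labels)
    n, p = X.shape
    if d > min(p, h - 1):
        raise ValueError(f"d={d} exceeds min(p, h-1)={min(p, h - 1)}")
    rng = np.random.default_rng(seed)

    lam0, B0, _, _ = _sir_core(X, codes, h)
    B_hat = B0[:, :d]

    if clusters is not None:
        clusters = np.asarray(clusters)
        uniq, cl_codes = np.unique(clusters, return_inverse=True)
        members = [np.flatnonzero(cl_codes == i) for i in range(len(uniq))]
    boot = np.empty((n_boot, p, d))
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise RuntimeError("bootstrap resampling kept producing "
                               "degenerate (single-slice) samples")
        if clusters is None:
            idx = rng.integers(0, n, size=n)
        else:
            draw = rng.integers(0, len(members), size=len(members))
            idx = np.concatenate([members[i] for i in draw])
        codes_b = codes[idx]
        if len(np.unique(codes_b)) < 2:
            continue
        Xb = X[idx]
        eps = 1e-8 if len(idx) <= p else 0.0
        try:
            _, Bb, _, _ = _sir_core(Xb, codes_b, h, ridge_eps=eps)
        except np.linalg.LinAlgError:
            _, Bb, _, _ = _sir_core(Xb, codes_b, h, ridge_eps=1e-8)
        Bb = Bb[:, :d]
        # orthogonal Procrustes: rotate Bb onto B_hat
        U, _, Vt = np.linalg.svd(Bb.T @ B_hat)
        boot[b] = Bb @ (U @ Vt)
        b += 1

    results: list[CoordinateTestResult] = []
    bonf = alpha / p
    for k, name in enumerate(names):
        V = np.cov(boot[:, k, :], rowvar=False, ddof=1).reshape(d, d)
        bk = B_hat[k]
        note = None
        try:
            w = float(bk @ np.linalg.solve(V, bk))
        except np.linalg.LinAlgError:
            w = float(bk @ np.linalg.pinv(V) @ bk)
            note = "singular bootstrap covariance; pseudo-inverse used"
            logger.warning("marker %s: %s", name, note)
        pv = float(stats.chi2.sf(w, d))
        results.append(CoordinateTestResult(
            marker=name, wald_stat=w, df=d, p_value=pv,
            bonferroni_sig=bool(pv <= bonf), note=note,
        ))
    return results


def coordinate_results_to_frame(results: list[CoordinateTestResult]
                                ) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
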