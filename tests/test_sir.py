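"""Sliced inverse regression: oracle equivalence, invariants, inference."""

import numpy as np
import pytest
from scipy import stats

from ppbc.sir import (coordinate_test, fit_sir, marginal_dimension_test,
                      quantile_slices, slice_assignments)


def sir_by_definition(X, labels):
    """Loop-based oracle: no vectorized shortcuts, definitions only.

    Standardize by the inverse symmetric square root of the (1/n) sample
    covariance; form the between-slice covariance of whitened slice means;
    eigen-decompose.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mean = [sum(X[i, j] for i in range(n)) / n for j in range(p)]
    cov = np.empty((p, p))
    for a in range(p):
        for b in range(p):
            cov[a, b] = sum((X[i, a] - mean[a]) * (X[i, b] - mean[b])
                            for i in range(n)) / n
    w, V = np.linalg.eigh(cov)
    inv_sqrt = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    Z = np.array([[sum(inv_sqrt[j, k] * (X[i, k] - mean[k]) for k in range(p))
                   for j in range(p)] for i in range(n)])
    uniq = sorted(set(labels))
    M = np.zeros((p, p))
    for s in uniq:
        idx = [i for i in range(n) if labels[i] == s]
        zbar = [sum(Z[i, j] for i in idx) / len(idx) for j in range(p)]
        for a in range(p):
            for b in range(p):
                M[a, b] += len(idx) / n * zbar[a] * zbar[b]
    lam, U = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    return lam[order], inv_sqrt @ U[:, order]


@pytest.fixture(scope="module")
def toy_instance():
    rng = np.random.default_rng(20260109)
    n, p = 90, 5
    X = rng.standard_normal((n, p)) @ rng.normal(size=(p, p)) * 0.7
    beta = np.array([1.0, -0.5, 0.0, 0.0, 0.3])
    idx = X @ beta
    labels = np.digitize(idx, np.quantile(idx, [1 / 3, 2 / 3]))
    return X, labels


class TestFitAgainstOracle:
    def test_eigenvalues_match_bydefinition_oracle(self, toy_instance):
        X, labels = toy_instance
        lam_o, B_o = sir_by_definition(X, labels)
        sir = fit_sir(X, labels)
        assert np.allclose(sir.kernel_eigenvalues, lam_o, atol=1e-10)

    def test_directions_span_matches_oracle(self, toy_instance):
        X, labels = toy_instance
        _, B_o = sir_by_definition(X, labels)
        sir = fit_sir(X, labels)
        for j in range(2):  # informative columns (h-1 = 2)
            a, b = sir.directions[:, j], B_o[:, j]
            cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_slice_weights_and_bookkeeping(self, toy_instance):
        X, labels = toy_instance
        sir = fit_sir(X, labels)
        assert sir.slice_weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert sir.n_obs == len(X)
        assert sir.h == 3
        lam = sir.kernel_eigenvalues
        assert np.all(lam >= -1e-10) and np.all(lam <= 1 + 1e-10)
        assert np.all(np.diff(lam) <= 1e-12)
        # at most h-1 nonzero eigenvalues
        assert np.all(lam[2:] < 1e-10)


class TestInvariants:
    def test_affine_rescaling_of_a_marker_is_removed_by_whitening(
            self, toy_instance):
        X, labels = toy_instance
        lam1 = fit_sir(X, labels).kernel_eigenvalues
        X2 = X.copy()
        X2[:, 1] *= 10.0
        lam2 = fit_sir(X2, labels).kernel_eigenvalues
        assert np.allclose(lam1, lam2, atol=1e-8)

    def test_two_slices_give_the_lda_direction(self):
        # with h=2 the single SIR direction is proportional to
        # Sigma^{-1} (mu_1 - mu_0), the two-group discriminant direction
        rng = np.random.default_rng(5)
        n, p = 400, 4
        X = rng.standard_normal((n, p)) @ np.diag([1.0, 2.0, 0.5, 1.5])
        labels = (X[:, 0] + X[:, 2] + rng.standard_normal(n) > 0).astype(int)
        sir = fit_sir(X, labels)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / n
        delta = X[labels == 1].mean(axis=0) - X[labels == 0].mean(axis=0)
        lda = np.linalg.solve(cov, delta)
        d1 = sir.directions[:, 0]
        cos = abs(d1 @ lda) / (np.linalg.norm(d1) * np.linalg.norm(lda))
        assert cos == pytest.approx(1.0, abs=1e-8)
        assert np.all(sir.kernel_eigenvalues[1:] < 1e-10)

    def test_sign_convention(self, toy_instance):
        X, labels = toy_instance
        B = fit_sir(X, labels).directions
        for j in range(B.shape[1]):
            assert B[np.abs(B[:, j]).argmax(), j] > 0

    def test_null_kernel_statistic_is_chi_square(self):
        # response independent of predictors: n * sum(lambda) ~ chi2_{p(h-1)}
        rng = np.random.default_rng(6)
        p, h, n = 5, 3, 300
        stats_ = []
        for _ in range(300):
            X = rng.standard_normal((n, p))
            labels = rng.integers(0, h, size=n)
            sir = fit_sir(X, labels)
            stats_.append(n * sir.kernel_eigenvalues.sum())
        ks = stats.kstest(stats_, stats.chi2(df=p * (h - 1)).cdf)
        assert ks.pvalue > 0.01


class TestDimensionTest:
    def test_statistic_identity(self, toy_instance):
        X, labels = toy_instance
        sir = marginal_dimension_test(fit_sir(X, labels))
        lam = sir.kernel_eigenvalues
        n = sir.n_obs
        for d, pv in enumerate(sir.dimension_pvalues):
            stat = n * (lam.sum() - lam[:d].sum())
            df = (sir.p - d) * (sir.h - 1 - d)
            assert pv == pytest.approx(float(stats.chi2.sf(stat, df)))

    def test_single_index_recovery(self):
        rng = np.random.default_rng(7)
        n, p = 2000, 6
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[0], beta[2] = 1.0, 1.0
        idx = X @ beta + 0.3 * rng.standard_normal(n)
        labels = quantile_slices(idx, 4)
        sir = marginal_dimension_test(fit_sir(X, labels))
        assert sir.dimension == 1
        b1 = sir.directions[:, 0]
        cos = abs(b1 @ beta) / (np.linalg.norm(b1) * np.linalg.norm(beta))
        assert cos > 0.95

    def test_dmax_truncated(self, toy_instance):
        X, labels = toy_instance
        sir = marginal_dimension_test(fit_sir(X, labels), d_max=99)
        assert len(sir.dimension_pvalues) == min(sir.p, sir.h - 1)


class TestCoordinateTest:
    def test_rejects_small_nboot_and_bad_dimension(self, toy_instance):
        X, labels = toy_instance
        with pytest.raises(ValueError, match="too small"):
            coordinate_test(X, labels, d=1, n_boot=50)
        with pytest.raises(ValueError, match="exceeds"):
            coordinate_test(X, labels, d=4, n_boot=300)

    def test_planted_marker_detected_null_markers_not(self):
        rng = np.random.default_rng(8)
        n, p = 800, 5
        X = rng.standard_normal((n, p))
        idx = X[:, 0] + 0.3 * rng.standard_normal(n)
        labels = quantile_slices(idx, 4)
        results = coordinate_test(X, labels, d=1, n_boot=300, seed=9)
        assert results[0].p_value < 1e-4
        assert all(r.df == 1 for r in results)
        assert min(r.p_value for r in results[1:]) > 1e-3

    def test_procrustes_alignment_is_identity_on_point_estimate(
            self, toy_instance):
        X, labels = toy_instance
        sir = fit_sir(X, labels)
        B = sir.directions[:, :2]
        U, _, Vt = np.linalg.svd(B.T @ B)
        R = U @ Vt
        assert np.allclose(R, np.eye(2), atol=1e-10)

    def test_bonferroni_flags_use_marker_count(self):
        rng = np.random.default_rng(10)
        n, p = 600, 4
        X = rng.standard_normal((n, p))
        idx = X[:, 1]
        labels = quantile_slices(idx, 3)
        results = coordinate_test(X, labels, d=1, n_boot=250, seed=11)
        for r in results:
            assert r.bonferroni_sig == (r.p_value <= 0.05 / p)


def test_slice_assignments_requires_known_women(small_dataset):
    cfg, cohort, rois = small_dataset
    from ppbc import residualize
    res = residualize(rois, cohort, ["age_dx"])
    labels = slice_assignments(res, cohort)
    assert len(labels) == len(res)
    assert set(labels) <= {"0-3", "3-5", "6-10", "11-21"}
    bad = res.copy()
    bad.loc[0, "woman_id"] = "UNKNOWN"
    with pytest.raises(ValueError, match="missing from cohort"):
        slice_assignments(bad, cohort)
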