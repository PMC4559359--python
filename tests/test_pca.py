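"""PCA model fit, component-selection rules and monitoring statistics."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netcure import (
    NumericMatrix,
    PCAModel,
    fit_pca,
    hotelling_t2,
    select_components_eigenvalue,
    select_components_variance,
    spe,
    spe_contributions,
)


def svd_oracle(values, A):
    """Independent decomposition: plain numpy SVD of the centered matrix."""
    xc = values - values.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    return vt[:A].T, s[:A] ** 2 / (values.shape[0] - 1), xc - xc @ vt[:A].T @ vt[:A]


class TestFitPCA:
    def test_rank1_two_columns(self, rng):
        col = rng.normal(size=10)
        X = np.column_stack([col, 2 * col])
        m = fit_pca(X, 1)
        assert np.allclose(m.residuals, 0, atol=1e-10)
        assert select_components_variance(X) == 1

    def test_full_rank_reconstruction(self, random_matrix):
        X = random_matrix.values
        A = min(X.shape[0] - 1, X.shape[1])
        m = fit_pca(X, A)
        assert np.allclose(m.mean + m.scores @ m.loadings.T, X, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_svd_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 6))
        m = fit_pca(X, 3)
        P, lam, E = svd_oracle(X, 3)
        # sign-invariant loading comparison
        assert np.allclose(np.abs(m.loadings), np.abs(P), atol=1e-10)
        assert np.allclose(m.score_variances, lam, atol=1e-10)
        assert np.allclose(m.residuals, E, atol=1e-10)

    def test_matches_sklearn(self, random_matrix):
        sk = pytest.importorskip("sklearn.decomposition")
        m = fit_pca(random_matrix.values, 3)
        pca = sk.PCA(n_components=3).fit(random_matrix.values)
        assert np.allclose(np.abs(m.loadings.T), np.abs(pca.components_), atol=1e-10)

    def test_model_invariants(self, random_matrix):
        m = fit_pca(random_matrix.values, 4)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-8)
        cov = np.cov(m.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(cov))
        assert np.all(np.diff(m.score_variances) <= 1e-12)

    def test_rejections(self, random_matrix):
        with pytest.raises(ValueError, match="missing"):
            bad = random_matrix.values.copy()
            bad[0, 0] = np.nan
            fit_pca(bad, 2)
        with pytest.raises(ValueError):
            fit_pca(random_matrix.values, 0)
        with pytest.raises(ValueError):
            fit_pca(random_matrix.values, 7)
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.ones((5, 3)), 1)

    def test_json_roundtrip(self, random_matrix):
        m = fit_pca(random_matrix.values, 2)
        m2 = PCAModel.from_json(m.to_json(), X=random_matrix.values)
        assert np.allclose(m2.loadings, m.loadings)
        assert np.allclose(m2.residuals, m.residuals)
        assert json.loads(m.to_json())["n_components"] == 2


class TestComponentSelection:
    def test_three_factor_variance_shares(self, rng):
        # orthogonal factors carrying 80/15/5 % of the variance: two reach 90 %
        n = 2000
        scores = rng.normal(size=(n, 3)) * np.sqrt([0.80, 0.15, 0.05])
        q, _ = np.linalg.qr(rng.normal(size=(6, 3)))
        X = scores @ q.T
        assert select_components_variance(X, 0.90) == 2
        assert select_components_variance(X, 0.96) == 3

    def test_cap_truncates(self, rng):
        X = rng.normal(size=(60, 55))
        assert select_components_variance(X, 1.0) <= 50
        assert select_components_variance(X, 1.0, cap=7) == 7

    def test_eigenvalue_rule_duplicated_variable(self, rng):
        # var1 == var2 exactly, var3 independent: correlation eigenvalues {2,1,0}
        v = rng.normal(size=5000)
        X = np.column_stack([v, v, rng.normal(size=5000)])
        assert select_components_eigenvalue(X) == 1

    def test_eigenvalue_rule_floor(self, rng):
        # exactly uncorrelated columns: every correlation eigenvalue is 1, so
        # none is strictly above it and the floor keeps one component
        b = np.column_stack([np.ones(200), rng.normal(size=(200, 4))])
        q, _ = np.linalg.qr(b)
        X = q[:, 1:]  # orthogonal to each other and to the constant
        assert select_components_eigenvalue(X) == 1

    def test_eigenvalue_rule_collinear(self, rng):
        v = rng.normal(size=100)
        X = np.column_stack([v, 2 * v, -v, 3 * v])  # eigenvalues {4,0,0,0}
        assert select_components_eigenvalue(X) == 1

    def test_eigenvalue_rule_rejects_constant_column(self, rng):
        X = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        with pytest.raises(ValueError, match="constant"):
            select_components_eigenvalue(X)


def manual_model(p=3, lam=4.0):
    """Hand-built single-component model with loading e1 and center 0."""
    return PCAModel(
        mean=np.zeros(p),
        loadings=np.eye(p)[:, :1],
        scores=np.zeros((3, 1)),
        score_variances=np.array([lam]),
        residuals=np.zeros((3, p)),
        n_components=1,
    )


class TestMonitoringStatistics:
    def test_t2_at_center_is_zero(self):
        assert hotelling_t2(manual_model(), np.zeros(3)) == 0.0

    def test_t2_direct_formula(self):
        # one component, lambda = 4, score t = 2 -> T^2 = 1
        assert hotelling_t2(manual_model(lam=4.0), np.array([2.0, 0, 0])) == 1.0

    def test_t2_matches_score_space_oracle(self, random_matrix):
        m = fit_pca(random_matrix.values, 3)
        t2 = hotelling_t2(m)
        loop = [sum(t[a] ** 2 / m.score_variances[a] for a in range(3)) for t in m.scores]
        assert np.allclose(t2, loop, atol=1e-10)

    def test_t2_rejects_degenerate_component(self):
        m = manual_model()
        m.score_variances = np.array([0.0])
        with pytest.raises(ValueError, match="degenerate"):
            hotelling_t2(m, np.zeros(3))

    def test_spe_in_subspace_is_zero(self, random_matrix):
        m = fit_pca(random_matrix.values, 2)
        x = m.mean + 0.7 * m.loadings[:, 0] - 1.3 * m.loadings[:, 1]
        assert spe(m, x) == pytest.approx(0.0, abs=1e-16)

    def test_spe_direct_formula(self):
        # residual vector (1, 2) off the e1 subspace -> SPE = 5
        assert spe(manual_model(), np.array([0.0, 1.0, 2.0])) == pytest.approx(5.0)

    def test_spe_matches_oracle_residuals(self, random_matrix):
        m = fit_pca(random_matrix.values, 3)
        _, _, E = svd_oracle(random_matrix.values, 3)
        assert np.allclose(spe(m), np.sum(E**2, axis=1), atol=1e-10)

    def test_rowwise_matches_batch(self, random_matrix):
        m = fit_pca(random_matrix.values, 3)
        rows = np.array([spe(m, x) for x in random_matrix.values])
        assert np.allclose(rows, spe(m), atol=1e-12)
        t2rows = np.array([hotelling_t2(m, x) for x in random_matrix.values])
        assert np.allclose(t2rows, hotelling_t2(m), atol=1e-12)

    def test_contributions_direct(self):
        c = spe_contributions(manual_model(), np.array([0.0, 1.0, -3.0]))
        assert np.allclose(c, [0.0, 1.0, 9.0])
        assert c.sum() == pytest.approx(spe(manual_model(), np.array([0.0, 1.0, -3.0])))

    def test_contributions_zero_residual(self, random_matrix):
        m = fit_pca(random_matrix.values, 2)
        x = m.mean + 2.0 * m.loadings[:, 0]
        assert np.allclose(spe_contributions(m, x), 0.0, atol=1e-16)

    def test_contribution_argmax_matches_residual(self, random_matrix):
        m = fit_pca(random_matrix.values, 2)
        c = spe_contributions(m)
        e = m.residuals
        assert np.array_equal(np.argmax(c, axis=1), np.argmax(np.abs(e), axis=1))

    def test_dimension_mismatch_rejected(self, random_matrix):
        m = fit_pca(random_matrix.values, 2)
        with pytest.raises(ValueError, match="variables"):
            spe(m, np.zeros(4))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(4, 15),
    p=st.integers(2, 8),
    seed=st.integers(0, 10_000),
)
def test_reconstruction_and_explained_variance_properties(n, p, seed):
    """mean + T P' + E reproduces X; explained variance hits 1 at full rank."""
    X = np.random.default_rng(seed).normal(size=(n, p))
    A = min(n - 1, p)
    m = fit_pca(X, A)
    assert np.allclose(m.mean + m.scores @ m.loadings.T + m.residuals, X, atol=1e-8)
    from netcure.pca import explained_variance_ratio

    cum = explained_variance_ratio(X)
    assert np.all(np.diff(cum) >= -1e-12)
    assert cum[A - 1] == pytest.approx(1.0, abs=1e-9)
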