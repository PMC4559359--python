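"""Principal component analysis and the latent-structure monitoring statistics.

The model is the usual bilinear decomposition

    X = 1 m' + T_A P_A' + E_A

with column means ``m``, scores ``T_A`` (n x A), orthonormal loadings ``P_A``
(p x A) and residuals ``E_A``. Two monitoring statistics follow:

* Hotelling T^2 = sum_a t_a^2 / lambda_a — the Mahalanobis distance of an
  observation's projection from the model centre (lambda_a is the variance of
  score column a);
* SPE = e' e — the squared perpendicular distance from the observation to the
  A-dimensional subspace, decomposable per variable into the squared residual
  contributions e_{i,k}^2 used for fault isolation.

The numerical engine is a singular value decomposition of the centered matrix;
eigenvalues are singular_value^2 / (n - 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .matrix import NumericMatrix, autoscale

__all__ = [
    "PCAModel",
    "OutlierStatistics",
    "fit_pca",
    "select_components_variance",
    "select_components_eigenvalue",
    "hotelling_t2",
    "spe",
    "spe_contributions",
]


@dataclass
class PCAModel:
    """Fitted PCA model: mean, loadings, scores, score variances, residuals."""

    mean: np.ndarray          # (p,)
    loadings: np.ndarray      # (p, A), orthonormal columns
    scores: np.ndarray        # (n, A)
    score_variances: np.ndarray  # (A,), non-increasing
    residuals: np.ndarray     # (n, p)
    n_components: int

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project (centered internally) observations onto the loadings."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self._check_dim(x)
        return (x - self.mean) @ self.loadings

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Projection of x onto the model subspace, back on the data scale."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self._check_dim(x)
        xc = x - self.mean
        return self.mean + xc @ self.loadings @ self.loadings.T

    def _check_dim(self, x: np.ndarray) -> None:
        if x.shape[-1] != self.mean.shape[0]:
            raise ValueError(
                f"observation has {x.shape[-1]} variables, model expects {self.mean.shape[0]}"
            )

    # JSON sidecar for reproducibility (residuals/scores are derivable and omitted)
    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "loadings": self.loadings.tolist(),
                "score_variances": self.score_variances.tolist(),
                "n_components": self.n_components,
            }
        )

    @classmethod
    def from_json(cls, text: str, X: np.ndarray | None = None) -> "PCAModel":
        d = json.loads(text)
        mean = np.array(d["mean"], dtype=float)
        loadings = np.array(d["loadings"], dtype=float)
        lam = np.array(d["score_variances"], dtype=float)
        if X is not None:
            xc = np.asarray(X, dtype=float) - mean
            scores = xc @ loadings
            residuals = xc - scores @ loadings.T
        else:
            scores = np.zeros((0, loadings.shape[1]))
            residuals = np.zeros((0, loadings.shape[0]))
        return cls(mean, loadings, scores, lam, residuals, int(d["n_components"]))


@dataclass
class OutlierStatistics:
    """Per-row monitoring statistics of a fitted model on some data."""

    t2: np.ndarray             # (n,)
    spe: np.ndarray            # (n,)
    contributions: np.ndarray  # (n, p), squared residuals; rows sum to spe


def _centered(X: NumericMatrix | np.ndarray) -> np.ndarray:
    values = X.values if isinstance(X, NumericMatrix) else np.asarray(X, dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix has missing cells; impute first")
    return values


def _svd_centered(values: np.ndarray):
    mean = values.mean(axis=0)
    xc = values - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    return mean, xc, u, s, vt


def fit_pca(X: NumericMatrix | np.ndarray, n_components: int) -> PCAModel:
    """Fit a PCA model with ``n_components`` components on complete data.

    Loadings are the right singular vectors of the centered matrix ordered by
    singular value; the sign of each loading column is fixed so its
    largest-magnitude entry is positive. Requires n >= 3 rows, p >= 2 columns
    and 1 <= n_components <= min(n - 1, p).
    """
    values = _centered(X)
    n, p = values.shape
    if n < 3 or p < 2:
        raise ValueError(f"need n >= 3 and p >= 2, got {n} x {p}")
    A = int(n_components)
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"n_components={A} outside [1, {min(n - 1, p)}]")
    mean, xc, u, s, vt = _svd_centered(values)
    if s[0] <= 0:
        raise ValueError("zero-variance matrix: PCA undefined")
    loadings = vt[:A].T
    # deterministic sign: largest-|entry| of each loading column positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(A)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = xc @ loadings
    lam = s[:A] ** 2 / (n - 1)
    residuals = xc - scores @ loadings.T
    return PCAModel(mean, loadings, scores, lam, residuals, A)


def explained_variance_ratio(X: NumericMatrix | np.ndarray) -> np.ndarray:
    """Cumulative fraction of variance explained by the first a components."""
    values = _centered(X)
    _, _, _, s, _ = _svd_centered(values)
    ev = s**2
    total = ev.sum()
    if total <= 0:
        raise ValueError("zero-variance matrix")
    return np.cumsum(ev) / total


def select_components_variance(
    X: NumericMatrix | np.ndarray,
    fraction: float = 0.90,
    cap: int | None = None,
) -> int:
    """Smallest A whose cumulative explained variance reaches ``fraction``.

    This is the component rule of the imputation path (centered data, no
    scaling). ``cap`` defaults to min(n - 1, p, 50); the 50 keeps the model
    tractable on wide matrices.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    values = _centered(X)
    n, p = values.shape
    cap = min(n - 1, p, 50) if cap is None else min(cap, n - 1, p)
    cum = explained_variance_ratio(values)
    # tiny tolerance so exact-rank data does not overshoot by float error
    reached = np.flatnonzero(cum >= fraction - 1e-12)
    A = int(reached[0]) + 1 if reached.size else len(cum)
    return max(1, min(A, cap))


def select_components_eigenvalue(X: NumericMatrix | np.ndarray) -> int:
    """Number of correlation-matrix eigenvalues strictly above one (floor 1).

    Kaiser-type rule on autoscaled data, used by the outlier path: components
    carrying more variance than a single standardized variable.
    """
    values = _centered(X)
    n, _ = values.shape
    scaled, _, _ = autoscale(values)
    s = np.linalg.svd(scaled, compute_uv=False)
    eig = s**2 / (n - 1)
    return max(1, int(np.sum(eig > 1.0 + 1e-12)))


def hotelling_t2(model: PCAModel, x: np.ndarray | None = None) -> np.ndarray | float:
    """Hotelling T^2 = sum_a t_a^2 / lambda_a per observation.

    With ``x=None`` the statistic is computed for the training rows.
    """
    if np.any(model.score_variances <= 0):
        raise ValueError("degenerate component: some score variance is zero")
    scores = model.scores if x is None else model.transform(x)
    t2 = np.sum(scores**2 / model.score_variances, axis=-1)
    return float(t2[0]) if (x is not None and np.asarray(x).ndim == 1) else t2


def _residual(model: PCAModel, x: np.ndarray | None) -> np.ndarray:
    if x is None:
        return model.residuals
    x = np.atleast_2d(np.asarray(x, dtype=float))
    model._check_dim(x)
    xc = x - model.mean
    return xc - xc @ model.loadings @ model.loadings.T


def spe(model: PCAModel, x: np.ndarray | None = None) -> np.ndarray | float:
    """Square prediction error e'e: squared distance to the model subspace."""
    e = _residual(model, x)
    out = np.sum(e**2, axis=-1)
    return float(out[0]) if (x is not None and np.asarray(x).ndim == 1) else out


def spe_contributions(model: PCAModel, x: np.ndarray | None = None) -> np.ndarray:
    """Per-variable squared residuals e_{i,k}^2; each row sums to its SPE."""
    e = _residual(model, x)
    out = e**2
    return out[0] if (x is not None and np.asarray(x).ndim == 1) else out
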