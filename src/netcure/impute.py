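"""Missing-data imputation: TSR, IA, CC, mean, linear interpolation, nearest neighbor.

All six methods share one contract: originally observed cells are never
modified, and (except for complete-case analysis, which drops rows) the output
has no missing cells. The two latent-structure methods iterate a PCA model to
convergence:

* TSR (trimmed scores regression) — for each missing pattern, regress the
  missing columns on the scores of a PCA restricted to that pattern's observed
  columns, and impute the regression predictions;
* IA (iterative algorithm) — impute the reconstruction T_A P_A' of the full
  model at the missing cells.

Both assume the missingness mechanism is MCAR or MAR; under NMAR the observed
data carry no information about why cells are absent and no imputation here is
valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import NumericMatrix
from .pca import select_components_variance

__all__ = [
    "ImputationResult",
    "impute_tsr",
    "impute_ia",
    "impute_cc",
    "impute_mean",
    "impute_li",
    "impute_nn",
    "impute",
    "METHODS",
]


@dataclass
class ImputationResult:
    """Completed matrix plus method metadata."""

    completed: NumericMatrix
    method: str
    n_components: int | None = None
    iterations: int = 0
    converged: bool = True
    imputed_cells: list[tuple[int, int, float]] = field(default_factory=list)
    dropped_rows: list[int] = field(default_factory=list)


def _as_matrix(X) -> NumericMatrix:
    return X if isinstance(X, NumericMatrix) else NumericMatrix(np.asarray(X, dtype=float))


def _check_rows_cols_observed(mask: np.ndarray) -> None:
    if mask.all(axis=1).any():
        bad = np.flatnonzero(mask.all(axis=1)).tolist()
        raise ValueError(f"rows entirely missing: {bad}")
    if mask.all(axis=0).any():
        bad = np.flatnonzero(mask.all(axis=0)).tolist()
        raise ValueError(f"columns entirely missing: {bad}")


def _default_tol(values: np.ndarray) -> float:
    # scale-free stopping rule: a small multiple of the pooled observed spread,
    # tight enough that the iterates settle well below any practical tolerance
    sd = float(np.nanstd(values))
    return 1e-9 * (sd if sd > 0 else 1.0)


def _identity_result(X: NumericMatrix, method: str, A: int | None = None) -> ImputationResult:
    return ImputationResult(X.copy(), method, n_components=A, iterations=0, converged=True)


def _finish_pca_result(
    X: NumericMatrix, filled: np.ndarray, mask: np.ndarray, method: str,
    A: int, iterations: int, converged: bool,
) -> ImputationResult:
    out = X.copy()
    out.values[mask] = filled[mask]
    cells = [(int(i), int(j), float(filled[i, j])) for i, j in zip(*np.nonzero(mask))]
    return ImputationResult(out, method, n_components=A, iterations=iterations,
                            converged=converged, imputed_cells=cells)


def _lstsq_ridge(T: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of Y on T with a tiny ridge fallback."""
    G = T.T @ T
    try:
        return np.linalg.solve(G, T.T @ Y)
    except np.linalg.LinAlgError:
        lam = 1e-8 * np.trace(G) / max(G.shape[0], 1)
        return np.linalg.solve(G + lam * np.eye(G.shape[0]), T.T @ Y)


def impute_tsr(
    X: NumericMatrix | np.ndarray,
    fraction: float = 0.90,
    tol: float | None = None,
    max_iter: int = 500,
    cap: int | None = None,
) -> ImputationResult:
    """Trimmed scores regression imputation.

    Iterates: fill missing cells (zeros initially), center, fit PCA with the
    component count reaching ``fraction`` cumulative variance, then for every
    group of rows sharing a missing pattern regress the missing columns on the
    scores of a PCA over that pattern's observed columns and impute the
    predictions. Stops when the mean absolute change of the imputed values
    drops below ``tol`` (default 1e-9 x pooled observed SD).
    """
    X = _as_matrix(X)
    mask = X.missing_mask()
    if not mask.any():
        return _identity_result(X, "TSR")
    _check_rows_cols_observed(mask)
    tol = _default_tol(X.values) if tol is None else float(tol)

    work = X.values.copy()
    work[mask] = 0.0
    n, p = work.shape

    # group rows by identical missing pattern
    patterns: dict[bytes, list[int]] = {}
    for i in np.flatnonzero(mask.any(axis=1)):
        patterns.setdefault(mask[i].tobytes(), []).append(i)

    converged = False
    A = 1
    it = 0
    for it in range(1, max_iter + 1):
        mu = work.mean(axis=0)
        xc = work - mu
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        ev = s**2
        cum = np.cumsum(ev) / ev.sum()
        cap_eff = min(n - 1, p, 50) if cap is None else min(cap, n - 1, p)
        reached = np.flatnonzero(cum >= fraction - 1e-12)
        A = max(1, min((int(reached[0]) + 1) if reached.size else len(cum), cap_eff))

        new_xc = xc.copy()
        for key, rows in patterns.items():
            pat = np.frombuffer(key, dtype=bool)
            obs = np.flatnonzero(~pat)
            mis = np.flatnonzero(pat)
            sub = xc[:, obs]
            a_star = min(A, obs.size, n - 1)
            _, _, vt_sub = np.linalg.svd(sub, full_matrices=False)
            P_sub = vt_sub[:a_star].T
            T_sub = sub @ P_sub                       # trimmed scores, all rows
            B = _lstsq_ridge(T_sub, xc[:, mis])       # regress missing part on them
            pred = T_sub[rows] @ B
            new_xc[np.ix_(rows, mis)] = pred
        new_work = new_xc + mu
        new_work[~mask] = X.values[~mask]             # observed cells stay put
        delta = float(np.mean(np.abs(new_work[mask] - work[mask])))
        work = new_work
        if delta < tol:
            converged = True
            break

    return _finish_pca_result(X, work, mask, "TSR", A, it, converged)


def impute_ia(
    X: NumericMatrix | np.ndarray,
    fraction: float = 0.90,
    tol: float | None = None,
    max_iter: int = 500,
    cap: int | None = None,
) -> ImputationResult:
    """Iterative-algorithm imputation: missing cells <- full-model reconstruction."""
    X = _as_matrix(X)
    mask = X.missing_mask()
    if not mask.any():
        return _identity_result(X, "IA")
    _check_rows_cols_observed(mask)
    tol = _default_tol(X.values) if tol is None else float(tol)

    work = X.values.copy()
    work[mask] = 0.0
    n, p = work.shape
    converged = False
    A = 1
    it = 0
    for it in range(1, max_iter + 1):
        mu = work.mean(axis=0)
        xc = work - mu
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        ev = s**2
        cum = np.cumsum(ev) / ev.sum()
        cap_eff = min(n - 1, p, 50) if cap is None else min(cap, n - 1, p)
        reached = np.flatnonzero(cum >= fraction - 1e-12)
        A = max(1, min((int(reached[0]) + 1) if reached.size else len(cum), cap_eff))
        P = vt[:A].T
        recon = xc @ P @ P.T + mu
        new_work = work.copy()
        new_work[mask] = recon[mask]
        delta = float(np.mean(np.abs(new_work[mask] - work[mask])))
        work = new_work
        if delta < tol:
            converged = True
            break

    return _finish_pca_result(X, work, mask, "IA", A, it, converged)


def impute_cc(X: NumericMatrix | np.ndarray) -> ImputationResult:
    """Complete-case analysis: drop every row containing a missing cell."""
    X = _as_matrix(X)
    mask = X.missing_mask()
    keep = np.flatnonzero(~mask.any(axis=1))
    if keep.size == 0:
        raise ValueError("CC not applicable: every row has missing values")
    dropped = np.flatnonzero(mask.any(axis=1)).tolist()
    return ImputationResult(X.subset_rows(keep), "CC", dropped_rows=dropped)


def impute_mean(X: NumericMatrix | np.ndarray) -> ImputationResult:
    """Unconditional mean imputation: each hole <- its column's observed mean."""
    X = _as_matrix(X)
    mask = X.missing_mask()
    if not mask.any():
        return _identity_result(X, "MI")
    out = X.copy()
    col_means = np.nanmean(X.values, axis=0)
    rows, cols = np.nonzero(mask)
    out.values[rows, cols] = col_means[cols]
    cells = [(int(i), int(j), float(col_means[j])) for i, j in zip(rows, cols)]
    return ImputationResult(out, "MI", imputed_cells=cells)


def impute_li(X: NumericMatrix | np.ndarray) -> ImputationResult:
    """Linear interpolation in time (row order) per column.

    Interior holes get the line between the nearest preceding and following
    observed values; boundary holes carry the nearest observed value. Columns
    with fewer than two observed values are rejected.
    """
    X = _as_matrix(X)
    mask = X.missing_mask()
    if not mask.any():
        return _identity_result(X, "LI")
    n, p = X.shape
    out = X.copy()
    cells: list[tuple[int, int, float]] = []
    t = np.arange(n, dtype=float)
    for j in range(p):
        col = X.values[:, j]
        obs = np.flatnonzero(~np.isnan(col))
        if not np.isnan(col).any():
            continue
        if obs.size < 2:
            raise ValueError(
                f"LI not applicable: column {X.column_ids[j]!r} has <2 observed values"
            )
        # np.interp clamps to the boundary observed values, which is the carry rule
        filled = np.interp(t, t[obs], col[obs])
        for i in np.flatnonzero(np.isnan(col)):
            out.values[i, j] = filled[i]
            cells.append((int(i), int(j), float(filled[i])))
    return ImputationResult(out, "LI", imputed_cells=cells)


def impute_nn(X: NumericMatrix | np.ndarray, k: int = 1) -> ImputationResult:
    """Nearest-neighbor imputation.

    A row's holes are copied from its nearest neighbor(s): Euclidean distance
    averaged over the mutually observed columns, neighbors required to be
    observed on all the columns the row is missing. Ties go to the lowest row
    index; ``k > 1`` averages the k nearest eligible neighbors.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = _as_matrix(X)
    mask = X.missing_mask()
    if not mask.any():
        return _identity_result(X, "NN")
    n, p = X.shape
    out = X.copy()
    cells: list[tuple[int, int, float]] = []
    for i in np.flatnonzero(mask.any(axis=1)):
        mis = np.flatnonzero(mask[i])
        obs_i = ~mask[i]
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i or mask[j, mis].any():
                continue  # neighbor must be observed on the needed columns
            shared = obs_i & ~mask[j]
            if not shared.any():
                continue
            diff = X.values[i, shared] - X.values[j, shared]
            dists[j] = float(np.sqrt(np.mean(diff**2)))
        eligible = np.flatnonzero(np.isfinite(dists))
        if eligible.size == 0:
            raise ValueError(f"NN not applicable: no eligible neighbor for row {i}")
        kk = min(k, eligible.size)
        # stable sort => ties resolved by lowest row index
        order = eligible[np.argsort(dists[eligible], kind="stable")][:kk]
        vals = X.values[np.ix_(order, mis)].mean(axis=0)
        out.values[i, mis] = vals
        cells.extend((int(i), int(j2), float(v)) for j2, v in zip(mis, vals))
    return ImputationResult(out, "NN", imputed_cells=cells)


METHODS = {
    "tsr": impute_tsr,
    "ia": impute_ia,
    "cc": impute_cc,
    "mi": impute_mean,
    "li": impute_li,
    "nn": impute_nn,
}


def impute(X: NumericMatrix | np.ndarray, method: str, **kwargs) -> ImputationResult:
    """Dispatch to one of the six methods by its lowercase tag."""
    try:
        fn = METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}") from None
    return fn(X, **kwargs)
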