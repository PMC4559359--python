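"""Synthetic data generators and study runners for the curation benchmarks.

Provides: a linear lagged stochastic chain generator with known network truth
(the 4-species chain W -> Y -> X -> Z, the W-Y coupling being the weakest), a
low-rank correlated Gaussian generator, MCAR hole injection on an exact cell
count, univariate (beyond the 3*IQR fences) and multivariate (reflection
across the column mean) outlier injection with exact ground-truth cell lists,
precision/recall scoring of inferred networks, and a study runner that
corrupts data, applies each curation method, re-infers and scores against the
clean-data network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .impute import METHODS, impute
from .matrix import NumericMatrix
from .netinfer import Edge, InferredNetwork, infer_network
from .outliers import cure_dataset

__all__ = [
    "BenchmarkSpec",
    "EvalResult",
    "default_chain_spec",
    "generate_chain_timeseries",
    "generate_lowrank_gaussian",
    "inject_missing_mcar",
    "inject_univariate_outliers",
    "inject_multivariate_outliers",
    "precision_recall",
    "run_study",
]


@dataclass
class BenchmarkSpec:
    """Topology and noise settings of the chain generator.

    ``topology`` lists (source, target, weight, lag); ``autoregression`` is the
    lag-1 self-memory of every species, which keeps the linear system stable
    (triangular dynamics, spectral radius = autoregression < 1) while giving
    each series enough temporal structure for lagged estimators.
    """

    topology: list[tuple[str, str, float, int]] = field(default_factory=lambda: [
        ("W", "Y", 0.50, 1),   # the weak coupling
        ("Y", "X", 0.80, 1),
        ("X", "Z", 0.80, 1),
    ])
    variables: list[str] = field(default_factory=lambda: ["W", "Y", "X", "Z"])
    n_timepoints: int = 200
    noise_sd: float = 1.0
    autoregression: float = 0.55
    burn_in: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30")
        for s, t, w, lag in self.topology:
            if not np.isfinite(w):
                raise ValueError("weights must be finite")
            if s not in self.variables or t not in self.variables:
                raise ValueError(f"unknown variable in edge {s}->{t}")
            if lag < 1:
                raise ValueError("edge lags must be >= 1")


@dataclass
class EvalResult:
    """Link-recovery counts and Eq.-style precision/recall.

    P or R is None (not 0) when its denominator is zero.
    """

    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    reference: str = "complete_data_network"


def default_chain_spec(**overrides) -> BenchmarkSpec:
    return BenchmarkSpec(**overrides)


def _companion_spectral_radius(spec: BenchmarkSpec) -> float:
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    max_lag = max([lag for *_, lag in spec.topology] + [1])
    A = [np.zeros((p, p)) for _ in range(max_lag)]
    A[0] += np.eye(p) * spec.autoregression
    for s, t, w, lag in spec.topology:
        A[lag - 1][idx[t], idx[s]] += w
    top = np.hstack(A)
    comp = np.vstack([top, np.hstack([np.eye(p * (max_lag - 1)),
                                      np.zeros((p * (max_lag - 1), p))])]) \
        if max_lag > 1 else top
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def generate_chain_timeseries(spec: BenchmarkSpec | None = None,
                              seed: int | None = None) -> tuple[NumericMatrix, InferredNetwork]:
    """Simulate the lagged linear chain and return (standardized data, truth).

    x_j(t) = ar * x_j(t-1) + sum_parents w * x_parent(t - lag) + eps, with the
    first ``burn_in`` samples discarded and columns standardized.
    """
    spec = spec or default_chain_spec()
    if _companion_spectral_radius(spec) >= 1.0:
        raise ValueError("unstable dynamics: spectral radius >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    total = spec.n_timepoints + spec.burn_in
    max_lag = max([lag for *_, lag in spec.topology] + [1])
    x = np.zeros((total, p))
    eps = rng.normal(0.0, spec.noise_sd, size=(total, p))
    for t in range(total):
        row = eps[t].copy()
        if t >= 1:
            row += spec.autoregression * x[t - 1]
        for s, tgt, w, lag in spec.topology:
            if t >= lag:
                row[idx[tgt]] += w * x[t - lag, idx[s]]
        x[t] = row
    x = x[spec.burn_in:]
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    data = NumericMatrix(x, [f"t{t}" for t in range(spec.n_timepoints)], list(spec.variables))
    wmax = max([abs(w) for *_, w, _ in spec.topology] + [0.0]) or 1.0
    truth = InferredNetwork(
        list(spec.variables),
        [Edge(s, t, min(1.0, abs(w) / wmax), "source->target", lag)
         for s, t, w, lag in spec.topology],
        {"generator": "linear_lagged_chain"},
    )
    return data, truth


def generate_lowrank_gaussian(
    n: int, p: int, rank: int, noise_sd: float = 0.1, seed: int | None = None,
    factor_scales: np.ndarray | None = None,
) -> NumericMatrix:
    """Rank-``rank`` correlated Gaussian data plus isotropic noise.

    Latent scores are standard normal on a random orthonormal p x rank frame.
    Factors have equal strength by default, keeping every latent direction
    well clear of the Kaiser eigenvalue threshold so component-selection rules
    see the true rank rather than a knife-edge; pass ``factor_scales`` for
    unequal strengths.
    """
    if rank >= min(n, p):
        raise ValueError("rank must be below min(n, p)")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(p, rank)))
    scale = np.ones(rank) if factor_scales is None else np.asarray(factor_scales, float)
    scores = rng.normal(size=(n, rank)) * scale
    x = scores @ q.T + rng.normal(0.0, noise_sd, size=(n, p))
    return NumericMatrix(x)


def generate_noiseless_lowrank(
    n: int, p: int, rank: int, seed: int | None = None
) -> NumericMatrix:
    """Exact rank-``rank`` matrix with equal-strength latent factors.

    Row and column factors are orthonormal frames, scaled so each latent
    direction carries the same variance; the 90 %-variance component rule
    therefore identifies the true rank. This is the ground truth for
    exact-recovery studies of the latent-structure imputation methods.
    """
    if rank >= min(n, p):
        raise ValueError("rank must be below min(n, p)")
    rng = np.random.default_rng(seed)
    u, _ = np.linalg.qr(rng.normal(size=(n, rank)))
    v, _ = np.linalg.qr(rng.normal(size=(p, rank)))
    return NumericMatrix((u * math.sqrt(n)) @ v.T)


def inject_missing_mcar(
    X: NumericMatrix, pct: float, seed: int | None = None,
    min_row_observed: int = 1, max_tries: int = 1000,
) -> NumericMatrix:
    """Set exactly round(pct/100 * n * p) cells missing completely at random.

    Masks that would leave a row with fewer than ``min_row_observed`` observed
    cells, or empty a column, are redrawn; if the count makes the guarantee
    infeasible the call is rejected. Raising ``min_row_observed`` above the
    data's latent rank keeps every row identifiable for latent-structure
    imputation.
    """
    if not 0 <= pct < 50:
        raise ValueError("pct must be in [0, 50)")
    n, p = X.shape
    count = int(round(pct / 100.0 * n * p))
    if count == 0:
        return X.copy()
    if count > n * (p - min_row_observed) or count > n * p - max(n, p):
        raise ValueError(f"{pct}% missing cannot satisfy the observedness guarantee")
    rng = np.random.default_rng(seed)
    existing = X.missing_mask()
    row_cap = p - min_row_observed
    col_cap = n - 1
    for _ in range(max_tries):
        # greedy pass over a random cell order, honoring the per-row and
        # per-column caps; exact-count masks under tight caps are vanishingly
        # rare under plain rejection sampling
        order = rng.permutation(n * p)
        mask = np.zeros((n, p), dtype=bool)
        row_miss = existing.sum(axis=1).astype(int)
        col_miss = existing.sum(axis=0).astype(int)
        placed = 0
        for flat in order:
            i, j = divmod(int(flat), p)
            if existing[i, j] or row_miss[i] >= row_cap or col_miss[j] >= col_cap:
                continue
            mask[i, j] = True
            row_miss[i] += 1
            col_miss[j] += 1
            placed += 1
            if placed == count:
                break
        if placed == count:
            out = X.copy()
            out.values[mask] = np.nan
            return out
    raise ValueError("could not draw a feasible MCAR mask; lower pct")


def _n_outliers(n: int, pct: float, min_count: int) -> int:
    return max(min_count, int(round(pct / 100.0 * n)))


def inject_univariate_outliers(
    X: NumericMatrix, pct: float, seed: int | None = None, min_count: int = 2
) -> tuple[NumericMatrix, list[tuple[int, int, float]]]:
    """Replace one cell in each of max(min_count, round(pct% * n)) rows by a
    value beyond its column's 3*IQR box-plot fence (fence +/- 0.5*IQR).

    Returns (corrupted copy, [(row, col, original_value), ...]).
    """
    n, p = X.shape
    k = _n_outliers(n, pct, min_count)
    if k > n:
        raise ValueError("more outliers requested than rows")
    rng = np.random.default_rng(seed)
    q1 = np.nanpercentile(X.values, 25, axis=0)
    q3 = np.nanpercentile(X.values, 75, axis=0)
    iqr = q3 - q1
    eligible_cols = np.flatnonzero(iqr > 0)
    if eligible_cols.size == 0:
        raise ValueError("no column with positive IQR")
    rows = rng.choice(n, size=k, replace=False)
    out = X.copy()
    truth: list[tuple[int, int, float]] = []
    for i in rows:
        j = int(rng.choice(eligible_cols))
        high = bool(rng.integers(2))
        val = q3[j] + 3.5 * iqr[j] if high else q1[j] - 3.5 * iqr[j]
        truth.append((int(i), j, float(X.values[i, j])))
        out.values[i, j] = val
    return out, truth


def inject_multivariate_outliers(
    X: NumericMatrix, pct: float, seed: int | None = None, min_count: int = 2,
    max_tries: int = 1000,
) -> tuple[NumericMatrix, list[tuple[int, int, float]]]:
    """Reflect one eligible cell per chosen row across its column mean.

    Eligible cells lie beyond 1.5 column SDs from the mean; reflection
    (v <- 2*mean - v) keeps the value in the univariate range but breaks the
    row's correlation structure — a multivariate outlier.
    """
    n, p = X.shape
    k = _n_outliers(n, pct, min_count)
    if k > n:
        raise ValueError("more outliers requested than rows")
    rng = np.random.default_rng(seed)
    mean = np.nanmean(X.values, axis=0)
    sd = np.nanstd(X.values, axis=0, ddof=1)
    eligible = np.abs(X.values - mean) > 1.5 * sd
    rows_with = np.flatnonzero(eligible.any(axis=1))
    if rows_with.size < k:
        raise ValueError("not enough rows with a cell beyond 1.5 SD")
    out = X.copy()
    truth: list[tuple[int, int, float]] = []
    chosen: set[int] = set()
    tries = 0
    while len(chosen) < k and tries < max_tries:
        tries += 1
        i = int(rng.choice(n))
        if i in chosen or not eligible[i].any():
            continue
        j = int(rng.choice(np.flatnonzero(eligible[i])))
        truth.append((i, j, float(X.values[i, j])))
        out.values[i, j] = 2.0 * mean[j] - X.values[i, j]
        chosen.add(i)
    if len(chosen) < k:
        raise ValueError("could not place the requested multivariate outliers")
    return out, truth


def precision_recall(
    inferred: InferredNetwork, reference: InferredNetwork, directed: bool = False
) -> EvalResult:
    """TP/FP/FN of inferred vs reference links, undirected by default."""
    if not set(inferred.variables) & set(reference.variables):
        raise ValueError("networks share no variables")

    def keys(net: InferredNetwork) -> set:
        if not directed:
            return net.edge_pairs()
        out = set()
        for e in net.edges:
            if e.direction == "undirected":
                out.add((e.source, e.target))
                out.add((e.target, e.source))
            else:
                out.add((e.source, e.target))
        return out

    a, b = keys(inferred), keys(reference)
    tp, fp, fn = len(a & b), len(a - b), len(b - a)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return EvalResult(tp, fp, fn, precision, recall)


# ---------------------------------------------------------------------------
# study runner

_CURATION = "cure"


def _apply_method(method: str, corrupted: NumericMatrix, seed: int) -> NumericMatrix | None:
    """Run one curation method; None when it is not applicable here."""
    try:
        if method == _CURATION:
            cured, _ = cure_dataset(corrupted, seed=seed)
            return cured
        if method == "none":
            return corrupted if corrupted.is_complete() else None
        res = impute(corrupted, method)
        if method == "cc" and res.completed.n_rows < 0.5 * corrupted.n_rows:
            # the rows are a time series: once most are dropped the lag
            # structure the inference relies on is destroyed
            return None
        return res.completed
    except ValueError:
        return None


def run_study(config: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt / cure / re-infer / score, over a (method x percentage) grid.

    ``config`` keys: kind ("missing" | "univariate_outliers" |
    "multivariate_outliers"), methods (list of tags; imputation tags for
    missing, "cure"/"none" for outliers), percentages, n_repetitions, seed,
    optional generator ({"n_timepoints", "noise_sd", ...}) and infer
    (settings forwarded to infer_network) sections.

    Returns (long-format results table, paired one-sided test summaries
    comparing the first listed method against each other method per
    percentage). The reference network for scoring is the one inferred from
    the same repetition's uncorrupted data.
    """
    kind = config.get("kind", "missing")
    methods = list(config.get("methods", ["tsr", "ia", "cc", "mi", "li", "nn"]))
    percentages = list(config.get("percentages", [5, 10, 15, 20, 25, 30, 35]))
    n_rep = int(config.get("n_repetitions", 100))
    master_seed = int(config.get("seed", 0))
    gen_cfg = dict(config.get("generator", {}))
    infer_cfg = dict(config.get("infer", {}))

    valid = set(METHODS) | {_CURATION, "none"}
    unknown = [m for m in methods if m not in valid]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")

    ss = np.random.SeedSequence(master_seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_rep)]

    rows = []
    for rep, rseed in enumerate(rep_seeds):
        spec = default_chain_spec(**gen_cfg)
        clean, _truth = generate_chain_timeseries(spec, seed=rseed)
        reference = infer_network(clean, seed=rseed, **infer_cfg)
        for pct in percentages:
            if kind == "missing":
                corrupted = inject_missing_mcar(clean, pct, seed=rseed + 1)
            elif kind == "univariate_outliers":
                corrupted, _ = inject_univariate_outliers(clean, pct, seed=rseed + 1)
            elif kind == "multivariate_outliers":
                corrupted, _ = inject_multivariate_outliers(clean, pct, seed=rseed + 1)
            else:
                raise ValueError(f"unknown study kind {kind!r}")
            for method in methods:
                completed = (_apply_method(method, corrupted, seed=rseed + 2)
                             if pct > 0 else clean.copy())
                if completed is None or not completed.is_complete():
                    rows.append({"method": method, "pct": pct, "rep": rep,
                                 "precision": np.nan, "recall": np.nan})
                    continue
                net = infer_network(completed, seed=rseed, **infer_cfg)
                ev = precision_recall(net, reference)
                rows.append({
                    "method": method, "pct": pct, "rep": rep,
                    "precision": np.nan if ev.precision is None else ev.precision,
                    "recall": np.nan if ev.recall is None else ev.recall,
                })
    table = pd.DataFrame(rows)

    # paired one-sided tests: first method vs each competitor, per percentage
    summaries = []
    base = methods[0]
    for pct in percentages:
        sub = table[table["pct"] == pct]
        base_df = sub[sub["method"] == base].set_index("rep")
        for other in methods[1:]:
            oth = sub[sub["method"] == other].set_index("rep")
            for metric in ("precision", "recall"):
                a = base_df[metric]
                b = oth[metric].reindex(a.index)
                ok = a.notna() & b.notna()
                if ok.sum() < 3 or np.allclose(a[ok], b[ok]):
                    pval = np.nan
                else:
                    pval = float(stats.ttest_rel(a[ok], b[ok], alternative="greater").pvalue)
                summaries.append({
                    "pct": pct, "comparison": f"{base}>{other}", "metric": metric,
                    "n_pairs": int(ok.sum()),
                    "mean_base": float(a[ok].mean()) if ok.any() else np.nan,
                    "mean_other": float(b[ok].mean()) if ok.any() else np.nan,
                    "p_value": pval,
                })
    return table, pd.DataFrame(summaries)
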