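"""SPE outlier detection with a resampled control limit, fault isolation, and
TSR-based correction.

The flow: autoscale the (complete) matrix, fit PCA with the eigenvalue > 1
rule, compute each row's square prediction error (SPE), set a 95 % control
limit as the median of empirical 95 % quantiles over a thousand random data
subsets, classify the rows above the limit into extreme outliers versus
admissible false alarms, isolate the faulty variable of each extreme row as
the one with the largest squared residual, replace that cell by a missing
value, and re-impute it with trimmed scores regression. Rounds repeat until no
extreme outlier remains (or ``max_rounds``).

Only SPE outliers are corrected: they break the correlation structure of the
data, which is what masks the true relations between variables. Hotelling-T^2
outliers stay coherent with that structure and are reported, not touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .impute import impute_tsr
from .matrix import NumericMatrix, autoscale
from .pca import fit_pca, hotelling_t2, select_components_eigenvalue, spe, spe_contributions

__all__ = [
    "ControlLimit",
    "OutlierRecord",
    "CurationReport",
    "compute_cv_limit",
    "classify_extreme",
    "isolate_faulty_variable",
    "cure_dataset",
]

RULE_2X = "above_2x_limit"
RULE_DISTANCE = "distance_10x_false_alarm"
RULE_QUOTA = "excess_false_alarm_quota"


@dataclass
class ControlLimit:
    """Resampled upper control limit for a monitoring statistic."""

    statistic: str
    alpha: float
    n_subsets: int
    subset_fraction: float
    per_subset_limits: np.ndarray
    limit: float
    seed: int | None


@dataclass
class OutlierRecord:
    row_index: int
    spe_value: float
    rule: str
    faulty_col: int
    original_value: float
    corrected_value: float | None = None
    round: int = 1


@dataclass
class CurationReport:
    records: list[OutlierRecord] = field(default_factory=list)
    limits: list[ControlLimit] = field(default_factory=list)
    n_false_alarms_excused: int = 0
    rounds: int = 0
    model_components: list[int] = field(default_factory=list)
    converged: bool = True
    t2: np.ndarray | None = None
    spe: np.ndarray | None = None

    @property
    def limit(self) -> ControlLimit | None:
        """Control limit of the first (detection) round."""
        return self.limits[0] if self.limits else None


def _empirical_upper_quantile(sorted_vals: np.ndarray, alpha: float) -> np.ndarray:
    """Order statistic leaving at most ``alpha`` of the sample above it.

    For m values returns the ceil((1 - alpha) * m)-th smallest, along the last
    axis of an already-sorted array.
    """
    m = sorted_vals.shape[-1]
    idx = int(math.ceil((1.0 - alpha) * m)) - 1
    return sorted_vals[..., idx]


def compute_cv_limit(
    spe_values: np.ndarray,
    alpha: float = 0.05,
    n_subsets: int = 1000,
    subset_fraction: float = 0.8,
    seed: int | None = None,
) -> ControlLimit:
    """Cross-validated control limit: median of per-subset empirical quantiles.

    Each of ``n_subsets`` subsets (without replacement, size
    ceil(subset_fraction * n)) yields the empirical (1 - alpha) quantile of its
    SPE values; the final limit is the median of those quantiles. Theoretical
    chi-square-type limits assume distributional conditions real data rarely
    meet; resampling the empirical quantile is robust to that.
    """
    spe_values = np.asarray(spe_values, dtype=float).ravel()
    n = spe_values.size
    if n < 10:
        raise ValueError(f"need at least 10 SPE values, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 < subset_fraction <= 1:
        raise ValueError("subset_fraction must be in (0, 1]")
    m = int(math.ceil(subset_fraction * n))
    if math.ceil((1 - alpha) * m) < 1:
        raise ValueError("subset too small for the requested quantile")
    rng = np.random.default_rng(seed)
    if m == n:
        full = np.sort(spe_values)
        per = np.full(n_subsets, _empirical_upper_quantile(full, alpha))
    else:
        # one (n_subsets, n) draw; argsort rows -> subsets without replacement
        keys = rng.random((n_subsets, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        subs = np.sort(spe_values[idx], axis=1)
        per = _empirical_upper_quantile(subs, alpha)
    return ControlLimit("SPE", alpha, n_subsets, subset_fraction,
                        per, float(np.median(per)), seed)


def classify_extreme(
    spe_values: np.ndarray, limit: ControlLimit | float, order: str = "quota_first"
) -> tuple[list[tuple[int, str]], list[int]]:
    """Split the rows above the control limit into extremes and false alarms.

    A point above twice the limit is extreme and never excusable. Of the
    remaining above-limit points, up to ceil(alpha * n) — the admissible
    false-alarm count of a limit at confidence 1 - alpha — are excused,
    closest to the limit first. With the default ``order="quota_first"`` the
    excusal happens before the distance rule, whose yardstick is then the gap
    of the lowest excused false alarm: a beyond-quota point is extreme when
    its distance to the limit exceeds 10 times that gap. On in-control data
    the handful of threshold-crossers all fall inside the quota and nothing is
    flagged. With ``order="rules_first"`` both extremeness rules are applied
    before any excusal, the distance yardstick being the lowest above-limit
    point; this is stricter and can flag in-control rows whose gap merely
    exceeds 10x the smallest gap. Beyond-quota points caught by neither rule
    are flagged with a quota tag either way.

    Returns (extreme [(row, rule), ...] sorted by decreasing SPE, excused row
    indices).
    """
    spe_values = np.asarray(spe_values, dtype=float).ravel()
    if isinstance(limit, ControlLimit):
        L, alpha = limit.limit, limit.alpha
    else:
        L, alpha = float(limit), 0.05
    if order not in ("quota_first", "rules_first"):
        raise ValueError("order must be 'quota_first' or 'rules_first'")
    above = np.flatnonzero(spe_values > L)
    if above.size == 0:
        return [], []
    above = above[np.argsort(-spe_values[above], kind="stable")]
    lowest_gap = spe_values[above[-1]] - L
    quota = int(math.ceil(alpha * spe_values.size))
    extreme: list[tuple[int, str]] = []

    if order == "rules_first":
        plain: list[int] = []
        for i in above:
            s = spe_values[i]
            if s > 2.0 * L:
                extreme.append((int(i), RULE_2X))
            elif (s - L) > 10.0 * lowest_gap:
                extreme.append((int(i), RULE_DISTANCE))
            else:
                plain.append(int(i))
        plain_sorted = sorted(plain, key=lambda i: spe_values[i])
        excused = sorted(plain_sorted[:quota])
        extreme.extend((i, RULE_QUOTA) for i in plain_sorted[quota:])
    else:
        hits_2x = [int(i) for i in above if spe_values[i] > 2.0 * L]
        extreme.extend((i, RULE_2X) for i in hits_2x)
        rest = sorted((int(i) for i in above if spe_values[i] <= 2.0 * L),
                      key=lambda i: spe_values[i])
        excused = sorted(rest[:quota])
        # yardstick: gap of the lowest false alarm (smallest excused SPE)
        yardstick = (spe_values[rest[0]] - L) if excused else lowest_gap
        for i in rest[quota:]:
            if (spe_values[i] - L) > 10.0 * yardstick:
                extreme.append((i, RULE_DISTANCE))
            else:
                extreme.append((i, RULE_QUOTA))

    extreme.sort(key=lambda t: -spe_values[t[0]])
    return extreme, excused


def isolate_faulty_variable(contrib_row: np.ndarray) -> int:
    """Index of the variable with the largest SPE contribution (lowest wins ties)."""
    contrib_row = np.asarray(contrib_row, dtype=float).ravel()
    if np.all(contrib_row == 0):
        raise ValueError("all contributions zero: cannot isolate a faulty variable")
    return int(np.argmax(contrib_row))  # np.argmax takes the first maximum


def cure_dataset(
    X: NumericMatrix | np.ndarray,
    alpha: float = 0.05,
    n_subsets: int = 1000,
    subset_fraction: float = 0.8,
    max_rounds: int = 5,
    fraction: float = 0.90,
    seed: int | None = None,
) -> tuple[NumericMatrix, CurationReport]:
    """Detect extreme SPE outliers and correct them via TSR imputation.

    Missing cells, if present, are TSR-imputed first. Each round fixes at most
    one variable per flagged row (the contribution argmax); rows corrupted in
    several variables are repaired across successive rounds.
    """
    X = X if isinstance(X, NumericMatrix) else NumericMatrix(np.asarray(X, dtype=float))
    report = CurationReport()
    work = X.copy()
    if not work.is_complete():
        work = impute_tsr(work, fraction=fraction).completed

    ss = np.random.SeedSequence(seed)
    round_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max_rounds)]

    for rnd in range(1, max_rounds + 1):
        report.rounds = rnd
        scaled, mu, sd = autoscale(work.values)
        A = select_components_eigenvalue(work.values)
        model = fit_pca(scaled, A)
        report.model_components.append(A)
        spe_vals = spe(model)
        report.t2 = hotelling_t2(model)
        report.spe = spe_vals
        lim = compute_cv_limit(spe_vals, alpha=alpha, n_subsets=n_subsets,
                               subset_fraction=subset_fraction, seed=round_seeds[rnd - 1])
        report.limits.append(lim)
        extreme, excused = classify_extreme(spe_vals, lim)
        if rnd == 1:
            report.n_false_alarms_excused = len(excused)
        if not extreme:
            report.records.sort(key=lambda r: -r.spe_value)
            return work, report
        contrib = spe_contributions(model)
        punctured = work.copy()
        new_records = []
        for i, rule in extreme:
            col = isolate_faulty_variable(contrib[i])
            new_records.append(OutlierRecord(
                row_index=i, spe_value=float(spe_vals[i]), rule=rule, faulty_col=col,
                original_value=float(work.values[i, col]), round=rnd,
            ))
            punctured.values[i, col] = np.nan
        fixed = impute_tsr(punctured, fraction=fraction).completed
        for rec in new_records:
            rec.corrected_value = float(fixed.values[rec.row_index, rec.faulty_col])
        report.records.extend(new_records)
        work = fixed

    report.converged = False  # max_rounds exhausted with extremes still present
    report.records.sort(key=lambda r: -r.spe_value)
    return work, report
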