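# Methods

This note documents the models behind `netcure`, the defaults that matter and
why, what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Latent-structure model

All curation rests on the bilinear PCA decomposition of an n × p data matrix:

    X = 1 m' + T_A P_A' + E_A

with column means `m`, orthonormal loadings `P_A` (p × A), scores
`T_A = (X − 1 m') P_A` and residuals `E_A`. The engine is a singular value
decomposition of the centered matrix; score variances are
λ_a = s_a²/(n − 1), and each loading column's sign is fixed so its
largest-magnitude entry is positive (reproducible output; PCA is otherwise
sign-ambiguous).

Two component-count rules serve two purposes:

* **Imputation path** — the smallest A whose cumulative explained variance of
  the *centered* matrix reaches `fraction` (default **0.90**), capped at
  min(n − 1, p, 50). Imputation wants to capture nearly all systematic
  variability; the cap keeps wide matrices tractable. Centering-only matches
  the imputation algorithms, which center but do not scale.
* **Outlier path** — the number of correlation-matrix eigenvalues strictly
  above 1 on *autoscaled* data (Kaiser-type rule), floored at 1. Outlier
  monitoring wants only the dominant directions, so that structure-breaking
  cells land in the residuals where SPE sees them.

Whether to autoscale before the 90 %-variance rule is left to the caller;
both modes are reachable because the right choice depends on whether the
variables share units.

## Missing-data imputation

Six methods share one contract: observed cells are returned bit-identical,
and (except complete-case analysis) the output is complete. All assume the
missingness mechanism is MCAR or MAR; under NMAR the observed data carry no
information about the missingness and none of these methods is valid.

**TSR (trimmed scores regression).** Fill holes with zeros; then iterate:
center; fit PCA with the 90 %-variance rule (recomputed every iteration, so
the component count can adapt as imputations improve); for each group of rows
sharing a missing pattern, fit a fresh PCA on the observed-column submatrix
(all rows, current values), regress the missing columns on those "trimmed"
scores by least squares, and impute the group's predictions; restore means.
Stop when the mean absolute change of the imputed values falls below `tol`.
The per-pattern regression uses a ridge fallback (λ = 10⁻⁸·trace) if the
score Gram matrix is singular.

**IA (iterative algorithm).** Same loop, but every hole is replaced by the
full model's reconstruction `m + T_A P_A'` at that cell. IA is a projection
fixed-point iteration: its contraction rate is the squared cosine of the
angle between the model subspace and the missing-coordinate subspace of the
worst row, and approaches 1 when a row's observed cells barely pin down its
scores. TSR solves the same linear subproblem directly, which is why it
converges orders of magnitude faster on hard patterns — the practical reason
to prefer it.

**Stopping rule.** `tol` defaults to 10⁻⁹ × the pooled SD of the observed
values. The scale factor makes the rule unit-free; the 10⁻⁹ multiple is
deliberately tight because the remaining truth error of a fixed-point
iteration is roughly (change at stop)/(1 − rate): with a contraction rate of
0.99 a looser 10⁻⁶ stop can leave errors near 10⁻⁴. Iterations cost one SVD
each, so the tight default is cheap; `max_iter` = 500 bounds runaway cases
and the result then reports `converged=False`.

**Exact-recovery domain.** For noiseless rank-A data, masked cells are
recovered exactly (≈10⁻⁸ in the tests) provided the completion problem is
identifiable: every row must keep at least A observed cells, and in practice
at least A + 2 so the row subsystems are overdetermined and well-conditioned.
A mask that leaves a row with fewer observed cells than the rank admits
infinitely many completions — no method can recover it — and near-square
patterns make IA arbitrarily slow. The MCAR injector exposes
`min_row_observed` for exactly this reason. The 90 %-variance rule finds the
true rank only when no latent factor is negligible next to the others; the
exact-recovery generator therefore uses equal-strength factors, and the
recovery studies pass the known rank as the component cap.

**The simple methods.** Mean imputation fills column means of the observed
cells (and provably preserves them). Linear interpolation treats rows as
consecutive time points, interpolating interior gaps and carrying the nearest
observed value at the boundaries (interpolation is undefined there); columns
with fewer than two observed values are rejected. Nearest-neighbor uses the
Euclidean distance averaged over mutually observed columns, requires the
neighbor to be observed on all needed columns, breaks ties toward the lowest
row index, and averages k neighbors when k > 1. Complete-case analysis keeps
the complete rows in order and reports the dropped ones; it fails loudly when
no complete row exists.

## Outlier detection and correction

Pipeline per round: TSR-impute any holes → autoscale → PCA with the
eigenvalue rule → per-row SPE → resampled control limit → classify → puncture
the faulty cell of each extreme row → TSR-reconstruct → repeat until clean or
`max_rounds` (default 5; one cell is corrected per flagged row per round, so
rows corrupted in several variables need several rounds).

**Control limit.** The 95 % limit is the median over 1000 random subsets
(without replacement, default 80 % of the rows — the subset size is a free
parameter, exposed as `subset_fraction`) of the empirical quantile leaving at
most 5 % of the subset above it (the ⌈0.95·m⌉-th order statistic).
Resampling the empirical quantile avoids distributional assumptions that real
SPE values rarely meet. On in-control rank-3 Gaussian data (n=100, p=8) the
fraction of rows above the limit calibrates to 5.0 % across seeds.

**Classification.** A limit at confidence 1 − α admits ⌈α·n⌉ expected false
alarms. Default ordering (`quota_first`): points above **twice** the limit
are extreme and never excusable; of the rest, up to the quota are excused,
closest to the limit first; a beyond-quota point is extreme when its distance
to the limit exceeds **10×** the distance of the lowest excused false alarm.
The alternative (`rules_first`) applies both extremeness rules before any
excusal, with the lowest above-limit point as the distance yardstick. The
default was chosen because on continuous in-control data the lowest
above-limit gap is an order-statistic spacing near zero, so the rules-first
distance criterion flags clean rows at a high rate, while quota-first leaves
clean data untouched (all crossers fall inside the quota) and still catches
genuine faults, which sit far above the limit. Points above the limit that
exhaust the quota yet trigger neither rule are flagged with a separate
`excess_false_alarm_quota` tag rather than silently dropped.

Only SPE outliers are corrected. T² measures distance *within* the model
plane — unusual but structure-coherent behaviour — and is reported without
correction. The faulty variable of an extreme row is the argmax of the
squared-residual contributions (ties to the lowest column index).

## Information-theoretic inference

Entropies are plug-in estimates over equal-frequency bins, base 2. Every
series is discretized once by its own quantile edges
(B = min(10, ⌈√n/2⌉) by default) and all joint quantities are assembled from
those shared labels, so I(X,X) = H(X) and the chain rule hold exactly, MI is
symmetric at lag 0, and H, I and T are clipped non-negative. Transfer entropy
conditions on the target's own past and requires lag ≥ 1; when a link's best
lag is 0 the orientation step uses lag 1.

`infer_network`, per ordered pair: (1) pick τ* maximizing I(Xᵗ⁻τ; Yᵗ) over
τ ∈ {0..max_lag} (default 5); (2) candidate if that MI exceeds
mean + 3 SD of the *lag-maximized* MI under 30 circular shifts of the source
— maximizing the null over the same lag grid is essential, a single-lag null
understates both estimator bias and the selection effect of picking the best
lag; (3) prune indirect links: a candidate (i, j) is removed if conditioning
on 1–3 other candidate neighbours (each at its own best lag) reduces the
extra entropy reduction of i below a circular-shift null of the same
statistic (plus a 1 % of H(j) floor). Only conditioners whose links to both
endpoints carry *more* MI than the tested pair are eligible — by the data
processing inequality an indirect link is the weakest leg of its triangle, so
this guard keeps direct links from being explained away by their own
descendants; (4) strength = (H(Y) − H(Y|X))/H(Y) clipped to [0, 1], direction
by the larger transfer entropy, `undirected` when the two directions differ
by less than 5 % of their mean. Fixed settings and seed give identical
output.

These estimator and threshold choices trade a small false-positive rate
(~4 % per variable pair on pure-noise data) for ~85–95 % exact-adjacency
recovery of the simulated chain; raising the permutation count or the SD
multiplier lowers the former at the cost of the weakest true links.

## Synthetic generators and what they do (not) show

**Chain generator.** x_j(t) = 0.55·x_j(t−1) + Σ w·x_parent(t−lag) + ε with
unit Gaussian noise, couplings 0.5 (W→Y, the weak link), 0.8 (Y→X, X→Z) at
lag 1, a 100-sample burn-in, standardized columns, n = 200 by default. The
system is triangular, so stability is the AR coefficient 0.55 < 1 and is
checked via the companion-matrix spectral radius. The AR memory gives every
species the temporal structure lagged estimators need; the weak coupling was
set at the detection margin of the MI threshold so the benchmark discriminates
between curation methods rather than saturating. Structural-recovery studies
run at n = 400, where the conditional-entropy estimators have adequate power;
at n = 200 the weak link sits near 50 % detection probability and the study
would measure estimator luck. This generator is linear and Gaussian: passing
it says nothing about strongly nonlinear kinetics, non-Gaussian noise,
unobserved species or measurement artefacts beyond the two injected kinds.

**Low-rank Gaussian generator.** Standard-normal scores on a random
orthonormal frame, equal factor strengths by default (unequal strengths are a
parameter), plus isotropic noise (default SD 0.1 against unit-scale factors).
Equal strengths keep all latent eigenvalues of the autoscaled data well above
the Kaiser threshold; with strongly unequal factors the weakest eigenvalue
can sit at 1.0 and the component rule — hence outlier detection — becomes a
coin flip, which is a property of the rule worth knowing about but a useless
study condition.

**Corruption injectors.** MCAR holes are placed on an exact cell count by a
greedy pass over a random cell order honoring per-row/per-column observedness
caps. Univariate outliers replace one cell per chosen row
(max(2, round(pct·n)) rows, the minimum of 2 keeping tiny studies
non-degenerate) with a value half an IQR beyond the 3·IQR box-plot fence —
unambiguously a univariate outlier, but only just. Multivariate outliers
reflect a cell lying beyond 1.5 column SDs across its column mean: the value
stays within its marginal range (inside the fences for Gaussian columns) but
breaks the row's correlation structure, which is precisely what SPE detects
and univariate screens miss. Both injectors return exact ground-truth lists.

**Scoring.** Precision and recall compare edge sets undirected by default
(link recovery, not orientation), against the network inferred from the
*uncorrupted* data of the same repetition — curation is judged by how much of
the clean-data answer it preserves, not by closeness to the generator truth,
so inference-engine error cancels out of the comparison. 0/0 is reported as
missing, never as 0. Study runners derive every repetition's seed from one
master seed; results are reproducible tables, and paired one-sided t-tests
summarize method contrasts per corruption level.

## Known limitations

* TSR with many distinct missing patterns fits one PCA per pattern per
  iteration; on very wide matrices this is the dominant cost (the component
  cap of 50 bounds it).
* The entropy estimators are histogram plug-ins; in more than ~4 dimensions
  or at small n they are bias-dominated and the conditional pruning relies on
  its permutation null, not on the raw values.
* Orientation of weak or lag-0 links by transfer entropy is unreliable; the
  adjacency is the robust output.
* The outlier scheme corrects one cell per row per round; a row corrupted in
  most of its variables can defeat fault isolation entirely.
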