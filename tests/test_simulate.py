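"""Generators, corruption injectors, scoring and the study runner."""

import numpy as np
import pytest

from netcure import (
    BenchmarkSpec,
    InferredNetwork,
    NumericMatrix,
    precision_recall,
    run_study,
)
from netcure.netinfer import Edge, infer_network
from netcure.simulate import (
    default_chain_spec,
    generate_chain_timeseries,
    generate_lowrank_gaussian,
    generate_noiseless_lowrank,
    inject_missing_mcar,
    inject_multivariate_outliers,
    inject_univariate_outliers,
)


class TestChainGenerator:
    def test_deterministic(self):
        a, _ = generate_chain_timeseries(seed=4)
        b, _ = generate_chain_timeseries(seed=4)
        assert np.array_equal(a.values, b.values)

    def test_zero_weights_give_independent_noise(self):
        spec = BenchmarkSpec(topology=[("W", "Y", 0.0, 1), ("Y", "X", 0.0, 1),
                                       ("X", "Z", 0.0, 1)])
        # decoupled species: no systematic edges (stray threshold crossings
        # at the 3-SD permutation null are tolerated at the null rate)
        total = 0
        for s in (1, 2, 3, 4, 5):
            data, _ = generate_chain_timeseries(spec, seed=s)
            total += len(infer_network(data, seed=s).edges)
        assert total <= 2

    def test_weak_link_has_weaker_lagged_correlation(self):
        ok = 0
        for s in range(10):
            data, _ = generate_chain_timeseries(seed=s)
            v = data.values
            c_wy = abs(np.corrcoef(v[1:, 1], v[:-1, 0])[0, 1])
            c_yx = abs(np.corrcoef(v[1:, 2], v[:-1, 1])[0, 1])
            ok += c_wy < c_yx
        assert ok >= 9

    def test_unstable_spec_rejected(self):
        spec = default_chain_spec(autoregression=1.05)
        with pytest.raises(ValueError, match="unstable"):
            generate_chain_timeseries(spec, seed=0)

    def test_truth_network_matches_topology(self):
        _, truth = generate_chain_timeseries(seed=0)
        assert truth.edge_pairs() == {frozenset(p) for p in
                                      [("W", "Y"), ("Y", "X"), ("X", "Z")]}

    def test_standardized_columns(self):
        data, _ = generate_chain_timeseries(seed=3)
        assert np.allclose(data.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(data.values.std(axis=0, ddof=1), 1, atol=1e-10)


class TestMCARInjection:
    def test_exact_count(self, rng):
        X = NumericMatrix(rng.normal(size=(10, 10)))
        assert inject_missing_mcar(X, 5, seed=1).n_missing == 5

    def test_zero_pct_identity(self, rng):
        X = NumericMatrix(rng.normal(size=(10, 10)))
        assert inject_missing_mcar(X, 0.4, seed=1).n_missing == 0

    def test_deterministic_mask(self, rng):
        X = NumericMatrix(rng.normal(size=(20, 5)))
        a = inject_missing_mcar(X, 20, seed=9)
        b = inject_missing_mcar(X, 20, seed=9)
        assert np.array_equal(a.missing_mask(), b.missing_mask())

    def test_rows_and_columns_keep_observations(self, rng):
        X = NumericMatrix(rng.normal(size=(12, 4)))
        for s in range(10):
            Xm = inject_missing_mcar(X, 35, seed=s)
            mask = Xm.missing_mask()
            assert (~mask).sum(axis=1).min() >= 1
            assert (~mask).sum(axis=0).min() >= 1

    def test_min_row_observed_honored(self, rng):
        X = NumericMatrix(rng.normal(size=(15, 6)))
        Xm = inject_missing_mcar(X, 30, seed=2, min_row_observed=4)
        assert (~Xm.missing_mask()).sum(axis=1).min() >= 4

    def test_infeasible_constraint_rejected(self, rng):
        X = NumericMatrix(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            inject_missing_mcar(X, 40, seed=0, min_row_observed=3)


class TestOutlierInjection:
    def test_univariate_minimum_count(self):
        X = generate_lowrank_gaussian(57, 6, 2, seed=0)
        _, truth = inject_univariate_outliers(X, 1, seed=0)
        assert len(truth) == 2

    def test_univariate_fence_arithmetic(self, rng):
        # uniform column: Q1~0.25-scale, injected high value beyond Q3 + 3 IQR
        X = NumericMatrix(np.column_stack([rng.uniform(0, 1, 100),
                                           rng.normal(size=100)]))
        Xc, truth = inject_univariate_outliers(X, 5, seed=1)
        q1 = np.percentile(X.values, 25, axis=0)
        q3 = np.percentile(X.values, 75, axis=0)
        iqr = q3 - q1
        for i, j, _orig in truth:
            v = Xc.values[i, j]
            assert v > q3[j] + 3 * iqr[j] or v < q1[j] - 3 * iqr[j]

    def test_univariate_truth_is_exact(self):
        X = generate_lowrank_gaussian(50, 5, 2, seed=3)
        Xc, truth = inject_univariate_outliers(X, 10, seed=3)
        changed = set(zip(*np.nonzero(Xc.values != X.values)))
        assert changed == {(i, j) for i, j, _ in truth}

    def test_multivariate_reflection(self):
        X = generate_lowrank_gaussian(60, 6, 2, seed=4)
        Xc, truth = inject_multivariate_outliers(X, 5, seed=4)
        mean = X.values.mean(axis=0)
        sd = X.values.std(axis=0, ddof=1)
        for i, j, orig in truth:
            assert Xc.values[i, j] == pytest.approx(2 * mean[j] - orig)
            assert abs(orig - mean[j]) > 1.5 * sd[j]

    def test_multivariate_reflection_is_involution(self):
        X = generate_lowrank_gaussian(60, 6, 2, seed=5)
        Xc, truth = inject_multivariate_outliers(X, 5, seed=5)
        mean = X.values.mean(axis=0)
        for i, j, orig in truth:
            assert 2 * mean[j] - Xc.values[i, j] == pytest.approx(orig)

    def test_multivariate_stays_inside_univariate_fences(self):
        # reflected Gaussian cells do not become box-plot outliers
        X = generate_lowrank_gaussian(200, 8, 3, noise_sd=0.1, seed=6)
        Xc, truth = inject_multivariate_outliers(X, 5, seed=6)
        q1 = np.percentile(X.values, 25, axis=0)
        q3 = np.percentile(X.values, 75, axis=0)
        iqr = q3 - q1
        for i, j, _ in truth:
            v = Xc.values[i, j]
            assert q1[j] - 3 * iqr[j] < v < q3[j] + 3 * iqr[j]


class TestPrecisionRecall:
    def net(self, pairs, variables=("a", "b", "c", "d")):
        return InferredNetwork(list(variables),
                               [Edge(s, t, 1.0, "undirected") for s, t in pairs])

    def test_identical_sets(self):
        n = self.net([("a", "b"), ("c", "d")])
        ev = precision_recall(n, n)
        assert ev.precision == 1.0 and ev.recall == 1.0

    def test_hand_counts(self):
        inferred = self.net([("a", "b"), ("b", "c"), ("a", "d")])
        reference = self.net([("a", "b"), ("b", "c"), ("c", "d")])
        ev = precision_recall(inferred, reference)
        assert (ev.tp, ev.fp, ev.fn) == (2, 1, 1)
        assert ev.precision == pytest.approx(2 / 3)
        assert ev.recall == pytest.approx(2 / 3)

    def test_empty_inferred_undefined_precision(self):
        ev = precision_recall(self.net([]), self.net([("a", "b")]))
        assert ev.precision is None and ev.recall == 0.0

    def test_disjoint_variables_rejected(self):
        with pytest.raises(ValueError, match="share no variables"):
            precision_recall(self.net([], variables=("a", "b")),
                             self.net([], variables=("x", "y")))


class TestRunStudy:
    CFG = {
        "kind": "missing",
        "methods": ["tsr", "mi", "cc"],
        "percentages": [0, 35],
        "n_repetitions": 2,
        "seed": 11,
        "generator": {"n_timepoints": 120},
        "infer": {"max_lag": 2, "n_permutations": 10},
    }

    def test_zero_pct_identity_and_cc_infeasible_at_35(self):
        table, _ = run_study(self.CFG)
        zero = table[table.pct == 0]
        assert (zero.precision == 1.0).all() and (zero.recall == 1.0).all()
        cc35 = table[(table.method == "cc") & (table.pct == 35)]
        assert cc35.precision.isna().all()
        tsr35 = table[(table.method == "tsr") & (table.pct == 35)]
        assert tsr35.precision.notna().all()

    def test_reproducible_from_master_seed(self):
        t1, _ = run_study(self.CFG)
        t2, _ = run_study(self.CFG)
        assert t1.equals(t2)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown methods"):
            run_study({**self.CFG, "methods": ["tsr", "bogus"]})


def test_noiseless_generator_has_exact_rank():
    X = generate_noiseless_lowrank(30, 8, 3, seed=0)
    s = np.linalg.svd(X.values - X.values.mean(axis=0), compute_uv=False)
    assert s[3] < 1e-10 * s[0]
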