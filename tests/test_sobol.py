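"""Sobol index estimator, densities and total-variation distance."""

import numpy as np
import pytest

from mvsens.sobol_sensitivity import (
    SobolResult,
    common_grid,
    estimate_density,
    first_order_indices,
    rank_parameters,
    total_variation,
)


def _uniform_cube_sampler(d, lo=0.0, hi=1.0):
    def sampler(n, rng):
        return lo + (hi - lo) * rng.random((n, d))

    return sampler


class TestFirstOrderIndices:
    def test_additive_linear_model_variance_split(self):
        # Y = X1 + 2 X2 + 0 X3, Xi ~ U(0,1): S = (0.2, 0.8, 0.0)
        model = lambda X: X[:, 0] + 2.0 * X[:, 1]
        res = first_order_indices(model, _uniform_cube_sampler(3),
                                  n_outer=1000, n_inner=1000, seed=0)
        np.testing.assert_allclose(res.indices, [0.2, 0.8, 0.0], atol=0.02)

    def test_constant_model_warns_and_returns_zero(self):
        model = lambda X: np.full(len(X), 7.0)
        with pytest.warns(UserWarning, match="zero variance"):
            res = first_order_indices(model, _uniform_cube_sampler(2),
                                      n_outer=5, n_inner=5, seed=0)
        assert res.degenerate
        np.testing.assert_array_equal(res.indices, 0.0)

    def test_deterministic_for_equal_seeds(self):
        model = lambda X: X[:, 0] ** 2 + X[:, 1]
        r1 = first_order_indices(model, _uniform_cube_sampler(2), 20, 20, seed=3)
        r2 = first_order_indices(model, _uniform_cube_sampler(2), 20, 20, seed=3)
        np.testing.assert_array_equal(r1.indices, r2.indices)

    def test_matches_bruteforce_double_loop_exactly(self):
        """The vectorized estimator agrees with an independently coded
        scalar double loop to 1e-12 when both consume identical draws."""

        def poly(x1, x2, x3):
            return 1.0 + 2.0 * x1 - x2**2 + 0.5 * x1 * x3

        model = lambda X: poly(X[:, 0], X[:, 1], X[:, 2])
        sampler = _uniform_cube_sampler(3)
        n_outer, n_inner, seed = 25, 40, 123

        res = first_order_indices(model, sampler, n_outer, n_inner, seed=seed)

        # --- brute force: plain loops, replaying the documented draw order
        rng = np.random.default_rng(seed)
        all_outputs = []
        v = []
        for d in range(3):
            fixed = sampler(n_outer, rng)[:, d]
            means = []
            for i in range(n_outer):
                X = sampler(n_inner, rng)
                total = 0.0
                for j in range(n_inner):
                    row = [X[j, 0], X[j, 1], X[j, 2]]
                    row[d] = fixed[i]
                    val = poly(row[0], row[1], row[2])
                    total += val
                    all_outputs.append(val)
                means.append(total / n_inner)
            mbar = sum(means) / n_outer
            v.append(sum((m - mbar) ** 2 for m in means) / (n_outer - 1))
        ybar = sum(all_outputs) / len(all_outputs)
        var_y = sum((y - ybar) ** 2 for y in all_outputs) / (len(all_outputs) - 1)

        np.testing.assert_allclose(res.indices, np.array(v) / var_y, rtol=1e-12)
        assert res.total_variance == pytest.approx(var_y, rel=1e-10)

    def test_error_shrinks_with_quadrupled_budget(self):
        model = lambda X: X[:, 0] + 2.0 * X[:, 1] + 3.0 * X[:, 2]
        truth = np.array([1.0, 4.0, 9.0]) / 14.0
        errs = {}
        for n in (50, 200):
            e = []
            for seed in range(5):
                res = first_order_indices(model, _uniform_cube_sampler(3),
                                          n, n, seed=seed)
                e.append(np.abs(res.indices - truth).max())
            errs[n] = np.mean(e)
        assert errs[200] < errs[50]

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            first_order_indices(lambda X: X[:, 0], _uniform_cube_sampler(1), 1, 10)


class TestRanking:
    def _result(self, names, s):
        s = np.asarray(s, float)
        return SobolResult(list(names), s, s.copy(), 1.0, 10, 10, 0)

    def test_top_k_by_index(self):
        r = self._result(["a", "b", "c"], [0.5, 0.3, 0.1])
        assert rank_parameters(r, 2) == ["a", "b"]
        assert rank_parameters(r, 3) == ["a", "b", "c"]

    def test_ties_broken_alphabetically(self):
        r = self._result(["z", "a", "m"], [0.4, 0.4, 0.1])
        assert rank_parameters(r, 2) == ["a", "z"]

    def test_k_larger_than_dimension_rejected(self):
        r = self._result(["a", "b"], [0.6, 0.4])
        with pytest.raises(ValueError):
            rank_parameters(r, 3)


class TestDensity:
    def test_single_bin_mass(self):
        edges = np.linspace(0.0, 10.0, 11)
        d = estimate_density(np.full(50, 3.5), edges)
        assert d.density[3] == pytest.approx(1.0 / d.bin_width)
        assert d.density.sum() * d.bin_width == pytest.approx(1.0)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        d = estimate_density(rng.normal(size=5000), n_bins=64)
        assert d.density.sum() * d.bin_width == pytest.approx(1.0, abs=1e-6)

    def test_uniform_samples_flat_density(self):
        rng = np.random.default_rng(1)
        samples = rng.uniform(2.0, 6.0, 200000)
        d = estimate_density(samples, np.linspace(2.0, 6.0, 41))
        np.testing.assert_allclose(d.density, 0.25, rtol=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.array([1.0]))


class TestTotalVariation:
    def test_identical_densities_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        edges = common_grid([x], 50)
        d = estimate_density(x, edges)
        assert total_variation(d, d) == 0.0

    def test_disjoint_supports_one(self):
        edges = np.linspace(0.0, 10.0, 101)
        p = estimate_density(np.random.default_rng(3).uniform(0, 2, 1000), edges)
        q = estimate_density(np.random.default_rng(4).uniform(8, 10, 1000), edges)
        assert total_variation(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 3000), rng.normal(0.7, 1.3, 3000)
        edges = common_grid([a, b], 60)
        p, q = estimate_density(a, edges), estimate_density(b, edges)
        tv = total_variation(p, q)
        assert tv == total_variation(q, p)
        assert 0.0 <= tv <= 1.0

    def test_triangle_inequality(self):
        rng = np.random.default_rng(6)
        xs = [rng.normal(mu, 1, 4000) for mu in (0.0, 1.0, 2.5)]
        edges = common_grid(xs, 80)
        p, q, r = (estimate_density(x, edges) for x in xs)
        assert total_variation(p, r) <= total_variation(p, q) + total_variation(q, r) + 1e-12

    def test_mismatched_grids_rejected(self):
        p = estimate_density(np.arange(10.0), np.linspace(0, 9, 11))
        q = estimate_density(np.arange(10.0), np.linspace(0, 9, 12))
        with pytest.raises(ValueError, match="grids"):
            total_variation(p, q)
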