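"""Sobol' machinery: sample-size rule, Saltelli design, Jansen estimators."""

import numpy as np
import pytest

from ricesalt.sensitivity import (
    ParameterDistributionSet,
    sobol_sample_size,
    base_sample_size,
    saltelli_sample,
    sobol_indices,
    select_ideotype,
)


def brute_force_sample_size(n, gamma):
    """Independent enumeration of the 2**(q+3)*(2n+2) rule."""
    candidates = [2 ** (q + 3) * (2 * n + 2) for q in range(1, 40)]
    return min(m for m in candidates if m > gamma * n)


class TestSampleSizeRule:
    @pytest.mark.parametrize("n,gamma", [(10, 500), (1, 1), (3, 100), (7, 250), (10, 1)])
    def test_matches_brute_force_enumeration(self, n, gamma):
        assert sobol_sample_size(n, gamma) == brute_force_sample_size(n, gamma)

    def test_reference_configuration(self):
        assert sobol_sample_size(10, 500) == 5632

    def test_single_parameter_floor(self):
        assert sobol_sample_size(1, 1) == 64

    def test_minimal_admissible_size(self):
        n = 4
        assert sobol_sample_size(n, 0) == 2**4 * (2 * n + 2)

    def test_base_block_consistency(self):
        n, gamma = 10, 500
        assert base_sample_size(n, gamma) * (2 * n + 2) == 5632


class TestSaltelliSample:
    def test_row_count_for_reference_setup(self):
        dists = ParameterDistributionSet.for_traits()
        X = saltelli_sample(dists, 256, seed=0)
        assert X.shape == (5632, 10)

    def test_zero_sd_collapses_to_means(self):
        dists = ParameterDistributionSet(names=("a", "b"), means=(3.0, 7.0), sds=(0.0, 0.0))
        X = saltelli_sample(dists, 8, seed=0)
        assert np.allclose(X, [3.0, 7.0])

    def test_reproducible_by_seed(self):
        dists = ParameterDistributionSet.for_traits()
        assert np.array_equal(saltelli_sample(dists, 16, seed=5), saltelli_sample(dists, 16, seed=5))
        assert not np.array_equal(saltelli_sample(dists, 16, seed=5), saltelli_sample(dists, 16, seed=6))

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            saltelli_sample(ParameterDistributionSet.for_traits(), 100, seed=0)

    def test_truncation_respects_physical_bounds(self):
        dists = ParameterDistributionSet.for_traits()
        X = saltelli_sample(dists, 64, seed=1)
        for j, nm in enumerate(dists.names):
            assert np.all(X[:, j] >= dists.lower[j])
            assert np.all(X[:, j] <= dists.upper[j])
            # +-4 sd truncation
            assert np.all(np.abs(X[:, j] - dists.means[j]) <= 4 * dists.sds[j] + 1e-12)


class TestSobolIndices:
    def test_additive_linear_model_matches_closed_form(self):
        a = np.array([1.0, 2.0, 0.5])
        s = np.array([1.0, 0.5, 2.0])
        dists = ParameterDistributionSet(names=("x1", "x2", "x3"), means=(0, 0, 0), sds=tuple(s))
        X = saltelli_sample(dists, 512, seed=7)
        res = sobol_indices(X @ a, X, n_boot=20, seed=7)
        expected = (a * s) ** 2 / np.sum((a * s) ** 2)
        assert res.first_order == pytest.approx(expected, abs=0.05)
        assert res.total_order == pytest.approx(expected, abs=0.05)

    def test_inactive_parameter_has_null_indices(self):
        dists = ParameterDistributionSet(names=("x1", "x2"), means=(0, 0), sds=(1, 1))
        X = saltelli_sample(dists, 256, seed=3)
        res = sobol_indices(X[:, 0] ** 2, X, n_boot=20, seed=3)
        assert abs(res.first_order[1]) < 0.05
        assert abs(res.total_order[1]) < 0.05

    def test_total_order_bounds_first_order(self):
        dists = ParameterDistributionSet(
            names=("x1", "x2", "x3"), means=(0, 0, 0), sds=(1, 1, 1),
            families=("uniform",) * 3, lower=(-np.pi,) * 3, upper=(np.pi,) * 3,
        )
        X = saltelli_sample(dists, 512, seed=2)
        y = np.sin(X[:, 0]) + 7 * np.sin(X[:, 1]) ** 2 + 0.1 * X[:, 2] ** 4 * np.sin(X[:, 0])
        res = sobol_indices(y, X, n_boot=50, seed=2)
        for i in range(3):
            assert res.total_order[i] >= res.first_order[i] - 0.05
            assert -0.05 <= res.first_order[i] <= 1.05

    def test_estimates_converge_as_base_doubles(self):
        a = np.array([1.0, 2.0, 0.5])
        dists = ParameterDistributionSet(names=("x1", "x2", "x3"), means=(0, 0, 0), sds=(1, 1, 1))
        expected = a**2 / np.sum(a**2)
        errs = []
        for base_n in (128, 2048):
            rms = []
            for seed in range(4):
                X = saltelli_sample(dists, base_n, seed=seed)
                res = sobol_indices(X @ a, X, n_boot=2, seed=seed)
                rms.append(np.sqrt(np.mean((res.first_order - expected) ** 2)))
            errs.append(np.mean(rms))
        assert errs[1] < errs[0]

    def test_zero_variance_flagged_degenerate(self):
        dists = ParameterDistributionSet(names=("x1",), means=(1.0,), sds=(0.0,))
        X = saltelli_sample(dists, 16, seed=0)
        res = sobol_indices(np.ones(X.shape[0]), X, n_boot=5, seed=0)
        assert res.degenerate
        assert np.all(np.isnan(res.first_order))

    def test_misaligned_outputs_rejected(self):
        dists = ParameterDistributionSet(names=("x1", "x2"), means=(0, 0), sds=(1, 1))
        X = saltelli_sample(dists, 16, seed=0)
        with pytest.raises(ValueError):
            sobol_indices(np.zeros(X.shape[0] - 1), X[:-1], n_params=2)


class TestSelectIdeotype:
    def test_single_row(self):
        X = np.array([[1.0, 2.0]])
        assert select_ideotype(X, np.array([5.0])) == pytest.approx([1.0, 2.0])

    def test_increasing_outputs_pick_last_row(self):
        X = np.arange(10).reshape(5, 2)
        assert select_ideotype(X, np.arange(5)) == pytest.approx(X[-1])

    def test_tie_breaks_to_lowest_index(self):
        X = np.array([[1.0], [2.0], [3.0]])
        assert select_ideotype(X, np.array([7.0, 7.0, 1.0])) == pytest.approx([1.0])

    def test_quadratic_response_surface_optimum(self):
        """Brute-force check: the selected row is the best on a known bowl."""
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(500, 2))
        y = -((X[:, 0] - 0.3) ** 2) - (X[:, 1] + 0.2) ** 2
        best = select_ideotype(X, y)
        assert np.all(y <= y[np.argmax(y)])
        assert np.hypot(best[0] - 0.3, best[1] + 0.2) < 0.15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_ideotype(np.empty((0, 2)), np.array([]))
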