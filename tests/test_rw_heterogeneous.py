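"""Grid likelihood surfaces, population distributions and the mixture model."""

import math

import numpy as np
import pytest

from beelearn import (
    ParamGrid,
    RWParams,
    build_cr_matrix,
    likelihood_surface,
    marginals,
    mixture_loglik,
    population_distribution,
    predicted_curve,
    rw_trajectory,
    simulate_cr_matrix,
)
from beelearn.cr_data import ROLE_CONDITIONING
from beelearn.rw_heterogeneous import (
    NORM_GRID_SUM,
    GridDistribution,
    dataset_mixture_nll,
    point_mass,
)
from beelearn.rw_model import dataset_nll
from beelearn.synthetic_data import PopulationSpec, ProtocolSpec, sample_parameters


@pytest.fixture(scope="module")
def grid():
    return ParamGrid.regular(0.1)


class TestGrid:
    def test_default_grid_is_11_by_11_with_endpoints(self, grid):
        assert grid.shape == (11, 11)
        assert grid.alphas[0] == 0.0 and grid.alphas[-1] == 1.0

    def test_grid_sum_mass_must_normalise(self, grid):
        mass = np.full(grid.shape, 1.0)
        with pytest.raises(ValueError):
            GridDistribution(grid, mass, NORM_GRID_SUM, 1)


class TestSurface:
    def test_all_zero_sequence_peaks_on_axes(self, grid):
        s = likelihood_surface([0] * 5, grid)
        assert np.allclose(s[0, :], 1.0)   # alpha = 0
        assert np.allclose(s[:, 0], 1.0)   # lambda = 0
        assert s[-1, -1] == 0.0            # perfect learner point excluded

    def test_perfect_learner_maximal_at_corner(self, grid):
        s = likelihood_surface([0, 1, 1, 1, 1], grid)
        assert s[-1, -1] == pytest.approx(1.0)
        assert s.max() == pytest.approx(1.0)

    def test_hand_value_at_grid_point(self, grid):
        s = likelihood_surface([0, 1, 1, 1], grid)
        i = list(grid.alphas).index(0.5)
        j = list(grid.lambdas).index(1.0)
        assert s[i, j] == pytest.approx(0.328125)

    def test_entries_are_probabilities(self, grid):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = np.concatenate([[0], rng.integers(0, 2, 5)])
            s = likelihood_surface(x, grid)
            assert np.all((s >= 0) & (s <= 1))


class TestPopulationDistribution:
    def test_single_animal_identity(self, grid):
        m = build_cr_matrix([[0, 1, 1]], [ROLE_CONDITIONING] * 3)
        d = population_distribution(m, grid)
        assert np.allclose(d.mass, likelihood_surface([0, 1, 1], grid))

    def test_duplicate_animals_scale_invariant(self, grid):
        m1 = build_cr_matrix([[0, 1, 1]], [ROLE_CONDITIONING] * 3)
        m2 = build_cr_matrix([[0, 1, 1]] * 2, [ROLE_CONDITIONING] * 3)
        assert np.allclose(
            population_distribution(m1, grid).mass,
            population_distribution(m2, grid).mass,
        )

    def test_nonlearner_dataset_concentrates_on_axes(self, grid):
        m = build_cr_matrix(np.zeros((10, 5), dtype=int), [ROLE_CONDITIONING] * 5)
        d = population_distribution(m, grid)
        interior = d.mass[1:, 1:]
        assert d.mass[0, :].min() == pytest.approx(1.0)
        assert interior.max() < 1.0

    def test_per_animal_mass_is_average_of_likelihoods(self, grid):
        rng = np.random.default_rng(1)
        resp = rng.integers(0, 2, (12, 5))
        resp[:, 0] = 0
        m = build_cr_matrix(resp, [ROLE_CONDITIONING] * 5)
        d = population_distribution(m, grid)
        assert np.all(d.mass >= 0) and np.all(d.mass <= 1)

    def test_grid_sum_normalisation_sums_to_one(self, grid):
        m = build_cr_matrix([[0, 1, 0], [0, 0, 1]], [ROLE_CONDITIONING] * 3)
        d = population_distribution(m, grid, NORM_GRID_SUM)
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-12)


class TestMarginals:
    def test_point_mass_marginals(self, grid):
        d = point_mass(grid, RWParams(0.5, 1.0))
        pa, pl = marginals(d)
        assert pa[list(grid.alphas).index(0.5)] == 1.0
        assert pl[-1] == 1.0
        assert pa.sum() == pytest.approx(1.0) and pl.sum() == pytest.approx(1.0)

    def test_nonlearner_marginal_peaks_at_zero(self, grid):
        m = build_cr_matrix(np.zeros((5, 5), dtype=int), [ROLE_CONDITIONING] * 5)
        d = population_distribution(m, grid)
        pa, _ = marginals(d)
        assert pa[0] == pa.max()


class TestMixture:
    def test_point_mass_reduces_to_sequence_likelihood(self, grid):
        d = point_mass(grid, RWParams(0.5, 1.0))
        assert mixture_loglik([0, 1, 1, 1], d) == pytest.approx(math.log(0.328125))

    def test_impossible_sequence_is_minus_inf(self, grid):
        m = build_cr_matrix([[0, 1, 0], [0, 0, 1]], [ROLE_CONDITIONING] * 3)
        d = population_distribution(m, grid, NORM_GRID_SUM)
        assert mixture_loglik([1, 0, 0], d) == float("-inf")

    def test_uniform_mass_single_zero_trial(self, grid):
        mass = np.full(grid.shape, 1.0 / 121)
        d = GridDistribution(grid, mass, NORM_GRID_SUM, 1)
        assert mixture_loglik([0], d) == pytest.approx(0.0, abs=1e-12)

    def test_requires_grid_sum_normalisation(self, grid):
        m = build_cr_matrix([[0, 1]], [ROLE_CONDITIONING] * 2)
        d = population_distribution(m, grid)  # per_animal_count
        with pytest.raises(ValueError):
            mixture_loglik([0, 1], d)

    def test_mixture_not_worse_than_best_single_grid_point(self, grid):
        """On data fitted to itself, the dataset mixture NLL never exceeds the
        dataset NLL at the single best grid point."""
        spec = PopulationSpec(
            "two_component", nonlearner_fraction=0.3,
            learner_params=RWParams(0.7, 0.95),
        )
        for seed in range(20):
            params = sample_parameters(spec, 40, seed)
            m = simulate_cr_matrix(
                params, ProtocolSpec("fixed_trials", n_conditioning=6), seed + 50
            )
            d = population_distribution(m, grid, NORM_GRID_SUM)
            mix_nll = dataset_mixture_nll(m, d, clamp=1e-9)
            best_point = min(
                dataset_nll(m, RWParams(float(a), float(l)), clamp=1e-9)
                for a in grid.alphas
                for l in grid.lambdas
            )
            assert mix_nll <= best_point + 1e-9

    def test_grid_refinement_consistency(self):
        """Halving the grid spacing moves dataset mixture NLLs of random
        datasets by < 2% (smoothness of the grid approximation)."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            resp = rng.integers(0, 2, (50, 6))
            resp[:, 0] = 0
            m = build_cr_matrix(resp, [ROLE_CONDITIONING] * 6)
            nlls = []
            for spacing in (0.1, 0.05):
                grid_s = ParamGrid.regular(spacing)
                d = population_distribution(m, grid_s, NORM_GRID_SUM)
                nlls.append(dataset_mixture_nll(m, d, clamp=1e-9))
            ok += abs(nlls[1] - nlls[0]) / nlls[0] < 0.02
        assert ok >= 18


class TestPredictedCurve:
    def test_point_masses(self, grid):
        d = point_mass(grid, RWParams(1.0, 1.0))
        assert np.allclose(predicted_curve(d, 4), [0, 1, 1, 1])
        d2 = point_mass(grid, RWParams(0.5, 0.8))
        assert np.allclose(
            predicted_curve(d2, 6), rw_trajectory(RWParams(0.5, 0.8), 6)
        )

    def test_linear_mixing(self, grid):
        mass = np.zeros(grid.shape)
        mass[-1, -1] = 0.5  # (1, 1)
        mass[0, 0] = 0.5    # (0, 0)
        d = GridDistribution(grid, mass, NORM_GRID_SUM, 2)
        assert np.allclose(predicted_curve(d, 5), [0, 0.5, 0.5, 0.5, 0.5])

    def test_monotone_nondecreasing_for_any_mass(self, grid):
        rng = np.random.default_rng(9)
        for _ in range(20):
            mass = rng.random(grid.shape)
            mass /= mass.sum()
            d = GridDistribution(grid, mass / mass.sum(), NORM_GRID_SUM, 1)
            curve = predicted_curve(d, 10)
            assert np.all(np.diff(curve) >= -1e-12)
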