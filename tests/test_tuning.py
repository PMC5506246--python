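"""Parameter identification: brute-force grid, contour fit, rate model, GA."""

import numpy as np
import pytest

from colliculus import tuning
from colliculus.map_geometry import build_grid
from colliculus.tuning import (
    GridResult,
    MapParameterTable,
    assign_map_parameters,
    fit_contour_quadratic,
    fitness_from_summaries,
    genetic_algorithm,
    rate_model_peak,
)


class TestBruteForceGrid:
    def test_count_surface_trend(self, grid_result):
        """More drive (higher w) and faster adaptation recovery (lower
        tau_q) give more spikes.  The trend is asserted globally; the
        discrete count surface carries +/-1-2 local jitter from marginal
        late-burst spikes."""
        counts = grid_result.spike_counts
        # along w: weakest vs strongest drive, every tau row
        assert np.all(counts[:, -1] > counts[:, 0])
        # along tau: slowest vs fastest adaptation, every w column
        assert np.all(counts[0, :] >= counts[-1, :])
        # local jitter stays small
        assert np.diff(counts, axis=1).min() >= -2
        assert np.diff(counts, axis=0).max() <= 2

    def test_contour_exists_and_is_well_sampled(self, grid_result):
        tau, w = grid_result.contour_points()
        assert tau.size >= 10
        assert tau.min() >= 10.0 and tau.max() <= 80.0
        assert w.min() >= 5.0 and w.max() <= 16.0

    def test_peak_rate_rises_with_tau_along_contour(self, grid_result):
        """Rostral cells (high tau_q, strong w) burst at higher rates."""
        tau, w = grid_result.contour_points()
        rates = []
        for t, wv in zip(tau, w):
            i = np.argmin(np.abs(grid_result.tau_q_values - t))
            j = np.argmin(np.abs(grid_result.w_values - wv))
            rates.append(grid_result.peak_rates[i, j])
        lo = np.mean([r for t, r in zip(tau, rates) if t <= 30])
        hi = np.mean([r for t, r in zip(tau, rates) if t >= 60])
        assert hi > lo


class TestContourFit:
    def test_exact_quadratic_recovered(self):
        """A synthetic contour lying exactly on a quadratic is recovered
        to numerical precision with zero residual."""
        tau = np.linspace(10, 80, 12)
        coeffs_true = np.array([-0.002, 0.3, 3.5])
        counts = np.zeros((12, 12), dtype=int)
        np.fill_diagonal(counts, 20)  # cell (i, i) holds w = quad(tau_i)
        grid = GridResult(
            tau_q_values=tau,
            w_values=np.polyval(coeffs_true, tau),
            spike_counts=counts,
            peak_rates=np.zeros((12, 12)),
        )
        coeffs, resid = fit_contour_quadratic(grid)
        assert np.allclose(coeffs, coeffs_true, atol=1e-9)
        assert resid < 1e-9

    def test_fitted_strengths_stay_in_range(self, quadratic):
        tau = np.linspace(10, 80, 100)
        w = np.polyval(quadratic, tau)
        assert w.min() >= 5.0 and w.max() <= 16.0

    def test_too_few_contour_points_rejected(self):
        grid = GridResult(
            tau_q_values=np.array([10.0, 20.0]),
            w_values=np.array([5.0, 6.0]),
            spike_counts=np.array([[20, 0], [0, 0]]),
            peak_rates=np.zeros((2, 2)),
        )
        with pytest.raises(ValueError):
            fit_contour_quadratic(grid)

    def test_closed_loop_counts_cluster_at_target(self, grid_result, quadratic,
                                                  ref_train):
        """Re-simulating at fitted pairs recovers the 20-spike target as
        the modal count, within 2 spikes everywhere."""
        taus = np.unique(grid_result.contour_points()[0])
        counts = tuning.resimulate_counts(taus, quadratic, ref_train)
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == 20
        assert np.all(np.abs(counts - 20) <= 2)


class TestMapAssignment:
    def test_linear_tau_gradient(self, quadratic):
        table = assign_map_parameters(build_grid(), quadratic)
        assert table.tau_q[0] == pytest.approx(80.0)
        assert table.tau_q[-1] == pytest.approx(10.0)
        mid = np.argmin(np.abs(table.u - 2.5))
        assert table.tau_q[mid] == pytest.approx(45.0, abs=0.5)

    def test_strengths_finite_positive_and_parabolic(self, map_table):
        assert np.all(np.isfinite(map_table.w_ff))
        assert np.all(map_table.w_ff > 0)
        # decreasing from rostral (~15-16 nS) to caudal (~6 nS)
        assert map_table.w_ff[0] > map_table.w_ff[-1]
        assert 14.0 < map_table.w_ff[0] < 16.5
        assert 5.0 < map_table.w_ff[-1] < 8.0

    def test_mismatched_columns_rejected(self):
        with pytest.raises(ValueError):
            MapParameterTable(u=np.zeros(3), tau_q=np.zeros(3), w_ff=np.ones(2))


class TestRateModel:
    @pytest.mark.parametrize(
        "r, expected",
        [(0.0, 800.0), (2.0, 800.0 / np.sqrt(1.14)), (35.0, 800.0 / np.sqrt(3.45))],
    )
    def test_values(self, r, expected):
        assert rate_model_peak(r) == pytest.approx(expected, rel=1e-12)

    def test_rounded_extremes_match_the_fitness_targets(self):
        assert round(rate_model_peak(2.0) / 10) * 10 == 750
        assert round(rate_model_peak(35.0) / 10) * 10 == 430


class TestFitness:
    AMPS = np.asarray(tuning.GA_AMPLITUDES)

    def test_perfect_network_scores_zero(self):
        peaks = rate_model_peak(self.AMPS)
        score = fitness_from_summaries(peaks, np.full(7, 20), np.ones(5), self.AMPS)
        assert score == 0.0

    def test_one_spike_count_error_costs_ten(self):
        peaks = rate_model_peak(self.AMPS)
        score = fitness_from_summaries(peaks, np.full(7, 21), np.ones(5), self.AMPS)
        assert score == pytest.approx(10.0)

    def test_small_desynchronization_costs_ten(self):
        peaks = rate_model_peak(self.AMPS)
        score = fitness_from_summaries(
            peaks, np.full(7, 20), np.full(5, 0.99), self.AMPS
        )
        assert score == pytest.approx(10.0)


class TestGeneticAlgorithm:
    @staticmethod
    def cheap_fitness(pair):
        """Smooth surrogate with optimum at (160, 50) pS."""
        return (pair[0] - 160.0) ** 2 + (pair[1] - 50.0) ** 2

    def test_best_fitness_never_worsens(self):
        _, history = genetic_algorithm(self.cheap_fitness, seed=3)
        best = [st.best_fitness for st in history]
        assert all(b2 <= b1 for b1, b2 in zip(best, best[1:]))

    def test_same_seed_same_history(self):
        best1, h1 = genetic_algorithm(self.cheap_fitness, seed=11)
        best2, h2 = genetic_algorithm(self.cheap_fitness, seed=11)
        assert best1 == best2
        assert [st.population for st in h1] == [st.population for st in h2]

    def test_different_seeds_explore_differently(self):
        _, h1 = genetic_algorithm(self.cheap_fitness, seed=1)
        _, h2 = genetic_algorithm(self.cheap_fitness, seed=2)
        assert h1[0].population != h2[0].population

    def test_search_descends_toward_the_surrogate_optimum(self):
        """The elitist search stops by the repeat-rank rule within the
        generation cap and can descend far below the initial population."""
        best, history = genetic_algorithm(self.cheap_fitness, seed=2)
        assert 2 <= len(history) <= 50
        assert history[-1].best_fitness < 0.05 * history[0].best_fitness
        assert abs(best[0] - 160) <= 30 and abs(best[1] - 50) <= 30

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            genetic_algorithm(self.cheap_fitness, seed=0, bounds=((500, 10), (10, 500)))
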