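"""Parameter identification for the collicular network.

Two procedures set up the model:

1. **Brute-force single-neuron grid.**  A single SC-preset AdEx neuron
   is driven by the spike train of the most active input-layer neuron
   (the one at the target's image point) for every (tau_q, w) pair on a
   grid spanning the physiological ranges (tau_q 10-80 ms, w 5-16 nS).
   The pairs yielding exactly 20 burst spikes — the average spike count
   of recorded saccade-related collicular cells — form an iso-count
   contour that is fitted with a second-order polynomial w(tau_q).  The
   adaptation time constant is then assigned linearly along the map
   (80 ms rostral to 10 ms caudal) and the feedforward strengths follow
   from the fit, giving every SC neuron distinct burst dynamics with a
   fixed spike count.

2. **Genetic algorithm for the lateral weight scales.**  Candidate
   (w_bar_exc, w_bar_inh) pairs are scored by full network simulations
   at seven amplitudes against (a) the closed-form peak-rate model
   F_peak(r) = F0 / sqrt(1 + beta r), (b) the 20-spike count target and
   (c) unity burst-profile cross-correlations, with a weighted-RMSE
   fitness (weights 0.1 / 10 / 1000).  The search keeps 2 elites out of
   a population of 10 and breeds 8 children per generation by
   single-point crossover on a decimal-digit encoding with 5% per-digit
   mutation, stopping when the two top candidates repeat across
   generations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import adex
from .adex import FEF_PRESET, SC_PRESET, AdExParams, integrate_conductance_batch, integrate_neuron
from .analysis import peak_rate, population_cross_correlations, spike_density
from .connectivity import MexicanHatParams, SynapseParams
from .input_drive import InputParams, external_current
from .map_geometry import MapConstants, MotorMapGrid, build_grid, snap_amplitude
from .network import SimulationConfig, UnstableNetworkError, simulate

__all__ = [
    "GridResult",
    "MapParameterTable",
    "GAState",
    "reference_fef_train",
    "brute_force_grid",
    "fit_contour_quadratic",
    "assign_map_parameters",
    "resimulate_counts",
    "default_map_table",
    "tuned_config",
    "rate_model_peak",
    "fitness_from_summaries",
    "network_fitness",
    "genetic_algorithm",
    "GA_AMPLITUDES",
    "TARGET_SPIKES",
]

#: burst spike-count target for central cells (spikes per optimal saccade)
TARGET_SPIKES = 20

#: saccade amplitudes (deg) used by the genetic-algorithm fitness
GA_AMPLITUDES = (2.0, 5.0, 9.0, 14.0, 20.0, 27.0, 35.0)

#: default brute-force grid: tau_q 10-80 ms (36 values), w 5-16 nS (45 values)
DEFAULT_TAU_GRID = np.linspace(10.0, 80.0, 36)
DEFAULT_W_GRID = np.linspace(5.0, 16.0, 45)


@dataclass
class GridResult:
    """Spike-count and peak-rate surfaces over the (tau_q, w) grid.

    ``spike_counts[i, j]`` and ``peak_rates[i, j]`` correspond to
    ``tau_q_values[i]`` and ``w_values[j]``.  Peak rates use an 8-ms
    Gaussian kernel.
    """

    tau_q_values: np.ndarray
    w_values: np.ndarray
    spike_counts: np.ndarray
    peak_rates: np.ndarray

    def contour_points(self, target_spikes: int = TARGET_SPIKES):
        """(tau_q, w) pairs whose burst holds exactly ``target_spikes``."""
        i, j = np.nonzero(self.spike_counts == target_spikes)
        return self.tau_q_values[i], self.w_values[j]


@dataclass
class MapParameterTable:
    """Per-SC-neuron tuned parameters along the map.

    tau_q decreases linearly from the rostral to the caudal pole;
    w_ff follows the fitted iso-count polynomial w(tau_q).
    """

    u: np.ndarray
    tau_q: np.ndarray
    w_ff: np.ndarray
    quadratic: np.ndarray | None = None  # polyfit coefficients, highest first

    def __post_init__(self) -> None:
        if not (len(self.u) == len(self.tau_q) == len(self.w_ff)):
            raise ValueError("table columns must have equal length")
        if np.any(self.w_ff <= 0) or not np.all(np.isfinite(self.w_ff)):
            raise ValueError("feedforward strengths must be positive and finite")


def reference_fef_train(
    input_params: InputParams | None = None,
    fef_params: AdExParams = FEF_PRESET,
    dt: float = adex.DT_DEFAULT,
    horizon: float = 300.0,
) -> np.ndarray:
    """Spike train (ms) of the most active input-layer neuron.

    The input current is translation invariant, so the neuron at the
    target's image point sees the on-center current regardless of the
    target; its response is the canonical drive for single-neuron tuning.
    """
    ip = input_params or InputParams()
    t = np.arange(int(np.ceil(horizon / dt))) * dt
    current = external_current(0.0, 0.0, t, ip)
    return integrate_neuron(fef_params, dt=dt, horizon=horizon, current=current)


def brute_force_grid(
    tau_q_values: np.ndarray = DEFAULT_TAU_GRID,
    w_values: np.ndarray = DEFAULT_W_GRID,
    reference_train: np.ndarray | None = None,
    sc_params: AdExParams = SC_PRESET,
    synapse: SynapseParams | None = None,
    dt: float = adex.DT_DEFAULT,
    horizon: float = 300.0,
    rate_kernel: float = 8.0,
) -> GridResult:
    """Single-neuron spike-count / peak-rate surfaces over (tau_q, w).

    All grid points are integrated in one vectorized pass, each driven
    by the same reference input-layer spike train through an excitatory
    synapse of the point's strength ``w``.
    """
    if reference_train is None:
        reference_train = reference_fef_train(dt=dt, horizon=horizon)
    tau_q_values = np.asarray(tau_q_values, dtype=float)
    w_values = np.asarray(w_values, dtype=float)
    tau_mesh, w_mesh = np.meshgrid(tau_q_values, w_values, indexing="ij")
    trains = integrate_conductance_batch(
        tau_mesh, w_mesh, reference_train,
        p=sc_params, synapse=synapse, dt=dt, horizon=horizon,
    )
    shape = tau_mesh.shape
    counts = np.array([t.size for t in trains]).reshape(shape)
    rates = np.array(
        [
            peak_rate(spike_density(t, kernel_width=rate_kernel)) if t.size else 0.0
            for t in trains
        ]
    ).reshape(shape)
    return GridResult(
        tau_q_values=tau_q_values,
        w_values=w_values,
        spike_counts=counts,
        peak_rates=rates,
    )


def fit_contour_quadratic(
    grid_result: GridResult, target_spikes: int = TARGET_SPIKES
) -> tuple[np.ndarray, float]:
    """Least-squares quadratic w(tau_q) through the iso-count contour.

    Returns the polynomial coefficients (highest power first, as used by
    ``numpy.polyval``) and the RMS residual in nS.  Raises if the grid
    holds fewer than three contour points.
    """
    tau, w = grid_result.contour_points(target_spikes)
    if tau.size < 3:
        raise ValueError(
            f"need at least 3 grid points with {target_spikes} spikes "
            f"(found {tau.size}); refine the grid"
        )
    coeffs = np.polyfit(tau, w, deg=2)
    resid = float(np.sqrt(np.mean((np.polyval(coeffs, tau) - w) ** 2)))
    return coeffs, resid


def assign_map_parameters(
    grid: MotorMapGrid,
    quadratic: np.ndarray,
    tau_rostral: float = 80.0,
    tau_caudal: float = 10.0,
) -> MapParameterTable:
    """Per-neuron (tau_q, w_ff) table from the fitted iso-count contour.

    tau_q interpolates linearly from ``tau_rostral`` at u = 0 to
    ``tau_caudal`` at the caudal pole; w_ff = quadratic(tau_q).
    """
    u = grid.positions
    frac = u / grid.constants.map_length
    tau_q = tau_rostral + (tau_caudal - tau_rostral) * frac
    w_ff = np.polyval(quadratic, tau_q)
    return MapParameterTable(u=u, tau_q=tau_q, w_ff=w_ff, quadratic=np.asarray(quadratic))


def resimulate_counts(
    tau_q: np.ndarray,
    quadratic: np.ndarray,
    reference_train: np.ndarray | None = None,
    dt: float = adex.DT_DEFAULT,
    horizon: float = 300.0,
) -> np.ndarray:
    """Closed-loop check: spike counts at fitted (tau_q, w(tau_q)) pairs."""
    tau_q = np.asarray(tau_q, dtype=float)
    if reference_train is None:
        reference_train = reference_fef_train(dt=dt, horizon=horizon)
    w = np.polyval(quadratic, tau_q)
    trains = integrate_conductance_batch(
        tau_q, w, reference_train, dt=dt, horizon=horizon
    )
    return np.array([t.size for t in trains])


def default_map_table(
    map_constants: MapConstants | None = None,
    tau_q_values: np.ndarray = DEFAULT_TAU_GRID,
    w_values: np.ndarray = DEFAULT_W_GRID,
    dt: float = adex.DT_DEFAULT,
    horizon: float = 300.0,
) -> MapParameterTable:
    """Full neuron-tuning pipeline with default settings.

    Reference train -> brute-force grid -> quadratic contour fit ->
    linear tau_q assignment along the map.
    """
    mc = map_constants or MapConstants()
    train = reference_fef_train(dt=dt, horizon=horizon)
    grid_result = brute_force_grid(
        tau_q_values, w_values, train, dt=dt, horizon=horizon
    )
    coeffs, _ = fit_contour_quadratic(grid_result)
    return assign_map_parameters(build_grid(mc), coeffs)


def tuned_config(
    target_amplitude: float,
    table: MapParameterTable,
    map_constants: MapConstants | None = None,
    snap: bool = True,
    **overrides,
) -> SimulationConfig:
    """Simulation configuration for a tuned network.

    With ``snap`` (default) the amplitude is moved to the nearest
    grid-representable value so the trial is an optimal saccade for its
    central cell.
    """
    mc = map_constants or MapConstants()
    r = snap_amplitude(target_amplitude, mc) if snap else target_amplitude
    return SimulationConfig(
        target_amplitude=r,
        tau_q=table.tau_q,
        w_ff=table.w_ff,
        map_constants=mc,
        **overrides,
    )


def rate_model_peak(r, F0: float = 800.0, beta: float = 0.07):
    """Closed-form peak-rate model ``F0 / sqrt(1 + beta r)`` (spikes/s).

    ``r`` in degrees; ``beta`` in 1/deg.  Predicts ~750 spikes/s for a
    2-deg saccade falling to ~430 spikes/s at 35 deg.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("amplitude must be nonnegative")
    out = F0 / np.sqrt(1.0 + beta * r)
    return float(out) if out.ndim == 0 else out


def fitness_from_summaries(
    peak_rates: np.ndarray,
    spike_counts: np.ndarray,
    correlations: np.ndarray,
    amplitudes: np.ndarray = np.asarray(GA_AMPLITUDES),
    target_spikes: int = TARGET_SPIKES,
) -> float:
    """Weighted-RMSE fitness from measured burst summaries.

    fitness = 0.1 * RMSE(peak rates vs rate model)
            + 10  * RMSE(central spike counts vs the 20-spike target)
            + 1000 * RMSE(1 - cross-correlations)

    ``correlations`` pools the central-vs-recruited correlations over all
    amplitudes.  Lower is better; a network matching the rate model with
    20 spikes everywhere and perfectly synchronized bursts scores 0.
    """
    peak_rates = np.asarray(peak_rates, dtype=float)
    spike_counts = np.asarray(spike_counts, dtype=float)
    correlations = np.asarray(correlations, dtype=float)
    model = rate_model_peak(np.asarray(amplitudes, dtype=float))
    rmse_peaks = np.sqrt(np.mean((peak_rates - model) ** 2))
    rmse_counts = np.sqrt(np.mean((spike_counts - target_spikes) ** 2))
    rmse_corr = np.sqrt(np.mean((1.0 - correlations) ** 2))
    return float(0.1 * rmse_peaks + 10.0 * rmse_counts + 1000.0 * rmse_corr)


def network_fitness(
    candidate: tuple[float, float],
    table: MapParameterTable,
    amplitudes: tuple[float, ...] = GA_AMPLITUDES,
    map_constants: MapConstants | None = None,
    hat_widths: tuple[float, float] = (0.4, 1.2),
    rate_kernel: float = 8.0,
    **config_overrides,
) -> float:
    """Eq.-of-the-model fitness of a lateral weight pair (pS, pS).

    Runs one full network simulation per amplitude with the candidate's
    Mexican-hat strengths, collects central-cell peak rates and spike
    counts and the recruited-population cross-correlations, and combines
    them with :func:`fitness_from_summaries`.  Invalid hats (excitation
    not dominating) or unstable simulations score ``inf``.
    """
    w_exc, w_inh = candidate
    try:
        hat = MexicanHatParams(
            w_bar_exc=w_exc, w_bar_inh=w_inh,
            sigma_exc=hat_widths[0], sigma_inh=hat_widths[1],
        )
    except ValueError:
        return math.inf
    peaks, counts, corrs = [], [], []
    for r in amplitudes:
        cfg = tuned_config(
            r, table, map_constants=map_constants,
            hat_params=hat, lateral_enabled=True, **config_overrides,
        )
        try:
            spikes = simulate(cfg)
        except UnstableNetworkError:
            return math.inf
        central = spikes.central_index
        train = spikes.sc[central]
        if train.size == 0:
            return math.inf
        counts.append(train.size)
        peaks.append(peak_rate(spike_density(train, kernel_width=rate_kernel)))
        corrs.extend(population_cross_correlations(spikes).values())
    if not corrs:
        return math.inf
    return fitness_from_summaries(
        np.array(peaks), np.array(counts), np.array(corrs), np.asarray(amplitudes)
    )


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

_DIGITS = 4  # each weight encoded as 4 decimal digits of its value in pS


@dataclass
class GAState:
    """One generation of the search: candidates with their fitness."""

    generation: int
    population: list[tuple[int, int]]
    fitness: list[float]
    seed: int | None = None

    @property
    def ranked(self) -> list[tuple[int, int]]:
        order = np.argsort(self.fitness, kind="stable")
        return [self.population[i] for i in order]

    @property
    def best_fitness(self) -> float:
        return float(min(self.fitness))


def _encode(pair: tuple[int, int]) -> list[int]:
    digits = []
    for value in pair:
        digits.extend(int(d) for d in f"{int(round(value)):0{_DIGITS}d}")
    return digits


def _decode(digits: list[int], bounds) -> tuple[int, int]:
    vals = []
    for g, (lo, hi) in zip(range(2), bounds):
        v = int("".join(str(d) for d in digits[g * _DIGITS:(g + 1) * _DIGITS]))
        vals.append(int(np.clip(v, lo, hi)))
    return tuple(vals)


def genetic_algorithm(
    fitness_fn,
    seed: int,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((10, 500), (10, 500)),
    pop_size: int = 10,
    n_elites: int = 2,
    parent_pool: int = 6,
    n_children: int = 8,
    mutation_p: float = 0.05,
    max_generations: int = 50,
) -> tuple[tuple[int, int], list[GAState]]:
    """Evolve (w_bar_exc, w_bar_inh) pairs (integer pS) to minimize fitness.

    Each generation keeps the ``n_elites`` best candidates and breeds
    ``n_children`` children from distinct parent pairs drawn from the
    ``parent_pool`` best, by single-point crossover on the concatenated
    8-digit decimal encoding with per-digit mutation probability
    ``mutation_p``.  The loop stops when the two top-ranked candidates
    are identical in successive generations, or at ``max_generations``.
    Same seed, same ``fitness_fn`` -> identical history.
    """
    (lo0, hi0), (lo1, hi1) = bounds
    if lo0 > hi0 or lo1 > hi1:
        raise ValueError("inverted bounds")
    rng = np.random.default_rng(seed)
    population = [
        (int(rng.integers(lo0, hi0 + 1)), int(rng.integers(lo1, hi1 + 1)))
        for _ in range(pop_size)
    ]
    cache: dict[tuple[int, int], float] = {}

    def score(pair):
        if pair not in cache:
            cache[pair] = float(fitness_fn(pair))
        return cache[pair]

    history: list[GAState] = []
    prev_top2 = None
    for gen in range(max_generations):
        fitness = [score(p) for p in population]
        state = GAState(generation=gen, population=list(population),
                        fitness=fitness, seed=seed)
        history.append(state)
        ranked = state.ranked
        top2 = ranked[:2]
        if prev_top2 is not None and top2 == prev_top2:
            break
        prev_top2 = top2

        elites = ranked[:n_elites]
        pool = ranked[:parent_pool]
        pairs = list(itertools.combinations(range(len(pool)), 2))
        chosen = rng.choice(len(pairs), size=min(n_children, len(pairs)),
                            replace=False)
        children = []
        for idx in chosen:
            i, j = pairs[idx]
            d1, d2 = _encode(pool[i]), _encode(pool[j])
            cut = int(rng.integers(1, 2 * _DIGITS))
            child = d1[:cut] + d2[cut:]
            for k in range(len(child)):
                if rng.random() < mutation_p:
                    child[k] = int(rng.integers(0, 10))
            children.append(_decode(child, bounds))
        population = elites + children
        while len(population) < pop_size:  # degenerate pools
            population.append(
                (int(rng.integers(lo0, hi0 + 1)), int(rng.integers(lo1, hi1 + 1)))
            )

    best = min(cache, key=cache.get)
    return best, history
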