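"""Burst-train summary measures.

Spike-density functions (Gaussian-kernel convolution), peak firing
rates, inter-spike intervals, movement fields and the peak-normalized
cross-correlation used to quantify burst-profile similarity within a
recruited population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import SimulationConfig, SpikeTrainSet, simulate

__all__ = [
    "BurstProfile",
    "spike_density",
    "peak_rate",
    "cross_correlation",
    "movement_field",
    "isi_list",
    "isi_histogram",
    "population_cross_correlations",
]

#: spike-density time-grid resolution, ms (finer than any kernel in use)
GRID_RESOLUTION = 0.5


@dataclass
class BurstProfile:
    """Firing-rate estimate on a time grid aligned to burst onset.

    ``time`` is in ms with t = 0 at the alignment point (first spike of
    the source cell, or of the population's central cell); ``rate`` is in
    spikes/s.  The integral of ``rate`` over the grid recovers the spike
    count when the kernel mass lies inside the window.
    """

    time: np.ndarray
    rate: np.ndarray
    neuron_id: int | None = None
    kernel_width: float = 5.0

    def integral(self) -> float:
        """Time integral of the rate (expected ~ spike count)."""
        return float(np.trapezoid(self.rate, self.time / 1000.0))


def spike_density(
    spike_times: np.ndarray,
    kernel_width: float = 5.0,
    time_grid: np.ndarray | None = None,
    t0: float | None = None,
    neuron_id: int | None = None,
) -> BurstProfile:
    """Spike-density function: sum of unit-mass Gaussians at spike times.

    ``kernel_width`` is the Gaussian standard deviation in ms.  Each
    spike contributes unit mass on the seconds scale, so a single spike
    peaks at ``1000 / (kernel_width * sqrt(2 pi))`` spikes/s.  Times are
    re-expressed relative to ``t0`` (default: the first spike; 0 for an
    empty train).  An empty train yields an all-zero profile.
    """
    if kernel_width <= 0:
        raise ValueError("kernel width must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    if t0 is None:
        t0 = float(spike_times.min()) if spike_times.size else 0.0
    rel = spike_times - t0
    if time_grid is None:
        lo = rel.min() - 5 * kernel_width if rel.size else -5 * kernel_width
        hi = rel.max() + 5 * kernel_width if rel.size else 5 * kernel_width
        time_grid = np.arange(lo, hi + GRID_RESOLUTION, GRID_RESOLUTION)
    else:
        time_grid = np.asarray(time_grid, dtype=float)
    if rel.size:
        d = time_grid[:, None] - rel[None, :]
        rate = (
            np.exp(-(d * d) / (2.0 * kernel_width**2)).sum(axis=1)
            * 1000.0
            / (kernel_width * np.sqrt(2.0 * np.pi))
        )
    else:
        rate = np.zeros_like(time_grid)
    return BurstProfile(
        time=time_grid, rate=rate, neuron_id=neuron_id, kernel_width=kernel_width
    )


def peak_rate(profile: BurstProfile) -> float:
    """Maximum of the spike-density profile (spikes/s)."""
    return float(profile.rate.max()) if profile.rate.size else 0.0


def cross_correlation(
    p_center: BurstProfile,
    p_n: BurstProfile,
    window: tuple[float, float] = (-10.0, 40.0),
) -> float:
    """Peak-normalized profile correlation over an onset-locked window.

    Both profiles are divided by their own maximum, restricted to
    ``window`` (ms relative to burst onset), and correlated as a
    normalized inner product:

        r = sum(Pc_hat * Pn_hat) / (||Pc_hat|| * ||Pn_hat||)

    which lies in [0, 1] for nonnegative profiles and equals 1 iff the
    windows are proportional.  Profiles must share the time grid; an
    all-zero window is undefined and raises ``ValueError``.
    """
    if p_center.time.shape != p_n.time.shape or not np.allclose(
        p_center.time, p_n.time
    ):
        raise ValueError("profiles must share a common time grid")
    mask = (p_center.time >= window[0]) & (p_center.time <= window[1])
    a = p_center.rate[mask]
    b = p_n.rate[mask]
    if a.max(initial=0.0) == 0.0 or b.max(initial=0.0) == 0.0:
        raise ValueError("cross-correlation undefined for an all-zero profile")
    a = a / a.max()
    b = b / b.max()
    denom = np.sqrt((a * a).sum()) * np.sqrt((b * b).sum())
    return float((a * b).sum() / denom)


def population_cross_correlations(
    spikes: SpikeTrainSet,
    kernel_width: float = 5.0,
    window: tuple[float, float] = (-10.0, 40.0),
    radius: float = 0.65,
) -> dict[int, float]:
    """Correlation of each recruited cell's burst with the central cell's.

    Saccade onset (t = 0) is the central cell's first spike; all profiles
    are evaluated on one grid spanning the window.  Returns a mapping
    ``neuron_id -> r`` over active recruited cells, central cell excluded.
    """
    center = spikes.central_index
    central_train = spikes.sc[center]
    if central_train.size == 0:
        raise ValueError("central cell fired no spikes")
    onset = float(central_train.min())
    grid = np.arange(window[0], window[1] + GRID_RESOLUTION, GRID_RESOLUTION)
    p_center = spike_density(
        central_train, kernel_width, time_grid=grid, t0=onset, neuron_id=center
    )
    out: dict[int, float] = {}
    for n in spikes.recruited_indices(radius=radius):
        if n == center:
            continue
        p_n = spike_density(
            spikes.sc[n], kernel_width, time_grid=grid, t0=onset, neuron_id=n
        )
        if p_n.rate.max() == 0.0:
            continue  # no spikes inside the window
        out[n] = cross_correlation(p_center, p_n, window)
    return out


def movement_field(
    neuron_id: int,
    amplitudes: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Spike count of one SC neuron across saccade amplitudes (deg).

    Runs one simulation per amplitude (all other configuration fields
    unchanged) and counts the fixed neuron's spikes.  The count peaks at
    the neuron's preferred amplitude and falls off as the saccade
    diverges from it, more gradually (in degrees) for caudal cells.
    """
    counts = np.empty(len(amplitudes), dtype=int)
    for i, r in enumerate(amplitudes):
        result = simulate(replace_amplitude(config, float(r)))
        counts[i] = result.sc[neuron_id].size
    return counts


def replace_amplitude(config: SimulationConfig, r: float) -> SimulationConfig:
    return replace(config, target_amplitude=r)


def isi_list(spike_times: np.ndarray) -> np.ndarray:
    """Inter-spike intervals (ms); empty for trains with < 2 spikes."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 2:
        return np.empty(0)
    return np.diff(spike_times)


def isi_histogram(
    trains: list[np.ndarray], bin_width: float = 1.0, max_isi: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ISI histogram over many trains: (bin_edges, counts)."""
    isis = np.concatenate([isi_list(t) for t in trains]) if trains else np.empty(0)
    edges = np.arange(0.0, max_isi + bin_width, bin_width)
    counts, _ = np.histogram(isis, bins=edges)
    return edges, counts
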