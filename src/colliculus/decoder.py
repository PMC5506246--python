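"""Dynamic linear ensemble decoding of SC population spikes.

Each SC spike moves the eye by its neuron's fixed, site-specific
minivector; the eye trajectory is the running sum

    S(t) = sum_n sum_s m_n * delta(t - tau_{n,s})

evaluated here for horizontal saccades (v = 0), where the minivector
magnitude is ``kappa * A * (exp(u_n / B_u) - 1)`` — kappa times the
neuron's preferred amplitude.  The global scale ``kappa`` is calibrated
so the decoded 21-degree saccade lands exactly on target; the decoded
step function is then resampled to 1-ms resolution and smoothed with a
Savitzky-Golay filter whose derivative gives the eye velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter

from .map_geometry import inverse_afferent
from .network import SimulationConfig, SpikeTrainSet, simulate

__all__ = [
    "EyeTrace",
    "decode_trajectory",
    "calibrate_kappa",
    "smooth_and_differentiate",
    "decode_eye_trace",
    "peak_velocity_ratio",
    "velocity_ratio_scan",
    "CALIBRATION_AMPLITUDE",
]

#: saccade amplitude (deg) on which kappa is calibrated
CALIBRATION_AMPLITUDE = 21.0

#: resampling grid step, ms
RESAMPLE_DT = 1.0

#: Savitzky-Golay smoothing window (ms) and polynomial order
SAVGOL_WINDOW = 15
SAVGOL_ORDER = 3


@dataclass
class EyeTrace:
    """Decoded eye movement on a uniform time grid.

    time : ms (absolute simulation time)
    position : deg, monotone non-decreasing for single-target trials
    velocity : deg/s
    endpoint : deg, the decoded displacement (kappa-weighted spike sum)
    peak_velocity : deg/s
    onset, offset : ms (offset = first post-peak drop below 5% of peak;
    reporting convenience only)
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    endpoint: float
    peak_velocity: float
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _minivector_magnitudes(spikes: SpikeTrainSet, kappa: float) -> np.ndarray:
    """Horizontal minivector (deg/spike) of every SC neuron."""
    grid = spikes.grid
    return kappa * inverse_afferent(grid.positions, grid.constants)


def decode_trajectory(
    spikes: SpikeTrainSet, kappa: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative eye position at SC spike times.

    Returns ``(times, positions)``: the sorted SC spike times (ms) and
    the running minivector sum after each spike (deg).  FEF spikes do
    not contribute.  The endpoint equals
    ``kappa * sum_n count_n * A (exp(u_n/B_u) - 1)`` independent of the
    spike timing.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    m = _minivector_magnitudes(spikes, kappa)
    times = []
    steps = []
    for n, train in enumerate(spikes.sc):
        if train.size:
            times.append(train)
            steps.append(np.full(train.size, m[n]))
    if not times:
        return np.empty(0), np.empty(0)
    times = np.concatenate(times)
    steps = np.concatenate(steps)
    order = np.argsort(times, kind="stable")
    return times[order], np.cumsum(steps[order])


def calibrate_kappa(
    spikes: SpikeTrainSet, target: float | None = None
) -> float:
    """Efferent scale such that the decoded endpoint hits the target.

    ``target`` defaults to the trial's own target amplitude.  The
    endpoint is linear in kappa, so calibration is a single division of
    the target by the unit-kappa weighted spike sum.  Raises if the SC
    population fired no spikes.
    """
    if target is None:
        target = spikes.config.target_amplitude
    unit = _minivector_magnitudes(spikes, kappa=1.0)
    total = float((unit * spikes.sc_counts()).sum())
    if total == 0.0:
        raise ValueError("cannot calibrate kappa: no SC spikes")
    return target / total


def smooth_and_differentiate(
    times: np.ndarray,
    positions: np.ndarray,
    resample_dt: float = RESAMPLE_DT,
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_ORDER,
) -> EyeTrace:
    """Resample, smooth and differentiate a decoded spike-position series.

    The cumulative positions are linearly interpolated (first-order
    spline) onto a ``resample_dt`` grid, smoothed with a Savitzky-Golay
    filter, and differentiated by the same filter to obtain velocity
    (deg/s).  The filter preserves polynomials up to ``polyorder``, so an
    exact ramp maps to its own slope.
    """
    if times.size < 2:
        raise ValueError("need at least two decoded points")
    grid = np.arange(times[0], times[-1] + resample_dt, resample_dt)
    pos = interp1d(
        times, positions, kind="linear", bounds_error=False,
        fill_value=(positions[0], positions[-1]),
    )(grid)
    window = min(window if window % 2 else window + 1, len(grid) - (len(grid) + 1) % 2)
    if window <= polyorder:
        smoothed = pos
        vel = np.gradient(pos, resample_dt) * 1000.0
    else:
        smoothed = savgol_filter(pos, window, polyorder)
        vel = savgol_filter(pos, window, polyorder, deriv=1, delta=resample_dt) * 1000.0
    peak = float(vel.max()) if vel.size else 0.0
    onset = float(grid[0])
    offset = onset
    if vel.size:
        ipk = int(np.argmax(vel))
        below = np.nonzero(vel[ipk:] < 0.05 * peak)[0]
        offset = float(grid[ipk + below[0]]) if below.size else float(grid[-1])
    return EyeTrace(
        time=grid,
        position=smoothed,
        velocity=vel,
        endpoint=float(positions[-1]),
        peak_velocity=peak,
        onset=onset,
        offset=offset,
    )


def decode_eye_trace(spikes: SpikeTrainSet, kappa: float) -> EyeTrace:
    """Full decode: spike sum -> resampled, smoothed position and velocity."""
    times, positions = decode_trajectory(spikes, kappa)
    return smooth_and_differentiate(times, positions)


def peak_velocity_ratio(
    config: SimulationConfig,
    amplitude: float = CALIBRATION_AMPLITUDE,
) -> float:
    """Peak eye velocity with lateral connections relative to without.

    Simulates the same target twice — lateral connections enabled and
    disabled — recalibrating kappa on each condition's own spike set (the
    calibration saccade is the decoded trial itself), and returns the
    ratio of the two peak velocities.  A zero-weight hat gives exactly 1.
    """
    cfg_on = replace(config, target_amplitude=amplitude, lateral_enabled=True)
    cfg_off = replace(config, target_amplitude=amplitude, lateral_enabled=False)
    peaks = []
    for cfg in (cfg_on, cfg_off):
        spikes = simulate(cfg)
        kappa = calibrate_kappa(spikes)
        peaks.append(decode_eye_trace(spikes, kappa).peak_velocity)
    return peaks[0] / peaks[1]


def velocity_ratio_scan(
    config: SimulationConfig,
    w_inh_values,
    amplitude: float = CALIBRATION_AMPLITUDE,
) -> dict[float, float]:
    """Peak-velocity ratio for each inhibitory strength (pS).

    Excitation and both Gaussian ranges come from ``config.hat_params``;
    only ``w_bar_inh`` varies.  The lateral-free baseline is simulated
    once and shared by all scan points, each condition calibrating its
    own kappa.
    """
    from .connectivity import MexicanHatParams

    base = simulate(replace(config, target_amplitude=amplitude,
                            lateral_enabled=False))
    v_off = decode_eye_trace(base, calibrate_kappa(base)).peak_velocity
    hat = config.hat_params
    out: dict[float, float] = {}
    for w_inh in w_inh_values:
        scan_hat = MexicanHatParams(
            w_bar_exc=hat.w_bar_exc, w_bar_inh=float(w_inh),
            sigma_exc=hat.sigma_exc, sigma_inh=hat.sigma_inh,
        )
        spikes = simulate(replace(config, target_amplitude=amplitude,
                                  lateral_enabled=True, hat_params=scan_hat))
        v_on = decode_eye_trace(spikes, calibrate_kappa(spikes)).peak_velocity
        out[float(w_inh)] = v_on / v_off
    return out
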