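"""Full two-layer trial simulation.

One trial: the target amplitude is placed on the map, the Gaussian-gamma
current drives the input (FEF) layer, FEF spikes reach the SC layer
through one-to-one feedforward synapses, SC spikes recur through the
Mexican-hat lateral synapses, and all spike times are recorded.  The
model is fully deterministic: identical configurations produce
bit-identical spike sets.

Spikes fired at step k are delivered to their targets at step k+1 (the
minimal causal convention, one-step axonal delay).  FEF neurons receive
no synapses; they take the external current directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adex
from .adex import AdExParams, FEF_PRESET, SC_PRESET, euler_update
from .connectivity import MexicanHatParams, SynapseParams, mexican_hat_weights
from .input_drive import InputParams, spatial_profile, temporal_profile
from .map_geometry import MapConstants, MotorMapGrid, afferent_position, build_grid

__all__ = ["SimulationConfig", "SpikeTrainSet", "simulate", "UnstableNetworkError"]


class UnstableNetworkError(RuntimeError):
    """Raised when a neuron exceeds the runaway spike-count guard."""


@dataclass
class SimulationConfig:
    """Everything needed for one deterministic trial.

    ``tau_q`` and ``w_ff`` are per-SC-neuron parameter tables (ms, nS),
    normally produced by :mod:`colliculus.tuning`; they must cover all
    ``map_constants.n_neurons`` neurons.  ``rng_seed`` is recorded for
    provenance only (the simulation itself has no randomness; only the
    genetic algorithm consumes it).
    """

    target_amplitude: float
    tau_q: np.ndarray
    w_ff: np.ndarray
    dt: float = adex.DT_DEFAULT
    horizon: float = 300.0
    lateral_enabled: bool = True
    map_constants: MapConstants = field(default_factory=MapConstants)
    input_params: InputParams = field(default_factory=InputParams)
    fef_params: AdExParams = FEF_PRESET
    sc_params: AdExParams = SC_PRESET
    synapse_params: SynapseParams = field(default_factory=SynapseParams)
    hat_params: MexicanHatParams = field(default_factory=MexicanHatParams)
    spike_guard: int = 200
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon <= 0:
            raise ValueError("dt and horizon must be positive")
        self.tau_q = np.asarray(self.tau_q, dtype=float)
        self.w_ff = np.asarray(self.w_ff, dtype=float)
        n = self.map_constants.n_neurons
        if self.tau_q.size != n or self.w_ff.size != n:
            raise ValueError("parameter tables must cover all SC neurons")


@dataclass
class SpikeTrainSet:
    """Recorded spikes of one trial: per-neuron spike-time arrays (ms)."""

    fef: list[np.ndarray]
    sc: list[np.ndarray]
    grid: MotorMapGrid
    config: SimulationConfig

    @property
    def central_index(self) -> int:
        """SC neuron whose map position is nearest the target image point."""
        u_T = afferent_position(
            self.config.target_amplitude, self.grid.constants
        )
        return self.grid.nearest_index(u_T)

    def sc_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.sc])

    def fef_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.fef])

    def recruited_indices(
        self, radius: float = 0.65, active_only: bool = True
    ) -> np.ndarray:
        """SC neurons within ``radius`` mm of the central neuron.

        With ``active_only`` (the default) only neurons that fired at
        least one spike are returned; firing rates beyond 0.65 mm drop
        to zero, which motivates the default radius.
        """
        center_u = self.grid.positions[self.central_index]
        near = np.abs(self.grid.positions - center_u) <= radius
        if active_only:
            near &= self.sc_counts() > 0
        return np.nonzero(near)[0]

    def event_frame(self) -> pd.DataFrame:
        """All spikes as a (layer, neuron, time_ms) event table."""
        frames = []
        for layer, trains in (("FEF", self.fef), ("SC", self.sc)):
            for n, times in enumerate(trains):
                if times.size:
                    frames.append(
                        pd.DataFrame(
                            {"layer": layer, "neuron": n, "time_ms": times}
                        )
                    )
        if not frames:
            return pd.DataFrame(columns=["layer", "neuron", "time_ms"])
        return pd.concat(frames, ignore_index=True)


def _split_events(
    steps: list[np.ndarray], ids: list[np.ndarray], n: int, dt: float
) -> list[np.ndarray]:
    if not steps:
        return [np.empty(0) for _ in range(n)]
    all_steps = np.concatenate(steps)
    all_ids = np.concatenate(ids)
    trains: list[np.ndarray] = []
    for i in range(n):
        trains.append(np.sort(all_steps[all_ids == i]) * dt)
    return trains


def simulate(config: SimulationConfig) -> SpikeTrainSet:
    """Run one deterministic trial and return the complete spike record.

    Raises :class:`UnstableNetworkError` (naming the worst neuron) if any
    neuron exceeds ``config.spike_guard`` spikes, which signals runaway
    recurrent excitation from unbalanced lateral weights.
    """
    mc = config.map_constants
    grid = build_grid(mc)
    n = grid.n
    dt = config.dt
    n_steps = int(np.ceil(config.horizon / dt))

    u_T = afferent_position(config.target_amplitude, mc)
    ip = config.input_params
    spatial = ip.I0 * spatial_profile(grid.positions, u_T, ip)
    temporal = temporal_profile(np.arange(n_steps) * dt, ip)

    syn = config.synapse_params
    dec_e = np.exp(-dt / syn.tau_e)
    dec_i = np.exp(-dt / syn.tau_i)
    lateral = config.lateral_enabled and (
        config.hat_params.w_bar_exc > 0 or config.hat_params.w_bar_inh > 0
    )
    if lateral:
        W_exc, W_inh = mexican_hat_weights(grid, config.hat_params)

    fef = config.fef_params
    sc = config.sc_params
    w_ff = config.w_ff
    tau_q = config.tau_q

    V_f = np.full(n, fef.E_L)
    q_f = np.zeros(n)
    V_s = np.full(n, sc.E_L)
    q_s = np.zeros(n)
    g_e = np.zeros(n)
    g_i = np.zeros(n)

    f_steps: list[np.ndarray] = []
    f_ids: list[np.ndarray] = []
    s_steps: list[np.ndarray] = []
    s_ids: list[np.ndarray] = []
    counts = np.zeros(n, dtype=int)

    for k in range(n_steps):
        I_f = spatial * temporal[k]
        V_f, q_f, f_spk = euler_update(V_f, q_f, I_f, fef, dt)

        I_s = g_e * (syn.E_e - V_s) + g_i * (syn.E_i - V_s)
        V_s, q_s, s_spk = euler_update(V_s, q_s, I_s, sc, dt, tau_q=tau_q)

        # conductance advance for the next step (decay + delayed delivery)
        g_e *= dec_e
        g_i *= dec_i
        if f_spk.any():
            ids = np.nonzero(f_spk)[0]
            g_e[ids] += w_ff[ids]
            f_ids.append(ids)
            f_steps.append(np.full(ids.size, k + 1.0))
        if s_spk.any():
            ids = np.nonzero(s_spk)[0]
            if lateral:
                g_e = g_e + W_exc[ids].sum(axis=0)
                g_i = g_i + W_inh[ids].sum(axis=0)
            s_ids.append(ids)
            s_steps.append(np.full(ids.size, k + 1.0))
            counts[ids] += 1
            if counts.max() > config.spike_guard:
                worst = int(counts.argmax())
                raise UnstableNetworkError(
                    f"SC neuron {worst} exceeded {config.spike_guard} spikes "
                    f"at t={dt * (k + 1):.2f} ms; lateral weights are likely "
                    "unbalanced"
                )

    return SpikeTrainSet(
        fef=_split_events(f_steps, f_ids, n, dt),
        sc=_split_events(s_steps, s_ids, n, dt),
        grid=grid,
        config=config,
    )
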