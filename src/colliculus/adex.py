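"""Adaptive exponential integrate-and-fire (AdEx) dynamics.

State per neuron: membrane potential ``V`` (mV) and adaptation current
``q`` (pA), evolving as

    C dV/dt = -g_L (V - E_L) + g_L eta exp((V - V_T)/eta) - q + I_inp
    tau_q dq/dt = a (V - E_L) - q

with forward-Euler integration at a fixed step (0.01 ms by default).
When the updated ``V`` reaches the practical spiking threshold
``V_peak``, a spike is recorded and the reset ``V -> V_r``,
``q -> q + b`` is applied within the same step.

The collicular preset has ``V_r = -45 mV > V_T = -50 mV``: after each
reset the exponential term immediately re-drives the neuron, so bursts
terminate only once the accumulated adaptation current ``q`` outweighs
the synaptic drive.  Units are pF, nS, mV, ms, pA throughout (pA/pF =
mV/ms, nS*mV = pA), so no unit conversions appear in the update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .connectivity import SynapseParams

__all__ = [
    "AdExParams",
    "NeuronState",
    "FEF_PRESET",
    "SC_PRESET",
    "DT_DEFAULT",
    "adex_step",
    "euler_update",
    "integrate_neuron",
    "integrate_conductance_batch",
    "unit_conductance_trace",
]

#: default integration step, ms
DT_DEFAULT = 0.01

#: extra headroom on the exponential argument beyond the largest value a
#: sub-reset state can produce; V >= V_peak fires regardless, so the clamp
#: cannot alter spike times
_EXP_ARG_MARGIN = 5.0


@dataclass(frozen=True)
class AdExParams:
    """AdEx biophysical constants.

    C: pF; g_L: nS; E_L: mV; V_T: mV; V_peak: mV; eta: mV (slope factor);
    a: nS (subthreshold adaptation); b: pA (spike-triggered adaptation);
    V_r: mV (reset); tau_q: ms (adaptation time constant).
    """

    C: float
    g_L: float
    E_L: float
    V_T: float
    V_peak: float
    eta: float
    a: float
    b: float
    V_r: float
    tau_q: float

    def __post_init__(self) -> None:
        if min(self.C, self.g_L, self.eta, self.tau_q) <= 0:
            raise ValueError("C, g_L, eta and tau_q must be positive")
        if self.V_peak <= self.V_T:
            raise ValueError("V_peak must exceed V_T")

    def with_tau_q(self, tau_q: float) -> "AdExParams":
        return replace(self, tau_q=tau_q)

    @property
    def exp_arg_max(self) -> float:
        return (self.V_peak - self.V_T) / self.eta + _EXP_ARG_MARGIN


#: input-layer (FEF) neuron preset
FEF_PRESET = AdExParams(
    C=50.0, g_L=2.0, E_L=-70.0, V_T=-50.0, V_peak=-30.0,
    eta=2.0, a=0.0, b=60.0, V_r=-55.0, tau_q=30.0,
)

#: collicular (SC) neuron preset; tau_q varies with map position (10-80 ms)
SC_PRESET = AdExParams(
    C=280.0, g_L=10.0, E_L=-70.0, V_T=-50.0, V_peak=-30.0,
    eta=2.0, a=4.0, b=80.0, V_r=-45.0, tau_q=30.0,
)


class NeuronState(NamedTuple):
    """Membrane potential V (mV) and adaptation current q (pA)."""

    V: float
    q: float


def rest_state(p: AdExParams) -> NeuronState:
    """Initial condition: rest at the leak reversal with no adaptation."""
    return NeuronState(V=p.E_L, q=0.0)


def euler_update(V, q, I_inp, p: AdExParams, dt: float, tau_q=None):
    """One vectorized forward-Euler step; returns (V, q, spiked).

    ``V``, ``q``, ``I_inp`` broadcast together; ``tau_q`` may be an array
    to give each element its own adaptation time constant (defaults to
    ``p.tau_q``).  The reset is applied in-place within the step so the
    returned ``V`` never exceeds ``V_peak``.
    """
    if tau_q is None:
        tau_q = p.tau_q
    arg = np.minimum((V - p.V_T) / p.eta, p.exp_arg_max)
    dV = (-p.g_L * (V - p.E_L) + p.g_L * p.eta * np.exp(arg) - q + I_inp) / p.C
    dq = (p.a * (V - p.E_L) - q) / tau_q
    V_new = V + dt * dV
    q_new = q + dt * dq
    spiked = V_new >= p.V_peak
    V_new = np.where(spiked, p.V_r, V_new)
    q_new = np.where(spiked, q_new + p.b, q_new)
    return V_new, q_new, spiked


def adex_step(
    state: NeuronState, I_inp: float, p: AdExParams, dt: float = DT_DEFAULT
) -> tuple[NeuronState, bool]:
    """Advance a single neuron by one Euler step.

    Returns the new state and whether the neuron spiked (threshold
    crossing followed by reset within the step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.V) and np.isfinite(state.q) and np.isfinite(I_inp)):
        raise ValueError("non-finite state or input")
    V, q, spiked = euler_update(
        np.float64(state.V), np.float64(state.q), I_inp, p, dt
    )
    return NeuronState(float(V), float(q)), bool(spiked)


def unit_conductance_trace(
    presyn_times: np.ndarray, tau: float, dt: float, n_steps: int
) -> np.ndarray:
    """Conductance trace for unit synaptic weight (jump 1 per spike).

    Each presynaptic spike at step k increments the conductance seen from
    step k+1 onward (one-step axonal delay); between spikes the decay is
    exact, ``g <- g * exp(-dt/tau)``.
    """
    g = np.zeros(n_steps)
    decay = np.exp(-dt / tau)
    spike_steps = np.floor(np.asarray(presyn_times, dtype=float) / dt).astype(int)
    jumps = np.bincount(spike_steps[spike_steps < n_steps], minlength=n_steps)
    for k in range(1, n_steps):
        g[k] = g[k - 1] * decay + jumps[k - 1]
    return g


def integrate_neuron(
    p: AdExParams,
    dt: float = DT_DEFAULT,
    horizon: float = 300.0,
    current: np.ndarray | None = None,
    presyn_times: np.ndarray | None = None,
    w: float | None = None,
    synapse: SynapseParams | None = None,
    record: bool = False,
):
    """Integrate one neuron over ``horizon`` ms and return its spike times.

    The drive is either ``current`` (pA per time step, length
    ``ceil(horizon/dt)``; shorter arrays are zero-padded) or a
    presynaptic spike train ``presyn_times`` (ms) delivered through an
    excitatory conductance synapse of strength ``w`` (nS).  With
    ``record=True`` also returns the (V, q) traces.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n_steps = int(np.ceil(horizon / dt))
    if presyn_times is not None:
        if w is None:
            raise ValueError("synaptic drive requires a weight w")
        syn = synapse or SynapseParams()
        g = w * unit_conductance_trace(presyn_times, syn.tau_e, dt, n_steps)
        E_e = syn.E_e
    else:
        if current is None:
            current = np.zeros(n_steps)
        current = np.asarray(current, dtype=float)
        if current.size < n_steps:
            current = np.pad(current, (0, n_steps - current.size))
        g = None

    V = np.float64(p.E_L)
    q = np.float64(0.0)
    spike_times: list[float] = []
    if record:
        V_trace = np.empty(n_steps)
        q_trace = np.empty(n_steps)
    for k in range(n_steps):
        I = g[k] * (E_e - V) if g is not None else current[k]
        V, q, spiked = euler_update(V, q, I, p, dt)
        if spiked:
            spike_times.append((k + 1) * dt)
        if record:
            V_trace[k] = V
            q_trace[k] = q
    times = np.asarray(spike_times)
    if record:
        return times, V_trace, q_trace
    return times


def integrate_conductance_batch(
    tau_q: np.ndarray,
    w: np.ndarray,
    presyn_times: np.ndarray,
    p: AdExParams = SC_PRESET,
    synapse: SynapseParams | None = None,
    dt: float = DT_DEFAULT,
    horizon: float = 300.0,
) -> list[np.ndarray]:
    """Integrate many independent neurons driven by one FEF spike train.

    Each element of ``tau_q`` (ms) / ``w`` (nS) — broadcast to a common
    shape — defines one neuron; all receive the same presynaptic train
    through an excitatory synapse.  Because the drive has unit shape, the
    per-neuron conductance is just ``w * g_unit(t)``, so the whole batch
    advances in one vectorized Euler pass.  Returns one spike-time array
    per neuron (ms).
    """
    syn = synapse or SynapseParams()
    tau_q, w = np.broadcast_arrays(
        np.asarray(tau_q, dtype=float), np.asarray(w, dtype=float)
    )
    shape = tau_q.shape
    tau_q = tau_q.ravel()
    w = w.ravel()
    n = tau_q.size
    n_steps = int(np.ceil(horizon / dt))
    g_unit = unit_conductance_trace(presyn_times, syn.tau_e, dt, n_steps)

    V = np.full(n, p.E_L)
    q = np.zeros(n)
    spikes: list[list[float]] = [[] for _ in range(n)]
    for k in range(n_steps):
        I = w * g_unit[k] * (syn.E_e - V)
        V, q, spiked = euler_update(V, q, I, p, dt, tau_q=tau_q)
        if spiked.any():
            t = (k + 1) * dt
            for idx in np.nonzero(spiked)[0]:
                spikes[idx].append(t)
    del shape  # callers reshape counts themselves if needed
    return [np.asarray(s) for s in spikes]
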