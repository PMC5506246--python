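"""Synapses: feedforward FEF->SC weights and Mexican-hat lateral matrices.

The SC layer receives conductance-based synaptic input

    I_syn = g_exc (E_e - V) + g_inh (E_i - V)

where each conductance jumps instantly by the synaptic strength for every
presynaptic spike and decays exponentially otherwise (time constants
tau_e, tau_i).  Feedforward projections are one-to-one and topographic;
lateral projections follow a difference-of-Gaussians ("Mexican hat")
profile: strong short-range excitation (w_bar_exc, sigma_exc) and weak
long-range inhibition (w_bar_inh, sigma_inh), with self-projections
removed to keep the recurrent activity bounded.  This implements a soft
winner-take-all in which the most active (central) neuron entrains the
burst profiles of its neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_geometry import MotorMapGrid

__all__ = [
    "SynapseParams",
    "MexicanHatParams",
    "ConductanceState",
    "ConnectivityMatrices",
    "mexican_hat_weights",
    "synaptic_current",
    "conductance_step",
]


@dataclass(frozen=True)
class SynapseParams:
    """Reversal potentials (mV) and conductance decay constants (ms)."""

    E_e: float = 0.0
    E_i: float = -80.0
    tau_e: float = 5.0
    tau_i: float = 10.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")


@dataclass(frozen=True)
class MexicanHatParams:
    """Lateral-connectivity profile parameters.

    w_bar_exc, w_bar_inh : pS, Gaussian peak strengths
    sigma_exc, sigma_inh : mm, Gaussian ranges

    The proper Mexican-hat regime has dominant local excitation
    (w_bar_exc > w_bar_inh) reaching less far than the inhibition
    (sigma_inh > sigma_exc); :meth:`validate_hat_shape` enforces this
    and is applied when loading a configuration file.  The constructor
    itself accepts any nonnegative strengths so that characterization
    scans can probe the strong-inhibition regime.
    """

    w_bar_exc: float = 160.0
    w_bar_inh: float = 50.0
    sigma_exc: float = 0.4
    sigma_inh: float = 1.2

    def __post_init__(self) -> None:
        if self.w_bar_exc < 0 or self.w_bar_inh < 0:
            raise ValueError("lateral strengths must be nonnegative")
        if self.sigma_exc <= 0 or self.sigma_inh <= 0:
            raise ValueError("lateral ranges must be positive")

    def validate_hat_shape(self) -> None:
        """Require the soft winner-take-all regime (raises otherwise)."""
        if self.w_bar_exc == self.w_bar_inh == 0.0:
            return  # lateral connections disabled
        if self.w_bar_exc <= self.w_bar_inh:
            raise ValueError("excitation must outweigh inhibition "
                             "(w_bar_exc > w_bar_inh)")
        if self.sigma_inh <= self.sigma_exc:
            raise ValueError("inhibition must reach further "
                             "(sigma_inh > sigma_exc)")

    @classmethod
    def disabled(cls) -> "MexicanHatParams":
        return cls(w_bar_exc=0.0, w_bar_inh=0.0)


@dataclass
class ConductanceState:
    """Per-SC-neuron excitatory and inhibitory conductances (nS)."""

    g_exc: np.ndarray
    g_inh: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "ConductanceState":
        return cls(g_exc=np.zeros(n), g_inh=np.zeros(n))


@dataclass
class ConnectivityMatrices:
    """Feedforward strengths (nS) and lateral matrices (nS).

    ``w_ff[n]`` is the one-to-one FEF->SC strength onto SC neuron n.
    ``W_exc[i, n]`` / ``W_inh[i, n]`` are the lateral strengths from SC
    neuron i onto SC neuron n (symmetric, nonnegative, zero diagonal).
    Lateral entries are stored in nS for consistency with the
    conductance state even though the hat parameters are quoted in pS.
    """

    w_ff: np.ndarray
    W_exc: np.ndarray
    W_inh: np.ndarray
    hat: MexicanHatParams = field(default_factory=MexicanHatParams)


def mexican_hat_weights(
    grid: MotorMapGrid, hat: MexicanHatParams
) -> tuple[np.ndarray, np.ndarray]:
    """Lateral weight matrices (nS) from the difference-of-Gaussians profile.

    W_exc[i, n] = w_bar_exc * exp(-(u_i - u_n)^2 / (2 sigma_exc^2)),
    W_inh analogously, both with zero diagonal.  Strengths are converted
    from pS to nS.
    """
    u = grid.positions
    d2 = (u[:, None] - u[None, :]) ** 2
    W_exc = hat.w_bar_exc * 1e-3 * np.exp(-d2 / (2.0 * hat.sigma_exc**2))
    W_inh = hat.w_bar_inh * 1e-3 * np.exp(-d2 / (2.0 * hat.sigma_inh**2))
    np.fill_diagonal(W_exc, 0.0)
    np.fill_diagonal(W_inh, 0.0)
    return W_exc, W_inh


def synaptic_current(V, g: ConductanceState, p: SynapseParams = SynapseParams()):
    """Total synaptic current (pA): driving-force-weighted conductance sum."""
    return g.g_exc * (p.E_e - V) + g.g_inh * (p.E_i - V)


def conductance_step(
    g: ConductanceState,
    fef_spikes: np.ndarray,
    sc_spikes: np.ndarray,
    conn: ConnectivityMatrices,
    p: SynapseParams = SynapseParams(),
    dt: float = 0.01,
) -> ConductanceState:
    """Advance conductances by one step of ``dt`` ms.

    Decay is exact (``g *= exp(-dt/tau)``).  ``fef_spikes`` and
    ``sc_spikes`` are boolean masks of presynaptic spikes to deliver this
    step (the caller applies the one-step axonal delay): each FEF spike
    at neuron n adds ``w_ff[n]`` to ``g_exc[n]``; each SC spike at neuron
    i adds row ``W_exc[i]`` to ``g_exc`` and ``W_inh[i]`` to ``g_inh``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g_exc = g.g_exc * np.exp(-dt / p.tau_e)
    g_inh = g.g_inh * np.exp(-dt / p.tau_i)
    fef_spikes = np.asarray(fef_spikes, dtype=bool)
    sc_spikes = np.asarray(sc_spikes, dtype=bool)
    if fef_spikes.any():
        g_exc = g_exc.copy()
        g_exc[fef_spikes] += conn.w_ff[fef_spikes]
    if sc_spikes.any():
        g_exc = g_exc + conn.W_exc[sc_spikes].sum(axis=0)
        g_inh = g_inh + conn.W_inh[sc_spikes].sum(axis=0)
    return ConductanceState(g_exc=g_exc, g_inh=g_inh)
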