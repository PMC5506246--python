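"""Log-polar motor-map geometry of the collicular midline.

The afferent mapping places a saccade target of amplitude ``r`` (deg) at
anatomical position ``u = B_u * log((r + A) / A)`` (mm) on the
rostral-caudal axis.  The efferent mapping inverts it: each neuron at
``(u, v)`` contributes a fixed "minivector" per spike whose horizontal
component is ``kappa * A * (exp(u/B_u) * cos(v/B_v) - 1)``.  The model is
one-dimensional (horizontal saccades, direction 0 deg), so the ``v``
coordinate is carried in the formulas but always evaluated at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MapConstants",
    "MotorMapGrid",
    "afferent_position",
    "inverse_afferent",
    "efferent_minivector",
    "build_grid",
    "snap_amplitude",
]


@dataclass(frozen=True)
class MapConstants:
    """Motor-map scaling constants (monkey best-fit values).

    Parameters
    ----------
    B_u : float
        Scale along the rostral-caudal axis, mm.
    B_v : float
        Scale along the direction axis, mm/rad (kept for the 2-D formula;
        evaluated at v = 0 throughout).
    A : float
        Foveal offset of the log mapping, degrees.
    kappa : float
        Degrees-per-spike scaling of the efferent minivectors.  The
        working value is calibrated at run time (see
        :func:`colliculus.decoder.calibrate_kappa`); the default is an
        order-of-magnitude placeholder.
    map_length : float
        Extent of the simulated midline, mm.
    n_neurons : int
        Neurons per layer.
    """

    B_u: float = 1.4
    B_v: float = 1.8
    A: float = 3.0
    kappa: float = 1e-6
    map_length: float = 5.0
    n_neurons: int = 200

    def __post_init__(self) -> None:
        if self.B_u <= 0 or self.A <= 0 or self.map_length <= 0:
            raise ValueError("B_u, A and map_length must be positive")
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons per layer")


@dataclass(frozen=True)
class MotorMapGrid:
    """Uniform neuron grid on the motor-map midline.

    ``positions`` are the anatomical positions ``u_n`` in mm, strictly
    increasing, endpoint-inclusive on ``[0, map_length]``.
    """

    positions: np.ndarray
    constants: MapConstants = field(default_factory=MapConstants)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("grid needs at least two positions")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if pos[0] < 0 or pos[-1] > self.constants.map_length + 1e-12:
            raise ValueError("positions must lie within [0, map_length]")
        spacing = np.diff(pos)
        if not np.allclose(spacing, spacing[0], rtol=1e-9, atol=1e-12):
            raise ValueError("grid spacing must be uniform")

    @property
    def n(self) -> int:
        return self.positions.size

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def nearest_index(self, u: float) -> int:
        """Index of the neuron closest to position ``u`` (mm); ties break
        toward the rostral (smaller-``u``) neuron."""
        d = np.abs(self.positions - u)
        return int(np.argmin(d))  # argmin returns the first (rostral) tie

    def preferred_amplitude(self, index: int) -> float:
        """Optimal saccade amplitude (deg) of neuron ``index``."""
        return inverse_afferent(float(self.positions[index]), self.constants)


def afferent_position(r, c: MapConstants = MapConstants()):
    """Map target amplitude ``r`` (deg) to map position ``u`` (mm).

    ``u = B_u * log((r + A) / A)``; monotonically increasing, u(0) = 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("saccade amplitude must be nonnegative")
    u = c.B_u * np.log((r + c.A) / c.A)
    return float(u) if u.ndim == 0 else u


def inverse_afferent(u, c: MapConstants = MapConstants()):
    """Analytic inverse of :func:`afferent_position`: ``r = A(e^{u/B_u}-1)``."""
    u = np.asarray(u, dtype=float)
    r = c.A * (np.exp(u / c.B_u) - 1.0)
    return float(r) if r.ndim == 0 else r


def efferent_minivector(u, v=0.0, c: MapConstants = MapConstants()):
    """Per-spike movement contribution of a neuron at map site ``(u, v)``.

    Returns the (horizontal, vertical) components in degrees per spike:

    ``m = kappa * [A (e^{u/B_u} cos(v/B_v) - 1),  A e^{u/B_u} sin(v/B_v)]``

    At ``v = 0`` the vertical component vanishes exactly and the
    horizontal component reduces to ``kappa * A * (e^{u/B_u} - 1)``,
    i.e. ``kappa`` times the preferred amplitude of the site.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    e = np.exp(u / c.B_u)
    horiz = c.kappa * c.A * (e * np.cos(v / c.B_v) - 1.0)
    vert = c.kappa * c.A * e * np.sin(v / c.B_v)
    if horiz.ndim == 0:
        return float(horiz), float(vert)
    return horiz, vert


def build_grid(c: MapConstants = MapConstants()) -> MotorMapGrid:
    """Endpoint-inclusive uniform grid of ``n_neurons`` map positions.

    ``u_n = map_length * n / (n_neurons - 1)`` for ``n = 0 .. n_neurons-1``;
    the rostral pole sits at 0 mm and the caudal pole at ``map_length``.
    """
    pos = np.linspace(0.0, c.map_length, c.n_neurons)
    return MotorMapGrid(positions=pos, constants=c)


def snap_amplitude(r: float, c: MapConstants = MapConstants()) -> float:
    """Nearest grid-representable (optimal) saccade amplitude to ``r``.

    Returns the preferred amplitude of the neuron whose map position is
    closest to the afferent image of ``r``, so that a simulation at the
    returned amplitude is an *optimal* saccade for its central cell.
    """
    grid = build_grid(c)
    return grid.preferred_amplitude(grid.nearest_index(afferent_position(r, c)))
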