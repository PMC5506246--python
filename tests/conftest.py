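"""Shared fixtures: the tuned network and a small library of simulations.

All heavyweight objects (reference input train, brute-force tuning grid,
tuned parameter table, standard trial simulations) are session-scoped so
the whole suite pays for each simulation once.
"""

from __future__ import annotations

import pytest

from colliculus import tuning
from colliculus.network import simulate

#: amplitudes (deg) of the three standard populations examined with and
#: without lateral connections
POPULATION_AMPLITUDES = (5.0, 15.0, 25.0)

#: optimal-saccade survey spanning the map
SURVEY_AMPLITUDES = (3.0, 9.0, 15.0, 21.0, 33.0, 47.0, 63.0)


@pytest.fixture(scope="session")
def ref_train():
    return tuning.reference_fef_train()


@pytest.fixture(scope="session")
def grid_result(ref_train):
    return tuning.brute_force_grid(reference_train=ref_train)


@pytest.fixture(scope="session")
def quadratic(grid_result):
    coeffs, _ = tuning.fit_contour_quadratic(grid_result)
    return coeffs


@pytest.fixture(scope="session")
def map_table(quadratic):
    from colliculus.map_geometry import build_grid

    return tuning.assign_map_parameters(build_grid(), quadratic)


@pytest.fixture(scope="session")
def population_sims(map_table):
    """{(amplitude, lateral): SpikeTrainSet} for the three populations."""
    sims = {}
    for r in POPULATION_AMPLITUDES:
        for lateral in (True, False):
            cfg = tuning.tuned_config(r, map_table, lateral_enabled=lateral)
            sims[(r, lateral)] = simulate(cfg)
    return sims


@pytest.fixture(scope="session")
def survey_sims(map_table):
    """{amplitude: SpikeTrainSet} over the optimal-saccade survey (lateral on)."""
    sims = {}
    for r in SURVEY_AMPLITUDES:
        cfg = tuning.tuned_config(r, map_table)
        sims[r] = simulate(cfg)
    return sims


@pytest.fixture(scope="session")
def calibration_sim(map_table):
    """The 21-degree trial (exact target, lateral on) used for kappa."""
    cfg = tuning.tuned_config(21.0, map_table, snap=False)
    return simulate(cfg)
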