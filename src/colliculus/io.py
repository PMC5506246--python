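"""Plain-text file formats for spike sets, tables and traces.

Spike events are stored as a two-column-per-layer CSV event table
(layer, neuron, time_ms).  Every file starts with ``#``-prefixed
metadata lines carrying the configuration hash and the trial settings,
so any output can be traced back to the parameters that produced it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .network import SimulationConfig, SpikeTrainSet
from .map_geometry import build_grid

__all__ = ["write_table", "read_metadata", "write_spikes", "read_spikes"]


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict[str, object] | None = None
) -> None:
    """Write a DataFrame as CSV with ``# key: value`` metadata lines."""
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    with path.open("w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_metadata(path: str | Path) -> dict[str, str]:
    meta = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_spikes(
    spikes: SpikeTrainSet, path: str | Path, run_config: RunConfig | None = None
) -> None:
    meta = {
        "amplitude_deg": spikes.config.target_amplitude,
        "lateral_enabled": spikes.config.lateral_enabled,
        "dt_ms": spikes.config.dt,
        "horizon_ms": spikes.config.horizon,
    }
    if run_config is not None:
        meta["config"] = config_hash(run_config)
    write_table(spikes.event_frame(), path, meta)


def read_spikes(
    path: str | Path, run_config: RunConfig | None = None
) -> SpikeTrainSet:
    """Reload a saved spike set for analysis or decoding.

    The tuned parameter tables are not stored with the events; they are
    irrelevant for analysis, so placeholder tables are attached.
    """
    rc = run_config or RunConfig()
    meta = read_metadata(path)
    df = pd.read_csv(path, comment="#")
    n = rc.map.n_neurons
    cfg = SimulationConfig(
        target_amplitude=float(meta.get("amplitude_deg", 0.0)),
        tau_q=np.full(n, rc.sc.tau_q),
        w_ff=np.ones(n),
        dt=float(meta.get("dt_ms", rc.simulation.dt)),
        horizon=float(meta.get("horizon_ms", rc.simulation.horizon)),
        lateral_enabled=str(meta.get("lateral_enabled", "True")) == "True",
        map_constants=rc.map,
        input_params=rc.input,
        fef_params=rc.fef,
        sc_params=rc.sc,
        synapse_params=rc.synapse,
        hat_params=rc.hat,
    )
    grid = build_grid(rc.map)
    fef = [np.empty(0) for _ in range(n)]
    sc = [np.empty(0) for _ in range(n)]
    for layer, trains in (("FEF", fef), ("SC", sc)):
        sub = df[df["layer"] == layer]
        for neuron, group in sub.groupby("neuron"):
            trains[int(neuron)] = np.sort(group["time_ms"].to_numpy(dtype=float))
    return SpikeTrainSet(fef=fef, sc=sc, grid=grid, config=cfg)
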