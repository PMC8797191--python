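"""File formats: YAML model specs, HDF5 voltage traces, CSV spike trains
and gain curves with JSON sidecars."""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import yaml

from .model import (MorphologySpec, PassiveSpec, SodiumSpec, DiscretizedCell,
                    SpikeTrain, build_cell)

__all__ = [
    "load_model_specs",
    "dump_model_specs",
    "cell_from_config",
    "write_voltage_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_gain_csv",
]


_SPEC_KEYS = {"morphology": MorphologySpec, "passive": PassiveSpec,
              "sodium": SodiumSpec}


def load_model_specs(path: str):
    """Read (MorphologySpec, PassiveSpec, SodiumSpec) from a YAML config.

    Keys mirror the dataclass field names, grouped under 'morphology',
    'passive' and 'sodium'; missing groups or fields take the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = []
    for key, cls in _SPEC_KEYS.items():
        section = dict(raw.get(key) or {})
        if key == "passive" and "region_overrides" in section:
            section["region_overrides"] = tuple(
                tuple(item) for item in section["region_overrides"])
        out.append(cls(**section))
    return tuple(out)


def dump_model_specs(path: str, morphology: MorphologySpec,
                     passive: PassiveSpec, sodium: SodiumSpec):
    payload = {key: dataclasses.asdict(spec) for key, spec in
               zip(_SPEC_KEYS, (morphology, passive, sodium))}
    payload["passive"]["region_overrides"] = [
        list(item) for item in payload["passive"]["region_overrides"]]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def cell_from_config(path: str) -> DiscretizedCell:
    return build_cell(*load_model_specs(path))


def write_voltage_h5(path: str, cell: DiscretizedCell, times: np.ndarray,
                     node_indices, voltages: np.ndarray, seed=None,
                     **attrs):
    """Voltage recordings with full model provenance in the attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ms", data=np.asarray(times))
        fh.create_dataset("node_position_um",
                          data=cell.node_positions[list(node_indices)])
        fh.create_dataset("voltage_mv", data=np.asarray(voltages))
        meta = {k: dataclasses.asdict(s) for k, s in
                zip(_SPEC_KEYS, (cell.morphology, cell.passive, cell.sodium))}
        fh.attrs["model_spec_json"] = json.dumps(meta, default=str)
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        for k, v in attrs.items():
            fh.attrs[k] = v


def write_spikes_csv(path: str, trains):
    """Spike trains as (trial_id, spike_time_ms) rows."""
    import pandas as pd

    rows = [(i, t) for i, tr in enumerate(trains) for t in tr.spike_times]
    pd.DataFrame(rows, columns=["trial_id", "spike_time_ms"]).to_csv(
        path, index=False)


def read_spikes_csv(path: str, trial_duration: float, burn_in: float):
    import pandas as pd

    df = pd.read_csv(path)
    trains = []
    for _tid, grp in df.groupby("trial_id"):
        trains.append(SpikeTrain(
            spike_times=np.sort(grp["spike_time_ms"].to_numpy()),
            trial_duration=trial_duration, burn_in=burn_in))
    return trains


def write_gain_csv(path: str, result, extra_meta: dict | None = None):
    """GainCurve to CSV plus a JSON sidecar with the full configuration."""
    result.curve.to_frame().to_csv(path, index=False)
    meta = {
        "n_trials": result.model.n_trials,
        "n_spikes": result.sta.n_spikes,
        "mean_rate_hz": result.sta.mean_rate,
        "mean_current_na": result.sta.mean_current,
        "ou": dataclasses.asdict(result.model.ou),
        "config": dataclasses.asdict(result.model.config),
        "seed": result.seed,
        "cutoff_hz": result.curve.cutoff,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(os.path.splitext(path)[0] + ".json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
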