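"""On-disk formats for spike data and analysis tables.

Spike tables use one canonical dialect: a long-format table with columns
``cell_id, kind, sf0, speed, trial, spike_time_s`` plus a JSON header
recording duration, trial count and generator provenance. The table is
offered both as delimited text (CSV) and inside an HDF5 container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic_retina import SpikeData

__all__ = [
    "spikes_to_dataframe",
    "spikes_from_dataframe",
    "save_spikes_csv",
    "load_spikes_csv",
    "save_spikes_hdf5",
    "load_spikes_hdf5",
]

COLUMNS = ["cell_id", "kind", "sf0", "speed", "trial", "spike_time_s"]


def spikes_to_dataframe(data: SpikeData) -> pd.DataFrame:
    rows = []
    for (cid, cond, trial), st in data.spike_times.items():
        kind, sf0, speed = cond
        for t in st:
            rows.append((cid, kind, sf0, speed, trial, t))
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(COLUMNS[:5], kind="stable").reset_index(drop=True)


def _header(data: SpikeData) -> dict:
    meta = {
        k: v for k, v in data.meta.items() if k != "expected_counts"
    }
    return {
        "cells": list(data.cells),
        "conditions": [list(c) for c in data.conditions],
        "n_trials": data.n_trials,
        "duration": data.duration,
        "provenance": meta,
    }


def spikes_from_dataframe(df: pd.DataFrame, header: dict) -> SpikeData:
    cells = header["cells"]
    conditions = [tuple(c) for c in header["conditions"]]
    n_trials = header["n_trials"]
    spike_times = {
        (c, cond, t): np.empty(0)
        for c in cells
        for cond in conditions
        for t in range(n_trials)
    }
    for key, grp in df.groupby(["cell_id", "kind", "sf0", "speed", "trial"]):
        cid, kind, sf0, speed, trial = key
        spike_times[(cid, (kind, sf0, speed), trial)] = np.sort(
            grp.spike_time_s.values.astype(float)
        )
    return SpikeData(
        cells=cells,
        conditions=conditions,
        n_trials=n_trials,
        duration=header["duration"],
        spike_times=spike_times,
        meta=header.get("provenance", {}),
    )


def save_spikes_csv(data: SpikeData, stem: str | Path) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    spikes_to_dataframe(data).to_csv(stem.with_suffix(".csv"), index=False)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(_header(data), fh, indent=1)
    return stem.with_suffix(".csv")


def load_spikes_csv(stem: str | Path) -> SpikeData:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    with open(stem.with_suffix(".json")) as fh:
        header = json.load(fh)
    return spikes_from_dataframe(df, header)


def save_spikes_hdf5(data: SpikeData, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = spikes_to_dataframe(data)
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(_header(data))
        g = f.create_group("spikes")
        for col in COLUMNS:
            vals = df[col].values
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)
    return path


def load_spikes_hdf5(path: str | Path) -> SpikeData:
    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        cols = {}
        for col in COLUMNS:
            vals = f["spikes"][col][()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
    return spikes_from_dataframe(pd.DataFrame(cols), header)
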