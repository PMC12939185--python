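"""Container I/O: RF frames, parametric maps, masks, ground-truth tables.

RF frames are stored as HDF5 with the 2-D sample array at ``rf/samples``
and the acquisition metadata as a JSON string at ``rf/meta`` (also written
to a sidecar ``.json`` next to the file).  Parametric maps use
``map/values`` / ``map/meta``, masks ``mask/values``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .imaging import ParametricMap, WindowSpec
from .phantom import RFFrame

__all__ = [
    "save_rf_frame",
    "load_rf_frame",
    "save_parametric_map",
    "load_parametric_map",
    "save_mask",
    "load_mask",
    "save_ground_truth",
]


def _frame_meta(frame: RFFrame) -> dict:
    return {
        "fs": frame.fs,
        "f0": frame.f0,
        "pulse_length": frame.pulse_length,
        "lateral_pitch": frame.lateral_pitch,
        "sound_speed": frame.sound_speed,
    }


def save_rf_frame(frame: RFFrame, path: str | Path, sidecar: bool = True) -> Path:
    path = Path(path)
    meta = _frame_meta(frame)
    with h5py.File(path, "w") as f:
        f.create_dataset("rf/samples", data=frame.samples)
        f.create_dataset("rf/meta", data=json.dumps(meta, sort_keys=True))
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_rf_frame(path: str | Path) -> RFFrame:
    with h5py.File(path, "r") as f:
        samples = f["rf/samples"][()]
        meta = json.loads(f["rf/meta"][()].decode())
    return RFFrame(samples=samples, **meta)


def save_parametric_map(pmap: ParametricMap, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "parameter_id": pmap.parameter_id,
        "origin": list(pmap.origin),
        "window": {
            "side_axial": pmap.window.side_axial,
            "side_lateral": pmap.window.side_lateral,
            "step_axial": pmap.window.step_axial,
            "step_lateral": pmap.window.step_lateral,
            "multiplier": pmap.window.multiplier,
        },
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("map/values", data=pmap.values)
        f.create_dataset("map/meta", data=json.dumps(meta, sort_keys=True))
    return path


def load_parametric_map(path: str | Path) -> ParametricMap:
    with h5py.File(path, "r") as f:
        values = f["map/values"][()]
        meta = json.loads(f["map/meta"][()].decode())
    window = WindowSpec(**meta["window"])
    return ParametricMap(
        values=values,
        parameter_id=meta["parameter_id"],
        window=window,
        origin=tuple(meta["origin"]),
    )


def save_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("mask/values", data=np.asarray(mask, dtype=bool))
    return path


def load_mask(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["mask/values"][()].astype(bool)


def save_ground_truth(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, index=False)
    return path
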