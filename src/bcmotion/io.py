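"""Array/table serialization for stimuli, RFs and simulation results.

One schema, two containers: NPZ (default) and HDF5 (``.h5``/``.hdf5``), each
storing the value arrays plus the physical-grid attributes ({dx, dt,
origin_um, ...}).  Loading validates the schema and reports any missing
attributes.  Feature and DSI tables go through pandas CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaValidationError
from .motion import PredictedResponse
from .responses import SmoothedResponse
from .rf import SpaceTimeRF
from .stimuli import SpaceTimeStimulus

__all__ = [
    "save_stimulus", "load_stimulus",
    "save_rf", "load_rf", "save_rf_population", "load_rf_population",
    "save_smoothed", "load_smoothed",
    "save_table", "load_table",
]

_STIM_REQ = ("values", "dx", "dt", "origin_um")
_RF_REQ = ("weights", "dx", "dt", "origin_um", "center_um", "polarity")


def _is_h5(path) -> bool:
    return str(path).endswith((".h5", ".hdf5"))


def _save(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_h5(path):
        with h5py.File(path, "w") as f:
            for key, val in payload.items():
                if isinstance(val, np.ndarray):
                    f.create_dataset(key, data=val)
                elif val is None:
                    f.attrs[key] = "__none__"
                else:
                    f.attrs[key] = val
    else:
        meta = {k: v for k, v in payload.items() if not isinstance(v, np.ndarray)}
        arrays = {k: v for k, v in payload.items() if isinstance(v, np.ndarray)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _load(path) -> dict:
    path = Path(path)
    if _is_h5(path):
        with h5py.File(path, "r") as f:
            out = {k: f[k][...] for k in f.keys()}
            for k, v in f.attrs.items():
                out[k] = None if (isinstance(v, str) and v == "__none__") else v
        return out
    with np.load(path, allow_pickle=False) as npz:
        out = {k: npz[k] for k in npz.files if k != "__meta__"}
        if "__meta__" in npz.files:
            out.update(json.loads(npz["__meta__"].tobytes().decode()))
    return out


def _require(data: dict, keys, path) -> None:
    missing = [k for k in keys if k not in data]
    if missing:
        raise SchemaValidationError(
            f"{path}: missing required attributes {missing}"
        )


def save_stimulus(path, stim: SpaceTimeStimulus) -> None:
    _save(path, dict(kind="stimulus", values=stim.values, dx=stim.dx,
                     dt=stim.dt, origin_um=stim.origin_um, label=stim.label))


def load_stimulus(path) -> SpaceTimeStimulus:
    data = _load(path)
    _require(data, _STIM_REQ, path)
    return SpaceTimeStimulus(data["values"], dx=float(data["dx"]),
                             dt=float(data["dt"]),
                             origin_um=float(data["origin_um"]),
                             label=str(data.get("label", "")))


def _rf_payload(rf: SpaceTimeRF, prefix: str = "") -> dict:
    return {
        prefix + "weights": rf.weights,
        prefix + "dx": rf.dx,
        prefix + "dt": rf.dt,
        prefix + "origin_um": rf.origin_um,
        prefix + "center_um": rf.center_um,
        prefix + "polarity": int(rf.polarity),
        prefix + "ipl_depth": rf.ipl_depth if rf.ipl_depth is not None else -1.0,
        prefix + "label": rf.label,
    }


def _rf_from(data: dict, prefix: str = "") -> SpaceTimeRF:
    depth = float(data.get(prefix + "ipl_depth", -1.0))
    return SpaceTimeRF(
        data[prefix + "weights"],
        dx=float(data[prefix + "dx"]),
        dt=float(data[prefix + "dt"]),
        origin_um=float(data[prefix + "origin_um"]),
        center_um=float(data[prefix + "center_um"]),
        polarity=int(data[prefix + "polarity"]),
        ipl_depth=None if depth < 0 else depth,
        label=str(data.get(prefix + "label", "")),
    )


def save_rf(path, rf: SpaceTimeRF) -> None:
    _save(path, dict(kind="rf", **_rf_payload(rf)))


def load_rf(path) -> SpaceTimeRF:
    data = _load(path)
    _require(data, _RF_REQ, path)
    return _rf_from(data)


def save_rf_population(path, rfs: list) -> None:
    """All RFs of a population in one container (one group of keys per ROI)."""
    payload: dict = {"kind": "rf_population", "n_rois": len(rfs)}
    for i, rf in enumerate(rfs):
        payload.update(_rf_payload(rf, prefix=f"roi{i:05d}_"))
    _save(path, payload)


def load_rf_population(path) -> list:
    data = _load(path)
    _require(data, ("n_rois",), path)
    n = int(data["n_rois"])
    out = []
    for i in range(n):
        prefix = f"roi{i:05d}_"
        _require(data, [prefix + k for k in _RF_REQ], path)
        out.append(_rf_from(data, prefix))
    return out


def save_smoothed(path, responses: dict) -> None:
    """Persist a {condition: SmoothedResponse} mapping."""
    payload: dict = {"kind": "smoothed", "conditions": json.dumps(list(responses))}
    for label, resp in responses.items():
        payload[f"{label}__mean"] = resp.mean
        payload[f"{label}__sd"] = resp.sd
        payload[f"{label}__times"] = resp.times_s
        payload[f"{label}__discarded"] = bool(resp.discarded)
    _save(path, payload)


def load_smoothed(path) -> dict:
    data = _load(path)
    _require(data, ("conditions",), path)
    out = {}
    for label in json.loads(data["conditions"]):
        _require(data, (f"{label}__mean", f"{label}__sd", f"{label}__times"), path)
        out[label] = SmoothedResponse(
            data[f"{label}__mean"], data[f"{label}__sd"], data[f"{label}__times"],
            condition_label=label,
            discarded=bool(data.get(f"{label}__discarded", False)),
        )
    return out


def save_table(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
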