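"""Recording container I/O and table export.

The on-disk recording container is HDF5 with datasets ``signal`` (channels x
samples, float32), ``fs`` (scalar) and ``channel_area`` (string array), plus
a ``meta`` group whose attributes hold the trial metadata.  A small plain-text
fixture layout (CSV signal matrix + JSON sidecar) is supported for tests.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .core import Recording, TrialMeta

_META_FIELDS = ("culture_id", "trial_index", "genotype", "div", "onset_s", "duration_s")


class SchemaError(ValueError):
    """Raised when a recording container lacks a required field."""


def write_recording(rec: Recording, path: Union[str, Path]) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=np.asarray(rec.signal, dtype=np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("channel_area",
                         data=np.asarray(rec.channel_area, dtype=object),
                         dtype=h5py.string_dtype())
        g = f.create_group("meta")
        for name in _META_FIELDS:
            g.attrs[name] = getattr(rec.meta, name)
    return path


def read_recording(path: Union[str, Path]) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("signal", "fs", "channel_area"):
            if name not in f:
                raise SchemaError(f"recording file {path} lacks dataset {name!r}")
        if "meta" not in f:
            raise SchemaError(f"recording file {path} lacks group 'meta'")
        g = f["meta"]
        for name in _META_FIELDS:
            if name not in g.attrs:
                raise SchemaError(f"recording file {path} lacks meta attribute {name!r}")
        meta = TrialMeta(
            culture_id=str(g.attrs["culture_id"]),
            trial_index=int(g.attrs["trial_index"]),
            genotype=str(g.attrs["genotype"]),
            div=int(g.attrs["div"]),
            onset_s=float(g.attrs["onset_s"]),
            duration_s=float(g.attrs["duration_s"]),
        )
        areas = np.array([a.decode() if isinstance(a, bytes) else str(a)
                          for a in f["channel_area"][()]], dtype=object)
        return Recording(signal=f["signal"][()], fs=float(f["fs"][()]),
                         channel_area=areas, meta=meta)


def write_recording_csv(rec: Recording, signal_path: Union[str, Path],
                        sidecar_path: Union[str, Path]) -> None:
    """Plain-text fixture layout: CSV signal matrix + JSON sidecar."""
    np.savetxt(signal_path, np.asarray(rec.signal, dtype=np.float32), delimiter=",")
    sidecar = {"fs": float(rec.fs),
               "channel_area": [str(a) for a in rec.channel_area],
               "meta": {k: getattr(rec.meta, k) for k in _META_FIELDS}}
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_recording_csv(signal_path: Union[str, Path],
                       sidecar_path: Union[str, Path]) -> Recording:
    sidecar = json.loads(Path(sidecar_path).read_text())
    for name in ("fs", "channel_area", "meta"):
        if name not in sidecar:
            raise SchemaError(f"sidecar {sidecar_path} lacks field {name!r}")
    signal = np.loadtxt(signal_path, delimiter=",", ndmin=2).astype(np.float32)
    return Recording(signal=signal, fs=float(sidecar["fs"]),
                     channel_area=np.asarray(sidecar["channel_area"], dtype=object),
                     meta=TrialMeta(**sidecar["meta"]))


DETECTION_COLUMNS = ["culture_id", "genotype", "div", "area", "band", "present",
                     "n_active_channels", "mode_freq_hz", "peak_power_rel"]


def write_table(df: pd.DataFrame, path: Union[str, Path], columns=None) -> Path:
    """CSV export with a header row and stable column order."""
    path = Path(path)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, index=False, lineterminator="\n")
    return path
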