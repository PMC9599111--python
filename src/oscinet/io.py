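"""Trial-container I/O: HDF5 layout plus an NPZ fallback.

HDF5 layout: datasets ``/data`` (trials x ROIs x samples), ``/time``,
``/group`` (per-trial labels), an ``/atlas`` group with ``labels``,
``hemisphere`` and ``system`` datasets, and root attributes for the
sampling rate and the paradigm window bounds.  ``read(write(ds))``
round-trips bit-exactly, including metadata.  The same container is the
entry point for real source-reconstructed ROI data.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .atlas import AtlasSpec
from .simulate import ParadigmSpec, TrialDataset

__all__ = ["write_dataset", "read_dataset"]

_STR = h5py.string_dtype(encoding="utf-8")


def _paradigm_meta(p: ParadigmSpec) -> dict:
    return {
        "baseline_window": list(p.baseline_window),
        "cue_window": list(p.cue_window),
        "task_window": list(p.task_window),
        "rest_lead": p.rest_lead,
        "sampling_rate": p.sampling_rate,
        "group_sizes": dict(p.group_sizes),
    }


def _paradigm_from_meta(meta: dict) -> ParadigmSpec:
    return ParadigmSpec(
        baseline_window=tuple(meta["baseline_window"]),
        cue_window=tuple(meta["cue_window"]),
        task_window=tuple(meta["task_window"]),
        rest_lead=float(meta["rest_lead"]),
        sampling_rate=float(meta["sampling_rate"]),
        group_sizes={str(k): int(v) for k, v in meta["group_sizes"].items()},
    )


def write_dataset(ds: TrialDataset, path) -> None:
    """Write a trial dataset to ``.h5``/``.hdf5`` or ``.npz``."""
    path = Path(path)
    meta = _paradigm_meta(ds.paradigm)
    if path.suffix == ".npz":
        np.savez(
            path,
            data=ds.data,
            time=ds.time,
            group=np.asarray(ds.group, dtype=str),
            atlas_labels=np.asarray(ds.atlas.roi_labels, dtype=str),
            atlas_hemisphere=np.asarray(ds.atlas.hemisphere, dtype=str),
            atlas_system=np.asarray(ds.atlas.system, dtype=str),
            paradigm_json=np.asarray(json.dumps(meta)),
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
        f.create_dataset("time", data=ds.time)
        f.create_dataset("group", data=np.asarray(ds.group, dtype=object), dtype=_STR)
        g = f.create_group("atlas")
        g.create_dataset("labels", data=list(ds.atlas.roi_labels), dtype=_STR)
        g.create_dataset("hemisphere", data=list(ds.atlas.hemisphere), dtype=_STR)
        g.create_dataset("system", data=list(ds.atlas.system), dtype=_STR)
        f.attrs["sampling_rate"] = ds.sampling_rate
        f.attrs["paradigm_json"] = json.dumps(meta)


def read_dataset(path) -> TrialDataset:
    """Read a trial dataset; validates the container invariants."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            required = {"data", "time", "group", "atlas_labels", "paradigm_json"}
            missing = required - set(z.files)
            if missing:
                raise ValueError(f"malformed container: missing {sorted(missing)}")
            meta = json.loads(str(z["paradigm_json"]))
            atlas = AtlasSpec(
                tuple(str(s) for s in z["atlas_labels"]),
                tuple(str(s) for s in z["atlas_hemisphere"]),
                tuple(str(s) for s in z["atlas_system"]),
            )
            data, time = z["data"], z["time"]
            group = np.asarray([str(s) for s in z["group"]], dtype=object)
    else:
        with h5py.File(path, "r") as f:
            for key in ("data", "time", "group", "atlas"):
                if key not in f:
                    raise ValueError(f"malformed container: missing /{key}")
            if "paradigm_json" not in f.attrs:
                raise ValueError("malformed container: missing paradigm metadata")
            meta = json.loads(f.attrs["paradigm_json"])
            atlas = AtlasSpec(
                tuple(s.decode() for s in f["atlas/labels"][()]),
                tuple(s.decode() for s in f["atlas/hemisphere"][()]),
                tuple(s.decode() for s in f["atlas/system"][()]),
            )
            data = f["data"][()]
            time = f["time"][()]
            group = np.asarray([s.decode() for s in f["group"][()]], dtype=object)
    paradigm = _paradigm_from_meta(meta)
    return TrialDataset(
        data=data,
        group=group,
        time=time,
        sampling_rate=paradigm.sampling_rate,
        atlas=atlas,
        paradigm=paradigm,
    )
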