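"""Readers and writers for the on-disk artifact formats.

Epochs live in an HDF5 container with datasets ``/data``, ``/times``,
``/image_id``, ``/condition``, ``/channel_names``, ``/channel_group`` and root
attributes ``sampling_rate``, ``subject_id``, ``layout_version``.  Derived
results are UTF-8 delimited text with a JSON metadata sidecar so every
figure-level artifact can be regenerated from its sidecar alone.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, FormatError, RDMSeries, ValidationError

LAYOUT_VERSION = 1

_EPOCH_DATASETS = ("data", "times", "image_id", "condition", "channel_names", "channel_group")


def write_epochs(epochs: EpochSet, path: str | os.PathLike, overwrite: bool = False) -> Path:
    """Write a validated :class:`EpochSet` to an HDF5 container."""
    epochs.validate()
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("image_id", data=epochs.image_id)
        f.create_dataset("condition", data=np.asarray(epochs.condition, dtype=str_dt))
        f.create_dataset("channel_names", data=np.asarray(epochs.channel_names, dtype=str_dt))
        f.create_dataset("channel_group", data=np.asarray(epochs.channel_group, dtype=str_dt))
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["layout_version"] = LAYOUT_VERSION
    return path


def read_epochs(path: str | os.PathLike) -> EpochSet:
    """Read an HDF5 epochs container written by :func:`write_epochs`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("layout_version", -1))
        if version != LAYOUT_VERSION:
            raise FormatError(f"unsupported layout_version {version}")
        for name in _EPOCH_DATASETS:
            if name not in f:
                raise FormatError(f"epochs container missing dataset '/{name}'")
        def _strings(name):
            return np.asarray([s.decode() if isinstance(s, bytes) else str(s)
                               for s in f[name][()]], dtype=object)
        epochs = EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            image_id=f["image_id"][()],
            condition=_strings("condition"),
            channel_names=_strings("channel_names"),
            channel_group=_strings("channel_group"),
            sampling_rate=float(f.attrs["sampling_rate"]),
            subject_id=str(f.attrs.get("subject_id", "")),
        )
    return epochs.validate()


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def read_json(path: str | os.PathLike):
    return json.loads(Path(path).read_text())


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_rdm_series(rdm: RDMSeries, path: str | os.PathLike, precision: int = 6) -> Path:
    """Write an RDM series as a long-format CSV plus JSON sidecar.

    The table holds the lower triangle only (``image_i < image_j``), one row
    per (time, pair); the sidecar carries the labels needed to rebuild the
    full symmetric series with :func:`read_rdm_series`.
    """
    rdm.validate()
    path = Path(path)
    K = rdm.n_images
    iu, ju = np.triu_indices(K, k=1)
    rows = {
        "time_ms": np.repeat(rdm.times, iu.size),
        "image_i": np.tile(rdm.image_ids[iu], rdm.times.size),
        "image_j": np.tile(rdm.image_ids[ju], rdm.times.size),
        "accuracy": np.round(rdm.values[:, iu, ju].ravel(), precision),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format=f"%.{precision}f")
    write_json(
        {
            "kind": "rdm_series",
            "subject_id": rdm.subject_id,
            "image_ids": rdm.image_ids,
            "condition_of": {str(k): v for k, v in rdm.condition_of.items()},
            "n_times": int(rdm.times.size),
            "precision": precision,
        },
        _sidecar(path),
    )
    return path


def read_rdm_series(path: str | os.PathLike) -> RDMSeries:
    path = Path(path)
    meta = read_json(_sidecar(path))
    if meta.get("kind") != "rdm_series":
        raise FormatError(f"sidecar of {path} is not an rdm_series sidecar")
    table = pd.read_csv(path)
    image_ids = np.asarray(meta["image_ids"], dtype=np.int64)
    K = image_ids.size
    pos = {int(img): k for k, img in enumerate(image_ids)}
    times = np.unique(table["time_ms"].to_numpy())
    values = np.zeros((times.size, K, K))
    t_index = {t: k for k, t in enumerate(times)}
    ti = table["time_ms"].map(t_index).to_numpy()
    ii = table["image_i"].map(pos).to_numpy()
    jj = table["image_j"].map(pos).to_numpy()
    acc = table["accuracy"].to_numpy()
    values[ti, ii, jj] = acc
    values[ti, jj, ii] = acc
    rdm = RDMSeries(
        values=values,
        times=times,
        image_ids=image_ids,
        condition_of={int(k): v for k, v in meta["condition_of"].items()},
        subject_id=meta.get("subject_id", ""),
    )
    return rdm.validate()


def write_timecourse_table(courses, path: str | os.PathLike, meta: dict | None = None) -> Path:
    """Write a set of :class:`DecodingTimeCourse` objects as one long CSV."""
    path = Path(path)
    frames = []
    for c in courses:
        frames.append(pd.DataFrame({
            "time_ms": c.times, "value": c.accuracy,
            "tag": c.tag, "subject_id": c.subject_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if meta is not None:
        write_json(dict(meta, kind="timecourses"), _sidecar(path))
    return path
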