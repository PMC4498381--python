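"""Dataset, model and configuration I/O.

Two dataset dialects are supported losslessly:

* a directory with one CSV per trial (T rows x M muscle columns, header =
  muscle names) plus a ``manifest.json`` listing trial files and task
  labels;
* a single HDF5 file with a 3-D ``data`` array (S, T, M), an optional
  ``labels`` vector and muscle names as an attribute.

Models are saved either to HDF5 (``temporal``, ``spatial``,
``coefficients`` datasets) or to JSON for small problems. Configurations
are YAML or JSON mappings of CLI flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .model import EMGDataset, SpaceByTimeModel

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "load_config",
]

_HDF5_SUFFIXES = {".h5", ".hdf5"}


def save_dataset(dataset: EMGDataset, path) -> None:
    """Write a dataset to HDF5 (``.h5``/``.hdf5``) or to a CSV+manifest
    directory (any other path)."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=dataset.data)
            if dataset.labels is not None:
                f.create_dataset("labels", data=dataset.labels)
            if dataset.muscle_names is not None:
                f.attrs["muscle_names"] = list(dataset.muscle_names)
        return
    path.mkdir(parents=True, exist_ok=True)
    S, T, M = dataset.dims
    names = dataset.muscle_names or [f"m{j + 1}" for j in range(M)]
    trials = []
    width = max(3, len(str(S)))
    for s in range(S):
        fname = f"trial_{s:0{width}d}.csv"
        pd.DataFrame(dataset.data[s], columns=names).to_csv(path / fname, index=False)
        trials.append(
            {
                "file": fname,
                "label": None if dataset.labels is None else int(dataset.labels[s]),
            }
        )
    manifest = {"trials": trials, "muscle_names": names}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_hdf5_dataset(path: Path) -> EMGDataset:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"])
        labels = np.asarray(f["labels"]) if "labels" in f else None
        names = (
            [str(n) for n in f.attrs["muscle_names"]]
            if "muscle_names" in f.attrs
            else None
        )
    return EMGDataset(data, labels, names)


def _load_manifest_dataset(root: Path) -> EMGDataset:
    manifest_path = root / "manifest.json" if root.is_dir() else root
    root = manifest_path.parent
    try:
        manifest = json.loads(manifest_path.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(f"no dataset manifest at {manifest_path}") from None
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed manifest {manifest_path}: {exc}") from exc
    if "trials" not in manifest:
        raise ValueError(f"malformed manifest {manifest_path}: missing 'trials'")

    matrices, labels, shape = [], [], None
    for entry in manifest["trials"]:
        fpath = root / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing trial file {fpath}")
        mat = pd.read_csv(fpath).to_numpy(dtype=float)
        if np.any(mat < 0):
            raise ValueError(f"trial {entry['file']} contains negative entries")
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise ValueError(
                f"trial {entry['file']} has shape {mat.shape}, expected {shape}"
            )
        matrices.append(mat)
        labels.append(entry.get("label"))
    has_labels = all(lbl is not None for lbl in labels)
    return EMGDataset(
        np.stack(matrices),
        np.asarray(labels, dtype=int) if has_labels else None,
        manifest.get("muscle_names"),
    )


def load_dataset(path) -> EMGDataset:
    """Load a dataset from either on-disk dialect (auto-detected)."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        return _load_hdf5_dataset(path)
    return _load_manifest_dataset(path)


def save_model(model: SpaceByTimeModel, path) -> None:
    """Write a model to HDF5 (``.h5``/``.hdf5``) or JSON (``.json``)."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            f.create_dataset("temporal", data=model.temporal_modules)
            f.create_dataset("spatial", data=model.spatial_modules)
            f.create_dataset("coefficients", data=model.coefficients)
        return
    payload = {
        "temporal": model.temporal_modules.tolist(),
        "spatial": model.spatial_modules.tolist(),
        "coefficients": model.coefficients.tolist(),
    }
    path.write_text(json.dumps(payload))


def load_model(path) -> SpaceByTimeModel:
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            return SpaceByTimeModel(
                np.asarray(f["temporal"]),
                np.asarray(f["spatial"]),
                np.asarray(f["coefficients"]),
            )
    payload = json.loads(path.read_text())
    return SpaceByTimeModel(
        np.asarray(payload["temporal"]),
        np.asarray(payload["spatial"]),
        np.asarray(payload["coefficients"]),
    )


def load_config(path) -> dict:
    """Read a YAML or JSON configuration mapping CLI flags to values."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration {path} must be a mapping")
    return cfg
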