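"""File formats: HDF5 cubes, TIFF masks and images, YAML configs, checkpoints."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .phantom import SpectralCube, WavenumberAxis, make_wavenumber_axis

__all__ = [
    "write_cube", "read_cube", "write_mask", "read_mask",
    "write_rgb", "read_rgb", "write_yaml", "read_yaml",
    "save_checkpoint", "load_checkpoint", "write_metrics_csv",
]


def write_cube(path: str | Path, cube: SpectralCube, seed: int | None = None) -> Path:
    """HDF5 layout: datasets ``data``, ``wavenumbers``; attrs ``pixel_size_um``
    and optionally the generator ``seed``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data, compression="gzip")
        f.create_dataset("wavenumbers", data=cube.axis.values)
        f.attrs["pixel_size_um"] = cube.pixel_size
        if seed is not None:
            f.attrs["seed"] = int(seed)
    return path


def read_cube(path: str | Path) -> SpectralCube:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        nu = f["wavenumbers"][...]
        ps = float(f.attrs["pixel_size_um"])
    step = float(nu[0] - nu[1]) if len(nu) > 1 else 1.0
    axis = WavenumberAxis(float(nu[0]), float(nu[-1]), step, nu)
    return SpectralCube(data, axis, ps)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_rgb(path: str | Path, img: np.ndarray) -> Path:
    """RGB image in [0, 1] -> 8-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.clip(np.asarray(img) * 255, 0, 255).astype(np.uint8))
    return path


def read_rgb(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(float) / 255.0


def write_yaml(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def save_checkpoint(path: str | Path, model, extra: dict | None = None) -> Path:
    """Weights as npz plus a JSON sidecar with architecture and metadata."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    meta = {"in_channels": model.spec.in_channels,
            "depth": model.spec.depth,
            "base_width": model.spec.base_width}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_checkpoint(path: str | Path):
    from .nn import ModelSpec, build_model
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec(in_channels=meta["in_channels"], depth=meta["depth"],
                     base_width=meta["base_width"])
    model = build_model(spec, seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, meta


def write_metrics_csv(path: str | Path, history) -> Path:
    """Per-epoch training log as CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["epoch", "lr", "train_loss", "val_loss", "accuracy",
                     "sensitivity", "specificity", "f1", "auc_roc"])
        for rec in history:
            m = rec.metrics
            wr.writerow([rec.epoch, rec.lr, rec.train_loss, rec.val_loss,
                         m.accuracy, m.sensitivity, m.specificity, m.f1,
                         "" if m.auc_roc is None else m.auc_roc])
    return path
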