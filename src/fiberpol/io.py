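"""File I/O for Mueller images, intensity stacks, parameter maps and FDHs.

Formats
-------
* Mueller image: multi-page float32 TIFF (16 pages, row-major element order
  m11, m12, ..., m44) or HDF5 dataset ``mueller`` of shape (H, W, 4, 4).
* Intensity stack: multi-page float32 TIFF (one page per frame) or HDF5
  dataset ``frames`` of shape (n_frames, H, W).
* Parameter maps: HDF5 group with datasets theta, delta_lr, Delta, alphaP,
  alphaQ, D, mask, or a 7-page float32 TIFF in that order.
* FDH: CSV with columns ``bin_center_deg``, ``mass``.
* Configs and summaries: YAML / JSON.

Every writer embeds a JSON metadata header (TIFF description tag / HDF5
attribute ``config``) echoing the run configuration, so an artifact is
traceable to the run that produced it. Angles are serialized in degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .decomposition import ParamMaps
from .orientation import AxialHistogram

__all__ = [
    "save_mueller", "load_mueller",
    "save_stack", "load_stack",
    "save_param_maps", "load_param_maps",
    "save_fdh", "load_fdh",
    "save_json", "load_json",
    "load_config",
]

ELEMENT_ORDER = [f"m{i}{j}" for i in range(1, 5) for j in range(1, 5)]

_PARAM_NAMES = ["theta", "delta_lr", "Delta", "alphaP", "alphaQ", "D", "mask"]


def _meta_json(meta: dict | None) -> str:
    return json.dumps({"element_order": ELEMENT_ORDER, **(meta or {})})


def _is_hdf5(path) -> bool:
    return Path(path).suffix.lower() in {".h5", ".hdf5"}


def save_mueller(path, M: np.ndarray, meta: dict | None = None):
    M = np.asarray(M, dtype=np.float32)
    if M.ndim != 4 or M.shape[-2:] != (4, 4):
        raise ValueError("Mueller image must have shape (H, W, 4, 4)")
    if _is_hdf5(path):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("mueller", data=M)
            ds.attrs["config"] = _meta_json(meta)
    else:
        pages = np.moveaxis(M.reshape(M.shape[0], M.shape[1], 16), -1, 0)
        tifffile.imwrite(path, pages, photometric="minisblack", description=_meta_json(meta))


def load_mueller(path) -> np.ndarray:
    if _is_hdf5(path):
        with h5py.File(path, "r") as fh:
            return np.asarray(fh["mueller"], dtype=float)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 16:
        raise ValueError(f"expected a 16-page TIFF, got shape {pages.shape}")
    return np.moveaxis(pages, 0, -1).reshape(pages.shape[1], pages.shape[2], 4, 4).astype(float)


def save_stack(path, frames: np.ndarray, meta: dict | None = None):
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3:
        raise ValueError("intensity stack must have shape (n_frames, H, W)")
    if _is_hdf5(path):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=frames)
            ds.attrs["config"] = _meta_json(meta)
    else:
        tifffile.imwrite(path, frames, photometric="minisblack", description=_meta_json(meta))


def load_stack(path) -> np.ndarray:
    if _is_hdf5(path):
        with h5py.File(path, "r") as fh:
            return np.asarray(fh["frames"], dtype=float)
    return np.asarray(tifffile.imread(path), dtype=float)


def save_param_maps(path, maps: ParamMaps, meta: dict | None = None):
    arrays = [
        np.asarray(getattr(maps, name), dtype=np.float32) for name in _PARAM_NAMES
    ]
    if _is_hdf5(path):
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("params")
            grp.attrs["config"] = _meta_json(meta)
            for name, arr in zip(_PARAM_NAMES, arrays):
                if name == "mask":
                    grp.create_dataset(name, data=np.asarray(maps.mask, dtype=np.uint8))
                else:
                    grp.create_dataset(name, data=arr)
    else:
        tifffile.imwrite(path, np.stack(arrays), photometric="minisblack", description=_meta_json(meta))


def load_param_maps(path) -> ParamMaps:
    if _is_hdf5(path):
        with h5py.File(path, "r") as fh:
            grp = fh["params"]
            data = {name: np.asarray(grp[name], dtype=float) for name in _PARAM_NAMES}
    else:
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] != len(_PARAM_NAMES):
            raise ValueError(f"expected a {len(_PARAM_NAMES)}-page TIFF, got {pages.shape}")
        data = {name: np.asarray(pages[i], dtype=float) for i, name in enumerate(_PARAM_NAMES)}
    data["mask"] = data["mask"].astype(np.uint8)
    return ParamMaps(**data)


def save_fdh(path, fdh: AxialHistogram):
    fdh.to_frame().to_csv(path, index=False, float_format="%.6f")


def load_fdh(path) -> AxialHistogram:
    df = pd.read_csv(path)
    centers = df["bin_center_deg"].to_numpy(dtype=float)
    mass = df["mass"].to_numpy(dtype=float)
    width = float(centers[1] - centers[0]) if centers.size > 1 else 180.0
    return AxialHistogram(
        bin_width=width, bin_centers=centers, mass=mass, n_samples=-1
    )


def save_json(path, obj: dict):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if Path(path).suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
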