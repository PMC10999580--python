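"""Lossless image and volume I/O (32-bit TIFF and HDF5)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .recon import Volume, VolumeGrid
from .transport import CountImage

__all__ = [
    "save_count_image_tiff",
    "load_count_image_tiff",
    "save_count_image_hdf5",
    "load_count_image_hdf5",
    "save_volume_hdf5",
    "load_volume_hdf5",
]


def _meta(image: CountImage) -> dict:
    return {
        "panel_id": int(image.panel_id),
        "exposure_time": float(image.exposure_time),
        "rng_seed": None if image.rng_seed is None else int(image.rng_seed),
        "model_tag": image.model_tag,
    }


def save_count_image_tiff(image: CountImage, path: str | Path) -> None:
    """Write counts as 32-bit TIFF with metadata in the image description."""
    counts = np.asarray(image.counts)
    if counts.max(initial=0) > np.iinfo(np.uint32).max:
        raise ValueError("counts exceed the 32-bit TIFF range")
    tifffile.imwrite(
        str(path), counts.astype(np.uint32), description=json.dumps(_meta(image))
    )


def load_count_image_tiff(path: str | Path) -> CountImage:
    with tifffile.TiffFile(str(path)) as tif:
        counts = tif.asarray().astype(np.int64)
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    return CountImage(counts=counts, **_meta_kwargs(meta))


def _meta_kwargs(meta: dict) -> dict:
    return {
        "panel_id": int(meta.get("panel_id", 0)),
        "exposure_time": float(meta.get("exposure_time", 1.0)),
        "rng_seed": meta.get("rng_seed"),
        "model_tag": meta.get("model_tag", "monte-carlo"),
    }


def save_count_image_hdf5(image: CountImage, path: str | Path, name: str = "image") -> None:
    with h5py.File(str(path), "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("counts", data=np.asarray(image.counts, dtype=np.int64))
        for k, v in _meta(image).items():
            g.attrs[k] = "null" if v is None else v


def load_count_image_hdf5(path: str | Path, name: str = "image") -> CountImage:
    with h5py.File(str(path), "r") as f:
        g = f[name]
        counts = g["counts"][()]
        meta = {k: (None if isinstance(v, str) and v == "null" else v) for k, v in g.attrs.items()}
        if isinstance(meta.get("model_tag"), bytes):
            meta["model_tag"] = meta["model_tag"].decode()
    return CountImage(counts=counts, **_meta_kwargs(meta))


def save_volume_hdf5(volume: Volume, path: str | Path, name: str = "volume") -> None:
    with h5py.File(str(path), "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("values", data=np.asarray(volume.values, dtype=np.float64))
        g.attrs["voxel_size"] = float(volume.voxel_size)
        g.attrs["origin"] = np.asarray(volume.origin, dtype=float)


def load_volume_hdf5(path: str | Path, name: str = "volume") -> Volume:
    with h5py.File(str(path), "r") as f:
        g = f[name]
        values = g["values"][()]
        grid = VolumeGrid(tuple(values.shape), float(g.attrs["voxel_size"]), np.asarray(g.attrs["origin"]))
    return Volume(values, grid)
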