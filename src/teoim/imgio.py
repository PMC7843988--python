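"""Image read/write with JSON sidecars carrying the physical grid.

Analyzer frames are stored as 16-bit integer TIFF (or PNG) with values
``round(v * 65535)`` for ``v`` in full-scale [0, 1]; reconstructed maps as
32-bit float TIFF (lossless). Every image gets a ``<path>.json`` sidecar
recording grid geometry and role; reading without the sidecar is an error.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, ParameterError
from .forward_sim import AnalyzerFrameSet
from .grid import GridSpec, ScalarFieldMap

_U16_MAX = 65535


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, grid: GridSpec, role: str, dtype: str, extra=None) -> None:
    doc = {
        "nx": grid.nx,
        "ny": grid.ny,
        "pitch_mm": grid.pitch_mm,
        "x0_mm": grid.x0_mm,
        "y0_mm": grid.y0_mm,
        "role": role,
        "dtype": dtype,
    }
    if extra:
        doc.update(extra)
    _sidecar_path(path).write_text(json.dumps(doc, indent=1))


def write_image(path, field_map: ScalarFieldMap, dtype: str = "uint16",
                extra_sidecar=None) -> None:
    """Write a field map as TIFF/PNG plus its JSON sidecar.

    ``dtype='uint16'`` quantizes full-scale [0, 1] values to 16 bits;
    ``dtype='float32'`` writes a lossless float TIFF (TIFF only).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = field_map.values
    if dtype == "uint16":
        if values.min() < 0 or values.max() > 1:
            raise ParameterError("uint16 images require values in [0, 1] full scale")
        data = np.round(values * _U16_MAX).astype(np.uint16)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, data)
        elif path.suffix.lower() == ".png":
            iio.imwrite(path, data)
        else:
            raise ParameterError(f"unsupported frame format {path.suffix!r}")
    elif dtype == "float32":
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ParameterError("float32 maps are written as TIFF only")
        tifffile.imwrite(path, values.astype(np.float32))
    else:
        raise ParameterError(f"unsupported dtype {dtype!r}; uint16 or float32")
    _write_sidecar(path, field_map.grid, field_map.role, dtype, extra_sidecar)


def read_image(path) -> ScalarFieldMap:
    """Read an image written by :func:`write_image`; requires the sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigError(f"missing sidecar {sidecar} for image {path}")
    doc = json.loads(sidecar.read_text())
    grid = GridSpec(
        doc["nx"], doc["ny"], doc["pitch_mm"], doc.get("x0_mm", 0.0), doc.get("y0_mm", 0.0)
    )
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.shape != grid.shape:
        raise ConfigError(
            f"image {path} shape {data.shape} does not match sidecar grid {grid.shape}"
        )
    if doc["dtype"] == "uint16":
        values = data.astype(float) / _U16_MAX
    else:
        values = data.astype(float)
    return ScalarFieldMap(grid, values, doc.get("role", "field_intensity"), dict(doc))


_FRAME_KEYS = ("i0", "i45", "baseline0", "baseline45")


def write_frame_sets(out_dir, frame_sets, manifest: pd.DataFrame) -> pd.DataFrame:
    """Write every frame set as four 16-bit TIFFs; return manifest with paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for key in _FRAME_KEYS:
        manifest[f"path_{key}"] = ""
    for idx, frames in enumerate(frame_sets):
        stem = f"frame_{idx:04d}"
        for key in _FRAME_KEYS:
            rel = f"{stem}_{key}.tif"
            fmap = ScalarFieldMap(frames.grid, getattr(frames, key), "field_intensity")
            write_image(out_dir / rel, fmap, "uint16", {"i_full": frames.i_full})
            manifest.loc[idx, f"path_{key}"] = rel
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_frame_set(base_dir, row: pd.Series, i_full: float = 1.0) -> AnalyzerFrameSet:
    """Rebuild an :class:`AnalyzerFrameSet` from one manifest row."""
    base = Path(base_dir)
    maps = {key: read_image(base / row[f"path_{key}"]) for key in _FRAME_KEYS}
    grid = maps["i0"].grid
    i_full = float(maps["i0"].meta.get("i_full", i_full))
    return AnalyzerFrameSet(
        grid,
        maps["i0"].values,
        maps["i45"].values,
        maps["baseline0"].values,
        maps["baseline45"].values,
        i_full,
        meta={k: row[k] for k in row.index if not k.startswith("path_")},
    )
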