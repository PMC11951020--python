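"""Scan containers: HDF5 (native) and multi-page TIFF + YAML sidecar.

The native container is a single HDF5 file with datasets ``/pa`` and
``/us`` (float32, shape ``(frame, axial, lateral)``) and the geometry as
root attributes.  For interchange with imaging toolchains a scan can also
be stored as a pair of multi-page TIFF stacks (one page per frame) next to
a YAML geometry sidecar.  Cohorts are described by a manifest CSV with
columns ``scan_id, path, group_label``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError, FormatError
from .geometry import ScanGeometry
from .volume import PaUsVolume

__all__ = ["save_scan", "load_scan", "write_manifest", "read_manifest"]

_GEOM_SCALARS = ("n_frames", "n_lateral", "n_axial", "lateral_pitch_mm",
                 "axial_spacing_mm", "elevation_span_mm", "wavelength_nm",
                 "uniform_step_mm")


def _geometry_to_dict(g: ScanGeometry) -> dict:
    d = {k: getattr(g, k) for k in _GEOM_SCALARS}
    d["elevation_positions_mm"] = np.asarray(g.elevation_positions_mm, dtype=float)
    return d


def _geometry_from_dict(d: dict) -> ScanGeometry:
    missing = [k for k in _GEOM_SCALARS if k not in d]
    if missing:
        raise FormatError(f"geometry metadata missing fields: {missing}")
    kwargs = {k: (int(d[k]) if k.startswith("n_") else float(d[k]))
              for k in _GEOM_SCALARS}
    pos = d.get("elevation_positions_mm")
    if pos is not None:
        kwargs["elevation_positions_mm"] = np.asarray(pos, dtype=float)
    return ScanGeometry(**kwargs)


def save_scan(volume: PaUsVolume, path: os.PathLike | str) -> None:
    """Write a scan to ``path``.

    ``.h5``/``.hdf5`` selects the native HDF5 container; ``.tif``/``.tiff``
    writes ``<stem>.pa.tif`` and ``<stem>.us.tif`` stacks plus a
    ``<stem>.yaml`` geometry sidecar.  Lossless at float32.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        _save_hdf5(volume, path)
    elif suffix in (".tif", ".tiff"):
        _save_tiff(volume, path)
    else:
        raise FormatError(f"unsupported scan container suffix {suffix!r}")


def load_scan(path: os.PathLike | str) -> PaUsVolume:
    """Read a scan written by :func:`save_scan` and validate its invariants."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        if not path.exists():
            raise FileNotFoundError(path)
        return _load_hdf5(path)
    if suffix in (".tif", ".tiff"):
        return _load_tiff(path)  # resolves the .pa/.us stack pair itself
    raise FormatError(f"unsupported scan container suffix {suffix!r}")


def _save_hdf5(volume: PaUsVolume, path: Path) -> None:
    # track_times=False keeps repeated saves byte-identical
    with h5py.File(path, "w", libver="v108") as fh:
        fh.create_dataset("pa", data=volume.pa.astype(np.float32),
                          track_times=False)
        fh.create_dataset("us", data=volume.us.astype(np.float32),
                          track_times=False)
        for k, v in _geometry_to_dict(volume.geometry).items():
            fh.attrs[k] = v
        fh.attrs["scan_id"] = volume.scan_id
        fh.attrs["group_label"] = volume.group_label if volume.group_label else ""


def _load_hdf5(path: Path) -> PaUsVolume:
    with h5py.File(path, "r") as fh:
        if "pa" not in fh or "us" not in fh:
            raise FormatError(f"{path}: missing /pa or /us dataset")
        pa = fh["pa"][()]
        us = fh["us"][()]
        attrs = dict(fh.attrs)
    geometry = _geometry_from_dict(attrs)
    if np.isnan(pa).any() or np.isnan(us).any():
        raise DataError(f"{path}: NaN values in stored volume")
    group = str(attrs.get("group_label", "")) or None
    return PaUsVolume(pa=pa, us=us, geometry=geometry,
                      scan_id=str(attrs.get("scan_id", "")), group_label=group)


def _tiff_parts(path: Path) -> Tuple[Path, Path, Path]:
    stem = path.with_suffix("")
    if stem.suffix in (".pa", ".us"):
        stem = stem.with_suffix("")
    return (stem.with_suffix(".pa.tif"), stem.with_suffix(".us.tif"),
            stem.with_suffix(".yaml"))


def _save_tiff(volume: PaUsVolume, path: Path) -> None:
    pa_path, us_path, meta_path = _tiff_parts(path)
    tifffile.imwrite(pa_path, volume.pa.astype(np.float32))
    tifffile.imwrite(us_path, volume.us.astype(np.float32))
    meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in _geometry_to_dict(volume.geometry).items()}
    meta["scan_id"] = volume.scan_id
    meta["group_label"] = volume.group_label
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def _load_tiff(path: Path) -> PaUsVolume:
    pa_path, us_path, meta_path = _tiff_parts(path)
    for p in (pa_path, us_path):
        if not p.exists():
            raise FormatError(f"missing TIFF stack {p}")
    if not meta_path.exists():
        raise FormatError(f"missing YAML geometry sidecar {meta_path}")
    pa = tifffile.imread(pa_path)
    us = tifffile.imread(us_path)
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    geometry = _geometry_from_dict(meta)
    if np.isnan(pa).any() or np.isnan(us).any():
        raise DataError(f"{path}: NaN values in stored volume")
    return PaUsVolume(pa=pa, us=us, geometry=geometry,
                      scan_id=str(meta.get("scan_id") or ""),
                      group_label=meta.get("group_label"))


def write_manifest(rows: List[Tuple[str, str, Optional[str]]],
                   path: os.PathLike | str) -> None:
    """Write a cohort manifest CSV (scan_id, path, group_label)."""
    df = pd.DataFrame(rows, columns=["scan_id", "path", "group_label"])
    df.to_csv(path, index=False)


def read_manifest(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"scan_id", "path", "group_label"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest missing columns {required - set(df.columns)}")
    return df
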