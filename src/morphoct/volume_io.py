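"""Reading and writing 3D volumes (multi-page TIFF) and descriptor tables (CSV).

Volumes are stored one z-slice per TIFF page; the page order is the first
grid axis (z), within-page rows are y and columns x.  Voxel spacing is
isotropic and carried in the TIFF metadata; when a file carries none, a
spacing of 1.0 is assumed and a warning logged (descriptors are then in
voxel units).

Binary masks are encoded on disk as 8-bit 0/255; on reading, any nonzero
voxel decodes to foreground.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import TableFormatError, VolumeFormatError

logger = logging.getLogger(__name__)

#: dtypes accepted when reading TIFF pages
_SUPPORTED_DTYPES = (
    np.uint8, np.int8, np.uint16, np.int16, np.uint32, np.int32,
    np.float32, np.float64,
)

#: descriptor-table schema; ``label`` is optional
DESCRIPTOR_COLUMNS = ("name", "V", "Vc", "A", "Ac", "C", "S")
_NUMERIC_COLUMNS = ("V", "Vc", "A", "Ac", "C", "S")


def _check_grid(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"volume grid must be 3D, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all grid dimensions must be >= 1, got {data.shape}")
    return data


@dataclass
class Volume3D:
    """Grayscale voxel grid with isotropic spacing.

    Parameters
    ----------
    data
        3D array indexed (z, y, x); arbitrary CT intensity units.
    spacing
        Voxel edge length (isotropic). Defaults to 1.0 (voxel units).
    name
        Sample identifier.
    """

    data: np.ndarray
    spacing: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = _check_grid(self.data)
        self.spacing = float(self.spacing)
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryVolume:
    """Boolean voxel grid (mask / extracted plant body)."""

    data: np.ndarray
    spacing: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        data = _check_grid(self.data)
        if data.dtype != bool:
            values = np.unique(data)
            if not np.isin(values, (0, 1)).all():
                raise ValueError(
                    "binary volume may only contain {0,1}; "
                    f"found values {values[:5]}"
                )
            data = data.astype(bool)
        self.data = data
        self.spacing = float(self.spacing)
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# TIFF I/O


def write_volume(v: Volume3D | BinaryVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF.

    Binary volumes are stored as 8-bit 0/255.  Spacing and name are stored
    in the image-description metadata so that :func:`read_volume` recovers
    them losslessly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    is_binary = isinstance(v, BinaryVolume)
    data = (v.data.astype(np.uint8) * 255) if is_binary else v.data
    metadata = {
        "axes": "ZYX",
        "spacing": v.spacing,
        "name": v.name,
        "binary": is_binary,
    }
    tifffile.imwrite(path, data, metadata=metadata, photometric="minisblack")


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a single- or multi-page TIFF stack as a :class:`Volume3D`.

    The page order becomes the first (z) axis; a single page yields a
    volume with first dimension 1.  Spacing is taken from the file's
    metadata when present (either the JSON image description written by
    :func:`write_volume`, ImageJ metadata, or the X-resolution tag), else
    1.0 with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:  # tifffile raises various types on corrupt input
        raise VolumeFormatError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise VolumeFormatError(
                f"non-uniform page shapes in {path}: {sorted(shapes)}"
            )
        dtype = tf.pages[0].dtype
        if not any(dtype == np.dtype(t) for t in _SUPPORTED_DTYPES):
            raise VolumeFormatError(
                f"unsupported pixel type {dtype} in {path}; expected one of "
                + ", ".join(np.dtype(t).name for t in _SUPPORTED_DTYPES)
            )
        arr = tf.asarray()
        spacing, name = _read_tiff_metadata(tf, path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise VolumeFormatError(f"expected a 2D/3D TIFF stack in {path}, got ndim={arr.ndim}")
    if spacing is None:
        logger.warning(
            "no voxel-spacing metadata in %s; assuming spacing 1.0 (voxel units)", path
        )
        spacing = 1.0
    return Volume3D(data=arr, spacing=spacing, name=name or path.stem)


def _read_tiff_metadata(tf: tifffile.TiffFile, path: Path) -> tuple[float | None, str]:
    spacing: float | None = None
    name = ""
    meta = None
    if tf.shaped_metadata:
        meta = tf.shaped_metadata[0]
    elif tf.imagej_metadata:
        meta = tf.imagej_metadata
    if meta:
        if meta.get("spacing") is not None:
            spacing = float(meta["spacing"])
        name = str(meta.get("name", "") or "")
    if spacing is None:
        tags = tf.pages[0].tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            # (1, 1) is the TIFF placeholder written by default; treat it
            # as "no calibration" rather than a genuine 1.0 spacing
            if num and (num, den) != (1, 1):
                spacing = den / num
    return spacing, name


def read_mask(path: str | os.PathLike) -> BinaryVolume:
    """Read a TIFF stack as a binary mask (any nonzero voxel → foreground)."""
    v = read_volume(path)
    return BinaryVolume(data=v.data != 0, spacing=v.spacing, name=v.name)


# ---------------------------------------------------------------------------
# Descriptor tables


def write_descriptor_table(records: Sequence, path: str | os.PathLike) -> None:
    """Write descriptor records to CSV (full double precision)."""
    rows = []
    any_label = any(getattr(r, "label", None) is not None for r in records)
    for r in records:
        row = {"name": r.name, "V": r.V, "Vc": r.Vc, "A": r.A, "Ac": r.Ac,
               "C": r.C, "S": r.S}
        if any_label:
            row["label"] = "" if r.label is None else r.label
        rows.append(row)
    columns = list(DESCRIPTOR_COLUMNS) + (["label"] if any_label else [])
    df = pd.DataFrame(rows, columns=columns)
    # %.17g preserves doubles exactly (stronger than the 12-digit contract)
    df.to_csv(path, index=False, float_format="%.17g")


def read_descriptor_table(path: str | os.PathLike) -> list:
    """Read a descriptor CSV into a list of ``MorphDescriptors``.

    Required columns: name,V,Vc,A,Ac,C,S; ``label`` is optional.  A
    non-numeric cell raises :class:`TableFormatError` naming the row and
    column.
    """
    from .hull_descriptors import MorphDescriptors  # deferred: avoids cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    df = pd.read_csv(path, dtype={"name": str, "label": str})
    missing = [c for c in DESCRIPTOR_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s) {missing} in {path}")
    records = []
    for i, row in df.iterrows():
        values = {}
        for col in _NUMERIC_COLUMNS:
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise TableFormatError(
                    f"non-numeric cell in {path}: row {i}, column {col!r}: {row[col]!r}"
                ) from exc
            if not np.isfinite(values[col]):
                raise TableFormatError(
                    f"non-finite cell in {path}: row {i}, column {col!r}"
                )
        label = None
        if "label" in df.columns and isinstance(row.get("label"), str) and row["label"]:
            label = row["label"]
        records.append(MorphDescriptors(name=str(row["name"]), label=label, **values))
    return records
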