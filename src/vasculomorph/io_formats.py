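"""Reading and writing the volumetric and tabular formats used by the pipeline.

NIfTI-1 (via nibabel) and multi-page TIFF stacks (via tifffile) are the two
volume containers; tables go to RFC-4180 CSV through pandas.  NIfTI spacing
is stored in the ``pixdim`` header fields in µm; orientation is handled as
stored-array order (no reorientation to canonical axes — every map in a run
shares one grid).  TIFF stacks carry no spacing metadata, so reading one
requires an explicit spacing override.
"""

from __future__ import annotations

import os
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .volume import Volume3D, VolumeKind

VolumeFormat = Literal["nifti", "tiff-stack"]

_SUPPORTED_DTYPES = (np.uint8, np.int16, np.uint16, np.int32, np.float32, np.float64)


class VolumeFormatError(RuntimeError):
    """Raised when a file cannot be parsed as the named volume format."""


class VolumeMetadataError(RuntimeError):
    """Raised when required geometry metadata is absent."""


def _infer_format(path: str | os.PathLike) -> VolumeFormat:
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff-stack"
    raise VolumeFormatError(f"cannot infer volume format from extension: {path}")


def read_volume(
    path: str | os.PathLike,
    format: VolumeFormat | None = None,
    *,
    spacing: Sequence[float] | None = None,
    origin: Sequence[float] | None = None,
    kind: VolumeKind = "intensity",
) -> Volume3D:
    """Read a 3D volume from NIfTI or a multi-page TIFF stack.

    Spacing is taken from the NIfTI header when present; TIFF stacks (and
    headerless NIfTI) require the ``spacing`` override (µm).  A ``z``-paged
    TIFF of ``n`` frames of shape ``(ny, nx)`` becomes a volume of shape
    ``(nx, ny, n)`` so that axis order is (x, y, z) throughout.
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises several types
            raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected 3D NIfTI, got shape {data.shape}")
        if spacing is None:
            zooms = img.header.get_zooms()[:3]
            if any(z <= 0 for z in zooms):
                raise VolumeMetadataError(f"{path}: non-positive pixdim and no spacing override")
            spacing = tuple(float(z) for z in zooms)
        if origin is None:
            origin = tuple(float(v) for v in img.affine[:3, 3])
    elif fmt == "tiff-stack":
        try:
            pages = tifffile.imread(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"cannot read {path} as TIFF: {exc}") from exc
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise VolumeFormatError(f"{path}: expected a stack of 2D frames, got {pages.shape}")
        # tifffile yields (page, row, col) = (z, y, x); store as (x, y, z)
        data = np.ascontiguousarray(np.transpose(pages, (2, 1, 0)))
        if spacing is None:
            raise VolumeMetadataError(f"{path}: TIFF stacks carry no spacing; pass spacing=")
        if origin is None:
            origin = (0.0, 0.0, 0.0)
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")
    return Volume3D(data=data, spacing=tuple(spacing), origin=tuple(origin), kind=kind)


def write_volume(vol: Volume3D, path: str | os.PathLike, format: VolumeFormat | None = None) -> None:
    """Write a volume to NIfTI or a multi-page TIFF stack.

    Integer data round-trips bit-exactly; float data is stored as float32
    for NIfTI (ε-identity round-trip) and float64 for TIFF.
    """
    fmt = format or _infer_format(path)
    data = np.asarray(vol.data)
    if not any(np.issubdtype(data.dtype, d) for d in (np.integer, np.floating, np.bool_)):
        raise TypeError(f"unsupported dtype for volume writing: {data.dtype}")
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    if fmt == "nifti":
        if np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif fmt == "tiff-stack":
        pages = np.transpose(data, (2, 1, 0))  # back to (z, y, x)
        tifffile.imwrite(str(path), np.ascontiguousarray(pages))
    else:
        raise VolumeFormatError(f"unknown format {fmt!r}")


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write records to a UTF-8 CSV with a deterministic column order.

    Record dicts must share one schema (same keys); the column order of the
    first record is kept.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows:
            schema = list(rows[0].keys())
            for i, r in enumerate(rows):
                if list(r.keys()) != schema:
                    raise ValueError(f"record {i} schema {list(r.keys())} differs from {schema}")
            df = pd.DataFrame(rows, columns=schema)
        else:
            df = pd.DataFrame()
    df.to_csv(str(path), index=False, encoding="utf-8")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), encoding="utf-8")
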