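"""Readers and writers for the on-disk formats the pipelines consume.

NIfTI volumes go through :mod:`nibabel`, TIFF images through
:mod:`tifffile`, PNG through :mod:`imageio`, tables through :mod:`pandas`.
Gradient tables follow the FSL dialect: one whitespace-separated row of
b-values and three whitespace-separated rows (x, y, z) of direction
components.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

log = logging.getLogger("callosal.io")

__all__ = [
    "VolumeOnGrid",
    "Acquisition",
    "TableSchema",
    "read_volume",
    "write_volume",
    "read_gradient_table",
    "write_gradient_table",
    "read_table",
    "write_table",
    "read_image",
    "write_image",
]


@dataclass
class VolumeOnGrid:
    """A 3D or 4D voxel array with its grid geometry.

    The time axis, if present, is last.  ``voxel_size_mm`` covers the three
    spatial axes; ``affine`` maps 0-based voxel indices to world mm.
    Hemisphere assignment downstream uses the sign of the first world
    coordinate.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    units: str = "arbitrary"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValidationError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def read_volume(path) -> VolumeOnGrid:
    """Read a NIfTI-1/2 volume, preserving shape, zooms and affine."""
    import nibabel as nib

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise FormatError(f"cannot parse NIfTI header/data of {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: field dim={data.ndim} (expected 3 or 4)")
    return VolumeOnGrid(data, img.affine, tuple(float(z) for z in zooms))


def write_volume(vol: VolumeOnGrid, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.voxel_size_mm + ((1.0,) if vol.data.ndim == 4 else ()))
    nib.save(img, str(path))


@dataclass
class Acquisition:
    """Diffusion acquisition: b-values (s mm^-2) and unit direction vectors."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3), unit rows where weighted
    b0_threshold: float = 0.0

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValidationError("bvecs must be (n, 3) matching bvals")

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def n_weighted(self) -> int:
        return int((~self.is_b0).sum())


def read_gradient_table(bval_path, bvec_path, b0_threshold: float = 0.0) -> Acquisition:
    """Read an FSL-style bval/bvec pair.

    Directions of weighted entries are renormalised to unit length
    (tolerance 1e-6); b = 0 entries are flagged non-diffusion-weighted and
    may carry a zero vector.
    """
    try:
        bvals = np.loadtxt(bval_path, dtype=float).ravel()
        bvecs = np.loadtxt(bvec_path, dtype=float)
    except Exception as exc:
        raise FormatError(f"cannot parse gradient table: {exc}") from exc
    if bvecs.ndim == 1 and bvecs.size == 3 and bvals.size == 1:
        bvecs = bvecs.reshape(3, 1)  # single-volume file: one value per row
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows, got shape {bvecs.shape}")
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"entry count mismatch: {bvals.size} b-values vs {bvecs.shape[0]} directions")
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > b0_threshold
    if np.any(weighted & (norms == 0.0)):
        raise FormatError("zero direction vector with b > 0 cannot be normalised")
    out = bvecs.copy()
    nz = norms > 0
    out[nz] = bvecs[nz] / norms[nz, None]
    return Acquisition(bvals, out, b0_threshold)


def write_gradient_table(acq: Acquisition, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, acq.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, acq.bvecs.T, fmt="%.9g")


@dataclass
class TableSchema:
    """Declared columns for a CSV/TSV table.

    ``required`` maps column name -> dtype; ``optional`` maps column name ->
    (dtype, default).  Unknown columns are preserved with a logged warning.
    """

    required: dict[str, type] = field(default_factory=dict)
    optional: dict[str, tuple[type, object]] = field(default_factory=dict)


def read_table(path, schema: TableSchema | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a headered CSV/TSV into a typed DataFrame.

    An empty file yields an empty table with the schema's columns.  Missing
    optional columns are filled with their declared defaults; a missing
    required column raises :class:`SchemaError` naming it.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        cols = list(schema.required) + list(schema.optional) if schema else []
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    if schema is None:
        return df
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col, dtype in schema.required.items():
        df[col] = df[col].astype(dtype)
    for col, (dtype, default) in schema.optional.items():
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].astype(dtype)
    known = set(schema.required) | set(schema.optional)
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.warning("table %s has unknown column(s) %s; preserved", path, extra)
    return df


def write_table(df: pd.DataFrame, path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)


def read_image(path, pixel_size_nm: float | None = None) -> tuple[np.ndarray, float | None]:
    """Read a grayscale TIFF/PNG micrograph; returns (array, pixel size nm).

    TIFF resolution metadata is used when present and no explicit pixel size
    is given.  Origin is top-left, row-major.
    """
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        with tifffile.TiffFile(p) as tf:
            arr = tf.asarray()
            if pixel_size_nm is None:
                try:
                    page = tf.pages[0]
                    xres = page.tags["XResolution"].value  # pixels per unit
                    unit = page.tags["ResolutionUnit"].value
                    per_px_cm = xres[1] / xres[0]
                    if getattr(unit, "value", unit) in (3, "CENTIMETER"):
                        pixel_size_nm = per_px_cm * 1e7
                except Exception:
                    pixel_size_nm = None
    else:
        import imageio.v3 as iio

        arr = iio.imread(p)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB to grayscale
        arr = arr[..., :3].mean(axis=-1)
    return arr, pixel_size_nm


def write_image(arr: np.ndarray, path, pixel_size_nm: float | None = None) -> None:
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        kwargs = {}
        if pixel_size_nm is not None:
            px_per_cm = 1e7 / pixel_size_nm
            kwargs = {"resolution": (px_per_cm, px_per_cm), "resolutionunit": "CENTIMETER"}
        tifffile.imwrite(p, arr, **kwargs)
    else:
        import imageio.v3 as iio

        iio.imwrite(p, arr)
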