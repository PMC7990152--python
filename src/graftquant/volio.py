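"""Volumetric image and measurement-table I/O.

Images are held in a minimal axis-aligned container (:class:`VolumeImage`)
with voxel spacing and origin in millimetres.  Two on-disk formats are
supported, MetaImage (``.mha``/``.mhd``, via SimpleITK) and NIfTI
(``.nii``/``.nii.gz``, via nibabel).  Arrays are indexed ``(x, y, z)``;
world position of voxel ``(i, j, k)`` is ``origin + index * spacing``.
Oblique direction matrices are rejected rather than silently resampled.

CBCT intensities are not calibrated Hounsfield units, so every volume
carries a ``unit_state`` flag distinguishing raw scanner units from the
mean-0 / SD-1000 normalized units used downstream.  The flag survives a
round trip to disk through a small JSON sidecar.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "GeometryError",
    "VolumeImage",
    "BinaryMask",
    "MeasurementTable",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_measurements",
    "write_measurements",
]

RAW = "raw"
NORMALIZED = "normalized"

#: columns of the measurement CSV, in order
MEASUREMENT_COLUMNS = ["patient_id", "treated_side", "side", "timepoint", "volume_mm3"]
SIDES = ("Dx", "Sin")
TIMEPOINTS = ("baseline", "6mo")


class GeometryError(ValueError):
    """Invalid or unsupported image geometry (spacing, orientation, shape)."""


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {a.size}")
    return a


@dataclass
class VolumeImage:
    """A 3D scalar grid with axis-aligned geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Attenuation values; raw CBCT units or normalized units.
    spacing : (3,) float
        Voxel size in mm along x, y, z; all positive.
    origin : (3,) float
        World position (mm) of voxel (0, 0, 0).
    unit_state : {"raw", "normalized"}
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    unit_state: str = RAW

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise GeometryError(
                f"expected a 3D scalar volume, got shape {self.values.shape}"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(self.spacing > 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.unit_state not in (RAW, NORMALIZED):
            raise ValueError(f"unknown unit_state {self.unit_state!r}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def center(self) -> np.ndarray:
        """World coordinate (mm) of the geometric center of the grid."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    def with_values(self, values: np.ndarray, unit_state: str | None = None) -> "VolumeImage":
        return VolumeImage(
            values,
            self.spacing.copy(),
            self.origin.copy(),
            self.unit_state if unit_state is None else unit_state,
        )

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


@dataclass
class BinaryMask:
    """A boolean grid geometrically aligned with a reference :class:`VolumeImage`."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise GeometryError(
                f"expected a 3D mask, got shape {self.values.shape}"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(self.spacing > 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_mm3(self) -> float:
        """Total mask volume = voxel count x voxel volume."""
        return float(np.count_nonzero(self.values)) * self.voxel_volume

    def with_values(self, values: np.ndarray) -> "BinaryMask":
        return BinaryMask(values, self.spacing.copy(), self.origin.copy())

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )

    @staticmethod
    def like(reference: VolumeImage, values: np.ndarray) -> "BinaryMask":
        m = BinaryMask(values, reference.spacing.copy(), reference.origin.copy())
        if m.shape != reference.shape:
            raise GeometryError("mask shape does not match its reference volume")
        return m


# ---------------------------------------------------------------------------
# volume I/O

_META_EXTS = (".mha", ".mhd")
_NII_EXTS = (".nii", ".nii.gz")


def _sidecar_path(path: str) -> str:
    return str(path) + ".units.json"


def _format_of(path: str) -> str:
    p = str(path).lower()
    if p.endswith(_META_EXTS):
        return "meta"
    if p.endswith(_NII_EXTS):
        return "nifti"
    raise ValueError(
        f"unsupported volume format for {path!r} "
        "(expected .mha/.mhd or .nii/.nii.gz)"
    )


def read_volume(path) -> VolumeImage:
    """Read a 3D scalar MetaImage or NIfTI volume.

    The returned grid carries spacing and origin from the header.  The
    unit_state flag defaults to ``raw`` unless a sidecar written by
    :func:`write_volume` restores ``normalized``.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _format_of(path)
    if fmt == "meta":
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:  # ITK refuses degenerate headers itself
            if "spacing" in str(exc).lower():
                raise GeometryError(f"{path}: invalid voxel spacing in header") from exc
            raise
        if img.GetDimension() != 3:
            raise GeometryError(f"{path}: expected 3D image, got {img.GetDimension()}D")
        if img.GetNumberOfComponentsPerPixel() != 1:
            raise GeometryError(f"{path}: expected scalar image")
        direction = np.array(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise GeometryError(
                f"{path}: non-identity direction matrix; only axis-aligned "
                "volumes are supported"
            )
        spacing = np.array(img.GetSpacing(), float)
        origin = np.array(img.GetOrigin(), float)
        # SimpleITK arrays are (z, y, x); transpose to (x, y, z)
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    else:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise GeometryError(f"{path}: expected 3D image, got {data.ndim}D")
        aff = img.affine
        rot = aff[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6):
            raise GeometryError(
                f"{path}: oblique/rotated NIfTI affine; only axis-aligned "
                "volumes are supported"
            )
        spacing = np.diag(rot).astype(float)
        if np.any(spacing < 0):
            raise GeometryError(f"{path}: negative affine diagonal (axis flip)")
        origin = aff[:3, 3].astype(float)
        values = data.astype(np.float64)
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: non-positive voxel spacing {spacing}")
    unit_state = RAW
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            unit_state = json.load(fh).get("unit_state", RAW)
    return VolumeImage(values, spacing, origin, unit_state)


def write_volume(vol: VolumeImage, path) -> None:
    """Write a volume; readable back by :func:`read_volume` with identical
    values and geometry.  A normalized unit_state is recorded in a JSON
    sidecar next to the file."""
    path = str(path)
    fmt = _format_of(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if fmt == "meta":
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(vol.values.transpose(2, 1, 0))
        )
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, path)
    else:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vol.spacing)
        aff[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.values, aff), path)
    sc = _sidecar_path(path)
    if vol.unit_state != RAW:
        with open(sc, "w") as fh:
            json.dump({"unit_state": vol.unit_state}, fh)
    elif os.path.exists(sc):
        os.remove(sc)


def write_mask(mask: BinaryMask, path) -> None:
    """Masks are stored as 8-bit 0/1 images for format compatibility."""
    vol = VolumeImage(mask.values.astype(np.uint8), mask.spacing, mask.origin)
    path = str(path)
    fmt = _format_of(path)
    if fmt == "meta":
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(vol.values.transpose(2, 1, 0).astype(np.uint8))
        )
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, path)
    else:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vol.spacing)
        aff[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.values.astype(np.uint8), aff), path)


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    vals = vol.values
    extra = np.setdiff1d(np.unique(vals), [0.0, 1.0])
    if extra.size:
        raise ValueError(f"{path}: not a binary mask, found values {extra[:5]}")
    return BinaryMask(vals > 0, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# measurement tables


@dataclass
class MeasurementTable:
    """Long-format per-side graft volumes.

    One row per (patient, side, timepoint); ``treated_side`` marks the
    ibandronate-treated side and is constant within a patient.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        df = df[MEASUREMENT_COLUMNS].copy()
        df["patient_id"] = df["patient_id"].astype(str)
        for col in ("treated_side", "side"):
            bad = set(df[col].unique()) - set(SIDES)
            if bad:
                raise ValueError(f"invalid {col} values {sorted(bad)}; expected {SIDES}")
        bad = set(df["timepoint"].unique()) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"invalid timepoint values {sorted(bad)}; expected {TIMEPOINTS}")
        df["volume_mm3"] = df["volume_mm3"].astype(float)
        if (df["volume_mm3"] < 0).any():
            rows = df.loc[df["volume_mm3"] < 0, "patient_id"].tolist()
            raise ValueError(f"negative volumes for patients {rows}")
        dup = df.duplicated(subset=["patient_id", "side", "timepoint"])
        if dup.any():
            keys = df.loc[dup, ["patient_id", "side", "timepoint"]].values.tolist()
            raise ValueError(f"duplicate (patient, side, timepoint) rows: {keys}")
        nts = df.groupby("patient_id")["treated_side"].nunique()
        incons = nts[nts > 1].index.tolist()
        if incons:
            raise ValueError(f"treated_side not constant within patients {incons}")
        self.data = df.reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    def patients(self) -> list:
        return list(dict.fromkeys(self.data["patient_id"]))


def read_measurements(path) -> MeasurementTable:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return MeasurementTable(df)


def write_measurements(table: MeasurementTable, path) -> None:
    table.data.to_csv(path, index=False)
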