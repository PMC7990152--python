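"""Intensity normalization, masking and grid resampling.

CBCT voxel values are not calibrated Hounsfield units, so every scan is
linearly rescaled to mean 0 and standard deviation 1000 before any
threshold is applied.  All fixed thresholds downstream (the 300/600
segmentation window, the metal threshold) are expressed in these
normalized units.  Segmentation runs on a coarser working grid (160 um by
default, versus the scanner's native 80 um) and the resulting surface is
carried back to the native grid by interpolating the level-set function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import NORMALIZED, BinaryMask, GeometryError, VolumeImage

__all__ = [
    "NormalizationParams",
    "normalize_intensity",
    "downsample",
    "detect_metal",
    "build_roi_mask",
    "upsample_mask",
    "ball_element",
]


@dataclass
class NormalizationParams:
    target_mean: float = 0.0
    target_sd: float = 1000.0
    scope: str = "whole_volume"  # or "within_mask"
    mask: BinaryMask | None = None

    def __post_init__(self):
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if self.scope not in ("whole_volume", "within_mask"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "within_mask" and self.mask is None:
            raise ValueError("scope='within_mask' requires a mask")


def normalize_intensity(vol: VolumeImage, params: NormalizationParams | None = None) -> VolumeImage:
    """Affinely rescale to mean ``target_mean`` and SD ``target_sd``.

    The mean and SD are computed with the population (n) denominator over
    the whole volume, or within a mask if requested; the rescale is applied
    to every voxel either way.  Idempotent, and invariant to any per-scan
    gain a > 0 and offset b.
    """
    params = params or NormalizationParams()
    if params.scope == "within_mask":
        sample = vol.values[params.mask.values]
        if sample.size == 0:
            raise ValueError("normalization mask is empty")
    else:
        sample = vol.values
    mean = float(np.mean(sample))
    sd = float(np.std(sample))  # population denominator
    if sd == 0.0:
        raise ValueError("cannot normalize a constant volume (zero SD)")
    out = (vol.values - mean) * (params.target_sd / sd) + params.target_mean
    return vol.with_values(out, unit_state=NORMALIZED)


def downsample(vol: VolumeImage, target_spacing: float) -> VolumeImage:
    """Down-sample to ``target_spacing`` (isotropic, mm).

    Integer spacing ratios use a non-overlapping block mean (any trailing
    partial block is dropped); non-integer ratios use Gaussian
    pre-smoothing (sigma = 0.4 * factor voxels) followed by linear
    interpolation.  A no-op if the target equals the current spacing.
    """
    target_spacing = float(target_spacing)
    spacing = vol.spacing
    if np.allclose(spacing, target_spacing, rtol=1e-9):
        return vol
    if np.any(target_spacing < spacing - 1e-12):
        raise GeometryError(
            f"target spacing {target_spacing} is finer than native {spacing}"
        )
    factors = target_spacing / spacing
    if np.allclose(factors, np.round(factors), atol=1e-9):
        f = np.round(factors).astype(int)
        nx, ny, nz = (np.array(vol.shape) // f) * f
        v = vol.values[:nx, :ny, :nz]
        v = v.reshape(nx // f[0], f[0], ny // f[1], f[1], nz // f[2], f[2])
        out = v.mean(axis=(1, 3, 5))
        # block-mean voxel centers sit at the mean of the source centers
        new_origin = vol.origin + (f - 1) / 2.0 * spacing
        return VolumeImage(out, spacing * f, new_origin, vol.unit_state)
    smoothed = ndimage.gaussian_filter(vol.values, sigma=0.4 * factors)
    new_shape = np.maximum(1, np.floor(np.array(vol.shape) * spacing / target_spacing)).astype(int)
    idx = np.meshgrid(
        *[
            (np.arange(n) * target_spacing + (target_spacing - s) / 2.0) / s
            for n, s in zip(new_shape, spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(smoothed, np.array(idx), order=1, mode="nearest")
    new_origin = vol.origin + (target_spacing - spacing) / 2.0
    return VolumeImage(out, np.full(3, target_spacing), new_origin, vol.unit_state)


def ball_element(radius_mm: float, spacing) -> np.ndarray:
    """Boolean ball structuring element of the given physical radius."""
    spacing = np.asarray(spacing, float)
    r = np.maximum(0, np.floor(radius_mm / spacing + 1e-9)).astype(int)
    grids = np.meshgrid(*[np.arange(-n, n + 1) * s for n, s in zip(r, spacing)], indexing="ij")
    dist2 = sum(g ** 2 for g in grids)
    return dist2 <= radius_mm ** 2 + 1e-9


def detect_metal(vol: VolumeImage, metal_threshold: float = 3000.0, dilate_mm: float = 0.32) -> BinaryMask:
    """Threshold out titanium hardware on a normalized scan.

    Titanium attenuates far beyond bone, so after SD-1000 normalization a
    fixed threshold (default 3000 normalized units) isolates it; the mask
    is then dilated by a ball of radius ``dilate_mm`` to also cover the
    bright partial-volume halo.  An empty result is allowed.
    """
    if vol.unit_state != NORMALIZED:
        raise ValueError("detect_metal expects a normalized volume")
    core = vol.values > metal_threshold
    if dilate_mm > 0 and core.any():
        core = ndimage.binary_dilation(core, structure=ball_element(dilate_mm, vol.spacing))
    return BinaryMask.like(vol, core)


def _region_mask(vol: VolumeImage, region: dict) -> np.ndarray:
    """Rasterize one exclusion region (world mm, baseline frame)."""
    kind = region.get("type")
    coords = [
        vol.origin[i] + np.arange(vol.shape[i]) * vol.spacing[i] for i in range(3)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    if kind == "box":
        lo = np.asarray(region["min_mm"], float)
        hi = np.asarray(region["max_mm"], float)
        return (
            (x >= lo[0]) & (x <= hi[0])
            & (y >= lo[1]) & (y <= hi[1])
            & (z >= lo[2]) & (z <= hi[2])
        )
    if kind == "halfspace":
        point = np.asarray(region["point_mm"], float)
        normal = np.asarray(region["normal"], float)
        normal = normal / np.linalg.norm(normal)
        return (
            (x - point[0]) * normal[0]
            + (y - point[1]) * normal[1]
            + (z - point[2]) * normal[2]
        ) >= 0
    raise ValueError(f"unknown exclusion region type {kind!r}")


def build_roi_mask(
    baseline: VolumeImage,
    metal: BinaryMask | None = None,
    exclusion_geometry: list | None = None,
) -> BinaryMask:
    """Build the analysis ROI from the baseline scan.

    Mirrors the study's baseline-derived mask: the full field minus the
    metal hardware and minus user-supplied exclusion regions (boxes or
    half-spaces in baseline world coordinates) covering the host mandible.
    The largest-continuous-bone rule is evaluated within this mask.
    """
    roi = np.ones(baseline.shape, dtype=bool)
    if metal is not None:
        if metal.shape != baseline.shape:
            raise GeometryError("metal mask grid does not match baseline grid")
        roi &= ~metal.values
    for region in exclusion_geometry or []:
        roi &= ~_region_mask(baseline, region)
    if not roi.any():
        raise ValueError("ROI is empty after applying exclusions")
    return BinaryMask.like(baseline, roi)


def upsample_mask(phi_or_mask, target_spacing: float):
    """Carry a segmentation from the working grid back to a finer grid.

    Preferred input is the level-set field (a :class:`VolumeImage` holding
    the signed distance), which is interpolated trilinearly and
    re-thresholded at zero so the surface lands with sub-voxel precision.
    A plain :class:`BinaryMask` falls back to nearest-neighbor replication.
    """
    target_spacing = float(target_spacing)
    spacing = phi_or_mask.spacing
    if np.any(target_spacing > spacing + 1e-12):
        raise GeometryError("upsample target spacing must be <= current spacing")
    if isinstance(phi_or_mask, BinaryMask):
        if np.allclose(spacing, target_spacing):
            return phi_or_mask
        values, origin = _resample_to_finer(
            phi_or_mask.values.astype(np.float64), spacing, phi_or_mask.origin,
            target_spacing, order=0,
        )
        return BinaryMask(values > 0.5, np.full(3, target_spacing), origin)
    vol = phi_or_mask
    if np.allclose(spacing, target_spacing):
        return BinaryMask.like(vol, vol.values < 0)
    # phi is in voxel units of the coarse grid; rescaling is monotone so the
    # zero level is unaffected
    values, origin = _resample_to_finer(
        vol.values, spacing, vol.origin, target_spacing, order=1
    )
    return BinaryMask(values < 0, np.full(3, target_spacing), origin)


def _resample_to_finer(values, spacing, origin, target, order):
    factors = spacing / target
    new_shape = np.round(np.array(values.shape) * factors).astype(int)
    new_origin = origin - spacing / 2.0 + target / 2.0
    idx = np.meshgrid(
        *[
            (new_origin[i] + np.arange(new_shape[i]) * target - origin[i]) / spacing[i]
            for i in range(3)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        values, np.array(idx), order=order, mode="nearest"
    )
    return out, new_origin
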