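"""Synthetic paired CBCT scans of a mandible-angle graft scene.

The generator emulates the study geometry: a cortical-shelled mandible
slab, an onlay cortical bone block (~10 x 10 mm footprint) fixed to its
buccal face by a titanium position screw, imaged twice.  Between the two
scans the graft gains or loses a programmed volume fraction; the follow-up
scan is rigidly misaligned, and each scan has its own intensity gain and
offset (CBCT units are not calibrated), Gaussian PSF blur, and i.i.d.
Gaussian noise.  Ground-truth graft volumes at both timepoints and the
applied transform are returned for validation.

Default attenuation values are chosen so that, after mean-0 / SD-1000
normalization of the default scene, cortical bone (and hence the graft)
falls near the middle of the fixed 300-600 segmentation window, i.e. the
phantom emulates scans for which those published thresholds are
appropriate.  Metal is set far above cortical bone (as titanium is in
CBCT) so it is separable by thresholding; this also gives the scene
histogram the heavy bright tail that places bone at a fraction of an SD
above the mean.

Randomness uses numpy's PCG64 (``numpy.random.default_rng``) seeded per
scan from the scene seed, so pairs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .align import RigidTransform, resample
from .volio import BinaryMask, VolumeImage

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "LBL_BACKGROUND",
    "LBL_TRABECULAR",
    "LBL_CORTICAL",
    "LBL_GRAFT",
    "LBL_METAL",
    "build_labels",
    "apply_volume_change",
    "simulate_scan",
    "generate_pair",
]

LBL_BACKGROUND = 0
LBL_TRABECULAR = 1
LBL_CORTICAL = 2
LBL_GRAFT = 3
LBL_METAL = 4


def _default_misalignment() -> RigidTransform:
    return RigidTransform(rotation_deg=(2.0, -1.5, 1.0), translation_mm=(1.2, -0.8, 1.5))


@dataclass
class PhantomSpec:
    """Scene and acquisition parameters for one simulated patient side.

    Geometry is in mm; the x axis is the buccal direction: the mandible
    block sits lingually (low x) with an oblique lingual face, its flat
    buccal face carries the graft block, and the screw enters through the
    graft's outer face.  Intensities are raw scanner units before the
    per-scan gain/offset.
    """

    field_of_view: tuple = (20.0, 20.0, 20.0)
    spacing: float = 0.16
    slab_thickness: float = 6.0        # buccal-lingual (x) extent of the mandible block
    slab_footprint: tuple = (14.0, 14.0)  # y, z extent; kept inside the FOV so
                                          # misalignment does not push bone out of field
    slab_offset: float = 1.5           # lingual gap between FOV border and the block
    slab_wedge: tuple = (1.5, 2.5)     # mm of lingual-face obliquity across the y and z
                                       # footprint (mandibles are oblique; an axis-aligned
                                       # box would leave rotation about the screw axis
                                       # almost unconstrained for the registration)
    cortical_thickness: float = 1.2
    graft_size: tuple = (4.0, 10.0, 10.0)  # depth (x) and footprint (y, z)
    screw_radius: float = 1.2
    screw_length: float = 9.0
    screw_tilt_deg: tuple = (8.0, 4.0)  # obliquity of the screw axis (about y, z);
                                        # a perfectly axial screw would make the
                                        # scene nearly symmetric under rotation
                                        # about the buccal axis
    mu_soft: float = 0.0
    mu_trabecular: float = 700.0
    mu_cortical: float = 1300.0
    mu_metal: float = 32000.0
    trabecular_texture_sigma: float = 400.0  # raw units; trabecular bone is textured,
                                             # which is what locks rotation for
                                             # intensity-based registration
    texture_correlation_mm: float = 0.4
    blur_sigma: float = 0.12          # mm, scanner PSF
    noise_sigma: float = 100.0        # raw intensity units
    gain_baseline: float = 1.0
    offset_baseline: float = 0.0
    gain_followup: float = 1.15
    offset_followup: float = 150.0
    followup_volume_fraction: float = 0.5
    misalignment: RigidTransform = field(default_factory=_default_misalignment)
    roi_slab_margin: float = 0.25     # mm, dilation of the slab exclusion
    roi_metal_margin: float = 0.40    # mm, dilation of the metal exclusion
    seed: int = 0

    def __post_init__(self):
        if not (self.mu_metal > self.mu_cortical > self.mu_trabecular > self.mu_soft):
            raise ValueError("intensities must satisfy metal > cortical > trabecular > soft")
        if self.followup_volume_fraction < 0:
            raise ValueError("followup_volume_fraction must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.graft_size) <= 0:
            raise ValueError("graft extents must be positive")
        fov = np.asarray(self.field_of_view, float)
        buccal_face = self.slab_offset + sum(self.slab_wedge) / 2.0 + self.slab_thickness
        if buccal_face + self.graft_size[0] > fov[0]:
            raise ValueError("graft does not fit inside the field of view (x)")
        if self.graft_size[1] > fov[1] or self.graft_size[2] > fov[2]:
            raise ValueError("graft does not fit inside the field of view (y/z)")

    @property
    def shape(self) -> tuple:
        return tuple(int(round(f / self.spacing)) for f in self.field_of_view)

    @property
    def origin(self) -> np.ndarray:
        # voxel centers at (i + 1/2) * spacing, so the grid spans [0, fov]
        return np.full(3, self.spacing / 2.0)

    def grid_like(self, values) -> VolumeImage:
        return VolumeImage(values, np.full(3, self.spacing), self.origin)

    def intensity_of(self) -> np.ndarray:
        lut = np.zeros(5)
        lut[LBL_BACKGROUND] = self.mu_soft
        lut[LBL_TRABECULAR] = self.mu_trabecular
        lut[LBL_CORTICAL] = self.mu_cortical
        lut[LBL_GRAFT] = self.mu_cortical  # the graft is a cortical block
        lut[LBL_METAL] = self.mu_metal
        return lut


def _coords(spec: PhantomSpec):
    s = spec.spacing
    return np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n in spec.shape], indexing="ij", sparse=True
    )


def build_labels(spec: PhantomSpec) -> VolumeImage:
    """Rasterize the five-class label scene on the phantom grid."""
    x, y, z = _coords(spec)
    fov = np.asarray(spec.field_of_view, float)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    cy, cz = fov[1] / 2.0, fov[2] / 2.0

    fy, fz = spec.slab_footprint
    wy, wz = spec.slab_wedge
    # oblique lingual face: x0 rises across the footprint
    sx0 = (
        spec.slab_offset
        + wy * (y - (cy - fy / 2.0)) / fy
        + wz * (z - (cz - fz / 2.0)) / fz
    )
    sx1 = spec.slab_offset + (wy + wz) / 2.0 + spec.slab_thickness
    slab = (
        (x >= sx0) & (x <= sx1)
        & (np.abs(y - cy) <= fy / 2.0)
        & (np.abs(z - cz) <= fz / 2.0)
    )
    labels[slab] = LBL_TRABECULAR
    ct = spec.cortical_thickness
    interior = (
        (x >= sx0 + ct) & (x <= sx1 - ct)
        & (np.abs(y - cy) <= fy / 2.0 - ct)
        & (np.abs(z - cz) <= fz / 2.0 - ct)
    )
    labels[slab & ~interior] = LBL_CORTICAL

    gx, gy, gz = spec.graft_size
    graft = (
        (x > sx1)
        & (x <= sx1 + gx)
        & (np.abs(y - cy) <= gy / 2.0)
        & (np.abs(z - cz) <= gz / 2.0)
    )
    labels[graft] = LBL_GRAFT

    # screw: oblique cylinder entering through the graft's outer face
    ty, tz = np.deg2rad(spec.screw_tilt_deg)
    d = np.array([1.0, np.tan(ty), np.tan(tz)])
    d /= np.linalg.norm(d)
    head = np.array([sx1 + gx, cy, cz])         # axis point at the graft face
    rx, ry, rz = x - head[0], y - head[1], z - head[2]
    proj = rx * d[0] + ry * d[1] + rz * d[2]    # signed distance along the axis
    perp2 = (rx - proj * d[0]) ** 2 + (ry - proj * d[1]) ** 2 + (rz - proj * d[2]) ** 2
    tip = head - spec.screw_length * d
    if np.any(tip < 0) or np.any(head > fov):
        raise ValueError("screw extends outside the field of view")
    screw = (proj >= -spec.screw_length) & (proj <= 0) & (perp2 <= spec.screw_radius ** 2)
    labels[screw] = LBL_METAL

    if not (labels == LBL_GRAFT).any():
        raise ValueError("graft rasterized to zero voxels")
    return spec.grid_like(labels)


def apply_volume_change(
    graft_mask: BinaryMask,
    target_fraction: float,
    allowed: np.ndarray | None = None,
    attached: np.ndarray | None = None,
) -> BinaryMask:
    """Morph a graft mask to ``target_fraction`` of its volume.

    Shrinkage keeps the voxels deepest inside the graft (thresholding the
    interior Euclidean distance transform at the offset whose level set
    hits the target count, with sub-voxel ties broken deterministically in
    array order); growth adds the nearest exterior voxels analogously,
    restricted to ``allowed`` (e.g. soft tissue only).  ``attached`` marks
    host bone the graft is fused to: that interface is not a free surface,
    so remodeling does not proceed from it (the interior distance is
    computed on the union).  The result is within 1 voxel of the target
    volume by construction.
    """
    if target_fraction < 0:
        raise ValueError("target_fraction must be >= 0")
    mask = graft_mask.values
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("graft mask is empty")
    if target_fraction == 1.0:
        return graft_mask
    target = int(round(target_fraction * n))
    if target == 0:
        return graft_mask.with_values(np.zeros_like(mask))
    if target <= n:
        interior = mask if attached is None else (mask | attached)
        dist = ndimage.distance_transform_edt(interior)
        flat = np.flatnonzero(mask)
        order = np.argsort(-dist.ravel()[flat], kind="stable")
        keep = flat[order[:target]]
        out = np.zeros_like(mask)
        out.ravel()[keep] = True
        return graft_mask.with_values(out)
    grow_allowed = ~mask if allowed is None else (allowed & ~mask)
    dist = ndimage.distance_transform_edt(~mask)
    cand = np.flatnonzero(grow_allowed)
    need = target - n
    if cand.size < need:
        raise ValueError(
            f"unreachable target: growth needs {need} voxels but only "
            f"{cand.size} are available"
        )
    order = np.argsort(dist.ravel()[cand], kind="stable")
    out = mask.copy()
    out.ravel()[cand[order[:need]]] = True
    return graft_mask.with_values(out)


def simulate_scan(labels: VolumeImage, spec: PhantomSpec, which: str = "baseline") -> VolumeImage:
    """Render one CBCT scan from a label scene.

    intensity = gain * mu(label) + offset, convolved with a Gaussian PSF
    and corrupted by i.i.d. Gaussian noise.  The follow-up scan is first
    rigidly moved by ``spec.misalignment`` (i.e. the scene is sampled in
    the misaligned frame, so registering follow-up to baseline should
    recover ``spec.misalignment``).
    """
    if which not in ("baseline", "followup"):
        raise ValueError(f"which must be 'baseline' or 'followup', got {which!r}")
    scene = spec.intensity_of()[labels.values.astype(int)]
    if spec.trabecular_texture_sigma > 0:
        # anatomy-fixed texture: one realization per scene seed, shared by
        # both timepoints and moved rigidly with the scene
        rng_scene = np.random.default_rng([int(spec.seed), 2])
        tex = ndimage.gaussian_filter(
            rng_scene.standard_normal(scene.shape),
            sigma=spec.texture_correlation_mm / spec.spacing,
        )
        tex /= max(float(tex.std()), 1e-12)
        scene = scene + (labels.values == LBL_TRABECULAR) * (
            spec.trabecular_texture_sigma * tex
        )
    scene_vol = labels.with_values(scene)
    if which == "followup":
        # F(q) = S(T(q)): sample the baseline-frame scene through the
        # forward transform, i.e. resample by its inverse.
        scene_vol = resample(
            scene_vol, spec.misalignment.inverse(), scene_vol, interpolation="linear"
        )
    vals = scene_vol.values
    if spec.blur_sigma > 0:
        vals = ndimage.gaussian_filter(vals, sigma=spec.blur_sigma / spec.spacing)
    gain = spec.gain_baseline if which == "baseline" else spec.gain_followup
    offset = spec.offset_baseline if which == "baseline" else spec.offset_followup
    vals = gain * vals + offset
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([int(spec.seed), 0 if which == "baseline" else 1])
        vals = vals + gain * spec.noise_sigma * rng.standard_normal(vals.shape)
    return spec.grid_like(vals)


@dataclass
class PhantomTruth:
    """Ground truth for a simulated pair, all in the baseline frame."""

    graft_volume_baseline: float
    graft_volume_followup: float
    applied_transform: RigidTransform
    labels_baseline: VolumeImage
    labels_followup: VolumeImage

    @property
    def volume_ratio(self) -> float:
        return self.graft_volume_followup / self.graft_volume_baseline

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.volume_ratio - 1.0)


def followup_labels(labels: VolumeImage, spec: PhantomSpec) -> VolumeImage:
    """Label scene at 6 months: same slab and screw, morphed graft."""
    base = labels.values
    graft0 = BinaryMask(base == LBL_GRAFT, labels.spacing, labels.origin)
    graft1 = apply_volume_change(
        graft0,
        spec.followup_volume_fraction,
        allowed=(base == LBL_BACKGROUND),
        attached=(base == LBL_TRABECULAR) | (base == LBL_CORTICAL),
    )
    out = base.copy()
    out[base == LBL_GRAFT] = LBL_BACKGROUND
    out[graft1.values] = LBL_GRAFT
    out[base == LBL_METAL] = LBL_METAL
    return labels.with_values(out)


def generate_pair(spec: PhantomSpec):
    """Simulate one patient side.

    Returns ``(baseline, followup, roi, truth)``: two raw-unit scans, the
    baseline-frame analysis ROI (everything except the dilated slab and the
    dilated screw, so it contains the graft with a margin), and the
    :class:`PhantomTruth`.
    """
    labels0 = build_labels(spec)
    labels1 = followup_labels(labels0, spec)
    baseline = simulate_scan(labels0, spec, "baseline")
    followup = simulate_scan(labels1, spec, "followup")

    from .prep import ball_element  # local import to avoid a cycle

    base = labels0.values
    slab = (base == LBL_TRABECULAR) | (base == LBL_CORTICAL)
    metal = base == LBL_METAL
    spacing = np.full(3, spec.spacing)
    excl = ndimage.binary_dilation(slab, ball_element(spec.roi_slab_margin, spacing))
    excl |= ndimage.binary_dilation(metal, ball_element(spec.roi_metal_margin, spacing))
    roi = BinaryMask(~excl, spacing, spec.origin)

    voxvol = spec.spacing ** 3
    v0 = float(np.count_nonzero(base == LBL_GRAFT)) * voxvol
    v1 = float(np.count_nonzero(labels1.values == LBL_GRAFT)) * voxvol
    truth = PhantomTruth(v0, v1, spec.misalignment, labels0, labels1)
    return baseline, followup, roi, truth
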