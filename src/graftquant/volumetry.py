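"""Volume-of-interest extraction and volume measurement.

The quantity of clinical interest is the largest continuous volume of
segmented bone inside the predefined mask: connected components are
labeled on (segmentation AND ROI) and the biggest one, by voxel count, is
the graft VOI.  Volumes are voxel count times voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, GeometryError

__all__ = ["ComponentInfo", "ComponentReport", "largest_component_within", "measure_volume"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ComponentInfo:
    label: int
    voxel_count: int
    volume_mm3: float
    bbox_min_mm: tuple
    bbox_max_mm: tuple


@dataclass
class ComponentReport:
    components: list = field(default_factory=list)
    selected: int | None = None         # label of the selected component
    connectivity: int = 26
    tie: bool = False                   # size tie resolved deterministically

    @property
    def total_voxels(self) -> int:
        return sum(c.voxel_count for c in self.components)


def largest_component_within(
    seg: BinaryMask, roi: BinaryMask | None = None, connectivity: int = 26
):
    """Largest connected component of ``seg`` restricted to ``roi``.

    Connectivity is 6, 18 or 26 (default 26: the permissive standard for
    3D foreground).  Size ties are broken deterministically by the
    lexicographically smallest bounding-box corner and recorded in the
    report.  Empty input yields an empty mask and an empty report.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    values = seg.values
    if roi is not None:
        if not seg.same_grid(roi):
            raise GeometryError("segmentation and ROI are on different grids")
        values = values & roi.values
    report = ComponentReport(connectivity=connectivity)
    out = seg.with_values(np.zeros_like(values))
    if not values.any():
        return out, report
    labels, n = ndimage.label(values, structure=_STRUCTURES[connectivity])
    voxvol = seg.voxel_volume
    objects = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel())[1:]
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        lo = tuple(
            float(seg.origin[i] + sl[i].start * seg.spacing[i]) for i in range(3)
        )
        hi = tuple(
            float(seg.origin[i] + (sl[i].stop - 1) * seg.spacing[i]) for i in range(3)
        )
        report.components.append(
            ComponentInfo(lab, int(counts[lab - 1]), float(counts[lab - 1]) * voxvol, lo, hi)
        )
    best = max(counts)
    tied = [c for c in report.components if c.voxel_count == best]
    if len(tied) > 1:
        report.tie = True
        tied.sort(key=lambda c: c.bbox_min_mm)
    chosen = tied[0]
    report.selected = chosen.label
    out = seg.with_values(labels == chosen.label)
    return out, report


def measure_volume(mask: BinaryMask) -> float:
    """Volume in mm^3 = voxel count x spacing_x * spacing_y * spacing_z."""
    return mask.volume_mm3()
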