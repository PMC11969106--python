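"""Threshold-based body contouring and the multi-threshold baseline.

A body contour is the largest 3-D connected component of voxels at or above
an HU threshold, with enclosed cavities filled (body structures are solid in
treatment-planning convention).  The baseline repeats the contour at several
thresholds — by default −300, −450 and −600 HU — and reports the mean volume
with its sample standard deviation as the contouring uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ImageGrid, StructureMask

__all__ = ["BaselineContour", "threshold_body", "crop_z", "baseline_contour"]

DEFAULT_THRESHOLDS_HU = (-300.0, -450.0, -600.0)

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def threshold_body(
    image: ImageGrid,
    threshold_hu: float,
    largest_component: bool = True,
    fill_holes: bool = True,
) -> StructureMask:
    """Segment the body as ``HU ≥ threshold``.

    Post-processing (on by default): keep the largest 26-connected 3-D
    component, then fill fully enclosed cavities.  An empty result is valid
    and flagged via the mask's ``label`` (``body(empty)``).
    """
    raw = np.asarray(image.values) >= threshold_hu
    if not raw.any():
        return StructureMask.like(image, raw, label="body(empty)")
    mask = raw
    if largest_component:
        labels, n = ndimage.label(raw, structure=_STRUCTURE_26)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mask = labels == int(np.argmax(counts))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return StructureMask.like(image, mask, label="body")


def crop_z(mask: StructureMask, z_lo_cm: float, z_hi_cm: float) -> StructureMask:
    """Clear voxels whose centre z lies outside ``[z_lo, z_hi)`` (cm).

    The half-open interval keeps a voxel when its centre satisfies
    ``z_lo ≤ z < z_hi``, so adjacent crops never double-count a slice.
    """
    if z_lo_cm >= z_hi_cm:
        raise ValueError("z_lo must be below z_hi")
    z_mm = mask.axis_coords(0)
    lo_mm, hi_mm = z_lo_cm * 10.0, z_hi_cm * 10.0
    if lo_mm < z_mm[0] - mask.spacing[0] / 2 or hi_mm > z_mm[-1] + mask.spacing[0] / 2:
        raise ValueError("crop bounds extend beyond the lattice z extent")
    keep = (z_mm >= lo_mm) & (z_mm < hi_mm)
    out = mask.values.copy()
    out[~keep] = False
    return mask.with_values(out)


@dataclass
class BaselineContour:
    """Multi-threshold baseline: member masks, mean volume and its spread."""

    members: list
    thresholds_hu: tuple
    mean_volume_cm3: float
    volume_sd_cm3: float

    @property
    def volumes_cm3(self) -> list:
        return [m.volume_cm3 for m in self.members]


def baseline_contour(
    image: ImageGrid,
    thresholds_hu=DEFAULT_THRESHOLDS_HU,
    z_bounds_cm: tuple | None = None,
    largest_component: bool = True,
    fill_holes: bool = True,
) -> BaselineContour:
    """Contour at each threshold, crop in z, and average the volumes.

    The standard deviation across thresholds (sample SD, n−1) quantifies
    how sensitive the body volume is to the thresholding choice.  Any empty
    member makes the baseline undefined and raises.
    """
    thresholds_hu = tuple(float(t) for t in thresholds_hu)
    if len(thresholds_hu) < 2:
        raise ValueError("baseline needs at least two thresholds")
    members = []
    for t in thresholds_hu:
        m = threshold_body(image, t, largest_component, fill_holes)
        if not m.values.any():
            raise ValueError(f"baseline undefined: threshold {t} HU gives an empty body")
        if z_bounds_cm is not None:
            m = crop_z(m, *z_bounds_cm)
            if not m.values.any():
                raise ValueError(
                    f"baseline undefined: threshold {t} HU empty after z-crop"
                )
        members.append(m)
    volumes = np.array([m.volume_cm3 for m in members])
    return BaselineContour(
        members=members,
        thresholds_hu=thresholds_hu,
        mean_volume_cm3=float(volumes.mean()),
        volume_sd_cm3=float(volumes.std(ddof=1)),
    )
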