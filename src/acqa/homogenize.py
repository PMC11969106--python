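"""HU homogenization: turn a bolus-plus-air-gap image into a weight-loss image.

The algorithm works slice by slice, row by row along a configurable lattice
axis:

1. voxels below the air threshold are provisionally removed (NaN);
2. consecutive-pixel HU jumps larger than the spike threshold additionally
   remove the pixel on the low-HU side of the jump, which otherwise anchors
   poor interpolation at gap interfaces;
3. voxels inside the bolus HU window are replaced by random values whose
   mean and range match a sampled tissue background region;
4. removed runs lying strictly between remaining values in a row are filled
   by linear interpolation, closing former air gaps;
5. removed voxels outside the outer edge (exterior air) get their original
   values back, so everything outside the phantom is untouched.

The result has a uniform tissue-like interior whose outer outline is the
former bolus surface — a synthetic "heavier" anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import ImageGrid, StructureMask

__all__ = ["HomogenizeParams", "classify_air", "sample_background", "homogenize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomogenizeParams:
    """Tuning of the homogenization algorithm.

    Defaults follow typical CBCT magnitudes: everything below −200 HU is
    air, adjacent-pixel jumps above 45 HU flag gap interfaces, and silicone
    bolus lives in the 100–600 HU window.
    """

    air_threshold_hu: float = -200.0
    spike_threshold_hu: float = 45.0
    bolus_window_hu: tuple = (100.0, 600.0)
    fill_seed: int = 0
    interpolation_axis: int = 2
    spike_after_replacement: bool = False

    def __post_init__(self):
        lo, hi = self.bolus_window_hu
        if lo >= hi:
            raise ValueError("bolus window must be a non-empty interval")
        if self.air_threshold_hu >= lo:
            raise ValueError("air threshold must lie below the bolus window")
        if self.spike_threshold_hu <= 0:
            raise ValueError("spike threshold must be positive")
        if self.interpolation_axis not in (1, 2):
            raise ValueError("rows run along in-slice axes 1 or 2")


def classify_air(image: ImageGrid, threshold_hu: float = -200.0) -> StructureMask:
    """Mask of voxels strictly below the air threshold."""
    return StructureMask.like(image, image.values < threshold_hu, label="air")


def _region_values(image: ImageGrid, region) -> np.ndarray:
    if isinstance(region, StructureMask):
        sel = region.values
    elif isinstance(region, np.ndarray) and region.dtype == bool:
        sel = region
    else:  # index-slice box ((z0, z1), (y0, y1), (x0, x1))
        (z0, z1), (y0, y1), (x0, x1) = region
        sel = np.zeros(image.shape, dtype=bool)
        sel[z0:z1, y0:y1, x0:x1] = True
    return np.asarray(image.values)[sel]


def sample_background(
    image: ImageGrid, region, air_threshold_hu: float = -200.0
) -> tuple:
    """Empirical mean and (low, high) HU range of a tissue background region.

    Replacement values for the bolus are later drawn uniformly over this
    range, so its mean and spread set the statistics of the filled-in shell.
    The region must be tissue only: any air voxel inside it is an error.
    """
    vals = _region_values(image, region)
    if vals.size == 0:
        raise ValueError("background region is empty")
    if np.any(vals < air_threshold_hu):
        raise ValueError("background region intersects air")
    vals = vals.astype(float)
    return float(vals.mean()), (float(vals.min()), float(vals.max()))


def _spike_flags(arr: np.ndarray, threshold: float, axis: int) -> np.ndarray:
    """Flag the low-HU side of adjacent-pixel jumps exceeding the threshold."""
    d = np.diff(arr, axis=axis)
    rising = d > threshold  # x[i+1] - x[i] > thr → low side is i
    falling = d < -threshold  # → low side is i + 1
    flags = np.zeros(arr.shape, dtype=bool)
    lead = [slice(None)] * arr.ndim
    lag = [slice(None)] * arr.ndim
    lead[axis] = slice(0, -1)
    lag[axis] = slice(1, None)
    with np.errstate(invalid="ignore"):
        flags[tuple(lead)] |= rising
        flags[tuple(lag)] |= falling
    return flags


def homogenize(
    image: ImageGrid, params: HomogenizeParams, background
) -> tuple[ImageGrid, dict]:
    """Run the five-step homogenization; returns image + diagnostic masks.

    ``background`` is the tissue region (mask, boolean array or index box)
    whose HU statistics parameterize the bolus replacement.  Deterministic
    for a fixed ``params.fill_seed``.  Diagnostics: ``air``, ``spike``,
    ``bolus_replaced``, ``interpolated`` masks on the image lattice.
    """
    orig = np.asarray(image.values).astype(float)
    axis = params.interpolation_axis
    bg_mean, (bg_lo, bg_hi) = sample_background(
        image, background, params.air_threshold_hu
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(params.fill_seed), 0xF111]))

    air = orig < params.air_threshold_hu
    work = orig.copy()
    work[air] = np.nan

    spike = np.zeros_like(air)
    if not params.spike_after_replacement:
        spike = _spike_flags(orig, params.spike_threshold_hu, axis) & ~air
        work[spike] = np.nan

    lo, hi = params.bolus_window_hu
    replaced = (orig >= lo) & (orig <= hi) & ~np.isnan(work)
    work[replaced] = rng.uniform(bg_lo, bg_hi, size=int(replaced.sum()))

    if params.spike_after_replacement:
        with np.errstate(invalid="ignore"):
            spike = _spike_flags(work, params.spike_threshold_hu, axis) & ~air
        work[spike] = np.nan

    interpolated = np.zeros_like(air)
    # iterate rows of each slice along the chosen axis
    work_rows = np.moveaxis(work, axis, -1)  # view: row edits land in `work`
    interp_rows = np.moveaxis(interpolated, axis, -1)
    n_empty = 0
    idx = np.arange(work.shape[axis])
    for pos in np.ndindex(work_rows.shape[:-1]):
        row, irow = work_rows[pos], interp_rows[pos]
        valid = ~np.isnan(row)
        nv = int(valid.sum())
        if nv == 0:
            n_empty += 1
            continue
        if nv == row.size or nv < 2:
            continue
        first, last = np.flatnonzero(valid)[[0, -1]]
        interior = ~valid
        interior[: first + 1] = False
        interior[last:] = False
        if not interior.any():
            continue
        row[interior] = np.interp(idx[interior], idx[valid], row[valid])
        irow[interior] = True
    if n_empty:
        log.debug("%d rows had no above-air content and were passed through", n_empty)

    remaining = np.isnan(work)
    work[remaining] = orig[remaining]

    out = image.with_values(np.rint(work).astype(np.int16))
    diagnostics = {
        "air": StructureMask.like(image, air, label="air"),
        "spike": StructureMask.like(image, spike, label="spike"),
        "bolus_replaced": StructureMask.like(image, replaced, label="bolus_replaced"),
        "interpolated": StructureMask.like(image, interpolated, label="interpolated"),
    }
    return out, diagnostics
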