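"""Dosimetric evaluation: DVH metrics, 3-D gamma analysis, and a toy beam model.

The gamma index compares two dose distributions by combining a dose
difference (DD, %) with a distance-to-agreement (DTA, mm): for every
reference voxel above a low-dose cutoff,

    γ = min over nearby evaluated positions of
        sqrt((Δdose / DD)² + (Δdistance / DTA)²),

and the voxel passes when γ ≤ 1.  The search samples the evaluated grid by
trilinear interpolation on a sub-voxel step inside a ball of a few DTA radii.

The toy dose model is deliberately not a physics engine: per beam it forms a
target-conformal fluence aperture with a Gaussian penumbra and attenuates it
exponentially along the radiological path (HU-derived relative density).  It
exists so that planned / scheduled / adapted dose contrasts can be studied
against known phantom geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .grids import DoseGrid, ImageGrid, StructureMask

__all__ = [
    "GammaParams",
    "PlanGoals",
    "Goal",
    "BeamParams",
    "TreatmentPlan",
    "dvh_metric",
    "evaluate_goals",
    "gamma_pass_rate",
    "dose_deviation_track",
    "toy_dose_model",
    "plan_beams",
    "compute_dose",
    "resample_dose",
    "crop_target_from_surface",
]


# --------------------------------------------------------------------------
# DVH


def dvh_metric(dose: DoseGrid, mask: StructureMask, q_percent: float) -> float:
    """Dq%: dose level (Gy) received by at least q% of the structure volume.

    Computed from the voxel dose multiset with linear interpolation between
    order statistics; masks are binary, so no sub-voxel partial volumes.
    """
    if not dose.same_lattice(mask):
        raise ValueError("dose and mask must share one lattice (resample first)")
    if not 0 < q_percent <= 100:
        raise ValueError("q must lie in (0, 100]")
    vals = dose.values[mask.values]
    if vals.size == 0:
        raise ValueError("DVH metric of an empty structure is undefined")
    return float(np.percentile(vals, 100.0 - q_percent, method="linear"))


@dataclass(frozen=True)
class Goal:
    """One plan goal, e.g. D95% > 70 Gy."""

    metric: str  # "D95", "D99", ...
    threshold_gy: float
    direction: str = ">"

    @property
    def q_percent(self) -> float:
        if not self.metric.upper().startswith("D"):
            raise ValueError(f"unsupported metric {self.metric!r}")
        return float(self.metric.upper().lstrip("D").rstrip("%"))


@dataclass(frozen=True)
class PlanGoals:
    """Prescription and target dose goals."""

    prescription_gy: float = 70.0
    n_fractions: int = 35
    goals: tuple = (Goal("D95", 70.0, ">"), Goal("D99", 66.5, ">"))

    def __post_init__(self):
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.prescription_gy / self.n_fractions


def evaluate_goals(dose: DoseGrid, mask: StructureMask, goals: PlanGoals) -> dict:
    """Evaluate each goal; returns metric → (value, passed)."""
    out = {}
    for g in goals.goals:
        value = dvh_metric(dose, mask, g.q_percent)
        passed = value > g.threshold_gy if g.direction == ">" else value < g.threshold_gy
        out[g.metric] = (value, bool(passed))
    return out


# --------------------------------------------------------------------------
# Gamma


@dataclass(frozen=True)
class GammaParams:
    """Gamma criteria and search controls (defaults: global 3%/3 mm, 10% cutoff)."""

    dd_percent: float = 3.0
    dta_mm: float = 3.0
    normalization: str = "global"  # or "local"
    cutoff_percent: float = 10.0
    search_radius_factor: float = 2.0
    interpolation_step_mm: float = 1.0

    def __post_init__(self):
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("DD and DTA must be positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")
        if not 0 <= self.cutoff_percent < 100:
            raise ValueError("cutoff must lie in [0, 100)")
        if self.interpolation_step_mm > self.dta_mm / 3 + 1e-12:
            raise ValueError("interpolation step must not exceed DTA/3")


def _offsets(params: GammaParams) -> np.ndarray:
    """Search offsets (mm) inside a ball of radius factor × DTA, sorted by radius."""
    r_max = params.search_radius_factor * params.dta_mm
    step = params.interpolation_step_mm
    ax = np.arange(-np.floor(r_max / step), np.floor(r_max / step) + 1) * step
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    radii = np.linalg.norm(offs, axis=1)
    keep = radii <= r_max + 1e-9
    offs, radii = offs[keep], radii[keep]
    order = np.argsort(radii, kind="stable")
    return offs[order], radii[order]


def gamma_pass_rate(
    ref: DoseGrid, eval_dose: DoseGrid, params: GammaParams = GammaParams()
) -> tuple[float, np.ndarray]:
    """Percent of reference voxels with γ ≤ 1, plus the γ map.

    Reference voxels below the low-dose cutoff are excluded (NaN in the
    map).  The evaluated grid may live on a different lattice; it is sampled
    by trilinear interpolation, and positions outside it do not contribute.
    """
    ref_vals = ref.values
    ref_max = float(ref_vals.max())
    if params.normalization == "global" and ref_max <= 0:
        raise ValueError("global normalization undefined for a zero reference")
    cutoff = params.cutoff_percent / 100.0 * ref_max
    include = ref_vals >= cutoff if cutoff > 0 else np.ones_like(ref_vals, bool)
    if not include.any():
        raise ValueError("all reference voxels lie below the low-dose cutoff")

    pts = np.stack(
        np.meshgrid(*[ref.axis_coords(a) for a in range(3)], indexing="ij"), axis=-1
    )[include]
    r = ref_vals[include].astype(float)
    if params.normalization == "global":
        norm = np.full_like(r, params.dd_percent / 100.0 * ref_max)
    else:
        norm = params.dd_percent / 100.0 * r
        norm[norm == 0] = np.inf  # zero-dose reference voxels: only DTA can pass

    interp = RegularGridInterpolator(
        [eval_dose.axis_coords(a) for a in range(3)],
        eval_dose.values.astype(float),
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )

    offs, radii = _offsets(params)
    gamma2 = np.full(r.shape, np.inf)
    dta2 = params.dta_mm**2
    for off, rad in zip(offs, radii):
        space2 = rad**2 / dta2
        active = gamma2 > space2
        if not active.any():
            break
        vals = interp(pts[active] + off)
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        cand = (vals[ok] - r[active][ok]) ** 2 / norm[active][ok] ** 2 + space2
        idx = np.flatnonzero(active)[ok]
        gamma2[idx] = np.minimum(gamma2[idx], cand)

    gamma = np.sqrt(gamma2)
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0))
    gamma_map = np.full(ref_vals.shape, np.nan)
    gamma_map[include] = gamma
    return pass_rate, gamma_map


# --------------------------------------------------------------------------
# Deviation tracking


def dose_deviation_track(session_values_gy, planned_gy: float) -> tuple[list, float]:
    """Percent deviation of a per-session metric from its planned value.

    Returns the signed per-session deviations and the maximum |deviation|.
    """
    if planned_gy == 0:
        raise ValueError("planned value must be nonzero")
    devs = [100.0 * (v - planned_gy) / planned_gy for v in session_values_gy]
    return devs, max(abs(d) for d in devs) if devs else 0.0


# --------------------------------------------------------------------------
# Toy dose model

_DIRECTIONS = {
    # name → (axis along which the beam travels, reversed entry side?)
    "anterior": (1, False),  # enters the anterior face, travels +y
    "posterior": (1, True),
    "left": (2, False),  # travels +x
    "right": (2, True),
}


@dataclass(frozen=True)
class BeamParams:
    """Axis-aligned beam arrangement for the toy model.

    ``mu_per_mm`` is the effective exponential attenuation per mm of
    water-equivalent path (≈0.005/mm mimics a few percent dose change per cm
    of tissue, the magnitude relevant to surface-layer changes).
    """

    directions: tuple = ("anterior",)
    mu_per_mm: float = 0.005
    penumbra_mm: float = 5.0
    aperture_margin_mm: float = 5.0

    def __post_init__(self):
        for d in self.directions:
            if d not in _DIRECTIONS:
                raise ValueError(f"unknown beam direction {d!r}")
        if self.mu_per_mm < 0:
            raise ValueError("attenuation coefficient must be non-negative")


def _relative_density(image: ImageGrid) -> np.ndarray:
    """Affine HU → relative (water = 1) density, clipped at zero."""
    return np.clip(1.0 + np.asarray(image.values, float) / 1000.0, 0.0, None)


def _radiological_depth(image: ImageGrid, direction: str) -> np.ndarray:
    """Density-weighted path length (mm) from the entry face to each voxel."""
    axis, reverse = _DIRECTIONS[direction]
    dens = _relative_density(image)
    if reverse:
        dens = np.flip(dens, axis=axis)
    depth = (np.cumsum(dens, axis=axis) - dens / 2.0) * image.spacing[axis]
    if reverse:
        depth = np.flip(depth, axis=axis)
    return depth


def _fluence(image: ImageGrid, target: StructureMask, direction: str, beams: BeamParams):
    """Target-conformal 2-D aperture with a Gaussian penumbra, in [0, 1]."""
    axis, _ = _DIRECTIONS[direction]
    proj = target.values.any(axis=axis)
    other_axes = [a for a in range(3) if a != axis]
    spac = [image.spacing[a] for a in other_axes]
    if beams.aperture_margin_mm > 0:
        d = ndimage.distance_transform_edt(~proj, sampling=spac)
        proj = d <= beams.aperture_margin_mm
    flu = proj.astype(float)
    if beams.penumbra_mm > 0:
        sigma = [beams.penumbra_mm / s for s in spac]
        flu = ndimage.gaussian_filter(flu, sigma=sigma)
    return flu, axis


@dataclass
class TreatmentPlan:
    """Frozen beam fluences + output scale; replayable on any session image."""

    beams: BeamParams
    fluences: list  # (direction, 2-D fluence) pairs
    scale: float
    prescription_gy: float


def _raw_dose(image: ImageGrid, plan_fluences, beams: BeamParams) -> np.ndarray:
    dose = np.zeros(image.shape)
    for direction, flu in plan_fluences:
        depth = _radiological_depth(image, direction)
        axis = _DIRECTIONS[direction][0]
        dose += np.expand_dims(flu, axis=axis) * np.exp(-beams.mu_per_mm * depth)
    return dose


def plan_beams(
    image: ImageGrid,
    target: StructureMask,
    beams: BeamParams = BeamParams(),
    prescription_gy: float = 70.0,
) -> TreatmentPlan:
    """Build a plan on one anatomy: conform fluence to the target and scale
    the summed attenuated beams so the target mean equals the prescription."""
    if not target.values.any():
        raise ValueError("target mask is empty")
    if not image.same_lattice(target):
        raise ValueError("target must live on the image lattice")
    fluences = [
        ( d, _fluence(image, target, d, beams)[0]) for d in beams.directions
    ]
    raw = _raw_dose(image, fluences, beams)
    mean_t = float(raw[target.values].mean())
    if mean_t <= 0:
        raise ValueError("beam arrangement deposits no dose in the target")
    return TreatmentPlan(
        beams=beams,
        fluences=fluences,
        scale=prescription_gy / mean_t,
        prescription_gy=prescription_gy,
    )


def compute_dose(plan: TreatmentPlan, image: ImageGrid) -> DoseGrid:
    """Replay a plan's fluences on a (possibly different) session anatomy."""
    dose = plan.scale * _raw_dose(image, plan.fluences, plan.beams)
    return DoseGrid(values=dose, spacing=image.spacing, origin=image.origin)


def toy_dose_model(
    image: ImageGrid,
    target: StructureMask,
    beams: BeamParams = BeamParams(),
    prescription_gy: float = 70.0,
) -> DoseGrid:
    """Plan and compute in one step (the 'adapted' behaviour)."""
    return compute_dose(plan_beams(image, target, beams, prescription_gy), image)


# --------------------------------------------------------------------------
# Lattice utilities


def resample_dose(dose: DoseGrid, like, method: str = "nearest") -> DoseGrid:
    """Resample a dose grid onto another lattice (``like``: grid-like object).

    ``method`` is ``nearest`` (default, preserves values exactly on matching
    lattices) or ``linear`` (trilinear).
    """
    if method not in ("nearest", "linear"):
        raise ValueError("method must be 'nearest' or 'linear'")
    interp = RegularGridInterpolator(
        [dose.axis_coords(a) for a in range(3)],
        dose.values,
        method=method,
        bounds_error=False,
        fill_value=0.0,
    )
    pts = np.stack(
        np.meshgrid(*[like.axis_coords(a) for a in range(3)], indexing="ij"), axis=-1
    )
    vals = interp(pts.reshape(-1, 3)).reshape(pts.shape[:-1])
    return DoseGrid(values=np.clip(vals, 0, None), spacing=like.spacing, origin=like.origin)


def crop_target_from_surface(
    target: StructureMask, body: StructureMask, margin_mm: float = 3.0
) -> StructureMask:
    """Skin-sparing crop: drop target voxels within ``margin_mm`` of the
    body surface (erosion restricted to the surface side)."""
    if not target.same_lattice(body):
        raise ValueError("target and body must share one lattice")
    depth = ndimage.distance_transform_edt(body.values, sampling=body.spacing)
    keep = target.values & (depth > margin_mm)
    return target.with_values(keep, label=f"{target.label}_spared")
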