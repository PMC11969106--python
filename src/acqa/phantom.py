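"""Synthetic neck-phantom generator.

Builds ground-truth CBCT-like HU volumes of a neck surrogate: an elliptical
tissue cylinder with an optional bone insert, a hemispherical target attached
flush to the anterior surface, and a uniform-thickness bolus shell separated
from the skin by a configurable air-gap profile.  Every structure is also
returned as a boolean truth mask, so downstream preprocessing, contouring and
dose stages can be validated against known geometry.

Axial geometry: angle ``theta`` is measured in the (y, x) plane around the
core centre, ``theta = 0`` at the anterior pole (−y), ±90° lateral, 180°
posterior.  All lengths are millimetres unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import ImageGrid, StructureMask

__all__ = [
    "GapSector",
    "GapProfile",
    "PhantomSpec",
    "Phantom",
    "ContourEmulationParams",
    "WeightLossSession",
    "make_phantom",
    "make_weight_loss_series",
    "emulate_autocontour",
]

CM_TO_MM = 10.0


@dataclass(frozen=True)
class GapSector:
    """Piecewise-constant air-gap override over an angular (and z) range."""

    theta_lo_deg: float
    theta_hi_deg: float
    width_mm: float
    z_lo_mm: float = -np.inf
    z_hi_mm: float = np.inf

    def __post_init__(self):
        if self.width_mm < 0:
            raise ValueError("gap width must be non-negative")


@dataclass(frozen=True)
class GapProfile:
    """Air gap between skin and bolus inner surface, per angle and slice.

    ``base_width_mm`` applies everywhere; each :class:`GapSector` overrides it
    on its angular/z range (later sectors win on overlap).
    """

    base_width_mm: float = 0.0
    sectors: tuple = ()

    def __post_init__(self):
        if self.base_width_mm < 0:
            raise ValueError("gap width must be non-negative")
        object.__setattr__(self, "sectors", tuple(self.sectors))

    @property
    def is_zero(self) -> bool:
        return self.base_width_mm == 0 and all(s.width_mm == 0 for s in self.sectors)

    @property
    def max_width_mm(self) -> float:
        return max([self.base_width_mm] + [s.width_mm for s in self.sectors])

    def evaluate(self, theta_deg: np.ndarray, z_mm: float):
        """Gap width and sector index per angle at one slice position.

        Returns ``(width_mm, sector_index)`` arrays; index −1 marks the base
        profile.
        """
        width = np.full(theta_deg.shape, float(self.base_width_mm))
        sector = np.full(theta_deg.shape, -1, dtype=np.int16)
        for i, s in enumerate(self.sectors):
            if not (s.z_lo_mm <= z_mm < s.z_hi_mm):
                continue
            sel = (theta_deg >= s.theta_lo_deg) & (theta_deg < s.theta_hi_deg)
            width[sel] = s.width_mm
            sector[sel] = i
        return width, sector


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the synthetic neck phantom.

    Defaults give a 1 mm isotropic lattice, a 55 × 45 mm semi-axis tissue
    ellipse over the full z slab, a 23 cm³ hemispherical surface target
    (radius 22.23 mm), and CBCT-plausible HU levels: air −1000, tissue
    0 ± 20 SD, bolus 300 ± 30 SD, bone 700.
    """

    shape: tuple = (74, 200, 176)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple = (45.0, 55.0)  # (anterior-posterior, lateral)
    slab_length_mm: float | None = None  # None → full z extent
    center_yx_mm: tuple | None = None  # None → lattice centre
    tissue_hu: float = 0.0
    tissue_noise_sd: float = 20.0
    air_hu: float = -1000.0
    air_noise_sd: float = 10.0
    include_bone: bool = False
    bone_hu: float = 700.0
    bone_radius_mm: float = 10.0
    bone_offset_yx_mm: tuple = (15.0, 0.0)  # posterior of centre
    target_radius_mm: float | None = 22.23
    target_hu: float = 0.0
    surface_layer_thickness_cm: float = 0.0
    bolus_hu: float = 300.0
    bolus_noise_sd: float = 30.0
    gap_profile: GapProfile = field(default_factory=GapProfile)
    edge_blur_mm: float = 0.8  # scanner PSF / partial-volume surrogate; 0 → crisp edges
    seed: int = 0

    def __post_init__(self):
        if self.surface_layer_thickness_cm < 0:
            raise ValueError("surface layer thickness must be non-negative")
        if self.target_radius_mm is not None and self.target_radius_mm <= 0:
            raise ValueError("target radius must be positive")
        if self.tissue_hu <= -200:
            raise ValueError("tissue HU must exceed the air window (−200 HU)")
        if not (100 <= self.bolus_hu <= 600):
            raise ValueError("bolus HU must lie within [100, 600]")
        if self.air_hu >= -200:
            raise ValueError("exterior HU must be below −200")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if self.edge_blur_mm < 0:
            raise ValueError("edge blur must be non-negative")

    @property
    def thickness_mm(self) -> float:
        return self.surface_layer_thickness_cm * CM_TO_MM


@dataclass
class Phantom:
    """A generated phantom: image, truth masks and the per-voxel gap width."""

    image: ImageGrid
    masks: dict
    gap_width_mm: np.ndarray
    spec: PhantomSpec
    sector_map: np.ndarray | None = None

    @property
    def body(self) -> StructureMask:
        return self.masks["body"]

    def outline(self) -> StructureMask:
        """Filled outer outline: body ∪ gap ∪ bolus."""
        values = (
            self.masks["body"].values
            | self.masks["gap"].values
            | self.masks["bolus"].values
        )
        return self.masks["body"].with_values(values, label="outline")


def _axial_geometry(spec: PhantomSpec):
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing_mm
    if spec.center_yx_mm is None:
        cy, cx = (ny - 1) * sy / 2.0, (nx - 1) * sx / 2.0
    else:
        cy, cx = spec.center_yx_mm
    yy = (np.arange(ny) * sy - cy)[:, None]
    xx = (np.arange(nx) * sx - cx)[None, :]
    a_y, a_x = spec.semi_axes_mm
    core2d = (yy / a_y) ** 2 + (xx / a_x) ** 2 <= 1.0
    # theta = 0 anterior (−y), ±90° lateral, ±180° posterior
    theta = np.degrees(np.arctan2(xx + np.zeros_like(yy), -(yy + np.zeros_like(xx))))
    return core2d, theta, (cy, cx)


def _slab_slices(spec: PhantomSpec) -> np.ndarray:
    nz = spec.shape[0]
    sz = spec.spacing_mm[0]
    z = np.arange(nz) * sz
    if spec.slab_length_mm is None:
        return np.ones(nz, dtype=bool)
    zc = (nz - 1) * sz / 2.0
    return np.abs(z - zc) <= spec.slab_length_mm / 2.0


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize the phantom geometry and assemble a noisy HU image.

    Raises if the bolus shell would clip the lattice boundary, or if a
    nonzero gap profile is requested without a bolus to stand off from.
    """
    if spec.thickness_mm == 0 and not spec.gap_profile.is_zero:
        raise ValueError("nonzero gap profile requires a nonzero bolus thickness")

    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing_mm
    core2d, theta2d, (cy, cx) = _axial_geometry(spec)
    in_slab = _slab_slices(spec)

    core = np.zeros(spec.shape, dtype=bool)
    core[in_slab] = core2d[None, :, :]

    target = np.zeros(spec.shape, dtype=bool)
    if spec.target_radius_mm is not None:
        r = spec.target_radius_mm
        a_y = spec.semi_axes_mm[0]
        y_att = cy - a_y  # anterior pole of the ellipse
        zc = (nz - 1) * sz / 2.0
        zz = (np.arange(nz) * sz - zc)[:, None, None]
        yy = (np.arange(ny) * sy - y_att)[None, :, None]
        xx = (np.arange(nx) * sx - cx)[None, None, :]
        sphere = zz**2 + yy**2 + xx**2 <= r**2
        # flat face flush with the anterior tangent plane
        target = sphere & (yy <= 0)
        target &= in_slab[:, None, None]

    bone = np.zeros(spec.shape, dtype=bool)
    if spec.include_bone:
        oy, ox = spec.bone_offset_yx_mm
        yy = (np.arange(ny) * sy - (cy + oy))[:, None]
        xx = (np.arange(nx) * sx - (cx + ox))[None, :]
        bone2d = yy**2 + xx**2 <= spec.bone_radius_mm**2
        bone[in_slab] = (bone2d & core2d)[None, :, :]

    body = core | target

    # per-slice Euclidean distance outside the body, and the gap profile
    gap = np.zeros(spec.shape, dtype=bool)
    bolus = np.zeros(spec.shape, dtype=bool)
    gap_width = np.zeros(spec.shape, dtype=np.float32)
    sector_map = np.full(spec.shape, -1, dtype=np.int16)
    t_mm = spec.thickness_mm
    for k in range(nz):
        if not body[k].any():
            continue
        w2d, sec2d = spec.gap_profile.evaluate(theta2d, k * sz)
        gap_width[k] = w2d
        sector_map[k] = sec2d
        if t_mm == 0:
            continue
        d = ndimage.distance_transform_edt(~body[k], sampling=(sy, sx))
        outer = w2d + t_mm
        gap[k] = (d > 0) & (d <= w2d)
        bolus[k] = (d > w2d) & (d <= outer)
        shell = gap[k] | bolus[k]
        if shell[0, :].any() or shell[-1, :].any() or shell[:, 0].any() or shell[:, -1].any():
            raise ValueError("bolus shell exceeds the lattice extent")

    image = _assemble_image(spec, body, bone, gap, bolus)
    masks = {
        name: StructureMask.like(image, vals, label=name)
        for name, vals in [
            ("body", body),
            ("bolus", bolus),
            ("target", target),
            ("gap", gap),
            ("bone", bone),
        ]
    }
    return Phantom(
        image=image, masks=masks, gap_width_mm=gap_width, spec=spec,
        sector_map=sector_map,
    )


def _noise_field(spec: PhantomSpec) -> np.ndarray:
    """One standard-normal draw per voxel; shared across a seed's variants.

    Because the field is drawn over the whole lattice before region scaling,
    phantoms differing only in shell thickness share identical core noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xACA]))
    return rng.standard_normal(spec.shape)


def _assemble_image(spec, body, bone, gap, bolus) -> ImageGrid:
    hu = np.full(spec.shape, float(spec.air_hu))
    sd = np.full(spec.shape, float(spec.air_noise_sd))
    hu[body] = spec.tissue_hu
    sd[body] = spec.tissue_noise_sd
    # target keeps its own mean but tissue-like noise
    hu[bone] = spec.bone_hu
    hu[gap] = spec.air_hu
    sd[gap] = spec.air_noise_sd
    hu[bolus] = spec.bolus_hu
    sd[bolus] = spec.bolus_noise_sd
    hu = _blur(hu, spec) + sd * _noise_field(spec)
    values = np.rint(hu).astype(np.int16)
    return ImageGrid(values=values, spacing=spec.spacing_mm, origin=(0.0, 0.0, 0.0))


def _blur(hu: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Smooth the mean HU field to emulate scanner PSF / partial volume."""
    if spec.edge_blur_mm == 0:
        return hu
    sigma = [spec.edge_blur_mm / s for s in spec.spacing_mm]
    return ndimage.gaussian_filter(hu, sigma=sigma)


def _homogenized_truth(spec: PhantomSpec, body_full: np.ndarray) -> ImageGrid:
    """Ground-truth weight-loss twin: shell already at tissue HU, no gaps."""
    hu = np.full(spec.shape, float(spec.air_hu))
    sd = np.full(spec.shape, float(spec.air_noise_sd))
    hu[body_full] = spec.tissue_hu
    sd[body_full] = spec.tissue_noise_sd
    hu = _blur(hu, spec) + sd * _noise_field(spec)
    values = np.rint(hu).astype(np.int16)
    return ImageGrid(values=values, spacing=spec.spacing_mm, origin=(0.0, 0.0, 0.0))


@dataclass
class WeightLossSession:
    """One simulated weight-loss session: raw bolus image plus its truth twin."""

    thickness_cm: float
    phantom: Phantom
    homogenized_truth: ImageGrid
    truth_body: StructureMask  # core ∪ target ∪ former gap ∪ former bolus


def make_weight_loss_series(spec: PhantomSpec, thicknesses_cm) -> list:
    """Generate one phantom per surface-layer thickness with a shared core.

    Each session carries both the raw image (bolus HU, air gaps) and the
    homogenized ground truth (surface layer already at tissue HU, gaps
    filled), so HU homogenization can be validated against it.  The 0 cm
    session has no bolus, hence no gap.
    """
    thicknesses_cm = list(thicknesses_cm)
    if not thicknesses_cm:
        raise ValueError("thickness list must be non-empty")
    if any(t < 0 for t in thicknesses_cm):
        raise ValueError("thicknesses must be non-negative")
    sessions = []
    for t in thicknesses_cm:
        s = replace(
            spec,
            surface_layer_thickness_cm=t,
            gap_profile=spec.gap_profile if t > 0 else GapProfile(),
        )
        ph = make_phantom(s)
        body_full = (
            ph.masks["body"].values | ph.masks["gap"].values | ph.masks["bolus"].values
        )
        sessions.append(
            WeightLossSession(
                thickness_cm=float(t),
                phantom=ph,
                homogenized_truth=_homogenized_truth(s, body_full),
                truth_body=StructureMask.like(ph.image, body_full, label="body"),
            )
        )
    return sessions


@dataclass(frozen=True)
class ContourEmulationParams:
    """Behavioural knobs of the auto-contour emulator.

    ``accurate`` reproduces the truth outline; ``reference_anchored`` returns
    the reference-session body regardless of current anatomy (the failure
    mode of deformation-anchored contouring under geometry change);
    ``bolus_excluding`` drops the bolus from the body wherever the local
    skin–bolus air gap exceeds ``gap_exclusion_threshold_mm``, with seeded
    unstable behaviour below ``small_gap_instability_threshold_mm``.
    """

    mode: str = "accurate"
    gap_exclusion_threshold_mm: float = 2.5
    small_gap_instability_threshold_mm: float = 0.4
    instability_probability: float = 0.5
    adaptation_fraction_max: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("accurate", "reference_anchored", "bolus_excluding"):
            raise ValueError(f"unknown emulation mode {self.mode!r}")
        if self.gap_exclusion_threshold_mm < 0 or self.small_gap_instability_threshold_mm < 0:
            raise ValueError("thresholds must be non-negative")
        if self.gap_exclusion_threshold_mm <= self.small_gap_instability_threshold_mm:
            raise ValueError("exclusion threshold must exceed instability threshold")
        if not 0 <= self.instability_probability <= 1:
            raise ValueError("instability probability must lie in [0, 1]")
        if not 0 <= self.adaptation_fraction_max <= 1:
            raise ValueError("adaptation fraction must lie in [0, 1]")


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Euclidean signed distance in mm, negative inside the mask."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def emulate_autocontour(
    phantom: Phantom,
    params: ContourEmulationParams,
    reference_body: StructureMask | None = None,
) -> StructureMask:
    """Produce a system-style body contour for one session phantom."""
    outline = phantom.outline()
    if params.mode == "accurate":
        return outline.with_values(outline.values, label="body_auto")
    if params.mode == "reference_anchored":
        if reference_body is None:
            raise ValueError("reference_anchored mode requires a reference body mask")
        if not reference_body.same_lattice(outline):
            raise ValueError("reference mask must share the session lattice")
        if params.adaptation_fraction_max == 0:
            # limiting case: a pure copy of the reference-session body
            return reference_body.with_values(reference_body.values, label="body_auto")
        # erratic partial deformation: morph the reference surface a seeded
        # random fraction of the way toward the current truth, per session
        t_key = int(round(phantom.spec.surface_layer_thickness_cm * 1000))
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), t_key, 0x4EF])
        )
        alpha = rng.uniform(0.0, params.adaptation_fraction_max)
        sd_ref = _signed_distance(reference_body.values, reference_body.spacing)
        sd_cur = _signed_distance(outline.values, outline.spacing)
        morphed = (1.0 - alpha) * sd_ref + alpha * sd_cur <= 0
        return outline.with_values(morphed, label="body_auto")

    # bolus_excluding
    shell = phantom.masks["bolus"].values | phantom.masks["gap"].values
    gw = phantom.gap_width_mm
    keep = outline.values.copy()
    exclude = shell & (gw > params.gap_exclusion_threshold_mm)
    unstable = shell & (gw < params.small_gap_instability_threshold_mm) & (gw >= 0)
    if unstable.any():
        # one seeded coin per (slice, gap sector): instability is coherent
        # over contiguous surface patches, not per-voxel speckle
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), 0x1B5])
        )
        sector_map = phantom.sector_map
        if sector_map is None:
            sector_map = np.full(gw.shape, -1, np.int16)
        zidx = np.arange(gw.shape[0])[:, None, None] + np.zeros_like(sector_map)
        keys = np.unique(
            np.stack([zidx[unstable], sector_map[unstable]], axis=1), axis=0
        )
        for z, sec in keys:
            if rng.random() < params.instability_probability:
                sel = unstable & (zidx == z) & (sector_map == sec)
                exclude = exclude | sel
    keep[exclude] = False
    return outline.with_values(keep, label="body_auto")
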