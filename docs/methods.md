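# Methods

This note documents the synthetic model, the algorithms, the meaning and
defaults of every tunable parameter, and the numerical choices made in the
implementation. It is the companion to the API reference in the module
docstrings.

## 1. Coordinate and data conventions

All 3-D arrays are ordered **(z, y, x)** = (superior→inferior,
anterior→posterior, left→right), with voxel sizes `spacing` in mm and the
physical position of voxel (0,0,0) in `origin` (mm, voxel centre). Three
thin dataclasses wrap arrays with this lattice metadata:

* `ImageGrid` — HU values (stored as `int16` when generated),
* `StructureMask` — boolean, with `volume_cm3 = count · voxel volume / 1000`,
* `DoseGrid` — float Gy.

File I/O goes through SimpleITK (MetaImage `.mha`/`.mhd`, NIfTI
`.nii`/`.nii.gz`, DICOM series with rescale slope/intercept applied);
SimpleITK's (x,y,z) metadata order is reversed at the boundary.

## 2. Phantom generator (`acqa.phantom`)

### Geometry

The phantom is an elliptical cylinder ("neck") spanning the full z extent
of the lattice, with semi-axes `semi_axes_mm = (anterior–posterior,
lateral)`. A hemispherical target of radius `target_radius_mm` sits flush
on the anterior pole, flat face outward, so it is a *surface* structure —
the kind most sensitive to body-outline errors. At the default radius of
22.23 mm on a 1 mm isotropic lattice the voxelized target volume is
22.96 cm³, i.e. 23 cm³ to the nearest cm³ (analytic ⅔πr³ = 23.0 cm³).

An optional **surface layer** (bolus) of thickness
`surface_layer_thickness_cm` wraps the cylinder as a shell, separated from
the skin by an **air gap** described by a `GapProfile`: a base width in mm
plus optional `GapSector`s that override the width over an angular range
(and optionally a z range). The shell and gap are constructed per slice
from the 2-D Euclidean distance transform of the body, so the gap width is
controlled point-wise: a voxel at distance d from the skin is gap if
d ≤ width(θ, z) and bolus if width(θ, z) < d ≤ width(θ, z) + thickness.

### HU assignment

Each region (air −1000, tissue 0, bolus +300, optional bone +700) gets
independent Gaussian noise with its own SD (defaults 10/20/30 HU). The
noise is drawn once for the **full lattice** per region from
`SeedSequence([seed, tag])`, so the same voxel receives the same noise in
every member of a weight-loss series — thinner sessions are true subsets
of the thicker anatomy, not re-noised images. Values are rounded to
integer HU (adding 1/12 quantization variance, visible in tests).

A Gaussian blur of the *mean* HU field with `edge_blur_mm = 0.8` (SD, mm)
models the scanner's partial-volume effect before noise is added. This is
what makes the three contouring thresholds disagree slightly: on a
noiseless, perfectly sharp edge every threshold between air and tissue
bisects the same boundary and the baseline SD would be exactly zero,
which would make "agreement within baseline uncertainty" an empty
criterion. 0.8 mm is of the order of a CBCT point-spread function and
produces baseline SDs of a few cm³ on litre-scale bodies.

### Weight-loss series and truth

`make_weight_loss_series(spec, thicknesses_cm)` builds one phantom per
surface-layer thickness (the gap is forced to zero at thickness 0). For
each session the **truth body** is core body ∪ gap ∪ bolus — the outline
an ideal contour should find after homogenization — and
`homogenized_truth` is the corresponding piecewise-constant HU image.

### Auto-contour emulation

`emulate_autocontour(phantom, params, reference_body=...)` produces the
body contour a given workflow *would* draw; failure modes are emulated on
known geometry rather than learned:

* `accurate` — returns the truth outline.
* `reference_anchored` — returns the reference (heaviest-session) outline,
  optionally morphed a random fraction α ~ U(0, `adaptation_fraction_max`)
  of the way toward the session truth via signed-distance interpolation.
  α is drawn per session from `SeedSequence([seed, thickness key])`. With
  the default `adaptation_fraction_max = 0` the reference is copied
  verbatim; the study runner uses 0.5 so the emulated workflow adapts
  erratically and partially — a constant copy would have zero volume
  variance, leaving the R² tracking statistic undefined.
* `bolus_excluding` — excludes the bolus shell wherever the local air gap
  exceeds `gap_exclusion_threshold_mm` (default 2.5 mm), and where the gap
  is below `small_gap_instability_threshold_mm` (0.4 mm) excludes it with
  probability `instability_probability` per (slice, sector), seeded — the
  "snug bolus sometimes drops out" instability.

## 3. HU homogenization (`acqa.homogenize`)

The weight-loss simulation replaces bolus and air-gap HU with tissue-like
values in five steps, row by row along `interpolation_axis` (x by
default, y allowed):

1. voxels `< air_threshold_hu` (−200 HU) are marked air and set to NaN;
2. adjacent-voxel differences `> spike_threshold_hu` (45 HU) flag the
   low-HU side as a spike and set it to NaN (reconstruction streaks);
3. voxels inside `bolus_window_hu` ([100, 600] HU) are replaced by uniform
   random values matching the sampled background mean and range;
4. interior NaN runs are linearly interpolated per row between their
   bounding valid voxels;
5. NaNs with no valid neighbour on one side (the exterior) are restored to
   their original values — the air outside the outline is untouched.

The background (mean and range of healthy tissue) is **required** and is
sampled from a caller-supplied region that must contain no air: silently
guessing a background from an arbitrary image is how a filling algorithm
quietly corrupts tissue, so the function refuses instead. Replacement
randomness comes from `SeedSequence([fill_seed, tag])`; the function is
deterministic given its parameters and idempotent on its own output.

Step order matters: spikes are flagged on the *original* values before
bolus replacement (`spike_after_replacement=False` by default), so the
synthetic bolus fill cannot create new spike flags at its borders.

## 4. Body contouring and baseline (`acqa.contouring`)

`threshold_body(image, t)` keeps HU ≥ t, takes the largest 26-connected
component, and fills internal holes. The **baseline contour** runs this at
several thresholds — default **−300 / −450 / −600 HU**, bracketing the
air–tissue transition — and reports their mean volume and SD (ddof = 1).
The SD is the contouring uncertainty against which auto-contour deviations
are judged. `crop_z(mask, lo_cm, hi_cm)` restricts volumes to an axial
slab (half-open on voxel centres, so adjacent slabs never double count).

## 5. Contour metrics (`acqa.metrics`)

For a series of sessions and one workflow:

* **MAD** — mean over sessions of |auto volume − baseline mean volume|,
  cm³. A workflow whose MAD exceeds the series' **maximum baseline SD**
  disagrees with threshold contouring beyond its own uncertainty.
* **R²** (percent) — with y the auto volumes and ŷ their ordinary
  least-squares line against surface-layer thickness,
  `R² = 100 − var(y − ŷ)/var(y) · 100`, where `var` is the **population
  (1/N) variance**. The OLS line is `np.polyfit(x, y, 1)`; tests verify
  equivalence with a brute-force slope/intercept grid search to 10⁻⁴.
  Constant y or fewer than three sessions raise (R² is undefined).

## 6. Dose evaluation (`acqa.dose`)

### Toy beam model

The dose engine is deliberately simple — it exists to make the
scheduled-vs-adapted comparison *mechanistically* sensitive to the body
outline, not to predict clinical dose:

* relative density ρ = clip(1 + HU/1000, 0) (air ≈ 0, tissue ≈ 1);
* radiological depth along each beam axis by cumulative sum of ρ·Δs;
* per-beam fluence: the target's beam's-eye-view projection, dilated by
  `aperture_margin_mm` (5 mm) and smoothed with a Gaussian penumbra
  (`penumbra_mm` = 5);
* dose ∝ fluence · exp(−μ·depth), μ = `mu_per_mm` = 0.005/mm;
* the sum over beams is scaled so the target mean equals the
  prescription (70 Gy in 35 fractions by default).

`plan_beams` freezes fluences and scale into a `TreatmentPlan`;
`compute_dose(plan, image)` replays it on *any* anatomy. "Scheduled" =
reference plan replayed on the session image; "adapted" = re-planned on
the session image. Goals follow DVH metrics: `dvh_metric(dose, mask, q)`
is the (100−q)-th linear-interpolated percentile of dose in the mask
(D95% = dose exceeded by 95% of the volume).

### Gamma index

`gamma_pass_rate(reference, evaluated, params)` implements the global
3%/3 mm gamma with a 10% low-dose cutoff. For each reference voxel above
the cutoff it searches evaluated positions within
`search_radius_factor · DTA` (factor 2), at steps of
`interpolation_step_mm ≤ DTA/3` (default 1 mm), using trilinear
interpolation; offsets are visited in order of increasing distance with
early termination once no closer offset can reduce γ. With the default
1 mm step on a 1 mm lattice every search point is a lattice point, where
trilinear interpolation is exact — the tests exploit this to require
*exact* agreement with a brute-force, no-interpolation oracle.

The study runner's "independent recalculation" is the adapted plan
re-planned and re-computed on a 2.5 mm lattice (`dose_grid_mm`), compared
against the fine dose resampled onto it.

### Skin sparing

At surface-layer thickness 0 the hemispherical target reaches the skin; a
clinical plan would not chase dose into the build-up region, so the
evaluation target for DVH deviations is cropped by
`skin_spare_margin_mm = 3` (voxels within 3 mm of the exterior removed)
for that session only.

## 7. Study runner (`acqa.study`)

`run_study(StudyConfig)` executes both arms from one master seed:

* **weight loss** — five sessions (2.0, 1.5, 1.0, 0.5, 0 cm surface
  layer, 1 mm gap); each raw image is homogenized, baseline-contoured,
  and compared against `accurate` and `reference_anchored` emulations;
  the dose arm plans on the heaviest session and tracks scheduled vs
  adapted D95% and gamma across all five.
* **bolus application** — 1.0 and 0.5 cm bolus with a 3 mm gap (above the
  2.5 mm exclusion threshold), raw baseline vs `bolus_excluding`
  emulation.

The master seed spawns per-stage seeds (phantom noise, homogenization
fill, emulator instability, bolus phantoms) via
`SeedSequence.generate_state`, each reduced mod 2³¹. Re-running a config
reproduces `summary.json` byte for byte.

## 8. Realism and limitations

The generator is a *mechanistic caricature*, adequate for testing the
pipeline's logic but not for clinical claims:

* geometry is a convex cylinder — no anatomy, no heterogeneity beyond an
  optional bone insert, no couch or immobilization devices;
* noise is i.i.d. Gaussian per region — no streaks, beam hardening, or
  scatter, so step 2 of the homogenizer (spike removal) is exercised by
  construction in tests, not organically;
* auto-contour failure modes are scripted, not learned: the emulators
  reproduce the *phenomenology* (reference anchoring, gap-driven bolus
  exclusion) with controllable severity;
* the beam model has no scatter, build-up, or beamlet optimization; its
  D95% deviations show the right *ordering* (adapted ≪ scheduled) but
  their magnitudes are not calibrated to any clinical system;
* the default lattice (74×200×176 at 1 mm) keeps the full study around
  20 s on one CPU; all problem sizes are package choices, chosen so the
  acceptance pipeline runs comfortably inside a laptop-scale budget.

## 9. Numerical choices

* distance computations use `scipy.ndimage.distance_transform_edt`
  (per-slice 2-D for shell construction, 3-D for skin sparing and
  signed-distance morphing);
* connected components / hole filling use `scipy.ndimage.label` (26- and
  6-connectivity structuring elements) and `binary_fill_holes`;
* resampling uses `scipy.interpolate.RegularGridInterpolator` (linear for
  HU and dose, nearest for masks);
* OLS fits use `np.polyfit`, percentiles `np.percentile(...,
  method="linear")`;
* every random stream is a `numpy.random.Generator` seeded from a
  `SeedSequence` keyed by (caller seed, fixed stream tag), so independent
  stages never share or race a global state, and all derived seeds stay
  below 2³¹ for portability.
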