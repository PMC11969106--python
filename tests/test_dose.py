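"""DVH metrics, gamma analysis and the toy beam model."""

from dataclasses import replace

import numpy as np
import pytest

from acqa import (
    BeamParams,
    DoseGrid,
    GammaParams,
    Goal,
    ImageGrid,
    PhantomSpec,
    PlanGoals,
    StructureMask,
    compute_dose,
    crop_target_from_surface,
    dose_deviation_track,
    dvh_metric,
    evaluate_goals,
    gamma_pass_rate,
    make_phantom,
    plan_beams,
    resample_dose,
    toy_dose_model,
)


def _mask_like(dose, sel=None):
    vals = np.ones(dose.shape, bool) if sel is None else sel
    return StructureMask(values=vals, spacing=dose.spacing, origin=dose.origin)


class TestDvh:
    @pytest.mark.parametrize("q", [1, 50, 95, 99, 100])
    def test_uniform_dose_returns_the_uniform_value(self, q):
        dose = DoseGrid(values=np.full((4, 5, 6), 70.0))
        assert dvh_metric(dose, _mask_like(dose), q) == pytest.approx(70.0)

    def test_uniform_ramp_closed_form(self):
        # doses evenly spread over [0, 100] Gy → D95% is the 5th percentile
        dose = DoseGrid(values=np.linspace(0, 100, 21 * 10 * 10).reshape(21, 10, 10))
        d95 = dvh_metric(dose, _mask_like(dose), 95)
        assert d95 == pytest.approx(5.0, abs=0.1)

    def test_dq_non_increasing_in_q(self):
        rng = np.random.default_rng(0)
        dose = DoseGrid(values=rng.uniform(0, 80, (8, 8, 8)))
        mask = _mask_like(dose)
        qs = [10, 30, 50, 70, 90, 99]
        vals = [dvh_metric(dose, mask, q) for q in qs]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_goal_evaluation(self):
        dose = DoseGrid(values=np.full((4, 4, 4), 71.0))
        goals = PlanGoals(goals=(Goal("D95", 70.0, ">"), Goal("D99", 66.5, ">")))
        res = evaluate_goals(dose, _mask_like(dose), goals)
        assert res["D95"] == (pytest.approx(71.0), True)
        assert res["D99"] == (pytest.approx(71.0), True)

    def test_empty_mask_and_bad_q_raise(self):
        dose = DoseGrid(values=np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            dvh_metric(dose, _mask_like(dose, np.zeros((3, 3, 3), bool)), 95)
        with pytest.raises(ValueError):
            dvh_metric(dose, _mask_like(dose), 0)


def _oracle_gamma(ref, ev, p):
    """Brute-force exhaustive gamma: voxel positions only, no interpolation."""
    rv, evv = ref.values, ev.values
    mx = rv.max()
    cut = p.cutoff_percent / 100 * mx
    coords = [ref.axis_coords(i) for i in range(3)]
    pts = np.stack(np.meshgrid(*coords, indexing="ij"), -1).reshape(-1, 3)
    e_coords = [ev.axis_coords(i) for i in range(3)]
    e_pts = np.stack(np.meshgrid(*e_coords, indexing="ij"), -1).reshape(-1, 3)
    inc = rv.ravel() >= cut
    rp, rr = pts[inc], rv.ravel()[inc]
    R = p.search_radius_factor * p.dta_mm
    if p.normalization == "global":
        norm = np.full(rr.shape, p.dd_percent / 100 * mx)
    else:
        norm = p.dd_percent / 100 * rr
    passed = 0
    ev_flat = evv.ravel()
    for i in range(rp.shape[0]):
        d2 = ((e_pts - rp[i]) ** 2).sum(1)
        sel = d2 <= R * R + 1e-9
        g2 = (ev_flat[sel] - rr[i]) ** 2 / norm[i] ** 2 + d2[sel] / p.dta_mm**2
        passed += g2.min() <= 1.0
    return 100.0 * passed / rp.shape[0]


class TestGamma:
    def test_identity_passes_everywhere(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.1, 2.0, (10, 10, 10))
        rate, gmap = gamma_pass_rate(DoseGrid(a), DoseGrid(a.copy()))
        assert rate == 100.0
        assert np.nanmax(gmap) == pytest.approx(0.0)

    def test_three_percent_global_scaling_passes(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.1, 2.0, (10, 10, 10))
        rate, _ = gamma_pass_rate(DoseGrid(a), DoseGrid(1.03 * a))
        assert rate == 100.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.2, 2.0, (16, 16, 16))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, None)
        p = GammaParams()  # 1 mm step on a 1 mm lattice → same search set
        mine, _ = gamma_pass_rate(DoseGrid(a), DoseGrid(b), p)
        assert mine == pytest.approx(_oracle_gamma(DoseGrid(a), DoseGrid(b), p), abs=0.1)

    def test_loosening_criteria_never_decreases_pass_rate(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.2, 2.0, (12, 12, 12))
        b = np.clip(a + rng.normal(0, 0.08, a.shape), 0, None)
        tight, _ = gamma_pass_rate(
            DoseGrid(a), DoseGrid(b), GammaParams(dd_percent=2, dta_mm=2,
                                                  interpolation_step_mm=2 / 3)
        )
        loose_dd, _ = gamma_pass_rate(
            DoseGrid(a), DoseGrid(b), GammaParams(dd_percent=4, dta_mm=2,
                                                  interpolation_step_mm=2 / 3)
        )
        loose_dta, _ = gamma_pass_rate(
            DoseGrid(a), DoseGrid(b), GammaParams(dd_percent=2, dta_mm=4,
                                                  interpolation_step_mm=2 / 3)
        )
        assert loose_dd >= tight
        assert loose_dta >= tight

    def test_asymmetric_in_reference_and_evaluated(self):
        # a hot spike in the evaluated grid is forgiven when it is the
        # reference that is searched, so swapping arguments can change the rate
        a = np.full((9, 9, 9), 1.0)
        b = a.copy()
        b[4, 4, 4] = 2.0
        p = GammaParams(cutoff_percent=0.0, search_radius_factor=1.0)
        r_ab, _ = gamma_pass_rate(DoseGrid(a), DoseGrid(b), p)
        r_ba, _ = gamma_pass_rate(DoseGrid(b), DoseGrid(a), p)
        assert r_ab != r_ba

    def test_self_resampled_at_half_spacing_passes(self):
        rng = np.random.default_rng(6)
        coarse = DoseGrid(rng.uniform(0.5, 2.0, (8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        fine_grid = DoseGrid(
            np.zeros((15, 15, 15)), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)
        )
        fine = resample_dose(coarse, fine_grid, method="linear")
        rate, _ = gamma_pass_rate(fine, coarse)
        assert rate >= 99.9

    def test_degenerate_inputs_raise(self):
        zero = DoseGrid(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            gamma_pass_rate(zero, zero)
        with pytest.raises(ValueError):
            GammaParams(interpolation_step_mm=2.0)  # > DTA/3


class TestDeviationTracking:
    def test_equal_sessions_are_zero(self):
        devs, mx = dose_deviation_track([2.0, 2.0, 2.0], 2.0)
        assert devs == [0.0, 0.0, 0.0] and mx == 0.0

    def test_direct_percentage(self):
        devs, mx = dose_deviation_track([1.76], 2.0)
        assert devs[0] == pytest.approx(-12.0)
        assert mx == pytest.approx(12.0)

    def test_zero_planned_raises(self):
        with pytest.raises(ValueError):
            dose_deviation_track([1.0], 0.0)


@pytest.fixture(scope="module")
def uniform_phantom():
    """Water-equivalent block with a small interior target."""
    vals = np.zeros((20, 60, 40))
    img = ImageGrid(values=vals)
    target = np.zeros(vals.shape, bool)
    target[8:12, 28:34, 16:24] = True
    return img, StructureMask.like(img, target, label="target")


class TestToyDoseModel:
    def test_central_axis_depth_dose_is_exponential(self, uniform_phantom):
        img, target = uniform_phantom
        beams = BeamParams(directions=("anterior",), mu_per_mm=0.01, penumbra_mm=0.0,
                           aperture_margin_mm=0.0)
        dose = toy_dose_model(img, target, beams, prescription_gy=1.0)
        z, x = 10, 20
        profile = dose.values[z, :, x]
        inside = profile > 0
        ys = np.flatnonzero(inside)
        ratio = profile[ys[1:]] / profile[ys[:-1]]
        # water density 1 → attenuation per 1 mm step is exp(−0.01)
        assert ratio == pytest.approx(np.exp(-0.01) * np.ones(ratio.size), rel=1e-6)

    def test_opposed_beams_give_midplane_symmetry(self):
        vals = np.zeros((12, 40, 40))
        img = ImageGrid(values=vals)
        target = np.zeros(vals.shape, bool)
        target[4:8, 17:23, 17:23] = True
        tm = StructureMask.like(img, target)
        beams = BeamParams(directions=("anterior", "posterior"), penumbra_mm=2.0)
        dose = toy_dose_model(img, tm, beams, prescription_gy=2.0)
        assert np.allclose(dose.values, dose.values[:, ::-1, :], rtol=1e-9)

    def test_doubling_prescription_doubles_dose(self, uniform_phantom):
        img, target = uniform_phantom
        d1 = toy_dose_model(img, target, prescription_gy=1.0)
        d2 = toy_dose_model(img, target, prescription_gy=2.0)
        assert np.allclose(d2.values, 2.0 * d1.values)

    def test_target_mean_equals_prescription(self, uniform_phantom):
        img, target = uniform_phantom
        dose = toy_dose_model(img, target, prescription_gy=70.0)
        assert dose.values[target.values].mean() == pytest.approx(70.0)

    def test_added_surface_layer_reduces_scheduled_target_dose(self):
        spec = PhantomSpec(
            shape=(30, 120, 110), semi_axes_mm=(30.0, 26.0), target_radius_mm=8.0,
            tissue_noise_sd=0.0, bolus_noise_sd=0.0, air_noise_sd=0.0,
            edge_blur_mm=0.0,
        )
        thin = make_phantom(spec)
        thick = make_phantom(replace(spec, surface_layer_thickness_cm=1.0,
                                     bolus_hu=300.0))
        plan = plan_beams(thin.image, thin.masks["target"], prescription_gy=2.0)
        d_thin = dvh_metric(compute_dose(plan, thin.image), thin.masks["target"], 95)
        d_thick = dvh_metric(compute_dose(plan, thick.image), thick.masks["target"], 95)
        assert d_thick < d_thin

    def test_empty_target_raises(self, uniform_phantom):
        img, target = uniform_phantom
        empty = target.with_values(np.zeros(img.shape, bool))
        with pytest.raises(ValueError):
            plan_beams(img, empty)


class TestSkinSparingCrop:
    def test_crop_removes_only_surface_side(self, noiseless_spec):
        ph = make_phantom(noiseless_spec)
        target, body = ph.masks["target"], ph.masks["body"]
        spared = crop_target_from_surface(target, body, margin_mm=3.0)
        assert spared.values.sum() < target.values.sum()
        assert spared.values.any()
        # removed voxels all lie within 3 mm of the exterior
        from scipy import ndimage

        depth = ndimage.distance_transform_edt(body.values, sampling=body.spacing)
        removed = target.values & ~spared.values
        assert (depth[removed] <= 3.0).all()
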