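import dataclasses
import math

import numpy as np
import pytest

from sctdoseval.agreement import dice, mean_absolute_error
from sctdoseval.grids import BinaryMask, ScalarVolume, VolumeGrid, resample
from sctdoseval.synthetic import (
    CorruptionSpec,
    DoseModelSpec,
    PhantomGeometry,
    PhantomSpec,
    compute_dose,
    corrupt_to_sct,
    default_ct_grid,
    default_sct_grid,
    make_cohort,
    make_phantom,
)


class TestPhantom:
    def test_default_grids_match_acquisition_protocol(self):
        spec = PhantomSpec()
        assert default_ct_grid(spec).spacing == (1.2, 1.2, 3.0)
        assert default_sct_grid(spec).spacing == (1.0, 1.0, 1.5)

    def test_same_seed_is_bit_identical(self):
        a = make_phantom(seed=5)
        b = make_phantom(seed=5)
        np.testing.assert_array_equal(a.ct.values, b.ct.values)
        for name in a.masks:
            np.testing.assert_array_equal(a.masks[name].values, b.masks[name].values)

    def test_rendered_skull_matches_analytic_shell(self):
        """Feature-free phantom: rendered bone mask vs the analytic shell."""
        spec = dataclasses.replace(
            PhantomSpec(), sinuses=(), n_drill_holes=0, n_screws=0
        )
        geom = PhantomGeometry(spec, seed=0)
        grid = default_ct_grid(spec)
        rendered = BinaryMask(grid, geom.render_feature_masks(grid)["bone"])
        x, y, z = grid.meshgrid_world()
        analytic = BinaryMask(grid, geom.bone_region(x, y, z))
        assert dice(rendered, analytic) >= 0.98

    def test_impossible_ptv_is_named(self):
        with pytest.raises(ValueError, match="PTV"):
            PhantomSpec(ptv_center_mm=(60.0, 0.0, 0.0),
                        ptv_semiaxes_mm=(30.0, 30.0, 30.0)).validate()

    def test_truth_bone_fraction_consistent_with_voxel_counting(self):
        spec = dataclasses.replace(
            PhantomSpec(), ptv_center_mm=(0.0, 0.0, -50.0),
            ptv_semiaxes_mm=(22.0, 22.0, 18.0),
        )
        geom = PhantomGeometry(spec, seed=0)
        grid = default_sct_grid(spec)
        f = geom.render_feature_masks(grid)
        ptv = geom.render_masks(grid)["ptv"].values
        counted = (f["bone"] & ptv).sum() / ptv.sum()
        assert geom.bone_fraction_in_ptv() == pytest.approx(counted, abs=0.02)


class TestCorruption:
    def test_zero_corruption_equals_resampled_ct(self, default_phantom):
        spec = CorruptionSpec(
            noise_sigma_hu=0.0, interface_mislabel_prob=0.0,
            mislabel_drill_holes=False, mislabel_screws=False,
            mislabel_implant=False,
        )
        # same-grid target isolates the corruption model from resampling
        sct = corrupt_to_sct(
            default_phantom.ct, default_phantom.geometry, spec,
            target_grid=default_phantom.ct.grid,
        )
        body = default_phantom.masks["body"]
        assert mean_absolute_error(default_phantom.ct, sct, body) == 0.0

    def test_noise_only_mae_matches_half_normal_mean(self, default_phantom):
        sigma = 40.0
        spec = CorruptionSpec(
            noise_sigma_hu=sigma, interface_mislabel_prob=0.0,
            mislabel_drill_holes=False, mislabel_screws=False,
            mislabel_implant=False, seed=3,
        )
        sct = corrupt_to_sct(
            default_phantom.ct, default_phantom.geometry, spec,
            target_grid=default_phantom.ct.grid,
        )
        body = default_phantom.masks["body"]
        assert body.voxel_count >= 1e5
        mae = mean_absolute_error(default_phantom.ct, sct, body)
        assert mae == pytest.approx(sigma * math.sqrt(2 / math.pi), rel=0.05)

    def test_implant_mislabeled_as_bone(self):
        spec = dataclasses.replace(PhantomSpec(), has_implant=True)
        geom = PhantomGeometry(spec, seed=9)
        ct = geom.render_hu(default_ct_grid(spec))
        sct = corrupt_to_sct(ct, geom, CorruptionSpec(seed=9))
        implant = geom.render_feature_masks(sct.grid)["implant"]
        assert implant.sum() > 0
        ct_on_sct = resample(ct, sct.grid)
        # low-density implant in the truth (checked away from the bone rim,
        # where trilinear resampling blends with adjacent bone), bone-level
        # HU everywhere in the sCT
        from scipy import ndimage

        interior = ndimage.binary_erosion(implant, iterations=2)
        assert interior.sum() > 0
        assert np.all(ct_on_sct.values[interior] < 100.0)
        assert np.all(sct.values[implant] >= 100.0)

    def test_mislabel_probability_is_monotone_in_skull_error(self, default_phantom):
        maes = []
        for p in (0.1, 0.45, 0.8):
            spec = CorruptionSpec(interface_mislabel_prob=p, seed=5)
            sct = corrupt_to_sct(default_phantom.ct, default_phantom.geometry, spec)
            maes.append(
                mean_absolute_error(
                    default_phantom.ct,
                    resample(sct, default_phantom.ct.grid),
                    default_phantom.masks["skull_region"],
                )
            )
        assert maes[0] < maes[1] < maes[2]

    def test_noise_increases_body_mae(self, default_phantom):
        maes = []
        for sigma in (5.0, 25.0):
            spec = CorruptionSpec(
                noise_sigma_hu=sigma, interface_mislabel_prob=0.0,
                mislabel_drill_holes=False, mislabel_screws=False,
                mislabel_implant=False, seed=6,
            )
            sct = corrupt_to_sct(
                default_phantom.ct, default_phantom.geometry, spec,
                target_grid=default_phantom.ct.grid,
            )
            maes.append(
                mean_absolute_error(default_phantom.ct, sct,
                                    default_phantom.masks["body"])
            )
        assert maes[0] < maes[1]


class TestDoseModel:
    def test_central_axis_attenuation_closed_form(self):
        g = VolumeGrid((0, 0, 0), (2.5, 2.5, 2.5), (80, 60, 20))
        water = ScalarVolume(g, np.zeros(g.size, dtype=np.float32))
        ptv = np.zeros(g.size, bool)
        ptv[30:40, 25:35, 8:12] = True
        spec = DoseModelSpec(gantry_angles_deg=(0.0,))
        dose = compute_dose(water, BinaryMask(g, ptv), spec, prescription_gy=50.0)
        prof = dose.values[5:70, 30, 10].astype(float)
        depth = (np.arange(80)[5:70] + 0.5) * 2.5
        expected = np.exp(-spec.mu_per_mm * depth)
        ratio = prof / expected
        assert ratio.max() / ratio.min() - 1 < 0.01

    def test_ptv_mean_equals_prescription_and_dose_nonnegative(self, default_phantom):
        dose = compute_dose(
            default_phantom.ct, default_phantom.masks["ptv"], DoseModelSpec(),
            prescription_gy=54.0,
        )
        ptv_d = resample(default_phantom.masks["ptv"], dose.grid, mode="nearest")
        assert dose.values[ptv_d.values].mean() == pytest.approx(54.0, rel=1e-5)
        assert dose.values.min() >= 0.0
        assert dose.grid.spacing == (2.5, 2.5, 2.5)

    def test_identical_inputs_identical_dose_in_each_mode(self, default_phantom):
        for mode in ("water", "medium"):
            spec = DoseModelSpec(mode=mode)
            d1 = compute_dose(default_phantom.ct, default_phantom.masks["ptv"],
                              spec, 50.0)
            d2 = compute_dose(default_phantom.ct, default_phantom.masks["ptv"],
                              spec, 50.0)
            np.testing.assert_array_equal(d1.values, d2.values)

    def test_medium_mode_boosts_bone_dose(self, default_phantom):
        ptv = default_phantom.masks["ptv"]
        water = compute_dose(default_phantom.ct, ptv, DoseModelSpec(mode="water"), 50.0)
        medium = compute_dose(default_phantom.ct, ptv,
                              DoseModelSpec(mode="medium"), 50.0)
        bone = resample(
            BinaryMask(default_phantom.ct.grid,
                       default_phantom.ct.values >= 500), water.grid
        ).values
        hot = bone & (water.values > 0.3 * 50.0)
        assert hot.sum() > 0
        # relative to the (PTV-normalized) water dose, bone runs hotter
        assert np.median(medium.values[hot] / water.values[hot]) > 1.02

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            DoseModelSpec(mode="proton").validate()
        with pytest.raises(ValueError, match="monotone"):
            DoseModelSpec(calibration=((-1000, 1.0), (0, 0.5))).validate()

    def test_ptv_outside_dose_grid_rejected(self):
        g = VolumeGrid((0, 0, 0), (2.5, 2.5, 2.5), (20, 20, 20))
        water = ScalarVolume(g, np.zeros(g.size, dtype=np.float32))
        far = VolumeGrid((500.0, 0, 0), (2.5, 2.5, 2.5), (4, 4, 4))
        ptv = BinaryMask(far, np.ones(far.size, bool))
        with pytest.raises(Exception, match="overlap|coverage"):
            compute_dose(water, ptv, DoseModelSpec(), 50.0)


class TestCohort:
    def test_same_seed_reproduces_cohort(self):
        a = make_cohort(n=2, seed=3, with_dose=False)
        b = make_cohort(n=2, seed=3, with_dose=False)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.sct.values, cb.sct.values)
            assert ca.prescription_gy == cb.prescription_gy

    def test_severity_zero_disables_corruption(self):
        cases = make_cohort(n=1, seed=4, with_dose=False, severity_scale=0.0)
        case = cases[0]
        ct_on_sct = resample(case.ct, case.sct.grid)
        body = resample(case.masks["body"], case.sct.grid)
        diffs = case.sct.values[body.values] - ct_on_sct.values[body.values]
        assert np.abs(diffs).max() == 0.0

    def test_bone_fraction_increases_across_design_targets(self):
        cases = make_cohort(n=4, seed=5, with_dose=False)
        fracs = [c.truth["bone_fraction_in_ptv"] for c in cases]
        assert fracs[0] < 0.1
        assert fracs[-1] > 0.3
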