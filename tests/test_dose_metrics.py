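import numpy as np
import pytest

from sctdoseval.dose_metrics import (
    PlanMetrics,
    compute_plan_metrics,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    homogeneity_index,
    metric_difference,
    point_metrics,
    volume_at_dose,
)
from sctdoseval.grids import BinaryMask, EmptyStructureError, ScalarVolume

from conftest import full_mask, grid, uniform


def _sorted_oracle_dx(doses, x_pct):
    """Brute-force Dx: dose received by at least x% of the voxels."""
    doses = np.sort(doses)[::-1]
    k = int(np.ceil(x_pct / 100.0 * doses.size))
    return doses[k - 1]


class TestCumulativeDvh:
    def test_uniform_dose_step_curve(self):
        dvh = cumulative_dvh(uniform(40.0), full_mask(), 0.5)
        assert np.all(dvh.cumulative[dvh.edges_gy <= 40.0] == 1.0)
        assert np.all(dvh.cumulative[dvh.edges_gy > 40.0] == 0.0)

    def test_two_voxel_curve(self):
        g = grid((2, 1, 1))
        dose = ScalarVolume(g, np.array([20.0, 60.0]).reshape(2, 1, 1))
        dvh = cumulative_dvh(dose, full_mask(g), 1.0)
        assert volume_at_dose(dvh, 20.0) == 100.0
        assert volume_at_dose(dvh, 21.0) == pytest.approx(50.0)
        assert volume_at_dose(dvh, 61.0) == 0.0

    def test_curve_is_non_increasing(self):
        rng = np.random.default_rng(0)
        g = grid((6, 6, 6))
        dose = ScalarVolume(g, rng.uniform(0, 70, g.size))
        dvh = cumulative_dvh(dose, full_mask(g), 0.1)
        assert np.all(np.diff(dvh.cumulative) <= 0)

    def test_empty_structure_raises(self):
        with pytest.raises(EmptyStructureError):
            cumulative_dvh(
                uniform(1.0), BinaryMask(grid(), np.zeros((8, 8, 8), bool)), 0.1
            )


class TestDoseAtVolume:
    def test_uniform_dose_all_quantiles_equal(self):
        dvh = cumulative_dvh(uniform(40.0), full_mask(), 0.02)
        for x in (2, 50, 95, 98):
            assert dose_at_volume(dvh, x) == pytest.approx(40.0, abs=0.02)

    def test_linear_ramp_closed_form(self):
        g = grid((10, 10, 10))
        ramp = ScalarVolume(
            g, np.linspace(0, 100, 1000, endpoint=False).reshape(g.size)
        )
        dvh = cumulative_dvh(ramp, full_mask(g), 0.05)
        assert dose_at_volume(dvh, 95.0) == pytest.approx(5.0, abs=0.15)
        assert volume_at_dose(dvh, 50.0) == pytest.approx(50.0, abs=0.2)

    def test_monotone_in_x(self):
        rng = np.random.default_rng(1)
        g = grid((6, 6, 6))
        dvh = cumulative_dvh(
            ScalarVolume(g, rng.uniform(0, 60, g.size)), full_mask(g), 0.05
        )
        xs = np.linspace(1, 99, 25)
        ds = [dose_at_volume(dvh, x) for x in xs]
        assert np.all(np.diff(ds) <= 1e-12)

    def test_x_out_of_range_rejected(self):
        dvh = cumulative_dvh(uniform(40.0), full_mask(), 0.1)
        for bad in (0.0, 100.0, -3.0, 120.0):
            with pytest.raises(ValueError):
                dose_at_volume(dvh, bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_sort_oracle_on_random_volumes(self, seed):
        rng = np.random.default_rng(seed)
        size = tuple(rng.integers(3, 12, 3))
        g = grid(size)
        doses = rng.uniform(0, 60, size)
        bw = 0.02
        dvh = cumulative_dvh(ScalarVolume(g, doses), full_mask(g), bw)
        flat = doses.astype(np.float32).ravel()
        for x in (2, 50, 95, 98):
            assert dose_at_volume(dvh, x) == pytest.approx(
                _sorted_oracle_dx(flat, x), abs=bw
            )


class TestPointMetrics:
    def test_uniform(self):
        m = point_metrics(uniform(40.0), full_mask())
        assert m == {"Dmax_gy": 40.0, "Dmean_gy": 40.0}

    def test_two_voxels(self):
        g = grid((2, 1, 1))
        m = point_metrics(
            ScalarVolume(g, np.array([20.0, 60.0]).reshape(2, 1, 1)), full_mask(g)
        )
        assert m["Dmax_gy"] == 60.0
        assert m["Dmean_gy"] == 40.0


class TestIndices:
    def test_hi_zero_for_uniform_dose(self):
        dvh = cumulative_dvh(uniform(40.0), full_mask(), 0.02)
        assert homogeneity_index(dvh) == 0.0

    def test_hi_direct_arithmetic(self):
        # D2 = 42, D98 = 38, D50 = 40 -> HI = 10
        g = grid((100, 1, 1))
        doses = np.full(100, 40.0)
        doses[:2] = 42.0
        doses[-3:] = 38.0  # strictly fewer than 98% stay at/above 40
        dvh = cumulative_dvh(
            ScalarVolume(g, doses.reshape(100, 1, 1)), full_mask(g), 0.01
        )
        assert homogeneity_index(dvh) == pytest.approx(10.0, abs=0.1)

    def test_ci_exact_cases(self):
        g = grid((10, 10, 10))
        dose_vals = np.zeros(g.size)
        ptv = np.zeros(g.size, bool)
        ptv[2:6, 2:6, 2:6] = True
        dose_vals[ptv] = 50.0
        dose = ScalarVolume(g, dose_vals)
        body = full_mask(g)
        assert conformity_index(dose, BinaryMask(g, ptv), body, 50.0) == 1.0
        # isodose region twice the PTV volume
        big = np.zeros(g.size, bool)
        big[2:6, 2:6, 1:9] = True
        dose2 = ScalarVolume(g, np.where(big, 50.0, 0.0))
        assert conformity_index(dose2, BinaryMask(g, ptv), body, 50.0) == 2.0
        # nothing reaches the prescription
        assert conformity_index(dose, BinaryMask(g, ptv), body, 60.0) == 0.0


class TestMetricDifference:
    def _metrics(self, dmean=40.0, dmax=41.0, brainstem=30.0):
        return PlanMetrics(
            prescription_gy=40.0,
            ptv_dmax_gy=dmax,
            ptv_dmean_gy=dmean,
            ptv_d95_gy=38.5,
            ptv_v95_pct=99.0,
            hi=5.0,
            ci=1.1,
            oar_dose_gy={"brainstem": brainstem},
        )

    def test_identical_sets_give_zero(self):
        d = metric_difference(self._metrics(), self._metrics())
        assert all(v == 0.0 for v in d.values())

    def test_prescription_normalization_and_cgy(self):
        ref = self._metrics(dmean=40.2, brainstem=30.10)
        ev = self._metrics(dmean=40.0, brainstem=30.00)
        d = metric_difference(ref, ev)
        assert d["ptv_dmean_pct"] == pytest.approx(0.5)
        assert d["brainstem_cgy"] == pytest.approx(10.0, abs=1e-9)

    def test_structure_mismatch_raises(self):
        ref = self._metrics()
        ev = self._metrics()
        ev.oar_dose_gy = {"cochlea_l": 10.0}
        with pytest.raises(ValueError, match="mismatch"):
            metric_difference(ref, ev)


class TestDvhOrderInvariant:
    @pytest.mark.parametrize("seed", range(4))
    def test_quantile_ordering(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = grid((8, 8, 8))
        dose = ScalarVolume(g, rng.gamma(8.0, 5.0, g.size))
        bw = 0.02
        dvh = cumulative_dvh(dose, full_mask(g), bw)
        d98 = dose_at_volume(dvh, 98)
        d95 = dose_at_volume(dvh, 95)
        d50 = dose_at_volume(dvh, 50)
        d2 = dose_at_volume(dvh, 2)
        dmax = point_metrics(dose, full_mask(g))["Dmax_gy"]
        assert d98 <= d95 + bw <= d50 + 2 * bw <= d2 + 3 * bw <= dmax + 4 * bw
        # mutual consistency of the two DVH lookups
        assert volume_at_dose(dvh, d95) >= 95.0 - 100.0 * bw / max(d95, bw)


def test_compute_plan_metrics_requires_ptv_and_body():
    g = grid((6, 6, 6))
    dose = uniform(40.0, g)
    with pytest.raises(KeyError, match="ptv"):
        compute_plan_metrics(dose, {"body": full_mask(g)}, 40.0)
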