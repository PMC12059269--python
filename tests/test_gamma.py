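import numpy as np
import pytest

from sctdoseval.gamma import (
    PAPER_CRITERIA,
    GammaCriteria,
    GammaResult,
    gamma_index_map,
    gamma_suite,
    passing_rate,
)
from sctdoseval.grids import BinaryMask, ScalarVolume, VolumeGrid

from conftest import grid


def _smooth_pair(seed, size=(10, 10, 10), spacing=(3.0, 3.0, 3.0), noise=0.02):
    """A dome-shaped reference dose and a perturbed evaluated dose."""
    rng = np.random.default_rng(seed)
    g = VolumeGrid((0, 0, 0), spacing, size)
    idx = [np.arange(n) - (n - 1) / 2 for n in size]
    r2 = (
        idx[0][:, None, None] ** 2
        + idx[1][None, :, None] ** 2
        + idx[2][None, None, :] ** 2
    )
    base = 50.0 * np.exp(-r2 / (0.5 * max(size) ** 2))
    ref = ScalarVolume(g, base)
    ev = ScalarVolume(g, base * (1 + rng.normal(0, noise, size)))
    return ref, ev


class TestGammaMap:
    def test_identical_pair_gives_zero_gamma(self):
        ref, _ = _smooth_pair(0)
        res = gamma_index_map(ref, ref.copy(), GammaCriteria(3.0, 2.0))
        assert np.nanmax(res.gamma.values) == 0.0
        assert passing_rate(res) == 100.0

    def test_uniform_offset_by_exactly_delta_d_gives_gamma_one(self):
        g = grid((8, 8, 8), spacing=(2.0, 2.0, 2.0))
        ref = ScalarVolume(g, np.full(g.size, 40.0))
        ev = ScalarVolume(g, np.full(g.size, 40.0 * 1.02))
        res = gamma_index_map(ref, ev, GammaCriteria(2.0, 2.0))
        gam = res.gamma.values[res.analyzed.values]
        np.testing.assert_allclose(gam, 1.0, atol=1e-5)

    @pytest.mark.parametrize("seed", range(3))
    def test_optimized_engine_equals_brute_force(self, seed):
        ref, ev = _smooth_pair(seed, size=(8, 8, 8))
        crit = GammaCriteria(2.0, 2.0)
        fast = gamma_index_map(ref, ev, crit)
        slow = gamma_index_map(ref, ev, crit, engine="brute-force")
        sel = fast.analyzed.values
        np.testing.assert_array_equal(sel, slow.analyzed.values)
        np.testing.assert_allclose(
            fast.gamma.values[sel], slow.gamma.values[sel], atol=1e-6
        )

    def test_scaling_both_doses_leaves_gamma_unchanged(self):
        ref, ev = _smooth_pair(4)
        crit = GammaCriteria(2.0, 1.0)
        res1 = gamma_index_map(ref, ev, crit)
        res2 = gamma_index_map(
            ScalarVolume(ref.grid, ref.values * 3.0),
            ScalarVolume(ev.grid, ev.values * 3.0),
            crit,
        )
        sel = res1.analyzed.values
        np.testing.assert_allclose(
            res1.gamma.values[sel], res2.gamma.values[sel], atol=1e-5
        )

    def test_low_dose_threshold_excludes_voxels(self):
        g = grid((4, 4, 4))
        vals = np.full(g.size, 1.0)
        vals[0, 0, 0] = 100.0
        ref = ScalarVolume(g, vals)
        res = gamma_index_map(ref, ref.copy(), GammaCriteria(3.0, 1.0, 10.0))
        assert res.analyzed.voxel_count == 1
        assert np.isnan(res.gamma.values[1, 1, 1])

    def test_zero_normalization_dose_rejected(self):
        g = grid((4, 4, 4))
        zero = ScalarVolume(g, np.zeros(g.size))
        with pytest.raises(ValueError, match="normalization"):
            gamma_index_map(zero, zero.copy(), GammaCriteria(3.0, 1.0))

    def test_spatial_shift_resolved_by_dta(self):
        # a 1-voxel (2 mm) shift of a steep ramp passes 3%/2mm but fails 1%/1mm
        g = grid((20, 8, 8), spacing=(2.0, 2.0, 2.0))
        ramp = np.tile(
            np.linspace(10, 60, 20)[:, None, None], (1, 8, 8)
        )
        ref = ScalarVolume(g, ramp)
        ev = ScalarVolume(g, np.roll(ramp, 1, axis=0))
        loose = gamma_index_map(ref, ev, GammaCriteria(3.0, 2.0))
        tight = gamma_index_map(ref, ev, GammaCriteria(1.0, 1.0))
        inner = np.zeros(g.size, bool)
        inner[3:-3] = True
        region = BinaryMask(g, inner)
        assert passing_rate(loose, region) == 100.0
        assert passing_rate(tight, region) < 50.0


class TestPassingRate:
    def test_direct_counting(self):
        g = grid((4, 1, 1))
        gam = np.array([0.5, 0.9, 1.0, 1.5], dtype=np.float32).reshape(4, 1, 1)
        res = GammaResult(
            gamma=ScalarVolume(g, gam),
            analyzed=BinaryMask(g, np.ones(g.size, bool)),
            boundary=BinaryMask(g, np.zeros(g.size, bool)),
            criteria=GammaCriteria(1.0, 1.0),
            normalization_dose_gy=50.0,
        )
        assert passing_rate(res) == 75.0  # gamma = 1 passes (inclusive)

    def test_empty_region_raises(self):
        ref, ev = _smooth_pair(1)
        res = gamma_index_map(ref, ev, GammaCriteria(3.0, 2.0))
        cold = BinaryMask(ref.grid, ~res.analyzed.values)
        with pytest.raises(ValueError, match="analyzed"):
            passing_rate(res, cold)


class TestGammaSuite:
    def test_identical_pair_all_hundred(self):
        ref, _ = _smooth_pair(2)
        ptv = np.zeros(ref.grid.size, bool)
        ptv[4:7, 4:7, 4:7] = True
        table = gamma_suite(ref, ref.copy(), BinaryMask(ref.grid, ptv))
        assert len(table) == 8
        assert (table["passing_rate_pct"] == 100.0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_rates_non_increasing_as_criteria_tighten(self, seed):
        ref, ev = _smooth_pair(seed, noise=0.03)
        ptv = np.zeros(ref.grid.size, bool)
        ptv[3:8, 3:8, 3:8] = True
        table = gamma_suite(ref, ev, BinaryMask(ref.grid, ptv))
        for region in ("volume", "ptv"):
            rates = table[table.region == region].passing_rate_pct.to_numpy()
            # suite order: 3/2, 3/1, 2/1, 1/1 — strictly tightening
            assert np.all(np.diff(rates) <= 1e-9)

    def test_paper_criteria_constants(self):
        labels = [c.label for c in PAPER_CRITERIA]
        assert labels == ["3%/2mm", "3%/1mm", "2%/1mm", "1%/1mm"]
        assert all(c.low_dose_threshold_pct == 10.0 for c in PAPER_CRITERIA)
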