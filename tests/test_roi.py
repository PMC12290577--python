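"""Lesion mask rules: size filter, partial-volume downsampling, vessel
exclusion, control-region normalization, ROI bookkeeping."""

import math

import numpy as np
import pytest

from cthperf.deconv import ConfigurationError, PerfusionMaps
from cthperf.roi import (
    HighResMask,
    build_normal_appearing_masks,
    downsample_mask_to_dsc,
    exclude_high_cbv,
    filter_lesions_by_size,
    normalize_to_control,
    summarize_roi,
)


def _mask(data, voxel_mm=(1.0, 1.0, 1.0), label="ms_t2flair"):
    return HighResMask(data=np.asarray(data, dtype=bool), voxel_mm=voxel_mm, label=label)


def _blank(shape=(9, 9, 4)):
    return np.zeros(shape, dtype=bool)


class TestSizeFilter:
    def test_two_voxel_component_removed(self):
        data = _blank()
        data[4, 4, 1] = data[5, 4, 1] = True
        out = filter_lesions_by_size(_mask(data))
        assert not out.data.any()

    def test_inline_component_single_slice_removed(self):
        # 3 voxels spanning 3 mm in-plane but only one slice
        data = _blank()
        data[3:6, 4, 1] = True
        out = filter_lesions_by_size(_mask(data))
        assert not out.data.any()

    def test_component_with_two_contiguous_qualifying_slices_kept(self):
        data = _blank()
        data[3:6, 4, 1] = True
        data[3:6, 4, 2] = True
        out = filter_lesions_by_size(_mask(data))
        assert out.data.sum() == 6

    def test_qualifying_slices_must_be_contiguous(self):
        data = _blank()
        data[3:6, 4, 0] = True
        data[4, 4, 1] = True  # bridge voxel, under 3 mm in-plane
        data[3:6, 4, 2] = True
        out = filter_lesions_by_size(_mask(data))
        assert not out.data.any()

    def test_extent_uses_voxel_size(self):
        # 3 voxels at 0.5 mm span 1.5 mm: fails the 3 mm cross-section
        data = _blank()
        data[3:6, 4, 1] = True
        data[3:6, 4, 2] = True
        out = filter_lesions_by_size(_mask(data, voxel_mm=(0.5, 0.5, 0.5)))
        assert not out.data.any()

    def test_empty_mask(self):
        out = filter_lesions_by_size(_mask(_blank()))
        assert not out.data.any()

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        data = rng.random((12, 12, 6)) > 0.7
        once = filter_lesions_by_size(_mask(data))
        twice = filter_lesions_by_size(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_lesions_by_size(_mask(_blank()), connectivity=18)


class TestDownsample:
    def test_under_half_omitted(self):
        # 4 of 9 high-res cells (fraction 0.444...) in a single-slice block
        data = np.zeros((3, 3, 1), dtype=bool)
        data[:2, :2, 0] = True
        coarse, frac = downsample_mask_to_dsc(_mask(data), (3, 3, 1))
        assert frac[0, 0, 0] == pytest.approx(4 / 9)
        assert not coarse[0, 0, 0]

    def test_exactly_half_retained(self):
        data = np.zeros((2, 2, 2), dtype=bool)
        data[:, :, 0] = True  # fraction exactly 0.5
        coarse, frac = downsample_mask_to_dsc(_mask(data), (2, 2, 2))
        assert frac[0, 0, 0] == 0.5
        assert coarse[0, 0, 0]

    def test_full_coverage_retained(self):
        data = np.ones((3, 3, 3), dtype=bool)
        coarse, _ = downsample_mask_to_dsc(_mask(data), (3, 3, 3))
        assert coarse.all()

    def test_threshold_is_a_step_at_half(self):
        """Retention as a function of injected lesion fraction steps at 0.5."""
        r = 3
        for n_cells in range(r**3 + 1):
            data = np.zeros((r, r, r), dtype=bool)
            data.ravel()[:n_cells] = True
            coarse, frac = downsample_mask_to_dsc(_mask(data), (r, r, r))
            assert frac[0, 0, 0] == pytest.approx(n_cells / r**3)
            assert bool(coarse[0, 0, 0]) == (n_cells / r**3 >= 0.5)

    def test_non_nesting_grid_rejected(self):
        data = np.zeros((7, 9, 3), dtype=bool)
        with pytest.raises(ConfigurationError):
            downsample_mask_to_dsc(_mask(data), (3, 3, 3))


class TestVesselExclusion:
    def test_exact_count_with_distinct_values(self):
        rng = np.random.default_rng(0)
        cbv = rng.permutation(10_000).astype(float).reshape(100, 100, 1)
        excl = exclude_high_cbv(cbv, np.ones_like(cbv, dtype=bool), 0.08)
        assert excl.sum() == 800
        # excluded voxels are exactly the 800 largest
        assert cbv[excl].min() > cbv[~excl].max()

    def test_constant_map_tie_break(self):
        cbv = np.ones((10, 10, 1))
        excl = exclude_high_cbv(cbv, np.ones_like(cbv, dtype=bool), 0.08)
        assert excl.sum() == math.ceil(0.08 * 100)
        # deterministic: lexicographically first voxels go
        assert excl.ravel()[: excl.sum()].all()

    def test_respects_valid_mask(self):
        cbv = np.arange(100, dtype=float).reshape(10, 10, 1)
        valid = cbv >= 50
        excl = exclude_high_cbv(cbv, valid, 0.10)
        assert excl.sum() == 5
        assert not excl[~valid].any()

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.3])
    def test_fraction_domain(self, fraction):
        with pytest.raises(ValueError):
            exclude_high_cbv(np.ones((2, 2, 1)), np.ones((2, 2, 1), bool), fraction)

    def test_empty_valid_set(self):
        excl = exclude_high_cbv(np.ones((2, 2, 1)), np.zeros((2, 2, 1), bool), 0.08)
        assert not excl.any()


def _uniform_maps(shape=(4, 4, 1), cbf=2.0, mtt=1.6, cth=1.4):
    ones = np.ones(shape)
    return PerfusionMaps(
        cbf=cbf * ones, cbv=cbf * mtt * ones, mtt=mtt * ones, cth=cth * ones,
        rth=(cth / mtt) * ones, valid=np.ones(shape, dtype=bool),
        alpha=(mtt / cth) ** 2 * ones, beta=(cth**2 / mtt) * ones,
        k_leak=0 * ones, delay=0 * ones, rss=0 * ones,
    )


class TestNormalization:
    def test_control_mean_becomes_unity(self):
        maps = _uniform_maps()
        maps.cbf[0, 0, 0] = 4.0  # make the volume inhomogeneous
        control = np.zeros(maps.shape, dtype=bool)
        control[2:, 2:, :] = True
        out = normalize_to_control(maps, control)
        assert np.mean(out.rcbf[control]) == pytest.approx(1.0)
        assert np.mean(out.rcbv[control]) == pytest.approx(1.0)

    def test_absolute_maps_untouched(self):
        maps = _uniform_maps()
        before = maps.mtt.copy()
        out = normalize_to_control(maps, np.ones(maps.shape, dtype=bool))
        np.testing.assert_array_equal(out.mtt, before)

    def test_empty_control_rejected(self):
        with pytest.raises(ConfigurationError):
            normalize_to_control(_uniform_maps(), np.zeros((4, 4, 1), dtype=bool))

    def test_zero_mean_rejected(self):
        maps = _uniform_maps(cbf=0.0)
        with pytest.raises(ConfigurationError):
            normalize_to_control(maps, np.ones(maps.shape, dtype=bool))


class TestRoiSummary:
    def test_single_voxel_roi(self):
        maps = _uniform_maps()
        maps.rcbf = maps.cbf / 2.0
        maps.rcbv = maps.cbv / (2.0 * 1.6)
        roi = np.zeros(maps.shape, dtype=bool)
        roi[1, 1, 0] = True
        s = summarize_roi(maps, roi, subject="s1", label="ms_t2flair")
        assert s.n_voxels_used == 1
        assert s.means["mtt_s"] == pytest.approx(1.6)
        assert s.means["rth"] == pytest.approx(1.4 / 1.6)

    def test_rth_is_mean_of_ratios(self):
        """Two voxels (cth, mtt) = (1, 1) and (1, 4): mean RTH must be
        (1 + 0.25) / 2 = 0.625, not mean(cth)/mean(mtt) = 0.4."""
        shape = (2, 1, 1)
        mtt = np.array([1.0, 4.0]).reshape(shape)
        cth = np.ones(shape)
        maps = PerfusionMaps(
            cbf=np.ones(shape), cbv=mtt.copy(), mtt=mtt, cth=cth, rth=cth / mtt,
            valid=np.ones(shape, dtype=bool), alpha=(mtt / cth) ** 2,
            beta=cth**2 / mtt, k_leak=np.zeros(shape), delay=np.zeros(shape),
            rss=np.zeros(shape),
        )
        s = summarize_roi(maps, np.ones(shape, dtype=bool))
        assert s.means["rth"] == pytest.approx(0.625)
        assert s.means["cth_s"] / s.means["mtt_s"] == pytest.approx(0.4)

    def test_fully_vessel_excluded_roi_is_missing(self):
        maps = _uniform_maps()
        roi = np.ones(maps.shape, dtype=bool)
        s = summarize_roi(maps, roi, vessel_excluded=roi.copy())
        assert s.missing
        assert s.n_voxels_used == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        maps = _uniform_maps((6, 6, 2))
        maps.valid = rng.random(maps.shape) > 0.2
        roi = rng.random(maps.shape) > 0.4
        vessel = rng.random(maps.shape) > 0.7
        retained = rng.random(maps.shape) > 0.3
        s = summarize_roi(maps, roi, vessel_excluded=vessel, pve_retained=retained)
        assert (
            s.n_voxels_total
            == s.n_voxels_used + s.n_invalid + s.n_excluded_pve + s.n_excluded_vessel
        )

    def test_wrong_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize_roi(_uniform_maps(), np.ones((2, 2, 1), dtype=bool))


class TestNormalAppearingMasks:
    def test_no_lesions_keeps_whole_compartment(self):
        wm = np.ones((4, 4, 2), dtype=bool)
        gm = ~wm
        out = build_normal_appearing_masks(wm, gm, [])
        np.testing.assert_array_equal(out["nawm"], wm)

    def test_lesion_covering_all_wm_empties_nawm(self):
        wm = np.ones((4, 4, 2), dtype=bool)
        out = build_normal_appearing_masks(wm, ~wm, [wm.copy()])
        assert not out["nawm"].any()

    def test_auto_wml_also_excludes(self):
        wm = np.ones((4, 4, 2), dtype=bool)
        auto = np.zeros_like(wm)
        auto[0, 0, 0] = True
        out = build_normal_appearing_masks(wm, ~wm, [], auto_wml=auto)
        assert not out["nawm"][0, 0, 0]
        assert out["nawm"].sum() == wm.sum() - 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            build_normal_appearing_masks(
                np.ones((4, 4, 2), bool), np.ones((4, 4, 2), bool),
                [np.ones((2, 2, 2), bool)],
            )
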