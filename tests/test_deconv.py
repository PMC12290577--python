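"""Signal conversion, leakage-augmented forward model, per-voxel fitting."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from cthperf.deconv import (
    AcquisitionParams,
    Aif,
    ConfigurationError,
    FitConfig,
    concentration_to_signal,
    fit_voxel,
    fit_volume,
    signal_to_concentration,
    tissue_forward_model,
)
from cthperf.transit import TransitTimeDistribution, residue_function, transit_summary


class TestSignalConversion:
    def test_baseline_signal_maps_to_zero(self, acq):
        s = np.full(20, 123.4)
        c = signal_to_concentration(s, acq)
        assert np.allclose(c, 0.0, atol=1e-12)

    def test_single_frame_closed_form(self, acq):
        s = np.full(20, 50.0)
        s[10] = 50.0 * np.exp(-acq.te)  # concentration exactly 1 there
        c = signal_to_concentration(s, acq)
        assert c[10] == pytest.approx(1.0, rel=1e-12)

    def test_round_trip(self, acq):
        rng = np.random.default_rng(0)
        conc = np.abs(rng.normal(0, 5, 40))
        conc[: acq.baseline[1]] = 0.0
        sig = concentration_to_signal(conc, 77.0, acq)
        back = signal_to_concentration(sig, acq)
        assert np.allclose(back, conc, atol=1e-10)

    def test_nonpositive_signal_flags_voxel(self, acq):
        s = np.full(20, 80.0)
        s[7] = -1.0
        c = signal_to_concentration(s, acq)
        assert np.all(np.isnan(c))

    def test_monotone_concentration_to_signal(self, acq):
        s_low = concentration_to_signal(np.array([1.0]), 100.0, acq)
        s_high = concentration_to_signal(np.array([5.0]), 100.0, acq)
        assert s_high < s_low

    def test_empty_baseline_rejected(self):
        with pytest.raises(ConfigurationError):
            AcquisitionParams(te=0.03, dt=1.0, baseline=(3, 3))

    def test_works_on_volumes(self, acq):
        vol = np.full((2, 2, 1, 20), 90.0)
        c = signal_to_concentration(vol, acq)
        assert c.shape == vol.shape
        assert np.allclose(c, 0.0)


class TestForwardModel:
    def test_zero_flow_zero_output(self, aif):
        d = TransitTimeDistribution(4.0, 0.5)
        ct = tissue_forward_model(0.0, d, 0.0, 0.0, aif)
        assert np.allclose(ct, 0.0)

    def test_narrow_bolus_approximates_residue(self, acq):
        """With a near-impulse AIF the tissue curve approaches cbf * R(t)."""
        dt = 0.05
        t = np.arange(0, 2400) * dt
        # unit-area triangular pulse at the origin, much narrower than R
        ca = np.zeros_like(t)
        ca[0] = 1.0 / dt
        ca[1] = 1.0 / dt
        area = np.trapezoid(ca, dx=dt)
        aif = Aif(times=t, conc=ca / area)
        d = TransitTimeDistribution(4.0, 0.5)
        ct = tissue_forward_model(2.0, d, 0.0, 0.0, aif)
        want = 2.0 * residue_function(t, d)
        sl = slice(5, 400)
        assert np.max(np.abs(ct[sl] - want[sl])) < 0.05  # discretization level

    def test_central_volume_area_identity(self):
        """Integral of Ct equals cbf * mtt * integral of Ca (trapezoid oracle
        on a 1200-frame extended grid)."""
        dt = 0.25
        t = np.arange(1200) * dt
        u = np.clip(t - 10, 0, None)
        ca = u**2 * np.exp(-u / 1.5)
        aif = Aif(times=t, conc=ca)
        d = TransitTimeDistribution.from_moments(2.0, 1.0)
        ct = tissue_forward_model(1.3, d, 0.0, 0.0, aif, extend_factor=3)
        lhs = np.trapezoid(ct, dx=dt)
        rhs = 1.3 * 2.0 * np.trapezoid(ca, dx=dt)
        assert lhs == pytest.approx(rhs, rel=1e-4)

    def test_delay_shifts_onset(self, aif):
        d = TransitTimeDistribution(4.0, 0.5)
        delay = 5 * aif.dt  # exactly five frames
        ct0 = tissue_forward_model(1.0, d, 0.0, 0.0, aif)
        ct5 = tissue_forward_model(1.0, d, 0.0, delay, aif)
        assert np.allclose(ct5[5:], ct0[: ct0.size - 5], atol=1e-8)

    def test_leakage_accumulates_in_tail(self, aif):
        d = TransitTimeDistribution(4.0, 0.5)
        tight = tissue_forward_model(1.0, d, 0.0, 0.0, aif)
        leaky = tissue_forward_model(1.0, d, 0.01, 0.0, aif)
        extra = leaky - tight
        cum = cumulative_trapezoid(aif.conc, dx=aif.dt, initial=0.0)
        assert np.allclose(extra, 0.01 * cum, rtol=1e-6, atol=1e-9)
        # intravascular curve returns toward zero; leaky tail does not
        assert tight[-1] < 0.05 * tight.max()
        assert leaky[-1] > 0.01 * cum[-1] * 0.99

    def test_grid_mismatch_rejected(self, aif, acq):
        with pytest.raises(ConfigurationError):
            fit_voxel(np.zeros(7), aif, acq)


class TestFitVoxel:
    def test_noiseless_round_trip_within_one_percent(self, aif, acq):
        d = TransitTimeDistribution(4.0, 0.5)
        ct = tissue_forward_model(1.0, d, 0.0, 2.0, aif)
        r = fit_voxel(ct, aif, acq)
        assert r.converged
        s = transit_summary(r.d)
        assert r.cbf == pytest.approx(1.0, rel=0.01)
        assert s.mtt == pytest.approx(2.0, rel=0.01)
        assert s.cth == pytest.approx(1.0, rel=0.01)
        assert r.delay == pytest.approx(2.0, abs=0.05)

    def test_noiseless_leaky_voxel_recovers_leak_and_reduces_cbv_bias(self, aif, acq):
        d = TransitTimeDistribution(4.0, 0.5)
        ct = tissue_forward_model(1.0, d, 0.01, 0.0, aif)
        free = fit_voxel(ct, aif, acq)
        assert free.converged
        assert free.k_leak == pytest.approx(0.01, rel=0.10)
        cbv_free = free.cbf * transit_summary(free.d).mtt

        frozen_cfg = FitConfig(k_leak_bounds=(0.0, 1e-12))
        frozen = fit_voxel(ct, aif, acq, frozen_cfg)
        cbv_frozen = frozen.cbf * transit_summary(frozen.d).mtt
        truth = 2.0
        assert abs(cbv_free - truth) < abs(cbv_frozen - truth)

    def test_all_zero_concentration_not_converged(self, aif, acq):
        r = fit_voxel(np.zeros(aif.times.size), aif, acq)
        assert not r.converged

    def test_nonfinite_concentration_not_converged(self, aif, acq):
        conc = np.zeros(aif.times.size)
        conc[3] = np.nan
        r = fit_voxel(conc, aif, acq)
        assert not r.converged


class TestFitVolume:
    def test_noiseless_slab_recovery(self, aif, acq):
        """4x4x1 noiseless phantom slab: all voxels valid, < 1 % error."""
        d = TransitTimeDistribution(4.0, 0.5)
        ct = tissue_forward_model(1.2, d, 0.0, 2.0, aif)
        conc4d = np.broadcast_to(ct, (4, 4, 1, ct.size)).copy()
        maps = fit_volume(conc4d, aif, acq)
        assert maps.valid.all()
        assert np.allclose(maps.cbf, 1.2, rtol=0.01)
        assert np.allclose(maps.mtt, 2.0, rtol=0.01)
        assert np.allclose(maps.cth, 1.0, rtol=0.01)

    def test_mask_excludes_exactly(self, aif, acq):
        d = TransitTimeDistribution(4.0, 0.5)
        ct = tissue_forward_model(1.0, d, 0.0, 0.0, aif)
        conc4d = np.broadcast_to(ct, (2, 2, 1, ct.size)).copy()
        mask = np.zeros((2, 2, 1), dtype=bool)
        mask[0, :, 0] = True
        maps = fit_volume(conc4d, aif, acq, mask=mask)
        np.testing.assert_array_equal(maps.valid, mask)
        assert np.isnan(maps.cbf[~mask]).all()

    def test_identical_voxels_identical_results(self, aif, acq):
        d = TransitTimeDistribution(2.0, 0.8)
        ct = tissue_forward_model(0.9, d, 0.005, 1.0, aif)
        conc4d = np.broadcast_to(ct, (1, 2, 1, ct.size)).copy()
        maps = fit_volume(conc4d, aif, acq)
        assert maps.cbf[0, 0, 0] == maps.cbf[0, 1, 0]
        assert maps.cth[0, 0, 0] == maps.cth[0, 1, 0]
        assert maps.k_leak[0, 0, 0] == maps.k_leak[0, 1, 0]

    def test_map_identities(self, aif, acq):
        rng = np.random.default_rng(8)
        shapes = [(1.1, 4.0, 0.5), (0.8, 2.0, 1.0), (1.5, 9.0, 0.25)]
        curves = [
            tissue_forward_model(c, TransitTimeDistribution(a, b), 0.0, 1.0, aif)
            for c, a, b in shapes
        ]
        conc4d = np.stack(curves)[:, None, None, :]
        maps = fit_volume(conc4d, aif, acq)
        sel = maps.valid
        np.testing.assert_allclose(maps.cbv[sel], (maps.cbf * maps.mtt)[sel], rtol=1e-12)
        np.testing.assert_allclose(maps.rth[sel], (maps.cth / maps.mtt)[sel], rtol=1e-12)

    def test_shape_mismatch_rejected(self, aif, acq):
        with pytest.raises(ConfigurationError):
            fit_volume(np.zeros((2, 2, 1, 5)), aif, acq)
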