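"""Phase correction, noise estimation and sub-FID filtering."""

import numpy as np
import pytest

from cupidnmr import (
    ExpInfo,
    FID2D,
    Oscillator2D,
    PhaseCorrection,
    Region,
    estimate_noise_variance,
    filter_subfid,
    make_fid2d,
    mpm_1d,
    phase_correct,
    shift_and_decimate,
    truncate_subfid,
)
from cupidnmr.preprocess import auto_phase0, baseline_sigma, decimate_subfid


class TestRegion:
    def test_bounds_ordered_either_way(self):
        assert Region(10.0, -10.0).center == Region(-10.0, 10.0).center == 0.0
        assert Region(10.0, -10.0).bandwidth == 20.0

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError, match="zero width"):
            Region(5.0, 5.0)

    def test_region_outside_sweep_rejected(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        with pytest.raises(ValueError, match="sweep width"):
            filter_subfid(fid, Region(900.0, 700.0))


class TestPhaseCorrect:
    def test_zero_correction_is_identity(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        out = phase_correct(fid, PhaseCorrection(0.0, 0.0, 100.0))
        assert np.allclose(out.data, fid.data, atol=1e-12 * np.abs(fid.data).max())

    def test_on_pivot_zero_order_removes_oscillator_phase(self, small_expinfo):
        osc = Oscillator2D(1.0, 0.3, 0.0, 150.0, 0.0, 2.0)
        fid = make_fid2d([osc], small_expinfo)
        out = phase_correct(fid, PhaseCorrection(0.3, 0.0, 150.0))
        est = mpm_1d(out.first_slice(), 1, small_expinfo.dwell[1])
        assert abs(est[0].phase) < 1e-6

    def test_correction_and_inverse_round_trip(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        pc = PhaseCorrection(0.7, 1.3, 120.0)
        back = phase_correct(phase_correct(fid, pc), pc.inverse())
        assert np.allclose(back.data, fid.data, atol=1e-12 * np.abs(fid.data).max())

    def test_auto_phase0_finds_common_phase(self, small_expinfo):
        osc = [Oscillator2D(1.0, 0.8, 0.0, f2, 0.0, 3.0) for f2 in (-200.0, 50.0, 310.0)]
        fid = make_fid2d(osc, small_expinfo)
        pc = auto_phase0(fid)
        assert pc.p0 == pytest.approx(0.8, abs=0.05)


class TestNoiseVariance:
    def test_zero_grid_gives_zero(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        assert estimate_noise_variance(fid, Region(200.0, 100.0)) == 0.0

    def test_unit_noise_recovered_within_15_percent(self, small_expinfo):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((32, 128)) + 1j * rng.standard_normal((32, 128))
        fid = FID2D(data, small_expinfo)
        var = estimate_noise_variance(fid, Region(400.0, -400.0))
        assert var == pytest.approx(1.0, rel=0.15)

    def test_noiseless_far_region_is_clean(self):
        # well-decayed line: the far region sees only negligible leakage
        info = ExpInfo(points=(8, 512), dwell=(0.02, 0.001))
        fid = make_fid2d([Oscillator2D(1, 0, 0, -300.0, 0, 8.0)], info)
        var = estimate_noise_variance(fid, Region(450.0, 350.0))
        assert var < 1e-6

    def test_empty_region_rejected(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_noise_variance(fid, Region(100.004, 100.001))


class TestFilterSubfid:
    def test_transmission_is_unity_at_center(self):
        from cupidnmr.preprocess import _super_gaussian

        assert _super_gaussian(np.array([10.0]), Region(60.0, -40.0), 40)[0] == 1.0

    def test_in_band_oscillator_amplitude_preserved(self):
        info = ExpInfo(points=(8, 512), dwell=(0.02, 0.001))
        osc = Oscillator2D(1.0, 0.0, 0.0, 100.0, 0.0, 3.0)
        fid = make_fid2d([osc], info)
        sub = filter_subfid(fid, Region(150.0, 50.0), noise_fill=False)
        est = mpm_1d(sub.first_slice(), 1, info.dwell[1])
        assert est[0].amplitude == pytest.approx(1.0, rel=0.005)

    def test_out_of_band_oscillator_suppressed(self):
        # 5 bandwidths from the region centre: the surviving amplitude of the
        # original oscillator (its projection coefficient) is < 1e-4
        info = ExpInfo(points=(8, 512), dwell=(0.02, 0.001))
        osc = Oscillator2D(1.0, 0.0, 0.0, 400.0, 0.0, 3.0)
        fid = make_fid2d([osc], info)
        sub = filter_subfid(fid, Region(-50.0, -150.0), noise_fill=False)
        coef = np.vdot(fid.data, sub.data) / np.vdot(fid.data, fid.data)
        assert abs(coef) < 1e-4

    def test_in_band_parameters_recovered_within_1e3(self):
        # phased data: sub-FID filtering acts on the virtual echo
        info = ExpInfo(points=(8, 512), dwell=(0.02, 0.001))
        truth = [
            Oscillator2D(1.0, 0.0, -3.5, 96.5, 1.0, 3.0),
            Oscillator2D(0.8, 0.0, 3.5, 103.5, 1.0, 3.0),
        ]
        fid = make_fid2d(truth, info)
        sub = filter_subfid(fid, Region(150.0, 50.0), sg_power=40, noise_fill=False)
        est = mpm_1d(sub.first_slice(), 2, info.dwell[1])
        for e, t in zip(est, truth):
            assert e.f2 == pytest.approx(t.f2, abs=1e-3 * abs(t.f2))
            assert e.amplitude == pytest.approx(t.amplitude, rel=1e-3)

    def test_partition_of_spectrum_conserves_energy(self, small_expinfo):
        osc = [
            Oscillator2D(1.0, 0.0, 0.0, -250.0, 0.5, 3.0),
            Oscillator2D(1.0, 0.0, 0.0, 250.0, 0.5, 3.0),
        ]
        fid = make_fid2d(osc, small_expinfo)
        left = filter_subfid(fid, Region(0.0, -499.0), noise_fill=False)
        right = filter_subfid(fid, Region(499.0, 0.0), noise_fill=False)
        recon = left.data + right.data
        rel = np.linalg.norm(recon - fid.data) / np.linalg.norm(fid.data)
        assert rel < 0.01

    def test_noise_fill_matches_baseline_level(self, small_expinfo):
        rng = np.random.default_rng(5)
        sigma = 0.3
        data = sigma * (rng.standard_normal((32, 128)) + 1j * rng.standard_normal((32, 128)))
        fid = FID2D(data, small_expinfo)
        sub = filter_subfid(fid, Region(100.0, -100.0), noise_fill=True, seed=9)
        var = np.mean(sub.data.real**2 + sub.data.imag**2) / 2
        assert var == pytest.approx(sigma**2, rel=0.35)


class TestReduction:
    def test_truncate_keeps_prefix(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        tr = truncate_subfid(fid, 64)
        assert tr.expinfo.points == (32, 64)
        assert np.array_equal(tr.data, fid.data[:, :64])

    def test_shift_and_decimate_preserves_in_band_parameters(self, small_expinfo):
        osc = Oscillator2D(1.0, 0.1, 0.0, 105.0, 0.0, 2.0)
        fid = make_fid2d([osc], small_expinfo)
        red, shift = shift_and_decimate(fid, 100.0, 4)
        assert red.expinfo.points == (32, 32)
        assert red.expinfo.dwell[1] == pytest.approx(0.004)
        est = mpm_1d(red.first_slice(), 1, red.expinfo.dwell[1])
        assert est[0].f2 + shift == pytest.approx(105.0, abs=1e-8)

    def test_decimate_subfid_fill_whitens_reduced_band(self, small_expinfo):
        rng = np.random.default_rng(17)
        sigma = 0.4
        data = sigma * (rng.standard_normal((32, 128)) + 1j * rng.standard_normal((32, 128)))
        fid = FID2D(data, small_expinfo)
        region = Region(150.0, 50.0)
        sub = filter_subfid(fid, region, noise_fill=False)
        red, _ = decimate_subfid(sub, region, 4, noise_sigma=sigma, seed=2)
        # matched-density fill: per-sample noise variance ~ sigma^2 / factor
        var = np.mean(red.data.real**2 + red.data.imag**2) / 2
        assert var == pytest.approx(sigma**2 / 4, rel=0.4)

    def test_baseline_sigma_estimates_noise(self, small_expinfo):
        rng = np.random.default_rng(23)
        sigma = 0.7
        data = sigma * (rng.standard_normal((32, 128)) + 1j * rng.standard_normal((32, 128)))
        fid = FID2D(data, small_expinfo)
        est = baseline_sigma(fid, Region(100.0, 50.0))
        assert est == pytest.approx(sigma, rel=0.3)
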