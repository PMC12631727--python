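"""Matrix-pencil estimators: 1D pencil and 2D MMEMPM."""

import numpy as np
import pytest

from cupidnmr import ExpInfo, FID2D, Oscillator2D, make_fid2d, mmempm, mpm_1d
from cupidnmr.pencil import PoleSet

from .conftest import max_relative_error, random_separated_oscillators


class TestMpm1d:
    def test_noiseless_single_oscillator_exact(self):
        info = ExpInfo(points=(2, 128), dwell=(1.0, 0.001))
        truth = Oscillator2D(1.0, 0.5, 0.0, 37.0, 0.0, 3.0)
        y = make_fid2d([truth], info).first_slice()
        est = mpm_1d(y, 1, 0.001)
        assert est[0].amplitude == pytest.approx(1.0, rel=1e-8)
        assert est[0].phase == pytest.approx(0.5, abs=1e-8)
        assert est[0].f2 == pytest.approx(37.0, abs=1e-6)
        assert est[0].eta2 == pytest.approx(3.0, rel=1e-6)

    def test_three_well_separated_oscillators(self):
        info = ExpInfo(points=(2, 128), dwell=(1.0, 0.001))
        truth = [
            Oscillator2D(1.0, 0.3, 0.0, -200.0, 0.0, 2.0),
            Oscillator2D(0.5, -1.0, 0.0, 40.0, 0.0, 4.0),
            Oscillator2D(2.0, 2.0, 0.0, 310.0, 0.0, 1.0),
        ]
        y = make_fid2d(truth, info).first_slice()
        est = mpm_1d(y, 3, 0.001)
        assert max_relative_error(est, truth) < 1e-6

    def test_overfit_yields_negligible_spurious_amplitude(self):
        info = ExpInfo(points=(2, 128), dwell=(1.0, 0.001))
        y = make_fid2d([Oscillator2D(1.0, 0.0, 0.0, 50.0, 0.0, 2.0)], info).first_slice()
        est = mpm_1d(y, 2, 0.001)
        amps = sorted(o.amplitude for o in est)
        assert amps[1] == pytest.approx(1.0, rel=1e-6)
        assert amps[0] < 1e-6 * amps[1]

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            mpm_1d(np.ones(3, dtype=complex), 1, 0.001)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            mpm_1d(np.zeros(64, dtype=complex), 1, 0.001)


class TestPoleSet:
    def test_growing_poles_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            ps = PoleSet([1.5 + 0j], [0.5 + 0j], [1.0 + 0j])
        assert abs(ps.poles1[0]) == pytest.approx(1.0)
        info = ExpInfo(points=(4, 4), dwell=(0.01, 0.001))
        assert ps.to_oscillators(info)[0].eta1 == 0.0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            PoleSet([1.0 + 0j], [1.0 + 0j, 0.5 + 0j], [1.0 + 0j])


class TestMmempm:
    def test_noiseless_two_oscillator_grid_exact(self, small_expinfo):
        truth = [
            Oscillator2D(1.0, 0.2, -3.5, 196.5, 1.0, 3.0),
            Oscillator2D(0.7, -0.3, 3.5, 203.5, 1.5, 2.0),
        ]
        est = mmempm(make_fid2d(truth, small_expinfo), 2)
        assert max_relative_error(est, truth) < 1e-6

    def test_first_order_doublet_poles_come_out_paired(self, small_expinfo):
        fc = 200.0
        truth = [
            Oscillator2D(1.0, 0.0, -3.5, fc - 3.5, 1.0, 3.0),
            Oscillator2D(1.0, 0.0, 3.5, fc + 3.5, 1.0, 3.0),
        ]
        est = mmempm(make_fid2d(truth, small_expinfo), 2)
        for o in est:
            assert o.f2 - o.f1 == pytest.approx(fc, abs=1e-6)

    def test_duplicate_indirect_poles_resolved(self, small_expinfo):
        # two lines sharing f1 and eta1 exactly: pairing must still be correct
        truth = sorted(
            [
                Oscillator2D(1.0, 0.0, 3.5, 103.5, 1.0, 3.0),
                Oscillator2D(0.8, 0.0, 3.5, 303.5, 1.0, 2.0),
            ],
            key=lambda o: (o.f2, o.f1),
        )
        est = mmempm(make_fid2d(truth, small_expinfo), 2)
        assert max_relative_error(est, truth) < 1e-6

    def test_zero_grid_rejected(self, small_expinfo):
        with pytest.raises(ValueError, match="rank"):
            mmempm(make_fid2d([], small_expinfo), 1)

    def test_order_beyond_rank_bound_rejected(self, small_expinfo):
        fid = make_fid2d([Oscillator2D(1, 0, 0, 0, 0, 0)], small_expinfo)
        with pytest.raises(ValueError, match="rank bound|exceeds"):
            mmempm(fid, 10_000)

    def test_noiseless_random_draws_recovered(self, small_expinfo):
        # spot-check of the exact-recovery property (full sweep in acceptance)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truth = random_separated_oscillators(rng, small_expinfo, m_max=5)
            est = mmempm(make_fid2d(truth, small_expinfo), len(truth))
            assert max_relative_error(est, truth) < 1e-6, f"seed {seed}"

    def test_equivariance_under_direct_frequency_shift(self, small_expinfo):
        rng = np.random.default_rng(41)
        truth = random_separated_oscillators(rng, small_expinfo, m_max=3)
        delta = 37.0
        shifted = [
            Oscillator2D(o.amplitude, o.phase, o.f1, o.f2 + delta, o.eta1, o.eta2)
            for o in truth
        ]
        est0 = mmempm(make_fid2d(truth, small_expinfo), len(truth))
        est1 = mmempm(make_fid2d(shifted, small_expinfo), len(truth))
        for a, b in zip(est0, est1):
            assert b.f2 - a.f2 == pytest.approx(delta, abs=1e-6)
            assert b.f1 == pytest.approx(a.f1, abs=1e-6)
            assert b.amplitude == pytest.approx(a.amplitude, rel=1e-6)

    def test_noise_consistency_rmse_shrinks_with_n2(self):
        # frequency RMSE at SNR 20 dB decreases monotonically as N2 doubles
        rmses = []
        for n2 in (64, 128, 256):
            info = ExpInfo(points=(16, n2), dwell=(0.02, 0.001))
            truth = [Oscillator2D(1.0, 0.0, -3.0, 100.0, 1.0, 3.0)]
            clean = make_fid2d(truth, info)
            sigma = np.max(np.abs(clean.data)) / 10 ** (20 / 20)
            errs = []
            for seed in range(100):
                rng = np.random.default_rng(seed)
                noisy = FID2D(
                    clean.data
                    + sigma * (rng.standard_normal(info.points) + 1j * rng.standard_normal(info.points)),
                    info,
                )
                est = mmempm(noisy, 1)
                errs.append(est[0].f2 - 100.0)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] > rmses[1] > rmses[2]
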