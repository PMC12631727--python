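"""Signal-model synthesis: direct evaluation, linearity, -45 degree collapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupidnmr import (
    ExpInfo,
    FID2D,
    Oscillator2D,
    make_cupid_signal,
    make_fid2d,
    subtract_model,
)
from cupidnmr.core import wrap_phase

from .conftest import random_separated_oscillators


class TestOscillator2D:
    def test_negative_amplitude_folds_into_phase(self):
        o = Oscillator2D(-2.0, 0.3, 1.0, 2.0, 0.1, 0.2)
        assert o.amplitude == 2.0
        assert o.phase == pytest.approx(wrap_phase(0.3 + np.pi))

    @given(st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_phase_always_wrapped(self, phi):
        o = Oscillator2D(1.0, phi, 0.0, 0.0, 0.0, 0.0)
        assert -np.pi < o.phase <= np.pi
        # same complex amplitude either way
        assert np.exp(1j * o.phase) == pytest.approx(np.exp(1j * phi), abs=1e-9)

    def test_growing_signal_rejected(self):
        with pytest.raises(ValueError, match="eta"):
            Oscillator2D(1.0, 0.0, 0.0, 0.0, -0.5, 0.0)

    def test_pure_shift_freq(self):
        assert Oscillator2D(1, 0, 5.0, 105.0, 0, 0).pure_shift_freq == 100.0


class TestExpInfo:
    def test_sweep_width_is_reciprocal_dwell(self, small_expinfo):
        assert small_expinfo.sweep_widths == (50.0, 1000.0)

    @pytest.mark.parametrize("points,dwell", [((1, 4), (0.1, 0.1)), ((4, 4), (0.0, 0.1))])
    def test_invalid_geometry_rejected(self, points, dwell):
        with pytest.raises(ValueError):
            ExpInfo(points=points, dwell=dwell)

    def test_fid_shape_must_match(self, small_expinfo):
        with pytest.raises(ValueError, match="shape"):
            FID2D(np.zeros((3, 3)), small_expinfo)


class TestMakeFid2d:
    def test_trivial_oscillator_gives_constant_grid(self, small_expinfo):
        fid = make_fid2d([Oscillator2D(1, 0, 0, 0, 0, 0)], small_expinfo)
        assert np.allclose(fid.data, 1.0)

    def test_first_sample_is_complex_amplitude(self, small_expinfo):
        fid = make_fid2d([Oscillator2D(2, np.pi / 2, 0, 0, 0, 0)], small_expinfo)
        assert fid.data[0, 0] == pytest.approx(2j)

    def test_direct_evaluation_at_second_sample(self, small_expinfo):
        # f2 = 100 Hz, tau2 = 1 ms -> phase advance 0.2 pi per sample
        fid = make_fid2d([Oscillator2D(1, 0, 0, 100, 0, 0)], small_expinfo)
        assert fid.data[0, 1] == pytest.approx(np.exp(1j * 0.2 * np.pi))

    def test_empty_list_gives_zero_grid(self, small_expinfo):
        assert not np.any(make_fid2d([], small_expinfo).data)

    def test_linearity(self, small_expinfo):
        rng = np.random.default_rng(7)
        a = random_separated_oscillators(rng, small_expinfo)
        b = random_separated_oscillators(rng, small_expinfo)
        lhs = make_fid2d(a + b, small_expinfo).data
        rhs = make_fid2d(a, small_expinfo).data + make_fid2d(b, small_expinfo).data
        assert np.allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())

    def test_conjugate_symmetry(self, small_expinfo):
        rng = np.random.default_rng(8)
        osc = random_separated_oscillators(rng, small_expinfo)
        neg = [
            Oscillator2D(o.amplitude, -o.phase, -o.f1, -o.f2, o.eta1, o.eta2) for o in osc
        ]
        assert np.allclose(
            make_fid2d(neg, small_expinfo).data,
            np.conj(make_fid2d(osc, small_expinfo).data),
        )


class TestCupidSignal:
    def test_single_oscillator_frequency_difference(self, small_expinfo):
        y = make_cupid_signal([Oscillator2D(1, 0, 5, 105, 2.0, 1.5)], small_expinfo)
        t = np.arange(128) * 0.001
        assert np.allclose(y, np.exp((2j * np.pi * 100 - 1.5) * t))

    def test_first_order_doublet_collapses(self, small_expinfo):
        fc = 100.0
        doublet = [
            Oscillator2D(1, 0, -3.5, fc - 3.5, 1.0, 2.0),
            Oscillator2D(1, 0, 3.5, fc + 3.5, 1.0, 2.0),
        ]
        collapsed = make_cupid_signal([Oscillator2D(2, 0, 0, fc, 0, 2.0)], small_expinfo)
        assert np.allclose(make_cupid_signal(doublet, small_expinfo), collapsed)

    def test_modulus_decays_with_eta2(self, small_expinfo):
        y = make_cupid_signal([Oscillator2D(3, 0.4, 7, 50, 5.0, 2.0)], small_expinfo)
        t = np.arange(128) * 0.001
        assert np.allclose(np.abs(y), 3 * np.exp(-2.0 * t))


class TestSubtractModel:
    def test_exact_cancellation(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        res = subtract_model(fid, three_oscillators)
        assert np.max(np.abs(res.data)) < 1e-10 * np.max(np.abs(fid.data))

    def test_empty_model_leaves_data_unchanged(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        assert np.array_equal(subtract_model(fid, []).data, fid.data)

    def test_residual_variance_matches_noise(self):
        # 128 x 128 grid = 16384 samples: residual variance within 10% of sigma^2
        info = ExpInfo(points=(128, 128), dwell=(0.02, 0.001))
        osc = [Oscillator2D(1.0, 0.0, -3.0, 100.0, 1.0, 2.0)]
        sigma = 0.5
        rng = np.random.default_rng(21)
        noise = sigma * (rng.standard_normal((128, 128)) + 1j * rng.standard_normal((128, 128)))
        fid = FID2D(make_fid2d(osc, info).data + noise, info)
        res = subtract_model(fid, osc)
        var = np.mean(res.data.real**2 + res.data.imag**2) / 2
        assert var == pytest.approx(sigma**2, rel=0.10)
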