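"""Spectrum construction: pure shift, multiplet, first-slice, residual, tilt."""

import numpy as np
import pytest

from cupidnmr import (
    ExpInfo,
    FID2D,
    Oscillator2D,
    first_slice_spectrum,
    group_multiplets,
    magnitude_tilt_projection,
    make_fid2d,
    multiplet_spectra,
    pure_shift_spectrum,
    residual_slice,
)


def fwhm(spec):
    y = spec.intensity
    half = y.max() / 2
    above = np.flatnonzero(y >= half)
    return abs(spec.axis_hz[above[-1]] - spec.axis_hz[above[0]])


class TestPureShiftSpectrum:
    def test_constant_signal_peak_height(self, small_expinfo):
        # FT of a constant with first-point halving: max = N2 - 1/2 at 0 Hz
        spec = pure_shift_spectrum([Oscillator2D(1, 0, 0, 0, 0, 0)], small_expinfo, zf=1)
        n2 = small_expinfo.points[1]
        assert spec.intensity.max() == pytest.approx(n2 - 0.5)
        assert spec.peak_position() == pytest.approx(0.0, abs=spec.resolution)

    def test_doublet_collapses_with_integral_conserved(self, small_expinfo):
        doublet = [
            Oscillator2D(1.0, 0.0, -3.5, 96.5, 1.0, 2.0),
            Oscillator2D(1.0, 0.0, 3.5, 103.5, 1.0, 2.0),
        ]
        spec = pure_shift_spectrum(doublet, small_expinfo, zf=4)
        assert spec.peak_position() == pytest.approx(100.0, abs=spec.resolution)
        # integral equals that of the pulse-acquire doublet built from the
        # same amplitudes (collapse conserves quantitation)
        pa = [
            Oscillator2D(1.0, 0.0, 0.0, 96.5, 0.0, 2.0),
            Oscillator2D(1.0, 0.0, 0.0, 103.5, 0.0, 2.0),
        ]
        ref = pure_shift_spectrum(pa, small_expinfo, zf=4)
        assert spec.integral() == pytest.approx(ref.integral(), rel=0.005)

    def test_quadrature_phase_gives_dispersion_lineshape(self, small_expinfo):
        spec = pure_shift_spectrum(
            [Oscillator2D(1.0, np.pi / 2, 0.0, 0.0, 0.0, 3.0)], small_expinfo, zf=2
        )
        # antisymmetric about the peak: equal positive and negative extremes
        assert spec.intensity.max() == pytest.approx(-spec.intensity.min(), rel=0.05)

    def test_linearity_over_multiplets(self, small_expinfo, three_oscillators):
        full = pure_shift_spectrum(three_oscillators, small_expinfo)
        parts = [pure_shift_spectrum([o], small_expinfo) for o in three_oscillators]
        assert np.allclose(full.intensity, sum(p.intensity for p in parts))

    def test_axis_is_high_to_low(self, small_expinfo):
        spec = pure_shift_spectrum([], small_expinfo)
        assert np.all(np.diff(spec.axis_hz) < 0)


class TestMultipletSpectra:
    def test_single_group_equals_full_direct_model(self, small_expinfo, three_oscillators):
        groups = group_multiplets(three_oscillators, 1000.0)
        assert len(groups) == 1
        (spec,) = multiplet_spectra(three_oscillators, groups, small_expinfo)
        direct = [
            Oscillator2D(o.amplitude, o.phase, 0.0, o.f2, 0.0, o.eta2)
            for o in three_oscillators
        ]
        from cupidnmr import make_cupid_signal

        ref = pure_shift_spectrum(
            [Oscillator2D(o.amplitude, o.phase, 0.0, o.f2, 0.0, o.eta2) for o in direct],
            small_expinfo,
        )
        assert np.allclose(spec.intensity, ref.intensity)

    def test_doublet_peak_separation_reads_coupling(self):
        info = ExpInfo(points=(8, 1024), dwell=(0.02, 0.001))
        j = 7.0
        doublet = [
            Oscillator2D(1.0, 0.0, -j / 2, 100 - j / 2, 1.0, 1.5),
            Oscillator2D(1.0, 0.0, j / 2, 100 + j / 2, 1.0, 1.5),
        ]
        groups = group_multiplets(doublet, 1.0)
        (spec,) = multiplet_spectra(doublet, groups, info, zf=4)
        order = np.argsort(spec.intensity)[::-1]
        # two tallest well-separated maxima
        peaks = []
        for i in order:
            f = spec.axis_hz[i]
            if all(abs(f - p) > 3 for p in peaks):
                peaks.append(f)
            if len(peaks) == 2:
                break
        assert abs(peaks[0] - peaks[1]) == pytest.approx(j, abs=2 * spec.resolution)

    def test_empty_groups_give_empty_list(self, small_expinfo):
        assert multiplet_spectra([], [], small_expinfo) == []


class TestFirstSliceAndResidual:
    def test_peaks_at_direct_frequencies(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        spec = first_slice_spectrum(fid, zf=4)
        for o in three_oscillators:
            pos = spec.peak_position(near=o.f2, window=5.0)
            assert pos == pytest.approx(o.f2, abs=spec.resolution)

    def test_processing_record_keeps_line_broadening(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        spec = first_slice_spectrum(fid, lb=0.29)
        assert spec.processing["lb_hz"] == 0.29

    def test_zero_input_gives_zero_spectrum(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        assert not np.any(first_slice_spectrum(fid).intensity)

    def test_residual_flat_for_exact_model(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        res = residual_slice(fid, three_oscillators)
        full = first_slice_spectrum(fid)
        assert np.max(np.abs(res.intensity)) < 1e-9 * np.max(np.abs(full.intensity))

    def test_residual_with_no_model_is_first_slice(self, small_expinfo, three_oscillators):
        fid = make_fid2d(three_oscillators, small_expinfo)
        res = residual_slice(fid, [])
        ref = first_slice_spectrum(fid)
        assert np.allclose(res.intensity, ref.intensity)

    def test_residual_consistent_with_noise_floor(self, small_expinfo, three_oscillators):
        sigma = 0.05
        rng = np.random.default_rng(31)
        clean = make_fid2d(three_oscillators, small_expinfo)
        noisy = FID2D(
            clean.data
            + sigma
            * (rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)),
            small_expinfo,
        )
        res = residual_slice(noisy, three_oscillators, zf=1)
        n2 = small_expinfo.points[1]
        spec_sigma = sigma * np.sqrt(n2)  # per-bin noise std of the FT
        # no peak above 5 sigma at any model frequency
        for o in three_oscillators:
            idx = np.argmin(np.abs(res.axis_hz - o.f2))
            assert abs(res.intensity[idx]) < 5 * spec_sigma


class TestTiltProjection:
    def test_zero_grid_projects_to_zero(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        assert not np.any(magnitude_tilt_projection(fid).intensity)

    def test_doublet_collapses_after_tilt(self):
        info = ExpInfo(points=(64, 512), dwell=(0.02, 0.001))
        fc = 100.0
        doublet = [
            Oscillator2D(1.0, 0.0, -3.5, fc - 3.5, 0.5, 2.0),
            Oscillator2D(1.0, 0.0, 3.5, fc + 3.5, 0.5, 2.0),
        ]
        fid = make_fid2d(doublet, info)
        proj = magnitude_tilt_projection(fid)
        pos = proj.peak_position(near=fc, window=30.0)
        assert pos == pytest.approx(fc, abs=2 * proj.resolution)
        # single collapsed peak: no second maximum above 60% within the multiplet span
        window = (np.abs(proj.axis_hz - fc) < 15) & (np.abs(proj.axis_hz - pos) > 5)
        assert proj.intensity[window].max() < 0.6 * proj.intensity.max()

    def test_magnitude_peak_broader_than_parametric_peak(self):
        info = ExpInfo(points=(64, 512), dwell=(0.02, 0.001))
        singlet = [Oscillator2D(1.0, 0.0, 0.0, 100.0, 0.5, 2.0)]
        fid = make_fid2d(singlet, info)
        proj = magnitude_tilt_projection(fid, zf=2)
        cupid = pure_shift_spectrum(singlet, info, zf=2)
        assert fwhm(proj) > fwhm(cupid)

    def test_unknown_projection_mode_rejected(self, small_expinfo):
        fid = make_fid2d([], small_expinfo)
        with pytest.raises(ValueError, match="projection"):
            magnitude_tilt_projection(fid, projection="median")
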