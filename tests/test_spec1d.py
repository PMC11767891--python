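import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmlab import spec1d, synthetic
from nmlab.core import AcqPars, Fid
from nmlab.errors import InputError, ReferencingError
from nmlab.spec1d import SplineBaselineSpec


def simple_acq(n=2048, sw=1000.0, sf=100.0, carrier=0.0, gd=0.0):
    return AcqPars(spectral_width_hz=sw, spectrometer_freq_mhz=sf,
                   n_points_td=n, carrier_offset_hz=carrier, group_delay=gd)


def fwhm_hz(spec):
    """Half-maximum width of the tallest line, linear interpolation."""
    r = spec.points.real
    i = int(np.argmax(r))
    half = r[i] / 2
    lo = i
    while r[lo] > half:
        lo -= 1
    hi = i
    while r[hi] > half:
        hi += 1
    # linear interpolation on both sides
    fl = lo + (half - r[lo]) / (r[lo + 1] - r[lo])
    fr = hi - (half - r[hi]) / (r[hi - 1] - r[hi])
    dppm = spec.ppm_spacing * (fr - fl)
    return dppm * spec.acq.spectrometer_freq_mhz


class TestApodize:
    def test_lb_zero_identity(self):
        fid = Fid(points=np.ones(64, complex), acq=simple_acq(64))
        out = spec1d.apodize_exponential(fid, 0.0)
        np.testing.assert_array_equal(out.points, fid.points)

    def test_closed_form_decay(self):
        # dwell = 1 ms, lb = 0.3 Hz, k = 1000 -> exp(-pi*0.3*1.0)
        fid = Fid(points=np.ones(1500, complex), acq=simple_acq(1500, sw=1000.0))
        out = spec1d.apodize_exponential(fid, 0.3)
        assert abs(out.points[0]) == 1.0
        assert np.isclose(abs(out.points[1000]), np.exp(-np.pi * 0.3 * 1.0), rtol=1e-12)

    def test_linewidth_increases_by_lb(self):
        acq = synthetic.default_acq(32768)
        peak = [synthetic.PeakSpec(ppm=5.0, amplitude=1.0, linewidth_hz=2.0)]
        fid = synthetic.gen_fid(peak, acq)
        w0 = fwhm_hz(spec1d.fourier_transform(spec1d.zero_fill(fid, 131072)))
        fid_b = spec1d.apodize_exponential(fid, 0.3)
        w1 = fwhm_hz(spec1d.fourier_transform(spec1d.zero_fill(fid_b, 131072)))
        assert w1 - w0 == pytest.approx(0.3, abs=0.05)

    def test_negative_lb_rejected(self):
        fid = Fid(points=np.ones(64, complex), acq=simple_acq(64))
        with pytest.raises(InputError):
            spec1d.apodize_exponential(fid, -0.1)


class TestZeroFill:
    def test_batch_setting_doubles(self):
        fid = Fid(points=np.ones(65536, complex), acq=simple_acq(65536))
        assert len(spec1d.zero_fill(fid, 131072)) == 131072

    def test_identity_at_current_length(self):
        fid = Fid(points=np.arange(32) + 0j, acq=simple_acq(32))
        out = spec1d.zero_fill(fid, 32)
        np.testing.assert_array_equal(out.points, fid.points)

    def test_absolute_sum_conserved_and_prefix(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        fid = Fid(points=pts, acq=simple_acq(100))
        out = spec1d.zero_fill(fid, 256)
        assert np.abs(out.points).sum() == pytest.approx(np.abs(pts).sum(), rel=1e-12)
        np.testing.assert_array_equal(out.points[:100], pts)
        assert np.all(out.points[100:] == 0)

    def test_shrink_rejected(self):
        fid = Fid(points=np.ones(64, complex), acq=simple_acq(64))
        with pytest.raises(InputError):
            spec1d.zero_fill(fid, 32)


class TestFourierTransform:
    def test_peak_at_500hz_offset(self):
        acq = simple_acq(n=4096, sw=5000.0, sf=100.0, carrier=0.0)
        t = np.arange(4096) / 5000.0
        fid = Fid(points=np.exp((2j * np.pi * 500.0 - 3.0) * t), acq=acq)
        spec = spec1d.fourier_transform(fid)
        peak_ppm = spec.ppm_axis[np.argmax(spec.points.real)]
        assert peak_ppm == pytest.approx(500.0 / 100.0, abs=2 * spec.ppm_spacing)

    def test_parseval(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal(2048) + 1j * rng.standard_normal(2048)
        fid = Fid(points=pts, acq=simple_acq(2048))
        spec = spec1d.fourier_transform(fid)
        e_time = np.sum(np.abs(pts) ** 2)
        e_freq = np.sum(np.abs(spec.points) ** 2) / 2048
        assert e_freq == pytest.approx(e_time, rel=1e-9)

    def test_axis_descending_and_centered(self):
        acq = simple_acq(n=1024, sw=1200.0, sf=100.0, carrier=500.0)
        fid = Fid(points=np.ones(1024, complex), acq=acq)
        spec = spec1d.fourier_transform(fid)
        assert np.all(np.diff(spec.ppm_axis) < 0)
        assert np.mean(spec.ppm_axis) == pytest.approx(5.0, abs=0.01)

    def test_no_phase_ramp_without_group_delay(self):
        acq = synthetic.default_acq(8192)
        peaks = [synthetic.PeakSpec(ppm=p, linewidth_hz=2.0) for p in (1.0, 3.0, 5.0, 7.0, 9.0)]
        spec = spec1d.fourier_transform(synthetic.gen_fid(peaks, acq))
        idx = [spec.index_of_ppm(p) for p in (1.0, 3.0, 5.0, 7.0, 9.0)]
        phases = np.rad2deg(np.angle(spec.points[idx]))
        slope = np.polyfit(idx, phases, 1)[0]
        assert abs(slope) < 0.1  # deg / point

    def test_group_delay_compensation(self):
        # delay the fid through the frequency domain, then let the transform
        # compensate; compare against the undelayed spectrum
        acq0 = synthetic.default_acq(8192)
        fid = synthetic.gen_fid([synthetic.PeakSpec(ppm=4.0, linewidth_hz=2.0)], acq0)
        ref = spec1d.fourier_transform(fid)
        gd = 67.98
        delayed = np.fft.ifft(np.fft.fft(fid.points)
                              * np.exp(-2j * np.pi * np.fft.fftfreq(8192) * gd))
        acq_gd = synthetic.default_acq(8192, group_delay=gd)
        out = spec1d.fourier_transform(Fid(points=delayed, acq=acq_gd))
        np.testing.assert_allclose(out.points, ref.points, atol=1e-6 * np.abs(ref.points).max())


class TestApplyPhase:
    def test_zero_identity(self, mix_spectrum):
        out = spec1d.apply_phase(mix_spectrum, 0.0, 0.0)
        np.testing.assert_array_equal(out.points, mix_spectrum.points)

    def test_half_turn_negates(self, mix_spectrum):
        out = spec1d.apply_phase(mix_spectrum, 180.0, 0.0)
        np.testing.assert_allclose(out.points.real, -mix_spectrum.points.real,
                                   atol=1e-12 * np.abs(mix_spectrum.points.real).max())

    def test_inverse_restores(self, mix_spectrum):
        out = spec1d.apply_phase(spec1d.apply_phase(mix_spectrum, 37.0, -121.0), -37.0, 121.0)
        np.testing.assert_allclose(out.points, mix_spectrum.points,
                                   atol=1e-12 * np.abs(mix_spectrum.points).max())
        assert out.phi0_deg == pytest.approx(0.0, abs=1e-12)
        assert out.phi1_deg == pytest.approx(0.0, abs=1e-12)

    @given(phi0=st.floats(-180, 180), phi1=st.floats(-360, 360),
           psi0=st.floats(-180, 180), psi1=st.floats(-360, 360))
    @settings(max_examples=25, deadline=None)
    def test_group_action(self, phi0, phi1, psi0, psi1):
        rng = np.random.default_rng(11)
        from tests.conftest import make_flat_spectrum
        spec = make_flat_spectrum(np.zeros(128))
        spec.points = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        a = spec1d.apply_phase(spec1d.apply_phase(spec, phi0, phi1), psi0, psi1)
        b = spec1d.apply_phase(spec, phi0 + psi0, phi1 + psi1)
        np.testing.assert_allclose(a.points, b.points, atol=1e-10)
        assert a.phi0_deg == pytest.approx(b.phi0_deg)


class TestReference:
    def test_tmsp_mode(self):
        acq = synthetic.default_acq(8192)
        spec = spec1d.fourier_transform(
            synthetic.gen_fid([synthetic.PeakSpec(ppm=0.05, linewidth_hz=1.0)], acq))
        out = spec1d.reference_spectrum(spec, "tmsp")
        peak_ppm = out.ppm_axis[np.argmax(out.points.real)]
        assert abs(peak_ppm) <= out.ppm_spacing / 2
        np.testing.assert_array_equal(out.points, spec.points)  # data untouched

    def test_manual_anchor_shift(self):
        acq = synthetic.default_acq(8192)
        spec = spec1d.fourier_transform(
            synthetic.gen_fid([synthetic.PeakSpec(ppm=5.25, linewidth_hz=1.0)], acq))
        out = spec1d.reference_spectrum(spec, "manual", anchor_ppm=5.22)
        shift = out.ppm_axis[0] - spec.ppm_axis[0]
        assert shift == pytest.approx(-0.03, abs=spec.ppm_spacing / 2)

    def test_already_referenced_zero_shift(self):
        acq = synthetic.default_acq(8192)
        spec = spec1d.fourier_transform(
            synthetic.gen_fid([synthetic.PeakSpec(ppm=0.0, linewidth_hz=1.0)], acq))
        # peak lands on the grid point closest to 0; shift is below resolution
        out = spec1d.reference_spectrum(spec, "tmsp")
        assert abs(out.ppm_axis[0] - spec.ppm_axis[0]) <= spec.ppm_spacing / 2

    def test_no_positive_maximum(self, flat_spectrum_factory):
        spec = flat_spectrum_factory(-np.ones(256))
        with pytest.raises(ReferencingError):
            spec1d.reference_spectrum(spec, "manual", anchor_ppm=5.0)


class TestWaterSuppression:
    def test_constant_fid_removed(self):
        fid = Fid(points=np.full(512, 2.0 + 1.0j), acq=simple_acq(512))
        out = spec1d.suppress_water_conv(fid, "gauss", 32)
        assert np.max(np.abs(out.points)) < 1e-10 * np.abs(fid.points).max()

    @pytest.mark.parametrize("window", ["gauss", "sine"])
    def test_offcarrier_signal_preserved(self, window):
        acq = simple_acq(n=8192, sw=7200.0)
        t = np.arange(8192) / 7200.0
        carrier_sig = np.ones(8192, complex)
        osc = np.exp(2j * np.pi * 1500.0 * t)
        fid = Fid(points=carrier_sig + osc, acq=acq)
        out = spec1d.suppress_water_conv(fid, window, 32)
        f_in = np.abs(np.fft.fft(fid.points))
        f_out = np.abs(np.fft.fft(out.points))
        k_dc = 0
        k_osc = int(round(1500.0 / 7200.0 * 8192))
        assert f_out[k_dc] < 0.10 * f_in[k_dc]
        assert f_out[k_osc] == pytest.approx(f_in[k_osc], rel=0.05)

    def test_width_one_zeroes_everything(self):
        rng = np.random.default_rng(5)
        fid = Fid(points=rng.standard_normal(128) + 0j, acq=simple_acq(128))
        out = spec1d.suppress_water_conv(fid, "gauss", 1)
        np.testing.assert_allclose(out.points, 0.0, atol=1e-14)

    def test_width_out_of_range(self):
        fid = Fid(points=np.ones(16, complex), acq=simple_acq(16))
        with pytest.raises(InputError):
            spec1d.suppress_water_conv(fid, "gauss", 16)

    def test_poly_orthogonal_unchanged(self):
        rng = np.random.default_rng(9)
        n, order = 256, 3
        t = np.linspace(-1, 1, n)
        V = np.polynomial.polynomial.polyvander(t, order)
        raw = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        # project out the polynomial subspace -> fixture orthogonal to it
        Q, _ = np.linalg.qr(V)
        ortho = raw - Q @ (Q.conj().T @ raw)
        fid = Fid(points=ortho, acq=simple_acq(n))
        out = spec1d.suppress_water_poly(fid, order)
        np.testing.assert_allclose(out.points, ortho, atol=1e-10)

    def test_poly_removes_quadratic(self):
        n = 256
        t = np.linspace(-1, 1, n)
        fid = Fid(points=(3.0 + 2.0 * t - 5.0 * t ** 2) + 0j, acq=simple_acq(n))
        out = spec1d.suppress_water_poly(fid, 2)
        np.testing.assert_allclose(out.points, 0.0, atol=1e-10)

    def test_poly_preserves_oscillation(self):
        acq = simple_acq(n=8192, sw=7200.0)
        t = np.arange(8192) / 7200.0
        u = np.linspace(-1, 1, 8192)
        osc = np.exp(2j * np.pi * 2000.0 * t)
        fid = Fid(points=osc + (1.0 + u + u ** 2 + u ** 3), acq=acq)
        out = spec1d.suppress_water_poly(fid, 3)
        k = int(round(2000.0 / 7200.0 * 8192))
        a_in = np.abs(np.fft.fft(osc))[k]
        a_out = np.abs(np.fft.fft(out.points))[k]
        assert a_out == pytest.approx(a_in, rel=0.02)

    def test_wavelet_hook_not_implemented(self):
        fid = Fid(points=np.ones(64, complex), acq=simple_acq(64))
        with pytest.raises(NotImplementedError):
            spec1d.suppress_water(fid, "wavelet")


class TestSplineBaseline:
    def test_linear_spectrum_fully_removed(self, flat_spectrum_factory):
        n = 2000
        line = np.linspace(3.0, -1.0, n)
        spec = flat_spectrum_factory(line)
        bspec = SplineBaselineSpec(anchor_ppms=[spec.ppm_axis[2], spec.ppm_axis[-3]],
                                   max_gap_points=100)
        out, baseline = spec1d.spline_baseline(spec, bspec)
        span = np.ptp(line)
        assert np.max(np.abs(out.points.real)) < 1e-9 * span

    def test_baseline_linear_under_peak_cluster(self, flat_spectrum_factory):
        n = 2000
        base = np.linspace(0.0, 2.0, n)
        signal = base.copy()
        for c in (900, 1000, 1100):
            k = np.arange(n)
            signal += 50.0 * np.exp(-0.5 * ((k - c) / 8.0) ** 2)
        spec = flat_spectrum_factory(signal)
        bspec = SplineBaselineSpec(anchor_ppms=[spec.ppm_axis[300], spec.ppm_axis[1700]],
                                   max_gap_points=200)
        out, baseline = spec1d.spline_baseline(spec, bspec)
        inner = baseline[800:1200]
        second = np.diff(inner, 2)
        assert np.max(np.abs(second)) < 1e-6 * np.ptp(baseline)

    def test_no_synthetic_anchors_at_exact_spacing(self):
        from nmlab.spec1d import _augment_anchors
        idx = np.array([0, 100, 200])
        vals = np.array([1.0, 2.0, 3.0])
        out_i, out_v = _augment_anchors(idx, vals, max_gap=100)
        np.testing.assert_array_equal(out_i, idx)

    def test_synthetic_anchors_inserted_on_line(self):
        from nmlab.spec1d import _augment_anchors
        idx = np.array([0, 300])
        vals = np.array([0.0, 3.0])
        out_i, out_v = _augment_anchors(idx, vals, max_gap=100)
        assert len(out_i) == 4
        assert np.all(np.diff(out_i) <= 100)
        np.testing.assert_allclose(out_v, out_i / 100.0, atol=1e-12)

    def test_too_few_anchors(self, flat_spectrum_factory):
        with pytest.raises(InputError):
            SplineBaselineSpec(anchor_ppms=[1.0], max_gap_points=10)

    def test_zero_baseline_untouched(self, flat_spectrum_factory):
        # flat zero spectrum with anchors on noise-free zero regions
        spec = flat_spectrum_factory(np.zeros(1000))
        bspec = SplineBaselineSpec(
            anchor_ppms=[spec.ppm_axis[i] for i in (50, 300, 600, 950)],
            max_gap_points=100)
        out, baseline = spec1d.spline_baseline(spec, bspec)
        assert np.max(np.abs(out.points.real)) < 1e-9


def test_full_chain_deterministic():
    acq = synthetic.default_acq(4096)
    def chain():
        fid = synthetic.gen_fid(synthetic.metabolite_mix_peaks(), acq, noise_sd=0.01, seed=3)
        fid = spec1d.apodize_exponential(fid, 0.3)
        fid = spec1d.zero_fill(fid, 8192)
        s = spec1d.fourier_transform(fid)
        s = spec1d.apply_phase(s, 12.5, -30.0)
        return spec1d.reference_spectrum(s, "manual", anchor_ppm=5.8, search_window=(5.5, 6.1))
    a, b = chain(), chain()
    np.testing.assert_array_equal(a.points, b.points)
    np.testing.assert_array_equal(a.ppm_axis, b.ppm_axis)


def test_zero_fill_interpolates_peak_position():
    acq = synthetic.default_acq(4096)
    fid = synthetic.gen_fid([synthetic.PeakSpec(ppm=3.21, linewidth_hz=2.0)], acq)
    s0 = spec1d.fourier_transform(fid)
    s1 = spec1d.fourier_transform(spec1d.zero_fill(fid, 16384))
    p0 = s0.ppm_axis[np.argmax(s0.points.real)]
    p1 = s1.ppm_axis[np.argmax(s1.points.real)]
    assert abs(p1 - p0) < s0.ppm_spacing
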