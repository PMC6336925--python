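"""Filter design, stability classification, zero-delay application,
amplitude response, Kaiser order estimation, and Welch PSD."""

import numpy as np
import pytest

from fnirsfilt import (
    ChannelSeries,
    DigitalFilter,
    FilterSpec,
    UnstableFilterError,
    amplitude_response,
    apply_filter,
    check_stability,
    design_filter,
    estimate_fir_order_kaiser,
    welch_psd,
)
from fnirsfilt.filters import default_filter_grid, movavg_window_length

FS = 5.0

ORDERS = [3, 4, 5, 20, 100, 200, 500, 1000]
BP_BANDS = [(0.01, 0.09), (0.01, 0.2), (0.01, 0.3), (0.01, 0.5)]
LP_FCS = [0.09, 0.1, 0.14, 0.5]

# Butterworth stability pattern in transfer-function form at fs = 5 Hz:
# which (order, band) cells admit a usable design. Derived from pole
# analysis; higher orders lose stability, band-pass earlier than low-pass.
BP_STABLE = {(3, b) for b in BP_BANDS} | {(4, b) for b in BP_BANDS} | {
    (5, b) for b in BP_BANDS[1:]
}
LP_STABLE = {(o, fc) for o in (3, 4, 5) for fc in LP_FCS} | {(20, 0.5)}


class TestDesign:
    def test_fir_lp_order4_coefficients(self):
        c = design_filter(FilterSpec("LP", "FIR", 4, 0.5, None, FS))
        b = c.numerator
        assert b.size == 5
        np.testing.assert_allclose(b, b[::-1], rtol=1e-12)  # symmetric
        assert b.sum() == pytest.approx(1.0, rel=1e-12)  # unit DC gain
        assert c.group_delay == 2.0

    def test_movavg_uniform_window(self):
        c = design_filter(FilterSpec("LP", "MovAvg", 1, 0.09, None, FS))
        L = movavg_window_length(0.09, FS)
        np.testing.assert_allclose(c.numerator, np.full(L, 1.0 / L))
        assert c.denominator.tolist() == [1.0]

    def test_movavg_bandpass_unsupported(self):
        with pytest.raises(ValueError):
            FilterSpec("BP", "MovAvg", 1, 0.09, 0.01, FS)

    def test_butterworth_matches_bilinear_transform_oracle(self):
        """Order-3 low-pass vs an independent analog-prototype + bilinear
        transform construction."""
        order, fc = 3, 0.5
        c = design_filter(FilterSpec("LP", "BW", order, fc, None, FS))
        # analog Butterworth poles on the left half-plane circle, prewarped
        wc = 2 * FS * np.tan(np.pi * fc / FS)
        k = np.arange(1, order + 1)
        theta = np.pi / 2 + np.pi * (2 * k - 1) / (2 * order)
        poles_s = wc * np.exp(1j * theta)
        poles_z = (2 * FS + poles_s) / (2 * FS - poles_s)
        a = np.real(np.poly(poles_z))
        b = np.real(np.poly(-np.ones(order)))
        b *= a.sum() / b.sum()  # unit DC gain
        np.testing.assert_allclose(c.denominator, a, rtol=1e-8)
        np.testing.assert_allclose(c.numerator, b, rtol=1e-8)

    def test_fir_linear_phase_symmetry(self):
        c = design_filter(FilterSpec("BP", "FIR", 1000, 0.09, 0.01, FS))
        np.testing.assert_allclose(c.numerator, c.numerator[::-1], atol=1e-12)


class TestStability:
    @pytest.mark.parametrize("order", ORDERS)
    def test_bandpass_grid_classification(self, order):
        for band in BP_BANDS:
            rep = check_stability(
                design_filter(FilterSpec("BP", "BW", order, band[1], band[0], FS))
            )
            assert rep.is_stable == ((order, band) in BP_STABLE), (order, band)

    @pytest.mark.parametrize("order", ORDERS)
    def test_lowpass_grid_classification(self, order):
        for fc in LP_FCS:
            rep = check_stability(
                design_filter(FilterSpec("LP", "BW", order, fc, None, FS))
            )
            assert rep.is_stable == ((order, fc) in LP_STABLE), (order, fc)

    def test_fir_and_movavg_always_stable(self):
        for spec in default_filter_grid():
            if spec.family == "BW":
                continue
            assert check_stability(design_filter(spec)).is_stable

    def test_unstable_iir_refused_at_application(self, rng):
        c = design_filter(FilterSpec("BP", "BW", 20, 0.2, 0.01, FS))
        s = ChannelSeries(rng.normal(0, 1, 2900), FS, "HbO2")
        with pytest.raises(UnstableFilterError):
            apply_filter(c, s)


class TestApplication:
    def test_zero_in_zero_out(self):
        s = ChannelSeries(np.zeros(2900), FS, "HbO2")
        for spec in (
            FilterSpec("BP", "BW", 5, 0.2, 0.01, FS),
            FilterSpec("BP", "FIR", 1000, 0.09, 0.01, FS),
        ):
            out = apply_filter(design_filter(spec), s)
            assert np.allclose(out.values, 0)
            assert len(out) == len(s)

    @pytest.mark.parametrize(
        "spec",
        [
            FilterSpec("BP", "BW", 5, 0.2, 0.01, FS),
            FilterSpec("BP", "FIR", 1000, 0.09, 0.01, FS),
            FilterSpec("BP", "FIR", 500, 0.09, 0.01, FS),
        ],
        ids=["bw5", "fir1000", "fir500"],
    )
    def test_zero_net_delay_on_inband_sinusoid(self, spec):
        """Cross-correlation of an in-band sinusoid with its filtered copy
        peaks at lag 0."""
        t = np.arange(0, 580, 1 / FS)
        s = ChannelSeries(np.sin(2 * np.pi * 0.05 * t), FS, "HbO2")
        out = apply_filter(design_filter(spec), s)
        lags = np.arange(-20, 21)
        xc = [np.dot(out.values, np.roll(s.values, l)) for l in lags]
        assert lags[np.argmax(xc)] == 0

    def test_bandpass_removes_dc_offset(self):
        s = ChannelSeries(np.full(2900, 3.0), FS, "HbO2")
        out = apply_filter(design_filter(FilterSpec("BP", "FIR", 1000, 0.09, 0.01, FS)), s)
        assert abs(out.values.mean()) < 0.01 * 3.0

    def test_lowpass_passes_dc_offset(self):
        s = ChannelSeries(np.full(2900, 3.0), FS, "HbO2")
        out = apply_filter(design_filter(FilterSpec("LP", "FIR", 100, 0.09, None, FS)), s)
        np.testing.assert_allclose(out.values, 3.0, rtol=1e-6)


class TestAmplitudeResponse:
    def test_recommended_bp_flat_at_stimulation_frequency(self):
        c = design_filter(FilterSpec("BP", "FIR", 1000, 0.09, 0.01, FS))
        w, mag = amplitude_response(c, 8192)
        db = 20 * np.log10(mag[np.argmin(abs(w - 0.025))])
        assert abs(db) < 0.1
        db_1hz = 20 * np.log10(mag[np.argmin(abs(w - 1.0))])
        assert db_1hz < -40

    def test_movavg_unity_at_dc(self):
        c = design_filter(FilterSpec("LP", "MovAvg", 1, 0.09, None, FS))
        w, mag = amplitude_response(c, 1024)
        # first grid point approximates DC
        assert mag[0] == pytest.approx(1.0, abs=1e-3)
        assert np.sum(c.numerator) == pytest.approx(1.0, rel=1e-12)

    def test_iir_response_is_squared(self):
        c = design_filter(FilterSpec("LP", "BW", 3, 0.5, None, FS))
        from scipy.signal import freqz

        w, h = freqz(c.numerator, c.denominator, worN=256, fs=FS)
        _, mag = amplitude_response(c, 256)
        np.testing.assert_allclose(mag, np.abs(h) ** 2, rtol=1e-10)


class TestKaiserOrder:
    def test_matches_published_formula(self):
        """Independent evaluation of N = (A - 7.95) / (2.285 dw) + 1 taps."""
        a_db, width = 60.0, 0.02
        numtaps = int(np.ceil((a_db - 7.95) / (2.285 * np.pi * (width / (FS / 2))))) + 1
        expected = numtaps - 1
        expected += expected % 2
        assert estimate_fir_order_kaiser(width, FS, a_db) == expected

    def test_inverse_proportional_to_transition_width(self):
        wide = estimate_fir_order_kaiser(0.04, FS, 60.0)
        narrow = estimate_fir_order_kaiser(0.02, FS, 60.0)
        assert narrow >= 2 * wide - 4

    def test_monotone_in_attenuation(self):
        orders = [estimate_fir_order_kaiser(0.02, FS, a) for a in (20, 40, 60, 80)]
        assert orders == sorted(orders)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            estimate_fir_order_kaiser(3.0, FS)


class TestWelchPSD:
    def test_sinusoid_peak_location(self):
        t = np.arange(0, 600, 1 / FS)
        s = ChannelSeries(np.sin(2 * np.pi * 0.1 * t), FS, "HbO2")
        f, p = welch_psd(s)
        assert f[np.argmax(p)] == pytest.approx(0.1, abs=f[1] - f[0])

    def test_zero_series_zero_psd(self):
        s = ChannelSeries(np.zeros(3000), FS, "HbO2")
        _, p = welch_psd(s)
        assert np.all(p == 0)

    def test_single_segment_matches_direct_dft(self, rng):
        """A one-segment Welch estimate equals the windowed periodogram
        computed by direct DFT."""
        n = int(120 * FS)
        x = rng.normal(0, 1, n)
        s = ChannelSeries(x, FS, "HbO2")
        f, p = welch_psd(s, window_s=120.0)
        w = np.hamming(n)
        xw = x * w
        freqs = np.fft.rfftfreq(n, 1 / FS)
        dft = np.array(
            [np.sum(xw * np.exp(-2j * np.pi * k * np.arange(n) / n)) for k in range(freqs.size)]
        )
        pxx = np.abs(dft) ** 2 / (FS * np.sum(w**2))
        pxx[1:-1] *= 2  # one-sided density
        np.testing.assert_allclose(p, pxx, rtol=1e-8, atol=1e-12)

    def test_short_record_falls_back_with_warning(self):
        s = ChannelSeries(np.sin(np.arange(200) / 3.0), FS, "HbO2")
        with pytest.warns(UserWarning):
            welch_psd(s, window_s=120.0)


def test_digital_filter_sklearn_contract(rng):
    from sklearn.base import clone

    est = DigitalFilter(order=100, fc_high=0.09, fc_low=0.01)
    est2 = clone(est)
    assert est2.get_params()["order"] == 100
    X = rng.normal(0, 1, (2900, 3))
    out = est.fit(X).transform(X)
    assert out.shape == X.shape
    assert est.stability_.is_stable
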