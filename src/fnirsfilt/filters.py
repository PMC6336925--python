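"""Design, stability analysis, and zero-net-delay application of the
benchmark's filter families.

Three families are covered, in band-pass (BP) and low-pass (LP)
characteristics:

* ``BW`` — Butterworth IIR, realized as transfer-function (b, a)
  coefficients and applied forward–backward (``filtfilt``), which cancels
  the frequency-dependent phase delay at the cost of squaring the magnitude
  response.
* ``FIR`` — linear-phase windowed (Hamming) designs of length order+1 with
  the −6 dB point at the cut-off, applied in a single pass with the output
  advanced by the constant group delay (order/2 samples).
* ``MovAvg`` — uniform moving average, a special low-pass FIR whose window
  length is derived from the requested cut-off via the first −3 dB point of
  a length-L average, L = round(0.443·fs/fc).

Stability is judged on the transfer-function denominator in double
precision: Butterworth designs of high order are numerically unstable in
this representation (poles migrate outside the unit circle, or the
coefficients overflow entirely), which is exactly the behavior the
filter-selection tables report. FIR filters have all poles at the origin and
are always stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ChannelSeries, round_half_up

__all__ = [
    "FilterSpec",
    "FilterCoeffs",
    "StabilityReport",
    "UnstableFilterError",
    "design_filter",
    "check_stability",
    "apply_filter",
    "amplitude_response",
    "estimate_fir_order_kaiser",
    "welch_psd",
    "DigitalFilter",
    "default_filter_grid",
]

#: a pole magnitude must stay below 1 - this margin to count as stable
STABILITY_TOL = 1e-12

#: first -3 dB crossing of a length-L uniform average occurs near 0.443*fs/L
_MOVAVG_BW_CONST = 0.443


@dataclass(frozen=True)
class FilterSpec:
    """One cell of the filter grid.

    ``characteristic`` is ``"BP"`` or ``"LP"``; ``family`` is ``"BW"``
    (Butterworth IIR), ``"FIR"`` or ``"MovAvg"``. ``fc_low`` applies to BP
    only. For MovAvg the ``order`` field is ignored at design time (the
    window length comes from ``fc_high``).
    """

    characteristic: str
    family: str
    order: int
    fc_high: float
    fc_low: Optional[float] = None
    fs: float = 5.0

    def __post_init__(self):
        if self.characteristic not in ("BP", "LP"):
            raise ValueError(f"unknown characteristic {self.characteristic!r}")
        if self.family not in ("BW", "FIR", "MovAvg"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        nyq = self.fs / 2
        if not 0 < self.fc_high < nyq:
            raise ValueError(f"fc_high must lie in (0, {nyq}), got {self.fc_high}")
        if self.characteristic == "BP":
            if self.family == "MovAvg":
                raise ValueError("moving-average filters are low-pass only")
            if self.fc_low is None or not 0 < self.fc_low < self.fc_high:
                raise ValueError("BP requires 0 < fc_low < fc_high")
        elif self.fc_low is not None:
            raise ValueError("LP filters take no fc_low")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    @property
    def band(self) -> tuple:
        return (self.fc_low, self.fc_high) if self.characteristic == "BP" else (self.fc_high,)

    @property
    def spec_id(self) -> str:
        if self.characteristic == "BP":
            return f"{self.characteristic}-{self.family}-o{self.order}-fc{self.fc_low}-{self.fc_high}"
        return f"{self.characteristic}-{self.family}-o{self.order}-fc{self.fc_high}"


@dataclass
class FilterCoeffs:
    """Realized transfer-function coefficients plus bookkeeping."""

    numerator: np.ndarray
    denominator: np.ndarray
    fs: float
    spec: FilterSpec
    group_delay: Optional[float] = None  # samples; FIR/MovAvg only
    design_note: str = ""

    @property
    def is_fir(self) -> bool:
        return self.denominator.size == 1

    @property
    def length(self) -> int:
        return max(self.numerator.size, self.denominator.size)


@dataclass
class StabilityReport:
    """Pole magnitudes of the transfer-function denominator."""

    pole_magnitudes: np.ndarray
    is_stable: bool
    representation: str = "transfer-function"
    note: str = ""


class UnstableFilterError(ValueError):
    """Raised when applying an IIR design whose poles leave the unit circle."""

    def __init__(self, report: StabilityReport, spec: FilterSpec):
        self.report = report
        self.spec = spec
        mx = np.max(report.pole_magnitudes) if report.pole_magnitudes.size else np.nan
        super().__init__(
            f"filter {spec.spec_id} is unstable (max |pole| = {mx:.6g}); "
            "refusing to apply"
        )


def movavg_window_length(fc_high: float, fs: float) -> int:
    """Window length whose first −3 dB point falls at ``fc_high``."""
    return max(2, round_half_up(_MOVAVG_BW_CONST * fs / fc_high))


def design_filter(spec: FilterSpec) -> FilterCoeffs:
    """Realize a :class:`FilterSpec` as transfer-function coefficients.

    Butterworth designs use the bilinear transform in (b, a) form; FIR
    designs are Hamming-windowed sinc filters of length order+1 (−6 dB at
    the cut-off); MovAvg is a uniform window scaled by 1/L.
    """
    nyq = spec.fs / 2
    if spec.family == "BW":
        wn = [f / nyq for f in spec.band] if spec.characteristic == "BP" else spec.fc_high / nyq
        btype = "bandpass" if spec.characteristic == "BP" else "lowpass"
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b, a = signal.butter(spec.order, wn, btype=btype, output="ba")
        b, a = np.atleast_1d(np.asarray(b, float)), np.atleast_1d(np.asarray(a, float))
        return FilterCoeffs(b, a, spec.fs, spec, design_note="bilinear-transform Butterworth")
    if spec.family == "FIR":
        numtaps = spec.order + 1
        pass_zero = spec.characteristic == "LP"
        cutoff = list(spec.band) if spec.characteristic == "BP" else spec.fc_high
        b = signal.firwin(numtaps, cutoff, pass_zero=pass_zero, window="hamming", fs=spec.fs)
        return FilterCoeffs(
            np.asarray(b, float),
            np.ones(1),
            spec.fs,
            spec,
            group_delay=spec.order / 2,
            design_note="Hamming-windowed linear-phase FIR, -6 dB at fc",
        )
    # MovAvg
    L = movavg_window_length(spec.fc_high, spec.fs)
    b = np.full(L, 1.0 / L)
    return FilterCoeffs(
        b,
        np.ones(1),
        spec.fs,
        spec,
        group_delay=(L - 1) / 2,
        design_note=f"uniform moving average, window {L} samples",
    )


def check_stability(coeffs: FilterCoeffs) -> StabilityReport:
    """Locate the denominator poles relative to the unit circle.

    Non-finite coefficients (high-order Butterworth designs overflow in
    double precision) are classified unstable outright.
    """
    b, a = coeffs.numerator, coeffs.denominator
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        return StabilityReport(
            pole_magnitudes=np.array([np.inf]),
            is_stable=False,
            note="non-finite coefficients (design overflow)",
        )
    if a.size == 1:  # FIR: all poles at the origin
        return StabilityReport(np.zeros(max(b.size - 1, 0)), True, note="FIR")
    mags = np.abs(np.roots(a))
    return StabilityReport(mags, bool(np.max(mags) < 1.0 - STABILITY_TOL))


def _reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    pad = min(pad, x.size - 1)
    left = 2 * x[0] - x[1 : pad + 1][::-1]
    right = 2 * x[-1] - x[-pad - 1 : -1][::-1]
    return np.concatenate([left, x, right]), pad


def apply_filter(coeffs: FilterCoeffs, series: ChannelSeries) -> ChannelSeries:
    """Apply a designed filter with zero net delay.

    IIR coefficients go through forward–backward filtering (zero phase,
    squared magnitude); an unstable IIR design raises
    :class:`UnstableFilterError`. FIR/MovAvg coefficients are applied once
    on a reflection-padded copy and the output advanced by the (rounded)
    group delay. Output length equals input length.
    """
    if series.fs != coeffs.fs:
        raise ValueError("series and filter sampling rates differ")
    x = series.values
    if coeffs.is_fir:
        b = coeffs.numerator
        padded, pad = _reflect_pad(x, 3 * b.size)
        y = signal.lfilter(b, [1.0], padded)
        shift = round_half_up(coeffs.group_delay or 0)
        y = y[pad + shift : pad + shift + x.size]
        return series.with_values(y)
    report = check_stability(coeffs)
    if not report.is_stable:
        raise UnstableFilterError(report, coeffs.spec)
    padlen = min(3 * coeffs.length, x.size - 1)
    y = signal.filtfilt(coeffs.numerator, coeffs.denominator, x, padlen=padlen)
    return series.with_values(y)


def amplitude_response(coeffs: FilterCoeffs, n_points: int = 1024):
    """Magnitude of the *realized* response on a grid spanning (0, fs/2).

    For IIR coefficients this is the squared magnitude (the forward–backward
    application squares |H|); for FIR it is the single-pass magnitude.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    w, h = signal.freqz(coeffs.numerator, coeffs.denominator, worN=n_points, fs=coeffs.fs)
    mag = np.abs(h)
    if not coeffs.is_fir:
        mag = mag**2
    return w, mag


def estimate_fir_order_kaiser(transition_width: float, fs: float, ripple_db: float = 60.0) -> int:
    """Kaiser's FIR order estimate, rounded up to an even order.

    The order is inversely proportional to the normalized transition
    bandwidth: N ≈ (A − 7.95) / (2.285 · Δω) for stop-band attenuation A in
    dB and Δω = 2π·Δf/fs.
    """
    if not 0 < transition_width < fs / 2:
        raise ValueError("transition_width must lie in (0, fs/2)")
    numtaps, _ = signal.kaiserord(ripple_db, transition_width / (fs / 2))
    order = numtaps - 1
    return order + (order % 2)


def welch_psd(series: ChannelSeries, window_s: float = 120.0, overlap: float = 0.5):
    """Welch power spectral density with a 120 s window and 50% overlap.

    Hamming-windowed averaged modified periodograms, one-sided density
    normalization (power per Hz). Falls back to a single segment with a
    warning when the record is shorter than the window.
    """
    nperseg = round_half_up(window_s * series.fs)
    n = len(series)
    if nperseg > n:
        warnings.warn("record shorter than PSD window; using a single segment")
        nperseg = n
    noverlap = int(nperseg * overlap)
    f, p = signal.welch(
        series.values,
        fs=series.fs,
        window=np.hamming(nperseg),  # symmetric Hamming, pwelch convention
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )
    return f, p


class DigitalFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping design + zero-delay application.

    Parameters mirror :class:`FilterSpec`. ``fit`` designs the filter and
    runs the stability check (fitted attributes ``coeffs_`` and
    ``stability_``); ``transform`` filters each column of an
    (n_samples, n_channels) array. Unstable IIR designs raise at
    ``transform`` time, matching :func:`apply_filter`.
    """

    def __init__(
        self,
        characteristic: str = "BP",
        family: str = "FIR",
        order: int = 1000,
        fc_high: float = 0.09,
        fc_low: Optional[float] = 0.01,
        fs: float = 5.0,
    ):
        self.characteristic = characteristic
        self.family = family
        self.order = order
        self.fc_high = fc_high
        self.fc_low = fc_low
        self.fs = fs

    def _spec(self) -> FilterSpec:
        return FilterSpec(
            characteristic=self.characteristic,
            family=self.family,
            order=self.order,
            fc_high=self.fc_high,
            fc_low=self.fc_low if self.characteristic == "BP" else None,
            fs=self.fs,
        )

    def fit(self, X=None, y=None):
        self.coeffs_ = design_filter(self._spec())
        self.stability_ = check_stability(self.coeffs_)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        cols = X[:, None] if one_d else X
        out = np.empty_like(cols)
        for j in range(cols.shape[1]):
            s = ChannelSeries(cols[:, j], fs=self.fs, kind="HbO2")
            out[:, j] = apply_filter(self.coeffs_, s).values
        return out[:, 0] if one_d else out


def default_filter_grid(fs: float = 5.0) -> list:
    """The full benchmark grid: BP {BW, FIR} × orders
    {3,4,5,20,100,200,500,1000} × bands {0.01–0.09, 0.01–0.2, 0.01–0.3,
    0.01–0.5}; LP {BW, FIR} × same orders × cut-offs {0.09, 0.1, 0.14, 0.5};
    LP MovAvg at {0.09, 0.1, 0.14}.
    """
    orders = [3, 4, 5, 20, 100, 200, 500, 1000]
    bp_bands = [(0.01, 0.09), (0.01, 0.2), (0.01, 0.3), (0.01, 0.5)]
    lp_fcs = [0.09, 0.1, 0.14, 0.5]
    grid = []
    for family in ("BW", "FIR"):
        for order in orders:
            for lo, hi in bp_bands:
                grid.append(FilterSpec("BP", family, order, hi, lo, fs))
            for fc in lp_fcs:
                grid.append(FilterSpec("LP", family, order, fc, None, fs))
    for fc in (0.09, 0.1, 0.14):
        L = movavg_window_length(fc, fs)
        grid.append(FilterSpec("LP", "MovAvg", L - 1, fc, None, fs))
    return grid
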