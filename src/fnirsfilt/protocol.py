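"""Block-design protocol, hemodynamic response function, and task component.

The benchmark's simulated experiment is a block design: ``n_blocks`` task
blocks of ``task_dur`` seconds alternating with ``rest_dur`` seconds of rest,
after a ``lead_in`` rest period. The stimulation frequency is
``f_stim = 1/(task_dur + rest_dur)`` — 0.025 Hz for the default 20 s/20 s
design — and band-pass cut-offs are judged against it.

The task-evoked component is the convolution of the protocol boxcar with a
canonical double-gamma hemodynamic response function (positive response
gamma, smaller negative undershoot gamma), rescaled to unit peak and
multiplied by a chromophore amplitude. Because the GLM regressor is the same
unit-peak waveform, the generating amplitude *is* the ground-truth β.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special

from .core import ChannelSeries, molar, round_half_up

__all__ = [
    "ProtocolSpec",
    "HRFSpec",
    "AmplitudeSpec",
    "AMPLITUDE_PRESETS",
    "build_boxcar",
    "sample_hrf",
    "make_task_component",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of the simulated block-design experiment.

    Defaults give the 14-block 20 s-on / 20 s-off design with a 20 s lead-in
    rest (580 s total, f_stim = 0.025 Hz).
    """

    n_blocks: int = 14
    task_dur: float = 20.0
    rest_dur: float = 20.0
    lead_in: float = 20.0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.task_dur <= 0 or self.rest_dur <= 0:
            raise ValueError("task and rest durations must be positive")
        if self.lead_in < 0:
            raise ValueError("lead_in must be non-negative")

    @property
    def f_stim(self) -> float:
        """Stimulation (block-cycle) frequency in Hz: 1/(task + rest)."""
        return 1.0 / (self.task_dur + self.rest_dur)

    @property
    def total_duration(self) -> float:
        """Total protocol duration in seconds."""
        return self.lead_in + self.n_blocks * (self.task_dur + self.rest_dur)

    def n_samples(self, fs: float) -> int:
        return round_half_up(self.total_duration * fs)


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma hemodynamic response function parameters.

    ``peak_time`` and ``undershoot_time`` are the *analytic* extrema of the
    kernel in seconds; the two gamma shape parameters are solved so that the
    difference of the two unit-scale gamma densities peaks and troughs exactly
    there (with the response peak at 6 s and the undershoot trough at 16 s by
    default). ``undershoot_ratio`` is the weight of the undershoot gamma
    relative to the response gamma before peak normalization.
    """

    peak_time: float = 6.0
    undershoot_time: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_duration: float = 32.0

    def __post_init__(self):
        if not (0 < self.peak_time < self.undershoot_time < self.kernel_duration):
            raise ValueError(
                "require 0 < peak_time < undershoot_time < kernel_duration, got "
                f"{self.peak_time}, {self.undershoot_time}, {self.kernel_duration}"
            )
        if self.undershoot_ratio <= 0:
            raise ValueError("undershoot_ratio must be positive")


@dataclass(frozen=True)
class AmplitudeSpec:
    """Ground-truth task amplitudes (Molar) for the two chromophores.

    The HbR amplitude is negative and roughly −1/3 of the HbO2 one, matching
    the physiology of task-evoked deoxyhemoglobin decreases.
    """

    hbo2_amp: float
    hbr_amp: float
    label: str

    def __post_init__(self):
        if self.hbo2_amp <= 0:
            raise ValueError("hbo2_amp must be positive")
        if self.hbr_amp >= 0:
            raise ValueError("hbr_amp must be negative")


#: The three signal-to-noise presets: 0.8/-0.27, 0.5/-0.17, 0.3/-0.1 uM.
AMPLITUDE_PRESETS = (
    AmplitudeSpec(molar(0.8), molar(-0.27), "Amplitude1"),
    AmplitudeSpec(molar(0.5), molar(-0.17), "Amplitude2"),
    AmplitudeSpec(molar(0.3), molar(-0.1), "Amplitude3"),
)


def build_boxcar(protocol: ProtocolSpec, fs: float) -> ChannelSeries:
    """Sample the protocol's 0/1 boxcar at ``fs`` Hz.

    The series is 0 during the lead-in and rest periods and 1 during task
    blocks; durations are converted to sample counts with round-half-up.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n_lead = round_half_up(protocol.lead_in * fs)
    n_task = round_half_up(protocol.task_dur * fs)
    n_rest = round_half_up(protocol.rest_dur * fs)
    if n_task == 0:
        raise ValueError("task_dur shorter than one sample at this fs")
    parts = [np.zeros(n_lead)]
    for _ in range(protocol.n_blocks):
        parts.append(np.ones(n_task))
        parts.append(np.zeros(n_rest))
    return ChannelSeries(np.concatenate(parts), fs=fs, kind="boxcar")


def _gamma_pdf(t: np.ndarray, shape: float) -> np.ndarray:
    """Unit-scale gamma density, zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = special.xlogy(shape - 1.0, t) - t - special.gammaln(shape)
        out = np.where(t > 0, np.exp(logp), 0.0)
    return out


def _gamma_pdf_deriv(t: float, shape: float) -> float:
    return float(_gamma_pdf(np.array(t), shape) * ((shape - 1.0) / t - 1.0))


@lru_cache(maxsize=32)
def _solve_shapes(peak_time: float, undershoot_time: float, ratio: float):
    """Shape parameters (a1, a2) placing the kernel extrema analytically.

    Solves h'(peak_time) = h'(undershoot_time) = 0 for
    h(t) = Gamma(t; a1) - ratio * Gamma(t; a2) (unit scale).
    """

    def equations(p):
        a1, a2 = p
        return [
            _gamma_pdf_deriv(peak_time, a1) - ratio * _gamma_pdf_deriv(peak_time, a2),
            _gamma_pdf_deriv(undershoot_time, a1) - ratio * _gamma_pdf_deriv(undershoot_time, a2),
        ]

    # gamma mode = shape - 1 at unit scale: good starting point
    guess = [peak_time + 1.0, undershoot_time + 1.0]
    sol, info, ier, msg = optimize.fsolve(equations, guess, full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
        raise RuntimeError(f"HRF shape solve failed: {msg}")
    return float(sol[0]), float(sol[1])


def sample_hrf(hrf: HRFSpec, fs: float) -> ChannelSeries:
    """Sample the double-gamma kernel at ``fs`` Hz, scaled to unit peak.

    The returned kernel spans [0, kernel_duration], starts at exactly zero,
    attains its global maximum at ``peak_time`` and its global minimum at
    ``undershoot_time`` (to sample resolution).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    a1, a2 = _solve_shapes(hrf.peak_time, hrf.undershoot_time, hrf.undershoot_ratio)
    n = round_half_up(hrf.kernel_duration * fs) + 1
    t = np.arange(n) / fs
    h = _gamma_pdf(t, a1) - hrf.undershoot_ratio * _gamma_pdf(t, a2)
    h = h / np.max(h)
    return ChannelSeries(h, fs=fs, kind="regressor")


def make_task_component(
    boxcar: ChannelSeries, hrf_kernel: ChannelSeries, amplitude: float
) -> ChannelSeries:
    """Task-evoked component: amplitude x unit-peak (boxcar * HRF).

    The convolution is truncated to the boxcar length and rescaled to unit
    peak magnitude *before* amplitude scaling, so that an OLS fit with the
    matching unit-peak regressor recovers ``amplitude`` exactly as β.
    """
    if boxcar.fs != hrf_kernel.fs:
        raise ValueError("boxcar and kernel must share the sampling rate")
    conv = np.convolve(boxcar.values, hrf_kernel.values)[: len(boxcar)]
    peak = np.max(np.abs(conv))
    if peak > 0:
        conv = conv / peak
    kind = "regressor" if amplitude == 1.0 else ("HbO2" if amplitude > 0 else "HbR")
    return ChannelSeries(conv * amplitude, fs=boxcar.fs, kind=kind)
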