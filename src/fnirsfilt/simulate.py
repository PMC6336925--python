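"""Seeded multi-subject synthetic fNIRS concentration data.

The generator emulates resting-state hemodynamic concentration series with
the structure the analysis assumes:

* **Systemic oscillations** at the cardiac (~1.1 Hz), respiratory (~0.3 Hz),
  Mayer-wave (~0.095 Hz) and very-low-frequency (~0.02 Hz) bands. Each
  subject draws its own component frequencies, amplitudes and phases; within
  a subject the oscillations are *shared across channels* (systemic
  physiology is spatially global) up to small per-channel phase and
  amplitude perturbations.
* **A settling trend**: an exponential approach to plateau with
  subject-varying amplitude and timescale, emulating the slow perfusion/
  coupling stabilization after probe placement. Its direction is consistent
  across subjects (HbO2 rising toward baseline, HbR mirrored), which is what
  makes inadequately filtered GLM fits *overestimate* the task response
  rather than merely scatter around it.
* **Channel-specific noise**: a smoothed random-walk drift and white
  measurement noise, independent per channel.

The HbR member of a pair shares the subject's systemic parameters but has
independent channel noise and phases, mirrored in sign and attenuated by
``hbr_scale`` (deoxyhemoglobin carries weaker physiological interference).

The known task component (double-gamma HRF ⊗ block boxcar, unit peak,
scaled by a preset amplitude) is added identically to every channel of a
subject, so the generating amplitude is the recoverable ground-truth β.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ChannelSeries, SubjectRecording, molar
from .protocol import (
    AMPLITUDE_PRESETS,
    HRFSpec,
    ProtocolSpec,
    build_boxcar,
    make_task_component,
    sample_hrf,
)

__all__ = [
    "NoiseSpec",
    "SubjectPhysiology",
    "draw_subject_physiology",
    "simulate_resting_pair",
    "assemble_dataset",
    "inject_motion_artifacts",
]


def _default_components():
    # (center Hz, freq jitter SD Hz, amplitude M, amplitude jitter SD M)
    return (
        (1.1, 0.15, molar(0.2), molar(0.05)),    # cardiac
        (0.3, 0.05, molar(0.15), molar(0.04)),   # respiration
        (0.095, 0.01, molar(0.2), molar(0.05)),  # Mayer wave
        (0.02, 0.01, molar(0.3), molar(0.08)),   # very-low-frequency
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological + instrumental noise model for one chromophore pair.

    ``components`` lists systemic oscillators as
    (center_freq Hz, freq_jitter_sd Hz, amplitude M, amplitude_jitter_sd M);
    frequency/amplitude/phase are drawn once per subject, then perturbed per
    channel by ``channel_phase_jitter`` (rad) and a multiplicative amplitude
    factor with SD ``channel_amp_jitter``. ``settle_amp``/``settle_amp_sd``
    set the subject-varying amplitude of the exponential settling trend
    (timescale ``settle_timescale`` ± ``settle_timescale_sd`` s).
    ``drift_amp`` is the RMS of a channel-specific smoothed random-walk
    drift with correlation time ``drift_timescale``; ``white_sd`` is
    per-sample measurement noise; ``hbr_scale`` attenuates the whole noise
    process on the HbR channel.
    """

    components: tuple = field(default_factory=_default_components)
    channel_phase_jitter: float = 0.5
    channel_amp_jitter: float = 0.3
    settle_amp: float = molar(1.0)
    settle_amp_sd: float = molar(0.5)
    settle_timescale: float = 180.0
    settle_timescale_sd: float = 60.0
    drift_amp: float = molar(0.5)
    drift_timescale: float = 120.0
    white_sd: float = molar(0.05)
    hbr_scale: float = 1.0 / 3.0

    def __post_init__(self):
        for c, fj, a, aj in self.components:
            if fj < 0 or aj < 0:
                raise ValueError("jitter SDs must be non-negative")
            if c <= 0:
                raise ValueError("component frequencies must be positive")
        if not 0 < self.hbr_scale <= 1:
            raise ValueError("hbr_scale must lie in (0, 1]")
        if min(self.drift_amp, self.white_sd, self.settle_amp_sd,
               self.channel_phase_jitter, self.channel_amp_jitter) < 0:
            raise ValueError("noise scales must be non-negative")

    def validate_rate(self, fs: float):
        for c, *_ in self.components:
            if c >= fs / 2:
                raise ValueError(f"component at {c} Hz is above Nyquist for fs={fs}")


@dataclass(frozen=True)
class SubjectPhysiology:
    """Per-subject systemic draws shared by all channels of a recording."""

    freqs: tuple
    amps: tuple
    phases_hbo2: tuple
    phases_hbr: tuple
    settle_amp: float
    settle_tau: float


def draw_subject_physiology(noise: NoiseSpec, rng: np.random.Generator) -> SubjectPhysiology:
    """Draw the subject-level systemic parameters."""
    freqs, amps = [], []
    for c, fj, a, aj in noise.components:
        freqs.append(max(1e-4, rng.normal(c, fj)))
        amps.append(max(0.0, rng.normal(a, aj)))
    k = len(freqs)
    return SubjectPhysiology(
        freqs=tuple(freqs),
        amps=tuple(amps),
        phases_hbo2=tuple(rng.uniform(0, 2 * np.pi, k)),
        phases_hbr=tuple(rng.uniform(0, 2 * np.pi, k)),
        settle_amp=rng.normal(noise.settle_amp, noise.settle_amp_sd),
        settle_tau=max(30.0, rng.normal(noise.settle_timescale, noise.settle_timescale_sd)),
    )


def _smooth_drift(rng: np.random.Generator, n: int, fs: float, amp: float, timescale: float):
    """Zero-mean smoothed random walk with RMS ``amp``."""
    if amp == 0:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    L = max(2, min(int(timescale * fs), n))
    sm = np.convolve(walk, np.ones(L) / L, mode="same")
    sm -= sm.mean()
    rms = np.sqrt(np.mean(sm**2))
    return amp * sm / rms if rms > 0 else sm


def _channel_noise(
    noise: NoiseSpec,
    phys: SubjectPhysiology,
    phases,
    t: np.ndarray,
    fs: float,
    rng: np.random.Generator,
):
    """One channel's noise: perturbed systemic waves + settle + drift + white."""
    x = np.zeros_like(t)
    for f, a, ph in zip(phys.freqs, phys.amps, phases):
        scale = max(0.1, rng.normal(1.0, noise.channel_amp_jitter))
        dphi = rng.normal(0.0, noise.channel_phase_jitter)
        x += a * scale * np.sin(2 * np.pi * f * t + ph + dphi)
    # settling trend: starts depressed by settle_amp, rises toward plateau
    x += -phys.settle_amp * np.exp(-t / phys.settle_tau)
    x += _smooth_drift(rng, t.size, fs, noise.drift_amp, noise.drift_timescale)
    x += noise.white_sd * rng.standard_normal(t.size)
    return x


def simulate_resting_pair(
    noise: NoiseSpec,
    duration: float,
    fs: float,
    seed,
    physiology: SubjectPhysiology = None,
) -> tuple:
    """One channel's (HbO2, HbR) resting concentration pair.

    Deterministic given ``seed``. ``physiology`` carries the subject-level
    systemic draws; when omitted it is drawn from the same seed (a
    stand-alone single-channel subject). The HbR series shares the
    subject's component frequencies/amplitudes and settling trend but has
    its own phases, drift and white noise, and is mirrored in sign and
    attenuated by ``hbr_scale``.
    """
    noise.validate_rate(fs)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if noise.drift_amp > 0 and duration < 2 * noise.drift_timescale:
        warnings.warn("record shorter than twice the drift timescale; drift poorly resolved")
    t = np.arange(n) / fs
    phys = physiology if physiology is not None else draw_subject_physiology(noise, rng)
    hbo = _channel_noise(noise, phys, phys.phases_hbo2, t, fs, rng)
    hbr = -noise.hbr_scale * _channel_noise(noise, phys, phys.phases_hbr, t, fs, rng)
    return (
        ChannelSeries(hbo, fs=fs, kind="HbO2"),
        ChannelSeries(hbr, fs=fs, kind="HbR"),
    )


def assemble_dataset(
    n_subjects: int = 18,
    n_channels: int = 16,
    protocol: ProtocolSpec = ProtocolSpec(),
    hrf: HRFSpec = HRFSpec(),
    amplitudes=AMPLITUDE_PRESETS,
    noise: NoiseSpec = NoiseSpec(),
    fs: float = 5.0,
    master_seed: int = 0,
) -> dict:
    """Generate one dataset per amplitude preset.

    Returns ``{amplitude_label: [SubjectRecording, ...]}``. The resting
    noise of a subject/channel is identical across the amplitude datasets
    (as when different task amplitudes are superimposed on the same real
    resting recordings); only the added task component differs. Per-subject
    and per-channel seeds derive deterministically from ``master_seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    boxcar = build_boxcar(protocol, fs)
    kernel = sample_hrf(hrf, fs)
    duration = len(boxcar) / fs
    task_unit = make_task_component(boxcar, kernel, 1.0).values
    ss = np.random.SeedSequence(master_seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]
    datasets = {amp.label: [] for amp in amplitudes}
    for i, sseed in enumerate(subject_seeds):
        subj_ss = np.random.SeedSequence(sseed)
        phys = draw_subject_physiology(noise, np.random.default_rng(subj_ss))
        chan_seeds = [int(cs.generate_state(1)[0] % (2**31)) for cs in subj_ss.spawn(n_channels)]
        rest_pairs = [
            simulate_resting_pair(noise, duration, fs, cseed, physiology=phys)
            for cseed in chan_seeds
        ]
        for amp in amplitudes:
            channels = [
                (
                    hbo.with_values(hbo.values + amp.hbo2_amp * task_unit),
                    hbr.with_values(hbr.values + amp.hbr_amp * task_unit),
                )
                for hbo, hbr in rest_pairs
            ]
            datasets[amp.label].append(
                SubjectRecording(
                    subject_id=f"sub{i + 1:02d}", channels=channels, seed=sseed
                )
            )
    return datasets


def inject_motion_artifacts(series: ChannelSeries, events) -> ChannelSeries:
    """Add spike/shift motion artifacts at given times.

    ``events`` is a list of ``(time_s, type, magnitude)`` with type
    ``"spike"`` (1-sample rise, exponential decay with 1 s time constant) or
    ``"shift"`` (a step). Overlapping events add; samples before the first
    event are bit-identical to the input.
    """
    out = series.values.copy()
    n = out.size
    for time_s, etype, mag in events:
        idx = int(round(time_s * series.fs))
        if not 0 <= idx < n:
            raise ValueError(f"event at {time_s} s outside the record")
        if etype == "shift":
            out[idx:] += mag
        elif etype == "spike":
            tau = series.fs  # 1 s decay
            k = np.arange(n - idx)
            out[idx:] += mag * np.exp(-k / tau)
        else:
            raise ValueError(f"unknown event type {etype!r}")
    return series.with_values(out)
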