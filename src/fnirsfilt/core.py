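"""Core containers for sampled fNIRS time-series.

Everything downstream (Beer–Lambert conversion, filtering, GLM fitting)
operates on :class:`ChannelSeries` objects: a uniformly sampled series with a
sampling rate and a ``kind`` tag recording which physical quantity it holds.
Concentrations are carried internally in Molar; micromolar values are accepted
at configuration boundaries and converted (see :func:`molar`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: valid series kinds
KINDS = ("intensity", "OD", "HbO2", "HbR", "boxcar", "regressor")

MICROMOLAR = 1e-6


def molar(value_umol: float) -> float:
    """Convert a micromolar value to Molar."""
    return float(value_umol) * MICROMOLAR


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero toward +inf.

    Used wherever a duration in seconds must become a sample count, so that
    e.g. 0.5-sample boundaries behave the way users of block protocols expect
    (numpy's banker's rounding would round 2.5 -> 2).
    """
    return int(np.floor(x + 0.5))


@dataclass
class ChannelSeries:
    """A uniformly sampled single-channel time-series.

    Parameters
    ----------
    values : ndarray
        Sample values. Units depend on ``kind``: Molar for HbO2/HbR,
        dimensionless for OD/boxcar/regressor, arbitrary for intensity.
    fs : float
        Sampling rate in Hz.
    kind : str
        One of ``intensity``, ``OD``, ``HbO2``, ``HbR``, ``boxcar``,
        ``regressor``.
    wavelength : float, optional
        Wavelength in nm; meaningful for intensity/OD series only.
    """

    values: np.ndarray
    fs: float
    kind: str = "HbO2"
    wavelength: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("ChannelSeries values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("ChannelSeries needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ChannelSeries values must be finite")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.values.size / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds starting at 0."""
        return np.arange(self.values.size) / self.fs

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "ChannelSeries":
        """Copy of this series with new values (and optionally a new kind)."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if kind is not None:
            out.kind = kind
        return out


@dataclass
class SubjectRecording:
    """One simulated session: paired HbO2/HbR concentration series per channel.

    ``channels`` is a list of ``(HbO2, HbR)`` :class:`ChannelSeries` pairs; all
    channels share sampling rate and length. ``excluded_channels`` holds
    1-based channel indices dropped from group statistics (mirroring manual
    rejection of badly coupled optodes).
    """

    subject_id: str
    channels: list
    excluded_channels: set = field(default_factory=set)
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.channels:
            raise ValueError("recording must contain at least one channel pair")
        fs = self.channels[0][0].fs
        n = len(self.channels[0][0])
        for hbo, hbr in self.channels:
            if hbo.fs != fs or hbr.fs != fs or len(hbo) != n or len(hbr) != n:
                raise ValueError("all channels must share fs and length")
        bad = set(self.excluded_channels) - set(range(1, len(self.channels) + 1))
        if bad:
            raise ValueError(f"excluded channel indices out of range: {sorted(bad)}")
        self.excluded_channels = set(self.excluded_channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def fs(self) -> float:
        return self.channels[0][0].fs

    @property
    def n_samples(self) -> int:
        return len(self.channels[0][0])

    def stack(self, chromophore: str) -> np.ndarray:
        """(n_samples, n_channels) matrix of one chromophore across channels."""
        idx = {"HbO2": 0, "HbR": 1}[chromophore]
        return np.column_stack([pair[idx].values for pair in self.channels])
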