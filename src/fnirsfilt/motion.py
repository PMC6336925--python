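"""Motion-artifact detection and targeted-PCA correction on ΔOD data.

Detection follows the standard windowed change criterion: a sample is
flagged when, within any window of ``t_motion`` seconds containing it, the
signal excursion (max − min) exceeds ``std_thresh`` times the channel's
noise scale or the absolute ``amp_thresh``; flagged samples are dilated by
``t_mask`` seconds on each side and the mask is the union over channels.
The noise scale is the standard deviation of the first difference of the
channel, which is robust to slow drifts.

Correction is targeted PCA: principal components are estimated from the
flagged segments only (all channels jointly) and the leading components are
removed until the cumulative explained variance reaches ``n_sv``; detection
and removal repeat up to ``max_iter`` times. Samples outside the mask are
never touched, so the frequency content of clean data is preserved. After
removal each segment is re-anchored with a linear ramp so its endpoints
match the neighboring clean samples, avoiding introduced steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MotionParams",
    "ArtifactMask",
    "detect_motion",
    "tpca_correct",
    "MotionCorrector",
]


@dataclass(frozen=True)
class MotionParams:
    """Detection/correction parameters (Homer2-style naming and defaults)."""

    t_motion: float = 0.5
    t_mask: float = 1.0
    std_thresh: float = 10.0
    amp_thresh: float = 5.0
    n_sv: float = 0.97
    max_iter: int = 5

    def __post_init__(self):
        if min(self.t_motion, self.t_mask, self.std_thresh, self.amp_thresh) <= 0:
            raise ValueError("all motion parameters must be positive")
        if not 0 < self.n_sv <= 1:
            raise ValueError("n_sv must lie in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ArtifactMask:
    """Per-sample boolean artifact flags plus merged segment list."""

    flags: np.ndarray
    fs: float

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def any(self) -> bool:
        return bool(self.flags.any())

    @property
    def segments(self):
        """Merged flagged segments as (start_s, end_s) pairs, sorted."""
        f = np.concatenate([[False], self.flags, [False]]).astype(int)
        d = np.diff(f)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        return [(s / self.fs, e / self.fs) for s, e in zip(starts, ends)]

    @property
    def segment_indices(self):
        f = np.concatenate([[False], self.flags, [False]]).astype(int)
        d = np.diff(f)
        return list(zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]))


def detect_motion(od: np.ndarray, fs: float, params: MotionParams = MotionParams()) -> ArtifactMask:
    """Flag motion-artifact samples in an (n_samples, n_channels) ΔOD array."""
    od = np.atleast_2d(np.asarray(od, dtype=float))
    if od.shape[0] == 1:
        od = od.T
    n, n_ch = od.shape
    win = max(2, int(round(params.t_motion * fs)))
    if n < 2 * win:
        raise ValueError("record too short for the detection window")
    flags = np.zeros(n, dtype=bool)
    for j in range(n_ch):
        x = od[:, j]
        sd = np.std(np.diff(x))
        thresh = params.std_thresh * sd
        # sliding max-min excursion over the detection window
        windows = np.lib.stride_tricks.sliding_window_view(x, win)
        excursion = windows.max(axis=1) - windows.min(axis=1)
        hit = (excursion > thresh) | (excursion > params.amp_thresh)
        for start in np.nonzero(hit)[0]:
            flags[start : start + win] = True
    if flags.any():
        dil = int(round(params.t_mask * fs))
        idx = np.nonzero(flags)[0]
        dilated = np.zeros(n, dtype=bool)
        for i in idx:
            dilated[max(0, i - dil) : min(n, i + dil + 1)] = True
        flags = dilated
    return ArtifactMask(flags, fs)


def _remove_components(seg: np.ndarray, n_sv: float) -> np.ndarray:
    """Remove leading PCs of a (n_samples, n_channels) segment block until
    cumulative explained variance >= n_sv."""
    mean = seg.mean(axis=0)
    centered = seg - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return seg.copy()
    cum = np.cumsum(var) / total
    n_remove = int(np.searchsorted(cum, n_sv) + 1)
    n_remove = min(n_remove, s.size)
    proj = (u[:, :n_remove] * s[:n_remove]) @ vt[:n_remove]
    return centered - proj + mean


def tpca_correct(
    od: np.ndarray,
    fs: float,
    params: MotionParams = MotionParams(),
    mask: ArtifactMask = None,
) -> tuple:
    """Iteratively correct flagged segments by targeted PCA.

    Returns ``(corrected, final_mask)`` where ``corrected`` has the same
    shape as the input and samples outside the (initial) mask are
    bit-identical. Segments shorter than 3 samples are skipped with a
    warning.
    """
    od = np.array(od, dtype=float)
    one_d = od.ndim == 1
    x = od[:, None] if one_d else od
    current = detect_motion(x, fs, params) if mask is None else mask
    for _ in range(params.max_iter):
        if not current.any:
            break
        seg_list = current.segment_indices
        block = x[current.flags]
        cleaned = _remove_components(block, params.n_sv)
        out = x.copy()
        out[current.flags] = cleaned
        # re-anchor every contiguous segment to its clean neighbors
        for s, e in seg_list:
            if e - s < 3:
                warnings.warn(f"segment of {e - s} samples too short to correct; skipped")
                out[s:e] = x[s:e]
                continue
            for j in range(out.shape[1]):
                left = x[s - 1, j] if s > 0 else out[s, j]
                right = x[e, j] if e < x.shape[0] else out[e - 1, j]
                ramp = np.linspace(left - out[s, j], right - out[e - 1, j], e - s)
                out[s:e, j] += ramp
        x = out
        current = detect_motion(x, fs, params)
    return (x[:, 0] if one_d else x), current


class MotionCorrector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: detect + targeted-PCA-correct ΔOD arrays."""

    def __init__(self, params: MotionParams = MotionParams(), fs: float = 5.0):
        self.params = params
        self.fs = fs

    def fit(self, X, y=None):
        self.mask_ = detect_motion(np.asarray(X, dtype=float), self.fs, self.params)
        return self

    def transform(self, X):
        corrected, self.final_mask_ = tpca_correct(
            np.asarray(X, dtype=float), self.fs, self.params, mask=self.mask_
        )
        return corrected
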