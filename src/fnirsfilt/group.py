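"""Group-level statistics of estimated task β-values.

Channel-level β estimates are collapsed to one median per subject (robust to
single bad channels); the subject medians are then tested against the known
reference β with a two-sided one-sample t-test (df = n_subjects − 1), after
checking normality (Shapiro–Wilk, appropriate for small samples) and
flagging Tukey-fence outliers (beyond Q1 − 1.5·IQR or Q3 + 1.5·IQR,
linear-interpolation quartiles). A paired t-test compares β-values from two
pipelines subject-by-subject; exactly equal pipelines (e.g. filtering ΔOD
versus concentrations, which commute through the linear Beer–Lambert map)
are reported as degenerate "no difference" rather than a spurious t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupResult",
    "subject_median",
    "shapiro_wilk",
    "iqr_outliers",
    "one_sample_t",
    "paired_t",
    "group_result",
]

ALPHA = 0.05

#: paired differences entirely below this relative scale count as "no difference"
_PAIR_TOL = 1e-12


@dataclass
class GroupResult:
    """All group-level statistics for one sweep cell."""

    subject_medians: np.ndarray
    reference_beta: float
    shapiro_w: float
    shapiro_p: float
    outlier_flags: np.ndarray
    t_stat: float
    t_p: float
    df: int
    alpha: float = ALPHA

    @property
    def mean_beta(self) -> float:
        return float(np.mean(self.subject_medians))

    @property
    def bias(self) -> float:
        """Signed group bias: mean subject-median β − reference β (Molar)."""
        return self.mean_beta - self.reference_beta


def subject_median(per_channel_betas, excluded_channels=()) -> float:
    """Median β over non-excluded channels (1-based exclusion indices)."""
    betas = np.asarray(per_channel_betas, dtype=float)
    keep = np.ones(betas.size, dtype=bool)
    for idx in excluded_channels:
        if not 1 <= idx <= betas.size:
            raise ValueError(f"excluded channel {idx} out of range")
        keep[idx - 1] = False
    if not keep.any():
        raise ValueError("all channels excluded")
    return float(np.median(betas[keep]))


def shapiro_wilk(values) -> tuple:
    """Shapiro–Wilk W and p for 3 <= n <= 50 samples."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 50:
        raise ValueError(f"Shapiro-Wilk needs 3..50 values, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant) input")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def iqr_outliers(values) -> np.ndarray:
    """Tukey-fence outlier flags with linear (type-7) quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def one_sample_t(values, reference: float) -> tuple:
    """Two-sided one-sample t-test of mean(values) == reference.

    Returns ``(t, p, df)`` with df = n − 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(v, reference)
    return float(res.statistic), float(res.pvalue), int(v.size - 1)


def paired_t(a, b) -> tuple:
    """Two-sided paired t-test; returns ``(t, p, df, identical)``.

    When the paired differences are all (numerically) zero the comparison is
    degenerate — the two pipelines agree exactly — and ``identical=True`` is
    returned with t and p as NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)), 1e-300)
    if np.all(np.abs(d) <= _PAIR_TOL * scale):
        return float("nan"), float("nan"), int(a.size - 1), True
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), int(a.size - 1), False


def group_result(subject_medians, reference_beta: float) -> GroupResult:
    """Assemble the full :class:`GroupResult` for one condition.

    Normality and outlier diagnostics require minimum group sizes (3 and 4
    respectively); below those they are reported as NaN / all-clear rather
    than failing the whole sweep cell.
    """
    v = np.asarray(subject_medians, dtype=float)
    w, p_w = shapiro_wilk(v) if v.size >= 3 else (float("nan"), float("nan"))
    flags = iqr_outliers(v) if v.size >= 4 else np.zeros(v.size, dtype=bool)
    t, p_t, df = one_sample_t(v, reference_beta)
    return GroupResult(
        subject_medians=v,
        reference_beta=float(reference_beta),
        shapiro_w=w,
        shapiro_p=p_w,
        outlier_flags=flags,
        t_stat=t,
        t_p=p_t,
        df=df,
    )
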