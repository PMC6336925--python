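"""Full-factorial filter sweep and ranking by β recovery.

For every combination of (amplitude dataset × filter specification ×
filtered-signal domain × serial-correlation treatment × chromophore) the
sweep:

1. optionally motion-corrects the ΔOD data (targeted PCA),
2. applies the filter in the requested domain (directly on concentrations,
   or on ΔOD followed by conversion back to concentration),
3. estimates the task β per channel by OLS with the requested correction,
4. collapses to subject medians and computes the group statistics against
   the reference β.

Unstable IIR designs are recorded as skipped rather than applied. Ranking
orders stable specifications by |t| against the reference (default), by
closeness of p to the 0.05 threshold, or by absolute group bias; ties break
toward lower order, then narrower passband.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SubjectRecording
from .filters import FilterSpec, check_stability, design_filter
from .glm import CORRECTIONS, HemodynamicGLM
from .group import GroupResult, group_result, subject_median
from .mbll import MBLLParams, conc_from_od, od_from_conc
from .motion import MotionParams, tpca_correct
from .protocol import AMPLITUDE_PRESETS, HRFSpec, ProtocolSpec

logger = logging.getLogger("fnirsfilt.sweep")

__all__ = ["SweepRecord", "SweepTable", "run_sweep", "rank_filters"]

DOMAINS = ("conc", "OD")
CHROMOPHORES = ("HbO2", "HbR")


@dataclass
class SweepRecord:
    """Group statistics for one sweep cell (or a skip marker)."""

    amplitude_label: str
    spec: FilterSpec
    signal_domain: str
    correction: str
    chromophore: str
    result: GroupResult = None
    status: str = "ok"
    reason: str = ""
    per_subject_medians: np.ndarray = None


@dataclass
class SweepTable:
    """All sweep records plus provenance for reproducibility."""

    records: list
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "amplitude": r.amplitude_label,
                "spec_id": r.spec.spec_id,
                "characteristic": r.spec.characteristic,
                "family": r.spec.family,
                "order": r.spec.order,
                "fc_low": r.spec.fc_low,
                "fc_high": r.spec.fc_high,
                "domain": r.signal_domain,
                "correction": r.correction,
                "chromophore": r.chromophore,
                "status": r.status,
                "reason": r.reason,
            }
            if r.result is not None:
                row.update(
                    mean_beta=r.result.mean_beta,
                    bias=r.result.bias,
                    abs_bias=abs(r.result.bias),
                    t_stat=r.result.t_stat,
                    t_p=r.result.t_p,
                    df=r.result.df,
                    shapiro_w=r.result.shapiro_w,
                    shapiro_p=r.result.shapiro_p,
                    n_outliers=int(r.result.outlier_flags.sum()),
                    reference_beta=r.result.reference_beta,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _reference_beta(label: str, chromophore: str, amplitudes) -> float:
    for amp in amplitudes:
        if amp.label == label:
            return amp.hbo2_amp if chromophore == "HbO2" else amp.hbr_amp
    raise KeyError(label)


def _filter_recording(
    rec: SubjectRecording,
    coeffs,
    domain: str,
    mbll_params: MBLLParams,
    motion_params: MotionParams = None,
):
    """Filtered concentration matrices (HbO2, HbR), each (n_samples, n_ch)."""
    from .filters import apply_filter

    hbo_cols, hbr_cols = [], []
    for hbo, hbr in rec.channels:
        if domain == "conc":
            hbo_f = apply_filter(coeffs, hbo)
            hbr_f = apply_filter(coeffs, hbr)
        else:  # OD domain: convert, (motion-correct), filter, convert back
            od1, od2 = od_from_conc((hbo, hbr), mbll_params)
            if motion_params is not None:
                stacked = np.column_stack([od1.values, od2.values])
                corrected, _ = tpca_correct(stacked, rec.fs, motion_params)
                od1 = od1.with_values(corrected[:, 0])
                od2 = od2.with_values(corrected[:, 1])
            od1_f = apply_filter(coeffs, od1)
            od2_f = apply_filter(coeffs, od2)
            hbo_f, hbr_f = conc_from_od((od1_f, od2_f), mbll_params)
            hbo_f = hbo.with_values(hbo_f.values)
            hbr_f = hbr.with_values(hbr_f.values)
        hbo_cols.append(hbo_f.values)
        hbr_cols.append(hbr_f.values)
    return np.column_stack(hbo_cols), np.column_stack(hbr_cols)


def run_sweep(
    datasets: dict,
    grid,
    corrections=("none", "downsample", "precolor"),
    domains=("conc",),
    protocol: ProtocolSpec = ProtocolSpec(),
    hrf: HRFSpec = HRFSpec(),
    amplitudes=AMPLITUDE_PRESETS,
    mbll_params: MBLLParams = None,
    motion_params: MotionParams = None,
    provenance: dict = None,
) -> SweepTable:
    """Run the factorial sweep over ``datasets`` (label -> recordings).

    ``motion_params=None`` (default) disables motion correction; it applies
    only in the OD domain when enabled.
    """
    for c in corrections:
        if c not in CORRECTIONS:
            raise ValueError(f"unknown correction {c!r}")
    for d in domains:
        if d not in DOMAINS:
            raise ValueError(f"unknown domain {d!r}")
    mbll_params = mbll_params or MBLLParams()
    records = []
    for spec in grid:
        t0 = time.perf_counter()
        coeffs = design_filter(spec)
        stability = check_stability(coeffs)
        if spec.family == "BW" and not stability.is_stable:
            for label in datasets:
                for domain in domains:
                    for corr in corrections:
                        for chrom in CHROMOPHORES:
                            records.append(
                                SweepRecord(
                                    label, spec, domain, corr, chrom,
                                    status="skipped-unstable",
                                    reason=f"max |pole| = {np.max(stability.pole_magnitudes):.6g}",
                                )
                            )
            logger.info("spec=%s status=skipped-unstable", spec.spec_id)
            continue
        for label, recordings in datasets.items():
            fs = recordings[0].fs
            for domain in domains:
                # filter every subject once per domain, reuse across corrections
                filtered = [
                    _filter_recording(rec, coeffs, domain, mbll_params, motion_params)
                    for rec in recordings
                ]
                for corr in corrections:
                    glm = HemodynamicGLM(protocol=protocol, hrf=hrf, fs=fs, correction=corr)
                    med = {c: [] for c in CHROMOPHORES}
                    for rec, (hbo_mat, hbr_mat) in zip(recordings, filtered):
                        for chrom, mat in (("HbO2", hbo_mat), ("HbR", hbr_mat)):
                            betas = glm.fit(mat).beta_task_
                            med[chrom].append(
                                subject_median(betas, rec.excluded_channels)
                            )
                    for chrom in CHROMOPHORES:
                        ref = _reference_beta(label, chrom, amplitudes)
                        res = group_result(med[chrom], ref)
                        records.append(
                            SweepRecord(
                                label, spec, domain, corr, chrom,
                                result=res,
                                per_subject_medians=np.asarray(med[chrom]),
                            )
                        )
        logger.info(
            "spec=%s status=ok runtime=%.2fs", spec.spec_id, time.perf_counter() - t0
        )
    return SweepTable(records, provenance=provenance or {})


_CRITERIA = ("abs_t", "p_near_alpha", "abs_bias")


def rank_filters(table: SweepTable, criterion: str = "abs_t", subset=None) -> pd.DataFrame:
    """Rank filter specifications by β recovery.

    Scores are aggregated (mean) over all non-skipped records of a
    specification (both chromophores, all amplitudes/corrections present in
    the table); ``subset`` is an optional predicate on :class:`FilterSpec`.
    Ties break toward lower order, then narrower passband.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    rows = {}
    for r in table.records:
        if r.status != "ok" or (subset is not None and not subset(r.spec)):
            continue
        if r.spec.spec_id not in rows:
            rows[r.spec.spec_id] = {"spec": r.spec, "scores": []}
        if criterion == "abs_t":
            rows[r.spec.spec_id]["scores"].append(abs(r.result.t_stat))
        elif criterion == "p_near_alpha":
            rows[r.spec.spec_id]["scores"].append(abs(r.result.t_p - r.result.alpha))
        else:
            rows[r.spec.spec_id]["scores"].append(abs(r.result.bias))
    if not rows:
        raise ValueError("no rankable records in table")
    out = []
    for spec_id, d in rows.items():
        spec = d["spec"]
        width = spec.fc_high - (spec.fc_low or 0.0)
        out.append(
            {
                "spec_id": spec_id,
                "characteristic": spec.characteristic,
                "family": spec.family,
                "order": spec.order,
                "fc_low": spec.fc_low,
                "fc_high": spec.fc_high,
                "score": float(np.mean(d["scores"])),
                "_width": width,
            }
        )
    df = pd.DataFrame(out).sort_values(
        ["score", "order", "_width"], kind="mergesort"
    ).drop(columns="_width").reset_index(drop=True)
    return df
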