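"""Plain-text dataset persistence, report export, and YAML configuration.

A dataset is written as one tab-separated file per subject with columns
``time_s, ch01_HbO2, ch01_HbR, ...`` (concentrations in Molar) plus a JSON
sidecar carrying the sampling rate, seed, protocol timing and amplitude
label. Configuration documents mirror the spec dataclasses field-for-field;
micromolar amplitude values are accepted under ``*_umol`` keys and converted
to Molar at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .core import ChannelSeries, SubjectRecording, molar
from .filters import FilterSpec
from .protocol import AmplitudeSpec, HRFSpec, ProtocolSpec
from .simulate import NoiseSpec

__all__ = [
    "write_recording",
    "read_recording",
    "write_dataset",
    "read_dataset",
    "write_mask_segments",
    "load_config",
    "grid_from_config",
]


def write_recording(rec: SubjectRecording, directory, protocol: ProtocolSpec = None,
                    amplitude_label: str = None) -> Path:
    """Write one subject as TSV + JSON sidecar; returns the TSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = {"time_s": rec.channels[0][0].time}
    for i, (hbo, hbr) in enumerate(rec.channels, start=1):
        cols[f"ch{i:02d}_HbO2"] = hbo.values
        cols[f"ch{i:02d}_HbR"] = hbr.values
    path = directory / f"{rec.subject_id}.tsv"
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10e")
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "seed": rec.seed,
        "n_channels": rec.n_channels,
        "excluded_channels": sorted(rec.excluded_channels),
        "amplitude_label": amplitude_label,
    }
    if protocol is not None:
        sidecar["protocol"] = {
            "n_blocks": protocol.n_blocks,
            "task_dur": protocol.task_dur,
            "rest_dur": protocol.rest_dur,
            "lead_in": protocol.lead_in,
        }
    (directory / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_recording(tsv_path) -> SubjectRecording:
    """Read a subject written by :func:`write_recording`."""
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    sidecar = json.loads(tsv_path.with_suffix(".json").read_text())
    fs = float(sidecar["fs"])
    n_ch = int(sidecar["n_channels"])
    channels = []
    for i in range(1, n_ch + 1):
        hbo = ChannelSeries(df[f"ch{i:02d}_HbO2"].to_numpy(), fs=fs, kind="HbO2")
        hbr = ChannelSeries(df[f"ch{i:02d}_HbR"].to_numpy(), fs=fs, kind="HbR")
        channels.append((hbo, hbr))
    return SubjectRecording(
        subject_id=sidecar["subject_id"],
        channels=channels,
        excluded_channels=set(sidecar.get("excluded_channels", [])),
        seed=sidecar.get("seed"),
    )


def write_dataset(datasets: dict, root, protocol: ProtocolSpec = None):
    """Write ``{label: [recordings]}`` under ``root/<label>/``."""
    root = Path(root)
    for label, recordings in datasets.items():
        for rec in recordings:
            write_recording(rec, root / label, protocol=protocol, amplitude_label=label)
    return root


def read_dataset(root) -> dict:
    root = Path(root)
    out = {}
    for label_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        out[label_dir.name] = [
            read_recording(p) for p in sorted(label_dir.glob("*.tsv"))
        ]
    return out


def write_mask_segments(masks: dict, path):
    """Export artifact masks as a (channel, start_s, end_s) TSV."""
    rows = []
    for channel, mask in masks.items():
        for start_s, end_s in mask.segments:
            rows.append({"channel": channel, "start_s": start_s, "end_s": end_s})
    pd.DataFrame(rows, columns=["channel", "start_s", "end_s"]).to_csv(
        path, sep="\t", index=False
    )


def _amplitude_from_dict(d: dict) -> AmplitudeSpec:
    if "hbo2_amp_umol" in d:
        return AmplitudeSpec(molar(d["hbo2_amp_umol"]), molar(d["hbr_amp_umol"]), d["label"])
    return AmplitudeSpec(d["hbo2_amp"], d["hbr_amp"], d["label"])


def load_config(path) -> dict:
    """Load a YAML/JSON config into spec objects.

    Recognized top-level keys: ``protocol``, ``hrf``, ``noise``,
    ``amplitudes`` (list), ``fs``, ``n_subjects``, ``n_channels``,
    ``master_seed``, ``grid``.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out = dict(doc)
    if "protocol" in doc:
        out["protocol"] = ProtocolSpec(**doc["protocol"])
    if "hrf" in doc:
        out["hrf"] = HRFSpec(**doc["hrf"])
    if "noise" in doc:
        nd = dict(doc["noise"])
        if "components" in nd:
            nd["components"] = tuple(tuple(c) for c in nd["components"])
        out["noise"] = NoiseSpec(**nd)
    if "amplitudes" in doc:
        out["amplitudes"] = tuple(_amplitude_from_dict(a) for a in doc["amplitudes"])
    if "grid" in doc:
        out["grid"] = grid_from_config(doc["grid"], fs=doc.get("fs", 5.0))
    return out


def grid_from_config(entries, fs: float = 5.0) -> list:
    """Build a filter grid from a list of spec dictionaries."""
    grid = []
    for e in entries:
        grid.append(
            FilterSpec(
                characteristic=e["characteristic"],
                family=e["family"],
                order=int(e["order"]),
                fc_high=float(e["fc_high"]),
                fc_low=float(e["fc_low"]) if e.get("fc_low") is not None else None,
                fs=float(e.get("fs", fs)),
            )
        )
    return grid


def write_report_tables(table, directory):
    """Export group tables in the benchmark layout (rows = order, columns =
    cut-off band, cells = statistic and p), one CSV per
    (amplitude, characteristic, family, chromophore, correction, statistic).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = table.to_frame()
    ok = df[df.status == "ok"].copy()
    if ok.empty:
        return directory
    ok["band"] = ok.apply(
        lambda r: f"{r.fc_low}-{r.fc_high}" if pd.notna(r.fc_low) else f"{r.fc_high}",
        axis=1,
    )
    for (amp, char, fam, chrom, corr), g in ok.groupby(
        ["amplitude", "characteristic", "family", "chromophore", "correction"]
    ):
        for stat in ("t_stat", "t_p", "shapiro_w", "shapiro_p"):
            pivot = g.pivot_table(index="order", columns="band", values=stat)
            name = f"{amp}_{char}_{fam}_{chrom}_{corr}_{stat}.csv"
            pivot.to_csv(directory / name)
    return directory
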