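"""Delimited-text I/O for simulated trials and synthetic experiments.

Everything is plain text: per-trial CSV tables, a TSV manifest, and JSON
sidecars for parameters and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import STATE_NAMES
from .emg import CHANNELS, EmgTrial
from .lqg import TrialRecord

__all__ = [
    "trial_record_frame",
    "write_trial_record",
    "write_simulation",
    "write_experiment",
    "read_experiment",
]


def trial_record_frame(rec: TrialRecord) -> pd.DataFrame:
    """Tidy table of one simulated trial (true and estimated core states)."""
    cols = {"time_s": rec.time}
    for i, name in enumerate(STATE_NAMES):
        cols[name] = rec.x_true[:, i]
    cols["u"] = rec.u
    for i, name in enumerate(STATE_NAMES):
        cols[f"hat_{name}"] = rec.x_hat[:, i]
    return pd.DataFrame(cols)


def write_trial_record(rec: TrialRecord, path: str | Path) -> None:
    trial_record_frame(rec).to_csv(path, index=False)


def write_simulation(records: list[TrialRecord], out_dir: str | Path) -> Path:
    """Write trial tables plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"trial_{i:04d}.csv"
        write_trial_record(rec, out / fname)
        rows.append({
            "trial": i,
            "condition": rec.events.get("condition", ""),
            "seed": rec.events.get("seed", ""),
            "onset_step": rec.events.get("onset_step", ""),
            "file": fname,
        })
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def _trial_frame(trial: EmgTrial) -> pd.DataFrame:
    cols = {"time_s": trial.time}
    for ch in CHANNELS:
        if ch in trial.emg:
            cols[f"ch_{ch}"] = trial.emg[ch]
    for k, v in trial.kin.items():
        cols[k] = v
    return pd.DataFrame(cols)


def write_experiment(
    trials: list[EmgTrial],
    ground_truth: list[dict],
    out_dir: str | Path,
) -> Path:
    """Write a synthetic experiment: manifest, trial tables, ground truth."""
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tr in enumerate(trials):
        fname = f"trials/trial_{i:04d}.csv"
        # 17 significant digits: exact binary round-trip for float64
        _trial_frame(tr).to_csv(out / fname, index=False, float_format="%.17g")
        row = {
            "trial": i,
            "participant": tr.participant,
            "condition": tr.condition,
            "load_sign": tr.load_sign,
            "file": fname,
        }
        for key in ("onset_s", "latency_s", "cursor_off_s"):
            row[key] = tr.events.get(key, "")
        rows.append(row)
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1)
    return manifest


def read_experiment(out_dir: str | Path) -> tuple[list[EmgTrial], list[dict]]:
    """Read an experiment written by :func:`write_experiment`."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
    trials = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(out / row["file"], float_precision="round_trip")
        emg = {c[3:]: df[c].to_numpy() for c in df.columns if c.startswith("ch_")}
        kin = {c: df[c].to_numpy() for c in df.columns
               if c not in ("time_s",) and not c.startswith("ch_")}
        events = {}
        for key in ("onset_s", "latency_s", "cursor_off_s"):
            val = row.get(key)
            if val is not None and val == val and val != "":
                events[key] = float(val)
        trials.append(EmgTrial(
            participant=str(row["participant"]),
            condition=str(row["condition"]),
            load_sign=str(row["load_sign"]),
            time=df["time_s"].to_numpy(),
            emg=emg,
            kin=kin,
            events=events,
        ))
    gt_path = out / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else []
    return trials, ground_truth
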