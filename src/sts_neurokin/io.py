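"""Plain-text interchange formats.

A trial is stored as two TSV tables sharing t = 0: a marker table
(``time_s`` plus ``<marker>_X/_Y/_Z`` in metres at the kinematic rate) and an
EMG table (``time_s`` plus ``<muscle>_<MI|LI>`` in volts at the EMG rate).
A cohort manifest is a YAML file naming every trial's files and ground-truth
event times.  Group reports round-trip through JSON.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import EMG_CHANNELS, MARKER_NAMES
from .synthetic import Cohort, TrialRecording

__all__ = [
    "write_trial",
    "read_trial",
    "write_cohort",
    "read_cohort",
    "write_curves",
    "read_curves",
    "write_report_json",
    "read_report_json",
]


def write_trial(trial: TrialRecording, directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rep = f"_rep{trial.repetition}" if trial.repetition is not None else ""
    stem = f"{trial.subject_id}_{trial.condition}{rep}"

    cols = {"time_s": trial.t_kin}
    for name in MARKER_NAMES:
        xyz = trial.markers[name]
        for k, axis in enumerate("XYZ"):
            cols[f"{name}_{axis}"] = xyz[:, k]
    markers_path = directory / f"{stem}_markers.tsv"
    pd.DataFrame(cols).to_csv(markers_path, sep="\t", index=False,
                              float_format="%.6f")

    emg_cols = {"time_s": trial.t_emg}
    emg_cols |= {ch: trial.emg[ch] for ch in EMG_CHANNELS}
    emg_path = directory / f"{stem}_emg.tsv"
    pd.DataFrame(emg_cols).to_csv(emg_path, sep="\t", index=False,
                                  float_format="%.9f")
    return markers_path, emg_path


def read_trial(
    markers_path: str | Path,
    emg_path: str | Path,
    subject_id: str,
    condition: str,
    repetition: int | None = None,
) -> TrialRecording:
    mdf = pd.read_csv(markers_path, sep="\t")
    markers = {}
    for name in MARKER_NAMES:
        want = [f"{name}_{axis}" for axis in "XYZ"]
        for col in want:
            if col not in mdf.columns:
                raise ValueError(f"{markers_path}: missing marker column {col!r}")
        markers[name] = mdf[want].to_numpy(dtype=float)
    edf = pd.read_csv(emg_path, sep="\t")
    for ch in EMG_CHANNELS:
        if ch not in edf.columns:
            raise ValueError(f"{emg_path}: missing EMG channel column {ch!r}")
    return TrialRecording(
        subject_id=subject_id,
        condition=condition,
        t_kin=mdf["time_s"].to_numpy(dtype=float),
        markers=markers,
        t_emg=edf["time_s"].to_numpy(dtype=float),
        emg={ch: edf[ch].to_numpy(dtype=float) for ch in EMG_CHANNELS},
        repetition=repetition,
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write every trial plus a YAML manifest with truth event times."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in cohort.trials:
        mp, ep = write_trial(trial, directory)
        entry = {
            "subject": trial.subject_id,
            "condition": trial.condition,
            "repetition": trial.repetition,
            "markers_file": mp.name,
            "emg_file": ep.name,
        }
        if trial.truth is not None:
            entry["true_events"] = [
                {k: float(v) for k, v in ev.items()}
                for ev in trial.truth.event_times
            ]
        entries.append(entry)
    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": cohort.config.n_subjects,
        "n_repetitions": cohort.config.n_repetitions,
        "conditions": list(cohort.config.conditions),
        "kin_rate": cohort.config.kin_rate,
        "emg_rate": cohort.config.emg_rate,
        "trials": entries,
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_cohort(manifest_path: str | Path) -> list[TrialRecording]:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    trials = []
    for entry in manifest["trials"]:
        trials.append(read_trial(
            base / entry["markers_file"], base / entry["emg_file"],
            entry["subject"], entry["condition"], entry.get("repetition")))
    return trials


def write_curves(curves: pd.DataFrame, path: str | Path) -> Path:
    """Per-node curve table in long TSV (the exchange format for the stats stage)."""
    node_cols = [c for c in curves.columns if re.fullmatch(r"v\d+", c)]
    id_cols = [c for c in curves.columns if c not in node_cols]
    long = curves.melt(id_vars=id_cols, value_vars=node_cols,
                       var_name="node", value_name="value")
    long["node"] = long["node"].str.removeprefix("v").astype(int)
    path = Path(path)
    long.sort_values(id_cols + ["node"]).to_csv(path, sep="\t", index=False)
    return path


def read_curves(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    id_cols = [c for c in long.columns if c not in ("node", "value")]
    wide = long.pivot_table(index=id_cols, columns="node", values="value",
                            dropna=False)
    wide.columns = [f"v{c}" for c in wide.columns]
    return wide.reset_index()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [None if np.isnan(x) else float(x) for x in obj.tolist()] \
            if obj.dtype.kind == "f" else obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report_json(report_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report_dict), indent=2))
    return path


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
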