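"""End-to-end orchestration: trials → events → curves → group SPM → report.

Stages per trial: smooth markers, split into repetitions, detect the four STS
events, compute trunk/joint angle curves and EMG envelopes, window each
repetition from 500 ms before Start to 500 ms after End, and time-normalize
to 101 nodes.  EMG curves are then amplitude-normalized per participant,
muscle and side across *all* of that participant's data (both conditions,
all repetitions).  Repetitions are averaged into one representative curve
per subject/side, and each condition gets side-vs-side permutation SPM per
variable with Benjamini–Hochberg FDR within its variable family (hip, knee
and ankle angles; the seven muscles).

A trial whose segmentation fails is flagged and excluded — the pipeline
continues; a subject missing one condition's EMG is excluded from that
condition's EMG comparisons only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import kinematics as kin
from .config import MUSCLES, SIDES, SpmConfig
from .spm import SpmCurveResult, bh_fdr, permutation_inference
from .synthetic import TrialRecording

__all__ = [
    "average_subject_curves",
    "process_trial",
    "run_pipeline",
    "VariableComparison",
    "GroupComparisonReport",
]

KINEMATIC_FAMILY = ("hip", "knee", "ankle")
N_NODES = 101
PAD_MS = 500.0


def average_subject_curves(curves: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Pointwise mean across a subject's repetition curves (the representative curve)."""
    arr = np.atleast_2d(np.asarray(curves, dtype=float))
    if arr.shape[0] == 0:
        raise ValueError("no repetition curves to average")
    return arr.mean(axis=0)


@dataclass
class VariableComparison:
    condition: str
    variable: str
    family: str  # "kinematic" | "emg"
    n: int
    result: SpmCurveResult | None
    min_p: float | None
    fdr_reject: bool = False
    note: str = ""


@dataclass
class GroupComparisonReport:
    comparisons: list[VariableComparison]
    events: pd.DataFrame
    curves: pd.DataFrame
    skipped: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def comparison(self, condition: str, variable: str) -> VariableComparison:
        for c in self.comparisons:
            if c.condition == condition and c.variable == variable:
                return c
        raise KeyError((condition, variable))

    def to_dict(self) -> dict:
        rows = []
        for c in self.comparisons:
            row = {
                "condition": c.condition, "variable": c.variable,
                "family": c.family, "n": c.n, "min_p": c.min_p,
                "fdr_reject": bool(c.fdr_reject), "note": c.note,
            }
            if c.result is not None:
                row["crit"] = c.result.crit
                row["n_permutations"] = c.result.n_permutations
                row["clusters"] = [
                    {"node_start": cl.node_start, "node_end": cl.node_end,
                     "extent": cl.extent, "p": cl.p_value, "sign": cl.sign}
                    for cl in c.result.clusters
                ]
                row["t_curve"] = c.result.t_curve
            rows.append(row)
        return {
            "comparisons": rows,
            "events": self.events.to_dict(orient="records"),
            "skipped": self.skipped,
            "metadata": self.metadata,
        }


def process_trial(
    trial: TrialRecording,
    kin_rate: float,
    emg_rate: float,
    clip_k: float = 5.0,
    clip_window_ms: float = 20.0,
) -> tuple[list[dict], list[dict]]:
    """Segment one recording and extract per-repetition 101-node curves.

    Returns (event rows, curve rows).  Curve rows carry the raw (not yet
    amplitude-normalized) EMG values plus the windowed-segment maximum used
    later as the participant-level normalization divisor.
    """
    smoothed = kin.smooth_markers(trial.markers, kin_rate)
    windows = kin.split_repetitions(smoothed, kin_rate)
    angles = kin.trunk_angles(smoothed) | kin.planar_joint_angles(smoothed)
    envelopes = {
        ch: emg_mod.envelope(
            emg_mod.clip_spikes(trial.emg[ch], emg_rate, clip_k, clip_window_ms),
            emg_rate)
        for ch in trial.emg
    }

    event_rows: list[dict] = []
    curve_rows: list[dict] = []
    for w_idx, window in enumerate(windows):
        rep = trial.repetition if trial.repetition is not None else w_idx
        events = kin.detect_events(smoothed, kin_rate, window,
                                   repetition_index=rep)
        event_rows.append({
            "subject": trial.subject_id, "condition": trial.condition,
            "repetition": rep, "start": events.start, "liftoff": events.liftoff,
            "stand": events.stand, "end": events.end,
            "duration": kin.movement_duration(events),
        })

        def _row(kind, variable, side, values, seg_max=np.nan):
            return {
                "subject": trial.subject_id, "condition": trial.condition,
                "repetition": rep, "kind": kind, "variable": variable,
                "side": side, "seg_max": seg_max,
                **{f"v{i}": values[i] for i in range(N_NODES)},
            }

        for name, curve in angles.items():
            seg = emg_mod.window_trial(curve, kin_rate, events, PAD_MS)
            values = emg_mod.time_normalize(seg, N_NODES)
            if name.startswith("trunk"):
                curve_rows.append(_row("angle", name, "NA", values))
            else:
                variable, side = name.rsplit("_", 1)
                curve_rows.append(_row("angle", variable, side, values))

        for ch, env in envelopes.items():
            seg = emg_mod.window_trial(env, emg_rate, events, PAD_MS)
            values = emg_mod.time_normalize(seg, N_NODES)
            muscle, side = ch.rsplit("_", 1)
            curve_rows.append(
                _row("emg", muscle, side, values, seg_max=float(seg.max())))
    return event_rows, curve_rows


def _normalize_emg(curves: pd.DataFrame) -> pd.DataFrame:
    """Amplitude-normalize EMG rows per (subject, variable, side) across everything."""
    node_cols = [f"v{i}" for i in range(N_NODES)]
    out = curves.copy()
    is_emg = out["kind"] == "emg"
    for (_, _, _), idx in out[is_emg].groupby(
            ["subject", "variable", "side"]).groups.items():
        peak = out.loc[idx, "seg_max"].max()
        if not np.isfinite(peak) or peak <= 0:
            raise ValueError("silent EMG channel during normalization")
        out.loc[idx, node_cols] = out.loc[idx, node_cols] / peak
    return out


def run_pipeline(
    trials: list[TrialRecording],
    kin_rate: float,
    emg_rate: float,
    spm_config: SpmConfig = SpmConfig(),
    exclude_emg: set[tuple[str, str]] | None = None,
    clip_k: float = 5.0,
    clip_window_ms: float = 20.0,
) -> GroupComparisonReport:
    """Run the whole analysis over a set of recordings.

    ``exclude_emg`` lists (subject, condition) pairs whose EMG is unusable;
    those subjects stay in the kinematic comparisons for that condition.
    Deterministic given (trials, configuration).
    """
    exclude_emg = exclude_emg or set()
    event_rows: list[dict] = []
    curve_rows: list[dict] = []
    skipped: list[dict] = []
    for trial in trials:
        try:
            ev, cv = process_trial(trial, kin_rate, emg_rate, clip_k,
                                   clip_window_ms)
        except (kin.SegmentationError, ValueError) as exc:
            skipped.append({
                "subject": trial.subject_id, "condition": trial.condition,
                "repetition": trial.repetition, "reason": str(exc)})
            continue
        event_rows.extend(ev)
        curve_rows.extend(cv)

    events = pd.DataFrame(event_rows)
    curves = pd.DataFrame(curve_rows)
    if curves.empty:
        raise ValueError("no trial could be segmented")
    curves = _normalize_emg(curves)
    node_cols = [f"v{i}" for i in range(N_NODES)]

    conditions = sorted(curves["condition"].unique())
    comparisons: list[VariableComparison] = []
    for condition in conditions:
        sub = curves[curves["condition"] == condition]
        for family, variables in (("kinematic", KINEMATIC_FAMILY),
                                  ("emg", MUSCLES)):
            results: dict[str, VariableComparison] = {}
            for variable in variables:
                rows = sub[(sub["variable"] == variable)]
                if family == "emg":
                    rows = rows[~rows["subject"].isin(
                        {s for s, c in exclude_emg if c == condition})]
                per_side: dict[str, dict[str, np.ndarray]] = {}
                for (subject, side), grp in rows.groupby(["subject", "side"]):
                    per_side.setdefault(subject, {})[side] = \
                        average_subject_curves(grp[node_cols].to_numpy())
                complete = sorted(s for s, d in per_side.items()
                                  if set(d) >= set(SIDES))
                if len(complete) < 2:
                    results[variable] = VariableComparison(
                        condition, variable, family, len(complete), None,
                        None, note="not testable (n < 2)")
                    continue
                more = np.stack([per_side[s]["MI"] for s in complete])
                less = np.stack([per_side[s]["LI"] for s in complete])
                res = permutation_inference(more - less, spm_config)
                results[variable] = VariableComparison(
                    condition, variable, family, len(complete), res,
                    res.min_p)
            testable = {v: c.min_p if c.min_p is not None else 1.0
                        for v, c in results.items() if c.result is not None}
            if testable:
                decision = bh_fdr(testable, alpha=spm_config.alpha)
                for v, rej in zip(decision.variables, decision.reject):
                    results[v].fdr_reject = bool(rej)
            comparisons.extend(results.values())

    return GroupComparisonReport(
        comparisons=comparisons, events=events, curves=curves,
        skipped=skipped,
        metadata={
            "alpha": spm_config.alpha,
            "kin_rate": kin_rate,
            "emg_rate": emg_rate,
            "n_trials": len(trials),
            "n_skipped": len(skipped),
        })
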