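"""Marker smoothing, STS event segmentation and joint/trunk angles.

Events per repetition (full stand-up-and-sit-down cycle):

* **Start** — first instant the anteroposterior (X) C7 speed reaches 10% of
  its in-window peak.
* **Lift-off** — first instant the greater-trochanter markers (left/right
  averaged) cover 10% of their total vertical (Y) displacement.
* **Stand** — C7 vertical apex.
* **End** — last instant the anteroposterior C7 speed is at or above 10% of
  its peak (the moment it falls below and stays below).

"Speed" is the absolute central-difference velocity of the low-pass-filtered
X coordinate; the smoother is applied forward–backward so event timing is
not lag-biased.  Trunk angles are the orientation of the sacrum→C7 vector
projected on the sagittal (X–Y) and frontal (Z–Y) planes, positive forward /
toward +Z.  Hip, knee and ankle angles are planar sagittal-plane
vector angles (not musculoskeletal inverse kinematics): hip = trunk vs
thigh, knee = thigh vs shank, ankle = shank vs foot minus 90° so neutral
standing is 0° dorsiflexion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .config import SIDES

__all__ = [
    "SegmentationError",
    "StsEvents",
    "smooth_markers",
    "split_repetitions",
    "detect_events",
    "movement_duration",
    "trunk_angles",
    "planar_joint_angles",
    "label_phases",
]

#: physical marker prefix per impairment side (right hemiparesis cohort).
SIDE_PREFIX = {"MI": "R", "LI": "L"}

PHASES = ("preparatory", "rising", "lowering", "final")


class SegmentationError(RuntimeError):
    """A repetition could not be segmented (reported and skipped, never imputed)."""


@dataclass(frozen=True)
class StsEvents:
    """Start / Lift-off / Stand / End instants (seconds) for one repetition."""

    start: float
    liftoff: float
    stand: float
    end: float
    repetition_index: int = 0

    def __post_init__(self) -> None:
        if not (self.start < self.liftoff < self.stand < self.end):
            raise SegmentationError(
                f"events out of order: start={self.start:.3f}, "
                f"liftoff={self.liftoff:.3f}, stand={self.stand:.3f}, "
                f"end={self.end:.3f}")


def smooth_markers(
    markers: dict[str, np.ndarray],
    rate: float,
    cutoff_hz: float = 20.0,
    order: int = 4,
) -> dict[str, np.ndarray]:
    """Zero-phase Butterworth low-pass of every marker coordinate."""
    b, a = butter(order, cutoff_hz / (rate / 2.0), btype="low")
    out = {}
    for name, xyz in markers.items():
        if xyz.shape[0] <= 3 * (order + 1):
            raise SegmentationError(f"trajectory too short to filter: {name}")
        out[name] = filtfilt(b, a, xyz, axis=0)
    return out


def split_repetitions(
    markers: dict[str, np.ndarray],
    rate: float,
    min_prominence_frac: float = 0.3,
    min_separation_s: float = 1.0,
) -> list[tuple[int, int]]:
    """Candidate repetition windows, one per standing apex of C7 height.

    Peaks are picked on the C7 vertical coordinate with a prominence of
    ``min_prominence_frac`` of the global vertical excursion; window edges
    are placed midway between consecutive peaks.
    """
    y = markers["C7"][:, 1]
    excursion = float(np.ptp(y))
    if excursion <= 0:
        raise SegmentationError("no movement detected")
    peaks, _ = find_peaks(
        y, prominence=min_prominence_frac * excursion,
        distance=max(1, int(min_separation_s * rate)))
    if peaks.size == 0:
        raise SegmentationError("no movement detected")
    edges = [0] + [int((a + b) // 2) for a, b in zip(peaks[:-1], peaks[1:])]
    edges.append(len(y))
    return list(zip(edges[:-1], edges[1:]))


def _c7_speed(markers: dict[str, np.ndarray], rate: float) -> np.ndarray:
    return np.abs(np.gradient(markers["C7"][:, 0], 1.0 / rate))


def detect_events(
    markers: dict[str, np.ndarray],
    rate: float,
    window: tuple[int, int],
    repetition_index: int = 0,
    sustain_s: float = 0.1,
) -> StsEvents:
    """Detect the four STS events within one repetition window.

    Threshold crossings must be sustained for ``sustain_s`` so that a single
    noisy velocity sample cannot trigger Start/End early; this refinement
    matters only on noisy data (on clean data the first crossing already
    persists).
    """
    i0, i1 = window
    if i1 - i0 < 5:
        raise SegmentationError(f"window too short: {window}")
    t = np.arange(i0, i1) / rate
    speed = _c7_speed(markers, rate)[i0:i1]
    peak = float(speed.max())
    if peak <= 0:
        raise SegmentationError(
            f"flat C7 speed in repetition {repetition_index}: no movement")
    above = speed >= 0.1 * peak
    k = max(1, int(round(sustain_s * rate)))
    start_idx = _first_sustained(above, k)
    end_idx = len(above) - 1 - _first_sustained(above[::-1], k)
    if start_idx is None or end_idx is None:
        raise SegmentationError(
            f"10% speed threshold never sustained in repetition {repetition_index}")

    stand_idx = int(np.argmax(markers["C7"][i0:i1, 1]))

    troch = 0.5 * (markers["RTROC"][i0:i1, 1] + markers["LTROC"][i0:i1, 1])
    disp = float(troch.max() - troch.min())
    if disp <= 0:
        raise SegmentationError(
            f"no trochanter displacement in repetition {repetition_index}")
    crossed = troch >= troch.min() + 0.1 * disp
    lift_rel = _first_sustained(crossed, k)
    if lift_rel is None:
        raise SegmentationError(
            f"lift-off threshold never crossed in repetition {repetition_index}")

    return StsEvents(
        start=float(t[start_idx]),
        liftoff=float(t[lift_rel]),
        stand=float(t[stand_idx]),
        end=float(t[end_idx]),
        repetition_index=repetition_index,
    )


def _first_sustained(mask: np.ndarray, k: int) -> int | None:
    """Index of the first True that begins a run of at least ``k`` Trues."""
    if k <= 1:
        idx = int(np.argmax(mask))
        return idx if mask[idx] else None
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= k:
            return i - k + 1
    return None


def movement_duration(events: StsEvents) -> float:
    """Full-cycle movement time, Start to End, in seconds."""
    return events.end - events.start


def trunk_angles(markers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Sagittal and frontal trunk angles (degrees) from the sacrum→C7 vector.

    theta_sag = atan2(X, Y) (positive = forward flexion);
    theta_front = atan2(Z, Y) (positive = lateral flexion toward +Z).
    """
    v = markers["C7"] - markers["SACR"]
    norm = np.linalg.norm(v, axis=1)
    if np.any(norm == 0):
        raise ValueError("zero-length trunk vector")
    return {
        "trunk_sag": np.rad2deg(np.arctan2(v[:, 0], v[:, 1])),
        "trunk_front": np.rad2deg(np.arctan2(v[:, 2], v[:, 1])),
    }


def _sagittal_angle(v: np.ndarray) -> np.ndarray:
    """Angle of a segment vector from vertical, in the sagittal plane (deg)."""
    return np.rad2deg(np.arctan2(v[:, 0], v[:, 1]))


def planar_joint_angles(markers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-side hip/knee flexion and ankle dorsiflexion (degrees, planar).

    Segments: trunk = SACR→C7, thigh = knee→trochanter, shank = malleolus→
    knee, foot = heel→5th metatarsal.  All angles are differences of
    sagittal-plane segment orientations, so they are invariant to global
    translation.
    """
    trunk = markers["C7"] - markers["SACR"]
    th_trunk = _sagittal_angle(trunk)
    out: dict[str, np.ndarray] = {}
    for side in SIDES:
        p = SIDE_PREFIX[side]
        for m in (f"{p}TROC", f"{p}FEMEPI", f"{p}MALL", f"{p}MET5", f"{p}HEEL"):
            if m not in markers:
                raise KeyError(f"missing marker {m} for side {side}")
        thigh = markers[f"{p}TROC"] - markers[f"{p}FEMEPI"]
        shank = markers[f"{p}FEMEPI"] - markers[f"{p}MALL"]
        foot = markers[f"{p}MET5"] - markers[f"{p}HEEL"]
        th_thigh = _sagittal_angle(thigh)
        th_shank = _sagittal_angle(shank)
        th_foot = _sagittal_angle(foot)
        out[f"hip_{side}"] = th_trunk - th_thigh
        out[f"knee_{side}"] = th_shank - th_thigh
        out[f"ankle_{side}"] = 90.0 - th_foot + th_shank
    return out


def label_phases(
    events: StsEvents,
    seat_contact: float | None = None,
    n_nodes: int = 101,
    pad_s: float = 0.5,
) -> np.ndarray:
    """Phase label for each node of the padded, time-normalized cycle.

    Node 0 maps to ``start - pad_s`` and the last node to ``end + pad_s``.
    Phases: preparatory [start, liftoff], rising [liftoff, stand], lowering
    [stand, seat contact], final [seat contact, end]; the pads take the
    adjacent outer label.  Seat contact defaults to the midpoint of
    [stand, end] when no seat-contact estimate is supplied.
    """
    if seat_contact is None:
        seat_contact = 0.5 * (events.stand + events.end)
    t0 = events.start - pad_s
    t1 = events.end + pad_s
    times = np.linspace(t0, t1, n_nodes)
    labels = np.empty(n_nodes, dtype=object)
    labels[:] = "final"
    labels[times < seat_contact] = "lowering"
    labels[times < events.stand] = "rising"
    labels[times < events.liftoff] = "preparatory"
    return labels


def seat_contact_time(
    markers: dict[str, np.ndarray],
    rate: float,
    window: tuple[int, int],
    events: StsEvents,
) -> float:
    """Seat-contact instant: trochanter height back within 10% of seated baseline.

    Mirrors the Lift-off rule on the descending half of the cycle; used only
    to split the lowering and final phases.
    """
    i0, i1 = window
    troch = 0.5 * (markers["RTROC"][i0:i1, 1] + markers["LTROC"][i0:i1, 1])
    t = np.arange(i0, i1) / rate
    disp = troch.max() - troch.min()
    thr = troch.min() + 0.1 * disp
    stand_rel = int(np.argmax(markers["C7"][i0:i1, 1]))
    below = troch[stand_rel:] <= thr
    if not below.any():
        return 0.5 * (events.stand + events.end)
    return float(t[stand_rel + int(np.argmax(below))])
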