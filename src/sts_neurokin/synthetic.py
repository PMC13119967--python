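"""Synthetic sit-to-stand (STS) trial generator.

Produces motion-capture marker trajectories (100 Hz) and bilateral surface-EMG
channels (1 kHz) for a stand-up-and-sit-back-down cycle, with known
ground-truth events, so the segmentation, envelope and statistical stages can
be exercised without access to recorded data.

Kinematic model
---------------
Each leg is a planar ankle–knee–hip chain in the sagittal (X–Y) plane, feet
fixed on the floor.  While seated (before lift-off and after seat contact)
the hip is pinned at chair height and the knee angle follows from the
commanded ankle dorsiflexion; between lift-off and seat contact the thigh
orientation is interpolated monotonically to vertical (standing) and back.
The trunk is a single segment from the sacrum whose sagittal/frontal
orientation is commanded directly, so the trunk-angle definitions used by the
analysis invert it exactly.  Joint-angle keypoints are drawn per subject from
the configured phase ranges and interpolated with shape-preserving (PCHIP)
cubics, which keeps the hip's vertical rise monotone through the rising
phase.

EMG model
---------
Each muscle's activation envelope is a baseline plus Gaussian bursts at fixed
cycle fractions (major burst near 30%, minor near 70% for the trunk muscles).
The raw signal is that envelope modulating a band-limited (80–300 Hz) noise
carrier, plus broadband sensor noise and optional high-amplitude spike
artifacts.  Side asymmetries scale burst amplitude and/or width on the
more-impaired (MI) side; an optional "surplus" burst confined to a cycle
interval is planted on the MI side only, as a recoverable effect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .config import (
    CONDITIONS,
    EMG_CHANNELS,
    MARKER_NAMES,
    MUSCLES,
    SIDES,
    ConfigurationError,
    GeneratorConfig,
    SurplusSpec,
)

__all__ = [
    "GroundTruth",
    "TrialRecording",
    "Cohort",
    "generate_trial",
    "generate_cohort",
    "inject_spikes",
    "null_difference_curves",
]

# anthropometry (metres); fixed — subject scaling is not the point of the model
L_SHANK = 0.43
L_THIGH = 0.44
L_TRUNK = 0.50
ANKLE_Y = 0.07
HIP_HALF_WIDTH = 0.16

# physical side per impairment label: right hemiparesis -> right = more impaired
SIDE_SIGN = {"MI": +1.0, "LI": -1.0}  # Z points to the right


@dataclass
class GroundTruth:
    """Planted truth for one recording.

    ``event_times`` holds, per repetition, the Start / Lift-off / Stand / End
    instants obtained by applying the event rules to the clean trajectories;
    ``phase_times`` holds the commanded phase-boundary keypoints
    (motion onset, lift-off, stand, seat contact, motion end).
    """

    event_times: list[dict[str, float]]
    phase_times: list[dict[str, float]]
    cycle_duration_s: float
    envelope_model: dict[str, np.ndarray]  # channel -> 101 nodes on the cycle
    commanded_angles: dict[str, np.ndarray]  # e.g. "knee_MI" -> deg vs t_kin
    spike_times: dict[str, np.ndarray] = field(default_factory=dict)
    planted_surplus: tuple[SurplusSpec, ...] = ()


@dataclass
class TrialRecording:
    """One synchronized STS recording (markers + EMG share t = 0)."""

    subject_id: str
    condition: str
    t_kin: np.ndarray
    markers: dict[str, np.ndarray]  # name -> (n, 3) in metres, X fwd/Y up/Z right
    t_emg: np.ndarray
    emg: dict[str, np.ndarray]  # "<muscle>_<MI|LI>" -> (m,)
    truth: GroundTruth | None = None
    repetition: int | None = None

    def __post_init__(self) -> None:
        if set(self.markers) != set(MARKER_NAMES):
            raise ConfigurationError("marker set must match the 28-marker protocol")
        if set(self.emg) != set(EMG_CHANNELS):
            raise ConfigurationError("EMG channels must match the 14-channel montage")


@dataclass
class Cohort:
    trials: list[TrialRecording]
    manifest: pd.DataFrame
    config: GeneratorConfig


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode()) & 0x7FFFFFFF


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def _subject_params(config: GeneratorConfig, subject_id: str) -> dict:
    """Per-subject kinematic/temporal draws, shared by all the subject's trials."""
    rng = _rng(config.seed, _stable_hash(subject_id), 7919)
    u = rng.uniform
    base_off = config.ankle_side_offset_deg
    return {
        "cycle_duration_s": u(*config.cycle_duration_range),
        "knee0": u(*config.seated_knee_deg),
        "ankle0": u(*config.seated_ankle_deg),
        "trunk_peak": u(*config.trunk_flexion_deg),
        "ankle_extra": u(*config.extra_ankle_dorsi_deg),
        "frontal_amp": u(*config.frontal_osc_deg),
        "trunk0": u(4.0, 10.0),
        # per-subject side differences: LI ankle more dorsiflexed in most
        # subjects; a minority hold the LI foot slightly behind (which offsets
        # the knee angle without a group-level knee effect)
        "ankle_side_offset": 0.0 if base_off == 0
        else max(0.0, rng.normal(base_off, 1.0)),
        "li_foot_back_m": u(-0.04, -0.01)
        if (base_off != 0 and rng.random() < 0.3) else 0.0,
    }


def _unit(theta_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal-plane unit vector at ``theta`` degrees from vertical (+Y toward +X)."""
    th = np.deg2rad(theta_deg)
    return np.sin(th), np.cos(th)


def _pchip(knots_t: np.ndarray, knots_v: np.ndarray, t: np.ndarray) -> np.ndarray:
    return PchipInterpolator(knots_t, knots_v)(t)


def _leg_chain(
    t: np.ndarray,
    motion: dict[str, float],
    ankle_deg: np.ndarray,
    ankle_xyz: np.ndarray,
    hip_seated: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Knee and hip joint centres plus knee-flexion curve for one leg.

    Hip pinned at ``hip_seated`` outside [lift-off, seat contact]; thigh
    orientation interpolated to vertical (standing) in between.
    """
    sx, sy = _unit(ankle_deg)
    knee = np.stack(
        [ankle_xyz[0] + L_SHANK * sx, ankle_xyz[1] + L_SHANK * sy,
         np.full_like(sx, ankle_xyz[2])], axis=1)

    # thigh angle from vertical when the hip is pinned on the chair
    dx = hip_seated[0] - knee[:, 0]
    dy = hip_seated[1] - knee[:, 1]
    theta_pin = np.rad2deg(np.arctan2(dx, dy))

    t_lo, t_st, t_sc = motion["liftoff"], motion["stand"], motion["seat_contact"]
    i_lo, i_st, i_sc = (int(np.searchsorted(t, x)) for x in (t_lo, t_st, t_sc))
    theta = theta_pin.copy()
    # airborne: PCHIP through (lift-off pin angle, ~vertical at stand, pin at contact)
    knots_t = np.array([t_lo, t_st, t_sc])
    knots_v = np.array([theta_pin[min(i_lo, len(t) - 1)], -1.0,
                        theta_pin[min(i_sc, len(t) - 1)]])
    seg = slice(i_lo, i_sc)
    if i_sc > i_lo:
        theta[seg] = _pchip(knots_t, knots_v, t[seg])

    tx, ty = _unit(theta)
    hip = np.stack(
        [knee[:, 0] + L_THIGH * tx, knee[:, 1] + L_THIGH * ty, knee[:, 2]], axis=1)
    knee_flex = ankle_deg - theta
    return knee, hip, knee_flex


def _angle_profiles(
    config: GeneratorConfig, params: dict, t: np.ndarray, motion_start: float,
    duration: float, rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Commanded ankle-dorsiflexion and trunk-angle curves over one repetition."""
    f1, f2, f3, _ = config.phase_fractions
    t_lo = motion_start + f1 * duration
    t_st = motion_start + (f1 + f2) * duration
    t_sc = motion_start + (f1 + f2 + f3) * duration
    t_end = motion_start + duration
    jit = lambda: rng.uniform(-1.5, 1.5)  # small per-repetition keypoint jitter, deg

    pads = [t[0] - 1.0, t[0]]
    tails = [t[-1], t[-1] + 1.0]
    knots_t = np.array(pads + [motion_start, t_lo, t_st, t_sc, t_end] + tails)

    a0, ax = params["ankle0"], params["ankle_extra"]
    ankle = np.array(
        [a0, a0, a0, a0 + ax + jit(), 1.0, a0 + 0.8 * ax + jit(), a0, a0, a0])
    th0, thp = params["trunk0"], params["trunk_peak"]
    trunk = np.array(
        [th0, th0, th0, th0 + thp + jit(), 4.0, th0 + 0.75 * thp + jit(), th0,
         th0, th0])
    out = {
        "ankle": _pchip(knots_t, ankle, t),
        "trunk_sag": _pchip(knots_t, trunk, t),
    }
    # frontal-plane lateral sway toward the less-impaired (-Z) side, < 10 deg
    u = np.clip((t - motion_start) / duration, 0.0, 1.0)
    out["trunk_front"] = -params["frontal_amp"] * np.sin(np.pi * u) ** 2
    return out


def _band_limited_carrier(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean unit-RMS noise carrier band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    x = filtfilt(b, a, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _envelope_value(
    frac: np.ndarray, muscle: str, side: str, config: GeneratorConfig,
    amp_jit: float = 1.0,
) -> np.ndarray:
    """Model activation envelope as a function of cycle fraction in [0, 1]."""
    amp_mult, dur_mult = (config.asymmetry_for(muscle) if side == "MI" else (1.0, 1.0))
    env = np.full_like(frac, config.emg_baseline, dtype=float)
    inside = (frac >= 0.0) & (frac <= 1.0)
    for b in config.bursts.get(muscle, ()):
        w = b.width * dur_mult
        env += np.where(
            inside,
            amp_jit * amp_mult * b.amplitude * np.exp(-0.5 * ((frac - b.center) / w) ** 2),
            0.0,
        )
    if side == "MI":
        for s in config.surplus:
            if s.muscle == muscle:
                env += np.where(
                    inside,
                    amp_jit * s.amplitude * np.exp(-0.5 * ((frac - s.center) / s.width) ** 2),
                    0.0,
                )
    return env


def _rule_events(
    t: np.ndarray, c7: np.ndarray, troch_y: np.ndarray,
) -> dict[str, float]:
    """Apply the four event rules to clean trajectories by direct scan.

    Start/End: first/last instant the anteroposterior C7 speed is at or above
    10% of its peak; Lift-off: first instant the (averaged) trochanter height
    covers 10% of its total vertical displacement; Stand: C7 apex.
    """
    dt = t[1] - t[0]
    speed = np.abs(np.gradient(c7[:, 0], dt))
    peak = speed.max()
    above = speed >= 0.1 * peak
    start = t[int(np.argmax(above))]
    end = t[len(above) - 1 - int(np.argmax(above[::-1]))]
    stand = t[int(np.argmax(c7[:, 1]))]
    disp = troch_y.max() - troch_y.min()
    lift = t[int(np.argmax(troch_y >= troch_y.min() + 0.1 * disp))]
    return {"start": float(start), "liftoff": float(lift),
            "stand": float(stand), "end": float(end)}


def generate_trial(
    config: GeneratorConfig,
    subject_id: str,
    condition: str,
    seed: int | None = None,
    n_repetitions: int = 1,
    repetition: int | None = None,
) -> TrialRecording:
    """Generate one synchronized recording with ``n_repetitions`` STS cycles.

    ``seed`` overrides the substream derived from ``config.seed``; per-subject
    kinematic parameters depend only on (config.seed, subject_id) so that all
    of a subject's trials share anthropometry and pace.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    params = _subject_params(config, subject_id)
    base = seed if seed is not None else config.seed
    rng = _rng(base, _stable_hash(subject_id), CONDITIONS.index(condition),
               repetition or 0)

    duration = params["cycle_duration_s"]
    rest = config.rest_s
    rep_len = rest + duration + rest
    total = n_repetitions * rep_len
    n_kin = int(round(total * config.kin_rate)) + 1
    t = np.arange(n_kin) / config.kin_rate
    n_emg = int(round(total * config.emg_rate)) + 1
    t_emg = np.arange(n_emg) / config.emg_rate

    # ---- commanded angles (concatenated repetitions) -----------------------
    ankle_cmd = {s: np.empty(n_kin) for s in SIDES}
    trunk_sag = np.empty(n_kin)
    trunk_front = np.empty(n_kin)
    phase_times: list[dict[str, float]] = []
    f1, f2, f3, _ = config.phase_fractions
    for r in range(n_repetitions):
        t0 = r * rep_len
        t1 = (r + 1) * rep_len
        m = (t >= t0) & (t < t1) if r < n_repetitions - 1 else (t >= t0)
        ms = t0 + rest
        prof = _angle_profiles(config, params, t[m], ms, duration, rng)
        trunk_sag[m] = prof["trunk_sag"]
        trunk_front[m] = prof["trunk_front"]
        for side in SIDES:
            ankle_cmd[side][m] = prof["ankle"]
        phase_times.append({
            "motion_start": ms,
            "liftoff": ms + f1 * duration,
            "stand": ms + (f1 + f2) * duration,
            "seat_contact": ms + (f1 + f2 + f3) * duration,
            "motion_end": ms + duration,
        })

    # ---- forward kinematics ------------------------------------------------
    markers: dict[str, np.ndarray] = {}
    hip = {}
    knee = {}
    knee_flex = {}
    for side in SIDES:
        z = SIDE_SIGN[side] * HIP_HALF_WIDTH
        x_off = 0.0 if side == "MI" else params["li_foot_back_m"]
        ankle_xyz = np.array([x_off, ANKLE_Y, z])
        th0 = params["ankle0"] - params["knee0"]
        sx0, sy0 = _unit(np.array(params["ankle0"]))
        tx0, ty0 = _unit(np.array(th0))
        hip_seated = np.array([
            ankle_xyz[0] + L_SHANK * sx0 + L_THIGH * tx0,
            ankle_xyz[1] + L_SHANK * sy0 + L_THIGH * ty0,
            z,
        ])
        kn, hp, kf = [], [], []
        for r in range(n_repetitions):
            t0, t1 = r * rep_len, (r + 1) * rep_len
            m = (t >= t0) & (t < t1) if r < n_repetitions - 1 else (t >= t0)
            motion = phase_times[r]
            k, h, f = _leg_chain(t[m], motion, ankle_cmd[side][m], ankle_xyz,
                                 hip_seated)
            kn.append(k); hp.append(h); kf.append(f)
        knee[side] = np.concatenate(kn)
        hip[side] = np.concatenate(hp)
        knee_flex[side] = np.concatenate(kf)

        sx, sy = _unit(ankle_cmd[side])
        prefix = "R" if SIDE_SIGN[side] > 0 else "L"
        mall = np.tile(ankle_xyz, (n_kin, 1))
        markers[f"{prefix}MALL"] = mall
        heel = mall + [-0.06, -0.04, 0.0]
        markers[f"{prefix}HEEL"] = heel
        # LI foot slightly inclined (toes up): raises the measured ankle
        # dorsiflexion on that side without perturbing the leg chain
        tilt = 0.0 if side == "MI" else np.deg2rad(params["ankle_side_offset"])
        fx, fy = 0.21, 0.0
        foot_vec = [fx * np.cos(tilt) - fy * np.sin(tilt),
                    fx * np.sin(tilt) + fy * np.cos(tilt),
                    SIDE_SIGN[side] * 0.02]
        markers[f"{prefix}MET5"] = heel + foot_vec
        shank_dir = np.stack([sx, sy, np.zeros(n_kin)], axis=1)
        markers[f"{prefix}FIBHEAD"] = mall + 0.90 * L_SHANK * shank_dir
        markers[f"{prefix}SHANKBAR"] = (
            mall + 0.50 * L_SHANK * shank_dir + [0.0, 0.0, SIDE_SIGN[side] * 0.04])
        markers[f"{prefix}FEMEPI"] = knee[side] + [0.0, 0.0, SIDE_SIGN[side] * 0.05]
        markers[f"{prefix}THIGHBAR"] = (
            0.5 * (knee[side] + hip[side]) + [0.0, 0.0, SIDE_SIGN[side] * 0.05])
        markers[f"{prefix}TROC"] = hip[side] + [0.0, 0.0, SIDE_SIGN[side] * 0.05]

    pelvis = 0.5 * (hip["MI"] + hip["LI"])
    sacr = pelvis + [-0.10, 0.05, 0.0]
    markers["SACR"] = sacr
    for side in SIDES:
        prefix = "R" if SIDE_SIGN[side] > 0 else "L"
        markers[f"{prefix}ASIS"] = pelvis + [0.12, 0.05, SIDE_SIGN[side] * 0.12]

    tan_s = np.tan(np.deg2rad(trunk_sag))
    tan_f = np.tan(np.deg2rad(trunk_front))
    v = np.stack([tan_s, np.ones(n_kin), tan_f], axis=1)
    v *= L_TRUNK / np.linalg.norm(v, axis=1, keepdims=True)
    c7 = sacr + v
    markers["C7"] = c7
    markers["STERN"] = sacr + 0.75 * v + [0.10, 0.0, 0.0]
    markers["HEAD"] = sacr + 1.25 * v
    for side in SIDES:
        zs = SIDE_SIGN[side]
        acro = c7 + [0.02, -0.03, zs * 0.18]
        markers[f"{'R' if zs > 0 else 'L'}ACRO"] = acro
        elb = acro + [0.03, -0.28, zs * 0.02]
        markers[f"{'R' if zs > 0 else 'L'}ELB"] = elb
        if condition == "crossed_arms":
            wrist = markers["STERN"] + [0.05, -0.06, -zs * 0.05]
        else:
            wrist = elb + [0.18, -0.16, 0.0]
        markers[f"{'R' if zs > 0 else 'L'}WRIST"] = wrist

    # ---- ground-truth events on the clean trajectories ---------------------
    troch_y = 0.5 * (markers["RTROC"][:, 1] + markers["LTROC"][:, 1])
    event_times = []
    for r in range(n_repetitions):
        t0, t1 = r * rep_len, (r + 1) * rep_len
        m = (t >= t0) & (t < t1) if r < n_repetitions - 1 else (t >= t0)
        event_times.append(_rule_events(t[m], c7[m], troch_y[m]))

    # ---- EMG ---------------------------------------------------------------
    cond_gain = 1.15 if condition == "crossed_arms" else 1.0
    frac = np.full(n_emg, -1.0)
    for r in range(n_repetitions):
        ms = phase_times[r]["motion_start"]
        u = (t_emg - ms) / duration
        sel = (u >= 0.0) & (u <= 1.0)
        frac[sel] = u[sel]
    emg: dict[str, np.ndarray] = {}
    spike_times: dict[str, np.ndarray] = {}
    env_model: dict[str, np.ndarray] = {}
    nodes = np.linspace(0.0, 1.0, 101)
    for muscle in MUSCLES:
        amp_jit = float(rng.uniform(0.85, 1.15))
        for side in SIDES:
            ch = f"{muscle}_{side}"
            env = cond_gain * _envelope_value(frac, muscle, side, config, amp_jit)
            env_model[ch] = cond_gain * _envelope_value(nodes, muscle, side, config)
            carrier = _band_limited_carrier(n_emg, config.emg_rate,
                                            config.carrier_band, rng)
            raw = env * carrier
            if config.emg_noise_sd > 0:
                raw = raw + (config.emg_noise_sd * env.max()
                             * rng.standard_normal(n_emg))
            if config.spike_rate > 0:
                raw, idx = inject_spikes(
                    raw, config.spike_rate, config.spike_amplitude_factor,
                    config.emg_rate, rng)
                spike_times[ch] = t_emg[idx]
            else:
                spike_times[ch] = np.empty(0)
            emg[ch] = raw

    if config.marker_noise_sd_m > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, config.marker_noise_sd_m, size=markers[name].shape)

    commanded = {f"knee_{s}": knee_flex[s] for s in SIDES}
    commanded |= {
        "ankle_MI": ankle_cmd["MI"],
        "ankle_LI": ankle_cmd["LI"] + params["ankle_side_offset"],
    }
    commanded |= {"trunk_sag": trunk_sag, "trunk_front": trunk_front}
    truth = GroundTruth(
        event_times=event_times,
        phase_times=phase_times,
        cycle_duration_s=duration,
        envelope_model=env_model,
        commanded_angles=commanded,
        spike_times=spike_times,
        planted_surplus=config.surplus,
    )
    return TrialRecording(
        subject_id=subject_id, condition=condition, t_kin=t, markers=markers,
        t_emg=t_emg, emg=emg, truth=truth, repetition=repetition)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """One recording per (subject, condition, repetition), reproducible from the seed."""
    if config.n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    trials: list[TrialRecording] = []
    rows = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        for condition in config.conditions:
            for rep in range(config.n_repetitions):
                trial = generate_trial(config, subject, condition,
                                       n_repetitions=1, repetition=rep)
                trials.append(trial)
                ev = trial.truth.event_times[0]
                rows.append({
                    "subject": subject, "condition": condition, "repetition": rep,
                    "cycle_duration_s": trial.truth.cycle_duration_s,
                    **{f"true_{k}": v for k, v in ev.items()},
                })
    manifest = pd.DataFrame(rows)
    return Cohort(trials=trials, manifest=manifest, config=config)


def inject_spikes(
    signal: np.ndarray,
    rate: float,
    amplitude_factor: float,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Overwrite Poisson-distributed samples with high-amplitude artifacts.

    Each spike is set to ``±amplitude_factor`` times the channel's robust SD
    (1.4826 × median absolute deviation), i.e. well above the downstream
    clipping threshold.  Returns the modified copy and the spike indices.
    """
    if rate < 0:
        raise ConfigurationError("spike rate must be >= 0")
    out = np.asarray(signal, dtype=float).copy()
    if rate == 0 or out.size == 0:
        return out, np.empty(0, dtype=int)
    n_spikes = rng.poisson(rate * out.size / fs)
    if n_spikes == 0:
        return out, np.empty(0, dtype=int)
    idx = np.sort(rng.choice(out.size, size=min(n_spikes, out.size), replace=False))
    robust_sd = 1.4826 * np.median(np.abs(out - np.median(out)))
    if robust_sd == 0:
        robust_sd = np.std(out) or 1.0
    signs = rng.choice([-1.0, 1.0], size=idx.size)
    out[idx] = signs * amplitude_factor * robust_sd
    return out, idx


def null_difference_curves(
    n_subjects: int,
    rng: np.random.Generator,
    n_nodes: int = 101,
    noise_sd: float = 0.1,
    smooth_sd: float = 3.0,
) -> np.ndarray:
    """Paired difference curves under the null of exchangeable sides.

    Both sides share a smooth subject-specific profile; each side adds
    independent smooth noise, so the MI−LI difference is exchangeable in sign.
    Used for Type-I-error simulations of the curve-level statistics.
    """
    from scipy.ndimage import gaussian_filter1d

    def smooth_noise(size):
        w = gaussian_filter1d(rng.standard_normal(size), smooth_sd, axis=-1,
                              mode="nearest")
        return noise_sd * w / np.std(w, axis=-1, keepdims=True)

    more = smooth_noise((n_subjects, n_nodes))
    less = smooth_noise((n_subjects, n_nodes))
    return more - less
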