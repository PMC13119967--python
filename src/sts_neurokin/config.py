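"""Configuration objects and the fixed experimental vocabulary.

The marker set is the 22-marker Davis lower-body protocol plus six auxiliary
markers (sternum, head, bilateral elbow and wrist), and the EMG montage is a
bilateral seven-muscle trunk/gluteal set — latissimus dorsi (LD), erector
spinae iliocostalis (ESI) and longissimus (ESL), external oblique (OEA),
multifidus (MF), gluteus medius (GMED) and gluteus maximus (GMAX) — giving
14 channels.  The global frame is Y up, X forward, Z to the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MUSCLES",
    "SIDES",
    "CONDITIONS",
    "MARKER_NAMES",
    "EMG_CHANNELS",
    "ConfigurationError",
    "BurstSpec",
    "SurplusSpec",
    "GeneratorConfig",
    "SpmConfig",
]

MUSCLES = ("LD", "ESI", "ESL", "OEA", "MF", "GMED", "GMAX")

#: more-impaired ("MI", hemiparetic) vs less-impaired ("LI") body side.
SIDES = ("MI", "LI")

CONDITIONS = ("crossed_arms", "free_arms")

_BILATERAL = (
    "ACRO",      # acromion
    "ASIS",      # anterior superior iliac spine
    "TROC",      # greater trochanter
    "THIGHBAR",  # mid-thigh wand marker
    "FEMEPI",    # lateral femoral epicondyle
    "FIBHEAD",   # fibular head
    "SHANKBAR",  # mid-shank wand marker
    "MALL",      # lateral malleolus
    "MET5",      # fifth metatarsal head
    "HEEL",      # heel
    "ELB",       # lateral humeral epicondyle
    "WRIST",     # ulnar styloid
)

#: 28 marker names: C7, sacrum, sternum, head + 12 bilateral landmarks (R/L).
MARKER_NAMES = tuple(
    ["C7", "SACR", "STERN", "HEAD"]
    + [f"{side}{name}" for name in _BILATERAL for side in ("R", "L")]
)

#: 14 EMG channel names, `<muscle>_<MI|LI>`.
EMG_CHANNELS = tuple(f"{m}_{s}" for m in MUSCLES for s in SIDES)


class ConfigurationError(ValueError):
    """Raised when a generator or analysis configuration is invalid."""


@dataclass(frozen=True)
class BurstSpec:
    """One Gaussian activation burst on the normalized movement cycle.

    ``center`` and ``width`` are cycle fractions (width is the Gaussian SD);
    ``amplitude`` is relative to the muscle's strongest burst.
    """

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class SurplusSpec:
    """Extra activation planted on the more-impaired side only."""

    muscle: str
    center: float = 0.65
    width: float = 0.07
    amplitude: float = 0.4


# Default burst structure per muscle: erector spinae group, latissimus dorsi
# and multifidus carry a major burst near 30% of the cycle and a smaller one
# near 70%; the external oblique is flatter with early/late bursts; gluteus
# medius is broadly active around 30% and gluteus maximus peaks near 40%.
DEFAULT_BURSTS: dict[str, tuple[BurstSpec, ...]] = {
    "LD": (BurstSpec(0.30, 0.06, 1.0), BurstSpec(0.70, 0.08, 0.6)),
    "ESI": (BurstSpec(0.30, 0.06, 1.0), BurstSpec(0.70, 0.08, 0.6)),
    "ESL": (BurstSpec(0.30, 0.06, 1.0), BurstSpec(0.70, 0.08, 0.6)),
    "OEA": (BurstSpec(0.15, 0.08, 0.5), BurstSpec(0.85, 0.08, 0.4)),
    "MF": (BurstSpec(0.30, 0.06, 1.0), BurstSpec(0.70, 0.08, 0.6)),
    "GMED": (BurstSpec(0.30, 0.12, 1.0),),
    "GMAX": (BurstSpec(0.40, 0.08, 1.0),),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world for the synthetic sit-to-stand cohort generator.

    Defaults mirror the acquisition protocol being emulated: five consecutive
    repetitions per condition, markers at 100 Hz, EMG at 1 kHz, movement
    durations drawn per subject from 2–8 s, phases at 20/30/30/20% of the
    cycle, and trunk-muscle bursts near 30% and 70% of the cycle.
    """

    n_subjects: int = 7
    n_repetitions: int = 5
    conditions: tuple[str, ...] = CONDITIONS
    kin_rate: float = 100.0
    emg_rate: float = 1000.0
    cycle_duration_range: tuple[float, float] = (2.0, 8.0)
    phase_fractions: tuple[float, float, float, float] = (0.20, 0.30, 0.30, 0.20)
    rest_s: float = 1.5  # seated rest before/after each repetition (>= 1 s)

    # kinematic keypoint ranges, degrees (uniform per-subject draws)
    seated_knee_deg: tuple[float, float] = (85.0, 95.0)
    seated_ankle_deg: tuple[float, float] = (5.0, 15.0)
    trunk_flexion_deg: tuple[float, float] = (20.0, 45.0)  # peak at lift-off
    extra_ankle_dorsi_deg: tuple[float, float] = (3.0, 8.0)
    frontal_osc_deg: tuple[float, float] = (2.0, 8.0)  # < 10 deg
    ankle_side_offset_deg: float = 3.0  # LI foot slightly more dorsiflexed

    # EMG model
    bursts: dict[str, tuple[BurstSpec, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BURSTS)
    )
    emg_baseline: float = 0.02
    carrier_band: tuple[float, float] = (80.0, 300.0)
    side_asymmetry: dict[str, dict[str, float]] = field(default_factory=dict)
    surplus: tuple[SurplusSpec, ...] = ()

    # noise / artifacts
    marker_noise_sd_m: float = 0.0005
    emg_noise_sd: float = 0.05
    spike_rate: float = 0.1  # spikes per second
    spike_amplitude_factor: float = 10.0

    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phase_fractions) != 4:
            raise ConfigurationError("phase_fractions must have four entries")
        if any(f <= 0 for f in self.phase_fractions):
            raise ConfigurationError("phase_fractions must all be positive")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("phase_fractions must sum to 1")
        if self.kin_rate <= 0 or self.emg_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.emg_rate < self.kin_rate:
            raise ConfigurationError("emg_rate must be >= kin_rate")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        lo, hi = self.cycle_duration_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("cycle_duration_range must be positive and ordered")
        if self.spike_rate < 0:
            raise ConfigurationError("spike_rate must be >= 0")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")
        for m in self.side_asymmetry:
            if m not in MUSCLES:
                raise ConfigurationError(f"side_asymmetry for unknown muscle {m!r}")
        for s in self.surplus:
            if s.muscle not in MUSCLES:
                raise ConfigurationError(f"surplus for unknown muscle {s.muscle!r}")

    def asymmetry_for(self, muscle: str) -> tuple[float, float]:
        """(amplitude, duration) multipliers applied to the MI side."""
        entry = self.side_asymmetry.get(muscle, {})
        return entry.get("amplitude", 1.0), entry.get("duration", 1.0)

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SpmConfig:
    """Settings for the permutation SPM engine.

    ``directional_counting`` keeps the convention under which a saturated
    one-sided effect attains the smallest possible cluster p of 1/2^n; the
    inclusive alternative counts both tails (min p = 2/2^n).
    """

    alpha: float = 0.05
    exhaustive: bool = True
    max_exhaustive: int = 2 ** 20
    n_monte_carlo: int = 10_000
    directional_counting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
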