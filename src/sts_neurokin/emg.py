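"""Surface-EMG conditioning: spike clipping, envelope extraction,
movement windowing, time normalization and amplitude normalization.

The processing order is fixed — clip, band-pass (40–450 Hz FIR), rectify,
low-pass (4 Hz Butterworth) — and the envelope is then cut to a window from
500 ms before movement Start to 500 ms after End, resampled to 101 nodes by
nearest-neighbour lookup (no interpolation: every output value occurs in the
input), and finally scaled by the maximum over all of a participant's data
for that muscle and side, so 1 means "the highest activity observed for
that muscle".
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, firwin, lfilter

from .kinematics import StsEvents

__all__ = [
    "clip_spikes",
    "envelope",
    "window_trial",
    "time_normalize",
    "normalize_amplitude",
]


def robust_sd(x: np.ndarray) -> float:
    """Gaussian-consistent median-absolute-deviation scale estimate."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def clip_spikes(
    raw: np.ndarray,
    fs: float,
    k_sd: float = 5.0,
    window_ms: float = 20.0,
) -> np.ndarray:
    """Replace transient high-amplitude spikes, preserving polarity.

    A sample whose magnitude exceeds ``k_sd`` robust SDs of the channel is
    replaced by sign(x) times the median |x| over the surrounding
    ``window_ms`` window; all other samples are untouched.  An all-zero (or
    constant) channel has a degenerate threshold and is returned unchanged.
    """
    x = np.asarray(raw, dtype=float)
    sd = robust_sd(x)
    if sd == 0:
        return x.copy()
    thr = k_sd * sd
    bad = np.flatnonzero(np.abs(x) > thr)
    out = x.copy()
    half = max(1, int(round(window_ms / 1000.0 * fs / 2)))
    absx = np.abs(x)
    for i in bad:
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = np.sign(x[i]) * np.median(absx[lo:hi])
    return out


def _fir_bandpass(fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    numtaps = int(np.ceil(3 * fs / lo))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return firwin(numtaps, [lo, hi], fs=fs, pass_zero=False, window="hamming")


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with group-delay compensation (reflect-padded)."""
    delay = (len(taps) - 1) // 2
    pad = len(taps)
    ext = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    y = lfilter(taps, 1.0, ext)
    return y[pad + delay : pad + delay + len(x)]


def envelope(
    cleaned: np.ndarray,
    fs: float,
    band: tuple[float, float] = (40.0, 450.0),
    lp_cutoff: float = 4.0,
    lp_order: int = 2,
) -> np.ndarray:
    """Linear envelope: FIR band-pass, full-wave rectification, low-pass.

    The low-pass stage is a Butterworth of the stated design order applied
    forward–backward (zero phase), so the effective roll-off is doubled.
    Requires the band's upper edge below Nyquist (fs > 900 for 450 Hz).
    """
    if fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz cannot support a {band[1]} Hz band edge")
    x = np.asarray(cleaned, dtype=float)
    bp = _zero_phase_fir(x, _fir_bandpass(fs, band))
    rect = np.abs(bp)
    b, a = butter(lp_order, lp_cutoff / (fs / 2.0), btype="low")
    env = filtfilt(b, a, rect)
    return np.clip(env, 0.0, None)


def window_trial(
    signal: np.ndarray,
    fs: float,
    events: StsEvents,
    pad_ms: float = 500.0,
) -> np.ndarray:
    """Cut a signal to [Start − pad, End + pad] at its own sampling rate."""
    pad = pad_ms / 1000.0
    i0 = int(round((events.start - pad) * fs))
    i1 = int(round((events.end + pad) * fs))
    if i0 < 0 or i1 > len(signal):
        raise ValueError(
            f"recording too short for the padded window of repetition "
            f"{events.repetition_index} ({i0}..{i1} vs {len(signal)} samples)")
    return np.asarray(signal[i0:i1], dtype=float)


def time_normalize(segment: np.ndarray, n: int = 101) -> np.ndarray:
    """Resample to ``n`` equally spaced nodes by nearest-neighbour lookup.

    Output node k takes input sample round(k/(n−1)·(L−1)), rounding half away
    from zero, so the first/last outputs equal the first/last inputs and no
    new values are invented.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty segment")
    if seg.size == 1:
        return np.full(n, seg[0])
    pos = np.arange(n) / (n - 1) * (seg.size - 1)
    idx = np.floor(pos + 0.5).astype(int)  # half-away-from-zero for pos >= 0
    return seg[idx]


def normalize_amplitude(curves: list[np.ndarray]) -> list[np.ndarray]:
    """Scale a participant's curves for one muscle/side by their global maximum.

    The divisor is the single maximum over *all* supplied curves (all
    repetitions and conditions), so exactly one sample maps to 1.
    """
    if not curves:
        raise ValueError("no curves to normalize")
    peak = max(float(np.max(c)) for c in curves)
    if peak <= 0:
        raise ValueError("silent channel: maximum amplitude is zero")
    return [np.asarray(c, dtype=float) / peak for c in curves]
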