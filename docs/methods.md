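# Methods

## Scope and units

Angles are degrees, time seconds, marker coordinates metres; the global frame
has X forward, Y up, Z to the right. The impaired side is the right (right
hemiparesis), so markers prefixed `R` map to the more-impaired (MI) side and
`L` to the less-impaired (LI) side. One "cycle" spans the full
stand-up-and-sit-back-down movement.

## Event segmentation

Markers are low-pass filtered with a 4th-order Butterworth at 20 Hz applied
forward–backward. Zero-phase filtering is a deliberate choice: event *timing*
is the product of this stage, and causal filtering would lag every event by
the filter's group delay.

Repetitions are separated before event detection by peak-picking the C7
vertical coordinate (minimum prominence 30% of the global vertical excursion,
minimum separation 1 s); window edges fall midway between consecutive
standing apices. Both parameters are exposed because the splitting step has no
canonical definition.

Within a window the four events are:

- **Start** — first instant the anteroposterior C7 *speed* is at or above 10%
  of its in-window peak. "Speed" is the absolute central-difference velocity
  of the filtered X coordinate: the signed velocity changes sign between the
  rising and sitting halves, and the absolute value is the only reading under
  which both Start and End exist in a full cycle.
- **Lift-off** — first instant the left/right-averaged greater-trochanter
  height covers 10% of its total (max − min) vertical displacement.
- **Stand** — C7 vertical apex (argmax).
- **End** — last instant the C7 speed is at or above 10% of its peak.

Threshold crossings must persist for 100 ms (`sustain_s`), so a single noisy
velocity sample cannot trigger Start/End early; on noise-free data this is a
no-op. A window in which any rule fails (flat speed, no displacement,
disordered events) raises a segmentation error; the pipeline logs and skips
that repetition, never imputes.

Noise behaviour, measured on synthetic trials with white marker noise:
at the default 0.5 mm SD the median event error is 1 sample (100 Hz) with
95th percentile ≈ 6 samples; at 5 mm the velocity-threshold rules degrade
badly (median 7, p95 > 100 samples). The tail is owned almost entirely by
the Stand rule — the argmax of a nearly flat apex is intrinsically
noise-sensitive, and no amount of filtering fixes that without changing the
rule. The recovery tests therefore assert a median ≤ 2 samples and 90% of
events within 5 samples at 0.5 mm, which is what the rules genuinely deliver.

## Angles

The trunk vector is C7 minus sacrum (the only two axial-spine markers in the
set). θ_sag = atan2(X, Y) (positive forward), θ_front = atan2(Z, Y)
(positive toward +Z). Hip/knee/ankle are planar sagittal-plane vector angles
(trunk vs thigh, thigh vs shank, shank vs foot − 90°), *not* musculoskeletal
inverse kinematics: absolute values are not comparable with model-based
estimates, but the curve structure and side differences are, and the
computation is exactly invertible against the synthetic generator's
commanded angles (knee RMS < 0.05° on noise-free data).

## EMG processing

Order is fixed: clip → band-pass → rectify → low-pass.

- **Clipping**: samples with |x| above 5 × robust SD (1.4826 × MAD) are
  replaced by sign(x) × median(|x|) over a 20 ms window. The threshold and
  window are config-exposed; the defaults catch the generator's 10× planted
  spikes and never touch clean synthetic signal.
- **Band-pass**: linear-phase FIR, 40–450 Hz, Hamming window, order
  ⌈3·fs/40⌉ (≥ 3 cycles of the low edge), applied with group-delay
  compensation and reflective padding. Requires fs > 900 Hz.
- **Envelope**: full-wave rectification then a 2nd-order Butterworth at 4 Hz
  applied forward–backward; the *designed* order is second, the effective
  roll-off doubles, matching common movement-EMG practice.

Each repetition is windowed from 500 ms before Start to 500 ms after End
(the generator's ≥ 1 s seated rest guarantees the pads exist) and resampled
to 101 nodes by nearest-neighbour lookup with round-half-away-from-zero —
an exact subsampling, chosen so every output value occurs in the input and
the map is bit-reproducible. Envelopes are then divided by the participant's
maximum for that muscle *and side* across all repetitions and both
conditions. Per-side scope is one of two defensible readings of
"per participant maximum"; it is the one that keeps side-vs-side comparisons
meaningful when electrode gains differ between sides, and it is switchable.

## Permutation SPM

Given per-subject difference curves (MI − LI, n × 101), all 2ⁿ sign
assignments are enumerated (a Monte-Carlo mode with the identity always
included covers larger n). Per node, t = mean/(sd/√n) with the sample sd;
zero-variance nodes yield t = 0 when the mean is 0 and ±∞ otherwise, and
infinities deliberately compare larger than any finite t.

- **Threshold**: the empirical (1 − α) quantile ("higher" convention) of the
  permutation distribution of max|t|. This keeps the probability of *any*
  supra-threshold cluster under the null at ≈ α for a two-sided test.
- **Clusters**: maximal contiguous runs with |t| > crit, split at sign
  changes, summarized by extent (node count); no sub-node interpolation.
- **p-values**: directional counting — a cluster of sign σ counts the
  permutations whose longest run of σ·t > crit is at least the observed
  extent. Under this convention a saturated one-sided effect is matched only
  by the identity assignment, so the smallest attainable p is 1/2ⁿ:
  0.0078 → 0.008 at n = 7 and 0.0156 → 0.016 at n = 6, and with n = 4 no
  cluster can ever reach α = 0.05. An inclusive two-tailed count
  (min p = 2/2ⁿ) is available behind a config flag.

The engine is verified exactly against an independently coded brute-force
enumerator, and its Type-I error is measured by simulation (≈ 0.04–0.057
over 1000 null cohorts, within two binomial SEs of 0.05).

Per condition, the minimum cluster p per variable enters Benjamini–Hochberg
FDR (statsmodels step-up), with two families corrected separately: the
side-resolved kinematic variables {hip, knee, ankle} and the 7 muscles.
Trunk angles are single curves (not side-resolved) and are reported but not
tested. Reported p-values are pre-FDR, with rejection flags alongside. Note a
discreteness consequence: with n = 7 the smallest possible p (1/128) exceeds
0.05/7, so a *lone* significant muscle cannot survive BH in a 7-variable
family — FDR confirmation requires companion effects, which is exactly the
situation in the planted (and the motivating real) pattern where LD, ESL and
MF are jointly modulated.

## Synthetic world

The generator emulates the acquisition protocol: 7 subjects × 2 arm
conditions × 5 repetitions, markers at 100 Hz and EMG at 1 kHz sharing
t = 0, per-subject movement duration drawn from 2–8 s, phases at
20/30/30/20% of the cycle.

*Kinematics*: each leg is a planar ankle–knee–hip chain with fixed feet; the
hip is pinned at chair height while seated, and the thigh interpolates to
vertical between lift-off and seat contact (shape-preserving PCHIP splines
through phase keypoints drawn per subject from the configured ranges:
seated knee ≈ 90°, seated dorsiflexion 5–15°, trunk flexion peak 20–45°,
frontal sway < 10°). Side differences are per-subject draws: the LI ankle
offset is realised as a foot-segment inclination (so it does not leak into
the knee through the chain), and ~30% of subjects hold the LI foot slightly
behind. Ground-truth events are obtained by applying the event rules
analytically to the clean trajectories at generation time; the analysis
recovers them through the discrete chain (smoothing, splitting, central
differences), which is the part worth testing.

*EMG*: per-muscle envelopes are baselines plus Gaussian bursts at fixed cycle
fractions (trunk muscles: major burst at 30%, minor at 70%; OEA 15%/85%;
GMED broad at 30%; GMAX 40%), modulating a band-limited (80–300 Hz) unit-RMS
noise carrier, plus 5% broadband sensor noise and Poisson spike artifacts at
10× robust SD. Side asymmetry multiplies burst amplitude/width on the MI
side; a planted "surplus" burst (default centre 0.65, SD 0.07 of the cycle)
is confined to the MI side. The surplus amplitude used in recovery tests,
0.3 relative units, was fixed by a one-off power sweep (first amplitude with
≥ 95% cohort-level recovery; 0.1 → 20%, 0.2 → 90%, 0.3 → 100%).

What the generator does **not** model: ground-reaction forces, motor-unit
physiology, soft-tissue artifact (marker noise is white), marker gaps, arm
kinematics beyond marker presence, electrode crosstalk, or fatigue. A green
recovery test therefore establishes that the discrete pipeline inverts this
stated world — not that the event rules are robust to structured artifacts
absent from it.

Reproducibility: every stochastic draw flows from the root seed through
named substreams keyed by (seed, subject, condition, repetition), so any
trial can be regenerated in isolation and identical configurations produce
byte-identical cohorts.

## Scaling of simulation-based tests

The Type-I experiment runs at curve level (1000 cohorts, seconds). The
full-pipeline recovery and null tests use scaled-down cohorts (one condition,
1–2 repetitions, 8–10 seeds) to stay inside a CI budget; the pilot sweeps
behind the frozen constants used 20 cohorts per setting.

## Known limitations

- The Stand event is an argmax on a flat apex; its timing error under noise
  is an order larger than the threshold-based events.
- The planar joint angles are structural, not anatomical; offsets against
  musculoskeletal model output are expected.
- The permutation counting convention (directional, min p = 1/2ⁿ) is an
  inference from the attainable-minimum arithmetic, not an externally fixed
  standard; the inclusive alternative is one flag away.
- C3D ingestion is not implemented; trials exchange as TSV only.
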