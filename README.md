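# sts-neurokin

Analysis pipeline for **sit-to-stand (STS) asymmetry in hemiparetic stroke**,
combining synchronized optical motion capture (28 markers, 100 Hz) and
bilateral surface EMG (7 trunk/gluteal muscles × 2 sides, 1 kHz). It is aimed
at movement-analysis labs that want to quantify *side-dependent* kinematic and
neuromuscular strategies over the whole STS cycle rather than at scalar
summary instants.

The pipeline:

1. **Segmentation** — marker trajectories are smoothed (4th-order zero-phase
   Butterworth, 20 Hz) and each repetition is bounded by four events:
   *Start* (anteroposterior C7 speed reaches 10% of its peak), *Lift-off*
   (greater-trochanter height covers 10% of its total vertical displacement),
   *Stand* (C7 vertical apex) and *End* (C7 speed falls below 10% of peak).
2. **Angles** — trunk orientation from the sacrum→C7 vector,
   θ_sag = atan2(X, Y), θ_front = atan2(Z, Y); planar hip/knee/ankle
   sagittal angles per side.
3. **EMG envelopes** — spike clipping (median replacement, polarity
   preserved), 40–450 Hz FIR band-pass, rectification, 4 Hz Butterworth
   low-pass; windowed from 500 ms before Start to 500 ms after End;
   time-normalized to 101 nodes (nearest neighbour); amplitude-normalized to
   each participant's maximum per muscle and side.
4. **Statistics** — per subject, repetitions are averaged into one
   representative curve per side; the more- vs less-impaired comparison uses
   1D **Statistical Parametric Mapping** with an exhaustive sign-flip
   permutation test: at each node t(k) = mean(d)/(sd(d)/√n) over paired
   differences d, the cluster-forming threshold is the (1−α) quantile of the
   permutation distribution of max|t|, and cluster p-values count
   permutations whose longest sign-matched supra-threshold run is at least
   the observed extent (so the smallest attainable p is 1/2ⁿ).
   Benjamini–Hochberg FDR is applied across variables within each condition.

Because no recordings are distributable, the package includes a first-class
**synthetic cohort generator** (planar leg/trunk chain driven by
phase-keypoint splines; burst-structured EMG on a band-limited carrier) with
planted ground truth for events, angles, artifacts and side effects.

## Worked example

```
python analysis/01_simulate.py        # 70 trials -> scratch/cohort/
python analysis/02_segment_events.py  # events table + truth audit
python analysis/03_group_spm.py       # group SPM + FDR report
python analysis/04_validation.py      # Type-I error / granularity checks
```

On the default simulated cohort (7 subjects, 5 repetitions × 2 conditions,
with a planted more-impaired-side surplus on LD, ESL and MF over 50–80% of
the cycle) the run prints, among others:

```
movement durations: 3.1-6.6 s (median 3.9 s)
event error vs truth: median 0 ms, p95 60 ms
   free_arms  emg  LD   6  0.015625  True  54-56% (p=0.016); 59-62% (p=0.016)
   free_arms  emg  ESL  6  0.015625  True  ... 48-69% (p=0.016)
   free_arms  emg  MF   6  0.015625  True  51-63% (p=0.016)
type-I error rate: 0.040 (bound 0.064) over 1000 cohorts
```

i.e. the planted late-cycle trunk-muscle surplus is recovered as significant
clusters overlapping 50–80% of the cycle (surviving FDR), kinematic ankle
asymmetry is detected, knee/hip stay null, and the free-arms EMG comparisons
run at n = 6 because one subject's EMG is marked unusable in that condition
only. The same library functions are exposed as a CLI
(`sts-neurokin simulate|segment|envelope|compare|run`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch: the empirical whole-curve false-positive rate of
the permutation SPM test over 1000 simulated null cohorts (n = 7), and the
minimum attainable cluster p-values with 7 and 6 paired subjects obtained by
planting a saturated side effect. All numbers are produced by running the
package's own generator and inference engine at the given seed.
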