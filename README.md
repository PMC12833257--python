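# neuroadapt

Multimodal physiological analysis and closed-loop adaptive learning
simulation for AR-assisted special education research.

Children with neurodevelopmental conditions — autism spectrum disorder
(ASD), attention-deficit/hyperactivity disorder (ADHD), and specific
learning disability (SLD) — show distinct physiological signatures during
learning tasks: an elevated frontal theta/beta ratio (TBR) in ADHD, raised
frontal-temporal gamma coherence in ASD, atypical alpha asymmetry and
frequent reading regressions in SLD, and shifted autonomic balance (LF/HF)
across groups. This package implements, as tested library code, the full
analysis chain that turns raw EEG/ECG/eye-tracking recordings into those
markers, fuses them into a disorder classifier, and closes the loop: a
controller that reads the markers every 30 s and adapts task difficulty in
real time, evaluated against therapist-reactive and fixed-schedule
baselines. Because no recordings are publicly deposited, a first-class
synthetic-data module generates seeded multimodal cohorts whose population
statistics match the reference group/condition values, so every stage is
validated by parameter recovery.

## What is inside

| module | contents |
| --- | --- |
| `neuroadapt.signatures` | group × condition physiological target panel (the study conditions) |
| `neuroadapt.synth` | seeded EEG / RR-tachogram / ECG-trace / gaze generators, cohort assembly |
| `neuroadapt.eeg_features` | Welch band powers, TBR composite, alpha asymmetry, MSC coherence with permutation + FDR inference, artifact rejection |
| `neuroadapt.cardiac_features` | Pan–Tompkins R-peak detection, RR artifact correction, time/frequency/entropy HRV |
| `neuroadapt.gaze_features` | I-VT segmentation (30°/s, 60 ms), on-task gaze, reading regressions, microsaccades, pupil variance |
| `neuroadapt.fusion` | feature table, stratified 10×5 nested CV with in-fold top-k selection, 40/35/25 soft-voting ensemble, temporal hold-out |
| `neuroadapt.adaptive` | 30-s state classifier, adaptive/reactive/fixed policies, latent learner simulator, three-condition comparison |
| `neuroadapt.stats` | percent/absolute change, Cohen's d, paired/Welch t, report tables |

Key formulas, in the field's standard notation:

- **TBR** = mean over {Fz, FCz, Cz} of P(4–8 Hz)/P(13–30 Hz), Welch
  estimates with 2-s Hann windows at 50% overlap.
- **Alpha asymmetry** AI = (P_L − P_R)/P_R over homologous site lists, so a
  left hemisphere 28% below the right gives −0.28.
- **MSC** γ²(f) = |S_ab|²/(S_aa·S_bb), band-averaged between region-mean
  signals; inference by circular-shift permutation with
  Benjamini–Hochberg FDR.
- **HRV**: RMSSD, SDNN, pNN50, CV on corrected RR; Welch periodogram of the
  4-Hz cubic-spline tachogram with VLF/LF/HF = 0.003–0.04/0.04–0.15/
  0.15–0.4 Hz; SampEn(m = 2, r = 0.2·SDNN).
- **Controller reward** r = 0.5·Δperformance − 0.3·load penalty +
  0.2·engagement, logged per 30-s window.

## Worked example

Run the numbered drivers in order (each is a thin script over the library;
`analysis/04` expects the feature table written by `analysis/03`):

```
python analysis/01_report_changes.py
python analysis/02_simulate_cohort.py
python analysis/03_extract_features.py
python analysis/04_classify.py
python analysis/05_closed_loop.py
```

`analysis/03` extracts features from a seeded 60-participant cohort and
prints the group-level recoveries:

```
traditional: TBR(ADHD) 3.29 | LF/HF 2.84 | fixation 325 ms | on-task 67% | gamma coh (ASD) 0.71
AR:          TBR(ADHD) 2.51 | LF/HF 1.99 | fixation 252 ms | on-task 84% | gamma coh (ASD) 0.71
```

— the extractors recover the generator targets (ADHD TBR 3.18 → 2.34,
LF/HF 2.83 → 1.92, fixation 342 → 263 ms, on-task 67 → 84%) within
estimator noise, i.e. the full generate → analyze loop is self-consistent.

`analysis/05` compares the three adaptation policies over 18 clinical
profiles × 2 sessions each:

```
items_per_hour         adaptive    6.52  reactive    5.59  fixed    1.96
pct_overload           adaptive    3.95  reactive   15.06  fixed   72.96
detection_latency_s    adaptive   16.00  reactive   71.00  fixed     nan
preventive_pct         adaptive   87.14  reactive    9.08  fixed    0.00
```

The physiological controller detects latent overload within one 30-s
window (~16 s given mid-window onsets), before it manifests behaviorally
(~41 s lag), so most of its adjustments are preventive; the
therapist-reactive policy responds only after manifestation plus a reaction
time (~71 s), and the fixed schedule escalates difficulty regardless of
state and spends most of the session in overload. Absolute items/hour are
smaller than a human classroom because the simulated learner masters at
most one item per window; the orderings and relative gaps are the
meaningful output.

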