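# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Signature panel

All generator targets live in one table (`neuroadapt.signatures`), per
diagnostic group (ASD, ADHD, SLD, TD) and learning condition (traditional
screen-based vs AR). Pooled condition contrasts anchor the
traditional → AR axis: theta power 38.4 ± 7.2 → 27.9 ± 5.8 μV², LF/HF
2.83 ± 0.67 → 1.92 ± 0.45, fixation duration 342 ± 58 → 263 ± 42 ms, pupil
variance 2.14 ± 0.38 → 1.82 ± 0.31 mm², sample entropy 1.23 → 1.48.
Group-level values are obtained by scaling the pooled traditional mean by
each group's share of the cross-group baseline profile (theta: TD 24.3,
ASD 31.2, ADHD 29.8, SLD 28.4 μV²; LF/HF: 1.67/2.24/2.41/2.03) and
applying group-specific AR reductions (theta −23.7/−27.3/−29.1/−25.8%,
LF/HF −27.7/−32.1/−35.8/−30.4%). This construction is internally
consistent: it reproduces the per-group values reported independently
(ASD theta 42.6 → 31.2 μV², TD LF/HF 2.31 → 1.67). Disorder biomarkers are
condition-independent defaults: frontal-temporal gamma coherence
0.68/0.51/0.49/0.42, alpha asymmetry +0.12/+0.08/−0.28/+0.05, reading
regression rate 18/31/42/13%, HRV fluctuation coefficient
0.34/0.71/0.38/0.34 (ADHD 2.1× controls). Where only one group's value is
reported (e.g. ADHD resting TBR 3.18 ± 0.45 → 2.34 ± 0.38), the remaining
groups follow the standard pediatric ordering (TD < ASD ≈ SLD < ADHD);
those fill-ins, the TD regression rate, the RMSSD baseline (42 ms
traditional, +18.4 ms under AR), and the delta/alpha/gamma band-power
defaults are the package's own choices of physiologically typical values.
Between-subject SDs default to the reported group SDs — the only
dispersion information available.

Participant profiles draw each parameter as
`group mean + z · between_subject_SD` with one shared `z` per parameter
across conditions, so individuals keep their rank across conditions (the
within-subject consistency paired analyses rely on). Draws are truncated
to physiological ranges.

## Synthetic recordings

**EEG** is a sum of independent band-limited Gaussian processes per
canonical band (delta 1–4, theta 4–8, alpha 8–12, beta 13–30, gamma
30–45 Hz), synthesized in the frequency domain with the sample variance
normalized to the target power, on a 9-channel desk-scale montage (Fz,
FCz, Cz, F3, F4, C3, C4, T7, T8). Beta power is derived as theta/TBR so
the TBR target is realized exactly in expectation. Left-hemisphere alpha is
scaled by (1 + AI). Gamma coherence is realized by mixing a common source
into frontal and temporal channels; because the analysis averages site
groups before computing MSC, the mixing fraction a² is solved from
`MSC = a⁴ / ((a² + (1−a²)/m_f)(a² + (1−a²)/m_t))` with group sizes
m_f = 3, m_t = 2. Single-channel pairs therefore show lower coherence than
the region-level target — the region level is what the pipeline analyzes.

**RR tachograms** are mean RR plus fixed-frequency carriers at 0.095 Hz
(LF) and 0.275 Hz (HF), a 0.01 Hz VLF drift scaled by the group HRV
coefficient, and white per-beat noise. Carrier amplitudes solve the 2×2
system that fixes both the analyzed LF/HF (including the noise power
landing in each band, approximated as `2·T·σ²` per Hz) and the RMSSD
(`RMSSD² = 4 sin²(πf_LF T) P_LF + 4 sin²(πf_HF T) P_HF + 2σ²`). The
white-noise share of RMSSD² rises monotonically with the sample-entropy
target (ν = 0.15 + 0.3·(SampEn−1)), so AR records are more irregular than
traditional ones; absolute SampEn values are emergent, not controlled, and
are not asserted as recovery targets. Mean heart rate is 98 bpm
(traditional) / 90 bpm (AR), reflecting the ~8 bpm task-related
difference. **ECG traces** place a Gaussian P-QRS-T template (R width
~12 ms) at each R time, with optional white noise at a stated SNR.

**Gaze** is an alternating fixation/saccade renewal process at 1200 Hz:
lognormal fixation durations (SD = 0.17 × mean, a typical oculomotor
dispersion), main-sequence saccade durations (21 ms + 2.2 ms/deg) with
raised-cosine trajectories, AR(1) drift tremor (~0.03° SD), Poisson
microsaccades (0.3–0.5°, 25 ms, peak velocity below the 30°/s I-VT
threshold), and blinks as validity-loss runs inserted *between* fixations
— masking the intervening saccade, as real blinks do, so measured fixation
durations are not split. The blink probability per cycle corrects for
blinks lengthening the cycle. In freeview/social tasks each fixation's
on-task membership is drawn Bernoulli(p_on) up front and the landing point
steered to realize it, making the on-task time fraction unbiased; when no
direction at the drawn amplitude reaches the required region, the point is
placed directly (slightly diluting the amplitude distribution). Reading
lays fixations left-to-right with ~2° forward steps; regressions (~1.8°
leftward) are scheduled by a renewal debt counter so their long-run rate
equals the target even though edge-of-line steps can never regress.
Line-return sweeps change lines (|Δy| > 1°) and are excluded from the
regression statistic, following reading-research convention. On-task
steering is not applied during reading (the regression and on-task targets
would interact); on-task recovery is validated on freeview records.

## Feature extraction

Band powers and coherence use Welch's method with 2-s Hann windows at 50%
overlap (the coherence settings, reused for power, which is not separately
specified); powers are PSD integrals over half-open bands. The TBR
composite averages per-site theta/beta ratios over Fz/FCz/Cz —
per-site-first, the neurofeedback convention. The TBR beta band is
13–30 Hz; 12–30 Hz is treated as a display convention. Alpha asymmetry is
(P_L − P_R)/P_R, chosen so "left 28% below right" maps to −0.28; a
log-ratio variant is exposed. Spectral leakage of neighboring bands under
the Hann taper slightly dilutes measured asymmetry toward zero (~0.02 at
default powers); the index remains monotone in the generated asymmetry.
Coherence inference circularly shifts one region's signal (preserving
autocorrelation, destroying alignment) with p = (1 + #{null ≥ obs})/(1 +
n_perm) and Benjamini–Hochberg correction across region pairs; measured
type-I error at α = 0.05 is ~4–5%. Artifact handling is amplitude-threshold
epoch rejection (2-s epochs, 150 μV default) with the rejected fraction
reported — a deliberate simplification standing in for decomposition-based
cleaning, adequate for synthetic data whose artifacts are injected spikes.

R-peak detection implements the Pan–Tompkins stages (band-pass 5–15 Hz,
derivative, squaring, 150 ms integration, adaptive dual thresholds with
search-back and 200 ms refractory), refined to the band-passed local
maximum. RR correction replaces intervals deviating > 0.25 s from an
11-beat rolling median with cubic-spline interpolants; the
aggressiveness presets of commercial HRV software are unpublished, so the
median rule is the package's own. HRV spectra use the Task-Force
conventions: cubic-spline tachogram resampling at 4 Hz, linear detrend,
Welch with 256-s windows (records shorter than one window degenerate to a
single periodogram — required for 3–6-min desk runs). SampEn uses m = 2,
r = 0.2·SDNN, r floored at 1e-6·mean(RR) for near-constant series; the
vectorized implementation is tested to 1e-10 against an explicit-loop
O(n²) oracle.

I-VT computes velocity from Savitzky–Golay-differentiated positions (20 ms
window, order 2; raw two-point differences at 1200 Hz are
noise-dominated). Sub-75-ms validity losses are interpolated; longer ones
are blinks. Fixations under 60 ms merge into the preceding fixation when
centroids lie within 0.5°, else are discarded; every valid sample ends in
exactly one class, and the event lists are the run-length encoding of the
per-sample label array (exposed for oracle testing). The microsaccade
detector thresholds within-fixation velocity at λ = 6 × the robust
median-SD estimator, floored at 1°/s (numerical velocity noise on clean
data), requiring ≥ 6 samples and displacement in [0.1°, 1°).

## Fusion classification

Features are named `<modality>.<metric>[.<site|band>]`; the default panel
yields 66 features per (participant, condition) row (a desk-scale set; the
reference feature count is an order of magnitude larger because of its
64-channel montage). Evaluation is stratified 10-fold outer CV with
5-fold inner CV per training fold; the inner loop selects the SVM cost
from {0.1, 1, 10, 100, 1000}; median imputation, ANOVA-F top-k selection
(k = 124, capped at the available count) and z-scaling are fitted on
training rows only. The ensemble soft-votes an RBF-SVM (0.40), a
two-hidden-layer feed-forward network with early stopping (0.35; standing
in for an unspecified CNN — inputs here are feature vectors, not time
series), and a 500-tree random forest (0.25); weights renormalize with a
warning if they do not sum to one; ties break by the fixed class order
ASD, ADHD, SLD, TD. The temporal hold-out sequesters the last 20% of
participants by recruitment order (whole participants, never split). With
both conditions in the table, the two rows of one participant could
straddle a fold boundary and leak identity, so the classification analysis
uses one condition per participant.

On the default panel the four groups genuinely overlap (between-subject
SDs equal the reported group SDs), so nested-CV accuracy sits around
70–80% at n = 60 — far above the ~29% prior ceiling but below the
well-separated benchmark (≥ 95% on a cohort with 3-SD class spacing),
which is the machinery check. Human-cohort accuracy figures are not
reproducible from synthetic data and are not asserted.

## Closed-loop simulation

Every 30 s the controller z-scores the emitted TBR against the
participant's resting baseline (individualized thresholds) and classifies
state in the priority order overload > disengagement > fatigue >
under-challenge > optimal, with thresholds overload (TBR z > 1.5 and
LF/HF z > 1.0), under-challenge (TBR z < −0.5, engagement ≥ 0.6),
disengagement (engagement < 0.3), fatigue (engagement trend < −0.02 per
window, engagement < 0.75, elapsed ≥ 25 min, TBR not elevated). The
thresholds are design choices — the states and inputs are given, the
cutoffs are not — and live in one config object. Actions: overload →
−20% difficulty, then modality switch, then a break on consecutive
recurrence (the escalation order is a design choice); under-challenge →
+10% (mirroring the fixed condition's step for comparability); fatigue →
break; disengagement → switch. Difficulty is clamped to [0.1, 3] × base.
A per-window reward r = 0.5·Δperformance − 0.3·load penalty +
0.2·engagement is logged (load enters as a penalty by sign convention); a
tabular ε-greedy Q-learning controller over the 5 states × 5 actions is
available as an optional drop-in for the rule policy.

The learner simulator is invented plumbing with these mechanics: latent
load = logistic((difficulty − skill)/0.3) + 0.5·fatigue + AR(1)
fluctuation noise (stationary SD 0.09; 0.16 for ADHD, whose attention
fluctuates faster — this is what makes physiological early-detection most
valuable there); mastery is Bernoulli per window, peaking (p = 0.075)
when load is inside the ZPD band [0.4, 0.7] and falling off
asymmetrically outside it (σ = 0.15 below, 0.06 above: too-easy material
is still learnable, overload is not), scaled by engagement; skill grows
0.04 per mastered item; fatigue accrues with time and load and recovers
0.25 per break; engagement is an inverted-U in load minus fatigue.
Uncorrected overload is self-perpetuating: a dysregulation state builds
while load exceeds the ZPD ceiling, decays slowly (×0.95 per window) on
its own, suppresses mastery and engagement, and is largely cleared
(×0.25) by any corrective action — the mechanism by which early
intervention pays and delayed intervention costs. Emission gains map load
to TBR z and LF/HF z so that the latent overload boundary (load 0.7)
coincides with the controller's thresholds.

Latent overload onsets are timed at the midpoint of the first window above
the ZPD ceiling; each onset draws a behavioral-manifestation lag
~N(41.2, 17.8) s truncated at 0. The reactive (therapist) policy sees only
behavior: it can act on an episode a reaction time ~N(20, 5) s (floor 5 s)
after manifestation, and skips episodes that have already resolved.
Detection latency attributes the first corrective action within an episode
(plus a 90-s grace) to its onset; unanswered onsets are censored.
Condition order per participant follows a 3×3 Latin square.

At the evaluation scale (18 clinical profiles × 20 sessions per condition)
the comparison reproduces the qualitative pattern: items/hour adaptive >
reactive > fixed (≈ 6.1 > 5.1 > 1.8), overload occupancy adaptive <
reactive < fixed (≈ 4 < 15 < 74%), detection latency ≈ 16 s vs ≈ 70 s
(the latter ≈ lag + reaction, window-quantized), preventive adjustments
≈ 91% vs ≈ 9%. Absolute magnitudes are scaled-down analogues — the
simulated learner masters at most one item per window, and the fixed
schedule's overload fraction is larger than a human classroom's because
the simulator has no teacher-independent coping — but every reported
ordering is a structural consequence of the delay model and the ZPD
mastery mechanics, not of tuned constants: setting the behavioral lag and
reaction time to zero makes reactive behave like the adaptive policy.

## Statistics

Percent change is 100·(post − pre)/pre (rounded to one decimal for
reporting only); Cohen's d is the equal-n pooled form
|m1 − m2|/√((sd1² + sd2²)/2). Recomputing the reference contrast's theta
effect size from its own means and SDs gives d = 1.606 where the source
table prints 1.62; the package asserts its own formula and treats printed
effect sizes as report-only. Paired and Welch t statistics use the
standard closed forms with two-sided p from the t distribution;
Monte-Carlo type-I error under the null is calibrated at α = 0.05.

## Problem sizes and limitations

Validation sizes are chosen for a single-CPU workflow: 60-s EEG at 256 Hz,
3–6-min tachograms, 1–5-min gaze records, cohorts of 48–100, 20-seed
recovery batteries, 1080 simulated sessions. The synthetic cohort captures
population means, dispersions, and cross-parameter group structure, but
not volume conduction, non-stationarity, real artifact morphology,
medication or session effects, or within-session learning in the
recordings themselves; passing recovery tests therefore demonstrates
estimator correctness and pipeline self-consistency, not clinical
validity. The montage is 9 channels, so source localization and dense
connectivity are out of scope, and scalp-site proxies (frontal vs temporal
site groups) stand in for anatomical region pairs. A "DLD" group that
appears in some reference figures is not defined in its methods and is not
generated; the classifier accepts extra labels via configuration.
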