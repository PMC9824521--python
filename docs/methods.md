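# Methods

## Signal model

Wrist-worn trackers report heart rate (bpm) on a coarse cadence — nominally
every 15 s — rather than beat-by-beat intervals. Each sample is mapped to an
equivalent R-R interval, RRI = 60000 / bpm in milliseconds, so "RRI" here is
a per-sample quantity, not a per-beat one; rapid beat-level variability is
below the sensor's resolution by construction.

Consecutive RRI pairs (RRI(t), RRI(t+1)) are summarised by the Lorenz
(Poincaré) ellipse. Each pair (a, b) is projected onto the identity axis,
u = (a+b)/√2, and the anti-identity axis, v = (a−b)/√2; δx and δ(−x) are the
standard deviations of u and v, and the ellipse area is S = π·δx·δ(−x).
Two conventions are deliberately fixed and isolated as constants:

* **Divisor.** Population (n) standard deviations, consistent with the
  classical moment definitions of the Poincaré SD1/SD2 descriptors. The
  module constant `SD_DDOF` flips this to the sample convention.
* **Centering.** Spreads are taken about the projections' own means. The
  alternative (RMS about the origin) would conflate mean asymmetry with
  spread and break the property that a constant series has area 0.
* **Gap rule.** Pairs are only formed between samples at most `max_gap`
  apart (default 30 s = two nominal periods), so sensor dropouts and
  activity-interval boundaries never produce spurious "consecutive" pairs.
  When one activity occurs in several intervals, pairs are built per
  occurrence segment and pooled; no pair crosses segments.

With fewer than two pairs (or samples) the statistics are reported as an
explicit *undefined* marker (`None` at the API level, NaN + mask in feature
tables), never as silently propagating NaN.

## Windows and anchoring

Two aggregation windows feed the features: the 24 h ending at the
questionnaire answer time, and the 4 h after waking. Waking is defined as
the end of the last sleeping interval finishing between 00:00 and 14:00
local time; a morning without such an interval leaves the post-wake
features missing. For the *morning* questionnaire the post-wake window uses
the **previous** day's wake — this morning's 4 h have not happened yet —
while the night questionnaire uses the same day's wake. Both windows are
therefore strictly pre-questionnaire, and a test perturbs post-anchor data
to prove no feature changes. When the answers file lacks timestamps, the
morning answer is anchored at wake and the night answer at bedtime.
Intervals are half-open [start, end) in timezone-naive local time.

## Indicators

Ar(s,a) = seconds of activity *a* in the last 24 h / 86400; Br(s,a) = the
Lorenz area during *a* in that window. Both are divided by their
gender-group mean to give Ai and Bi, whose group means are exactly 1 —
an identity the tests verify to 1e−9. Zero participation counts: Ar = 0
enters the group mean, and an undefined Br (no pairs) is treated as 0,
giving that subject Bi = 0. A group whose mean is 0 (nobody did the
activity) leaves the indicator undefined. Mixed = Ai × Bi.

Normalization scope was genuinely open: the defining equations run over
subjects without mentioning days. The default normalizes within each
(date, question, gender, activity) cell — every value remains computable on
the day it describes, with no look-ahead — and a `period` mode normalizes
by gender-group means of subjects' whole-study averages instead.

## Feature variants

The five variants are cumulative; the full proposed2 roster has
4 + 1 + 12 + 12 + 12 = 41 named features (the companion manifest lists
them). A published contribution analysis of this method family refers to
30 features; the exact roster behind that count is not reconstructible, so
the literal cumulative reading is the default and a `compact` profile
(dropping the sleeping activity from the per-activity families, which
sleep duration already covers) is provided for sensitivity analysis. The
mixed products use last-24h per-activity values only, since the indicator
is defined on 24 h quantities.

Missing features (no wake event, too few pairs) are imputed with
per-feature training medians fitted inside each training fold — robust and
leakage-safe; the study protocol is silent on this point.

## Classifier and resampling

Labels come from 5-point Likert answers collapsed to three classes; the
morning question (felt refreshed?) maps {1,2}→bad, {3}→neutral, {4,5}→good
and the night question (stress felt?) the reverse. The per-class SMOTE
targets use integer class codes 1 = bad, 2 = neutral, 3 = good, so the
majority "good" class is raised to 200 and the minorities to 100 — the
assignment consistent with good being the largest class; it is
configurable.

Training composes SMOTE (k = 3 neighbours, random_state 0, interpolation
between a class member and one of its k nearest same-class neighbours),
random undersampling with replacement to the post-SMOTE minority count, and
10 bagged random forests whose undersample seeds are 1…10, combined by
per-row majority vote. Ties resolve by the fixed priority
bad > neutral > good: the method's purpose is early detection of
deterioration, so ties go to the costliest class. A class already above its
SMOTE target passes through; a class at or below k rows falls back to
resampling with replacement (both logged). Forests keep scikit-learn
default hyperparameters, recorded verbatim in the model manifest; each
member's forest is seeded (from the base seed and its undersample seed) so
that repeated fits give identical vote matrices — an invariant the tests
assert. Resampling and imputation run inside each cross-validation training
fold only; applying them before the split would leak synthetic copies of
test rows into training.

Five data-processing schemes are exposed for ablation: no manipulation,
SMOTE only, undersampling only, undersampled bagging, and the full
SMOTE + undersampled bagging.

## Evaluation protocol

Stratified 3-fold cross-validation (seeded, row-level by default; a
grouped-by-subject mode exists for leakage-conservative evaluation since
the protocol does not state whether folds respected subject boundaries —
with ~30 days per subject, row-level matches the original setting).
Out-of-fold predictions are pooled into one 3×3 confusion matrix per
(variant, question); accuracy = trace/total, per-class
F1 = 2RP/(R+P) with the 0/0 → 0 convention, and method summaries average
the morning and night accuracies. All variants share identical fold splits.

## Synthetic cohorts

No public dataset exists for this setting, so the simulator generates
cohorts carrying exactly the structure the method assumes, with defaults
mirroring the original protocol: 5 households (four couples, one single;
9 subjects), 30 days, 15 s cadence, six activity labels, 2% sensor dropout.

* **Latent stress** z ∈ [0,1] per subject-day: clipped AR(1) with mean 0.5,
  persistence 0.55, innovation sd 0.18 — day-to-day correlation makes the
  morning answer (generated from the previous day's state, so day 1 has no
  morning row) and night answer share signal.
* **Schedules**: sleeping anchors the day at both ends (wake ≈ N(07:00,
  20 min); bedtime ≈ 22:30, delayed up to ±1.5 h by stress, so sleep
  duration carries signal); waking hours are tiled by activity blocks whose
  totals follow a per-gender Dirichlet (women's profile weights cooking
  ~4× men's; concentration 30), with the going-out weight tilted
  exp(0.8·(z−0.5)) by stress. Couples share a household clock but have
  independent physiology.
* **HRV link**: within an activity, RRI ~ N(μ_a, σ_a(z)) per sample, with
  activity means 720–1050 ms and σ_a(z) = σ_a·(1 − 0.6·z): dispersion
  *strictly decreasing* in stress, halving-plus at maximal stress, in line
  with the contraction short-term HRV shows under acute stress. Samples
  are emitted as bpm rounded to 2 decimals (quantization ≪ HRV scale), so
  the pipeline exercises its own inversion.
* **Answers**: z plus N(0, 0.08) noise binned by thresholds
  (0.35, 0.55, 0.70, 0.80) into 1–5; the morning answer is reverse-coded
  (6 − bin). This yields roughly 60 / 20 / 20% good / neutral / bad — the
  imbalance the resampling pipeline exists for.

All values invented here are placeholders chosen once as plausible for an
elderly cohort, documented rather than fitted: no distributional facts
about the original households are available. `null_config()` disables all
three stress links (dispersion, behaviour, sleep) for null experiments.

What the simulator does **not** emulate: beat-level ECG/PPG physiology,
circadian heart-rate drift, sensor noise beyond dropout, annotation errors
in the activity log, or inter-subject heterogeneity in the HRV link.
Passing signal-recovery tests therefore show the pipeline recovers the
kind of signal the method posits when it is present — not that real
questionnaires are this predictable.

## Null behaviour

With the stress links disabled, an unmanipulated forest on ~100-tree
averages collapses to majority-class prediction, so its accuracy is the
right quantity to compare against the binomial band around the
majority-class rate. The balanced ensemble is intentionally prior-uniform:
on null data its accuracy converges toward the mean class frequency (~1/3
per predicted class), *below* the majority rate — a design property, not a
defect — so the null check asserts it does not exceed the band.

## Problem sizes and determinism

Signal-recovery checks run 20 replicate cohorts at the full default scale
(~530 questionnaire rows each); structural identity checks use smaller
cohorts (2–3 households, 2–4 days, 60 s cadence with the pair gap widened
accordingly). Every stochastic component — generator, SMOTE, undersampler,
forests, fold splits — is seeded, and repeated runs are bit-identical.

## Known limitations

* The bpm→RRI mapping inherits the tracker's smoothing; features are
  dispersion *of the reported rate*, a proxy for true beat-level HRV.
* Cross-subject gender normalization requires at least one same-gender
  subject with data on the same (date, question); single-gender-singleton
  cells pin Ai = Bi = 1 and carry no between-subject information.
* Row-level folds allow adjacent days of one subject to straddle folds;
  use the grouped mode when subject-level generalisation is the question.
* Frequency-domain HRV (LF/HF), artifact/ectopic correction, and
  probability calibration are out of scope.
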