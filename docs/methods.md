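# Methods

## Problem and pipeline

`gaitprog` predicts whether a patient undergoing knee osteotomy will reach a
good two-year outcome, using only a preoperative walking recording from two
synchronized inertial sensors (lumbar spine and tibial tuberosity; 3-axis
accelerometer + 3-axis gyroscope each, 100 Hz). The outcome is dichotomized
from patient-reported scores: a subject is a responder ("Good") when the
KOOS improvement exceeds the minimal clinically important difference (MCID)
on at least three of the five subscales (Pain, Symptoms, ADL, Sport/Rec,
QOL); two or fewer responding subscales is "Poor". "Exceeding" is a strict
inequality by default (config flag for `>=`). The per-subscale MCID values
must be supplied for any real analysis; the built-in 10-point table is a
documented placeholder, not a citation.

The processing chain:

1. **Filtering.** Every channel passes a 4th-order Butterworth low-pass at
   20 Hz, applied forward-backward (zero phase). The bidirectional pass
   squares the magnitude response: attenuation at frequency f is
   1/(1 + (f/f_c)^8).
2. **Event detection.** Initial contact (IC) is the anterior peak of the
   lumbar anteroposterior acceleration; toe-off (TO) the anterior pitch
   peak of the tibial angular velocity (GYR about the mediolateral axis).
   Peaks are picked with a prominence threshold of 0.3 x the 95th
   percentile of the channel's absolute value and a minimum separation of
   half the stride period; the stride period is estimated as the first
   autocorrelation peak reaching 70% of the strongest peak in a 0.4–2.5 s
   lag window (taking the global maximum instead can lock onto two
   strides). An `anterior_is_positive` flag per channel absorbs device
   mounting polarity. Ties between close peaks resolve to the higher one.
3. **Segmentation.** Each IC pairs with the earliest TO strictly after it;
   a second IC arriving before any TO invalidates the earlier IC, and TOs
   before the first IC are dropped. The stance segment includes both event
   samples. The first two and last two cycles of every trial are excluded
   (gait initiation/termination); a trial with fewer than five paired
   cycles contributes nothing. Retained cycles = max(0, paired − 4).
4. **Time normalization.** Each stance magnitude is resampled to 101 points
   over 0–100% of its duration with a cubic spline (exact at the knots);
   segments shorter than 4 samples are rejected.
5. **Features.** The tibial acceleration magnitude √(X²+Y²+Z²) is
   transformed with an analytic Morlet CWT (atom exp(i2πCt)·exp(−t²/B),
   defaults B = 2, C = 6/2π, i.e. the classic ω₀ = 6 Morlet; 12 voices per
   octave over 5–20 Hz). The stance is divided into six equal time slices
   and five 3 Hz bands; each of the 30 regions yields the mean and the
   SD (denominator n−1) of the absolute coefficients — 60 features per
   cycle, named `<Mean|SD>_<lo>-<hi>Hz_s<k>`.
6. **Selection and classification (per training fold only).** Features are
   z-scored, reduced 60 → 30 by greedy mRMR (quotient form, plug-in mutual
   information on equal-frequency bins, min(10, ⌊√n⌋) bins), ranked by
   ReliefF (k = 10 neighbors, all instances, range-normalized diffs), and
   the top K feed a random-undersampling boosting ensemble (RUSBoost).
7. **Evaluation.** Nested leave-one-subject-out cross-validation. The inner
   loop selects K by pooled inner AUC on the coarse grid {7, 13, 19, 25}
   followed by refinement at the odd neighbors (best ± 2, ± 4) within
   [5, 25]; ties take the smallest K. Cycle probabilities of a held-out
   subject aggregate to one score by the median. Subject-level scores give
   the ROC/AUC (Mann–Whitney identity, ties ½), a DeLong 95% CI (bootstrap
   by config), the Youden operating point (candidates are midpoints of
   consecutive distinct scores; ties prefer higher specificity, then the
   lower threshold), the confusion-matrix metrics and the distribution of
   selected K. A post-hoc global ReliefF heatmap (bands × slices, Mean and
   SD maps) is interpretive only and never enters model selection.

## CWT domain and edges

The transform runs on the raw-time stance segment at native sampling rate,
not on the 101-point normalized waveform, because the band edges are
physical Hz, which have no meaning on a percent-of-stance axis; the
coefficient time axis is mapped to stance percent afterwards for slicing
(`cwt.on_normalized` switches this). The series mean is removed before the
transform: the Morlet atom is zero-mean, so the DC level carries no
information, and removing it suppresses numerical leakage of truncated
wavelet tails at the segment edges.

No cone-of-influence masking is applied (the loading-response slice abuts
the edge and masking would empty it). The segment is zero-extended beyond
its edges by default. Mirror padding was implemented first and is still
available (`cwt.pad_mode`), but measurement showed it mislocalizes the
frequency content of bursts near an edge: the reflection creates a twin
burst, and the pair interferes as a comb that moves the apparent band of a
6.5 Hz loading-response burst into 8–11 Hz. Zero extension only attenuates
edge coefficients, uniformly across frequency, and keeps the band ordering
correct.

## RUSBoost

Two-class adaptive boosting with per-round random undersampling. Each round
draws all minority-class cycles plus a weighted sample (without
replacement, via Gumbel-perturbed log-weights) of majority cycles down to
the target ratio (default 50:50); the depth-limited tree (default depth 3,
minimum leaf 5) is fitted on the subsample with the current boosting
weights, but the round's error ε_t is always computed on the full weighted
training set, so undersampling affects learner fitting only. The vote
weight is α_t = lr·½·ln((1−ε_t)/ε_t) (lr = 0.1, 100 learners by default;
ε floored at 10⁻⁶ when a round is perfect). Initial boosting weights are
class-balanced — each class carries total weight ½ — so the round error is
prevalence-neutral: in leave-one-subject-out folds the training set always
carries a one-subject surplus of the class not held out, and uniform
initial weights let that surplus tilt every round's vote slightly against
the held-out class, which biases null cross-validated AUCs visibly below
0.5 at small cohort sizes. Rounds with ε_t ≥ 0.5 are
discarded and resampled (bounded retries), after which the ensemble stops
early. Probabilities are sigmoid(2·Σα_t h_t(x)) — monotone in the vote
margin and consumed only by rank-based metrics downstream; no calibration
is claimed. On exactly balanced data the undersampling step is a no-op and
the ensemble coincides bitwise with plain adaptive boosting under the same
seed.

The weak learner is an in-package histogram tree: features are
pre-discretized into 64 quantile bins and splits are searched over bin
boundaries by weighted Gini. The tree builder and the whole
round loop are numba-compiled; the nested protocol fits tens of thousands
of small ensembles, and a compiled learner keeps the full protocol within
interactive runtimes on one CPU.

## Nested protocol and the pair cache

All preprocessing (scaler, mRMR, ReliefF) is fitted strictly inside its
training fold. The inner fold of outer subject i with inner holdout j
trains on the subject set minus {i, j}, which is symmetric in (i, j); fold
artifacts are therefore cached per unordered pair and reused for the
mirrored fold, halving the cost. Seeds derive from the run seed and the
sorted pair (SeedSequence spawn keys), so results are deterministic and
independent of evaluation order. The cache never contains anything
computed from held-out rows; mutation tests corrupt a held-out subject's
cycles and assert bitwise-identical fold artifacts.

Cycle labels inherit the subject's outcome for training; splitting is
strictly by subject.

## Synthetic cohort generator

No clinical recordings ship with the package; the generator reproduces the
statistical and detectability structure the pipeline assumes, not
biomechanics:

* **Timing.** Stride period ~ N(1.1 s, 0.08 s) and stance ~ N(0.65 s,
  0.05 s) per subject, with small within-subject jitter (0.02 s / 0.01 s);
  each trial carries `cycles_per_subject + 4` strides so the edge exclusion
  retains exactly `cycles_per_subject` analyzable cycles (default 18; the
  default cohort of 67 subjects then yields 1206 analyzable cycles).
* **Events.** Gaussian peaks (σ = 25 ms, amplitude 3 m/s²; σ = 20 ms,
  150 °/s) are planted at the exact IC/TO sample instants on the lumbar AP
  and tibial pitch channels on top of phase-locked harmonics whose maxima
  coincide with the events; the periodic baseline is tapered outside
  [first IC, last TO] so the lead-in/out carries no pseudo-events. Ground
  truth is returned alongside, and detection recovers it to ±1 sample.
* **Tibial acceleration.** Gravity plus stride-locked harmonics (≤ 3× the
  stride frequency, safely below the 5 Hz analysis floor) plus planted
  Gabor bursts on the dominant (vertical) axis, plus white noise
  (default SD 0.25 m/s²). Burst carrier = band center; window SD = half
  the slice duration for a lone burst — wide enough that the burst is
  genuinely band-limited (spectral σ ≈ 3 Hz); a narrower window makes the
  "5–8 Hz" burst effectively broadband and its strongest feature response
  appears in the wrong band.
* **Planted effects.** A *mean-amplitude* effect is one burst per cycle at
  the slice midpoint, amplitude drawn from a bounded (uniform) law with
  group-specific mean (default Good 0.5 vs Poor 1.5 m/s²). A
  *cycle-variability* effect is a train of three sub-bursts across the
  slice whose amplitudes deviate antithetically from a common base by the
  group level (default base 0.8, Good 0.05 vs Poor 0.8 m/s²): the
  amplitude SD within every single cycle equals the group level, so the
  within-region SD signature — what the SD features measure — is present
  consistently in every Poor cycle rather than only as across-cycle
  scatter. A purely across-cycle amplitude dispersion was implemented
  first and proved structurally hard for instance-based importance
  weighting to rank (nearest misses are preferentially the overlapping
  middle of the dispersed class), which says something real about what
  such pipelines can recover from dispersion-only group differences.
* **KOOS.** Pre-operative subscale scores are drawn per group (Good lower
  at baseline, matching the clinical pattern of responders having more
  room to improve; SD 15, clipped to [0, 100]); the number of responding
  subscales is drawn from {3, 4, 5} (Good) or {0, 1, 2} (Poor), responding
  subscales improve by MCID + U(2, 25) points and the rest change by
  MCID + U(−15, −1); draws whose clipping would flip the label are
  resampled (bounded attempts, then an explicit error).
* **Seeding.** Child generators come from
  `SeedSequence(master, spawn_key=(subject_index, stream[, trial]))`;
  adding or removing a subject never shifts another subject's draws.

What passing tests on this generator do **not** show: robustness to real
sensor artifacts (drift, saturation, mounting variation), to heterogeneous
walking speeds' effect on frequency content, to imperfect event detection,
or to label noise in the MCID dichotomization — none of which the
generator emulates.

## Numerical and design choices

* Analysis frequency grid: f_max · 2^(−k/12), covering [5, 20] Hz; bands
  are half-open [lo, hi) except the top band, closed at 20 Hz.
* Slices are exact sixths of stance; the printed 0–17/17–33/... labels are
  rounded sixths. A stance-percent column belongs to slice
  min(5, ⌊p/(100/6)⌋).
* z-scoring floors the SD of constant features (they scale to 0, with a
  warning).
* mRMR quotient denominator floored at 10⁻¹²; the difference (MID) variant
  is a config switch. All ties — mRMR scores, ReliefF ranks, Youden
  candidates — break deterministically (alphabetical feature name; higher
  specificity then lower threshold).
* DeLong is the default AUC CI; it is the standard analytic choice at
  n ≈ 67 subjects, and a subject-level bootstrap is available by config.
* Logistic sensitivity analysis (outcome ~ prediction score + baseline
  KOOS total, the mean of the five subscales): maximum likelihood via
  statsmodels, likelihood-ratio tests per covariate (χ², 1 df), Wald CIs
  for odds ratios (profile likelihood not implemented). Perfect separation
  is detected and reported as an explicit error — with strong planted
  effects and a small cohort, subject scores can separate the groups
  completely, in which case the MLE does not exist and no OR is reported.
* Group comparisons: pooled-variance t-test by default (Welch by flag);
  Pearson chi-square without continuity correction (flag available).

## Problem sizes in the shipped checks

The end-to-end recovery check runs the full protocol on 67 subjects
(37 Good / 30 Poor, 18 cycles each, ensemble size 50); the null
calibration runs 20 effect-free cohorts of 30 subjects × 8 cycles; the
event-detection check uses 50 trials of 18 strides. These sizes were
chosen to exercise the protocol at the scale of a realistic single-center
cohort while keeping the full suite runnable interactively.

## Known limitations

* The MCID table is a placeholder; published per-subscale values must be
  supplied for clinical use.
* ReliefF importance under-ranks group differences that live purely in
  across-cycle dispersion (see above); the importance heatmap should be
  read as "what the classifier can see", not as a complete census of group
  differences.
* Boosting probabilities are uncalibrated by construction.
* The vendor CSV layout is not standardized; the reader's column-mapping
  table must be configured per device export.
* Mixed acceleration units within one cohort are refused rather than
  converted; the pipeline is scale-covariant only within a cohort sharing
  units.
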