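# Methods

## Problem

Segment-level emotion classification from EEG is usually evaluated by
cutting each recording into short windows, inheriting the trial's label,
and cross-validating over the pooled windows. How those windows are
assigned to training and test partitions decides what the reported
accuracy means: windows from the same subject, the same stimulus video, or
adjacent moments of the same trial are statistically dependent, and any of
them appearing on both sides of the split inflates the estimate. This
package implements a controlled-leakage evaluation framework around the
**data transfer rate** β: a fixed test set is drawn once per fold, and β
of the fold's remaining segments (the pool `R`) is deliberately moved into
the training partition. Because the test set never changes along a β
sweep, the accuracy-vs-β curve isolates the value of leaked information.

Three split families cover the standard scenarios:

* **subject-independent** — k folds of disjoint subjects (k = S is
  leave-one-subject-out); at β = 0 no test subject contributes training
  data (affective decoding / cross-subject generalisation).
* **video-independent** — folds of disjoint stimulus videos; subjects are
  shared between partitions (affective annotation).
* **time-based** — the last `test_tail` (default 20%) of every trial is
  the test set; training windows come from the leading ρ fraction of the
  remainder (forward) or the trailing ρ fraction (backward).
* **combined** — subject-independent transfer with the training material
  additionally restricted to the leading ρ·D seconds of each trial.

With k = 5 the counting identities are: fold share = 20% of segments,
pool R = 20% − F, and the transferred fraction of the whole dataset is
β·R (e.g. 3.2% at F = 4%, β = 0.2). Fractional counts round half-to-even
so every |test| and |transfer| is a reproducible integer. Transfer draws
are *nested*: one permutation per fold, with each β taking a prefix, so
training sets along a sweep differ only by added segments. The fixed test
draw is seeded by (seed, fold) only — never by β.

## Preprocessing

Per trial: (1) the per-channel mean of the 3-s pre-stimulus rest recording
is subtracted channel-wise from the stimulus signal (the grand rest mean
equals the mean of the three 1-s segment means, so the two published
formulations coincide); (2) each channel is scaled to unit maximum
absolute value over the whole trial; (3) the trial is segmented into
T-second windows with stride T·(1−overlap), dropping an incomplete
remainder; (4) the 1–9 valence rating is binarised at ℓ ≤ 5 → negative,
ℓ > 5 → positive, and every segment inherits the trial label. Scaling is
per trial by default (`scale_scope="trial"`) so overlapping segments
remain consistent slices of one signal; per-segment scaling is available
as a switch. Arousal and dominance are carried through as alternative
label dimensions.

## Classifier

The segment classifier is a small two-block convolutional network over
the raw scaled time-domain segment (C channels × L = f·T samples):
Conv(512 filters, 1×65) → ELU(α=1) → BatchNorm → AvgPool(1×2) →
Conv(10, 1×33) → ELU → BatchNorm → AvgPool(1×4) → Flatten → Linear(160) →
BatchNorm → ReLU → Linear(1). Kernels are 1×k, so convolutions and pools
act along time only and channels are never mixed before the dense head.
Training: binary cross-entropy on the logit, Adam (β₁=0.9, β₂=0.999) with
L2 weight decay 0.01 added to the gradient, learning rate 10⁻³ with
linear warm-up over the first 10% of steps then linear decay to zero,
batches of 100 segments, up to 15 epochs; a 10% validation split is
carved from the training indices (never from the test set or pool) and
the parameters of the minimum-validation-loss epoch are kept. Both
convolutions use `same` padding by default so the shape arithmetic is
uniform across T ∈ {1, 2, 4} s (L → L/2 → L/8 through the pools; `valid`
padding is available and requires L ≥ 196). A logit of exactly 0
classifies as negative, mirroring the ℓ ≤ 5 labelling convention.

The network, its backward pass, and the optimiser are implemented in
numpy. The two convolutions are single large GEMMs (im2col for the
1-input-channel first layer; a tap-stacked weight matrix for the 512→10
second layer, skipping zero-padding rows), with preallocated, reused
scratch buffers; everything is float32 and bit-deterministic under a
seed on a fixed BLAS. Gradient correctness is established against central
differences in float64 (max relative error ~3·10⁻⁷).

A regularised logistic regression on flattened segments
(`LinearSegmentBaseline`, scikit-learn underneath) serves as the
model-agnostic cross-check: partition effects that appear under both
models are attributable to the split, not the architecture.

One root seed is split into named independent streams (generation, fold
assignment, test draw, transfer draw, model init), so varying one stage
never perturbs another.

## Synthetic data generator

Real affective EEG is not redistributable here, so every experiment runs
on a generator that emulates the *dependence structure* of a DEAP-shaped
dataset — one trial per (subject, video), 3-s rest prefix, continuous
1–9 ratings — with an additive latent model per channel c and sample t:

    x(c,t) = b_s(c) + u_s(c)·g_sv(t) + w_v(c)·h_v(t)
             + y_sv·d_s(c)·a(t) + AR(1) noise

with y_sv ∈ {−1,+1} a fair coin per trial, u_s/w_v unit spatial patterns,
smoothed-noise carriers (moving average, ~0.5 s window; not sinusoids, to
avoid learnable periodicity), b_s a per-subject rest baseline present in
rest and stimulus alike, and a(t) a profile ramping linearly from 0 to
`class_amp` over the first `ramp` fraction of the trial. A subject's
stable trait is the spatial pattern u_s; the temporal carrier g_sv is
drawn fresh per trial (a subject does not replay an identical time course
in every recording — and a repeated carrier would freeze one arbitrary
drift into all of a held-out subject's trials, collapsing the effective
test sample size). The video carrier h_v is stimulus-locked: one time
course per video, shared across subjects, which is what makes a video
recognisable across subjects. Ratings are drawn uniformly on [1,5]
(negative) or (5,9] (positive), so binarisation recovers the latent class
exactly.

Key defaults and why:

| parameter | default | role |
|---|---|---|
| S, V, C, f, D | 8, 10, 8, 128 Hz, 60 s | DEAP-like shape at desk scale |
| sigma_subject | 1.0 | subject idiosyncrasy dominates the signal |
| sigma_video | 0.5 | weaker, shared video signature |
| class_amp | 5.0 | within-subject decodable class component |
| ramp | 0.5 | later segments more discriminative |
| phi | 0.995 | per-sample AR(1) coefficient |
| sigma_noise | 0.1 | innovation scale (stationary sd ≈ 1) |
| subject_specific_classes | on | class direction randomised per subject |
| balanced_classes | off | exactly V/2 positive trials per subject |
| rest_offset_scale | 0.5 | baseline the rest-subtraction removes |

When `subject_specific_classes` is set and S ≤ C, the per-subject class
directions d_s are mutually orthogonalised (QR of a Gaussian matrix): a
class code learned on one subject then carries exactly zero information
about another's, which is the cleanest model of "subject-specific
structure" and pins cross-subject decoding at chance. With S > C,
independent random directions are used (orthogonality is impossible).

Two calibration points deserve emphasis, because they were genuinely open
design choices:

* **Noise correlation time.** The segment-length and overlap effects
  hinge on neighbouring windows being *similar*. If the AR(1) noise
  decorrelates much faster than a segment (e.g. φ per sample giving a
  ~0.15 s correlation time), longer segments win by averaging noise away
  and the segment-length ordering inverts. The defaults therefore set the
  correlation time comparable to the longest segments in use
  (φ = 0.995 ≈ 1.6 s at 128 Hz; tests at 32 Hz keep φ = 0.995, ≈ 6 s),
  with `sigma_noise` chosen to keep the stationary noise sd at ≈ 1.
* **Amplitude ratios.** `class_amp` = 5 makes a nearest-class-centroid
  oracle trained within one subject exceed 90% segment accuracy (at
  ramp = 0) while the same oracle trained on disjoint subjects stays at
  50% ± 5% — the generator's central contract, verified by brute force at
  S=6, V=10. The contract check uses ramp = 0 because with ramp = 0.5 the
  early-trial segments carry no class signal *by design*, structurally
  capping mean accuracy near 0.88; the ramp has its own property test.

Classes default to i.i.d. fair coins per trial (the simplest null).
`balanced_classes` forces exactly V/2 positive trials per subject and
exists for point estimates of chance-level accuracy: with only S·V = 60
trials, the training set's class majority anti-correlates with the
held-out fold's balance (drawing without replacement from one finite
table), so a prior-sensitive classifier lands measurably *below* 50% —
a bare majority-class predictor scores ~47% at this geometry. At the
full scale the construct refers to (32 subjects × 40 videos) the effect
is negligible; balancing removes it from the desk-scale estimate while
leaving every other structure, including per-video label flukes, intact.

What the generator does **not** emulate: physiological spectra
(alpha/beta bands), volume conduction, artifacts, non-stationarity across
trials, label noise, or class imbalance beyond binomial fluctuation.
Passing tests therefore show that the *partition machinery* produces the
documented leakage effects on data with the stated dependence structure —
not that any particular accuracy level transfers to real recordings.

## Experiment layer

`run_sweep` walks a grid of (mode, T, overlap, F, β, ρ, direction) cells,
running prepare → split → fit → predict → evaluate per fold and replicate
seed, and returns a tidy DataFrame (accuracy, positive-class F1 with
0/0 := 0, confusion counts, partition sizes); `summarize` aggregates
mean ± sd per cell over folds and seeds. Failed cells — e.g. an empty
training window at ρ = 0.2 with T = 4 s, which is a real phenomenon of
the combined design — are recorded with their cause, never dropped.
Within a replicate, fold assignment, test draw, transfer permutation and
model initialisation derive from one stream that does not depend on the
cell, so the combined mode at ρ = 1 reproduces the subject-independent
results cell for cell. Replicate seeds regenerate the *dataset* as well:
with only S·V trials, a fixed label table lets any model exploit
per-video majority flukes (≈ 4 pp of dataset-level spread at S=6, V=10),
which averaging over regenerated datasets removes.

## Problem sizes used in tests and the acceptance script

All shipped checks run at desk scale, chosen once: qualitative sweeps use
S=6, V=10, C=8 at 32 Hz with 24-s or 60-s trials and the linear baseline
(the convolutional model is exercised on the chance-level acceptance
point and in unit tests); the acceptance script trains the full
convolutional architecture at 128 Hz on 10-s trials (3 regenerated
datasets × 5 folds, 5 epochs, per-subject balanced classes). Its
chance-level point is evaluated on F = 16% fixed test sets: at β = 0 the
training partition is the same for every F (F only selects which fold
segments are *evaluated*), so a larger fixed test set estimates the same
quantity with less sampling noise. The qualitative suite asserts orderings
with explicit tolerances rather than strict inequalities where the
underlying effect is within Monte-Carlo resolution at this scale; in
particular the 25%-overlap point is bounded within ±6 pp of the
no-overlap cell, while the 50%-overlap gain is asserted strictly — the
full three-way overlap ordering is driven by sample-memorisation capacity
that a convex baseline lacks.

## Numerical choices and edge cases

* Rounding of fractional counts: Python's banker's rounding everywhere.
* An all-zero channel cannot be max-abs scaled; it is left unchanged with
  a logged warning.
* Segment grids require integer sample counts for T·f and the stride;
  anything else is an error naming the offending combination.
* ℓ = 5.0 is negative exactly; no exclusion band.
* Ties at logit 0 classify negative.
* Empty training windows raise; `run_sweep` converts that into a recorded
  failed cell.
* Batch-norm statistics use running estimates (momentum 0.1) at
  evaluation time; the restored best-epoch state includes them.

## Known limitations

* The DEAP adapter is shape-checked but, the dataset being
  access-restricted, has never been run against real DEAP files.
* Accuracy levels on synthetic data are calibration-dependent; only
  orderings and the chance-level anchor are meaningful.
* The numpy training loop is single-core and unsuitable for full-scale
  (32-subject, 60-s, 15-epoch) replication; the pipeline supports those
  sizes, but at substantial wall-clock cost.
* The validation split for model selection is random within-training;
  a subject-disjoint validation variant is not implemented.
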