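# Methods

This note documents the models, numerical choices and limitations of
`eldergait` the way a maintainer would want them written down. It states no
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal representation

All learning operates on tri-axial acceleration in gravitational units (g),
resampled to 30 Hz and segmented into non-overlapping 10-s windows
(3×300 samples). Gait content sits below ~10 Hz, so 30 Hz is above Nyquist
for the signal of interest; resampling uses polyphase FIR filtering
(`scipy.signal.resample_poly`) rather than naive decimation so that the gait
band is anti-aliased. Categorical per-sample labels are carried through
resampling by nearest-neighbour lookup, with ties at half-sample offsets
resolved to the earlier sample. A window counts as *gait* when at least half
of its samples (150/300, i.e. ≥ 5 s) are labeled gait; the rule is monotone
in the number of gait samples, which the suite checks as a property.

Optional corpus-level whitening (per-axis pooled mean/std) exists for the
pretraining corpus; it is applied only where configured, since standardizing
pretraining data but not fine-tuning data is a supported asymmetric regime.

## Synthetic data generator

The generator emulates four wrist regimes per 30 Hz sample and axis:

* **gait** — `a(t) = g·orientation + Σ_k w_k·A·sin(2πkf·t + φ_axis,k) + ε`,
  a step-frequency fundamental `f` (default 1.9 Hz, realistic range
  1.4–2.3 Hz) with decaying harmonics (weights 1.0/0.4/0.15), arm-swing
  amplitude `A` (default 0.35 g; impaired profiles would use less), per-axis
  phases drawn once per bout, Gaussian noise ε (σ = 0.03 g);
* **activity** — 2–4 smooth sub-1 Hz sinusoidal components per axis plus
  broadband noise: hand use without walking, i.e. energy without sustained
  gait-band periodicity;
* **rest** — gravity plus noise;
* **non-wear** — gravity plus σ = 1 mg noise (well under any wear threshold).

Bout durations are lognormal; gait bouts average ~30 s, matching published
bout-length statistics for older adults in daily living, and the default
state mix yields roughly 15% gait time, in the 10–18% range such cohorts
show. Cohort simulation schedules, for each subject and day, gait bouts
whose durations are renormalized to hit the subject's true daily walking
target exactly, separated by Dirichlet-distributed rest/activity gaps; per-
state sample rounding is pinned back to exact calendar-day length with rest
padding. True targets are Normal(group mean, between-subject SD) draws,
clipped at zero; covariates (age ~ N(83,7) in 62–103, 24% male,
BMI ~ N(27,4.5)) are drawn independently of walking. All randomness flows
from one `numpy` generator per call (SeedSequence-spawned per subject), so
identical (spec, seed) give byte-identical output.

What the generator does **not** emulate: biomechanically faithful arm
kinematics, device-specific noise floors, posture transitions, tremor or
dyskinesia, walking-while-texting ambiguity, or covariate-walking
correlations. Passing tests therefore demonstrate that the machinery — the
losses, the protocol, the statistics — is correct and that the pipeline can
recover separable gait, not that the learned detector would transfer to any
real cohort.

## Augmentations

The four MTL pretext transforms apply independently with probability 0.5
each (balanced pretext bits), in the fixed order reverse → permute → warp →
scale for reproducibility:

* reversal of the sample order;
* permutation of the thirty 10-sample segments, one permutation shared by
  all three axes so 3-D samples stay intact;
* time warping via a strictly increasing piecewise-linear map of [0,1] with
  4 interior knots, interval lengths jittered by at most ±20% and
  renormalized (endpoints fixed), then linear re-interpolation to 300
  samples — the warp parameterization is this package's construction;
* per-axis scaling with factors uniform on [0.5, 2].

Flags record *application*, not visible change (reversing a palindrome
still sets the bit). SimCLR views are two independent random rotations
(Rodrigues form; axis from a normalized 3-D Gaussian, angle uniform on
[0, 2π)) of the same window; the original window is not itself a view.

## Architecture

The encoder is a 1-D pre-activation residual network: a stride-2 stem
convolution, residual stages with stride-2 downsampling and channel
doubling, a final BN+ReLU, global average pooling, and a linear map to the
embedding. `depth=18` (channels 32→256, two blocks per stage) emits
1024-dimensional embeddings; `depth=8` (`tiny`: channels 8→32, one block per
stage, 64 dimensions) is the CPU-scale preset used throughout the tests.
The channel schedule and head widths are this package's choices.

Three heads sit on the embedding: three stacked fully-connected layers with
no non-linearity (provably a single affine map — tested by composing the
layer matrices), the same with ReLU between layers (the reference
configuration), and a small 1-D U-Net run along the feature axis with one
skip connection, globally pooled to the output width. The gait classifier is
one linear layer to 2 logits with softmax; two logits rather than one
sigmoid keeps symmetric class-weighting hooks.

Since no tensor/autodiff library is available in the supported environment,
`eldergait._nn` provides a compact reverse-mode autodiff over float32 numpy
arrays (conv1d via strided im2col, batch norm, Adam). Every primitive's
backward pass is verified against central finite differences; float64
inputs are propagated unchanged, which the oracle tests use for tight
tolerances.

## Pretraining and fine-tuning

MTL: encoder → head → one linear task layer to 4 logits;
loss = binary cross-entropy averaged over the four tasks and the batch,
computed in the numerically stable softplus form. SimCLR: embeddings are
ℓ2-normalized *inside* the NT-Xent loss (cosine similarity), τ = 0.1 by
default, and the loss averages over all 2N ordered positive pairs with the
2N−2 in-batch negatives; both losses are pinned to independent brute-force
oracles in the tests (1e-6 / 1e-8).

Optimization uses Adam, batch 64, default learning rates 1e-3 for head-only
training and 1e-4 for full fine-tuning (3e-4 is used for some CPU-scale
fixtures where the smaller corpus tolerates a faster rate). Fine-tuning
updates all weights by default (`unfreeze_all=True`); a frozen encoder is
enforced by excluding its parameters from the optimizer and is checked via
parameter checksums.

The evaluation protocol is subject-wise throughout: 75/25 train/test at the
subject level, 80/20 inner train/validation, and stratified subject-grouped
5-fold cross-validation repeated over three seeds (15 fold results,
mean ± SD), realized with scikit-learn's `GroupShuffleSplit` and
`StratifiedGroupKFold`. Subject leakage is a hard assertion inside every
split, not an assumption. Early stopping monitors validation loss with
strict-decrease semantics and min-delta 1e-4; training halts after five
epochs without improvement and the best-validation epoch's weights are
restored (the conservative choice consistent with early stopping).
Window-level metrics come from the confusion matrix as percentages;
per-subject reporting computes metrics per subject and averages, excluding
(with a logged note) subjects whose precision is undefined because they have
no predicted positives. F1 drives model selection because daily-living gait
is rare and accuracy rewards the majority class; ties break by lower SD,
then lexical configuration name.

## Daily walking and construct validity

Non-wear is flagged when the standard deviation of **every** axis stays
below 13 mg — the conventional actigraphy cut-off, since only "sustained low
variance" is specified by the underlying method — over 1-min non-overlapping
blocks for at least 30 consecutive minutes. Windows overlapping non-wear are
excluded before classification (masking precedence). Days are calendar-day
spans aligned to the recording start; a day is *full* when entirely inside
the recording with ≥ 20 h wear, and the first four full days are analyzed —
subjects without four are flagged excluded rather than raised. Consecutive
gait windows merge into bouts (duration = 10 s × run length; total bout time
conserves 10 s × gait-window count exactly). Daily walking duration is the
median of the four per-day totals in minutes; the per-day bout *count*
median is carried as an alternative column because "summing gait sequences"
is ambiguous between time and count — the time reading is primary since the
quantity is reported in minutes per day.

Group differences use `scipy.stats.kruskal` plus a hand-implemented Dunn
post-hoc (pooled mean ranks, tie-corrected variance, two-sided normal p,
Bonferroni `min(1, p·n_pairs)`) — no Dunn implementation is available among
the supported dependencies, so it is written out and unit-tested against a
hand-computed example and the rank-formula H. Partial correlation is
computed by explicit residualization: both variables are regressed on the
covariates (with intercept) by least squares and the residuals correlated,
with a t-based p on n−k−2 degrees of freedom. An inverse-covariance
implementation was rejected because it returns r = −1 on the degenerate
x ≡ y input; the residualization form is the definition used here and is
cross-checked against `pingouin` on regular data in the tests. When a
variable is fully explained by the covariates the partial correlation is
reported as 0 with p = 1.

## Problem sizes

Desk-scale runs use the `tiny` encoder: pretraining on ~2 000 unlabeled
windows (5 epochs), fine-tuning on 30 synthetic subjects (~600 s each,
~60 windows/subject) evaluated on 10 held-out subjects over three seeds; the
low-label comparison uses 4 labeled subjects; the construct-validity cohort
uses three strata of 10 subjects walking 120/80/40 min/day (SD 10) over four
24-h days each. These sizes keep a full run in minutes on one CPU core
while leaving all statistical conclusions (ordering, omnibus and post-hoc
significance) far from their thresholds, since the group separation is
8 SDs end to end.

## Known limitations

* The generator's separability makes window metrics optimistic relative to
  any real cohort; the SSL-vs-random comparison direction, not its
  magnitude, is the meaningful output.
* The U-Net head runs along the embedding axis, not the raw 300-sample
  axis, because heads consume embeddings in this architecture.
* `depth` accepts only the two published schedules (18 and the tiny 8);
  arbitrary depths are out of scope.
* Early stopping monitors validation loss; monitoring training loss is a
  plausible alternative reading of the protocol and would stop later.
* Calibration to local gravity, temperature correction and timestamp-gap
  repair are out of scope; malformed inputs are rejected, not repaired.
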