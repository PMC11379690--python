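# eldergait

Self-supervised gait detection from wrist-worn accelerometer data, with
daily walking-duration analytics for older-adult cohorts.

## The problem

Gait impairment is a hallmark of aging and of conditions such as Parkinson's
disease, but supervised gait detectors need labeled daily-living recordings,
which are scarce — especially for older adults whose wrist signals often lack
the clean periodic arm swing that detectors trained on young, healthy
walkers rely on. This package implements a two-stage remedy:

1. **Self-supervised pretraining** on unlabeled tri-axial wrist acceleration,
   by either of two pretext tasks:
   - **Multi-task augmentation prediction (MTL):** each 10-s window is
     independently transformed by up to four augmentations — reversal,
     permutation of 10-sample segments, time warping, per-axis scaling — and
     the network predicts the four application bits. The loss is the binary
     cross-entropy averaged over the four tasks.
   - **SimCLR contrastive learning:** two random 3-D rotations of the same
     window form a positive pair; the NT-Xent loss over cosine similarities

     `ℓ(i,j) = −log [ exp(cos(z_i, z_j)/τ) / Σ_{k≠i} exp(cos(z_i, z_k)/τ) ]`

     pulls positives together against the 2N−2 negatives in the batch.
2. **Supervised fine-tuning** of the pretrained encoder + head with a 2-logit
   linear classifier for window-level gait / non-gait decisions, under a
   subject-wise protocol: 75/25 train/test split, 80/20 inner validation,
   stratified subject-grouped 5-fold cross-validation repeated over three
   seeds, 30 epochs with patience-5 early stopping on validation loss.

Downstream, continuous multi-day recordings are masked for non-wear
(rolling per-axis standard deviation < 13 mg on all axes for ≥ 30 min),
the first four complete 24-h days are selected, consecutive gait windows are
merged into bouts, and daily walking duration is summarized as the median of
the four per-day totals. Construct validity is assessed with Kruskal–Wallis
omnibus tests, Dunn's Bonferroni-corrected post-hoc comparisons, and partial
correlations adjusted for age, sex and BMI.

Everything runs on standardized input: acceleration resampled to 30 Hz
(anti-aliased polyphase filtering) and cut into non-overlapping 10-s windows
(3×300 samples); a window is *gait* when at least half of its samples
(≥ 5 s) are labeled gait.

The encoder is a 1-D pre-activation residual network (18 weighted layers by
default, producing a 1024-dimensional embedding; a `tiny` preset with 8
layers and 64 dimensions trains on a laptop CPU in seconds). Because no
tensor-autodiff engine ships in the target environment, the package includes
a small, fully tested reverse-mode autodiff and layer library
(`eldergait._nn`) on top of numpy.

No clinical data ships with the package: `eldergait.synthetic_data`
generates labeled multi-day wrist recordings — quasi-periodic gait bouts
with configurable step frequency and arm-swing amplitude, aperiodic arm
activity, rest, non-wear — and cohorts whose true daily walking duration
differs by group, so the whole pipeline is testable end to end.

## Worked example

```python
import numpy as np
from eldergait import synthetic_data as sd, preprocess as pp
from eldergait import model_core as mc, ssl, finetune_eval as fe

def subject_windows(n, seed0, dur=600.0):
    wins = []
    for s in range(n):
        rng = np.random.default_rng(seed0 + s)
        sch = sd.BoutSchedule.sample(dur, rng)
        rec = sd.simulate_recording(sd.ActivityProfile(), sch, fs=30,
                                    seed=seed0 + s, subject_id=f"subj{seed0 + s}")
        wins += pp.segment_windows(rec, drop_nonwear=True)
    return wins

# stage 1: self-supervised pretraining on unlabeled windows
unlabeled = subject_windows(10, 100)
encoder = mc.Encoder(mc.EncoderConfig.tiny(), seed=0)
head = mc.build_head(mc.HeadConfig.tiny(), 64, seed=0)
pre = ssl.pretrain(unlabeled, encoder, head, "mtl",
                   ssl.PretrainConfig(epochs=5), seed=0, head_out_dim=32)
print(f"MTL pretext loss over 5 epochs: {pre.losses[0]:.3f} -> {pre.losses[-1]:.3f}")

# stage 2: supervised fine-tuning, subject-wise split
ds = fe.WindowDataset.from_windows(subject_windows(12, 300))
train, val, test = fe.split_subjectwise(ds, fe.SplitPlan(), seed=0)
model = mc.GaitModel(encoder, head, 32, seed=0)
model, hist = fe.finetune(ds.subset(train), ds.subset(val), model,
                          fe.TrainState(learning_rate=3e-4), seed=0)
preds, probs = fe.predict_dataset(model, ds.X[test])
report = fe.window_metrics(preds, ds.y[test], per_subject=True,
                           subjects=ds.subjects[test])
print(f"held-out subjects: F1 {report.f1:.1f}%, accuracy {report.accuracy:.1f}%, "
      f"recall {report.recall:.1f}%")
```

Output:

```
MTL pretext loss over 5 epochs: 0.688 -> 0.591
held-out subjects: F1 96.7%, accuracy 98.9%, recall 97.0%
```

The pretext loss falls from chance (ln 2 ≈ 0.693) as the encoder learns to
recognize the augmentations; after fine-tuning, per-subject-averaged window
metrics on the three held-out subjects are in the high 90s because the
synthetic gait regime here is well separated (arm swing 0.35 g).

A command-line interface mirrors the pipeline:
`eldergait simulate | preprocess | pretrain | finetune | evaluate | predict |
daily-summary | construct-stats` (see `eldergait --help`).

## Layout

| module | role |
| --- | --- |
| `eldergait.synthetic_data` | labeled recordings, bout schedules, cohorts |
| `eldergait.preprocess` | 30 Hz resampling, 10-s windows, labels, whitening |
| `eldergait.augment` | MTL augmentations and SimCLR rotation views |
| `eldergait.model_core` | residual encoder, head variants, classifier, checkpoints |
| `eldergait.ssl` | MTL / NT-Xent losses and pretraining loops |
| `eldergait.finetune_eval` | subject-wise splits, fine-tuning, CV, metrics |
| `eldergait.daily_gait` | non-wear, bouts, daily minutes, cohort statistics |
| `eldergait._nn` | minimal numpy autodiff + layers + Adam |
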