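"""Raw recordings to standardized, labeled 10-s windows.

The learning pipeline operates on a fixed representation: tri-axial
acceleration resampled to 30 Hz and cut into non-overlapping 10-s windows
(3 x 300 samples). A window counts as a gait window when at least half of its
samples (>= 5 s) are labeled gait. Optional corpus-level whitening
(zero-mean, unit-variance per axis) is fit on a pretraining corpus and
applied where configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

TARGET_FS = 30
WINDOW_SAMPLES = 300
WINDOW_SECONDS = 10.0

GAIT, NON_GAIT = 1, 0
NONWEAR_LABEL = -1


@dataclass
class Recording:
    """A continuous tri-axial acceleration trace.

    ``samples`` is (T, 3) in gravitational units (g). ``labels`` is an
    optional per-sample track with 1 = gait, 0 = non-gait and -1 = non-wear.
    ``wear`` is an optional boolean track (True = device worn); when absent it
    is derived from ``labels`` where available.
    """

    samples: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    wear: np.ndarray | None = None
    subject_id: str = "anon"
    device_range_g: float | None = 8.0
    start_time_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be (T, 3)")
        T = self.samples.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (T,):
                raise ValueError("label track length must equal sample count")
        if self.wear is not None:
            self.wear = np.asarray(self.wear, dtype=bool)
            if self.wear.shape != (T,):
                raise ValueError("wear track length must equal sample count")
        if self.device_range_g is not None:
            peak = float(np.abs(self.samples).max(initial=0.0))
            if peak > self.device_range_g + 1e-6:
                raise ValueError(
                    f"|samples| exceeds declared device range +/-{self.device_range_g} g")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def wear_track(self) -> np.ndarray:
        if self.wear is not None:
            return self.wear
        if self.labels is not None:
            return self.labels != NONWEAR_LABEL
        return np.ones(self.n_samples, dtype=bool)


@dataclass
class Window:
    """A 10-s, 3-axis segment: the atomic unit of learning (3 x 300 array)."""

    samples: np.ndarray
    label: Literal["gait", "non-gait", "unlabeled"] = "unlabeled"
    subject_id: str = "anon"
    start_time_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.shape != (3, WINDOW_SAMPLES):
            raise ValueError(f"window must be (3, {WINDOW_SAMPLES})")


@dataclass
class StandardizationStats:
    mean: np.ndarray  # per-axis, in g
    std: np.ndarray
    scope: Literal["corpus", "none"] = "corpus"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        self.std = np.asarray(self.std, dtype=np.float64).reshape(3)
        if self.scope == "corpus" and not np.all(self.std > 0):
            raise ValueError("std must be positive on every axis")


def resample_to_30hz(rec: Recording) -> Recording:
    """Anti-aliased polyphase resampling to 30 Hz; labels by nearest neighbour.

    Gait content lives below ~10 Hz, so a 30 Hz grid keeps it intact provided
    the decimation is low-pass filtered; naive sample dropping is not used.
    """
    if rec.fs < TARGET_FS:
        raise ValueError(f"fs={rec.fs} < {TARGET_FS} Hz: upsampling is out of scope")
    if rec.fs == TARGET_FS:
        return rec
    frac = Fraction(TARGET_FS, int(round(rec.fs)))
    up, down = frac.numerator, frac.denominator
    samples = resample_poly(rec.samples.astype(np.float64), up, down, axis=0)
    samples = samples.astype(np.float32)
    T_out = samples.shape[0]
    # nearest-neighbour index map; ties at .5 resolve to the earlier sample
    src = np.ceil(np.arange(T_out) * (rec.fs / TARGET_FS) - 0.5).astype(np.int64)
    src = np.clip(src, 0, rec.n_samples - 1)
    labels = rec.labels[src] if rec.labels is not None else None
    wear = rec.wear[src] if rec.wear is not None else None
    return Recording(samples=samples, fs=TARGET_FS, labels=labels, wear=wear,
                     subject_id=rec.subject_id, device_range_g=None,
                     start_time_s=rec.start_time_s)


def label_window(per_sample_labels: Sequence[int]) -> str:
    """A window is gait iff at least half its samples (>= 150/300) are gait."""
    labels = np.asarray(per_sample_labels)
    if labels.shape != (WINDOW_SAMPLES,):
        raise ValueError(f"expected exactly {WINDOW_SAMPLES} labels")
    return "gait" if int((labels == GAIT).sum()) >= WINDOW_SAMPLES // 2 else "non-gait"


def segment_windows(rec: Recording, drop_nonwear: bool = False) -> list[Window]:
    """Cut a 30 Hz recording into non-overlapping 10-s windows.

    The trailing remainder (< 300 samples) is dropped. With
    ``drop_nonwear=True`` any window containing a non-worn sample is excluded
    (training hygiene); the default keeps the exact partition.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("segment_windows expects a 30 Hz recording")
    n_win = rec.n_samples // WINDOW_SAMPLES
    wear = rec.wear_track()
    out: list[Window] = []
    for k in range(n_win):
        lo, hi = k * WINDOW_SAMPLES, (k + 1) * WINDOW_SAMPLES
        if drop_nonwear and not wear[lo:hi].all():
            continue
        if rec.labels is not None:
            label = label_window(np.where(wear[lo:hi], rec.labels[lo:hi], 0))
        else:
            label = "unlabeled"
        out.append(Window(samples=rec.samples[lo:hi].T, label=label,
                          subject_id=rec.subject_id,
                          start_time_s=rec.start_time_s + lo / TARGET_FS))
    return out


def fit_standardization(corpus: Iterable[Recording]) -> StandardizationStats:
    """Per-axis mean/std pooled over every sample of the corpus."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    n_total = 0
    s1 = np.zeros(3, dtype=np.float64)
    s2 = np.zeros(3, dtype=np.float64)
    for rec in corpus:
        x = rec.samples.astype(np.float64)
        n_total += x.shape[0]
        s1 += x.sum(axis=0)
        s2 += (x ** 2).sum(axis=0)
    mean = s1 / n_total
    var = s2 / n_total - mean ** 2
    var = np.maximum(var, 0.0)
    if np.any(var <= 0):
        bad = [ax for ax, v in zip("xyz", var) if v <= 0]
        raise ValueError(f"zero variance on axis/axes {bad}: cannot standardize")
    return StandardizationStats(mean=mean, std=np.sqrt(var), scope="corpus")


def apply_standardization(w: Window, stats: StandardizationStats) -> Window:
    if stats.scope == "none":
        return w
    out = (w.samples - stats.mean[:, None].astype(np.float32)) / \
        stats.std[:, None].astype(np.float32)
    return Window(samples=out, label=w.label, subject_id=w.subject_id,
                  start_time_s=w.start_time_s)


def invert_standardization(w: Window, stats: StandardizationStats) -> Window:
    if stats.scope == "none":
        return w
    out = w.samples * stats.std[:, None].astype(np.float32) + \
        stats.mean[:, None].astype(np.float32)
    return Window(samples=out, label=w.label, subject_id=w.subject_id,
                  start_time_s=w.start_time_s)


def read_recording_csv(path, fs: float | None = None,
                       subject_id: str | None = None) -> Recording:
    """Read a ``time,x,y,z[,label[,subject_id]]`` CSV (either header dialect).

    The sampling rate is inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tcol = cols.get("time_s", cols.get("time"))
    if tcol is None or not {"x", "y", "z"} <= set(cols):
        raise ValueError("expected columns time[,_s],x,y,z[,label]")
    t = df[tcol].to_numpy(dtype=float)
    if fs is None:
        dt = np.median(np.diff(t))
        if not np.isfinite(dt) or dt <= 0:
            raise ValueError("cannot infer sampling rate from time column")
        fs = float(round(1.0 / dt, 6))
    samples = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=np.float32)
    labels = df[cols["label"]].to_numpy(dtype=np.int64) if "label" in cols else None
    if subject_id is None:
        subject_id = (str(df[cols["subject_id"]].iloc[0])
                      if "subject_id" in cols else "anon")
    return Recording(samples=samples, fs=fs, labels=labels,
                     subject_id=subject_id, device_range_g=None,
                     start_time_s=float(t[0]))
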