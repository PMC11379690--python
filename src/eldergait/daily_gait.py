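"""Continuous multi-day inference and construct-validity statistics.

Pipeline for a multi-day wrist recording: detect non-wear (sustained
near-zero variance on every axis for >= 30 min), select the first four
complete 24-h days with enough wear time, classify every worn 10-s window
with the fine-tuned model, merge consecutive gait windows into bouts, and
summarize walking as the median across the four days of per-day walking
minutes.

Construct validity: daily walking duration is compared across clinical
strata with the Kruskal-Wallis omnibus test, Dunn's pairwise post-hoc z
tests (tie-corrected, Bonferroni-adjusted), and partial correlations
adjusted for age, sex and BMI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .finetune_eval import predict_dataset
from .model_core import GaitModel
from .preprocess import TARGET_FS, WINDOW_SAMPLES, WINDOW_SECONDS, Recording
from .synthetic_data import DAY_SECONDS

#: conventional actigraphy non-wear variance cut-off (13 mg) and block length
DEFAULT_NONWEAR_STD_G = 0.013
NONWEAR_BLOCK_S = 60.0
DEFAULT_MIN_NONWEAR_MIN = 30
MIN_WEAR_HOURS_PER_DAY = 20.0


@dataclass
class WearMask:
    """Alternating (start_s, end_s, wearing) intervals partitioning a trace."""

    intervals: list[tuple[float, float, bool]]

    def wearing_track(self, n_samples: int, fs: float,
                      start_time_s: float = 0.0) -> np.ndarray:
        track = np.ones(n_samples, dtype=bool)
        t = start_time_s + np.arange(n_samples) / fs
        for lo, hi, wearing in self.intervals:
            if not wearing:
                track[(t >= lo) & (t < hi)] = False
        return track

    def wear_seconds(self, lo_s: float, hi_s: float) -> float:
        total = 0.0
        for a, b, wearing in self.intervals:
            if wearing:
                total += max(0.0, min(b, hi_s) - max(a, lo_s))
        return total


def detect_nonwear(rec: Recording, threshold_g: float = DEFAULT_NONWEAR_STD_G,
                   min_duration_min: float = DEFAULT_MIN_NONWEAR_MIN) -> WearMask:
    """Flag maximal runs of low-variance 1-min blocks lasting >= 30 min.

    A block is a non-wear candidate when the standard deviation of *every*
    axis stays below ``threshold_g``; only runs of at least
    ``min_duration_min`` consecutive candidate blocks become non-wear.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("detect_nonwear expects a 30 Hz recording")
    block = int(NONWEAR_BLOCK_S * rec.fs)
    n_blocks = rec.n_samples // block
    t0 = rec.start_time_s
    end_s = t0 + rec.duration_s
    if n_blocks == 0:
        return WearMask(intervals=[(t0, end_s, True)])
    x = rec.samples[:n_blocks * block].reshape(n_blocks, block, 3)
    low = (x.std(axis=1) < threshold_g).all(axis=1)
    min_blocks = int(np.ceil(min_duration_min * 60.0 / NONWEAR_BLOCK_S))
    intervals: list[tuple[float, float, bool]] = []
    i = 0
    while i < n_blocks:
        j = i
        while j < n_blocks and low[j] == low[i]:
            j += 1
        run_is_nonwear = bool(low[i]) and (j - i) >= min_blocks
        lo_s = t0 + i * NONWEAR_BLOCK_S
        hi_s = t0 + j * NONWEAR_BLOCK_S
        _append_interval(intervals, lo_s, hi_s, not run_is_nonwear)
        i = j
    if end_s > t0 + n_blocks * NONWEAR_BLOCK_S:  # trailing partial block
        _append_interval(intervals, t0 + n_blocks * NONWEAR_BLOCK_S, end_s, True)
    return WearMask(intervals=intervals)


def _append_interval(intervals, lo_s, hi_s, wearing) -> None:
    if intervals and intervals[-1][2] == wearing:
        prev = intervals.pop()
        intervals.append((prev[0], hi_s, wearing))
    else:
        intervals.append((lo_s, hi_s, wearing))


@dataclass
class WindowPredictions:
    """Per-window decisions over one recording; excluded = any non-wear."""

    start_times_s: np.ndarray
    predictions: np.ndarray        # -1 for excluded windows
    probabilities: np.ndarray      # NaN for excluded windows

    @property
    def n_decided(self) -> int:
        return int((self.predictions >= 0).sum())


def predict_recording(model: GaitModel, rec: Recording,
                      wear_mask: WearMask | None = None,
                      batch_size: int = 512) -> WindowPredictions:
    """Classify every worn window of a 30 Hz recording.

    Windows overlapping non-wear are excluded, never classified: non-wear
    masking takes precedence over gait prediction.
    """
    if rec.fs != TARGET_FS:
        raise ValueError("predict_recording expects a 30 Hz recording")
    if wear_mask is None:
        wear_mask = detect_nonwear(rec)
    wear = wear_mask.wearing_track(rec.n_samples, rec.fs, rec.start_time_s)
    n_win = rec.n_samples // WINDOW_SAMPLES
    starts = rec.start_time_s + np.arange(n_win) * WINDOW_SECONDS
    wear_win = wear[:n_win * WINDOW_SAMPLES].reshape(n_win, WINDOW_SAMPLES)
    decided = wear_win.all(axis=1)
    predictions = np.full(n_win, -1, dtype=np.int64)
    probabilities = np.full(n_win, np.nan)
    if decided.any():
        X = rec.samples[:n_win * WINDOW_SAMPLES].reshape(n_win, WINDOW_SAMPLES, 3)
        X = X[decided].transpose(0, 2, 1).astype(np.float32)
        preds, probs = predict_dataset(model, X, batch_size=batch_size)
        predictions[decided] = preds
        probabilities[decided] = probs
    return WindowPredictions(start_times_s=starts, predictions=predictions,
                             probabilities=probabilities)


@dataclass
class GaitBout:
    start_s: float
    end_s: float
    n_windows: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def assemble_bouts(preds: WindowPredictions) -> list[GaitBout]:
    """Merge maximal runs of consecutive gait windows into bouts."""
    bouts: list[GaitBout] = []
    run_start = None
    run_len = 0
    for t, p in zip(preds.start_times_s, preds.predictions):
        if p == 1:
            if run_start is None:
                run_start = t
                run_len = 0
            run_len += 1
        else:
            if run_start is not None:
                bouts.append(GaitBout(run_start, run_start + run_len * WINDOW_SECONDS,
                                      run_len))
            run_start = None
    if run_start is not None:
        bouts.append(GaitBout(run_start, run_start + run_len * WINDOW_SECONDS,
                              run_len))
    return bouts


@dataclass
class DaySelection:
    days: list[tuple[float, float]]   # (start_s, end_s) of selected days
    excluded: bool
    reason: str = ""


def select_full_days(rec: Recording, wear_mask: WearMask,
                     n_days: int = 4,
                     min_wear_hours: float = MIN_WEAR_HOURS_PER_DAY,
                     ) -> DaySelection:
    """First ``n_days`` complete calendar days with enough wear time.

    Calendar days are 24-h spans aligned to the recording's start timestamp's
    day boundary. A day counts as full when it lies entirely inside the
    recording and has >= ``min_wear_hours`` of wear. Subjects without four
    such days are flagged excluded (insufficient data), not raised.
    """
    first_day = np.floor(rec.start_time_s / DAY_SECONDS) * DAY_SECONDS
    if first_day < rec.start_time_s:
        first_day += DAY_SECONDS
    end_s = rec.start_time_s + rec.duration_s
    days: list[tuple[float, float]] = []
    d = first_day
    while d + DAY_SECONDS <= end_s + 1e-9 and len(days) < n_days:
        wear_h = wear_mask.wear_seconds(d, d + DAY_SECONDS) / 3600.0
        if wear_h >= min_wear_hours:
            days.append((d, d + DAY_SECONDS))
        d += DAY_SECONDS
    if len(days) < n_days:
        return DaySelection(days=days, excluded=True,
                            reason=f"only {len(days)} full days available")
    return DaySelection(days=days, excluded=False)


@dataclass
class DailySummary:
    subject_id: str
    per_day_minutes: list[float]
    daily_walk_min: float
    per_day_bout_counts: list[int] = field(default_factory=list)
    daily_bout_count: float = np.nan
    covariates: dict = field(default_factory=dict)
    excluded: bool = False


def daily_walking_time(bouts_per_day: Sequence[Sequence[GaitBout]],
                       subject_id: str = "anon",
                       covariates: dict | None = None) -> DailySummary:
    """Median over the four analyzed days of per-day walking minutes.

    Per-day minutes sum the durations of that day's detected gait bouts; the
    even-count median is the mean of the two middle values. The per-day bout
    *count* is carried as an alternative summary column.
    """
    if len(bouts_per_day) != 4:
        raise ValueError("exactly 4 day spans are analyzed")
    minutes = [sum(b.duration_s for b in day) / 60.0 for day in bouts_per_day]
    counts = [len(day) for day in bouts_per_day]
    return DailySummary(subject_id=subject_id, per_day_minutes=minutes,
                        daily_walk_min=float(np.median(minutes)),
                        per_day_bout_counts=counts,
                        daily_bout_count=float(np.median(counts)),
                        covariates=covariates or {})


def analyze_recording(model: GaitModel, rec: Recording,
                      covariates: dict | None = None) -> DailySummary:
    """Full daily-gait pipeline for one subject's multi-day 30 Hz recording."""
    mask = detect_nonwear(rec)
    selection = select_full_days(rec, mask)
    if selection.excluded:
        return DailySummary(subject_id=rec.subject_id, per_day_minutes=[],
                            daily_walk_min=np.nan, covariates=covariates or {},
                            excluded=True)
    preds = predict_recording(model, rec, wear_mask=mask)
    bouts = assemble_bouts(preds)
    bouts_per_day = []
    for lo, hi in selection.days:
        bouts_per_day.append([b for b in bouts if lo <= b.start_s < hi])
    return daily_walking_time(bouts_per_day, subject_id=rec.subject_id,
                              covariates=covariates)


def summaries_to_frame(summaries: Iterable[DailySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append({"subject_id": s.subject_id,
                     "daily_walk_min": s.daily_walk_min,
                     "daily_bout_count": s.daily_bout_count,
                     "excluded": s.excluded, **s.covariates})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# construct-validity statistics


@dataclass
class GroupTestReport:
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group_a, group_b, dunn_z, p_unadjusted, p_adjusted


def _dunn_pairwise(values: list[np.ndarray], labels: list) -> pd.DataFrame:
    """Dunn's z tests on pooled ranks with tie correction; Bonferroni-adjusted."""
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_total - 1))
    splits = np.cumsum([len(v) for v in values])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [len(v) for v in values]
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(len(values)), 2))
    rows = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "dunn_z": z, "p_unadjusted": p,
                     "p_adjusted": min(1.0, p * len(pairs))})
    return pd.DataFrame(rows)


def group_difference_tests(summaries: pd.DataFrame, group_col: str,
                           value_col: str = "daily_walk_min") -> GroupTestReport:
    """Kruskal-Wallis omnibus + Dunn post-hoc with Bonferroni correction."""
    df = summaries.dropna(subset=[value_col, group_col])
    groups = sorted(df[group_col].unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    values = [df.loc[df[group_col] == g, value_col].to_numpy(float)
              for g in groups]
    if any(len(v) < 2 for v in values):
        small = [g for g, v in zip(groups, values) if len(v) < 2]
        raise ValueError(f"groups with < 2 members: {small}")
    h, p = stats.kruskal(*values)
    return GroupTestReport(kruskal_h=float(h), kruskal_p=float(p),
                           pairwise=_dunn_pairwise(values, groups))


def partial_correlation(summaries: pd.DataFrame, x_col: str, y_col: str,
                        covariate_cols: Sequence[str] = ("age", "sex", "bmi"),
                        ) -> tuple[float, float]:
    """Partial correlation of x and y adjusted for the covariates.

    Residualizes both variables on the covariates (plus an intercept) by
    least squares and correlates the residuals; the p-value is t-based on
    n - k - 2 degrees of freedom for k covariates.
    """
    covariate_cols = list(covariate_cols)
    df = summaries.dropna(subset=[x_col, y_col, *covariate_cols])
    n, k = len(df), len(covariate_cols)
    if n <= k + 2:
        raise ValueError("not enough observations for the partial correlation")
    A = np.column_stack([np.ones(n), df[covariate_cols].to_numpy(float)])
    x = df[x_col].to_numpy(float)
    y = df[y_col].to_numpy(float)
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:  # a variable fully explained by the covariates
        return 0.0, 1.0
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r ** 2))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p
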