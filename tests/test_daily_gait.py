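"""Non-wear masking, bout assembly, daily summaries and cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import kruskal_h_oracle
from eldergait import daily_gait as dg
from eldergait import preprocess as pp
from eldergait import synthetic_data as sd
from eldergait.synthetic_data import DAY_SECONDS


def active_samples(n, rng, std=0.1):
    return (rng.normal(0.0, std, (n, 3)) + np.array([0, 0, 1.0])).astype(np.float32)


def flat_samples(n, rng, std=0.001):
    return (rng.normal(0.0, std, (n, 3)) + np.array([0, 0, 1.0])).astype(np.float32)


class TestDetectNonwear:
    def make_rec(self, flat_minutes):
        rng = np.random.default_rng(0)
        parts = [active_samples(40 * 60 * 30, rng),
                 flat_samples(int(flat_minutes * 60 * 30), rng),
                 active_samples(40 * 60 * 30, rng)]
        return pp.Recording(samples=np.concatenate(parts), fs=30,
                            device_range_g=None)

    def test_31min_flat_segment_flagged(self):
        mask = dg.detect_nonwear(self.make_rec(31))
        nonwear = [iv for iv in mask.intervals if not iv[2]]
        assert len(nonwear) == 1
        lo, hi, _ = nonwear[0]
        assert hi - lo >= 30 * 60

    def test_29min_flat_segment_not_flagged(self):
        mask = dg.detect_nonwear(self.make_rec(29))
        assert all(w for _, _, w in mask.intervals)

    def test_all_active_single_wearing_interval(self):
        rng = np.random.default_rng(1)
        rec = pp.Recording(samples=active_samples(45 * 60 * 30, rng), fs=30,
                           device_range_g=None)
        mask = dg.detect_nonwear(rec)
        assert mask.intervals == [(0.0, rec.duration_s, True)]


class TestAssembleBouts:
    def make_preds(self, pattern):
        pattern = np.asarray(pattern)
        return dg.WindowPredictions(
            start_times_s=np.arange(len(pattern)) * 10.0,
            predictions=pattern,
            probabilities=np.where(pattern >= 0, 0.9, np.nan))

    def test_example_pattern(self):
        bouts = dg.assemble_bouts(self.make_preds([0, 1, 1, 0, 1, 0]))
        assert [(b.start_s, b.duration_s) for b in bouts] == \
            [(10.0, 20.0), (40.0, 10.0)]

    def test_all_zero_gives_empty(self):
        assert dg.assemble_bouts(self.make_preds([0] * 6)) == []

    def test_all_ones_single_bout(self):
        bouts = dg.assemble_bouts(self.make_preds([1] * 12))
        assert len(bouts) == 1 and bouts[0].duration_s == 120.0

    def test_duration_conservation(self):
        rng = np.random.default_rng(2)
        pattern = rng.integers(0, 2, 500)
        bouts = dg.assemble_bouts(self.make_preds(pattern))
        assert sum(b.duration_s for b in bouts) == 10.0 * pattern.sum()


class TestSelectFullDays:
    def day_mask(self, wear_hours_per_day, total_days):
        """WearMask with the given wear hours placed at each day's start."""
        intervals = []
        for d in range(total_days):
            t0 = d * DAY_SECONDS
            wear_s = wear_hours_per_day[d] * 3600.0
            if wear_s > 0:
                intervals.append((t0, t0 + wear_s, True))
            if wear_s < DAY_SECONDS:
                intervals.append((t0 + wear_s, t0 + DAY_SECONDS, False))
        return dg.WearMask(intervals=intervals)

    def fake_rec(self, days):
        # 1 sample per minute keeps the fixture tiny; day selection only
        # reads the start time and duration
        n = int(days * 24 * 60)
        return pp.Recording(samples=np.zeros((n, 3), np.float32), fs=1 / 60.0,
                            device_range_g=None)

    def test_five_days_gives_first_four(self):
        sel = dg.select_full_days(self.fake_rec(5), self.day_mask([24] * 5, 5))
        assert not sel.excluded
        assert sel.days == [(d * DAY_SECONDS, (d + 1) * DAY_SECONDS)
                            for d in range(4)]

    def test_three_days_flags_excluded(self):
        sel = dg.select_full_days(self.fake_rec(3), self.day_mask([24] * 3, 3))
        assert sel.excluded

    def test_low_wear_day_skipped(self):
        sel = dg.select_full_days(self.fake_rec(5),
                                  self.day_mask([24, 10, 24, 24, 24], 5))
        assert not sel.excluded
        assert sel.days[0] == (0.0, DAY_SECONDS)
        assert sel.days[1] == (2 * DAY_SECONDS, 3 * DAY_SECONDS)


class TestDailyWalkingTime:
    def bouts_of_minutes(self, minutes):
        n_windows = int(round(minutes * 6))
        return [dg.GaitBout(0.0, n_windows * 10.0, n_windows)]

    def test_odd_pattern_median(self):
        days = [self.bouts_of_minutes(m) for m in (2, 3, 3, 5)]
        assert dg.daily_walking_time(days).daily_walk_min == pytest.approx(3.0)

    def test_even_count_median_is_mean_of_middle_two(self):
        days = [self.bouts_of_minutes(m) for m in (2, 3, 4, 5)]
        assert dg.daily_walking_time(days).daily_walk_min == pytest.approx(3.5)

    def test_twelve_windows_are_two_minutes(self):
        days = [[dg.GaitBout(0.0, 120.0, 12)]] + [[] for _ in range(3)]
        s = dg.daily_walking_time(days)
        assert s.per_day_minutes[0] == pytest.approx(2.0)

    def test_requires_four_days(self):
        with pytest.raises(ValueError, match="4 day"):
            dg.daily_walking_time([[], []])


class TestGroupStats:
    def test_kruskal_matches_rank_formula(self):
        df = pd.DataFrame({"daily_walk_min": [1, 2, 3, 4, 5, 6],
                           "group": list("aaabbb")})
        rep = dg.group_difference_tests(df, "group")
        assert rep.kruskal_h == pytest.approx(3.857, abs=1e-3)
        assert rep.kruskal_h == pytest.approx(
            kruskal_h_oracle([[1, 2, 3], [4, 5, 6]]), abs=1e-9)

    def test_dunn_hand_computed_example(self):
        # groups {1,2,3} vs {4,5,6}: mean ranks 2 and 5, no ties,
        # se = sqrt(3.5 * 2/3), z = -3/se = -1.9640, p = 0.0495
        df = pd.DataFrame({"daily_walk_min": [1, 2, 3, 4, 5, 6],
                           "group": list("aaabbb")})
        rep = dg.group_difference_tests(df, "group")
        row = rep.pairwise.iloc[0]
        assert row.dunn_z == pytest.approx(-1.9640, abs=1e-3)
        assert row.p_adjusted == pytest.approx(0.0495, abs=1e-3)

    def test_identical_groups_null(self):
        df = pd.DataFrame({"daily_walk_min": [1, 2, 3, 1, 2, 3],
                           "group": list("aaabbb")})
        rep = dg.group_difference_tests(df, "group")
        assert rep.kruskal_h == pytest.approx(0.0, abs=1e-9)
        assert (rep.pairwise.p_adjusted == 1.0).all()

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        rows = []
        for g, mu in (("0", 120.0), ("1", 80.0), ("2", 40.0)):
            for v in rng.normal(mu, 10.0, 30):
                rows.append({"daily_walk_min": v, "group": g})
        rep = dg.group_difference_tests(pd.DataFrame(rows), "group")
        assert rep.kruskal_p < 0.01
        extreme = rep.pairwise[(rep.pairwise.group_a == "0")
                               & (rep.pairwise.group_b == "2")]
        assert float(extreme.p_adjusted.iloc[0]) < 0.05

    def test_small_groups_rejected(self):
        df = pd.DataFrame({"daily_walk_min": [1, 2, 3], "group": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="2 members"):
            dg.group_difference_tests(df, "group")


class TestPartialCorrelation:
    def test_x_equals_y_gives_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(0, 1, 50)})
        df["y"] = df["x"]
        df["age"] = rng.normal(80, 5, 50)
        df["sex"] = rng.integers(0, 2, 50)
        df["bmi"] = rng.normal(27, 3, 50)
        rho, _ = dg.partial_correlation(df, "x", "y")
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_pure_covariate_effect_removed(self):
        rng = np.random.default_rng(5)
        age = rng.normal(80, 5, 200)
        df = pd.DataFrame({"x": rng.normal(0, 1, 200), "y": age, "age": age,
                           "sex": rng.integers(0, 2, 200),
                           "bmi": rng.normal(27, 3, 200)})
        rho, _ = dg.partial_correlation(df, "x", "y")
        assert abs(rho) < 0.1

    def test_independent_covariates_match_pearson(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "age": rng.normal(80, 5, n),
                           "sex": rng.integers(0, 2, n),
                           "bmi": rng.normal(27, 3, n)})
        rho, _ = dg.partial_correlation(df, "x", "y")
        pearson = sps.pearsonr(x, y)[0]
        assert rho == pytest.approx(pearson, abs=0.05)

    def test_matches_pingouin_on_regular_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n = 150
        df = pd.DataFrame({"age": rng.normal(80, 5, n),
                           "sex": rng.integers(0, 2, n).astype(float),
                           "bmi": rng.normal(27, 3, n)})
        df["x"] = 0.1 * df.age + rng.normal(0, 1, n)
        df["y"] = -0.3 * df.x + 0.05 * df.bmi + rng.normal(0, 1, n)
        rho, p = dg.partial_correlation(df, "x", "y")
        ref = pg.partial_corr(data=df, x="x", y="y", covar=["age", "sex", "bmi"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(7)
        n = 120
        cov = rng.normal(0, 1, (n, 3))
        x = cov @ [0.5, -0.2, 0.1] + rng.normal(0, 1, n)
        y = 0.4 * x + cov @ [0.3, 0.1, -0.4] + rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y": y, "age": cov[:, 0], "sex": cov[:, 1],
                           "bmi": cov[:, 2]})
        rho, _ = dg.partial_correlation(df, "x", "y")
        # independent oracle: correlate OLS residuals
        A = np.column_stack([np.ones(n), cov])
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert rho == pytest.approx(sps.pearsonr(rx, ry)[0], abs=1e-6)


class TestPredictRecording:
    def make_recording(self, n_windows=90, seed=0):
        rng = np.random.default_rng(seed)
        return pp.Recording(samples=active_samples(n_windows * 300, rng),
                            fs=30, device_range_g=None)

    def test_masking_arithmetic(self, fixture_model):
        rec = self.make_recording(90)
        # mark 10 windows (100 s) as non-wear via an explicit mask
        mask = dg.WearMask(intervals=[(0.0, 100.0, False),
                                      (100.0, rec.duration_s, True)])
        preds = dg.predict_recording(fixture_model, rec, wear_mask=mask)
        assert len(preds.predictions) == 90
        assert preds.n_decided == 80
        assert (preds.predictions[:10] == -1).all()
        assert np.isnan(preds.probabilities[:10]).all()

    def test_deterministic(self, fixture_model):
        rec = self.make_recording(30, seed=1)
        a = dg.predict_recording(fixture_model, rec)
        b = dg.predict_recording(fixture_model, rec)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_bout_recall_on_separable_recording(self, fixture_model):
        profile = sd.ActivityProfile(arm_swing_amplitude_g=0.35)
        states = []
        for _ in range(6):
            states += [("rest", 120.0), ("gait", 60.0), ("activity", 60.0)]
        rec = sd.simulate_recording(profile, sd.BoutSchedule(states), fs=30,
                                    seed=11, subject_id="probe")
        preds = dg.predict_recording(fixture_model, rec)
        true_gait = rec.labels.reshape(-1, 300).mean(axis=1) >= 0.5
        detected = preds.predictions == 1
        recall = detected[true_gait].mean()
        assert recall >= 0.9


def test_estimation_accuracy_within_ten_percent(fixture_model):
    """Per-subject |estimated - true| daily walking <= 10% of true."""
    spec = sd.SyntheticCohortSpec(groups=[sd.GroupSpec("g", 2, 60.0, 15.0)])
    for rec, meta in sd.iter_cohort(spec, seed=21):
        summary = dg.analyze_recording(fixture_model, rec)
        assert not summary.excluded
        true = meta["true_median_daily_walk_min"]
        assert abs(summary.daily_walk_min - true) <= 0.10 * true
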