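"""Agreement statistics: quartile tables, ICC(2,k), Bland-Altman, Mann-Whitney."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gaitval import (
    DetectionCounts,
    MatchedStridePair,
    absolute_error_quartiles,
    bland_altman,
    detection_summary,
    icc2k,
    icc2k_for_feature,
    mann_whitney_two_sided,
)
from gaitval.agreement import distance_summary, left_right_tests, pairs_frame


def _pairs(diffs, exercise="normal_walk", foot="left", base=1.5):
    return [MatchedStridePair(
        imu_length=base + d, imu_velocity=(base + d) / 1.1,
        mocap_length=base, mocap_velocity=base / 1.1,
        imu_midpoint=float(i), mocap_midpoint=float(i),
        exercise=exercise, foot=foot, subject="01")
        for i, d in enumerate(diffs)]


class TestQuartiles:
    def test_four_point_median(self):
        tab = absolute_error_quartiles(_pairs([0.01, 0.02, 0.03, 0.04]), "length")
        row = tab[(tab.exercise == "overall") & (tab.side == "overall")].iloc[0]
        assert row["median"] == pytest.approx(0.025)

    def test_matches_sorted_array_oracle(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(0.0, 0.03, 1000)
        tab = absolute_error_quartiles(_pairs(diffs), "length")
        row = tab[(tab.exercise == "overall") & (tab.side == "overall")].iloc[0]
        srt = np.sort(np.abs(diffs))

        def quantile(q):
            # linear-interpolation (type 7) definition on the sorted array
            h = (len(srt) - 1) * q
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert row["q1"] == pytest.approx(quantile(0.25), abs=1e-12)
        assert row["median"] == pytest.approx(quantile(0.5), abs=1e-12)
        assert row["q3"] == pytest.approx(quantile(0.75), abs=1e-12)

    def test_all_zero_diffs(self):
        tab = absolute_error_quartiles(_pairs([0.0] * 10), "length")
        assert (tab[["q1", "median", "q3"]].to_numpy() == 0.0).all()

    def test_quartiles_ordered(self):
        rng = np.random.default_rng(1)
        tab = absolute_error_quartiles(_pairs(rng.normal(0, 0.05, 200)), "velocity")
        assert (tab.q1 <= tab["median"]).all()
        assert (tab["median"] <= tab.q3).all()
        assert (tab.q1 >= 0).all()

    def test_groups_by_exercise_and_side(self):
        pairs = (_pairs([0.01] * 5, "normal_walk", "left")
                 + _pairs([0.02] * 5, "normal_walk", "right")
                 + _pairs([0.03] * 5, "fast_walk", "left"))
        tab = absolute_error_quartiles(pairs, "length")
        keyed = {(r.exercise, r.side): r for r in tab.itertuples()}
        assert keyed[("normal_walk", "left")].median == pytest.approx(0.01)
        assert keyed[("normal_walk", "right")].median == pytest.approx(0.02)
        assert keyed[("fast_walk", "left")].median == pytest.approx(0.03)
        assert keyed[("overall", "overall")].n == 15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            absolute_error_quartiles([], "length")


def _icc_oracle(x, y):
    """Independent two-way ANOVA decomposition for k=2 raters."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = float(((data - grand) ** 2).sum())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestIcc:
    def test_duplicated_columns_give_one(self):
        x = np.array([1.1, 1.5, 0.9, 2.0, 1.7, 1.3])
        res = icc2k(x, x.copy())
        assert res.icc2k == pytest.approx(1.0, abs=1e-12)

    def test_six_by_two_anova_oracle(self):
        x = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        res = icc2k(x, y)
        assert res.icc2k == pytest.approx(_icc_oracle(x, y), abs=1e-10)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.uniform(0.5, 2.5, 30)
            y = x + rng.normal(0.0, 0.1, 30)
            res = icc2k(x, y)
            assert res.icc2k == pytest.approx(_icc_oracle(x, y), abs=1e-10)

    def test_against_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.uniform(0.5, 2.5, 25)
            y = x + rng.normal(0.0, 0.08, 25)
            res = icc2k(x, y)
            long = pd.DataFrame({
                "target": np.repeat(np.arange(25), 2),
                "rater": np.tile(["a", "b"], 25),
                "score": np.column_stack([x, y]).ravel()})
            ref = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                           ratings="score")
            ref_val = float(ref.loc[ref.Type == "ICC(A,k)", "ICC"].iloc[0])
            assert res.icc2k == pytest.approx(ref_val, abs=1e-6)

    def test_simulated_study_scale_exceeds_99(self):
        rng = np.random.default_rng(42)
        truth = rng.uniform(0.5, 2.5, 2820)
        a = truth + rng.normal(0.0, 0.025, 2820)
        b = truth + rng.normal(0.0, 0.001, 2820)
        res = icc2k(a, b)
        assert res.icc2k >= 0.99

    def test_ci_covers_point_estimate(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.5, 2.5, 40)
        y = x + rng.normal(0.0, 0.2, 40)
        res = icc2k(x, y)
        assert res.ci95[0] <= res.icc2k <= res.ci95[1]
        assert res.icc2k <= 1.0

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValueError):
            icc2k(np.ones(4), np.ones(4))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc2k(np.full(10, 1.5), np.full(10, 1.5))

    def test_for_feature_wrapper(self):
        rng = np.random.default_rng(7)
        pairs = _pairs(rng.normal(0, 0.02, 50))
        res = icc2k_for_feature(pairs, "length")
        assert res.n_targets == 50 and res.k_raters == 2


class TestBlandAltman:
    def test_constant_offset_bias_exact(self):
        res = bland_altman(_pairs([0.03] * 10), "length")
        assert res.bias == pytest.approx(0.03, abs=1e-15)
        assert res.sd == 0.0

    def test_zero_differences_degenerate_band(self):
        res = bland_altman(_pairs([0.0] * 10), "length")
        assert res.bias == 0.0
        assert res.band == (0.0, 0.0)

    def test_band_width_is_twice_sd(self):
        rng = np.random.default_rng(8)
        res = bland_altman(_pairs(rng.normal(0.01, 0.02, 200)), "length")
        assert res.band[1] - res.band[0] == pytest.approx(2 * res.sd, abs=1e-12)

    def test_conventional_limits_flag(self):
        rng = np.random.default_rng(9)
        res = bland_altman(_pairs(rng.normal(0.0, 0.02, 200)), "length",
                           band_multiplier=1.96)
        assert res.band[1] - res.band[0] == pytest.approx(2 * 1.96 * res.sd,
                                                          abs=1e-12)

    def test_clt_bias_bound(self):
        # symmetric noise: |bias| < 3 sd / sqrt(n) almost surely (CLT)
        rng = np.random.default_rng(10)
        res = bland_altman(_pairs(rng.normal(0.0, 0.05, 1000)), "length")
        assert abs(res.bias) < 3 * res.sd / np.sqrt(1000)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs([0.01]), "length")

    def test_fraction_outside_band(self):
        rng = np.random.default_rng(11)
        res = bland_altman(_pairs(rng.normal(0.0, 0.05, 2000)), "length")
        # mu +- sigma contains ~68% of a normal sample
        assert 0.25 < res.fraction_outside < 0.40


class TestMannWhitney:
    def test_identical_samples_large_p(self):
        x = np.arange(30, dtype=float)
        res = mann_whitney_two_sided(x, x.copy())
        assert res.p_value > 0.9

    def test_exact_small_sample(self):
        res = mann_whitney_two_sided([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_exact_equals_permutation_oracle(self):
        # brute-force enumeration of all assignments for tie-free n <= 8
        rng = np.random.default_rng(12)
        for _ in range(5):
            pool = rng.permutation(rng.uniform(0, 10, 9))
            x, y = pool[:4], pool[4:]
            res = mann_whitney_two_sided(x, y)

            def u_stat(a, b):
                return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)

            u_obs = u_stat(x, y)
            n1 = len(x)
            both = np.concatenate([x, y])
            us = [u_stat(both[list(c)],
                         both[[i for i in range(len(both)) if i not in c]])
                  for c in itertools.combinations(range(len(both)), n1)]
            mu = n1 * (len(both) - n1) / 2.0
            p_oracle = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(13)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0.0, 1.0, 25)
            y = rng.normal(0.0, 1.0, 25)
            if mann_whitney_two_sided(x, y).p_value < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_sided([], [1.0])

    def test_u_bounded(self):
        res = mann_whitney_two_sided([1.0, 2.0], [3.0, 4.0, 5.0])
        assert res.u_statistic <= res.n_left * res.n_right

    def test_left_right_table(self):
        pairs = (_pairs([0.01, 0.02, 0.03] * 4, foot="left")
                 + _pairs([0.015, 0.025, 0.035] * 4, foot="right"))
        tab = left_right_tests(pairs)
        assert set(tab.scope) == {"all", "normal_walk"}
        assert set(tab.feature) == {"length", "velocity"}
        assert ((tab.p_value >= 0) & (tab.p_value <= 1)).all()


class TestDetectionSummary:
    def test_printed_fn_fraction(self):
        counts = {("all_exercises", "both"): DetectionCounts(tp=6218, fp=19, fn=262)}
        tab = detection_summary(counts)
        total = tab[(tab.exercise == "all") & (tab.side == "all")].iloc[0]
        fn_fraction = total.fn / total.truth_total
        assert round(100 * fn_fraction, 1) == 4.0

    def test_undefined_rate_flagged(self):
        tab = detection_summary({("tug", "left"): DetectionCounts(0, 3, 0)})
        row = tab[(tab.exercise == "tug")].iloc[0]
        assert bool(row.rate_undefined)
        assert np.isnan(row.true_positive_rate)

    def test_three_exercise_toy_rates(self):
        counts = {
            ("a", "left"): DetectionCounts(tp=9, fp=1, fn=1),
            ("b", "left"): DetectionCounts(tp=18, fp=0, fn=2),
            ("c", "right"): DetectionCounts(tp=27, fp=3, fn=3),
        }
        tab = detection_summary(counts)
        keyed = {(r.exercise, r.side): r for r in tab.itertuples()}
        assert keyed[("a", "left")].true_positive_rate == pytest.approx(0.9)
        assert keyed[("b", "left")].true_positive_rate == pytest.approx(0.9)
        assert keyed[("c", "right")].true_positive_rate == pytest.approx(0.9)
        total = keyed[("all", "all")]
        assert total.tp == 54 and total.fp == 4 and total.fn == 6
        assert total.true_positive_rate == pytest.approx(54 / 60)


class TestDistanceSummary:
    def test_totals_per_group(self):
        import pandas as pd

        rows = ([dict(subject="01", exercise="normal_walk", foot="left",
                      system="imu", length_m=1.5)] * 4
                + [dict(subject="01", exercise="normal_walk", foot="left",
                        system="mocap", length_m=1.4)] * 2)
        tab = distance_summary(pd.DataFrame(rows))
        imu = tab[tab.system == "imu"].iloc[0]
        moc = tab[tab.system == "mocap"].iloc[0]
        assert imu.total_distance_m == pytest.approx(6.0)
        assert imu.n_strides == 4
        assert moc.total_distance_m == pytest.approx(2.8)


class TestPairsFrame:
    def test_signed_diffs_exact(self):
        pairs = _pairs([0.02, -0.01])
        df = pairs_frame(pairs)
        for p, r in zip(pairs, df.itertuples()):
            assert r.diff_length_m == p.imu_length - p.mocap_length
            assert r.diff_velocity_mps == p.imu_velocity - p.mocap_velocity
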