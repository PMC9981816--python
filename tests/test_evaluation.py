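import numpy as np
import pandas as pd
import pytest

from cogem import (
    aggregate_metrics,
    compare_feature_sets,
    map_r2,
    noise_ceiling_table,
    session_avg_corr,
    split_type_breakdown,
    subject_accuracy,
    task_noise_ceiling,
    two_way_classify,
)
from cogem.evaluation import SplitResult, pearson_r


def make_split(subject, tasks, correct, r=0.5, assignment=None):
    a, b = tasks
    if assignment is None:
        assignment = {a: a, b: b} if correct else {a: b, b: b}
    return SplitResult(
        subject=subject, tasks=tasks, alpha=1.0,
        r={a: r, b: r}, r2={a: r, b: r},
        assignment=assignment, correct=correct,
    )


class TestSessionAvgCorr:
    def test_identical_maps_give_one(self):
        m = np.array([1.0, 2.0, 3.0, 1.0])
        assert session_avg_corr(m, np.tile(m, (4, 1))) == pytest.approx(1.0)

    def test_opposite_sessions_average_to_zero(self):
        pred = np.array([1.0, 2.0, 3.0])
        sessions = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert session_avg_corr(pred, sessions) == pytest.approx(0.0)

    def test_region_permutation_invariance(self, rng):
        pred = rng.standard_normal(30)
        sessions = rng.standard_normal((3, 30))
        perm = rng.permutation(30)
        assert session_avg_corr(pred, sessions) == pytest.approx(
            session_avg_corr(pred[perm], sessions[:, perm])
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            session_avg_corr(np.ones(5), np.arange(5.0)[None, :])
        with pytest.raises(ValueError):
            pearson_r(np.arange(5.0), np.full(5, 2.0))


class TestMapR2:
    def test_perfect_prediction(self):
        obs = np.array([[0.0, 1.0, 2.0]])
        assert map_r2(obs[0], obs) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = np.array([[0.0, 1.0, 2.0]])
        assert map_r2(np.full(3, 1.0), obs) == pytest.approx(0.0)

    def test_hand_computed_negative_value(self):
        # 1 - (0 + 1 + 4) / 2 = -1.5
        assert map_r2(np.zeros(3), np.array([[0.0, 1.0, 2.0]])) == pytest.approx(-1.5)

    def test_zero_variance_observed_errors(self):
        with pytest.raises(ValueError):
            map_r2(np.arange(3.0), np.ones((1, 3)))


class TestTwoWayClassify:
    def test_faithful_predictions_correct(self, rng):
        obs_a = rng.standard_normal((2, 20))
        obs_b = rng.standard_normal((2, 20))
        assignment, correct, tied = two_way_classify(
            obs_a.mean(0), obs_b.mean(0), obs_a, obs_b, labels=("a", "b")
        )
        assert correct and assignment == {"a": "a", "b": "b"} and not tied

    def test_identical_predictions_never_correct(self, rng):
        pred = rng.standard_normal(20)
        obs_a = rng.standard_normal((2, 20))
        obs_b = rng.standard_normal((4, 20))
        assignment, correct, _ = two_way_classify(pred, pred, obs_a, obs_b)
        assert not correct
        assert assignment["a"] == assignment["b"]

    def test_swapped_predictions_both_wrong(self, rng):
        obs_a = rng.standard_normal((2, 20))
        obs_b = rng.standard_normal((2, 20))
        assignment, correct, _ = two_way_classify(
            obs_b.mean(0), obs_a.mean(0), obs_a, obs_b, labels=("a", "b")
        )
        assert not correct
        assert assignment == {"a": "b", "b": "a"}


class TestSubjectAccuracy:
    def test_extremes_and_fraction(self):
        all_good = [make_split("s", ("a", "b"), True)] * 4
        assert subject_accuracy(all_good) == 1.0
        none = [make_split("s", ("a", "b"), False)] * 4
        assert subject_accuracy(none) == 0.0
        half = all_good[:2] + none[:2]
        assert subject_accuracy(half) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            subject_accuracy([])


class TestNoiseCeiling:
    def test_identical_sessions_ceiling_one(self):
        m = np.arange(6.0)
        ceiling, n_valid, n_exc = task_noise_ceiling(
            np.tile(m, (2, 1)), (0, 0)
        )
        assert ceiling == pytest.approx(1.0)
        assert (n_valid, n_exc) == (1, 0)

    def test_sqrt_of_reliability(self, rng):
        # construct two maps with between-session r exactly 0.64
        x = rng.standard_normal(200)
        z = rng.standard_normal(200)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        zc = z - z.mean() - ((z - z.mean()) @ xc) * xc
        zc /= np.linalg.norm(zc)
        y = 0.64 * xc + np.sqrt(1 - 0.64**2) * zc
        ceiling, _, _ = task_noise_ceiling(np.vstack([xc, y]), (0, 0))
        assert ceiling == pytest.approx(0.8, abs=1e-9)

    def test_negative_reliability_flagged_undefined(self):
        m = np.array([1.0, 2.0, 3.0])
        ceiling, n_valid, n_exc = task_noise_ceiling(
            np.vstack([m, m[::-1]]), (0, 0)
        )
        assert np.isnan(ceiling)
        assert (n_valid, n_exc) == (0, 1)

    def test_two_timepoints_average_their_estimates(self):
        base = np.arange(8.0)
        # timepoint 0: identical (r=1 -> 1.0); timepoint 1: identical too
        maps = np.vstack([base, base, 2 * base, 2 * base])
        ceiling, n_valid, _ = task_noise_ceiling(maps, (0, 0, 1, 1))
        assert ceiling == pytest.approx(1.0)
        assert n_valid == 2

    def test_single_session_errors(self):
        with pytest.raises(ValueError):
            task_noise_ceiling(np.arange(4.0)[None, :], (0,))

    def test_table_covers_dataset(self, small_sim):
        _, _, data = small_sim
        table = noise_ceiling_table(data)
        assert len(table) == len(data.subjects) * len(data.task_ids)
        valid = table["ceiling"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()


class TestAggregateMetrics:
    def test_counts_match_combinatorics(self, small_splits):
        per_subject, per_task = aggregate_metrics(small_splits)
        # 10 tasks: every task appears in n-1 = 9 splits
        assert (per_task["n_appearances"] == 9).all()
        assert per_task["n_appearances"].sum() == 2 * len(small_splits)
        assert len(per_subject) == 1

    def test_single_split_summary_equals_split(self):
        s = make_split("s", ("a", "b"), True, r=0.7)
        per_subject, per_task = aggregate_metrics([s])
        assert per_subject["mean_r"].iloc[0] == pytest.approx(0.7)
        assert per_subject["accuracy"].iloc[0] == 1.0
        assert (per_task["mean_r"] == 0.7).all()

    def test_model_r_below_ceiling_on_moderate_noise(self, small_sim, small_splits):
        _, _, data = small_sim
        table = noise_ceiling_table(data)
        _, per_task = aggregate_metrics(small_splits, table)
        sub_rows = per_task[per_task["subject"] == data.subjects[0].subject]
        assert sub_rows["mean_r"].mean() <= sub_rows["ceiling"].mean() + 0.1


class TestCompareFeatureSets:
    def test_dof_match_design(self, rng):
        acc = pd.DataFrame(
            rng.random((23, 3)), columns=["all", "cognitive", "pm"]
        )
        res = compare_feature_sets(acc)
        assert res.df == (2, 44)
        assert len(res.pairwise) == 3
        assert (res.pairwise["df"] == 22).all()

    def test_identical_sets_give_zero_f(self, rng):
        col = rng.random(10)
        acc = pd.DataFrame({"a": col, "b": col, "c": col})
        res = compare_feature_sets(acc)
        assert res.f_statistic == 0.0

    def test_matches_statsmodels_anova(self, rng):
        from statsmodels.stats.anova import AnovaRM

        acc = pd.DataFrame(rng.random((12, 3)), columns=["a", "b", "c"])
        res = compare_feature_sets(acc)
        long = acc.reset_index().melt(
            id_vars="index", var_name="set", value_name="acc"
        )
        sm = AnovaRM(long, "acc", "index", within=["set"]).fit()
        assert res.f_statistic == pytest.approx(
            float(sm.anova_table["F Value"].iloc[0])
        )
        assert res.p_value == pytest.approx(
            float(sm.anova_table["Pr > F"].iloc[0])
        )

    def test_zero_variance_difference_flagged(self):
        acc = pd.DataFrame({"a": [0.5, 0.6, 0.7], "b": [0.6, 0.7, 0.8]})
        res = compare_feature_sets(acc)
        row = res.pairwise.iloc[0]
        assert row["degenerate"]
        assert np.isinf(row["t"])


class TestSplitTypeBreakdown:
    def test_all_singleton_meta_tasks_label_zero(self, small_splits, small_sim):
        fm, _, _ = small_sim
        meta = {t: t for t in fm.task_ids}
        df = split_type_breakdown(small_splits, meta, fm.task_ids)
        assert df["label"].tolist() == [0]
        assert df["n_splits"].sum() == len(small_splits)

    def test_three_condition_meta_task_pair_labeled_two(self):
        tasks = ["rot_easy", "rot_med", "rot_hard", "other"]
        meta = {t: ("rotation" if t.startswith("rot") else t) for t in tasks}
        splits = [
            make_split("s", ("rot_easy", "rot_med"), True),
            make_split("s", ("rot_easy", "other"), True),
            make_split("s", ("rot_med", "other"), False),
        ]
        df = split_type_breakdown(splits, meta, tasks).set_index("label")
        # easy+med held out: hard remains -> both have counterparts
        assert df.loc[2, "n_splits"] == 1
        assert df.loc[1, "n_splits"] == 2
        assert df["n_splits"].sum() == 3

    def test_unmapped_task_errors(self, small_splits, small_sim):
        fm, _, _ = small_sim
        with pytest.raises(ValueError):
            split_type_breakdown(small_splits, {}, fm.task_ids)
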