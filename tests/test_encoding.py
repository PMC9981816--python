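import numpy as np
import pytest
from sklearn.linear_model import Ridge

from cogem import (
    SyntheticConfig,
    fit_ridge,
    generate_dataset,
    leave_two_out_splits,
    predict_map,
    run_subject_cv,
    select_alpha,
)
from cogem.datasets import SubjectData

from _oracles import ridge_oracle


class TestFitRidge:
    def test_small_alpha_recovers_exact_linear_map(self, rng):
        X = rng.standard_normal((12, 4))
        B = rng.standard_normal((4, 3))
        Y = X @ B + 2.0
        fit = fit_ridge(X, Y, alpha=1e-10)
        np.testing.assert_allclose(fit.weights, B, atol=1e-6)
        np.testing.assert_allclose(fit.intercepts, [2, 2, 2], atol=1e-6)

    def test_huge_alpha_shrinks_to_intercept_model(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        fit = fit_ridge(X, Y, alpha=1e12)
        np.testing.assert_allclose(fit.weights, 0, atol=1e-9)
        np.testing.assert_allclose(fit.intercepts, Y.mean(axis=0), atol=1e-9)

    def test_matches_generic_optimizer_oracle(self, rng):
        X = rng.standard_normal((6, 3))
        Y = rng.standard_normal((6, 2))
        fit = fit_ridge(X, Y, alpha=1.0)
        W, b = ridge_oracle(X, Y, 1.0)
        assert np.abs(fit.weights - W).max() / np.abs(W).max() < 1e-6
        np.testing.assert_allclose(fit.intercepts, b, atol=1e-6)

    def test_matches_sklearn_ridge(self, rng):
        X = rng.standard_normal((15, 5))
        Y = rng.standard_normal((15, 4))
        for alpha in (0.01, 1.0, 10.0):
            fit = fit_ridge(X, Y, alpha)
            sk = Ridge(alpha=alpha, fit_intercept=True).fit(X, Y)
            np.testing.assert_allclose(fit.weights, sk.coef_.T, atol=1e-8)
            np.testing.assert_allclose(fit.intercepts, sk.intercept_, atol=1e-8)

    def test_invalid_inputs_raise(self, rng):
        X = rng.standard_normal((5, 2))
        Y = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            fit_ridge(X, Y, alpha=0.0)
        with pytest.raises(ValueError):
            fit_ridge(X[:0], Y[:0], alpha=1.0)
        bad = Y.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_ridge(X, bad, alpha=1.0)


class TestPredictMap:
    def test_zero_vector_returns_intercepts(self, rng):
        fit = fit_ridge(rng.standard_normal((8, 3)),
                        rng.standard_normal((8, 4)), 1.0)
        np.testing.assert_allclose(predict_map(fit, np.zeros(3)), fit.intercepts)

    def test_affine_linearity(self, rng):
        fit = fit_ridge(rng.standard_normal((8, 3)),
                        rng.standard_normal((8, 4)), 1.0)
        a, b = rng.random(3), rng.random(3)
        np.testing.assert_allclose(
            predict_map(fit, a + b),
            predict_map(fit, a) + predict_map(fit, b) - fit.intercepts,
            atol=1e-12,
        )

    def test_length_mismatch_raises(self, rng):
        fit = fit_ridge(rng.standard_normal((8, 3)),
                        rng.standard_normal((8, 4)), 1.0)
        with pytest.raises(ValueError):
            predict_map(fit, np.zeros(5))


class TestLeaveTwoOut:
    @pytest.mark.parametrize("n, expected", [(3, 3), (5, 10), (44, 946)])
    def test_pair_counts(self, n, expected):
        pairs = leave_two_out_splits([f"t{i}" for i in range(n)])
        assert len(pairs) == expected
        assert len(set(map(frozenset, pairs))) == expected

    def test_deterministic_order(self):
        assert leave_two_out_splits(["a", "b", "c"]) == [
            ("a", "b"), ("a", "c"), ("b", "c")
        ]

    def test_too_few_tasks(self):
        with pytest.raises(ValueError):
            leave_two_out_splits(["a", "b"])


class TestSelectAlpha:
    def _grouped(self, rng, n_tasks=12, k=4, noise=0.0):
        tasks = np.repeat([f"t{i}" for i in range(n_tasks)], 2)
        F = rng.standard_normal((n_tasks, k))
        X = np.repeat(F, 2, axis=0)
        B = rng.standard_normal((k, 6))
        Y = X @ B + noise * rng.standard_normal((2 * n_tasks, 6))
        return X, Y, tasks

    def test_noiseless_selects_smallest_alpha(self, rng):
        X, Y, tasks = self._grouped(rng)
        alpha = select_alpha(X, Y, k=4, rng=0, task_of_row=tasks)
        assert alpha == 0.001

    def test_single_value_grid_short_circuits(self, rng):
        X, Y, tasks = self._grouped(rng)
        assert select_alpha(X, Y, grid=(3.0,), k=4, rng=0,
                            task_of_row=tasks) == 3.0

    def test_constant_maps_tie_to_smallest(self, rng):
        X, _, tasks = self._grouped(rng)
        Y = np.ones((X.shape[0], 5))
        assert select_alpha(X, Y, k=4, rng=0, task_of_row=tasks) == 0.001

    def test_fewer_tasks_than_folds_raises(self, rng):
        X, Y, tasks = self._grouped(rng, n_tasks=5)
        with pytest.raises(ValueError):
            select_alpha(X, Y, k=10, rng=0, task_of_row=tasks)


class TestRunSubjectCV:
    def test_split_count_reduced_run(self, small_sim):
        fm, _, data = small_sim
        splits = run_subject_cv(data.subjects[0], fm, inner_k=4, rng=0)
        assert len(splits) == 45  # C(10, 2)

    def test_no_split_trains_on_held_out_tasks(self, small_splits, small_sim):
        fm, _, _ = small_sim
        for s in small_splits:
            # alpha came from the configured grid and metrics exist per task
            assert s.alpha in (0.001, 0.01, 0.1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
            assert set(s.r) == set(s.tasks)
            assert all(-1 <= v <= 1 for v in s.r.values())

    def test_region_permutation_equivariance(self, small_sim):
        fm, _, data = small_sim
        sub = data.subjects[0]
        perm = np.random.default_rng(5).permutation(sub.n_regions)
        shuffled = SubjectData(
            subject=sub.subject,
            task_ids=list(sub.task_ids),
            maps={t: sub.maps[t][:, perm] for t in sub.task_ids},
            timepoints=dict(sub.timepoints),
        )
        a = run_subject_cv(sub, fm, inner_k=4, rng=0)
        b = run_subject_cv(shuffled, fm, inner_k=4, rng=0)
        for sa, sb in zip(a, b):
            assert sa.correct == sb.correct
            for task in sa.tasks:
                assert sa.r[task] == pytest.approx(sb.r[task], abs=1e-10)
                assert sa.r2[task] == pytest.approx(sb.r2[task], abs=1e-10)

    def test_noiseless_data_classified_perfectly(self):
        # a draw whose features stay identifiable in every training subset,
        # so noiseless predictions interpolate exactly
        config = SyntheticConfig(
            n_tasks=8, n_features=4, n_cognitive=2, n_parametric=2,
            n_regions=60, n_networks=3, n_subjects=1,
            n_four_session_tasks=3, noise_sd=0.0,
        )
        fm, _, data = generate_dataset(config, seed=6)
        splits = run_subject_cv(data.subjects[0], fm, inner_k=3, rng=0)
        assert len(splits) == 28  # C(8, 2)
        assert all(s.correct for s in splits)
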