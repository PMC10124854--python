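"""Nested CV machinery: folds, OLS, held-out R2, ranking, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from semsel.selection import (
    EvaluationTask,
    evaluate_predictor_on_task,
    evaluate_space_on_task,
    final_select,
    fit_linear,
    make_folds,
    nested_cv,
    overfit_demo,
    r2_heldout,
    rank_aggregate,
)
from semsel.simulate import build_tasks


class TestFolds:
    def test_even_split(self):
        f = make_folds(10, 5, seed=1)
        assert sorted(np.bincount(f.fold_of).tolist()) == [2, 2, 2, 2, 2]

    def test_uneven_split(self):
        f = make_folds(11, 5, seed=1)
        assert sorted(np.bincount(f.fold_of).tolist()) == [2, 2, 2, 2, 3]

    def test_deterministic(self):
        assert np.array_equal(make_folds(50, 5, 3).fold_of, make_folds(50, 5, 3).fold_of)

    def test_every_item_exactly_once(self):
        f = make_folds(37, 4, 0)
        all_items = np.concatenate([f.test_items(k) for k in range(4)])
        assert sorted(all_items.tolist()) == list(range(37))

    def test_errors(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, 0)
        with pytest.raises(ValueError):
            make_folds(10, 1, 0)


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(5, dtype=float)[:, None]
        fit = fit_linear(x, 2 * x.ravel())
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2_train == pytest.approx(1.0)

    def test_orthogonal_response(self):
        x = np.array([[-1.0], [0.0], [1.0]])
        y = np.array([1.0, -2.0, 1.0])  # orthogonal to x and centered
        fit = fit_linear(x, y)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2_train == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_by_hand(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0], [5.0, 7.0]])
        y = np.array([3.0, 4.0, 10.0, 7.0, 15.0])
        D = np.hstack([np.ones((5, 1)), X])
        beta_hand = np.linalg.solve(D.T @ D, D.T @ y)
        fit = fit_linear(X, y, ["a", "b"])
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coefficients], beta_hand, atol=1e-10
        )

    def test_collinearity_named(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="dup"):
            fit_linear(X, np.arange(6.0), ["base", "dup"])


class TestHeldoutR2:
    def test_perfect_prediction(self):
        fit = fit_linear(np.arange(4.0)[:, None], 3 * np.arange(4.0) + 1)
        X = np.array([[10.0], [20.0]])
        assert r2_heldout(fit, X, np.array([31.0, 61.0])) == pytest.approx(1.0)

    def test_predicting_test_mean_scores_zero(self):
        fit = fit_linear(np.array([[0.0], [1.0]]), np.array([5.0, 5.0]))
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([4.0, 5.0, 6.0])
        assert r2_heldout(fit, x, y) == pytest.approx(0.0)

    def test_negative_r2_matches_hand_computation(self):
        # model predicts constant 10; test y = (0, 2, 4, 6), mean 3
        fit = fit_linear(np.array([[0.0], [1.0]]), np.array([10.0, 10.0]))
        y = np.array([0.0, 2.0, 4.0, 6.0])
        ss_res = np.sum((y - 10.0) ** 2)  # 100+64+36+16 = 216
        ss_tot = np.sum((y - 3.0) ** 2)  # 9+1+1+9 = 20
        expected = 1 - ss_res / ss_tot  # = -9.8
        got = r2_heldout(fit, np.zeros((4, 1)), y)
        assert got == pytest.approx(expected)
        assert got < 0

    def test_zero_test_variance_rejected(self):
        fit = fit_linear(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="variance"):
            r2_heldout(fit, np.zeros((3, 1)), np.full(3, 7.0))


def brute_force_ranks(scores: pd.DataFrame) -> pd.Series:
    """Independent average-rank computation via pairwise counting."""
    avg = {}
    for sid in scores.index:
        ranks = []
        for task in scores.columns:
            col = scores[task]
            v = col[sid]
            if np.isnan(v):
                ranks.append(len(col))
                continue
            better = sum(1 for o in col.dropna() if o > v)
            equal = sum(1 for o in col.dropna() if o == v)
            ranks.append(better + (equal + 1) / 2)
        avg[sid] = np.mean(ranks)
    return pd.Series(avg)


class TestRankAggregate:
    def test_hand_example_with_tie(self):
        scores = pd.DataFrame(
            {"t1": [0.5, 0.3, 0.1], "t2": [0.4, 0.6, 0.1]}, index=["A", "B", "C"]
        )
        ranks, avg, winner = rank_aggregate(scores)
        assert avg["A"] == pytest.approx(1.5)
        assert avg["B"] == pytest.approx(1.5)
        assert avg["C"] == pytest.approx(3.0)
        assert winner == "A"  # lexicographic tie-break

    def test_single_task_is_argmax(self):
        scores = pd.DataFrame({"t": [0.2, 0.9, 0.5]}, index=["x", "y", "z"])
        _, _, winner = rank_aggregate(scores)
        assert winner == "y"

    def test_identical_scores_tie_broken_deterministically(self):
        scores = pd.DataFrame(
            {"t1": [0.3, 0.3], "t2": [0.3, 0.3]}, index=["b_space", "a_space"]
        )
        ranks, avg, winner = rank_aggregate(scores)
        assert avg.nunique() == 1
        assert winner == "a_space"

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n_s, n_t = int(rng.integers(2, 8)), int(rng.integers(1, 5))
            vals = np.round(rng.random((n_s, n_t)), 2)  # rounding forces ties
            scores = pd.DataFrame(
                vals, index=[f"s{i}" for i in range(n_s)],
                columns=[f"t{j}" for j in range(n_t)],
            )
            _, avg, _ = rank_aggregate(scores)
            pd.testing.assert_series_equal(
                avg.sort_index(), brute_force_ranks(scores).sort_index(),
                check_names=False,
            )

    def test_task_subsets(self):
        scores = pd.DataFrame(
            {"ratings": [0.9, 0.1], "simlex": [0.1, 0.9]}, index=["A", "B"]
        )
        _, _, winner_r = rank_aggregate(scores, task_subset=["ratings"])
        _, _, winner_s = rank_aggregate(scores, task_subset=["simlex"])
        assert (winner_r, winner_s) == ("A", "B")

    def test_disqualified_gets_worst_rank(self):
        scores = pd.DataFrame({"t": [0.5, np.nan, 0.2]}, index=["a", "b", "c"])
        ranks, _, winner = rank_aggregate(scores)
        assert ranks.loc["b", "t"] == 3.0
        assert winner == "a"


def _simple_task(n_pairs=24, seed=0, noise=0.1):
    """A pair-level task whose response is a noisy linear map of a predictor."""
    rng = np.random.default_rng(seed)
    pairs = [(f"p{i}", f"t{i}") for i in range(n_pairs)]
    x = rng.normal(0, 1, n_pairs)
    y = 2.0 + 1.5 * x + rng.normal(0, noise, n_pairs)
    return EvaluationTask("ratings", pairs, y), x


class TestEvaluatePredictor:
    def test_two_fold_matches_hand_rolled_split(self):
        task, x = _simple_task(20, seed=4)
        folds = make_folds(20, 2, seed=1)
        got = evaluate_predictor_on_task(x, task, folds).mean_r2
        hand = []
        for f in (0, 1):
            tr, te = folds.train_items(f), folds.test_items(f)
            fit = fit_linear(x[tr][:, None], task.response[tr])
            hand.append(r2_heldout(fit, x[te][:, None], task.response[te]))
        assert got == pytest.approx(np.mean(hand))

    def test_low_coverage_disqualifies(self):
        task, x = _simple_task(20, seed=5)
        x = x.copy()
        x[:5] = np.nan  # 75% coverage
        es = evaluate_predictor_on_task(x, task, make_folds(20, 4, 0), min_coverage=0.95)
        assert es.disqualified and "coverage" in es.reason
        assert np.isnan(es.mean_r2)

    def test_noise_predictor_near_zero_r2(self):
        rng = np.random.default_rng(8)
        scores = []
        for rep in range(50):
            task, _ = _simple_task(60, seed=100 + rep, noise=1.0)
            noise_pred = rng.normal(0, 1, 60)
            scores.append(
                evaluate_predictor_on_task(noise_pred, task, make_folds(60, 5, rep)).mean_r2
            )
        assert np.mean(scores) < 0.02


class TestNestedCv:
    def test_single_space_equals_plain_kfold(self, small_world):
        tasks, _ = build_tasks(small_world, seed=2, n_simlex_pairs=120)
        spaces = [small_world.spaces[0], small_world.spaces[0]]
        # duplicate id is rejected; use two distinct but identical-vector spaces
        from semsel.spaces import SemanticSpace

        twin = SemanticSpace(
            "space_01b", spaces[0].dimension, list(spaces[0].vocabulary),
            spaces[0].vectors.copy(),
        )
        res = nested_cv(tasks, [spaces[0], twin], k_outer=3, k_inner=3, seed=5)
        # with identical candidates, outer estimates equal plain k-fold CV of
        # that one model on each task, using the same outer folds
        from semsel.selection import _derive, pair_predictor

        for task in tasks:
            folds = make_folds(task.n_pairs, 3, _derive(5, "outer", task.task_id))
            plain = evaluate_space_on_task(spaces[0], task, folds).mean_r2
            assert res.outer_estimates[task.task_id] == pytest.approx(plain, abs=1e-12)

    def test_outer_test_never_in_inner_loop(self, small_world):
        # structural leakage check: the inner loop sees only outer-train pairs
        tasks, _ = build_tasks(small_world, seed=3, n_simlex_pairs=120)
        task = tasks[1]
        from semsel.selection import _derive

        folds = make_folds(task.n_pairs, 5, _derive(9, "outer", task.task_id))
        for f in range(5):
            train = set(folds.train_items(f).tolist())
            test = set(folds.test_items(f).tolist())
            assert not train & test
            sub = task.subset(np.array(sorted(train)))
            # every pair in the inner task maps back to an outer-train pair
            orig = {task.pairs.index(p) for p in sub.pairs}
            assert orig <= train and not orig & test

    def test_planted_best_chosen(self, small_world):
        tasks, _ = build_tasks(small_world, seed=2, n_simlex_pairs=150)
        res = nested_cv(tasks, small_world.spaces, seed=2)
        assert res.chosen_space_id == "space_01"
        assert res.scores.loc["space_01", "ratings"] == res.scores["ratings"].max()

    def test_requires_two_spaces(self, small_world):
        tasks, _ = build_tasks(small_world, seed=1, n_simlex_pairs=120)
        with pytest.raises(ValueError, match="2 candidate"):
            nested_cv(tasks, small_world.spaces[:1], seed=0)

    def test_degenerate_sizes_rejected(self, small_world):
        task = EvaluationTask(
            "ratings", [(f"a{i}", f"b{i}") for i in range(8)], np.arange(8.0)
        )
        with pytest.raises(ValueError, match="nested splitting"):
            nested_cv([task], small_world.spaces[:2], k_outer=5, k_inner=5, seed=0)


class TestFinalSelect:
    def test_single_candidate_returned(self, small_world):
        tasks, _ = build_tasks(small_world, seed=6, n_simlex_pairs=120)
        winner, scores, avg = final_select(tasks, small_world.spaces[:1], seed=0)
        assert winner == "space_01"

    def test_winner_invariant_to_order(self, small_world):
        tasks, _ = build_tasks(small_world, seed=6, n_simlex_pairs=120)
        w1, _, _ = final_select(tasks, small_world.spaces, seed=3)
        w2, _, _ = final_select(tasks, list(reversed(small_world.spaces)), seed=3)
        assert w1 == w2

    def test_planted_best_on_behavioral_subset(self, small_world):
        tasks, _ = build_tasks(small_world, seed=6, n_simlex_pairs=120)
        winner, _, _ = final_select(
            tasks, small_world.spaces, seed=3, task_subset=["ldt_logrt", "ratings"]
        )
        assert winner == "space_01"


class TestOverfitDemo:
    def test_single_space_degenerate_case(self, small_world):
        tasks, _ = build_tasks(small_world, seed=8, n_simlex_pairs=120)
        task = tasks[1]
        demo = overfit_demo(
            small_world.spaces[:1], task, make_folds(task.n_pairs, 5, 0)
        )
        assert demo["selected_space_id"] == "space_01"
        # without selection over many candidates, train R2 only reflects fitting
        assert demo["train_r2"] >= demo["heldout_r2"] - 0.05

    def test_train_selection_inflates_with_noise_spaces(self, small_world):
        rng = np.random.default_rng(0)
        tasks, _ = build_tasks(small_world, seed=9, n_simlex_pairs=120)
        task = tasks[1].subset(np.arange(100))
        vocab = sorted({w for p in task.pairs for w in p})
        from semsel.spaces import SemanticSpace

        noise_spaces = [
            SemanticSpace(f"noise_{i:03d}", 8, vocab, rng.standard_normal((len(vocab), 8)))
            for i in range(60)
        ]
        demo = overfit_demo(noise_spaces, task, make_folds(task.n_pairs, 5, 1))
        assert demo["train_r2"] > 0
        assert demo["train_r2"] > demo["heldout_r2"]
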