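"""Robust semantic-space selection by nested cross-validation.

Candidate semantic spaces are compared by how much held-out variance their
cosine similarities explain in several behavioral prediction tasks
(per-trial log lexical-decision RTs with frequency/length baseline
covariates, mean relatedness ratings, and SimLex-style similarity and
relatedness norms). Scores are aggregated across tasks by average rank,
and a nested cross-validation loop keeps model selection honest: an inner
k-fold loop picks the winning space on each outer-training portion, the
winner is refit on that portion and scored on the untouched outer-test
fold, and the mean of those outer scores estimates how the selected model
generalizes to new data. A companion overfitting demonstrator shows how
selecting on training-set fit alone inflates the apparent performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import rng_for
from .spaces import SemanticSpace

__all__ = [
    "EvaluationTask",
    "FoldAssignment",
    "LinearModelFit",
    "EvalScore",
    "SelectionResult",
    "make_folds",
    "fit_linear",
    "r2_heldout",
    "pair_predictor",
    "evaluate_space_on_task",
    "evaluate_predictor_on_task",
    "rank_aggregate",
    "nested_cv",
    "final_select",
    "overfit_demo",
]

TASK_IDS = ("ldt_logrt", "ratings", "simlex_relatedness", "simlex_similarity")


@dataclass
class EvaluationTask:
    """A response vector over word pairs, plus optional baseline covariates.

    ``pairs`` lists the unique (word1, word2) items; ``response`` is one
    value per observation. For per-trial tasks (log RTs) several
    observations share a pair, mapped through ``obs_pair_index``; fold
    splitting always happens at the pair level so all trials of a pair stay
    on one side of a split. ``covariates`` (per observation) are baseline
    predictors included in every model for this task.
    """

    task_id: str
    pairs: list[tuple[str, str]]
    response: np.ndarray
    obs_pair_index: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if self.obs_pair_index is None:
            if len(self.response) != len(self.pairs):
                raise ValueError("response length must equal pair count")
            self.obs_pair_index = np.arange(len(self.pairs))
        else:
            self.obs_pair_index = np.asarray(self.obs_pair_index, dtype=int)
            if len(self.obs_pair_index) != len(self.response):
                raise ValueError("obs_pair_index length must equal response length")
        if self.covariates is not None and len(self.covariates) != len(self.response):
            raise ValueError("covariates must have one row per observation")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def subset(self, pair_indices: np.ndarray) -> "EvaluationTask":
        """Restrict the task to a subset of pairs (for outer-loop splits)."""
        pair_indices = np.asarray(pair_indices, dtype=int)
        remap = -np.ones(self.n_pairs, dtype=int)
        remap[pair_indices] = np.arange(len(pair_indices))
        obs_mask = remap[self.obs_pair_index] >= 0
        return EvaluationTask(
            task_id=self.task_id,
            pairs=[self.pairs[i] for i in pair_indices],
            response=self.response[obs_mask],
            obs_pair_index=remap[self.obs_pair_index[obs_mask]],
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[obs_mask].reset_index(drop=True),
        )


@dataclass
class FoldAssignment:
    """A balanced random partition of n items into k folds."""

    n_items: int
    k: int
    seed: int
    fold_of: np.ndarray  # item -> fold label in [0, k)

    def test_items(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_items(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def make_folds(n: int, k: int, seed: int = 0) -> FoldAssignment:
    """Randomly partition n items into k folds whose sizes differ by <= 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    rng = rng_for(seed, "folds")
    labels = np.arange(n) % k  # interleaved: sizes differ by at most 1
    return FoldAssignment(n, k, seed, labels[rng.permutation(n)])


@dataclass
class LinearModelFit:
    """An ordinary-least-squares fit with named predictors."""

    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    r2_train: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are (near-)linear combinations of earlier ones."""
    bad, basis = [], np.ones((X.shape[0], 1))
    for j, name in enumerate(names):
        col = X[:, j : j + 1]
        resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        if np.linalg.norm(resid) <= 1e-8 * max(1.0, np.linalg.norm(col)):
            bad.append(name)
        else:
            basis = np.hstack([basis, col])
    return bad


def fit_linear(
    X: np.ndarray, y: np.ndarray, predictor_names: Sequence[str] | None = None
) -> LinearModelFit:
    """OLS fit of y on X plus an intercept.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y have different numbers of rows")
    names = list(predictor_names or [f"x{j}" for j in range(X.shape[1])])
    design = np.hstack([np.ones((X.shape[0], 1)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(X, names)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return LinearModelFit(names, beta[1:], float(beta[0]), float(r2))


def r2_heldout(fit: LinearModelFit, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Out-of-sample variance explained, 1 - SS_res/SS_tot.

    SS_tot is taken about the test-set mean, so a model worse than the
    test-set mean scores negative.
    """
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    ss_tot = np.sum((y_test - y_test.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("test responses have zero variance")
    resid = y_test - fit.predict(X_test)
    return float(1.0 - np.sum(resid**2) / ss_tot)


def pair_predictor(space: SemanticSpace, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """Cosine similarity per pair, NaN where either word is out of vocabulary."""
    out = np.full(len(pairs), np.nan)
    for i, (a, b) in enumerate(pairs):
        ia, ib = space.index_of(a), space.index_of(b)
        if ia is None or ib is None:
            continue
        cos = np.dot(space.vectors[ia], space.vectors[ib]) / (
            space._norms[ia] * space._norms[ib]
        )
        out[i] = np.clip(cos, -1.0, 1.0)
    return out


@dataclass
class EvalScore:
    """Cross-validated score of one candidate predictor on one task."""

    candidate_id: str
    task_id: str
    mean_r2: float
    fold_r2: list[float] = field(default_factory=list)
    coverage: float = 1.0
    disqualified: bool = False
    reason: str = ""


def _design(
    task: EvaluationTask, values: np.ndarray, obs_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, names) for a set of observations."""
    pred = values[task.obs_pair_index[obs_idx]][:, None]
    names = ["similarity"]
    if task.covariates is not None:
        cov = task.covariates.iloc[obs_idx].to_numpy(dtype=float)
        X = np.hstack([cov, pred])
        names = list(task.covariates.columns) + names
    else:
        X = pred
    return X, task.response[obs_idx], names


def evaluate_predictor_on_task(
    values: np.ndarray,
    task: EvaluationTask,
    folds: FoldAssignment,
    candidate_id: str = "predictor",
    min_coverage: float = 0.95,
) -> EvalScore:
    """Mean held-out R-squared of one per-pair predictor on one task.

    ``values`` holds one number per task pair, NaN where the candidate
    cannot score the pair (e.g. out-of-vocabulary words). Evaluation is
    restricted to covered pairs; if coverage falls below ``min_coverage``
    the candidate is disqualified for the task rather than silently scored
    on a shrunken item set. Per fold, the model (baseline covariates, when
    the task has them, plus the predictor) is fit on the training pairs and
    scored on the held-out pairs.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != task.n_pairs:
        raise ValueError("predictor must have one value per task pair")
    if folds.n_items != task.n_pairs:
        raise ValueError("fold assignment does not match task size")
    covered = np.isfinite(values)
    coverage = float(covered.mean())
    if coverage < min_coverage:
        return EvalScore(
            candidate_id, task.task_id, np.nan, [], coverage, True,
            f"coverage {coverage:.3f} < {min_coverage}",
        )
    covered_obs = covered[task.obs_pair_index]
    fold_scores = []
    for f in range(folds.k):
        in_test = (folds.fold_of == f)[task.obs_pair_index]
        train = np.flatnonzero(~in_test & covered_obs)
        test = np.flatnonzero(in_test & covered_obs)
        if len(test) == 0 or len(train) == 0:
            continue
        X_tr, y_tr, names = _design(task, values, train)
        X_te, y_te, _ = _design(task, values, test)
        fit = fit_linear(X_tr, y_tr, names)
        fold_scores.append(r2_heldout(fit, X_te, y_te))
    if not fold_scores:
        return EvalScore(candidate_id, task.task_id, np.nan, [], coverage, True,
                         "no scorable folds")
    return EvalScore(
        candidate_id, task.task_id, float(np.mean(fold_scores)), fold_scores,
        coverage,
    )


def evaluate_space_on_task(
    space: SemanticSpace,
    task: EvaluationTask,
    folds: FoldAssignment,
    min_coverage: float = 0.95,
) -> EvalScore:
    """Cross-validated R-squared of a space's cosines on one task."""
    return evaluate_predictor_on_task(
        pair_predictor(space, task.pairs), task, folds,
        candidate_id=space.space_id, min_coverage=min_coverage,
    )


def rank_aggregate(
    scores: pd.DataFrame, task_subset: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, str]:
    """Average-rank aggregation of an R-squared table (spaces x tasks).

    Within each task, candidates are ranked descending by R-squared (rank 1
    is best) with midranks for ties; disqualified candidates (NaN) receive
    the worst rank in that task. Returns (per-task ranks, average ranks,
    winner); winner ties are broken by lexicographic candidate id.
    """
    if task_subset is not None:
        scores = scores[list(task_subset)]
    if scores.isna().all(axis=1).all():
        raise ValueError("all candidates disqualified on all tasks")
    ranks = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for task in scores.columns:
        col = scores[task].to_numpy(dtype=float)
        r = rankdata(-col, method="average", nan_policy="omit")
        r[np.isnan(col)] = len(col)  # disqualified: worst rank
        ranks[task] = r
    avg = ranks.mean(axis=1)
    winner = avg.sort_index().idxmin()  # lexicographic tie-break via stable sort
    return ranks, avg, str(winner)


@dataclass
class SelectionResult:
    """Outcome of the nested cross-validated selection."""

    scores: pd.DataFrame  # full-data inner-loop R2 per (space, task)
    task_ranks: pd.DataFrame
    average_ranks: pd.Series
    chosen_space_id: str
    outer_estimates: dict[str, float]  # task -> mean outer-fold held-out R2
    outer_fold_scores: pd.DataFrame  # rows: outer folds; columns: tasks
    outer_selections: list[str]  # space chosen in each outer fold
    coverage: pd.DataFrame
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "chosen_space_id": self.chosen_space_id,
            "average_ranks": self.average_ranks.to_dict(),
            "scores": {c: self.scores[c].to_dict() for c in self.scores.columns},
            "outer_estimates": self.outer_estimates,
            "outer_selections": list(self.outer_selections),
            "seed": self.seed,
        }


def _space_predictors(
    spaces: Sequence[SemanticSpace], tasks: Sequence[EvaluationTask]
) -> dict[str, dict[str, np.ndarray]]:
    """task_id -> space_id -> per-pair cosine vector (computed once)."""
    return {
        task.task_id: {s.space_id: pair_predictor(s, task.pairs) for s in spaces}
        for task in tasks
    }


def nested_cv(
    tasks: Sequence[EvaluationTask],
    spaces: Sequence[SemanticSpace],
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
    min_coverage: float = 0.95,
) -> SelectionResult:
    """Nested cross-validated space selection with rank aggregation.

    For each outer fold, the inner k-fold loop scores every space on every
    task within the outer-training portion only; the space with the lowest
    average rank is selected, refit on the whole outer-training portion,
    and scored on the untouched outer-test fold. The per-task means of
    those outer-test scores (``outer_estimates``) estimate the selected
    model's performance on independent data. Finally one more inner loop
    runs on the full data to name the space to publish.
    """
    if len(spaces) < 2:
        raise ValueError("need at least 2 candidate spaces")
    _check_sizes(tasks, k_outer, k_inner)
    ids = sorted({s.space_id for s in spaces})
    if len(ids) != len(spaces):
        raise ValueError("space ids must be unique")

    all_preds = _space_predictors(spaces, tasks)
    outer_folds = {
        t.task_id: make_folds(t.n_pairs, k_outer, _derive(seed, "outer", t.task_id))
        for t in tasks
    }

    fold_scores = pd.DataFrame(
        index=range(k_outer), columns=[t.task_id for t in tasks], dtype=float
    )
    selections: list[str] = []
    for f in range(k_outer):
        # inner loop: select on the outer-training portion only
        inner_tasks, inner_folds, inner_preds = [], {}, {}
        for task in tasks:
            tr_pairs = outer_folds[task.task_id].train_items(f)
            sub = task.subset(tr_pairs)
            inner_tasks.append(sub)
            inner_folds[task.task_id] = make_folds(
                sub.n_pairs, k_inner, _derive(seed, "inner", task.task_id, str(f))
            )
            inner_preds[task.task_id] = {
                sid: all_preds[task.task_id][sid][tr_pairs] for sid in ids
            }
        inner_scores = pd.DataFrame(index=ids,
                                    columns=[t.task_id for t in tasks], dtype=float)
        for sub in inner_tasks:
            for sid in ids:
                es = evaluate_predictor_on_task(
                    inner_preds[sub.task_id][sid], sub,
                    inner_folds[sub.task_id], sid, min_coverage,
                )
                inner_scores.loc[sid, sub.task_id] = es.mean_r2
        _, _, selected = rank_aggregate(inner_scores)
        selections.append(selected)

        # refit the selected space on the outer-training portion, score on test
        for task in tasks:
            fold_scores.loc[f, task.task_id] = _refit_score(
                task, all_preds[task.task_id][selected],
                outer_folds[task.task_id], f,
            )

    outer_estimates = {
        t.task_id: float(fold_scores[t.task_id].mean()) for t in tasks
    }

    # one last inner loop on the full data names the space to publish
    full_folds = {
        t.task_id: make_folds(t.n_pairs, k_inner, _derive(seed, "final", t.task_id))
        for t in tasks
    }
    scores, coverage = _score_table_from_cache(
        all_preds, ids, tasks, full_folds, min_coverage
    )
    task_ranks, avg_ranks, chosen = rank_aggregate(scores)

    return SelectionResult(
        scores=scores,
        task_ranks=task_ranks,
        average_ranks=avg_ranks,
        chosen_space_id=chosen,
        outer_estimates=outer_estimates,
        outer_fold_scores=fold_scores,
        outer_selections=selections,
        coverage=coverage,
        seed=seed,
    )


def _score_table_from_cache(all_preds, ids, tasks, folds_by_task, min_coverage):
    scores = pd.DataFrame(index=ids, columns=[t.task_id for t in tasks], dtype=float)
    coverage = scores.copy()
    for task in tasks:
        for sid in ids:
            es = evaluate_predictor_on_task(
                all_preds[task.task_id][sid], task, folds_by_task[task.task_id],
                sid, min_coverage,
            )
            scores.loc[sid, task.task_id] = es.mean_r2
            coverage.loc[sid, task.task_id] = es.coverage
    return scores, coverage


def _refit_score(
    task: EvaluationTask, values: np.ndarray, folds: FoldAssignment, fold: int
) -> float:
    """Fit on the outer-training pairs, score on the outer-test pairs."""
    covered = np.isfinite(values)[task.obs_pair_index]
    in_test = (folds.fold_of == fold)[task.obs_pair_index]
    train = np.flatnonzero(~in_test & covered)
    test = np.flatnonzero(in_test & covered)
    X_tr, y_tr, names = _design(task, values, train)
    X_te, y_te, _ = _design(task, values, test)
    return r2_heldout(fit_linear(X_tr, y_tr, names), X_te, y_te)


def final_select(
    tasks: Sequence[EvaluationTask],
    spaces: Sequence[SemanticSpace],
    k_inner: int = 5,
    seed: int = 0,
    min_coverage: float = 0.95,
    task_subset: Sequence[str] | None = None,
) -> tuple[str, pd.DataFrame, pd.Series]:
    """One inner-loop selection over the full data.

    Returns (winner, score table, average ranks). ``task_subset`` restricts
    the rank aggregation to a subset of tasks (e.g. behavioral only).
    """
    if not spaces:
        raise ValueError("no candidate spaces")
    _check_sizes(tasks, 1, k_inner)
    all_preds = _space_predictors(spaces, tasks)
    ids = sorted(s.space_id for s in spaces)
    folds = {
        t.task_id: make_folds(t.n_pairs, k_inner, _derive(seed, "final", t.task_id))
        for t in tasks
    }
    scores, _ = _score_table_from_cache(all_preds, ids, tasks, folds, min_coverage)
    _, avg, winner = rank_aggregate(scores, task_subset)
    return winner, scores, avg


def overfit_demo(
    spaces: Sequence[SemanticSpace],
    task: EvaluationTask,
    folds: FoldAssignment,
    other_tasks: Sequence[EvaluationTask] = (),
    min_coverage: float = 0.0,
) -> dict:
    """Demonstrate selection bias of train-set-only model selection.

    Every candidate space is fit on the full task with no train/test split;
    the space with the best training R-squared is "selected". Its
    cross-validated held-out R-squared on the same task (and on any other
    tasks supplied) is then reported, exposing how far the training-set
    number overstates generalization.
    """
    best_id, best_train = None, -np.inf
    for space in spaces:
        values = pair_predictor(space, task.pairs)
        covered = np.isfinite(values)[task.obs_pair_index]
        if not covered.any():
            continue
        obs = np.flatnonzero(covered)
        X, y, names = _design(task, values, obs)
        fit = fit_linear(X, y, names)
        if fit.r2_train > best_train:
            best_id, best_train = space.space_id, fit.r2_train
    if best_id is None:
        raise ValueError("no space covers the task")
    winner = next(s for s in spaces if s.space_id == best_id)
    heldout = evaluate_space_on_task(winner, task, folds, min_coverage)
    cross = {}
    for other in other_tasks:
        of = make_folds(other.n_pairs, folds.k, folds.seed)
        cross[other.task_id] = evaluate_space_on_task(
            winner, other, of, min_coverage
        ).mean_r2
    return {
        "selected_space_id": best_id,
        "train_r2": float(best_train),
        "heldout_r2": float(heldout.mean_r2),
        "cross_task_r2": cross,
    }


def _check_sizes(tasks: Sequence[EvaluationTask], k_outer: int, k_inner: int) -> None:
    if not tasks:
        raise ValueError("no evaluation tasks")
    for t in tasks:
        smallest_inner = (t.n_pairs * (k_outer - 1)) // k_outer if k_outer > 1 else t.n_pairs
        if smallest_inner < 2 * k_inner:
            raise ValueError(
                f"task {t.task_id}: {t.n_pairs} pairs cannot support "
                f"{k_outer}x{k_inner} nested splitting"
            )


def _derive(seed: int, *names: str) -> int:
    """A reproducible child seed below 2**31 for a named substream."""
    return int(rng_for(seed, *names).integers(2**31))
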