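"""End-to-end validation experiments on planted synthetic worlds.

These routines run the full pipeline — generate a world, simulate the
behavioral datasets, build the evaluation tasks, run the selection — and
measure the properties that matter for trusting the method: how often the
planted-best space is recovered, how honest the nested-CV generalization
estimates are against the generative ground truth, how strongly naive
train-set selection inflates apparent performance, and how well OLS
recovers the planted similarity effect from simulated lexical decisions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import rng_for
from .preprocess import condition_summaries, drop_incorrect, filter_rt_outliers
from .selection import (
    _design,
    evaluate_space_on_task,
    fit_linear,
    make_folds,
    nested_cv,
    overfit_demo,
    pair_predictor,
    r2_heldout,
)
from .simulate import GeneratorConfig, build_tasks, make_world, simulate_ldt
from .spaces import SemanticSpace

__all__ = [
    "small_study_config",
    "selection_run",
    "selection_frequency",
    "true_generalization_r2",
    "calibration_run",
    "noise_spaces",
    "train_selection_inflation",
    "similarity_recovery",
]

#: Scaled-down study conditions used for repeated end-to-end runs. The
#: structure (5 spaces, 3 conditions, 4 tasks) matches the full design;
#: sizes are reduced so hundreds of replications stay cheap.
SMALL = dict(n_triplets=60, vocab_size=700, n_subjects=12, n_rating_subjects=20)
SMALL_SIMLEX_PAIRS = 150


def small_study_config(seed: int, **overrides) -> GeneratorConfig:
    kw = dict(SMALL)
    kw.update(overrides)
    return GeneratorConfig(seed=seed, **kw)


def selection_run(
    seed: int, noise_sds: tuple | None = None, k_outer: int = 5, k_inner: int = 5
):
    """One scaled-down end-to-end run; returns the nested-CV SelectionResult."""
    overrides = {"noise_sds": noise_sds} if noise_sds is not None else {}
    world = make_world(small_study_config(seed, **overrides))
    tasks, _ = build_tasks(world, seed=seed, n_simlex_pairs=SMALL_SIMLEX_PAIRS)
    return nested_cv(tasks, world.spaces, k_outer=k_outer, k_inner=k_inner, seed=seed)


def selection_frequency(
    seeds, noise_sds: tuple | None = None
) -> float:
    """Fraction of runs in which the planted-best space is selected."""
    wins = sum(
        selection_run(s, noise_sds=noise_sds).chosen_space_id == "space_01"
        for s in seeds
    )
    return wins / len(list(seeds))


def true_generalization_r2(world, space, tasks, fresh_seed: int) -> dict[str, float]:
    """Generative ground-truth R2 of one space's model per task.

    The model (baseline covariates where the task has them, plus the
    space's cosine) is fit on the observed tasks, then scored on a fresh
    draw of the same datasets from the same world — new subjects, new
    response noise, new pair idiosyncrasies. This Monte-Carlo ground truth
    is what an honest generalization estimate should approximate.
    """
    fresh_tasks, _ = build_tasks(world, seed=fresh_seed, n_simlex_pairs=SMALL_SIMLEX_PAIRS)
    fresh_by_id = {t.task_id: t for t in fresh_tasks}
    out = {}
    for task in tasks:
        values = pair_predictor(space, task.pairs)
        obs = np.flatnonzero(np.isfinite(values)[task.obs_pair_index])
        X, y, names = _design(task, values, obs)
        fit = fit_linear(X, y, names)
        fresh = fresh_by_id[task.task_id]
        fvalues = pair_predictor(space, fresh.pairs)
        fobs = np.flatnonzero(np.isfinite(fvalues)[fresh.obs_pair_index])
        Xf, yf, _ = _design(fresh, fvalues, fobs)
        out[task.task_id] = r2_heldout(fit, Xf, yf)
    return out


def calibration_run(seed: int) -> pd.Series:
    """Outer-loop estimate minus ground-truth R2, per task, for one run."""
    world = make_world(small_study_config(seed))
    tasks, _ = build_tasks(world, seed=seed, n_simlex_pairs=SMALL_SIMLEX_PAIRS)
    result = nested_cv(tasks, world.spaces, seed=seed)
    chosen = next(s for s in world.spaces if s.space_id == result.chosen_space_id)
    truth = true_generalization_r2(world, chosen, tasks, fresh_seed=seed + 10_000)
    return pd.Series(
        {t: result.outer_estimates[t] - truth[t] for t in result.outer_estimates}
    )


def noise_spaces(words, n: int, dim: int, seed: int) -> list[SemanticSpace]:
    """Candidate spaces with no relation to the truth (pure noise vectors)."""
    rng = rng_for(seed, "noise-spaces")
    words = list(words)
    return [
        SemanticSpace(f"noise_{i:03d}", dim, words, rng.standard_normal((len(words), dim)))
        for i in range(n)
    ]


def train_selection_inflation(
    seed: int, n_noise_spaces: int = 200, n_pairs: int = 100
) -> dict:
    """Train-set-only selection over many noise spaces on a small task.

    Returns the winner's training R2 and its cross-validated held-out R2.
    With enough candidates the best training fit is pure selection bias, so
    the training number should exceed the held-out one almost always.
    """
    world = make_world(small_study_config(seed))
    tasks, _ = build_tasks(world, seed=seed, n_simlex_pairs=SMALL_SIMLEX_PAIRS)
    ratings = next(t for t in tasks if t.task_id == "ratings")
    task = ratings.subset(np.arange(min(n_pairs, ratings.n_pairs)))
    vocab = sorted({w for p in task.pairs for w in p})
    candidates = noise_spaces(vocab, n_noise_spaces, dim=8, seed=seed)
    folds = make_folds(task.n_pairs, 5, seed)
    return overfit_demo(candidates, task, folds)


def similarity_recovery(seed: int, n_triplets: int = 216, n_subjects: int = 72) -> dict:
    """Fit OLS to one simulated LDT at the published scale.

    Returns the recovered similarity coefficient (true value is the
    generator's rt_coefficients[-1]), plus the filtered per-condition RT
    means. Incorrect responses are dropped and the anticipation-floor and
    2.5 SD outlier rules applied before fitting, as in the analysis
    pipeline.
    """
    cfg = GeneratorConfig(seed=seed, n_triplets=n_triplets, n_subjects=n_subjects)
    world = make_world(cfg)
    trials = simulate_ldt(world, seed=seed)
    exp = drop_incorrect(trials)
    exp = exp[exp.trial_class.isin(("strong", "weak", "unrelated"))]
    kept, _, _ = filter_rt_outliers(exp)

    lex = world.lexicon
    sims = np.array(
        [world.true_cosine(p, t) for p, t in zip(kept["prime"], kept["target"])]
    )
    X = np.column_stack(
        [
            lex.loc[kept["target"], "zipf"].to_numpy(),
            lex.loc[kept["target"], "length"].to_numpy(dtype=float),
            lex.loc[kept["prime"], "zipf"].to_numpy(),
            lex.loc[kept["prime"], "length"].to_numpy(dtype=float),
            sims,
        ]
    )
    y = np.log(kept["rt_ms"].to_numpy(dtype=float))
    fit = fit_linear(
        X, y, ["target_zipf", "target_length", "prime_zipf", "prime_length", "similarity"]
    )
    summary = condition_summaries(kept)
    return {
        "beta_similarity": fit.coefficients[-1],
        "beta_true": cfg.rt_coefficients[-1],
        "means": summary["means"],
        "priming_effects": summary["priming_effects"],
    }
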