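"""Synthetic worlds with a planted ground truth.

The generator emulates every input the selection pipeline consumes: a
latent "true" similarity structure over a synthetic Polish-like lexicon,
a ladder of candidate semantic spaces whose fidelity to that truth
decreases in a planted order (space 1 is the objectively best candidate),
three-condition triplets whose clean-space cosines fall in the strong /
weak / unrelated bands, ordinal ratings produced by thresholding a latent
response, and lexical-decision RTs produced by a log-normal model with
additive frequency, length, and similarity effects. Because the truth is
planted, tests can ask the one question real data never answers: does the
selection procedure find the best space, and are its generalization
estimates honest?

Default band centers (0.69 / 0.49 / 0.12), rating condition means
(5.73 / 4.14 / 1.27), and RT condition means (613 / 630 / 644 ms) follow
the published norms the generator is calibrated to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import rng_for
from .pseudowords import make_pseudowords, valid_pseudowords
from .spaces import SemanticSpace
from .stimuli import CONDITIONS, LdtList, Triplet, build_ldt_lists, partition_survey_blocks

__all__ = [
    "GeneratorConfig",
    "SyntheticWorld",
    "make_world",
    "simulate_ratings",
    "simulate_ldt",
    "simulate_simlex",
    "make_ldt_materials",
    "build_tasks",
]

_CONSONANTS = "bcdfgjklmnprstwz"
_VOWELS = "aeiouy"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic world.

    Sizes default to the published design (264 triplets normed, 72 LDT
    subjects, 61 rating subjects over two presentation orders); noise
    levels are calibrated so the rating and RT condition means land on the
    published values, and ``noise_sds`` plants a strongly separated
    fidelity ladder with space 1 best.
    """

    vocab_size: int = 1600
    dimension: int = 50
    n_spaces: int = 5
    noise_sds: tuple = (0.10, 0.45, 0.80, 1.15, 1.50)
    band_centers: tuple = (0.69, 0.49, 0.12)
    band_sds: tuple = (0.07, 0.04, 0.13)
    band_clips: tuple = ((0.50, 0.88), (0.40, 0.60), (-0.18, 0.45))
    n_triplets: int = 264
    n_subjects: int = 72  # LDT participants
    n_rating_subjects: int = 61  # split across the two presentation orders
    # ordinal rating model: latent = intercept + slope * sgn(s)|s|^power,
    # mildly convex in similarity so the scale compresses near "unrelated"
    rating_thresholds: tuple = (1.5, 2.5, 3.5, 4.5, 5.5, 6.5)
    rating_slope: float = 9.6833
    rating_intercept: float = -1.7377
    rating_power: float = 0.7
    rating_noise_sd: float = 0.55
    rating_subject_sd: float = 0.20
    rating_pair_sd: float = 1.2  # stable pair-specific deviation from the latent line
    # log-RT model: (intercept, b_target_zipf, b_target_len,
    #                b_prime_zipf, b_prime_len, b_similarity)
    rt_coefficients: tuple = (6.564, -0.04, 0.008, -0.01, 0.002, -0.076)
    rt_noise_sd: float = 0.16
    subject_sd: float = 0.08
    item_sd: float = 0.05
    rt_deadline_ms: float = 1000.0
    error_rate: float = 0.022
    anticipation_rate: float = 0.005
    # lexicon frequency range follows the published Zipf span
    zipf_mean: float = 3.3
    zipf_sd: float = 0.6
    zipf_range: tuple = (1.1, 5.5)
    word_length_range: tuple = (4, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.noise_sds) != self.n_spaces:
            raise ValueError("noise_sds must have one entry per space")
        diffs = np.diff(self.noise_sds)
        if np.any(diffs <= 0):
            raise ValueError("noise_sds must be strictly increasing (space 1 best)")
        if list(self.band_centers) != sorted(self.band_centers, reverse=True):
            raise ValueError("band centers must decrease strong -> weak -> unrelated")
        if list(self.rating_thresholds) != sorted(self.rating_thresholds):
            raise ValueError("rating thresholds must be increasing")
        if self.vocab_size < 4 * self.n_triplets + 50:
            raise ValueError(
                "vocab_size too small for the requested triplet count: "
                f"need >= {4 * self.n_triplets + 50}"
            )


@dataclass
class SyntheticWorld:
    """One generated study: truth, candidate spaces, stimuli, lexicon."""

    clean: SemanticSpace  # the latent true embedding (unit rows)
    spaces: list[SemanticSpace]
    triplets: list[Triplet]
    lexicon: pd.DataFrame  # index word; columns zipf, length
    extra_words: list[str]  # vocab never used as target or prime
    config: GeneratorConfig = field(repr=False, default=None)

    def true_cosine(self, word1: str, word2: str) -> float:
        v1, v2 = self.clean.vector(word1), self.clean.vector(word2)
        return float(np.clip(np.dot(v1, v2), -1.0, 1.0))

    def true_similarity_matrix(self, words: Sequence[str]) -> np.ndarray:
        idx = [self.clean.index_of(w) for w in words]
        V = self.clean.vectors[idx]
        return np.clip(V @ V.T, -1.0, 1.0)


def _make_words(rng: np.random.Generator, n: int, length_range: tuple) -> list[str]:
    """Unique consonant/vowel-alternating strings (pronounceable-ish)."""
    words: list[str] = []
    seen: set[str] = set()
    lo, hi = length_range
    while len(words) < n:
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(2))
        chars = []
        for i in range(length):
            pool = _CONSONANTS if (i + start) % 2 == 0 else _VOWELS
            chars.append(pool[rng.integers(len(pool))])
        w = "".join(chars)
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def make_world(config: GeneratorConfig | None = None) -> SyntheticWorld:
    """Generate a synthetic world; identical configs give identical worlds.

    The clean embedding holds unit vectors; each triplet's primes are
    constructed so their clean-space cosine with the target is drawn from
    the condition's band. Candidate space i is the clean embedding plus
    isotropic noise of total magnitude ``noise_sds[i]`` relative to the
    unit vectors, so cosine fidelity decreases strictly down the ladder.
    """
    cfg = config or GeneratorConfig()
    rng = rng_for(cfg.seed, "world")
    n_t = cfg.n_triplets
    words = _make_words(rng, cfg.vocab_size, cfg.word_length_range)

    targets = words[:n_t]
    primes = {
        "strong": words[n_t: 2 * n_t],
        "weak": words[2 * n_t: 3 * n_t],
        "unrelated": words[3 * n_t: 4 * n_t],
    }
    extra = words[4 * n_t:]

    dim = cfg.dimension
    vectors = np.empty((cfg.vocab_size, dim))
    target_vecs = np.array([_unit(rng.standard_normal(dim)) for _ in range(n_t)])
    vectors[:n_t] = target_vecs
    for c_idx, cond in enumerate(CONDITIONS):
        center, sd = cfg.band_centers[c_idx], cfg.band_sds[c_idx]
        lo, hi = cfg.band_clips[c_idx]
        cos = np.clip(rng.normal(center, sd, size=n_t), lo, hi)
        for i in range(n_t):
            t = target_vecs[i]
            w = rng.standard_normal(dim)
            w = _unit(w - np.dot(w, t) * t)  # orthonormal to the target
            vectors[(c_idx + 1) * n_t + i] = cos[i] * t + np.sqrt(1 - cos[i] ** 2) * w
    for j in range(4 * n_t, cfg.vocab_size):
        vectors[j] = _unit(rng.standard_normal(dim))

    clean = SemanticSpace("clean", dim, words, vectors)

    spaces = []
    for i, sd in enumerate(cfg.noise_sds):
        noise = rng.standard_normal((cfg.vocab_size, dim))
        noise *= sd / np.sqrt(dim)  # total noise magnitude ~ sd per vector
        spaces.append(
            SemanticSpace(f"space_{i + 1:02d}", dim, list(words), vectors + noise)
        )

    triplets = [
        Triplet(
            target=targets[i],
            prime_strong=primes["strong"][i],
            prime_weak=primes["weak"][i],
            prime_unrelated=primes["unrelated"][i],
        )
        for i in range(n_t)
    ]

    lengths = [len(w) for w in words]
    zipf = np.clip(
        rng.normal(cfg.zipf_mean, cfg.zipf_sd, size=cfg.vocab_size), *cfg.zipf_range
    )
    lexicon = pd.DataFrame({"zipf": zipf, "length": lengths}, index=pd.Index(words, name="word"))

    world = SyntheticWorld(clean, spaces, triplets, lexicon, extra, cfg)
    _assert_planted_ordering(world, rng)
    return world


def _assert_planted_ordering(world: SyntheticWorld, rng: np.random.Generator) -> None:
    """Space 1's cosines must correlate best with the truth (sampled pairs)."""
    n = len(world.clean)
    i = rng.integers(n, size=400)
    j = (i + 1 + rng.integers(n - 1, size=400)) % n
    truth = np.einsum("ij,ij->i", world.clean.vectors[i], world.clean.vectors[j])
    cors = []
    for s in world.spaces:
        V = s.vectors
        norms = np.linalg.norm(V, axis=1)
        cos = np.einsum("ij,ij->i", V[i], V[j]) / (norms[i] * norms[j])
        cors.append(np.corrcoef(truth, cos)[0, 1])
    if np.argmax(cors) != 0:
        raise RuntimeError(
            f"planted ordering violated: fidelity correlations {cors}"
        )


def simulate_ratings(
    world: SyntheticWorld, n_subjects: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-subject ordinal ratings (1-7) of all triplet pairs.

    Latent response = intercept + slope * true similarity + subject shift
    + noise, discretized through the ordered thresholds. Subjects are split
    between the two presentation orders; no order effect is generated.
    Survey blocks follow a counterbalanced 5-block plan.
    """
    cfg = world.config
    n_subjects = n_subjects or cfg.n_rating_subjects
    rng = rng_for(seed, "ratings")
    plan = partition_survey_blocks(world.triplets, n_blocks=5, seed=seed)

    pairs, conds, blocks = [], [], []
    for (i, c), b in plan.assignment.items():
        t = world.triplets[i]
        pairs.append((t.prime(c), t.target))
        conds.append(c)
        blocks.append(b + 1)
    sims = np.array([world.true_cosine(p, t) for p, t in pairs])
    latent_mean = cfg.rating_intercept + cfg.rating_slope * (
        np.sign(sims) * np.abs(sims) ** cfg.rating_power
    )
    # pair-specific semantic idiosyncrasy shared by all raters of a pair
    latent_mean = latent_mean + rng.normal(0, cfg.rating_pair_sd, len(pairs))
    cuts = np.asarray(cfg.rating_thresholds)

    rows = []
    for s in range(n_subjects):
        order = "target-prime" if s < n_subjects // 2 else "prime-target"
        shift = rng.normal(0, cfg.rating_subject_sd)
        latent = latent_mean + shift + rng.normal(0, cfg.rating_noise_sd, len(pairs))
        rating = 1 + np.searchsorted(cuts, latent)
        for k, (prime, target) in enumerate(pairs):
            rows.append(
                (f"S{s + 1:03d}", prime, target, conds[k], order, blocks[k],
                 int(rating[k]))
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "prime", "target", "condition",
                 "presentation_order", "block", "rating"],
    )


def make_ldt_materials(
    world: SyntheticWorld, seed: int = 0
) -> tuple[list[Triplet], list[tuple[str, str]], list[tuple[str, str]]]:
    """Experimental triplets, filler pairs, and pseudoword trials for the LDT.

    Keeps the first 6k-divisible subset of the world's triplets (after the
    norming step the published design retains 216 of 264), builds unrelated
    filler pairs from the unused word pool, and generates pseudoword trials
    whose primes never occur among experimental or filler words.
    """
    n = (len(world.triplets) // 6) * 6
    triplets = world.triplets[:n]
    n_fillers = n // 6
    n_pseudo = n // 2 + n_fillers

    pool = list(world.extra_words)
    need = 2 * n_fillers + n_pseudo
    if len(pool) < need:
        raise ValueError(f"extra word pool too small: {len(pool)} < {need}")
    fillers = [(pool[2 * i], pool[2 * i + 1]) for i in range(n_fillers)]
    pw_primes = pool[2 * n_fillers: 2 * n_fillers + n_pseudo]

    all_words = set(world.lexicon.index)
    pseudo_trials = []
    for k, prime in enumerate(pw_primes):
        source = pool[(2 * n_fillers + n_pseudo + k) % len(pool)]
        cands = make_pseudowords(source, all_words, n=1, seed=seed + k)
        valid = valid_pseudowords(cands)
        pw = valid[0] if valid else source[::-1] + "x"  # fallback, still a nonword
        pseudo_trials.append((prime, pw))
    return triplets, fillers, pseudo_trials


def simulate_ldt(
    world: SyntheticWorld,
    lists: Sequence[LdtList] | None = None,
    n_subjects: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial lexical-decision records for all subjects.

    log RT = linear predictor (frequency, length, similarity; facilitation
    is a negative similarity coefficient) + subject and item shifts +
    Gaussian noise; RTs are exponentiated and censored at the response
    deadline (a censored trial is a timeout, accuracy 0). A small error
    rate and a small fraction of sub-250 ms anticipations are injected so
    preprocessing has something to remove.
    """
    cfg = world.config
    n_subjects = n_subjects or cfg.n_subjects
    rng = rng_for(seed, "ldt")
    if lists is None:
        triplets, fillers, pseudo = make_ldt_materials(world, seed)
        lists = build_ldt_lists(triplets, fillers, pseudo, seed=seed)

    b0, b_tz, b_tl, b_pz, b_pl, b_sim = cfg.rt_coefficients
    lex = world.lexicon

    # item (target) shifts, shared across subjects and lists
    all_targets = sorted({t for lst in lists for t in lst.trials["target"]})
    item_shift = dict(
        zip(all_targets, rng.normal(0, cfg.item_sd, len(all_targets)))
    )

    # fixed part of the linear predictor, precomputed once per list
    fixed_mu: list[np.ndarray] = []
    for lst in lists:
        df = lst.trials
        is_word = (df["trial_class"] != "pseudoword").to_numpy()
        mu = np.full(len(df), np.log(700.0))  # nonword decisions: slower baseline
        word_rows = df[is_word]
        sims = np.array(
            [world.true_cosine(p, t)
             for p, t in zip(word_rows["prime"], word_rows["target"])]
        )
        mu[is_word] = (
            b0
            + b_tz * lex.loc[word_rows["target"], "zipf"].to_numpy()
            + b_tl * lex.loc[word_rows["target"], "length"].to_numpy()
            + b_pz * lex.loc[word_rows["prime"], "zipf"].to_numpy()
            + b_pl * lex.loc[word_rows["prime"], "length"].to_numpy()
            + b_sim * sims
        )
        mu += np.array([item_shift[t] for t in df["target"]])
        fixed_mu.append(mu)

    frames = []
    for s in range(n_subjects):
        lst = lists[s % len(lists)]
        mu = fixed_mu[s % len(lists)]
        n = len(mu)
        u_subj = rng.normal(0, cfg.subject_sd)
        rt = np.exp(mu + u_subj + rng.normal(0, cfg.rt_noise_sd, n))
        accuracy = (rng.random(n) >= cfg.error_rate).astype(int)
        anticip = rng.random(n) < cfg.anticipation_rate
        rt[anticip] = rng.uniform(80.0, 240.0, int(anticip.sum()))
        timeout = rt > cfg.rt_deadline_ms
        rt[timeout] = cfg.rt_deadline_ms
        accuracy[timeout] = 0
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": f"P{s + 1:03d}",
                    "list_id": lst.list_id,
                    "set_id": lst.set_id,
                    "prime": lst.trials["prime"].to_numpy(),
                    "target": lst.trials["target"].to_numpy(),
                    "trial_class": lst.trials["trial_class"].to_numpy(),
                    "rt_ms": np.round(rt, 1),
                    "accuracy": accuracy,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_simlex(
    world: SyntheticWorld, n_pairs: int = 300, seed: int = 0
) -> pd.DataFrame:
    """A SimLex-999-style pair table with similarity and relatedness columns.

    Half the pairs are drawn from the planted triplets (covering the full
    similarity range), half are random vocabulary pairs. Relatedness tracks
    the true similarity closely; similarity ratings mix in an independent
    component and more noise, mirroring how much harder similarity norms
    are to predict than relatedness norms.
    """
    rng = rng_for(seed, "simlex")
    triplet_pairs = [
        (t.prime(c), t.target) for t in world.triplets for c in CONDITIONS
    ]
    k = min(n_pairs // 2, len(triplet_pairs))
    chosen = [triplet_pairs[i] for i in rng.choice(len(triplet_pairs), k, replace=False)]
    vocab = list(world.lexicon.index)
    seen = set(chosen)
    while len(chosen) < n_pairs:
        a, b = rng.choice(len(vocab), 2, replace=False)
        pair = (vocab[a], vocab[b])
        if pair not in seen:
            seen.add(pair)
            chosen.append(pair)

    sims = np.array([world.true_cosine(a, b) for a, b in chosen])
    rel = 5.0 + 4.5 * sims + rng.normal(0, 0.9, n_pairs)
    indep = rng.normal(0, 1.0, n_pairs)
    sml = 5.0 + 4.5 * (0.55 * sims + 0.45 * indep) + rng.normal(0, 1.3, n_pairs)
    return pd.DataFrame(
        {
            "word1": [a for a, _ in chosen],
            "word2": [b for _, b in chosen],
            "similarity": np.clip(sml, 0, 10),
            "relatedness": np.clip(rel, 0, 10),
        }
    )


def build_tasks(
    world: SyntheticWorld,
    ldt_trials: pd.DataFrame | None = None,
    ratings: pd.DataFrame | None = None,
    simlex: pd.DataFrame | None = None,
    seed: int = 0,
    n_subjects: int | None = None,
    n_rating_subjects: int | None = None,
    n_simlex_pairs: int = 300,
    ldt_per_trial: bool = False,
):
    """Simulate (when not supplied) and assemble the four evaluation tasks.

    Returns ``(tasks, datasets)`` where tasks is a list of EvaluationTask
    (per-trial log RTs with frequency/length covariates; mean ratings per
    pair; SimLex relatedness; SimLex similarity) and datasets maps names to
    the underlying tables. LDT trials are cleaned first: incorrect
    responses dropped, then the anticipation-floor and 2.5 SD outlier rules.
    """
    from .preprocess import drop_incorrect, filter_rt_outliers
    from .selection import EvaluationTask

    if ldt_trials is None:
        ldt_trials = simulate_ldt(world, n_subjects=n_subjects, seed=seed)
    if ratings is None:
        ratings = simulate_ratings(world, n_subjects=n_rating_subjects, seed=seed)
    if simlex is None:
        simlex = simulate_simlex(world, n_pairs=n_simlex_pairs, seed=seed)

    lex = world.lexicon
    correct = drop_incorrect(ldt_trials)
    exp = correct[correct.trial_class.isin(CONDITIONS)]
    kept, _, _ = filter_rt_outliers(exp)
    kept = kept.assign(log_rt=np.log(kept["rt_ms"].to_numpy(dtype=float)))
    if ldt_per_trial:
        pair_keys = sorted(set(zip(kept["prime"], kept["target"])))
        pair_index = {p: i for i, p in enumerate(pair_keys)}
        obs_idx = np.array(
            [pair_index[(p, t)] for p, t in zip(kept["prime"], kept["target"])]
        )
        response = kept["log_rt"].to_numpy()
        primes = kept["prime"]
        targets = kept["target"]
    else:
        # mean log RT per pair: the item-level aggregate the task is scored on
        agg = kept.groupby(["prime", "target"])["log_rt"].mean().reset_index()
        pair_keys = list(zip(agg["prime"], agg["target"]))
        obs_idx = None
        response = agg["log_rt"].to_numpy()
        primes = agg["prime"]
        targets = agg["target"]
    covariates = pd.DataFrame(
        {
            "prime_zipf": lex.loc[primes, "zipf"].to_numpy(),
            "prime_length": lex.loc[primes, "length"].to_numpy(dtype=float),
            "target_zipf": lex.loc[targets, "zipf"].to_numpy(),
            "target_length": lex.loc[targets, "length"].to_numpy(dtype=float),
        }
    )
    ldt_task = EvaluationTask(
        task_id="ldt_logrt",
        pairs=pair_keys,
        response=response,
        obs_pair_index=obs_idx,
        covariates=covariates,
    )

    mean_ratings = (
        ratings.groupby(["prime", "target"])["rating"].mean().reset_index()
    )
    ratings_task = EvaluationTask(
        task_id="ratings",
        pairs=list(zip(mean_ratings["prime"], mean_ratings["target"])),
        response=mean_ratings["rating"].to_numpy(dtype=float),
    )

    simlex_pairs = list(zip(simlex["word1"], simlex["word2"]))
    rel_task = EvaluationTask(
        task_id="simlex_relatedness",
        pairs=simlex_pairs,
        response=simlex["relatedness"].to_numpy(dtype=float),
    )
    sim_task = EvaluationTask(
        task_id="simlex_similarity",
        pairs=simlex_pairs,
        response=simlex["similarity"].to_numpy(dtype=float),
    )
    tasks = [ldt_task, ratings_task, rel_task, sim_task]
    datasets = {"ldt": ldt_trials, "ratings": ratings, "simlex": simlex}
    return tasks, datasets
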