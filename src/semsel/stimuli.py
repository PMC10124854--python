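"""Three-condition priming stimulus design.

The unit of design is the *triplet*: one target word with a strongly
related, a weakly related, and an unrelated prime. This module builds and
validates the stimulus pipeline around triplets:

* candidate primes from cosine nearest neighbors,
* per-condition cosine band summaries,
* rating-threshold filtering of triplets after a norming survey,
* partition of the rating survey into counterbalanced blocks in which no
  target is seen twice,
* construction of the six lexical-decision lists (two target sets x three
  lists, Latin-square rotation of prime condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import rng_for
from .spaces import SemanticSpace, nearest_neighbors, pair_similarities

__all__ = [
    "CONDITIONS",
    "Triplet",
    "SurveyBlockPlan",
    "LdtList",
    "generate_candidates",
    "verify_condition_bands",
    "filter_triplets_by_ratings",
    "partition_survey_blocks",
    "build_ldt_lists",
    "triplets_to_frame",
    "triplets_from_frame",
]

CONDITIONS = ("strong", "weak", "unrelated")


@dataclass(frozen=True)
class Triplet:
    """One target with its strong, weak, and unrelated primes."""

    target: str
    prime_strong: str
    prime_weak: str
    prime_unrelated: str

    def __post_init__(self) -> None:
        words = (self.target, self.prime_strong, self.prime_weak, self.prime_unrelated)
        if any(not w for w in words):
            raise ValueError("triplet words must be non-empty")
        if len(set(words)) != 4:
            raise ValueError(f"triplet words must be distinct: {words}")

    def prime(self, condition: str) -> str:
        return {
            "strong": self.prime_strong,
            "weak": self.prime_weak,
            "unrelated": self.prime_unrelated,
        }[condition]

    def pairs(self) -> list[tuple[str, str, str]]:
        """(condition, prime, target) for the three conditions."""
        return [(c, self.prime(c), self.target) for c in CONDITIONS]


@dataclass
class SurveyBlockPlan:
    """Assignment of each (triplet, condition) pair to a survey block."""

    n_blocks: int
    assignment: dict[tuple[int, str], int]  # (triplet index, condition) -> block
    triplets: list[Triplet]
    seed: int

    def block_pairs(self, block: int) -> list[tuple[str, str, str]]:
        """(condition, prime, target) pairs shown in one block."""
        return [
            (c, self.triplets[i].prime(c), self.triplets[i].target)
            for (i, c), b in self.assignment.items()
            if b == block
        ]

    def validate(self) -> None:
        for i in range(len(self.triplets)):
            blocks = {self.assignment[(i, c)] for c in CONDITIONS}
            if len(blocks) != 3:
                raise AssertionError(
                    f"triplet {i}: its three pairs share a block {blocks}"
                )
        for b in range(self.n_blocks):
            targets = [t for _, _, t in self.block_pairs(b)]
            if len(targets) != len(set(targets)):
                raise AssertionError(f"block {b}: a target appears twice")
        # every condition follows the same per-block quota vector
        n, k = len(self.triplets), self.n_blocks
        quotas = _block_quotas(n, k)
        for c in CONDITIONS:
            counts = np.zeros(k, dtype=int)
            for i in range(n):
                counts[self.assignment[(i, c)]] += 1
            if sorted(counts) != sorted(quotas):
                raise AssertionError(
                    f"condition {c}: block counts {counts.tolist()} do not "
                    f"match quotas {quotas}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "block": b + 1,
                "condition": c,
                "prime": self.triplets[i].prime(c),
                "target": self.triplets[i].target,
                "triplet_index": i,
                "seed": self.seed,
            }
            for (i, c), b in sorted(self.assignment.items(), key=lambda kv: kv[1])
        ]
        return pd.DataFrame(rows)


@dataclass
class LdtList:
    """One lexical-decision list: experimental, filler, and pseudoword trials."""

    list_id: int  # 1..6
    set_id: int  # 1..2
    trials: pd.DataFrame  # columns: prime, target, trial_class
    seed: int = 0

    def validate(self) -> None:
        classes = set(self.trials["trial_class"])
        if not classes <= {"strong", "weak", "unrelated", "filler", "pseudoword"}:
            raise AssertionError(f"unknown trial classes: {classes}")
        exp = self.trials[self.trials.trial_class.isin(CONDITIONS)]
        if exp["target"].duplicated().any():
            raise AssertionError("an experimental target occurs twice in a list")
        pw_primes = set(self.trials.loc[self.trials.trial_class == "pseudoword", "prime"])
        exp_words = set(exp["prime"]) | set(exp["target"])
        if pw_primes & exp_words:
            raise AssertionError("pseudoword-trial primes overlap experimental words")


def generate_candidates(
    space: SemanticSpace,
    target: str,
    k: int = 800,
    predicate: Callable[[str], bool] | None = None,
) -> list[tuple[str, float]]:
    """Top-k cosine neighbors of the target, optionally filtered.

    The predicate (e.g., membership in a noun list) is applied after
    ranking, mirroring a judge-facing candidate shortlist. An empty result
    raises a warning, not an error.
    """
    k = min(k, len(space) - 1)
    ranked = nearest_neighbors(space, target, k)
    if predicate is not None:
        ranked = [(w, c) for w, c in ranked if predicate(w)]
    if not ranked:
        warnings.warn(f"no candidates left for target {target!r} after filtering")
    return ranked


def verify_condition_bands(
    space: SemanticSpace, triplets: Sequence[Triplet]
) -> pd.DataFrame:
    """Per-condition cosine summaries (n, mean, sd, min, max, n_oov).

    OOV pairs are excluded from the statistics but counted, so a space with
    poor coverage cannot silently shrink a band.
    """
    rows = []
    for cond in CONDITIONS:
        pairs = [(t.prime(cond), t.target) for t in triplets]
        sims = pair_similarities(space, pairs)
        vals = np.array([s.cosine for s in sims if s.cosine is not None])
        n_oov = sum(1 for s in sims if s.cosine is None)
        rows.append(
            {
                "condition": cond,
                "n": len(vals),
                "n_oov": n_oov,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "min": vals.min() if len(vals) else np.nan,
                "max": vals.max() if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def filter_triplets_by_ratings(
    triplets: Sequence[Triplet],
    mean_ratings: Mapping[tuple[str, str], float],
    strong_min: float = 4.0,
    weak_min: float = 3.0,
    weak_max: float = 5.5,
    unrelated_max: float = 2.0,
) -> tuple[list[Triplet], list[Triplet], list[Triplet]]:
    """Keep triplets whose three pairs pass the rating thresholds.

    Thresholds are strict: the strong pair must be rated above ``strong_min``,
    the weak pair above ``weak_min`` and below ``weak_max``, and the
    unrelated pair below ``unrelated_max``; boundary values fail. Triplets
    whose weak pair out-rates the strong pair are additionally returned as
    inversions (they may pass or fail the thresholds independently; the
    choice of replacement primes is left to human judges).

    Returns ``(kept, removed, inversions)``.
    """
    kept: list[Triplet] = []
    removed: list[Triplet] = []
    inversions: list[Triplet] = []
    missing: list[tuple[str, str]] = []
    for t in triplets:
        ratings = {}
        for cond, prime, target in t.pairs():
            key = (prime, target)
            if key not in mean_ratings:
                missing.append(key)
                continue
            ratings[cond] = mean_ratings[key]
        if len(ratings) != 3:
            continue
        if ratings["weak"] > ratings["strong"]:
            inversions.append(t)
        ok = (
            ratings["strong"] > strong_min
            and weak_min < ratings["weak"] < weak_max
            and ratings["unrelated"] < unrelated_max
        )
        (kept if ok else removed).append(t)
    if missing:
        raise KeyError(f"missing mean ratings for pairs: {missing[:10]}")
    return kept, removed, inversions


def _block_quotas(n: int, n_blocks: int, multiple: int = 6) -> list[int]:
    """Per-condition triplet quota per block.

    Equal-sized blocks whose quota is rounded up to a multiple of
    ``multiple``, with the shortfall collected in one final shorter block;
    when that rounding is infeasible (small n) the quotas fall back to a
    balanced split. 264 triplets over 5 blocks gives [54, 54, 54, 54, 48]:
    four survey blocks of 162 pairs and one of 144.
    """
    q = -(-n // n_blocks)  # ceil
    q_r = -(-q // multiple) * multiple
    last = n - (n_blocks - 1) * q_r
    if 0 < last <= q_r:
        return [q_r] * (n_blocks - 1) + [last]
    base, rem = divmod(n, n_blocks)
    return [base + (1 if i < rem else 0) for i in range(n_blocks)]


def partition_survey_blocks(
    triplets: Sequence[Triplet], n_blocks: int = 5, seed: int = 0
) -> SurveyBlockPlan:
    """Assign each triplet's three pairs to three distinct survey blocks.

    Constraints: no target is shown twice within a block (each triplet's
    pairs all contain its target, so the three pairs must land in three
    different blocks) and each condition is spread over blocks according to
    the same quota vector. Implemented as a randomized greedy assignment
    with swap repair; one valid realization of the published layout.
    """
    n = len(triplets)
    if n_blocks < 3:
        raise ValueError(
            "n_blocks must be >= 3: each triplet has three same-target pairs "
            "that must be shown in distinct blocks"
        )
    if n < n_blocks:
        raise ValueError(f"need at least {n_blocks} triplets, got {n}")
    targets = [t.target for t in triplets]
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate target across triplets")

    rng = rng_for(seed, "survey-blocks")
    quotas = _block_quotas(n, n_blocks)

    for _attempt in range(20):
        remaining = {c: np.array(quotas, dtype=int) for c in CONDITIONS}
        assignment: dict[tuple[int, str], int] = {}
        order = rng.permutation(n)
        ok = True
        for i in order:
            used: set[int] = set()
            for c in rng.permutation(CONDITIONS):
                # prefer blocks with most remaining quota (breaks ties randomly)
                avail = [
                    b
                    for b in range(n_blocks)
                    if remaining[c][b] > 0 and b not in used
                ]
                if not avail:
                    ok = False
                    break
                weights = remaining[c][avail].astype(float)
                b = int(rng.choice(avail, p=weights / weights.sum()))
                assignment[(int(i), c)] = b
                remaining[c][b] -= 1
                used.add(b)
            if not ok:
                break
        if ok:
            plan = SurveyBlockPlan(n_blocks, assignment, list(triplets), seed)
            plan.validate()
            return plan
    raise RuntimeError(
        f"could not satisfy block constraints for n={n}, n_blocks={n_blocks}; "
        "the per-condition quotas leave no system of distinct blocks"
    )


def build_ldt_lists(
    triplets: Sequence[Triplet],
    fillers: Sequence[tuple[str, str]],
    pseudoword_trials: Sequence[tuple[str, str]],
    seed: int = 0,
) -> list[LdtList]:
    """Build the six lexical-decision lists.

    Targets are split into two sets; for each set three lists rotate the
    prime condition Latin-square fashion so that across a set's lists every
    target is paired once with each of its three primes. Every list carries
    the same filler pairs and all pseudoword trials; trial order is
    randomized per list. With 216 triplets, 36 fillers, and 144 pseudoword
    trials each list has 36 trials per experimental condition and 288 trials
    in total.
    """
    n = len(triplets)
    if n % 6 != 0:
        raise ValueError(
            f"triplet count {n} must be divisible by 6 "
            "(two target sets, each rotated over three lists)"
        )
    filler_words = {w for p in fillers for w in p}
    exp_words = {w for t in triplets for w in (t.target, t.prime_strong,
                                               t.prime_weak, t.prime_unrelated)}
    pw_primes = {p for p, _ in pseudoword_trials}
    if pw_primes & (exp_words | filler_words):
        raise ValueError("pseudoword-trial primes must not occur as "
                         "experimental or filler words")

    rng = rng_for(seed, "ldt-lists")
    order = rng.permutation(n)
    half = n // 2
    sets = {1: [triplets[i] for i in order[:half]],
            2: [triplets[i] for i in order[half:]]}

    lists: list[LdtList] = []
    for set_id in (1, 2):
        members = sets[set_id]
        third = len(members) // 3
        groups = [members[:third], members[third: 2 * third], members[2 * third:]]
        for j in range(3):
            list_id = (set_id - 1) * 3 + j + 1
            rows = []
            for g, group in enumerate(groups):
                cond = CONDITIONS[(g + j) % 3]
                for t in group:
                    rows.append(
                        {"prime": t.prime(cond), "target": t.target,
                         "trial_class": cond}
                    )
            for prime, target in fillers:
                rows.append({"prime": prime, "target": target,
                             "trial_class": "filler"})
            for prime, pw in pseudoword_trials:
                rows.append({"prime": prime, "target": pw,
                             "trial_class": "pseudoword"})
            df = pd.DataFrame(rows)
            df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
            lst = LdtList(list_id=list_id, set_id=set_id, trials=df, seed=seed)
            lst.validate()
            lists.append(lst)
    return lists


def triplets_to_frame(triplets: Iterable[Triplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": t.target,
                "prime_strong": t.prime_strong,
                "prime_weak": t.prime_weak,
                "prime_unrelated": t.prime_unrelated,
            }
            for t in triplets
        ]
    )


def triplets_from_frame(df: pd.DataFrame) -> list[Triplet]:
    return [
        Triplet(r.target, r.prime_strong, r.prime_weak, r.prime_unrelated)
        for r in df.itertuples(index=False)
    ]
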