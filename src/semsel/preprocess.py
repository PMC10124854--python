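"""Preprocessing of rating and lexical-decision data.

Implements the standard cleaning pipeline for a primed lexical-decision
experiment and its norming survey:

* participant exclusion by |z| > 2.5 of a per-subject summary statistic,
* trial exclusion below a 250 ms anticipation floor and beyond 2.5 SD of
  the participant-by-condition and item-by-condition means,
* the inverse RT transform -1000/RT (larger = faster, so facilitation
  keeps a negative sign in regression),
* sum-to-zero (deviation) contrast coding with unrelated as baseline,
* per-condition descriptive summaries and priming effects.

Inferential mixed-model fitting is out of scope; the module emits
model-ready tables (coded contrasts, transformed responses) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessReport",
    "exclude_participants_zscore",
    "drop_incorrect",
    "filter_rt_outliers",
    "inverse_transform",
    "deviation_code",
    "two_level_code",
    "condition_summaries",
]

CONDITION_ORDER = ("strong", "weak", "unrelated")


@dataclass
class PreprocessReport:
    """Audit trail of one preprocessing run."""

    n_input: int
    n_kept: int
    n_removed_floor: int
    n_removed_sd: int
    excluded_subjects: list = field(default_factory=list)
    rules: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept

    @property
    def proportion_outliers(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "n_removed_floor": self.n_removed_floor,
            "n_removed_sd": self.n_removed_sd,
            "proportion_outliers": self.proportion_outliers,
            "excluded_subjects": list(self.excluded_subjects),
            "rules": dict(self.rules),
        }


def exclude_participants_zscore(
    per_subject_stat: Mapping, threshold: float = 2.5
) -> tuple[list, list]:
    """Split subjects into (kept, excluded) by |z| > threshold.

    z-scores are computed against the sample mean and SD (ddof=1) of the
    per-subject statistic. With zero SD no one is excluded and a warning is
    issued.
    """
    subjects = list(per_subject_stat)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for z-score exclusion")
    vals = np.array([per_subject_stat[s] for s in subjects], dtype=float)
    sd = vals.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance across subjects; no exclusions")
        return subjects, []
    z = (vals - vals.mean()) / sd
    kept = [s for s, zi in zip(subjects, z) if abs(zi) <= threshold]
    excluded = [s for s, zi in zip(subjects, z) if abs(zi) > threshold]
    return kept, excluded


def drop_incorrect(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only correct responses (accuracy == 1)."""
    return trials[trials["accuracy"] == 1].copy()


def filter_rt_outliers(
    trials: pd.DataFrame,
    sd_mult: float = 2.5,
    floor_ms: float = 250.0,
    combine: str = "union",
    subject_col: str = "subject_id",
    item_col: str = "target",
    condition_col: str = "trial_class",
    rt_col: str = "rt_ms",
) -> tuple[pd.DataFrame, pd.DataFrame, PreprocessReport]:
    """Remove RT outliers; expects correct trials only.

    A trial is an outlier if its RT is below ``floor_ms``, or deviates more
    than ``sd_mult`` SDs from its participant-by-condition mean or its
    item-by-condition mean (``combine="union"``; ``"intersection"``
    requires both SD rules to fire). Cells with fewer than 2 trials are
    skipped for the SD rule. Returns (kept, removed, report); kept plus
    removed always partition the input.
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    rt = trials[rt_col].to_numpy(dtype=float)
    floor_mask = rt < floor_ms

    def sd_flags(group_cols: list[str]) -> np.ndarray:
        grp = trials.groupby(group_cols, sort=False)[rt_col]
        mean = grp.transform("mean").to_numpy()
        sd = grp.transform("std").to_numpy()  # ddof=1; NaN for singleton cells
        count = grp.transform("count").to_numpy()
        with np.errstate(invalid="ignore"):
            dev = np.abs(rt - mean) > sd_mult * sd
        dev[(count < 2) | ~np.isfinite(sd)] = False
        return dev

    by_subject = sd_flags([subject_col, condition_col])
    by_item = sd_flags([item_col, condition_col])
    sd_mask = (by_subject | by_item) if combine == "union" else (by_subject & by_item)
    removed_mask = floor_mask | sd_mask

    kept = trials[~removed_mask].copy()
    removed = trials[removed_mask].copy()
    report = PreprocessReport(
        n_input=len(trials),
        n_kept=len(kept),
        n_removed_floor=int(floor_mask.sum()),
        n_removed_sd=int((sd_mask & ~floor_mask).sum()),
        rules={"sd_mult": sd_mult, "floor_ms": floor_ms, "combine": combine},
    )
    return kept, removed, report


def inverse_transform(rt_ms):
    """-1000/RT: monotone increasing with response speed.

    Scaling by -1000 keeps the transformed values on a unit-ish scale and
    makes facilitation (faster responses) carry the same sign as in raw-RT
    models.
    """
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("reaction times must be positive")
    out = -1000.0 / rt
    return float(out) if np.isscalar(rt_ms) else out


def deviation_code(conditions) -> pd.DataFrame:
    """Sum-to-zero contrasts for condition with unrelated as baseline.

    Two columns: ``strong_vs_unrelated`` (strong 1, weak 0, unrelated -1)
    and ``weak_vs_unrelated`` (strong 0, weak 1, unrelated -1). Each column
    sums to zero over the three levels and the coding matrix has rank 2.
    """
    mapping = {
        "strong": (1.0, 0.0),
        "weak": (0.0, 1.0),
        "unrelated": (-1.0, -1.0),
    }
    conditions = pd.Series(conditions)
    unknown = set(conditions.unique()) - set(mapping)
    if unknown:
        raise ValueError(f"unknown condition levels: {sorted(unknown)}")
    rows = conditions.map(mapping)
    return pd.DataFrame(
        rows.tolist(),
        columns=["strong_vs_unrelated", "weak_vs_unrelated"],
        index=conditions.index,
    )


def two_level_code(values, level_pos, level_neg) -> pd.Series:
    """Code a two-level factor as +0.5 / -0.5."""
    values = pd.Series(values)
    unknown = set(values.unique()) - {level_pos, level_neg}
    if unknown:
        raise ValueError(f"unknown levels: {sorted(unknown)}")
    return values.map({level_pos: 0.5, level_neg: -0.5})


def condition_summaries(
    trials: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
    condition_col: str = "trial_class",
    rt_col: str = "rt_ms",
) -> dict:
    """Descriptive outcomes: per-condition RT means/SDs and priming effects.

    Priming effects are unrelated - strong, unrelated - weak, and
    weak - strong, in ms. When a per-pair rating table (columns prime,
    target, rating) is supplied, the Pearson correlation between mean
    rating and mean RT per pair is added.
    """
    present = [c for c in CONDITION_ORDER if c in set(trials[condition_col])]
    missing = [c for c in CONDITION_ORDER if c not in present]
    if missing:
        raise ValueError(f"empty conditions: {missing}")
    grp = trials.groupby(condition_col)[rt_col]
    means = grp.mean()
    sds = grp.std(ddof=1)
    out = {
        "means": {c: float(means[c]) for c in present},
        "sds": {c: float(sds[c]) for c in present},
        "priming_effects": {
            "strong": float(means["unrelated"] - means["strong"]),
            "weak": float(means["unrelated"] - means["weak"]),
            "weak_vs_strong": float(means["weak"] - means["strong"]),
        },
    }
    if ratings is not None:
        pair_rt = (
            trials.groupby(["prime", "target"])[rt_col].mean().rename("rt")
        )
        pair_rating = (
            ratings.groupby(["prime", "target"])["rating"].mean().rename("rating")
        )
        merged = pd.concat([pair_rt, pair_rating], axis=1, join="inner").dropna()
        if len(merged) >= 3:
            out["rating_rt_correlation"] = float(
                np.corrcoef(merged["rating"], merged["rt"])[0, 1]
            )
    return out
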