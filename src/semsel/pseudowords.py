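"""Pseudoword generation for lexical-decision "no" trials.

A pseudoword is built from a real source word by replacing one random
letter with another letter of the same category (vowel with vowel,
consonant with consonant), then checking that the result is not itself a
word and contains only attested bigrams and trigrams. The vowel inventory
defaults to Polish (including ą, ę, ó); both it and the n-gram legality
sets can be supplied explicitly, so the generator works for any alphabetic
language.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable, Sequence

from ._util import rng_for

__all__ = [
    "POLISH_VOWELS",
    "POLISH_ALPHABET",
    "PseudowordCandidate",
    "ngram_inventory",
    "make_pseudowords",
    "enumerate_substitutions",
    "valid_pseudowords",
]

POLISH_VOWELS = frozenset("aąeęioóuy")
POLISH_ALPHABET = frozenset("aąbcćdeęfghijklłmnńoóprsśtuwyzźż")


@dataclass(frozen=True)
class PseudowordCandidate:
    """One single-substitution candidate with its validation outcome."""

    source_word: str
    pseudoword: str
    substituted_position: int
    valid: bool
    rejection_reason: str = "none"  # none | real_word | bad_bigram | bad_trigram | same_as_source


def ngram_inventory(
    lexicon: Iterable[str], n: int
) -> frozenset[str]:
    """All attested length-n substrings of the lexicon words."""
    grams: set[str] = set()
    for w in lexicon:
        for i in range(len(w) - n + 1):
            grams.add(w[i : i + n])
    return frozenset(grams)


def _category(letter: str, vowels: Collection[str]) -> str:
    return "vowel" if letter in vowels else "consonant"


def enumerate_substitutions(
    word: str,
    alphabet: Collection[str] = POLISH_ALPHABET,
    vowels: Collection[str] = POLISH_VOWELS,
) -> list[tuple[int, str]]:
    """All (position, candidate) single same-category substitutions.

    Excludes the identity substitution; ordered by position then alphabet
    for reproducibility.
    """
    out = []
    letters = sorted(alphabet)
    for pos, orig in enumerate(word):
        cat = _category(orig, vowels)
        for letter in letters:
            if letter != orig and _category(letter, vowels) == cat:
                out.append((pos, word[:pos] + letter + word[pos + 1 :]))
    return out


def make_pseudowords(
    word: str,
    lexicon: Collection[str],
    legal_bigrams: Collection[str] | None = None,
    legal_trigrams: Collection[str] | None = None,
    n: int = 5,
    seed: int = 0,
    alphabet: Collection[str] = POLISH_ALPHABET,
    vowels: Collection[str] = POLISH_VOWELS,
) -> list[PseudowordCandidate]:
    """Generate up to ``n`` valid pseudowords from one source word.

    Substitutions are tried in seeded random order and the full
    single-substitution space is exhausted before giving up; every
    candidate tried is returned with its validation outcome, so a caller
    can inspect why generation failed. A candidate is valid when it is not
    in the lexicon, all its internal bigrams are in ``legal_bigrams``, and
    all its internal trigrams are in ``legal_trigrams`` (n-gram sets
    default to the inventory attested in the lexicon).
    """
    if len(word) < 2:
        raise ValueError("source word must have at least 2 letters")
    if legal_bigrams is None:
        legal_bigrams = ngram_inventory(lexicon, 2)
    if legal_trigrams is None:
        legal_trigrams = ngram_inventory(lexicon, 3)

    rng = rng_for(seed, "pseudowords", word)
    candidates = enumerate_substitutions(word, alphabet, vowels)
    order = rng.permutation(len(candidates))

    results: list[PseudowordCandidate] = []
    n_valid = 0
    for idx in order:
        pos, cand = candidates[idx]
        reason = "none"
        if cand == word:
            reason = "same_as_source"
        elif cand in lexicon:
            reason = "real_word"
        elif any(
            cand[i : i + 2] not in legal_bigrams for i in range(len(cand) - 1)
        ):
            reason = "bad_bigram"
        elif any(
            cand[i : i + 3] not in legal_trigrams for i in range(len(cand) - 2)
        ):
            reason = "bad_trigram"
        valid = reason == "none"
        results.append(PseudowordCandidate(word, cand, pos, valid, reason))
        if valid:
            n_valid += 1
            if n_valid >= n:
                break
    return results


def valid_pseudowords(candidates: Sequence[PseudowordCandidate]) -> list[str]:
    """The accepted pseudowords, in generation order."""
    return [c.pseudoword for c in candidates if c.valid]
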