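"""Semantic spaces: loading, cosine similarity, neighbors, hyperparameters.

A semantic space is a vocabulary of words with one real vector per word.
Spaces arrive in the word2vec text format (optional ``"n_words dim"``
header, then one word and ``dim`` floats per line; plain or gzipped).
Cosine similarity between word vectors is the relatedness proxy used
throughout the package; out-of-vocabulary lookups are legal and reported,
never silently dropped.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._util import rng_for

__all__ = [
    "SemanticSpace",
    "HyperparameterConfig",
    "PairSimilarity",
    "SpaceFormatError",
    "HYPERPARAMETER_GRID",
    "load_space",
    "write_space",
    "cosine_similarity",
    "nearest_neighbors",
    "pair_similarities",
    "sample_hyperparameters",
    "read_lexicon",
]


class SpaceFormatError(ValueError):
    """Malformed embedding file (row width, header mismatch, empty file)."""


#: Candidate values for every word2vec training hyperparameter explored by
#: random search. ``corpora`` selects between a form-based and a lemmatized
#: training corpus; the rest are the gensim Word2Vec arguments.
HYPERPARAMETER_GRID: dict[str, tuple] = {
    "corpora": ("form-based", "lemmatized"),
    "size": (100, 200, 300, 400, 500, 600, 800, 1000),
    "alpha": (0.001, 0.005, 0.02, 0.025, 0.03, 0.05, 0.1),
    "window": (3, 5, 6, 7, 8, 9, 10, 11, 12, 15),
    "min_count": (30, 50, 100, 200, 300),
    "sample": (0.0, 0.0001, 0.001, 0.01, 0.1),
    "min_alpha": (0.0001, 0.0005, 0.001, 0.005),
    "sg": (0, 1),
    "hs": (0, 1),
    "negative": (5, 10, 15, 20),
    "cbow_mean": (0, 1),
    "iter": (1, 2, 3, 5, 7),
}


@dataclass(frozen=True)
class HyperparameterConfig:
    """One point of the word2vec hyperparameter grid."""

    corpora: str
    size: int
    alpha: float
    window: int
    min_count: int
    sample: float
    min_alpha: float
    sg: int
    hs: int
    negative: int
    cbow_mean: int
    iter: int

    def __post_init__(self) -> None:
        for name, candidates in HYPERPARAMETER_GRID.items():
            if getattr(self, name) not in candidates:
                raise ValueError(
                    f"hyperparameter {name}={getattr(self, name)!r} not in "
                    f"candidate set {candidates}"
                )


@dataclass(frozen=True)
class PairSimilarity:
    """Cosine similarity of one word pair, or the reason it is missing."""

    word1: str
    word2: str
    cosine: float | None
    missing_reason: str = "none"  # none | word1_oov | word2_oov | both_oov

    def __post_init__(self) -> None:
        if (self.cosine is None) != (self.missing_reason != "none"):
            raise ValueError("cosine must be present iff missing_reason is 'none'")


@dataclass
class SemanticSpace:
    """A vocabulary -> vector map with optional training metadata.

    Vectors are stored as a dense ``|V| x dimension`` float array; words with
    zero-norm or malformed vectors are excluded at load time and listed in
    ``excluded_words``.
    """

    space_id: str
    dimension: int
    vocabulary: list[str]
    vectors: np.ndarray
    hyperparams: HyperparameterConfig | None = None
    excluded_words: list[str] = field(default_factory=list)
    lowercase_fallback: bool = False
    _index: dict[str, int] = field(init=False, repr=False)
    _norms: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.vocabulary), self.dimension):
            raise ValueError(
                f"vectors shape {self.vectors.shape} does not match "
                f"({len(self.vocabulary)}, {self.dimension})"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain non-finite entries")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary contains duplicate words")
        self._norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(self._norms == 0):
            bad = [w for w, n in zip(self.vocabulary, self._norms) if n == 0]
            raise ValueError(f"zero-norm vectors for words: {bad[:5]}")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, word: str) -> bool:
        return self.index_of(word) is not None

    def index_of(self, word: str) -> int | None:
        i = self._index.get(word)
        if i is None and self.lowercase_fallback:
            i = self._index.get(word.lower())
        return i

    def vector(self, word: str) -> np.ndarray:
        i = self.index_of(word)
        if i is None:
            raise KeyError(word)
        return self.vectors[i]

    def coverage(self, pairs: Sequence[tuple[str, str]]) -> float:
        """Fraction of pairs with both words in vocabulary."""
        if not pairs:
            return 1.0
        ok = sum(1 for a, b in pairs if a in self and b in self)
        return ok / len(pairs)


def _open_text(path: Path) -> io.TextIOBase:
    raw = path.open("rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def load_space(
    path: str | Path,
    expect_dimension: int | None = None,
    space_id: str | None = None,
    on_duplicate: str = "error",
    lowercase_fallback: bool = False,
) -> SemanticSpace:
    """Load a word2vec-style text embedding file (plain or gzipped).

    The first line may be a ``"n_words dim"`` header; headerless files are
    accepted when all rows have a consistent width. Zero-norm vectors are
    excluded from the space and reported in ``excluded_words``. Duplicate
    words either raise (``on_duplicate="error"``) or keep the first
    occurrence (``on_duplicate="keep_first"``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if on_duplicate not in ("error", "keep_first"):
        raise ValueError("on_duplicate must be 'error' or 'keep_first'")

    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SpaceFormatError(f"{path}: empty embedding file")

    header_count: int | None = None
    first = lines[0].split()
    if len(first) == 2:
        try:
            header_count, dim = int(first[0]), int(first[1])
            body = lines[1:]
        except ValueError:
            header_count, dim, body = None, None, lines
    else:
        dim, body = None, lines

    words: list[str] = []
    rows: list[np.ndarray] = []
    excluded: list[str] = []
    seen: set[str] = set()
    for lineno, line in enumerate(body, start=2 if header_count is not None else 1):
        parts = line.split()
        if dim is None:
            dim = len(parts) - 1
            if dim < 1:
                raise SpaceFormatError(f"{path}:{lineno}: no vector entries")
        if len(parts) != dim + 1:
            raise SpaceFormatError(
                f"{path}:{lineno}: expected {dim + 1} fields, got {len(parts)}"
            )
        word = parts[0]
        try:
            vec = np.array(parts[1:], dtype=float)
        except ValueError as exc:
            raise SpaceFormatError(f"{path}:{lineno}: non-numeric entry") from exc
        if word in seen:
            if on_duplicate == "error":
                raise SpaceFormatError(f"{path}:{lineno}: duplicate word {word!r}")
            excluded.append(word)
            continue
        seen.add(word)
        if not np.all(np.isfinite(vec)) or np.linalg.norm(vec) == 0:
            excluded.append(word)
            continue
        words.append(word)
        rows.append(vec)

    if header_count is not None and header_count != len(body):
        raise SpaceFormatError(
            f"{path}: header declares {header_count} words but file has {len(body)}"
        )
    if expect_dimension is not None and dim != expect_dimension:
        raise SpaceFormatError(
            f"{path}: dimension {dim} does not match expected {expect_dimension}"
        )
    if not words:
        raise SpaceFormatError(f"{path}: no usable vectors")

    return SemanticSpace(
        space_id=space_id or path.name.removesuffix(".gz").removesuffix(".txt"),
        dimension=int(dim),
        vocabulary=words,
        vectors=np.vstack(rows),
        excluded_words=excluded,
        lowercase_fallback=lowercase_fallback,
    )


def write_space(space: SemanticSpace, path: str | Path, header: bool = True) -> None:
    """Write a space in word2vec text format (gzipped iff path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(space)} {space.dimension}\n")
        for word, row in zip(space.vocabulary, space.vectors):
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in row) + "\n")


def cosine_similarity(space: SemanticSpace, word1: str, word2: str) -> PairSimilarity:
    """Cosine of the two word vectors, clamped to [-1, 1]; OOV is flagged."""
    i, j = space.index_of(word1), space.index_of(word2)
    if i is None or j is None:
        reason = (
            "both_oov" if i is None and j is None
            else "word1_oov" if i is None
            else "word2_oov"
        )
        return PairSimilarity(word1, word2, None, reason)
    cos = float(
        np.dot(space.vectors[i], space.vectors[j]) / (space._norms[i] * space._norms[j])
    )
    return PairSimilarity(word1, word2, float(np.clip(cos, -1.0, 1.0)))


def nearest_neighbors(
    space: SemanticSpace, word: str, k: int
) -> list[tuple[str, float]]:
    """Top-k words by cosine to ``word``, excluding the word itself.

    Sorted descending by cosine; ties broken by vocabulary index so the
    ranking is reproducible.
    """
    i = space.index_of(word)
    if i is None:
        raise KeyError(f"word not in vocabulary: {word!r}")
    if not 1 <= k < len(space):
        raise ValueError(f"k must be in [1, |V|-1], got {k}")
    sims = (space.vectors @ space.vectors[i]) / (space._norms * space._norms[i])
    sims = np.clip(sims, -1.0, 1.0)
    order = np.lexsort((np.arange(len(sims)), -sims))  # cosine desc, index asc
    out = []
    for j in order:
        if j == i:
            continue
        out.append((space.vocabulary[j], float(sims[j])))
        if len(out) == k:
            break
    return out


def pair_similarities(
    space: SemanticSpace, pairs: Iterable[tuple[str, str]]
) -> list[PairSimilarity]:
    """Cosine for each pair, order preserved, OOV pairs flagged not dropped."""
    return [cosine_similarity(space, a, b) for a, b in pairs]


def sample_hyperparameters(seed: int) -> HyperparameterConfig:
    """Draw one hyperparameter configuration uniformly from the grid.

    Each field is drawn independently and uniformly from its candidate set;
    the draw is reproducible given the seed.
    """
    rng = rng_for(seed, "hyperparameters")
    values = {
        name: candidates[rng.integers(len(candidates))]
        for name, candidates in HYPERPARAMETER_GRID.items()
    }
    return HyperparameterConfig(**values)


def read_lexicon(path: str | Path):
    """Read a word-frequency table with columns word, zipf, length.

    Accepts comma- or tab-delimited files (SUBTLEX-like layout). Returns a
    pandas DataFrame indexed by word.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("word", "zipf", "length") if c not in cols]
    if missing:
        raise ValueError(f"lexicon table missing columns: {missing}")
    df = df.rename(columns={cols[c]: c for c in ("word", "zipf", "length")})
    return df.set_index("word")[["zipf", "length"]]
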