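"""Shared fixtures: tiny hand-checkable spaces and scaled-down worlds."""

import numpy as np
import pytest

from semsel.simulate import GeneratorConfig, make_world
from semsel.spaces import SemanticSpace


@pytest.fixture
def tiny_space() -> SemanticSpace:
    """Five 2-d vectors with hand-computable cosines."""
    words = ["axis", "beam", "cone", "disk", "edge"]
    vectors = np.array(
        [
            [1.0, 0.0],
            [0.0, 1.0],
            [1.0, 1.0],
            [2.0, 0.0],
            [-1.0, 0.5],
        ]
    )
    return SemanticSpace("tiny", 2, words, vectors)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Scaled-down study conditions for fast repeated simulation."""
    kw = dict(
        seed=seed,
        n_triplets=60,
        vocab_size=700,
        n_subjects=12,
        n_rating_subjects=20,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def small_world():
    return make_world(small_config(seed=42))


@pytest.fixture(scope="session")
def full_world():
    """A world at the published study scale (264 triplets)."""
    return make_world(GeneratorConfig(seed=7))
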