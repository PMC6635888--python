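"""Deterministic small test instances (seconds to build, seeded)."""

from __future__ import annotations

import numpy as np

from .gsom import GrowingMap
from .language import Corpus, CorpusConfig, build_corpus
from .model import AssociationNet, SpeechModel

__all__ = ["make_fixture", "FIXTURES"]


def _tiny_corpus(seed: int) -> Corpus:
    config = CorpusConfig(
        vowels=("i", "a"),
        consonants=("b", "n"),
        clusters=(),
        seed=seed,
        semantic_categories=3,
    )
    return build_corpus(config)


def _hand_built_model(seed: int) -> SpeechModel:
    """Two-word model with one-hot associations; round trip is 1.0 by
    construction (each word's items sit on a private P-MAP node)."""
    config = CorpusConfig(
        vowels=("a",), consonants=("b",), clusters=(), seed=seed,
        semantic_categories=2,
    )
    corpus = build_corpus(config)
    sem = corpus.semantic_matrix()
    vecs = corpus.training_matrix("auditory")
    rng = np.random.default_rng(seed)

    s_map = GrowingMap(sem.shape[1], rng=rng)
    s_map.add_node((0, 0), sem[0])
    s_map.add_node((0, 1), sem[1])
    p_map = GrowingMap(vecs.shape[1], rng=rng)
    word_of_item = corpus.word_of_item
    p_map.add_node((0, 0), vecs[word_of_item == 0].mean(0))
    p_map.add_node((0, 1), vecs[word_of_item == 1].mean(0))
    assoc = AssociationNet(2, 2)
    assoc.weights[0, 0] = 1.0
    assoc.weights[1, 1] = 1.0
    return SpeechModel(
        s_map=s_map, p_map=p_map, assoc=assoc, mode="auditory", corpus=corpus
    )


def _toy_lattice_labelings(seed: int) -> dict:
    """Full-lattice labelings with known 4-connected region counts."""
    xs, ys = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
    positions = np.stack([xs.ravel(), ys.ravel()], axis=1)
    uniform = ["A"] * 16
    halves = ["A" if x < 2 else "B" for x, _ in positions]
    checker = ["A" if (x + y) % 2 == 0 else "B" for x, y in positions]
    return {
        "positions": positions,
        "labelings": {
            "uniform": (uniform, 1),
            "halves": (halves, 2),
            "checkerboard": (checker, 16),
        },
    }


FIXTURES = {
    "tiny-corpus": _tiny_corpus,
    "hand-built-model": _hand_built_model,
    "toy-lattice-labelings": _toy_lattice_labelings,
}


def make_fixture(name: str, seed: int = 0):
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    return FIXTURES[name](seed)
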