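"""Dual-map speech model: S-MAP + P-MAP bound by a Hebbian association net.

The semantic map (S-MAP) self-organizes on word feature vectors, the
phonetic map (P-MAP) on sensory training vectors.  A bidirectional link
matrix between the two maps is trained by temporally co-occurring
winner-takes-all activations: producing a word routes S-MAP -> P-MAP
(argmax over the winner's association row), perceiving an auditory form
routes P-MAP -> S-MAP (argmax over the winner's column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gsom import GrowingMap
from .language import Corpus, StimulusItem, vectorize

__all__ = [
    "AssociationNet",
    "SpeechModel",
    "RoundTrip",
    "NoLearnedFormError",
    "UnknownFormError",
    "ModeError",
    "associate_step",
    "produce",
    "perceive",
    "round_trip_accuracy",
]


class NoLearnedFormError(RuntimeError):
    """produce() hit an all-zero association row (word has no learned form)."""


class UnknownFormError(RuntimeError):
    """perceive() hit an all-zero association column (form not yet bound)."""


class ModeError(RuntimeError):
    """Operation undefined for the model's training modality."""


class AssociationNet:
    """Bidirectional S-MAP x P-MAP link-weight matrix with values in [0, 1].

    Rows and columns are appended (at zero) whenever either map grows; the
    backing array is over-allocated to avoid per-growth reallocation.
    """

    def __init__(self, n_s: int, n_p: int):
        self._cap_s = max(16, n_s)
        self._cap_p = max(16, n_p)
        self._w = np.zeros((self._cap_s, self._cap_p))
        self.n_s = n_s
        self.n_p = n_p

    @property
    def weights(self) -> np.ndarray:
        return self._w[: self.n_s, : self.n_p]

    def resize(self, n_s: int, n_p: int) -> None:
        if n_s < self.n_s or n_p < self.n_p:
            raise ValueError("association matrix never shrinks")
        if n_s > self._cap_s or n_p > self._cap_p:
            cap_s = max(self._cap_s * 2, n_s)
            cap_p = max(self._cap_p * 2, n_p)
            new = np.zeros((cap_s, cap_p))
            new[: self.n_s, : self.n_p] = self._w[: self.n_s, : self.n_p]
            self._w = new
            self._cap_s, self._cap_p = cap_s, cap_p
        self.n_s, self.n_p = n_s, n_p

    def update(self, s_node: int, p_node: int, lr: float, decay_ratio: float = 0.5) -> None:
        """Bounded Hebbian step with competitive decay.

        The co-active pair moves toward 1 by lr*(1 - w); every other weight
        in the winning row and column decays by (1 - lr*decay_ratio).
        """
        if lr <= 0.0:
            return
        w = self._w
        factor = 1.0 - lr * decay_ratio
        keep = w[s_node, p_node]
        w[s_node, : self.n_p] *= factor
        w[: self.n_s, p_node] *= factor
        w[s_node, p_node] = keep + lr * (1.0 - keep)


@dataclass
class SpeechModel:
    """Trained (or in-training) dual-map model over a fixed corpus."""

    s_map: GrowingMap
    p_map: GrowingMap
    assoc: AssociationNet
    mode: str
    corpus: Corpus
    frames: int = 30
    combined_query: str = "masked"     # or "impute": somato block = corpus mean
    # internal caches refreshed by the trainer
    _sem: np.ndarray | None = field(default=None, repr=False)
    _vectors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self._sem is None:
            self._sem = self.corpus.semantic_matrix()
        if self._vectors is None:
            self._vectors = self.corpus.training_matrix(self.mode, self.frames)

    # -- helpers -----------------------------------------------------------

    def sync_assoc(self) -> None:
        self.assoc.resize(self.s_map.n_nodes, self.p_map.n_nodes)

    def s_bmu_of_word(self, word_id: int) -> int:
        return self.s_map.find_bmu(self._sem[word_id])

    def query_vector(self, item_or_rep) -> np.ndarray:
        """Perception query for an auditory representation under this mode."""
        if self.mode == "somatosensory":
            raise ModeError("a somatosensory-only P-MAP has no auditory block")
        rep = item_or_rep.auditory if isinstance(item_or_rep, StimulusItem) else item_or_rep
        from .language import _time_normalize  # internal reuse

        sa, ss = self.corpus.block_scales(self.mode, self.frames)
        a = _time_normalize(rep.activation, self.frames).ravel() * sa
        if self.mode == "auditory":
            return a
        _, S = self.corpus.raw_blocks(self.frames)
        mean_s = (S * ss).mean(axis=0)
        return np.concatenate([a, mean_s])

    def _perception_bmu(self, query: np.ndarray) -> int:
        if self.mode == "combined" and self.combined_query == "masked":
            n_aud = query.size - 4 * self.frames
            w = self.p_map.weights[:, :n_aud]
            d2 = ((w - query[:n_aud]) ** 2).sum(axis=1)
            return int(np.argmin(d2))
        return self.p_map.find_bmu(query)


@dataclass
class RoundTrip:
    perception: float
    production: float


# ---------------------------------------------------------------------------
# operations


def associate_step(model: SpeechModel, s_bmu: int, p_bmu: int, lr: float,
                   decay_ratio: float = 0.5) -> None:
    model.sync_assoc()
    model.assoc.update(s_bmu, p_bmu, lr, decay_ratio)


def produce(model: SpeechModel, word_id: int) -> tuple[int, StimulusItem]:
    """Word concept -> S-MAP winner -> associated P-MAP node -> the stored
    exemplar nearest to that node's weights."""
    model.sync_assoc()
    s_bmu = model.s_bmu_of_word(word_id)
    row = model.assoc.weights[s_bmu]
    if not np.any(row > 0):
        raise NoLearnedFormError(f"word {word_id} has no learned form")
    p_node = int(np.argmax(row))
    vecs = model._vectors
    d2 = ((vecs - model.p_map.weights[p_node]) ** 2).sum(axis=1)
    exemplar = model.corpus.items[int(np.argmin(d2))]
    return p_node, exemplar


def perceive(model: SpeechModel, auditory_rep) -> int:
    """Auditory form -> P-MAP winner -> associated S-MAP node -> its word."""
    model.sync_assoc()
    query = model.query_vector(auditory_rep)
    p_bmu = model._perception_bmu(query)
    col = model.assoc.weights[:, p_bmu]
    if not np.any(col > 0):
        raise UnknownFormError("form maps to a node with no learned association")
    s_node = int(np.argmax(col))
    # the word whose semantic winner is that node, nearest semantic match on ties
    sem = model._sem
    d2 = ((sem - model.s_map.weights[s_node]) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def round_trip_accuracy(model: SpeechModel, corpus: Corpus | None = None) -> RoundTrip:
    """Perception accuracy over items and production success over words.

    Perception: fraction of items whose auditory form is perceived as their
    word (somatosensory-only models are scored on their mode-consistent
    training vectors, since no auditory block exists).  Production: fraction
    of words whose produced P-MAP node hosts only that word's items.
    """
    corpus = corpus or model.corpus
    model.sync_assoc()
    word_of_item = corpus.word_of_item
    sem = model._sem
    vecs = model._vectors

    # perception, vectorized
    if model.mode == "somatosensory":
        queries = vecs
    elif model.mode == "combined" and model.combined_query == "impute":
        queries = corpus.query_matrix(model.mode, model.frames)
    else:
        queries = corpus.training_matrix("auditory", model.frames) \
            if model.mode == "auditory" else None
        if queries is None:  # combined + masked
            queries = vecs[:, : 24 * model.frames]
    n_aud = queries.shape[1]
    W = model.p_map.weights[:, :n_aud] if n_aud < model.p_map.input_dim \
        else model.p_map.weights
    d2 = ((queries[:, None, :] - W[None, :, :]) ** 2).sum(axis=2) \
        if len(corpus) * W.shape[0] * n_aud < 2_000_000 else None
    if d2 is None:
        sq = np.einsum("ij,ij->i", W, W)
        d2 = sq[None, :] - 2.0 * queries @ W.T
    p_bmus = np.argmin(d2, axis=1)

    A = model.assoc.weights
    s_winner_of_word = np.array(
        [model.s_map.find_bmu(sem[w]) for w in range(len(corpus.lexicon))]
    )
    ok = 0
    for i, p in enumerate(p_bmus):
        col = A[:, p]
        if np.any(col > 0) and int(np.argmax(col)) == s_winner_of_word[word_of_item[i]]:
            ok += 1
    perception = ok / len(corpus)

    # production
    assignment = model.p_map.assign(vecs)
    ok_w = 0
    n_words = len(corpus.lexicon)
    for w in range(n_words):
        row = A[s_winner_of_word[w]]
        if not np.any(row > 0):
            continue
        p_node = int(np.argmax(row))
        hosted = assignment.items_of_node.get(p_node, [])
        if hosted and all(word_of_item[i] == w for i in hosted):
            ok_w += 1
    production = ok_w / n_words
    return RoundTrip(perception=perception, production=production)
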