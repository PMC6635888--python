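"""Map-quality measurements: node classification, feature regions, statistics.

Terminology (all at the phonetic-map level):
  * unclear node        — hosts items of >= 2 different words (confusable),
  * clear non-separated — hosts >= 2 items, all of the same word,
  * occupied node       — hosts >= 1 item,
  * feature region      — maximal 4-connected lattice component whose nodes
                          share one value of a phonetic feature; fewer
                          regions means better feature ordering.
Unoccupied lattice nodes inherit the label of the nearest occupied node in
lattice (graph) distance so region boundaries partition the whole map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.stats import rankdata

from .gsom import GrowingMap, ItemAssignment
from .language import Corpus, Word

__all__ = [
    "MetricsRecord",
    "FeatureLabeling",
    "FEATURE_EXTRACTORS",
    "classify_nodes",
    "label_lattice",
    "count_feature_regions",
    "word_clustering_score",
    "wilcoxon_rank_sum",
    "compare_modes",
    "word_feature_label",
]


@dataclass
class MetricsRecord:
    cycle: int
    n_unclear: int
    n_clear_nonseparated: int
    n_occupied: int
    feature_regions: dict[str, int] = field(default_factory=dict)
    round_trip_perception: float = float("nan")
    round_trip_production: float = float("nan")
    n_nodes: int = 0
    gsom_check_events: int = 0
    interconnection_events: int = 0


@dataclass
class FeatureLabeling:
    """Per-lattice-node feature label (full map, occupied and completed)."""

    positions: np.ndarray              # (n_nodes, 2)
    labels: list[str]                  # one label per node
    feature: str


# ---------------------------------------------------------------------------
# feature extraction per word


def _consonant_feature(word: Word, attr: str) -> str:
    onset = word.onset
    if not onset:
        return "none"              # V-syllables carry no consonant feature
    if attr == "manner" and len(onset) > 1:
        return "plosive-lateral"   # the CC clusters are plosive+lateral
    return getattr(onset[0], attr)


FEATURE_EXTRACTORS = {
    "place": lambda w: _consonant_feature(w, "place"),
    "manner": lambda w: _consonant_feature(w, "manner"),
    "voiced": lambda w: ("none" if not w.onset else str(w.onset[0].voiced)),
    "vowel_height": lambda w: w.vowel.vowel_height,
    "vowel_backness": lambda w: w.vowel.vowel_backness,
    "structure": lambda w: w.syllable_structure,
}


def word_feature_label(word: Word, feature: str) -> str:
    return FEATURE_EXTRACTORS[feature](word)


# ---------------------------------------------------------------------------
# node classification


def classify_nodes(
    assignment: ItemAssignment, word_of_item: np.ndarray
) -> tuple[int, int, int]:
    """(n_unclear, n_clear_nonseparated, n_occupied) per the node taxonomy."""
    n_unclear = n_nonsep = n_occ = 0
    for _, items in assignment.items_of_node.items():
        if not items:
            continue
        n_occ += 1
        words = {int(word_of_item[i]) for i in items}
        if len(words) > 1:
            n_unclear += 1
        elif len(items) > 1:
            n_nonsep += 1
    return n_unclear, n_nonsep, n_occ


# ---------------------------------------------------------------------------
# lattice labeling and region counting


def _lattice_graph(positions: np.ndarray) -> sparse.csr_matrix:
    idx = {tuple(p): i for i, p in enumerate(map(tuple, positions.tolist()))}
    rows, cols = [], []
    for (x, y), i in idx.items():
        for dx, dy in ((1, 0), (0, 1)):
            j = idx.get((x + dx, y + dy))
            if j is not None:
                rows += [i, j]
                cols += [j, i]
    n = len(positions)
    data = np.ones(len(rows))
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def label_lattice(
    gmap: GrowingMap, assignment: ItemAssignment, feature: str,
    lexicon: list[Word] | None = None, word_of_item: np.ndarray | None = None,
    corpus: Corpus | None = None,
) -> FeatureLabeling:
    """Label every lattice node with a feature value.

    Occupied nodes take the majority label of their items (ties to the label
    of the lowest item id); unoccupied nodes take the label of the nearest
    occupied node in lattice distance (ties to the lowest node id).
    """
    if corpus is not None:
        lexicon = corpus.lexicon
        word_of_item = corpus.word_of_item
    if lexicon is None or word_of_item is None:
        raise ValueError("need corpus or (lexicon, word_of_item)")
    if not assignment.items_of_node:
        raise ValueError("empty assignment")
    extractor = FEATURE_EXTRACTORS[feature]
    word_labels = [extractor(w) for w in lexicon]

    n = gmap.n_nodes
    node_label: list[str | None] = [None] * n
    occupied = sorted(assignment.items_of_node)
    for node in occupied:
        items = assignment.items_of_node[node]
        counts: dict[str, int] = {}
        first_item: dict[str, int] = {}
        for i in items:
            lab = word_labels[int(word_of_item[i])]
            counts[lab] = counts.get(lab, 0) + 1
            first_item.setdefault(lab, i)
        best = min(counts, key=lambda lab: (-counts[lab], first_item[lab]))
        node_label[node] = best

    unoccupied = [i for i in range(n) if node_label[i] is None]
    if unoccupied:
        graph = _lattice_graph(gmap.positions)
        dist = dijkstra(graph, directed=False, unweighted=True, indices=occupied)
        owner = np.asarray(occupied)[np.argmin(dist, axis=0)]
        for i in unoccupied:
            node_label[i] = node_label[int(owner[i])]
    return FeatureLabeling(
        positions=gmap.positions.copy(), labels=list(node_label), feature=feature
    )


def count_feature_regions(labeling: FeatureLabeling) -> int:
    """Number of 4-connected uniform-label components over the lattice."""
    pos = labeling.positions
    if len(pos) == 0:
        return 0
    mn = pos.min(axis=0)
    span = pos.max(axis=0) - mn + 1
    grid = np.full(tuple(span), -1, dtype=int)
    values = sorted(set(labeling.labels))
    code = {v: k for k, v in enumerate(values)}
    for (x, y), lab in zip(pos - mn, labeling.labels):
        grid[x, y] = code[lab]
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    total = 0
    for k in range(len(values)):
        _, n = ndimage.label(grid == k, structure=structure)
        total += n
    return total


# ---------------------------------------------------------------------------
# clustering diagnostics


def word_clustering_score(
    gmap: GrowingMap, assignment: ItemAssignment, word_of_item: np.ndarray
) -> tuple[float, float]:
    """(intra, inter): mean lattice distance between BMUs of same-word vs
    different-word item pairs (Euclidean distance on lattice coordinates)."""
    pos = gmap.positions[assignment.bmu_of_item]
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff.astype(float) ** 2).sum(axis=2))
    same = word_of_item[:, None] == word_of_item[None, :]
    iu = np.triu_indices(len(word_of_item), k=1)
    same_u = same[iu]
    d_u = d[iu]
    intra = float(d_u[same_u].mean()) if same_u.any() else 0.0
    inter = float(d_u[~same_u].mean()) if (~same_u).any() else 0.0
    return intra, inter


# ---------------------------------------------------------------------------
# statistics


def wilcoxon_rank_sum(sample_a, sample_b) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact by full enumeration of rank assignments (handles ties via
    midranks) when the combined sample size is <= 20; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0

    if n <= 20:
        idx = np.array(list(itertools.combinations(range(n), n1)))
        sums = ranks[idx].sum(axis=1)
        dev = np.abs(sums - mu)
        p = float(np.mean(dev >= abs(w_obs - mu) - 1e-9))
        return p

    # normal approximation with tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    from scipy.stats import norm

    return float(2.0 * norm.sf(max(z, 0.0)))


@dataclass
class ModeComparison:
    metric: str
    cycle: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float


def _metric_at_cycle(run_results, metric: str, cycle: int) -> np.ndarray:
    vals = []
    for rr in run_results:
        rec = rr.metrics[cycle]
        if metric.startswith("regions:"):
            vals.append(rec.feature_regions[metric.split(":", 1)[1]])
        else:
            vals.append(getattr(rec, metric))
    return np.asarray(vals, dtype=float)


def compare_modes(results_a, results_b, metric: str, cycle: int) -> ModeComparison:
    """Per-cycle mean +/- sd per mode with a two-sided rank-sum p across runs.

    `metric` is a MetricsRecord field name or "regions:<feature>".
    """
    if len(results_a) != len(results_b):
        raise ValueError("run collections must have equal size")
    va = _metric_at_cycle(results_a, metric, cycle)
    vb = _metric_at_cycle(results_b, metric, cycle)
    return ModeComparison(
        metric=metric,
        cycle=cycle,
        mean_a=float(va.mean()),
        sd_a=float(va.std(ddof=1)) if va.size > 1 else 0.0,
        mean_b=float(vb.mean()),
        sd_b=float(vb.std(ddof=1)) if vb.size > 1 else 0.0,
        p_value=wilcoxon_rank_sum(va, vb),
    )
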