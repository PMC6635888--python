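"""Evaluation metrics: node taxonomy, feature regions, rank-sum statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from speechmaps.fixtures import make_fixture
from speechmaps.gsom import GrowingMap, ItemAssignment, init_map
from speechmaps.metrics import (
    FeatureLabeling,
    classify_nodes,
    compare_modes,
    count_feature_regions,
    label_lattice,
    wilcoxon_rank_sum,
    word_clustering_score,
)


def assignment_from(bmus):
    return ItemAssignment.from_bmus(np.asarray(bmus))


class TestClassifyNodes:
    def test_all_private_nodes(self):
        bmus = np.arange(210)
        words = np.repeat(np.arange(70), 3)
        assert classify_nodes(assignment_from(bmus), words) == (0, 0, 210)

    def test_one_unclear_node(self):
        # items 0 (word 0) and 3 (word 1) share node 0; everyone else private
        bmus = np.array([0, 1, 2, 0, 4, 5])
        words = np.array([0, 0, 0, 1, 1, 1])
        n_unclear, n_nonsep, n_occ = classify_nodes(assignment_from(bmus), words)
        assert (n_unclear, n_occ) == (1, 5)

    def test_nonseparated_counts_same_word_sharing(self):
        bmus = np.array([0, 0, 0, 1, 2, 3])
        words = np.array([0, 0, 0, 1, 1, 1])
        assert classify_nodes(assignment_from(bmus), words) == (0, 1, 4)

    def test_against_tally_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_items, n_nodes = 60, 25
            bmus = rng.integers(0, n_nodes, n_items)
            words = rng.integers(0, 12, n_items)
            got = classify_nodes(assignment_from(bmus), words)
            unclear = nonsep = occ = 0
            for node in range(n_nodes):
                hosted = [i for i in range(n_items) if bmus[i] == node]
                if not hosted:
                    continue
                occ += 1
                ws = {words[i] for i in hosted}
                if len(ws) > 1:
                    unclear += 1
                elif len(hosted) > 1:
                    nonsep += 1
            assert got == (unclear, nonsep, occ)
            assert got[0] + got[1] <= got[2] <= n_items


def toy_map(n_side=4, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    m = GrowingMap(dim, rng=rng)
    for x in range(n_side):
        for y in range(n_side):
            m.add_node((x, y), rng.standard_normal(dim))
    return m


class TestLabelLattice:
    def test_single_occupied_node_floods_map(self, tiny_corpus):
        m = toy_map()
        bmus = np.zeros(len(tiny_corpus), dtype=int)  # everything on node 0
        lab = label_lattice(m, assignment_from(bmus), "structure", corpus=tiny_corpus)
        assert len(set(lab.labels)) == 1

    def test_two_corner_labels_partition_by_distance(self, tiny_corpus):
        m = toy_map(n_side=4)
        w = tiny_corpus.word_of_item
        v_item = int(np.nonzero([tiny_corpus.lexicon[i].syllable_structure == "V"
                                 for i in w])[0][0])
        cv_item = int(np.nonzero([tiny_corpus.lexicon[i].syllable_structure == "CV"
                                  for i in w])[0][0])
        corner_a = m.node_at((0, 0))
        corner_b = m.node_at((3, 3))
        bmus = np.full(len(tiny_corpus), corner_a)
        bmus[v_item] = corner_a
        bmus[cv_item] = corner_b
        # keep only the two chosen items informative: all others on corner_a
        lab = label_lattice(m, assignment_from(bmus), "structure", corpus=tiny_corpus)
        # node (3,3) carries the CV label, (0,0) the majority label
        assert lab.labels[corner_b] == "CV"
        assert lab.labels[m.node_at((3, 2))] == "CV"

    def test_empty_assignment_rejected(self, tiny_corpus):
        m = toy_map()
        with pytest.raises(ValueError):
            label_lattice(
                m, ItemAssignment(np.array([]), {}), "place", corpus=tiny_corpus
            )

    def test_matches_nearest_occupied_oracle(self, tiny_corpus):
        rng = np.random.default_rng(8)
        m = toy_map(n_side=5, seed=8)
        n = len(tiny_corpus)
        bmus = rng.integers(0, m.n_nodes, n)
        lab = label_lattice(m, assignment_from(bmus), "structure", corpus=tiny_corpus)
        # oracle: BFS distances on the lattice, majority labels recomputed
        from collections import Counter

        words = tiny_corpus.word_of_item
        occupied = sorted(set(int(b) for b in bmus))

        def graph_dist(a, b):
            # BFS over lattice adjacency
            frontier, seen, d = [a], {a}, 0
            while frontier:
                if b in frontier:
                    return d
                nxt = []
                for i in frontier:
                    for j in m.lattice_neighbors(i):
                        if j not in seen:
                            seen.add(j)
                            nxt.append(j)
                frontier = nxt
                d += 1
            return np.inf

        extractor = lambda wid: tiny_corpus.lexicon[wid].syllable_structure
        occ_label = {}
        for node in occupied:
            items = [i for i in range(n) if bmus[i] == node]
            counts = Counter(extractor(int(words[i])) for i in items)
            top = max(counts.values())
            cands = [lab_ for lab_, c in counts.items() if c == top]
            first = {extractor(int(words[i])): i for i in reversed(items)}
            occ_label[node] = min(cands, key=lambda L: first[L])
        for node in range(m.n_nodes):
            if node in occ_label:
                assert lab.labels[node] == occ_label[node]
            else:
                dists = [(graph_dist(node, o), o) for o in occupied]
                best = min(dists)
                assert lab.labels[node] == occ_label[best[1]]


class TestRegionCounting:
    def test_known_toy_labelings(self):
        fx = make_fixture("toy-lattice-labelings")
        pos = fx["positions"]
        for name, (labels, expected) in fx["labelings"].items():
            lab = FeatureLabeling(positions=pos, labels=labels, feature="toy")
            assert count_feature_regions(lab) == expected, name

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(3)
        xs, ys = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        pos = np.stack([xs.ravel(), ys.ravel()], axis=1)
        for _ in range(15):
            labels = [str(v) for v in rng.integers(0, 3, 64)]
            lab = FeatureLabeling(positions=pos, labels=labels, feature="toy")
            got = count_feature_regions(lab)
            # oracle: BFS flood fill with 4-connectivity
            lab_of = {tuple(p): L for p, L in zip(map(tuple, pos), labels)}
            seen, regions = set(), 0
            for p in map(tuple, pos):
                if p in seen:
                    continue
                regions += 1
                frontier = [p]
                seen.add(p)
                while frontier:
                    x, y = frontier.pop()
                    for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                        if q in lab_of and q not in seen and lab_of[q] == lab_of[p]:
                            seen.add(q)
                            frontier.append(q)
            assert got == regions

    def test_invariant_under_renaming_and_rotation(self):
        rng = np.random.default_rng(4)
        xs, ys = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        pos = np.stack([xs.ravel(), ys.ravel()], axis=1)
        labels = [str(v) for v in rng.integers(0, 3, 36)]
        base = count_feature_regions(FeatureLabeling(pos, labels, "toy"))
        renamed = [{"0": "x", "1": "y", "2": "z"}[L] for L in labels]
        assert count_feature_regions(FeatureLabeling(pos, renamed, "toy")) == base
        rotated = np.stack([pos[:, 1], -pos[:, 0]], axis=1)
        assert count_feature_regions(FeatureLabeling(rotated, labels, "toy")) == base

    def test_at_least_one_region_per_label(self):
        rng = np.random.default_rng(6)
        xs, ys = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        pos = np.stack([xs.ravel(), ys.ravel()], axis=1)
        labels = [str(v) for v in rng.integers(0, 4, 25)]
        count = count_feature_regions(FeatureLabeling(pos, labels, "toy"))
        assert count >= len(set(labels))


class TestClustering:
    def test_intra_zero_when_words_collapse(self, tiny_corpus):
        m = toy_map(n_side=3)
        w = tiny_corpus.word_of_item
        bmus = w.copy()  # word k -> node k
        intra, inter = word_clustering_score(m, assignment_from(bmus), w)
        assert intra == 0.0
        assert inter > 0.0

    def test_detects_scattered_words(self, tiny_corpus):
        """Counterexample: every word's realizations land on distant corners
        while different words co-locate, so intra exceeds inter."""
        m = toy_map(n_side=4)
        w = tiny_corpus.word_of_item
        corners = [m.node_at(p) for p in ((0, 0), (3, 3), (0, 3))]
        bmus = np.empty(len(w), dtype=int)
        for word in np.unique(w):
            idx = np.nonzero(w == word)[0]
            for k, i in enumerate(idx):
                bmus[i] = corners[k % 3]
        intra, inter = word_clustering_score(m, assignment_from(bmus), w)
        assert intra > inter


class TestWilcoxon:
    def test_fully_separated_triplets(self):
        # all three ranks at the extremes: p = 2 / C(6,3) = 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_samples_give_one(self):
        assert wilcoxon_rank_sum([3, 3, 4], [3, 3, 4]) == pytest.approx(1.0)

    def test_matches_exact_reference_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(loc=0.5, size=10)
            ours = wilcoxon_rank_sum(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_tied_data_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        b = np.array([2.0, 3.0, 3.0, 4.0, 4.0])
        ours = wilcoxon_rank_sum(a, b)
        # oracle: direct enumeration over index subsets with midranks
        ranks = rankdata(np.concatenate([a, b]))
        mu = len(a) * (len(a) + len(b) + 1) / 2
        obs = abs(ranks[: len(a)].sum() - mu)
        count = total = 0
        for comb in itertools.combinations(range(10), 5):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9:
                count += 1
        assert ours == pytest.approx(count / total)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=30)
        b = rng.normal(loc=1.2, size=30)
        p = wilcoxon_rank_sum(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic").pvalue
        assert p < 0.01
        assert p == pytest.approx(ref, rel=0.15)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class _FakeRun:
    def __init__(self, values, feature="place"):
        from speechmaps.metrics import MetricsRecord

        self.metrics = [
            MetricsRecord(
                cycle=c, n_unclear=0, n_clear_nonseparated=0, n_occupied=0,
                feature_regions={feature: v},
            )
            for c, v in enumerate(values)
        ]


class TestCompareModes:
    def test_identical_collections(self):
        runs = [_FakeRun([5, 5, 5]) for _ in range(6)]
        cmp = compare_modes(runs, list(runs), "regions:place", cycle=2)
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.mean_a == cmp.mean_b == 5.0

    def test_constant_shift_hits_enumeration_floor(self):
        import math

        a = [_FakeRun([float(10 + i * 0.01)]) for i in range(10)]
        b = [_FakeRun([float(20 + i * 0.01)]) for i in range(10)]
        cmp = compare_modes(a, b, "regions:place", cycle=0)
        floor = 2.0 / math.comb(20, 10)
        assert cmp.p_value == pytest.approx(floor)

    def test_unequal_run_counts_rejected(self):
        a = [_FakeRun([1.0])] * 3
        b = [_FakeRun([1.0])] * 4
        with pytest.raises(ValueError):
            compare_modes(a, b, "regions:place", cycle=0)
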