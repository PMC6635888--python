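"""Training regimen: initialization cycle, babbling, imitation with checks.

One run = cycle 0 (map establishment at high learning rate plus an initial
association pass) followed by `cycles` full training cycles.  Within a cycle
every stimulus item is presented `presentations_per_item` times in seeded
shuffled order; each presentation adapts the S-MAP on the word's semantic
vector, the P-MAP on the item's training vector, updates the association
between the two winners, and runs the per-step GSOM check (conflicting items
on a shared node get extra presentations).  From the first imitation cycle
(cycle babbling_cycles + 1) onward an interconnection check at cycle end
verifies every word's produce/perceive round trip and re-trains failures at
an elevated association learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gsom import growth_threshold, init_map
from .language import Corpus
from .metrics import (
    MetricsRecord,
    classify_nodes,
    count_feature_regions,
    label_lattice,
)
from .model import AssociationNet, SpeechModel, round_trip_accuracy

__all__ = ["TrainingConfig", "RunResult", "Trainer", "run_training", "run_experiment"]

MODE_ALIASES = {"a": "auditory", "s": "somatosensory", "a+s": "combined"}


@dataclass
class TrainingConfig:
    mode: str = "combined"
    cycles: int = 50
    babbling_cycles: int = 10
    presentations_per_item: int = 7
    runs: int = 10
    seed: int = 0
    frames: int = 30
    # GSOM hyperparameters
    spread_factor: float = 0.05
    lr_start: float = 0.35
    lr_end: float = 0.05
    radius_start: float = 3.0
    radius_end: float = 1.0
    cycle0_lr: float = 0.6
    error_decay: float = 0.8           # per-cycle forgetting of accumulated error
    s_radius: float = 1.0              # S-MAP neighborhood (discrete word clusters)
    # per-cycle growth budget: at most max(min, fraction * current size) new
    # nodes per map per cycle, giving exponential-then-saturating map growth
    growth_budget_fraction: float = 1.0
    growth_budget_min: int = 8
    cycle0_growth_budget: int = 128    # establishment cycle sizes the initial map
    # association hyperparameters
    assoc_lr: float = 0.2
    assoc_decay_ratio: float = 0.5
    interconnection_lr: float = 0.5
    # checking-process budgets
    gsom_check_extras: int = 2
    extras_cap_fraction: float = 0.2
    # evaluation
    region_features: tuple[str, ...] = ("place", "manner")
    combined_query: str = "masked"

    def __post_init__(self):
        self.mode = MODE_ALIASES.get(self.mode, self.mode)
        if 0 < self.cycles <= self.babbling_cycles:
            raise ValueError("babbling_cycles must be < cycles")
        if self.presentations_per_item < 1:
            raise ValueError("presentations_per_item must be >= 1")


@dataclass
class RunResult:
    model: SpeechModel
    metrics: list[MetricsRecord]
    seed: int
    mode: str
    cycle_log: list[dict] = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.metrics:
            base = {
                "cycle": rec.cycle,
                "n_unclear": rec.n_unclear,
                "n_clear_nonseparated": rec.n_clear_nonseparated,
                "n_occupied": rec.n_occupied,
                "n_nodes": rec.n_nodes,
                "round_trip_perception": rec.round_trip_perception,
                "round_trip_production": rec.round_trip_production,
                "gsom_check_events": rec.gsom_check_events,
                "interconnection_events": rec.interconnection_events,
            }
            for feat, cnt in rec.feature_regions.items():
                base[f"regions_{feat}"] = cnt
            rows.append(base)
        df = pd.DataFrame(rows)
        df.insert(0, "mode", self.mode)
        df.insert(0, "seed", self.seed)
        return df


class Trainer:
    """Stateful single-run trainer; `run()` yields a RunResult."""

    def __init__(self, config: TrainingConfig, corpus: Corpus, seed: int | None = None):
        self.config = config
        self.corpus = corpus
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x7124]))

        self.vectors = corpus.training_matrix(config.mode, config.frames)
        self.sem = corpus.semantic_matrix()
        self.word_of_item = corpus.word_of_item
        self.n_items = len(corpus)
        self.n_words = len(corpus.lexicon)

        self.p_map = init_map(self.vectors.shape[1], self.rng, mean=self.vectors.mean(0))
        self.s_map = init_map(self.sem.shape[1], self.rng, mean=self.sem.mean(0))
        self.assoc = AssociationNet(self.s_map.n_nodes, self.p_map.n_nodes)
        self.model = SpeechModel(
            s_map=self.s_map,
            p_map=self.p_map,
            assoc=self.assoc,
            mode=config.mode,
            corpus=corpus,
            frames=config.frames,
            combined_query=config.combined_query,
            _sem=self.sem,
            _vectors=self.vectors,
        )
        self.gt_p = growth_threshold(self.vectors.shape[1], config.spread_factor)
        self.gt_s = growth_threshold(self.sem.shape[1], config.spread_factor)
        self.last_bmu = np.full(self.n_items, -1, dtype=np.int64)
        self.cycle_log: list[dict] = []
        self.metrics: list[MetricsRecord] = []
        self._budget = {"s": 0, "p": 0}

    def _reset_growth_budget(self, cycle: int = 1) -> None:
        cfg = self.config
        if cycle == 0:
            self._budget["s"] = self._budget["p"] = cfg.cycle0_growth_budget
            return
        self._budget["s"] = max(
            cfg.growth_budget_min,
            int(cfg.growth_budget_fraction * self.s_map.n_nodes),
        )
        self._budget["p"] = max(
            cfg.growth_budget_min,
            int(cfg.growth_budget_fraction * self.p_map.n_nodes),
        )

    # -- schedules ---------------------------------------------------------

    def _schedule(self, cycle: int) -> tuple[float, float]:
        cfg = self.config
        if cycle <= 0:
            return cfg.cycle0_lr, cfg.radius_start
        frac = (cycle - 1) / max(cfg.cycles - 1, 1)
        lr = cfg.lr_start + (cfg.lr_end - cfg.lr_start) * frac
        radius = round(cfg.radius_start + (cfg.radius_end - cfg.radius_start) * frac)
        return lr, float(radius)

    # -- single presentation ----------------------------------------------

    def present(self, item: int, lr: float, radius: float, assoc_lr: float,
                grow: bool = True) -> tuple[int, int]:
        word = int(self.word_of_item[item])
        sv = self.sem[word]
        s_b, _ = self.s_map._bmu_fast(sv)
        self.s_map.adapt(sv, s_b, lr, self.config.s_radius)
        xv = self.vectors[item]
        p_b, _ = self.p_map._bmu_fast(xv)
        self.p_map.adapt(xv, p_b, lr, radius)
        if grow:
            if self._budget["s"] > 0:
                new = self.s_map.maybe_grow(
                    self.gt_s, node_ids=[s_b], max_new_nodes=self._budget["s"]
                )
                self._budget["s"] -= len(new)
            if self._budget["p"] > 0:
                new = self.p_map.maybe_grow(
                    self.gt_p, node_ids=[p_b], max_new_nodes=self._budget["p"]
                )
                self._budget["p"] -= len(new)
        self.assoc.resize(self.s_map.n_nodes, self.p_map.n_nodes)
        self.assoc.update(s_b, p_b, assoc_lr, self.config.assoc_decay_ratio)
        self.last_bmu[item] = p_b
        return s_b, p_b

    # -- checking processes -------------------------------------------------

    def gsom_check(self, item: int, p_bmu: int) -> list[int]:
        """Per-step check: if the item's node hosts items of other words,
        return those conflicting items for extra presentations."""
        hosted = np.nonzero(self.last_bmu == p_bmu)[0]
        word = self.word_of_item[item]
        return [int(i) for i in hosted if self.word_of_item[i] != word]

    def _word_s_winners(self) -> np.ndarray:
        return np.array([self.s_map._bmu_fast(self.sem[w])[0] for w in range(self.n_words)])

    def interconnection_check(self) -> tuple[int, int]:
        """Cycle-end check: verify every word's produce/perceive round trip;
        re-train failures.  Returns (n_failed_words, extra_steps)."""
        cfg = self.config
        A = self.assoc.weights
        s_win = self._word_s_winners()
        assignment = self.p_map.assign(self.vectors)
        bmus = assignment.bmu_of_item
        extra_steps = 0
        failed = 0
        lr, radius = self._schedule(self.current_cycle)
        for w in range(self.n_words):
            items = np.nonzero(self.word_of_item == w)[0]
            ok = True
            row = A[s_win[w]]
            p_node = int(np.argmax(row)) if np.any(row > 0) else -1
            if p_node < 0:
                ok = False
            else:
                hosted = assignment.items_of_node.get(p_node, [])
                if not hosted or any(self.word_of_item[i] != w for i in hosted):
                    ok = False
            conflicts: set[int] = set()
            if ok:
                for i in items:
                    col = A[:, bmus[i]]
                    if not np.any(col > 0) or int(np.argmax(col)) != s_win[w]:
                        ok = False
                    hosted = assignment.items_of_node.get(int(bmus[i]), [])
                    others = [j for j in hosted if self.word_of_item[j] != w]
                    conflicts.update(others)
            if ok:
                continue
            failed += 1
            for i in items:
                self.present(int(i), lr, radius, cfg.interconnection_lr)
                extra_steps += 1
            for j in sorted(conflicts):
                self.present(int(j), lr, radius, cfg.assoc_lr)
                extra_steps += 1
        return failed, extra_steps

    # -- cycles -------------------------------------------------------------

    current_cycle: int = 0

    def run_cycle(self, cycle_index: int) -> None:
        cfg = self.config
        self.current_cycle = cycle_index
        self._reset_growth_budget(cycle_index)
        lr, radius = self._schedule(cycle_index)
        reps = 1 if cycle_index == 0 else cfg.presentations_per_item
        order = self.rng.permutation(np.repeat(np.arange(self.n_items), reps))
        base_steps = len(order)
        extras_cap = int(cfg.extras_cap_fraction * base_steps)
        extras_queue: list[int] = []
        check_events = 0

        for item in order:
            _, p_b = self.present(int(item), lr, radius, cfg.assoc_lr)
            conflicts = self.gsom_check(int(item), p_b)
            if conflicts:
                check_events += 1
                room = extras_cap - len(extras_queue)
                if room > 0:
                    sched = (conflicts * cfg.gsom_check_extras)[:room]
                    extras_queue.extend(sched)

        for item in extras_queue:
            self.present(int(item), lr, radius, cfg.assoc_lr)

        interconn_events = 0
        interconn_steps = 0
        if cycle_index > cfg.babbling_cycles:
            interconn_events, interconn_steps = self.interconnection_check()

        self.s_map.decay_errors(cfg.error_decay)
        self.p_map.decay_errors(cfg.error_decay)

        self.cycle_log.append(
            {
                "cycle": cycle_index,
                "base_steps": base_steps,
                "gsom_check_events": check_events,
                "extra_steps": len(extras_queue),
                "interconnection_events": interconn_events,
                "interconnection_steps": interconn_steps,
            }
        )
        self.metrics.append(self._measure(cycle_index, check_events, interconn_events))

    def _measure(self, cycle: int, check_events: int, interconn_events: int) -> MetricsRecord:
        assignment = self.p_map.assign(self.vectors)
        n_unclear, n_nonsep, n_occ = classify_nodes(assignment, self.word_of_item)
        regions = {}
        for feat in self.config.region_features:
            lab = label_lattice(
                self.p_map, assignment, feat,
                lexicon=self.corpus.lexicon, word_of_item=self.word_of_item,
            )
            regions[feat] = count_feature_regions(lab)
        rt = round_trip_accuracy(self.model)
        return MetricsRecord(
            cycle=cycle,
            n_unclear=n_unclear,
            n_clear_nonseparated=n_nonsep,
            n_occupied=n_occ,
            feature_regions=regions,
            round_trip_perception=rt.perception,
            round_trip_production=rt.production,
            n_nodes=self.p_map.n_nodes,
            gsom_check_events=check_events,
            interconnection_events=interconn_events,
        )

    def run(self) -> RunResult:
        for c in range(self.config.cycles + 1):
            self.run_cycle(c)
        return RunResult(
            model=self.model,
            metrics=self.metrics,
            seed=self.seed,
            mode=self.config.mode,
            cycle_log=self.cycle_log,
        )


def run_training(config: TrainingConfig, corpus: Corpus, seed: int | None = None) -> RunResult:
    """Train one model instance: cycle 0 plus `config.cycles` full cycles."""
    return Trainer(config, corpus, seed=seed).run()


def run_experiment(
    config: TrainingConfig,
    corpus: Corpus,
    modes: tuple[str, ...] = ("auditory", "somatosensory", "combined"),
) -> dict[str, list[RunResult]]:
    """Multi-run, multi-mode experiment over the SAME corpus.

    Every mode uses the identical seed list, so per-run differences between
    modes are attributable to the input modality alone.
    """
    seeds = [
        int(s) for s in
        np.random.SeedSequence(config.seed).generate_state(config.runs) % (2 ** 31)
    ]
    out: dict[str, list[RunResult]] = {}
    for mode in modes:
        mode = MODE_ALIASES.get(mode, mode)
        cfg = replace(config, mode=mode)
        out[mode] = [run_training(cfg, corpus, seed=s) for s in seeds]
    return out


def experiment_frame(results: dict[str, list[RunResult]]) -> pd.DataFrame:
    """Tidy per-cycle metrics across all runs and modes."""
    frames = []
    for mode, runs in results.items():
        for i, rr in enumerate(runs):
            df = rr.metrics_frame()
            df.insert(0, "run", i)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
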