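"""Archives, tabular exports and configuration handling."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gsom import GrowingMap
from .language import Corpus, CorpusConfig
from .model import AssociationNet, SpeechModel
from .training import TrainingConfig

__all__ = [
    "config_hash",
    "save_config",
    "load_config",
    "lexicon_table",
    "save_corpus",
    "save_model",
    "load_model",
    "map_table",
    "write_metrics_csv",
]


def _config_dict(config) -> dict:
    d = dataclasses.asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def config_hash(*configs) -> str:
    """Stable short hash of resolved configuration(s)."""
    payload = json.dumps([_config_dict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(path, *configs) -> None:
    blobs = {type(c).__name__: _config_dict(c) for c in configs}
    blobs["config_hash"] = config_hash(*configs)
    Path(path).write_text(yaml.safe_dump(blobs, sort_keys=True))


def load_config(path) -> tuple[CorpusConfig, TrainingConfig]:
    blobs = yaml.safe_load(Path(path).read_text())
    cc = blobs.get("CorpusConfig", {})
    tc = blobs.get("TrainingConfig", {})
    for k, v in list(cc.items()):
        if isinstance(v, list):
            cc[k] = tuple(v)
    if isinstance(tc.get("region_features"), list):
        tc["region_features"] = tuple(tc["region_features"])
    return CorpusConfig(**cc), TrainingConfig(**tc)


def lexicon_table(corpus: Corpus) -> pd.DataFrame:
    rows = []
    for w in corpus.lexicon:
        feats = np.nonzero(w.semantic_vector)[0]
        rows.append(
            {
                "word_id": w.word_id,
                "structure": w.syllable_structure,
                "segments": w.symbols,
                "semantic_features": ";".join(f"f{int(i)}" for i in feats),
            }
        )
    return pd.DataFrame(rows)


def save_corpus(outdir, corpus: Corpus) -> None:
    """Lexicon TSV plus per-item representation arrays in one npz archive."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon_table(corpus).to_csv(outdir / "lexicon.tsv", sep="\t", index=False)
    arrays = {}
    for k, item in enumerate(corpus.items):
        arrays[f"aud_{k}"] = item.auditory.activation
        arrays[f"som_{k}"] = item.somato.activation
    arrays["word_of_item"] = corpus.word_of_item
    np.savez_compressed(outdir / "corpus.npz", **arrays)
    save_config(outdir / "config.yaml", corpus.config)


def _map_arrays(prefix: str, gmap: GrowingMap) -> dict:
    return {
        f"{prefix}_weights": gmap.weights.copy(),
        f"{prefix}_positions": gmap.positions.copy(),
        f"{prefix}_errors": gmap.errors.copy(),
    }


def save_model(path, model: SpeechModel) -> None:
    arrays = _map_arrays("s", model.s_map) | _map_arrays("p", model.p_map)
    arrays["assoc"] = model.assoc.weights.copy()
    arrays["meta"] = np.array(
        json.dumps({"mode": model.mode, "frames": model.frames,
                    "combined_query": model.combined_query})
    )
    np.savez_compressed(path, **arrays)


def _restore_map(npz, prefix: str) -> GrowingMap:
    w = npz[f"{prefix}_weights"]
    pos = npz[f"{prefix}_positions"]
    err = npz[f"{prefix}_errors"]
    m = GrowingMap(w.shape[1], rng=np.random.default_rng(0))
    for i in range(w.shape[0]):
        m.add_node(tuple(pos[i]), w[i])
        m.errors[i] = err[i]
    return m


def load_model(path, corpus: Corpus) -> SpeechModel:
    npz = np.load(path, allow_pickle=False)
    meta = json.loads(str(npz["meta"]))
    s_map = _restore_map(npz, "s")
    p_map = _restore_map(npz, "p")
    assoc = AssociationNet(s_map.n_nodes, p_map.n_nodes)
    assoc.weights[:] = npz["assoc"]
    return SpeechModel(
        s_map=s_map, p_map=p_map, assoc=assoc,
        mode=meta["mode"], corpus=corpus, frames=meta["frames"],
        combined_query=meta.get("combined_query", "impute"),
    )


def map_table(model: SpeechModel) -> pd.DataFrame:
    """TSV-ready lattice dump: node, position, hosted items, word labels."""
    assignment = model.p_map.assign(model.corpus.training_matrix(model.mode, model.frames))
    words = {w.word_id: w.symbols for w in model.corpus.lexicon}
    word_of_item = model.corpus.word_of_item
    rows = []
    for node in range(model.p_map.n_nodes):
        items = assignment.items_of_node.get(node, [])
        labels = sorted({words[int(word_of_item[i])] for i in items})
        x, y = model.p_map.positions[node]
        rows.append(
            {
                "node_id": node,
                "x": int(x),
                "y": int(y),
                "items": ";".join(str(i) for i in items),
                "words": ";".join(labels),
            }
        )
    return pd.DataFrame(rows)


def write_metrics_csv(path, frame: pd.DataFrame, header_hash: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_hash:
            fh.write(f"# config_hash={header_hash}\n")
        frame.to_csv(fh, index=False)
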