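"""End-to-end pipeline driver: corpus → vocabulary → curation → training →
evaluation → retrieval, with a reproducibility manifest.

A run is described by a single config (YAML/dict).  Every artifact lands in
the run directory together with ``manifest.json`` recording the config
hash, input hashes and per-stage outputs; a rerun with an unchanged config
and inputs reuses cached stage outputs instead of recomputing them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import synthetic
from .corpus import (ReactionRecord, curate, read_sentence_files, split_dataset,
                     write_sentence_files)
from .model import ModelConfig, Seq2SeqModel, build_model
from .retrieval import build_lookup, retrieval_success
from .similarity import SimilarityConfig
from .training import TrainConfig, evaluate_predictions, train, translate_corpus
from .vocab import KeyVocabulary

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    workdir: str = "fragretro_run"
    seed: int = 0
    # data: synthetic corpus parameters (reaction-file input goes through the
    # CLI curate/train subcommands; the one-shot pipeline is synthetic-first)
    n_reactions: int = 2000
    n_molecules: int = 12000
    subset: str = "combined"            # single | double | combined
    twin_rate: float = 0.0
    dup_rate: float = 0.0
    multi_reactant_rate: float = 0.0
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        embedding_dim=48, hidden_units=64, num_layers=1, bidirectional=True,
        dropout=0.1))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr=0.5, lr_decay=0.9, decay_every=5, clip_norm=2.0, batch_size=32,
        momentum=0.9, min_epochs=20))
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    max_discrepancy: int = 4

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "model" in kw:
            kw["model"] = ModelConfig(**kw["model"])
        if "train" in kw:
            kw["train"] = TrainConfig(**kw["train"])
        if "similarity" in kw:
            sim = dict(kw["similarity"])
            if "bands" in sim:
                sim["bands"] = tuple(sim["bands"])
            kw["similarity"] = SimilarityConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_cached(workdir: Path, stage: str, key: str, outputs: list[Path]) -> bool:
    hash_file = workdir / f".{stage}.hash"
    if hash_file.exists() and hash_file.read_text().strip() == key:
        return all(p.exists() for p in outputs)
    return False


def _mark_stage(workdir: Path, stage: str, key: str) -> None:
    (workdir / f".{stage}.hash").write_text(key + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the workdir)."""
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {"config": config.to_dict(), "config_hash": chash,
                      "stages": {}}

    # ---- corpus + vocabulary -----------------------------------------
    vocab_path = wd / "vocab.json"
    src_path, tgt_path = wd / "pairs.src", wd / "pairs.tgt"
    report_path = wd / "curation_report.json"
    corpus_key = f"{chash}:corpus"
    if not _stage_cached(wd, "corpus", corpus_key, [vocab_path, src_path, tgt_path]):
        mols = synthetic.make_molecule_corpus(config.n_molecules, seed=config.seed)
        vocab = synthetic.fixture_vocabulary(mols)
        rules = synthetic.default_rules(vocab)
        corp = synthetic.make_reaction_corpus(
            config.n_reactions, rules, seed=config.seed, vocab=vocab,
            molecules=mols, twin_rate=config.twin_rate, dup_rate=config.dup_rate,
            multi_reactant_rate=config.multi_reactant_rate)
        records, report = curate(corp.records, vocab, encoded=True)
        vocab.save(vocab_path)
        write_sentence_files(records, src_path, tgt_path)
        report.save(report_path)
        (wd / "molecules.smi").write_text("\n".join(mols[:config.n_molecules]) + "\n")
        _mark_stage(wd, "corpus", corpus_key)
    vocab = KeyVocabulary.load(vocab_path)
    pairs = read_sentence_files(src_path, tgt_path)
    manifest["stages"]["corpus"] = {"n_pairs": len(pairs),
                                    "vocab_size": len(vocab)}

    # ---- split --------------------------------------------------------
    records = [ReactionRecord(None, (), tuple(s), tuple(t)) for s, t in pairs]
    splits = split_dataset(records, seed=config.seed)[config.subset]
    manifest["stages"]["split"] = {k: len(v) for k, v in splits.items()}

    def as_pairs(rs):
        return [(list(r.source_sentence), list(r.target_sentence)) for r in rs]

    # ---- training -----------------------------------------------------
    model_path = wd / "model.npz"
    train_key = f"{chash}:train"
    if not _stage_cached(wd, "train", train_key, [model_path]):
        model = build_model(vocab.model_vocab_size, config.model, seed=config.seed)
        log = train(model, as_pairs(splits["train"]), config.train, vocab,
                    val_pairs=as_pairs(splits["val"]),
                    sim_config=config.similarity, checkpoint_dir=wd / "checkpoints")
        best = wd / "checkpoints" / "best.npz"
        if best.exists():
            model = Seq2SeqModel.load(best)
        model.save(model_path)
        log.save_csv(wd / "training_log.csv")
        _mark_stage(wd, "train", train_key)
    model = Seq2SeqModel.load(model_path)
    manifest["stages"]["train"] = {"n_parameters": model.n_parameters()}

    # ---- evaluation ---------------------------------------------------
    test_pairs = as_pairs(splits["test"])
    preds = translate_corpus(model, [s for s, _ in test_pairs], vocab)
    outcomes, summary = evaluate_predictions(
        preds, [t for _, t in test_pairs], vocab, config.similarity)
    with open(wd / "evaluation.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    with open(wd / "predictions.tgt", "w") as fh:
        for p in preds:
            fh.write(" ".join(p) + "\n")
    manifest["stages"]["evaluate"] = summary.to_dict()

    # ---- retrieval sanity over the molecule corpus --------------------
    mols = (wd / "molecules.smi").read_text().splitlines()
    lookup_mols = mols[:1000]
    table = build_lookup(lookup_mols, vocab)
    queries, truths = [], []
    for smi in table._by_smiles:
        queries.append(list(table.entries[table._by_smiles[smi]].sentence))
        truths.append(smi)
        if len(queries) >= 200:
            break
    retr = retrieval_success(table, queries, truths,
                             max_discrepancy=config.max_discrepancy)
    manifest["stages"]["retrieval"] = {str(k): v for k, v in retr.items()}

    with open(wd / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
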