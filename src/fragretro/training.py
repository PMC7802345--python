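"""SGD training loop, greedy translation, and held-out evaluation.

Training follows the classic attention-NMT recipe: plain stochastic
gradient descent on teacher-forced cross-entropy, initial learning rate
4.0 decayed by 0.85 every three epochs, global gradient-norm clipping at
0.25, batch size 64, dropout 0.1.  At the end of every epoch the model
greedily translates the validation set and the matched-similarity success
bands are logged; the checkpoint with the best validation exact-match rate
is retained.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import EOS_ID, PAD_ID, SEP_ID, SOS_ID, Seq2SeqModel
from .similarity import EvalOutcome, SimilarityConfig, corpus_success, match_pairs
from .vocab import SEP, KeyVocabulary, decode_sentence

__all__ = ["TrainConfig", "TrainingLog", "train", "translate", "translate_corpus",
           "evaluate_predictions", "epoch_lr"]

logger = logging.getLogger(__name__)

SentencePair = tuple[list[str], list[str]]


@dataclass
class TrainConfig:
    lr: float = 4.0
    lr_decay: float = 0.85
    decay_every: int = 3
    clip_norm: float = 0.25
    batch_size: int = 64
    min_epochs: int = 30
    epochs: int | None = None          # total epochs; defaults to min_epochs
    momentum: float = 0.0              # classical momentum; 0 = plain SGD
    average_last: int = 0              # average weights over the final k epochs
    seed: int = 0
    max_decode_len: int = 102

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0,1]")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.epochs is None:
            self.epochs = self.min_epochs


def epoch_lr(config: TrainConfig, epoch: int) -> float:
    """Learning rate in force during 1-based ``epoch``."""
    return config.lr * config.lr_decay ** ((epoch - 1) // config.decay_every)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.epochs.append(kw)

    def save_csv(self, path) -> None:
        if not self.epochs:
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.epochs[0]))
            writer.writeheader()
            writer.writerows(self.epochs)


def _to_ids(sentence: Sequence[str], ids: dict[str, int]) -> list[int]:
    out = []
    for tok in sentence:
        if tok not in ids:
            raise KeyError(f"token {tok!r} not in model vocabulary")
        out.append(ids[tok])
    return out


def _pad_batch(seqs: list[list[int]], pad: int = PAD_ID) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([max(len(s), 1) for s in seqs], dtype=int)
    T = max(1, max((len(s) for s in seqs), default=1))
    arr = np.full((len(seqs), T), pad, dtype=int)
    for i, s in enumerate(seqs):
        arr[i, :len(s)] = s
    return arr, lengths


def _clip_gradients(model: Seq2SeqModel, clip_norm: float) -> float:
    tensors = list(model.named_unique_parameters().values())
    total = 0.0
    for t in tensors:
        if t.grad is not None:
            total += float((t.grad.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if norm > clip_norm:
        scale = clip_norm / (norm + 1e-12)
        for t in tensors:
            if t.grad is not None:
                t.grad *= scale
    return norm


def train(model: Seq2SeqModel, train_pairs: Sequence[SentencePair],
          config: TrainConfig, vocab: KeyVocabulary,
          val_pairs: Sequence[SentencePair] = (),
          sim_config: SimilarityConfig = SimilarityConfig(),
          checkpoint_dir: str | Path | None = None) -> TrainingLog:
    """Train in place; returns the per-epoch log.

    ``train_pairs``/``val_pairs`` are (source tokens, target tokens)
    sentence pairs over ``vocab``'s words.  When ``checkpoint_dir`` is
    given, a checkpoint is written per epoch and ``best.npz`` tracks the
    best validation exact-match rate.
    """
    if not train_pairs:
        raise ValueError("empty training corpus")
    ids = vocab.token_ids()
    if len(ids) != model.vocab_size:
        raise ValueError(
            f"vocabulary size {len(ids)} does not match model ({model.vocab_size})")
    encoded = []
    for src, tgt in train_pairs:
        s = _to_ids(src, ids)
        t = _to_ids(tgt, ids)
        encoded.append((s, [SOS_ID] + t, t + [EOS_ID]))
    rng = np.random.default_rng(config.seed)
    log = TrainingLog()
    best_exact = -1.0
    velocity: dict[str, np.ndarray] = {}
    # running mean of end-of-epoch weights over the final `average_last`
    # epochs (checkpoint averaging smooths the SGD endpoint)
    avg_weights: dict[str, np.ndarray] = {}
    n_averaged = 0
    avg_from = config.epochs - config.average_last + 1
    ckdir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckdir:
        ckdir.mkdir(parents=True, exist_ok=True)
    # length-bucketed batches: sort by source length so padding stays small,
    # shuffle only the batch order each epoch
    by_len = sorted(range(len(encoded)), key=lambda i: len(encoded[i][0]))
    batches = [by_len[s:s + config.batch_size]
               for s in range(0, len(by_len), config.batch_size)]
    for epoch in range(1, config.epochs + 1):
        lr = epoch_lr(config, epoch)
        total_loss, total_tokens = 0.0, 0
        for bi in rng.permutation(len(batches)):
            batch = [encoded[i] for i in batches[bi]]
            src, src_len = _pad_batch([b[0] for b in batch])
            tgt_in, _ = _pad_batch([b[1] for b in batch])
            tgt_out, _ = _pad_batch([b[2] for b in batch])
            model.zero_grad()
            loss, n_tok = model.loss(src, src_len, tgt_in, tgt_out, train=True)
            loss.backward()
            _clip_gradients(model, config.clip_norm)
            for name, t in model.named_unique_parameters().items():
                if t.grad is None:
                    continue
                if config.momentum > 0.0:
                    v = velocity.get(name)
                    if v is None:
                        v = velocity[name] = np.zeros_like(t.data)
                    v *= config.momentum
                    v += t.grad
                    t.data -= lr * v
                else:
                    t.data -= lr * t.grad
            total_loss += float(loss.data) * n_tok
            total_tokens += n_tok
        if config.average_last > 0 and epoch >= avg_from:
            n_averaged += 1
            for name, t in model.named_unique_parameters().items():
                if name not in avg_weights:
                    avg_weights[name] = t.data.copy()
                else:
                    avg_weights[name] += (t.data - avg_weights[name]) / n_averaged
        row = {"epoch": epoch, "lr": lr,
               "train_loss": total_loss / max(total_tokens, 1)}
        if val_pairs:
            preds = translate_corpus(model, [s for s, _ in val_pairs], vocab,
                                     max_len=config.max_decode_len)
            _, summary = evaluate_predictions(
                preds, [t for _, t in val_pairs], vocab, sim_config)
            row.update(val_exact_pct=summary.exact_pct,
                       val_similar_pct=summary.bioactively_similar_pct,
                       val_mean_score=summary.mean_score)
            if ckdir and summary.exact_pct > best_exact:
                best_exact = summary.exact_pct
                model.save(ckdir / "best.npz")
        if ckdir:
            model.save(ckdir / f"epoch{epoch:03d}.npz")
        log.append(**row)
        logger.info("epoch %d: %s", epoch, row)
    if n_averaged > 1:
        for name, t in model.named_unique_parameters().items():
            t.data = avg_weights[name].astype(t.data.dtype)
    if ckdir:
        model.save(ckdir / "final.npz")
        log.save_csv(ckdir / "training_log.csv")
    return log


def _postprocess(tokens: list[str]) -> list[str]:
    """Keep at most one separator: truncate at a second SEP."""
    seen_sep = False
    out = []
    for tok in tokens:
        if tok == SEP:
            if seen_sep:
                break
            seen_sep = True
        out.append(tok)
    while out and out[-1] == SEP:
        out.pop()
    return out


def translate(model: Seq2SeqModel, source_sentence: Sequence[str],
              vocab: KeyVocabulary, max_len: int = 102) -> list[str]:
    """Greedy translation of one source sentence into target tokens."""
    return translate_corpus(model, [list(source_sentence)], vocab, max_len)[0]


def translate_corpus(model: Seq2SeqModel, sources: Sequence[Sequence[str]],
                     vocab: KeyVocabulary, max_len: int = 102,
                     batch_size: int = 256) -> list[list[str]]:
    ids = vocab.token_ids()
    rev = {v: k for k, v in ids.items()}
    out: list[list[str]] = []
    for start in range(0, len(sources), batch_size):
        chunk = sources[start:start + batch_size]
        src, src_len = _pad_batch([_to_ids(s, ids) for s in chunk])
        for id_seq in model.translate_ids(src, src_len, max_len=max_len):
            out.append(_postprocess([rev[i] for i in id_seq]))
    return out


def evaluate_predictions(predictions: Sequence[Sequence[str]],
                         truths: Sequence[Sequence[str]],
                         vocab: KeyVocabulary,
                         sim_config: SimilarityConfig = SimilarityConfig()
                         ) -> tuple[list[EvalOutcome], "CorpusSummary"]:
    """Score predicted against true target sentences with pair matching."""
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths are not aligned")
    metric = sim_config.scorer()
    outcomes = []
    for pred, true in zip(predictions, truths):
        pred_sets = decode_sentence(pred, vocab)
        true_sets = decode_sentence(true, vocab)
        assignment, score = match_pairs(true_sets, pred_sets, metric)
        outcomes.append(EvalOutcome(score=score, assignment=assignment,
                                    n_true=len(true_sets), n_predicted=len(pred_sets)))
    return outcomes, corpus_success(outcomes, sim_config)
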