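"""Canonical desk-scale experiments.

The learnability experiment is the package's standing end-to-end check
that the translator can actually extract reaction rules from data: a tiny
bidirectional model (64 hidden units, one layer) is trained on 2,000
synthetic rule-based pairs and must recover the held-out transformations
almost perfectly.  The unidirectional variant run under the identical
budget quantifies the benefit of the bidirectional encoder, mirroring the
full-scale Bi-LSTM-versus-LSTM comparison.

Desk-scale conditions, fixed once: products drawn from the packaged
molecule list (decorated, corpus seed 3), a 48-key vocabulary (the most
frequent keys, so every word has adequate support in 2,000 pairs), the
five standard toy rules, 2,000 training and 200 held-out pairs, and a
momentum-SGD budget of 50 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .model import ModelConfig, build_model
from .similarity import CorpusSummary
from .synthetic import (default_rules, fixture_vocabulary, make_molecule_corpus,
                        make_reaction_corpus)
from .training import TrainConfig, evaluate_predictions, train, translate_corpus

__all__ = ["learnability_corpus", "run_learnability", "LearnabilityResult"]

N_TRAIN = 2000
N_HELDOUT = 200
MOLECULE_SEED = 3
CORPUS_SEED = 5
MAX_KEYS = 48
EPOCHS = 50


@lru_cache(maxsize=2)
def learnability_corpus(corpus_seed: int = CORPUS_SEED):
    """The fixed synthetic corpus: (vocab, train pairs, held-out pairs)."""
    mols = make_molecule_corpus(12_000, seed=MOLECULE_SEED)
    vocab = fixture_vocabulary(mols, max_keys=MAX_KEYS)
    rules = default_rules(vocab)
    corp = make_reaction_corpus(N_TRAIN + N_HELDOUT, rules, seed=corpus_seed,
                                vocab=vocab, molecules=mols)
    pairs = [(list(r.source_sentence), list(r.target_sentence))
             for r in corp.clean_records]
    return vocab, pairs[:N_TRAIN], pairs[N_TRAIN:]


@dataclass
class LearnabilityResult:
    seed: int
    bidirectional: bool
    summary: CorpusSummary

    @property
    def exact_pct(self) -> float:
        return self.summary.exact_pct


def run_learnability(seed: int, bidirectional: bool = True,
                     epochs: int = EPOCHS) -> LearnabilityResult:
    """Train the tiny model under the standard conditions and score it on
    the held-out pairs."""
    vocab, train_pairs, heldout = learnability_corpus()
    mcfg = ModelConfig(embedding_dim=64, hidden_units=64, num_layers=1,
                       bidirectional=bidirectional, dropout=0.1,
                       tie_embeddings=True, tie_output=True)
    tcfg = TrainConfig(lr=1.0, lr_decay=0.9, decay_every=8, clip_norm=2.0,
                       batch_size=64, momentum=0.9, average_last=10,
                       epochs=epochs, min_epochs=epochs, seed=seed)
    model = build_model(vocab.model_vocab_size, mcfg, seed=seed)
    train(model, train_pairs, tcfg, vocab)
    preds = translate_corpus(model, [s for s, _ in heldout], vocab)
    _, summary = evaluate_predictions(preds, [t for _, t in heldout], vocab)
    return LearnabilityResult(seed=seed, bidirectional=bidirectional,
                              summary=summary)
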