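"""Mapping predicted key sets back to real molecules.

The translator emits fragment sentences, not structures.  A lookup table
over a molecule database stores, per canonical SMILES, its curated key set
and its sentence ("language representation").  A predicted sentence first
tries an exact sentence hit; failing that, near misses are ranked by the
number of *discrepant keys* — the symmetric difference between predicted
and stored key sets.  Since many molecules can share one curated key set,
ties are broken by re-ranking candidates with a higher-resolution circular
fingerprint (Morgan radius 2, 2048 bits) Tanimoto against a reference
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .keys import KeySet, SmilesParseError, canonical_smiles, compute_ecfp, compute_maccs
from .similarity import tanimoto
from .vocab import KeyVocabulary, decode_sentence, encode_molecule

__all__ = ["LookupEntry", "LookupTable", "build_lookup", "query",
           "rerank_candidates", "retrieval_success"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LookupEntry:
    smiles: str
    keyset: KeySet
    sentence: tuple[str, ...]


class LookupTable:
    """Entries indexed for exact-sentence hits and near-miss search."""

    def __init__(self, vocab: KeyVocabulary):
        self.vocab = vocab
        self.entries: list[LookupEntry] = []
        self._by_smiles: dict[str, int] = {}
        self._by_sentence: dict[tuple[str, ...], list[int]] = {}
        self._by_key: dict[int, set[int]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, smiles: str) -> bool:
        """Add one molecule; returns False for duplicates/parse failures."""
        try:
            can = canonical_smiles(smiles)
        except SmilesParseError:
            logger.warning("lookup table: skipping unparseable %r", smiles)
            return False
        if can in self._by_smiles:
            return False
        ks = compute_maccs(can).restrict(self.vocab.retained_keys)
        sent = tuple(encode_molecule(ks, self.vocab))
        idx = len(self.entries)
        self.entries.append(LookupEntry(can, ks, sent))
        self._by_smiles[can] = idx
        self._by_sentence.setdefault(sent, []).append(idx)
        for k in ks.indices:
            self._by_key.setdefault(k, set()).add(idx)
        return True


def build_lookup(molecule_db: list[str], vocab: KeyVocabulary) -> LookupTable:
    """One entry per canonical SMILES; unparseable inputs skipped-and-logged."""
    table = LookupTable(vocab)
    for smi in molecule_db:
        table.add(smi)
    return table


def query(table: LookupTable, predicted_sentence: list[str],
          max_discrepancy: int = 4) -> list[tuple[LookupEntry, int]]:
    """Entries within ``max_discrepancy`` discrepant keys of the prediction.

    Discrepancy is the size of the symmetric difference of key sets;
    results are sorted ascending by discrepancy (exact matches first),
    ties by insertion order.
    """
    sets = decode_sentence(predicted_sentence, table.vocab)
    if len(sets) != 1:
        raise ValueError("query expects a single-molecule sentence; split at SEP first")
    qset = sets[0]
    # candidate pool: entries sharing a key, plus key-poor entries that could
    # be within range even with zero overlap
    cand: set[int] = set()
    for k in qset.indices:
        cand |= table._by_key.get(k, set())
    for i, e in enumerate(table.entries):
        if len(e.keyset) + len(qset) <= max_discrepancy:
            cand.add(i)
    hits = []
    for i in sorted(cand):
        d = qset.symmetric_difference_size(table.entries[i].keyset)
        if d <= max_discrepancy:
            hits.append((table.entries[i], d))
    hits.sort(key=lambda t: t[1])
    return hits


def rerank_candidates(candidates: list[str], reference: str,
                      radius: int = 2, nbits: int = 2048
                      ) -> list[tuple[str, float]]:
    """Sort candidate SMILES by circular-fingerprint Tanimoto to a reference.

    Stable descending sort, so equally scored candidates keep input order.
    """
    ref_fp = compute_ecfp(reference, radius=radius, nbits=nbits)
    scored = []
    for smi in candidates:
        fp = compute_ecfp(smi, radius=radius, nbits=nbits)
        scored.append((smi, tanimoto(ref_fp, fp)))
    scored.sort(key=lambda t: -t[1])
    return scored


def retrieval_success(table: LookupTable, predicted_sentences: list[list[str]],
                      truths: list[str], max_discrepancy: int = 4
                      ) -> dict[int, float]:
    """Cumulative fraction of predictions whose true reactant is within
    ``k`` discrepant keys, for k = 0..max_discrepancy.

    ``truths`` are the true reactant SMILES aligned with the predictions;
    each is compared through its curated key set.
    """
    if len(predicted_sentences) != len(truths):
        raise ValueError("predictions and truths are not aligned")
    if not truths:
        raise ValueError("empty evaluation set")
    discrepancies = []
    for sent, true_smi in zip(predicted_sentences, truths):
        qset = decode_sentence(sent, table.vocab)[0]
        tset = compute_maccs(true_smi).restrict(table.vocab.retained_keys)
        discrepancies.append(qset.symmetric_difference_size(tset))
    out = {}
    n = len(discrepancies)
    for k in range(max_discrepancy + 1):
        out[k] = 100.0 * sum(1 for d in discrepancies if d <= k) / n
    return out
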