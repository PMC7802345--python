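"""Reaction-SMILES parsing and the dataset curation cascade.

A corpus is a text file of ``reactants>reagents>product`` records.  For the
retrosynthetic translation task the *source* sentence is the product and
the *target* sentence is the reactant(s), SEP-joined with the longer
reactant first.  Curation runs in a fixed order: keep single-product
records, encode everything with the curated key vocabulary, then — on the
encoded sentences — drop duplicate pairs, drop internal twins (records
whose chemical change is invisible at key resolution, so source equals
target), drop records with three or more reactants, drop pairs longer than
100 tokens, and finally collapse one-to-many product→reactant mappings to
an injective map by keeping the shortest target.  Every stage's removal
count telescopes into a :class:`CurationReport`.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .keys import SmilesParseError, canonical_smiles, compute_keyset
from .vocab import SEP, FragmentSentence, KeyVocabulary, encode_molecule, encode_reactants

__all__ = [
    "ReactionRecord",
    "CurationReport",
    "parse_reaction",
    "parse_reaction_file",
    "filter_single_product",
    "encode_records",
    "dedupe_pairs",
    "remove_internal_twins",
    "filter_reactant_count",
    "filter_pair_length",
    "collapse_injective",
    "split_dataset",
    "curate",
    "write_sentence_files",
]

logger = logging.getLogger(__name__)

MAX_PAIR_LENGTH = 100
MAX_REACTANTS = 2


@dataclass(frozen=True)
class ReactionRecord:
    """One product→reactant(s) record, optionally with encoded sentences."""

    product_smiles: str | None
    reactant_smiles: tuple[str, ...]
    source_sentence: tuple[str, ...] = ()
    target_sentence: tuple[str, ...] = ()
    multi_product: bool = False

    @property
    def n_reactants(self) -> int:
        if self.target_sentence:
            return self.target_sentence.count(SEP) + 1
        return len(self.reactant_smiles)

    @property
    def pair_length(self) -> int:
        return len(self.source_sentence) + len(self.target_sentence)


@dataclass
class CurationReport:
    """Telescoping per-stage record counts of one curation run."""

    input: int = 0
    parse_failures: int = 0
    multi_product_removed: int = 0
    single_product_kept: int = 0
    duplicates_removed: int = 0
    internal_twins_removed: int = 0
    too_many_reactants_removed: int = 0
    too_long_removed: int = 0
    injective_collapsed: int = 0
    final: int = 0
    subset_sizes: dict[str, int] = field(default_factory=dict)

    def check_telescoping(self) -> None:
        expected = (
            self.single_product_kept
            - self.duplicates_removed
            - self.internal_twins_removed
            - self.too_many_reactants_removed
            - self.too_long_removed
            - self.injective_collapsed
        )
        if expected != self.final:
            raise AssertionError(
                f"curation counts do not telescope: expected final {expected}, got {self.final}"
            )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "input", "parse_failures", "multi_product_removed", "single_product_kept",
            "duplicates_removed", "internal_twins_removed", "too_many_reactants_removed",
            "too_long_removed", "injective_collapsed", "final")}
        d["subset_sizes"] = dict(self.subset_sizes)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def parse_reaction(line: str) -> ReactionRecord:
    """Parse one ``reactants>reagents>products`` line; reagents discarded.

    Components are canonicalized.  Records with more than one product are
    returned flagged ``multi_product`` (they are dropped downstream, not
    split).  Malformed lines raise :class:`ValueError`.
    """
    parts = line.strip().split(">")
    if len(parts) != 3:
        raise ValueError(f"malformed reaction line (need 2 '>'): {line!r}")
    reactants_f, _reagents, products_f = parts
    reactants = [canonical_smiles(s) for s in reactants_f.split(".") if s]
    products = [canonical_smiles(s) for s in products_f.split(".") if s]
    if not reactants or not products:
        raise ValueError(f"reaction line missing reactants or products: {line!r}")
    return ReactionRecord(
        product_smiles=products[0],
        reactant_smiles=tuple(reactants),
        multi_product=len(products) > 1,
    )


def parse_reaction_file(lines: Iterable[str]) -> tuple[list[ReactionRecord], int]:
    """Parse a corpus, skipping-and-logging malformed lines.

    Returns ``(records, n_failures)``.
    """
    records: list[ReactionRecord] = []
    failures = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            records.append(parse_reaction(line))
        except (ValueError, SmilesParseError) as exc:
            logger.warning("line %d skipped: %s", lineno, exc)
            failures += 1
    return records, failures


def filter_single_product(records: Sequence[ReactionRecord],
                          report: CurationReport | None = None) -> list[ReactionRecord]:
    kept = [r for r in records if not r.multi_product]
    if report is not None:
        report.multi_product_removed += len(records) - len(kept)
        report.single_product_kept = len(kept)
    return kept


def encode_records(records: Sequence[ReactionRecord], vocab: KeyVocabulary,
                   backend_kwargs: dict | None = None) -> list[ReactionRecord]:
    """Attach source/target sentences computed from the SMILES fields."""
    kw = backend_kwargs or {}
    out = []
    for r in records:
        src = encode_molecule(compute_keyset(r.product_smiles, vocab.backend, **kw), vocab)
        tgt = encode_reactants(
            [compute_keyset(s, vocab.backend, **kw) for s in r.reactant_smiles], vocab
        )
        out.append(replace(r, source_sentence=tuple(src), target_sentence=tuple(tgt)))
    return out


def dedupe_pairs(records: Sequence[ReactionRecord],
                 report: CurationReport | None = None) -> list[ReactionRecord]:
    """Drop repeated (source, target) sentence pairs, keeping first occurrence."""
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    kept = []
    for r in records:
        key = (r.source_sentence, r.target_sentence)
        if key in seen:
            continue
        seen.add(key)
        kept.append(r)
    if report is not None:
        report.duplicates_removed += len(records) - len(kept)
    return kept


def remove_internal_twins(records: Sequence[ReactionRecord],
                          report: CurationReport | None = None) -> list[ReactionRecord]:
    """Drop records whose source and target sentences are identical."""
    kept = [r for r in records if r.source_sentence != r.target_sentence]
    if report is not None:
        report.internal_twins_removed += len(records) - len(kept)
    return kept


def filter_reactant_count(records: Sequence[ReactionRecord],
                          max_reactants: int = MAX_REACTANTS,
                          report: CurationReport | None = None) -> list[ReactionRecord]:
    kept = [r for r in records if r.n_reactants <= max_reactants]
    if report is not None:
        report.too_many_reactants_removed += len(records) - len(kept)
    return kept


def filter_pair_length(records: Sequence[ReactionRecord],
                       max_len: int = MAX_PAIR_LENGTH,
                       report: CurationReport | None = None) -> list[ReactionRecord]:
    """Keep records whose source+target token count (SEP included) is <= max_len."""
    kept = [r for r in records if r.pair_length <= max_len]
    if report is not None:
        report.too_long_removed += len(records) - len(kept)
    return kept


def collapse_injective(records: Sequence[ReactionRecord],
                       report: CurationReport | None = None) -> list[ReactionRecord]:
    """Force the source→target map to be a function.

    For each source sentence with several distinct targets, keep the record
    whose target has the fewest tokens (presumably the least complex
    reactant set); ties break lexicographically on the token sequence.
    Output preserves first-occurrence order of the sources.
    """
    by_source: dict[tuple[str, ...], ReactionRecord] = {}
    order: list[tuple[str, ...]] = []
    for r in records:
        cur = by_source.get(r.source_sentence)
        if cur is None:
            by_source[r.source_sentence] = r
            order.append(r.source_sentence)
        elif (len(r.target_sentence), r.target_sentence) < (
                len(cur.target_sentence), cur.target_sentence):
            by_source[r.source_sentence] = r
    kept = [by_source[s] for s in order]
    if report is not None:
        report.injective_collapsed += len(records) - len(kept)
    return kept


def split_dataset(records: Sequence[ReactionRecord], seed: int,
                  test_frac: float = 0.1, val_frac: float = 0.1
                  ) -> dict[str, dict[str, list[ReactionRecord]]]:
    """Seeded 9:1 train/test split with 10% of train held out as validation.

    Splits are drawn independently for the single-reactant, double-reactant
    and combined subsets, so the three experiments are self-contained.
    """
    subsets = {
        "single": [r for r in records if r.n_reactants == 1],
        "double": [r for r in records if r.n_reactants == 2],
        "combined": list(records),
    }
    out: dict[str, dict[str, list[ReactionRecord]]] = {}
    for name, subset in subsets.items():
        rng = random.Random(f"{seed}:{name}")  # str seeding is process-stable
        shuffled = list(subset)
        rng.shuffle(shuffled)
        n_test = round(len(shuffled) * test_frac)
        test, train_full = shuffled[:n_test], shuffled[n_test:]
        n_val = round(len(train_full) * val_frac)
        val, train = train_full[:n_val], train_full[n_val:]
        out[name] = {"train": train, "val": val, "test": test}
    return out


def curate(records: Sequence[ReactionRecord], vocab: KeyVocabulary,
           max_reactants: int = MAX_REACTANTS, max_len: int = MAX_PAIR_LENGTH,
           report: CurationReport | None = None,
           encoded: bool = False) -> tuple[list[ReactionRecord], CurationReport]:
    """Run the full cascade in canonical order on parsed records."""
    if report is None:
        report = CurationReport(input=len(records))
    recs = filter_single_product(records, report)
    if not encoded:
        recs = encode_records(recs, vocab)
    recs = dedupe_pairs(recs, report)
    recs = remove_internal_twins(recs, report)
    recs = filter_reactant_count(recs, max_reactants, report)
    recs = filter_pair_length(recs, max_len, report)
    recs = collapse_injective(recs, report)
    report.final = len(recs)
    report.subset_sizes = {
        "single": sum(1 for r in recs if r.n_reactants == 1),
        "double": sum(1 for r in recs if r.n_reactants == 2),
        "combined": len(recs),
    }
    report.check_telescoping()
    return recs, report


def write_sentence_files(records: Sequence[ReactionRecord], src_path, tgt_path) -> None:
    """Aligned source/target token files, one space-joined sentence per line."""
    with open(src_path, "w") as fs, open(tgt_path, "w") as ft:
        for r in records:
            fs.write(" ".join(r.source_sentence) + "\n")
            ft.write(" ".join(r.target_sentence) + "\n")


def read_sentence_files(src_path, tgt_path) -> list[tuple[list[str], list[str]]]:
    with open(src_path) as fs, open(tgt_path) as ft:
        src_lines = [l.rstrip("\n") for l in fs]
        tgt_lines = [l.rstrip("\n") for l in ft]
    if len(src_lines) != len(tgt_lines):
        raise ValueError("source/target files are not aligned")
    return [(s.split() if s else [], t.split() if t else [])
            for s, t in zip(src_lines, tgt_lines)]
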