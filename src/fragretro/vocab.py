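"""Key curation, the lettered-word vocabulary, and the sentence codec.

The fragment "language" is built in two steps.  Curation drops structural
keys that carry no signal: keys that never occur in the reaction corpus,
keys rarer than ``rare_primary`` there, and keys rarer than
``rare_reference`` in a reference corpus of drug-like molecules.  With the
default MACCS dictionary this yields the 126-key working set.  The
survivors are then ranked by frequency in the reaction corpus and each rank
is assigned a short artificial word: ranks 1-21 get the 21 most frequent
English letters uppercase (E, T, A, ...), ranks 22-42 the same letters
lowercase, ranks 43-84 the same 42 words suffixed with "x", ranks 85-126
suffixed with "z" — 126 words of length one or two.  A molecule's sentence
is its retained keys' words sorted by ascending rank (most frequent first),
so token position itself encodes frequency information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .keys import Backend, KeyFrequencyProfile, KeySet, MACCS_NUM_KEYS

__all__ = [
    "LETTER_ORDER",
    "SEP",
    "SOS",
    "EOS",
    "PAD",
    "SPECIAL_TOKENS",
    "KeyVocabulary",
    "curate_keys",
    "build_vocabulary",
    "encode_molecule",
    "decode_sentence",
    "DecodeError",
]

#: The 21 most frequent letters of English, most frequent first.
LETTER_ORDER = "ETAOINSHRDLCUMWFGYPBV"

PAD = "<pad>"
SOS = "<sos>"
EOS = "<eos>"
SEP = "–"  # "–" joins the two reactant sentences of a pair

#: Special tokens occupy the first four ids of every model vocabulary.
SPECIAL_TOKENS = (PAD, SOS, EOS, SEP)

FragmentSentence = list[str]


class DecodeError(KeyError):
    pass


def _lettered_words(n: int) -> list[str]:
    """The first ``n`` words of the lettered scheme (max 126)."""
    singles = [c for c in LETTER_ORDER] + [c.lower() for c in LETTER_ORDER]
    words = singles + [w + "x" for w in singles] + [w + "z" for w in singles]
    return words[:n]


def curate_keys(
    primary: KeyFrequencyProfile,
    reference: KeyFrequencyProfile | None = None,
    *,
    rare_primary: float = 1e-4,
    rare_reference: float = 1e-4,
    all_keys: Sequence[int] | None = None,
    explicit_keys: Sequence[int] | None = None,
) -> list[int]:
    """Select the keys retained in the working vocabulary.

    A key survives iff it occurs at least once in the primary (reaction)
    corpus, its primary normalized frequency is >= ``rare_primary``, and —
    when a reference profile is given — its reference frequency is >=
    ``rare_reference``.  ``explicit_keys`` bypasses thresholding entirely
    (for reproducing a published key list).  Survivors are returned in
    ascending key index.
    """
    if explicit_keys is not None:
        keys = sorted(set(int(k) for k in explicit_keys))
        return keys
    for name, t in (("rare_primary", rare_primary), ("rare_reference", rare_reference)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {t}")
    if reference is not None and reference.backend != primary.backend:
        raise ValueError("primary and reference profiles use different backends")
    if all_keys is None:
        if primary.backend == Backend.MACCS:
            all_keys = range(1, MACCS_NUM_KEYS + 1)
        else:
            all_keys = sorted(primary.counts)
    survivors = []
    for k in all_keys:
        if primary.count(k) == 0:
            continue
        if primary.frequency(k) < rare_primary:
            continue
        if reference is not None and reference.frequency(k) < rare_reference:
            continue
        survivors.append(int(k))
    return sorted(survivors)


@dataclass
class KeyVocabulary:
    """Curated key list with frequency ranks and lettered-word assignments."""

    backend: str
    retained_keys: list[int]
    rank: dict[int, int]              # key index -> rank, 1 = most frequent
    word: dict[int, str]              # key index -> word (bijective)
    curation_thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.retained_keys)) != len(self.retained_keys):
            raise ValueError("retained_keys contains duplicates")
        if sorted(self.rank.values()) != list(range(1, len(self.retained_keys) + 1)):
            raise ValueError("ranks are not a permutation of 1..n")
        if len(set(self.word.values())) != len(self.word):
            raise ValueError("word mapping is not injective")
        self._key_of_word = {w: k for k, w in self.word.items()}

    def __len__(self) -> int:
        return len(self.retained_keys)

    @property
    def words_by_rank(self) -> list[str]:
        order = sorted(self.retained_keys, key=lambda k: self.rank[k])
        return [self.word[k] for k in order]

    def key_of_word(self, w: str) -> int:
        try:
            return self._key_of_word[w]
        except KeyError:
            raise DecodeError(f"unknown token {w!r}") from None

    # ---- model-facing token ids (specials first) ----------------------
    def token_ids(self) -> dict[str, int]:
        ids = {t: i for i, t in enumerate(SPECIAL_TOKENS)}
        for w in self.words_by_rank:
            ids[w] = len(ids)
        return ids

    @property
    def model_vocab_size(self) -> int:
        return len(SPECIAL_TOKENS) + len(self.retained_keys)

    # ---- persistence ---------------------------------------------------
    def to_json(self) -> str:
        obj = {
            "backend": self.backend,
            "retained_keys": list(self.retained_keys),
            "rank": {str(k): self.rank[k] for k in sorted(self.rank)},
            "word": {str(k): self.word[k] for k in sorted(self.word)},
            "curation_thresholds": dict(sorted(self.curation_thresholds.items())),
        }
        return json.dumps(obj, indent=2, sort_keys=False)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def from_json(cls, text: str) -> "KeyVocabulary":
        obj = json.loads(text)
        return cls(
            backend=obj["backend"],
            retained_keys=[int(k) for k in obj["retained_keys"]],
            rank={int(k): int(v) for k, v in obj["rank"].items()},
            word={int(k): v for k, v in obj["word"].items()},
            curation_thresholds=obj.get("curation_thresholds", {}),
        )

    @classmethod
    def load(cls, path) -> "KeyVocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_vocabulary(
    retained_keys: Sequence[int],
    primary_profile: KeyFrequencyProfile,
    curation_thresholds: dict[str, float] | None = None,
) -> KeyVocabulary:
    """Rank retained keys by primary-corpus frequency and assign words.

    Rank 1 is the most frequent key; ties break toward the lower key index.
    Up to 126 keys receive lettered words; larger vocabularies fall back to
    ``w<rank>`` words.
    """
    keys = [int(k) for k in retained_keys]
    if len(set(keys)) != len(keys):
        raise ValueError("retained_keys contains duplicates")
    ranked = sorted(keys, key=lambda k: (-primary_profile.count(k), k))
    rank = {k: i + 1 for i, k in enumerate(ranked)}
    if len(keys) <= 126:
        words = _lettered_words(len(keys))
    else:
        words = [f"w{i+1}" for i in range(len(keys))]
    word = {k: words[rank[k] - 1] for k in keys}
    return KeyVocabulary(
        backend=primary_profile.backend,
        retained_keys=sorted(keys),
        rank=rank,
        word=word,
        curation_thresholds=dict(curation_thresholds or {}),
    )


def encode_molecule(keyset: KeySet, vocab: KeyVocabulary) -> FragmentSentence:
    """Tokens of one molecule: retained keys' words in ascending rank order.

    Keys outside the retained set are silently dropped — the deliberate
    information loss of the truncated-key representation.
    """
    if keyset.backend != vocab.backend:
        raise ValueError(f"backend mismatch: {keyset.backend} vs {vocab.backend}")
    present = keyset.indices & set(vocab.retained_keys)
    return [vocab.word[k] for k in sorted(present, key=lambda k: vocab.rank[k])]


def encode_reactants(keysets: Sequence[KeySet], vocab: KeyVocabulary) -> FragmentSentence:
    """SEP-joined sentence of 1..n reactants, longest sentence first."""
    sentences = [encode_molecule(ks, vocab) for ks in keysets]
    sentences.sort(key=lambda s: (-len(s), s))
    out: FragmentSentence = []
    for i, s in enumerate(sentences):
        if i:
            out.append(SEP)
        out.extend(s)
    return out


def decode_sentence(sentence: Iterable[str], vocab: KeyVocabulary) -> list[KeySet]:
    """Inverse of encoding: a (possibly SEP-joined) sentence back to key sets.

    Returns one :class:`KeySet` per SEP-separated segment; an empty sentence
    decodes to a single empty key set.
    """
    groups: list[set[int]] = [set()]
    for tok in sentence:
        if tok == SEP:
            groups.append(set())
        else:
            groups[-1].add(vocab.key_of_word(tok))
    return [KeySet(g, vocab.backend) for g in groups]


def decode_single(sentence: Iterable[str], vocab: KeyVocabulary) -> KeySet:
    """Decode a sentence known to describe one molecule."""
    sets = decode_sentence(sentence, vocab)
    if len(sets) != 1:
        raise DecodeError("sentence contains a separator; expected one molecule")
    return sets[0]
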