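"""Key curation, the lettered-word scheme, and the sentence codec."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fragretro.keys import Backend, KeyFrequencyProfile, KeySet
from fragretro.vocab import (SEP, DecodeError, KeyVocabulary, build_vocabulary,
                             curate_keys, decode_sentence, encode_molecule,
                             encode_reactants, _lettered_words)


def _profile(counts: dict[int, int], n: int) -> KeyFrequencyProfile:
    return KeyFrequencyProfile(counts, n, Backend.MACCS)


def planted_profiles():
    """Primary/reference profiles built so exactly 40 of 166 keys fail:
    5 never occur, 9 are too rare in the primary corpus, 26 too rare in the
    reference corpus — leaving the canonical 126 survivors."""
    n = 100_000
    primary = {k: n // 2 for k in range(1, 167)}
    reference = {k: n // 2 for k in range(1, 167)}
    never = list(range(1, 6))
    rare_primary = list(range(6, 15))
    rare_reference = list(range(15, 41))
    for k in never:
        primary[k] = 0
    for k in rare_primary:
        primary[k] = 1               # freq 1e-5 < 1e-4
    for k in rare_reference:
        reference[k] = 1
    return _profile(primary, n), _profile(reference, n), never + rare_primary + rare_reference


class TestCurateKeys:
    def test_zero_thresholds_keep_all_occurring(self):
        p = _profile({k: 1 for k in range(1, 167)}, 10)
        assert curate_keys(p, rare_primary=0.0, rare_reference=0.0) == list(range(1, 167))

    def test_never_occurring_key_always_removed(self):
        counts = {k: 5 for k in range(1, 167)}
        counts[42] = 0
        p = _profile(counts, 10)
        assert 42 not in curate_keys(p, rare_primary=0.0)

    def test_planted_profiles_yield_126_survivors(self):
        primary, reference, dropped = planted_profiles()
        kept = curate_keys(primary, reference)
        assert len(kept) == 126
        assert set(kept) == set(range(1, 167)) - set(dropped)

    def test_explicit_key_list_bypasses_thresholds(self):
        primary, reference, _ = planted_profiles()
        kept = curate_keys(primary, reference, explicit_keys=[3, 1, 2])
        assert kept == [1, 2, 3]

    def test_threshold_out_of_range_rejected(self):
        p = _profile({1: 1}, 1)
        with pytest.raises(ValueError):
            curate_keys(p, rare_primary=1.5)

    def test_raising_thresholds_never_adds_keys(self):
        rng = np.random.default_rng(0)
        p = _profile({k: int(rng.integers(0, 50)) for k in range(1, 167)}, 50)
        sizes = [len(curate_keys(p, rare_primary=t))
                 for t in (0.0, 0.05, 0.2, 0.5, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestLetteredScheme:
    def test_126_words_are_42_singles_plus_84_doubles(self):
        words = _lettered_words(126)
        assert len(words) == len(set(words)) == 126
        singles = [w for w in words if len(w) == 1]
        doubles = [w for w in words if len(w) == 2]
        assert len(singles) == 42 and len(doubles) == 84
        assert sum(1 for w in doubles if w.endswith("x")) == 42
        assert sum(1 for w in doubles if w.endswith("z")) == 42

    def test_rank_to_word_anchors(self):
        primary, reference, _ = planted_profiles()
        kept = curate_keys(primary, reference)
        # make frequencies distinct so rank i+1 falls on kept[i]
        prof = _profile({k: 10_000 - i for i, k in enumerate(kept)}, 10_000)
        vocab = build_vocabulary(kept, prof)
        by_rank = {r: k for k, r in vocab.rank.items()}
        assert vocab.word[by_rank[1]] == "E"
        assert vocab.word[by_rank[22]] == "e"
        assert vocab.word[by_rank[43]] == "Ex"
        assert vocab.word[by_rank[85]] == "Ez"

    def test_equal_counts_break_toward_lower_key(self):
        prof = _profile({5: 7, 3: 7, 9: 9}, 10)
        vocab = build_vocabulary([3, 5, 9], prof)
        assert vocab.rank[9] == 1 and vocab.rank[3] == 2 and vocab.rank[5] == 3

    def test_duplicate_keys_rejected(self):
        prof = _profile({1: 1}, 1)
        with pytest.raises(ValueError):
            build_vocabulary([1, 1], prof)

    def test_oversized_vocabulary_falls_back_to_numbered_words(self):
        prof = _profile({k: 1 for k in range(1, 167)}, 1)
        vocab = build_vocabulary(list(range(1, 167)), prof)
        assert all(w.startswith("w") for w in vocab.word.values())
        assert len(set(vocab.word.values())) == 166


class TestCodec:
    def test_tokens_sorted_by_ascending_rank(self, vocab):
        keys = sorted(vocab.retained_keys)[:6]
        ks = KeySet(keys)
        sent = encode_molecule(ks, vocab)
        ranks = [vocab.rank[vocab.key_of_word(w)] for w in sent]
        assert ranks == sorted(ranks)

    def test_removed_keys_silently_dropped(self, vocab):
        outside = sorted(set(range(1, 167)) - set(vocab.retained_keys))
        if not outside:
            pytest.skip("fixture vocabulary retains all keys")
        assert encode_molecule(KeySet(outside[:3]), vocab) == []

    def test_decode_splits_at_separator(self, vocab):
        k1 = sorted(vocab.retained_keys)[:3]
        k2 = sorted(vocab.retained_keys)[3:5]
        sent = encode_reactants([KeySet(k1), KeySet(k2)], vocab)
        sets = decode_sentence(sent, vocab)
        assert len(sets) == 2
        assert {frozenset(s.indices) for s in sets} == {frozenset(k1), frozenset(k2)}

    def test_reactants_ordered_longest_first(self, vocab):
        k_small = sorted(vocab.retained_keys)[:2]
        k_big = sorted(vocab.retained_keys)[2:8]
        sent = encode_reactants([KeySet(k_small), KeySet(k_big)], vocab)
        first = sent[:sent.index(SEP)]
        assert len(first) == 6

    def test_unknown_token_raises(self, vocab):
        with pytest.raises(DecodeError, match="bogus"):
            decode_sentence(["bogus"], vocab)

    def test_empty_sentence_decodes_to_empty_set(self, vocab):
        (ks,) = decode_sentence([], vocab)
        assert len(ks) == 0

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_is_identity_on_retained_keys(self, vocab, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(1, 50))
        keys = frozenset(int(k) for k in
                         rng.choice(np.arange(1, 167), size=size, replace=False))
        ks = KeySet(keys)
        (back,) = decode_sentence(encode_molecule(ks, vocab), vocab)
        assert back.indices == keys & set(vocab.retained_keys)


class TestPersistence:
    def test_json_roundtrip(self, vocab):
        clone = KeyVocabulary.from_json(vocab.to_json())
        assert clone.retained_keys == vocab.retained_keys
        assert clone.rank == vocab.rank
        assert clone.word == vocab.word

    def test_vocabulary_file_is_byte_stable(self, vocab, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        vocab.save(a)
        vocab.save(b)
        assert a.read_bytes() == b.read_bytes()

    def test_same_profiles_rebuild_identical_vocabulary(self, molecules):
        from fragretro.synthetic import fixture_vocabulary
        v1 = fixture_vocabulary(molecules)
        v2 = fixture_vocabulary(list(molecules))
        assert v1.to_json() == v2.to_json()
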