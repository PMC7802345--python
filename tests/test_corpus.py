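"""Reaction parsing and the curation cascade."""

import pytest

from fragretro.corpus import (CurationReport, ReactionRecord, collapse_injective,
                              curate, dedupe_pairs, filter_pair_length,
                              filter_reactant_count, filter_single_product,
                              parse_reaction, parse_reaction_file,
                              read_sentence_files, remove_internal_twins,
                              split_dataset, write_sentence_files)
from fragretro.synthetic import make_reaction_smiles_lines


def rec(src, tgt, multi=False):
    return ReactionRecord(None, (), tuple(src), tuple(tgt), multi_product=multi)


class TestParseReaction:
    def test_esterification_line(self):
        r = parse_reaction("CCO.CC(=O)O>>CCOC(C)=O")
        assert r.product_smiles == "CCOC(C)=O"
        assert set(r.reactant_smiles) == {"CCO", "CC(=O)O"}
        assert not r.multi_product

    def test_reagents_discarded(self):
        r = parse_reaction("CCO>O=S(=O)(O)O>CCOC(C)=O")
        assert r.reactant_smiles == ("CCO",)

    def test_multi_product_flagged(self):
        assert parse_reaction("CCO>>CCO.CC(=O)O").multi_product

    def test_malformed_line_raises(self):
        with pytest.raises(ValueError):
            parse_reaction("CCO>CC(=O)O")  # only one '>'

    def test_file_parse_skips_and_counts_failures(self):
        lines = make_reaction_smiles_lines(10, seed=1, malformed=2)
        records, failures = parse_reaction_file(lines)
        assert len(records) == 10 and failures == 2

    def test_components_canonicalized(self):
        r = parse_reaction("OCC>>C(C)O")   # both are ethanol, written oddly
        assert r.product_smiles == r.reactant_smiles[0] == "CCO"


class TestFilters:
    def test_single_product_filter(self):
        records = [rec("A", "B"), rec("A", "B", multi=True), rec("C", "D")]
        report = CurationReport(input=3)
        kept = filter_single_product(records, report)
        assert len(kept) == 2 and report.multi_product_removed == 1

    def test_dedupe_keeps_first_occurrence(self):
        a, b = rec("AB", "CD"), rec("AB", "CD")
        kept = dedupe_pairs([a, b, rec("AB", "CE")])
        assert len(kept) == 2 and kept[0] is a

    def test_twins_dropped_only_on_exact_sentence_equality(self):
        twin = rec(("A", "B"), ("A", "B"))
        near = rec(("A", "B"), ("B", "A"))
        assert remove_internal_twins([twin, near]) == [near]

    def test_reactant_count_uses_separator(self):
        one = rec("AB", ("C",))
        two = rec("AB", ("C", "–", "D"))
        three = rec("AB", ("C", "–", "D", "–", "E"))
        assert filter_reactant_count([one, two, three]) == [one, two]

    def test_pair_length_bound_is_inclusive(self):
        at_bound = rec(["A"] * 50, ["B"] * 50)      # exactly 100
        over = rec(["A"] * 50, ["B"] * 51)          # 101
        assert filter_pair_length([at_bound, over]) == [at_bound]


class TestCollapseInjective:
    def test_identity_when_already_injective(self):
        records = [rec("A", "B"), rec("C", "D")]
        assert collapse_injective(records) == records

    def test_shortest_target_wins(self):
        long_ = rec("A", ("X",) * 7)
        short = rec("A", ("Y",) * 4)
        assert collapse_injective([long_, short]) == [short]

    def test_length_tie_breaks_lexicographically(self):
        r1, r2 = rec("A", ("Z", "Z")), rec("A", ("B", "C"))
        assert collapse_injective([r1, r2]) == [r2]

    def test_result_is_a_function(self, contaminated_corpus, vocab):
        out, _ = curate(contaminated_corpus.records, vocab, encoded=True)
        sources = {}
        for r in out:
            assert sources.setdefault(r.source_sentence, r.target_sentence) \
                == r.target_sentence


class TestCurationReport:
    def test_planted_contamination_recovered_exactly(self, contaminated_corpus, vocab):
        corp = contaminated_corpus
        _, report = curate(corp.records, vocab, encoded=True)
        assert report.duplicates_removed == corp.planted["duplicates"]
        assert report.internal_twins_removed == corp.planted["twins"]
        assert report.too_many_reactants_removed == corp.planted["multi_reactant"]
        assert report.too_long_removed == corp.planted["too_long"]
        assert report.injective_collapsed == corp.planted["injective_extras"]
        assert report.final == len(corp.clean_records)

    def test_telescoping_enforced(self):
        report = CurationReport(input=10, single_product_kept=10, final=9)
        with pytest.raises(AssertionError):
            report.check_telescoping()


class TestSplitDataset:
    def _records(self, n):
        return [rec((f"s{i}",), (f"t{i}",)) for i in range(n)]

    def test_ninety_ten_then_ninety_ten(self):
        splits = split_dataset(self._records(100), seed=0)["combined"]
        assert len(splits["test"]) == 10
        assert len(splits["val"]) == 9
        assert len(splits["train"]) == 81

    def test_same_seed_reproduces_split(self):
        a = split_dataset(self._records(50), seed=3)
        b = split_dataset(self._records(50), seed=3)
        for subset in a:
            for part in a[subset]:
                assert a[subset][part] == b[subset][part]

    def test_subsets_partition_by_reactant_count(self):
        singles = [rec((f"s{i}",), ("t",)) for i in range(10)]
        doubles = [rec((f"d{i}",), ("t", "–", "u")) for i in range(10)]
        out = split_dataset(singles + doubles, seed=1)
        assert sum(len(v) for v in out["single"].values()) == 10
        assert sum(len(v) for v in out["double"].values()) == 10
        assert sum(len(v) for v in out["combined"].values()) == 20


class TestSentenceFiles:
    def test_roundtrip_and_byte_stability(self, clean_corpus, tmp_path):
        records = clean_corpus.clean_records[:20]
        s1, t1 = tmp_path / "a.src", tmp_path / "a.tgt"
        s2, t2 = tmp_path / "b.src", tmp_path / "b.tgt"
        write_sentence_files(records, s1, t1)
        write_sentence_files(records, s2, t2)
        assert s1.read_bytes() == s2.read_bytes()
        assert t1.read_bytes() == t2.read_bytes()
        pairs = read_sentence_files(s1, t1)
        assert pairs == [(list(r.source_sentence), list(r.target_sentence))
                         for r in records]
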