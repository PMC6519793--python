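"""The five false-positive filter rules."""

import pytest

from tripmine.corpus_io import parse_pubtator, split_sentences
from tripmine.pair_builder import extract_candidate_pairs
from tripmine.postprocess import (
    FilterResources,
    apply_postprocessing,
    apply_rule,
    default_negation_keywords,
    default_study_hyponyms,
    load_synonym_dictionaries,
    pattern_coordination,
    write_synonym_dictionaries,
)

from conftest import make_pubtator_block


def pairs_from_block(block, configuration="gene_chemical+disease"):
    doc = split_sentences(parse_pubtator(block)[0])
    return extract_candidate_pairs(doc, configuration)


@pytest.fixture(scope="module")
def printed_examples(positive_example_block, negative_example_block):
    pos = pairs_from_block(positive_example_block)
    neg = pairs_from_block(negative_example_block)
    assert pos and neg
    resources = FilterResources(synonyms={
        "gene": {"4879": ["BNP"], "1636": ["ACE"]},
        "chemical": {"C473478": ["SUN", "sunitinib"],
                     "D006830": ["hydralazine"]},
        "disease": {"D002292": ["renal cell carcinoma"],
                    "D005923": ["glomerulosclerosis"]},
    })
    return pos, neg, resources


class TestIndividualRules:
    def test_negation_rule_fires_on_printed_negative_pair(self, printed_examples):
        _, neg, resources = printed_examples
        # the relation sentence contains "but not hydralazine"
        fired = [p for p in neg if apply_rule(p, "iv", resources)]
        assert fired

    def test_no_rule_fires_on_printed_positive_pair(self, printed_examples):
        pos, _, resources = printed_examples
        for p in pos:
            for rule in ("i", "ii", "iii", "iv", "v"):
                assert not apply_rule(p, rule, resources), rule

    def test_dictionary_rule_fires_on_unknown_surface(self, printed_examples):
        pos, _, _ = printed_examples
        incomplete = FilterResources(synonyms={
            "gene": {"4879": ["brain natriuretic peptide"]},  # no "BNP"
            "chemical": {"C473478": ["SUN"]},
            "disease": {"D002292": ["renal cell carcinoma"]},
        })
        assert apply_rule(pos[0], "i", incomplete)

    def test_dictionary_rule_fires_on_unnormalized_mention(self):
        block = make_pubtator_block(
            "X1", "A title.", "Drugx increased ABC in foo disease cases.",
            [("Drugx", "Chemical", "-"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        (pair,) = pairs_from_block(block)
        resources = FilterResources(synonyms={
            "gene": {"G1": ["ABC"]}, "chemical": {"C1": ["Drugx"]},
            "disease": {"D1": ["foo disease"]}})
        assert apply_rule(pair, "i", resources)

    def test_dictionary_rule_is_case_insensitive(self):
        block = make_pubtator_block(
            "X1", "A title.", "DRUGX increased ABC in foo disease cases.",
            [("DRUGX", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        (pair,) = pairs_from_block(block)
        resources = FilterResources(synonyms={
            "gene": {"G1": ["abc"]}, "chemical": {"C1": ["drugx"]},
            "disease": {"D1": ["Foo Disease"]}})
        assert not apply_rule(pair, "i", resources)

    def test_type_conflict_rule(self):
        block = make_pubtator_block(
            "X1", "A title.", "Drugx increased ABC in foo disease cases.",
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        # the gene span is additionally annotated as a chemical
        text = "A title. Drugx increased ABC in foo disease cases."
        s = text.find("ABC")
        block = block.rstrip("\n") + f"\nX1\t{s}\t{s + 3}\tABC\tChemical\t-\n"
        pairs = pairs_from_block(block)
        assert pairs
        resources = FilterResources(synonyms={"gene": {"G1": ["ABC"]}})
        assert all(apply_rule(p, "ii", resources) for p in pairs)

    def test_study_hyponym_rule_with_lemmatization(self):
        for word, expect in [("study", True), ("studies", True),
                             ("surveys", True), ("analysis", False),
                             ("treatment", False)]:
            block = make_pubtator_block(
                "X1", "A title.",
                f"The {word} covered Drugx and its ABC target in foo disease .",
                [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
                 ("foo disease", "Disease", "D1")])
            (pair,) = pairs_from_block(block)
            assert apply_rule(pair, "iii", FilterResources()) is expect, word

    def test_negation_matches_whole_tokens_only(self):
        for text, expect in [
            ("We note Drugx increased ABC in foo disease cases.", False),
            ("Drugx did not increase ABC in foo disease cases.", True),
            ("Drugx didn't increase ABC in foo disease cases.", True),
            ("Drugx never increased ABC in foo disease cases.", True),
        ]:
            block = make_pubtator_block(
                "X1", "A title.", text,
                [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
                 ("foo disease", "Disease", "D1")])
            (pair,) = pairs_from_block(block)
            assert apply_rule(pair, "iv", FilterResources()) is expect, text

    def test_negation_scope_covers_context_sentence(self):
        block = make_pubtator_block(
            "X1", "A title.",
            "Drugx increased ABC levels. This was not seen in foo disease.",
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        (pair,) = pairs_from_block(block)
        assert apply_rule(pair, "iv", FilterResources())

    def test_coordination_rule_on_conjoined_mentions(self):
        for text, expect in [
            ("ABC and Drugx were measured in foo disease cases.", True),
            ("ABC , Drugx were measured in foo disease cases.", True),
            ("ABC or Drugx was measured in foo disease cases.", True),
            ("Drugx increased ABC in foo disease cases.", False),
        ]:
            block = make_pubtator_block(
                "X1", "A title.", text,
                [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
                 ("foo disease", "Disease", "D1")])
            (pair,) = pairs_from_block(block)
            assert apply_rule(pair, "v", FilterResources()) is expect, text

    def test_rule_v_without_detector_is_error(self, printed_examples):
        pos, _, _ = printed_examples
        resources = FilterResources(coordination=None)
        with pytest.raises(ValueError, match="rule v"):
            apply_rule(pos[0], "v", resources)

    def test_unknown_rule_is_error(self, printed_examples):
        pos, _, resources = printed_examples
        with pytest.raises(ValueError, match="rule"):
            apply_rule(pos[0], "vi", resources)

    def test_rule_i_without_dictionaries_is_error(self, printed_examples):
        pos, _, _ = printed_examples
        with pytest.raises(ValueError, match="dictionaries"):
            apply_rule(pos[0], "i", FilterResources())


def _counting_fixture():
    """10 pairs: 3 trip the negation rule, 2 the study rule, 1 pair both."""
    blocks = []
    texts = [
        "Drugx increased ABC in foo disease cases.",          # clean
        "Drugx did not change ABC in foo disease cases.",      # iv
        "Drugx never altered ABC in foo disease cases.",       # iv
        "This study found Drugx did not affect ABC in foo disease.",  # iii+iv
        "This study linked Drugx to ABC in foo disease.",      # iii
        "Drugx elevated ABC in foo disease cases.",            # clean
        "Drugx reduced ABC in foo disease cases.",             # clean
        "Drugx activated ABC in foo disease cases.",           # clean
        "Drugx suppressed ABC in foo disease cases.",          # clean
        "Drugx induced ABC in foo disease cases.",             # clean
    ]
    pairs = []
    for i, text in enumerate(texts):
        block = make_pubtator_block(
            f"X{i}", "A title.", text,
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        pairs.extend(pairs_from_block(block))
    assert len(pairs) == 10
    return pairs


class TestApplyPostprocessing:
    RESOURCES = FilterResources(synonyms={
        "gene": {"G1": ["ABC"]}, "chemical": {"C1": ["Drugx"]},
        "disease": {"D1": ["foo disease"]}})

    def test_empty_input(self):
        kept, decisions, summary = apply_postprocessing([], self.RESOURCES)
        assert kept == [] and decisions == []

    def test_counting_fixture_summary(self):
        pairs = _counting_fixture()
        kept, decisions, summary = apply_postprocessing(pairs, self.RESOURCES)
        assert len(kept) == 6
        assert summary["iii"] == 2 and summary["iv"] == 3
        assert summary["i"] == summary["ii"] == summary["v"] == 0

    def test_all_rules_disabled_keeps_everything(self):
        pairs = _counting_fixture()
        kept, decisions, _ = apply_postprocessing(pairs, self.RESOURCES, ())
        assert kept == pairs
        assert all(d.kept for d in decisions)

    def test_kept_iff_no_rule_fired(self):
        pairs = _counting_fixture()
        _, decisions, _ = apply_postprocessing(pairs, self.RESOURCES)
        for d in decisions:
            assert d.kept == (not d.fired_rules)

    def test_monotone_in_enabled_rules(self):
        pairs = _counting_fixture()
        rule_sets = [(), ("iv",), ("iii", "iv"), ("i", "iii", "iv"),
                     ("i", "ii", "iii", "iv", "v")]
        prev = None
        for rules in rule_sets:
            kept, _, _ = apply_postprocessing(pairs, self.RESOURCES, rules)
            keys = {p.key for p in kept}
            if prev is not None:
                assert keys <= prev
            prev = keys

    def test_firing_is_pure(self):
        pairs = _counting_fixture()
        a = apply_postprocessing(pairs, self.RESOURCES)[1]
        b = apply_postprocessing(pairs, self.RESOURCES)[1]
        assert [d.fired_rules for d in a] == [d.fired_rules for d in b]

    def test_order_preserved(self):
        pairs = _counting_fixture()
        kept, _, _ = apply_postprocessing(pairs, self.RESOURCES)
        assert [p.doc_id for p in kept] == \
            [p.doc_id for p in pairs if p.doc_id in {x.doc_id for x in kept}]


class TestResourceFiles:
    def test_shipped_lists_are_lowercase_and_nonempty(self):
        hyp = default_study_hyponyms()
        neg = default_negation_keywords()
        assert "study" in hyp and "not" in neg and "never" in neg
        assert all(w == w.lower() for w in hyp | neg)

    def test_synonym_tsv_roundtrip(self, tmp_path, small_corpus):
        path = str(tmp_path / "dict.tsv")
        write_synonym_dictionaries(small_corpus["dicts"], path)
        loaded = load_synonym_dictionaries(path)
        assert loaded == {
            etype: {k: list(v) for k, v in d.items()}
            for etype, d in small_corpus["dicts"].items()}
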