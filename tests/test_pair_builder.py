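"""BIO tagging, decoding, and candidate-pair enumeration."""

import numpy as np
import pytest

from tripmine.corpus_io import EntityMention, parse_pubtator, split_sentences
from tripmine.pair_builder import (
    BIO_TAGS,
    bio_tag,
    decode_bio,
    extract_candidate_pairs,
    tokenize,
)

from conftest import make_pubtator_block


def _mention(doc_id, text, surface, etype, norm_id="X1"):
    start = text.index(surface)
    return EntityMention(doc_id, start, start + len(surface), surface, etype,
                         norm_id)


class TestBioTag:
    def test_chemical_and_gene(self):
        text = "SUN increased BNP"
        toks = tokenize(text)
        tagged = bio_tag(toks, [_mention("d", text, "SUN", "chemical"),
                                _mention("d", text, "BNP", "gene")])
        assert [t.bio_tag for t in tagged] == ["B-chemical", "O", "B-gene"]

    def test_no_mentions_all_outside(self):
        tagged = bio_tag(tokenize("plain words only here"), [])
        assert all(t.bio_tag == "O" for t in tagged)

    def test_multi_token_disease(self):
        text = "renal cell carcinoma was studied"
        tagged = bio_tag(tokenize(text),
                         [_mention("d", text, "renal cell carcinoma", "disease")])
        assert [t.bio_tag for t in tagged][:3] == ["B-disease", "I-disease",
                                                   "I-disease"]

    def test_tag_set_has_seven_members(self):
        assert len(BIO_TAGS) == 7
        assert len(set(BIO_TAGS)) == 7

    def test_overlap_precedence_gene_over_chemical(self):
        text = "ABC levels rose"
        tagged = bio_tag(
            tokenize(text),
            [_mention("d", text, "ABC", "chemical"),
             _mention("d", text, "ABC", "gene")])
        assert tagged[0].bio_tag == "B-gene"

    def test_mention_overlapping_no_token_is_error(self):
        toks = tokenize("only three tokens")
        bad = EntityMention("d", 100, 105, "ghost", "gene")
        with pytest.raises(ValueError, match="overlaps no token"):
            bio_tag(toks, [bad])


class TestDecodeBio:
    def test_inverse_of_tagging_example(self):
        assert decode_bio(["B-chemical", "O", "B-gene"]) == [
            ("chemical", 0, 1), ("gene", 2, 3)]

    def test_all_outside(self):
        assert decode_bio(["O", "O", "O"]) == []

    def test_ill_formed_sequence_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            decode_bio(["O", "I-gene", "O"])
        with pytest.raises(ValueError, match="index 1"):
            decode_bio(["B-gene", "I-disease"])

    def test_roundtrip_on_random_wellformed_sequences(self):
        rng = np.random.default_rng(42)
        etypes = ["gene", "chemical", "disease"]
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            tags, open_type = [], None
            for _ in range(n):
                r = rng.random()
                if open_type is not None and r < 0.4:
                    tags.append(f"I-{open_type}")
                    continue
                if r < 0.7:
                    open_type = etypes[rng.integers(3)]
                    tags.append(f"B-{open_type}")
                else:
                    open_type = None
                    tags.append("O")
            spans = decode_bio(tags)
            re_encoded = ["O"] * n
            for etype, s, e in spans:
                re_encoded[s] = f"B-{etype}"
                for i in range(s + 1, e):
                    re_encoded[i] = f"I-{etype}"
            assert decode_bio(re_encoded) == spans

    def test_roundtrip_recovers_mention_token_spans(self, small_corpus):
        for doc in small_corpus["docs"][:30]:
            for si, (s, e) in enumerate(doc.sentences):
                mentions = [m for m in doc.mentions
                            if s <= m.start and m.end <= e]
                toks = tokenize(doc.sentence_text(si), offset=s)
                spans = decode_bio(bio_tag(toks, mentions))
                assert len(spans) == len(mentions)


def _doc_from_block(block):
    return split_sentences(parse_pubtator(block)[0])


def brute_force_pair_count(doc, max_distance=None):
    """Independent oracle: triple nested loop over mentions + set dedup."""
    keys = set()
    for g in doc.mentions:
        if g.etype != "gene":
            continue
        for c in doc.mentions:
            if c.etype != "chemical":
                continue
            gi = doc.sentence_index_of(g)
            if doc.sentence_index_of(c) != gi:
                continue
            if (g.start, g.end) == (c.start, c.end):
                continue
            for d in doc.mentions:
                if d.etype != "disease":
                    continue
                di = doc.sentence_index_of(d)
                if max_distance is not None and abs(di - gi) > max_distance:
                    continue
                keys.add((gi, (g.start, g.end), (c.start, c.end),
                          (d.start, d.end)))
    return len(keys)


class TestExtractCandidatePairs:
    def test_relation_and_context_in_separate_sentences(self):
        block = make_pubtator_block(
            "X1", "A study title.",
            "Drugx increased ABC levels. Patients had foo disease.",
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        pairs = extract_candidate_pairs(_doc_from_block(block))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.relation_sentence_index != p.context_sentence_index
        assert p.gene_mention.norm_id == "G1"

    def test_single_sentence_triplet_duplicates_sentence(self):
        block = make_pubtator_block(
            "X1", "A title.",
            "Drugx increased ABC in foo disease patients.",
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1")])
        pairs = extract_candidate_pairs(_doc_from_block(block))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.relation_sentence_index == p.context_sentence_index
        assert [t.text for t in p.relation_sentence] == \
            [t.text for t in p.context_sentence]
        assert [t.bio_tag for t in p.relation_sentence] == \
            [t.bio_tag for t in p.context_sentence]

    def test_cross_product_of_mentions(self):
        block = make_pubtator_block(
            "X1", "A title.",
            "Drugx and drugy increased ABC and XYZ. Patients had foo disease.",
            [("Drugx", "Chemical", "C1"), ("drugy", "Chemical", "C2"),
             ("ABC", "Gene", "G1"), ("XYZ", "Gene", "G2"),
             ("foo disease", "Disease", "D1")])
        pairs = extract_candidate_pairs(_doc_from_block(block))
        assert len(pairs) == 4

    def test_multiple_disease_mentions_each_yield_a_pair(self):
        block = make_pubtator_block(
            "X1", "A title.",
            "Drugx increased ABC. Cases of foo disease and bar disease rose.",
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1"), ("bar disease", "Disease", "D2")])
        assert len(extract_candidate_pairs(_doc_from_block(block))) == 2

    def test_unknown_configuration_is_fatal(self, small_corpus):
        with pytest.raises(ValueError, match="configuration"):
            extract_candidate_pairs(small_corpus["docs"][0], "bogus")

    def test_matches_brute_force_oracle(self, small_corpus):
        for doc in small_corpus["docs"]:
            assert len(doc.sentences) <= 10
            got = len(extract_candidate_pairs(doc))
            assert got == brute_force_pair_count(doc)

    def test_max_sentence_distance_matches_oracle(self, small_corpus):
        for doc in small_corpus["docs"][:40]:
            for dist in (0, 1):
                got = len(extract_candidate_pairs(
                    doc, max_sentence_distance=dist))
                assert got == brute_force_pair_count(doc, dist)

    def test_default_configuration_roles(self, small_corpus):
        for p in small_corpus["pairs"]:
            rel_spans = {(t.start, t.end) for t in p.relation_sentence}
            # gene and chemical anchor tokens lie in the relation sentence
            g, c = p.gene_mention, p.chemical_mention
            assert any(s < g.end and e > g.start for s, e in rel_spans)
            assert any(s < c.end and e > c.start for s, e in rel_spans)
            assert p.relation_sentence[p.anchor_relation].bio_tag == "B-gene"
            assert p.context_sentence[p.anchor_context].bio_tag == "B-disease"

    @pytest.mark.parametrize("configuration,rel_types,ctx_type,anchor_tag", [
        ("chemical_disease+gene", ("chemical", "disease"), "gene", "B-chemical"),
        ("gene_disease+chemical", ("gene", "disease"), "chemical", "B-gene"),
    ])
    def test_alternative_configurations(self, configuration, rel_types,
                                        ctx_type, anchor_tag):
        block = make_pubtator_block(
            "X1", "A title.",
            "Drugx worsened foo disease by ABC induction. ABC and Drugx rose.",
            [("Drugx", "Chemical", "C1"), ("foo disease", "Disease", "D1"),
             ("ABC", "Gene", "G1")])
        pairs = extract_candidate_pairs(_doc_from_block(block), configuration)
        assert pairs
        for p in pairs:
            assert p.relation_sentence[p.anchor_relation].bio_tag == anchor_tag
            assert p.context_sentence[p.anchor_context].bio_tag == \
                f"B-{ctx_type}"

    def test_deduplication_is_per_mention_tuple(self):
        # same gene/chemical pair, two context diseases in the same sentence
        block = make_pubtator_block(
            "X1", "A title.",
            "Drugx increased ABC in foo disease and foo disease patients.",
            [("Drugx", "Chemical", "C1"), ("ABC", "Gene", "G1"),
             ("foo disease", "Disease", "D1"), ("foo disease", "Disease", "D1")])
        pairs = extract_candidate_pairs(_doc_from_block(block))
        assert len(pairs) == 2  # distinct mention spans, same IDs
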