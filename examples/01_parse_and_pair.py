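"""Parse a PubTator block and enumerate candidate evidence sentence pairs.

The fixture abstract holds a chemical-gene sentence and a separate disease
sentence, so exactly one candidate pair comes out: the relation sentence
(gene + chemical) paired with the disease context sentence.
"""

from tripmine import extract_candidate_pairs, parse_pubtator, split_sentences

BLOCK = """\
900001|t|Sunitinib and cardiac stress markers.
900001|a|SUN increased BNP levels in treated myocytes. Sunitinib is used in renal cell carcinoma.
900001\t38\t41\tSUN\tChemical\tC473478
900001\t52\t55\tBNP\tGene\t4879
900001\t105\t125\trenal cell carcinoma\tDisease\tD002292
"""

doc = split_sentences(parse_pubtator(BLOCK)[0])
print(f"document {doc.doc_id}: {len(doc.sentences)} sentences, "
      f"{len(doc.mentions)} mentions")
for pair in extract_candidate_pairs(doc):
    print("relation :", pair.relation_text)
    print("context  :", pair.context_text)
    print("triplet  :", pair.triplet_ids)
    print("BIO tags :", [t.bio_tag for t in pair.relation_sentence])
# The BIO sequence marks the chemical (SUN) and gene (BNP) mentions; the
# triplet is the normalized (gene, chemical, disease) identifier triple the
# classifier will score.
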