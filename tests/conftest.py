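import pytest

from tripmine.synthetic_data import SimConfig, generate_labeled_pairs


@pytest.fixture(scope="session")
def small_corpus():
    """120 synthetic documents with labeled pairs, dictionaries and gold."""
    cfg = SimConfig(seed=5, n_documents=120)
    docs, pairs, dicts, gold = generate_labeled_pairs(cfg)
    return {"config": cfg, "docs": docs, "pairs": pairs, "dicts": dicts,
            "gold": gold}


def make_pubtator_block(doc_id: str, title: str, abstract: str,
                        mentions: list[tuple[str, str, str]]) -> str:
    """Build a PubTator block from (surface, etype, norm_id) triples.

    Offsets are computed by locating each surface in title + " " + abstract
    (first unused occurrence), so fixtures never hand-maintain offsets.
    """
    text = title + " " + abstract if abstract else title
    lines = [f"{doc_id}|t|{title}", f"{doc_id}|a|{abstract}"]
    used: list[tuple[int, int]] = []
    for surface, etype, norm_id in mentions:
        start = -1
        while True:
            start = text.find(surface, start + 1)
            if start < 0:
                raise AssertionError(f"{surface!r} not found in fixture text")
            span = (start, start + len(surface))
            if span not in used:
                used.append(span)
                break
        lines.append(
            f"{doc_id}\t{span[0]}\t{span[1]}\t{surface}\t{etype}\t{norm_id}"
        )
    return "\n".join(lines) + "\n"


# The printed evidence examples used across test modules: a positive pair
# (sunitinib/BNP/renal cell carcinoma) and a negative, negated pair
# (hydralazine/ACE/glomerulosclerosis).
POSITIVE_TITLE = "Sunitinib cardiotoxicity in experimental models."
POSITIVE_ABSTRACT = (
    "At the protein level, Western blot analysis showed that SUN increased "
    "BNP and b-MHC, while it inhibited a-MHC protein levels in a "
    "concentration-dependent manner. Sunitinib (SUN) is a multi-targeted "
    "tyrosine kinase inhibitor used for the treatment of gastrointestinal "
    "stromal tumors and renal cell carcinoma."
)
NEGATIVE_TITLE = "Podocyte number after ACE-inhibition."
NEGATIVE_ABSTRACT = (
    "OBJECTIVE: The objective of this article is to test the effects of "
    "angiotensin-converting enzyme (ACE)-inhibition on glomerular epithelial "
    "cell number in an inducible experimental model of focal segmental "
    "glomerulosclerosis (FSGS). CONCLUSION: The results show following an "
    "abrupt decline in podocyte number, the initiation of ACE-inhibition but "
    "not hydralazine, was accompanied by higher podocyte number in the "
    "absence of proliferation."
)


@pytest.fixture(scope="session")
def positive_example_block():
    return make_pubtator_block(
        "24984876", POSITIVE_TITLE, POSITIVE_ABSTRACT,
        [("SUN", "Chemical", "C473478"), ("BNP", "Gene", "4879"),
         ("SUN", "Chemical", "C473478"),
         ("renal cell carcinoma", "Disease", "D002292")],
    )


@pytest.fixture(scope="session")
def negative_example_block():
    return make_pubtator_block(
        "25143333", NEGATIVE_TITLE, NEGATIVE_ABSTRACT,
        [("ACE", "Gene", "1636"), ("glomerulosclerosis", "Disease", "D005923"),
         ("ACE", "Gene", "1636"), ("ACE", "Gene", "1636"),
         ("hydralazine", "Chemical", "D006830")],
    )
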