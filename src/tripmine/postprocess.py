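"""Rule-based false-positive filtering of predicted-positive sentence pairs.

Five deterministic rules screen candidate pairs that the classifier scored
positive.  A pair is discarded when:

i.   a mention's surface is not among the synonyms of its normalized
     identifier (dictionary validation; unnormalized mentions always fail);
ii.  any mention span is annotated as more than one entity type;
iii. either sentence contains a hyponym of "study" (research-purpose wording);
iv.  either sentence contains a negation keyword such as "not" or "never";
v.   the gene and chemical mentions are connected by a conjunction in the
     relation sentence's dependency parse (coordinated entities rarely
     interact).

The study-hyponym list is a frozen snapshot shipped with the package so
behavior does not drift with lexicon versions.  The dependency parser for
rule v is an injected interface; the bundled default is a deterministic
surface-pattern detector (mention "," / "and" / "or" mention) that needs no
parsing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import IO, Callable, Iterable, Sequence

from .corpus_io import EntityMention
from .pair_builder import CandidatePair, Token

RULES = ("i", "ii", "iii", "iv", "v")

#: A coordination detector: (tokens, gene mention, chemical mention) -> bool.
CoordinationDetector = Callable[[Sequence[Token], EntityMention, EntityMention], bool]


def _resource_terms(name: str) -> frozenset[str]:
    text = (
        importlib_resources.files("tripmine.resources").joinpath(name).read_text()
    )
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


def default_study_hyponyms() -> frozenset[str]:
    """The shipped frozen snapshot of 'study' hyponyms (lower-cased)."""
    return _resource_terms("study_hyponyms.txt")


def default_negation_keywords() -> frozenset[str]:
    return _resource_terms("negation_keywords.txt")


def pattern_coordination(
    tokens: Sequence[Token], a: EntityMention, b: EntityMention
) -> bool:
    """Bundled rule-v fallback: the two mentions are linked by coordination.

    Fires when every token strictly between the two mention spans is a comma
    or a coordinating conjunction ("and"/"or"), with at least one token in
    between — the surface pattern a dependency parser would label as conjunct.
    """
    first, second = (a, b) if a.start <= b.start else (b, a)
    between = [
        t.text.lower()
        for t in tokens
        if t.start >= first.end and t.end <= second.start
    ]
    return bool(between) and all(t in {",", "and", "or"} for t in between)


@dataclass
class FilterResources:
    """Lexical and syntactic resources consumed by the rules."""

    #: per entity type: normalized ID -> synonym strings (matched case-folded)
    synonyms: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    study_hyponyms: frozenset[str] = field(default_factory=default_study_hyponyms)
    negation_keywords: frozenset[str] = field(default_factory=default_negation_keywords)
    coordination: CoordinationDetector = pattern_coordination

    def __post_init__(self) -> None:
        self._syn_folded = {
            etype: {nid: {s.casefold() for s in syns} for nid, syns in d.items()}
            for etype, d in self.synonyms.items()
        }
        self._negation = {k.lower() for k in self.negation_keywords}

    def in_dictionary(self, mention: EntityMention) -> bool:
        if not mention.normalized:
            return False
        syns = self._syn_folded.get(mention.etype, {}).get(mention.norm_id)
        return syns is not None and mention.surface.casefold() in syns


@dataclass
class FilterDecision:
    """Outcome of filtering one pair: kept iff no rule fired."""

    pair: CandidatePair
    fired_rules: tuple[str, ...]

    @property
    def kept(self) -> bool:
        return not self.fired_rules


def _lemma_variants(word: str) -> set[str]:
    """Cheap noun lemma candidates: the word plus de-pluralized forms."""
    out = {word}
    if word.endswith("ies") and len(word) > 4:
        out.add(word[:-3] + "y")
    if word.endswith("es") and len(word) > 3:
        out.add(word[:-2])
    if word.endswith("s") and len(word) > 2:
        out.add(word[:-1])
    return out


def _pair_tokens(pair: CandidatePair) -> Iterable[Token]:
    yield from pair.relation_sentence
    if pair.context_sentence_index != pair.relation_sentence_index:
        yield from pair.context_sentence


def _pair_mentions(pair: CandidatePair) -> list[EntityMention]:
    seen = set()
    out = []
    for m in pair.relation_mentions + pair.context_mentions:
        k = (m.start, m.end, m.etype)
        if k not in seen:
            seen.add(k)
            out.append(m)
    return out


def apply_rule(pair: CandidatePair, rule_id: str, resources: FilterResources) -> bool:
    """Evaluate one rule on one pair; True means the rule fires (pair filtered)."""
    if rule_id == "i":
        if not resources.synonyms:
            raise ValueError("rule i needs synonym dictionaries")
        return not all(
            resources.in_dictionary(m)
            for m in (pair.gene_mention, pair.chemical_mention, pair.disease_mention)
        )
    if rule_id == "ii":
        mentions = _pair_mentions(pair)
        for i, a in enumerate(mentions):
            for b in mentions[i + 1 :]:
                if a.etype != b.etype and a.start < b.end and b.start < a.end:
                    return True
        return False
    if rule_id == "iii":
        for t in _pair_tokens(pair):
            if _lemma_variants(t.text.lower()) & resources.study_hyponyms:
                return True
        return False
    if rule_id == "iv":
        for t in _pair_tokens(pair):
            w = t.text.lower()
            if w in resources._negation or any(
                w.endswith(suffix) and len(w) > len(suffix)
                for suffix in ("n't", "n’t")
            ):
                return True
        return False
    if rule_id == "v":
        if resources.coordination is None:
            raise ValueError("rule v needs a coordination detector or parser")
        return resources.coordination(
            pair.relation_sentence, pair.gene_mention, pair.chemical_mention
        )
    raise ValueError(f"unknown rule {rule_id!r}")


def apply_postprocessing(
    pairs: Iterable[CandidatePair],
    resources: FilterResources,
    enabled_rules: Sequence[str] = RULES,
) -> tuple[list[CandidatePair], list[FilterDecision], dict[str, int]]:
    """Filter pairs through all enabled rules (no short-circuit).

    Returns (kept pairs in input order, per-pair decisions, firings per rule).
    """
    for r in enabled_rules:
        if r not in RULES:
            raise ValueError(f"unknown rule {r!r}")
    kept: list[CandidatePair] = []
    decisions: list[FilterDecision] = []
    summary = {r: 0 for r in enabled_rules}
    for pair in pairs:
        fired = tuple(r for r in enabled_rules if apply_rule(pair, r, resources))
        for r in fired:
            summary[r] += 1
        decisions.append(FilterDecision(pair, fired))
        if not fired:
            kept.append(pair)
    return kept, decisions, summary


# ---------------------------------------------------------------------------
# Resource file I/O
# ---------------------------------------------------------------------------


def load_synonym_dictionaries(source: str | IO[str]) -> dict[str, dict[str, list[str]]]:
    """Read a synonym TSV: ``etype<TAB>norm_id<TAB>synonym`` per line."""
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        out: dict[str, dict[str, list[str]]] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            etype, nid, synonym = line.split("\t")
            out.setdefault(etype, {}).setdefault(nid, []).append(synonym)
        return out
    finally:
        if own:
            fh.close()


def write_synonym_dictionaries(
    dictionaries: dict[str, dict[str, list[str]]], destination: str | IO[str]
) -> int:
    own = isinstance(destination, str)
    fh = open(destination, "w") if own else destination
    rows = 0
    try:
        for etype in sorted(dictionaries):
            for nid in sorted(dictionaries[etype]):
                for syn in dictionaries[etype][nid]:
                    fh.write(f"{etype}\t{nid}\t{syn}\n")
                    rows += 1
    finally:
        if own:
            fh.close()
    return rows


def write_decisions(
    decisions: Iterable[FilterDecision], destination: str | IO[str]
) -> int:
    """Decisions TSV: pair key, kept flag, fired rules (comma-joined)."""
    own = isinstance(destination, str)
    fh = open(destination, "w") if own else destination
    rows = 0
    try:
        fh.write("doc_id\trel_sent\tctx_sent\tgene_id\tchemical_id\tdisease_id"
                 "\tkept\tfired_rules\n")
        for d in decisions:
            p = d.pair
            g, c, dis = p.triplet_ids
            fh.write(
                f"{p.doc_id}\t{p.relation_sentence_index}\t{p.context_sentence_index}"
                f"\t{g}\t{c}\t{dis}\t{int(d.kept)}\t{','.join(d.fired_rules)}\n"
            )
            rows += 1
    finally:
        if own:
            fh.close()
    return rows
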