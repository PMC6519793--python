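"""Candidate evidence sentence pairs and BIO tagging.

A triplet relationship (gene, chemical, disease) is evidenced by a *pair* of
sentences from one abstract: a relation sentence holding two of the entities
(by default gene + chemical) and a context sentence holding the third (by
default disease).  When all three mentions share one sentence the pair is the
sentence duplicated.  Every (gene mention, chemical mention) co-occurrence is
crossed with every disease mention in range, so one sentence can seed several
candidates.

Tokens are tagged with a 7-tag BIO scheme (B/I for each of the three entity
types, plus O).  Tokenization is deterministic: runs of word characters with
internal hyphens/slashes/apostrophes/decimal points stay single tokens; any
other non-space character is its own token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corpus_io import AnnotatedDocument, EntityMention

#: The 7 BIO tags.
BIO_TAGS = (
    "B-gene", "I-gene",
    "B-chemical", "I-chemical",
    "B-disease", "I-disease",
    "O",
)

#: Overlap precedence for tagging (higher wins).
_TYPE_PRECEDENCE = {"gene": 2, "chemical": 1, "disease": 0}

#: Triplet configurations: relation-sentence entity types (anchor type first)
#: and the context-sentence entity type.
CONFIGURATIONS = {
    "gene_chemical+disease": (("gene", "chemical"), "disease"),
    "chemical_disease+gene": (("chemical", "disease"), "gene"),
    "gene_disease+chemical": (("gene", "disease"), "chemical"),
}

#: Short aliases used on the command line.
CONFIGURATION_ALIASES = {
    "gc+d": "gene_chemical+disease",
    "cd+g": "chemical_disease+gene",
    "gd+c": "gene_disease+chemical",
}

_TOKEN_RE = re.compile(r"\w+(?:[-/.'’]\w+)*|\S")


@dataclass(frozen=True)
class Token:
    """One token: text, sentence-local index, global char span, BIO tag."""

    text: str
    index: int
    start: int
    end: int
    bio_tag: str = "O"

    def __post_init__(self) -> None:
        if self.bio_tag not in BIO_TAGS:
            raise ValueError(f"unknown BIO tag {self.bio_tag!r}")


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Tokenize *text*; char spans are shifted by *offset* (global offsets)."""
    return [
        Token(m.group(), i, m.start() + offset, m.end() + offset)
        for i, m in enumerate(_TOKEN_RE.finditer(text))
    ]


def bio_tag(tokens: Sequence[Token], mentions: Iterable[EntityMention]) -> list[Token]:
    """Return *tokens* re-tagged for *mentions* (all inside the sentence).

    The first token overlapping a mention gets ``B-<type>``, later overlapping
    tokens ``I-<type>``, everything else ``O``.  Overlapping mentions of
    different types are resolved by precedence gene > chemical > disease: a
    token already claimed by a higher-precedence mention is not re-tagged.
    """
    claimed: list[EntityMention | None] = [None] * len(tokens)
    order = sorted(
        mentions,
        key=lambda m: (-_TYPE_PRECEDENCE[m.etype], m.start, m.end),
    )
    for m in order:
        overlapping = [
            t.index for t in tokens if t.start < m.end and t.end > m.start
        ]
        if not overlapping:
            raise ValueError(
                f"mention {m.surface!r} [{m.start},{m.end}) overlaps no token"
            )
        for i in overlapping:
            if claimed[i] is None:
                claimed[i] = m
    out = []
    for t in tokens:
        m = claimed[t.index]
        if m is None:
            tag = "O"
        elif t.index > 0 and claimed[t.index - 1] is m:
            tag = f"I-{m.etype}"
        else:
            tag = f"B-{m.etype}"
        out.append(replace(t, bio_tag=tag))
    return out


def decode_bio(tagged: Sequence[Token] | Sequence[str]) -> list[tuple[str, int, int]]:
    """Decode a BIO sequence into ``(etype, first, end)`` half-open token spans.

    Inverse of :func:`bio_tag` on its output.  Raises on an ill-formed
    sequence (``I-x`` after ``O``, after a different type, or at position 0),
    naming the offending index.
    """
    tags = [t.bio_tag if isinstance(t, Token) else t for t in tagged]
    spans: list[tuple[str, int, int]] = []
    open_type: str | None = None
    start = 0
    for i, tag in enumerate(tags):
        if tag not in BIO_TAGS:
            raise ValueError(f"unknown tag {tag!r} at index {i}")
        if tag.startswith("I-"):
            if open_type != tag[2:]:
                raise ValueError(f"ill-formed BIO sequence: {tag} at index {i}")
            continue
        if open_type is not None:
            spans.append((open_type, start, i))
            open_type = None
        if tag.startswith("B-"):
            open_type, start = tag[2:], i
    if open_type is not None:
        spans.append((open_type, start, len(tags)))
    return spans


@dataclass
class CandidatePair:
    """One candidate evidence sentence pair for a (gene, chemical, disease).

    ``relation_sentence``/``context_sentence`` are tagged token lists; for
    single-sentence triplets they are equal token-for-token.  ``anchor_relation``
    / ``anchor_context`` are sentence-local token indices of the alignment
    anchors (first token of the anchor mentions).
    """

    doc_id: str
    relation_sentence: list[Token]
    context_sentence: list[Token]
    gene_mention: EntityMention
    chemical_mention: EntityMention
    disease_mention: EntityMention
    configuration: str
    anchor_relation: int
    anchor_context: int
    relation_sentence_index: int
    context_sentence_index: int
    relation_text: str = ""
    context_text: str = ""
    relation_mentions: list[EntityMention] = field(default_factory=list)
    context_mentions: list[EntityMention] = field(default_factory=list)
    type_conflict: bool = False
    label: str | None = None
    score: float | None = None

    @property
    def key(self) -> tuple:
        """Deduplication/gold-matching key: document + the three mention spans."""
        return (
            self.doc_id,
            self.relation_sentence_index,
            (self.gene_mention.start, self.gene_mention.end),
            (self.chemical_mention.start, self.chemical_mention.end),
            (self.disease_mention.start, self.disease_mention.end),
        )

    @property
    def triplet_ids(self) -> tuple[str, str, str]:
        return (
            self.gene_mention.norm_id,
            self.chemical_mention.norm_id,
            self.disease_mention.norm_id,
        )


def _mention_first_token(tokens: Sequence[Token], mention: EntityMention) -> int:
    for t in tokens:
        if t.start < mention.end and t.end > mention.start:
            return t.index
    raise ValueError(f"mention {mention.surface!r} overlaps no token")


def _has_type_conflict(mentions: Sequence[EntityMention]) -> bool:
    for i, a in enumerate(mentions):
        for b in mentions[i + 1 :]:
            if a.etype != b.etype and a.start < b.end and b.start < a.end:
                return True
    return False


def extract_candidate_pairs(
    doc: AnnotatedDocument,
    configuration: str = "gene_chemical+disease",
    max_sentence_distance: int | None = None,
) -> list[CandidatePair]:
    """Enumerate candidate pairs of *doc* under a triplet configuration.

    For the default configuration: every (gene, chemical) mention pair
    co-occurring in a sentence is crossed with every disease mention in a
    sentence at most *max_sentence_distance* away (``None`` = anywhere in the
    abstract, either side).  Duplicates on (relation sentence, gene mention,
    chemical mention, disease mention) are emitted once, in document order.
    """
    configuration = CONFIGURATION_ALIASES.get(configuration, configuration)
    if configuration not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {configuration!r}")
    (type_a, type_b), ctx_type = CONFIGURATIONS[configuration]
    if not doc.sentences:
        raise ValueError(f"{doc.doc_id}: document is not sentence-segmented")

    n_sent = len(doc.sentences)
    by_sentence: list[list[EntityMention]] = [[] for _ in range(n_sent)]
    for m in doc.mentions:
        by_sentence[doc.sentence_index_of(m)].append(m)

    tagged: dict[int, list[Token]] = {}

    def sent_tokens(i: int) -> list[Token]:
        if i not in tagged:
            s, _ = doc.sentences[i]
            toks = tokenize(doc.sentence_text(i), offset=s)
            tagged[i] = bio_tag(toks, by_sentence[i])
        return tagged[i]

    pairs: list[CandidatePair] = []
    seen: set[tuple] = set()
    for i in range(n_sent):
        a_mentions = [m for m in by_sentence[i] if m.etype == type_a]
        b_mentions = [m for m in by_sentence[i] if m.etype == type_b]
        if not a_mentions or not b_mentions:
            continue
        for j in range(n_sent):
            if max_sentence_distance is not None and abs(i - j) > max_sentence_distance:
                continue
            ctx_mentions = [m for m in by_sentence[j] if m.etype == ctx_type]
            if not ctx_mentions:
                continue
            for a in a_mentions:
                for b in b_mentions:
                    if (a.start, a.end) == (b.start, b.end):
                        continue  # one span annotated as both types: no pair
                    for c in ctx_mentions:
                        roles = {type_a: a, type_b: b, ctx_type: c}
                        pair = CandidatePair(
                            doc_id=doc.doc_id,
                            relation_sentence=sent_tokens(i),
                            context_sentence=sent_tokens(j),
                            gene_mention=roles["gene"],
                            chemical_mention=roles["chemical"],
                            disease_mention=roles["disease"],
                            configuration=configuration,
                            anchor_relation=_mention_first_token(sent_tokens(i), a),
                            anchor_context=_mention_first_token(sent_tokens(j), c),
                            relation_sentence_index=i,
                            context_sentence_index=j,
                            relation_text=doc.sentence_text(i),
                            context_text=doc.sentence_text(j),
                            relation_mentions=list(by_sentence[i]),
                            context_mentions=list(by_sentence[j]),
                            type_conflict=_has_type_conflict(by_sentence[i])
                            or _has_type_conflict(by_sentence[j]),
                        )
                        if pair.key in seen:
                            continue
                        seen.add(pair.key)
                        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# JSON-lines serialization (shared with corpus_io)
# ---------------------------------------------------------------------------


def _token_to_list(t: Token) -> list:
    return [t.text, t.start, t.end, t.bio_tag]


def _mention_to_dict(m: EntityMention) -> dict:
    return {
        "doc_id": m.doc_id, "start": m.start, "end": m.end,
        "surface": m.surface, "etype": m.etype, "norm_id": m.norm_id,
        "source_tool": m.source_tool,
    }


def pair_to_dict(p: CandidatePair) -> dict:
    return {
        "doc_id": p.doc_id,
        "configuration": p.configuration,
        "relation_sentence_index": p.relation_sentence_index,
        "context_sentence_index": p.context_sentence_index,
        "relation_tokens": [_token_to_list(t) for t in p.relation_sentence],
        "context_tokens": [_token_to_list(t) for t in p.context_sentence],
        "gene_mention": _mention_to_dict(p.gene_mention),
        "chemical_mention": _mention_to_dict(p.chemical_mention),
        "disease_mention": _mention_to_dict(p.disease_mention),
        "anchor_relation": p.anchor_relation,
        "anchor_context": p.anchor_context,
        "relation_text": p.relation_text,
        "context_text": p.context_text,
        "relation_mentions": [_mention_to_dict(m) for m in p.relation_mentions],
        "context_mentions": [_mention_to_dict(m) for m in p.context_mentions],
        "type_conflict": p.type_conflict,
        "label": p.label,
        "score": p.score,
    }


def pair_from_dict(d: dict) -> CandidatePair:
    def toks(rows):
        return [Token(r[0], i, r[1], r[2], r[3]) for i, r in enumerate(rows)]

    def ment(md):
        return EntityMention(**md)

    return CandidatePair(
        doc_id=d["doc_id"],
        relation_sentence=toks(d["relation_tokens"]),
        context_sentence=toks(d["context_tokens"]),
        gene_mention=ment(d["gene_mention"]),
        chemical_mention=ment(d["chemical_mention"]),
        disease_mention=ment(d["disease_mention"]),
        configuration=d["configuration"],
        anchor_relation=d["anchor_relation"],
        anchor_context=d["anchor_context"],
        relation_sentence_index=d["relation_sentence_index"],
        context_sentence_index=d["context_sentence_index"],
        relation_text=d["relation_text"],
        context_text=d["context_text"],
        relation_mentions=[ment(m) for m in d["relation_mentions"]],
        context_mentions=[ment(m) for m in d["context_mentions"]],
        type_conflict=d["type_conflict"],
        label=d["label"],
        score=d["score"],
    )
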