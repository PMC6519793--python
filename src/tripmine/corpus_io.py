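"""Reading and writing entity-annotated abstracts in PubTator format.

The PubTator exchange format is plain text: each document block starts with a
title line ``PMID|t|...`` and an abstract line ``PMID|a|...``, followed by one
tab-separated annotation line per entity mention::

    PMID<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>normalized-id

Blocks are separated by blank lines.  Character offsets index into the
concatenation ``title + " " + abstract`` (the format's own convention) and are
0-based, half-open.  Only gene, chemical and disease annotations are consumed;
other annotation types carried by PubTator streams (Species, Mutation, ...)
are dropped.

This module also owns sentence segmentation (a deterministic, dependency-free
splitter) and the serialization of pipeline outputs (triplet TSV files and
candidate-pair JSON lines).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: The three entity types this pipeline consumes.
ENTITY_TYPES = ("gene", "chemical", "disease")

#: Annotation-type spellings mapped (case-insensitively) onto ENTITY_TYPES.
_TYPE_MAP = {
    "gene": "gene",
    "chemical": "chemical",
    "disease": "disease",
}


@dataclass(frozen=True)
class EntityMention:
    """One entity mention inside a document.

    ``start``/``end`` are 0-based half-open character offsets into the
    document text (``title + " " + abstract``).  ``norm_id`` is the
    normalized concept identifier (Entrez, MeSH/ChEBI, MEDIC, or a synthetic
    namespace); ``"-"`` marks an unnormalized mention.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    etype: str
    norm_id: str = "-"
    source_tool: str = ""

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad mention span [{self.start}, {self.end})")

    @property
    def normalized(self) -> bool:
        return self.norm_id not in ("", "-")


@dataclass
class AnnotatedDocument:
    """One abstract with its entity mentions and (optional) sentence spans.

    ``sentences`` holds ordered, non-overlapping ``(start, end)`` character
    spans over :attr:`text`; it is empty until :func:`split_sentences` runs.
    """

    doc_id: str
    title: str
    abstract: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        if self.abstract:
            return self.title + " " + self.abstract
        return self.title

    def sentence_text(self, index: int) -> str:
        s, e = self.sentences[index]
        return self.text[s:e]

    def sentence_index_of(self, mention: EntityMention) -> int:
        """Index of the sentence span containing *mention* (exactly one)."""
        for i, (s, e) in enumerate(self.sentences):
            if s <= mention.start and mention.end <= e:
                return i
        raise ValueError(
            f"mention {mention.surface!r} [{mention.start},{mention.end}) "
            f"of {self.doc_id} lies in no sentence span"
        )

    def validate(self) -> None:
        """Assert the structural invariants (offsets, slices, coverage)."""
        text = self.text
        for m in self.mentions:
            if m.end > len(text):
                raise ValueError(f"{self.doc_id}: mention ends past text")
            if text[m.start : m.end] != m.surface:
                raise ValueError(
                    f"{self.doc_id}: surface {m.surface!r} != slice "
                    f"{text[m.start:m.end]!r}"
                )
        prev_end = -1
        for s, e in self.sentences:
            if not (prev_end < s <= e <= len(text)):
                raise ValueError(f"{self.doc_id}: bad sentence span ({s},{e})")
            prev_end = e
        if self.sentences:
            for m in self.mentions:
                self.sentence_index_of(m)


@dataclass(frozen=True)
class TripletRecord:
    """A scored (gene, chemical, disease) triplet with its evidence location."""

    gene_id: str
    chemical_id: str
    disease_id: str
    score: float
    doc_id: str
    relation_sentence_index: int
    context_sentence_index: int

    def __post_init__(self) -> None:
        if not (self.gene_id and self.chemical_id and self.disease_id):
            raise ValueError("all three identifiers must be non-empty")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class ParseReport:
    """Per-parse bookkeeping of recoverable problems."""

    skipped_mentions: int = 0
    dropped_annotations: int = 0
    rejected_blocks: int = 0


# ---------------------------------------------------------------------------
# PubTator parsing / writing
# ---------------------------------------------------------------------------


def _iter_blocks(lines: Iterable[str]) -> Iterator[list[str]]:
    block: list[str] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            if block:
                yield block
                block = []
        else:
            block.append(line)
    if block:
        yield block


def parse_pubtator(
    stream: str | IO[str], report: ParseReport | None = None
) -> list[AnnotatedDocument]:
    """Parse a PubTator stream into :class:`AnnotatedDocument` objects.

    *stream* may be a string or a text file object.  Annotation lines whose
    type is not gene/chemical/disease are dropped; lines whose surface string
    does not equal the offset slice are skipped; blocks without a title line
    are rejected.  All three events are counted in *report* (if given) and
    logged as warnings.
    """
    if report is None:
        report = ParseReport()
    if not isinstance(stream, str):
        stream = stream.read()

    docs: list[AnnotatedDocument] = []
    for block in _iter_blocks(stream.splitlines()):
        title: str | None = None
        abstract = ""
        doc_id = ""
        ann_lines: list[str] = []
        for line in block:
            parts = line.split("|", 2)
            if len(parts) == 3 and parts[1] == "t":
                doc_id, title = parts[0], parts[2]
            elif len(parts) == 3 and parts[1] == "a":
                abstract = parts[2]
            else:
                ann_lines.append(line)
        if title is None or not doc_id:
            report.rejected_blocks += 1
            logger.warning("rejecting block without title line: %r...", block[0][:60])
            continue

        doc = AnnotatedDocument(doc_id=doc_id, title=title, abstract=abstract)
        text = doc.text
        for line in ann_lines:
            fields = line.split("\t")
            if len(fields) < 5:
                report.skipped_mentions += 1
                logger.warning("%s: malformed annotation line %r", doc_id, line)
                continue
            _, start_s, end_s, surface, rawtype = fields[:5]
            norm_id = fields[5] if len(fields) > 5 and fields[5] else "-"
            source = fields[6] if len(fields) > 6 else ""
            etype = _TYPE_MAP.get(rawtype.strip().lower())
            if etype is None:
                report.dropped_annotations += 1
                logger.warning("%s: dropping annotation of type %r", doc_id, rawtype)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                report.skipped_mentions += 1
                logger.warning("%s: non-integer offsets in %r", doc_id, line)
                continue
            if not (0 <= start < end <= len(text)) or text[start:end] != surface:
                report.skipped_mentions += 1
                logger.warning(
                    "%s: surface %r does not match slice %r",
                    doc_id,
                    surface,
                    text[start:end] if end <= len(text) else "<out of range>",
                )
                continue
            doc.mentions.append(
                EntityMention(doc_id, start, end, surface, etype, norm_id, source)
            )
        docs.append(doc)
    return docs


def write_pubtator(docs: Iterable[AnnotatedDocument], stream: IO[str] | None = None) -> str:
    """Serialize documents back to PubTator format (inverse of the parser)."""
    chunks: list[str] = []
    for doc in docs:
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for m in doc.mentions:
            # type written capitalized, as PubTator itself prints it
            lines.append(
                "\t".join(
                    [doc.doc_id, str(m.start), str(m.end), m.surface,
                     m.etype.capitalize(), m.norm_id]
                )
            )
        chunks.append("\n".join(lines))
    out = "\n\n".join(chunks) + ("\n" if chunks else "")
    if stream is not None:
        stream.write(out)
    return out


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# Tokens that end with a period without ending a sentence.
_ABBREVIATIONS = frozenset(
    "fig figs et al e.g i.e vs cf ca approx etc dr mr mrs ms prof inc ltd st no".split()
)

_BOUNDARY_RE = re.compile(r"[.!?]+[)\]\"']*(\s+)")
_PRECEDING_WORD_RE = re.compile(r"([A-Za-z][A-Za-z.]*)$")


def _segment(text: str, offset: int) -> list[tuple[int, int]]:
    """Deterministic sentence spans for *text*, shifted by *offset*."""
    if not text.strip():
        return []
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.start(1)  # sentence ends where trailing whitespace starts
        prefix = text[: m.start()]
        w = _PRECEDING_WORD_RE.search(prefix)
        if w:
            word = w.group(1).rstrip(".").lower()
            # abbreviation ("Fig.", "et al.") or initial ("J. Smith")
            if word in _ABBREVIATIONS or (len(word) == 1 and text[m.start()] == "."):
                continue
        rest = text[m.end() :]
        if rest and rest[0].islower():
            continue  # sentences do not start lower-case
        boundaries.append((end, m.end()))
    spans: list[tuple[int, int]] = []
    cursor = 0
    for end, nxt in boundaries:
        spans.append((cursor, end))
        cursor = nxt
    spans.append((cursor, len(text)))
    out = []
    for s, e in spans:
        # trim surrounding whitespace so spans stay tight
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            out.append((s + offset, e + offset))
    return out


def split_sentences(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Populate sentence spans on a copy of *doc*.

    The title is always its own sentence.  After segmentation, any mention
    crossing a candidate boundary causes the flanking spans to be merged until
    every mention lies inside exactly one span.
    """
    spans = _segment(doc.title, 0)
    if doc.abstract:
        spans += _segment(doc.abstract, len(doc.title) + 1)
    if not spans:
        spans = [(0, max(len(doc.text), 1))]

    # merge spans until no mention crosses a boundary
    changed = True
    while changed:
        changed = False
        for m in doc.mentions:
            first = last = None
            for i, (s, e) in enumerate(spans):
                if s <= m.start <= e and first is None:
                    first = i
                if s <= m.end - 1 < e or (s <= m.end <= e):
                    last = i
            if first is None or last is None:
                # mention sits in trimmed whitespace or spans everything: take
                # the spans it overlaps
                first = next(i for i, (s, e) in enumerate(spans) if e > m.start)
                last = next(
                    i for i, (s, e) in reversed(list(enumerate(spans))) if s < m.end
                )
            if first != last:
                merged = (spans[first][0], spans[last][1])
                spans = spans[:first] + [merged] + spans[last + 1 :]
                changed = True
                break

    out = dataclasses.replace(doc, sentences=spans)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Pipeline output serialization
# ---------------------------------------------------------------------------

_TRIPLET_HEADER = ["gene_id", "chemical_id", "disease_id", "score", "doc_id",
                   "rel_sent", "ctx_sent"]


def write_triplets(records: Iterable[TripletRecord], destination: str | IO[str]) -> int:
    """Write triplet records as TSV (scores with 4 decimals); returns row count."""
    rows = 0
    own = isinstance(destination, str)
    fh = open(destination, "w") if own else destination
    try:
        fh.write("\t".join(_TRIPLET_HEADER) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.chemical_id}\t{r.disease_id}\t{r.score:.4f}\t"
                f"{r.doc_id}\t{r.relation_sentence_index}\t{r.context_sentence_index}\n"
            )
            rows += 1
    finally:
        if own:
            fh.close()
    return rows


def read_triplets(source: str | IO[str]) -> list[TripletRecord]:
    """Read a triplet TSV written by :func:`write_triplets`."""
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRIPLET_HEADER:
            raise ValueError(f"unexpected triplet header {header}")
        out = []
        for line in fh:
            g, c, d, score, doc_id, rel, ctx = line.rstrip("\n").split("\t")
            out.append(
                TripletRecord(g, c, d, float(score), doc_id, int(rel), int(ctx))
            )
        return out
    finally:
        if own:
            fh.close()


def write_pairs_jsonl(pairs: Iterable, destination: str | IO[str]) -> int:
    """Dump candidate pairs as JSON lines (one object per pair)."""
    from .pair_builder import pair_to_dict  # local import: avoids cycle

    rows = 0
    own = isinstance(destination, str)
    fh = open(destination, "w") if own else destination
    try:
        for p in pairs:
            fh.write(json.dumps(pair_to_dict(p), sort_keys=True) + "\n")
            rows += 1
    finally:
        if own:
            fh.close()
    return rows


def read_pairs_jsonl(source: str | IO[str]) -> list:
    from .pair_builder import pair_from_dict

    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        return [pair_from_dict(json.loads(line)) for line in fh if line.strip()]
    finally:
        if own:
            fh.close()
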