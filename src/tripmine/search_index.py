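"""Inverted index and ranked retrieval over positive evidence pairs.

Each stored evidence pair carries a normalized (gene, chemical, disease) ID
triple, the classifier's positive-class score and the two sentence texts, so
searching never needs corpus access.  One posting map per entity type sends a
normalized ID to the pair identifiers mentioning it.

Query semantics: conjunction across the three fields, disjunction within a
field; an empty field is unconstrained (a disease-only query returns every
gene and chemical related to that disease).  Name terms are resolved to IDs
through the synonym dictionaries (case-insensitive exact match; a synonym
shared by several IDs expands to all of them).  Results are sorted by score
descending, ties broken by (doc_id, relation sentence index) ascending, and
truncated to the query limit.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from .corpus_io import TripletRecord
from .pair_builder import CandidatePair

logger = logging.getLogger(__name__)

_FIELDS = ("gene", "chemical", "disease")


@dataclass(frozen=True)
class EvidenceEntry:
    """One indexed evidence pair: the triplet plus its sentence texts."""

    triplet: TripletRecord
    relation_text: str
    context_text: str


@dataclass
class Query:
    """Search terms (IDs or names) per field; at least one field non-empty."""

    genes: list[str] = field(default_factory=list)
    chemicals: list[str] = field(default_factory=list)
    diseases: list[str] = field(default_factory=list)
    limit: int | None = None

    def field_terms(self) -> dict[str, list[str]]:
        return {"gene": self.genes, "chemical": self.chemicals,
                "disease": self.diseases}


@dataclass
class InvertedIndex:
    postings: dict[str, dict[str, set[int]]] = field(
        default_factory=lambda: {f: {} for f in _FIELDS}
    )
    evidence: dict[int, EvidenceEntry] = field(default_factory=dict)
    skipped: int = 0

    def add(self, entry: EvidenceEntry) -> int:
        pair_id = len(self.evidence)
        self.evidence[pair_id] = entry
        t = entry.triplet
        for etype, nid in (("gene", t.gene_id), ("chemical", t.chemical_id),
                           ("disease", t.disease_id)):
            self.postings[etype].setdefault(nid, set()).add(pair_id)
        return pair_id

    def validate(self) -> None:
        for etype, post in self.postings.items():
            for nid, ids in post.items():
                for pid in ids:
                    if pid not in self.evidence:
                        raise ValueError(f"dangling pair id {pid} under {nid}")
        for pid, entry in self.evidence.items():
            t = entry.triplet
            for etype, nid in (("gene", t.gene_id), ("chemical", t.chemical_id),
                               ("disease", t.disease_id)):
                if pid not in self.postings[etype].get(nid, set()):
                    raise ValueError(f"pair {pid} missing from posting {nid}")


def entry_from_pair(pair: CandidatePair) -> EvidenceEntry | None:
    """Turn a scored predicted-positive candidate pair into an index entry."""
    g, c, d = pair.triplet_ids
    if pair.score is None:
        raise ValueError(f"pair {pair.key} carries no score")
    if any(x in ("", "-") for x in (g, c, d)):
        return None
    return EvidenceEntry(
        TripletRecord(g, c, d, pair.score, pair.doc_id,
                      pair.relation_sentence_index, pair.context_sentence_index),
        pair.relation_text,
        pair.context_text,
    )


def build_index(entries) -> InvertedIndex:
    """Build an index from EvidenceEntry or scored CandidatePair objects.

    Pairs missing any of the three normalized IDs are skipped (counted and
    logged).  Idempotent: rebuilding from the same input yields an equivalent
    index.
    """
    index = InvertedIndex()
    for item in entries:
        entry = entry_from_pair(item) if isinstance(item, CandidatePair) else item
        if entry is None:
            index.skipped += 1
            continue
        index.add(entry)
    if index.skipped:
        logger.warning("skipped %d pairs lacking normalized IDs", index.skipped)
    index.validate()
    return index


def expand_terms(
    terms, dictionaries: dict[str, dict[str, list[str]]], etype: str
) -> set[str]:
    """Resolve query terms to normalized IDs.

    A term that is already a known ID of *etype* maps to itself; otherwise it
    is matched case-insensitively against synonym strings, collecting every ID
    sharing that synonym.  Unknown terms resolve to nothing (warning logged).
    """
    known = dictionaries.get(etype, {})
    folded: dict[str, set[str]] = {}
    for nid, syns in known.items():
        for s in syns:
            folded.setdefault(s.casefold(), set()).add(nid)
    out: set[str] = set()
    for term in terms:
        if term in known:
            out.add(term)
            continue
        hits = folded.get(term.casefold())
        if hits:
            out |= hits
        else:
            logger.warning("query term %r matches no %s identifier", term, etype)
    return out


def search(
    index: InvertedIndex,
    query: Query,
    dictionaries: dict[str, dict[str, list[str]]] | None = None,
) -> list[tuple[TripletRecord, tuple[str, str], float]]:
    """Ranked retrieval: list of (triplet, (relation, context) sentences, score)."""
    terms = query.field_terms()
    if not any(terms.values()):
        raise ValueError("query must constrain at least one field")
    result_ids: set[int] | None = None
    for etype, ts in terms.items():
        if not ts:
            continue
        if dictionaries is not None:
            # names resolve through the dictionaries; bare identifiers that
            # exist in the index are honored either way
            ids = expand_terms(ts, dictionaries, etype)
            ids |= {t for t in ts if t in index.postings[etype]}
        else:
            ids = set(ts)
        matched: set[int] = set()
        for nid in ids:
            matched |= index.postings[etype].get(nid, set())
        result_ids = matched if result_ids is None else (result_ids & matched)
    assert result_ids is not None
    ranked = sorted(
        result_ids,
        key=lambda pid: (
            -index.evidence[pid].triplet.score,
            index.evidence[pid].triplet.doc_id,
            index.evidence[pid].triplet.relation_sentence_index,
        ),
    )
    if query.limit is not None:
        ranked = ranked[: query.limit]
    return [
        (index.evidence[pid].triplet,
         (index.evidence[pid].relation_text, index.evidence[pid].context_text),
         index.evidence[pid].triplet.score)
        for pid in ranked
    ]


def group_by_triplet(results) -> list[tuple[tuple[str, str, str], float, int]]:
    """Collapse ranked results to unique triplets with their best score/count."""
    best: dict[tuple[str, str, str], tuple[float, int]] = {}
    for record, _sentences, score in results:
        key = (record.gene_id, record.chemical_id, record.disease_id)
        prev = best.get(key)
        if prev is None:
            best[key] = (score, 1)
        else:
            best[key] = (max(prev[0], score), prev[1] + 1)
    return sorted(
        ((k, s, n) for k, (s, n) in best.items()),
        key=lambda row: (-row[1], row[0]),
    )


# ---------------------------------------------------------------------------
# Persistence: one directory, line-oriented files
# ---------------------------------------------------------------------------


def save_index(index: InvertedIndex, directory: str) -> None:
    """Persist to ``postings-<etype>.tsv`` files plus ``evidence.jsonl``."""
    os.makedirs(directory, exist_ok=True)
    for etype in _FIELDS:
        with open(os.path.join(directory, f"postings-{etype}.tsv"), "w") as fh:
            for nid in sorted(index.postings[etype]):
                ids = ",".join(map(str, sorted(index.postings[etype][nid])))
                fh.write(f"{nid}\t{ids}\n")
    with open(os.path.join(directory, "evidence.jsonl"), "w") as fh:
        for pid in sorted(index.evidence):
            e = index.evidence[pid]
            t = e.triplet
            fh.write(json.dumps({
                "id": pid, "gene_id": t.gene_id, "chemical_id": t.chemical_id,
                "disease_id": t.disease_id, "score": t.score, "doc_id": t.doc_id,
                "rel_sent": t.relation_sentence_index,
                "ctx_sent": t.context_sentence_index,
                "relation_text": e.relation_text, "context_text": e.context_text,
            }, sort_keys=True) + "\n")


def load_index(directory: str) -> InvertedIndex:
    index = InvertedIndex()
    with open(os.path.join(directory, "evidence.jsonl")) as fh:
        for line in fh:
            d = json.loads(line)
            index.evidence[d["id"]] = EvidenceEntry(
                TripletRecord(d["gene_id"], d["chemical_id"], d["disease_id"],
                              d["score"], d["doc_id"], d["rel_sent"],
                              d["ctx_sent"]),
                d["relation_text"], d["context_text"],
            )
    for etype in _FIELDS:
        with open(os.path.join(directory, f"postings-{etype}.tsv")) as fh:
            for line in fh:
                nid, ids = line.rstrip("\n").split("\t")
                index.postings[etype][nid] = {int(x) for x in ids.split(",")}
    index.validate()
    return index
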