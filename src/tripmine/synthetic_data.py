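"""Seeded synthetic PubTator corpora with planted triplet patterns.

The generator emulates the construction of the gold evidence-pair corpus:
each document plants one (gene, chemical, disease) triplet realized either as
a single sentence carrying all three mentions or as a relation sentence
(gene + chemical) plus a separate disease context sentence — half and half by
default.  Positives use interaction templates ("<CHEM> increased <GENE> ...
in <DISEASE> patients"); negatives realize four patterns mirroring the false
positives the post-filters target: co-occurrence-only wording, negated
statements, study-purpose sentences, and context sentences naming an
unrelated disease.

Entity identifiers live in distinct synthetic namespaces (G#, C#, D#); every
mention surface is drawn from that entity's generated synonym list, so the
dictionaries shipped alongside the corpus are complete by construction.
Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np

from .corpus_io import AnnotatedDocument, EntityMention, parse_pubtator, split_sentences, write_pubtator
from .pair_builder import CandidatePair, extract_candidate_pairs

NEGATIVE_TYPES = ("cooccurrence", "negated", "study", "unrelated_disease")


def _load_words(name: str) -> list[str]:
    text = (
        importlib_resources.files("tripmine.resources").joinpath(name).read_text()
    )
    return [w.strip() for w in text.splitlines() if w.strip()]


@dataclass
class SimConfig:
    """Study conditions for corpus generation."""

    seed: int = 0
    n_documents: int = 200
    fraction_positive: float = 0.5
    #: fraction of triplets whose three mentions share one sentence (the gold
    #: corpus was built half from single-sentence triplets)
    fraction_single_sentence: float = 0.5
    n_genes: int = 40
    n_chemicals: int = 40
    n_diseases: int = 25
    n_filler: int = 120
    negative_mix: dict[str, float] = field(
        default_factory=lambda: {t: 0.25 for t in NEGATIVE_TYPES}
    )
    synonyms_per_entity: int = 2
    #: 0 keeps the classes lexically separable; > 0 mixes cue words across
    #: classes to stress the classifier
    hardness: float = 0.0

    def __post_init__(self) -> None:
        for frac in (self.fraction_positive, self.fraction_single_sentence,
                     self.hardness):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_genes, self.n_chemicals, self.n_diseases, self.n_filler) < 1:
            raise ValueError("vocabulary sizes must be >= 1")
        if set(self.negative_mix) - set(NEGATIVE_TYPES):
            raise ValueError(f"unknown negative types in mix: {self.negative_mix}")
        if abs(sum(self.negative_mix.values()) - 1.0) > 1e-9:
            raise ValueError("negative_mix weights must sum to 1")
        if self.synonyms_per_entity < 1:
            raise ValueError("synonyms_per_entity must be >= 1")


@dataclass(frozen=True)
class GoldRecord:
    """Bookkeeping for one planted candidate pair."""

    doc_id: str
    relation_sentence_index: int
    context_sentence_index: int
    gene_id: str
    chemical_id: str
    disease_id: str
    gene_span: tuple[int, int]
    chemical_span: tuple[int, int]
    disease_span: tuple[int, int]
    label: str
    negative_type: str | None = None

    @property
    def key(self) -> tuple:
        return (self.doc_id, self.relation_sentence_index, self.gene_span,
                self.chemical_span, self.disease_span)


# ---------------------------------------------------------------------------
# Entity name synthesis
# ---------------------------------------------------------------------------

_CONS = list("bdfglmnprstvz")
_VOWELS = list("aeiou")


def _syllables(rng: np.random.Generator, n: int) -> str:
    return "".join(
        _CONS[rng.integers(len(_CONS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n)
    )


def _make_entities(rng: np.random.Generator, config: SimConfig):
    """Generate synonym dictionaries: etype -> id -> [synonym, ...]."""
    dicts: dict[str, dict[str, list[str]]] = {"gene": {}, "chemical": {}, "disease": {}}
    seen: set[str] = set()

    def fresh(maker):
        while True:
            name = maker()
            if name.lower() not in seen:
                seen.add(name.lower())
                return name

    for i in range(config.n_genes):
        letters = "".join(
            chr(ord("A") + rng.integers(26)) for _ in range(int(rng.integers(3, 6)))
        )
        sym = fresh(lambda: letters + str(rng.integers(1, 10)))
        syns = [sym, sym + "-" + str(rng.integers(1, 5)), sym + " protein"]
        dicts["gene"][f"G{i + 1}"] = syns[: config.synonyms_per_entity]
    for i in range(config.n_chemicals):
        base = fresh(lambda: _syllables(rng, int(rng.integers(2, 4)))
                     + ["ine", "ol", "ate", "ide"][rng.integers(4)])
        syns = [base, base + " hydrochloride", "neo-" + base]
        dicts["chemical"][f"C{i + 1}"] = syns[: config.synonyms_per_entity]
    for i in range(config.n_diseases):
        base = fresh(lambda: _syllables(rng, int(rng.integers(2, 4))))
        syns = [base + " disease", base + " syndrome", base + " disorder"]
        dicts["disease"][f"D{i + 1}"] = syns[: config.synonyms_per_entity]
    return dicts


# ---------------------------------------------------------------------------
# Sentence templates
# ---------------------------------------------------------------------------

_PVERBS = ["increased", "decreased", "inhibited", "activated", "suppressed",
           "induced", "upregulated", "downregulated"]

# slots: {C} chemical, {G} gene, {D} disease, {V} interaction verb
_POS_SINGLE = [
    "{C} {V} {G} expression in {D} patients .",
    "{C} markedly {V} {G} signaling during treatment of {D} .",
    "In {D} patients , {C} {V} {G} activity .",
]
_POS_RELATION = [
    "{C} significantly {V} {G} expression in treated cells .",
    "Treatment with {C} {V} {G} levels in a dose-dependent manner .",
    "{C} {V} {G} activity through direct binding .",
]
_POS_CONTEXT = [
    "This mechanism contributes to the progression of {D} .",
    "These findings support a therapeutic role in {D} .",
    "Such changes are characteristic of {D} pathology .",
]
_NEG_TEMPLATES = {
    "cooccurrence": {
        "single": ["Both {G} and {C} were detected in samples from {D} patients ."],
        "relation": ["Both {G} and {C} were detected in serum samples .",
                     "Levels of {G} as well as {C} were recorded separately ."],
        "context": ["Samples were collected from {D} patients ."],
    },
    "negated": {
        "single": ["{C} did not alter {G} expression in {D} models ."],
        "relation": ["{C} did not alter {G} expression in any condition .",
                     "{C} never changed {G} abundance under these conditions ."],
        "context": ["The cohort included {D} patients ."],
    },
    "study": {
        "single": ["The aim of this study was to examine whether {C} modulates {G} in {D} ."],
        "relation": ["The aim of this study was to examine whether {C} modulates {G} .",
                     "This investigation was designed to compare {C} with {G} measurements ."],
        "context": ["Patients with {D} were enrolled in the survey ."],
    },
    "unrelated_disease": {
        "single": ["{C} {V} {G} in cultured cells , whereas {D} was unrelated to these measurements ."],
        "relation": ["{C} significantly {V} {G} expression in treated cells .",
                     "{C} {V} {G} activity through direct binding ."],
        "context": ["Unrelated cases of {D} were reviewed for comparison purposes ."],
    },
}

_HARD_POS_SUFFIX = "and were measured in the survey"  # negative-style cue words
_HARD_NEG_SUFFIX = "in treated patients during therapy"  # positive-style cue words


class _SentenceBuilder:
    """Accumulates document text, sentence spans and mention offsets."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.text = ""
        self.sentence_spans: list[tuple[int, int]] = []
        self.mentions: list[EntityMention] = []

    def add(self, template: str, fills: dict[str, tuple[str, str, str]]) -> int:
        """Append one sentence; fills maps slot -> (surface, etype, norm_id).

        Returns the sentence index.  The first character of the sentence is
        upper-cased (mention surfaces are adjusted accordingly).
        """
        if self.text:
            self.text += " "
        start = len(self.text)
        parts = template.split(" ")
        pieces: list[str] = []
        mention_offsets: list[tuple[int, str]] = []  # (offset in sentence, slot)
        cursor = 0
        for i, part in enumerate(parts):
            slot = part[1:-1] if part.startswith("{") and part.endswith("}") else None
            if slot in fills:
                surface = fills[slot][0]
                mention_offsets.append((cursor, slot))
                pieces.append(surface)
                cursor += len(surface)
            else:
                pieces.append(part)
                cursor += len(part)
            if i < len(parts) - 1:
                cursor += 1
        sentence = " ".join(pieces)
        sentence = sentence[0].upper() + sentence[1:]
        self.text += sentence
        end = len(self.text)
        for off, slot in mention_offsets:
            surface, etype, norm_id = fills[slot]
            realized = self.text[start + off : start + off + len(surface)]
            self.mentions.append(
                EntityMention(self.doc_id, start + off, start + off + len(surface),
                              realized, etype, norm_id)
            )
        self.sentence_spans.append((start, end))
        return len(self.sentence_spans) - 1


def generate_corpus(
    config: SimConfig,
) -> tuple[str, list[GoldRecord], dict[str, dict[str, list[str]]]]:
    """Generate (PubTator text, gold records, synonym dictionaries)."""
    rng = np.random.default_rng(config.seed)
    dicts = _make_entities(rng, config)
    fillers = _load_words("filler_words.txt")[: config.n_filler]
    gene_ids = sorted(dicts["gene"], key=lambda x: int(x[1:]))
    chem_ids = sorted(dicts["chemical"], key=lambda x: int(x[1:]))
    dis_ids = sorted(dicts["disease"], key=lambda x: int(x[1:]))

    def pick_surface(etype: str, norm_id: str) -> str:
        syns = dicts[etype][norm_id]
        return syns[int(rng.integers(len(syns)))]

    def filler_sentence() -> str:
        w = [fillers[int(rng.integers(len(fillers)))] for _ in range(4)]
        return (f"The {w[0]} {w[1]} was associated with {w[2]} {w[3]} "
                "under control conditions .")

    n_pos = int(round(config.n_documents * config.fraction_positive))
    labels = ["positive"] * n_pos + ["negative"] * (config.n_documents - n_pos)
    mix_types = sorted(config.negative_mix)
    mix_weights = np.asarray([config.negative_mix[t] for t in mix_types])

    docs_text: list[str] = []
    gold: list[GoldRecord] = []
    for d in range(config.n_documents):
        doc_id = f"SYN{d + 1:05d}"
        label = labels[d]
        b = _SentenceBuilder(doc_id)
        w1 = fillers[int(rng.integers(len(fillers)))]
        w2 = fillers[int(rng.integers(len(fillers)))]
        title_idx = b.add(f"Observations on {w1} and {w2} regulation .", {})
        title_end = len(b.text)

        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        cid = chem_ids[int(rng.integers(len(chem_ids)))]
        did = dis_ids[int(rng.integers(len(dis_ids)))]
        g = (pick_surface("gene", gid), "gene", gid)
        c = (pick_surface("chemical", cid), "chemical", cid)
        dd = (pick_surface("disease", did), "disease", did)
        verb = _PVERBS[int(rng.integers(len(_PVERBS)))]
        single = bool(rng.random() < config.fraction_single_sentence)
        neg_type = None
        if label == "negative":
            neg_type = mix_types[int(rng.choice(len(mix_types), p=mix_weights))]

        if rng.random() < 0.5:
            b.add(filler_sentence(), {})

        def fill(template: str) -> str:
            return template.replace("{V}", verb)

        hard = config.hardness > 0 and rng.random() < config.hardness
        if single:
            if label == "positive":
                tpl = _POS_SINGLE[int(rng.integers(len(_POS_SINGLE)))]
            else:
                opts = _NEG_TEMPLATES[neg_type]["single"]
                tpl = opts[int(rng.integers(len(opts)))]
            if hard:
                suffix = _HARD_POS_SUFFIX if label == "positive" else _HARD_NEG_SUFFIX
                tpl = tpl[:-1] + suffix + " ."
            rel_idx = ctx_idx = b.add(fill(tpl), {"C": c, "G": g, "D": dd})
        else:
            if label == "positive":
                rel_tpl = _POS_RELATION[int(rng.integers(len(_POS_RELATION)))]
                ctx_tpl = _POS_CONTEXT[int(rng.integers(len(_POS_CONTEXT)))]
            else:
                opts = _NEG_TEMPLATES[neg_type]
                rel_tpl = opts["relation"][int(rng.integers(len(opts["relation"])))]
                ctx_tpl = opts["context"][int(rng.integers(len(opts["context"])))]
            if hard:
                suffix = _HARD_POS_SUFFIX if label == "positive" else _HARD_NEG_SUFFIX
                rel_tpl = rel_tpl[:-1] + suffix + " ."
            context_first = bool(rng.random() < 0.5)
            if context_first:
                ctx_idx = b.add(fill(ctx_tpl), {"D": dd})
                rel_idx = b.add(fill(rel_tpl), {"C": c, "G": g})
            else:
                rel_idx = b.add(fill(rel_tpl), {"C": c, "G": g})
                ctx_idx = b.add(fill(ctx_tpl), {"D": dd})
        if rng.random() < 0.5:
            b.add(filler_sentence(), {})

        spans = {m.etype: (m.start, m.end) for m in b.mentions}
        gold.append(
            GoldRecord(doc_id, rel_idx, ctx_idx, gid, cid, did,
                       spans["gene"], spans["chemical"], spans["disease"],
                       label, neg_type)
        )
        title = b.text[:title_end]
        abstract = b.text[title_end + 1 :]
        doc = AnnotatedDocument(doc_id, title, abstract, mentions=b.mentions)
        doc.validate()
        docs_text.append(write_pubtator([doc]).rstrip("\n"))

    pubtator = "\n\n".join(docs_text) + "\n"
    return pubtator, gold, dicts


def attach_labels(pairs: list[CandidatePair], gold: list[GoldRecord]) -> int:
    """Attach gold labels to extracted candidate pairs by key; returns matches."""
    by_key = {g.key: g for g in gold}
    n = 0
    for p in pairs:
        g = by_key.get(p.key)
        if g is not None:
            p.label = g.label
            n += 1
    return n


def generate_labeled_pairs(
    config: SimConfig,
) -> tuple[list[AnnotatedDocument], list[CandidatePair], dict, list[GoldRecord]]:
    """Generate a corpus and run it through parsing, splitting and extraction.

    Returns (documents, labeled candidate pairs, dictionaries, gold records).
    Every gold record must be recovered as a candidate pair; a mismatch raises,
    as it indicates a generation or extraction defect.
    """
    text, gold, dicts = generate_corpus(config)
    docs = [split_sentences(d) for d in parse_pubtator(text)]
    pairs: list[CandidatePair] = []
    for doc in docs:
        pairs.extend(extract_candidate_pairs(doc))
    matched = attach_labels(pairs, gold)
    if matched != len(gold):
        missing = set(g.key for g in gold) - set(p.key for p in pairs)
        raise RuntimeError(f"planted pairs not recovered: {sorted(missing)[:3]}...")
    labeled = [p for p in pairs if p.label is not None]
    return docs, labeled, dicts, gold


_GOLD_HEADER = ["doc_id", "rel_sent", "ctx_sent", "gene_id", "chemical_id",
                "disease_id", "gene_span", "chemical_span", "disease_span",
                "label", "negative_type"]


def write_gold(gold: list[GoldRecord], destination) -> int:
    """Write gold records as TSV (spans as start-end); returns row count."""
    own = isinstance(destination, str)
    fh = open(destination, "w") if own else destination
    try:
        fh.write("\t".join(_GOLD_HEADER) + "\n")
        for g in gold:
            fh.write("\t".join([
                g.doc_id, str(g.relation_sentence_index),
                str(g.context_sentence_index), g.gene_id, g.chemical_id,
                g.disease_id,
                f"{g.gene_span[0]}-{g.gene_span[1]}",
                f"{g.chemical_span[0]}-{g.chemical_span[1]}",
                f"{g.disease_span[0]}-{g.disease_span[1]}",
                g.label, g.negative_type or "",
            ]) + "\n")
        return len(gold)
    finally:
        if own:
            fh.close()


def read_gold(source) -> list[GoldRecord]:
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GOLD_HEADER:
            raise ValueError(f"unexpected gold header {header}")
        out = []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            span = lambda s: tuple(int(x) for x in s.split("-"))
            out.append(GoldRecord(
                f[0], int(f[1]), int(f[2]), f[3], f[4], f[5],
                span(f[6]), span(f[7]), span(f[8]), f[9], f[10] or None,
            ))
        return out
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Annotation corruption (NER-error emulation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorruptionEntry:
    doc_id: str
    start: int
    end: int
    kind: str  # "surface" (off-dictionary) or "type_conflict"


def _shift_letters(s: str) -> str:
    out = []
    for ch in s:
        if "a" <= ch <= "z":
            out.append(chr((ord(ch) - ord("a") + 1) % 26 + ord("a")))
        elif "A" <= ch <= "Z":
            out.append(chr((ord(ch) - ord("A") + 1) % 26 + ord("A")))
        else:
            out.append(ch)
    return "".join(out)


def corrupt_annotations(
    pubtator_text: str, rate: float, seed: int
) -> tuple[str, list[CorruptionEntry]]:
    """Inject NER-style errors into a seeded fraction of mentions.

    Two error kinds, drawn evenly: ``surface`` rewrites the mention text (and
    annotation) to an off-dictionary string of the same length, the target of
    the dictionary-membership filter; ``type_conflict`` duplicates the span
    under a different entity type, the target of the multi-type filter.
    Returns the corrupted corpus and the manifest of injected errors.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    docs = parse_pubtator(pubtator_text)
    manifest: list[CorruptionEntry] = []
    other_type = {"gene": "chemical", "chemical": "disease", "disease": "gene"}
    out_docs = []
    for doc in docs:
        text = doc.text
        new_mentions: list[EntityMention] = []
        extra: list[EntityMention] = []
        for m in doc.mentions:
            if rng.random() >= rate:
                new_mentions.append(m)
                continue
            if rng.random() < 0.5:
                scrambled = _shift_letters(m.surface)
                text = text[: m.start] + scrambled + text[m.end :]
                new_mentions.append(dataclasses.replace(m, surface=scrambled))
                manifest.append(CorruptionEntry(doc.doc_id, m.start, m.end, "surface"))
            else:
                new_mentions.append(m)
                extra.append(
                    dataclasses.replace(m, etype=other_type[m.etype], norm_id="-")
                )
                manifest.append(
                    CorruptionEntry(doc.doc_id, m.start, m.end, "type_conflict")
                )
        title = text[: len(doc.title)]
        abstract = text[len(doc.title) + 1 :] if doc.abstract else ""
        out_docs.append(
            AnnotatedDocument(doc.doc_id, title, abstract,
                              mentions=new_mentions + extra)
        )
    return write_pubtator(out_docs), manifest
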