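"""Fixed-shape 2-D feature encodings of candidate sentence pairs.

Each token is represented by the concatenation of a word vector (200-d by
default, optionally pre-trained) and an entity-type vector for its BIO tag
(20-d, randomly initialized), giving a 220-d per-token embedding.

A candidate pair is encoded as a 2-D array.  Under the *parallel* strategies
the two sentences are stacked as two row blocks (rows = 2 x per-token
dimension) and column-shifted so that the two anchor tokens — by default the
gene mention in the relation sentence and the disease mention in the context
sentence — occupy the same column; shorter sides are left-padded for the
alignment and both sides right-padded to a common length.  Under the
*sequential* strategy the context sentence is appended after the relation
sentence (single row block) with one padding column between.  Padding cells
are exactly zero and mask-false; recurrent layers carry state through masked
columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

from .pair_builder import BIO_TAGS, CandidatePair, Token

#: Row index of padding cells in the tag table (one past the 7 real tags).
TAG_PAD_INDEX = len(BIO_TAGS)

#: Index of each BIO tag in the tag-vector table.
TAG_INDEX = {tag: i for i, tag in enumerate(BIO_TAGS)}

STRATEGIES = (
    "parallel_gene_disease",
    "parallel_first",
    "parallel_chem_disease",
    "sequential",
)

_PAD_ROW = 0
_UNK_ROW = 1


@dataclass
class EmbeddingTable:
    """Word-vector + entity-type-vector lookup tables.

    Row 0 of ``word_vectors`` is the all-zero padding row, row 1 the shared
    unknown-word row; real vocabulary starts at row 2.  ``tag_vectors`` has
    exactly 7 rows (one per BIO tag); a constant zero row for padding cells is
    appended on the fly by :meth:`tag_matrix`.
    """

    vocabulary: dict[str, int]
    word_vectors: np.ndarray
    tag_vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.tag_vectors.shape[0] != len(BIO_TAGS):
            raise ValueError("tag table must have exactly 7 rows")
        if not np.all(self.word_vectors[_PAD_ROW] == 0):
            raise ValueError("padding row must be exactly zero")

    @property
    def d_word(self) -> int:
        return self.word_vectors.shape[1]

    @property
    def d_ent(self) -> int:
        return self.tag_vectors.shape[1]

    @property
    def dim(self) -> int:
        """Per-token embedding dimension (word + entity-type)."""
        return self.d_word + self.d_ent

    def word_index(self, token: str) -> int:
        return self.vocabulary.get(token.lower(), _UNK_ROW)

    def tag_matrix(self) -> np.ndarray:
        """Tag table with the zero padding row appended (8 x d_ent)."""
        pad = np.zeros((1, self.d_ent), dtype=self.tag_vectors.dtype)
        return np.concatenate([self.tag_vectors, pad], axis=0)

    def embed(self, token: str | None, tag: str | None) -> np.ndarray:
        """Embedding of one token: word vector ++ tag vector.

        ``token=None`` (padding pseudo-token) yields the all-zero vector.
        """
        if token is None:
            return np.zeros(self.dim, dtype=self.word_vectors.dtype)
        if tag not in TAG_INDEX:
            raise ValueError(f"unknown BIO tag {tag!r}")
        return np.concatenate(
            [self.word_vectors[self.word_index(token)],
             self.tag_vectors[TAG_INDEX[tag]]]
        )

    def fingerprint(self) -> str:
        """Stable digest of shapes, vocabulary and parameters."""
        h = hashlib.sha256()
        h.update(json.dumps(sorted(self.vocabulary.items())).encode())
        h.update(np.ascontiguousarray(self.word_vectors, dtype=np.float32).tobytes())
        h.update(np.ascontiguousarray(self.tag_vectors, dtype=np.float32).tobytes())
        return h.hexdigest()


def load_pretrained_vectors(source: str | IO[str]) -> dict[str, np.ndarray]:
    """Read a plain-text embedding file: ``token v1 v2 ... vd`` per line."""
    own = isinstance(source, str)
    fh = open(source) if own else source
    try:
        vectors: dict[str, np.ndarray] = {}
        width: int | None = None
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float32)
            if width is None:
                width = vec.size
            elif vec.size != width:
                raise ValueError(
                    f"inconsistent vector length at line {lineno}: "
                    f"{vec.size} != {width}"
                )
            vectors[parts[0].lower()] = vec
        return vectors
    finally:
        if own:
            fh.close()


def build_table(
    corpus_tokens: Iterable[str],
    pretrained_vectors: dict[str, np.ndarray] | None = None,
    d_word: int = 200,
    d_ent: int = 20,
    seed: int = 0,
) -> EmbeddingTable:
    """Build an embedding table over the corpus vocabulary.

    Tokens present in *pretrained_vectors* use those rows; all other word
    rows (and the unknown row) are drawn from a seeded uniform(-0.05, 0.05),
    as are the 7 tag rows.  Reproducible bit-for-bit given the seed.
    """
    if d_word < 1 or d_ent < 1:
        raise ValueError("d_word and d_ent must be >= 1")
    vocab_tokens = sorted({t.lower() for t in corpus_tokens})
    vocabulary = {t: i + 2 for i, t in enumerate(vocab_tokens)}
    rng = np.random.default_rng(seed)
    word = rng.uniform(-0.05, 0.05, size=(len(vocab_tokens) + 2, d_word))
    word = word.astype(np.float32)
    word[_PAD_ROW] = 0.0
    if pretrained_vectors:
        width = next(iter(pretrained_vectors.values())).size
        if width != d_word:
            raise ValueError(f"pretrained vectors are {width}-d, expected {d_word}")
        for tok, row in vocabulary.items():
            vec = pretrained_vectors.get(tok)
            if vec is not None:
                word[row] = vec
    tags = rng.uniform(-0.05, 0.05, size=(len(BIO_TAGS), d_ent)).astype(np.float32)
    return EmbeddingTable(vocabulary, word, tags)


# ---------------------------------------------------------------------------
# Pair encoding
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Dense encoding of one candidate pair.

    ``values`` is (2d x L) for parallel strategies (relation block on rows
    0..d-1, context block on rows d..2d-1) and (d x L) for sequential.
    ``mask`` is boolean (blocks x L): True where a real token sits.
    """

    values: np.ndarray
    mask: np.ndarray
    strategy: str
    anchor_column: int | None = None


@dataclass
class IndexedPair:
    """Index-level encoding (used for training so embeddings stay trainable).

    Shapes are (blocks x L): ``word_idx`` rows into the word table (0 = pad),
    ``tag_idx`` rows into the padded tag table (7 = pad).
    """

    word_idx: np.ndarray
    tag_idx: np.ndarray
    mask: np.ndarray
    strategy: str
    anchor_column: int | None = None


def _mention_token_index(tokens: Sequence[Token], mention) -> int | None:
    for t in tokens:
        if t.start < mention.end and t.end > mention.start:
            return t.index
    return None


def _strategy_anchors(pair: CandidatePair, strategy: str) -> tuple[int, int]:
    if strategy == "parallel_gene_disease":
        return pair.anchor_relation, pair.anchor_context
    if strategy == "parallel_first":
        return 0, 0
    if strategy == "parallel_chem_disease":
        a = _mention_token_index(pair.relation_sentence, pair.chemical_mention)
        c = _mention_token_index(pair.context_sentence, pair.disease_mention)
        if a is None or c is None:
            raise ValueError(
                "parallel_chem_disease needs a chemical mention in the relation "
                "sentence and a disease mention in the context sentence"
            )
        return a, c
    raise ValueError(f"unknown strategy {strategy!r}")


def _truncate(tokens: Sequence[Token], pair: CandidatePair, anchor: int,
              max_tokens: int) -> list[Token]:
    if len(tokens) <= max_tokens:
        return list(tokens)
    keep = anchor + 1
    for m in (pair.gene_mention, pair.chemical_mention, pair.disease_mention):
        idx = _mention_token_index(tokens, m)
        if idx is not None:
            keep = max(keep, idx + 1)
    return list(tokens[: max(max_tokens, keep)])


def _indices(tokens: Sequence[Token], table: EmbeddingTable) -> tuple[list, list]:
    widx = [table.word_index(t.text) for t in tokens]
    tidx = [TAG_INDEX[t.bio_tag] for t in tokens]
    return widx, tidx


def encode_pair_indices(
    pair: CandidatePair,
    table: EmbeddingTable,
    strategy: str = "parallel_gene_disease",
    max_tokens: int = 128,
) -> IndexedPair:
    """Encode a pair as aligned index arrays (see :func:`encode_pair`)."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "sequential":
        rel = _truncate(pair.relation_sentence, pair, pair.anchor_relation, max_tokens)
        ctx = _truncate(pair.context_sentence, pair, pair.anchor_context, max_tokens)
        rw, rt = _indices(rel, table)
        cw, ct = _indices(ctx, table)
        word = np.asarray([rw + [_PAD_ROW] + cw], dtype=np.int64)
        tag = np.asarray([rt + [TAG_PAD_INDEX] + ct], dtype=np.int64)
        mask = np.asarray([[True] * len(rw) + [False] + [True] * len(cw)])
        return IndexedPair(word, tag, mask, strategy, None)

    a_rel, a_ctx = _strategy_anchors(pair, strategy)
    rel = _truncate(pair.relation_sentence, pair, a_rel, max_tokens)
    ctx = _truncate(pair.context_sentence, pair, a_ctx, max_tokens)
    anchor_col = max(a_rel, a_ctx)
    off_rel, off_ctx = anchor_col - a_rel, anchor_col - a_ctx
    length = max(off_rel + len(rel), off_ctx + len(ctx))
    word = np.full((2, length), _PAD_ROW, dtype=np.int64)
    tag = np.full((2, length), TAG_PAD_INDEX, dtype=np.int64)
    mask = np.zeros((2, length), dtype=bool)
    for block, (toks, off) in enumerate(((rel, off_rel), (ctx, off_ctx))):
        w, t = _indices(toks, table)
        word[block, off : off + len(w)] = w
        tag[block, off : off + len(t)] = t
        mask[block, off : off + len(w)] = True
    return IndexedPair(word, tag, mask, strategy, anchor_col)


def densify(indexed: IndexedPair, table: EmbeddingTable) -> FeatureMatrix:
    """Turn an index-level encoding into the dense (rows x L) matrix."""
    tag_table = table.tag_matrix()
    blocks = []
    for b in range(indexed.word_idx.shape[0]):
        w = table.word_vectors[indexed.word_idx[b]]  # (L, d_word)
        t = tag_table[indexed.tag_idx[b]]  # (L, d_ent)
        blocks.append(np.concatenate([w, t], axis=1).T)  # (d, L)
    values = np.concatenate(blocks, axis=0)
    return FeatureMatrix(values, indexed.mask.copy(), indexed.strategy,
                         indexed.anchor_column)


def encode_pair(
    pair: CandidatePair,
    table: EmbeddingTable,
    strategy: str = "parallel_gene_disease",
    max_tokens: int = 128,
) -> FeatureMatrix:
    """Encode one candidate pair as a dense 2-D feature matrix.

    Parallel strategies left-pad so the two anchor tokens share a column and
    right-pad to a common length L; column j stacks the relation-sentence
    token embedding (rows 0..d-1) over the context-sentence token embedding
    (rows d..2d-1).  Sequential appends the context after the relation with
    one padding column between (rows = d).  Padding cells are zero and
    mask-false.  Pure function of its inputs.
    """
    return densify(encode_pair_indices(pair, table, strategy, max_tokens), table)


@dataclass
class EncodedBatch:
    """A batch of index-level encodings padded to a common per-batch length."""

    word_idx: np.ndarray  # (B, blocks, L)
    tag_idx: np.ndarray
    mask: np.ndarray  # (B, blocks, L) bool
    strategy: str

    def __len__(self) -> int:
        return self.word_idx.shape[0]


def encode_batch(
    pairs: Sequence[CandidatePair],
    table: EmbeddingTable,
    strategy: str = "parallel_gene_disease",
    max_tokens: int = 128,
) -> EncodedBatch:
    """Encode pairs and right-pad them to the batch's maximum aligned length."""
    singles = [encode_pair_indices(p, table, strategy, max_tokens) for p in pairs]
    blocks = singles[0].word_idx.shape[0]
    length = max(s.word_idx.shape[1] for s in singles)
    n = len(singles)
    word = np.full((n, blocks, length), _PAD_ROW, dtype=np.int64)
    tag = np.full((n, blocks, length), TAG_PAD_INDEX, dtype=np.int64)
    mask = np.zeros((n, blocks, length), dtype=bool)
    for i, s in enumerate(singles):
        L = s.word_idx.shape[1]
        word[i, :, :L] = s.word_idx
        tag[i, :, :L] = s.tag_idx
        mask[i, :, :L] = s.mask
    return EncodedBatch(word, tag, mask, strategy)
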