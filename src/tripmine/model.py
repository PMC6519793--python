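"""Binary relation classifiers over encoded sentence pairs.

The default classifier reads the column sequence of the aligned 2-D encoding
with a bidirectional LSTM (each column is one time step), concatenates the
forward and backward hidden states per step, feeds the step-wise concatenated
states through a wide fully-connected layer, reduces over time (max by
default) and ends in a 2-way softmax.  LSTM, GRU, bi-GRU and a CNN comparator
share the identical input/output contract — only the sequence layer changes.

Training is plain mini-batch SGD on 2-class cross-entropy (a learning rate as
large as 0.80 is only workable without adaptive scaling), with seeded
shuffling and global-norm gradient clipping.  Entity-type (tag) vectors are
trained with the classifier; word vectors are frozen by default.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoder import (
    TAG_PAD_INDEX,
    EmbeddingTable,
    EncodedBatch,
    FeatureMatrix,
    STRATEGIES,
    encode_batch,
)

ARCHITECTURES = ("bilstm", "lstm", "gru", "bigru", "cnn")
REDUCTIONS = ("max", "mean", "final")


@dataclass
class ModelConfig:
    """Hyperparameters of the relation classifier.

    Defaults follow the tuned operating point: 100 recurrent hidden units,
    learning rate 0.80, fully-connected width 1,000, mini-batches of 200,
    decision threshold 0.5.
    """

    architecture: str = "bilstm"
    hidden_units: int = 100
    learning_rate: float = 0.80
    fc_size: int = 1000
    batch_size: int = 200
    epochs: int = 30
    seed: int = 0
    optimizer: str = "sgd"
    threshold: float = 0.5
    reduction: str = "max"
    dropout: float = 0.0
    clip_norm: float | None = 5.0
    strategy: str = "parallel_gene_disease"
    max_tokens: int = 128
    #: word vectors are trained with the model by default; freeze them when
    #: supplying pre-trained vectors that should stay fixed
    freeze_word_vectors: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if min(self.hidden_units, self.fc_size, self.batch_size) < 1:
            raise ValueError("hidden_units, fc_size and batch_size must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.optimizer != "sgd":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class Metrics:
    """Precision / recall / F-measure with the confusion counts behind them."""

    precision: float
    recall: float
    f_measure: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "Metrics":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return cls(p, r, f, tp, fp, fn, tn)


def evaluate_predictions(
    labels: np.ndarray, p_positive: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Confusion-count metrics at a decision threshold on the positive score."""
    labels = np.asarray(labels)
    pred = np.asarray(p_positive) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return Metrics.from_counts(tp, fp, fn, tn)


class _Embedding(nn.Layer):
    """Lookup layer tied to an EmbeddingTable; trains the tag vectors in place."""

    def __init__(self, table: EmbeddingTable, freeze_words: bool = True) -> None:
        super().__init__()
        self.table = table
        self.freeze_words = freeze_words
        self.params = {"tags": table.tag_vectors}
        if not freeze_words:
            self.params["words"] = table.word_vectors
        self.zero_grad()

    def forward(self, batch: EncodedBatch) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, step_mask): X is (B, T, blocks * dim)."""
        self._batch = batch
        word = self.table.word_vectors[batch.word_idx]  # (B, blocks, T, d_word)
        tag = self.table.tag_matrix()[batch.tag_idx]  # (B, blocks, T, d_ent)
        per_block = np.concatenate([word, tag], axis=3)  # (B, blocks, T, dim)
        B, blocks, T, dim = per_block.shape
        X = per_block.transpose(0, 2, 1, 3).reshape(B, T, blocks * dim)
        return X, batch.mask.any(axis=1)

    def backward(self, dX: np.ndarray) -> None:
        batch = self.table, self._batch
        table, b = batch
        B, T, _ = dX.shape
        blocks = b.word_idx.shape[1]
        d_word, d_ent = table.d_word, table.d_ent
        dim = d_word + d_ent
        d = dX.reshape(B, T, blocks, dim).transpose(0, 2, 1, 3)
        dtag = d[..., d_word:]
        # padding row (index 7) receives gradient too; discard it after scatter
        acc_t = np.zeros((TAG_PAD_INDEX + 1, d_ent), dtype=self.params["tags"].dtype)
        np.add.at(acc_t, b.tag_idx.reshape(-1), dtag.reshape(-1, d_ent))
        self.grads["tags"] += acc_t[:TAG_PAD_INDEX]
        if not self.freeze_words:
            dword = d[..., :d_word]
            acc_w = np.zeros_like(self.params["words"])
            np.add.at(acc_w, b.word_idx.reshape(-1), dword.reshape(-1, d_word))
            acc_w[0] = 0.0  # the padding row stays exactly zero
            self.grads["words"] += acc_w


class RelationClassifier:
    """A relation classifier: embedding -> sequence layer -> FC head -> softmax."""

    def __init__(self, config: ModelConfig, table: EmbeddingTable) -> None:
        self.config = config
        self.table = table
        blocks = 1 if config.strategy == "sequential" else 2
        self.input_dim = blocks * table.dim
        rng = np.random.default_rng(config.seed)
        h = config.hidden_units
        self.embedding = _Embedding(table, config.freeze_word_vectors)
        arch = config.architecture
        if arch == "bilstm":
            self.core = nn.Bidirectional(nn.LSTM(self.input_dim, h, rng),
                                         nn.LSTM(self.input_dim, h, rng))
            rep = 2 * h
        elif arch == "lstm":
            self.core = nn.LSTM(self.input_dim, h, rng)
            rep = h
        elif arch == "gru":
            self.core = nn.GRU(self.input_dim, h, rng)
            rep = h
        elif arch == "bigru":
            self.core = nn.Bidirectional(nn.GRU(self.input_dim, h, rng),
                                         nn.GRU(self.input_dim, h, rng))
            rep = 2 * h
        elif arch == "cnn":
            self.core = nn.Conv1D(self.input_dim, h, window=3, rng=rng)
            rep = h
        self.step_width = rep
        self.fc = nn.Dense(rep, config.fc_size, rng)
        self.fc_act = nn.ReLU()
        self.pool = {"max": nn.MaskedMaxPool, "mean": nn.MaskedMeanPool,
                     "final": nn.FinalState}[config.reduction]()
        self.out = nn.Dense(config.fc_size, 2, rng)
        self._rng = rng
        self.trained = False

    @property
    def layers(self) -> list[nn.Layer]:
        return [self.embedding, self.core, self.fc, self.fc_act, self.pool, self.out]

    def parameter_count(self) -> int:
        return sum(int(p.size) for l in self.layers for p in l.params.values())

    # -- forward / backward ------------------------------------------------

    def _forward_core(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if self.config.architecture == "cnn":
            # conv -> ReLU -> max-over-time -> FC -> ReLU -> output
            C = self.core.forward(X, mask)
            A = self.fc_act.forward(C)
            pooled = self.pool.forward(A, mask)
            Z = self.fc.forward(pooled)
            self._cnn_relu2 = nn.ReLU()
            A2 = self._cnn_relu2.forward(Z)
            return self.out.forward(A2)
        # recurrent: per-step FC on concatenated hidden states, then reduce
        H = self.core.forward(X, mask)
        Z = self.fc.forward(H)
        A = self.fc_act.forward(Z)
        if self._dropout_mask is not None:
            A = A * self._dropout_mask
        pooled = self.pool.forward(A, mask)
        return self.out.forward(pooled)

    def _backward_core(self, dlogits: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if self.config.architecture == "cnn":
            dA2 = self.out.backward(dlogits)
            dZ = self._cnn_relu2.backward(dA2)
            dpooled = self.fc.backward(dZ)
            dA = self.pool.backward(dpooled)
            dC = self.fc_act.backward(dA)
            return self.core.backward(dC)
        dpooled = self.out.backward(dlogits)
        dA = self.pool.backward(dpooled)
        if self._dropout_mask is not None:
            dA = dA * self._dropout_mask
        dZ = self.fc_act.backward(dA)
        dH = self.fc.backward(dZ)
        return self.core.backward(dH)

    def forward_logits(self, batch: EncodedBatch, training: bool = False) -> np.ndarray:
        X, mask = self.embedding.forward(batch)
        X = X.astype(np.float32, copy=False)
        self._dropout_mask = None
        if training and self.config.dropout > 0 and self.config.architecture != "cnn":
            keep = 1.0 - self.config.dropout
            self._dropout_mask = (
                self._rng.random((X.shape[0], X.shape[1], self.config.fc_size)) < keep
            ).astype(np.float32) / keep
        self._mask = mask
        return self._forward_core(X, mask)

    def predict_batch(self, batch: EncodedBatch) -> np.ndarray:
        """(B, 2) array of (p_negative, p_positive) rows."""
        return nn.softmax(self.forward_logits(batch))

    def predict_matrix(self, matrix: FeatureMatrix) -> tuple[float, float]:
        """Predict from one dense feature matrix; returns (p_neg, p_pos)."""
        if matrix.values.shape[0] != self.input_dim:
            raise ValueError(
                f"feature matrix has {matrix.values.shape[0]} rows, classifier "
                f"expects {self.input_dim}"
            )
        X = matrix.values.T[None].astype(np.float32)
        mask = matrix.mask.any(axis=0)[None]
        self._dropout_mask = None
        p = nn.softmax(self._forward_core(X, mask))[0]
        return float(p[0]), float(p[1])


def build_classifier(config: ModelConfig, table: EmbeddingTable) -> RelationClassifier:
    """Construct a classifier for the encoder output implied by *table*/*config*."""
    return RelationClassifier(config, table)


def predict(
    classifier: RelationClassifier,
    encoded: FeatureMatrix | EncodedBatch,
) -> tuple[float, float] | np.ndarray:
    """Class probabilities for one feature matrix or a batch.

    A pair is labeled positive iff ``p_positive >= config.threshold``.
    """
    if isinstance(encoded, FeatureMatrix):
        return classifier.predict_matrix(encoded)
    return classifier.predict_batch(encoded)


def _trim(batch: EncodedBatch, rows: np.ndarray) -> EncodedBatch:
    """Slice a batch by row indices and drop all-padding trailing columns."""
    word = batch.word_idx[rows]
    tag = batch.tag_idx[rows]
    mask = batch.mask[rows]
    valid = mask.any(axis=(0, 1))
    if valid.any():
        L = int(np.max(np.nonzero(valid)[0])) + 1
    else:
        L = 1
    return EncodedBatch(word[:, :, :L], tag[:, :, :L], mask[:, :, :L],
                        batch.strategy)


def train(
    classifier: RelationClassifier,
    batch: EncodedBatch,
    labels: np.ndarray,
    config: ModelConfig | None = None,
) -> list[float]:
    """Train in place by mini-batch SGD; returns the per-epoch mean loss history."""
    config = config or classifier.config
    labels = np.asarray(labels, dtype=np.int64)
    n = len(batch)
    if n < 2 or len(np.unique(labels)) < 2:
        raise ValueError("training needs at least two examples of both classes")
    rng = np.random.default_rng(config.seed + 1)
    opt = nn.SGD(classifier.layers, config.learning_rate, config.clip_norm)
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            rows = order[start : start + config.batch_size]
            sub = _trim(batch, rows)
            opt.zero_grad()
            logits = classifier.forward_logits(sub, training=True)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, labels[rows])
            dX = classifier._backward_core(dlogits, classifier._mask)
            classifier.embedding.backward(dX)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    classifier.trained = True
    return history


# ---------------------------------------------------------------------------
# Evaluation protocols
# ---------------------------------------------------------------------------


def _labels_of(pairs) -> np.ndarray:
    labels = []
    for p in pairs:
        if p.label not in ("positive", "negative"):
            raise ValueError(f"pair {p.key} has no gold label")
        labels.append(1 if p.label == "positive" else 0)
    return np.asarray(labels, dtype=np.int64)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition; per-class fold sizes differ by <= 1."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smaller class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    pairs,
    config: ModelConfig,
    table: EmbeddingTable,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[Metrics], Metrics]:
    """k-fold cross-validation of the full classify-from-pairs pipeline.

    Each fold's model trains on the other k-1 folds from a fresh copy of the
    embedding table (tag vectors are trainable, so folds must not share them).
    Returns per-fold metrics and their unweighted mean (confusion counts are
    summed).
    """
    pairs = list(pairs)
    labels = _labels_of(pairs)
    batch = encode_batch(pairs, table, config.strategy, config.max_tokens)
    folds = stratified_folds(labels, k, seed)
    per_fold: list[Metrics] = []
    for i, test_rows in enumerate(folds):
        train_rows = np.setdiff1d(np.arange(len(pairs)), test_rows)
        fold_table = copy.deepcopy(table)
        fold_config = dataclasses.replace(config, seed=config.seed + i)
        clf = RelationClassifier(fold_config, fold_table)
        clf_batch = EncodedBatch(batch.word_idx, batch.tag_idx, batch.mask,
                                 batch.strategy)
        train(clf, _trim(clf_batch, train_rows), labels[train_rows], fold_config)
        probs = clf.predict_batch(_trim(clf_batch, test_rows))
        per_fold.append(
            evaluate_predictions(labels[test_rows], probs[:, 1], config.threshold)
        )
    mean = Metrics(
        float(np.mean([m.precision for m in per_fold])),
        float(np.mean([m.recall for m in per_fold])),
        float(np.mean([m.f_measure for m in per_fold])),
        sum(m.tp for m in per_fold),
        sum(m.fp for m in per_fold),
        sum(m.fn for m in per_fold),
        sum(m.tn for m in per_fold),
    )
    return per_fold, mean


def imbalance_experiment(
    positive_pool,
    negative_pool,
    ratios: list[tuple[int, int]],
    config: ModelConfig,
    table: EmbeddingTable,
    k: int = 10,
    seed: int = 0,
):
    """Class-imbalance protocol: subsample each (n_pos, n_neg), cross-validate.

    Returns a pandas DataFrame with one row per ratio (columns n_pos, n_neg,
    precision, recall, f) mirroring the tabulated imbalance results.
    """
    import pandas as pd

    positive_pool, negative_pool = list(positive_pool), list(negative_pool)
    rng = np.random.default_rng(seed)
    rows = []
    for n_pos, n_neg in ratios:
        if n_pos < 1 or n_neg < 1:
            raise ValueError("each ratio needs examples of both classes")
        if n_pos > len(positive_pool) or n_neg > len(negative_pool):
            raise ValueError(f"ratio ({n_pos}, {n_neg}) exceeds the pools")
        pos = [positive_pool[i] for i in
               rng.choice(len(positive_pool), n_pos, replace=False)]
        neg = [negative_pool[i] for i in
               rng.choice(len(negative_pool), n_neg, replace=False)]
        _, mean = cross_validate(pos + neg, config, table, k=k, seed=seed)
        rows.append({"n_pos": n_pos, "n_neg": n_neg,
                     "precision": mean.precision, "recall": mean.recall,
                     "f": mean.f_measure})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(classifier: RelationClassifier, path: str) -> None:
    """Serialize parameters + config + embedding table into one ``.npz`` file."""
    arrays: dict[str, np.ndarray] = {}
    for li, layer in enumerate(classifier.layers):
        for k, p in layer.params.items():
            arrays[f"layer{li}.{k}"] = p
    table = classifier.table
    arrays["table.word_vectors"] = table.word_vectors
    arrays["table.tag_vectors"] = table.tag_vectors
    meta = {
        "config": dataclasses.asdict(classifier.config),
        "vocabulary": table.vocabulary,
        "fingerprint": table.fingerprint(),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str, expect_fingerprint: str | None = None) -> RelationClassifier:
    """Load a checkpoint; refuses a mismatched encoder fingerprint if given."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if expect_fingerprint is not None and meta["fingerprint"] != expect_fingerprint:
            raise ValueError(
                "checkpoint was trained against a different encoder "
                f"configuration (fingerprint {meta['fingerprint'][:12]}...)"
            )
        table = EmbeddingTable(
            {k: int(v) for k, v in meta["vocabulary"].items()},
            data["table.word_vectors"].copy(),
            data["table.tag_vectors"].copy(),
        )
        config = ModelConfig(**meta["config"])
        clf = RelationClassifier(config, table)
        for li, layer in enumerate(clf.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"layer{li}.{k}"]
        clf.trained = True
        return clf
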