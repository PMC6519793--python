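"""High-level glue: fit, score and evaluate classifiers on candidate pairs."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .encoder import EmbeddingTable, build_table, encode_batch
from .model import (
    Metrics,
    ModelConfig,
    RelationClassifier,
    evaluate_predictions,
    train,
)
from .pair_builder import CandidatePair


def pair_vocabulary(pairs: Iterable[CandidatePair]) -> list[str]:
    tokens: list[str] = []
    for p in pairs:
        tokens.extend(t.text for t in p.relation_sentence)
        tokens.extend(t.text for t in p.context_sentence)
    return tokens


def fit_classifier(
    pairs: Sequence[CandidatePair],
    config: ModelConfig,
    pretrained_vectors: dict[str, np.ndarray] | None = None,
    table: EmbeddingTable | None = None,
) -> tuple[RelationClassifier, list[float]]:
    """Build the embedding table (unless given), encode, and train.

    Returns the trained classifier and its loss history; the table is
    reachable as ``classifier.table``.
    """
    if table is None:
        table = build_table(pair_vocabulary(pairs), pretrained_vectors,
                            seed=config.seed)
    labels = np.asarray([1 if p.label == "positive" else 0 for p in pairs])
    batch = encode_batch(pairs, table, config.strategy, config.max_tokens)
    clf = RelationClassifier(config, table)
    history = train(clf, batch, labels, config)
    return clf, history


def score_pairs(
    classifier: RelationClassifier,
    pairs: Sequence[CandidatePair],
    chunk: int = 500,
) -> list[CandidatePair]:
    """Attach positive-class probabilities to pairs (in place); returns pairs."""
    cfg = classifier.config
    for start in range(0, len(pairs), chunk):
        sub = pairs[start : start + chunk]
        batch = encode_batch(sub, classifier.table, cfg.strategy, cfg.max_tokens)
        probs = classifier.predict_batch(batch)
        for p, row in zip(sub, probs):
            p.score = float(row[1])
    return list(pairs)


def predicted_positive(
    pairs: Sequence[CandidatePair], threshold: float = 0.5
) -> list[CandidatePair]:
    return [p for p in pairs if p.score is not None and p.score >= threshold]


def holdout_evaluation(
    pairs: Sequence[CandidatePair],
    config: ModelConfig,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[Metrics, RelationClassifier]:
    """Stratified train/test split, fit on train, metrics on the held-out set."""
    from sklearn.model_selection import train_test_split

    labels = np.asarray([1 if p.label == "positive" else 0 for p in pairs])
    idx_train, idx_test = train_test_split(
        np.arange(len(pairs)), test_size=test_fraction, stratify=labels,
        random_state=seed % (2**32),
    )
    clf, _ = fit_classifier([pairs[i] for i in idx_train], config)
    test = [pairs[i] for i in idx_test]
    score_pairs(clf, test)
    metrics = evaluate_predictions(
        labels[idx_test], np.asarray([p.score for p in test]), config.threshold
    )
    return metrics, clf
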