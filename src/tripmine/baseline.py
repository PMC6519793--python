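"""Bag-of-words logistic-regression baseline.

Not part of the extraction pipeline: it certifies that a labeled pair corpus
is lexically separable before any claim about the neural classifiers is
tested, and serves as an independent reference point in evaluations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import Metrics, evaluate_predictions
from .pair_builder import CandidatePair


def _pair_text(pair: CandidatePair) -> str:
    return (pair.relation_text + " " + pair.context_text).lower()


def bow_logistic_holdout(
    pairs: Sequence[CandidatePair],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> Metrics:
    """Hold-out F of a unigram count + logistic regression model."""
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    labels = np.asarray([1 if p.label == "positive" else 0 for p in pairs])
    texts = [_pair_text(p) for p in pairs]
    idx_train, idx_test = train_test_split(
        np.arange(len(pairs)), test_size=test_fraction, stratify=labels,
        random_state=seed % (2**32),
    )
    vec = CountVectorizer(token_pattern=r"[^\s]+")
    x_train = vec.fit_transform([texts[i] for i in idx_train])
    x_test = vec.transform([texts[i] for i in idx_test])
    clf = LogisticRegression(max_iter=1000, random_state=seed % (2**32))
    clf.fit(x_train, labels[idx_train])
    p_pos = clf.predict_proba(x_test)[:, 1]
    return evaluate_predictions(labels[idx_test], p_pos, 0.5)
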