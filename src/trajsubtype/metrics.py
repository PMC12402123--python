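"""Prediction metrics: support-weighted F1 and mean absolute error.

Both operate strictly on aligned observed (prediction, truth) pairs; the
caller filters by observedness before scoring.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import f1_score


def weighted_f1(predictions, truths, classes=None) -> float:
    """Per-class F1 averaged with weights proportional to class support.

    Raises on empty input (an absent metric is reported as absent upstream,
    never silently as 0).
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if truths.size == 0:
        raise ValueError("no observed pairs to score")
    labels = sorted(set(np.unique(truths)) | set(np.unique(predictions))) \
        if classes is None else list(classes)
    return float(f1_score(truths, predictions, labels=labels,
                          average="weighted", zero_division=0))


def mae(predictions, truths) -> float:
    """Mean absolute error over observed targets."""
    predictions = np.asarray(predictions, float)
    truths = np.asarray(truths, float)
    if truths.size == 0:
        raise ValueError("no observed pairs to score")
    return float(np.mean(np.abs(predictions - truths)))
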