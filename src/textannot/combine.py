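"""Combining predictions across methods and across granularities.

Two schemes: (i) an F1-weighted average of per-method probabilities, where
each method's weight is its F1 score for the term (binary 0/1 methods enter
with their raw scores); (ii) an additive sample+dataset combination, where a
sample's score and its parent dataset's score are simply added — the result
is a ranking score in [0, 2], not a probability.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .ontology import IGNORE, POS

logger = logging.getLogger(__name__)


def f1_from_predictions(
    scores: pd.Series | Mapping,
    labels: pd.Series | Mapping,
    threshold: float = 0.5,
) -> float:
    """F1 of thresholded predictions (score >= threshold counts positive).

    Returns 0 when nothing is predicted positive (logged).
    """
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).reindex(scores.index)
    if (labels == IGNORE).any():
        raise ValueError("IGNORE entities must be excluded before F1")
    y_true = (labels == POS).astype(int).to_numpy()
    if not y_true.any():
        raise ValueError("F1 requires at least one positive label")
    y_pred = (scores.to_numpy() >= threshold).astype(int)
    if not y_pred.any():
        logger.warning("no predicted positives; F1 = 0 by convention")
        return 0.0
    return float(f1_score(y_true, y_pred, zero_division=0))


def combine_weighted(
    per_method_scores: Mapping[str, pd.Series],
    per_method_f1: Mapping[str, float],
) -> pd.Series:
    """F1-weighted average of per-method predicted probabilities.

    All-zero weights fall back to the unweighted mean with a warning.
    """
    methods = sorted(per_method_scores)
    if len(methods) < 2:
        raise ValueError("need at least two methods to combine")
    weights = np.array([per_method_f1[m] for m in methods], dtype=float)
    if (weights < 0).any():
        raise ValueError("F1 weights must be non-negative")
    if weights.sum() == 0:
        logger.warning("all F1 weights are zero; using the unweighted mean")
        weights = np.ones_like(weights)
    frame = pd.DataFrame({m: pd.Series(per_method_scores[m], dtype=float) for m in methods})
    if frame.isna().any().any():
        raise ValueError("methods score different entity sets")
    return frame.mul(weights, axis=1).sum(axis=1) / weights.sum()


def combine_sample_dataset(
    p_sample: float, p_dataset: float, mode: str = "add"
) -> float:
    """Combine a sample's own score with its parent dataset's score.

    'add' returns their sum (a ranking score in [0, 2]); 'max' the larger.
    A missing dataset score leaves the sample score alone; both missing
    yields NaN.
    """
    s_missing = p_sample is None or (isinstance(p_sample, float) and math.isnan(p_sample))
    d_missing = p_dataset is None or (isinstance(p_dataset, float) and math.isnan(p_dataset))
    if s_missing and d_missing:
        return float("nan")
    if d_missing:
        return float(p_sample)
    if s_missing:
        return float(p_dataset)
    if mode == "add":
        return float(p_sample) + float(p_dataset)
    if mode == "max":
        return max(float(p_sample), float(p_dataset))
    raise ValueError(f"unknown combination mode {mode!r}")
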