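"""Dataset-stratified cross-validation, auPRC, and enrichment over the prior.

Samples from the same dataset are never split across folds, so a model is
always evaluated on samples from datasets it has never seen; this prevents
performance from being inflated by dataset/batch-specific vocabulary.  The
fold count follows data availability: 3 folds for terms with exactly three
positive datasets, 4 for four, 5 for five or more.

auPRC is computed as average precision.  Tied scores are grouped at a common
threshold (the precision-recall curve is traced over unique score values),
which makes a constant scorer's auPRC equal exactly the positive fraction —
the prior, the expected value of a random ranking.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from . import combine as _combine
from .embedding import (
    EmbeddingBackend,
    compute_idf,
    embed_dataset,
    embed_entity,
    term_frequencies,
)
from .models import train_term_model
from .ontology import IGNORE, NEG, POS
from .textprep import TokenBag, noop_lemmatizer

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Assignment of datasets (never samples) to cross-validation folds."""

    term: str
    k: int
    fold_of: dict[str, int]

    def datasets_in_fold(self, fold: int) -> set[str]:
        return {d for d, f in self.fold_of.items() if f == fold}


def k_for_pos_count(n_pos: int) -> int:
    if n_pos < 3:
        raise ValueError("fold planning requires at least 3 positive datasets")
    return min(n_pos, 5)


def plan_dataset_folds(dataset_labels: pd.Series, seed: int = 0) -> FoldPlan:
    """Partition datasets into folds, spreading positives evenly.

    Positive datasets are shuffled (seeded) and dealt round-robin so every
    fold holds at least one; negative datasets are shuffled and dealt
    round-robin to balance fold sizes.  IGNORE datasets are left out.
    """
    pos = sorted(dataset_labels.index[dataset_labels == POS])
    neg = sorted(dataset_labels.index[dataset_labels == NEG])
    k = k_for_pos_count(len(pos))
    rng = random.Random(seed)
    rng.shuffle(pos)
    rng.shuffle(neg)
    fold_of = {d: i % k for i, d in enumerate(pos)}
    fold_of.update({d: i % k for i, d in enumerate(neg)})
    return FoldPlan(term=str(dataset_labels.name), k=k, fold_of=fold_of)


def auprc(scores: pd.Series | Mapping, labels: pd.Series | Mapping) -> float:
    """Average precision of a ranked entity list.

    IGNORE entities must be excluded upstream.  Returns NaN (missing marker)
    when there is no positive.  With no negatives the ranking is trivially
    perfect and auPRC is 1.
    """
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).reindex(scores.index)
    if labels.isna().any():
        raise ValueError("labels missing for some scored entities")
    if (labels == IGNORE).any():
        raise ValueError("IGNORE entities must be excluded before auPRC")
    y = (labels == POS).to_numpy()
    if not y.any():
        logger.warning("no positive entities; auPRC undefined")
        return float("nan")
    if y.all():
        return 1.0
    return float(average_precision_score(y, scores.to_numpy()))


def log2_enrichment(auprc_value: float, prior: float) -> float:
    """log2(auPRC / prior): performance relative to a random ranking."""
    if not (0 < prior <= 1):
        raise ValueError("prior must be in (0, 1]")
    if not (auprc_value > 0):
        return float("nan")
    return math.log2(auprc_value / prior)


@dataclass
class EvalResult:
    term: str
    per_fold_auprc: list[float]
    mean_auprc: float
    prior: float
    k: int
    n_pos: int
    scores: pd.Series | None = field(default=None, repr=False)

    @property
    def log2_enrichment(self) -> float:
        return log2_enrichment(self.mean_auprc, self.prior)


ScoringMethod = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def l1_logistic_method(seed: int = 0, C: float = 1.0) -> ScoringMethod:
    """The default scorer: fit the per-term L1 logistic model, return probs."""

    def method(X_train, y_train, X_test):
        model = train_term_model(X_train, y_train, term="cv", C=C, seed=seed)
        return model.predict_proba(np.asarray(X_test, dtype=float))

    return method


def _split_entities(
    fold_plan: FoldPlan,
    sample_labels: pd.Series,
    dataset_of: Mapping[str, str],
    fold: int,
):
    test_ds = fold_plan.datasets_in_fold(fold)
    train_ds = set(fold_plan.fold_of) - test_ds
    assert not (train_ds & test_ds), "dataset integrity violated: fold overlap"
    train_ids, test_ids = [], []
    for sample in sample_labels.index:
        ds = dataset_of[sample]
        if sample_labels[sample] == IGNORE:
            continue
        if ds in test_ds:
            test_ids.append(sample)
        elif ds in train_ds:
            train_ids.append(sample)
    return train_ids, test_ids, train_ds, test_ds


def _finalize(
    term: str,
    k: int,
    fold_scores: list[pd.Series],
    fold_auprcs: list[float],
    sample_labels: pd.Series,
    evaluated: list[str],
) -> EvalResult:
    valid = [a for a in fold_auprcs if not math.isnan(a)]
    mean = float(np.mean(valid)) if valid else float("nan")
    labels = sample_labels.loc[evaluated]
    prior = float((labels == POS).mean()) if len(labels) else float("nan")
    pooled = pd.concat(fold_scores) if fold_scores else None
    return EvalResult(
        term=term,
        per_fold_auprc=fold_auprcs,
        mean_auprc=mean,
        prior=prior,
        k=k,
        n_pos=int((labels == POS).sum()),
        scores=pooled,
    )


def run_cv(
    method: ScoringMethod,
    fold_plan: FoldPlan,
    sample_labels: pd.Series,
    features: pd.DataFrame,
    dataset_of: Mapping[str, str],
) -> EvalResult:
    """Grouped CV of a scoring method on a fixed feature matrix.

    ``features`` is any entity-indexed numeric matrix — text embeddings, or
    e.g. expression profiles; the trainer is agnostic.  The method trains on
    the k-1 training folds' samples and scores the held-out fold; folds whose
    held-out part has no positive sample are skipped with a warning.
    """
    fold_scores: list[pd.Series] = []
    fold_auprcs: list[float] = []
    evaluated: list[str] = []
    for fold in range(fold_plan.k):
        train_ids, test_ids, _, _ = _split_entities(
            fold_plan, sample_labels, dataset_of, fold
        )
        if not test_ids or not train_ids:
            logger.warning("fold %d is empty; skipping", fold)
            continue
        y_train = sample_labels.loc[train_ids].to_numpy()
        scores = method(
            features.loc[train_ids].to_numpy(),
            y_train,
            features.loc[test_ids].to_numpy(),
        )
        s = pd.Series(np.asarray(scores, dtype=float), index=test_ids)
        evaluated.extend(test_ids)
        fold_scores.append(s)
        y_test = sample_labels.loc[test_ids]
        if not (y_test == POS).any():
            logger.warning("fold %d has no positive test sample; skipped", fold)
            fold_auprcs.append(float("nan"))
            continue
        fold_auprcs.append(auprc(s, y_test))
    return _finalize(
        fold_plan.term, fold_plan.k, fold_scores, fold_auprcs, sample_labels, evaluated
    )


def run_text_cv(
    sample_bags: Mapping[str, TokenBag],
    fold_plan: FoldPlan,
    sample_labels: pd.Series,
    dataset_of: Mapping[str, str],
    backend: EmbeddingBackend,
    scheme: str = "idf",
    dataset_texts: Mapping[str, str] | None = None,
    combine_mode: str = "add",
    seed: int = 0,
    lemmatizer=noop_lemmatizer,
) -> dict[str, EvalResult]:
    """Grouped CV of the full text pipeline, leakage-free.

    Word weights (IDF, and per-term TF for scheme='tfidf') are re-estimated
    inside every fold from the training samples only, so held-out datasets
    never influence the representation.  When ``dataset_texts`` is given, the
    held-out datasets' descriptions are scored by max-over-sentences with the
    same fold's model, transferred to their samples, and combined with the
    per-sample scores; returns results keyed 'sample', 'dataset', 'combined'.
    """
    modes = ["sample"] + (["dataset", "combined"] if dataset_texts else [])
    fold_scores = {m: [] for m in modes}
    fold_auprcs = {m: [] for m in modes}
    evaluated: list[str] = []
    term = fold_plan.term

    for fold in range(fold_plan.k):
        train_ids, test_ids, _, test_ds = _split_entities(
            fold_plan, sample_labels, dataset_of, fold
        )
        if not test_ids or not train_ids:
            logger.warning("fold %d is empty; skipping", fold)
            continue
        train_bags = [sample_bags[i] for i in train_ids]
        weights = compute_idf(train_bags) if scheme != "uniform" else None
        tf = None
        if scheme == "tfidf":
            pos_bags = [
                sample_bags[i]
                for i in train_ids
                if sample_labels[i] == POS
            ]
            tf = term_frequencies(pos_bags)
        X_train = np.vstack(
            [embed_entity(sample_bags[i], backend, weights, scheme, tf) for i in train_ids]
        )
        X_test = np.vstack(
            [embed_entity(sample_bags[i], backend, weights, scheme, tf) for i in test_ids]
        )
        model = train_term_model(
            X_train, sample_labels.loc[train_ids].to_numpy(), term=term, seed=seed
        )
        sample_probs = pd.Series(model.predict_proba(X_test), index=test_ids)
        per_mode = {"sample": sample_probs}

        if dataset_texts is not None:
            ds_prob = {}
            for ds in sorted(test_ds):
                M = embed_dataset(
                    dataset_texts.get(ds, ""), backend, weights, scheme, tf, lemmatizer
                )
                if M.shape[0] == 0:
                    ds_prob[ds] = float("nan")
                else:
                    ds_prob[ds] = float(np.max(model.predict_proba(M)))
            dataset_probs = pd.Series(
                [ds_prob[dataset_of[i]] for i in test_ids], index=test_ids
            )
            combined = pd.Series(
                [
                    _combine.combine_sample_dataset(
                        sample_probs[i], dataset_probs[i], mode=combine_mode
                    )
                    for i in test_ids
                ],
                index=test_ids,
            )
            per_mode["dataset"] = dataset_probs.fillna(0.0)
            per_mode["combined"] = combined

        evaluated.extend(test_ids)
        y_test = sample_labels.loc[test_ids]
        has_pos = bool((y_test == POS).any())
        for m in modes:
            fold_scores[m].append(per_mode[m])
            if has_pos:
                fold_auprcs[m].append(auprc(per_mode[m], y_test))
            else:
                logger.warning("fold %d has no positive test sample; skipped", fold)
                fold_auprcs[m].append(float("nan"))

    return {
        m: _finalize(term, fold_plan.k, fold_scores[m], fold_auprcs[m], sample_labels, evaluated)
        for m in modes
    }


def wilcoxon_compare(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
):
    """Wilcoxon signed-rank test across terms (convenience statistic).

    Exact distribution for small n (scipy picks it when there are no ties
    and n < 25); returns (statistic, p-value).
    """
    res = stats.wilcoxon(list(a), list(b), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def summary_report(
    results: Mapping[str, EvalResult],
    systems: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-term evaluation summary table."""
    rows = []
    for term, res in sorted(results.items()):
        systems_str = "NA"
        if systems and systems.get(term):
            systems_str = "|".join(sorted(systems[term]))
        rows.append(
            {
                "term": term,
                "n_pos": res.n_pos,
                "k": res.k,
                "mean_auprc": res.mean_auprc,
                "prior": res.prior,
                "log2_enrichment": res.log2_enrichment,
                "anatomical_system": systems_str,
            }
        )
    return pd.DataFrame(rows)
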