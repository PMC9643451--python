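"""Per-term one-vs-rest classifiers on entity embeddings.

One L1-regularized logistic regression model is trained per ontology term
(C = 1, liblinear), using only POS/NEG entities — IGNORE entities are
excluded as ambiguous.  The L1 penalty yields sparse, interpretable
coefficient vectors; because the L1 solution path is not unique, downstream
comparisons are made on rankings and on standardized-coefficient similarity
rather than on raw coefficient values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .embedding import EmbeddingBackend, IdfTable, embed_entity
from .ontology import IGNORE, NEG, POS
from .textprep import noop_lemmatizer, tokenize_and_clean

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    """Training data for a term contains only one class."""


@dataclass
class TermModel:
    """A fitted per-term logistic model plus its provenance fingerprint."""

    term: str
    coefficients: np.ndarray
    intercept: float
    config: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.coefficients.shape[0]

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision(X))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "term": self.term,
                    "coefficients": self.coefficients.tolist(),
                    "intercept": float(self.intercept),
                    "config": self.config,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "TermModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            term=d["term"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            config=d.get("config", {}),
        )


def train_term_model(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int] | pd.Series,
    term: str,
    C: float = 1.0,
    seed: int = 0,
    fingerprint: Mapping | None = None,
) -> TermModel:
    """Fit an L1 logistic model for one term on POS/NEG entities.

    ``y`` holds ternary codes; IGNORE rows are dropped here.  Raises
    :class:`SingleClassError` if only one class remains.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of entities")
    keep = y != IGNORE
    X, y = X[keep], y[keep]
    classes = set(y.tolist())
    if classes != {POS, NEG}:
        raise SingleClassError(
            f"term {term!r}: training data has classes {sorted(classes)}; "
            "need both positives and negatives"
        )
    # L1 penalty at C=1; sklearn >= 1.8 spells the penalty as l1_ratio
    try:
        clf = LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear", random_state=seed)
        clf.fit(X, y)
    except (TypeError, ValueError):
        clf = LogisticRegression(C=C, penalty="l1", solver="liblinear", random_state=seed)
        clf.fit(X, y)
    config = {"C": C, "penalty": "l1", "solver": "liblinear", "seed": seed}
    if fingerprint:
        config["fingerprint"] = dict(fingerprint)
    return TermModel(
        term=term,
        coefficients=clf.coef_.ravel().astype(float),
        intercept=float(clf.intercept_[0]),
        config=config,
    )


def predict_entities(
    model: TermModel, embeddings: np.ndarray | pd.DataFrame
) -> np.ndarray | pd.Series:
    """Per-entity probability of the term through the logistic link."""
    index = embeddings.index if isinstance(embeddings, pd.DataFrame) else None
    X = np.asarray(embeddings, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.dim:
        raise ValueError(
            f"embedding dim {X.shape[1]} != model dim {model.dim} "
            f"for term {model.term!r}"
        )
    probs = model.predict_proba(X)
    if index is not None:
        return pd.Series(probs, index=index, name=model.term)
    return probs


def predict_dataset(model: TermModel, dataset_matrix: np.ndarray) -> float:
    """Dataset probability = max per-sentence probability.

    An empty sentence matrix yields NaN (missing score), never 0.
    """
    M = np.asarray(dataset_matrix, dtype=float)
    if M.size == 0:
        return float("nan")
    return float(np.max(predict_entities(model, M)))


def embed_and_predict_text(
    text: str,
    models: Sequence[TermModel],
    backend: EmbeddingBackend,
    weights: IdfTable | None = None,
    scheme: str = "idf",
    lemmatizer: Callable[[str], str] = noop_lemmatizer,
) -> dict[str, float]:
    """Score any snippet of text — sample metadata, an ontology term's
    name+definition, a process description — against every model.

    An empty token bag yields NaN for every term.
    """
    bag = tokenize_and_clean(text, lemmatizer)
    if not bag:
        logger.warning("text cleaned to an empty bag; no scores")
        return {m.term: float("nan") for m in models}
    vec = embed_entity(bag, backend, weights, scheme)
    return {m.term: float(m.predict_proba(vec[None, :])[0]) for m in models}


def coefficient_similarity(models: Sequence[TermModel]) -> pd.DataFrame:
    """Cosine similarity between standardized model coefficient vectors.

    Coefficients are z-scored per feature across models (zero-variance
    features drop out); a model whose raw coefficient vector is all zero is
    flagged and given similarity 0 to every other model (diagonal stays 1).
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    dims = {m.dim for m in models}
    if len(dims) != 1:
        raise ValueError("models have inconsistent dimensionality")
    C = np.vstack([m.coefficients for m in models])
    zero_rows = ~np.any(C != 0, axis=1)
    if zero_rows.any():
        logger.warning(
            "%d model(s) have all-zero coefficients; similarities set to 0",
            int(zero_rows.sum()),
        )
    mu = C.mean(axis=0)
    sd = C.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (C - mu) / sd
    norms = np.linalg.norm(Z, axis=1)
    norms[norms == 0] = 1.0
    U = Z / norms[:, None]
    S = U @ U.T
    S[zero_rows, :] = 0.0
    S[:, zero_rows] = 0.0
    np.fill_diagonal(S, 1.0)
    terms = [m.term for m in models]
    return pd.DataFrame(S, index=terms, columns=terms)
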