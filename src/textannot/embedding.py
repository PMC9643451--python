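"""Word weights, pluggable word-vector backends, and pooled entity embeddings.

An entity (a sample, a sentence, an arbitrary snippet) is represented as the
element-wise weighted average of the vectors of the words in its token bag:

    v = sum_w weight(w) * e(w) / sum_w weight(w)

where the sum runs over token occurrences.  Weights are inverse document
frequencies, IDF(t) = log(N / n_t) with N the corpus size and n_t the number
of documents containing t (natural log; the base rescales all weights jointly
and leaves the weighted mean unchanged).  A token without a stored weight
receives the mean weight of the weighted tokens in the same bag, so
misspellings and concatenation artifacts still contribute through the
character-robust backend.  Multi-sentence dataset descriptions become one
vector per sentence.
"""

from __future__ import annotations

import hashlib
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Protocol

import numpy as np
import pandas as pd

from .textprep import TokenBag, noop_lemmatizer, split_sentences, tokenize_and_clean

logger = logging.getLogger(__name__)

SCHEMES = ("idf", "tfidf", "uniform")


@dataclass
class IdfTable:
    """Inverse document frequencies over a corpus of N documents."""

    weight: dict[str, float]
    n_docs: int
    doc_count: dict[str, int]

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"word": list(self.weight), "weight": list(self.weight.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IdfTable":
        df = pd.read_csv(path, sep="\t", dtype={"word": str, "weight": float})
        weight = dict(zip(df["word"], df["weight"]))
        return cls(weight=weight, n_docs=0, doc_count={})


def compute_idf(corpus: Iterable) -> IdfTable:
    """IDF(t) = ln(N / n_t) over a corpus of documents.

    A document is its set of unique words; each item of ``corpus`` may be a
    raw string (whitespace-split), an iterable of tokens, or a TokenBag.
    """
    n_docs = 0
    doc_count: Counter[str] = Counter()
    for doc in corpus:
        n_docs += 1
        words = doc.split() if isinstance(doc, str) else doc
        doc_count.update(set(words))
    if n_docs == 0:
        raise ValueError("IDF requires a non-empty corpus")
    weight = {t: math.log(n_docs / c) for t, c in doc_count.items()}
    return IdfTable(weight=weight, n_docs=n_docs, doc_count=dict(doc_count))


def term_frequencies(bags: Iterable[TokenBag]) -> dict[str, float]:
    """Within-class term frequencies from the positive training bags of a term."""
    total: Counter[str] = Counter()
    for bag in bags:
        total.update(bag)
    n = sum(total.values())
    if n == 0:
        return {}
    return {w: c / n for w, c in total.items()}


class EmbeddingBackend(Protocol):
    """Deterministic word -> vector map, defined for every string.

    Character-level contextual models (e.g. a stacked ELMo/BERT encoder)
    satisfy this contract and can be plugged in; the core ships a seeded
    hashed backend so the pipeline is testable offline.
    """

    dim: int
    backend_id: str

    def embed_word(self, word: str) -> np.ndarray: ...


class HashedBackend:
    """Seeded hash-based word vectors: unit-norm, stable across runs/platforms."""

    def __init__(self, dim: int = 128, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.seed = seed
        self.backend_id = f"hashed-d{dim}-s{seed}"
        self._cache: dict[str, np.ndarray] = {}

    def embed_word(self, word: str) -> np.ndarray:
        vec = self._cache.get(word)
        if vec is None:
            digest = hashlib.blake2b(
                word.encode("utf-8"),
                key=self.seed.to_bytes(8, "little", signed=True),
                digest_size=8,
            ).digest()
            child_seed = int.from_bytes(digest, "little") % (2**31 - 1)
            rng = np.random.default_rng(child_seed)
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[word] = vec
        return vec


def _resolve_weights(
    bag: TokenBag,
    weights: IdfTable | None,
    scheme: str,
    tf: Mapping[str, float] | None,
) -> dict[str, float]:
    if scheme == "uniform":
        return {w: 1.0 for w in bag}
    if weights is None:
        raise ValueError(f"scheme {scheme!r} requires an IdfTable")
    known = {w: weights.weight[w] for w in bag if w in weights.weight}
    if not known:
        logger.warning("no token has a stored weight; falling back to uniform")
        return {w: 1.0 for w in bag}
    # multiset mean of the weights present in this bag
    mean_known = sum(known[w] * bag[w] for w in known) / sum(bag[w] for w in known)
    resolved = {w: known.get(w, mean_known) for w in bag}
    if scheme == "tfidf":
        if tf is None:
            raise ValueError("scheme 'tfidf' requires per-term frequencies")
        resolved = {w: resolved[w] * tf.get(w, 0.0) for w in bag}
        if sum(resolved[w] * bag[w] for w in bag) <= 0:
            logger.warning("tfidf weights sum to zero; falling back to uniform")
            return {w: 1.0 for w in bag}
    elif scheme != "idf":
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return resolved


def embed_entity(
    bag: TokenBag,
    backend: EmbeddingBackend,
    weights: IdfTable | None = None,
    scheme: str = "idf",
    tf: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Weighted mean of word vectors over the token multiset.

    An empty bag yields the zero vector; callers that need a missing-score
    marker should test bag emptiness before embedding.
    """
    if not bag:
        return np.zeros(backend.dim)
    w = _resolve_weights(bag, weights, scheme, tf)
    num = np.zeros(backend.dim)
    denom = 0.0
    for word, count in bag.items():
        weight = w[word] * count
        num += weight * backend.embed_word(word)
        denom += weight
    return num / denom


def embed_dataset(
    description: str,
    backend: EmbeddingBackend,
    weights: IdfTable | None = None,
    scheme: str = "idf",
    tf: Mapping[str, float] | None = None,
    lemmatizer: Callable[[str], str] = noop_lemmatizer,
) -> np.ndarray:
    """One pooled vector per sentence of a dataset description.

    Sentences that clean to an empty bag are dropped; a fully empty
    description yields a (0, dim) matrix.
    """
    rows = []
    for sentence in split_sentences(description):
        bag = tokenize_and_clean(sentence, lemmatizer)
        if bag:
            rows.append(embed_entity(bag, backend, weights, scheme, tf))
    if not rows:
        return np.zeros((0, backend.dim))
    return np.vstack(rows)


def embed_samples(
    bags: Mapping[str, TokenBag],
    backend: EmbeddingBackend,
    weights: IdfTable | None = None,
    scheme: str = "idf",
    tf: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Entity-indexed dense embedding matrix (rows in sorted entity order)."""
    ids = sorted(bags)
    mat = np.vstack(
        [embed_entity(bags[i], backend, weights, scheme, tf) for i in ids]
    ) if ids else np.zeros((0, backend.dim))
    return pd.DataFrame(mat, index=pd.Index(ids, name="entity_id"))


def write_embeddings(embeddings: pd.DataFrame, path) -> None:
    embeddings.to_csv(path, sep="\t", index=True)


def read_embeddings(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="entity_id")
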