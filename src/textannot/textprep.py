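"""Turn raw metadata strings into cleaned bags of words.

The cleaning pipeline mirrors how unstructured repository metadata is
prepared for bag-of-words modeling: non-UTF-8-encodable characters are
dropped, punctuation is deleted, whitespace is collapsed, and tokens that
contain digits or URL markers or are shorter than three characters are
removed before lowercasing and lemmatization.  The lemmatizer is an injected
dependency: the default is a no-op, a light English suffix stripper is
provided, and a WordNet-style lemmatizer can be plugged in by the caller.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from functools import lru_cache
from typing import Callable, Iterable

import pandas as pd

TokenBag = Counter

_URL_MARKERS = ("http", "://", "www")

_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+(?=[\"'(\[]?[A-Z0-9])")


@lru_cache(maxsize=None)
def _is_punctuation(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def noop_lemmatizer(word: str) -> str:
    return word


def suffix_lemmatizer(word: str) -> str:
    """Idempotent English plural stripper (ies -> y; trailing s dropped).

    Intentionally conservative: a suffix is only stripped when the remainder
    is still at least three characters, so cleaned tokens survive re-cleaning
    unchanged.
    """
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ss"):
        return word
    if word.endswith("s") and len(word) > 3:
        return word[:-1]
    return word


def tokenize_and_clean(
    text: str, lemmatizer: Callable[[str], str] = noop_lemmatizer
) -> TokenBag:
    """Clean a raw metadata string into a multiset of tokens.

    Pipeline order: drop non-UTF-8-encodable characters, delete punctuation,
    collapse whitespace, split, filter (digits / URL markers / length < 3),
    lowercase, lemmatize.  Token counts are preserved for term-frequency
    weighting.
    """
    text = text.encode("utf-8", "ignore").decode("utf-8", "ignore")
    text = "".join(ch for ch in text if not _is_punctuation(ch))
    bag: TokenBag = Counter()
    for token in text.split():
        folded = token.casefold()
        if any(ch.isdigit() for ch in token):
            continue
        if any(marker in folded for marker in _URL_MARKERS):
            continue
        if len(token) < 3:
            continue
        bag[lemmatizer(token.lower())] += 1
    return bag


def split_sentences(text: str) -> list[str]:
    """Rule-based sentence segmentation.

    Splits after terminal ``. ! ?`` followed by whitespace and an
    uppercase letter or digit (optionally behind an opening quote/bracket),
    so common abbreviations like "e.g. liver" do not break a sentence.
    Text without terminal punctuation is a single sentence.
    """
    if not text.strip():
        return []
    return [seg for seg in _SENTENCE_RE.split(text) if seg.strip()]


def clean_corpus(
    texts: Iterable[str], lemmatizer: Callable[[str], str] = noop_lemmatizer
) -> list[TokenBag]:
    return [tokenize_and_clean(t, lemmatizer) for t in texts]


def read_sample_metadata(path) -> pd.DataFrame:
    """TSV with columns sample_id, dataset_id, text."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "dataset_id", "text"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample metadata needs columns {sorted(required)}")
    return df


def read_dataset_metadata(path) -> pd.DataFrame:
    """TSV with columns dataset_id, description."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"dataset_id", "description"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset metadata needs columns {sorted(required)}")
    return df


def write_token_bags(bags: dict[str, TokenBag], path) -> None:
    """Serialize bags as TSV (entity_id, space-joined tokens with repeats)."""
    rows = [
        {"entity_id": eid, "tokens": " ".join(sorted(bag.elements()))}
        for eid, bag in bags.items()
    ]
    pd.DataFrame(rows, columns=["entity_id", "tokens"]).to_csv(
        path, sep="\t", index=False
    )
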