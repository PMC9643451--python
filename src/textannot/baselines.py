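"""Dictionary-based exact-match NER baseline and external-annotator adapter.

The NER baseline scores a term as present (1) or absent (0) in a piece of
text by exact, case-insensitive, word-boundary matching against a dictionary
built from every term's name and synonyms.  Exact matching is intentionally
brittle — misspellings and substrings do not match — which is precisely the
behavior the learned models are compared against.  Output files of external
binary annotators (e.g. a graph-reasoning pipeline) are consumed through a
simple (entity, term) hit-list adapter.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Mapping

import pandas as pd

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

TermDictionary = dict[str, set[str]]


def build_dictionary(dag: OntologyDAG) -> TermDictionary:
    """Lowercased surface form -> set of term ids, from names and synonyms.

    Obsolete terms are excluded; multi-word forms are kept verbatim (matching
    happens on whitespace-normalized raw text, since dictionary entries may
    be short or contain digits and must not go through token filtering).
    """
    dictionary: TermDictionary = {}
    for term in dag.terms:
        if term in dag.obsolete:
            continue
        forms = [dag.names.get(term, "")] + dag.synonyms.get(term, [])
        for form in forms:
            form = " ".join(form.lower().split())
            if form:
                dictionary.setdefault(form, set()).add(term)
    return dictionary


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def tag_text(text: str, dictionary: TermDictionary) -> set[str]:
    """All term ids whose surface forms occur in the text at word boundaries."""
    norm = _normalize(text)
    hits: set[str] = set()
    for form, terms in dictionary.items():
        if re.search(rf"(?<!\w){re.escape(form)}(?!\w)", norm):
            hits |= terms
    return hits


def tagger_score(text: str, dictionary: TermDictionary, term: str) -> int:
    """1 iff any surface form of ``term`` occurs as an exact word-boundary
    match in the (case-insensitive, whitespace-normalized) text; else 0.

    No hierarchy expansion: a match to a descendant term does not set its
    ancestors.
    """
    norm = _normalize(text)
    for form, terms in dictionary.items():
        if term in terms and re.search(rf"(?<!\w){re.escape(form)}(?!\w)", norm):
            return 1
    return 0


def load_external_binary_annotations(
    path,
    terms: Iterable[str],
    entities: Iterable[str],
) -> pd.DataFrame:
    """Adapter for external annotator hit lists.

    ``path`` is a TSV of (entity_id, term_id) hits.  Returns a binary
    (entity x term) frame: 1 for listed pairs, 0 elsewhere.  Rows naming an
    unknown term are skipped with a warning; duplicates are idempotent.
    """
    terms = sorted(set(terms))
    entities = sorted(set(entities))
    out = pd.DataFrame(0, index=entities, columns=terms, dtype="int8")
    hits = pd.read_csv(path, sep="\t", dtype=str)
    required = {"entity_id", "term_id"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hit list needs columns {sorted(required)}")
    term_set, entity_set = set(terms), set(entities)
    for row in hits.itertuples(index=False):
        if row.term_id not in term_set:
            logger.warning("skipping hit with unknown term %s", row.term_id)
            continue
        if row.entity_id not in entity_set:
            logger.warning("skipping hit with unknown entity %s", row.entity_id)
            continue
        out.at[row.entity_id, row.term_id] = 1
    return out
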