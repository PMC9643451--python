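"""Ontology parsing, transitive closures, and gold-standard label construction.

Sample annotations to tissue/cell-type terms are propagated over the ontology
graph following the true-path rule: a sample is a positive example of a term
if it is directly annotated to that term or to any of its descendants; a
sample annotated only to a strict ancestor of the term is ambiguous and is
ignored (excluded from training and testing); every other sample is a
negative.  Dataset-level labels are derived by strict majority vote over the
dataset's samples.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

# Ternary label codes used throughout the package.
POS: int = 1
NEG: int = 0
IGNORE: int = -1

LABEL_NAMES = {POS: "pos", NEG: "neg", IGNORE: "ignore"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

#: Ancestor relations retained by default.  The extended anatomy + cell
#: ontology is navigated through both subclass (is_a) and partonomy
#: (part_of) edges, the convention used by ontology-based sample curation
#: pipelines; the set is configurable in :func:`parse_obo`.
DEFAULT_EDGE_TYPES = frozenset({"is_a", "part_of"})

_SYNONYM_RE = re.compile(r'"([^"]*)"')


class OntologyStructureError(ValueError):
    """Raised when the retained edge set is not a DAG."""


@dataclass
class OntologyDAG:
    """A directed acyclic graph of ontology terms.

    Edges point child -> parent, so the set of nodes reachable from a term
    is its ancestor set.
    """

    graph: nx.DiGraph
    names: dict[str, str]
    synonyms: dict[str, list[str]]
    obsolete: set[str] = field(default_factory=set)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _desc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"term {term!r} is not in the ontology")

    def ancestors(self, term: str) -> frozenset[str]:
        """Strict ancestors of ``term`` (term itself excluded)."""
        self._require(term)
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self.graph, term))
        return self._anc_cache[term]

    def descendants(self, term: str) -> frozenset[str]:
        """Strict descendants of ``term`` (term itself excluded)."""
        self._require(term)
        if term not in self._desc_cache:
            self._desc_cache[term] = frozenset(nx.ancestors(self.graph, term))
        return self._desc_cache[term]

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self.graph.predecessors(term))

    def leaves(self) -> list[str]:
        return sorted(t for t in self.graph.nodes if self.graph.in_degree(t) == 0)


def parse_obo(path, edge_types: Iterable[str] = DEFAULT_EDGE_TYPES) -> OntologyDAG:
    """Load an OBO file, keeping only edges of the requested relation types.

    Non-obsolete ``[Term]`` stanzas are loaded with their names and synonyms.
    Obsolete terms are skipped with a warning.  Edges pointing at undeclared
    terms are dropped with a warning.  A cycle among the retained edges is a
    structural error.
    """
    edge_types = set(edge_types)
    raw = obonet.read_obo(path, ignore_obsolete=False)

    obsolete: set[str] = set()
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    for node, data in raw.nodes(data=True):
        if str(data.get("is_obsolete", "false")).lower() == "true":
            obsolete.add(node)
            logger.warning("skipping obsolete term %s", node)
            continue
        if "name" not in data:
            # referenced but never declared with a [Term] stanza
            continue
        names[node] = data["name"]
        syns = []
        for raw_syn in data.get("synonym", []):
            m = _SYNONYM_RE.search(raw_syn)
            if m:
                syns.append(m.group(1))
        synonyms[node] = syns

    graph = nx.DiGraph()
    graph.add_nodes_from(names)
    for child, parent, rel in raw.edges(keys=True):
        if rel not in edge_types:
            continue
        if child not in names:
            continue
        if parent not in names:
            logger.warning(
                "dropping %s edge %s -> %s: target not declared", rel, child, parent
            )
            continue
        graph.add_edge(child, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyStructureError(
            f"ontology contains a cycle through term {cycle[0][0]!r}"
        )
    return OntologyDAG(graph=graph, names=names, synonyms=synonyms, obsolete=obsolete)


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialize a DAG to the OBO dialect consumed by :func:`parse_obo`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {dag.names.get(term, term)}\n")
            for syn in dag.synonyms.get(term, []):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(dag.parents(term)):
                rel = dag.graph.edges[term, parent].get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


@dataclass
class AnnotationTable:
    """Direct sample -> term annotations plus sample -> dataset membership."""

    direct: dict[str, set[str]]
    dataset_of: dict[str, str]

    def __post_init__(self):
        missing = set(self.direct) - set(self.dataset_of)
        if missing:
            raise ValueError(f"samples without a dataset: {sorted(missing)[:5]}")

    @property
    def samples(self) -> list[str]:
        return sorted(self.direct)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = 0) -> "AnnotationTable":
        """Build from a long table with columns sample_id, dataset_id, term_id.

        A sample listed under several datasets is assigned to a single one by
        a seeded deterministic choice.
        """
        required = {"sample_id", "dataset_id", "term_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        direct: dict[str, set[str]] = {}
        datasets: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            direct.setdefault(row.sample_id, set()).add(row.term_id)
            datasets.setdefault(row.sample_id, set()).add(row.dataset_id)
        rng = random.Random(seed)
        dataset_of: dict[str, str] = {}
        for sample in sorted(datasets):
            cands = sorted(datasets[sample])
            if len(cands) > 1:
                logger.warning(
                    "sample %s appears in %d datasets; picking one at random",
                    sample, len(cands),
                )
            dataset_of[sample] = rng.choice(cands)
        return cls(direct=direct, dataset_of=dataset_of)

    @classmethod
    def from_tsv(cls, path, seed: int = 0) -> "AnnotationTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str), seed=seed)

    def validate(self, dag: OntologyDAG) -> None:
        unknown = {t for ts in self.direct.values() for t in ts} - dag.terms
        if unknown:
            raise KeyError(f"annotated terms not in the ontology: {sorted(unknown)[:5]}")


@dataclass
class LabelMatrix:
    """Ternary (entity x term) labels at sample or dataset granularity."""

    granularity: str  # "sample" | "dataset"
    data: pd.DataFrame  # int8 values in {POS, NEG, IGNORE}

    def column(self, term: str) -> pd.Series:
        return self.data[term]

    @property
    def terms(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path) -> None:
        long = self.data.stack().rename("code").reset_index()
        long.columns = ["entity_id", "term_id", "code"]
        long["label"] = long["code"].map(LABEL_NAMES)
        long[["entity_id", "term_id", "label"]].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, granularity: str) -> "LabelMatrix":
        long = pd.read_csv(path, sep="\t", dtype=str)
        long["code"] = long["label"].map(LABEL_CODES).astype("int8")
        wide = long.pivot(index="entity_id", columns="term_id", values="code")
        return cls(granularity=granularity, data=wide.astype("int8"))


def propagate_sample_labels(
    dag: OntologyDAG, ann: AnnotationTable, term: str
) -> pd.Series:
    """Ternary sample labels for one term under the true-path rule.

    POS if any direct annotation is the term or one of its descendants; else
    IGNORE if any direct annotation is a strict ancestor of the term; else
    NEG.  POS takes precedence over IGNORE.
    """
    dag._require(term)
    positive_set = dag.descendants(term) | {term}
    ancestor_set = dag.ancestors(term)
    out = {}
    for sample in ann.samples:
        direct = ann.direct[sample]
        if direct & positive_set:
            out[sample] = POS
        elif direct & ancestor_set:
            out[sample] = IGNORE
        else:
            out[sample] = NEG
    return pd.Series(out, name=term, dtype="int8")


def build_sample_labels(
    dag: OntologyDAG, ann: AnnotationTable, terms: Iterable[str]
) -> LabelMatrix:
    cols = {t: propagate_sample_labels(dag, ann, t) for t in terms}
    return LabelMatrix(granularity="sample", data=pd.DataFrame(cols).astype("int8"))


def label_datasets(sample_labels: pd.Series, ann: AnnotationTable) -> pd.Series:
    """Dataset labels by strict majority over member samples.

    POS if a strict majority of the dataset's samples are POS; else IGNORE if
    a strict majority are IGNORE; else NEG.
    """
    groups: dict[str, list[int]] = {}
    for sample, label in sample_labels.items():
        groups.setdefault(ann.dataset_of[sample], []).append(int(label))
    out = {}
    for dataset in sorted(groups):
        labels = groups[dataset]
        n = len(labels)
        if n == 0:
            raise ValueError(f"dataset {dataset!r} has no samples")
        if sum(lb == POS for lb in labels) * 2 > n:
            out[dataset] = POS
        elif sum(lb == IGNORE for lb in labels) * 2 > n:
            out[dataset] = IGNORE
        else:
            out[dataset] = NEG
    return pd.Series(out, name=sample_labels.name, dtype="int8")


def build_dataset_labels(sample_labels: LabelMatrix, ann: AnnotationTable) -> LabelMatrix:
    cols = {t: label_datasets(sample_labels.column(t), ann) for t in sample_labels.terms}
    return LabelMatrix(granularity="dataset", data=pd.DataFrame(cols).astype("int8"))


def select_trainable_terms(
    dataset_labels: LabelMatrix, min_pos_datasets: int = 3
) -> set[str]:
    """Terms with positively labeled samples from enough distinct datasets."""
    counts = (dataset_labels.data == POS).sum(axis=0)
    return set(counts.index[counts >= min_pos_datasets])


def assign_anatomical_systems(
    dag: OntologyDAG,
    system_roots: Iterable[str],
    model_terms: Iterable[str],
    min_models_per_system: int = 8,
) -> dict[str, set[str]]:
    """Map each model term to the high-level system roots among its ancestors.

    Systems with ``min_models_per_system`` or fewer member terms are
    dissolved and their members re-labeled NA.  A term with no surviving
    system maps to the empty set (NA).
    """
    system_roots = list(system_roots)
    for root in system_roots:
        dag._require(root)
    mapping = {
        t: {r for r in system_roots if r == t or r in dag.ancestors(t)}
        for t in model_terms
    }
    counts = {r: sum(r in systems for systems in mapping.values()) for r in system_roots}
    kept = {r for r, c in counts.items() if c > min_models_per_system}
    return {t: systems & kept for t, systems in mapping.items()}
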