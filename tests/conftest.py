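import random

import networkx as nx
import numpy as np
import pytest

from textannot.ontology import AnnotationTable, OntologyDAG


def make_dag(edges, extra_terms=(), names=None, synonyms=None, obsolete=()):
    """Build an OntologyDAG directly from (child, parent, relation) tuples."""
    g = nx.DiGraph()
    for item in edges:
        child, parent = item[0], item[1]
        rel = item[2] if len(item) > 2 else "is_a"
        g.add_edge(child, parent, relation=rel)
    g.add_nodes_from(extra_terms)
    all_names = {t: (names or {}).get(t, f"name of {t}") for t in g.nodes}
    return OntologyDAG(
        graph=g,
        names=all_names,
        synonyms={t: (synonyms or {}).get(t, []) for t in g.nodes},
        obsolete=set(obsolete),
    )


@pytest.fixture
def chain_dag():
    """A <- B <- C: C is_a B is_a A."""
    return make_dag([("C", "B"), ("B", "A")], extra_terms=["D"])


def random_dag_and_annotations(rng: random.Random, max_terms: int = 20):
    """A random DAG (edges only from later to earlier terms, hence acyclic)
    plus random direct sample annotations."""
    n = rng.randint(2, max_terms)
    terms = [f"T{i}" for i in range(n)]
    edges = []
    for i in range(1, n):
        for j in range(i):
            if rng.random() < 0.25:
                edges.append((terms[i], terms[j]))
    dag = make_dag(edges, extra_terms=terms)
    n_samples = rng.randint(1, 8)
    direct = {
        f"s{k}": set(rng.sample(terms, rng.randint(1, min(3, n))))
        for k in range(n_samples)
    }
    ann = AnnotationTable(
        direct=direct, dataset_of={s: "d0" for s in direct}
    )
    return dag, ann, terms


def brute_force_labels(dag: OntologyDAG, direct: set, term: str) -> int:
    """Oracle: POS/IGNORE/NEG via an explicit transitive-closure matrix."""
    from textannot.ontology import IGNORE, NEG, POS

    terms = sorted(dag.terms)
    idx = {t: i for i, t in enumerate(terms)}
    n = len(terms)
    reach = np.zeros((n, n), dtype=bool)  # reach[a, b]: b is an ancestor of a
    for child, parent in dag.graph.edges:
        reach[idx[child], idx[parent]] = True
    for _ in range(n):  # Floyd-Warshall-style saturation
        new = reach | (reach @ reach)
        if (new == reach).all():
            break
        reach = new
    t = idx[term]
    if any(a == term or reach[idx[a], t] for a in direct):
        return POS
    if any(reach[t, idx[a]] for a in direct):
        return IGNORE
    return NEG


class FixedBackend:
    """Test backend with hand-specified vectors; unknown words get zeros."""

    def __init__(self, vectors: dict, dim: int):
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dim = dim
        self.backend_id = "fixed"

    def embed_word(self, word):
        return self.vectors.get(word, np.zeros(self.dim))
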