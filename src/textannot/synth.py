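"""Synthetic ontology and metadata corpus generator.

Produces a toy anatomy-like ontology (a forest of systems under a shared
root) and sample/dataset metadata tables with a controllable tissue signal:
each positive sample draws a tunable fraction of its tokens from its term's
signature vocabulary and the rest from a shared background vocabulary, with
URL / numeric / short-token noise injected on top.  Signature vocabularies
are assigned hierarchically — a child term inherits a fraction of its
parent's vocabulary — so models of related terms share predictive words the
way anatomically related tissues share descriptive language in real
metadata.

Default shape parameters mirror typical repository metadata: 16 samples per
dataset, ~30-word sample descriptions, ~8-sentence dataset descriptions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .ontology import AnnotationTable, OntologyDAG

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"


class _WordMint:
    """Deterministic generator of unique, digit-free pseudo-words."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int = 3) -> str:
        while True:
            w = "".join(
                self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
                for _ in range(n_syllables)
            )
            if w not in self.used:
                self.used.add(w)
                return w

    def words(self, n: int, n_syllables: int = 3) -> list[str]:
        return [self.word(n_syllables) for _ in range(n)]


def generate_toy_ontology(
    n_systems: int, terms_per_system: int, depth: int, seed: int = 0
) -> tuple[OntologyDAG, list[str]]:
    """A forest of is_a/part_of trees under system roots plus a shared root.

    Total term count is ``n_systems * terms_per_system + n_systems + 1``.
    ``depth`` bounds how far below a system root a term may sit.
    """
    if min(n_systems, terms_per_system, depth) < 1:
        raise ValueError("all counts must be >= 1")
    rng = random.Random(seed)
    mint = _WordMint(rng)
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}

    root = "TOY:0000000"
    graph.add_node(root)
    names[root] = "anatomical entity"
    synonyms[root] = []
    node_depth = {root: 0}

    counter = 1
    system_roots: list[str] = []
    for s in range(n_systems):
        sys_id = f"TOY:{counter:07d}"
        counter += 1
        graph.add_node(sys_id)
        graph.add_edge(sys_id, root, relation="is_a")
        names[sys_id] = f"{mint.word()} system"
        synonyms[sys_id] = []
        node_depth[sys_id] = 0  # depth counted below the system root
        system_roots.append(sys_id)

        members = [sys_id]
        for _ in range(terms_per_system):
            term_id = f"TOY:{counter:07d}"
            counter += 1
            eligible = [m for m in members if node_depth[m] < depth]
            parent = rng.choice(eligible)
            relation = "part_of" if rng.random() < 0.2 and parent != sys_id else "is_a"
            graph.add_node(term_id)
            graph.add_edge(term_id, parent, relation=relation)
            names[term_id] = mint.word()
            synonyms[term_id] = [mint.word()]
            node_depth[term_id] = node_depth[parent] + 1
            members.append(term_id)

    return (
        OntologyDAG(graph=graph, names=names, synonyms=synonyms, obsolete=set()),
        system_roots,
    )


@dataclass
class CorpusSpec:
    """Generation conditions for a synthetic metadata corpus."""

    n_terms: int = 10
    n_datasets_per_term: int = 4
    samples_per_dataset: int = 16
    signature_vocab_size: int = 15
    background_vocab_size: int = 300
    signal: float = 0.8
    tokens_per_sample: int = 30
    inherit_fraction: float = 0.25
    url_noise_rate: float = 0.05
    number_noise_rate: float = 0.05
    short_token_rate: float = 0.05
    sentences_per_dataset: int = 8
    tokens_per_sentence: int = 12
    seed: int = 0


def _signature_vocabularies(
    dag: OntologyDAG, spec: CorpusSpec, mint: _WordMint, rng: random.Random
) -> dict[str, list[str]]:
    """Own vocabulary per term, plus an inherited fraction of each parent's
    effective vocabulary, assigned top-down."""
    effective: dict[str, list[str]] = {}
    order = list(nx.topological_sort(dag.graph.reverse()))  # root first
    for term in order:
        vocab = list(mint.words(spec.signature_vocab_size))
        for parent in sorted(dag.parents(term)):
            pool = effective[parent]
            n_inherit = int(round(spec.inherit_fraction * len(pool)))
            vocab.extend(rng.sample(pool, min(n_inherit, len(pool))))
        effective[term] = sorted(set(vocab))
    return effective


def _noise_tokens(spec: CorpusSpec, rng: random.Random) -> list[str]:
    noise = []
    n = spec.tokens_per_sample

    def binom(p: float) -> int:
        return sum(rng.random() < p for _ in range(n))

    for _ in range(binom(spec.url_noise_rate)):
        noise.append(f"https://repo.example.org/acc{rng.randrange(10**6)}")
    for _ in range(binom(spec.number_noise_rate)):
        noise.append(f"{rng.randrange(100)}hr")
    for _ in range(binom(spec.short_token_rate)):
        noise.append(rng.choice(["of", "at", "in", "id", "no"]))
    return noise


def generate_corpus(
    spec: CorpusSpec,
    dag: OntologyDAG,
    terms: list[str] | None = None,
    return_vocab: bool = False,
):
    """Sample table, dataset table, and annotations with controlled signal.

    Every sample is annotated to exactly one leaf term; all samples of a
    dataset share that term, so datasets are coherent the way real studies
    are.  At ``signal=0`` token draws are background-only and identically
    distributed across terms.
    """
    rng = random.Random(spec.seed)
    mint = _WordMint(rng)
    if terms is None:
        terms = dag.leaves()[: spec.n_terms]
    if len(terms) < spec.n_terms:
        raise ValueError(
            f"ontology offers {len(terms)} usable terms; spec wants {spec.n_terms}"
        )
    terms = list(terms[: spec.n_terms])
    signature = _signature_vocabularies(dag, spec, mint, rng)
    background = mint.words(spec.background_vocab_size)

    sample_rows, dataset_rows, ann_rows = [], [], []
    for t_idx, term in enumerate(terms):
        vocab = signature[term]
        for d in range(spec.n_datasets_per_term):
            dataset_id = f"DS{t_idx:02d}{d:02d}"
            member_tokens: list[str] = []
            for s in range(spec.samples_per_dataset):
                sample_id = f"S{t_idx:02d}{d:02d}{s:03d}"
                tokens = [
                    rng.choice(vocab) if rng.random() < spec.signal else rng.choice(background)
                    for _ in range(spec.tokens_per_sample)
                ]
                member_tokens.extend(tokens)
                tokens = tokens + _noise_tokens(spec, rng)
                rng.shuffle(tokens)
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "dataset_id": dataset_id,
                        "text": " ".join(tokens),
                    }
                )
                ann_rows.append(
                    {
                        "sample_id": sample_id,
                        "dataset_id": dataset_id,
                        "term_id": term,
                    }
                )
            sentences = []
            for _ in range(spec.sentences_per_dataset):
                words = [rng.choice(member_tokens) for _ in range(spec.tokens_per_sentence)]
                sentences.append(" ".join(words).capitalize() + ".")
            dataset_rows.append(
                {"dataset_id": dataset_id, "description": " ".join(sentences)}
            )

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "dataset_id", "text"])
    datasets = pd.DataFrame(dataset_rows, columns=["dataset_id", "description"])
    ann = AnnotationTable.from_frame(pd.DataFrame(ann_rows), seed=spec.seed)
    if return_vocab:
        return samples, datasets, ann, {"signature": signature, "background": background}
    return samples, datasets, ann


def study_corpus(
    signal: float = 0.8, seed: int = 0, spec: CorpusSpec | None = None
) -> dict:
    """Convenience bundle at the package's reference study conditions:
    10 leaf terms, 4 datasets per term, 16 samples per dataset."""
    if spec is None:
        spec = CorpusSpec(signal=signal, seed=seed)
    dag, system_roots = generate_toy_ontology(
        n_systems=2, terms_per_system=10, depth=2, seed=seed
    )
    samples, datasets, ann = generate_corpus(spec, dag)
    return {
        "dag": dag,
        "system_roots": system_roots,
        "samples": samples,
        "datasets": datasets,
        "annotations": ann,
        "terms": sorted({t for ts in ann.direct.values() for t in ts}),
        "spec": spec,
    }


def write_corpus(
    outdir,
    dag: OntologyDAG,
    samples: pd.DataFrame,
    datasets: pd.DataFrame,
    ann: AnnotationTable,
) -> None:
    """Emit the TSV/OBO files consumed by the rest of the pipeline."""
    from pathlib import Path

    from .ontology import write_obo

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_obo(dag, outdir / "ontology.obo")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    datasets.to_csv(outdir / "datasets.tsv", sep="\t", index=False)
    rows = [
        {"sample_id": s, "dataset_id": ann.dataset_of[s], "term_id": t}
        for s in ann.samples
        for t in sorted(ann.direct[s])
    ]
    pd.DataFrame(rows, columns=["sample_id", "dataset_id", "term_id"]).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False
    )
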