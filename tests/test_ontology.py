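import random

import pandas as pd
import pytest

from textannot.ontology import (
    IGNORE,
    NEG,
    POS,
    AnnotationTable,
    LabelMatrix,
    OntologyStructureError,
    assign_anatomical_systems,
    build_dataset_labels,
    build_sample_labels,
    label_datasets,
    parse_obo,
    propagate_sample_labels,
    select_trainable_terms,
    write_obo,
)

from conftest import brute_force_labels, make_dag, random_dag_and_annotations

CHAIN_OBO = """format-version: 1.2

[Term]
id: A
name: alpha

[Term]
id: B
name: beta
is_a: A

[Term]
id: C
name: gamma
{c_edge}
"""


def _write(tmp_path, text, name="onto.obo"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParseObo:
    def test_is_a_chain_closure(self, tmp_path):
        dag = parse_obo(_write(tmp_path, CHAIN_OBO.format(c_edge="is_a: B")))
        assert dag.ancestors("C") == {"B", "A"}
        assert dag.descendants("A") == {"B", "C"}

    def test_part_of_participates_in_closure(self, tmp_path):
        path = _write(tmp_path, CHAIN_OBO.format(c_edge="relationship: part_of B"))
        dag = parse_obo(path, edge_types={"is_a", "part_of"})
        # oracle: transitive closure over the mixed-relation graph
        oracle = make_dag([("C", "B", "part_of"), ("B", "A", "is_a")])
        assert dag.ancestors("C") == oracle.ancestors("C") == {"B", "A"}

    def test_excluded_edge_type_breaks_closure(self, tmp_path):
        path = _write(tmp_path, CHAIN_OBO.format(c_edge="relationship: part_of B"))
        dag = parse_obo(path, edge_types={"is_a"})
        assert dag.ancestors("C") == set()

    def test_two_cycle_is_structural_error(self, tmp_path):
        text = "[Term]\nid: A\nname: a\nis_a: B\n\n[Term]\nid: B\nname: b\nis_a: A\n"
        with pytest.raises(OntologyStructureError, match="cycle"):
            parse_obo(_write(tmp_path, text))

    def test_dangling_edge_dropped_with_warning(self, tmp_path, caplog):
        text = "[Term]\nid: A\nname: a\nis_a: ZZZ\n"
        with caplog.at_level("WARNING"):
            dag = parse_obo(_write(tmp_path, text))
        assert "ZZZ" not in dag.terms
        assert dag.ancestors("A") == set()
        assert any("not declared" in r.message for r in caplog.records)

    def test_obsolete_terms_skipped(self, tmp_path):
        text = "[Term]\nid: A\nname: a\n\n[Term]\nid: B\nname: b\nis_obsolete: true\n"
        dag = parse_obo(_write(tmp_path, text))
        assert "B" not in dag.terms
        assert "B" in dag.obsolete

    def test_synonyms_parsed(self, tmp_path):
        text = '[Term]\nid: A\nname: brain\nsynonym: "encephalon" EXACT []\n'
        dag = parse_obo(_write(tmp_path, text))
        assert dag.synonyms["A"] == ["encephalon"]

    def test_roundtrip_preserves_closures(self, tmp_path):
        dag = make_dag(
            [("C", "B", "part_of"), ("B", "A"), ("D", "A")],
            synonyms={"C": ["gamma cell"]},
        )
        write_obo(dag, tmp_path / "rt.obo")
        back = parse_obo(tmp_path / "rt.obo")
        assert back.terms == dag.terms
        for t in dag.terms:
            assert back.ancestors(t) == dag.ancestors(t)
        assert back.synonyms["C"] == ["gamma cell"]


class TestPropagation:
    def _ann(self, direct):
        return AnnotationTable(
            direct=direct, dataset_of={s: "d0" for s in direct}
        )

    def test_descendant_annotation_is_positive(self, chain_dag):
        labels = propagate_sample_labels(chain_dag, self._ann({"s": {"C"}}), "A")
        assert labels["s"] == POS

    def test_ancestor_annotation_is_ignored(self, chain_dag):
        labels = propagate_sample_labels(chain_dag, self._ann({"s": {"A"}}), "C")
        assert labels["s"] == IGNORE

    def test_unrelated_annotation_is_negative(self, chain_dag):
        labels = propagate_sample_labels(chain_dag, self._ann({"s": {"D"}}), "C")
        assert labels["s"] == NEG

    def test_pos_takes_precedence_over_ignore(self, chain_dag):
        # annotations hit both a descendant (C) and an ancestor (A) of B
        labels = propagate_sample_labels(chain_dag, self._ann({"s": {"A", "C"}}), "B")
        assert labels["s"] == POS

    def test_unknown_term_raises(self, chain_dag):
        with pytest.raises(KeyError):
            propagate_sample_labels(chain_dag, self._ann({"s": {"A"}}), "Z")

    def test_matches_transitive_closure_oracle_on_random_dags(self):
        rng = random.Random(20240)
        for _ in range(30):
            dag, ann, terms = random_dag_and_annotations(rng)
            for term in terms:
                got = propagate_sample_labels(dag, ann, term)
                for s in ann.samples:
                    assert got[s] == brute_force_labels(dag, ann.direct[s], term)

    def test_true_path_rule_and_exhaustiveness(self):
        rng = random.Random(77)
        for _ in range(10):
            dag, ann, terms = random_dag_and_annotations(rng)
            mat = build_sample_labels(dag, ann, terms)
            assert mat.data.isin([POS, NEG, IGNORE]).all().all()
            for t in terms:
                pos_t = set(mat.data.index[mat.column(t) == POS])
                for a in dag.ancestors(t):
                    pos_a = set(mat.data.index[mat.column(a) == POS])
                    assert pos_t <= pos_a


class TestDatasetLabels:
    def _setup(self, labels_by_sample):
        samples = list(labels_by_sample)
        ann = AnnotationTable(
            direct={s: {"T"} for s in samples},
            dataset_of={s: "d0" for s in samples},
        )
        series = pd.Series(labels_by_sample, name="T", dtype="int8")
        return series, ann

    def test_majority_positive(self):
        series, ann = self._setup(
            {"a": POS, "b": POS, "c": POS, "d": NEG, "e": IGNORE}
        )
        assert label_datasets(series, ann)["d0"] == POS

    def test_majority_ignored(self):
        series, ann = self._setup({"a": IGNORE, "b": IGNORE, "c": IGNORE, "d": NEG})
        assert label_datasets(series, ann)["d0"] == IGNORE

    def test_tie_falls_to_negative(self):
        series, ann = self._setup({"a": POS, "b": POS, "c": NEG, "d": NEG})
        assert label_datasets(series, ann)["d0"] == NEG

    def test_invariant_under_sample_order(self):
        base = {"a": POS, "b": NEG, "c": POS, "d": IGNORE, "e": POS}
        series, ann = self._setup(base)
        shuffled = series.sample(frac=1, random_state=3)
        assert label_datasets(series, ann).equals(label_datasets(shuffled, ann))


class TestTermSelection:
    def _dataset_matrix(self, pos_counts):
        # build a dataset-granularity matrix with the requested POS counts
        n_ds = max(pos_counts.values()) + 2
        data = {}
        for term, k in pos_counts.items():
            col = [POS] * k + [NEG] * (n_ds - k)
            data[term] = pd.Series(col, index=[f"d{i}" for i in range(n_ds)])
        return LabelMatrix(granularity="dataset", data=pd.DataFrame(data).astype("int8"))

    def test_threshold_is_at_least_three(self):
        mat = self._dataset_matrix({"kept": 3, "dropped": 2})
        assert select_trainable_terms(mat) == {"kept"}

    def test_threshold_configurable(self):
        mat = self._dataset_matrix({"t1": 1, "t0": 0})
        assert select_trainable_terms(mat, min_pos_datasets=1) == {"t1"}


class TestAnatomicalSystems:
    def test_mapping_and_na_and_dissolution(self):
        # sysA has 9 member terms (kept: > 8), sysB has 2 (dissolved), one orphan
        edges = [(f"a{i}", "sysA") for i in range(9)]
        edges += [("b0", "sysB"), ("b1", "sysB")]
        dag = make_dag(edges, extra_terms=["orphan"])
        model_terms = [f"a{i}" for i in range(9)] + ["b0", "b1", "orphan"]
        out = assign_anatomical_systems(dag, ["sysA", "sysB"], model_terms)
        assert out["a0"] == {"sysA"}
        assert out["b0"] == set()  # system dissolved -> NA
        assert out["orphan"] == set()

    def test_exactly_threshold_members_dissolved(self):
        edges = [(f"a{i}", "sysA") for i in range(8)]
        dag = make_dag(edges)
        out = assign_anatomical_systems(dag, ["sysA"], [f"a{i}" for i in range(8)])
        assert all(v == set() for v in out.values())


class TestAnnotationTable:
    def test_multi_dataset_sample_gets_seeded_choice(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2"],
                "dataset_id": ["d1", "d2", "d1"],
                "term_id": ["T", "T", "T"],
            }
        )
        a = AnnotationTable.from_frame(df, seed=5)
        b = AnnotationTable.from_frame(df, seed=5)
        assert a.dataset_of == b.dataset_of
        assert a.dataset_of["s1"] in {"d1", "d2"}

    def test_label_matrix_tsv_roundtrip(self, chain_dag, tmp_path):
        ann = AnnotationTable(
            direct={"s1": {"C"}, "s2": {"D"}},
            dataset_of={"s1": "d1", "s2": "d1"},
        )
        mat = build_sample_labels(chain_dag, ann, ["A", "B", "C", "D"])
        mat.to_tsv(tmp_path / "labels.tsv")
        back = LabelMatrix.from_tsv(tmp_path / "labels.tsv", granularity="sample")
        pd.testing.assert_frame_equal(
            back.data.sort_index(axis=1), mat.data.sort_index(axis=1), check_names=False
        )

    def test_dataset_labels_from_propagated_chain(self, chain_dag):
        ann = AnnotationTable(
            direct={"s1": {"C"}, "s2": {"C"}, "s3": {"D"}},
            dataset_of={"s1": "d1", "s2": "d1", "s3": "d1"},
        )
        sample_mat = build_sample_labels(chain_dag, ann, ["A", "D"])
        ds_mat = build_dataset_labels(sample_mat, ann)
        assert ds_mat.column("A")["d1"] == POS  # 2/3 POS via descendant C
        assert ds_mat.column("D")["d1"] == NEG
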