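"""Min-occurrence filtering, node equating, cosine association and TMFG."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_association, toy_records
from oracles import tmfg_naive

from fluencynet import (
    AssociationMatrix,
    EstimationError,
    build_response_matrix,
    cosine_association,
    equate_nodes,
    filter_min_occurrence,
    tmfg_filter,
)
from fluencynet.network_estimation import (
    read_edgelist_csv,
    read_graphml,
    write_edgelist_csv,
    write_graphml,
)


def matrix_from_lists(lists, group="A"):
    return build_response_matrix(toy_records(group, lists))


class TestFilterMinOccurrence:
    def test_column_sum_threshold(self):
        mat = matrix_from_lists(
            {"P1": ["a", "b", "c"], "P2": ["b", "c"], "P3": ["c"]}
        )  # column sums a=1, b=2, c=3
        out = filter_min_occurrence(mat, min_count=2)
        assert out.exemplars == ["b", "c"]
        assert out.participants == mat.participants

    def test_min_count_one_is_identity(self):
        mat = matrix_from_lists({"P1": ["a"], "P2": ["b"]})
        out = filter_min_occurrence(mat, min_count=1)
        assert out.exemplars == mat.exemplars

    def test_empty_result_raises(self):
        mat = matrix_from_lists({"P1": ["a"], "P2": ["b"]})
        with pytest.raises(EstimationError, match="insufficient"):
            filter_min_occurrence(mat, min_count=2)

    def test_matches_brute_force_count_filter(self):
        rng = np.random.default_rng(11)
        lists = {
            f"P{i}": [f"w{j}" for j in rng.choice(30, size=8, replace=False)]
            for i in range(12)
        }
        mat = matrix_from_lists(lists)
        out = filter_min_occurrence(mat, min_count=3)
        counts = {}
        for words in lists.values():
            for w in set(words):
                counts[w] = counts.get(w, 0) + 1
        assert set(out.exemplars) == {w for w, c in counts.items() if c >= 3}


class TestEquateNodes:
    def test_intersection(self):
        a = matrix_from_lists({"P1": ["cat", "dog", "fox"], "P2": ["cat", "dog", "fox"]})
        b = matrix_from_lists({"Q1": ["cat", "dog", "owl"], "Q2": ["cat"]}, group="B")
        ea, eb = equate_nodes(a, b)
        assert ea.exemplars == eb.exemplars == ["cat", "dog"]

    def test_identical_sets_unchanged(self):
        a = matrix_from_lists({"P1": ["cat", "dog"]})
        b = matrix_from_lists({"Q1": ["dog", "cat"]}, group="B")
        ea, eb = equate_nodes(a, b)
        assert ea.exemplars == a.exemplars and eb.exemplars == b.exemplars

    def test_empty_intersection_raises(self):
        a = matrix_from_lists({"P1": ["cat"]})
        b = matrix_from_lists({"Q1": ["owl"]}, group="B")
        with pytest.raises(EstimationError, match="share no exemplars"):
            equate_nodes(a, b)

    def test_study_scale_matches_set_intersection(self):
        from fluencynet import study_cohort

        rec_a, rec_b, _, _ = study_cohort(3)
        fa = filter_min_occurrence(build_response_matrix(rec_a))
        fb = filter_min_occurrence(build_response_matrix(rec_b))
        ea, eb = equate_nodes(fa, fb)
        assert ea.exemplars == sorted(set(fa.exemplars) & set(fb.exemplars))
        assert ea.exemplars == eb.exemplars


class TestCosineAssociation:
    def test_always_cooccur_gives_one(self):
        mat = matrix_from_lists({"P1": ["a", "b"], "P2": ["a", "b"], "P3": ["a", "b"]})
        assoc = cosine_association(mat)
        assert assoc.values[0, 1] == pytest.approx(1.0)

    def test_never_cooccur_gives_zero(self):
        mat = matrix_from_lists({"P1": ["a"], "P2": ["b"]})
        assoc = cosine_association(mat)
        assert assoc.values[0, 1] == 0.0

    def test_formula_value(self):
        # f(a)=2, f(b)=3, co-occurrence=1 -> 1/sqrt(6)
        mat = matrix_from_lists(
            {"P1": ["a", "b"], "P2": ["a"], "P3": ["b"], "P4": ["b"]}
        )
        assoc = cosine_association(mat)
        assert assoc.values[0, 1] == pytest.approx(1 / np.sqrt(6))

    def test_symmetric_bounded_zero_diagonal(self):
        rng = np.random.default_rng(5)
        lists = {
            f"P{i}": [f"w{j}" for j in rng.choice(12, size=5, replace=False)]
            for i in range(10)
        }
        assoc = cosine_association(matrix_from_lists(lists))
        v = assoc.values
        assert np.allclose(v, v.T)
        assert np.all((v >= 0) & (v <= 1))
        assert np.all(np.diag(v) == 0)

    def test_participant_permutation_invariance(self):
        lists = {"P1": ["a", "b"], "P2": ["b", "c"], "P3": ["a", "c"]}
        mat = matrix_from_lists(lists)
        flipped = matrix_from_lists(dict(reversed(list(lists.items()))))
        assert np.allclose(
            cosine_association(mat).values, cosine_association(flipped).values
        )

    def test_zero_frequency_column_raises(self):
        mat = matrix_from_lists({"P1": ["a", "b"]})
        mat.data["ghost"] = 0
        with pytest.raises(EstimationError, match="zero-frequency"):
            cosine_association(mat)


class TestTMFG:
    def test_k4_for_four_nodes(self):
        net = tmfg_filter(random_association(4, seed=0))
        assert net.number_of_edges() == 6
        assert all(d == 3 for _, d in net.degree())

    def test_too_small_and_all_zero_raise(self):
        with pytest.raises(EstimationError, match="at least 4"):
            tmfg_filter(random_association(3, seed=0))
        zero = AssociationMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        with pytest.raises(EstimationError, match="all-zero"):
            tmfg_filter(zero)

    @pytest.mark.parametrize("n", [5, 9, 20, 47])
    def test_structural_invariants(self, n):
        net = tmfg_filter(random_association(n, seed=n))
        assert net.number_of_edges() == 3 * n - 6
        assert nx.is_connected(net)
        assert nx.check_planarity(net)[0]
        assert min(d for _, d in net.degree()) >= 3
        triangles = nx.triangles(net)
        assert all(t >= 1 for t in triangles.values())

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_exhaustive_insertion_oracle(self, n):
        for seed in range(5):
            assoc = random_association(n, seed=100 * n + seed)
            net = tmfg_filter(assoc)
            expected = tmfg_naive(list(assoc.labels), assoc.values.tolist())
            got = {frozenset((u, v)) for u, v in net.edges()}
            assert got == expected

    def test_weights_copied_from_association(self):
        assoc = random_association(10, seed=2)
        net = tmfg_filter(assoc)
        idx = {lab: i for i, lab in enumerate(assoc.labels)}
        for u, v, d in net.edges(data=True):
            assert d["weight"] == pytest.approx(assoc.values[idx[u], idx[v]])

    def test_total_weight_at_least_spanning_tree(self):
        assoc = random_association(15, seed=8)
        net = tmfg_filter(assoc)
        complete = nx.Graph()
        for i, a in enumerate(assoc.labels):
            for j, b in enumerate(assoc.labels):
                if i < j:
                    complete.add_edge(a, b, weight=assoc.values[i, j])
        mst = nx.maximum_spanning_tree(complete)
        tmfg_weight = sum(d["weight"] for _, _, d in net.edges(data=True))
        mst_weight = sum(d["weight"] for _, _, d in mst.edges(data=True))
        assert tmfg_weight >= mst_weight

    def test_deterministic(self):
        assoc = random_association(25, seed=4)
        e1 = sorted(tmfg_filter(assoc).edges())
        e2 = sorted(tmfg_filter(assoc).edges())
        assert e1 == e2


class TestNetworkIO:
    def test_graphml_round_trip(self, tmp_path):
        net = tmfg_filter(random_association(12, seed=1), group="A")
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        back = read_graphml(path)
        assert set(back.nodes()) == set(net.nodes())
        assert {frozenset(e) for e in back.edges()} == {
            frozenset(e) for e in net.edges()
        }
        assert back.graph["group"] == "A"

    def test_edgelist_round_trip(self, tmp_path):
        net = tmfg_filter(random_association(12, seed=1))
        path = tmp_path / "edges.csv"
        write_edgelist_csv(net, path)
        back = read_edgelist_csv(path)
        for u, v, d in net.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(d["weight"])
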