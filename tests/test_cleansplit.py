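"""Leakage decision tree, redundancy graph and greedy removal."""

import networkx as nx
import numpy as np
import pytest

from gems.cleansplit import (
    assemble_cleansplit,
    filter_train_test,
    greedy_redundancy_removal,
    independent_subset,
    leakage_exclude,
    redundancy_adjacency,
    redundancy_edge,
)
from gems.similarity import PairSimilarity


def sim(tanimoto, tm, rmsd, dpk):
    return PairSimilarity(tanimoto=tanimoto, tm_score=tm, ligand_rmsd=rmsd, delta_pk=dpk)


class TestLeakageDecision:
    def test_structural_overlap(self):
        decision = leakage_exclude(sim(0.5, 0.85, 0.4, 0.3))  # 0.5 + 0.6 = 1.1 > 0.8
        assert decision.excluded and decision.rule == "structural_overlap"

    def test_activity_cliff_never_excluded(self):
        decision = leakage_exclude(sim(0.95, 0.95, 0.1, 2.0))
        assert not decision.excluded and decision.rule == "none"

    def test_ligand_identity_independent_of_protein(self):
        decision = leakage_exclude(sim(0.95, 0.3, 3.0, 0.5))
        assert decision.excluded and decision.rule == "ligand_identity"

    def test_affinity_band_is_inclusive(self):
        assert leakage_exclude(sim(0.95, 0.3, 3.0, 1.0)).excluded      # dpK == 1 counts
        assert not leakage_exclude(sim(0.95, 0.3, 3.0, 1.0001)).excluded

    def test_thresholds_are_strict(self):
        assert not leakage_exclude(sim(0.9, 0.3, 3.0, 0.5)).excluded   # T == 0.9 not > 0.9
        assert not leakage_exclude(sim(0.5, 0.8, 0.4, 0.3)).excluded   # TM == 0.8 not > 0.8


class TestRedundancyEdge:
    @pytest.mark.parametrize(
        "t, tm, rmsd, dpk, expected",
        [
            (0.9, 0.9, 0.3, 0.2, True),    # 1.6 > 1.3
            (0.9, 0.9, 0.3, 0.6, False),   # dpK >= 0.5
            (0.5, 0.9, 0.4, 0.2, False),   # 1.1 <= 1.3 though it would leak a test set
        ],
    )
    def test_thresholds(self, t, tm, rmsd, dpk, expected):
        assert redundancy_edge(sim(t, tm, rmsd, dpk)) is expected
        if not expected and dpk <= 1.0:
            # the looser train-test rule can still fire where redundancy does not
            assert leakage_exclude(sim(t, tm, rmsd, dpk)).excluded or t <= 0.8


class TestGreedyRemoval:
    def test_edgeless_graph_empty_trace(self):
        graph = nx.Graph()
        graph.add_nodes_from("abc")
        assert greedy_redundancy_removal(graph).steps == []

    def test_star_graph_removes_center_only(self):
        graph = nx.star_graph(4)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in graph.nodes})
        trace = greedy_redundancy_removal(graph)
        assert trace.removed_ids == ["n0"]
        assert trace.steps[0].degree == 4

    def test_triangle_tie_breaks_by_subset_then_resolution(self):
        graph = nx.Graph()
        graph.add_node("A", subset="refined", resolution=1.9)
        graph.add_node("B", subset="general", resolution=2.5)
        graph.add_node("C", subset="general", resolution=1.8)
        graph.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
        trace = greedy_redundancy_removal(graph)
        # all degree 2: general preferred, worst resolution first -> B;
        # remaining edge A-C: general preferred -> C
        assert trace.removed_ids == ["B", "C"]

    def test_missing_resolution_sorts_worst(self):
        graph = nx.Graph()
        graph.add_node("A", subset="general", resolution=1.5)
        graph.add_node("B", subset="general", resolution=None)
        graph.add_edge("A", "B")
        assert greedy_redundancy_removal(graph).removed_ids == ["B"]

    def test_invariant_to_node_insertion_order(self, rng):
        graph = _random_metadata_graph(rng, n=40, p=0.1)
        trace = greedy_redundancy_removal(graph)
        shuffled = nx.Graph()
        order = list(graph.nodes)
        rng.shuffle(order)
        for node in order:
            shuffled.add_node(node, **graph.nodes[node])
        shuffled.add_edges_from(graph.edges)
        assert greedy_redundancy_removal(shuffled).removed_ids == trace.removed_ids

    @pytest.mark.parametrize("n,p,seed", [(50, 0.08, 0), (120, 0.03, 1), (200, 0.015, 2)])
    def test_matches_naive_reimplementation(self, n, p, seed):
        rng = np.random.default_rng(seed)
        graph = _random_metadata_graph(rng, n=n, p=p)
        trace = greedy_redundancy_removal(graph)
        assert trace.removed_ids == _naive_greedy(graph)
        # replaying the trace on a copy empties the edge set
        replay = graph.copy()
        for step in trace.steps:
            assert replay.degree(step.removed_id) == step.degree
            replay.remove_node(step.removed_id)
        assert replay.number_of_edges() == 0


def _random_metadata_graph(rng, n, p):
    graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    graph = nx.relabel_nodes(graph, {i: f"c{i:03d}" for i in graph.nodes})
    for node in graph.nodes:
        graph.nodes[node]["subset"] = str(rng.choice(["general", "refined"]))
        graph.nodes[node]["resolution"] = (
            None if rng.random() < 0.1 else float(np.round(rng.uniform(1.2, 3.2), 2))
        )
    return graph


def _naive_greedy(graph):
    """Independent re-implementation: degrees recomputed from scratch each pass."""
    adjacency = {n: set(graph.neighbors(n)) for n in graph.nodes}
    meta = {n: graph.nodes[n] for n in graph.nodes}
    removed = []
    while any(adjacency[n] for n in adjacency):
        def key(n):
            res = meta[n].get("resolution")
            return (
                -len(adjacency[n]),
                0 if meta[n].get("subset", "general") == "general" else 1,
                -(res if res is not None else float("inf")),
                n,
            )
        victim = min((n for n in adjacency if adjacency[n]), key=key)
        removed.append(victim)
        for other in adjacency[victim]:
            adjacency[other].discard(victim)
        del adjacency[victim]
    return removed


class TestScenarioFiltering:
    def test_planted_overlaps_recovered_exactly(self, scenario):
        report = filter_train_test(
            scenario.train_ids, [scenario.test_ids], [scenario.train_test_table]
        )
        assert report.excluded_ids == scenario.planted_overlap_ids

    def test_train_complex_matching_two_tests_listed_once_with_both(self, scenario):
        report = filter_train_test(
            scenario.train_ids,
            [scenario.test_ids, scenario.test_ids],
            [scenario.train_test_table, scenario.train_test_table],
        )
        assert report.excluded_ids == scenario.planted_overlap_ids
        for cid in report.excluded_ids:
            assert len(report.triggers[cid]) >= 2  # same partner via both test sets

    def test_missing_pair_is_a_hard_error(self, scenario):
        from gems.similarity import SimilarityTable

        with pytest.raises(KeyError):
            filter_train_test(
                scenario.train_ids, [scenario.test_ids], [SimilarityTable(entries={})]
            )

    def test_independent_subset_is_complement_of_planted(self, scenario):
        independent = independent_subset(
            scenario.test_ids, scenario.train_ids, scenario.train_test_table
        )
        leaked_tests = {f"te{cid[-2:]}" for cid in scenario.planted_overlap_ids}
        assert independent == set(scenario.test_ids) - leaked_tests

    def test_empty_training_set_leaves_all_tests_independent(self, scenario):
        from gems.similarity import SimilarityTable

        assert independent_subset(
            scenario.test_ids, [], SimilarityTable(entries={})
        ) == set(scenario.test_ids)


class TestAssembleCleansplit:
    def _assemble(self, scenario, train_ids=None):
        train_ids = train_ids if train_ids is not None else scenario.train_ids
        return assemble_cleansplit(
            train_ids,
            {"bench": scenario.test_ids},
            {"bench": scenario.train_test_table},
            scenario.train_train_table,
            subsets=scenario.subsets(),
            resolutions=scenario.resolutions(),
        )

    def test_retained_is_input_minus_planted(self, scenario):
        result = self._assemble(scenario)
        assert result.excluded_overlap == scenario.planted_overlap_ids
        for members in scenario.redundancy_clusters:
            assert result.excluded_redundancy <= result.excluded_redundancy | members
            assert len(members - result.excluded_redundancy) >= 1  # >= 1 survivor
        expected_retained = (
            set(scenario.train_ids)
            - result.excluded_overlap
            - result.excluded_redundancy
        )
        assert result.retained_train == expected_retained

    def test_post_filter_audit_is_clean(self, scenario):
        result = self._assemble(scenario)
        for train_id in result.retained_train:
            for test_id in scenario.test_ids:
                assert not leakage_exclude(
                    scenario.train_test_table.get(train_id, test_id)
                ).excluded
        rebuilt = redundancy_adjacency(
            sorted(result.retained_train), scenario.train_train_table
        )
        assert rebuilt.number_of_edges() == 0

    def test_idempotent_on_own_output(self, scenario):
        first = self._assemble(scenario)
        second = self._assemble(scenario, train_ids=sorted(first.retained_train))
        assert second.retained_train == first.retained_train
        assert second.excluded_overlap == set()
        assert second.excluded_redundancy == set()
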