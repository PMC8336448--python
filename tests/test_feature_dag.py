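"""Feature-DAG construction: binning, edge rules, splitting, acyclicity."""

import math

import networkx as nx
import pytest

from ms2path import (
    TicModel,
    bin_cluster,
    build_dag,
    integrate_intensity,
    longest_path,
    random_planning_instance,
)
from ms2path.feature_dag import enumerate_windows
from ms2path.planner import _solve

from .conftest import flat_cluster, make_cluster


class TestBinCluster:
    def test_half_open_binning(self):
        cluster = make_cluster("F1", [10.0, 10.4, 10.5, 11.0], [1.0, 2.0, 3.0, 4.0])
        nodes = bin_cluster(cluster, 0.5)
        assert [n.bin_index for n in nodes] == [0, 1, 2]
        assert [n.intensity for n in nodes] == [3.0, 3.0, 4.0]
        assert [n.rt for n in nodes] == [10.25, 10.75, 11.25]

    def test_singleton(self):
        cluster = make_cluster("F1", [5.0], [42.0])
        (node,) = bin_cluster(cluster, 1.0)
        assert node.intensity == 42.0

    def test_empty_cluster(self):
        cluster = make_cluster("F1", [5.0], [42.0])
        empty = type(cluster)(apex=cluster.apex, members=())
        assert bin_cluster(empty, 1.0) == []


class TestBuildDag:
    def two_cluster_dag(self, threshold):
        # A: bins at midpoints 10.5/11.5; B at 20.5/21.5. With delta=0.6 both
        # members fall in each padded window: integrals A=1500, B=2000.
        a = make_cluster("A", [10.0, 11.0], [1500.0, 1500.0], mz=100.0)
        b = make_cluster("B", [20.0, 21.0], [2000.0, 2000.0], mz=200.0)
        model = TicModel(slope=1.0, intercept=0.0, delta=0.6)
        return build_dag([a, b], model, threshold, bin_width=1.0, min_duration=1.0)

    def test_weight1_edges_gated_by_threshold(self):
        dag = self.two_cluster_dag(threshold=1000.0)
        assert len(dag.weight1_edges) == 2
        assert {e.from_node.cluster_id for e in dag.weight1_edges} == {"A", "B"}
        assert sorted(e.accumulated_intensity for e in dag.weight1_edges) == [1500.0, 2000.0]

    def test_transitions_follow_retention_time(self):
        dag = self.two_cluster_dag(threshold=1000.0)
        cross = [
            (e.from_node.cluster_id, e.to_node.cluster_id)
            for e in dag.iter_weight0_edges()
            if e.from_node.role == "out" and e.to_node.role == "in"
        ]
        assert ("A", "B") in cross
        assert ("B", "A") not in cross

    def test_all_below_threshold_gives_no_weight1_edges(self):
        dag = self.two_cluster_dag(threshold=1e6)
        assert dag.weight1_edges == []

    def test_empty_cluster_list(self):
        dag = build_dag([], TicModel.identity(), 1000.0, 1.0, 1.0)
        assert dag.nodes == []
        edges = list(dag.iter_weight0_edges())
        assert len(edges) == 1  # source -> sink only
        assert edges[0].from_node.role == "source" and edges[0].to_node.role == "sink"

    def test_raising_threshold_never_adds_edges(self):
        for seed in range(5):
            clusters, model, cfg = random_planning_instance(seed)
            lo = build_dag(clusters, model, cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
            hi = build_dag(clusters, model, 2 * cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
            lo_set = {(e.from_node.key, e.to_node.key) for e in lo.weight1_edges}
            hi_set = {(e.from_node.key, e.to_node.key) for e in hi.weight1_edges}
            assert hi_set <= lo_set


class TestDagStructure:
    @pytest.mark.parametrize("seed", range(8))
    def test_acyclic_and_topologically_consistent(self, seed):
        clusters, model, cfg = random_planning_instance(seed)
        dag = build_dag(clusters, model, cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
        g = dag.to_networkx()
        assert nx.is_directed_acyclic_graph(g)
        order = {n.key: i for i, n in enumerate(dag.topological_order)}
        for e in dag.edges:
            assert order[e.from_node.key] < order[e.to_node.key]

    def test_weight1_edges_connect_in_to_out_within_cluster(self):
        clusters, model, cfg = random_planning_instance(3)
        dag = build_dag(clusters, model, cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
        for e in dag.weight1_edges:
            assert e.from_node.role == "in" and e.to_node.role == "out"
            assert e.from_node.cluster_id == e.to_node.cluster_id
            assert e.rt_start < e.rt_end

    def test_planned_paths_never_reacquire_a_cluster(self):
        for seed in range(20):
            clusters, model, cfg = random_planning_instance(seed)
            dag = build_dag(clusters, model, cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
            path = longest_path(dag)
            assert len(set(path.feature_ids)) == path.score

    def test_nested_coelution_revisit_is_rejected_by_the_planner(self):
        """A long-eluting feature straddling a nested one: the raw graph
        admits a path that acquires the long feature twice, but the planner
        must return the best schedule with distinct features (score 2)."""
        a = flat_cluster("A", 0, 30, 1000.0, mz=100.0)
        b = flat_cluster("B", 12, 18, 1000.0, mz=200.0)
        dag = build_dag(
            [a, b], TicModel.identity(), tic_threshold=1000.0,
            bin_width=1.0, min_duration=4.0,
        )
        unconstrained = _solve(dag, {})
        assert unconstrained.weight == 3  # A, then nested B, then A again
        path = longest_path(dag)
        assert path.score == 2
        assert set(path.feature_ids) == {"A", "B"}


def test_vectorized_window_integrals_match_reference():
    """enumerate_windows' cumulative-trapezoid integrals equal the scalar
    trapezoid on the same padded windows."""
    for seed in range(5):
        clusters, model, cfg = random_planning_instance(seed)
        for cluster in clusters:
            bins = bin_cluster(cluster, cfg.bin_width)
            for _, _, rt_a, rt_b, integral in enumerate_windows(
                cluster, bins, model, cfg.tic_threshold, cfg.min_duration
            ):
                ref = integrate_intensity(cluster, rt_a, rt_b, model.delta)
                assert integral == pytest.approx(ref, rel=1e-9)
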