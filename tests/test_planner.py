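"""Path search, iterative exclusion, schedule validation, oracle equivalence."""

import io

import networkx as nx
import pytest

from ms2path import (
    AcquisitionWindow,
    ConstraintViolationError,
    PlannerConfig,
    TicModel,
    ValidationError,
    brute_force_optimum,
    build_dag,
    longest_path,
    plan_paths,
    plan_run,
    random_planning_instance,
    to_schedule_matrix,
    write_paths,
)
from ms2path.planner import _solve

from .conftest import flat_cluster

ABC_CONFIG = PlannerConfig(
    tic_threshold=6500.0, num_paths=2, bin_width=1.0, min_duration=8.0
)


class TestLongestPath:
    def test_single_feasible_window(self):
        cluster = flat_cluster("F1", 0, 4, 1000.0)
        dag = build_dag([cluster], TicModel.identity(), 1000.0, 1.0, 4.0)
        assert len(dag.weight1_edges) == 1
        path = longest_path(dag)
        assert path.score == 1
        (w,) = path.windows
        assert (w.rt_start, w.rt_end) == (0.5, 4.5)
        assert w.accumulated_intensity == pytest.approx(3000.0)

    def test_interleaved_windows_pick_compatible_pair(self, abc_clusters):
        dag = build_dag(
            abc_clusters, TicModel.identity(),
            ABC_CONFIG.tic_threshold, ABC_CONFIG.bin_width, ABC_CONFIG.min_duration,
        )
        path = longest_path(dag)
        assert path.score == 2
        assert path.feature_ids == ("A", "C")
        # tie-break: among max-count paths, largest summed intensity -> the
        # widest A window
        assert path.windows[0].rt_start == 0.5 and path.windows[0].rt_end == 10.5
        assert brute_force_optimum(abc_clusters, TicModel.identity(), ABC_CONFIG) == 2

    def test_no_feasible_windows_scores_zero(self):
        cluster = flat_cluster("F1", 0, 4, 1.0)
        dag = build_dag([cluster], TicModel.identity(), 1e9, 1.0, 4.0)
        assert longest_path(dag).score == 0

    def test_matches_networkx_longest_path_bound(self):
        """The distinct-feature optimum never exceeds the unconstrained
        max-weight path, which networkx computes independently."""
        for seed in range(10):
            clusters, model, cfg = random_planning_instance(seed)
            dag = build_dag(clusters, model, cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
            g = dag.to_networkx()
            nx_weight = nx.dag_longest_path_length(g, weight="weight")
            assert _solve(dag, {}).weight == nx_weight
            assert longest_path(dag).score <= nx_weight


class TestPlanPaths:
    def test_iterative_exclusion_on_interleaved_features(self, abc_clusters):
        paths = plan_paths(abc_clusters, TicModel.identity(), ABC_CONFIG)
        assert [p.score for p in paths] == [2, 1]
        assert paths[0].feature_ids == ("A", "C")
        assert paths[1].feature_ids == ("B",)
        assert [p.index for p in paths] == [0, 1]

    def test_early_stop_when_features_exhausted(self):
        cluster = flat_cluster("F1", 0, 4, 1000.0)
        cfg = PlannerConfig(tic_threshold=1000.0, num_paths=5, bin_width=1.0, min_duration=4.0)
        paths = plan_paths([cluster], TicModel.identity(), cfg)
        assert len(paths) == 1 and paths[0].score == 1

    def test_nothing_feasible_gives_empty_list(self):
        cluster = flat_cluster("F1", 0, 4, 1.0)
        cfg = PlannerConfig(tic_threshold=1e12, num_paths=3, bin_width=1.0, min_duration=4.0)
        assert plan_paths([cluster], TicModel.identity(), cfg) == []

    def test_deterministic_output_bytes(self):
        from ms2path import SyntheticRunSpec, generate_run

        spec = SyntheticRunSpec(n_features=15, rt_range=300.0, n_background=3, seed=21)
        signals, truth = generate_run(spec)
        cfg = PlannerConfig(num_paths=3, rt_tol=15.0)
        outs = []
        for _ in range(2):
            result = plan_run(signals, truth, config=cfg)
            buf = io.StringIO()
            write_paths(list(result.paths), buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]


class TestScheduleMatrix:
    def w(self, fid, s, e):
        return AcquisitionWindow(fid, 100.0, s, e, 10.0, 10.0, 1)

    def test_single_window_discretization(self):
        matrix = to_schedule_matrix([[self.w("F1", 3.0, 5.5)]], bin_width=1.0)
        assert matrix.objective == 1
        bins = sorted(t for t, fid in matrix.assignments)
        assert bins == [3, 4]  # bin centers 3.5, 4.5 fall inside [3.0, 5.5)
        assert all(b - a == 1 for a, b in zip(bins, bins[1:]))

    def test_overlap_violates_one_feature_per_bin(self):
        windows = [self.w("F1", 0.0, 2.0), self.w("F2", 1.0, 3.0)]
        with pytest.raises(ConstraintViolationError, match=r"\(4\)"):
            to_schedule_matrix([windows], bin_width=0.5)

    def test_feature_split_across_runs_violates_contiguity(self):
        runs = [[self.w("F1", 0.0, 2.0)], [self.w("F1", 5.0, 6.0)]]
        with pytest.raises(ConstraintViolationError, match=r"\(3\)"):
            to_schedule_matrix(runs, bin_width=0.5)

    def test_planner_solution_validates(self, abc_clusters):
        paths = plan_paths(abc_clusters, TicModel.identity(), ABC_CONFIG)
        matrix = to_schedule_matrix(paths)
        assert matrix.objective == 3
        assert matrix.n_runs == 2


class TestBruteForce:
    def test_refuses_oversized_instances(self):
        clusters = [flat_cluster(f"F{i}", 10 * i, 10 * i + 4, 1000.0, mz=100.0 + i) for i in range(9)]
        with pytest.raises(ValidationError, match="clusters"):
            brute_force_optimum(clusters, TicModel.identity(), PlannerConfig(bin_width=1.0, min_duration=4.0))

    def test_degenerate_cases(self):
        cfg = PlannerConfig(bin_width=1.0, min_duration=4.0)
        assert brute_force_optimum([], TicModel.identity(), cfg) == 0
        one = flat_cluster("F1", 0, 4, 1000.0)
        assert brute_force_optimum([one], TicModel.identity(), cfg) == 1


def test_oracle_equivalence_sample():
    """Quick spot check of the exhaustive-search equivalence (the full
    200-instance sweep runs in the acceptance suite)."""
    for seed in range(30):
        clusters, model, cfg = random_planning_instance(seed)
        dag = build_dag(clusters, model, cfg.tic_threshold, cfg.bin_width, cfg.min_duration)
        assert longest_path(dag).score == brute_force_optimum(clusters, model, cfg), seed
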