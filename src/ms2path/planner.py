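"""Optimal acquisition-path search and iterative multi-run planning.

The planning objective: over N detected features and the T scans of the run,
choose binary assignments X[t, i] (feature i acquired at time t) maximizing
the number of distinct features acquired, subject to (2) the predicted MS2
TIC of each feature's acquisition window meeting a user threshold, (3) each
feature being acquired in a single contiguous RT interval, (4) at most one
feature acquired per time point and (5) binary assignments.

On the feature-DAG this is the maximum-weight source-to-sink path: each
weight-1 edge is one feasible above-threshold acquisition window, and
weight-0 edges encode "move to a later feature". The path is found by dynamic
programming over the topological order; because weight-0 connectivity is the
bare later-in-time rule, the DP keeps a running best-two (from distinct
clusters) over finished out-nodes instead of materializing quadratically many
transition edges.

A pure max-weight path can, in one corner case, acquire the same feature
twice: when a long-eluting feature has feasible windows both entirely before
and entirely after another feature's whole window, the path may leave and
legally re-enter it. Such a path inflates the edge count above the true
distinct-feature optimum, so when the DP's path repeats a cluster the solver
branches — forbidding one or the other duplicated window — and recurses until
the best repeat-free path is found. The DP value bounds each branch, so the
search stays exact and, on realistic data where the nesting is rare, almost
always finishes in a single DP pass.

Iterated planning excludes every feature acquired by earlier paths and
re-plans on the remainder, emitting up to ``num_paths`` schedules for
consecutive instrument runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConstraintViolationError, ValidationError
from .feature_dag import DagEdge, FeatureDag, bin_cluster, build_dag, enumerate_windows
from .io_formats import AcquisitionWindow, ApexFeature, Path, RawSignal
from .preprocessing import Cluster, ClusterTolerance, assign_signals, filter_background
from .tic_model import DEFAULT_DELTA, TicModel, predict_tic

__all__ = [
    "PlannerConfig",
    "ScheduleMatrix",
    "longest_path",
    "plan_paths",
    "plan_run",
    "PlanResult",
    "to_schedule_matrix",
    "brute_force_optimum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class PlannerConfig:
    """All planning knobs in one place.

    ``bin_width`` / ``min_duration`` of None are resolved from the data: the
    median inter-scan interval of the raw signals serves as both the RT bin
    width and the minimum window duration (one scan).
    """

    tic_threshold: float = 1e3
    num_paths: int = 5
    delta: float = DEFAULT_DELTA
    bin_width: float | None = None
    min_duration: float | None = None
    max_duration: float = math.inf
    transition_gap: float = 0.0
    mz_tol: float = 0.01
    rt_tol: float = 5.0
    min_ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.num_paths < 1:
            raise ValidationError("num_paths must be >= 1")
        if not self.tic_threshold > 0:
            raise ValidationError("tic_threshold must be > 0")


def _median_scan_interval(clusters: Sequence[Cluster]) -> float:
    rts = sorted({m.rt for c in clusters for m in c.members})
    diffs = np.diff(rts)
    positive = diffs[diffs > 0]
    return float(np.median(positive)) if len(positive) else 1.0


def _resolve_grid(clusters: Sequence[Cluster], config: PlannerConfig) -> tuple[float, float]:
    if config.bin_width is not None and config.min_duration is not None:
        return config.bin_width, config.min_duration
    scan = _median_scan_interval(clusters)
    bw = config.bin_width if config.bin_width is not None else scan
    md = config.min_duration if config.min_duration is not None else scan
    return bw, md


# ---------------------------------------------------------------------------
# DP over the topological order
# ---------------------------------------------------------------------------


class _Cand:
    """A partial path ending at some node: total weight, tie-break keys, trail."""

    __slots__ = ("weight", "intensity", "pred", "edge", "_seq")

    def __init__(self, weight: int, intensity: float, pred: "_Cand | None", edge: DagEdge | None):
        self.weight = weight
        self.intensity = intensity
        self.pred = pred
        self.edge = edge
        self._seq: tuple[float, ...] | None = None

    def seq(self) -> tuple[float, ...]:
        """rt_start sequence of the acquisitions on this partial path."""
        if self._seq is None:
            parts = []
            c: _Cand | None = self
            while c is not None and c.edge is not None:
                parts.append(c.edge.rt_start)
                c = c.pred
            self._seq = tuple(reversed(parts))
        return self._seq

    def beats(self, other: "_Cand") -> bool:
        """Strict total preference: more windows, then more signal, then earliest."""
        if self.weight != other.weight:
            return self.weight > other.weight
        if self.intensity != other.intensity:
            return self.intensity > other.intensity
        return self.seq() < other.seq()

    def edges(self) -> list[DagEdge]:
        out = []
        c: _Cand | None = self
        while c is not None and c.edge is not None:
            out.append(c.edge)
            c = c.pred
        out.reverse()
        return out


def _solve(dag: FeatureDag, restrict: dict[str, tuple[float, float]]) -> _Cand:
    """Max-weight path DP; may repeat a cluster (callers resolve repeats).

    ``restrict`` confines a cluster's usable windows: cluster ``c`` with entry
    ``(start_lt, end_gt)`` may only use windows with rt_start < start_lt and
    rt_end > end_gt (the branching device of :func:`_best_distinct`).
    """
    empty = _Cand(0, 0.0, None, None)
    edges_by_out: dict[tuple, list[DagEdge]] = {}
    for e in dag.weight1_edges:
        r = restrict.get(e.from_node.cluster_id)
        if r is not None and not (e.rt_start < r[0] and e.rt_end > r[1]):
            continue
        edges_by_out.setdefault(e.to_node.key, []).append(e)

    in_best: dict[tuple, _Cand] = {}
    final = empty
    # top-2 finished out-node candidates from distinct clusters, best first
    top: list[tuple[_Cand, str]] = []
    pending: list[tuple[float, _Cand, str]] = []  # rt-ordered, awaiting gap eligibility
    p_head = 0

    def push(cand: _Cand, cid: str) -> None:
        # keep the best two finished out-candidates from distinct clusters,
        # best first, so each in-node finds its best foreign predecessor in O(1)
        for i, (c0, cid0) in enumerate(top):
            if cid0 == cid:
                if cand.beats(c0):
                    top[i] = (cand, cid)
                    if i == 1 and top[1][0].beats(top[0][0]):
                        top[0], top[1] = top[1], top[0]
                return
        if len(top) < 2:
            top.append((cand, cid))
            if len(top) == 2 and top[1][0].beats(top[0][0]):
                top[0], top[1] = top[1], top[0]
        elif cand.beats(top[0][0]):
            top[1] = top[0]
            top[0] = (cand, cid)
        elif cand.beats(top[1][0]):
            top[1] = (cand, cid)

    for node in dag.topological_order:
        if node.role == "in":
            while p_head < len(pending) and pending[p_head][0] + dag.transition_gap <= node.rt:
                _, cand, cid = pending[p_head]
                push(cand, cid)
                p_head += 1
            base = empty
            for cand, cid in top:
                if cid != node.cluster_id:
                    if cand.beats(base):
                        base = cand
                    break
            in_best[node.key] = base
        elif node.role == "out":
            best: _Cand | None = None
            for e in edges_by_out.get(node.key, ()):
                b = in_best[e.from_node.key]
                cand = _Cand(b.weight + 1, b.intensity + e.accumulated_intensity, b, e)
                if best is None or cand.beats(best):
                    best = cand
            if best is not None:
                pending.append((node.rt, best, node.cluster_id))
                if best.beats(final):
                    final = best
    return final


def _first_repeated_cluster(edges: list[DagEdge]) -> tuple[DagEdge, DagEdge] | None:
    seen: dict[str, DagEdge] = {}
    for e in edges:
        cid = e.from_node.cluster_id
        if cid in seen:
            return seen[cid], e
        seen[cid] = e
    return None


def _repair(edges: list[DagEdge]) -> list[DagEdge]:
    """Drop repeat acquisitions, keeping each cluster's first window.

    Removing windows from a feasible chain leaves a feasible chain (retention
    times only move forward along the path), so the result is always a valid
    repeat-free schedule.
    """
    seen: set[str] = set()
    kept = []
    for e in edges:
        cid = e.from_node.cluster_id
        if cid not in seen:
            seen.add(cid)
            kept.append(e)
    return kept


def _cand_from_edges(edges: list[DagEdge]) -> _Cand:
    cand = _Cand(0, 0.0, None, None)
    for e in edges:
        cand = _Cand(cand.weight + 1, cand.intensity + e.accumulated_intensity, cand, e)
    return cand


def _default_solve_budget(n_clusters: int) -> int:
    """DP-pass budget for the branch-and-bound.

    Small instances (the regime where exhaustive verification is possible)
    get a deep search; dense instances with hundreds of clusters — where a
    single DP pass already recovers essentially every feature and each pass
    is expensive — get a shallow one. The budget trades provable optimality
    for bounded runtime; the returned schedule is valid either way.
    """
    return max(4, min(400, 4000 // max(1, n_clusters)))


def _best_distinct(dag: FeatureDag, solve_budget: int | None = None) -> _Cand:
    """Best repeat-free max-weight path: DP plus branching on repeats.

    Whenever the unconstrained DP path acquires some cluster twice (windows
    w1 then w2), any repeat-free path confines that cluster to a single
    window either starting before or ending after the midpoint T between
    w1.rt_end and w2.rt_start — so the search branches on those two
    restrictions, each of which eliminates one of the offending windows and
    halves the cluster's usable range. Repaired (first-occurrence-only)
    variants of every DP path serve as feasible incumbents, and a branch is
    abandoned when its DP bound cannot exceed the incumbent score. The search
    is exact whenever it converges within ``solve_budget`` DP passes; on
    pathological instances it returns the best feasible path found, which is
    always a valid schedule.
    """
    if solve_budget is None:
        solve_budget = _default_solve_budget(len(dag.clusters))
    best: _Cand | None = None
    solves = 0

    def consider(cand: _Cand) -> None:
        nonlocal best
        if best is None or cand.beats(best):
            best = cand

    def rec(restrict: dict[str, tuple[float, float]]) -> None:
        nonlocal solves
        if solves >= solve_budget:
            return
        solves += 1
        cand = _solve(dag, restrict)
        edges = cand.edges()
        dup = _first_repeated_cluster(edges)
        if dup is None:
            consider(cand)
            return
        consider(_cand_from_edges(_repair(edges)))
        if best is not None and cand.weight <= best.weight:
            return  # bound: no repeat-free path in this branch can score higher
        e1, e2 = dup
        cid = e1.from_node.cluster_id
        t_mid = 0.5 * (e1.rt_end + e2.rt_start)
        start_lt, end_gt = restrict.get(cid, (math.inf, -math.inf))
        rec({**restrict, cid: (min(start_lt, t_mid), end_gt)})
        rec({**restrict, cid: (start_lt, max(end_gt, t_mid))})

    rec({})
    assert best is not None
    return best


def longest_path(dag: FeatureDag) -> Path:
    """The acquisition path maximizing the number of distinct features.

    Ties are broken by larger total accumulated intensity, then by the
    lexicographically earliest rt_start sequence, so output is deterministic.
    """
    cand = _best_distinct(dag)
    windows = []
    for e in cand.edges():
        apex = dag.clusters[e.from_node.cluster_id].apex
        windows.append(
            AcquisitionWindow(
                feature_id=apex.feature_id,
                iso_mz=apex.mz,
                rt_start=e.rt_start,
                rt_end=e.rt_end,
                accumulated_intensity=e.accumulated_intensity,
                predicted_tic=predict_tic(dag.model, e.accumulated_intensity),
                charge=apex.charge,
            )
        )
    return Path(index=0, windows=tuple(windows), score=len(windows))


# ---------------------------------------------------------------------------
# iterative planning with exclusion
# ---------------------------------------------------------------------------


def plan_paths(
    clusters: Sequence[Cluster],
    model: TicModel | None = None,
    config: PlannerConfig | None = None,
) -> list[Path]:
    """Plan up to ``config.num_paths`` acquisition runs.

    After each path, every feature it acquires is excluded and planning
    repeats on the remainder; iteration stops early once a path scores 0.
    """
    config = config or PlannerConfig()
    model = model or TicModel.identity(config.delta)
    remaining = list(clusters)
    if not remaining:
        return []
    bw, md = _resolve_grid(remaining, config)
    paths: list[Path] = []
    for k in range(config.num_paths):
        if not remaining:
            break
        dag = build_dag(
            remaining,
            model,
            tic_threshold=config.tic_threshold,
            bin_width=bw,
            min_duration=md,
            max_duration=config.max_duration,
            transition_gap=config.transition_gap,
        )
        path = longest_path(dag)
        if path.score == 0:
            break
        paths.append(replace(path, index=k))
        acquired = set(path.feature_ids)
        remaining = [c for c in remaining if c.cluster_id not in acquired]
        logger.info("iteration %d: %d feature(s) scheduled", k, path.score)
    return paths


@dataclass(frozen=True, slots=True)
class PlanResult:
    """Pipeline output: paths plus preprocessing diagnostics."""

    paths: tuple[Path, ...]
    clusters: tuple[Cluster, ...]
    n_background_discarded: int
    n_unassigned_signals: int

    @property
    def iteration_scores(self) -> list[int]:
        return [p.score for p in self.paths]


def plan_run(
    signals: Sequence[RawSignal],
    apexes: Sequence[ApexFeature],
    model: TicModel | None = None,
    config: PlannerConfig | None = None,
) -> PlanResult:
    """Full pipeline: background filter -> clustering -> iterative planning."""
    config = config or PlannerConfig()
    kept = filter_background(list(apexes), config.min_ratio)
    if not kept:
        return PlanResult((), (), len(apexes), len(signals))
    clusters = assign_signals(
        list(signals), kept, ClusterTolerance(config.mz_tol, config.rt_tol)
    )
    unassigned = len(signals) - sum(len(c.members) for c in clusters)
    paths = plan_paths(clusters, model, config)
    return PlanResult(
        paths=tuple(paths),
        clusters=tuple(clusters),
        n_background_discarded=len(apexes) - len(kept),
        n_unassigned_signals=unassigned,
    )


# ---------------------------------------------------------------------------
# schedule-matrix validation bridge
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ScheduleMatrix:
    """Discretized binary schedule X[t, i] with the planning objective value.

    Iterated paths are separate instrument runs, so the time axis concatenates
    the runs: run k occupies global bins [k*T, (k+1)*T). ``assignments`` holds
    the (global_bin, feature_id) pairs set to 1.
    """

    features: tuple[str, ...]
    n_time_bins_per_run: int
    n_runs: int
    bin_width: float
    assignments: frozenset[tuple[int, str]]
    objective: int


def to_schedule_matrix(
    paths: Sequence[Path] | Sequence[Sequence[AcquisitionWindow]],
    bin_width: float | None = None,
) -> ScheduleMatrix:
    """Discretize paths onto a time grid and verify the scheduling constraints.

    Raises :class:`ConstraintViolationError` naming the violated constraint:
    (3) a feature acquired in more than one contiguous interval, (4) more than
    one feature assigned to a time bin, (5) non-binary assignment. A bin
    belongs to a window when its center falls inside [rt_start, rt_end); the
    default bin width is half the shortest window so no window is lost.
    """
    runs: list[list[AcquisitionWindow]] = [
        list(p.windows) if isinstance(p, Path) else list(p) for p in paths
    ]
    windows = [w for run in runs for w in run]
    if not windows:
        return ScheduleMatrix((), 0, len(runs), bin_width or 1.0, frozenset(), 0)
    if bin_width is None:
        bin_width = min(w.rt_end - w.rt_start for w in windows) / 2.0
    if not bin_width > 0:
        raise ValidationError("bin_width must be > 0")
    t_per_run = int(math.ceil(max(w.rt_end for w in windows) / bin_width)) + 1

    occupancy: dict[int, str] = {}
    feature_bins: dict[str, list[int]] = {}
    assignments: set[tuple[int, str]] = set()
    for k, run in enumerate(runs):
        offset = k * t_per_run
        for w in run:
            j0 = max(0, int(math.floor(w.rt_start / bin_width)) - 1)
            covered = []
            j = j0
            while (j + 0.5) * bin_width < w.rt_end:
                if (j + 0.5) * bin_width >= w.rt_start:
                    covered.append(offset + j)
                j += 1
            if not covered:
                raise ValidationError(
                    f"bin_width {bin_width} too coarse: window "
                    f"[{w.rt_start}, {w.rt_end}] covers no bin"
                )
            for gb in covered:
                if gb in occupancy:
                    raise ConstraintViolationError(
                        f"constraint (4) violated: bin {gb} assigned to both "
                        f"{occupancy[gb]!r} and {w.feature_id!r}"
                    )
                if (gb, w.feature_id) in assignments:
                    raise ConstraintViolationError(
                        f"constraint (5) violated: duplicate assignment at bin {gb}"
                    )
                occupancy[gb] = w.feature_id
                assignments.add((gb, w.feature_id))
            feature_bins.setdefault(w.feature_id, []).extend(covered)

    for fid, bins in feature_bins.items():
        bins.sort()
        if any(b - a > 1 for a, b in zip(bins, bins[1:])):
            raise ConstraintViolationError(
                f"constraint (3) violated: feature {fid!r} acquired in more "
                f"than one contiguous interval"
            )

    features = tuple(sorted(feature_bins))
    return ScheduleMatrix(
        features=features,
        n_time_bins_per_run=t_per_run,
        n_runs=len(runs),
        bin_width=bin_width,
        assignments=frozenset(assignments),
        objective=len(features),
    )


# ---------------------------------------------------------------------------
# exhaustive oracle (test-scale instances only)
# ---------------------------------------------------------------------------


def brute_force_optimum(
    clusters: Sequence[Cluster],
    model: TicModel | None = None,
    config: PlannerConfig | None = None,
    limits: tuple[int, int] = (8, 12),
) -> int:
    """Exhaustive single-path optimum: max distinct features acquirable.

    Enumerates every cluster subset and visiting order; within a fixed order
    the window with the earliest end time is always chosen (an exchange
    argument shows this is optimal), so the search over orders is exact.
    Exponential — refuses instances above ``limits`` (clusters, bins/cluster).
    """
    config = config or PlannerConfig()
    model = model or TicModel.identity(config.delta)
    max_clusters, max_bins = limits
    if len(clusters) > max_clusters:
        raise ValidationError(
            f"brute_force_optimum limited to {max_clusters} clusters, got {len(clusters)}"
        )
    if not clusters:
        return 0
    bw, md = _resolve_grid(clusters, config)
    wins: dict[str, list[tuple[float, float]]] = {}
    for c in clusters:
        bins = bin_cluster(c, bw)
        if len(bins) > max_bins:
            raise ValidationError(
                f"brute_force_optimum limited to {max_bins} bins/cluster, "
                f"cluster {c.cluster_id!r} has {len(bins)}"
            )
        ws = enumerate_windows(
            c, bins, model, config.tic_threshold, md, config.max_duration
        )
        if ws:
            wins[c.cluster_id] = sorted((w[2], w[3]) for w in ws)
    gap = config.transition_gap

    def rec(remaining: tuple[str, ...], cur_end: float) -> int:
        best = 0
        for i, cid in enumerate(remaining):
            feasible_ends = [e for s, e in wins[cid] if s >= cur_end + gap]
            if not feasible_ends:
                continue
            rest = remaining[:i] + remaining[i + 1 :]
            best = max(best, 1 + rec(rest, min(feasible_ends)))
        return best

    return rec(tuple(wins), -math.inf)
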