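"""Split-node feature-DAG construction.

Each cluster's raw signals are binned by retention time; every bin becomes a
node whose intensity is the sum of the member signal intensities inside it.
Each node is split into an in-node and an out-node:

* weight-1 edges run inside a cluster from in(a) to out(b) for bin pairs with
  rt_a < rt_b whose padded window integral predicts an MS2 TIC at or above the
  user threshold — traversing one acquires that feature in [rt_a, rt_b];
* weight-0 edges run between clusters from an out-node to any in-node of a
  *different* cluster at an equal-or-later retention time (plus an optional
  transition gap for instrument overhead);
* a virtual source feeds every in-node and a virtual sink drains every
  out-node, so path search is a single-source/single-sink problem.

The split forbids re-acquiring a feature without leaving its cluster, and the
strictly nondecreasing retention times along every edge make the graph acyclic
by construction.

Weight-0 edges between clusters are implied by the retention-time rule rather
than stored: the number of (out, in) pairs grows quadratically while the path
search only ever needs, at each in-node, the best already-finished out-node of
a different cluster. :meth:`FeatureDag.iter_weight0_edges` materializes them
on demand for inspection and for exhaustive checks on small graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import ApexFeature
from .preprocessing import Cluster
from .tic_model import TicModel, predict_tic

__all__ = ["DagNode", "DagEdge", "FeatureDag", "bin_cluster", "enumerate_windows", "build_dag"]


@dataclass(frozen=True, slots=True)
class DagNode:
    """One RT bin of one cluster (or the virtual source/sink).

    ``role`` is "bin" for a pre-split node, "in"/"out" after splitting,
    "source"/"sink" for the virtual endpoints.
    """

    cluster_id: str
    bin_index: int
    rt: float
    intensity: float
    role: str

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError("DagNode.intensity must be >= 0")
        if self.role not in ("bin", "in", "out", "source", "sink"):
            raise ValidationError(f"unknown DagNode role {self.role!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.cluster_id, self.bin_index, self.role)


@dataclass(frozen=True, slots=True)
class DagEdge:
    """A directed edge; weight 1 = acquisition, weight 0 = transition.

    Weight-1 edges carry the acquisition window [rt_start, rt_end] and the
    padded-window integral used for the TIC prediction.
    """

    from_node: DagNode
    to_node: DagNode
    weight: int
    rt_start: float = 0.0
    rt_end: float = 0.0
    accumulated_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.weight not in (0, 1):
            raise ValidationError("edge weight must be 0 or 1")
        if self.weight == 1 and not self.rt_start < self.rt_end:
            raise ValidationError("weight-1 edge must have rt_start < rt_end")


@dataclass
class FeatureDag:
    """The acquisition-planning graph for one set of clusters."""

    source: DagNode
    sink: DagNode
    nodes: list[DagNode]                     # all in/out nodes (excl. source/sink)
    weight1_edges: list[DagEdge]
    clusters: dict[str, Cluster]             # cluster_id -> cluster (apex access)
    model: TicModel
    tic_threshold: float
    bin_width: float
    transition_gap: float = 0.0

    @property
    def topological_order(self) -> list[DagNode]:
        """Source, then nodes by (rt, out-before-in, cluster, bin), then sink.

        Out-nodes precede in-nodes at equal retention time because a weight-0
        transition at gap 0 may join them.
        """
        rank = {"out": 0, "in": 1}
        inner = sorted(
            self.nodes, key=lambda n: (n.rt, rank[n.role], n.cluster_id, n.bin_index)
        )
        return [self.source, *inner, self.sink]

    def iter_weight0_edges(self) -> Iterator[DagEdge]:
        """Materialize the implied transition edges (quadratic; small graphs).

        Yields source->in, out->sink, source->sink and the cross-cluster
        out->in edges satisfying rt_in >= rt_out + transition_gap.
        """
        ins = [n for n in self.nodes if n.role == "in"]
        outs = [n for n in self.nodes if n.role == "out"]
        for v in ins:
            yield DagEdge(self.source, v, 0)
        for u in outs:
            yield DagEdge(u, self.sink, 0)
        yield DagEdge(self.source, self.sink, 0)
        for u in outs:
            for v in ins:
                if v.cluster_id != u.cluster_id and v.rt >= u.rt + self.transition_gap:
                    yield DagEdge(u, v, 0)

    @property
    def edges(self) -> list[DagEdge]:
        return list(self.weight1_edges) + list(self.iter_weight0_edges())

    def to_networkx(self):
        """Explicit DiGraph (edge attr ``weight``) for inspection/cross-checks."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_node(self.source.key, rt=self.source.rt, role="source")
        g.add_node(self.sink.key, rt=self.sink.rt, role="sink")
        for n in self.nodes:
            g.add_node(n.key, rt=n.rt, role=n.role)
        for e in self.edges:
            g.add_edge(e.from_node.key, e.to_node.key, weight=e.weight, edge=e)
        return g


def bin_cluster(cluster: Cluster, bin_width: float) -> list[DagNode]:
    """Bin a cluster's raw signals into half-open RT intervals.

    Bins are [t0 + k*w, t0 + (k+1)*w) anchored at the first member's RT; only
    non-empty bins yield nodes. The node RT is the bin midpoint and the node
    intensity is the summed member intensity inside the bin.
    """
    if not bin_width > 0:
        raise ValidationError("bin_width must be > 0")
    if not cluster.members:
        return []
    t0 = cluster.members[0].rt
    sums: dict[int, float] = {}
    for m in cluster.members:
        k = int(math.floor((m.rt - t0) / bin_width))
        sums[k] = sums.get(k, 0.0) + m.intensity
    return [
        DagNode(
            cluster_id=cluster.cluster_id,
            bin_index=k,
            rt=t0 + (k + 0.5) * bin_width,
            intensity=sums[k],
            role="bin",
        )
        for k in sorted(sums)
    ]


def enumerate_windows(
    cluster: Cluster,
    bins: Sequence[DagNode],
    model: TicModel,
    tic_threshold: float,
    min_duration: float,
    max_duration: float = math.inf,
) -> list[tuple[int, int, float, float, float]]:
    """All feasible acquisition windows of one cluster.

    Returns (a_pos, b_pos, rt_a, rt_b, integral) for every ordered bin pair
    with min_duration <= rt_b - rt_a <= max_duration whose padded-window
    trapezoidal integral predicts TIC >= tic_threshold. Positions index into
    ``bins``. Integrals use a cumulative-trapezoid table over the member scan
    points, which matches :func:`ms2path.tic_model.integrate_intensity` on the
    same padded window.
    """
    n = len(bins)
    if n < 2:
        return []
    xs = np.array([m.rt for m in cluster.members])
    ys = np.array([m.intensity for m in cluster.members])
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (ys[1:] + ys[:-1]) * np.diff(xs))]
    )
    rts = np.array([b.rt for b in bins])
    ai, bi = np.triu_indices(n, k=1)
    dur = rts[bi] - rts[ai]
    ok = (dur >= min_duration) & (dur <= max_duration)
    ai, bi, dur = ai[ok], bi[ok], dur[ok]
    if len(ai) == 0:
        return []
    lo = rts[ai] - model.delta
    hi = rts[bi] + model.delta
    p0 = np.clip(np.searchsorted(xs, lo, side="left"), 0, len(cum) - 1)
    p1 = np.clip(np.searchsorted(xs, hi, side="right") - 1, 0, len(cum) - 1)
    integral = np.where(p1 > p0, cum[p1] - cum[p0], 0.0)
    predicted = np.maximum(0.0, model.slope * integral + model.intercept)
    feasible = predicted >= tic_threshold
    return [
        (int(a), int(b), float(rts[a]), float(rts[b]), float(itg))
        for a, b, itg in zip(ai[feasible], bi[feasible], integral[feasible])
    ]


def build_dag(
    clusters: Sequence[Cluster],
    model: TicModel,
    tic_threshold: float,
    bin_width: float,
    min_duration: float,
    max_duration: float = math.inf,
    transition_gap: float = 0.0,
) -> FeatureDag:
    """Construct the split-node feature-DAG over the given clusters."""
    if not (tic_threshold > 0 and bin_width > 0 and min_duration >= 0):
        raise ValidationError("build_dag parameters must be positive")
    if min_duration > max_duration:
        raise ValidationError("min_duration must be <= max_duration")
    if transition_gap < 0:
        raise ValidationError("transition_gap must be >= 0")

    nodes: list[DagNode] = []
    w1: list[DagEdge] = []
    cluster_map: dict[str, Cluster] = {}
    for cluster in clusters:
        cid = cluster.cluster_id
        if cid in cluster_map:
            raise ValidationError(f"duplicate cluster id {cid!r}")
        cluster_map[cid] = cluster
        bins = bin_cluster(cluster, bin_width)
        if not bins:
            continue
        split_in = [
            DagNode(cid, b.bin_index, b.rt, b.intensity, "in") for b in bins
        ]
        split_out = [
            DagNode(cid, b.bin_index, b.rt, b.intensity, "out") for b in bins
        ]
        nodes.extend(split_in)
        nodes.extend(split_out)
        for a, b, rt_a, rt_b, integral in enumerate_windows(
            cluster, bins, model, tic_threshold, min_duration, max_duration
        ):
            w1.append(
                DagEdge(
                    from_node=split_in[a],
                    to_node=split_out[b],
                    weight=1,
                    rt_start=rt_a,
                    rt_end=rt_b,
                    accumulated_intensity=integral,
                )
            )

    source = DagNode("", 0, -math.inf, 0.0, "source")
    sink = DagNode("", 0, math.inf, 0.0, "sink")
    dag = FeatureDag(
        source=source,
        sink=sink,
        nodes=nodes,
        weight1_edges=w1,
        clusters=cluster_map,
        model=model,
        tic_threshold=tic_threshold,
        bin_width=bin_width,
        transition_gap=transition_gap,
    )
    # every weight-1 edge must satisfy the TIC gate it was built from
    for e in dag.weight1_edges:
        if predict_tic(model, e.accumulated_intensity) < tic_threshold:
            raise ValidationError("internal invariant: sub-threshold weight-1 edge")
    return dag
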