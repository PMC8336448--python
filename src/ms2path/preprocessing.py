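"""Background filtering and apex-centered nearest-neighbor signal clustering.

This is the first pipeline step: features that are also present in the
background/control sample are discarded, then every raw MS1 scan point is
assigned to the surviving apex that is nearest in a tolerance-scaled
(m/z, RT) space.

Distance model
--------------
For signal *s* and apex *a*:

    d(s, a) = max(|mz_s - mz_a| / mz_tol, |rt_s - rt_a| / rt_tol)

i.e. Chebyshev distance after scaling each axis by its tolerance. A signal is
assigned to the apex minimizing *d*, but only if d <= 1 (a hard tolerance
cutoff); otherwise it stays unassigned and is only counted. Ties are broken by
smaller |Δmz|, then by smaller feature_id, so assignment is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io_formats import ApexFeature, RawSignal

__all__ = ["Cluster", "ClusterTolerance", "filter_background", "assign_signals"]

logger = logging.getLogger(__name__)

_CHUNK = 4096  # signals per distance-matrix block, bounds memory at scale


@dataclass(frozen=True, slots=True)
class ClusterTolerance:
    """Hard assignment tolerances: mz_tol in Th, rt_tol in seconds."""

    mz_tol: float = 0.01
    rt_tol: float = 5.0

    def __post_init__(self) -> None:
        if not (self.mz_tol > 0 and self.rt_tol > 0):
            raise ValidationError("cluster tolerances must be > 0")


@dataclass(frozen=True, slots=True)
class Cluster:
    """An apex together with the raw signals assigned to it (sorted by RT)."""

    apex: ApexFeature
    members: tuple[RawSignal, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        rts = [m.rt for m in self.members]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValidationError(
                f"cluster {self.apex.feature_id!r}: members must be RT-sorted"
            )

    @property
    def cluster_id(self) -> str:
        return self.apex.feature_id


def filter_background(
    apexes: list[ApexFeature], min_ratio: float = 3.0
) -> list[ApexFeature]:
    """Discard features present in the background/control sample.

    A feature is retained iff it is absent from the blank
    (``intensity_blank == 0``) or its sample/blank intensity ratio is at least
    ``min_ratio``. Order is preserved.
    """
    if not min_ratio > 0:
        raise ValidationError("min_ratio must be > 0")
    kept = [
        a
        for a in apexes
        if a.intensity_blank == 0 or a.intensity_sample / a.intensity_blank >= min_ratio
    ]
    discarded = len(apexes) - len(kept)
    if discarded:
        logger.info(
            "filter_background: discarded %d/%d feature(s) present in background",
            discarded,
            len(apexes),
        )
    return kept


def assign_signals(
    signals: list[RawSignal],
    apexes: list[ApexFeature],
    tol: ClusterTolerance | None = None,
) -> list[Cluster]:
    """Map raw signals onto apex-centered clusters by nearest neighbor.

    Returns one cluster per apex (possibly with an empty member list), in the
    input apex order. Signals farther than the tolerance from every apex stay
    unassigned; their count is logged.
    """
    if not apexes:
        raise ConfigurationError("assign_signals requires a non-empty apex list")
    tol = tol or ClusterTolerance()

    a_mz = np.array([a.mz for a in apexes])
    a_rt = np.array([a.rt for a in apexes])
    # apex rank under the tie-break ordering (smaller feature_id wins)
    id_rank = np.argsort(np.argsort([a.feature_id for a in apexes], kind="stable"))

    members: list[list[RawSignal]] = [[] for _ in apexes]
    unassigned = 0
    for lo in range(0, len(signals), _CHUNK):
        block = signals[lo : lo + _CHUNK]
        s_mz = np.array([s.mz for s in block])[:, None]
        s_rt = np.array([s.rt for s in block])[:, None]
        dmz = np.abs(s_mz - a_mz[None, :])
        d = np.maximum(dmz / tol.mz_tol, np.abs(s_rt - a_rt[None, :]) / tol.rt_tol)
        dmin = d.min(axis=1)
        for i, sig in enumerate(block):
            if dmin[i] > 1.0:
                unassigned += 1
                continue
            tied = np.flatnonzero(d[i] == dmin[i])
            if len(tied) > 1:
                # smaller |Δmz| first, then smaller feature_id
                order = np.lexsort((id_rank[tied], dmz[i, tied]))
                best = int(tied[order[0]])
            else:
                best = int(tied[0])
            members[best].append(sig)
    if unassigned:
        logger.info(
            "assign_signals: %d/%d signal(s) outside tolerance of every apex",
            unassigned,
            len(signals),
        )
    clusters = []
    for apex, mem in zip(apexes, members):
        mem.sort(key=lambda s: (s.rt, s.mz))
        clusters.append(Cluster(apex=apex, members=tuple(mem)))
    return clusters
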