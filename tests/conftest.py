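"""Shared builders for planner test instances."""

import numpy as np
import pytest

from ms2path import ApexFeature, Cluster, RawSignal, TicModel


def make_cluster(
    feature_id: str,
    rts,
    intensities,
    mz: float = 200.0,
    charge: int = 1,
) -> Cluster:
    """Cluster with explicit member scan points; apex at the max intensity."""
    rts = list(rts)
    intensities = list(intensities)
    assert len(rts) == len(intensities)
    k = int(np.argmax(intensities))
    apex = ApexFeature(
        feature_id=feature_id,
        mz=mz,
        rt=rts[k],
        intensity_sample=intensities[k],
        charge=charge,
    )
    members = sorted(
        (RawSignal(mz=mz, rt=r, intensity=i) for r, i in zip(rts, intensities)),
        key=lambda s: s.rt,
    )
    return Cluster(apex=apex, members=tuple(members))


def flat_cluster(feature_id: str, rt_start: int, rt_end: int, intensity: float,
                 mz: float = 200.0) -> Cluster:
    """Constant-intensity cluster sampled at integer RTs in [rt_start, rt_end]."""
    rts = list(range(rt_start, rt_end + 1))
    return make_cluster(feature_id, rts, [intensity] * len(rts), mz=mz)


@pytest.fixture
def identity_model() -> TicModel:
    return TicModel.identity()


@pytest.fixture
def abc_clusters() -> list[Cluster]:
    """Three features whose only long-enough windows interleave as
    A=[0,10], B=[5,15], C=[12,20]: A-then-C is schedulable in one run but any
    pair involving B is not."""
    return [
        flat_cluster("A", 0, 10, 1000.0, mz=100.0),
        flat_cluster("B", 5, 15, 1000.0, mz=200.0),
        flat_cluster("C", 12, 20, 1000.0, mz=300.0),
    ]
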