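"""Background filtering and nearest-neighbor signal assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ms2path import (
    ApexFeature,
    ClusterTolerance,
    ConfigurationError,
    RawSignal,
    assign_signals,
    filter_background,
    generate_run,
    SyntheticRunSpec,
)


def apex(fid, sample, blank=0.0, mz=100.0, rt=10.0):
    return ApexFeature(fid, mz, rt, sample, blank, 1)


class TestFilterBackground:
    def test_blank_absent_always_retained(self):
        a = apex("F1", 100.0, blank=0.0)
        for ratio in (0.1, 3.0, 1e9):
            assert filter_background([a], ratio) == [a]

    def test_ratio_boundary(self):
        kept = apex("K", 9000.0, blank=3000.0)
        dropped = apex("D", 8999.0, blank=3000.0)
        assert filter_background([kept, dropped], min_ratio=3.0) == [kept]

    def test_all_background_gives_empty(self):
        apexes = [apex(f"F{i}", 1000.0, blank=1000.0) for i in range(4)]
        assert filter_background(apexes, min_ratio=3.0) == []

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(1.0, 1e6, allow_nan=False),
                st.floats(0.0, 1e6, allow_nan=False),
            ),
            max_size=15,
        ),
        st.floats(0.5, 10.0),
        st.floats(0.0, 10.0),
    )
    def test_monotone_in_min_ratio(self, rows, ratio, bump):
        """Raising min_ratio never adds a retained feature."""
        apexes = [apex(f"F{i}", s, blank=b) for i, (s, b) in enumerate(rows)]
        loose = {a.feature_id for a in filter_background(apexes, ratio)}
        strict = {a.feature_id for a in filter_background(apexes, ratio + bump)}
        assert strict <= loose


class TestAssignSignals:
    def test_single_apex_collects_in_tolerance_signals(self):
        a = apex("F1", 100.0, mz=100.0, rt=10.0)
        signals = [RawSignal(100.0, rt, 50.0) for rt in (8.0, 10.0, 12.0)]
        (cluster,) = assign_signals(signals, [a], ClusterTolerance(0.01, 5.0))
        assert len(cluster.members) == 3

    def test_nearest_in_mz_wins(self):
        apexes = [apex("F1", 1.0, mz=100.0), apex("F2", 1.0, mz=200.0)]
        sig = RawSignal(100.001, 10.0, 5.0)
        c1, c2 = assign_signals([sig], apexes, ClusterTolerance(0.01, 5.0))
        assert len(c1.members) == 1 and len(c2.members) == 0

    def test_out_of_tolerance_unassigned(self):
        a = apex("F1", 1.0, rt=100.0)
        sig = RawSignal(100.0, 500.0, 5.0)
        (cluster,) = assign_signals([sig], [a], ClusterTolerance(0.01, 10.0))
        assert cluster.members == ()

    def test_empty_apex_list_is_config_error(self):
        with pytest.raises(ConfigurationError):
            assign_signals([], [], ClusterTolerance())

    def test_tie_breaks_by_smaller_feature_id(self):
        # signal exactly equidistant from both apexes in scaled space
        apexes = [apex("B", 1.0, mz=100.01), apex("A", 1.0, mz=99.99)]
        sig = RawSignal(100.0, 10.0, 5.0)
        clusters = assign_signals([sig], apexes, ClusterTolerance(0.02, 5.0))
        by_id = {c.cluster_id: len(c.members) for c in clusters}
        assert by_id == {"A": 1, "B": 0}

    def test_partition_and_idempotence_on_synthetic_run(self):
        """Each signal lands in at most one cluster; re-clustering members is stable."""
        signals, truth = generate_run(
            SyntheticRunSpec(n_features=12, rt_range=200.0, n_background=0, seed=11)
        )
        tol = ClusterTolerance(0.01, 15.0)
        clusters = assign_signals(signals, truth, tol)
        n_assigned = sum(len(c.members) for c in clusters)
        assert n_assigned <= len(signals)
        # partition: no signal object appears in two clusters
        seen = set()
        for c in clusters:
            for m in c.members:
                key = (m.mz, m.rt, m.intensity)
                assert key not in seen
                seen.add(key)
        # idempotence on assigned members
        members = [m for c in clusters for m in c.members]
        again = assign_signals(members, truth, tol)
        assert [len(c.members) for c in again] == [len(c.members) for c in clusters]
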