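"""Synthetic LC-MS1 run generation and a minimal top-N DDA simulator.

The generator emulates the preliminary full-scan MS1 experiment the planner
consumes: each feature is a Gaussian elution profile

    I(t) = h * exp(-(t - rt0)^2 / (2 sigma^2))

sampled on a regular scan grid, truncated at 3 sigma, with multiplicative
log-normal intensity noise (so intensities stay positive). Background
features — contaminants equally present in the blank — are emitted with
``intensity_blank == intensity_sample`` so the background filter removes
them. Feature m/z values are drawn without replacement from a 0.05 Th grid,
which keeps co-eluting features resolvable in m/z the way distinct
metabolites on a high-resolution instrument are.

The DDA simulator is deliberately minimal: at each MS1 scan it fragments the
``top_n`` most intense non-excluded features and puts each on dynamic
exclusion for a fixed window. It models neither injection time nor charge
filtering; it exists so relative properties (acquisition redundancy, coverage
per extra run) can be compared against planned acquisition on identical
synthetic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import ApexFeature, RawSignal
from .planner import PlannerConfig
from .preprocessing import Cluster, ClusterTolerance, assign_signals
from .tic_model import TicModel

__all__ = [
    "SyntheticRunSpec",
    "DdaConfig",
    "generate_run",
    "simulate_dda",
    "coelution_run_spec",
    "random_planning_instance",
]


@dataclass(frozen=True, slots=True)
class SyntheticRunSpec:
    """Parameters of one synthetic preliminary MS1 run.

    Defaults describe a short, ordinary metabolomics gradient: a 10-minute
    run scanned at 2 Hz, 4 s chromatographic peak sigma, apex heights
    log-uniform over 1e4-1e7 counts and 10% log-normal intensity noise.
    """

    n_features: int = 50
    rt_range: float = 600.0
    scan_interval: float = 0.5
    peak_width_sigma: float = 4.0
    height_range: tuple[float, float] = (1e4, 1e7)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    n_background: int = 10
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 0 or self.n_background < 0:
            raise ValidationError("feature counts must be >= 0")
        if not (self.scan_interval > 0 and self.rt_range > 0):
            raise ValidationError("scan_interval and rt_range must be > 0")


@dataclass(frozen=True, slots=True)
class DdaConfig:
    """Top-N data-dependent acquisition settings (default: top-5 with 10 s
    dynamic exclusion, five replicate runs)."""

    top_n: int = 5
    exclusion_window: float = 10.0
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")


_MZ_GRID_STEP = 0.05


def generate_run(spec: SyntheticRunSpec) -> tuple[list[RawSignal], list[ApexFeature]]:
    """Generate (raw signals, ground-truth apex table) for one MS1 run.

    Deterministic for a fixed ``spec.seed``. The truth table has
    ``n_features + n_background`` rows; background rows carry
    ``intensity_blank == intensity_sample``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_features + spec.n_background
    grid = np.arange(0.0, spec.rt_range + 1e-9, spec.scan_interval)

    lo, hi = spec.mz_range
    mz_grid = np.round(np.arange(lo, hi, _MZ_GRID_STEP), 6)
    if n_total > len(mz_grid):
        raise ValidationError("mz_range too narrow for the requested feature count")
    mzs = rng.choice(mz_grid, size=n_total, replace=False)

    sigma = spec.peak_width_sigma
    margin = min(3.0 * sigma, spec.rt_range / 2.0)
    rt0s = rng.uniform(margin, spec.rt_range - margin, size=n_total)
    h_lo, h_hi = spec.height_range
    heights = 10.0 ** rng.uniform(np.log10(h_lo), np.log10(h_hi), size=n_total)

    signals: list[RawSignal] = []
    truth: list[ApexFeature] = []
    width = len(str(max(n_total, 1)))
    for i in range(n_total):
        fid = f"F{i:0{width}d}"
        is_background = i >= spec.n_features
        t = grid[np.abs(grid - rt0s[i]) <= 3.0 * sigma]
        profile = heights[i] * np.exp(-((t - rt0s[i]) ** 2) / (2.0 * sigma**2))
        if spec.noise_sigma > 0:
            profile = profile * np.exp(
                spec.noise_sigma * rng.standard_normal(len(t))
            )
        for rt, inten in zip(t, profile):
            signals.append(RawSignal(mz=float(mzs[i]), rt=float(rt), intensity=float(inten)))
        truth.append(
            ApexFeature(
                feature_id=fid,
                mz=float(mzs[i]),
                rt=float(rt0s[i]),
                intensity_sample=float(heights[i]),
                intensity_blank=float(heights[i]) if is_background else 0.0,
                charge=1,
            )
        )
    signals.sort(key=lambda s: (s.rt, s.mz))
    return signals, truth


def simulate_dda(
    signals: Sequence[RawSignal],
    truth: Sequence[ApexFeature],
    dda: DdaConfig | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Scan-by-scan top-N DDA: MS2 acquisition counts per feature.

    At every MS1 scan the ``top_n`` most intense non-excluded features are
    fragmented once each and excluded for ``exclusion_window`` seconds.
    Replicate runs are independent restarts; counts are summed. The dynamics
    are deterministic (``seed`` is accepted for interface symmetry with the
    generator and reserved for future stochastic selection models).
    """
    dda = dda or DdaConfig()
    del seed  # selection is deterministic: intensity rank, m/z as tie-break
    if not truth:
        return {}
    # attribute each scan point to its ground-truth feature
    tol = ClusterTolerance(mz_tol=_MZ_GRID_STEP / 2.0, rt_tol=1e12)
    clusters = assign_signals(list(signals), list(truth), tol)
    by_scan: dict[float, list[tuple[float, float, str]]] = {}
    for c in clusters:
        for m in c.members:
            by_scan.setdefault(m.rt, []).append((m.intensity, c.apex.mz, c.cluster_id))
    scan_times = sorted(by_scan)

    counts: dict[str, int] = {a.feature_id: 0 for a in truth}
    for _ in range(dda.n_replicates):
        excluded_until: dict[str, float] = {}
        for t in scan_times:
            candidates = [
                (inten, mz, fid)
                for inten, mz, fid in by_scan[t]
                if excluded_until.get(fid, -np.inf) <= t
            ]
            candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
            for _, _, fid in candidates[: dda.top_n]:
                counts[fid] += 1
                excluded_until[fid] = t + dda.exclusion_window
    return counts


# ---------------------------------------------------------------------------
# canned study conditions
# ---------------------------------------------------------------------------


def coelution_run_spec(seed: int) -> SyntheticRunSpec:
    """A co-elution-heavy run: 30 features crowded into 150 s with wide peaks,
    so many features overlap and top-N DDA must repeatedly pick the same
    intense ions."""
    return SyntheticRunSpec(
        n_features=30,
        rt_range=150.0,
        scan_interval=1.0,
        peak_width_sigma=6.0,
        height_range=(1e4, 1e6),
        n_background=0,
        noise_sigma=0.2,
        seed=seed,
    )


def random_planning_instance(
    seed: int, max_clusters: int = 6, max_bins: int = 8
) -> tuple[list[Cluster], TicModel, PlannerConfig]:
    """A small random planning instance sized for exhaustive verification.

    Draws 2..max_clusters Gaussian features on a short gradient, clusters
    them, and picks a log-uniform TIC threshold wide enough to span
    everything-feasible through nothing-feasible regimes. Bin width is chosen
    so no cluster exceeds ``max_bins`` RT bins.
    """
    rng = np.random.default_rng(seed)
    sigma = float(rng.uniform(2.0, 6.0))
    spec = SyntheticRunSpec(
        n_features=int(rng.integers(2, max_clusters + 1)),
        rt_range=80.0,
        scan_interval=1.0,
        peak_width_sigma=sigma,
        height_range=(1e3, 1e5),
        n_background=0,
        noise_sigma=0.1,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    signals, truth = generate_run(spec)
    clusters = assign_signals(
        signals, truth, ClusterTolerance(mz_tol=0.01, rt_tol=4.0 * sigma)
    )
    bin_width = max(spec.scan_interval, 6.0 * sigma / max_bins + 1e-6)
    config = PlannerConfig(
        tic_threshold=10.0 ** rng.uniform(2.5, 5.5),
        num_paths=3,
        bin_width=bin_width,
        min_duration=spec.scan_interval,
    )
    return clusters, TicModel.identity(), config
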