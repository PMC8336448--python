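"""Linear prediction of MS2 total ion current from integrated MS1 intensity.

The quality gate for a candidate acquisition window [t_s, t_e] is the MS2 TIC
the instrument would collect there. TIC is linearly correlated with the
integral of the raw MS1 signal inside the window, padded by ±Δ (default
Δ = 0.2 s) to absorb retention-time fluctuation between the preliminary run
and the planned run. The model is

    predicted_tic = max(0, slope * integral + intercept)

fitted by ordinary least squares on (integral, observed TIC) training pairs
from a calibration DDA run. When no trained model is available the identity
model (slope 1, intercept 0) is used, which makes the TIC threshold a
threshold on the integrated MS1 signal itself — an equivalent and
platform-independent default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, FormatError, ValidationError
from .preprocessing import Cluster

__all__ = [
    "TicModel",
    "integrate_intensity",
    "fit_tic_model",
    "predict_tic",
    "read_training_pairs",
]

DEFAULT_DELTA = 0.2  # seconds of RT padding on each side of a window


@dataclass(frozen=True, slots=True)
class TicModel:
    """Linear map from integrated MS1 intensity (intensity*s) to MS2 TIC.

    ``r_squared`` is a fit diagnostic (None for hand-built models).
    """

    slope: float = 1.0
    intercept: float = 0.0
    delta: float = DEFAULT_DELTA
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValidationError("TicModel.delta must be >= 0")

    @classmethod
    def identity(cls, delta: float = DEFAULT_DELTA) -> "TicModel":
        """Threshold-on-integral mode: predicted TIC equals the raw integral."""
        return cls(slope=1.0, intercept=0.0, delta=delta)

    def save(self, sink: str | IO[str]) -> None:
        """Persist as a 3-field text file: slope, intercept, delta."""
        text = f"slope\tintercept\tdelta\n{self.slope!r}\t{self.intercept!r}\t{self.delta!r}\n"
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w") as fh:
                fh.write(text)

    @classmethod
    def load(cls, source: str | IO[str]) -> "TicModel":
        df = pd.read_csv(source, sep="\t")
        for col in ("slope", "intercept", "delta"):
            if col not in df.columns:
                raise FormatError(f"TIC model file is missing field {col!r}")
        row = df.iloc[0]
        return cls(
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            delta=float(row["delta"]),
        )


def integrate_intensity(
    cluster: Cluster, rt_start: float, rt_end: float, delta: float = DEFAULT_DELTA
) -> float:
    """Trapezoidal integral of member intensity over the padded window.

    Scan points with rt in [rt_start - delta, rt_end + delta] contribute;
    points outside are excluded entirely (no edge interpolation). Fewer than
    two points in the padded window integrate to 0.
    """
    if not rt_start < rt_end:
        raise ValidationError("integrate_intensity requires rt_start < rt_end")
    lo, hi = rt_start - delta, rt_end + delta
    xs = np.array([m.rt for m in cluster.members])
    ys = np.array([m.intensity for m in cluster.members])
    mask = (xs >= lo) & (xs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(ys[mask], xs[mask]))


def fit_tic_model(
    pairs: Sequence[tuple[float, float]], delta: float = DEFAULT_DELTA
) -> TicModel:
    """Ordinary least-squares fit of observed MS2 TIC against MS1 integrals."""
    if len(pairs) < 2:
        raise DegenerateFitError("TIC fit needs at least 2 training pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.all(x == x[0]):
        raise DegenerateFitError(
            "TIC fit needs at least 2 distinct integral values (all identical)"
        )
    res = stats.linregress(x, y)
    return TicModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        delta=delta,
        r_squared=float(res.rvalue**2),
    )


def predict_tic(model: TicModel, integral: float) -> float:
    """Predicted MS2 TIC for a window integral, floored at 0."""
    if integral < 0:
        raise ValidationError("integral must be >= 0")
    return max(0.0, model.slope * integral + model.intercept)


def read_training_pairs(
    source: str | IO[str], dialect: str = "tsv"
) -> list[tuple[float, float]]:
    """Read (integral, observed_tic) training pairs from a TSV/CSV table."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(source, sep=sep)
    for col in ("integral", "observed_tic"):
        if col not in df.columns:
            raise FormatError(f"training-pair table is missing column {col!r}")
    return list(zip(df["integral"].astype(float), df["observed_tic"].astype(float)))
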