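"""Tabular dialects for raw MS1 signals, feature apexes and acquisition paths.

The reference interchange formats are plain TSV/CSV with named header columns
(column order is irrelevant and unknown columns pass through harmlessly):

* raw-signal table: ``mz``, ``rt_sec``, ``intensity`` — one centroided MS1
  scan point per row;
* apex table: ``feature_id``, ``mz``, ``rt_sec``, ``intensity_sample``
  [, ``intensity_blank``, ``charge``] — one detected MS1 feature per row, as
  produced upstream by an OpenMS-style feature finder;
* path table: one row per scheduled acquisition window, ordered by
  ``(path_index, rt_start_sec)``.

Retention time is seconds everywhere inside the package; unit conversion (for
instruments/tools that report minutes) happens at the CLI boundary only.

An optional mzML reader (centroided MS1 scans only) provides the same
``RawSignal`` contract for users coming straight from converted raw data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "RawSignal",
    "ApexFeature",
    "AcquisitionWindow",
    "Path",
    "read_raw_signals",
    "write_raw_signals",
    "read_apexes",
    "write_apexes",
    "read_paths",
    "write_paths",
    "write_vendor_inclusion_list",
    "read_mzml_signals",
]

logger = logging.getLogger(__name__)

_DELIMS = {"tsv": "\t", "csv": ","}

RAW_COLUMNS = ("mz", "rt_sec", "intensity")
APEX_COLUMNS = ("feature_id", "mz", "rt_sec", "intensity_sample")
APEX_OPTIONAL = ("intensity_blank", "charge")
PATH_COLUMNS = (
    "path_index",
    "feature_id",
    "iso_mz",
    "rt_start_sec",
    "rt_end_sec",
    "accumulated_intensity",
    "predicted_tic",
    "charge",
)


@dataclass(frozen=True, slots=True)
class RawSignal:
    """One centroided MS1 scan point: m/z (Th), RT (s), ion intensity (>= 0)."""

    mz: float
    rt: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"RawSignal.mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValidationError(f"RawSignal.rt must be >= 0, got {self.rt}")
        if self.intensity < 0:
            raise ValidationError(
                f"RawSignal.intensity must be >= 0, got {self.intensity}"
            )


@dataclass(frozen=True, slots=True)
class ApexFeature:
    """A detected MS1 feature apex.

    ``intensity_blank`` is the apex intensity observed in the background /
    control sample (0 when the feature is absent from the blank); ``charge``
    0 means unknown.
    """

    feature_id: str
    mz: float
    rt: float
    intensity_sample: float
    intensity_blank: float = 0.0
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.intensity_sample > 0:
            raise ValidationError(
                f"ApexFeature.intensity_sample must be > 0 for {self.feature_id!r}"
            )


@dataclass(frozen=True, slots=True)
class AcquisitionWindow:
    """One contiguous MS2 acquisition interval for a single feature."""

    feature_id: str
    iso_mz: float
    rt_start: float
    rt_end: float
    accumulated_intensity: float
    predicted_tic: float
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.rt_start < self.rt_end:
            raise ValidationError(
                f"AcquisitionWindow rt_start must be < rt_end "
                f"({self.rt_start} >= {self.rt_end})"
            )
        if self.accumulated_intensity < 0:
            raise ValidationError("accumulated_intensity must be >= 0")


@dataclass(frozen=True, slots=True)
class Path:
    """A time-ordered MS2 acquisition schedule for one instrument run.

    ``score`` is the number of distinct features acquired, which equals the
    number of windows because feature ids within a path are unique.
    """

    index: int
    windows: tuple[AcquisitionWindow, ...]
    score: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        if self.index < 0:
            raise ValidationError("Path.index must be >= 0")
        if self.score != len(self.windows):
            raise ValidationError("Path.score must equal the number of windows")
        validate_window_sequence(self.windows)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(w.feature_id for w in self.windows)


def validate_window_sequence(windows: Sequence[AcquisitionWindow]) -> None:
    """Raise if windows are not strictly RT-ordered / non-overlapping / unique."""
    for prev, cur in zip(windows, windows[1:]):
        if cur.rt_start < prev.rt_end:
            raise ValidationError(
                f"overlapping acquisition windows: [{prev.rt_start}, {prev.rt_end}] "
                f"then [{cur.rt_start}, {cur.rt_end}]"
            )
    ids = [w.feature_id for w in windows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate feature ids within one path: {dupes}")


# ---------------------------------------------------------------------------
# table parsing helpers
# ---------------------------------------------------------------------------

def _read_table(source: str | IO[str], dialect: str) -> pd.DataFrame:
    try:
        sep = _DELIMS[dialect]
    except KeyError:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    df = pd.read_csv(source, sep=sep, dtype=str, skip_blank_lines=True)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing required column(s): {missing}")


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, counting the header line
        raise ParseError(
            f"{what} table: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"{column!r} at line {row}"
        )
    if out.isna().any():
        row = int(out.isna().idxmax()) + 2
        raise ParseError(f"{what} table: empty cell in column {column!r} at line {row}")
    return out.astype(float)


# ---------------------------------------------------------------------------
# raw signals
# ---------------------------------------------------------------------------

def read_raw_signals(source: str | IO[str], dialect: str = "tsv") -> list[RawSignal]:
    """Read the raw MS1 signal table (m/z, RT, intensity triplets).

    Rows with non-positive intensity are dropped (with a logged count); the
    result is sorted by (rt, mz).
    """
    df = _read_table(source, dialect)
    _require_columns(df, RAW_COLUMNS, "raw-signal")
    if df.empty:
        return []
    mz = _numeric(df, "mz", "raw-signal")
    rt = _numeric(df, "rt_sec", "raw-signal")
    inten = _numeric(df, "intensity", "raw-signal")
    keep = inten > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_raw_signals: dropped %d row(s) with intensity <= 0", dropped)
    signals = [
        RawSignal(mz=m, rt=r, intensity=i)
        for m, r, i in zip(mz[keep], rt[keep], inten[keep])
    ]
    signals.sort(key=lambda s: (s.rt, s.mz))
    return signals


def write_raw_signals(
    signals: Sequence[RawSignal], sink: str | IO[str], dialect: str = "tsv"
) -> None:
    df = pd.DataFrame(
        {
            "mz": [s.mz for s in signals],
            "rt_sec": [s.rt for s in signals],
            "intensity": [s.intensity for s in signals],
        },
        columns=list(RAW_COLUMNS),
    )
    df.to_csv(sink, sep=_DELIMS[dialect], index=False)


# ---------------------------------------------------------------------------
# apex features
# ---------------------------------------------------------------------------

def read_apexes(source: str | IO[str], dialect: str = "tsv") -> list[ApexFeature]:
    """Read the feature-apex table; optional columns default to blank=0, charge=0."""
    df = _read_table(source, dialect)
    _require_columns(df, APEX_COLUMNS, "apex")
    if df.empty:
        return []
    ids = df["feature_id"].astype(str).str.strip()
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise ValidationError(f"duplicate feature_id value(s) in apex table: {dupes}")
    mz = _numeric(df, "mz", "apex")
    rt = _numeric(df, "rt_sec", "apex")
    inten = _numeric(df, "intensity_sample", "apex")
    blank = (
        _numeric(df, "intensity_blank", "apex")
        if "intensity_blank" in df.columns
        else pd.Series(0.0, index=df.index)
    )
    charge = (
        _numeric(df, "charge", "apex").astype(int)
        if "charge" in df.columns
        else pd.Series(0, index=df.index)
    )
    return [
        ApexFeature(
            feature_id=fid,
            mz=m,
            rt=r,
            intensity_sample=s,
            intensity_blank=b,
            charge=int(z),
        )
        for fid, m, r, s, b, z in zip(ids, mz, rt, inten, blank, charge)
    ]


def write_apexes(
    apexes: Sequence[ApexFeature], sink: str | IO[str], dialect: str = "tsv"
) -> None:
    df = pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in apexes],
            "mz": [a.mz for a in apexes],
            "rt_sec": [a.rt for a in apexes],
            "intensity_sample": [a.intensity_sample for a in apexes],
            "intensity_blank": [a.intensity_blank for a in apexes],
            "charge": [a.charge for a in apexes],
        },
        columns=list(APEX_COLUMNS) + list(APEX_OPTIONAL),
    )
    df.to_csv(sink, sep=_DELIMS[dialect], index=False)


# ---------------------------------------------------------------------------
# acquisition paths (inclusion-list precursor table)
# ---------------------------------------------------------------------------

def write_paths(
    paths: Sequence[Path], sink: str | IO[str], dialect: str = "tsv"
) -> None:
    """Serialize paths, one row per acquisition window.

    Rows are ordered by ``(path_index, rt_start_sec)``; invalid schedules
    (overlapping windows within a path) are refused.
    """
    rows = []
    for p in paths:
        validate_window_sequence(p.windows)
        for w in p.windows:
            rows.append(
                (
                    p.index,
                    w.feature_id,
                    w.iso_mz,
                    w.rt_start,
                    w.rt_end,
                    w.accumulated_intensity,
                    w.predicted_tic,
                    w.charge,
                )
            )
    rows.sort(key=lambda r: (r[0], r[3]))
    df = pd.DataFrame(rows, columns=list(PATH_COLUMNS))
    df.to_csv(sink, sep=_DELIMS[dialect], index=False)


def read_paths(source: str | IO[str], dialect: str = "tsv") -> list[Path]:
    df = _read_table(source, dialect)
    _require_columns(df, PATH_COLUMNS, "path")
    if df.empty:
        return []
    idx = _numeric(df, "path_index", "path").astype(int)
    paths: list[Path] = []
    for path_index in sorted(idx.unique()):
        sub = df[idx == path_index]
        windows = [
            AcquisitionWindow(
                feature_id=str(r["feature_id"]).strip(),
                iso_mz=float(r["iso_mz"]),
                rt_start=float(r["rt_start_sec"]),
                rt_end=float(r["rt_end_sec"]),
                accumulated_intensity=float(r["accumulated_intensity"]),
                predicted_tic=float(r["predicted_tic"]),
                charge=int(float(r["charge"])),
            )
            for _, r in sub.iterrows()
        ]
        windows.sort(key=lambda w: w.rt_start)
        paths.append(Path(index=int(path_index), windows=tuple(windows), score=len(windows)))
    return paths


def write_vendor_inclusion_list(
    path: Path, sink: str | IO[str], polarity: str = "Positive"
) -> None:
    """Emit one path as a Q-Exactive/Exploris-style inclusion-list CSV.

    Thin, fixed column mapping from the path table: isolation m/z, charge
    (blank when unknown), polarity, and the RT window converted to minutes.
    One file per instrument run (path); not round-trippable by design — the
    TSV path table is the authoritative format.
    """
    df = pd.DataFrame(
        {
            "Mass [m/z]": [w.iso_mz for w in path.windows],
            "Formula [M]": "",
            "Species": "",
            "CS [z]": [w.charge if w.charge else "" for w in path.windows],
            "Polarity": polarity,
            "Start [min]": [w.rt_start / 60.0 for w in path.windows],
            "End [min]": [w.rt_end / 60.0 for w in path.windows],
            "Comment": [w.feature_id for w in path.windows],
        }
    )
    df.to_csv(sink, index=False)


# ---------------------------------------------------------------------------
# optional mzML ingestion
# ---------------------------------------------------------------------------

def _decode_binary_array(elem) -> "np.ndarray | None":
    """Decode one <binaryDataArray>: returns the float array or None.

    Handles the common centroided-MS1 subset: 32/64-bit float, zlib or no
    compression, base64 text payload.
    """
    import base64
    import zlib

    import numpy as np

    dtype = "<f8"
    compressed = False
    for cv in elem.iter():
        if not cv.tag.endswith("cvParam"):
            continue
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    binary = next((c for c in elem.iter() if c.tag.endswith("binary")), None)
    if binary is None or not (binary.text or "").strip():
        return None
    raw = base64.b64decode(binary.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_signals(source: str) -> list[RawSignal]:
    """Read centroided MS1 scans from an mzML file into RawSignal triplets.

    A deliberately small reader for the plain centroided-MS1 subset of mzML
    (base64 float arrays, optional zlib compression). Scan start times in
    minutes are converted to seconds; zero-intensity centroids are dropped.
    """
    import xml.etree.ElementTree as ET

    signals: list[RawSignal] = []
    for _, spectrum in ET.iterparse(source):
        if not spectrum.tag.endswith("spectrum") or spectrum.tag.endswith("chromatogram"):
            continue
        if "spectrumList" in spectrum.tag:
            continue
        ms_level = None
        rt_sec = None
        arrays: dict[str, "np.ndarray"] = {}
        for elem in spectrum.iter():
            tag = elem.tag
            if tag.endswith("cvParam"):
                acc = elem.get("accession", "")
                if acc == "MS:1000511":
                    ms_level = int(elem.get("value", "0"))
                elif acc == "MS:1000016":
                    value = float(elem.get("value", "nan"))
                    unit = elem.get("unitName", "second")
                    rt_sec = value * 60.0 if unit in ("minute", "min") else value
            elif tag.endswith("binaryDataArray"):
                kind = None
                for cv in elem.iter():
                    if cv.tag.endswith("cvParam"):
                        if cv.get("accession") == "MS:1000514":
                            kind = "mz"
                        elif cv.get("accession") == "MS:1000515":
                            kind = "intensity"
                if kind:
                    decoded = _decode_binary_array(elem)
                    if decoded is not None:
                        arrays[kind] = decoded
        if ms_level == 1 and rt_sec is not None and "mz" in arrays and "intensity" in arrays:
            for m, i in zip(arrays["mz"], arrays["intensity"]):
                if i > 0:
                    signals.append(RawSignal(mz=float(m), rt=rt_sec, intensity=float(i)))
        spectrum.clear()
    signals.sort(key=lambda s: (s.rt, s.mz))
    return signals
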