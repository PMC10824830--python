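"""Reading, validating and labeling motion-capture marker tables.

The on-disk dialect is a long-format CSV with header ``frame,marker,x_mm,y_mm,z_mm``,
one file per dyad, millimetres throughout, 0-based frame indices.  Frame rate is
supplied via metadata, never inferred from the file.  Empty cells (or NaN-like
tokens) mark occluded samples; they are carried as NaN internally and never
silently dropped.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    IntegrityError,
    LabelingError,
    MetadataError,
    ParameterError,
    ParseError,
)

INTERACTANTS = ("child", "storyteller")

#: Torso regions a marker may be assigned to. The three-marker identifier rig is
#: metadata only: it never enters the analysis streams.
REGIONS = (
    "upper_back_left",
    "upper_back_right",
    "lower_back_left",
    "lower_back_right",
    "identifier",
)
BACK_REGIONS = frozenset(REGIONS[:4])

AGE_GROUPS = ("3y", "6y")
CONDITIONS = ("PAI", "PII")

_MARKER_COLUMNS = ["frame", "marker", "x_mm", "y_mm", "z_mm"]
_COORD_COLUMNS = ["x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class MarkerLabel:
    """Assignment of one marker to an interactant and body region."""

    interactant: str
    region: str

    def __post_init__(self) -> None:
        if self.interactant not in INTERACTANTS:
            raise LabelingError(f"unknown interactant {self.interactant!r}")
        if self.region not in REGIONS:
            raise LabelingError(f"unknown region {self.region!r}")


#: marker_id -> MarkerLabel
LabelingMap = Mapping[str, MarkerLabel]


def make_labeling_map(entries: Mapping[str, tuple[str, str]]) -> dict[str, MarkerLabel]:
    """Build and validate a labeling map from ``{marker_id: (interactant, region)}``.

    Each analysis interactant must end up with at least one non-identifier marker.
    """
    labels = {m: MarkerLabel(*v) for m, v in entries.items()}
    for who in INTERACTANTS:
        n_back = sum(
            1 for lab in labels.values() if lab.interactant == who and lab.region in BACK_REGIONS
        )
        if n_back == 0:
            raise ConfigurationError(f"interactant {who!r} has no back markers in labeling map")
    return labels


@dataclass
class MarkerFrameTable:
    """Long-format marker trajectory table for one dyad.

    ``data`` has columns frame, marker, x_mm, y_mm, z_mm; frame indices are
    strictly increasing per marker and (frame, marker) pairs are unique.
    Missing coordinates are NaN.
    """

    data: pd.DataFrame
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParseError(f"fps must be positive, got {self.fps}")
        missing = [c for c in _MARKER_COLUMNS if c not in self.data.columns]
        if missing:
            raise ParseError(f"marker table missing columns {missing}")
        dup = self.data.duplicated(subset=["frame", "marker"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise IntegrityError(
                f"duplicated (frame, marker) pair ({int(row['frame'])}, {row['marker']!r})"
            )
        if (self.data["frame"] < 0).any():
            raise IntegrityError("negative frame index")

    @property
    def markers(self) -> list[str]:
        return sorted(self.data["marker"].unique())

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].max()) + 1 if len(self.data) else 0


def read_marker_table(path: str | Path, fps: float) -> MarkerFrameTable:
    """Read a long-format marker CSV.

    Malformed numeric cells raise :class:`ParseError` naming the file line;
    duplicated (frame, marker) pairs raise :class:`IntegrityError`.  Empty cells
    become NaN (missing), they are never dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        raw = pd.read_csv(path, dtype={"marker": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _MARKER_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ["frame", *_COORD_COLUMNS]:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        # NaN-like tokens are accepted as missing, anything else is malformed
        tokens = raw[col].astype(str).str.strip().str.lower()
        bad &= ~tokens.isin({"nan", "na", "n/a", "null"})
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: malformed value {raw[col][bad.idxmax()]!r} on line {line}")
        raw[col] = coerced
    if raw["frame"].isna().any():
        line = int(raw["frame"].isna().idxmax()) + 2
        raise ParseError(f"{path}: missing frame index on line {line}")
    raw["frame"] = raw["frame"].astype(np.int64)
    frame_ok = raw.groupby("marker")["frame"].apply(lambda s: bool(s.is_monotonic_increasing))
    if not frame_ok.all():
        bad_marker = frame_ok[~frame_ok].index[0]
        raise IntegrityError(f"{path}: frame indices not increasing for marker {bad_marker!r}")
    return MarkerFrameTable(raw[_MARKER_COLUMNS].reset_index(drop=True), fps=fps)


def write_marker_table(table: MarkerFrameTable, path: str | Path) -> Path:
    """Write the table in the canonical CSV dialect (missing -> empty cell)."""
    path = Path(path)
    df = table.data[_MARKER_COLUMNS].copy()
    out = _io.StringIO()
    df.to_csv(out, index=False, float_format="%.6f", na_rep="")
    path.write_text(out.getvalue())
    return path


@dataclass
class GapReport:
    """One run of missing samples for one marker trajectory."""

    interactant: str
    marker_id: str
    start_frame: int
    end_frame: int  # inclusive
    filled: bool

    @property
    def length(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class LabeledRecording:
    """Frame-aligned back-marker trajectories for both interactants.

    ``trajectories[interactant][marker_id]`` is an (n_frames, 3) float array on
    the common frame range ``frames`` (a contiguous 0-based index range after
    alignment).  Identifier markers are excluded at labeling time.
    """

    trajectories: dict[str, dict[str, np.ndarray]]
    frames: np.ndarray
    fps: float
    gap_reports: list[GapReport] = field(default_factory=list)
    has_unfilled_gaps: bool = False

    def __post_init__(self) -> None:
        for who in INTERACTANTS:
            if who not in self.trajectories or not self.trajectories[who]:
                raise ConfigurationError(f"interactant {who!r} absent from recording")
        n = len(self.frames)
        for who, marks in self.trajectories.items():
            for m, arr in marks.items():
                if arr.shape != (n, 3):
                    raise ConfigurationError(
                        f"trajectory {who}/{m} shape {arr.shape} != ({n}, 3)"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def markers_of(self, who: str) -> list[str]:
        return sorted(self.trajectories[who])

    def missing_fraction(self) -> float:
        """Fraction of (frame, marker) samples with any missing coordinate."""
        total = 0
        missing = 0
        for marks in self.trajectories.values():
            for arr in marks.values():
                total += arr.shape[0]
                missing += int(np.isnan(arr).any(axis=1).sum())
        return missing / total if total else 0.0


def apply_labels(table: MarkerFrameTable, labels: LabelingMap) -> LabeledRecording:
    """Partition a marker table into per-interactant back-marker trajectories.

    Coordinate values are never altered; rows are only routed by the map.
    Identifier-region markers are dropped from the analysis streams.  Every
    marker id in the table must appear in the map.
    """
    unlabeled = set(table.markers) - set(labels)
    if unlabeled:
        raise LabelingError(f"markers without labels: {sorted(unlabeled)}")
    f_lo = int(table.data["frame"].min())
    f_hi = int(table.data["frame"].max())
    frames = np.arange(f_lo, f_hi + 1)
    n = len(frames)
    trajectories: dict[str, dict[str, np.ndarray]] = {w: {} for w in INTERACTANTS}
    for marker_id, group in table.data.groupby("marker"):
        lab = labels[marker_id]
        if lab.region not in BACK_REGIONS:
            continue
        arr = np.full((n, 3), np.nan)
        idx = group["frame"].to_numpy() - f_lo
        arr[idx] = group[_COORD_COLUMNS].to_numpy(dtype=float)
        trajectories[lab.interactant][marker_id] = arr
    for who in INTERACTANTS:
        if not trajectories[who]:
            raise ConfigurationError(f"interactant {who!r} has zero back markers after labeling")
    return LabeledRecording(trajectories, frames, table.fps)


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in a boolean mask as (start, end) inclusive."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def fill_gaps(rec: LabeledRecording, max_gap_s: float = 0.25) -> LabeledRecording:
    """Linearly interpolate occlusion gaps of at most ``max_gap_s`` seconds.

    Longer runs, and runs touching either end of the recording (no anchor on
    one side), are left missing and reported.  Idempotent.  Never raises on
    degenerate input: the result carries a gap report instead.
    """
    if max_gap_s < 0:
        raise ParameterError("max_gap_s must be >= 0")
    max_len = int(np.floor(max_gap_s * rec.fps))
    reports: list[GapReport] = []
    unfilled = False
    new_traj: dict[str, dict[str, np.ndarray]] = {}
    n = rec.n_frames
    for who, marks in rec.trajectories.items():
        new_traj[who] = {}
        for marker_id, arr in marks.items():
            out = arr.copy()
            mask = np.isnan(arr).any(axis=1)
            for start, end in _nan_runs(mask):
                length = end - start + 1
                interior = start > 0 and end < n - 1
                fillable = interior and length <= max_len
                if fillable:
                    t = np.arange(start, end + 1)
                    for k in range(3):
                        out[start : end + 1, k] = np.interp(
                            t, [start - 1, end + 1], [arr[start - 1, k], arr[end + 1, k]]
                        )
                else:
                    unfilled = True
                reports.append(
                    GapReport(who, marker_id, int(rec.frames[start]), int(rec.frames[end]), fillable)
                )
            new_traj[who][marker_id] = out
    return LabeledRecording(
        new_traj, rec.frames.copy(), rec.fps, gap_reports=reports, has_unfilled_gaps=unfilled
    )


@dataclass(frozen=True)
class DyadMetadata:
    """Study metadata for one child-storyteller pair."""

    dyad_id: str
    age_group: str
    condition: str
    climax_time_s: float
    fps: float

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise MetadataError(f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")
        if self.condition not in CONDITIONS:
            raise MetadataError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.fps <= 0:
            raise MetadataError("fps must be positive")
        if self.climax_time_s <= 0:
            raise MetadataError("climax_time_s must be positive")


_META_COLUMNS = ["dyad_id", "age_group", "condition", "climax_time_s", "fps"]


def read_metadata_table(path: str | Path) -> list[DyadMetadata]:
    """Read the dyad metadata CSV ``dyad_id,age_group,condition,climax_time_s,fps``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"dyad_id": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["dyad_id"].duplicated().any():
        dup = df["dyad_id"][df["dyad_id"].duplicated()].iloc[0]
        raise IntegrityError(f"{path}: duplicated dyad_id {dup!r}")
    return [
        DyadMetadata(
            dyad_id=row["dyad_id"],
            age_group=row["age_group"],
            condition=row["condition"],
            climax_time_s=float(row["climax_time_s"]),
            fps=float(row["fps"]),
        )
        for _, row in df.iterrows()
    ]


def write_metadata_table(rows: Iterable[DyadMetadata], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "dyad_id": m.dyad_id,
                "age_group": m.age_group,
                "condition": m.condition,
                "climax_time_s": m.climax_time_s,
                "fps": m.fps,
            }
            for m in rows
        ],
        columns=_META_COLUMNS,
    )
    out = _io.StringIO()
    df.to_csv(out, index=False)
    path.write_text(out.getvalue())
    return path
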