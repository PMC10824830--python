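"""Zero-lag and delayed cross-correlation curves for one dyad.

The correlation statistic is the uncentered product-moment coefficient

    r = sum(a*b) / sqrt(sum(a^2) * sum(b^2)),

computed on speed signals without subtracting means: speed fluctuates around
zero by construction (motion events depart from and return to rest), so the
uncentered form is the natural one and is scale-invariant, which is why the
mm/frame unit never needs conversion.  Delayed correlations keep the
storyteller's series fixed and shift the child's, trimming the ends that do
not overlap; a positive lag therefore asks whether the child moves as the
storyteller did that many milliseconds earlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientDataError,
    MetadataError,
    ParameterError,
    UndefinedCorrelationError,
)
from .io import DyadMetadata, LabeledRecording
from .preprocess import SpeedSignal

#: The default grid: simultaneous coordination plus 15 delays of 100..1500 ms.
DEFAULT_LAGS_MS = tuple(range(0, 1501, 100))

SEGMENTS = ("pre", "post", "whole")


@dataclass(frozen=True)
class LagGrid:
    """Ordered unique millisecond lags and their frame equivalents at ``fps``.

    Lags are specified in ms and converted round-to-nearest frame; the default
    grid is exact at 120 fps (100 ms = 12 frames).
    """

    lags_ms: tuple[int, ...]
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if len(set(self.lags_ms)) != len(self.lags_ms):
            raise ParameterError("lags must be unique")
        if list(self.lags_ms) != sorted(self.lags_ms):
            raise ParameterError("lags must be sorted")

    @property
    def lags_frames(self) -> np.ndarray:
        return np.rint(np.asarray(self.lags_ms) * self.fps / 1000.0).astype(int)

    def __len__(self) -> int:
        return len(self.lags_ms)

    @classmethod
    def default(cls, fps: float = 120.0) -> "LagGrid":
        return cls(DEFAULT_LAGS_MS, fps)


@dataclass
class CrossCorrelationCurve:
    """Per-lag correlation r and pair count m for one dyad segment.

    Lags where the correlation is undefined (a zero-energy slice) carry NaN in
    ``r`` and are excluded from pooling; they are flagged, never fabricated.
    """

    grid: LagGrid
    r: np.ndarray  # (n_lags,), NaN = undefined at that lag
    m: np.ndarray  # (n_lags,) int pair counts
    dyad_id: str = ""
    segment: str = "whole"

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ParameterError(f"segment must be one of {SEGMENTS}")
        defined = ~np.isnan(self.r)
        if np.any(np.abs(self.r[defined]) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")

    @property
    def lags_ms(self) -> np.ndarray:
        return np.asarray(self.grid.lags_ms)


def corr(a: np.ndarray, b: np.ndarray, center: bool = False) -> float:
    """Uncentered product-moment correlation of two equal-length vectors.

    With ``center=True`` the means are removed first, giving the textbook
    Pearson coefficient — available to quantify how little the two differ on
    zero-mean speed data (default off).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InsufficientDataError("need two equal-length 1D vectors")
    if len(a) < 2:
        raise InsufficientDataError("need at least 2 samples")
    if center:
        a = a - a.mean()
        b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0.0:
        raise UndefinedCorrelationError("zero-energy signal; correlation undefined")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def corr_at_lag(
    storyteller: SpeedSignal | np.ndarray,
    child: SpeedSignal | np.ndarray,
    lag_frames: int,
    center: bool = False,
) -> tuple[float, int]:
    """Correlation of (s[t], c[t+lag]) over the overlapping range, plus its length.

    The storyteller's series is held fixed and the child's shifted; ends that
    do not overlap are trimmed, so m = n − |lag|.  Positive lags mean the child
    trails the storyteller.  Negative lags are supported by the same trimming.
    """
    s = storyteller.values if isinstance(storyteller, SpeedSignal) else np.asarray(storyteller)
    c = child.values if isinstance(child, SpeedSignal) else np.asarray(child)
    if s.shape != c.shape:
        raise InsufficientDataError("signals must be frame-aligned at lag 0")
    n = len(s)
    if abs(lag_frames) >= n:
        raise InsufficientDataError(f"|lag| {lag_frames} >= signal length {n}")
    if lag_frames >= 0:
        a, b = s[: n - lag_frames], c[lag_frames:]
    else:
        a, b = s[-lag_frames:], c[: n + lag_frames]
    m = n - abs(lag_frames)
    if m < 2:
        raise InsufficientDataError("fewer than 2 overlapping samples")
    return corr(a, b, center=center), m


def curve(
    storyteller: SpeedSignal,
    child: SpeedSignal,
    grid: LagGrid | None = None,
    dyad_id: str = "",
    segment: str = "whole",
    center: bool = False,
) -> CrossCorrelationCurve:
    """One (r, m) per grid lag; undefined correlations become NaN, not values."""
    if grid is None:
        grid = LagGrid.default(storyteller.fps)
    r = np.empty(len(grid))
    m = np.empty(len(grid), dtype=int)
    for i, lag in enumerate(grid.lags_frames):
        try:
            r[i], m[i] = corr_at_lag(storyteller, child, int(lag), center=center)
        except UndefinedCorrelationError:
            r[i] = np.nan
            m[i] = len(storyteller) - abs(int(lag))
    return CrossCorrelationCurve(grid, r, m, dyad_id=dyad_id, segment=segment)


def split_at_climax(
    rec: LabeledRecording, meta: DyadMetadata
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Half-open frame-index ranges partitioning the recording at the climax.

    The boundary is floor(climax_time_s * fps).  Each segment is re-preprocessed
    independently (axis and filter are segment-local); trimming for delayed
    correlations then happens within each segment, never across the boundary.
    """
    n = rec.n_frames
    k = int(np.floor(meta.climax_time_s * rec.fps))
    if not 0 < k < n:
        raise MetadataError(
            f"climax at frame {k} outside recording of {n} frames for dyad {meta.dyad_id!r}"
        )
    return (0, k), (k, n)
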