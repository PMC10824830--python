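"""Reduce a labeled recording to one oriented 1D speed signal per interactant.

Processing order is fixed: average back markers to a torso centroid, project
onto the proximity axis (approach-positive for *both* interactants), take
first differences, low-pass filter.  The approach-positive convention is what
gives downstream correlations their morphological reading: positive r means
mirror-like (symmetric) coordination — both approach or both retreat together
— and negative r means one approaches while the other retreats (asymmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter, lfiltic

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InsufficientDataError,
    ParameterError,
)
from .io import INTERACTANTS, LabeledRecording

#: Default filter cutoff, Hz. Removes high-frequency recording artifacts while
#: leaving torso-scale motion (< a few Hz) essentially untouched.
DEFAULT_CUTOFF_HZ = 10.0

#: Mean centroid distances below this are treated as degenerate geometry (mm).
MIN_AXIS_DISTANCE_MM = 1.0


@dataclass
class TorsoTrajectory:
    """Per-frame 3D torso centroid (mm) for one interactant."""

    positions: np.ndarray  # (n_frames, 3)
    fps: float
    interactant: str = ""

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def time_mean(self) -> np.ndarray:
        return np.nanmean(self.positions, axis=0)


@dataclass
class ProximityAxis:
    """Unit vector between the interactants plus per-side orientation signs.

    ``unit_vector`` points from interactant A toward interactant B.  A's
    oriented projection uses sign +1 (approaching B increases it), B's uses
    sign −1, so "increasing = approaching the partner" holds for both.
    """

    unit_vector: np.ndarray  # (3,), unit norm
    role_a: str
    role_b: str

    def sign(self, who: str) -> int:
        if who == self.role_a:
            return +1
        if who == self.role_b:
            return -1
        raise ConfigurationError(f"unknown interactant {who!r} for this axis")


@dataclass
class SpeedSignal:
    """Scalar speed (mm/frame) along the oriented proximity axis."""

    values: np.ndarray  # (n_frames - 1,)
    fps: float
    interactant: str = ""

    def __len__(self) -> int:
        return len(self.values)


def average_torso(rec: LabeledRecording, who: str) -> TorsoTrajectory:
    """Unweighted per-frame mean of the interactant's available back markers."""
    marks = rec.trajectories.get(who, {})
    if not marks:
        raise ConfigurationError(f"no back markers for interactant {who!r}")
    stack = np.stack(list(marks.values()))  # (n_markers, n_frames, 3)
    with np.errstate(invalid="ignore"):
        centroid = np.nanmean(stack, axis=0)
    return TorsoTrajectory(centroid, rec.fps, who)


def estimate_axis(traj_a: TorsoTrajectory, traj_b: TorsoTrajectory) -> ProximityAxis:
    """Proximity axis from the time-mean centroids of the two interactants.

    Estimated once per analysis segment: the interactants are seated, so the
    geometry is quasi-static, and a per-frame axis would leak the partner's
    motion into one's own projection.
    """
    if traj_a.n_frames == 0 or traj_b.n_frames == 0:
        raise InsufficientDataError("empty trajectory")
    delta = traj_b.time_mean() - traj_a.time_mean()
    dist = float(np.linalg.norm(delta))
    if not np.isfinite(dist) or dist < MIN_AXIS_DISTANCE_MM:
        raise DegenerateGeometryError(
            f"mean centroids {dist:.3g} mm apart; cannot orient proximity axis"
        )
    return ProximityAxis(delta / dist, role_a=traj_a.interactant, role_b=traj_b.interactant)


def project(traj: TorsoTrajectory, axis: ProximityAxis, who: str) -> np.ndarray:
    """Oriented 1D positions: ``sign(who) * (position . unit_vector)``.

    Increasing values mean approaching the partner, for either interactant.
    """
    return axis.sign(who) * (traj.positions @ axis.unit_vector)


def differentiate(positions: np.ndarray, fps: float, interactant: str = "") -> SpeedSignal:
    """First differences: s[t] = pos[t] − pos[t−1], in mm/frame."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or len(positions) < 2:
        raise InsufficientDataError("need a 1D position series of length >= 2")
    return SpeedSignal(np.diff(positions), fps, interactant)


def smoothing_coefficient(fps: float, cutoff_hz: float) -> float:
    """Per-sample weight of the single-pole low-pass recursion.

    alpha = dt / (RC + dt) with RC = 1 / (2*pi*cutoff); at 120 fps and a
    10 Hz cutoff this is about 0.3437.
    """
    if not 0 < cutoff_hz < fps / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={fps / 2} Hz), got {cutoff_hz}"
        )
    dt = 1.0 / fps
    rc = 1.0 / (2.0 * np.pi * cutoff_hz)
    return dt / (rc + dt)


def lowpass(speed: SpeedSignal, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> SpeedSignal:
    """Causal single-pole low-pass filter with unity DC gain.

    y[t] = y[t−1] + alpha * (s[t] − y[t−1]), initialized y[0] = s[0] to avoid a
    startup transient.  Single-pass (causal) on purpose: a forward–backward
    zero-phase pass would be a different, two-pole filter.
    """
    alpha = smoothing_coefficient(speed.fps, cutoff_hz)
    x = speed.values
    if len(x) == 0:
        return SpeedSignal(x.copy(), speed.fps, speed.interactant)
    b, a = [alpha], [1.0, -(1.0 - alpha)]
    zi = lfiltic(b, a, y=[x[0]], x=[x[0]])
    y, _ = lfilter(b, a, x, zi=zi)
    return SpeedSignal(y, speed.fps, speed.interactant)


def speed_signals(
    rec: LabeledRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    frame_range: tuple[int, int] | None = None,
) -> dict[str, SpeedSignal]:
    """Full preprocessing for one recording (or one segment of it).

    ``frame_range`` is a half-open (start, stop) index pair into the aligned
    frames; axis estimation and filtering are redone on the segment alone, so
    pre/post-climax segments are processed independently.
    Returns ``{"child": SpeedSignal, "storyteller": SpeedSignal}``.
    """
    if frame_range is not None:
        lo, hi = frame_range
        sub = {
            who: {m: arr[lo:hi] for m, arr in marks.items()}
            for who, marks in rec.trajectories.items()
        }
        rec = LabeledRecording(sub, rec.frames[lo:hi], rec.fps)
    trajs = {who: average_torso(rec, who) for who in INTERACTANTS}
    axis = estimate_axis(trajs["child"], trajs["storyteller"])
    out: dict[str, SpeedSignal] = {}
    for who in INTERACTANTS:
        pos1d = project(trajs[who], axis, who)
        out[who] = lowpass(differentiate(pos1d, rec.fps, who), cutoff_hz)
    return out
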