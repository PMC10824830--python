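"""Synthetic dyad recordings with known coupling structure.

Emulates the kind of session the pipeline analyses: two seated interactants
facing each other across ~1.2 m, each with four reflective back markers, recorded at
120 fps for about five minutes, with a story climax partway through.  The
storyteller's approach-axis speed is a zero-mean stationary AR(1) process; the
child's speed is a lagged linear mixture of the storyteller's plus independent
noise, with separate coupling regimes before and after the climax:

    c[t] = sum_k g_k * s[t - L_k] + eps[t]

A positive gain makes both interactants approach (and retreat) together —
mirror-like, symmetric coordination, positive downstream correlation; a
negative gain produces the complementary, asymmetric pattern.  Coupling acts
on *speeds*, because the correlation statistic does; positions are obtained by
leaky integration (a mild mean-reverting drift keeps seated posture from
random-walking away) and embedded in 3D facing geometry with per-marker
jitter.

Everything is reproducible from the config seed; groups derive one RNG stream
per dyad (base_seed + index) so parallel generation stays deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, ParameterError
from .io import (
    DyadMetadata,
    LabeledRecording,
    LabelingMap,
    MarkerFrameTable,
    MarkerLabel,
    make_labeling_map,
    write_marker_table,
    write_metadata_table,
)
from .preprocess import SpeedSignal

#: Leaky-integration coefficient: positions revert to the seat with a ~8 s
#: time constant at 120 fps, so speed is recovered essentially unchanged by
#: first differences while posture stays bounded.
POSITION_DRIFT = 0.999

#: Per-marker offsets from the torso centroid (mm), chosen to average to zero
#: so the centroid of the four back markers recovers the torso path exactly.
_MARKER_OFFSETS = {
    "upper_back_left": np.array([0.0, -150.0, 150.0]),
    "upper_back_right": np.array([0.0, 150.0, 150.0]),
    "lower_back_left": np.array([0.0, -150.0, -150.0]),
    "lower_back_right": np.array([0.0, 150.0, -150.0]),
}


@dataclass(frozen=True)
class Coupling:
    """One lagged linear coupling term: child speed gains ``gain`` times the
    storyteller's speed ``lag_ms`` earlier."""

    lag_ms: float
    gain: float


@dataclass(frozen=True)
class BaseMotion:
    """AR(1) parameters of the storyteller's approach-axis speed (mm/frame)."""

    sd: float = 1.0
    smoothness: float = 0.9  # AR(1) coefficient in [0, 1)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("base motion sd must be >= 0")
        if not 0 <= self.smoothness < 1:
            raise ParameterError("smoothness must lie in [0, 1)")


@dataclass(frozen=True)
class Geometry:
    """Seated facing geometry: seats on the x axis, y lateral, z vertical (mm)."""

    seat_distance_mm: float = 1200.0
    marker_jitter_sd_mm: float = 0.5
    seat_height_mm: float = 1100.0

    def __post_init__(self) -> None:
        if self.seat_distance_mm <= 0:
            raise ConfigurationError("seat distance must be positive")


@dataclass(frozen=True)
class DyadSimConfig:
    """Everything needed to generate one dyad recording.

    Defaults describe a typical session: five minutes at 120 fps, climax at
    the midpoint, torso speed ~1 mm/frame, and a weak (rho ~ 0.1) mirror-like
    coupling at 500 ms appearing only after the climax.
    """

    fps: float = 120.0
    duration_s: float = 300.0
    climax_time_s: float = 150.0
    base_motion: BaseMotion = field(default_factory=BaseMotion)
    couplings_pre: tuple[Coupling, ...] = ()
    couplings_post: tuple[Coupling, ...] = (Coupling(lag_ms=500.0, gain=0.1),)
    noise_sd: float = 1.0
    geometry: Geometry = field(default_factory=Geometry)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if not 0 < self.climax_time_s < self.duration_s:
            raise ParameterError("climax_time_s must lie strictly inside the session")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for c in (*self.couplings_pre, *self.couplings_post):
            if abs(c.lag_ms) * self.fps / 1000.0 >= self.n_frames - 1:
                raise ParameterError(f"coupling lag {c.lag_ms} ms exceeds the session")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def climax_frame(self) -> int:
        return int(np.floor(self.climax_time_s * self.fps))


def simulate_base_speed(cfg: DyadSimConfig, rng: np.random.Generator | None = None) -> SpeedSignal:
    """Storyteller approach-axis speed: stationary AR(1), reproducible from seed.

    s[t] = phi*s[t-1] + eta[t] with eta ~ N(0, sd^2*(1-phi^2)) and a stationary
    draw for s[0], so the marginal sd equals the configured sd at every t.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_frames - 1  # speeds live between consecutive frames
    phi = cfg.base_motion.smoothness
    sd = cfg.base_motion.sd
    if sd == 0:
        return SpeedSignal(np.zeros(n), cfg.fps, "storyteller")
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eta = rng.normal(0.0, innov_sd, size=n)
    s = np.empty(n)
    s[0] = rng.normal(0.0, sd)  # stationary start
    if n > 1:
        s[1:] = lfilter([1.0], [1.0, -phi], eta[1:], zi=np.array([phi * s[0]]))[0]
    return SpeedSignal(s, cfg.fps, "storyteller")


def simulate_speed_pair(
    cfg: DyadSimConfig, rng: np.random.Generator | None = None
) -> tuple[SpeedSignal, SpeedSignal]:
    """Ground-truth (storyteller, child) approach-axis speeds, pre-embedding.

    The child mixes lagged copies of the storyteller's speed (regime-specific
    gains switching at the climax frame) with independent Gaussian noise.
    Lagged samples reaching before the session start contribute zero.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    story = simulate_base_speed(cfg, rng)
    s = story.values
    n = len(s)
    child = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    t = np.arange(n)
    post = t >= cfg.climax_frame
    for regime_mask, couplings in ((~post, cfg.couplings_pre), (post, cfg.couplings_post)):
        for c in couplings:
            lag = int(round(c.lag_ms * cfg.fps / 1000.0))
            shifted = np.zeros(n)
            if lag >= 0:
                shifted[lag:] = s[: n - lag] if lag > 0 else s
            else:
                shifted[:lag] = s[-lag:]
            child = np.where(regime_mask, child + c.gain * shifted, child)
    return story, SpeedSignal(child, cfg.fps, "child")


def _integrate(speed: np.ndarray) -> np.ndarray:
    """Leaky cumulative sum: p[0] = 0, p[t] = POSITION_DRIFT*p[t-1] + v[t]."""
    n = len(speed) + 1
    p = np.empty(n)
    p[0] = 0.0
    p[1:] = lfilter([1.0], [1.0, -POSITION_DRIFT], speed)
    return p


def default_labeling_map(marker_ids: list[str] | None = None) -> dict[str, MarkerLabel]:
    """Labeling map for the simulator's marker naming scheme
    ``{child|storyteller}_{upper|lower}_back_{left|right}``."""
    entries: dict[str, tuple[str, str]] = {}
    for who in ("child", "storyteller"):
        for region in _MARKER_OFFSETS:
            entries[f"{who}_{region}"] = (who, region)
    if marker_ids is not None:
        unknown = set(marker_ids) - set(entries)
        if unknown:
            raise ConfigurationError(f"markers not in the default naming scheme: {sorted(unknown)}")
        entries = {m: entries[m] for m in marker_ids}
    return make_labeling_map(entries)


def _world_positions(cfg: DyadSimConfig, approach: np.ndarray, who: str) -> np.ndarray:
    """Embed an approach-axis position series as a 3D torso centroid path.

    The child sits at x = −d/2 facing +x, the storyteller at +d/2 facing −x;
    approaching the partner moves the child toward +x and the storyteller
    toward −x, matching the approach-positive projection downstream.
    """
    d = cfg.geometry.seat_distance_mm
    n = len(approach)
    pos = np.zeros((n, 3))
    pos[:, 2] = cfg.geometry.seat_height_mm
    if who == "child":
        pos[:, 0] = -d / 2.0 + approach
    else:
        pos[:, 0] = d / 2.0 - approach
    return pos


def simulate_dyad(
    cfg: DyadSimConfig,
    dyad_id: str = "sim",
    age_group: str = "3y",
    condition: str = "PII",
) -> tuple[LabeledRecording, DyadMetadata]:
    """Generate one labeled recording plus metadata with known ground truth."""
    rng = np.random.default_rng(cfg.seed)
    story, child = simulate_speed_pair(cfg, rng)
    paths = {
        "child": _world_positions(cfg, _integrate(child.values), "child"),
        "storyteller": _world_positions(cfg, _integrate(story.values), "storyteller"),
    }
    n = cfg.n_frames
    jitter_sd = cfg.geometry.marker_jitter_sd_mm
    trajectories: dict[str, dict[str, np.ndarray]] = {}
    for who, centroid in paths.items():
        trajectories[who] = {}
        for region, offset in _MARKER_OFFSETS.items():
            arr = centroid + offset
            if jitter_sd > 0:
                arr = arr + rng.normal(0.0, jitter_sd, size=(n, 3))
            trajectories[who][f"{who}_{region}"] = arr
    rec = LabeledRecording(trajectories, np.arange(n), cfg.fps)
    meta = DyadMetadata(dyad_id, age_group, condition, cfg.climax_time_s, cfg.fps)
    return rec, meta


def recording_to_table(rec: LabeledRecording) -> MarkerFrameTable:
    """Flatten a labeled recording into the canonical long-format marker table."""
    frames = rec.frames
    chunks = []
    for who in sorted(rec.trajectories):
        for marker_id in sorted(rec.trajectories[who]):
            arr = rec.trajectories[who][marker_id]
            chunks.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "marker": marker_id,
                        "x_mm": arr[:, 0],
                        "y_mm": arr[:, 1],
                        "z_mm": arr[:, 2],
                    }
                )
            )
    data = pd.concat(chunks, ignore_index=True).sort_values(["frame", "marker"], kind="stable")
    return MarkerFrameTable(data.reset_index(drop=True), rec.fps)


def theoretical_rho(cfg: DyadSimConfig, lag_ms: float, segment: str = "post") -> float:
    """Closed-form expected correlation at a grid lag for white-noise coupling.

    Valid only for a single coupling term and smoothness 0 (white base motion),
    where rho = g*sigma_s / sqrt(g^2*sigma_s^2 + sigma_eps^2) at the coupling
    lag and 0 elsewhere.  Smooth base motion or multiple couplings have no
    closed form here; measure by Monte-Carlo instead.
    """
    couplings = cfg.couplings_post if segment == "post" else cfg.couplings_pre
    if cfg.base_motion.smoothness != 0:
        raise ConfigurationError("closed form requires white base motion (smoothness = 0)")
    if len(couplings) > 1:
        raise ConfigurationError("closed form requires at most one coupling term")
    if not couplings:
        return 0.0
    (c,) = couplings
    if abs(c.lag_ms - lag_ms) > 1e-9:
        return 0.0
    g, sig_s, sig_e = c.gain, cfg.base_motion.sd, cfg.noise_sd
    denom = np.sqrt(g * g * sig_s * sig_s + sig_e * sig_e)
    if denom == 0:
        raise ConfigurationError("coupling and noise cannot both be zero")
    return float(g * sig_s / denom)


@dataclass(frozen=True)
class GroupSimConfig:
    """A 2x2 (age x condition) corpus of simulated dyads.

    ``cells`` maps (age_group, condition) to the number of dyads; per-cell
    config templates default to a shared template.  Dyad seeds are
    base_seed + running index, so regeneration is byte-identical.
    """

    cells: tuple[tuple[tuple[str, str], int], ...] = (
        (("3y", "PII"), 18),
        (("3y", "PAI"), 17),
        (("6y", "PII"), 21),
        (("6y", "PAI"), 19),
    )
    template: DyadSimConfig = field(default_factory=DyadSimConfig)
    cell_templates: tuple[tuple[tuple[str, str], DyadSimConfig], ...] = ()
    base_seed: int = 0

    def __post_init__(self) -> None:
        for _, n in self.cells:
            if n < 1:
                raise ConfigurationError("each cell needs at least one dyad")

    def config_for(self, cell: tuple[str, str], index: int) -> DyadSimConfig:
        template = dict(self.cell_templates).get(cell, self.template)
        return replace(template, seed=self.base_seed + index)


def simulate_group(cfg: GroupSimConfig, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write one marker CSV per dyad plus a metadata CSV, reproducibly.

    Returns (marker file paths, metadata path).  File formats are exactly the
    dialects the reader side consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker_paths: list[Path] = []
    metas: list[DyadMetadata] = []
    index = 0
    for (age, cond), n_dyads in cfg.cells:
        for k in range(n_dyads):
            dyad_id = f"d{age}{cond}{k:02d}"
            dyad_cfg = cfg.config_for((age, cond), index)
            rec, meta = simulate_dyad(dyad_cfg, dyad_id, age, cond)
            table = recording_to_table(rec)
            marker_paths.append(write_marker_table(table, out_dir / f"{dyad_id}.csv"))
            metas.append(meta)
            index += 1
    meta_path = write_metadata_table(metas, out_dir / "metadata.csv")
    return marker_paths, meta_path
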