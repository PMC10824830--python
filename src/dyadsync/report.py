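"""End-to-end analysis runs: marker tables in, curves, contrasts and figures out.

``run`` drives the whole pipeline for a corpus: per-dyad QC and preprocessing,
pre/post-climax cross-correlation curves, Fisher pooling per group, the
within-dyad climax contrast (post − pre by default; the direction is a
switch), between-group contrasts against named baseline groups, peak tables,
and a machine-readable QC log.  Outputs are plain CSV plus PNG/SVG figures;
identical inputs and config give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import preprocess, stats, synthetic, xcorr
from .errors import ConfigurationError, DyadsyncError
from .stats import AggregatedCurve, FisherCurve
from .xcorr import CrossCorrelationCurve, LagGrid


@dataclass
class AnalysisConfig:
    """Run-level configuration with the pipeline's standard analysis defaults.

    Defaults: 10 Hz cutoff, lag grid 0..1500 ms in 100 ms steps, family-wise
    alpha 0.001 with 41 Bonferroni comparisons, 0.25 s gap filling, exclusion
    above 10% missing samples, baselines 3y (age) and PII (condition).
    """

    marker_dir: str = "."
    metadata_path: str = "metadata.csv"
    out_dir: str = "out"
    labels_path: str | None = None  # CSV marker,interactant,region; default: infer
    lags_ms: tuple[int, ...] = xcorr.DEFAULT_LAGS_MS
    cutoff_hz: float = preprocess.DEFAULT_CUTOFF_HZ
    alpha: float = stats.DEFAULT_ALPHA
    n_comparisons: int = stats.DEFAULT_N_COMPARISONS
    max_gap_s: float = 0.25
    max_missing_fraction: float = 0.10
    center: bool = False
    weighted: bool = False
    contrast_direction: str = "post_minus_pre"  # or "pre_minus_post"
    age_baseline: str = "3y"
    condition_baseline: str = "PII"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.contrast_direction not in ("post_minus_pre", "pre_minus_post"):
            raise ConfigurationError(
                f"contrast_direction must be post_minus_pre or pre_minus_post,"
                f" got {self.contrast_direction!r}"
            )
        if self.age_baseline not in mio.AGE_GROUPS:
            raise ConfigurationError(f"age baseline must be one of {mio.AGE_GROUPS}")
        if self.condition_baseline not in mio.CONDITIONS:
            raise ConfigurationError(f"condition baseline must be one of {mio.CONDITIONS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "lags_ms" in raw:
            raw["lags_ms"] = tuple(int(v) for v in raw["lags_ms"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)


def _labels_for(table: mio.MarkerFrameTable, config: AnalysisConfig) -> mio.LabelingMap:
    if config.labels_path is not None:
        df = pd.read_csv(config.labels_path, dtype=str)
        return mio.make_labeling_map(
            {row["marker"]: (row["interactant"], row["region"]) for _, row in df.iterrows()}
        )
    return synthetic.default_labeling_map(table.markers)


def dyad_curves_frame(curves: Sequence[CrossCorrelationCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for lag, r, m in zip(c.lags_ms, c.r, c.m):
            rows.append(
                {"dyad_id": c.dyad_id, "segment": c.segment, "lag_ms": int(lag),
                 "r": r, "m": int(m)}
            )
    return pd.DataFrame(rows, columns=["dyad_id", "segment", "lag_ms", "r", "m"])


def aggregated_frame(curves: Sequence[AggregatedCurve]) -> pd.DataFrame:
    rows = []
    for ac in curves:
        for i, lag in enumerate(ac.lags_ms):
            rows.append(
                {
                    "label": ac.label, "lag_ms": int(lag), "R": ac.R[i],
                    "ci_low": ac.ci_low[i], "ci_high": ac.ci_high[i],
                    "X": ac.X[i], "se": ac.se[i], "m_total": ac.m_total[i],
                    "n_dyads": int(ac.n_dyads[i]),
                    "significant": bool(ac.significant[i]),
                    "morphology": ac.morphology[i],
                }
            )
    return pd.DataFrame(rows)


def peaks_frame(curves: Sequence[AggregatedCurve]) -> pd.DataFrame:
    rows = []
    for ac in curves:
        for p in stats.find_peaks(ac):
            rows.append(
                {"label": ac.label, "lag_ms": p.lag_ms, "R": p.R,
                 "morphology": p.morphology, "kind": p.kind, "is_global": p.is_global}
            )
    return pd.DataFrame(rows, columns=["label", "lag_ms", "R", "morphology", "kind", "is_global"])


@dataclass
class ResultBundle:
    """Everything one analysis run produced, in memory plus on disk."""

    dyad_curves: list[CrossCorrelationCurve]
    group_curves: dict[str, AggregatedCurve]
    contrast_curves: dict[str, AggregatedCurve]
    peaks: pd.DataFrame
    qc: pd.DataFrame
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)


def _process_dyad(
    meta: mio.DyadMetadata, config: AnalysisConfig, grid: LagGrid
) -> tuple[list[CrossCorrelationCurve], list[dict]]:
    """Read, QC and correlate one dyad; returns (curves, qc rows)."""
    path = Path(config.marker_dir) / f"{meta.dyad_id}.csv"
    qc: list[dict] = []
    table = mio.read_marker_table(path, fps=meta.fps)
    rec = mio.apply_labels(table, _labels_for(table, config))
    rec = mio.fill_gaps(rec, max_gap_s=config.max_gap_s)
    frac = rec.missing_fraction()
    if frac > config.max_missing_fraction:
        qc.append(
            {"dyad_id": meta.dyad_id, "status": "excluded", "reason": "too_many_missing",
             "detail": f"missing fraction {frac:.3f} > {config.max_missing_fraction}"}
        )
        return [], qc
    segments = {"whole": (0, rec.n_frames)}
    pre, post = xcorr.split_at_climax(rec, meta)
    segments["pre"], segments["post"] = pre, post
    curves = []
    for seg_name, frame_range in segments.items():
        signals = preprocess.speed_signals(rec, cutoff_hz=config.cutoff_hz, frame_range=frame_range)
        if any(np.isnan(sig.values).any() for sig in signals.values()):
            qc.append(
                {"dyad_id": meta.dyad_id, "status": "excluded", "reason": "unfilled_gaps",
                 "detail": f"NaN speed samples in segment {seg_name}"}
            )
            return [], qc
        curves.append(
            xcorr.curve(signals["storyteller"], signals["child"], grid,
                        dyad_id=meta.dyad_id, segment=seg_name, center=config.center)
        )
    qc.append({"dyad_id": meta.dyad_id, "status": "included", "reason": "", "detail": ""})
    return curves, qc


def run(config: AnalysisConfig) -> ResultBundle:
    """Execute the full pipeline for a corpus and write the result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metas = mio.read_metadata_table(config.metadata_path)
    if not metas:
        raise ConfigurationError("metadata table lists no dyads")
    grid = LagGrid(config.lags_ms, metas[0].fps)
    log_lines: list[str] = [f"dyads listed: {len(metas)}"]

    dyad_curves: list[CrossCorrelationCurve] = []
    qc_rows: list[dict] = []
    meta_by_id: dict[str, mio.DyadMetadata] = {}
    for meta in metas:
        try:
            curves, qc = _process_dyad(meta, config, grid)
        except DyadsyncError as exc:
            qc = [{"dyad_id": meta.dyad_id, "status": "excluded",
                   "reason": type(exc).__name__, "detail": str(exc)}]
            curves = []
        qc_rows.extend(qc)
        dyad_curves.extend(curves)
        if curves:
            meta_by_id[meta.dyad_id] = meta
    usable = sorted(meta_by_id)
    log_lines.append(f"dyads usable: {len(usable)}")
    if not usable:
        raise ConfigurationError(
            "zero usable dyads; exclusions: "
            + "; ".join(f"{q['dyad_id']}({q['reason']})" for q in qc_rows)
        )

    by_seg: dict[str, dict[str, CrossCorrelationCurve]] = {}
    for c in dyad_curves:
        by_seg.setdefault(c.segment, {})[c.dyad_id] = c

    def pooled(ids: list[str], segment: str, label: str) -> FisherCurve:
        return stats.pool([by_seg[segment][d] for d in ids], label=label,
                          weighted=config.weighted)

    def climax_contrast(ids: list[str], label: str) -> FisherCurve:
        post_fc = pooled(ids, "post", f"{label} post")
        pre_fc = pooled(ids, "pre", f"{label} pre")
        if config.contrast_direction == "post_minus_pre":
            return stats.subtract(post_fc, pre_fc, label=label)
        return stats.subtract(pre_fc, post_fc, label=label)

    def banded(fc: FisherCurve) -> AggregatedCurve:
        return stats.band(fc, alpha=config.alpha, n_comparisons=config.n_comparisons)

    groups: dict[tuple[str, str], list[str]] = {}
    for d in usable:
        m = meta_by_id[d]
        groups.setdefault((m.age_group, m.condition), []).append(d)

    group_curves: dict[str, AggregatedCurve] = {}
    contrast_curves: dict[str, AggregatedCurve] = {}
    for (age, cond), ids in sorted(groups.items()):
        name = f"{age} {cond}"
        group_curves[name] = banded(pooled(ids, "whole", name))
        contrast_curves[name] = banded(climax_contrast(ids, name))
        log_lines.append(f"group {name}: {len(ids)} dyads")

    # Between-group contrasts on the climax-contrast curves, pooled over the
    # other factor, against the configured baseline groups.
    by_age = {a: [d for d in usable if meta_by_id[d].age_group == a] for a in mio.AGE_GROUPS}
    by_cond = {c: [d for d in usable if meta_by_id[d].condition == c] for c in mio.CONDITIONS}
    if all(by_age.values()):
        other = next(a for a in mio.AGE_GROUPS if a != config.age_baseline)
        contrast_curves[f"age {other} - {config.age_baseline}"] = banded(
            stats.subtract(
                climax_contrast(by_age[other], other),
                climax_contrast(by_age[config.age_baseline], config.age_baseline),
                label=f"age {other} - {config.age_baseline}",
            )
        )
    if all(by_cond.values()):
        other = next(c for c in mio.CONDITIONS if c != config.condition_baseline)
        contrast_curves[f"condition {other} - {config.condition_baseline}"] = banded(
            stats.subtract(
                climax_contrast(by_cond[other], other),
                climax_contrast(by_cond[config.condition_baseline], config.condition_baseline),
                label=f"condition {other} - {config.condition_baseline}",
            )
        )

    all_agg = list(group_curves.values()) + list(contrast_curves.values())
    peaks = peaks_frame(all_agg)
    qc = pd.DataFrame(qc_rows, columns=["dyad_id", "status", "reason", "detail"])

    files: dict[str, Path] = {}
    files["per_dyad_curves"] = out_dir / "per_dyad_curves.csv"
    dyad_curves_frame(dyad_curves).to_csv(files["per_dyad_curves"], index=False)
    files["aggregated_curves"] = out_dir / "aggregated_curves.csv"
    aggregated_frame(list(group_curves.values())).to_csv(files["aggregated_curves"], index=False)
    files["contrast_curves"] = out_dir / "contrast_curves.csv"
    aggregated_frame(list(contrast_curves.values())).to_csv(files["contrast_curves"], index=False)
    files["peaks"] = out_dir / "peaks.csv"
    peaks.to_csv(files["peaks"], index=False)
    files["qc_log"] = out_dir / "qc_log.csv"
    qc.to_csv(files["qc_log"], index=False)
    files["log"] = out_dir / "run.log"
    files["log"].write_text("\n".join(log_lines) + "\n")

    if config.make_plots:
        _, paths = plot(list(group_curves.values()), out_dir / "group_curves")
        files["group_figure"] = paths[0]
        _, paths = plot(list(contrast_curves.values()), out_dir / "contrast_curves")
        files["contrast_figure"] = paths[0]
    return ResultBundle(dyad_curves, group_curves, contrast_curves, peaks, qc, out_dir, files)


def plot(
    curves: Sequence[AggregatedCurve], path_base: str | Path, annotate: bool = True
) -> tuple[plt.Figure, list[Path]]:
    """Aggregated-curve panels: solid R line, translucent CI band, zero line.

    The upper half of each panel is symmetric (mirror-like) coordination, the
    lower half asymmetric.  Writes both PNG and SVG next to ``path_base``.
    """
    if not curves:
        raise ConfigurationError("no curves to plot")
    grid0 = tuple(curves[0].grid.lags_ms)
    for c in curves[1:]:
        if tuple(c.grid.lags_ms) != grid0:
            raise ConfigurationError("curves do not share a lag grid")
    n = len(curves)
    ncols = min(n, 2)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(6 * ncols, 3.2 * nrows),
                             squeeze=False, sharex=True, sharey=True)
    for ax, ac in zip(axes.ravel(), curves):
        lags = ac.lags_ms
        ax.axhline(0.0, color="0.4", lw=0.8)
        ax.fill_between(lags, ac.ci_low, ac.ci_high, alpha=0.25, label="confidence band")
        ax.plot(lags, ac.R, lw=1.5, label=ac.label or "R")
        ax.set_title(ac.label)
        ax.set_xlabel("delay (ms)")
        ax.set_ylabel("cross-correlation R")
        if annotate:
            ax.annotate("symmetric", xy=(0.98, 0.95), xycoords="axes fraction",
                        ha="right", va="top", fontsize=8, color="0.3")
            ax.annotate("asymmetric", xy=(0.98, 0.05), xycoords="axes fraction",
                        ha="right", va="bottom", fontsize=8, color="0.3")
        ax.legend(fontsize=7, loc="lower left")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    path_base = Path(path_base)
    paths = [path_base.with_suffix(".png"), path_base.with_suffix(".svg")]
    for p in paths:
        fig.savefig(p, dpi=120)
    return fig, paths
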