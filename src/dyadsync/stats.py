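"""Pooling correlation curves across dyads in Fisher z space.

Per-dyad correlations rᵢ at a given lag are mapped through the Fisher
transform x = atanh(r), which is approximately normal with standard error
1/sqrt(m) for m sample pairs.  The group curve is the unweighted mean X of the
xᵢ; because the dyads' pair counts are similar, the standard error of the mean
collapses to 1/sqrt(sum(mᵢ)) — the se of a single correlation computed on the
concatenated length.  X maps back to the Pearson scale via R = tanh(X).
Confidence bands use a two-sided normal quantile at a Bonferroni-corrected
level, transformed endpoint-wise back through tanh.

Contrasts (pre/post-climax within a group, group vs. baseline group) are plain
differences of Fisher curves, with standard errors added in quadrature; the
result reads as a *comparative* level of coordination, not an absolute one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import AlignmentError, ConfigurationError, ParameterError
from .xcorr import CrossCorrelationCurve, LagGrid

#: Family-wise level and comparison count used throughout the analysis.
DEFAULT_ALPHA = 0.001
DEFAULT_N_COMPARISONS = 41

#: |r| is clamped to 1 - _R_CLAMP before the Fisher transform so that curves
#: from tiny, perfectly-coupled synthetic segments never pool to infinity.
_R_CLAMP = 1e-12

MORPHOLOGIES = ("symmetric", "asymmetric", "none")


def fisher(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform x = atanh(r) = 0.5*ln((1+r)/(1-r)); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| >= 1 has no finite Fisher transform; clamp first")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_inv(x: float | np.ndarray) -> float | np.ndarray:
    """Inverse Fisher transform R = tanh(X)."""
    out = np.tanh(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def clamp_correlation(r: np.ndarray) -> np.ndarray:
    """Pull values at exactly ±1 just inside the open interval, with a warning."""
    r = np.asarray(r, dtype=float)
    at_limit = np.abs(r) >= 1.0
    if np.any(at_limit & ~np.isnan(r)):
        warnings.warn(
            "correlation(s) at ±1 clamped before Fisher transform", RuntimeWarning, stacklevel=2
        )
        r = np.clip(r, -1.0 + _R_CLAMP, 1.0 - _R_CLAMP)
    return r


@dataclass
class FisherCurve:
    """Per-lag pooled Fisher mean X with its standard error.

    ``m_total`` sums the contributing dyads' pair counts at each lag and
    ``n_dyads`` counts dyads with a defined correlation there.
    """

    grid: LagGrid
    X: np.ndarray
    se: np.ndarray
    m_total: np.ndarray
    n_dyads: np.ndarray
    label: str = ""

    @property
    def lags_ms(self) -> np.ndarray:
        return np.asarray(self.grid.lags_ms)


def pool(
    curves: Sequence[CrossCorrelationCurve], label: str = "", weighted: bool = False
) -> FisherCurve:
    """Average per-dyad correlation curves in Fisher space.

    Per lag: X is the unweighted mean of atanh(rᵢ) over dyads with a defined
    correlation, and se = 1/sqrt(sum mᵢ) over those dyads.  ``weighted=True``
    switches to the inverse-variance (mᵢ-weighted) mean for sensitivity
    analysis; the se formula is the same in both cases.
    """
    if not curves:
        raise ConfigurationError("cannot pool zero curves")
    grid = curves[0].grid
    for c in curves[1:]:
        if tuple(c.grid.lags_ms) != tuple(grid.lags_ms) or c.grid.fps != grid.fps:
            raise AlignmentError("curves do not share a lag grid")
    R = np.stack([clamp_correlation(c.r) for c in curves])  # (n_dyads, n_lags)
    M = np.stack([c.m for c in curves]).astype(float)
    defined = ~np.isnan(R)
    with np.errstate(invalid="ignore"):
        Xi = np.arctanh(np.where(defined, R, 0.0))
    if weighted:
        w = np.where(defined, M, 0.0)
    else:
        w = defined.astype(float)
    wsum = w.sum(axis=0)
    n_dyads = defined.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(wsum > 0, (w * Xi).sum(axis=0) / np.where(wsum > 0, wsum, 1.0), np.nan)
        m_total = np.where(defined, M, 0.0).sum(axis=0)
        se = np.where(m_total > 0, 1.0 / np.sqrt(np.where(m_total > 0, m_total, 1.0)), np.nan)
    X = np.where(n_dyads > 0, X, np.nan)
    return FisherCurve(grid, X, se, m_total, n_dyads.astype(int), label=label)


def subtract(minuend: FisherCurve, subtrahend: FisherCurve, label: str = "") -> FisherCurve:
    """Fisher-space contrast: X difference with standard errors in quadrature."""
    if tuple(minuend.grid.lags_ms) != tuple(subtrahend.grid.lags_ms):
        raise AlignmentError("curves do not share a lag grid")
    X = minuend.X - subtrahend.X
    se = np.sqrt(minuend.se**2 + subtrahend.se**2)
    m_total = minuend.m_total + subtrahend.m_total
    n_dyads = minuend.n_dyads + subtrahend.n_dyads
    if not label:
        label = f"{minuend.label} - {subtrahend.label}".strip(" -")
    return FisherCurve(minuend.grid, X, se, m_total, n_dyads, label=label)


@dataclass
class AggregatedCurve:
    """Back-transformed group curve with family-wise-corrected confidence bands.

    Per lag: R = tanh(X) with CI [tanh(X − z*·se), tanh(X + z*·se)];
    ``significant`` flags lags whose interval excludes zero, and ``morphology``
    reads the sign: symmetric (mirror-like, ci_low > 0), asymmetric
    (ci_high < 0), or none.
    """

    grid: LagGrid
    R: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    X: np.ndarray
    se: np.ndarray
    m_total: np.ndarray
    n_dyads: np.ndarray
    significant: np.ndarray  # bool
    morphology: np.ndarray  # str
    label: str = ""
    alpha: float = DEFAULT_ALPHA
    n_comparisons: int = DEFAULT_N_COMPARISONS

    @property
    def lags_ms(self) -> np.ndarray:
        return np.asarray(self.grid.lags_ms)


def band(
    fc: FisherCurve,
    alpha: float = DEFAULT_ALPHA,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
) -> AggregatedCurve:
    """Attach Bonferroni-corrected z confidence bands and back-transform.

    The corrected level is p_c = alpha / n_comparisons and z* the two-sided
    standard-normal quantile at 1 − p_c/2.  ``n_comparisons`` is an explicit
    parameter (default 41), never derived from the grid length.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    defined = ~np.isnan(fc.X)
    if np.any(defined & ~(fc.se > 0)):
        raise ParameterError("standard error must be positive wherever X is defined")
    p_c = alpha / n_comparisons
    z_star = float(norm.ppf(1.0 - p_c / 2.0))
    lo = np.tanh(fc.X - z_star * fc.se)
    hi = np.tanh(fc.X + z_star * fc.se)
    R = np.tanh(fc.X)
    significant = defined & ((lo > 0) | (hi < 0))
    morphology = np.full(len(R), "none", dtype=object)
    morphology[defined & (lo > 0)] = "symmetric"
    morphology[defined & (hi < 0)] = "asymmetric"
    return AggregatedCurve(
        fc.grid, R, lo, hi, fc.X.copy(), fc.se.copy(), fc.m_total.copy(),
        fc.n_dyads.copy(), significant, morphology, label=fc.label,
        alpha=alpha, n_comparisons=n_comparisons,
    )


@dataclass(frozen=True)
class Peak:
    """A local extremum of an aggregated curve."""

    lag_ms: int
    R: float
    morphology: str  # by sign of R
    kind: str  # "max" or "min"
    is_global: bool


def find_peaks(ac: AggregatedCurve) -> list[Peak]:
    """Local extrema of R over the lag grid, each labeled by sign.

    Endpoints count (a monotone curve peaks at its boundary); plateaus report
    their first lag.  The global maximum and minimum are marked.
    """
    R = ac.R
    lags = ac.lags_ms
    n = len(R)
    if n == 0:
        return []
    finite = np.isfinite(R)
    peaks: list[Peak] = []

    def morph(v: float) -> str:
        return "symmetric" if v > 0 else "asymmetric" if v < 0 else "none"

    gmax = int(np.nanargmax(R)) if finite.any() else -1
    gmin = int(np.nanargmin(R)) if finite.any() else -1
    for i in range(n):
        if not finite[i]:
            continue
        left = R[i - 1] if i > 0 and finite[i - 1] else None
        right = R[i + 1] if i < n - 1 and finite[i + 1] else None
        is_max = (left is None or R[i] > left) and (right is None or R[i] >= right)
        is_min = (left is None or R[i] < left) and (right is None or R[i] <= right)
        if n == 1:
            is_max, is_min = True, False
        for cond, kind, g in ((is_max, "max", gmax), (is_min, "min", gmin)):
            if cond:
                peaks.append(Peak(int(lags[i]), float(R[i]), morph(R[i]), kind, i == g))
    return peaks
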