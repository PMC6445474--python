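"""Geostatistical aggregation curves, thresholding, and persistence maps.

Ranking occupied units (hauls or grid cells) by density from maximum to
minimum and accumulating abundance against area yields a curve from (0,0)
to (1,1) lying above the diagonal.  The tangent of slope 1 separates
aggregated space use (density above the tangent density z*) from dispersed
use.  For equal-area units the slope of the k-th segment is the k-th
density over the mean occupied density, so the slope-1 threshold density
equals the mean occupied density exactly - the module's primary oracle.
Classified yearly maps are summed into persistence grids, and a precision
metric reports the share of cells away from a +-0.025 cumulative-abundance
band around the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import GridLayer


@dataclass
class AggregationCurve:
    """Cumulative abundance vs area curve over density-ranked units."""

    x: np.ndarray                 # cumulative proportion of area, with leading 0
    y: np.ndarray                 # cumulative proportion of abundance
    densities: np.ndarray         # densities in ranked (descending) order
    areas: np.ndarray             # areas in ranked order
    source: str = "grid"

    @property
    def n_units(self) -> int:
        return len(self.densities)

    def mean_density(self) -> float:
        return float(np.sum(self.densities * self.areas) / np.sum(self.areas))


@dataclass
class TangentResult:
    """Slope-1 tangent threshold on an aggregation curve."""

    x_star: float
    y_star: float
    z_star: float                 # threshold density
    mode: str                     # "cubic" | "empirical"
    degenerate: bool = False
    cubic_coef: np.ndarray | None = None
    window: tuple[int, int] | None = None


def build_curve(densities, areas=None, source: str = "grid") -> AggregationCurve:
    """Rank occupied units by density (descending, stable) and accumulate.

    Zero-density units are excluded ("occupied area" is the positive
    support); all-zero input is fatal.
    """
    d_raw = np.asarray(densities, dtype=float).ravel()
    finite = np.isfinite(d_raw)
    d = d_raw[finite]
    if areas is None:
        a = np.ones_like(d)
    else:
        a = np.asarray(areas, dtype=float).ravel()[finite]
    occ = d > 0
    d, a = d[occ], a[occ]
    if len(d) < 1 or d.sum() <= 0:
        raise ValueError("no positive densities: aggregation curve undefined")
    order = np.argsort(-d, kind="stable")
    d, a = d[order], a[order]
    x = np.concatenate([[0.0], np.cumsum(a) / a.sum()])
    y = np.concatenate([[0.0], np.cumsum(d * a) / np.sum(d * a)])
    return AggregationCurve(x, y, d, a, source)


def fit_transition_cubic(curve: AggregationCurve,
                         slope_window: tuple[float, float] = (0.5, 2.0)):
    """Least-squares cubic on the transition phase of the curve.

    The transition phase is the run of points whose local central-
    difference slope lies in ``slope_window`` (bracketing slope 1); if
    fewer than 4 points qualify the window widens symmetrically.  Returns
    ``(coefficients, (i0, i1))`` with coefficients in ``np.polyfit`` order
    (a, b, c, d), or ``(None, None)`` when degenerate.
    """
    x, y = curve.x, curve.y
    if len(x) < 4:
        return None, None
    slopes = np.gradient(y, x, edge_order=1)
    inside = (slopes >= slope_window[0]) & (slopes <= slope_window[1])
    if inside.any():
        idx = np.where(inside)[0]
        i0, i1 = int(idx[0]), int(idx[-1])
    else:
        anchor = int(np.argmin(np.abs(slopes - 1.0)))
        i0 = i1 = anchor
    while (i1 - i0 + 1) < 4 and (i0 > 0 or i1 < len(x) - 1):
        i0 = max(i0 - 1, 0)
        i1 = min(i1 + 1, len(x) - 1)
    if i1 - i0 + 1 < 4 or np.ptp(x[i0:i1 + 1]) <= 0:
        return None, None
    coef = np.polyfit(x[i0:i1 + 1], y[i0:i1 + 1], 3)
    return coef, (i0, i1)


def _density_at_area(curve: AggregationCurve, x_star: float) -> float:
    """Density of the ranked unit at cumulative-area position x_star.

    Interpolates the ranked density profile against the upper edge of each
    unit's area share, so tied densities never split between classes.
    """
    edges = np.cumsum(curve.areas) / curve.areas.sum()
    return float(np.interp(x_star, edges, curve.densities,
                           left=curve.densities[0], right=curve.densities[-1]))


def tangent_threshold(curve: AggregationCurve,
                      mode: str = "cubic") -> TangentResult:
    """Slope-1 tangent point and the corresponding threshold density z*.

    ``mode="cubic"`` fits a cubic to the transition phase and solves
    3a x^2 + 2b x + c = 1 on the concave branch; ``mode="empirical"``
    uses the exact piecewise identity (for the ranked curve the slope-1
    density equals the abundance-per-area mean of occupied units).
    Uniform densities are degenerate: every unit sits on the diagonal and
    all cells classify as dispersed.
    """
    d = curve.densities
    mean_density = curve.mean_density()
    if np.ptp(d) <= 1e-12 * max(abs(d.max()), 1e-300):
        warnings.warn("uniform densities: degenerate curve, "
                      "all cells classified dispersed")
        return TangentResult(1.0, 1.0, float(d.max()), mode, degenerate=True)

    if mode == "empirical":
        z = mean_density
        agg = d > z
        share_area = float(curve.areas[agg].sum() / curve.areas.sum())
        share_ab = float((d[agg] * curve.areas[agg]).sum()
                         / (d * curve.areas).sum())
        return TangentResult(share_area, share_ab, z, "empirical")

    if mode != "cubic":
        raise ValueError(mode)
    coef, window = fit_transition_cubic(curve)
    if coef is not None:
        a, b, c, _ = coef
        disc = (2 * b) ** 2 - 4 * (3 * a) * (c - 1.0)
        roots = []
        if abs(a) > 1e-12 and disc >= 0:
            r = np.sqrt(disc)
            roots = [(-2 * b - r) / (6 * a), (-2 * b + r) / (6 * a)]
        elif abs(b) > 1e-12:
            roots = [(1.0 - c) / (2 * b)]
        # keep roots in [0,1] on the concave branch (second derivative <= 0)
        good = [x for x in roots
                if 0.0 <= x <= 1.0 and (6 * a * x + 2 * b) <= 1e-9]
        if good:
            x_star = float(min(good))
            y_star = float(np.polyval(coef, x_star))
            z_star = _density_at_area(curve, x_star)
            return TangentResult(x_star, y_star, z_star, "cubic",
                                 cubic_coef=np.asarray(coef), window=window)
    # fallback: first point where the empirical segment slope drops below 1
    slopes = d / mean_density
    below = np.where(slopes < 1.0)[0]
    if len(below) == 0:
        warnings.warn("no slope-1 crossing; degenerate classification")
        return TangentResult(1.0, 1.0, float(d.max()), "cubic", degenerate=True)
    k = int(below[0])
    edges = np.cumsum(curve.areas) / curve.areas.sum()
    x_star = float(edges[k - 1]) if k > 0 else 0.0
    y_idx = k  # curve arrays carry the leading (0,0) point
    y_star = float(curve.y[y_idx])
    z_star = float(d[k - 1]) if k > 0 else float(d[0])
    warnings.warn("cubic tangent fit degenerate; empirical crossing used")
    return TangentResult(x_star, y_star, z_star, "cubic-fallback")


def classify_cells(density: GridLayer, z_star: float) -> GridLayer:
    """Binary aggregated(1)/dispersed(0) map over occupied cells.

    Cells with density > z* are aggregated; unoccupied (zero or nodata)
    cells carry nodata.
    """
    if not np.isfinite(z_star):
        raise ValueError("threshold must be finite")
    vals = density.values
    out = np.full(vals.shape, np.nan)
    occ = np.isfinite(vals) & (vals > 0)
    out[occ] = (vals[occ] > z_star).astype(float)
    return density.like(out, f"{density.name}_classified")


def persistence(classified: list[GridLayer]) -> GridLayer:
    """Cellwise sum of yearly aggregation maps (nodata if nodata all years)."""
    if not classified:
        raise ValueError("need at least one classified grid")
    shape = classified[0].shape
    for g in classified:
        if g.shape != shape:
            raise ValueError("classified grids are not co-registered")
    stack = np.stack([g.values for g in classified])
    any_data = np.isfinite(stack).any(axis=0)
    total = np.nansum(np.where(np.isfinite(stack), stack, 0.0), axis=0)
    out = np.where(any_data, total, np.nan)
    return classified[0].like(out, "persistence")


def classification_precision(curve: AggregationCurve, tangent: TangentResult,
                             band: float = 0.025) -> float:
    """Percent of occupied cells outside a +-band window around the
    classification threshold under the ranked density distribution.

    Each occupied cell sits at a cumulative quantile of the density
    distribution (its cumulative-area position on the curve); cells whose
    quantile is within ``band`` of the threshold position x* are the ones
    whose classification a small threshold shift could flip, and the
    statistic is the percentage of cells outside that uncertainty band.
    At the tangent point the curve has slope 1, so an abundance-share band
    of the same width coincides to first order.
    """
    q = curve.x[1:]                       # per-unit cumulative area quantile
    outside = np.abs(q - tangent.x_star) > band
    return float(100.0 * outside.sum() / len(q))
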