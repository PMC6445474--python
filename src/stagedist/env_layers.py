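"""Environmental covariate layers.

Builds the model covariate stack from a bathymetry grid, a land mask, a raw
sediment classification and CTD point casts: Horn slope/aspect, distance to
shore, sediment reclassification to the five merged habitat classes,
near-bottom CTD selection, and Nadaraya-Watson Gaussian-kernel smoothing of
temperature/salinity with leave-one-out bandwidth selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import GridLayer, KM_PER_DEG_LAT, SEDIMENT_CLASSES

#: integer codes used in sediment layers, aligned with SEDIMENT_CLASSES
SEDIMENT_CODES = {name: i for i, name in enumerate(SEDIMENT_CLASSES)}
ROCK_CODE = SEDIMENT_CODES["rock"]

#: default merge of a 17-code raw substrate classification into the five
#: analysis classes (raw codes 0..16; assignment mirrors a grain-size merge)
DEFAULT_SEDIMENT_MERGE = {
    0: 0, 1: 0, 2: 0, 3: 0,            # muds -> mud_sandy_mud
    4: 1, 5: 1, 6: 1, 7: 1,            # sands -> sand_muddy_sand
    8: 2, 9: 2, 10: 2,                 # gravels -> coarse
    11: 3, 12: 3, 13: 3,               # heterogeneous -> mixed
    14: 4, 15: 4, 16: 4,               # bedrock/boulders -> rock
}


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------

def compute_slope_aspect(depth: GridLayer) -> tuple[GridLayer, GridLayer]:
    """Horn 3x3 slope (radians) and downslope aspect (degrees from North).

    ``depth`` is positive downwards; the seabed elevation is ``-depth``.
    Aspect is the compass direction faced by the slope (the downslope
    direction), 0 = North, increasing clockwise; flat cells get aspect 0.
    Cells whose full 3x3 neighbourhood is nodata give nodata.
    """
    z = -np.asarray(depth.values, dtype=float)
    valid = np.isfinite(z)
    zf = np.where(valid, z, 0.0)
    # replicate-pad so border cells use one-sided differences
    zp = np.pad(zf, 1, mode="edge")
    vp = np.pad(valid.astype(float), 1, mode="edge")

    kx, ky = depth.cell_km()
    dx_m, dy_m = kx * 1000.0, ky * 1000.0

    def sh(dr, dc):
        return zp[1 + dr:zp.shape[0] - 1 + dr, 1 + dc:zp.shape[1] - 1 + dc]

    # Horn weights: gradient east (gx) and north (gy); row index increases
    # southwards so "north" is row - 1.
    gx = ((sh(-1, 1) + 2 * sh(0, 1) + sh(1, 1))
          - (sh(-1, -1) + 2 * sh(0, -1) + sh(1, -1))) / (8 * dx_m)
    gy = ((sh(-1, -1) + 2 * sh(-1, 0) + sh(-1, 1))
          - (sh(1, -1) + 2 * sh(1, 0) + sh(1, 1))) / (8 * dy_m)

    grad = np.hypot(gx, gy)
    slope = np.arctan(grad)
    # downslope vector = -grad(z); compass angle of (east, north) components
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.where(grad == 0, 0.0, aspect)

    slope = np.where(valid, slope, np.nan)
    aspect = np.where(valid, aspect, np.nan)
    return depth.like(slope, "slope"), depth.like(aspect, "aspect")


# ---------------------------------------------------------------------------
# Distance to shore
# ---------------------------------------------------------------------------

def distance_to_shore(land: GridLayer, method: str = "planar") -> GridLayer:
    """Distance (m) from each sea-cell centre to the coastline.

    Convention: distance to the nearest land-cell centre minus half the
    east-west cell width (so a sea cell adjacent to land is half a cell
    away), floored at zero.  ``method`` is "planar" (Euclidean in km via a
    distance transform) or "haversine" (brute force great-circle).
    """
    mask = np.asarray(land.values, dtype=float) > 0.5
    kx, ky = land.cell_km()
    if not mask.any():
        warnings.warn("no land cells: all shore distances infinite")
        out = np.full(land.shape, np.inf)
        out[mask] = np.nan
        return land.like(out, "prox_shore")
    if method == "planar":
        dist_km = ndimage.distance_transform_edt(~mask, sampling=(ky, kx))
    elif method == "haversine":
        lons = land.lon_centers()
        lats = land.lat_centers()
        glon, glat = np.meshgrid(lons, lats)
        land_pts = np.column_stack([glon[mask], glat[mask]])
        dist_km = np.zeros(land.shape)
        sea_idx = np.argwhere(~mask)
        for r, c in sea_idx:
            dist_km[r, c] = haversine_km(glon[r, c], glat[r, c],
                                         land_pts[:, 0], land_pts[:, 1]).min()
    else:
        raise ValueError(method)
    out = np.maximum(dist_km - 0.5 * kx, 0.0) * 1000.0
    out[mask] = np.nan
    return land.like(out, "prox_shore")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2 * 6371.0 * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# Sediment
# ---------------------------------------------------------------------------

def reclassify_sediment(raw: GridLayer,
                        mapping: dict[int, int] | None = None) -> GridLayer:
    """Merge raw substrate codes into the five analysis classes.

    Rock cells survive the merge (code 4) but are masked out of modelling
    layers downstream.  Unmapped codes are fatal and listed.
    """
    mapping = DEFAULT_SEDIMENT_MERGE if mapping is None else mapping
    vals = np.asarray(raw.values, dtype=float)
    finite = np.isfinite(vals)
    codes = np.unique(vals[finite]).astype(int)
    unmapped = sorted(int(c) for c in set(codes) - set(mapping))
    if unmapped:
        raise ValueError(f"unmapped sediment codes: {unmapped}")
    out = np.full(raw.shape, np.nan)
    for code in codes:
        out[finite & (vals == code)] = mapping[int(code)]
    if finite.any() and np.all(out[finite] == ROCK_CODE):
        warnings.warn("sediment layer is all Rock: empty modelling domain")
    return raw.like(out, "sediment")


# ---------------------------------------------------------------------------
# CTD casts and kernel smoothing
# ---------------------------------------------------------------------------

CTD_COLUMNS = ["station_id", "lon", "lat", "year", "season", "pressure",
               "temperature", "salinity"]


def select_bottom_ctd(casts: pd.DataFrame) -> pd.DataFrame:
    """Keep, per station x year x season, the record of maximum pressure.

    Ties are broken by the last occurrence (flagged via a warning).
    """
    df = casts.reset_index(drop=True)
    keys = ["station_id", "year", "season"]
    gmax = df.groupby(keys)["pressure"].transform("max")
    at_max = df[df["pressure"] == gmax]
    n_ties = int((at_max.groupby(keys).size() > 1).sum())
    if n_ties:
        warnings.warn(f"{n_ties} station(s) with tied bottom pressure; "
                      "keeping last occurrence")
    return (at_max.groupby(keys, as_index=False).last()
            [CTD_COLUMNS if set(CTD_COLUMNS) <= set(df.columns)
             else at_max.columns.tolist()])


@dataclass
class KernelFit:
    """LOOCV bandwidth-selection result for the Gaussian kernel smoother."""

    theta_km: float
    score: float                      # LOOCV sum of squared errors at theta
    grid: np.ndarray = field(default_factory=lambda: np.array([]))
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    degenerate: bool = False


def _weights(dist_km: np.ndarray, theta: float) -> np.ndarray:
    return np.exp(-dist_km ** 2 / (2.0 * theta ** 2))


def kernel_smooth(casts: pd.DataFrame, template: GridLayer, theta_km: float,
                  value_col: str = "temperature") -> GridLayer:
    """Nadaraya-Watson surface of ``value_col`` on the template grid.

    Weight of cast i at cell x is exp(-d(x, x_i)^2 / (2 theta^2)), d the
    great-circle distance in km.  Cells where all weights underflow take the
    nearest cast's value (flagged).
    """
    if theta_km <= 0:
        raise ValueError("theta must be positive")
    y = casts[value_col].to_numpy(dtype=float)
    lons = template.lon_centers()
    lats = template.lat_centers()
    glon, glat = np.meshgrid(lons, lats)
    pts = np.column_stack([glon.ravel(), glat.ravel()])
    d = haversine_km(pts[:, None, 0], pts[:, None, 1],
                     casts["lon"].to_numpy()[None, :],
                     casts["lat"].to_numpy()[None, :])
    w = _weights(d, theta_km)
    sw = w.sum(axis=1)
    out = np.full(pts.shape[0], np.nan)
    good = sw > 1e-300
    out[good] = w[good] @ y / sw[good]
    if not good.all():
        warnings.warn(f"{(~good).sum()} cell(s) underflowed; "
                      "substituted nearest cast value")
        nearest = d[~good].argmin(axis=1)
        out[~good] = y[nearest]
    return template.like(out.reshape(template.shape), f"{value_col}_smooth")


def loocv_scores(casts: pd.DataFrame, theta_grid, value_col: str = "temperature"
                 ) -> np.ndarray:
    """Exact LOOCV sum of squared errors for each candidate bandwidth."""
    y = casts[value_col].to_numpy(dtype=float)
    lon = casts["lon"].to_numpy(dtype=float)
    lat = casts["lat"].to_numpy(dtype=float)
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    scores = np.empty(len(theta_grid))
    for k, theta in enumerate(theta_grid):
        w = _weights(d, float(theta))
        np.fill_diagonal(w, 0.0)
        sw = w.sum(axis=1)
        with np.errstate(invalid="ignore"):
            pred = w @ y / sw
        # isolated casts (all weights underflow) fall back to nearest cast
        bad = sw <= 1e-300
        if bad.any():
            d2 = d.copy()
            np.fill_diagonal(d2, np.inf)
            pred[bad] = y[d2[bad].argmin(axis=1)]
        scores[k] = np.sum((y - pred) ** 2)
    return scores


def select_bandwidth_loocv(casts: pd.DataFrame, theta_grid,
                           value_col: str = "temperature") -> KernelFit:
    """Bandwidth minimising the exact LOOCV least-squares score.

    Ties go to the smaller bandwidth.  If all casts are co-located the
    score curve is flat and the mid-grid bandwidth is returned, flagged.
    """
    if len(casts) < 3:
        raise ValueError("need at least 3 casts for LOOCV")
    theta_grid = np.asarray(sorted(theta_grid), dtype=float)
    lon = casts["lon"].to_numpy(dtype=float)
    lat = casts["lat"].to_numpy(dtype=float)
    if np.ptp(lon) == 0 and np.ptp(lat) == 0:
        warnings.warn("all casts co-located; returning mid-grid bandwidth")
        mid = float(theta_grid[len(theta_grid) // 2])
        return KernelFit(mid, np.nan, theta_grid,
                         np.full(len(theta_grid), np.nan), degenerate=True)
    scores = loocv_scores(casts, theta_grid, value_col)
    best = int(np.argmin(scores))   # argmin takes the first (smallest) theta
    return KernelFit(float(theta_grid[best]), float(scores[best]),
                     theta_grid, scores)


# ---------------------------------------------------------------------------
# Covariate extraction at hauls
# ---------------------------------------------------------------------------

def extract_at_hauls(env, hauls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nearest-cell covariate lookup for each haul.

    Returns ``(table, excluded)``: the covariate table for modellable hauls
    (depth, slope, aspect, prox_shore, sediment, year-matched temperature,
    salinity, longitude) and the excluded hauls with reasons (off grid, on
    land/nodata, on Rock).
    """
    template = env.layers["depth"]
    row, col = template.cell_index(hauls["lon"].to_numpy(),
                                   hauls["lat"].to_numpy())
    n = len(hauls)
    inside = (row >= 0) & (row < template.nrows) & (col >= 0) & (col < template.ncols)
    rows = []
    reasons = np.array([""] * n, dtype=object)
    reasons[~inside] = "off grid"
    rs, cs = np.where(inside, row, 0), np.where(inside, col, 0)
    depth = template.values[rs, cs]
    sediment = env.layers["sediment"].values[rs, cs]
    on_bad = inside & (~np.isfinite(depth) | ~np.isfinite(sediment))
    reasons[on_bad] = "land or nodata cell"
    on_rock = inside & ~on_bad & (sediment == ROCK_CODE)
    reasons[on_rock] = "rock cell"
    good = inside & ~on_bad & ~on_rock

    out = hauls.loc[good, ["haul_id", "survey", "year", "season", "lon", "lat"]].copy()
    out["depth"] = depth[good]
    out["slope"] = env.layers["slope"].values[rs, cs][good]
    out["aspect"] = env.layers["aspect"].values[rs, cs][good]
    out["prox_shore"] = env.layers["prox_shore"].values[rs, cs][good]
    out["sediment"] = sediment[good].astype(int)
    temp = np.full(n, np.nan)
    sal = np.full(n, np.nan)
    for (yr, seas), idx in hauls.groupby(["year", "season"]).groups.items():
        pos = hauls.index.get_indexer(idx)
        tl = env.layers.get(("temperature", yr, seas))
        sl = env.layers.get(("salinity", yr, seas))
        if tl is not None:
            temp[pos] = tl.values[rs[pos], cs[pos]]
        if sl is not None:
            sal[pos] = sl.values[rs[pos], cs[pos]]
    out["temperature"] = temp[good]
    out["salinity"] = sal[good]
    excluded = hauls.loc[~good, ["haul_id"]].copy()
    excluded["reason"] = reasons[~good]
    return out.reset_index(drop=True), excluded.reset_index(drop=True)
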