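"""Synthetic trawl survey with known ground truth.

Emulates the structure of the real inputs - two surveys with different tow
durations, nine spatial regions with region/sex/year-varying logistic
life-stage schedules, environmental grid layers, and zero-inflated catches
arising from a presence process times a zero-truncated Poisson count
process with a gear-level intercept - so every downstream stage can be
tested against exported truth without any data download.

Random fields are a fixed low-order trend plus seeded Gaussian noise
smoothed with a Gaussian filter; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from . import env_layers
from .io_core import (DURATION_BY_SURVEY, GEAR_BY_SURVEY, GridLayer,
                      LAT_MAX, LON_MIN, REGIONS, SEASONS,
                      STAGES_BY_SEASON, SURVEYS)
from .hurdle import sample_ztp

#: default per-stage length distributions (mean cm, sd cm); overlapping so
#: the stage decomposition is non-trivial
STAGE_LENGTH = {"AGE0": (15.0, 3.0), "AGE1": (22.0, 4.0), "MATURE": (30.0, 6.0)}

#: fixed gear-level intercepts (two levels: a variance is unidentifiable,
#: tests target the contrast)
GEAR_PRESENCE = {"SWC_IBTS": 0.0, "NIGFS": -0.5}
GEAR_COUNT = {"SWC_IBTS": 0.0, "NIGFS": -0.4}

DEFAULT_YEARS_AUTUMN = (2011, 2012, 2013, 2014)
DEFAULT_YEARS_SPRING = (2009, 2010, 2011, 2012, 2013, 2014, 2015)

#: region labels laid out on the 3x3 partition, row 0 = northern band;
#: the southern band plays the role of the Irish Sea (NIGFS) survey area
REGION_LAYOUT = (("N-O", "N-M", "S-O"),
                 ("S-M", "S-W", "Cl"),
                 ("W-IS", "E-IS", "SE-IS"))
NIGFS_REGIONS = ("W-IS", "E-IS", "SE-IS")


# ---------------------------------------------------------------------------
# Region partition
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """3x3 rectangular tiling of the grid extent into the nine regions."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray                  # ascending
    layout: tuple = REGION_LAYOUT

    @classmethod
    def for_extent(cls, lon_min, lon_max, lat_min, lat_max) -> "RegionPartition":
        return cls(np.linspace(lon_min, lon_max, 4),
                   np.linspace(lat_min, lat_max, 4))

    def region_of(self, lon, lat) -> np.ndarray:
        """Region label per point; boundary ties go north / west."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ci = np.clip(np.searchsorted(self.lon_edges, lon, side="left") - 1, 0, 2)
        band = np.clip(np.searchsorted(self.lat_edges, lat, side="right") - 1, 0, 2)
        ri = 2 - band                                   # row 0 = north
        labels = np.asarray(self.layout, dtype=object)
        return labels[ri, ci]

    def survey_of_region(self, region) -> np.ndarray:
        region = np.atleast_1d(np.asarray(region, dtype=object))
        return np.where(np.isin(region, NIGFS_REGIONS), "NIGFS", "SWC_IBTS")

    @property
    def boundary_lat(self) -> float:
        """Latitude separating the NIGFS band from the SWC bands."""
        return float(self.lat_edges[1])


# ---------------------------------------------------------------------------
# Environment stack
# ---------------------------------------------------------------------------

@dataclass
class EnvStack:
    """Co-registered grid layers keyed by name or (name, year, season)."""

    layers: dict

    @property
    def template(self) -> GridLayer:
        return self.layers["depth"]

    @property
    def shape(self):
        return self.template.shape

    def sea_mask(self) -> np.ndarray:
        return self.layers["land"].values < 0.5

    def extent(self):
        t = self.template
        return (t.xll, t.xll + t.ncols * t.cellsize,
                t.yll, t.yll + t.nrows * t.cellsize)

    def partition(self) -> RegionPartition:
        return RegionPartition.for_extent(*self.extent())


def _smooth_noise(rng, shape, sigma) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def generate_environment(seed: int, shape=(20, 30), bathymetry: str = "random",
                         years_autumn=DEFAULT_YEARS_AUTUMN,
                         years_spring=DEFAULT_YEARS_SPRING) -> EnvStack:
    """Build the full covariate stack for a synthetic study area.

    The bathymetry deepens westward with a coastline strip on the eastern
    edge; slope/aspect/shore-distance derive from it via the terrain
    operators; sediment is sampled with spatial autocorrelation; yearly
    temperature/salinity are a smooth base field plus a year offset plus
    noise.  ``bathymetry`` may be "random", "flat" (slope identically
    zero), or "monotone" (depth strictly monotone in longitude per row).
    """
    nrows, ncols = shape
    if nrows < 10 or ncols < 10:
        raise ValueError("grid must be at least 10 x 10")
    rng = np.random.default_rng(seed)
    cellsize = min(7.0 / ncols, 7.0 / nrows)
    xll = LON_MIN
    yll = LAT_MAX - nrows * cellsize
    template = GridLayer("depth", np.zeros(shape), xll, yll, cellsize)
    lon = template.lon_centers()
    lat = template.lat_centers()
    glon, glat = np.meshgrid(lon, lat)
    lon_frac = (glon - glon.min()) / np.ptp(glon)
    lat_frac = (glat - glat.min()) / np.ptp(glat)

    # coastline on the eastern edge, gently wavy with latitude
    coast_frac = 0.84 + 0.05 * np.sin(2.5 * np.pi * lat_frac + 1.0)
    land = lon_frac > coast_frac

    west = 1.0 - lon_frac / np.clip(coast_frac, 1e-6, None)  # 0 coast -> 1 west
    west = np.clip(west, 0.0, 1.0)
    if bathymetry == "flat":
        depth = np.full(shape, 50.0)
    elif bathymetry == "monotone":
        depth = 5.0 + 345.0 * west
    elif bathymetry == "random":
        depth = (5.0 + 330.0 * west ** 1.2
                 + 25.0 * _smooth_noise(rng, shape, 2.0))
        depth = np.clip(depth, 3.0, None)
    else:
        raise ValueError(bathymetry)
    depth = np.where(land, np.nan, depth)

    layers: dict = {}
    layers["land"] = template.like(land.astype(float), "land")
    layers["depth"] = template.like(depth, "depth")
    slope, aspect = env_layers.compute_slope_aspect(layers["depth"])
    layers["slope"] = slope
    layers["aspect"] = aspect
    layers["prox_shore"] = env_layers.distance_to_shore(layers["land"])

    # spatially autocorrelated sediment: quantile-binned smooth field;
    # top 5 percent of the field is Rock
    sed_field = _smooth_noise(rng, shape, 3.0)
    sea_vals = sed_field[~land]
    qs = np.quantile(sea_vals, [0.30, 0.60, 0.80, 0.95])
    sed = np.digitize(sed_field, qs).astype(float)
    sed = np.where(land, np.nan, sed)
    layers["sediment"] = template.like(sed, "sediment")

    base_by_season = {"FEB_MAR": 8.5, "OCT_NOV": 12.5}
    sal_base = 34.5
    for season in SEASONS:
        years = years_spring if season == "FEB_MAR" else years_autumn
        t_base = (base_by_season[season] - 1.2 * lat_frac
                  + 0.8 * _smooth_noise(rng, shape, 2.0))
        s_base = (sal_base + 0.6 * west + 0.3 * _smooth_noise(rng, shape, 2.0))
        for year in years:
            t_off = rng.uniform(-0.5, 0.5)
            s_off = rng.uniform(-0.15, 0.15)
            tvals = t_base + t_off + 0.15 * _smooth_noise(rng, shape, 1.5)
            svals = s_base + s_off + 0.05 * _smooth_noise(rng, shape, 1.5)
            layers[("temperature", year, season)] = template.like(
                np.where(land, np.nan, tvals), "temperature")
            layers[("salinity", year, season)] = template.like(
                np.where(land, np.nan, svals), "salinity")
    return EnvStack(layers)


# ---------------------------------------------------------------------------
# Truth specification
# ---------------------------------------------------------------------------

def _bump(x, center, width):
    x = np.asarray(x, dtype=float)
    return np.exp(-((x - center) / width) ** 2)


#: per-stage presence / count predictors as smooth functions of covariates
#: (depth m, prox_shore m, temperature degC); "null" has no covariate effect
def _eta_presence_strong(stage, cov):
    d = cov["depth"]
    t = cov["temperature"]
    pk = cov["prox_shore"] / 1000.0
    if stage == "AGE0":
        return -3.5 + 7.0 * _bump(d, 35.0, 45.0) + 2.5 * _bump(t, 12.5, 1.5)
    if stage == "AGE1":
        return -3.4 + 6.5 * _bump(d, 65.0, 50.0) + 2.2 * _bump(pk, 10.0, 25.0)
    return -3.4 + 6.5 * _bump(d, 150.0, 70.0) + 2.0 * _bump(t, 9.5, 1.5)


def _eta_count_strong(stage, cov):
    d = cov["depth"]
    t = cov["temperature"]
    pk = cov["prox_shore"] / 1000.0
    if stage == "AGE0":
        return 0.3 + 1.8 * _bump(d, 30.0, 55.0) + 0.8 * _bump(t, 12.5, 1.5)
    if stage == "AGE1":
        return 0.4 + 1.5 * _bump(d, 65.0, 55.0) + 0.6 * _bump(pk, 10.0, 25.0)
    return 0.4 + 1.6 * _bump(d, 150.0, 80.0) + 0.6 * _bump(t, 9.7, 1.5)


@dataclass
class TruthSpec:
    """Known ground truth for every synthetic process.

    ``stage_logit`` maps (stage, region, sex, year) to the (intercept,
    length-slope) of the true stage-membership logistic; the implied true
    L50 is -intercept/slope.  ``signal`` selects the presence/count
    predictor family: "strong" (smooth covariate effects) or "null"
    (constants - no covariate influence).
    """

    seed: int
    regions: RegionPartition
    stage_logit: dict
    signal: str = "strong"
    gear_presence: dict = field(default_factory=lambda: dict(GEAR_PRESENCE))
    gear_count: dict = field(default_factory=lambda: dict(GEAR_COUNT))
    stage_length: dict = field(default_factory=lambda: dict(STAGE_LENGTH))
    years_autumn: tuple = DEFAULT_YEARS_AUTUMN
    years_spring: tuple = DEFAULT_YEARS_SPRING

    def years_for_stage(self, stage: str) -> tuple:
        return self.years_autumn if stage == "AGE0" else self.years_spring

    def eta_presence(self, stage: str, cov) -> np.ndarray:
        if self.signal == "null":
            return np.full(len(cov["depth"]), 0.3)
        return _eta_presence_strong(stage, cov)

    def eta_count(self, stage: str, cov) -> np.ndarray:
        if self.signal == "null":
            return np.full(len(cov["depth"]), np.log(3.0))
        return _eta_count_strong(stage, cov)

    def logit_params(self, stage, region, sex, year):
        return self.stage_logit[(stage, region, sex, year)]

    def true_l50(self, stage, region, sex, year) -> float:
        alpha, beta = self.logit_params(stage, region, sex, year)
        return -alpha / beta

    def stage_prob(self, stage, region, sex, year, length) -> np.ndarray:
        alpha, beta = self.logit_params(stage, region, sex, year)
        return 1.0 / (1.0 + np.exp(-(alpha + beta * np.asarray(length, float))))


#: true base L50 (cm) and length slope per stage; slopes are negative for
#: the age stages (small fish more likely young) and positive for maturity
STAGE_L50_BASE = {"AGE0": 18.0, "AGE1": 24.0, "MATURE": 26.0}
STAGE_SLOPE = {"AGE0": -0.8, "AGE1": -0.5, "MATURE": 0.5}


def default_truth(seed: int, env: EnvStack, signal: str = "strong",
                  years_autumn=DEFAULT_YEARS_AUTUMN,
                  years_spring=DEFAULT_YEARS_SPRING,
                  sex_effect_cm: float = 0.4,
                  region_spread_cm: float = 2.0,
                  year_spread_cm: float = 0.8) -> TruthSpec:
    """Deterministic default truth: region/sex/year shifts of stage L50.

    Region offsets are drawn once from the seed (uniform within
    +-region_spread_cm); sex shifts L50 by +-sex_effect_cm (F positive);
    year offsets are uniform within +-year_spread_cm.
    """
    rng = np.random.default_rng(seed + 101)
    partition = env.partition()
    stage_logit = {}
    for stage, base in STAGE_L50_BASE.items():
        slope = STAGE_SLOPE[stage]
        years = years_autumn if stage == "AGE0" else years_spring
        region_off = {r: rng.uniform(-region_spread_cm, region_spread_cm)
                      for r in REGIONS}
        year_off = {y: rng.uniform(-year_spread_cm, year_spread_cm)
                    for y in years}
        for r in REGIONS:
            for y in years:
                for sex, soff in (("F", sex_effect_cm), ("M", -sex_effect_cm)):
                    l50 = base + region_off[r] + year_off[y] + soff
                    stage_logit[(stage, r, sex, y)] = (-slope * l50, slope)
    gear_p = dict(GEAR_PRESENCE)
    gear_c = dict(GEAR_COUNT)
    if signal == "null":        # a null truth has no gear signal either
        gear_p = {k: 0.0 for k in gear_p}
        gear_c = {k: 0.0 for k in gear_c}
    return TruthSpec(seed, partition, stage_logit, signal,
                     gear_presence=gear_p, gear_count=gear_c,
                     years_autumn=tuple(years_autumn),
                     years_spring=tuple(years_spring))


# ---------------------------------------------------------------------------
# Hauls
# ---------------------------------------------------------------------------

def generate_hauls(env: EnvStack, n_per_survey_year: dict | int, years,
                   season: str, seed: int) -> pd.DataFrame:
    """Uniform random haul positions on sea cells, per survey and year.

    SWC_IBTS hauls (30-minute tows) fall in the northern two bands of the
    partition, NIGFS hauls (60-minute tows) in the southern band.
    """
    if isinstance(n_per_survey_year, int):
        n_per_survey_year = {s: n_per_survey_year for s in SURVEYS}
    rng = np.random.default_rng(seed)
    template = env.template
    sea = env.sea_mask() & np.isfinite(template.values)
    if not sea.any():
        raise ValueError("no sea cells to place hauls on")
    boundary = env.partition().boundary_lat
    lat_c = template.lat_centers()
    glat = np.broadcast_to(lat_c[:, None], template.shape)
    rows = []
    half = template.cellsize / 2.0
    for survey in SURVEYS:
        # a cell is eligible only if jittered positions cannot cross the
        # survey boundary (cells straddling it are skipped)
        zone = sea & ((glat - half >= boundary) if survey == "SWC_IBTS"
                      else (glat + half <= boundary))
        cells = np.argwhere(zone)
        if len(cells) == 0:
            raise ValueError(f"no sea cells in the {survey} zone")
        n = n_per_survey_year[survey]
        for year in years:
            pick = cells[rng.integers(0, len(cells), size=n)]
            jit = rng.uniform(-0.45, 0.45, size=(n, 2))
            lon = template.xll + (pick[:, 1] + 0.5 + jit[:, 1]) * template.cellsize
            top = template.yll + template.nrows * template.cellsize
            lat = top - (pick[:, 0] + 0.5 + jit[:, 0]) * template.cellsize
            for i in range(n):
                rows.append({
                    "haul_id": f"{survey}_{season}_{year}_{i:04d}",
                    "survey": survey, "gear": GEAR_BY_SURVEY[survey],
                    "year": int(year), "season": season,
                    "lon": float(lon[i]), "lat": float(lat[i]),
                    "duration": DURATION_BY_SURVEY[survey]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SMALKs
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size):
    out = rng.normal(mean, sd, size=size)
    bad = out < 1.0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 1.0
    return out


def generate_smalks(truth: TruthSpec, n_per_region_year: int, years,
                    season: str, seed: int) -> pd.DataFrame:
    """Individual sex-age-maturity-length records with exact logistic truth.

    Lengths come from a season-specific mixture over stage length
    distributions; labels are then drawn from the true logistic
    probabilities at the drawn length, so each stage's conditional
    membership probability is exactly the truth's logistic curve.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region in REGIONS:
        survey = str(truth.regions.survey_of_region(region)[0])
        for year in years:
            n = n_per_region_year
            sex = rng.choice(["F", "M"], size=n)
            if season == "OCT_NOV":
                comp = rng.random(n) < 0.55
                length = np.where(
                    comp,
                    _truncated_normal(rng, *truth.stage_length["AGE0"], n),
                    _truncated_normal(rng, 25.0, 6.0, n))
            else:
                comp = rng.random(n) < 0.5
                length = np.where(
                    comp,
                    _truncated_normal(rng, *truth.stage_length["AGE1"], n),
                    _truncated_normal(rng, *truth.stage_length["MATURE"], n))
            for i in range(n):
                if season == "OCT_NOV":
                    p0 = truth.stage_prob("AGE0", region, sex[i], year, length[i])
                    if rng.random() < p0:
                        age = 0
                    else:
                        age = int(rng.integers(1, 3))
                else:
                    p1 = truth.stage_prob("AGE1", region, sex[i], year, length[i])
                    age = 1 if rng.random() < p1 else int(rng.integers(2, 4))
                mature = False
                if age >= 1:
                    pm = truth.stage_prob("MATURE", region, sex[i], year,
                                          length[i])
                    mature = bool(rng.random() < pm)
                rows.append({"length": float(length[i]), "sex": str(sex[i]),
                             "age": age, "mature": mature, "region": region,
                             "year": int(year), "survey": survey,
                             "season": season})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Catches
# ---------------------------------------------------------------------------

def haul_covariates(env: EnvStack, hauls: pd.DataFrame) -> pd.DataFrame:
    """Raw nearest-cell covariates at hauls (no Rock exclusion: generation
    needs values everywhere a haul can fall)."""
    template = env.template
    row, col = template.cell_index(hauls["lon"].to_numpy(),
                                   hauls["lat"].to_numpy())
    row = np.clip(row, 0, template.nrows - 1)
    col = np.clip(col, 0, template.ncols - 1)
    cov = {"depth": env.layers["depth"].values[row, col],
           "prox_shore": env.layers["prox_shore"].values[row, col]}
    temp = np.full(len(hauls), np.nan)
    for (yr, seas), idx in hauls.groupby(["year", "season"]).groups.items():
        pos = hauls.index.get_indexer(idx)
        layer = env.layers.get(("temperature", yr, seas))
        if layer is not None:
            temp[pos] = layer.values[row[pos], col[pos]]
    cov["temperature"] = temp
    return pd.DataFrame(cov, index=hauls.index)


def _length_class_probs(mean, sd, max_class=80):
    edges = np.arange(0, max_class + 1, dtype=float)
    cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
    p = np.diff(cdf)
    return p / p.sum()


def generate_catches(env: EnvStack, hauls: pd.DataFrame, truth: TruthSpec,
                     seed: int) -> pd.DataFrame:
    """Length-frequency catch rows from the zero-altered truth.

    Per haul and in-season stage: presence is Bernoulli of the true logit
    plus the gear intercept; given presence the standardized total is
    zero-truncated Poisson of the true log-rate plus the gear intercept.
    Totals are spread over 1-cm classes by the stage length distribution
    and summed across stages; raw counts are the standardized counts
    scaled back to the tow duration so that CPUE standardisation recovers
    them exactly.
    """
    rng = np.random.default_rng(seed)
    cov = haul_covariates(env, hauls)
    bad = ~np.isfinite(cov[["depth", "prox_shore", "temperature"]]).all(axis=1)
    if bad.any():
        raise ValueError("non-finite covariates at haul(s): "
                         + ", ".join(hauls.loc[bad, "haul_id"].head(5)))
    class_probs = {st: _length_class_probs(*truth.stage_length[st])
                   for st in truth.stage_length}
    rows = []
    for i, haul in hauls.reset_index(drop=True).iterrows():
        c = {k: np.array([cov[k].iloc[i]]) for k in cov.columns}
        scale = haul["duration"] / 30.0
        for stage in STAGES_BY_SEASON[haul["season"]]:
            eta_p = float(truth.eta_presence(stage, c)[0]
                          + truth.gear_presence[haul["survey"]])
            if rng.random() >= 1.0 / (1.0 + np.exp(-eta_p)):
                continue
            lam = float(np.exp(truth.eta_count(stage, c)[0]
                               + truth.gear_count[haul["survey"]]))
            std_total = int(sample_ztp(rng, lam, size=1)[0])
            counts = rng.multinomial(std_total, class_probs[stage])
            for lc in np.nonzero(counts)[0]:
                rows.append({"haul_id": haul["haul_id"],
                             "length_class": int(lc), "sex": "U",
                             "count": float(counts[lc] * scale)})
    if not rows:
        return pd.DataFrame(columns=["haul_id", "length_class", "sex", "count"])
    df = pd.DataFrame(rows)
    return (df.groupby(["haul_id", "length_class", "sex"], as_index=False)
            ["count"].sum())


def simulate_zap_dataset(env: EnvStack, hauls: pd.DataFrame, truth: TruthSpec,
                         stage: str, seed: int) -> pd.DataFrame:
    """Direct per-stage ZAP observations at hauls, with the truth attached.

    Returns the haul covariate table plus columns: presence (0/1), count
    (standardized; 0 when absent), true_eta_p, true_p, true_lambda and
    true_cpue (the population-level expected CPUE p * m(lambda)).
    Used for recovery tests of the hurdle machinery in isolation.
    """
    rng = np.random.default_rng(seed)
    tab, _ = env_layers.extract_at_hauls(env, hauls)
    cov = {k: tab[k].to_numpy(dtype=float)
           for k in ("depth", "prox_shore", "temperature")}
    eta_p = truth.eta_presence(stage, cov)
    eta_n = truth.eta_count(stage, cov)
    a_p = np.array([truth.gear_presence[s] for s in tab["survey"]])
    a_n = np.array([truth.gear_count[s] for s in tab["survey"]])
    p = 1.0 / (1.0 + np.exp(-(eta_p + a_p)))
    lam = np.exp(eta_n + a_n)
    present = (rng.random(len(tab)) < p).astype(int)
    counts = np.zeros(len(tab), dtype=int)
    if present.any():
        counts[present == 1] = sample_ztp(rng, lam[present == 1])
    out = tab.copy()
    out["present"] = present
    out["count"] = counts
    out["true_eta_p"] = eta_p
    out["true_p"] = 1.0 / (1.0 + np.exp(-eta_p))
    lam0 = np.exp(eta_n)
    out["true_lambda"] = lam0
    out["true_cpue"] = out["true_p"] * lam0 / (-np.expm1(-lam0))
    return out


# ---------------------------------------------------------------------------
# Truth export
# ---------------------------------------------------------------------------

def export_truth(truth: TruthSpec, env: EnvStack):
    """True L50 table and true presence/expected-CPUE grids.

    Returns ``(l50_df, grids)`` where grids maps (stage, year, kind) with
    kind in {"p", "lambda", "cpue"} to GridLayers sharing the stack shape.
    Grid truths are at the population gear level (intercept zero).
    """
    rows = []
    for (stage, region, sex, year), (alpha, beta) in sorted(
            truth.stage_logit.items()):
        rows.append({"stage": stage, "region": region, "sex": sex,
                     "year": int(year), "L50_cm": -alpha / beta})
    l50 = pd.DataFrame(rows)

    template = env.template
    grids = {}
    sea = env.sea_mask() & np.isfinite(env.layers["depth"].values)
    for stage in STAGE_L50_BASE:
        season = "OCT_NOV" if stage == "AGE0" else "FEB_MAR"
        years = truth.years_for_stage(stage)
        for year in years:
            tl = env.layers.get(("temperature", year, season))
            cov = {"depth": env.layers["depth"].values.ravel(),
                   "prox_shore": env.layers["prox_shore"].values.ravel(),
                   "temperature": (tl.values.ravel() if tl is not None
                                   else np.full(sea.size, np.nan))}
            eta_p = truth.eta_presence(stage, cov)
            lam = np.exp(truth.eta_count(stage, cov))
            p = 1.0 / (1.0 + np.exp(-eta_p))
            cpue = p * lam / (-np.expm1(-lam))
            for kind, vals in (("p", p), ("lambda", lam), ("cpue", cpue)):
                arr = np.where(sea.ravel(), vals, np.nan).reshape(env.shape)
                grids[(stage, int(year), kind)] = template.like(
                    arr, f"true_{kind}_{stage}_{year}")
    return l50, grids
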