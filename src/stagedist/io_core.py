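"""Survey-table and grid I/O, domain constants, and run configuration.

Tables travel as headed CSV (columns modelled on the DATRAS exchange
HH/HL/CA trio); grid layers travel as ESRI ASCII rasters.  Both formats are
plain text so fixtures stay legible and round-trips are bit-faithful at the
written precision.
"""

from __future__ import annotations

import dataclasses
import io
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Domain constants
# ---------------------------------------------------------------------------

SURVEYS = ("SWC_IBTS", "NIGFS")
#: each survey runs one gear type; the pairing is fixed by the survey designs
GEAR_BY_SURVEY = {"SWC_IBTS": "GOV", "NIGFS": "ROCKHOPPER"}
#: standard tow duration (minutes) per survey
DURATION_BY_SURVEY = {"SWC_IBTS": 30, "NIGFS": 60}
SEASONS = ("FEB_MAR", "OCT_NOV")
#: life stages; AGE0 is sampled in the autumn survey, AGE1/MATURE in spring
STAGES = ("AGE0", "AGE1", "MATURE")
STAGES_BY_SEASON = {"OCT_NOV": ("AGE0",), "FEB_MAR": ("AGE1", "MATURE")}
SEASON_BY_STAGE = {"AGE0": "OCT_NOV", "AGE1": "FEB_MAR", "MATURE": "FEB_MAR"}
#: the nine named assessment regions of the study area
REGIONS = ("N-O", "S-O", "N-M", "S-M", "S-W", "Cl", "W-IS", "E-IS", "SE-IS")
SEXES = ("F", "M")
#: study extent (degrees); all layers and hauls live inside this box
LON_MIN, LON_MAX = -10.0, -3.0
LAT_MIN, LAT_MAX = 52.0, 59.0

SEDIMENT_CLASSES = ("mud_sandy_mud", "sand_muddy_sand", "coarse", "mixed", "rock")

KM_PER_DEG_LAT = 111.2

HAUL_COLUMNS = ["haul_id", "survey", "gear", "year", "season", "lon", "lat",
                "duration"]
LENGTH_COLUMNS = ["haul_id", "length_class", "sex", "count"]
SMALK_COLUMNS = ["length", "sex", "age", "mature", "region", "year", "survey"]


# ---------------------------------------------------------------------------
# Grid layers (ESRI ASCII dialect)
# ---------------------------------------------------------------------------

NODATA = -9999.0


@dataclass
class GridLayer:
    """A single raster layer on a regular lon/lat grid.

    Geometry follows the ESRI ASCII convention: square cells of ``cellsize``
    degrees, ``xll``/``yll`` the lower-left corner, row 0 the northernmost
    row.  ``values`` holds NaN where there is no data.
    """

    name: str
    values: np.ndarray            # (nrows, ncols), float, NaN = nodata
    xll: float
    yll: float
    cellsize: float

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row centre, row 0 = northernmost."""
        top = self.yll + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def cell_index(self, lon, lat):
        """Nearest-cell (row, col) for points; may fall outside the grid."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        top = self.yll + self.nrows * self.cellsize
        row = np.floor((top - lat) / self.cellsize).astype(int)
        return row, col

    def like(self, values: np.ndarray, name: str) -> "GridLayer":
        if values.shape != self.shape:
            raise ValueError("shape mismatch in GridLayer.like")
        return GridLayer(name, np.asarray(values, dtype=float),
                         self.xll, self.yll, self.cellsize)

    def cell_km(self) -> tuple[float, float]:
        """Physical (east-west, north-south) cell size in km at mid latitude."""
        mid_lat = self.yll + 0.5 * self.nrows * self.cellsize
        kx = self.cellsize * KM_PER_DEG_LAT * np.cos(np.deg2rad(mid_lat))
        ky = self.cellsize * KM_PER_DEG_LAT
        return kx, ky


def write_grid(path: str | os.PathLike, layer: GridLayer, precision: int = 6) -> None:
    vals = np.where(np.isfinite(layer.values), layer.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {layer.ncols}\n")
        fh.write(f"nrows {layer.nrows}\n")
        fh.write(f"xllcorner {layer.xll:.10g}\n")
        fh.write(f"yllcorner {layer.yll:.10g}\n")
        fh.write(f"cellsize {layer.cellsize:.10g}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        np.savetxt(fh, vals, fmt=f"%.{precision}g")


def read_grid(path: str | os.PathLike, name: str | None = None) -> GridLayer:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(
            f"grid shape {vals.shape} does not match header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return GridLayer(name or os.path.splitext(os.path.basename(path))[0],
                     vals, header["xllcorner"], header["yllcorner"],
                     header["cellsize"])


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------

@dataclass
class RejectionReport:
    """Row-level validation outcome for one table read."""

    table: str
    n_read: int = 0
    n_kept: int = 0
    reasons: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_read - self.n_kept


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table} table missing columns: {missing}")
    return df[cols].copy()  # unknown columns ignored


def validate_hauls(df: pd.DataFrame) -> tuple[pd.DataFrame, RejectionReport]:
    df = _require_columns(df, HAUL_COLUMNS, "haul")
    rep = RejectionReport("haul", n_read=len(df))
    ok = pd.Series(True, index=df.index)

    def flag(bad: pd.Series, reason: str) -> None:
        nonlocal ok
        bad = bad & ok
        for hid in df.loc[bad, "haul_id"]:
            rep.reasons.append(f"haul {hid}: {reason}")
        ok &= ~bad

    flag(~df["survey"].isin(SURVEYS), "unknown survey")
    expected_gear = df["survey"].map(GEAR_BY_SURVEY)
    flag(df["survey"].isin(SURVEYS) & (df["gear"] != expected_gear),
         "gear inconsistent with survey")
    flag(~df["season"].isin(SEASONS), "unknown season")
    flag(~(df["duration"] > 0), "non-positive duration")
    flag(~df["lon"].between(LON_MIN, LON_MAX) | ~df["lat"].between(LAT_MIN, LAT_MAX),
         "outside study extent")
    rep.n_kept = int(ok.sum())
    return df[ok].reset_index(drop=True), rep


def validate_lengths(df: pd.DataFrame,
                     known_hauls: pd.Series | None = None
                     ) -> tuple[pd.DataFrame, RejectionReport]:
    df = _require_columns(df, LENGTH_COLUMNS, "length")
    rep = RejectionReport("length", n_read=len(df))
    ok = (df["length_class"] >= 0) & (df["count"] >= 0) & df["sex"].isin(("F", "M", "U"))
    for i in df.index[~ok]:
        rep.reasons.append(f"length row {i}: invariant violation "
                           f"(length_class={df.at[i, 'length_class']}, "
                           f"count={df.at[i, 'count']}, sex={df.at[i, 'sex']})")
    if known_hauls is not None:
        orphan = ~df["haul_id"].isin(known_hauls)
        for i in df.index[orphan & ok]:
            rep.reasons.append(f"length row {i}: haul_id {df.at[i, 'haul_id']} "
                               "absent from haul table")
        ok &= ~orphan
    rep.n_kept = int(ok.sum())
    return df[ok].reset_index(drop=True), rep


def validate_smalks(df: pd.DataFrame) -> tuple[pd.DataFrame, RejectionReport]:
    df = _require_columns(df, SMALK_COLUMNS, "smalk")
    if df["mature"].dtype != bool:
        df["mature"] = df["mature"].astype(str).str.lower().isin(("true", "1"))
    rep = RejectionReport("smalk", n_read=len(df))
    ok = ((df["length"] > 0) & (df["age"] >= 0) & df["sex"].isin(SEXES)
          & df["region"].isin(REGIONS) & df["survey"].isin(SURVEYS)
          & ~(df["mature"] & (df["age"] < 1)))
    for i in df.index[~ok]:
        rep.reasons.append(f"smalk row {i}: invariant violation")
    rep.n_kept = int(ok.sum())
    return df[ok].reset_index(drop=True), rep


def read_survey_tables(haul_path, length_path, smalk_path):
    """Read and validate the haul / length-frequency / SMALK CSV trio.

    Returns ``(hauls, lengths, smalks, reports)`` where reports is a list of
    per-table :class:`RejectionReport`.  Missing files raise; invalid rows
    are dropped and listed.
    """
    for p in (haul_path, length_path, smalk_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    hauls, rep_h = validate_hauls(pd.read_csv(haul_path))
    lengths, rep_l = validate_lengths(pd.read_csv(length_path),
                                      known_hauls=hauls["haul_id"])
    smalks, rep_s = validate_smalks(pd.read_csv(smalk_path))
    return hauls, lengths, smalks, [rep_h, rep_l, rep_s]


def write_survey_tables(out_dir, hauls: pd.DataFrame, lengths: pd.DataFrame,
                        smalks: pd.DataFrame) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df, cols in (("hauls", hauls, HAUL_COLUMNS),
                           ("lengths", lengths, LENGTH_COLUMNS),
                           ("smalks", smalks, SMALK_COLUMNS)):
        p = os.path.join(out_dir, f"{name}.csv")
        df.to_csv(p, index=False, columns=[c for c in cols if c in df.columns])
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full pipeline run depends on besides the input tables.

    All stochastic stages derive their generators from ``seed`` so a run is
    a pure function of (inputs, config).
    """

    seed: int = 1
    nrows: int = 20
    ncols: int = 30
    years_autumn: tuple[int, ...] = (2011, 2012, 2013)
    years_spring: tuple[int, ...] = (2011, 2012, 2013)
    hauls_swc_per_year: int = 20
    hauls_nigfs_per_year: int = 13
    smalks_per_region_year: int = 60
    cv_iterations: int = 20
    cv_train_fraction: float = 0.7
    stepwise: bool = False
    bandwidth_grid_km: tuple[float, ...] = tuple(
        float(x) for x in np.geomspace(5.0, 500.0, 20).round(3))
    truth: str = "strong"
    out_dir: str = "runs/default"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                val = getattr(self, f.name)
                if isinstance(val, tuple):
                    val = ",".join(str(v) for v in val)
                fh.write(f"{f.name} = {val}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, val = (s.strip() for s in line.split("=", 1))
                raw[key] = val
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.type.startswith("tuple"):
                elem = float if "float" in f.type else int
                kwargs[f.name] = tuple(elem(v) for v in val.split(",") if v)
            elif f.type == "int":
                kwargs[f.name] = int(val)
            elif f.type == "float":
                kwargs[f.name] = float(val)
            elif f.type == "bool":
                kwargs[f.name] = val.lower() in ("true", "1")
            else:
                kwargs[f.name] = val
        return cls(**kwargs)


class RunLog:
    """Structured, deterministic per-stage log written as JSON."""

    def __init__(self, seed: int):
        self.entries: list[dict] = []
        self.seed = seed

    def stage(self, name: str, **info) -> None:
        self.entries.append({"stage": name, **info})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stages": self.entries}, fh, indent=1,
                      default=str)


def run_pipeline(config: RunConfig):
    """End-to-end orchestration; see :mod:`stagedist.pipeline`."""
    from .pipeline import run_pipeline as _run
    return _run(config)
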