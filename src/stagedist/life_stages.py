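"""Life-stage probability models and stage CPUE decomposition.

Individual sex-maturity-age-length records are used to fit binomial GLMs
(logit link) of the probability that a fish of a given length, sex, region
and year belongs to a life stage (age-0, age-1, or mature among age-1+).
Backward stepwise elimination by likelihood-ratio test prunes the candidate
structure.  The length at which the fitted probability crosses 0.5 (L50)
summarises spatial/temporal variation in length-at-age and maturity.
Haul-level length frequencies are then decomposed into per-stage CPUE by
multiplying standardized counts with the fitted stage probabilities.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .io_core import REGIONS, SEASON_BY_STAGE, STAGES

#: candidate model structure per stage: main effects plus the pairwise
#: interactions entertained for that stage's ogive, per survey
DEFAULT_MAIN_EFFECTS = ("sex", "region", "length", "year")
DEFAULT_INTERACTIONS: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {
    ("AGE0", "SWC_IBTS"): (("length", "region"), ("length", "year"),
                           ("sex", "year")),
    ("AGE0", "NIGFS"): (("length", "region"), ("length", "year"),
                        ("sex", "region"), ("region", "year")),
    ("AGE1", "SWC_IBTS"): (("length", "region"), ("length", "year"),
                           ("region", "year")),
    ("AGE1", "NIGFS"): (("length", "year"), ("region", "year"),
                        ("sex", "year")),
    ("MATURE", "SWC_IBTS"): (("length", "sex"), ("region", "year"),
                             ("region", "sex")),
    ("MATURE", "NIGFS"): (("length", "year"), ("region", "year"),
                          ("sex", "year"), ("sex", "length")),
}

LRT_ALPHA = 0.05


def standardise_cpue(count, duration_minutes):
    """Standardise a haul count to a 30-minute tow, floored to whole fish."""
    duration = np.asarray(duration_minutes, dtype=float)
    if np.any(duration <= 0):
        raise ValueError("tow duration must be positive")
    count = np.asarray(count, dtype=float)
    if np.any(count < 0):
        raise ValueError("counts must be non-negative")
    out = np.floor(count * 30.0 / duration).astype(int)
    return out if out.shape else int(out)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _term_formula(term) -> str:
    parts = []
    for v in ([term] if isinstance(term, str) else term):
        parts.append(f"C({v})" if v != "length" else "length")
    return ":".join(parts)


def _build_formula(mains, interactions) -> str:
    rhs = [_term_formula(m) for m in mains]
    rhs += [_term_formula(t) for t in interactions]
    return "outcome ~ " + (" + ".join(rhs) if rhs else "1")


def _stage_outcome(smalks: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Training frame for one stage: outcome column + covariates.

    AGE0: all fish, outcome age == 0.  AGE1: all fish, outcome age == 1.
    MATURE: fish of age >= 1, outcome = maturity flag.
    """
    df = smalks.copy()
    if stage == "AGE0":
        df["outcome"] = (df["age"] == 0).astype(int)
    elif stage == "AGE1":
        df["outcome"] = (df["age"] == 1).astype(int)
    elif stage == "MATURE":
        df = df[df["age"] >= 1].copy()
        df["outcome"] = df["mature"].astype(int)
    else:
        raise ValueError(f"unknown stage {stage}")
    return df


@dataclass
class LogisticStageModel:
    """A fitted logit model of stage membership probability."""

    stage: str
    survey: str
    mains: tuple
    interactions: tuple
    result: object                        # statsmodels GLMResults
    n: int
    elimination_path: list = field(default_factory=list)
    separation_flag: bool = False

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    def _frame(self, length, sex, region, year) -> pd.DataFrame:
        return pd.DataFrame({"length": np.atleast_1d(np.asarray(length, float)),
                             "sex": sex, "region": region, "year": year})

    def predict(self, length, sex, region, year) -> np.ndarray:
        self._check_levels(sex=sex, region=region, year=year)
        return np.asarray(self.result.predict(
            self._frame(length, sex, region, year)))

    def linear_predictor(self, length, sex, region, year) -> np.ndarray:
        self._check_levels(sex=sex, region=region, year=year)
        return np.asarray(self.result.predict(
            self._frame(length, sex, region, year), which="linear"))

    def _used_vars(self) -> set:
        used = set(self.mains)
        for t in self.interactions:
            used.update(t)
        return used

    def _check_levels(self, **profile) -> None:
        data = self.result.model.data.frame
        used = self._used_vars()
        for var, val in profile.items():
            if var not in used:       # unused covariates cannot mislead
                continue
            known = set(data[var])
            for v in np.atleast_1d(val):
                if v not in known:
                    raise ValueError(
                        f"unseen {var} level {v!r} for {self.stage}/{self.survey}")


def _fit_glm(df: pd.DataFrame, formula: str):
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(formula, data=df, family=sm.families.Binomial())
        return model.fit(maxiter=200)


def _removable(mains, interactions):
    """Interactions are always removable; a main effect only while no
    retained interaction contains it (hierarchy)."""
    locked = set(itertools.chain.from_iterable(interactions))
    moves = [("interaction", t) for t in interactions]
    moves += [("main", m) for m in mains if m not in locked]
    return moves


def fit_stage_model(smalks: pd.DataFrame, stage: str, survey: str,
                    mains=DEFAULT_MAIN_EFFECTS,
                    interactions=None, alpha: float = LRT_ALPHA,
                    select: bool = True) -> LogisticStageModel:
    """Fit the stage ogive with backward LRT elimination.

    Starts from the full candidate structure (mains + stage/survey-specific
    pairwise interactions); repeatedly drops the removable term with the
    largest LRT p-value above ``alpha``, keeping main effects while any
    retained interaction contains them.  ``select=False`` fits the full
    structure without pruning.
    """
    if interactions is None:
        interactions = DEFAULT_INTERACTIONS.get((stage, survey), ())
    df = _stage_outcome(smalks[smalks["survey"] == survey], stage)
    if df["outcome"].nunique() < 2:
        raise ValueError(f"only one outcome class for {stage}/{survey}")
    # drop single-observation factor levels (cannot support a coefficient)
    for var in ("sex", "region", "year"):
        counts = df[var].value_counts()
        bad = counts[counts < 2].index
        if len(bad):
            warnings.warn(f"dropping {var} level(s) {list(bad)} with <2 obs")
            df = df[~df[var].isin(bad)]

    mains = list(mains)
    interactions = [tuple(t) for t in interactions]
    fit = _fit_glm(df, _build_formula(mains, interactions))
    path = []
    while select:
        moves = _removable(mains, interactions)
        best = None
        for kind, term in moves:
            new_mains = [m for m in mains if not (kind == "main" and m == term)]
            new_inter = [t for t in interactions
                         if not (kind == "interaction" and t == term)]
            red = _fit_glm(df, _build_formula(new_mains, new_inter))
            lr = 2.0 * (fit.llf - red.llf)
            ddf = fit.df_model - red.df_model
            p = float(stats.chi2.sf(max(lr, 0.0), max(ddf, 1)))
            if best is None or p > best[0]:
                best = (p, kind, term, new_mains, new_inter, red)
        if best is None or best[0] <= alpha:
            break
        p, kind, term, mains, interactions, fit = best
        path.append({"dropped": term, "kind": kind, "p": p})

    mu = fit.fittedvalues
    separation = bool(np.any((mu < 1e-8) | (mu > 1 - 1e-8)))
    if separation:
        warnings.warn(f"possible complete separation in {stage}/{survey}")
    return LogisticStageModel(stage, survey, tuple(mains), tuple(interactions),
                              fit, len(df), path, separation)


def stage_probability(model: LogisticStageModel, length, sex, region, year):
    """Fitted probability of stage membership at a covariate profile."""
    return model.predict(length, sex, region, year)


def compute_L50(model: LogisticStageModel, sex, region, year) -> float:
    """Length at which the fitted stage probability crosses 0.5.

    Solves linear-predictor = 0 for the fixed profile.  The predictor is
    linear in length, so L50 = -eta(0) / (eta(1) - eta(0)); a zero
    effective length slope leaves L50 undefined (NaN, flagged).
    """
    eta0 = float(model.linear_predictor(0.0, sex, region, year)[0])
    eta1 = float(model.linear_predictor(1.0, sex, region, year)[0])
    slope = eta1 - eta0
    if abs(slope) < 1e-12:
        warnings.warn(f"zero length slope for {sex}/{region}/{year}; "
                      "L50 undefined")
        return math.nan
    return -eta0 / slope


def l50_table(models: dict, smalks: pd.DataFrame) -> pd.DataFrame:
    """L50 per stage x survey x region x sex x year present in the SMALKs."""
    rows = []
    for (stage, survey), model in models.items():
        sub = smalks[smalks["survey"] == survey]
        for (region, year) in sorted(set(zip(sub["region"], sub["year"]))):
            for sex in ("F", "M"):
                try:
                    l50 = compute_L50(model, sex, region, year)
                except ValueError:
                    l50 = math.nan
                rows.append({"stage": stage, "survey": survey, "region": region,
                             "sex": sex, "year": year, "L50_cm": l50})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CPUE decomposition
# ---------------------------------------------------------------------------

def sex_ratio_by_length(smalks: pd.DataFrame) -> pd.Series:
    """P(female | 1-cm length bin) from the SMALK records (fallback 0.5)."""
    bins = np.floor(smalks["length"].to_numpy(dtype=float)).astype(int)
    return (pd.Series((smalks["sex"] == "F").to_numpy(dtype=float))
            .groupby(bins).mean())


def decompose_cpue(lengths: pd.DataFrame, hauls: pd.DataFrame,
                   models: dict, region_of, smalks: pd.DataFrame) -> pd.DataFrame:
    """Per-haul stage CPUE from length frequencies and stage probabilities.

    ``cpue_stage = sum_l standardized_count(l) * p_stage(l + 0.5, ...)``,
    probabilities evaluated at the bin midpoint.  Counts of unknown sex use
    a sex-averaged probability weighted by the SMALK sex ratio in that
    length bin (0.5/0.5 where no SMALK data).  Stages outside a haul's
    season are reported as NaN.
    """
    ratio = sex_ratio_by_length(smalks)
    merged = lengths.merge(
        hauls[["haul_id", "survey", "year", "season", "lon", "lat", "duration"]],
        on="haul_id", how="inner")
    merged["std_count"] = standardise_cpue(merged["count"].to_numpy(),
                                           merged["duration"].to_numpy())
    merged["region"] = region_of(merged["lon"].to_numpy(),
                                 merged["lat"].to_numpy())
    merged["mid"] = merged["length_class"].astype(float) + 0.5
    bin_idx = merged["length_class"].astype(int)
    merged["p_female"] = ratio.reindex(bin_idx).fillna(0.5).to_numpy()

    out = hauls[["haul_id", "survey", "year", "season", "lon", "lat"]].copy()
    for stage in STAGES:
        col = np.full(len(out), np.nan)
        season = SEASON_BY_STAGE[stage]
        sel = merged["season"] == season
        sub = merged[sel]
        vals = pd.Series(0.0, index=hauls.loc[hauls["season"] == season,
                                              "haul_id"])
        if len(sub):
            by_survey = []
            for survey, ss in sub.groupby("survey"):
                model = models.get((stage, survey))
                if model is None:
                    raise ValueError(f"no fitted model for {stage}/{survey}")
                pF = model.predict(ss["mid"], "F", ss["region"], ss["year"])
                pM = model.predict(ss["mid"], "M", ss["region"], ss["year"])
                w = ss["p_female"].to_numpy()
                p = np.where(ss["sex"] == "F", pF,
                             np.where(ss["sex"] == "M", pM,
                                      w * pF + (1 - w) * pM))
                by_survey.append(pd.Series(ss["std_count"].to_numpy() * p,
                                           index=ss["haul_id"]))
            contrib = pd.concat(by_survey).groupby(level=0).sum()
            vals = vals.add(contrib, fill_value=0.0)
        mapped = out["haul_id"].map(vals)
        col = mapped.to_numpy(dtype=float)
        out[f"cpue_{stage.lower()}"] = col
        out[f"present_{stage.lower()}"] = np.where(
            np.isnan(col), np.nan, (col > 0).astype(float))
    return out
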