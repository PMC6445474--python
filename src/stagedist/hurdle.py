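"""Zero-altered Poisson hurdle models of stage CPUE on environmental layers.

A hurdle model pairs a binomial presence component (fitted to all hauls)
with a zero-truncated Poisson count component (fitted to positive hauls
only).  Both are penalized-spline additive models with a survey/gear random
intercept (see :mod:`stagedist.gam`).  The combined expectation of CPUE is
``p * lambda / (1 - exp(-lambda))`` - the presence probability times the
truncated-Poisson conditional mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .gam import (FittedGam, Term, ZTPoisson, fit_gam, ztp_mean)
from .env_layers import ROCK_CODE

CONTINUOUS_COVARIATES = ("depth", "slope", "aspect", "prox_shore",
                         "temperature", "salinity", "lon")


# ---------------------------------------------------------------------------
# Collinearity screen
# ---------------------------------------------------------------------------

def vif_screen(table: pd.DataFrame, covariates=CONTINUOUS_COVARIATES,
               threshold: float = 3.0):
    """Iteratively drop the covariate with the largest VIF above threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing covariate j on the others.
    Returns ``(retained, report)`` with the per-round VIF table.
    """
    retained = [c for c in covariates if c in table.columns]
    if len(retained) < 2:
        return retained, pd.DataFrame(columns=["round", "covariate", "vif"])
    rows = []
    rnd = 0
    while True:
        rnd += 1
        vifs = {}
        for c in retained:
            yv = table[c].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(table))]
                                + [table[o].to_numpy(dtype=float)
                                   for o in retained if o != c])
            beta, res, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
            sst = np.sum((yv - yv.mean()) ** 2)
            sse = np.sum((yv - X @ beta) ** 2)
            if sst <= 0 or sse / sst < 1e-12:
                vifs[c] = np.inf          # exact collinearity
            else:
                vifs[c] = 1.0 / (sse / sst)
        for c, v in vifs.items():
            rows.append({"round": rnd, "covariate": c, "vif": v})
        worst = max(vifs, key=lambda c: vifs[c])
        if vifs[worst] > threshold and len(retained) > 1:
            if np.isinf(vifs[worst]):
                warnings.warn(f"exact collinearity: dropping {worst}")
            retained = [c for c in retained if c != worst]
        else:
            break
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Zero-truncated Poisson log-likelihood (exposed for tests/oracles)
# ---------------------------------------------------------------------------

def ztp_loglik(counts, lam) -> float:
    """Sum of zero-truncated Poisson log pmf terms.

    ``sum(y log lam - lam - log(y!) - log(1 - exp(-lam)))``; counts must be
    integers >= 1 (zeros belong to the presence component).
    """
    y = np.asarray(counts, dtype=float)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), y.shape)
    if np.any(y < 1) or np.any(y != np.round(y)):
        raise ValueError("ZTP counts must be integers >= 1")
    if np.any(lam <= 0):
        raise ValueError("lambda must be positive")
    return float(np.sum(y * np.log(lam) - lam - special.gammaln(y + 1)
                        - np.log(-np.expm1(-lam))))


def sample_ztp(rng: np.random.Generator, lam, size=None) -> np.ndarray:
    """Draw zero-truncated Poisson variates by redrawing zeros."""
    lam = np.asarray(lam, dtype=float)
    if size is not None:
        lam = np.broadcast_to(lam, (int(size),))
    else:
        lam = np.atleast_1d(lam)
    out = rng.poisson(lam)
    todo = out == 0
    while todo.any():
        out[todo] = rng.poisson(lam[todo])
        todo = out == 0
    return out


# ---------------------------------------------------------------------------
# Component fitters
# ---------------------------------------------------------------------------

def fit_presence_gam(table: pd.DataFrame, present, terms: list[Term],
                     **kwargs) -> FittedGam:
    """Binomial (logit) presence-absence component."""
    y = np.asarray(present, dtype=float)
    if y.min() == y.max():
        raise ValueError("presence component needs both classes")
    return fit_gam(table, y, terms, family="binomial", **kwargs)


def fit_ztp_gam(table: pd.DataFrame, counts, terms: list[Term],
                **kwargs) -> FittedGam:
    """Zero-truncated Poisson (log) abundance component on positive hauls."""
    y = np.asarray(counts, dtype=float)
    if np.any(y < 1):
        raise ValueError("count component requires counts >= 1")
    return fit_gam(table, y, terms, family="ztp", **kwargs)


_FITTERS = {"binomial": fit_presence_gam, "ztp": fit_ztp_gam}


# ---------------------------------------------------------------------------
# Stepwise selection and term importance
# ---------------------------------------------------------------------------

def stepwise_aic(table: pd.DataFrame, y, candidate_terms: list[Term],
                 family: str = "binomial", keep: tuple = (),
                 verbose: bool = False, **kwargs):
    """Bidirectional stepwise term selection by AIC.

    Starts from the full candidate model; each round evaluates every
    single-term drop and every re-add of a previously dropped term, takes
    the move with the lowest AIC, and stops at a local minimum.  Ties in
    AIC go to the model with fewer terms (drops are tried first).  A failed
    fit skips that move.
    """
    fitter = _FITTERS[family]
    current = list(candidate_terms)
    dropped: list[Term] = []

    def try_fit(terms):
        try:
            return fitter(table, y, terms, **kwargs)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            return None

    best_fit = try_fit(current)
    if best_fit is None:
        raise RuntimeError("stepwise selection: full candidate model failed")
    path = [([t.label for t in current], best_fit.aic)]
    while True:
        moves = []
        for t in current:
            if t in keep:
                continue
            moves.append(("drop", t, [u for u in current if u != t]))
        for t in dropped:
            moves.append(("add", t, current + [t]))
        best_move = None
        for kind, t, terms in moves:
            fit = try_fit(terms)
            if fit is None:
                continue
            if best_move is None or fit.aic < best_move[3].aic - 1e-9:
                best_move = (kind, t, terms, fit)
        if best_move is None or best_move[3].aic >= best_fit.aic - 1e-9:
            break
        kind, t, terms, fit = best_move
        if kind == "drop":
            dropped.append(t)
        else:
            dropped.remove(t)
        current, best_fit = list(terms), fit
        path.append(([u.label for u in current], fit.aic))
        if verbose:       # pragma: no cover
            print(f"{kind} {t.label}: AIC {fit.aic:.2f}")
    return current, best_fit, path


def term_importance(fit: FittedGam, table: pd.DataFrame, y) -> pd.DataFrame:
    """Single-term-deletion importance at the selected smoothing parameter.

    For each term: refit without it (smoothing fixed), report the deviance
    increase (delta deviance), the term's edf, an approximate chi-square
    statistic and p-value - mirroring a variable-importance summary table.
    """
    fitter = _FITTERS[fit.family_name]
    rows = []
    y = np.asarray(y, dtype=float)
    for t in fit.terms:
        reduced_terms = [u for u in fit.terms if u != t]
        try:
            red = fitter(table, y, reduced_terms, fixed_lam=fit.lam,
                         ri_lambda=fit.ri_lambda)
            ddev = red.deviance - fit.deviance
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            ddev = np.nan
        edf = fit.edf_by_term[t.label]
        chi2 = max(ddev, 0.0) if np.isfinite(ddev) else np.nan
        p = float(stats.chi2.sf(chi2, max(edf, 0.5))) if np.isfinite(chi2) else np.nan
        rows.append({"term": t.label, "delta_deviance": ddev, "edf": edf,
                     "chi_square": chi2, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hurdle model container and combined prediction
# ---------------------------------------------------------------------------

@dataclass
class HurdleModel:
    """Paired presence and count components for one life stage."""

    stage: str
    presence: FittedGam
    count: FittedGam
    presence_terms: list[Term] = field(default_factory=list)
    count_terms: list[Term] = field(default_factory=list)

    def predict_combined_at(self, table: pd.DataFrame,
                            ri_population: bool = True,
                            truncated_mean: bool = True) -> np.ndarray:
        p = self.presence.predict(table, ri_population=ri_population)
        lam = np.exp(self.count.linear_predictor(table,
                                                 ri_population=ri_population))
        cond = ztp_mean(lam) if truncated_mean else lam
        return p * cond


@dataclass
class PredictionGrid:
    """Cellwise presence probability, Poisson rate and combined CPUE."""

    stage: str
    year: int
    p: "np.ndarray"
    lam: "np.ndarray"
    combined: "np.ndarray"
    template: object                      # GridLayer carrying the geometry

    def layers(self):
        return {f"p_{self.stage}_{self.year}": self.template.like(self.p, "p"),
                f"lam_{self.stage}_{self.year}": self.template.like(self.lam, "lam"),
                f"cpue_{self.stage}_{self.year}":
                    self.template.like(self.combined, "combined")}


def grid_covariate_table(env, year: int, season: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate rows for every modellable grid cell (sea, non-Rock, data).

    Returns the table plus the flat boolean mask of included cells.
    """
    template = env.layers["depth"]
    shape = template.shape
    cols = {}
    for name in ("depth", "slope", "aspect", "prox_shore", "sediment"):
        cols[name] = env.layers[name].values.ravel()
    tl = env.layers.get(("temperature", year, season))
    sl = env.layers.get(("salinity", year, season))
    cols["temperature"] = (tl.values.ravel() if tl is not None
                           else np.full(shape[0] * shape[1], np.nan))
    cols["salinity"] = (sl.values.ravel() if sl is not None
                        else np.full(shape[0] * shape[1], np.nan))
    glon, glat = np.meshgrid(template.lon_centers(), template.lat_centers())
    cols["lon"] = glon.ravel()
    cols["lat"] = glat.ravel()
    df = pd.DataFrame(cols)
    needed = ["depth", "slope", "aspect", "prox_shore", "sediment",
              "temperature"]
    mask = np.all(np.isfinite(df[needed].to_numpy()), axis=1)
    mask &= df["sediment"].to_numpy() != ROCK_CODE
    df = df[mask].copy()
    df["sediment"] = df["sediment"].astype(int)
    return df.reset_index(drop=True), mask


def predict_combined(model: HurdleModel, env, year: int, season: str,
                     ri_population: bool = True,
                     truncated_mean: bool = True) -> PredictionGrid:
    """Predict the hurdle model over the environment grid for one year.

    The random intercept is set to the population level (zero) for mapping
    unless ``ri_population=False`` (then cells would need a survey column).
    Combined CPUE is ``p * lambda / (1 - exp(-lambda))`` by default.
    """
    template = env.layers["depth"]
    table, mask = grid_covariate_table(env, year, season)
    p = np.full(mask.shape, np.nan)
    lam = np.full(mask.shape, np.nan)
    comb = np.full(mask.shape, np.nan)
    if len(table):
        p[mask] = model.presence.predict(table, ri_population=ri_population)
        lam[mask] = np.exp(model.count.linear_predictor(
            table, ri_population=ri_population))
        cond = ztp_mean(lam[mask]) if truncated_mean else lam[mask]
        comb[mask] = p[mask] * cond
    shape = template.shape
    return PredictionGrid(model.stage, year, p.reshape(shape),
                          lam.reshape(shape), comb.reshape(shape), template)
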