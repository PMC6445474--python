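"""A compact penalized-regression-spline GAM engine.

Supports the model vocabulary needed for hurdle distribution models:

* ``s(x)``      - 1-d penalized cubic regression spline (P-spline: cubic
  B-spline basis with a second-order difference penalty),
* ``cyclic(x)`` - periodic P-spline (default period 360 deg, for aspect),
* ``te(x, z)``  - tensor-product smooth of two covariates,
* ``factor(x)`` - unpenalized dummy-coded categorical effect,
* ``lin(x)``    - unpenalized linear effect,
* ``ri(x)``     - ridge-penalized random intercept (categorical).

Smooths carry sum-to-zero constraints (absorbed by null-space projection)
so the model intercept is identifiable.  Fitting is penalized IRLS; a
single global smoothing parameter multiplies each term's Frobenius-
normalized penalty and is chosen on a grid by a GCV criterion
``n * deviance / (n - edf)^2``.  Families: binomial (logit) and the
zero-truncated Poisson (log link) used for hurdle count components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, special

ETA_MAX = 30.0
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.geomspace(1e-3, 1e4, 15))


# ---------------------------------------------------------------------------
# Term specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    kind: str                      # 's' | 'cyclic' | 'te' | 'factor' | 'lin' | 'ri'
    vars: tuple[str, ...]
    k: tuple[int, ...] = ()
    period: float = 360.0

    @property
    def label(self) -> str:
        inner = ",".join(self.vars)
        return f"{self.kind}({inner})"

    def __str__(self) -> str:           # pragma: no cover - repr sugar
        return self.label


def s(var: str, k: int = 10) -> Term:
    return Term("s", (var,), (k,))


def cyclic(var: str, k: int = 8, period: float = 360.0) -> Term:
    return Term("cyclic", (var,), (k,), period)


def te(var1: str, var2: str, k: tuple[int, int] = (5, 5)) -> Term:
    return Term("te", (var1, var2), tuple(k))


def factor(var: str) -> Term:
    return Term("factor", (var,))


def lin(var: str) -> Term:
    return Term("lin", (var,))


def ri(var: str) -> Term:
    return Term("ri", (var,))


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

def _bspline_basis(x01: np.ndarray, k: int) -> np.ndarray:
    """Cubic B-spline basis with k functions on [0, 1]; x clipped inside."""
    if k < 4:
        raise ValueError("need k >= 4 for a cubic basis")
    interior = np.linspace(0.0, 1.0, k - 2)[1:-1]
    t = np.concatenate([np.zeros(4), interior, np.ones(4)])
    x = np.clip(x01, 0.0, 1.0)
    return interpolate.BSpline.design_matrix(x, t, 3).toarray()


def _cyclic_basis(x: np.ndarray, k: int, period: float) -> np.ndarray:
    """Periodic cubic B-spline basis with k functions (wrapped columns)."""
    h = period / k
    t = np.arange(-3, k + 4) * h
    xm = np.mod(x, period)
    B = interpolate.BSpline.design_matrix(xm, t, 3).toarray()
    C = np.zeros((len(xm), k))
    for j in range(B.shape[1]):
        C[:, j % k] += B[:, j]
    return C


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _cyclic_penalty(k: int) -> np.ndarray:
    D = np.zeros((k, k))
    for i in range(k):
        D[i, i] += 1.0
        D[i, (i + 1) % k] += -2.0
        D[i, (i + 2) % k] += 1.0
    return D.T @ D


def _null_projector(c: np.ndarray) -> np.ndarray:
    """Basis Z of the null space of the row vector c (for sum-to-zero)."""
    return linalg.null_space(c[None, :])


# ---------------------------------------------------------------------------
# Per-term builders (fitted on training data, reusable at prediction)
# ---------------------------------------------------------------------------

class _Builder:
    penalized = False
    is_ri = False

    def transform(self, df: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _SmoothBuilder(_Builder):
    penalized = True

    def __init__(self, term: Term, df: pd.DataFrame):
        self.term = term
        x = df[term.vars[0]].to_numpy(dtype=float)
        self.lo, self.hi = float(np.min(x)), float(np.max(x))
        if self.hi <= self.lo:
            self.hi = self.lo + 1.0
        k = term.k[0]
        B = self._raw(x)
        self.Z = _null_projector(B.mean(axis=0))
        S = self.Z.T @ _diff_penalty(k) @ self.Z
        self.S = S / np.linalg.norm(S)
        self.ncol = self.Z.shape[1]

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x01 = (x - self.lo) / (self.hi - self.lo)
        return _bspline_basis(x01, self.term.k[0])

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        return self._raw(df[self.term.vars[0]].to_numpy(dtype=float)) @ self.Z


class _CyclicBuilder(_Builder):
    penalized = True

    def __init__(self, term: Term, df: pd.DataFrame):
        self.term = term
        x = df[term.vars[0]].to_numpy(dtype=float)
        B = _cyclic_basis(x, term.k[0], term.period)
        self.Z = _null_projector(B.mean(axis=0))
        S = self.Z.T @ _cyclic_penalty(term.k[0]) @ self.Z
        self.S = S / np.linalg.norm(S)
        self.ncol = self.Z.shape[1]

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.term.vars[0]].to_numpy(dtype=float)
        return _cyclic_basis(x, self.term.k[0], self.term.period) @ self.Z


class _TensorBuilder(_Builder):
    penalized = True

    def __init__(self, term: Term, df: pd.DataFrame):
        self.term = term
        self.ranges = []
        for v in term.vars:
            x = df[v].to_numpy(dtype=float)
            lo, hi = float(np.min(x)), float(np.max(x))
            self.ranges.append((lo, hi if hi > lo else lo + 1.0))
        B = self._raw(df)
        self.Z = _null_projector(B.mean(axis=0))
        k1, k2 = term.k
        S_raw = (np.kron(_diff_penalty(k1), np.eye(k2))
                 + np.kron(np.eye(k1), _diff_penalty(k2)))
        S = self.Z.T @ S_raw @ self.Z
        self.S = S / np.linalg.norm(S)
        self.ncol = self.Z.shape[1]

    def _raw(self, df: pd.DataFrame) -> np.ndarray:
        mats = []
        for v, (lo, hi), k in zip(self.term.vars, self.ranges, self.term.k):
            x01 = (df[v].to_numpy(dtype=float) - lo) / (hi - lo)
            mats.append(_bspline_basis(x01, k))
        return np.einsum("ij,ik->ijk", mats[0], mats[1]).reshape(len(df), -1)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        return self._raw(df) @ self.Z


class _FactorBuilder(_Builder):
    def __init__(self, term: Term, df: pd.DataFrame):
        self.term = term
        self.levels = sorted(pd.unique(df[term.vars[0]]).tolist())
        self.ncol = len(self.levels) - 1

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.term.vars[0]]
        unseen = set(pd.unique(x)) - set(self.levels)
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(map(str, unseen))} "
                             f"for {self.term.label}")
        out = np.zeros((len(df), self.ncol))
        for j, lev in enumerate(self.levels[1:]):
            out[:, j] = (x == lev).to_numpy(dtype=float)
        return out


class _LinearBuilder(_Builder):
    def __init__(self, term: Term, df: pd.DataFrame):
        self.term = term
        self.center = float(df[term.vars[0]].mean())
        self.ncol = 1

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.term.vars[0]].to_numpy(dtype=float)
        return (x - self.center)[:, None]


class _RandomInterceptBuilder(_Builder):
    penalized = True
    is_ri = True

    def __init__(self, term: Term, df: pd.DataFrame):
        self.term = term
        self.levels = sorted(pd.unique(df[term.vars[0]]).tolist())
        self.ncol = len(self.levels)
        self.S = np.eye(self.ncol)

    def transform(self, df: pd.DataFrame, population: bool = False) -> np.ndarray:
        if population:
            return np.zeros((len(df), self.ncol))
        x = df[self.term.vars[0]]
        unseen = set(pd.unique(x)) - set(self.levels)
        if unseen:
            raise ValueError(f"unseen level(s) {sorted(map(str, unseen))} "
                             f"for {self.term.label}")
        out = np.zeros((len(df), self.ncol))
        for j, lev in enumerate(self.levels):
            out[:, j] = (x == lev).to_numpy(dtype=float)
        return out


_BUILDERS = {"s": _SmoothBuilder, "cyclic": _CyclicBuilder, "te": _TensorBuilder,
             "factor": _FactorBuilder, "lin": _LinearBuilder,
             "ri": _RandomInterceptBuilder}


class GamDesign:
    """Full model design: intercept + one block per term."""

    def __init__(self, terms: list[Term], df: pd.DataFrame):
        self.terms = list(terms)
        self.builders = [_BUILDERS[t.kind](t, df) for t in self.terms]
        self.slices: list[slice] = []
        start = 1                                    # column 0 = intercept
        for b in self.builders:
            self.slices.append(slice(start, start + b.ncol))
            start += b.ncol
        self.ncol = start

    def build(self, df: pd.DataFrame, ri_population: bool = False) -> np.ndarray:
        X = np.zeros((len(df), self.ncol))
        X[:, 0] = 1.0
        for b, sl in zip(self.builders, self.slices):
            if b.is_ri:
                X[:, sl] = b.transform(df, population=ri_population)
            else:
                X[:, sl] = b.transform(df)
        return X

    def penalty(self, lam: float, ri_lambda: float) -> np.ndarray:
        P = np.zeros((self.ncol, self.ncol))
        for b, sl in zip(self.builders, self.slices):
            if b.is_ri:
                P[sl, sl] = ri_lambda * b.S
            elif b.penalized:
                P[sl, sl] = lam * b.S
        # tiny ridge on non-intercept columns guards rank deficiencies
        idx = np.arange(1, self.ncol)
        P[idx, idx] += 1e-9
        return P


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

class Binomial:
    name = "binomial"

    @staticmethod
    def init_eta(y: np.ndarray) -> np.ndarray:
        p = np.clip((y + 0.5) / 2.0, 0.05, 0.95)
        return np.log(p / (1 - p))

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return special.expit(eta)

    @staticmethod
    def working(y: np.ndarray, eta: np.ndarray):
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-8, None)
        z = eta + (y - mu) / w
        return w, z

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray) -> float:
        mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    @classmethod
    def deviance(cls, y: np.ndarray, eta: np.ndarray) -> float:
        return -2.0 * cls.loglik(y, eta)        # saturated loglik = 0 for 0/1 y


def ztp_mean(lam: np.ndarray) -> np.ndarray:
    """Mean of the zero-truncated Poisson, lambda / (1 - exp(-lambda))."""
    lam = np.asarray(lam, dtype=float)
    return lam / (-np.expm1(-np.clip(lam, 1e-12, None)))


def _ztp_lambda_for_mean(m: float) -> float:
    """Invert the truncated mean: solve lambda/(1-e^-lambda) = m (m > 1)."""
    if m <= 1.0 + 1e-12:
        return 0.0
    return float(optimize.brentq(lambda l: ztp_mean(l) - m, 1e-10, m, xtol=1e-12))


class ZTPoisson:
    name = "ztp"

    @staticmethod
    def init_eta(y: np.ndarray) -> np.ndarray:
        return np.log(np.clip(y - 0.5, 0.5, None))

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return ztp_mean(np.exp(np.clip(eta, -ETA_MAX, ETA_MAX)))

    @staticmethod
    def working(y: np.ndarray, eta: np.ndarray):
        lam = np.exp(np.clip(eta, -ETA_MAX, ETA_MAX))
        mu = ztp_mean(lam)
        w = np.clip(mu * (1 + lam - mu), 1e-8, None)   # Var(Y) for ZTP
        z = eta + (y - mu) / w
        return w, z

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray) -> float:
        eta = np.clip(eta, -ETA_MAX, ETA_MAX)
        lam = np.exp(eta)
        norm = np.log(-np.expm1(-lam))
        return float(np.sum(y * eta - lam - special.gammaln(y + 1) - norm))

    @classmethod
    def saturated_loglik(cls, y: np.ndarray) -> float:
        total = 0.0
        for yi, cnt in zip(*np.unique(y, return_counts=True)):
            if yi <= 1:
                continue                      # limit lambda -> 0 gives 0
            lam = _ztp_lambda_for_mean(float(yi))
            total += cnt * cls.loglik(np.array([yi]), np.array([np.log(lam)]))
        return total

    @classmethod
    def deviance(cls, y: np.ndarray, eta: np.ndarray) -> float:
        return 2.0 * (cls.saturated_loglik(y) - cls.loglik(y, eta))


FAMILIES = {"binomial": Binomial, "ztp": ZTPoisson}


# ---------------------------------------------------------------------------
# Penalized IRLS and smoothing selection
# ---------------------------------------------------------------------------

def _pirls(X: np.ndarray, y: np.ndarray, P: np.ndarray, family,
           max_iter: int = 100, tol: float = 1e-9):
    eta = np.clip(family.init_eta(y), -ETA_MAX, ETA_MAX)
    dev = family.deviance(y, eta)
    coef = None
    XtWX = None
    for _ in range(max_iter):
        w, z = family.working(y, eta)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + P
        new_coef = linalg.solve(A, Xw.T @ z, assume_a="pos")
        new_eta = np.clip(X @ new_coef, -ETA_MAX, ETA_MAX)
        new_dev = family.deviance(y, new_eta)
        # step halving if the penalized objective worsened
        if coef is not None:
            step = 1.0
            while (not np.isfinite(new_dev) or new_dev > dev + 1e-8) and step > 1e-4:
                step /= 2.0
                trial = coef + step * (new_coef - coef)
                new_eta = np.clip(X @ trial, -ETA_MAX, ETA_MAX)
                new_dev = family.deviance(y, new_eta)
                new_coef = trial
        if not np.isfinite(new_dev):
            raise RuntimeError("PIRLS diverged (non-finite deviance)")
        converged = abs(dev - new_dev) < tol * (abs(new_dev) + 0.1)
        coef, eta, dev = new_coef, new_eta, new_dev
        if converged:
            break
    else:
        raise RuntimeError("PIRLS failed to converge")
    w, _ = family.working(y, eta)
    XtWX = X.T @ (X * w[:, None])
    A = XtWX + P
    return coef, eta, dev, XtWX, A


@dataclass
class FittedGam:
    """A fitted penalized additive model (one hurdle component)."""

    design: GamDesign
    family_name: str
    coef: np.ndarray
    lam: float
    ri_lambda: float
    edf_by_term: dict[str, float]
    edf_total: float
    loglik: float
    deviance: float
    n: int
    cov: np.ndarray                       # (X'WX + P)^-1, for approximate SEs
    gcv_path: list[tuple[float, float]] = field(default_factory=list)
    smoothing_criterion: str = "GCV"

    @property
    def family(self):
        return FAMILIES[self.family_name]

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.edf_total

    @property
    def terms(self) -> list[Term]:
        return self.design.terms

    def linear_predictor(self, df: pd.DataFrame,
                         ri_population: bool = True) -> np.ndarray:
        X = self.design.build(df, ri_population=ri_population)
        return X @ self.coef

    def predict(self, df: pd.DataFrame, response: bool = True,
                ri_population: bool = True) -> np.ndarray:
        eta = self.linear_predictor(df, ri_population=ri_population)
        return self.family.mean(eta) if response else eta

    def term_effect(self, df: pd.DataFrame, label: str) -> np.ndarray:
        """Partial (centred) contribution of one term to the linear predictor."""
        for t, b, sl in zip(self.design.terms, self.design.builders,
                            self.design.slices):
            if t.label == label:
                Xb = (b.transform(df, population=False) if b.is_ri
                      else b.transform(df))
                return Xb @ self.coef[sl]
        raise KeyError(label)

    def ri_estimates(self) -> dict:
        """Estimated random-intercept values and SEs per level."""
        for t, b, sl in zip(self.design.terms, self.design.builders,
                            self.design.slices):
            if b.is_ri:
                se = np.sqrt(np.diag(self.cov)[sl])
                return {lev: (float(c), float(s))
                        for lev, c, s in zip(b.levels, self.coef[sl], se)}
        raise KeyError("model has no random intercept term")


def _edf(A: np.ndarray, XtWX: np.ndarray, design: GamDesign):
    F = linalg.solve(A, XtWX, assume_a="pos")
    d = np.diag(F)
    by_term = {t.label: float(d[sl].sum())
               for t, sl in zip(design.terms, design.slices)}
    return by_term, float(d.sum())


def fit_gam(df: pd.DataFrame, y: np.ndarray, terms: list[Term],
            family: str = "binomial",
            lam_grid=DEFAULT_LAMBDA_GRID, fixed_lam: float | None = None,
            ri_lambda: float = 1.0) -> FittedGam:
    """Fit a penalized additive model.

    A single global smoothing parameter scales every smooth term's
    normalized penalty; it is chosen on ``lam_grid`` by GCV unless
    ``fixed_lam`` is given (used for fixed-smoothing refits such as
    term-deletion importance).  The random intercept carries its own fixed
    mild ridge ``ri_lambda``.
    """
    fam = FAMILIES[family]
    y = np.asarray(y, dtype=float)
    design = GamDesign(terms, df)
    X = design.build(df)
    n = len(df)

    has_smooth = any(b.penalized and not b.is_ri for b in design.builders)
    if fixed_lam is not None or not has_smooth:
        lams = [fixed_lam if fixed_lam is not None else 1.0]
    else:
        lams = list(lam_grid)

    path = []
    best = None
    for lam in lams:
        P = design.penalty(lam, ri_lambda)
        try:
            coef, eta, dev, XtWX, A = _pirls(X, y, P, fam)
        except (RuntimeError, linalg.LinAlgError, np.linalg.LinAlgError):
            continue
        edf_by_term, edf_total = _edf(A, XtWX, design)
        gcv = n * dev / max(n - edf_total, 1.0) ** 2
        path.append((float(lam), float(gcv)))
        if best is None or gcv < best[0] - 1e-12:
            best = (gcv, lam, coef, eta, dev, A, XtWX, edf_by_term, edf_total)
    if best is None:
        raise RuntimeError("GAM fit failed on every smoothing parameter")
    _, lam, coef, eta, dev, A, XtWX, edf_by_term, edf_total = best
    cov = linalg.inv(A)
    return FittedGam(design, family, coef, float(lam), ri_lambda, edf_by_term,
                     edf_total, fam.loglik(y, eta), dev, n, cov, path)
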