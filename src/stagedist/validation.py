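"""Cross-validation and performance metrics for the hurdle models.

Follows the evaluation protocol of randomized 7:3 train/test splits at the
haul level, stratified so presence/absence classes keep their proportions,
with ROC AUC for the presence component and Spearman rank correlation for
the count and combined predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import ztp_mean
from .hurdle import fit_presence_gam, fit_ztp_gam


def stratified_split(presence: pd.Series, train_fraction: float = 0.7,
                     rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Haul-level split keeping each presence class near the 7:3 target.

    ``presence`` is indexed by haul id.  Per-class train counts use
    largest-remainder rounding so the total equals round(f * n) and each
    class is within one haul of its own target.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    ids = presence.index.to_numpy()
    flags = presence.to_numpy().astype(bool)
    if len(ids) < 10:
        raise ValueError("need at least 10 hauls to split")
    classes = [ids[flags], ids[~flags]]
    if min(len(c) for c in classes) < 2:
        raise ValueError("each presence class needs at least 2 hauls")
    n_train_total = int(round(train_fraction * len(ids)))
    base = [int(np.floor(train_fraction * len(c))) for c in classes]
    frac = [train_fraction * len(c) - b for c, b in zip(classes, base)]
    order = np.argsort(frac)[::-1]
    k = 0
    while sum(base) < n_train_total:
        base[order[k % 2]] += 1
        k += 1
    train = []
    for c, b in zip(classes, base):
        perm = rng.permutation(len(c))
        train.append(c[perm[:b]])
    train_ids = np.concatenate(train)
    test_ids = np.setdiff1d(ids, train_ids)
    return train_ids, test_ids


def auc_roc(labels, scores) -> float:
    """AUC = P(score+ > score-) + 0.5 P(tie), by the mid-rank formula."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class")
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def spearman_rho(predicted, observed) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) < 3:
        raise ValueError("need n >= 3 for a rank correlation")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        warnings.warn("Spearman undefined: zero variance input")
        return float("nan")
    return float(stats.spearmanr(predicted, observed).statistic)


@dataclass
class CvResult:
    """Aggregated cross-validation metrics for one stage's hurdle model."""

    stage: str
    iterations: int
    auc: np.ndarray
    rho_count: np.ndarray
    rho_combined: np.ndarray
    n_failed: int = 0
    notes: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric, vals in (("auc", self.auc),
                             ("spearman_count", self.rho_count),
                             ("spearman_combined", self.rho_combined)):
            vals = vals[np.isfinite(vals)]
            rows.append({"stage": self.stage, "metric": metric,
                         "mean": float(np.mean(vals)) if len(vals) else np.nan,
                         "sd": float(np.std(vals, ddof=1)) if len(vals) > 1
                         else np.nan,
                         "n_iterations": int(len(vals))})
        return pd.DataFrame(rows)


def cross_validate(table: pd.DataFrame, counts, presence_terms, count_terms,
                   stage: str = "", iterations: int = 100, seed: int = 0,
                   train_fraction: float = 0.7,
                   freeze_smoothing: bool = False,
                   **fit_kwargs) -> CvResult:
    """Repeated stratified splits with full refits and test-set scoring.

    Per iteration: split at haul level; refit presence (all training
    hauls) and count (positive training hauls); score the test set - AUC
    on presence, Spearman on positive-count predictions, Spearman of the
    combined prediction against observed CPUE including zeros.  Failed
    refits are logged and excluded; more than 20 percent failures aborts.
    ``freeze_smoothing`` fits the smoothing parameter once on the full data
    and reuses it in every refit.
    """
    counts = np.asarray(counts)
    presence = counts > 0
    rng = np.random.default_rng(seed)
    fixed = dict(fit_kwargs)
    if freeze_smoothing:
        full_p = fit_presence_gam(table, presence, presence_terms, **fit_kwargs)
        full_n = fit_ztp_gam(table[presence], counts[presence], count_terms,
                             **fit_kwargs)
        lam_p, lam_n = full_p.lam, full_n.lam
    aucs, rhos_n, rhos_c = [], [], []
    notes = []
    n_failed = 0
    idx = pd.Series(presence, index=pd.RangeIndex(len(table)))
    for it in range(iterations):
        train_ids, test_ids = stratified_split(idx, train_fraction, rng)
        tr = table.iloc[train_ids]
        te = table.iloc[test_ids]
        y_tr = counts[train_ids]
        y_te = counts[test_ids]
        try:
            kw_p = dict(fixed, fixed_lam=lam_p) if freeze_smoothing else fixed
            kw_n = dict(fixed, fixed_lam=lam_n) if freeze_smoothing else fixed
            pres = fit_presence_gam(tr, y_tr > 0, presence_terms, **kw_p)
            pos = y_tr > 0
            cnt = fit_ztp_gam(tr[pos], y_tr[pos], count_terms, **kw_n)
        except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            notes.append(f"iteration {it}: {exc}")
            if n_failed > 0.2 * iterations:
                raise RuntimeError(
                    f"more than 20% of CV refits failed ({n_failed})") from exc
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_hat = pres.predict(te, ri_population=False)
            aucs.append(auc_roc(y_te > 0, p_hat))
            pos_te = y_te > 0
            if pos_te.sum() >= 3:
                mu_hat = ztp_mean(np.exp(cnt.linear_predictor(
                    te[pos_te], ri_population=False)))
                rhos_n.append(spearman_rho(mu_hat, y_te[pos_te]))
            else:
                rhos_n.append(np.nan)
            comb = p_hat * ztp_mean(np.exp(cnt.linear_predictor(
                te, ri_population=False)))
            rhos_c.append(spearman_rho(comb, y_te))
    return CvResult(stage, iterations, np.asarray(aucs), np.asarray(rhos_n),
                    np.asarray(rhos_c), n_failed, notes)
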