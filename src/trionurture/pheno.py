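"""Rating-scale outcome scoring and multiple imputation.

The child outcome is an 18-item ADHD symptom rating scale scored on a
four-point scale: items 1-9 form the inattention subscale and items 10-18 the
hyperactivity-impulsivity subscale, so complete totals span 18-72.  Children
with fewer than half the items completed are excluded from complete-case
analysis; partially complete responders (9-17 items) are prorated via the
person-mean.  Missing outcomes are multiply imputed from polygenic scores and
auxiliary variables by predictive mean matching, and per-imputation fits are
pooled with Rubin's rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "N_ITEMS",
    "ITEM_COLUMNS",
    "score_items",
    "impute_outcomes",
    "pool_rubin",
    "ImputationResult",
    "PooledResult",
]

N_ITEMS = 18
ITEM_COLUMNS = tuple(f"item{i:02d}" for i in range(1, N_ITEMS + 1))
_INATTENTION = ITEM_COLUMNS[:9]
_HYPERACTIVITY = ITEM_COLUMNS[9:]


def _subscale(values: np.ndarray, min_complete: int, n_items: int, prorate: bool):
    completed = np.sum(~np.isnan(values), axis=1)
    s = np.nansum(values, axis=1)
    with np.errstate(invalid="ignore"):
        prorated = s / completed * n_items
    out = np.where(completed == n_items, s, np.nan)
    if prorate:
        partial = (completed >= min_complete) & (completed < n_items)
        out = np.where(partial, prorated, out)
    out[completed < min_complete] = np.nan
    return out, completed


def score_items(items: pd.DataFrame, prorate: bool = True) -> pd.DataFrame:
    """Score the 18-item scale into total and subscale sums.

    Returns a frame with columns ``total``, ``inattention``,
    ``hyperactivity``, ``n_completed``, ``complete`` (at least 9 of 18 items
    answered — the inclusion rule) and z-scored variants (``*_std``) computed
    over non-missing values.  With ``prorate=False``, only fully complete
    (sub)scales are scored.
    """
    missing_cols = [c for c in ITEM_COLUMNS if c not in items.columns]
    if missing_cols:
        raise ValueError(f"item table missing columns: {missing_cols}")
    vals = items[list(ITEM_COLUMNS)].to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (1.0, 2.0, 3.0, 4.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"item value {vals[r, c]} outside {{1,2,3,4}} at row {r}, "
            f"column {ITEM_COLUMNS[c]}"
        )
    total, n_completed = _subscale(vals, 9, 18, prorate)
    inatt, _ = _subscale(vals[:, :9], 5, 9, prorate)
    hyper, _ = _subscale(vals[:, 9:], 5, 9, prorate)
    out = pd.DataFrame(
        {
            "total": total,
            "inattention": inatt,
            "hyperactivity": hyper,
            "n_completed": n_completed,
            "complete": n_completed >= 9,
        },
        index=items.index,
    )
    for col in ("total", "inattention", "hyperactivity"):
        x = out[col]
        sd = x.std(ddof=0)
        out[col + "_std"] = (x - x.mean()) / sd if sd > 0 else x * 0.0
    return out


@dataclass
class ImputationResult:
    """M completed outcome vectors from predictive-mean-matching imputation."""

    completed: np.ndarray  # (M, n) — observed values untouched, missing filled
    observed_mask: np.ndarray
    M: int
    predictor_names: Optional[Sequence[str]] = None

    def __iter__(self):
        return iter(self.completed)


def impute_outcomes(
    outcome: np.ndarray,
    predictors,
    M: int = 20,
    seed: int = 0,
    donor_pool: int = 5,
) -> ImputationResult:
    """Multiply impute a partially observed outcome by predictive mean matching.

    A Bayesian linear regression of the outcome on the (complete) predictors
    is fit on observed rows; for each imputation, coefficients are drawn from
    their posterior, missing rows get predicted means, and each is filled
    with the observed outcome of one of its ``donor_pool`` nearest observed
    neighbours in predicted-mean space.  Observed values are never altered.
    Deterministic given ``seed``.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    y = np.asarray(outcome, dtype=float)
    names = None
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise ValueError("predictors must be complete")
    sds = X.std(axis=0)
    if (sds == 0).any():
        logger.warning("dropping %d zero-variance predictors", int((sds == 0).sum()))
        keep = sds > 0
        X = X[:, keep]
        if names is not None:
            names = [n for n, k in zip(names, keep) if k]
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("all outcomes missing; nothing to fit the imputation model on")
    X = np.column_stack([np.ones(len(y)), X])
    n_obs, p = int(obs.sum()), X.shape[1]
    rng = np.random.default_rng(seed)

    Xo, yo = X[obs], y[obs]
    xtx_inv = np.linalg.inv(Xo.T @ Xo)
    beta_hat = xtx_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    rss = float(resid @ resid)
    chol = np.linalg.cholesky(xtx_inv)

    yhat_obs = Xo @ beta_hat
    order = np.argsort(yhat_obs)
    yhat_obs_sorted = yhat_obs[order]
    yo_sorted = yo[order]

    completed = np.tile(y, (M, 1))
    mis_idx = np.flatnonzero(~obs)
    for imp in range(M):
        if mis_idx.size:
            sigma2 = rss / rng.chisquare(max(n_obs - p, 1))
            beta_star = beta_hat + np.sqrt(sigma2) * (chol @ rng.normal(size=p))
            yhat_mis = X[mis_idx] @ beta_star
            # candidate window of 2*donor_pool sorted neighbours, keep nearest
            pos = np.searchsorted(yhat_obs_sorted, yhat_mis)
            fills = np.empty(mis_idx.size)
            for j, (pm, po) in enumerate(zip(yhat_mis, pos)):
                lo = max(po - donor_pool, 0)
                hi = min(po + donor_pool, n_obs)
                window = yhat_obs_sorted[lo:hi]
                nearest = np.argsort(np.abs(window - pm))[:donor_pool]
                pick = nearest[rng.integers(len(nearest))]
                fills[j] = yo_sorted[lo + pick]
            completed[imp, mis_idx] = fills
    return ImputationResult(
        completed=completed, observed_mask=obs, M=M, predictor_names=names
    )


@dataclass
class PooledResult:
    """Rubin-pooled estimate with within/between decomposition."""

    estimate: np.ndarray
    within: np.ndarray
    between: np.ndarray
    variance: np.ndarray
    se: np.ndarray
    df: np.ndarray
    p: np.ndarray
    M: int


def pool_rubin(
    estimates: np.ndarray,
    ses: np.ndarray,
    df_complete: Optional[float] = None,
) -> PooledResult:
    """Pool M per-imputation fits of the same coefficient(s) by Rubin's rules.

    estimate = mean; variance = within-mean + (1 + 1/M) * between (ddof=1);
    degrees of freedom follow Barnard-Rubin when ``df_complete`` is given,
    otherwise the classical large-sample formula; p is two-sided from the t
    reference.
    """
    estimates = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    squeeze = estimates.ndim == 1
    if squeeze:
        estimates, ses = estimates[:, None], ses[:, None]
    if estimates.shape != ses.shape:
        raise ValueError("estimates and ses must have matching shapes (M, k)")
    M = estimates.shape[0]
    if M < 2:
        raise ValueError("need at least two imputations to pool")
    qbar = estimates.mean(axis=0)
    within = (ses**2).mean(axis=0)
    between = estimates.var(axis=0, ddof=1)
    total = within + (1 + 1 / M) * between
    se = np.sqrt(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / M) * between / within
        df_old = (M - 1) * (1 + 1 / r) ** 2
    df_old = np.where(between == 0, np.inf, df_old)
    if df_complete is not None:
        lam = (1 + 1 / M) * between / total
        df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    else:
        df = df_old
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = qbar / se
    p = np.where(
        np.isinf(df),
        2 * stats.norm.sf(np.abs(tstat)),
        2 * stats.t.sf(np.abs(tstat), np.where(np.isinf(df), 1, df)),
    )
    def _sq(x):
        return float(x[0]) if squeeze else x

    return PooledResult(
        estimate=_sq(qbar),
        within=_sq(within),
        between=_sq(between),
        variance=_sq(total),
        se=_sq(se),
        df=_sq(df),
        p=_sq(p),
        M=M,
    )
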