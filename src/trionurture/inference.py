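"""Within-family trio regressions separating genetic transmission from nurture.

The child's standardized trait is regressed on polygenic scores:

* unadjusted model — one family member's score at a time (plus child sex and
  birth year), estimating the marginal association;
* trio model — child, mother and father scores jointly; the child coefficient
  estimates the direct genetic effect (path ``c``) and the parental
  coefficients estimate genetic nurture (paths ``m``, ``f``);
* across-factor model — trio predictors for several parental factors jointly,
  to check that between-score correlations do not drive estimates.

Attenuation of a parental coefficient between the unadjusted and trio models
is evidence of genetic transmission; it is tested with a paired bootstrap (or
an analytic stacked-sandwich covariance) over the identical row set.
Discovery flags use Benjamini-Hochberg FDR, and the pattern of significance
and attenuation is classified into a transmission/nurture mechanism label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import pheno

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "FitResult",
    "DeltaBetaResult",
    "make_trio_frame",
    "frame_from_cohort",
    "fit_unadjusted",
    "fit_trio",
    "fit_trio_pooled",
    "fit_across_factors",
    "delta_beta",
    "bh_fdr",
    "classify_mechanism",
]

ROLES = ("child", "mother", "father")
DEFAULT_COVARIATES = ("sex", "birth_year")


@dataclass
class FitResult:
    """One regression coefficient with normal-reference inference."""

    model: str  # "unadjusted" | "trio" | "across-factor"
    factor: str
    role: str
    beta: float
    se: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    p: float = field(default=np.nan)
    n: int = 0
    covariates: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - 1.96 * self.se
            self.ci_high = self.beta + 1.96 * self.se
        if np.isnan(self.p):
            self.p = float(2 * stats.norm.sf(abs(self.beta / self.se)))


@dataclass
class DeltaBetaResult:
    """Attenuation of a coefficient between the unadjusted and trio models."""

    factor: str
    role: str
    beta_unadjusted: float
    beta_adjusted: float
    delta: float
    se_delta: float
    p_delta: float
    ci_low: float
    ci_high: float
    method: str
    p_resample: Optional[float] = None
    n: int = 0


def score_col(factor: str, role: str) -> str:
    return f"{factor}_{role}"


def make_trio_frame(
    outcome: np.ndarray,
    scores: Dict[str, Dict[str, np.ndarray]],
    sex: np.ndarray,
    birth_year: np.ndarray,
    trio_id: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Assemble the analysis frame: one row per trio, scores per factor/role."""
    n = len(outcome)
    data = {"outcome": np.asarray(outcome, dtype=float)}
    for factor, by_role in scores.items():
        for role in ROLES:
            data[score_col(factor, role)] = np.asarray(by_role[role], dtype=float)
    data["sex"] = np.asarray(sex, dtype=float)
    data["birth_year"] = np.asarray(birth_year, dtype=float)
    frame = pd.DataFrame(data)
    if trio_id is not None:
        if pd.Index(trio_id).duplicated().any():
            raise ValueError("duplicated trio ids")
        frame.insert(0, "trio_id", trio_id)
    return frame


def frame_from_cohort(
    cohort,
    factor: str = "score",
    scores: Optional[Dict[str, np.ndarray]] = None,
    complete_case: bool = False,
) -> pd.DataFrame:
    """Analysis frame from a simulated cohort.

    By default uses the generative true scores ("perfect scores"); pass
    ``scores`` (role -> vector) to analyse computed polygenic scores instead.
    With ``complete_case=True``, trios with a masked phenotype get a missing
    outcome.
    """
    if scores is None:
        scores = {r: cohort.true_scores(r) for r in ROLES}
    outcome = np.asarray(cohort.phenotype, dtype=float).copy()
    if complete_case and cohort.observed_mask is not None:
        outcome[~cohort.observed_mask] = np.nan
    return make_trio_frame(
        outcome=outcome,
        scores={factor: scores},
        sex=cohort.sex,
        birth_year=cohort.birth_year,
        trio_id=cohort.trio_id,
    )


def _design(frame: pd.DataFrame, predictors: Sequence[str], covariates: Sequence[str]):
    cols = list(predictors) + [c for c in covariates if c in frame.columns]
    sub = frame[["outcome"] + cols].dropna()
    y = sub["outcome"].to_numpy()
    X = sm.add_constant(sub[cols].to_numpy(), has_constant="add")
    return y, X, cols, sub.index


def _ols_fit(y: np.ndarray, X: np.ndarray, robust: bool = True):
    """OLS coefficients and (HC1 or classical) standard errors."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} rows cannot identify {p} parameters")
    model = sm.OLS(y, X)
    res = model.fit(cov_type="HC1" if robust else "nonrobust", use_t=False)
    return res.params, res.bse


def fit_unadjusted(
    frame: pd.DataFrame,
    factor: str,
    role: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    robust: bool = True,
) -> FitResult:
    """Regress the outcome on a single family member's score plus covariates."""
    col = score_col(factor, role)
    y, X, cols, _ = _design(frame, [col], covariates)
    if np.std(X[:, 1]) == 0:
        raise ValueError(f"score column {col} is constant (degenerate input)")
    beta, se = _ols_fit(y, X, robust)
    return FitResult(
        model="unadjusted",
        factor=factor,
        role=role,
        beta=float(beta[1]),
        se=float(se[1]),
        n=len(y),
        covariates=tuple(cols[1:]),
    )


def _check_rank(frame: pd.DataFrame, cols: Sequence[str]) -> None:
    sub = frame[list(cols)].dropna()
    corr = np.corrcoef(sub.to_numpy().T)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) > 0.9999:
                raise ValueError(
                    f"rank deficiency: scores {cols[i]} and {cols[j]} are collinear"
                )


def fit_trio(
    frame: pd.DataFrame,
    factor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    robust: bool = True,
) -> Dict[str, FitResult]:
    """Joint regression on child, mother and father scores for one factor.

    The child coefficient estimates the direct genetic effect (path c); the
    maternal and paternal coefficients estimate the nurture paths m and f.
    """
    cols = [score_col(factor, r) for r in ROLES]
    _check_rank(frame, cols)
    y, X, used, _ = _design(frame, cols, covariates)
    beta, se = _ols_fit(y, X, robust)
    return {
        role: FitResult(
            model="trio",
            factor=factor,
            role=role,
            beta=float(beta[1 + i]),
            se=float(se[1 + i]),
            n=len(y),
            covariates=tuple(used[3:]),
        )
        for i, role in enumerate(ROLES)
    }


def fit_trio_pooled(
    frame: pd.DataFrame,
    completed_outcomes: np.ndarray,
    factor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    robust: bool = True,
) -> Dict[str, FitResult]:
    """Trio model over M multiply-imputed outcomes, pooled by Rubin's rules."""
    completed_outcomes = np.atleast_2d(completed_outcomes)
    M = completed_outcomes.shape[0]
    if M == 1:
        fm = frame.copy()
        fm["outcome"] = completed_outcomes[0]
        return fit_trio(fm, factor, covariates, robust)
    betas = {r: [] for r in ROLES}
    ses = {r: [] for r in ROLES}
    n = 0
    for m in range(M):
        fm = frame.copy()
        fm["outcome"] = completed_outcomes[m]
        fits = fit_trio(fm, factor, covariates, robust)
        n = fits["child"].n
        for r in ROLES:
            betas[r].append(fits[r].beta)
            ses[r].append(fits[r].se)
    out = {}
    df_com = n - (3 + len(covariates) + 1)
    for r in ROLES:
        pooled = pheno.pool_rubin(np.array(betas[r]), np.array(ses[r]), df_complete=df_com)
        out[r] = FitResult(
            model="trio",
            factor=factor,
            role=r,
            beta=float(pooled.estimate),
            se=float(pooled.se),
            p=float(pooled.p),
            n=n,
            covariates=tuple(covariates),
        )
    return out


def fit_across_factors(
    frame: pd.DataFrame,
    factors: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    robust: bool = True,
) -> Dict[Tuple[str, str], FitResult]:
    """One joint regression with trio predictors for every listed factor."""
    if len(factors) < 2:
        raise ValueError("across-factor model needs at least two factors")
    cols = [score_col(fa, r) for fa in factors for r in ROLES]
    sub = frame[cols].dropna()
    corr = np.corrcoef(sub.to_numpy().T)
    hi = np.argwhere(np.triu(np.abs(corr), 1) > 0.8)
    for i, j in hi:
        logger.warning(
            "cross-score correlation %.2f between %s and %s",
            corr[i, j],
            cols[i],
            cols[j],
        )
    _check_rank(frame, cols)
    y, X, used, _ = _design(frame, cols, covariates)
    beta, se = _ols_fit(y, X, robust)
    out = {}
    k = 0
    for fa in factors:
        for role in ROLES:
            out[(fa, role)] = FitResult(
                model="across-factor",
                factor=fa,
                role=role,
                beta=float(beta[1 + k]),
                se=float(se[1 + k]),
                n=len(y),
                covariates=tuple(used[len(cols):]),
            )
            k += 1
    return out


def _beta_solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def delta_beta(
    frame: pd.DataFrame,
    factor: str,
    role: str,
    method: str = "bootstrap",
    B: int = 1000,
    seed: int = 0,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> DeltaBetaResult:
    """Test whether a coefficient attenuates between unadjusted and trio models.

    Both models are fit on the identical row set.  ``method='bootstrap'``
    resamples trios with replacement, refits both models per resample and
    reads a normal-approximation p from the bootstrap distribution of the
    difference (a resampling p with the (1 + k)/(B + 1) convention is also
    reported).  ``method='analytic'`` uses the stacked-sandwich covariance of
    the two coefficient estimators.
    """
    trio_cols = [score_col(factor, r) for r in ROLES]
    cov_cols = [c for c in covariates if c in frame.columns]
    sub = frame[["outcome"] + trio_cols + cov_cols].dropna()
    y = sub["outcome"].to_numpy()
    n = len(y)
    Z = sub[cov_cols].to_numpy() if cov_cols else np.empty((n, 0))
    ones = np.ones((n, 1))
    s_role = sub[score_col(factor, role)].to_numpy()[:, None]
    S3 = sub[trio_cols].to_numpy()
    X1 = np.hstack([ones, s_role, Z])  # unadjusted
    X2 = np.hstack([ones, S3, Z])  # trio
    j1 = 1
    j2 = 1 + ROLES.index(role)
    b1 = _beta_solve(X1, y)
    b2 = _beta_solve(X2, y)
    beta_un, beta_adj = float(b1[j1]), float(b2[j2])
    delta = beta_un - beta_adj

    if method == "bootstrap":
        if B < 100:
            raise ValueError("bootstrap requires B >= 100")
        rng = np.random.default_rng(seed)
        deltas = np.empty(B)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            d1 = _beta_solve(X1[idx], yb)[j1]
            d2 = _beta_solve(X2[idx], yb)[j2]
            deltas[b] = d1 - d2
        se_delta = float(deltas.std(ddof=1))
        p_norm = float(2 * stats.norm.sf(abs(delta) / se_delta)) if se_delta > 0 else 1.0
        centred = np.abs(deltas - deltas.mean())
        p_res = float((1 + np.sum(centred >= abs(delta))) / (B + 1))
        ci_low, ci_high = np.percentile(deltas, [2.5, 97.5])
        return DeltaBetaResult(
            factor=factor,
            role=role,
            beta_unadjusted=beta_un,
            beta_adjusted=beta_adj,
            delta=delta,
            se_delta=se_delta,
            p_delta=p_norm,
            ci_low=float(ci_low),
            ci_high=float(ci_high),
            method="bootstrap",
            p_resample=p_res,
            n=n,
        )
    if method == "analytic":
        e1 = y - X1 @ b1
        e2 = y - X2 @ b2
        A1 = np.linalg.inv(X1.T @ X1)
        A2 = np.linalg.inv(X2.T @ X2)
        V1 = A1 @ (X1.T * e1**2) @ X1 @ A1
        V2 = A2 @ (X2.T * e2**2) @ X2 @ A2
        C12 = A1 @ (X1.T * (e1 * e2)) @ X2 @ A2
        var_delta = V1[j1, j1] + V2[j2, j2] - 2 * C12[j1, j2]
        se_delta = float(np.sqrt(max(var_delta, 0)))
        p = float(2 * stats.norm.sf(abs(delta) / se_delta)) if se_delta > 0 else 1.0
        return DeltaBetaResult(
            factor=factor,
            role=role,
            beta_unadjusted=beta_un,
            beta_adjusted=beta_adj,
            delta=delta,
            se_delta=se_delta,
            p_delta=p,
            ci_low=delta - 1.96 * se_delta,
            ci_high=delta + 1.96 * se_delta,
            method="analytic",
            n=n,
        )
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags over one family of tests."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        raise ValueError("empty p-value family")
    if not ((pvalues > 0) & (pvalues <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


def classify_mechanism(
    unadjusted: FitResult,
    trio: FitResult,
    delta: DeltaBetaResult,
    fdr_unadjusted: bool,
    fdr_trio: bool,
    alpha_delta: float = 0.05,
) -> str:
    """Label the transmission mechanism for one parental factor/role.

    * "genetic transmission" — the marginal association is FDR-significant,
      attenuates significantly in the trio model, and the adjusted estimate
      is no longer FDR-significant;
    * "genetic nurture" — the adjusted parental estimate stays
      FDR-significant;
    * "both" — nurture plus significant attenuation;
    * "inconclusive — possible power limitation" — marginal association
      without significant attenuation or adjusted significance;
    * "no association" otherwise.
    """
    if not (unadjusted.factor == trio.factor == delta.factor):
        raise ValueError("inputs refer to different factors")
    if not (unadjusted.role == trio.role == delta.role):
        raise ValueError("inputs refer to different roles")
    attenuated = delta.p_delta < alpha_delta
    if fdr_trio and attenuated:
        return "both"
    if fdr_trio:
        return "genetic nurture"
    if fdr_unadjusted and attenuated:
        return "genetic transmission"
    if fdr_unadjusted:
        return "inconclusive — possible power limitation"
    return "no association"
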