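"""Polygenic scores from GWAS summary statistics.

A polygenic score is the weighted sum of an individual's effect-allele
dosages, with weights taken from GWAS summary statistics.  Scores are
computed at a ladder of p-value inclusion thresholds and combined into a
single composite (PRS-PC) as the first principal component of the
standardized threshold scores, which improves prediction without picking a
threshold post hoc.  Before entering family regressions, scores are
residualized on technical batch covariates and ancestry principal components
and standardized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SUMSTAT_COLUMNS",
    "DosagePanel",
    "PGSMatrix",
    "read_sumstats",
    "validate_sumstats",
    "compute_threshold_scores",
    "prs_pc",
    "compute_ancestry_pcs",
    "residualize_standardize",
]

DEFAULT_THRESHOLDS: tuple = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)

#: canonical summary-statistics column names (A1 = effect allele)
SUMSTAT_COLUMNS = ("SNP", "A1", "A2", "BETA", "SE", "P", "FRQ")

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class DosagePanel:
    """Effect-allele dosages for a set of individuals.

    ``counted_allele[v]`` names the allele whose copies ``matrix[:, v]``
    counts; scoring aligns it to each summary-statistic effect allele.
    """

    ids: np.ndarray
    variant_id: np.ndarray
    counted_allele: np.ndarray
    other_allele: np.ndarray
    matrix: np.ndarray

    @classmethod
    def from_cohort(cls, cohort, role: str) -> "DosagePanel":
        panel = cohort.panel
        suffix = {"mother": "m", "father": "f", "child": "c"}[role]
        return cls(
            ids=np.array([f"{t}_{suffix}" for t in cohort.trio_id], dtype=object),
            variant_id=panel.variant_id,
            counted_allele=panel.effect_allele,
            other_allele=panel.other_allele,
            matrix=cohort.dosages(role),
        )


@dataclass
class PGSMatrix:
    """Per-individual scores at each p-value threshold plus the composite."""

    ids: np.ndarray
    thresholds: np.ndarray
    raw_scores: np.ndarray  # (n_individuals, n_thresholds)
    prspc: Optional[np.ndarray] = None
    loadings: Optional[np.ndarray] = None
    n_variants_used: Optional[np.ndarray] = None


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the summary-statistics invariants, raising on violations."""
    missing = [c for c in ("SNP", "A1", "A2", "BETA", "P") if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].tolist()[:5]
        raise ValueError(f"duplicate variant ids in summary statistics: {dups}")
    bad_p = ~((df["P"] > 0) & (df["P"] <= 1))
    if bad_p.any():
        row = df.index[bad_p][0]
        raise ValueError(
            f"p-value outside (0, 1] at row {row} (SNP={df.loc[row, 'SNP']})"
        )
    if (df["A1"] == df["A2"]).any():
        raise ValueError("effect and other allele identical for some variants")
    return df


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV into the canonical column layout.

    ``column_map`` maps canonical names ("SNP", "A1", "BETA", ...) to the
    file's headers.  Rows with missing beta, p-value or alleles are dropped
    with a logged count.  Strand-ambiguous variants (A/T, C/G) are flagged
    and optionally removed.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    keep = [c for c in SUMSTAT_COLUMNS if c in raw.columns]
    df = raw[keep].copy()
    before = len(df)
    df = df.dropna(subset=[c for c in ("BETA", "P", "A1", "A2") if c in df.columns])
    if len(df) < before:
        logger.info("dropped %d rows with missing beta/p/alleles", before - len(df))
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    ambiguous = [
        (a1, a2) in _AMBIGUOUS for a1, a2 in zip(df["A1"], df["A2"])
    ]
    df["ambiguous"] = ambiguous
    if any(ambiguous):
        logger.info("%d strand-ambiguous (A/T or C/G) variants", sum(ambiguous))
        if drop_ambiguous:
            df = df[~df["ambiguous"]]
    df = df.reset_index(drop=True)
    return validate_sumstats(df)


def compute_threshold_scores(
    dosages: DosagePanel,
    sumstats: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> PGSMatrix:
    """Weighted sums of effect alleles at each p-value inclusion threshold.

    score(i, t) = sum over variants with p <= t of beta_v * dosage(i, v),
    after aligning the genotype file's counted allele to the summary
    statistics' effect allele (dosage -> 2 - dosage when the file counts the
    other allele).  Variants matching neither allele are dropped with a log
    message; an empty intersection is an error.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    ss = sumstats.set_index("SNP")
    shared_mask = pd.Index(dosages.variant_id).isin(ss.index)
    if not shared_mask.any():
        raise ValueError("no variants shared between dosages and summary statistics")
    idx = np.flatnonzero(shared_mask)
    vids = dosages.variant_id[idx]
    a1 = ss.loc[vids, "A1"].to_numpy()
    a2 = ss.loc[vids, "A2"].to_numpy()
    counted = dosages.counted_allele[idx]
    match_eff = counted == a1
    match_oth = counted == a2
    usable = match_eff | match_oth
    if not usable.all():
        logger.info(
            "dropping %d variants whose alleles match neither A1 nor A2",
            int((~usable).sum()),
        )
    idx, vids = idx[usable], vids[usable]
    flip = match_oth[usable]
    beta = ss.loc[vids, "BETA"].to_numpy(dtype=float)
    pvals = ss.loc[vids, "P"].to_numpy(dtype=float)
    dos = dosages.matrix[:, idx].astype(float)
    dos[:, flip] = 2.0 - dos[:, flip]

    n = dos.shape[0]
    raw = np.empty((n, len(thresholds)))
    n_used = np.empty(len(thresholds), dtype=int)
    for t, thr in enumerate(thresholds):
        sel = pvals <= thr
        n_used[t] = int(sel.sum())
        raw[:, t] = dos[:, sel] @ beta[sel] if sel.any() else 0.0
    return PGSMatrix(
        ids=dosages.ids,
        thresholds=thresholds,
        raw_scores=raw,
        n_variants_used=n_used,
    )


def prs_pc(raw_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of standardized threshold scores.

    Columns are z-scored (constant columns dropped with a log message), the
    leading eigenvector of their correlation structure is extracted, the
    composite is sign-aligned to correlate non-negatively with the mean
    standardized score, and re-standardized to mean 0, SD 1.

    Returns ``(composite, loadings)`` where ``loadings`` has one entry per
    input column (0 for dropped constant columns).
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    if raw_scores.ndim != 2 or raw_scores.shape[1] < 2:
        raise ValueError("need at least two threshold columns")
    if raw_scores.shape[0] < 3:
        raise ValueError("need at least three individuals")
    sds = raw_scores.std(axis=0)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all threshold columns are constant")
    if not keep.all():
        logger.info("dropping %d constant threshold columns", int((~keep).sum()))
    z = (raw_scores[:, keep] - raw_scores[:, keep].mean(axis=0)) / sds[keep]
    # leading right singular vector of the standardized matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    composite = z @ v
    mean_score = z.mean(axis=1)
    if np.dot(composite, mean_score) < 0:
        v, composite = -v, -composite
    composite = (composite - composite.mean()) / composite.std()
    loadings = np.zeros(raw_scores.shape[1])
    loadings[keep] = v
    return composite, loadings


def compute_ancestry_pcs(dosages: np.ndarray, k: int = 10) -> np.ndarray:
    """Principal components of the column-standardized dosage matrix.

    Returns an (n_individuals, k) orthonormal matrix ordered by singular
    value, as used to control for population stratification.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_individuals, n_variants)={min(n, m)}")
    sds = dosages.std(axis=0)
    keep = sds > 0
    z = (dosages[:, keep] - dosages[:, keep].mean(axis=0)) / sds[keep]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, :k]


def residualize_standardize(
    score: np.ndarray,
    covariates: pd.DataFrame,
    which: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Regress a score on covariates, return the standardized residual.

    Categorical columns become indicator sets (a batch level with a single
    member is merged into "other" first); numeric columns enter as-is.  The
    output has mean 0, SD 1 and is numerically uncorrelated with every
    included covariate column.  A score fully explained by the covariates is
    a degenerate input.
    """
    score = np.asarray(score, dtype=float)
    cols = list(which) if which is not None else list(covariates.columns)
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing columns: {missing}")
    if covariates[cols].isna().any().any():
        raise ValueError("covariates must be complete for all scored individuals")
    blocks = [np.ones((len(score), 1))]
    for c in cols:
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            col = col.astype(str)
            counts = col.value_counts()
            singletons = counts.index[counts == 1]
            if len(singletons):
                logger.warning(
                    "merging %d single-member levels of %s into 'other'",
                    len(singletons),
                    c,
                )
                col = col.where(~col.isin(singletons), "other")
            blocks.append(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float))
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    design = np.hstack(blocks)
    coef, *_ = np.linalg.lstsq(design, score, rcond=None)
    resid = score - design @ coef
    sd = resid.std()
    if sd < 1e-10 * (score.std() or 1.0):
        raise ValueError("score is fully explained by the covariates (degenerate)")
    return (resid - resid.mean()) / sd
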