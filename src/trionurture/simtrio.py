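"""Synthetic mother-father-child trio cohorts for within-family polygenic-score analysis.

The generator produces everything the trio design consumes: biallelic SNP
genotypes in Hardy-Weinberg proportions (optionally stratified into two demes
and/or assortatively paired), Mendelian transmission to offspring, a child
phenotype built from direct-genetic (``c``) and parental-nurture (``m``, ``f``)
paths plus covariates and noise, GWAS weights observed with sampling error,
and outcome missingness that may depend on auxiliary variables.

All latent "true scores" are centred weighted allele counts with population
variance 1 in the parental generation, so the path coefficients ``c``, ``m``
and ``f`` are in per-SD units and the analytic identities used throughout the
test-suite (e.g. Cov(child, parent) = (1+a)/2) hold on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "VariantPanel",
    "SimConfig",
    "TrioCohort",
    "make_variant_panel",
    "simulate_parents",
    "mendelian_transmission",
    "simulate_phenotype",
    "make_noisy_sumstats",
    "apply_missingness",
    "simulate_cohort",
    "items_from_phenotype",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantPanel:
    """A set of unlinked biallelic variants with generative effect sizes.

    ``true_beta`` is scaled so that the population variance of the raw causal
    score, ``sum_v beta_v^2 * 2 p_v (1 - p_v)``, equals 1.  ``deme_maf_shift``
    (n_demes x n_snps), when present, holds per-deme deviations from ``maf``.
    """

    variant_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    maf: np.ndarray
    true_beta: np.ndarray
    deme_maf_shift: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(set(self.variant_id)) != len(self.variant_id):
            raise ValueError("variant ids must be unique")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if np.any(self.effect_allele == self.other_allele):
            raise ValueError("effect and other allele must differ")
        if self.deme_maf_shift is not None:
            freqs = self.deme_freqs()
            if np.any(freqs <= 0) or np.any(freqs >= 1):
                raise ValueError("per-deme allele frequencies must stay in (0, 1)")

    @property
    def n_snps(self) -> int:
        return len(self.variant_id)

    def deme_freqs(self) -> np.ndarray:
        """Per-deme effect-allele frequencies, shape (n_demes, n_snps)."""
        if self.deme_maf_shift is None:
            return self.maf[None, :]
        return self.maf[None, :] + self.deme_maf_shift


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of a trio cohort.

    Paths ``c`` (direct genetic), ``m`` and ``f`` (maternal / paternal
    nurture) are per-SD effects of the true latent scores on the latent
    phenotype.  ``a_target`` is the intended spousal correlation of true
    scores (assortative mating); it requires ``mate_on`` != "random".
    ``noise_sd=None`` auto-calibrates the residual SD so the latent phenotype
    has population variance 1, keeping path coefficients interpretable after
    the post-hoc standardization.
    """

    n_trios: int = 5000
    n_snps: int = 1000
    n_causal: Optional[int] = None
    maf_range: Tuple[float, float] = (0.05, 0.5)
    c: float = 0.15
    m: float = 0.05
    f: float = 0.0
    a_target: float = 0.0
    mate_on: Literal["score", "phenotype", "random"] = "random"
    mate_h2: float = 0.5
    n_demes: int = 1
    deme_fst_like: float = 0.0
    deme_pheno_shift: float = 0.0
    gwas_n: float = 1e12
    noise_sd: Optional[float] = None
    sex_effect: float = 0.0
    birthyear_effect: float = 0.0
    birth_year_range: Tuple[int, int] = (1999, 2008)
    missing_rate: float = 0.0
    aux_count: int = 5
    aux_corr: float = 0.5
    mar_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trios < 1:
            raise ValueError("n_trios must be >= 1")
        if not (0 <= self.a_target <= 0.9):
            raise ValueError("a_target must lie in [0, 0.9]")
        if self.mate_on == "random" and self.a_target > 0:
            raise ValueError(
                "a_target > 0 requires mate_on='score' or 'phenotype' "
                "(random mating cannot produce spousal correlation)"
            )
        if not (0 <= self.missing_rate <= 0.95):
            raise ValueError("missing_rate must lie in [0, 0.95]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not np.all(np.isfinite([self.c, self.m, self.f])):
            raise ValueError("path coefficients must be finite")
        if self.n_demes not in (1, 2):
            raise ValueError("n_demes must be 1 or 2")
        if not (-1 < self.aux_corr < 1):
            raise ValueError("aux_corr must lie in (-1, 1)")

    def resolved_noise_sd(self) -> float:
        """Residual SD; if unset, the value making Var(latent phenotype) = 1."""
        if self.noise_sd is not None:
            return self.noise_sd
        a = self.a_target
        cov_cp = (1 + a) / 2  # Cov(child, each parent score)
        var_c = 1 + a / 2
        signal = (
            self.c**2 * var_c
            + self.m**2
            + self.f**2
            + 2 * self.c * self.m * cov_cp
            + 2 * self.c * self.f * cov_cp
            + 2 * self.m * self.f * a
        )
        signal += self.sex_effect**2 * 0.25
        lo, hi = self.birth_year_range
        signal += self.birthyear_effect**2 * ((hi - lo + 1) ** 2 - 1) / 12
        if self.n_demes == 2:
            signal += self.deme_pheno_shift**2 * 0.25
        if signal >= 1:
            raise ValueError(
                f"signal variance {signal:.3f} >= 1; set noise_sd explicitly"
            )
        return float(np.sqrt(1 - signal))


@dataclass
class TrioCohort:
    """Dosage matrices and phenotypes for n_trios mother-father-child trios."""

    panel: VariantPanel
    mother: np.ndarray  # (n_trios, n_snps) int8 effect-allele dosages
    father: np.ndarray
    child: np.ndarray
    true_score_mother: np.ndarray
    true_score_father: np.ndarray
    true_score_child: np.ndarray
    deme: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    phenotype: Optional[np.ndarray] = None
    auxiliaries: Optional[np.ndarray] = None
    observed_mask: Optional[np.ndarray] = None
    trio_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trio_id is None:
            self.trio_id = np.array(
                [f"trio{i:06d}" for i in range(self.n_trios)], dtype=object
            )

    @property
    def n_trios(self) -> int:
        return self.mother.shape[0]

    def dosages(self, role: str) -> np.ndarray:
        return {"mother": self.mother, "father": self.father, "child": self.child}[role]

    def true_scores(self, role: str) -> np.ndarray:
        return {
            "mother": self.true_score_mother,
            "father": self.true_score_father,
            "child": self.true_score_child,
        }[role]

    def mendelian_consistent(self) -> bool:
        """Check every locus of every trio against the transmission bounds."""
        lo = np.ceil((self.mother - 1) / 2) + np.ceil((self.father - 1) / 2)
        hi = np.minimum(self.mother, 1) + np.minimum(self.father, 1)
        return bool(np.all((self.child >= lo) & (self.child <= hi)))


def _check_dosages(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1, 2)).all():
        raise ValueError(f"{name} dosages must be in {{0, 1, 2}}")
    return arr


def make_variant_panel(
    n_snps: int,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    n_causal: Optional[int] = None,
    seed: int = 0,
    n_demes: int = 1,
    deme_fst_like: float = 0.0,
) -> VariantPanel:
    """Draw an unlinked variant panel with unit-variance causal architecture.

    ``n_causal`` variants (default: all) receive Gaussian effects rescaled so
    the population variance of the raw score is exactly 1.  With
    ``n_demes=2`` and ``deme_fst_like>0``, per-deme frequencies are drawn
    Balding-Nichols-style around the panel MAF.
    """
    if n_causal is None:
        n_causal = n_snps
    if not (1 <= n_causal <= n_snps):
        raise ValueError("n_causal must satisfy 1 <= n_causal <= n_snps")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be a non-empty interval within (0, 0.5]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    effect_idx = rng.integers(0, 4, size=n_snps)
    other_idx = (effect_idx + rng.integers(1, 4, size=n_snps)) % 4
    beta = np.zeros(n_snps)
    causal = rng.choice(n_snps, size=n_causal, replace=False)
    beta[causal] = rng.normal(size=n_causal)
    scale = np.sqrt(np.sum(beta**2 * 2 * maf * (1 - maf)))
    beta /= scale
    shift = None
    if n_demes == 2 and deme_fst_like > 0:
        f = deme_fst_like
        # Balding-Nichols: per-deme frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)
        a, b = maf * (1 - f) / f, (1 - maf) * (1 - f) / f
        freqs = rng.beta(a[None, :].repeat(2, 0), b[None, :].repeat(2, 0))
        freqs = np.clip(freqs, 1e-3, 1 - 1e-3)
        shift = freqs - maf[None, :]
    elif n_demes == 2:
        shift = np.zeros((2, n_snps))
    return VariantPanel(
        variant_id=np.array([f"rs{i + 1}" for i in range(n_snps)], dtype=object),
        effect_allele=_BASES[effect_idx],
        other_allele=_BASES[other_idx],
        maf=maf,
        true_beta=beta,
        deme_maf_shift=shift,
    )


def _true_score(panel: VariantPanel, dosages: np.ndarray) -> np.ndarray:
    # centred weighted allele count: population mean 0, parental variance 1
    return (dosages - 2 * panel.maf) @ panel.true_beta


def _pair_assortatively(
    key_m: np.ndarray, key_f: np.ndarray, a_target: float, rng: np.random.Generator
) -> np.ndarray:
    """Return a permutation of fathers achieving corr(key_m, key_f[perm]) ~= a_target.

    Rank-pairing with Gaussian jitter: mothers are sorted on their key and
    matched to fathers sorted on a jittered key; the jitter SD is bisected
    against the realized correlation on this very sample, so the target is
    hit deterministically given the seed.
    """
    n = len(key_m)
    order_m = np.argsort(key_m, kind="stable")
    jitter = rng.normal(size=n)
    sd_f = np.std(key_f) or 1.0

    def realized(s: float) -> float:
        order_f = np.argsort(key_f + s * sd_f * jitter, kind="stable")
        return float(np.corrcoef(key_m[order_m], key_f[order_f])[0, 1])

    lo, hi = 1e-6, 1e3
    if realized(lo) <= a_target:
        s = lo
    elif realized(hi) >= a_target:
        s = hi
    else:
        s = optimize.brentq(lambda x: realized(x) - a_target, lo, hi, xtol=1e-4)
    perm = np.empty(n, dtype=np.int64)
    perm[order_m] = np.argsort(key_f + s * sd_f * jitter, kind="stable")
    return perm


def simulate_parents(
    panel: VariantPanel, config: SimConfig, rng: Optional[np.random.Generator] = None
):
    """Draw paired parental genotypes under Hardy-Weinberg, per-deme frequencies.

    Returns ``(mother, father, score_m, score_f, deme)``.  Under
    ``mate_on='random'`` spouses are independent; otherwise fathers are
    re-paired within deme to achieve the target spousal correlation of the
    mating key (true score, or a noisy phenotype proxy with heritability
    ``mate_h2``).
    """
    if panel.n_snps != config.n_snps:
        raise ValueError("panel size does not match config.n_snps")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trios
    deme = (
        rng.integers(0, config.n_demes, size=n)
        if config.n_demes > 1
        else np.zeros(n, dtype=np.int64)
    )
    freqs = panel.deme_freqs()  # (n_demes_panel, n_snps)
    if config.n_demes > 1 and freqs.shape[0] == 1:
        freqs = np.repeat(freqs, config.n_demes, axis=0)
    p = freqs[np.minimum(deme, freqs.shape[0] - 1)]  # (n, n_snps)
    mother = rng.binomial(2, p).astype(np.int8)
    father = rng.binomial(2, p).astype(np.int8)
    score_m = _true_score(panel, mother)
    score_f = _true_score(panel, father)

    if config.mate_on != "random":
        if config.mate_on == "phenotype":
            h = np.sqrt(config.mate_h2)
            key_m = h * score_m + np.sqrt(1 - config.mate_h2) * rng.normal(size=n)
            key_f = h * score_f + np.sqrt(1 - config.mate_h2) * rng.normal(size=n)
        else:
            key_m, key_f = score_m, score_f
        perm = np.arange(n)
        for d in np.unique(deme):
            idx = np.flatnonzero(deme == d)
            sub = _pair_assortatively(key_m[idx], key_f[idx], config.a_target, rng)
            perm[idx] = idx[sub]
        father = father[perm]
        score_f = score_f[perm]
    return mother, father, score_m, score_f, deme


def mendelian_transmission(
    mother: np.ndarray, father: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Transmit one allele per parent per locus.

    A parent with dosage 0 contributes 0 effect alleles, dosage 2 contributes
    1, and a heterozygote contributes 1 with probability 1/2, independently
    per trio and locus.
    """
    mother = _check_dosages(mother, "mother")
    father = _check_dosages(father, "father")
    if mother.shape != father.shape:
        raise ValueError("parental dosage matrices must have equal shapes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(mother.shape + (2,))
    contrib_m = (mother == 2).astype(np.int8) + ((mother == 1) & (u[..., 0] < 0.5))
    contrib_f = (father == 2).astype(np.int8) + ((father == 1) & (u[..., 1] < 0.5))
    return (contrib_m + contrib_f).astype(np.int8)


def simulate_phenotype(
    cohort: TrioCohort, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Build the child latent phenotype from the generative paths, then z-score it.

    phenotype = c*G_child + m*G_mother + f*G_father + sex and birth-year
    effects + deme shift + Normal(0, noise_sd), standardized to sample mean 0
    and SD 1.
    """
    noise_sd = config.resolved_noise_sd()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = (
        config.c * cohort.true_score_child
        + config.m * cohort.true_score_mother
        + config.f * cohort.true_score_father
        + config.sex_effect * cohort.sex
        + config.birthyear_effect * (cohort.birth_year - cohort.birth_year.mean())
        + config.deme_pheno_shift * cohort.deme
        + rng.normal(0, noise_sd, size=cohort.n_trios)
    )
    sd = y.std()
    if sd == 0:
        return y - y.mean()
    return (y - y.mean()) / sd


def make_noisy_sumstats(
    panel: VariantPanel, gwas_n: float, seed: int = 0
) -> pd.DataFrame:
    """Observe the panel's true effects with GWAS sampling error.

    Per variant, BETA = true_beta + Normal(0, SE) with
    SE = 1 / sqrt(gwas_n * 2 p (1-p)); P is the two-sided normal tail of
    BETA/SE.  gwas_n -> infinity recovers the true effects.
    """
    if gwas_n < 1:
        raise ValueError("gwas_n must be >= 1")
    rng = np.random.default_rng(seed)
    se = 1.0 / np.sqrt(gwas_n * 2 * panel.maf * (1 - panel.maf))
    beta_hat = panel.true_beta + rng.normal(0, se)
    z = beta_hat / se
    # p = 2 * Phi(-|z|) via erfc for numerical range
    pvals = special.erfc(np.abs(z) / np.sqrt(2))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "SNP": panel.variant_id,
            "A1": panel.effect_allele,
            "A2": panel.other_allele,
            "BETA": beta_hat,
            "SE": se,
            "P": pvals,
            "FRQ": panel.maf,
        }
    )


def apply_missingness(
    cohort: TrioCohort, config: SimConfig, rng: Optional[np.random.Generator] = None
) -> TrioCohort:
    """Attach auxiliary variables and an observed/missing phenotype mask.

    Auxiliaries are continuous variables with correlation ``aux_corr`` to the
    phenotype (emulating earlier measures of risk available even when the
    outcome is not).  The missingness probability is a logistic function of
    the auxiliary mean with slope ``mar_strength`` (missing-at-random given
    auxiliaries), intercept-calibrated so the marginal rate matches
    ``missing_rate``; ``mar_strength=0`` is MCAR.
    """
    if cohort.phenotype is None:
        raise ValueError("phenotype must be simulated before missingness")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, k = cohort.n_trios, config.aux_count
    rho = config.aux_corr
    aux = rho * cohort.phenotype[:, None] + np.sqrt(1 - rho**2) * rng.normal(
        size=(n, k)
    )
    if config.missing_rate == 0:
        mask = np.ones(n, dtype=bool)
    else:
        z = aux.mean(axis=1)
        z = (z - z.mean()) / (z.std() or 1.0)
        g = config.mar_strength

        def marginal(alpha: float) -> float:
            return float(special.expit(alpha + g * z).mean()) - config.missing_rate

        alpha = optimize.brentq(marginal, -40, 40)
        p_miss = special.expit(alpha + g * z)
        mask = rng.random(n) >= p_miss
    out = replace(cohort)
    out.auxiliaries = aux
    out.observed_mask = mask
    return out


def simulate_cohort(config: SimConfig, panel: Optional[VariantPanel] = None) -> TrioCohort:
    """Run the full generative chain: parents, transmission, phenotype, missingness.

    All randomness derives from ``config.seed`` through named sub-streams, so
    identical configs yield byte-identical cohorts.
    """
    ss = np.random.SeedSequence(config.seed)
    s_panel, s_parents, s_trans, s_cov, s_pheno, s_miss = ss.spawn(6)
    if panel is None:
        panel = make_variant_panel(
            config.n_snps,
            config.maf_range,
            config.n_causal,
            seed=s_panel,
            n_demes=config.n_demes,
            deme_fst_like=config.deme_fst_like,
        )
    mother, father, score_m, score_f, deme = simulate_parents(
        panel, config, rng=np.random.default_rng(s_parents)
    )
    child = mendelian_transmission(mother, father, np.random.default_rng(s_trans))
    rng_cov = np.random.default_rng(s_cov)
    sex = rng_cov.integers(0, 2, size=config.n_trios)
    lo, hi = config.birth_year_range
    birth_year = rng_cov.integers(lo, hi + 1, size=config.n_trios)
    cohort = TrioCohort(
        panel=panel,
        mother=mother,
        father=father,
        child=child,
        true_score_mother=score_m,
        true_score_father=score_f,
        true_score_child=_true_score(panel, child),
        deme=deme,
        sex=sex,
        birth_year=birth_year,
    )
    cohort.phenotype = simulate_phenotype(
        cohort, config, rng=np.random.default_rng(s_pheno)
    )
    cohort = apply_missingness(cohort, config, rng=np.random.default_rng(s_miss))
    return cohort


def items_from_phenotype(
    phenotype: np.ndarray,
    seed: int = 0,
    n_items: int = 18,
    thresholds: Tuple[float, float, float] = (0.5, 1.5, 2.5),
    item_sd: float = 1.0,
    item_missing_rate: float = 0.0,
) -> np.ndarray:
    """Discretize a standardized latent trait into 4-point rating-scale items.

    Each item adds independent Gaussian noise to the latent trait and cuts at
    fixed thresholds, giving the right-skewed response pattern typical of
    population ADHD ratings (most children rated "never/rarely").  Returns a
    float array with values in {1,2,3,4} and NaN for item-level missingness.
    """
    rng = np.random.default_rng(seed)
    latent = phenotype[:, None] + item_sd * rng.normal(size=(len(phenotype), n_items))
    items = np.digitize(latent, thresholds) + 1.0
    if item_missing_rate > 0:
        items[rng.random(items.shape) < item_missing_rate] = np.nan
    return items
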