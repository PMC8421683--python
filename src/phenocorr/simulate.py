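"""Forward simulation of bivariate GWAS under the additive polygenic model.

Generates Hardy-Weinberg genotypes over a configurable MAF spectrum, two
phenotypes y_i = X beta_i + e_i with a shared causal SNP set (effects
correlated r_G, residuals correlated r_E on the overlapping individuals
only), per-SNP least-squares association Z-scores, and runs the full
estimator-comparison study (low-MAF cutoffs, Z-cut cutoffs, all-SNP, the
500-random-SNP estimator, and the individual-level truth) across replicates.

Individuals are laid out as [overlap block | trait-1 only | trait-2 only],
so trait 1 owns rows 0..n1 and trait 2 owns rows 0..n0 plus n1..n1+n2-n0.

Two effect scales are supported. With ``allele_count`` (the default), the
per-SNP effect variance is constant on the 0/1/2 allele-count scale, so a
variant's explained variance is proportional to 2f(1-f) and vanishes as
f -> 0 — the regime in which the low-MAF estimator removes the genetic
contamination of the Z-score correlation. With ``standardized``, effects are
drawn on variance-standardized genotype columns (each causal SNP explains
h2/M regardless of MAF), mirroring polygenic simulations on real genotype
panels where rare variants shed explained variance through low LD instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    CorrEstimate,
    OverlapSpec,
    corr_pvalue,
    wald_se_from_p,
    zscore_correlation,
)
from .theory import expected_phenotypic_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "MafSpectrum",
    "SimConfig",
    "GwasResult",
    "PhenotypePair",
    "SimStudyResult",
    "sample_mafs",
    "simulate_genotypes",
    "simulate_phenotype_pair",
    "simulate_binary_pair",
    "run_gwas",
    "gwas_zscore_pair",
    "random_snp_estimator",
    "run_simulation_study",
    "DEFAULT_METHOD_GRID",
]

_GWAS_BLOCK = 4000  # columns per GWAS block; bounds peak float64 memory


@dataclass(frozen=True)
class MafSpectrum:
    """Distribution of coding-allele frequencies for simulated SNPs.

    families
    --------
    log_uniform : log10(f) uniform on [log10(f_min), log10(f_max)] — heavy
        rare-variant tail so every MAF cutoff down to 5e-4 retains SNPs.
    uniform : f uniform on [f_min, f_max].
    point : all SNPs at frequency ``value``.
    """

    family: str = "log_uniform"
    f_min: float = 1e-4
    f_max: float = 0.5
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("log_uniform", "uniform", "point"):
            raise ValueError(f"unknown MAF spectrum family {self.family!r}")
        if self.family == "point":
            if self.value is None or not 0 < self.value <= 0.5:
                raise ValueError("point spectrum needs a value in (0, 0.5]")
        elif not 0 < self.f_min <= self.f_max <= 0.5:
            raise ValueError("need 0 < f_min <= f_max <= 0.5")

    def tail_mass(self, cutoff: float) -> float:
        """Probability that a sampled frequency falls strictly below cutoff."""
        if self.family == "point":
            return float(self.value < cutoff)
        lo, hi = self.f_min, self.f_max
        c = min(max(cutoff, lo), hi)
        if self.family == "uniform":
            return (c - lo) / (hi - lo)
        return (math.log(c) - math.log(lo)) / (math.log(hi) - math.log(lo))


@dataclass(frozen=True)
class SimConfig:
    """Complete specification of one bivariate phenotype simulation.

    Defaults reproduce the primary validation scenario at desk scale:
    heritability 0.3 for both traits, 10% causal SNPs, genetic correlation
    0.5, residual correlation 0.25, fully overlapping samples of 2,000 over
    20,000 independent SNPs on a log-uniform MAF spectrum down to 1e-4.
    """

    n1: int = 2000
    n2: int = 2000
    n0: int = 2000
    m: int = 20000
    causal_prop: float = 0.1
    h2_1: float = 0.3
    h2_2: float = 0.3
    r_g: float = 0.5
    r_e: float = 0.25
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    effect_scale: str = "allele_count"
    prevalence_1: Optional[float] = None
    prevalence_2: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n0 <= min(self.n1, self.n2):
            raise ValueError("need 0 <= n0 <= min(n1, n2)")
        for h in (self.h2_1, self.h2_2):
            if not 0 <= h <= 1:
                raise ValueError("heritabilities must lie in [0, 1]")
        for r in (self.r_g, self.r_e):
            if abs(r) > 1:
                raise ValueError("correlations must lie in [-1, 1]")
        if not 0 < self.causal_prop <= 1:
            raise ValueError("causal_prop must lie in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.effect_scale not in ("allele_count", "standardized"):
            raise ValueError("effect_scale must be 'allele_count' or 'standardized'")
        if (self.h2_1 > 0 or self.h2_2 > 0) and self.n_causal < 1:
            raise ValueError("causal count is zero but heritability is positive")

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2 - self.n0

    @property
    def n_causal(self) -> int:
        return int(round(self.causal_prop * self.m))

    @property
    def overlap(self) -> OverlapSpec:
        return OverlapSpec(n1=self.n1, n2=self.n2, n0=self.n0)

    @property
    def true_r_p(self) -> float:
        """Population phenotypic correlation implied by the model."""
        return expected_phenotypic_correlation(self.h2_1, self.h2_2, self.r_g, self.r_e)


@dataclass
class GwasResult:
    """Per-SNP least-squares association results for one trait.

    Arrays cover the retained (in-sample polymorphic) SNPs only;
    ``snp_index`` maps them back to columns of the genotype matrix.
    """

    beta_hat: np.ndarray
    se: np.ndarray
    z: np.ndarray
    maf_observed: np.ndarray
    n: int
    snp_index: np.ndarray
    trait: str = ""

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class PhenotypePair:
    """Two simulated phenotype vectors plus the row maps into the genotypes."""

    y1: np.ndarray
    y2: np.ndarray
    idx1: np.ndarray
    idx2: np.ndarray
    config: SimConfig
    true_r_p_individual: Optional[float]  # empirical cor on the overlap, None if n0=0


def sample_mafs(m: int, spectrum: Optional[MafSpectrum] = None, seed=None) -> np.ndarray:
    """Draw m coding-allele frequencies from a MAF spectrum.

    ``seed`` may be an int or a numpy Generator. The default log-uniform
    spectrum on [1e-4, 0.5] leaves every cutoff in {0.05, 0.005, 5e-4} with a
    usable expected SNP count (tail mass ln(c/1e-4)/ln(5000) per SNP).
    """
    spectrum = spectrum or MafSpectrum()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spectrum.family == "point":
        return np.full(m, spectrum.value, dtype=float)
    if spectrum.family == "uniform":
        return rng.uniform(spectrum.f_min, spectrum.f_max, size=m)
    lo, hi = math.log(spectrum.f_min), math.log(spectrum.f_max)
    return np.exp(rng.uniform(lo, hi, size=m))


def simulate_genotypes(n: int, mafs: np.ndarray, seed=None) -> np.ndarray:
    """HWE genotypes: independent binomial(2, f) per SNP, coded 0/1/2 (int8).

    Drawn as the sum of two Bernoulli(f) haplotypes (identical in law to a
    binomial(2, f) draw, and much faster for a matrix with per-column f).
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mafs = np.asarray(mafs, dtype=float)
    shape = (n, len(mafs))
    g = (rng.random(shape) < mafs).view(np.int8)
    g += (rng.random(shape) < mafs).view(np.int8)
    return g


def monomorphic_mask(genotypes: np.ndarray) -> np.ndarray:
    """True for columns constant in-sample (no association test possible)."""
    return genotypes.min(axis=0) == genotypes.max(axis=0)


def _draw_effects(config: SimConfig, mafs, causal, rng) -> np.ndarray:
    """Bivariate per-SNP effects over the causal set, shape (M, 2).

    allele_count scale: constant per-SNP variance chosen so the expected
    total genetic variance sum_causal 2f(1-f) sigma_b^2 equals h2.
    standardized scale: variance h2/M per causal SNP on standardized columns.
    """
    m_causal = len(causal)
    if config.effect_scale == "allele_count":
        het = 2.0 * mafs[causal] * (1.0 - mafs[causal])
        denom = het.sum()
        v1 = config.h2_1 / denom if denom > 0 else 0.0
        v2 = config.h2_2 / denom if denom > 0 else 0.0
    else:
        v1 = config.h2_1 / m_causal
        v2 = config.h2_2 / m_causal
    cov = np.array(
        [[v1, config.r_g * math.sqrt(v1 * v2)],
         [config.r_g * math.sqrt(v1 * v2), v2]]
    )
    # Cholesky with a graceful degenerate branch (h2 = 0 for a trait)
    if v1 > 0 and v2 > 0:
        chol = np.linalg.cholesky(cov)
        return rng.standard_normal((m_causal, 2)) @ chol.T
    out = np.zeros((m_causal, 2))
    if v1 > 0:
        out[:, 0] = rng.standard_normal(m_causal) * math.sqrt(v1)
    if v2 > 0:
        out[:, 1] = rng.standard_normal(m_causal) * math.sqrt(v2)
    return out


def _genetic_values(config: SimConfig, genotypes, mafs, causal, betas) -> np.ndarray:
    """Genetic values for all individuals, shape (n_total, 2)."""
    g = genotypes[:, causal].astype(np.float64)
    if config.effect_scale == "standardized":
        mean = g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = np.inf  # monomorphic causal SNPs contribute nothing
        g = (g - mean) / sd
    # allele-count scale: column centering is a per-column constant shift,
    # absorbed by the final mean-centering of y
    return g @ betas


def simulate_phenotype_pair(
    config: SimConfig,
    genotypes: Optional[np.ndarray] = None,
    mafs: Optional[np.ndarray] = None,
    seed=None,
) -> PhenotypePair:
    """Generate the two phenotypes y_i = X beta_i + e_i for one replicate.

    A single causal set of round(causal_prop * m) SNPs is shared by both
    traits; the per-SNP effect pairs are bivariate normal with correlation
    r_g, and residual pairs are correlated r_e for the n0 overlapping
    individuals and independent elsewhere. Phenotypes are mean-centered.

    When ``genotypes``/``mafs`` are omitted they are drawn from the config's
    spectrum using ``seed`` (int or Generator; defaults to config.seed).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    if mafs is None:
        mafs = sample_mafs(config.m, config.maf_spectrum, rng)
    if genotypes is None:
        genotypes = simulate_genotypes(config.n_total, mafs, rng)
    if genotypes.shape != (config.n_total, config.m):
        raise ValueError(
            f"genotypes must have shape ({config.n_total}, {config.m}), "
            f"got {genotypes.shape}"
        )

    n1, n2, n0, nt = config.n1, config.n2, config.n0, config.n_total
    idx1 = np.arange(n1)
    idx2 = np.concatenate([np.arange(n0), np.arange(n1, nt)])

    causal = rng.choice(config.m, size=config.n_causal, replace=False)
    betas = _draw_effects(config, mafs, causal, rng)
    gvals = _genetic_values(config, genotypes, mafs, causal, betas)

    s1 = math.sqrt(1.0 - config.h2_1)
    s2 = math.sqrt(1.0 - config.h2_2)
    e1 = np.empty(n1)
    e2 = np.empty(n2)
    if n0 > 0:
        # bivariate residuals on the overlap block
        u = rng.standard_normal(n0)
        v = rng.standard_normal(n0)
        e1[:n0] = s1 * u
        e2[:n0] = s2 * (config.r_e * u + math.sqrt(1.0 - config.r_e**2) * v)
    e1[n0:] = s1 * rng.standard_normal(n1 - n0)
    e2[n0:] = s2 * rng.standard_normal(n2 - n0)

    y1 = gvals[idx1, 0] + e1
    y2 = gvals[idx2, 1] + e2
    y1 -= y1.mean()
    y2 -= y2.mean()

    truth = None
    if n0 >= 3:
        truth = float(np.corrcoef(y1[:n0], y2[:n0])[0, 1])
    return PhenotypePair(y1=y1, y2=y2, idx1=idx1, idx2=idx2, config=config,
                         true_r_p_individual=truth)


def simulate_binary_pair(
    config: SimConfig,
    genotypes: Optional[np.ndarray] = None,
    mafs: Optional[np.ndarray] = None,
    seed=None,
):
    """Dichotomize simulated liabilities into 0/1 outcomes by prevalence.

    The continuous phenotypes act as liabilities; each trait is coded 1 above
    its in-sample (1 - prevalence) quantile. Returns (b1, b2, pair) where
    ``pair`` carries the underlying liabilities and their overlap correlation
    (the liability-scale truth the Z-score correlation estimates).
    """
    for prev in (config.prevalence_1, config.prevalence_2):
        if prev is None or not 0 < prev < 1:
            raise ValueError("binary simulation needs prevalences in (0, 1)")
    pair = simulate_phenotype_pair(config, genotypes, mafs, seed)
    t1 = np.quantile(pair.y1, 1.0 - config.prevalence_1)
    t2 = np.quantile(pair.y2, 1.0 - config.prevalence_2)
    b1 = (pair.y1 > t1).astype(float)
    b2 = (pair.y2 > t2).astype(float)
    if b1.std() == 0 or b2.std() == 0:
        raise ValueError("degenerate binary outcome: one class is empty")
    return b1, b2, pair


def run_gwas(genotypes: np.ndarray, y: np.ndarray, trait: str = "") -> GwasResult:
    """Per-SNP simple least squares of a centered phenotype on each genotype.

    beta_hat = g'y / g'g on the mean-centered genotype, se from that SNP's
    own residual variance with n-2 df, z = beta_hat / se. In-sample
    monomorphic SNPs are dropped. Vectorized in column blocks.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if genotypes.shape[0] != n:
        raise ValueError("genotypes and phenotype disagree on sample count")
    y = y - y.mean()
    yy = float(y @ y)
    m = genotypes.shape[1]
    beta = np.empty(m)
    se = np.empty(m)
    maf_obs = np.empty(m)
    poly = np.empty(m, dtype=bool)
    for start in range(0, m, _GWAS_BLOCK):
        sl = slice(start, min(start + _GWAS_BLOCK, m))
        g = genotypes[:, sl].astype(np.float64)
        s1 = g.sum(axis=0)
        gg = (g * g).sum(axis=0) - s1 * s1 / n  # centered sum of squares
        ok = gg > 0
        gy = g.T @ y  # equals centered cross-product since y is centered
        with np.errstate(divide="ignore", invalid="ignore"):
            b = gy / gg
            rss = np.maximum(yy - b * gy, 0.0)
            s2 = rss / (n - 2)
            se_blk = np.sqrt(s2 / gg)
        beta[sl] = b
        se[sl] = se_blk
        f_obs = s1 / (2.0 * n)
        maf_obs[sl] = np.minimum(f_obs, 1.0 - f_obs)
        poly[sl] = ok & (se_blk > 0)
    idx = np.flatnonzero(poly)
    return GwasResult(
        beta_hat=beta[idx], se=se[idx], z=beta[idx] / se[idx],
        maf_observed=maf_obs[idx], n=n, snp_index=idx, trait=trait,
    )


def gwas_zscore_pair(gw1: GwasResult, gw2: GwasResult, mafs: np.ndarray):
    """Align two GWAS results on SNPs polymorphic in both samples.

    Returns (z1, z2, maf) arrays over the shared SNPs, with maf taken from
    the known simulation spectrum (min(f, 1-f)).
    """
    shared, i1, i2 = np.intersect1d(gw1.snp_index, gw2.snp_index,
                                    assume_unique=True, return_indices=True)
    f = np.asarray(mafs, dtype=float)[shared]
    return gw1.z[i1], gw2.z[i2], np.minimum(f, 1.0 - f)


def _estimate_from_z(z1, z2, maf, method, cutoff, overlap) -> CorrEstimate:
    """Apply one selection rule and package the correlation estimate."""
    if method == "low_maf":
        sel = np.isfinite(maf) & (maf < cutoff)
    elif method == "z_cut":
        sel = (np.abs(z1) < cutoff) & (np.abs(z2) < cutoff)
    elif method in ("all_snp", "random_snp"):
        sel = np.ones(len(z1), dtype=bool)
    else:
        raise ValueError(f"unknown method {method!r}")
    n_sel = int(sel.sum())
    if n_sel < 4:
        raise ValueError(f"{method}: only {n_sel} SNPs selected")
    r = zscore_correlation(z1[sel], z2[sel])
    se = wald_se_from_p(r, n_sel) if abs(r) < 1 else 0.0
    shrink = overlap.shrinkage if overlap is not None else 1.0
    if shrink > 0:
        r_adj, se_adj = r / shrink, se / shrink
    else:
        r_adj, se_adj = math.nan, math.nan
    return CorrEstimate(
        method=method, cutoff=cutoff, n_snps=n_sel, r_raw=r, se_raw=se,
        p=corr_pvalue(r, n_sel), r_adjusted=r_adj, se_adjusted=se_adj,
        shrinkage=shrink if shrink > 0 else math.nan,
        small_overlap_warning=0 < shrink < 0.1,
        out_of_range=abs(r_adj) > 1 if shrink > 0 else False,
    )


def random_snp_estimator(
    pair: PhenotypePair,
    n_snps: int = 500,
    spectrum: Optional[MafSpectrum] = None,
    seed=None,
) -> CorrEstimate:
    """Correlation of Z-scores at freshly generated effect-free SNPs.

    Generates ``n_snps`` random genotype columns independent of both
    phenotypes (default spectrum uniform on [0.05, 0.5]), runs the per-SNP
    regression of each trait on its own samples, and correlates the Z-scores.
    With full overlap this reproduces the individual-level phenotypic
    correlation — the SNPs explain no variance, so their score statistics
    are projections of the phenotypes themselves.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectrum = spectrum or MafSpectrum(family="uniform", f_min=0.05, f_max=0.5)
    cfg = pair.config
    mafs = sample_mafs(n_snps, spectrum, rng)
    g = simulate_genotypes(cfg.n_total, mafs, rng)
    gw1 = run_gwas(g[pair.idx1], pair.y1, trait="trait1")
    gw2 = run_gwas(g[pair.idx2], pair.y2, trait="trait2")
    z1, z2, maf = gwas_zscore_pair(gw1, gw2, mafs)
    return _estimate_from_z(z1, z2, maf, "random_snp", None, cfg.overlap)


def simulate_single_snp_zscores(
    params,
    overlap: OverlapSpec,
    n_reps: int = 2000,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate the single-SNP bivariate association model n_reps times.

    Each replicate draws one HWE genotype column at frequency ``params.f``
    for the n1 + n2 - n0 individuals, a fresh effect pair (correlation r_g,
    variances sigma_b^2 on the allele-count scale), residual pairs correlated
    r_e on the overlap block, and returns the two least-squares Z-scores.
    The empirical correlation of the returned arrays estimates the closed
    form ``theory.zscore_cor_theory(params, overlap)``.

    Vectorized across replicates (columns); replicates where a genotype draw
    is monomorphic are redrawn not at all — they are dropped, which slightly
    reduces the effective replicate count at very low f.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1, n2, n0 = int(overlap.n1), int(overlap.n2), int(overlap.n0)
    nt = n1 + n2 - n0
    g = simulate_genotypes(nt, np.full(n_reps, params.f), rng).astype(np.float64)
    betas = np.empty((n_reps, 2))
    v1, v2 = params.sigma_b1_sq, params.sigma_b2_sq
    u = rng.standard_normal((n_reps, 2))
    betas[:, 0] = math.sqrt(v1) * u[:, 0]
    betas[:, 1] = math.sqrt(v2) * (
        params.r_g * u[:, 0] + math.sqrt(1.0 - params.r_g**2) * u[:, 1]
    )
    s1 = math.sqrt(params.sigma_e1_sq)
    s2 = math.sqrt(params.sigma_e2_sq)
    e1 = np.empty((n1, n_reps))
    e2 = np.empty((n2, n_reps))
    a = rng.standard_normal((n0, n_reps))
    b = rng.standard_normal((n0, n_reps))
    e1[:n0] = s1 * a
    e2[:n0] = s2 * (params.r_e * a + math.sqrt(1.0 - params.r_e**2) * b)
    e1[n0:] = s1 * rng.standard_normal((n1 - n0, n_reps))
    e2[n0:] = s2 * rng.standard_normal((n2 - n0, n_reps))

    g1 = g[:n1]
    g2 = np.vstack([g[:n0], g[n1:]])
    y1 = g1 * betas[:, 0] + e1
    y2 = g2 * betas[:, 1] + e2

    def _col_regress(gmat, ymat):
        n = gmat.shape[0]
        yc = ymat - ymat.mean(axis=0)
        gg = (gmat * gmat).sum(axis=0) - gmat.sum(axis=0) ** 2 / n
        gy = (gmat * yc).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = gy / gg
            rss = np.maximum((yc * yc).sum(axis=0) - beta * gy, 0.0)
            se = np.sqrt(rss / (n - 2) / gg)
            return beta / se, gg > 0

    z1, ok1 = _col_regress(g1, y1)
    z2, ok2 = _col_regress(g2, y2)
    keep = ok1 & ok2 & np.isfinite(z1) & np.isfinite(z2)
    return z1[keep], z2[keep]


#: the validation study's estimator grid: four MAF cutoffs (0.5 = all SNPs),
#: three Z cutoffs, and the 500-random-SNP estimator
DEFAULT_METHOD_GRID: tuple = (
    ("low_maf", 0.5),
    ("low_maf", 0.05),
    ("low_maf", 0.005),
    ("low_maf", 5e-4),
    ("z_cut", 0.5),
    ("z_cut", 1.0),
    ("z_cut", 2.0),
    ("random_snp", None),
)


@dataclass
class SimStudyResult:
    """Long-format estimates from a replicated simulation study."""

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Per (scenario, method, cutoff): mean/SD of estimates, mean SE, SE/SD."""
        ok = self.records[self.records["failed"] == False]  # noqa: E712
        grp = ok.groupby(["scenario", "method", "cutoff"], dropna=False)
        out = grp.agg(
            mean_estimate=("estimate", "mean"),
            sd_estimate=("estimate", "std"),
            mean_se=("se", "mean"),
            mean_n_snps=("n_snps", "mean"),
            n_replicates=("replicate", "count"),
            true_r_p=("true_r_p", "first"),
        ).reset_index()
        out["se_sd_ratio"] = out["mean_se"] / out["sd_estimate"]
        return out


def simulate_replicate(config: SimConfig, seed) -> tuple:
    """One replicate: mafs, genotypes, phenotypes, both GWAS, aligned Z-scores."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = sample_mafs(config.m, config.maf_spectrum, rng)
    genotypes = simulate_genotypes(config.n_total, mafs, rng)
    pair = simulate_phenotype_pair(config, genotypes, mafs, rng)
    gw1 = run_gwas(genotypes[pair.idx1], pair.y1, trait="trait1")
    gw2 = run_gwas(genotypes[pair.idx2], pair.y2, trait="trait2")
    z1, z2, maf = gwas_zscore_pair(gw1, gw2, mafs)
    return pair, (z1, z2, maf), rng


def run_simulation_study(
    configs,
    replicates: int = 30,
    seed: int = 0,
    methods: Sequence = DEFAULT_METHOD_GRID,
) -> SimStudyResult:
    """Run the estimator-comparison study over scenarios and replicates.

    Parameters
    ----------
    configs : SimConfig, sequence of SimConfig, or dict label -> SimConfig
        The scenarios to simulate.
    replicates : int
        Replicates per scenario (the validation design uses 30).
    seed : int
        Master seed; each (scenario, replicate) gets an independent child
        stream, so results are reproducible and scenario order-free.
    methods : sequence of (method, cutoff)
        Estimators to apply per replicate; the individual-level truth is
        always recorded when the overlap allows it.
    """
    if isinstance(configs, SimConfig):
        configs = {"scenario0": configs}
    elif not isinstance(configs, dict):
        configs = {f"scenario{i}": c for i, c in enumerate(configs)}
    if not configs:
        raise ValueError("empty scenario grid")

    root = np.random.SeedSequence(seed)
    scenario_seeds = root.spawn(len(configs))
    rows = []
    for s_i, (label, cfg) in enumerate(configs.items()):
        children = scenario_seeds[s_i].spawn(replicates)
        for rep in range(replicates):
            rng = np.random.default_rng(children[rep])
            pair, (z1, z2, maf), rng = simulate_replicate(cfg, rng)
            base = dict(scenario=label, replicate=rep, true_r_p=cfg.true_r_p,
                        true_r_p_individual=pair.true_r_p_individual)
            if pair.true_r_p_individual is not None:
                rows.append(dict(base, method="individual", cutoff=np.nan,
                                 estimate=pair.true_r_p_individual,
                                 r_adjusted=pair.true_r_p_individual,
                                 se=np.nan, n_snps=cfg.n0, failed=False))
            for method, cutoff in methods:
                try:
                    if method == "random_snp":
                        est = random_snp_estimator(pair, seed=rng)
                    else:
                        est = _estimate_from_z(z1, z2, maf, method, cutoff,
                                               cfg.overlap)
                    rows.append(dict(base, method=method,
                                     cutoff=np.nan if cutoff is None else cutoff,
                                     estimate=est.r_raw,
                                     r_adjusted=est.r_adjusted,
                                     se=est.se_raw, n_snps=est.n_snps,
                                     failed=False))
                except ValueError as exc:
                    logger.warning("scenario %s rep %d %s(%s) failed: %s",
                                   label, rep, method, cutoff, exc)
                    rows.append(dict(base, method=method,
                                     cutoff=np.nan if cutoff is None else cutoff,
                                     estimate=np.nan, r_adjusted=np.nan,
                                     se=np.nan, n_snps=0, failed=True))
    return SimStudyResult(records=pd.DataFrame(rows))
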