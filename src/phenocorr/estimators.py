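"""Phenotypic-correlation estimators from harmonized GWAS Z-scores.

The estimators share one computation — the Pearson correlation of the two
traits' per-SNP Z-scores over a selected SNP subset — and differ only in the
selection rule:

* ``LowMafCorrelation`` keeps SNPs with minor allele frequency strictly below
  a cutoff (default 5e-4). Rare variants explain negligible phenotypic
  variance, so their Z-score correlation converges to the phenotypic
  correlation without constraining the association statistics themselves.
* ``ZCutCorrelation`` keeps SNPs with |z| strictly below a bound on *both*
  traits — the classical "putative null SNP" strategy, retained here as the
  known-biased comparator (truncating on Z attenuates the correlation).
* ``AllSnpCorrelation`` uses every SNP.

When the two GWAS only partially share samples (N0 < N1, N2), the raw
Z-score correlation is shrunk by N0/sqrt(N1*N2); ``shrinkage_adjust`` undoes
that factor. Standard errors treat the selected low-MAF SNPs as independent
(their LD is negligible) and are back-calculated from the Wald p-value of
the Pearson correlation test.

The classes follow the scikit-learn estimator contract (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes); the
module-level functions are thin wrappers returning ``CorrEstimate`` records.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .sumstats import HarmonizedPair, SumStatsTable, harmonize_pair

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapSpec",
    "CorrEstimate",
    "PairMatrixResult",
    "LowMafCorrelation",
    "ZCutCorrelation",
    "AllSnpCorrelation",
    "zscore_correlation",
    "low_maf_estimate",
    "zcut_estimate",
    "all_snp_estimate",
    "shrinkage_adjust",
    "wald_se_from_p",
    "analytic_se",
    "pairwise_matrix",
]

#: below this overlap fraction the shrinkage adjustment is flagged unreliable
SMALL_OVERLAP_THRESHOLD = 0.1
#: below this SNP count a low-precision warning is emitted
MIN_RECOMMENDED_SNPS = 100


@dataclass(frozen=True)
class OverlapSpec:
    """Sample sizes of two GWAS and their overlap.

    n0 individuals appear in both studies; the Z-score correlation of null
    variants equals the phenotypic correlation times
    ``shrinkage = n0 / sqrt(n1 * n2)``.
    """

    n1: float
    n2: float
    n0: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("n1 and n2 must be >= 1")
        if not 0 <= self.n0 <= min(self.n1, self.n2):
            raise ValueError("n0 must satisfy 0 <= n0 <= min(n1, n2)")

    @property
    def shrinkage(self) -> float:
        return self.n0 / math.sqrt(self.n1 * self.n2)

    @classmethod
    def full(cls, n: float) -> "OverlapSpec":
        return cls(n1=n, n2=n, n0=n)


@dataclass
class CorrEstimate:
    """An estimated phenotypic correlation with provenance.

    ``r_raw`` is the Pearson correlation of the selected Z-score pairs;
    ``r_adjusted = r_raw / shrinkage`` recovers the full-overlap phenotypic
    correlation and may legitimately fall outside [-1, 1] when the overlap is
    small — such values are flagged (``out_of_range``), never clamped.
    """

    method: str
    cutoff: Optional[float]
    n_snps: int
    r_raw: float
    se_raw: float
    p: float
    r_adjusted: float
    se_adjusted: float
    shrinkage: float
    small_overlap_warning: bool = False
    out_of_range: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def zscore_correlation(z1, z2) -> float:
    """Pearson product-moment correlation of two Z-score vectors.

    Raises on fewer than 3 SNPs or a constant input (naming which trait).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z1 and z2 must have equal length")
    if z1.size < 3:
        raise ValueError(f"need at least 3 SNPs, got {z1.size}")
    if np.std(z1) == 0:
        raise ValueError("z-scores of trait 1 are constant")
    if np.std(z2) == 0:
        raise ValueError("z-scores of trait 2 are constant")
    return float(np.corrcoef(z1, z2)[0, 1])


def analytic_se(r: float, n_snps: int) -> float:
    """Large-sample standard error sqrt((1 - r^2) / (n - 2)) of a correlation."""
    if n_snps < 3:
        raise ValueError("n_snps must be >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return math.sqrt((1.0 - r * r) / (n_snps - 2))


def corr_pvalue(r: float, n_snps: int) -> float:
    """Two-sided p-value of the Pearson correlation t-test with n-2 df."""
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt((n_snps - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n_snps - 2))


def wald_se_from_p(r: float, n_snps: int) -> float:
    """Standard error back-calculated from the correlation test's p-value.

    The t statistic of the Pearson correlation, t = r * sqrt((n-2)/(1-r^2)),
    gives a two-sided p-value under t_{n-2}; the Wald standard error is then
    |r| divided by the upper-(p/2) standard-normal quantile. Valid because
    low-MAF SNPs are nearly LD-free, so the n_snps Z-score pairs can be
    treated as independent observations. Falls back to the analytic SE at
    r = 0 where the quantile is undefined.

    The computation runs in log space (``scipy.special.ndtri_exp``) so it
    stays finite for very small p-values.
    """
    if n_snps < 4:
        raise ValueError("n_snps must be >= 4")
    if abs(r) >= 1:
        raise ValueError("|r| = 1 is degenerate; no finite SE exists")
    if r == 0.0:
        return analytic_se(0.0, n_snps)
    t = abs(r) * math.sqrt((n_snps - 2) / (1.0 - r * r))
    log_half_p = stats.t.logsf(t, df=n_snps - 2)  # log(p/2) for two-sided p
    if math.isfinite(log_half_p):
        q = -special.ndtri_exp(log_half_p)  # norm.isf(p/2)
    else:
        # t so extreme the log-sf underflows: Wallace's normal-quantile
        # approximation of the t tail, accurate to <0.2% here
        nu = n_snps - 2
        q = (8 * nu + 1) / (8 * nu + 3) * math.sqrt(nu * math.log1p(t * t / nu))
    return abs(r) / q


def shrinkage_adjust(r_raw: float, overlap: OverlapSpec) -> tuple[float, bool]:
    """Undo the sample-overlap shrinkage of a raw Z-score correlation.

    Returns ``(r_raw * sqrt(n1*n2)/n0, small_overlap_warning)``. The result
    is never clamped to [-1, 1]; with a small overlap fraction the adjustment
    amplifies noise and the warning flag is set (below
    ``SMALL_OVERLAP_THRESHOLD``).
    """
    if overlap.n0 < 1:
        raise ValueError(
            "n0 = 0: non-overlapping samples carry no information about the "
            "phenotypic correlation"
        )
    shrink = overlap.shrinkage
    warn = shrink < SMALL_OVERLAP_THRESHOLD
    if warn:
        logger.warning(
            "overlap fraction %.3g < %.2g: shrinkage adjustment is unreliable",
            shrink, SMALL_OVERLAP_THRESHOLD,
        )
    return r_raw / shrink, warn


def _unpack(X, maf=None):
    """Accept a HarmonizedPair, an (n, 2|3) array, or a (z1, z2[, maf]) tuple."""
    if isinstance(X, HarmonizedPair):
        return X.z1, X.z2, X.maf
    if isinstance(X, (tuple, list)) and len(X) in (2, 3):
        z1 = np.asarray(X[0], dtype=float)
        z2 = np.asarray(X[1], dtype=float)
        m = np.asarray(X[2], dtype=float) if len(X) == 3 else maf
        return z1, z2, (np.asarray(m, dtype=float) if m is not None else None)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] not in (2, 3):
        raise ValueError(
            "X must be a HarmonizedPair or an array of shape (n_snps, 2) or "
            "(n_snps, 3) with columns z1, z2[, maf]"
        )
    m = X[:, 2] if X.shape[1] == 3 else (np.asarray(maf, float) if maf is not None else None)
    return X[:, 0], X[:, 1], m


class _ZScoreCorrelationBase(BaseEstimator):
    """Shared fit logic: select SNPs, correlate Z-scores, attach SE/p/shrinkage."""

    method = "all_snp"

    def __init__(self, overlap: Optional[OverlapSpec] = None):
        self.overlap = overlap

    def _select(self, z1, z2, maf):  # pragma: no cover - overridden
        return np.ones(len(z1), dtype=bool)

    def _cutoff(self) -> Optional[float]:
        return None

    def fit(self, X, y=None, *, maf=None):
        """Estimate the phenotypic correlation from Z-score pairs.

        Parameters
        ----------
        X : HarmonizedPair, array of shape (n_snps, 2) or (n_snps, 3), or tuple
            Per-SNP Z-scores for the two traits; the third column (or the
            ``maf`` keyword) carries per-SNP minor allele frequencies where
            the selection rule needs them.
        y : ignored
            Present for scikit-learn API compatibility.
        """
        z1, z2, maf_arr = _unpack(X, maf)
        sel = self._select(z1, z2, maf_arr)
        n_sel = int(sel.sum())
        if n_sel < 3:
            self._raise_empty(z1, z2, maf_arr, n_sel)
        if n_sel < MIN_RECOMMENDED_SNPS:
            warnings.warn(
                f"{self.method}: only {n_sel} SNPs selected; the estimate "
                "will be imprecise",
                UserWarning,
                stacklevel=2,
            )
        r = zscore_correlation(z1[sel], z2[sel])
        self.n_snps_ = n_sel
        self.r_raw_ = r
        self.se_raw_ = wald_se_from_p(r, n_sel) if abs(r) < 1 else 0.0
        self.p_value_ = corr_pvalue(r, n_sel)
        if self.overlap is None:
            logger.info(
                "%s: no OverlapSpec given; assuming fully overlapping samples "
                "(shrinkage factor 1)", self.method,
            )
            self.shrinkage_ = 1.0
            self.small_overlap_warning_ = False
            self.r_adjusted_ = r
            self.se_adjusted_ = self.se_raw_
        else:
            self.shrinkage_ = self.overlap.shrinkage
            self.r_adjusted_, self.small_overlap_warning_ = shrinkage_adjust(
                r, self.overlap
            )
            self.se_adjusted_ = self.se_raw_ / self.shrinkage_
        self.out_of_range_ = abs(self.r_adjusted_) > 1.0
        if self.out_of_range_:
            logger.warning(
                "%s: shrinkage-adjusted correlation %.4g lies outside [-1, 1]",
                self.method, self.r_adjusted_,
            )
        return self

    def _raise_empty(self, z1, z2, maf, n_sel):
        raise ValueError(
            f"{self.method}: only {n_sel} SNPs pass the filter (need >= 3)"
        )

    def to_estimate(self) -> CorrEstimate:
        """Return the fitted result as a CorrEstimate record."""
        return CorrEstimate(
            method=self.method,
            cutoff=self._cutoff(),
            n_snps=self.n_snps_,
            r_raw=self.r_raw_,
            se_raw=self.se_raw_,
            p=self.p_value_,
            r_adjusted=self.r_adjusted_,
            se_adjusted=self.se_adjusted_,
            shrinkage=self.shrinkage_,
            small_overlap_warning=self.small_overlap_warning_,
            out_of_range=self.out_of_range_,
        )


class LowMafCorrelation(_ZScoreCorrelationBase):
    """Phenotypic correlation from Z-scores of rare variants (MAF < maf_max).

    The recommended estimator: selecting on allele frequency places no
    constraint on the association statistics, so no truncation bias arises,
    and the near-zero LD among rare variants makes the back-calculated Wald
    SE well calibrated.

    Parameters
    ----------
    maf_max : float
        Strict upper MAF bound; default 5e-4 (recommended when enough SNPs
        survive; 0.5 retains every SNP).
    overlap : OverlapSpec, optional
        Sample sizes and overlap for the shrinkage adjustment; when omitted,
        fully overlapping samples are assumed (shrinkage 1).
    """

    method = "low_maf"

    def __init__(self, maf_max: float = 5e-4, overlap: Optional[OverlapSpec] = None):
        super().__init__(overlap=overlap)
        self.maf_max = maf_max

    def _cutoff(self):
        return self.maf_max

    def _select(self, z1, z2, maf):
        if maf is None:
            raise ValueError("low_maf selection requires per-SNP MAF values")
        maf = np.asarray(maf, dtype=float)
        return np.isfinite(maf) & (maf < self.maf_max)

    def _raise_empty(self, z1, z2, maf, n_sel):
        finite = np.asarray(maf, float)
        finite = finite[np.isfinite(finite)]
        smallest = finite.min() if len(finite) else math.nan
        raise ValueError(
            f"low_maf: {n_sel} SNPs with MAF < {self.maf_max:g} (need >= 3); "
            f"smallest available MAF is {smallest:g}"
        )


class ZCutCorrelation(_ZScoreCorrelationBase):
    """Phenotypic correlation from putative-null SNPs with |z| < z_max.

    The classical strategy, kept as a comparator: thresholding on the
    Z-scores truncates the bivariate Z distribution to a box and attenuates
    the correlation toward zero (see ``theory.truncated_corr_oracle``). The
    filter is applied jointly: a SNP must satisfy the bound on both traits.
    """

    method = "z_cut"

    def __init__(self, z_max: float = 2.0, overlap: Optional[OverlapSpec] = None):
        super().__init__(overlap=overlap)
        self.z_max = z_max

    def _cutoff(self):
        return self.z_max

    def _select(self, z1, z2, maf):
        if self.z_max <= 0:
            raise ValueError("z_max must be positive")
        return (np.abs(z1) < self.z_max) & (np.abs(z2) < self.z_max)


class AllSnpCorrelation(_ZScoreCorrelationBase):
    """Phenotypic correlation from the Z-scores of every available SNP."""

    method = "all_snp"

    def _select(self, z1, z2, maf):
        return np.ones(len(z1), dtype=bool)


def _default_overlap(pair, overlap):
    """Resolve the spec'd default: full overlap at trait 1's median N."""
    if overlap is not None:
        return overlap
    if isinstance(pair, HarmonizedPair) and pair.n1_median:
        logger.info(
            "no OverlapSpec given; assuming full overlap at trait 1's median "
            "sample size %.0f", pair.n1_median,
        )
        return OverlapSpec.full(pair.n1_median)
    return None


def low_maf_estimate(
    pair, maf_max: float = 5e-4, overlap: Optional[OverlapSpec] = None
) -> CorrEstimate:
    """Low-MAF phenotypic-correlation estimate; see LowMafCorrelation."""
    est = LowMafCorrelation(maf_max=maf_max, overlap=_default_overlap(pair, overlap))
    return est.fit(pair).to_estimate()


def zcut_estimate(
    pair, z_max: float = 2.0, overlap: Optional[OverlapSpec] = None
) -> CorrEstimate:
    """Z-cut phenotypic-correlation estimate (biased comparator); see ZCutCorrelation."""
    est = ZCutCorrelation(z_max=z_max, overlap=_default_overlap(pair, overlap))
    return est.fit(pair).to_estimate()


def all_snp_estimate(pair, overlap: Optional[OverlapSpec] = None) -> CorrEstimate:
    """All-SNP Z-score correlation estimate; see AllSnpCorrelation."""
    est = AllSnpCorrelation(overlap=_default_overlap(pair, overlap))
    return est.fit(pair).to_estimate()


@dataclass
class PairMatrixResult:
    """Pairwise phenotypic-correlation matrix over several traits."""

    labels: list
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    estimates: dict
    pairs: pd.DataFrame
    alpha: float
    n_pairs: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_pairs


def pairwise_matrix(
    tables: Sequence[SumStatsTable],
    labels: Optional[Sequence[str]] = None,
    maf_max: float = 5e-4,
    overlaps: Optional[dict] = None,
    alpha: float = 0.05,
    **harmonize_kwargs,
) -> PairMatrixResult:
    """Low-MAF correlation estimates for every unordered pair of traits.

    Each pair is harmonized and estimated independently; significance uses a
    Bonferroni-corrected threshold alpha / n_pairs with n_pairs = T(T-1)/2.
    A pair whose harmonization or estimation fails is recorded as missing
    (NaN), not fatal.

    Parameters
    ----------
    tables : sequence of SumStatsTable
        One table per trait (at least two).
    labels : sequence of str, optional
        Trait names; defaults to trait1, trait2, ...
    maf_max : float
        MAF cutoff for the low-MAF estimator.
    overlaps : dict, optional
        Mapping (label_i, label_j) -> OverlapSpec; missing pairs default to
        the full-overlap assumption.
    alpha : float
        Family-wise significance level.
    """
    t = len(tables)
    if t < 2:
        raise ValueError("need at least 2 traits")
    if labels is None:
        labels = [f"trait{i + 1}" for i in range(t)]
    labels = list(labels)
    if len(labels) != t:
        raise ValueError("labels must match the number of tables")
    n_pairs = t * (t - 1) // 2
    threshold = alpha / n_pairs

    r = pd.DataFrame(np.eye(t), index=labels, columns=labels)
    p = pd.DataFrame(np.nan, index=labels, columns=labels)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    estimates: dict = {}
    rows = []
    for i, j in itertools.combinations(range(t), 2):
        li, lj = labels[i], labels[j]
        ov = None
        if overlaps:
            ov = overlaps.get((li, lj)) or overlaps.get((lj, li))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                pair = harmonize_pair(tables[i], tables[j], **harmonize_kwargs)
                est = low_maf_estimate(pair, maf_max=maf_max, overlap=ov)
        except ValueError as exc:
            logger.warning("pair (%s, %s) failed: %s", li, lj, exc)
            r.loc[li, lj] = r.loc[lj, li] = np.nan
            rows.append(dict(trait1=li, trait2=lj, r=np.nan, se=np.nan,
                             p=np.nan, n_snps=0, significant=False,
                             error=str(exc)))
            continue
        estimates[(li, lj)] = est
        r.loc[li, lj] = r.loc[lj, li] = est.r_adjusted
        p.loc[li, lj] = p.loc[lj, li] = est.p
        is_sig = est.p < threshold
        sig.loc[li, lj] = sig.loc[lj, li] = is_sig
        rows.append(dict(trait1=li, trait2=lj, r=est.r_adjusted,
                         se=est.se_adjusted, p=est.p, n_snps=est.n_snps,
                         significant=is_sig, error=""))
    return PairMatrixResult(
        labels=labels, r=r, p=p, significant=sig, estimates=estimates,
        pairs=pd.DataFrame(rows), alpha=alpha, n_pairs=n_pairs,
    )
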