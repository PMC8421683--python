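"""Reading, validation and harmonization of GWAS summary-statistics tables.

Two traits' Z-scores are only comparable SNP-by-SNP if both are expressed
relative to the same effect allele. This module reads delimited summary
files (tab or whitespace, optionally gzipped) into a canonical table, then
aligns two tables on shared variants: when the second table's effect/other
alleles are swapped relative to the first, its Z-score is negated; variants
whose allele sets disagree even after the swap check are dropped, as are
strand-ambiguous palindromic (A/T, C/G) variants by default. Strand flips
are never guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnMap",
    "SumStatsTable",
    "HarmonizedPair",
    "read_sumstats",
    "write_sumstats",
    "harmonize_pair",
]

#: canonical column order of a SumStatsTable data frame
CANONICAL_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "z",
    "n",
    "p",
)

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

# header synonyms recognised by ColumnMap.infer, checked case-insensitively
_SYNONYMS = {
    "snp_id": ("SNP", "SNP_ID", "RSID", "ID", "MARKERNAME", "VARIANT_ID"),
    "effect_allele": ("A1", "EFFECT_ALLELE", "EA", "ALLELE1"),
    "other_allele": ("A2", "OTHER_ALLELE", "OA", "NEA", "ALLELE0", "ALLELE2"),
    "eaf": ("FREQ", "EAF", "A1FREQ", "FRQ", "AF", "MAF"),
    "beta": ("BETA", "B", "EFFECT"),
    "se": ("SE", "STDERR", "STDERRLOGOR"),
    "z": ("Z", "ZSCORE", "TSTAT", "Z_STAT"),
    "n": ("N", "NMISS", "N_COMPLETE_SAMPLES"),
    "p": ("P", "PVAL", "PVALUE", "P_VALUE"),
}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical summary-statistics fields to source headers.

    ``snp_id`` is mandatory; every other field may be None (absent). At least
    one route to a Z-score must exist: a ``z`` column, ``beta`` + ``se``, or
    ``beta`` + ``p``.
    """

    snp_id: str = "SNP"
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    eaf: Optional[str] = None
    beta: Optional[str] = None
    se: Optional[str] = None
    z: Optional[str] = None
    n: Optional[str] = None
    p: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("a snp_id column mapping is required")
        if self.z is None and not (self.beta and self.se) and not (self.beta and self.p):
            raise ValueError(
                "no route to a Z-score: map a z column, or beta+se, or beta+p"
            )

    @classmethod
    def ldsc(cls) -> "ColumnMap":
        """The LDSC munged-sumstats dialect: 'SNP A1 A2 N Z'."""
        return cls(snp_id="SNP", effect_allele="A1", other_allele="A2", n="N", z="Z")

    @classmethod
    def infer(cls, header) -> "ColumnMap":
        """Build a mapping from a file header using common column synonyms."""
        lookup = {h.upper(): h for h in header}
        found: dict[str, str] = {}
        for canon, names in _SYNONYMS.items():
            for name in names:
                if name in lookup:
                    found[canon] = lookup[name]
                    break
        if "snp_id" not in found:
            raise ValueError(
                f"cannot infer a variant-id column from header {list(header)}"
            )
        return cls(**found)

    def items(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is not None:
                yield f.name, v


@dataclass
class SumStatsTable:
    """Per-SNP GWAS summary statistics for one trait.

    ``df`` holds the canonical columns (missing fields are NaN); ``z`` is
    always populated for every retained row. Row counts dropped during
    reading are kept in ``n_dropped``.
    """

    df: pd.DataFrame
    n_dropped: int = 0
    source: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        for c in missing:
            self.df[c] = np.nan
        self.df = self.df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicated snp_id values: {sorted(set(dup.astype(str)))[:10]}"
            )
        both = self.df["beta"].notna() & self.df["se"].notna() & self.df["z"].notna()
        if both.any():
            sub = self.df[both]
            resid = np.abs(sub["z"] - sub["beta"] / sub["se"])
            bad = resid > 1e-6 * np.maximum(1.0, np.abs(sub["z"]))
            if bad.any():
                logger.warning(
                    "%d rows have z inconsistent with beta/se (kept as-is)",
                    int(bad.sum()),
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def maf(self) -> pd.Series:
        """Minor-allele frequency min(eaf, 1-eaf); NaN where eaf missing."""
        eaf = self.df["eaf"]
        return np.minimum(eaf, 1.0 - eaf)

    @property
    def median_n(self) -> Optional[float]:
        n = self.df["n"].dropna()
        return float(n.median()) if len(n) else None


@dataclass
class HarmonizedPair:
    """Allele-aligned Z-score pairs over the SNPs shared by two traits."""

    snp_id: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    maf: np.ndarray
    n_matched: int = 0
    n_flipped: int = 0
    n_dropped_allele_mismatch: int = 0
    n_dropped_palindromic: int = 0
    n_dropped_missing: int = 0
    n1_median: Optional[float] = None
    n2_median: Optional[float] = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id)
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if not (len(self.z1) == len(self.z2) == len(self.maf) == len(self.snp_id)):
            raise ValueError("z1, z2, maf and snp_id must have identical length")
        self.n_matched = len(self.z1)
        finite = self.maf[np.isfinite(self.maf)]
        if len(finite) and (finite.max() > 0.5 + 1e-12 or finite.min() < 0):
            raise ValueError("maf values must lie in [0, 0.5]")

    def __len__(self) -> int:
        return self.n_matched


def _fill_z(df: pd.DataFrame) -> pd.DataFrame:
    """Populate z from the best available route; drop rows with none."""
    z = df["z"].copy()
    need = z.isna()
    route_bs = need & df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
    z[route_bs] = df.loc[route_bs, "beta"] / df.loc[route_bs, "se"]
    need = z.isna()
    route_p = (
        need
        & df["beta"].notna()
        & df["p"].notna()
        & (df["p"] > 0)
        & (df["p"] <= 1)
    )
    if route_p.any():
        sub = df[route_p]
        z[route_p] = np.sign(sub["beta"]) * stats.norm.isf(sub["p"] / 2.0)
    df = df.assign(z=z)
    return df[z.notna()]


def read_sumstats(path, colmap: Optional[ColumnMap] = None) -> SumStatsTable:
    """Read a delimited (optionally gzipped) summary-statistics file.

    Parameters
    ----------
    path : str or Path
        Tab- or whitespace-delimited text file with a header; ``.gz`` handled
        transparently.
    colmap : ColumnMap, optional
        Source-header mapping. When omitted, inferred from common synonyms
        (covers the LDSC 'SNP A1 A2 N Z' dialect).

    Returns
    -------
    SumStatsTable
        Canonical table with ``z`` populated for every retained row (from the
        z column, else beta/se, else the signed inverse-normal of p/2). Rows
        with no computable Z-score or unparsable numerics are dropped and
        counted in ``n_dropped``.
    """
    raw = pd.read_csv(path, sep=r"\s+", compression="infer", dtype=str)
    if colmap is None:
        colmap = ColumnMap.infer(raw.columns)
    missing = [src for _, src in colmap.items() if src not in raw.columns]
    if missing:
        raise ValueError(f"mapped columns absent from header of {path}: {missing}")

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    n_in = len(df)
    if "snp_id" not in df.columns:
        raise ValueError("snp_id column is required")

    for col in ("effect_allele", "other_allele"):
        if col in df.columns:
            df[col] = df[col].str.upper()
    for col in ("eaf", "beta", "se", "z", "n", "p"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    if "effect_allele" not in df.columns:
        df["effect_allele"] = pd.NA
    if "other_allele" not in df.columns:
        df["other_allele"] = pd.NA

    # rows whose mapped numeric fields failed to parse are dropped, not imputed
    parse_ok = pd.Series(True, index=df.index)
    for canon, src in colmap.items():
        if canon in ("eaf", "beta", "se", "z", "n", "p"):
            parse_ok &= df[canon].notna() | raw[src].isna()
    df = df[parse_ok]
    df = df[df["snp_id"].notna()]
    df = _fill_z(df)
    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d rows with no usable Z-score", path, n_dropped)
    return SumStatsTable(df=df.reset_index(drop=True), n_dropped=n_dropped, source=str(path))


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a SumStatsTable as tab-delimited text (gzipped iff path ends .gz)."""
    out = table.df.copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    pairs = [a1.eq("A") & a2.eq("T"), a1.eq("T") & a2.eq("A"),
             a1.eq("C") & a2.eq("G"), a1.eq("G") & a2.eq("C")]
    out = pairs[0]
    for p in pairs[1:]:
        out = out | p
    return out


def harmonize_pair(
    t1: SumStatsTable,
    t2: SumStatsTable,
    drop_palindromic: bool = True,
    maf_source: str = "t1",
    assume_aligned: bool = False,
    require_maf: bool = True,
) -> HarmonizedPair:
    """Align two traits' Z-scores on shared SNPs with a common effect allele.

    Parameters
    ----------
    t1, t2 : SumStatsTable
        Tables for the two traits; both need allele columns unless
        ``assume_aligned`` is set.
    drop_palindromic : bool
        Drop strand-ambiguous A/T and C/G SNPs (default True).
    maf_source : {'t1', 't2', 'mean'}
        Which table's allele frequency provides the per-SNP MAF.
    assume_aligned : bool
        Skip allele logic entirely (both tables coded on the same allele).
        If allele columns are nevertheless present they are still honoured,
        with a warning.
    require_maf : bool
        Drop SNPs without a usable MAF (needed by the low-MAF filter). Set
        False to retain them with NaN maf, e.g. for all-SNP or Z-cut use on
        frequency-free dialects.

    Returns
    -------
    HarmonizedPair
        Aligned z1/z2/maf arrays plus bookkeeping counters; z2 is negated
        wherever t2's effect and other alleles are swapped relative to t1.
    """
    if maf_source not in ("t1", "t2", "mean"):
        raise ValueError("maf_source must be 't1', 't2' or 'mean'")
    d1 = t1.df.set_index("snp_id")
    d2 = t2.df.set_index("snp_id")
    shared = d1.index.intersection(d2.index)
    if len(shared) == 0:
        raise ValueError("no shared SNP ids between the two tables")
    a = d1.loc[shared]
    b = d2.loc[shared]

    have_alleles = (
        a["effect_allele"].notna().all()
        and a["other_allele"].notna().all()
        and b["effect_allele"].notna().all()
        and b["other_allele"].notna().all()
    )
    if not have_alleles and not assume_aligned:
        raise ValueError(
            "allele columns are incomplete; pass assume_aligned=True only if "
            "both tables are known to share effect-allele orientation"
        )
    if assume_aligned and have_alleles:
        logger.warning(
            "assume_aligned set but allele columns present; allele logic still applied"
        )

    n_pal = 0
    n_mismatch = 0
    if have_alleles:
        ea1, oa1 = a["effect_allele"], a["other_allele"]
        ea2, oa2 = b["effect_allele"], b["other_allele"]
        valid = (
            ea1.isin(_VALID_ALLELES) & oa1.isin(_VALID_ALLELES)
            & ea2.isin(_VALID_ALLELES) & oa2.isin(_VALID_ALLELES)
        )
        pal = _is_palindromic(ea1, oa1) & valid
        same = (ea1 == ea2) & (oa1 == oa2) & valid
        swapped = (ea1 == oa2) & (oa1 == ea2) & valid & ~same
        if drop_palindromic:
            n_pal = int(pal.sum())
            same &= ~pal
            swapped &= ~pal
        keep = same | swapped
        n_mismatch = int(len(shared) - keep.sum() - n_pal)
        sign2 = np.where(swapped, -1.0, 1.0)
        eaf2 = np.where(swapped, 1.0 - b["eaf"], b["eaf"])
    else:
        keep = pd.Series(True, index=shared)
        sign2 = np.ones(len(shared))
        eaf2 = b["eaf"].to_numpy()

    z1 = a["z"].to_numpy(dtype=float)
    z2 = b["z"].to_numpy(dtype=float) * sign2
    maf1 = np.minimum(a["eaf"], 1.0 - a["eaf"]).to_numpy(dtype=float)
    maf2 = np.minimum(eaf2, 1.0 - eaf2).astype(float)
    if maf_source == "t1":
        maf = maf1
    elif maf_source == "t2":
        maf = maf2
    else:
        maf = np.nanmean(np.column_stack([maf1, maf2]), axis=1)

    keep_arr = keep.to_numpy()
    usable = np.isfinite(z1) & np.isfinite(z2)
    if require_maf:
        usable &= np.isfinite(maf)
    n_missing = int((keep_arr & ~usable).sum())
    keep_arr = keep_arr & usable

    pair = HarmonizedPair(
        snp_id=np.asarray(shared)[keep_arr],
        z1=z1[keep_arr],
        z2=z2[keep_arr],
        maf=maf[keep_arr],
        n_flipped=int(np.sum(keep_arr & (sign2 < 0))),
        n_dropped_allele_mismatch=n_mismatch,
        n_dropped_palindromic=n_pal,
        n_dropped_missing=n_missing,
        n1_median=t1.median_n,
        n2_median=t2.median_n,
    )
    logger.info(
        "harmonize_pair: matched=%d flipped=%d dropped_mismatch=%d "
        "dropped_palindromic=%d dropped_missing=%d",
        pair.n_matched, pair.n_flipped, pair.n_dropped_allele_mismatch,
        pair.n_dropped_palindromic, pair.n_dropped_missing,
    )
    return pair
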