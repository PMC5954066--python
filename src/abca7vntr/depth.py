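"""Short-read depth over the repeat core as a rank proxy for VNTR length.

Absolute allele lengths cannot be read from short-read data over a long
GC-rich tandem repeat, but the number of reads aligning inside the
breakpoint-excluding core scales with diploid repeat content, so normalized
core coverage orders samples by VNTR length and supports nonparametric
association against SNP genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GenomicInterval

logger = logging.getLogger(__name__)

#: Samples with this many or fewer core reads are excluded as unreliable.
MIN_CORE_READS = 5

# SAM flag bits for secondary / supplementary alignments.
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


def core_coverage(reads: pd.DataFrame, core: GenomicInterval) -> pd.Series:
    """Count reads overlapping the repeat core by at least one base.

    ``reads`` columns: ``sample``, ``chrom``, ``start``, ``end`` (0-based
    half-open) and optionally ``flag``; secondary and supplementary
    alignments are excluded when flags are present, duplicates are counted
    as given.  Reads on another chromosome contribute zero (with a logged
    warning).  Returns a count per sample, indexed by sample id, including
    zeros for samples whose reads never touch the core.
    """
    required = {"sample", "chrom", "start", "end"}
    missing = required - set(reads.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    df = reads
    if "flag" in df.columns:
        flag = df["flag"].fillna(0).astype(int)
        df = df.loc[(flag & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY)) == 0]
    on_chrom = df["chrom"] == core.chrom
    if (~on_chrom).any():
        logger.warning(
            "%d reads on other chromosomes than %s ignored",
            int((~on_chrom).sum()), core.chrom,
        )
    overlap = on_chrom & (df["start"] < core.end) & (df["end"] > core.start)
    counts = df.loc[overlap].groupby("sample").size()
    return counts.reindex(df["sample"].unique(), fill_value=0).rename("core_reads")


@dataclass(frozen=True)
class CoverageStat:
    sample: str
    core_reads: int
    total_reads: int
    normalized: float
    included: bool
    exclusion_reason: str = ""


def normalize_and_filter(
    coverage: pd.DataFrame, min_core_reads: int = MIN_CORE_READS
) -> pd.DataFrame:
    """Normalize core counts by total reads and apply the low-coverage filter.

    ``coverage`` columns: ``sample``, ``core_reads``, ``total_reads``.
    Samples with ``core_reads <= min_core_reads`` are excluded
    (``reason='low_coverage'``); zero total reads is a distinct reason.
    Returns the table with ``normalized``, ``included`` and
    ``exclusion_reason`` columns; an all-excluded result is legal and logged.
    """
    df = coverage.copy()
    if (df["core_reads"] > df["total_reads"]).any():
        raise ValueError("core_reads exceeds total_reads for some sample")
    zero_total = df["total_reads"] <= 0
    low = df["core_reads"] <= min_core_reads
    df["normalized"] = np.where(
        zero_total, np.nan, df["core_reads"] / df["total_reads"].replace(0, np.nan)
    )
    df["included"] = ~(zero_total | low)
    df["exclusion_reason"] = ""
    df.loc[low, "exclusion_reason"] = "low_coverage"
    df.loc[zero_total, "exclusion_reason"] = "zero_total_reads"
    if not df["included"].any():
        logger.warning("all %d samples excluded by the coverage filter", len(df))
    return df


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float
    group_sizes: tuple[int, ...]


def genotypic_kruskal(values: np.ndarray, genotypes: np.ndarray) -> KruskalResult:
    """Kruskal-Wallis rank-sum test of a value across genotype groups.

    Genotypes are 0/1/2 copies of the risk allele; only groups that are
    present contribute.  Tie-corrected; a fully tied sample (all values
    identical) yields H = 0, p = 1 rather than an undefined statistic.
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    if values.shape != genotypes.shape:
        raise ValueError("values and genotypes must align")
    groups = [values[genotypes == g] for g in np.unique(genotypes)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("no contrast: need at least two non-empty genotype groups")
    if np.all(values == values[0]):
        return KruskalResult(h=0.0, df=len(groups) - 1, p=1.0,
                             group_sizes=tuple(len(g) for g in groups))
    h, p = stats.kruskal(*groups)
    return KruskalResult(h=float(h), df=len(groups) - 1, p=float(p),
                         group_sizes=tuple(len(g) for g in groups))


def coverage_genotype_association(
    coverage: pd.DataFrame, genotypes: pd.Series
) -> KruskalResult:
    """Genotypic Kruskal-Wallis of normalized coverage vs SNP genotype.

    Uses only samples passing the coverage filter and having a genotype.
    """
    df = coverage.loc[coverage["included"]].set_index("sample")
    joined = df.join(genotypes.rename("genotype"), how="inner").dropna(
        subset=["genotype"]
    )
    return genotypic_kruskal(
        joined["normalized"].to_numpy(), joined["genotype"].astype(int).to_numpy()
    )
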