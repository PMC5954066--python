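"""Statistics on bi-allelic VNTR length genotypes in a case-control cohort.

Covers the association surface built on Southern-blot style allele tables:
allelic Fisher tests for the tag SNPs, Kruskal-Wallis of length by genotype,
the data-derived expansion cutoff, the carrier-level exact odds ratio, the
liability-scale heritability attributable to expansion, and the onset-age
analyses within patients.

The exact 2x2 machinery reports the conditional maximum-likelihood odds
ratio with an exact 95% CI obtained by inverting the noncentral
hypergeometric distribution (the behaviour of classical exact-test software).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .depth import KruskalResult, genotypic_kruskal

EXCLUSION_REASONS = ("none", "single_band", "ptc_carrier", "mendelian_mutation")

LengthStatistic = Literal["longest", "smallest", "sum"]


# ---------------------------------------------------------------------------
# Subject / genotype containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VntrGenotype:
    """Two measured VNTR allele lengths (bp) for one subject."""

    allele_long: float
    allele_short: float

    def __post_init__(self) -> None:
        if self.allele_short <= 0:
            raise ValueError("allele lengths must be positive")
        if self.allele_long < self.allele_short:
            raise ValueError("allele_long must be >= allele_short")

    @property
    def sum(self) -> float:
        return self.allele_long + self.allele_short

    def expanded(self, cutoff_bp: float) -> bool:
        """Strictly greater than the cutoff; ties are wild-type."""
        return self.allele_long > cutoff_bp


def filter_included(subjects: pd.DataFrame) -> pd.DataFrame:
    """Drop subjects flagged for exclusion before any statistic.

    Exclusion reasons (single Southern-blot band, PTC-haplotype carrier,
    Mendelian-gene mutation carrier) are applied upstream of every
    association analysis; excluded subjects remain representable in the
    table but never contribute counts.
    """
    if "excluded_reason" not in subjects.columns:
        return subjects
    reasons = subjects["excluded_reason"].fillna("none")
    unknown = set(reasons.unique()) - set(EXCLUSION_REASONS)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    return subjects.loc[reasons == "none"]


def length_statistic(alleles: pd.DataFrame, statistic: LengthStatistic) -> pd.Series:
    if statistic == "longest":
        return alleles["allele_long"]
    if statistic == "smallest":
        return alleles["allele_short"]
    if statistic == "sum":
        return alleles["allele_long"] + alleles["allele_short"]
    raise ValueError(f"unknown length statistic: {statistic!r}")


# ---------------------------------------------------------------------------
# Exact 2x2 association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    """A 2x2 exact-test result: counts, OR with exact CI, two-sided p."""

    a: int  # exposed cases
    b: int  # unexposed cases
    c: int  # exposed controls
    d: int  # unexposed controls
    odds_ratio: float
    ci95: tuple[float, float]
    p_two_sided: float
    or_method: str = "cmle"

    @property
    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    @property
    def exposed_fraction_cases(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def exposed_fraction_controls(self) -> float:
        return self.c / (self.c + self.d)


def _cond_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE of the odds ratio given all four margins."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf

    def mean_shift(log_psi: float) -> float:
        rv = stats.nchypergeom_fisher(n, row1, col1, math.exp(log_psi))
        return rv.mean() - a

    return math.exp(brentq(mean_shift, -36, 36, xtol=1e-12))


def _exact_ci(a: int, b: int, c: int, d: int, level: float = 0.95) -> tuple[float, float]:
    """Exact CI by inverting noncentral-hypergeometric tail probabilities."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    alpha = (1.0 - level) / 2.0

    def sf_geq(log_psi: float) -> float:
        # P(X >= a | psi)
        rv = stats.nchypergeom_fisher(n, row1, col1, math.exp(log_psi))
        return rv.sf(a - 1)

    def cdf_leq(log_psi: float) -> float:
        rv = stats.nchypergeom_fisher(n, row1, col1, math.exp(log_psi))
        return rv.cdf(a)

    if a == lo:
        lower = 0.0
    else:
        lower = math.exp(brentq(lambda t: sf_geq(t) - alpha, -36, 36, xtol=1e-10))
    if a == hi:
        upper = math.inf
    else:
        upper = math.exp(brentq(lambda t: cdf_leq(t) - alpha, -36, 36, xtol=1e-10))
    return lower, upper


def fisher_or(a: int, b: int, c: int, d: int) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 table with exact OR and CI.

    Rows are phenotype (cases, controls), columns exposure (exposed,
    unexposed).  The odds ratio is the conditional maximum-likelihood
    estimate; the CI inverts the exact conditional distribution.  A zero
    margin yields p = 1 with an undefined (NaN) odds ratio.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        return AssociationResult(a, b, c, d, math.nan, (0.0, math.inf), 1.0)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return AssociationResult(a, b, c, d, _cond_mle_or(a, b, c, d), _exact_ci(a, b, c, d), float(p))


def snp_allelic_fisher(subjects: pd.DataFrame, rsid: str) -> AssociationResult:
    """Allelic Fisher exact test of a SNP against phenotype.

    Each subject contributes two alleles; genotypes are 0/1/2 risk-allele
    dosages.  A monomorphic SNP yields an undefined OR (zero margin).
    """
    df = filter_included(subjects)
    df = df.loc[df[rsid].notna()]
    pat = df.loc[df["phenotype"] == "patient", rsid].astype(int)
    ctl = df.loc[df["phenotype"] == "control", rsid].astype(int)
    if len(pat) == 0 or len(ctl) == 0:
        raise ValueError("need genotypes for at least one patient and one control")
    a = int(pat.sum())
    b = 2 * len(pat) - a
    c = int(ctl.sum())
    d = 2 * len(ctl) - c
    return fisher_or(a, b, c, d)


def length_by_genotype_kw(
    subjects: pd.DataFrame,
    alleles: pd.DataFrame,
    rsid: str,
    statistic: LengthStatistic = "longest",
) -> KruskalResult:
    """Kruskal-Wallis of a VNTR length statistic across SNP genotype groups."""
    df = filter_included(subjects).merge(alleles, on="id")
    df = df.loc[df[rsid].notna()]
    values = length_statistic(df, statistic)
    return genotypic_kruskal(values.to_numpy(float), df[rsid].astype(int).to_numpy())


# ---------------------------------------------------------------------------
# Expansion cutoff and carrier association
# ---------------------------------------------------------------------------

def expansion_cutoff(
    subjects: pd.DataFrame, alleles: pd.DataFrame, rsid: str = "rs3764650"
) -> float:
    """Data-derived expansion cutoff.

    The largest VNTR allele observed among control individuals carrying no
    risk allele of the tag SNP; alleles strictly longer are "expanded".
    """
    df = filter_included(subjects).merge(alleles, on="id")
    qual = df.loc[(df["phenotype"] == "control") & (df[rsid] == 0)]
    if len(qual) == 0:
        raise ValueError("no qualifying control (phenotype=control, genotype 0)")
    return float(pd.concat([qual["allele_long"], qual["allele_short"]]).max())


def carrier_table(
    subjects: pd.DataFrame, alleles: pd.DataFrame, cutoff_bp: float
) -> tuple[int, int, int, int]:
    """Counts (expanded patients, wt patients, expanded controls, wt controls).

    Carrier-level: a subject is an expansion carrier iff either allele is
    strictly longer than the cutoff.
    """
    df = filter_included(subjects).merge(alleles, on="id")
    expanded = df["allele_long"] > cutoff_bp
    pat = df["phenotype"] == "patient"
    a = int((expanded & pat).sum())
    b = int((~expanded & pat).sum())
    c = int((expanded & ~pat).sum())
    d = int((~expanded & ~pat).sum())
    return a, b, c, d


def expansion_association(
    subjects: pd.DataFrame, alleles: pd.DataFrame, cutoff_bp: float
) -> AssociationResult:
    """Fisher exact test of expansion-carrier status against phenotype."""
    return fisher_or(*carrier_table(subjects, alleles, cutoff_bp))


# ---------------------------------------------------------------------------
# Heritability of liability
# ---------------------------------------------------------------------------

FreqSource = Literal["controls", "pooled"]
RiskModel = Literal["multiplicative", "carrier"]


@dataclass(frozen=True)
class HeritabilityInputs:
    """Inputs to the liability-threshold variance calculation.

    ``risk_freq`` is the population frequency of the risk factor: under the
    multiplicative (per-allele) model it is treated as a risk-allele
    frequency with Hardy-Weinberg genotype proportions and per-genotype odds
    ratios (1, OR, OR^2); under the carrier model it is the carrier
    frequency of a binary exposure with odds ratio OR.
    """

    K: float = 0.13
    h2_total: float = 0.79
    risk_freq: float = 0.0
    odds_ratio: float = 1.0
    model: RiskModel = "multiplicative"

    def __post_init__(self) -> None:
        if not 0 < self.K < 1:
            raise ValueError("prevalence K must be in (0, 1)")
        if not 0 <= self.h2_total <= 1:
            raise ValueError("h2_total must be in [0, 1]")
        if not 0 < self.risk_freq < 1:
            raise ValueError("risk_freq must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class HeritabilityResult:
    inputs: HeritabilityInputs
    variance_liability: float  # fraction of total liability variance
    as_share_of_h2: float  # fraction of total heritability
    group_freqs: tuple[float, ...] = field(repr=False, default=())
    group_risks: tuple[float, ...] = field(repr=False, default=())


def _or_to_rr(odds_ratio: float, K: float) -> float:
    """Odds ratio to risk ratio at stated prevalence."""
    return odds_ratio / (1.0 - K + K * odds_ratio)


def liability_variance_explained(inputs: HeritabilityInputs) -> HeritabilityResult:
    """Variance in disease liability attributable to a risk factor.

    Liability-threshold calculation: (1) per-genotype odds ratios are
    converted to risk ratios at prevalence K; (2) the baseline risk is
    solved so the population risk equals K; (3) each genotype group's risk
    is mapped to a mean liability shift through the inverse standard-normal
    (the threshold is shared, group liabilities are unit-variance normals);
    (4) the explained variance is the between-group variance of those means,
    reported both as a fraction of total liability variance and as a share
    of the stated total heritability.
    """
    K = inputs.K
    if inputs.model == "multiplicative":
        p = inputs.risk_freq
        freqs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        ors = np.array([1.0, inputs.odds_ratio, inputs.odds_ratio**2])
    elif inputs.model == "carrier":
        p = inputs.risk_freq
        freqs = np.array([1 - p, p])
        ors = np.array([1.0, inputs.odds_ratio])
    else:
        raise ValueError(f"unknown model: {inputs.model!r}")

    rrs = _or_to_rr(ors, K)
    f0 = K / float(np.sum(freqs * rrs))
    risks = f0 * rrs
    if np.any(risks >= 1.0):
        raise ValueError("model saturated: a genotype group's risk reaches 1")

    threshold = stats.norm.isf(K)
    mu = threshold - stats.norm.isf(risks)
    mu_bar = float(np.sum(freqs * mu))
    variance = float(np.sum(freqs * (mu - mu_bar) ** 2))
    return HeritabilityResult(
        inputs=inputs,
        variance_liability=variance,
        as_share_of_h2=variance / inputs.h2_total if inputs.h2_total > 0 else math.nan,
        group_freqs=tuple(freqs),
        group_risks=tuple(risks),
    )


def carrier_frequency_from_table(
    a: int, b: int, c: int, d: int, source: FreqSource = "controls"
) -> float:
    """Carrier frequency of the exposure from a case-control 2x2 table."""
    if source == "controls":
        return c / (c + d)
    if source == "pooled":
        return (a + c) / (a + b + c + d)
    raise ValueError(f"unknown frequency source: {source!r}")


def expansion_heritability(
    table: tuple[int, int, int, int],
    K: float = 0.13,
    h2_total: float = 0.79,
    freq_source: FreqSource = "controls",
    model: RiskModel = "multiplicative",
    odds_ratio: float | None = None,
) -> HeritabilityResult:
    """Heritability of liability attributable to expansion, from a 2x2 table.

    The default parameterization — control-derived carrier frequency entered
    as the risk frequency of a multiplicative per-allele model, with the
    result read as a share of total heritability — is the pinned convention
    for this cohort's headline estimate (see the methods note).
    """
    a, b, c, d = table
    if odds_ratio is None:
        odds_ratio = fisher_or(a, b, c, d).odds_ratio
    freq = carrier_frequency_from_table(a, b, c, d, source=freq_source)
    if freq <= 0:
        raise ValueError(
            f"no expansion carriers among {freq_source}; heritability undefined"
        )
    return liability_variance_explained(
        HeritabilityInputs(K=K, h2_total=h2_total, risk_freq=freq,
                           odds_ratio=odds_ratio, model=model)
    )


# ---------------------------------------------------------------------------
# Onset-age analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    term: str
    beta: float
    se: float
    p: float
    n: int


@dataclass(frozen=True)
class MwuResult:
    u: float
    p: float
    n1: int
    n2: int


def aao_regression(
    subjects: pd.DataFrame,
    alleles: pd.DataFrame,
    statistic: LengthStatistic = "sum",
) -> RegressionResult:
    """OLS of patient onset age on a VNTR length statistic.

    Covariates: APOE e4 dosage and gender, mirroring the cohort analysis.
    Returns the VNTR term only.
    """
    import statsmodels.api as sm

    df = filter_included(subjects).merge(alleles, on="id")
    df = df.loc[df["phenotype"] == "patient"].dropna(subset=["aao"])
    if len(df) < 10:
        raise ValueError("need at least 10 patients with complete covariates")
    y = df["aao"].astype(float)
    if y.nunique() == 1:
        raise ValueError("onset age is constant; regression undefined")
    x = pd.DataFrame(
        {
            "vntr": length_statistic(df, statistic).astype(float),
            "apoe_e4": df["apoe_e4"].astype(float),
            "gender": (df["gender"] == "F").astype(float),
        }
    )
    constant = [c for c in x.columns if x[c].nunique() == 1]
    if "vntr" in constant:
        raise ValueError("VNTR statistic is constant; no contrast")
    x = x.drop(columns=constant)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        term=f"vntr_{statistic}",
        beta=float(fit.params["vntr"]),
        se=float(fit.bse["vntr"]),
        p=float(fit.pvalues["vntr"]),
        n=int(fit.nobs),
    )


def aao_expanded_mwu(
    subjects: pd.DataFrame, alleles: pd.DataFrame, cutoff_bp: float
) -> MwuResult:
    """Mann-Whitney U of onset age: expanded-carrier vs other patients."""
    df = filter_included(subjects).merge(alleles, on="id")
    df = df.loc[(df["phenotype"] == "patient") & df["aao"].notna()]
    expanded = df.loc[df["allele_long"] > cutoff_bp, "aao"].to_numpy(float)
    wild = df.loc[df["allele_long"] <= cutoff_bp, "aao"].to_numpy(float)
    if len(expanded) == 0 or len(wild) == 0:
        raise ValueError("both onset-age groups must be non-empty")
    pooled = np.concatenate([expanded, wild])
    if np.all(pooled == pooled[0]):
        return MwuResult(u=len(expanded) * len(wild) / 2.0, p=1.0,
                         n1=len(expanded), n2=len(wild))
    u, p = stats.mannwhitneyu(expanded, wild, alternative="two-sided")
    return MwuResult(u=float(u), p=float(p), n1=len(expanded), n2=len(wild))
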