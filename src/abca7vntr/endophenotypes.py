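"""CSF biomarker regressions and expression-versus-VNTR modelling.

Three layers: ordinary least squares of log2 biomarker levels on a VNTR
length statistic; qBase-style relative quantification of qPCR Ct tables
against multiple reference genes; and a linear mixed model of normalized
expression on the diploid VNTR length sum with a random culture-batch
intercept, tested by likelihood ratio and summarised as a fold change
between two stated diploid sums.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allelestats import RegressionResult, LengthStatistic, length_statistic

logger = logging.getLogger(__name__)

ANALYTES = ("Abeta42", "Ptau181", "Ttau")


def csf_regression(
    biomarkers: pd.DataFrame,
    alleles: pd.DataFrame,
    statistic: LengthStatistic = "sum",
) -> dict[str, RegressionResult]:
    """OLS of log2 biomarker level on a VNTR length statistic, per analyte.

    ``biomarkers`` columns: ``id``, ``analyte``, ``level`` (pg/mL, > 0).
    Nonpositive levels are rejected with the offending subject ids.  Beta is
    reported per bp of the chosen statistic.
    """
    import statsmodels.api as sm

    bad = biomarkers.loc[biomarkers["level"] <= 0, "id"].tolist()
    if bad:
        raise ValueError(f"nonpositive biomarker levels for subjects: {bad}")
    out: dict[str, RegressionResult] = {}
    for analyte, sub in biomarkers.groupby("analyte"):
        df = sub.merge(alleles, on="id")
        if len(df) < 10:
            raise ValueError(f"{analyte}: need at least 10 paired records")
        y = np.log2(df["level"].astype(float))
        if y.nunique() == 1:
            raise ValueError(f"{analyte}: biomarker is constant")
        x = length_statistic(df, statistic).astype(float)
        fit = sm.OLS(y, sm.add_constant(x.rename("vntr"))).fit()
        out[analyte] = RegressionResult(
            term=f"vntr_{statistic}",
            beta=float(fit.params["vntr"]),
            se=float(fit.bse["vntr"]),
            p=float(fit.pvalues["vntr"]),
            n=int(fit.nobs),
        )
    return out


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def relative_expression(
    measurements: pd.DataFrame,
    target_gene: str = "target",
    reference_genes: Sequence[str] = ("ref1", "ref2", "ref3"),
    efficiency: float | dict[str, float] = 2.0,
) -> pd.Series:
    """Normalized relative expression per sample from qPCR Ct values.

    qBase-style arithmetic with multiple reference genes: technical
    replicates are averaged on the Ct scale; per gene the relative quantity
    is ``E**(Ct_cal - Ct)`` with the sample-mean Ct of that gene as
    calibrator; the normalization factor is the geometric mean of the
    reference-gene quantities; the result is the target quantity divided by
    the normalization factor.  Amplification efficiency E defaults to
    perfect doubling and may be set per gene.

    ``measurements`` columns: ``sample``, ``gene``, ``ct`` (one row per
    technical replicate).  Samples missing any reference gene are dropped
    with a warning.
    """
    df = measurements
    bad_ct = ~df["ct"].between(0, 45, inclusive="neither")
    if bad_ct.any():
        raise ValueError("Ct values must lie in (0, 45)")

    genes = [target_gene, *reference_genes]
    mean_ct = (
        df.loc[df["gene"].isin(genes)]
        .groupby(["sample", "gene"])["ct"]
        .mean()
        .unstack("gene")
    )
    complete = mean_ct.dropna(subset=genes)
    dropped = sorted(set(mean_ct.index) - set(complete.index))
    if dropped:
        logger.warning("samples missing a gene, dropped: %s", dropped)
    if complete.empty:
        raise ValueError("no sample has the target and every reference gene")

    def eff(gene: str) -> float:
        return efficiency[gene] if isinstance(efficiency, dict) else efficiency

    rq = pd.DataFrame(
        {
            g: eff(g) ** (complete[g].mean() - complete[g])
            for g in genes
        }
    )
    nf = np.exp(np.log(rq[list(reference_genes)]).mean(axis=1))
    return (rq[target_gene] / nf).rename("normalized_expression")


# ---------------------------------------------------------------------------
# Mixed-model expression association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LmmResult:
    """Mixed-model VNTR association: slope, LRT against the null, fold change."""

    beta_vntr: float  # per bp of diploid VNTR sum
    se: float
    lrt_chi2: float
    lrt_p: float
    fold_change: float  # predicted ratio at (sum_hi, sum_lo)
    fold_change_sums: tuple[float, float]
    n: int
    random_batch: bool  # False when the fixed-effect fallback was used

    @property
    def percent_change(self) -> float:
        """Percent change at the high vs low diploid sum (negative = lower)."""
        return 100.0 * (self.fold_change - 1.0)


#: Diploid VNTR sums (bp) bracketing the observed range, used as default
#: evaluation points for fold changes: largest (5399+4575) and smallest
#: (557+315) diploid combinations.
DEFAULT_FOLD_SUMS = (5399.0 + 4575.0, 557.0 + 315.0)


def expression_vntr_lmm(
    values: pd.Series,
    covariates: pd.DataFrame,
    fold_sums: tuple[float, float] = DEFAULT_FOLD_SUMS,
) -> LmmResult:
    """Linear mixed model of an expression-like value on the VNTR sum.

    Fixed effects: VNTR sum (bp) and gender; random intercept: the batch in
    which cell lines were grown.  The VNTR term is tested by a likelihood
    ratio against the model without it (ML fits, chi2 on 1 df).  The fold
    change between two stated diploid sums is computed from the fixed slope
    on the linear-predictor scale at covariate means.

    ``covariates`` columns: ``vntr_sum``, ``gender``, ``batch``; the index
    must align with ``values``.  With a single batch, or when the random
    intercept is degenerate, the model falls back to OLS with batch as a
    fixed effect (logged); the LRT then compares the corresponding OLS fits.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = covariates.copy()
    df["y"] = np.asarray(values, dtype=float)
    df = df.dropna(subset=["y", "vntr_sum", "gender", "batch"])
    if df["vntr_sum"].nunique() <= 1:
        raise ValueError("VNTR sum has no variance")
    df["female"] = (df["gender"] == "F").astype(float)
    n_batches = df["batch"].nunique()

    use_random = n_batches >= 2
    beta = se = None
    if use_random:
        try:
            import warnings

            with warnings.catch_warnings():
                # Degenerate random intercepts are handled by the explicit
                # fixed-effect fallback below.
                warnings.simplefilter("ignore")
                full = smf.mixedlm("y ~ vntr_sum + female", df, groups=df["batch"]).fit(
                    reml=False, method="lbfgs"
                )
                null = smf.mixedlm("y ~ female", df, groups=df["batch"]).fit(
                    reml=False, method="lbfgs"
                )
                var_re = float(full.cov_re.iloc[0, 0])
                llf_full, llf_null = float(full.llf), float(null.llf)
            if not np.isfinite(llf_full) or not np.isfinite(llf_null) or var_re < 0:
                raise np.linalg.LinAlgError("degenerate random intercept")
            beta = float(full.params["vntr_sum"])
            se = float(full.bse["vntr_sum"])
            intercept = float(full.params["Intercept"])
            fem_beta = float(full.params["female"])
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("mixed model failed (%s); falling back to fixed batch", err)
            use_random = False

    if not use_random:
        full = smf.ols("y ~ vntr_sum + female + C(batch)", df).fit()
        null = smf.ols("y ~ female + C(batch)", df).fit()
        beta = float(full.params["vntr_sum"])
        se = float(full.bse["vntr_sum"])
        llf_full, llf_null = float(full.llf), float(null.llf)
        intercept = float(full.params["Intercept"])
        fem_beta = float(full.params["female"])

    chi2 = max(0.0, 2.0 * (llf_full - llf_null))
    p = float(stats.chi2.sf(chi2, df=1))
    fem_mean = float(df["female"].mean())
    hi, lo = fold_sums
    pred_hi = intercept + beta * hi + fem_beta * fem_mean
    pred_lo = intercept + beta * lo + fem_beta * fem_mean
    fold = pred_hi / pred_lo if pred_lo != 0 else math.nan
    return LmmResult(
        beta_vntr=beta,
        se=se,
        lrt_chi2=chi2,
        lrt_p=p,
        fold_change=fold,
        fold_change_sums=fold_sums,
        n=len(df),
        random_batch=use_random,
    )
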