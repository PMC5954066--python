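"""Synthetic case-control cohort generator for the VNTR analysis pipeline.

Emulates the statistical structure of the study cohort so that every
pipeline stage can run end-to-end without external data:

* per-haplotype VNTR lengths from a right-skewed (log-normal) distribution,
  shifted longer on tag-SNP risk haplotypes (linkage disequilibrium), with
  a rare expansion mixture component above the cutoff placed predominantly
  on risk haplotypes;
* disease through a liability-threshold model whose carrier effect is
  calibrated numerically so expansion carriers have the configured odds
  ratio at the configured prevalence;
* onset age independent of VNTR length (the cohort's null finding);
* measurement layers: read intervals over the repeat core with Poisson
  depth proportional to diploid repeat content, qPCR Ct tables, CSF
  biomarker levels with log2-scale length effects, fragment-analysis peak
  tables (optionally cycloheximide-paired), and junction-tagged reads for
  allele-specific expression.

All randomness flows from a single seeded generator in a fixed layer order,
so a fixed seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .regions import RepeatRegion, abca7_vntr_region
from .splicing import EVENTS, MODEL_DELTAS, PTC_EVENTS, combination_sizes

ALL_LAYERS = ("reads", "csf", "expression", "peaks", "chx", "ase")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort-scale quantities the analysis targets:
    275 patients / 177 controls with Southern-blot style allele pairs, a
    13% disease risk after 65, total liability heritability 0.79, a carrier
    odds ratio of 4.5 for expansions beyond 5720 bp, allele lengths with
    median 2388 bp and the smallest allele at 298 bp, an expression
    gradient of -33% and an exon-19 skip gradient of 3.2x across the
    observed diploid-sum range (872 to 9974 bp), and CSF effects of
    -4.6e-5 / -4.0e-5 / 0 log2 units per bp.
    """

    n_patients: int = 275
    n_controls: int = 177
    prevalence: float = 0.13
    h2_total: float = 0.79
    expansion_cutoff_truth: float = 5720.0
    carrier_OR: float = 4.5

    # haplotype structure
    risk_allele_freq: float = 0.12  # tag-SNP risk haplotype frequency
    snp2_given_risk: float = 0.5  # secondary SNP risk allele | risk haplotype
    snp2_given_nonrisk: float = 0.01
    ld_shift: float = 800.0  # bp added to allele length on risk haplotypes
    allele_median: float = 2388.0
    allele_log_sigma: float = 0.641  # matches the observed interquartile range
    allele_min: float = 298.0
    expansion_prob_risk_hap: float = 0.0925
    expansion_prob_nonrisk_hap: float = 0.0015
    expansion_tail_mean: float = 1500.0  # exponential tail above the cutoff

    # demographics
    aao_mean: float = 73.0
    aao_sd: float = 9.0
    female_prob: float = 0.55
    apoe_e4_freq: float = 0.2

    # expression layer (relative units; linear in diploid sum)
    expression_ref_sum: float = 872.0
    expression_slope: float = -0.33 / 9102.0  # -33% across 872..9974 bp
    expression_noise_sd: float = 0.12
    n_lcl: int = 64
    n_growth_batches: int = 3

    # splicing layer (event probabilities; skip linear in diploid sum)
    skip_base: float = 0.06
    skip_slope: float = 0.06 * 2.2 / 9102.0  # 3.2x across 872..9974 bp
    skip_noise_sd: float = 0.015
    cryptic_acceptor_ratio: float = 0.12
    unit_retention_ratio: float = 0.02
    amplicon_base_size: float = 520.0
    peak_total_area: float = 1.0e4
    peak_area_cv: float = 0.05
    n_chx: int = 24
    chx_uplift: float = 1.8  # PTC-transcript stabilisation, length-independent

    # CSF layer (log2 pg/mL)
    csf_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"Abeta42": -4.6e-5, "Ptau181": -4.0e-5, "Ttau": 0.0}
    )
    csf_base_log2: Mapping[str, float] = field(
        default_factory=lambda: {
            "Abeta42": math.log2(500.0),
            "Ptau181": math.log2(60.0),
            "Ttau": math.log2(400.0),
        }
    )
    csf_noise_sd: float = 0.5
    n_csf: int = 168

    # read-depth layer
    depth_rate: float = 20.0  # expected core reads per kb of diploid repeat
    flank_read_rate: float = 10.0
    total_reads_mean: float = 1.0e6
    read_length: int = 100

    # allele-specific expression layer
    ase_alleles: tuple[float, float] = (837.0, 9711.0)  # wild-type, expanded
    ase_skip_intercept: float = 0.035394
    ase_skip_slope: float = 1.74686e-5  # per bp; yields ~4.1x for the defaults
    ase_n_reads: int = 4000

    layers: tuple[str, ...] = ALL_LAYERS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "h2_total", "risk_allele_freq", "female_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.carrier_OR <= 0:
            raise ValueError("carrier_OR must be positive")
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("need at least one patient and one control")
        unknown = set(self.layers) - set(ALL_LAYERS)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")


@dataclass
class SimCohort:
    """All tables produced by one simulated cohort, plus generator truth."""

    subjects: pd.DataFrame
    alleles: pd.DataFrame
    haplotypes: pd.DataFrame
    reads: pd.DataFrame | None = None
    read_totals: pd.Series | None = None
    biomarkers: pd.DataFrame | None = None
    ct: pd.DataFrame | None = None
    lcl_covariates: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    chx_peaks: pd.DataFrame | None = None
    junction_reads: pd.DataFrame | None = None
    ase_phasing: dict[str, str] | None = None
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Liability model calibration
# ---------------------------------------------------------------------------

import functools


@functools.lru_cache(maxsize=64)
def liability_carrier_effect(
    carrier_or: float, prevalence: float, carrier_freq: float
) -> tuple[float, float]:
    """Solve (liability shift, threshold) for a binary carrier factor.

    Finds the carrier mean-liability shift beta and threshold t such that,
    with unit-variance normal residual liability, the population prevalence
    equals ``prevalence`` and carriers have odds ratio ``carrier_or``.
    """
    if carrier_or == 1.0:
        return 0.0, float(stats.norm.isf(prevalence))

    def threshold_for(beta: float) -> float:
        def prev_gap(t: float) -> float:
            risk = (1 - carrier_freq) * stats.norm.sf(t) + carrier_freq * stats.norm.sf(
                t - beta
            )
            return risk - prevalence

        return brentq(prev_gap, -10, 10, xtol=1e-12)

    def or_gap(beta: float) -> float:
        t = threshold_for(beta)
        f1 = stats.norm.sf(t - beta)
        f0 = stats.norm.sf(t)
        return (f1 / (1 - f1)) / (f0 / (1 - f0)) - carrier_or

    beta = brentq(or_gap, 1e-6, 6.0, xtol=1e-10)
    return float(beta), float(threshold_for(beta))


# ---------------------------------------------------------------------------
# Haplotype and subject generation
# ---------------------------------------------------------------------------

def _draw_haplotypes(cfg: SimConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    risk = rng.random(n) < cfg.risk_allele_freq
    snp2 = np.where(
        risk,
        rng.random(n) < cfg.snp2_given_risk,
        rng.random(n) < cfg.snp2_given_nonrisk,
    )
    exp_prob = np.where(risk, cfg.expansion_prob_risk_hap, cfg.expansion_prob_nonrisk_hap)
    expanded = rng.random(n) < exp_prob
    # Wild-type lengths: log-normal truncated (inverse-CDF) so that length
    # plus the LD shift stays at or below the truth cutoff; expansions are a
    # separate exponential tail strictly above it.
    shift = np.where(risk, cfg.ld_shift, 0.0)
    ceiling = cfg.expansion_cutoff_truth - shift
    cdf_cap = stats.lognorm.cdf(ceiling, s=cfg.allele_log_sigma, scale=cfg.allele_median)
    base = stats.lognorm.ppf(
        rng.random(n) * cdf_cap, s=cfg.allele_log_sigma, scale=cfg.allele_median
    )
    base = np.maximum(base + shift, cfg.allele_min)
    tail = cfg.expansion_cutoff_truth + rng.exponential(cfg.expansion_tail_mean, n)
    length = np.where(expanded, tail, base)
    return pd.DataFrame(
        {"risk": risk.astype(int), "snp2": snp2.astype(int),
         "expanded": expanded, "length": np.round(length, 0)}
    )


def population_carrier_freq(cfg: SimConfig) -> float:
    q_hap = (
        cfg.risk_allele_freq * cfg.expansion_prob_risk_hap
        + (1 - cfg.risk_allele_freq) * cfg.expansion_prob_nonrisk_hap
    )
    return 1.0 - (1.0 - q_hap) ** 2


def simulate_population(
    cfg: SimConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` population subjects (no case-control ascertainment)."""
    beta, t = liability_carrier_effect(
        cfg.carrier_OR, cfg.prevalence, population_carrier_freq(cfg)
    )
    h1 = _draw_haplotypes(cfg, rng, n)
    h2 = _draw_haplotypes(cfg, rng, n)
    carrier = (h1["expanded"] | h2["expanded"]).to_numpy()
    liability = beta * carrier + rng.standard_normal(n)
    case = liability > t
    return pd.DataFrame(
        {
            "hap1_risk": h1["risk"], "hap2_risk": h2["risk"],
            "hap1_snp2": h1["snp2"], "hap2_snp2": h2["snp2"],
            "hap1_len": h1["length"], "hap2_len": h2["length"],
            "carrier": carrier, "case": case,
        }
    )


def _sample_case_control(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw from the population until the case/control quotas are filled."""
    need_cases, need_controls = cfg.n_patients, cfg.n_controls
    chunks: list[pd.DataFrame] = []
    got_cases = got_controls = 0
    # Expected draws ~ n_cases / prevalence; cap generously.
    for _ in range(1000):
        if got_cases >= need_cases and got_controls >= need_controls:
            break
        n = max(2000, int(2 * need_cases / cfg.prevalence / 10))
        pop = simulate_population(cfg, n, rng)
        chunks.append(pop)
        got_cases += int(pop["case"].sum())
        got_controls += int((~pop["case"]).sum())
    pop = pd.concat(chunks, ignore_index=True)
    cases = pop.loc[pop["case"]].head(need_cases)
    controls = pop.loc[~pop["case"]].head(need_controls)
    if len(cases) < need_cases or len(controls) < need_controls:
        raise RuntimeError("failed to fill case/control quotas; check config")
    return pd.concat([cases, controls], ignore_index=True)


# ---------------------------------------------------------------------------
# Measurement layers
# ---------------------------------------------------------------------------

def simulate_reads(
    allele_lengths: tuple[float, float],
    region: RepeatRegion,
    rng: np.random.Generator,
    depth_rate: float = 20.0,
    flank_read_rate: float = 10.0,
    read_length: int = 100,
    sample: str = "S1",
) -> pd.DataFrame:
    """Read intervals over the repeat locus for one diploid genotype.

    The number of core-overlapping reads is Poisson with mean
    ``depth_rate * (L1 + L2) / 1000``; core reads start uniformly over the
    positions overlapping the core by at least one base.  Flank reads
    (locus coverage unrelated to repeat content) are placed entirely
    upstream of the core so the breakpoint-excluding core query is
    exercised.  A degenerate (0, 0) genotype yields flank reads only.
    """
    if depth_rate <= 0:
        raise ValueError("depth_rate must be positive")
    core = region.core if region.core is not None else region.span
    l1, l2 = allele_lengths
    n_core = rng.poisson(depth_rate * (l1 + l2) / 1000.0)
    starts = rng.integers(core.start - read_length + 1, core.end, size=n_core)
    n_flank = rng.poisson(flank_read_rate)
    flank_starts = rng.integers(
        core.start - 2000, core.start - read_length + 1, size=n_flank
    )
    all_starts = np.concatenate([starts, flank_starts])
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": core.chrom,
            "start": all_starts,
            "end": all_starts + read_length,
            "flag": 0,
        }
    )


def _event_probs(cfg: SimConfig, vntr_sum: float, noise: float) -> dict[str, float]:
    p_skip = cfg.skip_base + cfg.skip_slope * (vntr_sum - cfg.expression_ref_sum) + noise
    return {
        "cryptic_acceptor_18": float(np.clip(cfg.cryptic_acceptor_ratio, 0.001, 0.9)),
        "unit_retention": float(np.clip(cfg.unit_retention_ratio, 0.001, 0.9)),
        "exon19_skip": float(np.clip(p_skip, 0.005, 0.9)),
    }


def _peaks_for_sample(
    cfg: SimConfig,
    rng: np.random.Generator,
    sample: str,
    probs: Mapping[str, float],
    condition: str,
) -> pd.DataFrame:
    sizes = combination_sizes(cfg.amplicon_base_size)
    rows = []
    for combo, size in sizes.items():
        frac = 1.0
        for ev in EVENTS:
            frac *= probs[ev] if ev in combo else 1.0 - probs[ev]
        area = cfg.peak_total_area * frac * rng.lognormal(0.0, cfg.peak_area_cv)
        rows.append(
            {
                "sample": sample,
                "size": size + rng.normal(0.0, 0.4),
                "area": area,
                "condition": condition,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig | None = None) -> SimCohort:
    """Generate a complete synthetic cohort under one seeded configuration."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    region = abca7_vntr_region()

    raw = _sample_case_control(cfg, rng)
    n = len(raw)
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    phenotype = np.where(raw["case"], "patient", "control")

    gender = np.where(rng.random(n) < cfg.female_prob, "F", "M")
    apoe = rng.binomial(2, cfg.apoe_e4_freq, n)
    # Onset age (patients) / inclusion age (controls): independent of length.
    aao = np.round(rng.normal(cfg.aao_mean, cfg.aao_sd, n), 1)

    subjects = pd.DataFrame(
        {
            "id": ids,
            "phenotype": phenotype,
            "aao": aao,
            "gender": gender,
            "apoe_e4": apoe,
            "rs3764650": (raw["hap1_risk"] + raw["hap2_risk"]).astype(int),
            "rs78117248": (raw["hap1_snp2"] + raw["hap2_snp2"]).astype(int),
            "excluded_reason": "none",
        }
    )
    lengths = raw[["hap1_len", "hap2_len"]].to_numpy()
    alleles = pd.DataFrame(
        {
            "id": ids,
            "allele_long": lengths.max(axis=1),
            "allele_short": lengths.min(axis=1),
        }
    )
    haplotypes = raw.assign(id=ids)

    beta, t = liability_carrier_effect(
        cfg.carrier_OR, cfg.prevalence, population_carrier_freq(cfg)
    )
    cohort = SimCohort(
        subjects=subjects,
        alleles=alleles,
        haplotypes=haplotypes,
        truth={
            "liability_shift": beta,
            "liability_threshold": t,
            "carrier_freq_population": population_carrier_freq(cfg),
            "expansion_cutoff": cfg.expansion_cutoff_truth,
            "carrier_OR": cfg.carrier_OR,
            "config": cfg,
        },
    )
    vntr_sum = alleles["allele_long"] + alleles["allele_short"]

    if "reads" in cfg.layers:
        tables = [
            simulate_reads(
                (lengths[i, 0], lengths[i, 1]),
                region,
                rng,
                depth_rate=cfg.depth_rate,
                flank_read_rate=cfg.flank_read_rate,
                read_length=cfg.read_length,
                sample=ids[i],
            )
            for i in range(n)
        ]
        cohort.reads = pd.concat(tables, ignore_index=True)
        cohort.read_totals = pd.Series(
            rng.poisson(cfg.total_reads_mean, n), index=ids, name="total_reads"
        )

    if "csf" in cfg.layers:
        pat_ids = subjects.loc[subjects["phenotype"] == "patient", "id"].head(cfg.n_csf)
        sums = vntr_sum[subjects["id"].isin(pat_ids).to_numpy()].to_numpy()
        rows = []
        for analyte in cfg.csf_slopes:
            log2_level = (
                cfg.csf_base_log2[analyte]
                + cfg.csf_slopes[analyte] * sums
                + rng.normal(0.0, cfg.csf_noise_sd, len(pat_ids))
            )
            rows.append(
                pd.DataFrame(
                    {"id": pat_ids.to_numpy(), "analyte": analyte,
                     "level": np.power(2.0, log2_level)}
                )
            )
        cohort.biomarkers = pd.concat(rows, ignore_index=True)

    lcl_ids: list[str] = []
    if {"expression", "peaks", "chx"} & set(cfg.layers):
        # Balanced patient/control LCL panel.
        pat = subjects.loc[subjects["phenotype"] == "patient", "id"]
        ctl = subjects.loc[subjects["phenotype"] == "control", "id"]
        half = cfg.n_lcl // 2
        lcl_ids = pd.concat([pat.head(half), ctl.head(cfg.n_lcl - half)]).tolist()
        lcl_sums = vntr_sum[subjects["id"].isin(lcl_ids).to_numpy()].to_numpy()
        lcl_gender = subjects.set_index("id").loc[lcl_ids, "gender"].to_numpy()
        batches = rng.integers(1, cfg.n_growth_batches + 1, len(lcl_ids))
        cohort.lcl_covariates = pd.DataFrame(
            {"vntr_sum": lcl_sums, "gender": lcl_gender, "batch": batches},
            index=pd.Index(lcl_ids, name="sample"),
        )

    if "expression" in cfg.layers:
        batch_effect = rng.normal(0.0, 0.05, cfg.n_growth_batches + 1)
        ref_base_ct = {"ref1": 22.0, "ref2": 20.0, "ref3": 24.0}
        rows = []
        for i, sid in enumerate(lcl_ids):
            rel = (
                1.0
                + cfg.expression_slope * (lcl_sums[i] - cfg.expression_ref_sum)
                + rng.normal(0.0, cfg.expression_noise_sd)
            )
            rel = max(rel, 0.05)
            sample_shift = rng.normal(0.0, 0.3)  # RNA input; cancels on normalization
            for cdna in (1, 2):
                for gene, base in [("target", 25.0), *ref_base_ct.items()]:
                    for rep in (1, 2, 3):
                        ct = base + sample_shift + rng.normal(0.0, 0.05)
                        if gene == "target":
                            ct -= math.log2(rel)
                            ct += batch_effect[batches[i]]
                        rows.append(
                            {"sample": sid, "gene": gene, "replicate": rep,
                             "ct": round(ct, 3), "batch": int(batches[i]),
                             "cdna_batch": cdna, "condition": "untreated"}
                        )
        cohort.ct = pd.DataFrame(rows)

    if "peaks" in cfg.layers:
        tables = []
        skip_noise = rng.normal(0.0, cfg.skip_noise_sd, len(lcl_ids))
        probs_by_sample = {}
        for i, sid in enumerate(lcl_ids):
            probs = _event_probs(cfg, lcl_sums[i], skip_noise[i])
            probs_by_sample[sid] = probs
            tables.append(_peaks_for_sample(cfg, rng, sid, probs, "untreated"))
        cohort.peaks = pd.concat(tables, ignore_index=True)

        if "chx" in cfg.layers:
            tables = []
            for sid in lcl_ids[: cfg.n_chx]:
                probs = dict(probs_by_sample[sid])
                for ev in PTC_EVENTS:
                    probs[ev] = min(0.95, probs[ev] * cfg.chx_uplift)
                tables.append(_peaks_for_sample(cfg, rng, sid, probs, "CHX"))
            cohort.chx_peaks = pd.concat(tables, ignore_index=True)

    if "ase" in cfg.layers:
        wt_len, exp_len = cfg.ase_alleles
        phasing = {"A": "wild_type", "G": "expanded"}
        p_skip = {
            "wild_type": cfg.ase_skip_intercept + cfg.ase_skip_slope * wt_len,
            "expanded": cfg.ase_skip_intercept + cfg.ase_skip_slope * exp_len,
        }
        rows = []
        for i in range(cfg.ase_n_reads):
            allele = "expanded" if rng.random() < 0.5 else "wild_type"
            base = "G" if allele == "expanded" else "A"
            u = rng.random()
            if u < 0.01:
                base = "N"
            if rng.random() < 0.01:
                category = "unclassified"
            elif rng.random() < p_skip[allele]:
                category = "exon19_skip"
            elif rng.random() < 0.15:
                category = "cryptic_acceptor_18"
            else:
                category = "canonical"
            rows.append({"read": f"r{i}", "snp_base": base, "category": category})
        cohort.junction_reads = pd.DataFrame(rows)
        cohort.ase_phasing = phasing
        cohort.truth["ase_skip_prob"] = p_skip
        cohort.truth["ase_fold_truth"] = p_skip["expanded"] / p_skip["wild_type"]

    return cohort


def case_control_config(**overrides) -> SimConfig:
    """A configuration generating only subject/allele tables (no layers)."""
    return SimConfig(layers=(), **overrides)
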