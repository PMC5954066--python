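"""Table readers/writers and the end-to-end pipeline driver.

TSV with documented headers is the canonical exchange format; SAM is
accepted for read alignments where a SAM toolchain is natural.  Every
reader validates its schema and reports offending line numbers or ids; the
pipeline runs each stage independently, so a failure in one stage does not
silence the others, and the JSON report records per-stage provenance
(operation, n used, exclusions applied).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import allelestats, depth, endophenotypes, splicing
from .regions import GenomicInterval, parse_region
from .simulate import SimCohort

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "subjects": ["id", "phenotype", "aao", "gender", "apoe_e4",
                 "rs3764650", "rs78117248", "excluded_reason"],
    "alleles": ["id", "allele_long", "allele_short"],
    "reads": ["sample", "chrom", "start", "end"],
    "read_totals": ["sample", "total_reads"],
    "biomarkers": ["id", "analyte", "level"],
    "ct": ["sample", "gene", "replicate", "ct", "batch", "cdna_batch", "condition"],
    "covariates": ["sample", "vntr_sum", "gender", "batch"],
    "peaks": ["sample", "size", "area", "condition"],
    "junction_reads": ["read", "snp_base", "category"],
}

_UNIQUE_KEY = {"subjects": "id", "alleles": "id", "read_totals": "sample"}


class SchemaError(ValueError):
    pass


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one of the documented TSV/CSV tables with schema validation.

    Unknown columns are preserved.  Missing required columns and duplicated
    keys raise :class:`SchemaError` naming the column or id.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind: {kind!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    key = _UNIQUE_KEY.get(kind)
    if key is not None:
        dup = df[key][df[key].duplicated()]
        if len(dup):
            raise SchemaError(f"{path}: duplicated {key}(s): {sorted(set(dup))}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def read_reads(path: str | Path) -> pd.DataFrame:
    """Read alignments as TSV (sample, chrom, start, end[, flag]) or SAM.

    SAM records are converted to 0-based half-open intervals spanning the
    aligned reference length; the read group / query prefix before the
    first ``:`` is not interpreted — a ``sample`` column is taken from the
    RG tag when present, else the file stem.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                rows.append(
                    {
                        "sample": rec.get_tag("RG") if rec.has_tag("RG") else path.stem,
                        "chrom": rec.reference_name,
                        "start": rec.reference_start,
                        "end": rec.reference_end,
                        "flag": rec.flag,
                    }
                )
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "flag"])
    return read_table(path, "reads")


def write_sam(reads: pd.DataFrame, path: str | Path, chrom_length: int = 59128983) -> None:
    """Write a read-interval table as minimal single-reference SAM."""
    import pysam

    chroms = sorted(reads["chrom"].unique())
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": chrom_length} for c in chroms],
        "RG": [{"ID": s} for s in reads["sample"].unique()],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i}"
            a.flag = int(getattr(row, "flag", 0))
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = 30
            a.cigarstring = f"{int(row.end) - int(row.start)}M"
            a.query_sequence = "N" * (int(row.end) - int(row.start))
            a.set_tag("RG", str(row.sample))
            fh.write(a)


def write_cohort(cohort: SimCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every table of a simulated cohort to an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def put(df: pd.DataFrame | None, name: str, filename: str) -> None:
        if df is None:
            return
        p = outdir / filename
        write_table(df, p)
        written[name] = p

    put(cohort.subjects, "subjects", "subjects.tsv")
    put(cohort.alleles, "alleles", "alleles.tsv")
    if cohort.reads is not None:
        put(cohort.reads, "reads", "reads.tsv")
    if cohort.read_totals is not None:
        put(cohort.read_totals.rename_axis("sample").reset_index(),
            "read_totals", "read_totals.tsv")
    put(cohort.biomarkers, "biomarkers", "biomarkers.tsv")
    put(cohort.ct, "ct", "ct.tsv")
    if cohort.lcl_covariates is not None:
        put(cohort.lcl_covariates.rename_axis("sample").reset_index(),
            "covariates", "lcl_covariates.tsv")
    put(cohort.peaks, "peaks", "peaks.csv")
    put(cohort.chx_peaks, "chx_peaks", "chx_peaks.csv")
    put(cohort.junction_reads, "junction_reads", "junction_reads.tsv")
    if cohort.ase_phasing is not None:
        p = outdir / "ase_phasing.json"
        p.write_text(json.dumps(cohort.ase_phasing, indent=1))
        written["ase_phasing"] = p
    return written


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """File paths and statistical options binding the pipeline end-to-end."""

    subjects: str | Path | None = None
    alleles: str | Path | None = None
    reads: str | Path | None = None
    read_totals: str | Path | None = None
    biomarkers: str | Path | None = None
    ct: str | Path | None = None
    covariates: str | Path | None = None
    peaks: str | Path | None = None
    chx_peaks: str | Path | None = None
    junction_reads: str | Path | None = None
    ase_phasing: dict[str, str] = field(
        default_factory=lambda: {"G": "expanded", "A": "wild_type"}
    )

    vntr_span: str = "chr19:1049437-1050028"
    vntr_core: str = "chr19:1049514-1049953"
    cutoff_snp: str = "rs3764650"
    length_statistic: str = "sum"
    heritability_K: float = 0.13
    heritability_h2: float = 0.79
    heritability_freq_source: str = "controls"
    heritability_model: str = "multiplicative"
    amplicon_base_size: float = 520.0
    peak_tolerance_bp: float = 3.0
    seed: int = 0


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for which inputs are configured; collect a report.

    Stage failures are captured per stage (with the error message) and do
    not prevent later independent stages from running.
    """
    report: dict[str, Any] = {"stages": {}, "seed": config.seed}

    def stage(name: str, func: Callable[[], dict]) -> None:
        try:
            out = func()
            out.setdefault("operation", name)
            report["stages"][name] = {"status": "ok", **_asdict(out)}
        except Exception as err:  # noqa: BLE001 - stage isolation is the contract
            logger.error("stage %s failed: %s", name, err)
            report["stages"][name] = {"status": "error", "error": str(err)}

    subjects = alleles = None
    if config.subjects:
        subjects = read_table(config.subjects, "subjects")
    if config.alleles:
        alleles = read_table(config.alleles, "alleles")

    if config.reads and config.read_totals:
        def depth_stage() -> dict:
            reads = read_reads(config.reads)
            totals = read_table(config.read_totals, "read_totals").set_index("sample")[
                "total_reads"
            ]
            core = parse_region(config.vntr_core)
            counts = depth.core_coverage(reads, core)
            cov = pd.DataFrame(
                {"sample": counts.index, "core_reads": counts.to_numpy()}
            )
            cov["total_reads"] = totals.reindex(cov["sample"]).to_numpy()
            cov = depth.normalize_and_filter(cov)
            out: dict[str, Any] = {
                "n": int(cov["included"].sum()),
                "excluded": int((~cov["included"]).sum()),
            }
            if subjects is not None:
                geno = subjects.set_index("id")[config.cutoff_snp]
                kw = depth.coverage_genotype_association(cov, geno)
                out["kruskal"] = kw
            return out

        stage("depth", depth_stage)

    if subjects is not None and alleles is not None:
        def assoc_stage() -> dict:
            cutoff = allelestats.expansion_cutoff(subjects, alleles, config.cutoff_snp)
            table = allelestats.carrier_table(subjects, alleles, cutoff)
            assoc = allelestats.fisher_or(*table)
            n_excluded = int((subjects["excluded_reason"].fillna("none") != "none").sum())
            return {
                "cutoff_bp": cutoff,
                "table": list(table),
                "association": assoc,
                "snp_fisher": {
                    rsid: allelestats.snp_allelic_fisher(subjects, rsid)
                    for rsid in ("rs3764650", "rs78117248")
                },
                "length_kw": {
                    rsid: allelestats.length_by_genotype_kw(
                        subjects, alleles, rsid, "longest"
                    )
                    for rsid in ("rs3764650", "rs78117248")
                },
                "n": sum(table),
                "exclusions": n_excluded,
            }

        stage("association", assoc_stage)

        def herit_stage() -> dict:
            cutoff = allelestats.expansion_cutoff(subjects, alleles, config.cutoff_snp)
            table = allelestats.carrier_table(subjects, alleles, cutoff)
            res = allelestats.expansion_heritability(
                table,
                K=config.heritability_K,
                h2_total=config.heritability_h2,
                freq_source=config.heritability_freq_source,  # type: ignore[arg-type]
                model=config.heritability_model,  # type: ignore[arg-type]
            )
            return {"heritability": res, "n": sum(table)}

        stage("heritability", herit_stage)

        def aao_stage() -> dict:
            cutoff = allelestats.expansion_cutoff(subjects, alleles, config.cutoff_snp)
            reg = allelestats.aao_regression(subjects, alleles, config.length_statistic)
            mwu = allelestats.aao_expanded_mwu(subjects, alleles, cutoff)
            return {"regression": reg, "mwu": mwu, "n": reg.n}

        stage("aao", aao_stage)

    if config.biomarkers and alleles is not None:
        def csf_stage() -> dict:
            biomarkers = read_table(config.biomarkers, "biomarkers")
            res = endophenotypes.csf_regression(
                biomarkers, alleles, config.length_statistic
            )
            return {"regressions": res, "n": max(r.n for r in res.values())}

        stage("csf", csf_stage)

    covariates = None
    if config.covariates:
        covariates = read_table(config.covariates, "covariates").set_index("sample")

    if config.ct and covariates is not None:
        def expression_stage() -> dict:
            ct = read_table(config.ct, "ct")
            nrq = endophenotypes.relative_expression(ct)
            res = endophenotypes.expression_vntr_lmm(nrq, covariates.loc[nrq.index])
            return {"lmm": res, "n": res.n}

        stage("expression", expression_stage)

    ratio_tables: dict[str, pd.DataFrame] = {}
    if config.peaks:
        def splicing_stage() -> dict:
            peaks = read_table(config.peaks, "peaks")
            expected = splicing.combination_sizes(config.amplicon_base_size)
            rows = []
            for sample, sub in peaks.groupby("sample"):
                ratios = splicing.peaks_to_ratios(
                    sub, expected, tolerance_bp=config.peak_tolerance_bp
                )
                for category, r in ratios.event_ratios.items():
                    rows.append({"sample": sample, "category": category, "ratio": r})
            ratio_tables["untreated"] = pd.DataFrame(rows)
            out: dict[str, Any] = {"n": ratio_tables["untreated"]["sample"].nunique()}
            if covariates is not None:
                out["lmm"] = splicing.ratios_vntr_lmm(
                    ratio_tables["untreated"], covariates
                )
            return out

        stage("splicing", splicing_stage)

    if config.chx_peaks and covariates is not None:
        def nmd_stage() -> dict:
            if "untreated" not in ratio_tables:
                raise ValueError("splicing stage must run before the CHX contrast")
            chx = read_table(config.chx_peaks, "peaks")
            expected = splicing.combination_sizes(config.amplicon_base_size)
            rows = []
            for sample, sub in chx.groupby("sample"):
                ratios = splicing.peaks_to_ratios(
                    sub, expected, tolerance_bp=config.peak_tolerance_bp
                )
                for category, r in ratios.event_ratios.items():
                    rows.append({"sample": sample, "category": category, "ratio": r})
            res = splicing.nmd_chx_delta(
                ratio_tables["untreated"], pd.DataFrame(rows), covariates["vntr_sum"]
            )
            return {
                "regressions": res.regressions,
                "n": len(res.deltas),
            }

        stage("nmd", nmd_stage)

    if config.junction_reads:
        def ase_stage() -> dict:
            jr = read_table(config.junction_reads, "junction_reads")
            res = splicing.allele_specific_skip(jr, config.ase_phasing)
            return {"ase": res, "n": int(len(jr))}

        stage("ase", ase_stage)

    report["n_stages_ok"] = sum(
        1 for s in report["stages"].values() if s["status"] == "ok"
    )
    report["n_stages_failed"] = sum(
        1 for s in report["stages"].values() if s["status"] == "error"
    )
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_asdict(report), indent=1, sort_keys=True))
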