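"""Splice-junction classification and isoform quantification around the VNTR.

Three non-canonical splicing events flank the repeat: use of a cryptic
acceptor inside the upstream exon (removing 52 coding bases), use of a
cryptic donor inside the intron that retains one 25-bp repeat unit, and
skipping of the downstream 132-bp exon.  The two exon-18 events shift the
reading frame and introduce a premature termination codon (PTC); the skip
is in-frame and deletes 44 residues of the first nucleotide-binding domain.

Quantification layers: capillary fragment-analysis peak tables (areas per
combination amplicon), per-sample event ratios modelled against the diploid
VNTR sum, allele-specific skip counts via a phased exonic SNP, and the
cycloheximide (CHX) contrast probing nonsense-mediated decay.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .allelestats import RegressionResult
from .endophenotypes import LmmResult, expression_vntr_lmm, DEFAULT_FOLD_SUMS
from .regions import GenomicInterval, parse_region

logger = logging.getLogger(__name__)

Category = Literal[
    "canonical", "cryptic_acceptor_18", "unit_retention", "exon19_skip", "unclassified"
]

EVENTS: tuple[str, ...] = ("cryptic_acceptor_18", "unit_retention", "exon19_skip")
PTC_EVENTS: tuple[str, ...] = ("cryptic_acceptor_18", "unit_retention")


@dataclass(frozen=True)
class TranscriptModel:
    """Exons 17-20 of the locus plus the cryptic splice sites, + strand.

    Exon intervals are 0-based half-open.  The cryptic acceptor and donor
    are stored verbatim as the published 3-bp intervals (not reduced to
    AG/GT dinucleotides); junction positions within one base of a site are
    accepted.  The exon-18 start is configuration chosen so that cryptic
    acceptor usage removes the measured 52 coding bases.
    """

    exon17: GenomicInterval
    exon18: GenomicInterval
    exon19: GenomicInterval
    exon20: GenomicInterval
    cryptic_acceptor: GenomicInterval
    cryptic_donor: GenomicInterval
    vntr_span: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        exons = [self.exon17, self.exon18, self.exon19, self.exon20]
        for up, down in zip(exons, exons[1:]):
            if up.end > down.start:
                raise ValueError("exons must be non-overlapping and ascending")
        if not self.exon18.contains(self.cryptic_acceptor):
            raise ValueError("cryptic acceptor must lie inside exon 18")
        if not (self.exon18.end <= self.cryptic_donor.start < self.exon19.start):
            raise ValueError("cryptic donor must lie inside intron 18")
        if self.cryptic_donor.start - self.vntr_span.start > 25:
            raise ValueError("cryptic donor must sit within one unit of the VNTR start")

    # 1-based convenience accessors for junction arithmetic ------------------
    def donor_end(self, exon: GenomicInterval) -> int:
        """1-based position of the last exonic base (the splice donor side)."""
        return exon.end

    def acceptor_start(self, exon: GenomicInterval) -> int:
        """1-based position of the first exonic base (the acceptor side)."""
        return exon.start + 1

    @property
    def cryptic_acceptor_delta(self) -> int:
        """Coding change (bp) from cryptic acceptor usage: loss of the exon-18
        bases up to and including the site."""
        return -(self.cryptic_acceptor.end - self.exon18.start)

    @property
    def unit_retention_delta(self) -> int:
        """Coding change (bp) from the intronic cryptic donor: retention of
        the repeat bases from the VNTR start through the first base of the
        verbatim 3-bp site (one full repeat unit)."""
        return self.cryptic_donor.start + 1 - self.vntr_span.start

    @property
    def exon19_skip_delta(self) -> int:
        return -self.exon19.length()


def abca7_transcript_model() -> TranscriptModel:
    """Default locus model (hg19 coordinates around intron 18).

    The cryptic splice sites and the VNTR span are the published
    coordinates; exon boundaries not derivable from print are fixed
    configuration consistent with the measured coding deltas
    (-52, +25, -132).
    """
    return TranscriptModel(
        exon17=parse_region("chr19:1048900-1049050", assembly="hg19"),
        exon18=parse_region("chr19:1049265-1049436", assembly="hg19"),
        exon19=parse_region("chr19:1050150-1050281", assembly="hg19"),
        exon20=parse_region("chr19:1050400-1050550", assembly="hg19"),
        cryptic_acceptor=parse_region("chr19:1049314-1049316", assembly="hg19"),
        cryptic_donor=parse_region("chr19:1049461-1049463", assembly="hg19"),
        vntr_span=parse_region("chr19:1049437-1050028", assembly="hg19"),
    )


@dataclass(frozen=True)
class FrameCall:
    frame: Literal["in_frame", "frameshift"]
    ptc: bool
    aa_delta: int | None


def frame_consequence(coding_delta_bp: int) -> FrameCall:
    """Reading-frame consequence of a signed coding-length change.

    A delta divisible by 3 preserves frame and adds/removes ``delta/3``
    amino acids; any other delta shifts the frame, which at this locus
    introduces a premature termination codon.
    """
    if coding_delta_bp % 3 == 0:
        return FrameCall("in_frame", ptc=False, aa_delta=coding_delta_bp // 3)
    return FrameCall("frameshift", ptc=True, aa_delta=None)


@dataclass(frozen=True)
class IsoformCall:
    category: str
    coding_delta_bp: int
    frame: str
    ptc: bool
    aa_delta: int | None

    @staticmethod
    def from_delta(category: str, delta: int) -> "IsoformCall":
        fc = frame_consequence(delta)
        return IsoformCall(category, delta, fc.frame, fc.ptc, fc.aa_delta)


def _near(pos: int, site: GenomicInterval) -> bool:
    # Accept positions within the verbatim 3-bp site or one base past it.
    return site.start <= pos <= site.end + 1


def classify_junction(
    donor_end: int, acceptor_start: int, model: TranscriptModel | None = None
) -> IsoformCall:
    """Classify one splice junction against the four-category locus model.

    Positions are 1-based: ``donor_end`` is the last base of the upstream
    exon, ``acceptor_start`` the first base of the downstream exon.
    Junctions outside the exon 17-20 window, or not matching any expected
    pattern, are returned as ``unclassified`` (never dropped).
    """
    m = model or abca7_transcript_model()
    canonical_pairs = {
        (m.donor_end(m.exon17), m.acceptor_start(m.exon18)),
        (m.donor_end(m.exon18), m.acceptor_start(m.exon19)),
        (m.donor_end(m.exon19), m.acceptor_start(m.exon20)),
    }
    if (donor_end, acceptor_start) in canonical_pairs:
        return IsoformCall.from_delta("canonical", 0)
    if donor_end == m.donor_end(m.exon17) and _near(acceptor_start, m.cryptic_acceptor):
        return IsoformCall.from_delta("cryptic_acceptor_18", m.cryptic_acceptor_delta)
    if _near(donor_end, m.cryptic_donor) and acceptor_start == m.acceptor_start(m.exon19):
        return IsoformCall.from_delta("unit_retention", m.unit_retention_delta)
    if donor_end == m.donor_end(m.exon18) and acceptor_start == m.acceptor_start(m.exon20):
        return IsoformCall.from_delta("exon19_skip", m.exon19_skip_delta)
    return IsoformCall("unclassified", 0, "in_frame", False, None)


def synthesize_junction(category: str, model: TranscriptModel | None = None) -> tuple[int, int]:
    """Donor/acceptor positions realising a category (inverse of classify)."""
    m = model or abca7_transcript_model()
    if category == "canonical":
        return m.donor_end(m.exon18), m.acceptor_start(m.exon19)
    if category == "cryptic_acceptor_18":
        return m.donor_end(m.exon17), m.cryptic_acceptor.start + 1
    if category == "unit_retention":
        return m.cryptic_donor.start + 1, m.acceptor_start(m.exon19)
    if category == "exon19_skip":
        return m.donor_end(m.exon18), m.acceptor_start(m.exon20)
    raise ValueError(f"cannot synthesize junction for {category!r}")


# ---------------------------------------------------------------------------
# Fragment-analysis peak quantification
# ---------------------------------------------------------------------------

Combo = tuple[str, ...]

MODEL_DELTAS: dict[str, int] = {
    "cryptic_acceptor_18": -52,
    "unit_retention": +25,
    "exon19_skip": -132,
}


def combination_sizes(
    base_size: float,
    deltas: Mapping[str, int] = MODEL_DELTAS,
    events: Sequence[str] = EVENTS,
) -> dict[Combo, float]:
    """Expected amplicon sizes for every combination of splicing events.

    The canonical amplicon length is a fixture parameter; each of the eight
    combinations (all subsets of the three events) adds the sum of its
    event deltas.
    """
    out: dict[Combo, float] = {}
    for r in range(len(events) + 1):
        for combo in itertools.combinations(events, r):
            out[tuple(combo)] = base_size + sum(deltas[e] for e in combo)
    return out


@dataclass(frozen=True)
class IsoformRatios:
    """Event-level signal ratios from one fragment-analysis run.

    ``combo_fractions`` sum to 1 over the quantified peaks;
    ``event_ratios`` are containment sums (a combination peak counts toward
    every event it carries), with ``canonical`` being the pure-canonical
    fraction.
    """

    combo_fractions: dict[Combo, float]
    event_ratios: dict[str, float]
    unmatched_peaks: tuple[tuple[float, float], ...] = ()
    total_area: float = 0.0


def peaks_to_ratios(
    peaks: pd.DataFrame,
    expected: Mapping[Combo, float],
    tolerance_bp: float = 3.0,
    include_unit_retention: bool = True,
) -> IsoformRatios:
    """Convert a peak table (size, area) into isoform-event ratios.

    Each peak is assigned to the nearest expected combination size within
    ``tolerance_bp``; unmatched peaks are reported, never silently dropped.
    With ``include_unit_retention=False`` the denominator follows the
    three-peak convention (canonical, cryptic acceptor, exon-19 skip):
    combinations carrying a retained unit are excluded from quantification.
    """
    sizes = sorted(expected.values())
    for s1, s2 in zip(sizes, sizes[1:]):
        if s2 - s1 <= 2 * tolerance_bp:
            raise ValueError(
                f"expected sizes {s1} and {s2} closer than 2x tolerance ({tolerance_bp})"
            )
    if (peaks["area"] < 0).any():
        raise ValueError("peak areas must be nonnegative")

    combos = list(expected)
    assigned: dict[Combo, float] = {}
    unmatched: list[tuple[float, float]] = []
    for size, area in zip(peaks["size"], peaks["area"]):
        dists = [abs(size - expected[c]) for c in combos]
        j = int(np.argmin(dists))
        if dists[j] <= tolerance_bp:
            combo = combos[j]
            if combo in assigned:
                logger.warning("multiple peaks in bin %s; areas summed", combo)
            assigned[combo] = assigned.get(combo, 0.0) + float(area)
        else:
            unmatched.append((float(size), float(area)))

    if not include_unit_retention:
        assigned = {c: a for c, a in assigned.items() if "unit_retention" not in c}
    total = sum(assigned.values())
    if total <= 0:
        raise ValueError("zero total matched peak area")

    fractions = {c: a / total for c, a in assigned.items()}
    events = EVENTS if include_unit_retention else tuple(
        e for e in EVENTS if e != "unit_retention"
    )
    event_ratios = {
        "canonical": fractions.get((), 0.0),
        **{e: sum(f for c, f in fractions.items() if e in c) for e in events},
    }
    return IsoformRatios(
        combo_fractions=fractions,
        event_ratios=event_ratios,
        unmatched_peaks=tuple(unmatched),
        total_area=float(total),
    )


def ratios_vntr_lmm(
    ratios: pd.DataFrame,
    covariates: pd.DataFrame,
    fold_sums: tuple[float, float] = DEFAULT_FOLD_SUMS,
) -> dict[str, LmmResult]:
    """Mixed-model VNTR-sum association per isoform category.

    ``ratios`` columns: ``sample``, ``category``, ``ratio``; ``covariates``
    is indexed by sample with ``vntr_sum``, ``gender``, ``batch``.  Shares
    the expression mixed-model contract (random batch intercept, LRT on the
    VNTR term, fold change between stated diploid sums).
    """
    wide = ratios.pivot(index="sample", columns="category", values="ratio")
    out: dict[str, LmmResult] = {}
    for category in wide.columns:
        values = wide[category].dropna()
        out[category] = expression_vntr_lmm(
            values, covariates.loc[values.index], fold_sums=fold_sums
        )
    return out


# ---------------------------------------------------------------------------
# Allele-specific skipping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AseCount:
    """Per-allele exon-skip counts from junction-tagged reads."""

    counts: dict[str, dict[str, int]]  # allele -> {"skip": n, "nonskip": n}
    skip_ratio: dict[str, float]
    fold_change: float  # expanded-allele ratio / wild-type-allele ratio
    n_ambiguous_base: int = 0
    n_unclassified: int = 0


def allele_specific_skip(
    junction_reads: pd.DataFrame,
    phasing: Mapping[str, str],
    expanded_allele: str = "expanded",
    wildtype_allele: str = "wild_type",
) -> AseCount:
    """Allele-specific exon-19 skip ratios via a phased heterozygous SNP.

    ``junction_reads`` columns: ``snp_base`` (read base at the phasing SNP)
    and ``category`` (per-read junction call).  ``phasing`` maps base ->
    allele label (e.g. ``{"G": "expanded", "A": "wild_type"}``).  Reads with
    a base outside the phasing map or an unclassified junction are counted
    separately and excluded from ratios.  The fold change is the expanded
    allele's skip ratio over the wild-type allele's; a zero denominator
    yields NaN.
    """
    alleles = sorted(set(phasing.values()))
    if len(alleles) < 2:
        raise ValueError("phasing must map bases to two distinct alleles")
    counts = {al: {"skip": 0, "nonskip": 0} for al in alleles}
    n_ambig = n_uncls = 0
    for base, category in zip(junction_reads["snp_base"], junction_reads["category"]):
        if base not in phasing:
            n_ambig += 1
            continue
        if category == "unclassified":
            n_uncls += 1
            continue
        key = "skip" if category == "exon19_skip" else "nonskip"
        counts[phasing[base]][key] += 1

    ratios: dict[str, float] = {}
    for al, c in counts.items():
        denom = c["skip"] + c["nonskip"]
        ratios[al] = c["skip"] / denom if denom else math.nan
    r_exp = ratios.get(expanded_allele, math.nan)
    r_wt = ratios.get(wildtype_allele, math.nan)
    fold = r_exp / r_wt if r_wt and not math.isnan(r_wt) and r_wt > 0 else math.nan
    return AseCount(
        counts=counts,
        skip_ratio=ratios,
        fold_change=fold,
        n_ambiguous_base=n_ambig,
        n_unclassified=n_uncls,
    )


# ---------------------------------------------------------------------------
# NMD / cycloheximide contrast
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NmdResult:
    deltas: pd.DataFrame  # sample x category, CHX ratio - untreated ratio
    regressions: dict[str, RegressionResult]


def nmd_chx_delta(
    untreated: pd.DataFrame,
    chx: pd.DataFrame,
    vntr_sums: pd.Series,
    categories: Sequence[str] = PTC_EVENTS,
) -> NmdResult:
    """CHX-minus-untreated ratio changes for PTC categories vs VNTR sum.

    Both ratio tables carry ``sample``, ``category``, ``ratio``; only
    samples present in both conditions are used.  Per PTC category the
    change in ratio is regressed (OLS) on the diploid VNTR sum; under
    length-independent NMD the slope is null.
    """
    import statsmodels.api as sm

    u = untreated.pivot(index="sample", columns="category", values="ratio")
    t = chx.pivot(index="sample", columns="category", values="ratio")
    common = u.index.intersection(t.index)
    if len(common) == 0:
        raise ValueError("no paired samples across conditions")
    categories = [c for c in categories if c in u.columns and c in t.columns]
    if not categories:
        raise ValueError("no requested category present in both conditions")
    deltas = (t.loc[common] - u.loc[common])[list(categories)]

    regressions: dict[str, RegressionResult] = {}
    for category in categories:
        df = pd.DataFrame(
            {"delta": deltas[category], "vntr_sum": vntr_sums.reindex(common)}
        ).dropna()
        x = sm.add_constant(df["vntr_sum"].astype(float))
        fit = sm.OLS(df["delta"].astype(float), x).fit()
        regressions[category] = RegressionResult(
            term="vntr_sum",
            beta=float(fit.params["vntr_sum"]),
            se=float(fit.bse["vntr_sum"]),
            p=float(fit.pvalues["vntr_sum"]),
            n=int(fit.nobs),
        )
    return NmdResult(deltas=deltas, regressions=regressions)
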