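"""Coordinate and repeat-unit arithmetic for a tandem-repeat locus.

Intervals are held 0-based half-open internally (BED convention), so that
``length == end - start`` with no off-by-one bookkeeping.  Region strings in
the ``chrom:start-end`` style used in publications are 1-based inclusive at
the boundary; both conventions are supported explicitly on parse and format.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Literal

Convention = Literal["1-inclusive", "0-half-open"]

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")

_VALID_BASES = frozenset("ACGT")

#: Consensus of the 25-bp repeat unit; the leading GT doubles as the splice
#: donor of the upstream exon.  Individual genomic units deviate from this by
#: a few substitutions.
UNIT_CONSENSUS_25 = "GTGAGCCCCAGGAGCCCTCCCCACC"


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name, e.g. ``"chr19"``.
    start, end : int
        0-based half-open coordinates; ``start < end``.
    assembly : str
        Free-text assembly tag such as ``"hg19"``.
    """

    chrom: str
    start: int
    end: int
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Whether ``other`` lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1-base overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def format(self, convention: Convention = "1-inclusive") -> str:
        if convention == "1-inclusive":
            return f"{self.chrom}:{self.start + 1}-{self.end}"
        if convention == "0-half-open":
            return f"{self.chrom}:{self.start}-{self.end}"
        raise ValueError(f"unknown convention: {convention!r}")


def parse_region(
    text: str, convention: Convention = "1-inclusive", assembly: str = ""
) -> GenomicInterval:
    """Parse a ``chrom:start-end`` region string.

    ``"chr19:1049437-1050028"`` parsed as 1-based inclusive yields an
    interval of length 592.  Formatting the result with the same convention
    restores the input string.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    chrom = m.group("chrom")
    start = int(m.group("start"))
    end = int(m.group("end"))
    if convention == "1-inclusive":
        start -= 1
    elif convention != "0-half-open":
        raise ValueError(f"unknown convention: {convention!r}")
    if start >= end:
        raise ValueError(f"start must not exceed end in {text!r}")
    return GenomicInterval(chrom, start, end, assembly)


@dataclass(frozen=True)
class RepeatRegion:
    """A VNTR locus: its genomic span, unit, and breakpoint-excluding core.

    The core interval excludes reads aligning across the repeat breakpoints,
    so that a read counted against the core lies within unambiguous repeat
    sequence.
    """

    span: GenomicInterval
    unit_length: int = 25
    unit_consensus: str = UNIT_CONSENSUS_25
    core: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if self.core is not None:
            if not self.span.contains(self.core) or (
                self.core.start == self.span.start and self.core.end == self.span.end
            ):
                raise ValueError("core must be strictly contained in span")

    def reference_units(self) -> "RepeatCount":
        return unit_count(self.span.length(), self.unit_length)


def abca7_vntr_region() -> RepeatRegion:
    """The intron-18 VNTR locus on hg19: 592-bp span, 440-bp core."""
    return RepeatRegion(
        span=parse_region("chr19:1049437-1050028", assembly="hg19"),
        unit_length=25,
        core=parse_region("chr19:1049514-1049953", assembly="hg19"),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class RepeatCount:
    """A length expressed in repeat units."""

    length_bp: float
    unit_length: int
    units: float = field(init=False)
    units_rounded: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", self.length_bp / self.unit_length)
        object.__setattr__(self, "units_rounded", _round_half_away(self.units))

    @property
    def units_1dp(self) -> float:
        """Unit count to one decimal, as customarily printed (e.g. 23.7)."""
        return round(self.units, 1)


def unit_count(length_bp: float, unit_length: int = 25) -> RepeatCount:
    """Express an allele length in repeat units (592 bp / 25 → 23.7)."""
    if length_bp < 0:
        raise ValueError("length must be nonnegative")
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    return RepeatCount(length_bp, unit_length)


@dataclass(frozen=True)
class UnitMatch:
    offset: int
    mismatch_positions: tuple[int, ...]


@dataclass(frozen=True)
class RepeatDecomposition:
    units: tuple[UnitMatch, ...]
    n_units: int
    consumed_bp: int
    remainder_bp: int


def decompose_repeat(
    sequence: str,
    unit_consensus: str = UNIT_CONSENSUS_25,
    max_mismatch_per_unit: int = 2,
) -> RepeatDecomposition:
    """Greedily tile a Sanger-read sequence into consensus repeat units.

    Left-to-right, substitution-only: each successive window of
    ``len(unit_consensus)`` bases is accepted as one unit when it differs
    from the consensus by at most ``max_mismatch_per_unit`` substitutions;
    tiling stops at the first rejected window.  This mirrors the slight
    inter-unit sequence variation seen in the genomic repeat.
    """
    consensus = unit_consensus.upper()
    if set(consensus) - _VALID_BASES:
        raise ValueError("consensus contains non-ACGT characters")
    seq = sequence.upper()
    k = len(consensus)
    units: list[UnitMatch] = []
    pos = 0
    while pos + k <= len(seq):
        window = seq[pos : pos + k]
        mismatches = tuple(i for i in range(k) if window[i] != consensus[i])
        if len(mismatches) > max_mismatch_per_unit:
            break
        units.append(UnitMatch(offset=pos, mismatch_positions=mismatches))
        pos += k
    return RepeatDecomposition(
        units=tuple(units),
        n_units=len(units),
        consumed_bp=pos,
        remainder_bp=len(seq) - pos,
    )


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3 file (0-based half-open) into intervals."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
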