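"""Core genomic domain types and interval arithmetic.

All coordinates are 0-based half-open (BED convention).  Peaks are
strandless; only gene records carry strand.  Promoter windows are
strand-aware, defaulting to 2,000 bp upstream / 1,000 bp downstream of
the transcription start site.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "Mark",
    "Condition",
    "Strand",
    "GenomicInterval",
    "PeakSet",
    "TssRecord",
    "PromoterWindow",
    "CoordinateError",
    "overlaps",
    "merge_intervals",
    "make_promoter_window",
]


class CoordinateError(ValueError):
    """Raised when a coordinate violates its sequence bounds or ordering."""


class Mark(str, enum.Enum):
    H3AC = "H3Ac"
    S5P = "S5P_RNAPII"
    SP1 = "Sp1"


class Condition(str, enum.Enum):
    MINUS = "minus_LPS"
    PLUS = "plus_LPS"


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Strandless half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 when on different sequences)."""
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff *a* and *b* share >= 1 base."""
    return a.seq_id == b.seq_id and a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (seq_id, start) and merge overlapping intervals.

    Abutting intervals (end == start) are *not* merged: overlap means at
    least one shared base.  Idempotent on already-merged input.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.seq_id, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].seq_id == iv.seq_id and iv.start < out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.seq_id, prev.start, iv.end)
        else:
            out.append(iv)
    return out


@dataclass
class PeakSet:
    """Named collection of intervals for one (mark, condition).

    Intervals are canonicalized on construction: sorted by
    (seq_id, start) and self-merged so members are pairwise
    non-overlapping.  ``n_merged`` records how many raw intervals were
    absorbed by the self-merge.
    """

    mark: Mark
    condition: Condition
    intervals: list[GenomicInterval] = field(default_factory=list)
    label: str = ""
    n_merged: int = 0

    def __post_init__(self) -> None:
        raw = list(self.intervals)
        merged = merge_intervals(raw)
        self.n_merged = len(raw) - len(merged)
        self.intervals = merged

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def mean_length(self) -> float | None:
        if not self.intervals:
            return None
        return sum(iv.length for iv in self.intervals) / len(self.intervals)


@dataclass
class TssRecord:
    """One annotated transcription start site of a gene.

    A gene with alternative TSSs owns several records sharing
    ``gene_id``.  ``tss_pos`` is 0-based; for a ``+`` gene with exons it
    equals the minimum exon start, for a ``-`` gene the maximum exon
    end - 1.
    """

    gene_id: str
    seq_id: str
    tss_pos: int
    strand: Strand
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tss_pos < 0:
            raise CoordinateError(f"{self.gene_id}: negative tss_pos {self.tss_pos}")
        if self.exons:
            if self.strand is Strand.PLUS:
                expect = min(e.start for e in self.exons)
            else:
                expect = max(e.end for e in self.exons) - 1
            if self.tss_pos != expect:
                raise CoordinateError(
                    f"{self.gene_id}: tss_pos {self.tss_pos} inconsistent with "
                    f"exons (expected {expect} for strand {self.strand.value})"
                )

    @property
    def span(self) -> GenomicInterval | None:
        """Transcribed span: min exon start to max exon end."""
        if not self.exons:
            return None
        return GenomicInterval(
            self.seq_id,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )


@dataclass
class PromoterWindow:
    """Strand-aware promoter window around one TSS, clamped to [0, L)."""

    tss: TssRecord
    upstream_bp: int
    downstream_bp: int
    interval: GenomicInterval

    @property
    def gene_id(self) -> str:
        return self.tss.gene_id


def make_promoter_window(
    tss: TssRecord,
    upstream_bp: int = 2000,
    downstream_bp: int = 1000,
    seq_length: int | None = None,
) -> PromoterWindow:
    """Build the promoter window for one TSS.

    For a ``+`` gene the window is ``[tss - upstream, tss + downstream)``;
    for a ``-`` gene its mirror image around the TSS base,
    ``[tss - downstream + 1, tss + upstream + 1)``.  The window is
    clamped to ``[0, seq_length)`` when a sequence length is given.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("upstream_bp and downstream_bp must be non-negative")
    if seq_length is not None and not (0 <= tss.tss_pos < seq_length):
        raise CoordinateError(
            f"gene {tss.gene_id}: tss_pos {tss.tss_pos} outside sequence "
            f"{tss.seq_id} of length {seq_length}"
        )
    if tss.strand is Strand.PLUS:
        start = tss.tss_pos - upstream_bp
        end = tss.tss_pos + downstream_bp
    else:
        start = tss.tss_pos - downstream_bp + 1
        end = tss.tss_pos + upstream_bp + 1
    start = max(0, start)
    if seq_length is not None:
        end = min(end, seq_length)
    if end <= start:  # degenerate after clamping (zero-size request)
        end = start + 1
    return PromoterWindow(
        tss=tss,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        interval=GenomicInterval(tss.seq_id, start, end),
    )
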