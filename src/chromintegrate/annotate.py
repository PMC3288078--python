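"""Genomic-feature classification of peaks and CpG co-localization.

Classes are assigned with the precedence promoter > exon > intron >
intergenic, where a class applies if the peak overlaps >= 1 bp of any
feature of that class.  "Intron" means inside a gene's transcribed span
(min exon start to max exon end) without touching a promoter or exon.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .genomic_model import (
    GenomicInterval,
    PeakSet,
    PromoterWindow,
    TssRecord,
    merge_intervals,
    overlaps,
)

__all__ = [
    "FEATURE_CLASSES",
    "classify_peak",
    "classify_peaks",
    "promoter_fraction",
    "cpg_split",
    "genome_composition",
]

FEATURE_CLASSES = ("promoter", "exon", "intron", "intergenic")


def classify_peak(
    peak: GenomicInterval,
    promoters: Sequence[PromoterWindow],
    genes: Sequence[TssRecord],
) -> str:
    """Assign one of promoter/exon/intron/intergenic by any-overlap precedence."""
    for w in promoters:
        if overlaps(peak, w.interval):
            return "promoter"
    for g in genes:
        for e in g.exons:
            if overlaps(peak, e):
                return "exon"
    for g in genes:
        span = g.span
        if span is not None and overlaps(peak, span):
            return "intron"
    return "intergenic"


def classify_peaks(
    peaks: Iterable[GenomicInterval],
    promoters: Sequence[PromoterWindow],
    genes: Sequence[TssRecord],
) -> list[str]:
    return [classify_peak(p, promoters, genes) for p in peaks]


def promoter_fraction(
    peaks: PeakSet | Sequence[GenomicInterval],
    promoters: Sequence[PromoterWindow],
    genes: Sequence[TssRecord] = (),
) -> float | None:
    """Percentage of peaks classified as promoter; None for an empty set."""
    ivs = list(peaks.intervals if isinstance(peaks, PeakSet) else peaks)
    if not ivs:
        return None
    n_prom = sum(
        1 for p in ivs if classify_peak(p, promoters, genes) == "promoter"
    )
    return 100.0 * n_prom / len(ivs)


def cpg_split(
    peaks: PeakSet,
    islands: Iterable[GenomicInterval],
) -> tuple[PeakSet, PeakSet]:
    """Split peaks into (high_cpg, low_cpg) by >=1 bp island overlap."""
    island_list = merge_intervals(islands)
    high, low = [], []
    for p in peaks:
        if any(overlaps(p, isl) for isl in island_list):
            high.append(p)
        else:
            low.append(p)
    return (
        PeakSet(peaks.mark, peaks.condition, high, label=f"{peaks.label}|high_cpg"),
        PeakSet(peaks.mark, peaks.condition, low, label=f"{peaks.label}|low_cpg"),
    )


def genome_composition(
    genes: Sequence[TssRecord],
    promoters: Sequence[PromoterWindow],
    seq_lengths: dict[str, int],
) -> dict[str, float]:
    """Fraction of genome bases per feature class under the same precedence.

    Computed by sweeping the sorted boundary points of all features per
    sequence, so it is exact without materializing per-base arrays.
    """
    total = sum(seq_lengths.values())
    if total <= 0:
        raise ValueError("seq_lengths must cover >= 1 base")
    base_counts = Counter({c: 0 for c in FEATURE_CLASSES})

    for seq_id, length in seq_lengths.items():
        prom = [w.interval for w in promoters if w.interval.seq_id == seq_id]
        exon = [e for g in genes if g.seq_id == seq_id for e in g.exons]
        span = [
            g.span for g in genes if g.seq_id == seq_id and g.span is not None
        ]
        feats = {
            "promoter": merge_intervals(prom),
            "exon": merge_intervals(exon),
            "intron": merge_intervals(span),
        }
        cuts = {0, length}
        for ivs in feats.values():
            for iv in ivs:
                cuts.add(min(iv.start, length))
                cuts.add(min(iv.end, length))
        pts = sorted(cuts)
        for a, b in zip(pts, pts[1:]):
            mid = a  # class is constant on [a, b)
            cls = "intergenic"
            for name in ("promoter", "exon", "intron"):
                if any(iv.start <= mid < iv.end for iv in feats[name]):
                    cls = name
                    break
            base_counts[cls] += b - a

    return {c: base_counts[c] / total for c in FEATURE_CLASSES}
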