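"""Per-TSS integration of chromatin, motif and expression tracks.

Each annotated TSS gets a feature profile (promoter H3Ac component,
extension direction, per-condition S5P/Sp1 status, CpG island, TATA
box, expression result) and — when the gene is regulated — a
promoter-architecture class: class 2 when a common acetylation
component touches the promoter window, class 1 when none does.
Secondary features (CpG, TATA, Sp1) are diagnostics, not deciders:
the one documented tie-break case is decided by promoter acetylation
alone.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .diffexpr import DEResult
from .genomic_model import (
    Condition,
    GenomicInterval,
    PeakSet,
    PromoterWindow,
    TssRecord,
    make_promoter_window,
    merge_intervals,
    overlaps,
)
from .peak_compare import (
    EXTENSION_NONE,
    CommonPeakComponent,
    ComparisonResult,
    extension_call,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TssFeatureProfile",
    "build_profile",
    "classify_group",
    "consistency_score",
    "colocalization_summary",
    "intragenic_unique_analysis",
    "gene_rollup",
]

STATUS_NONE = "NO"
STATUS_MINUS = "-LPS"
STATUS_PLUS = "+LPS"
STATUS_BOTH = "+/-LPS"


@dataclass
class TssFeatureProfile:
    gene_id: str
    tss: TssRecord
    de: DEResult | None = None
    h3ac_common: bool = False
    extension: str = EXTENSION_NONE
    s5p_status: str = STATUS_NONE
    sp1_status: str = STATUS_NONE
    cpg: bool = False
    tata: bool = False
    group: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.h3ac_common and self.extension != EXTENSION_NONE:
            raise ValueError(
                f"{self.gene_id}: extension call without a common H3Ac component"
            )


def _condition_status(
    window: GenomicInterval,
    minus: PeakSet | Sequence[GenomicInterval] | None,
    plus: PeakSet | Sequence[GenomicInterval] | None,
) -> str:
    def hit(track) -> bool:
        if track is None:
            return False
        ivs = track.intervals if isinstance(track, PeakSet) else track
        return any(overlaps(window, iv) for iv in ivs)

    m, p = hit(minus), hit(plus)
    if m and p:
        return STATUS_BOTH
    if m:
        return STATUS_MINUS
    if p:
        return STATUS_PLUS
    return STATUS_NONE


def build_profile(
    tss: TssRecord,
    h3ac: ComparisonResult | None,
    s5p_minus: PeakSet | None = None,
    s5p_plus: PeakSet | None = None,
    sp1_minus: PeakSet | None = None,
    sp1_plus: PeakSet | None = None,
    cpg_islands: Sequence[GenomicInterval] = (),
    tata: bool = False,
    de: DEResult | None = None,
    upstream_bp: int = 2000,
    downstream_bp: int = 1000,
    seq_length: int | None = None,
    min_extension_bp: int = 200,
) -> TssFeatureProfile:
    """Assemble the feature profile of one TSS.

    The promoter window is the strand-aware -upstream/+downstream
    interval.  When several common H3Ac components overlap it, the one
    with the largest window overlap is used (tie logged).  S5P/Sp1
    status uses raw per-condition peak sets, matching the
    NO / -LPS / +LPS / +/-LPS report vocabulary.
    """
    window = make_promoter_window(tss, upstream_bp, downstream_bp, seq_length).interval

    h3ac_common = False
    extension = EXTENSION_NONE
    if h3ac is not None:
        touching = [
            c
            for c in h3ac.components
            if c.seq_id == tss.seq_id
            and (overlaps(window, c.extent_minus) or overlaps(window, c.extent_plus))
        ]
        if touching:
            h3ac_common = True
            ranked = sorted(
                touching,
                key=lambda c: max(
                    window.overlap_bp(c.extent_minus), window.overlap_bp(c.extent_plus)
                ),
                reverse=True,
            )
            if len(ranked) > 1:
                logger.info(
                    "gene %s: %d common H3Ac components overlap the promoter; "
                    "using the largest-overlap one",
                    tss.gene_id,
                    len(ranked),
                )
            extension = extension_call(ranked[0], tss, min_extension_bp)

    profile = TssFeatureProfile(
        gene_id=tss.gene_id,
        tss=tss,
        de=de,
        h3ac_common=h3ac_common,
        extension=extension,
        s5p_status=_condition_status(window, s5p_minus, s5p_plus),
        sp1_status=_condition_status(window, sp1_minus, sp1_plus),
        cpg=any(overlaps(window, isl) for isl in cpg_islands),
        tata=tata,
    )
    profile.group = classify_group(profile)
    return profile


def classify_group(profile: TssFeatureProfile) -> str:
    """Promoter-architecture class of a regulated TSS.

    Pure function of (regulation call, promoter H3Ac): class "2" when a
    common acetylation component overlaps the promoter window, class
    "1" when none does; TSSs of unregulated genes stay "unassigned".
    """
    if profile.de is None or profile.de.call not in ("up", "down"):
        return "unassigned"
    return "2" if profile.h3ac_common else "1"


# modal secondary-feature patterns of the two classes, used only for the
# consistency diagnostic (never for classification)
_MODAL = {
    "1": {"cpg": False, "tata": True, "sp1_none": True},
    "2": {"cpg": True, "tata": False, "sp1_none": False},
}


def consistency_score(profile: TssFeatureProfile) -> float | None:
    """Fraction of secondary features matching the assigned class's modal
    pattern; None for unassigned TSSs."""
    if profile.group not in _MODAL:
        return None
    modal = _MODAL[profile.group]
    checks = [
        profile.cpg == modal["cpg"],
        profile.tata == modal["tata"],
        (profile.sp1_status == STATUS_NONE) == modal["sp1_none"],
    ]
    return sum(checks) / len(checks)


def gene_rollup(profiles: Iterable[TssFeatureProfile]) -> dict[str, str]:
    """Gene-level class from per-TSS classes: the single assigned class, or
    "mixed" when assigned TSSs of one gene disagree."""
    by_gene: dict[str, set[str]] = {}
    for p in profiles:
        if p.group != "unassigned":
            by_gene.setdefault(p.gene_id, set()).add(p.group)
    return {
        g: (groups.pop() if len(groups) == 1 else "mixed")
        for g, groups in ((g, set(s)) for g, s in by_gene.items())
    }


# ---------------------------------------------------------------------------
# Cross-mark co-localization

def _frac_overlapping(
    ivs: Sequence[GenomicInterval],
    others: Sequence[GenomicInterval],
    promoters: Sequence[PromoterWindow],
) -> dict:
    n = len(ivs)
    hit = [iv for iv in ivs if any(overlaps(iv, o) for o in others)]
    in_prom = [
        iv for iv in hit if any(overlaps(iv, w.interval) for w in promoters)
    ]
    return {
        "n": n,
        "n_overlapping": len(hit),
        "frac_overlapping": (len(hit) / n) if n else 0.0,
        "frac_overlapping_in_promoter": (len(in_prom) / len(hit)) if hit else 0.0,
    }


def colocalization_summary(
    a: ComparisonResult,
    b: ComparisonResult,
    promoters: Sequence[PromoterWindow] = (),
) -> dict[str, dict]:
    """Overlap of each class of A's peaks with B's matching-condition peaks.

    Classes: all -LPS / all +LPS peaks (vs B's same-condition peaks),
    common members (vs the union of all B peaks), and unique-/unique+
    (vs B's same-condition peaks).  Each entry reports count, fraction
    overlapping, and the promoter fraction among overlapping peaks.
    """
    b_minus = b.all_peaks(Condition.MINUS)
    b_plus = b.all_peaks(Condition.PLUS)
    b_union = merge_intervals(b_minus + b_plus)
    return {
        "all_minus": _frac_overlapping(a.all_peaks(Condition.MINUS), b_minus, promoters),
        "all_plus": _frac_overlapping(a.all_peaks(Condition.PLUS), b_plus, promoters),
        "common": _frac_overlapping(
            a.common_minus_peaks + a.common_plus_peaks, b_union, promoters
        ),
        "unique_minus": _frac_overlapping(
            list(a.unique_minus.intervals), b_minus, promoters
        ),
        "unique_plus": _frac_overlapping(
            list(a.unique_plus.intervals), b_plus, promoters
        ),
    }


# ---------------------------------------------------------------------------
# Stimulation-unique intragenic peaks in genes with open promoters

def intragenic_unique_analysis(
    h3ac: ComparisonResult,
    genes: Sequence[TssRecord],
    promoters: Sequence[PromoterWindow],
    cpg_islands: Sequence[GenomicInterval],
) -> tuple[int, int]:
    """Count (+)-condition-unique acetylation peaks inside gene bodies.

    Qualifying peaks are unique to the stimulated condition, classified
    exon or intron (promoter precedence applies), and overlap no CpG
    island.  The second count is how many of those sit in a gene whose
    promoter window overlaps a common-component envelope.
    """
    from .annotate import classify_peak  # local import avoids a cycle

    islands = merge_intervals(cpg_islands)
    extents = [
        e
        for c in h3ac.components
        for e in (c.extent_minus, c.extent_plus)
    ]
    open_genes: set[str] = set()
    for w in promoters:
        if any(overlaps(w.interval, e) for e in extents):
            open_genes.add(w.gene_id)

    n_qualifying = 0
    n_in_open = 0
    for peak in h3ac.unique_plus:
        cls = classify_peak(peak, promoters, genes)
        if cls not in ("exon", "intron"):
            continue
        if any(overlaps(peak, isl) for isl in islands):
            continue
        hosts = {
            g.gene_id
            for g in genes
            if g.span is not None and overlaps(peak, g.span)
        }
        if not hosts:
            continue
        n_qualifying += 1
        if hosts & open_genes:
            n_in_open += 1
    return n_qualifying, n_in_open
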