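"""Cross-replicate and cross-condition peak-set comparison.

Two-condition comparison partitions peaks into connected components of
the bipartite cross-condition overlap graph ("common" peaks) plus peaks
unique to either condition.  Because overlaps can be many-to-many, the
per-condition member counts and the component count are reported
separately — common counts are not additive across conditions.
"""
from __future__ import annotations

from dataclasses import dataclass

from .genomic_model import (
    Condition,
    GenomicInterval,
    PeakSet,
    Strand,
    TssRecord,
    merge_intervals,
)

__all__ = [
    "CommonPeakComponent",
    "ComparisonResult",
    "replicated_peaks",
    "compare_conditions",
    "extension_call",
    "length_summary",
    "EXTENSION_UP",
    "EXTENSION_DOWN",
    "EXTENSION_BOTH",
    "EXTENSION_NONE",
]

# direction glyphs: upstream-only, downstream-only, both, none
EXTENSION_UP = "→"      # →
EXTENSION_DOWN = "←"    # ←
EXTENSION_BOTH = "↔"    # ↔
EXTENSION_NONE = "-"


@dataclass
class CommonPeakComponent:
    """One connected component of the cross-condition overlap graph."""

    members_minus: list[GenomicInterval]
    members_plus: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.members_minus or not self.members_plus:
            raise ValueError("a common component needs members in both conditions")

    @property
    def seq_id(self) -> str:
        return self.members_minus[0].seq_id

    def extent(self, condition: Condition) -> GenomicInterval:
        members = (
            self.members_minus if condition is Condition.MINUS else self.members_plus
        )
        return GenomicInterval(
            members[0].seq_id,
            min(m.start for m in members),
            max(m.end for m in members),
        )

    @property
    def extent_minus(self) -> GenomicInterval:
        return self.extent(Condition.MINUS)

    @property
    def extent_plus(self) -> GenomicInterval:
        return self.extent(Condition.PLUS)


@dataclass
class ComparisonResult:
    mark: object
    components: list[CommonPeakComponent]
    unique_minus: PeakSet
    unique_plus: PeakSet

    @property
    def common_minus_peaks(self) -> list[GenomicInterval]:
        return [iv for c in self.components for iv in c.members_minus]

    @property
    def common_plus_peaks(self) -> list[GenomicInterval]:
        return [iv for c in self.components for iv in c.members_plus]

    def all_peaks(self, condition: Condition) -> list[GenomicInterval]:
        if condition is Condition.MINUS:
            return sorted(
                self.common_minus_peaks + list(self.unique_minus.intervals)
            )
        return sorted(self.common_plus_peaks + list(self.unique_plus.intervals))


def replicated_peaks(
    rep1: PeakSet,
    rep2: PeakSet,
    min_overlap_bp: int = 1,
    symmetric: bool = False,
) -> PeakSet:
    """Intervals of rep1 supported by >= min_overlap_bp of some rep2 interval.

    Reference-asymmetric (rep1 is kept) unless ``symmetric``, which
    returns the union of both directions.  Result is self-merged.
    """
    if rep1.mark != rep2.mark or rep1.condition != rep2.condition:
        raise ValueError(
            f"replicate mark/condition mismatch: ({rep1.mark}, {rep1.condition}) "
            f"vs ({rep2.mark}, {rep2.condition})"
        )

    def supported(source: PeakSet, other: PeakSet) -> list[GenomicInterval]:
        kept = []
        for iv in source:
            if any(iv.overlap_bp(jv) >= min_overlap_bp for jv in other):
                kept.append(iv)
        return kept

    intervals = supported(rep1, rep2)
    if symmetric:
        intervals += supported(rep2, rep1)
    return PeakSet(
        mark=rep1.mark,
        condition=rep1.condition,
        intervals=intervals,
        label=f"replicated({rep1.label},{rep2.label})",
    )


def compare_conditions(minus: PeakSet, plus: PeakSet) -> ComparisonResult:
    """Partition two condition peak sets into common components and uniques.

    Both sets are canonical (self-merged), so same-condition members
    never overlap and connected components of the full interval overlap
    graph coincide with those of the bipartite cross-condition graph.
    A single sorted sweep finds them: a new interval joins the open
    cluster iff it starts before the cluster's running max end.
    """
    if minus.mark != plus.mark:
        raise ValueError(f"mark mismatch: {minus.mark} vs {plus.mark}")
    tagged = [(iv, Condition.MINUS) for iv in minus] + [
        (iv, Condition.PLUS) for iv in plus
    ]
    tagged.sort(key=lambda t: (t[0].seq_id, t[0].start, t[0].end))

    components: list[CommonPeakComponent] = []
    uniq_minus: list[GenomicInterval] = []
    uniq_plus: list[GenomicInterval] = []

    cluster: list[tuple[GenomicInterval, Condition]] = []
    cluster_end = -1
    cluster_seq = None

    def flush() -> None:
        if not cluster:
            return
        m = [iv for iv, c in cluster if c is Condition.MINUS]
        p = [iv for iv, c in cluster if c is Condition.PLUS]
        if m and p:
            components.append(CommonPeakComponent(members_minus=m, members_plus=p))
        elif m:
            uniq_minus.extend(m)
        else:
            uniq_plus.extend(p)

    for iv, cond in tagged:
        if cluster and iv.seq_id == cluster_seq and iv.start < cluster_end:
            cluster.append((iv, cond))
            cluster_end = max(cluster_end, iv.end)
        else:
            flush()
            cluster = [(iv, cond)]
            cluster_end = iv.end
            cluster_seq = iv.seq_id
    flush()

    return ComparisonResult(
        mark=minus.mark,
        components=components,
        unique_minus=PeakSet(minus.mark, Condition.MINUS, uniq_minus,
                             label="unique_minus"),
        unique_plus=PeakSet(plus.mark, Condition.PLUS, uniq_plus,
                            label="unique_plus"),
    )


def extension_call(
    component: CommonPeakComponent,
    tss: TssRecord,
    min_extension_bp: int = 200,
) -> str:
    """Classify envelope growth of a common component relative to a TSS.

    Growth is measured on the per-condition envelopes; shrinkage counts
    as zero.  Upstream/downstream are strand-aware.  Returns one of
    {→, ←, ↔, -}.
    """
    ext_minus = component.extent_minus
    ext_plus = component.extent_plus
    if ext_minus.seq_id != tss.seq_id:
        raise ValueError(
            f"component on {ext_minus.seq_id} vs TSS of {tss.gene_id} on {tss.seq_id}"
        )
    left_growth = max(0, ext_minus.start - ext_plus.start)
    right_growth = max(0, ext_plus.end - ext_minus.end)
    if tss.strand is Strand.PLUS:
        up, down = left_growth, right_growth
    else:
        up, down = right_growth, left_growth
    up_hit = up >= min_extension_bp
    down_hit = down >= min_extension_bp
    if up_hit and down_hit:
        return EXTENSION_BOTH
    if up_hit:
        return EXTENSION_UP
    if down_hit:
        return EXTENSION_DOWN
    return EXTENSION_NONE


def _mean_len(intervals: list[GenomicInterval]) -> float | None:
    if not intervals:
        return None
    return sum(iv.length for iv in intervals) / len(intervals)


def length_summary(result: ComparisonResult) -> dict:
    """Per-class counts and mean lengths, plus the common widening ratio.

    Empty classes report mean None (never 0).  ``widening_ratio`` is
    mean(+LPS common member length) / mean(-LPS common member length).
    """
    cm = result.common_minus_peaks
    cp = result.common_plus_peaks
    um = list(result.unique_minus.intervals)
    up = list(result.unique_plus.intervals)
    mean_cm, mean_cp = _mean_len(cm), _mean_len(cp)
    ratio = None
    if mean_cm and mean_cp is not None:
        ratio = mean_cp / mean_cm
    return {
        "n_components": len(result.components),
        "n_common_minus": len(cm),
        "n_common_plus": len(cp),
        "n_unique_minus": len(um),
        "n_unique_plus": len(up),
        "n_total_minus": len(cm) + len(um),
        "n_total_plus": len(cp) + len(up),
        "mean_len_common_minus": mean_cm,
        "mean_len_common_plus": mean_cp,
        "mean_len_unique_minus": _mean_len(um),
        "mean_len_unique_plus": _mean_len(up),
        "mean_len_all_minus": _mean_len(cm + um),
        "mean_len_all_plus": _mean_len(cp + up),
        "widening_ratio": ratio,
    }
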