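"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (per-base sets, all-pairs loops,
exhaustive enumeration) and shares no code with the implementation
paths it checks.
"""
from __future__ import annotations

import itertools
import math

from chromintegrate.genomic_model import GenomicInterval


def bases(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.seq_id, p) for p in range(iv.start, iv.end)}


def overlaps_bruteforce(a: GenomicInterval, b: GenomicInterval) -> bool:
    return bool(bases(a) & bases(b))


def merge_bruteforce(intervals) -> list[GenomicInterval]:
    """Union-find over pairwise per-base overlap; envelopes of the
    resulting components.  Abutting intervals share no base, so they
    stay separate — matching the >=1-shared-base overlap definition."""
    items = list(intervals)
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        if overlaps_bruteforce(items[i], items[j]):
            parent[find(i)] = find(j)

    groups: dict[int, list[GenomicInterval]] = {}
    for i, iv in enumerate(items):
        groups.setdefault(find(i), []).append(iv)
    out = [
        GenomicInterval(
            members[0].seq_id,
            min(m.start for m in members),
            max(m.end for m in members),
        )
        for members in groups.values()
    ]
    return sorted(out)


def replicated_bruteforce(rep1, rep2, min_overlap_bp: int = 1):
    """All-pairs filter: rep1 intervals sharing >= k bases with some rep2."""
    kept = []
    for a in rep1:
        for b in rep2:
            if len(bases(a) & bases(b)) >= min_overlap_bp:
                kept.append(a)
                break
    return merge_bruteforce(kept) if kept else []


def components_bruteforce(minus, plus):
    """Union-find over all cross-pairs; returns (component frozensets of
    ("m"/"p", interval), unique_minus, unique_plus)."""
    items = [("m", iv) for iv in minus] + [("p", iv) for iv in plus]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        if overlaps_bruteforce(items[i][1], items[j][1]):
            parent[find(i)] = find(j)

    groups: dict[int, list] = {}
    for i, item in enumerate(items):
        groups.setdefault(find(i), []).append(item)
    comps, uniq_m, uniq_p = [], [], []
    for members in groups.values():
        tags = {t for t, _ in members}
        if tags == {"m", "p"}:
            comps.append(frozenset(members))
        elif tags == {"m"}:
            uniq_m.extend(iv for _, iv in members)
        else:
            uniq_p.extend(iv for _, iv in members)
    return comps, sorted(uniq_m), sorted(uniq_p)


def classify_base(seq_id: str, pos: int, promoters, genes) -> str:
    for w in promoters:
        iv = w.interval
        if iv.seq_id == seq_id and iv.start <= pos < iv.end:
            return "promoter"
    for g in genes:
        for e in g.exons:
            if e.seq_id == seq_id and e.start <= pos < e.end:
                return "exon"
    for g in genes:
        span = g.span
        if span and span.seq_id == seq_id and span.start <= pos < span.end:
            return "intron"
    return "intergenic"


def classify_peak_bruteforce(peak, promoters, genes) -> str:
    """Per-base precedence: best class over any covered base."""
    rank = {"promoter": 0, "exon": 1, "intron": 2, "intergenic": 3}
    best = "intergenic"
    for p in range(peak.start, peak.end):
        c = classify_base(peak.seq_id, p, promoters, genes)
        if rank[c] < rank[best]:
            best = c
    return best


def genome_composition_bruteforce(genes, promoters, seq_lengths):
    counts = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
    total = 0
    for seq_id, L in seq_lengths.items():
        for pos in range(L):
            counts[classify_base(seq_id, pos, promoters, genes)] += 1
        total += L
    return {k: v / total for k, v in counts.items()}


def similarity_bruteforce(freqs, s: str) -> float:
    """Direct evaluation of the conservation-weighted similarity formula,
    written independently of the library (freqs: list of 4-dicts)."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ci = []
    for row in freqs:
        total = 0.0
        for f in row:
            if f > 0:
                total += f * math.log(4 * f)
        ci.append(total / math.log(4))
    denom = sum(c * max(row) for c, row in zip(ci, freqs))
    num = 0.0
    for j, ch in enumerate(s):
        if ch in idx:
            num += ci[j] * freqs[j][idx[ch]]
    return num / denom


def best_kmer_exhaustive(freqs) -> tuple[str, float]:
    """Best-scoring W-mer over all 4^W sequences (exhaustive)."""
    best, best_score = None, -1.0
    for kmer in itertools.product("ACGT", repeat=len(freqs)):
        s = "".join(kmer)
        score = similarity_bruteforce(freqs, s)
        if score > best_score:
            best, best_score = s, score
    return best, best_score
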