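"""Matrix-similarity TATA-box detection in core-promoter windows.

The default matrices are reconstructed from the two published consensus
strings (VTATA.01 ``gTATAAAa``, VTATA.02 ``ctATAAAA``) using a fixed
frequency-assignment rule — uppercase (core) positions get a dominant
frequency of 0.85, lowercase (weak) positions 0.40 — because the
vendor's numeric matrices are proprietary.  User-supplied matrices
(one row per position: four whitespace-separated A C G T frequencies)
override the defaults.

The similarity of a W-mer ``s`` to a matrix is

    sim(s) = sum_j Ci(j) * f_j(s_j)  /  sum_j Ci(j) * max_b f_j(b)

with per-position conservation weights

    Ci(j) = (1/ln 4) * sum_b f_j(b) * ln(4 * f_j(b)),   0*ln(0) := 0,

so sim is in [0, 1] and equals 1 exactly on per-position argmax
sequences.  ``N`` bases contribute 0 at their position.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_model import Strand, TssRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "matrix_from_consensus",
    "matrix_similarity",
    "scan_sequence",
    "scan_tata",
    "default_tata_matrices",
    "read_matrix_file",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position base frequencies plus derived conservation weights."""

    name: str
    freqs: np.ndarray  # shape (W, 4), rows sum to 1

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError(f"{self.name}: freqs must be (W, 4)")
        if (f < 0).any() or not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: rows must be non-negative and sum to 1")
        object.__setattr__(self, "freqs", f)

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def info(self) -> np.ndarray:
        """Ci(j) = (1/ln4) * sum_b f*ln(4f), in [0, 1]."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
        return terms.sum(axis=1) / math.log(4.0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    matrix_name: str
    offset: int          # window-relative start of the match
    strand: str          # strand of the scanned sequence ("+" = gene sense)
    similarity: float
    matched: str


def matrix_from_consensus(consensus: str, name: str = "") -> PositionWeightMatrix:
    """Build a matrix from a case-encoded consensus string.

    Uppercase position: dominant base 0.85, others 0.05 each.
    Lowercase position: dominant base 0.40, others 0.20 each.
    """
    rows = []
    for ch in consensus:
        if ch.upper() not in _BASE_INDEX:
            raise ValueError(f"consensus character {ch!r} not in ACGT/acgt")
        dom = 0.85 if ch.isupper() else 0.40
        rest = (1.0 - dom) / 3.0
        row = [rest] * 4
        row[_BASE_INDEX[ch.upper()]] = dom
        rows.append(row)
    return PositionWeightMatrix(name=name or consensus, freqs=np.array(rows))


def default_tata_matrices() -> list[PositionWeightMatrix]:
    return [
        matrix_from_consensus("gTATAAAa", name="VTATA.01"),
        matrix_from_consensus("ctATAAAA", name="VTATA.02"),
    ]


def read_matrix_file(path: str | Path, name: str | None = None) -> PositionWeightMatrix:
    """Read a plain-text matrix: one row per position, four frequencies (A C G T)."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = [float(x) for x in line.split()]
        if len(vals) != 4:
            raise ValueError(f"{path}: each row needs 4 frequencies, got {len(vals)}")
        rows.append(vals)
    return PositionWeightMatrix(name=name or path.stem, freqs=np.array(rows))


def matrix_similarity(pwm: PositionWeightMatrix, s: str) -> float:
    """Conservation-weighted similarity of a W-mer to the matrix, in [0, 1]."""
    if len(s) != pwm.width:
        raise ValueError(
            f"sequence length {len(s)} != matrix width {pwm.width} ({pwm.name})"
        )
    ci = pwm.info
    denom = float((ci * pwm.freqs.max(axis=1)).sum())
    if denom == 0.0:  # fully uniform matrix matches everything
        return 1.0
    num = 0.0
    for j, ch in enumerate(s.upper()):
        idx = _BASE_INDEX.get(ch)
        if idx is None:  # N or other ambiguity: contributes 0
            continue
        num += ci[j] * pwm.freqs[j, idx]
    return num / denom


def scan_sequence(
    seq: str,
    matrices: Sequence[PositionWeightMatrix],
    cutoff: float = 0.9,
    strand: str = "+",
) -> list[MotifHit]:
    """All matrix hits >= cutoff over every offset, sorted by similarity desc."""
    hits: list[MotifHit] = []
    for pwm in matrices:
        w = pwm.width
        for off in range(0, len(seq) - w + 1):
            sub = seq[off : off + w]
            sim = matrix_similarity(pwm, sub)
            if sim >= cutoff:
                hits.append(MotifHit(pwm.name, off, strand, sim, sub))
    hits.sort(key=lambda h: (-h.similarity, h.offset, h.matrix_name))
    return hits


def core_promoter_sequence(
    tss: TssRecord,
    genome: Mapping[str, str],
    window_up: int = 150,
    window_down: int = 50,
) -> tuple[str, int]:
    """Sense-strand sequence of the -window_up/+window_down core window.

    Returns (sequence, genomic start of the extracted region).  Windows
    running off the sequence are clamped with a logged warning.
    """
    seq = genome.get(tss.seq_id)
    if seq is None:
        raise KeyError(f"no sequence {tss.seq_id!r} for gene {tss.gene_id}")
    if tss.strand is Strand.PLUS:
        start, end = tss.tss_pos - window_up, tss.tss_pos + window_down
    else:
        start, end = tss.tss_pos - window_down + 1, tss.tss_pos + window_up + 1
    cstart, cend = max(0, start), min(len(seq), end)
    if (cstart, cend) != (start, end):
        logger.warning(
            "core window of %s clamped to [%d, %d)", tss.gene_id, cstart, cend
        )
    sub = seq[cstart:cend]
    if tss.strand is Strand.MINUS:
        sub = reverse_complement(sub)
    return sub, cstart


def scan_tata(
    tss: TssRecord,
    genome: Mapping[str, str],
    window_up: int = 150,
    window_down: int = 50,
    cutoff: float = 0.9,
    matrices: Sequence[PositionWeightMatrix] | None = None,
    both_strands: bool = False,
) -> tuple[bool, list[MotifHit]]:
    """Scan the strand-aware core-promoter window of one TSS.

    Sense-strand only by default (TATA boxes are orientation-dependent);
    ``both_strands`` additionally scans the reverse complement.
    """
    if matrices is None:
        matrices = default_tata_matrices()
    window, _ = core_promoter_sequence(tss, genome, window_up, window_down)
    hits = scan_sequence(window, matrices, cutoff, strand="+")
    if both_strands:
        hits += scan_sequence(reverse_complement(window), matrices, cutoff, strand="-")
        hits.sort(key=lambda h: (-h.similarity, h.offset, h.matrix_name))
    return bool(hits), hits
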