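"""Ground-truth simulator for the whole pipeline.

Emits a small genome (FASTA), gene models, CpG islands, per-mark
per-condition peak tracks, a replicated log2 expression matrix and a
ground-truth table, with planted structure:

* regulated genes carry one of two promoter architectures — class 1
  (no promoter acetylation, no CpG island, a TATA consensus written
  into the -150/+50 core window) or class 2 (a common acetylation peak
  whose stimulated extent is widened by ``widen_factor`` in a planted
  direction, a CpG island spanning the promoter, no TATA);
* null genes draw their architecture from a background mix;
* extra background peaks realize configured common/unique fractions;
* optional stimulation-unique peaks are planted inside gene bodies.

Genes are laid out on alternating strands with enough spacing that no
planted feature can collide with a neighbour, so every planted label is
recoverable by the corresponding downstream stage in the noiseless
limit.  A single seeded NumPy generator drives all randomness; the same
config and seed give byte-identical files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import format_io
from .format_io import ExpressionMatrix
from .genomic_model import (
    Condition,
    GenomicInterval,
    Mark,
    PeakSet,
    Strand,
    TssRecord,
)
from .motif_scan import default_tata_matrices, reverse_complement, scan_sequence
from .peak_compare import (
    EXTENSION_BOTH,
    EXTENSION_DOWN,
    EXTENSION_NONE,
    EXTENSION_UP,
)

__all__ = ["SimulationConfig", "GroundTruth", "ConfigError", "simulate"]

_BASES = np.array(list("ACGT"))
TATA_CONSENSUS = "GTATAAAA"  # argmax sequence of the primary default matrix


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_sequences: int = 2
    seq_length: int = 800_000
    n_genes: int = 60
    n_up: int = 20
    n_down: int = 5
    frac_group1: float = 0.5
    frac_group2: float = 0.5
    fc_up: float = 4.0
    fc_down: float = 4.0
    replicate_sd: float = 0.25
    n_replicates: int = 4
    # peak geometry
    mean_peak_len_minus: int = 3000
    widen_factor: float = 2.0
    min_extension_guarantee: int = 200
    extension_direction_mix: dict = field(
        default_factory=lambda: {
            EXTENSION_UP: 0.3,
            EXTENSION_DOWN: 0.3,
            EXTENSION_BOTH: 0.3,
            EXTENSION_NONE: 0.1,
        }
    )
    # background (gene-free) peaks realizing the class fractions
    n_background_peaks: int = 0
    frac_common: float = 0.6
    frac_unique_minus: float = 0.3
    frac_unique_plus: float = 0.1
    # intragenic stimulation-unique peaks
    n_intragenic_unique: int = 0
    frac_intragenic_in_open: float = 0.7
    # promoter / motif geometry
    upstream_bp: int = 2000
    downstream_bp: int = 1000
    tata_window_up: int = 150
    tata_window_down: int = 50
    tata_offset: int = -31  # motif start relative to TSS on the sense strand
    tata_matrix_similarity_target: float = 0.9
    cpg_island_len: int = 1000
    gene_length: int = 12_000
    # null-gene background architecture
    null_h3ac_prob: float = 0.6
    # class-2 / null S5P and Sp1 planting probabilities
    g2_sp1_prob: float = 0.5
    g1_s5p_plus_prob: float = 0.4

    def validate(self) -> None:
        if abs(self.frac_group1 + self.frac_group2 - 1.0) > 1e-9:
            raise ConfigError("frac_group1 + frac_group2 must equal 1")
        s = self.frac_common + self.frac_unique_minus + self.frac_unique_plus
        if abs(s - 1.0) > 1e-9:
            raise ConfigError("peak class fractions must sum to 1")
        mix_sum = sum(self.extension_direction_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigError("extension_direction_mix must sum to 1")
        bad = set(self.extension_direction_mix) - {
            EXTENSION_UP, EXTENSION_DOWN, EXTENSION_BOTH, EXTENSION_NONE
        }
        if bad:
            raise ConfigError(f"unknown extension directions {bad}")
        if self.n_up + self.n_down > self.n_genes:
            raise ConfigError("n_up + n_down exceeds n_genes")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per condition")
        if self.widen_factor < 1.0:
            raise ConfigError("widen_factor must be >= 1")
        directed = any(
            p > 0
            for d, p in self.extension_direction_mix.items()
            if d != EXTENSION_NONE
        )
        min_len = int(0.8 * self.mean_peak_len_minus)
        if directed and (self.widen_factor - 1.0) * min_len / 2 < self.min_extension_guarantee:
            raise ConfigError(
                "widen_factor/mean_peak_len_minus too small to guarantee "
                f">= {self.min_extension_guarantee} bp extension per side"
            )
        if self.gene_length < 9000:
            raise ConfigError("gene_length must be >= 9000 for the exon layout")

    # --- derived geometry -------------------------------------------------
    @property
    def _max_peak_len(self) -> int:
        return int(math.ceil(1.2 * self.mean_peak_len_minus * self.widen_factor))

    @property
    def _slot_margin(self) -> int:
        half = int(0.6 * self.mean_peak_len_minus)
        ext = int(math.ceil((self.widen_factor - 1.0) * 1.2 * self.mean_peak_len_minus))
        return max(self.upstream_bp + self.downstream_bp, half + ext) + 500

    @property
    def _slot_len(self) -> int:
        return self.gene_length + 2 * self._slot_margin

    def genes_per_sequence(self) -> int:
        return self.seq_length // self._slot_len


@dataclass
class GroundTruth:
    genes: pd.DataFrame   # one row per gene
    peaks: pd.DataFrame   # one row per planted peak (any mark)
    files: dict[str, Path]
    config: SimulationConfig


def _draw_direction(rng: np.random.Generator, mix: dict) -> str:
    dirs = sorted(mix)  # stable order for determinism
    probs = np.array([mix[d] for d in dirs])
    return str(rng.choice(dirs, p=probs / probs.sum()))


def _widen(
    minus: GenomicInterval,
    direction: str,
    strand: Strand,
    widen_factor: float,
) -> GenomicInterval:
    """Stimulated extent: the unstimulated interval extended on the planted
    side(s); always contains the unstimulated interval."""
    ext = int(round((widen_factor - 1.0) * minus.length))
    if direction == EXTENSION_NONE or ext == 0:
        return minus
    if direction == EXTENSION_BOTH:
        left = right = ext // 2
    else:
        upstream = direction == EXTENSION_UP
        to_left = upstream if strand is Strand.PLUS else not upstream
        left, right = (ext, 0) if to_left else (0, ext)
    return GenomicInterval(minus.seq_id, max(0, minus.start - left), minus.end + right)


def simulate(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Run the simulation and write all files under *outdir*."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    per_seq = config.genes_per_sequence()
    capacity = config.n_sequences * per_seq
    if capacity < config.n_genes:
        raise ConfigError(
            f"geometry cannot fit {config.n_genes} genes: capacity {capacity} "
            f"({per_seq} per sequence of {config.seq_length} bp; "
            f"slot {config._slot_len} bp)"
        )

    # ---- gene placement --------------------------------------------------
    genes: list[TssRecord] = []
    margin, glen = config._slot_margin, config.gene_length
    for i in range(config.n_genes):
        seq_id = f"chr{i // per_seq + 1}"
        a = margin + (i % per_seq) * config._slot_len  # gene body start
        strand = Strand.PLUS if i % 2 == 0 else Strand.MINUS
        gid = f"gene{i + 1:04d}"
        if strand is Strand.PLUS:
            tss = a
            exons = [
                GenomicInterval(seq_id, tss, tss + 400),
                GenomicInterval(seq_id, tss + 8000, tss + glen),
            ]
        else:
            tss = a + glen - 1
            exons = [
                GenomicInterval(seq_id, a, tss + 1 - 8000),
                GenomicInterval(seq_id, tss + 1 - 400, tss + 1),
            ]
        genes.append(TssRecord(gid, seq_id, tss, strand, exons))

    # ---- role assignment -------------------------------------------------
    n_reg = config.n_up + config.n_down
    order = rng.permutation(config.n_genes)
    reg_idx = list(order[:n_reg])
    regulation = ["null"] * config.n_genes
    for j, gi in enumerate(reg_idx):
        regulation[gi] = "up" if j < config.n_up else "down"
    n_g1 = int(round(config.frac_group1 * n_reg))
    reg_shuffled = list(rng.permutation(reg_idx))
    group = ["null"] * config.n_genes
    for j, gi in enumerate(reg_shuffled):
        group[gi] = "1" if j < n_g1 else "2"

    # ---- per-gene architecture -------------------------------------------
    h3ac_minus: list[GenomicInterval] = []
    h3ac_plus: list[GenomicInterval] = []
    s5p_minus: list[GenomicInterval] = []
    s5p_plus: list[GenomicInterval] = []
    sp1_minus: list[GenomicInterval] = []
    sp1_plus: list[GenomicInterval] = []
    cpg_islands: list[GenomicInterval] = []
    peak_rows: list[dict] = []
    gene_rows: list[dict] = []

    def add_promoter_mark(g: TssRecord, status: str, minus_l, plus_l) -> None:
        iv = GenomicInterval(g.seq_id, max(0, g.tss_pos - 300), g.tss_pos + 300)
        if status in ("-LPS", "+/-LPS"):
            minus_l.append(iv)
        if status in ("+LPS", "+/-LPS"):
            plus_l.append(iv)

    for gi, g in enumerate(genes):
        grp, reg = group[gi], regulation[gi]
        has_h3ac = False
        direction = EXTENSION_NONE
        has_cpg = False
        has_tata = False
        s5p_status = "NO"
        sp1_status = "NO"

        if grp == "2":
            has_h3ac, has_cpg = True, True
            s5p_status = "+/-LPS"
            sp1_status = "+/-LPS" if rng.random() < config.g2_sp1_prob else "NO"
        elif grp == "1":
            has_tata = True
            s5p_status = "+LPS" if rng.random() < config.g1_s5p_plus_prob else "NO"
        else:  # null gene: background architecture
            if rng.random() < config.null_h3ac_prob:
                has_h3ac, has_cpg = True, True
                s5p_status = "+/-LPS"

        if has_h3ac:
            direction = _draw_direction(rng, config.extension_direction_mix)
            L = int(
                np.clip(
                    rng.normal(config.mean_peak_len_minus, 0.1 * config.mean_peak_len_minus),
                    0.8 * config.mean_peak_len_minus,
                    1.2 * config.mean_peak_len_minus,
                )
            )
            minus_iv = GenomicInterval(
                g.seq_id, max(0, g.tss_pos - L // 2), g.tss_pos - L // 2 + L
            )
            plus_iv = _widen(minus_iv, direction, g.strand, config.widen_factor)
            h3ac_minus.append(minus_iv)
            h3ac_plus.append(plus_iv)
            peak_rows.append(
                {
                    "seq_id": g.seq_id,
                    "start_minus": minus_iv.start,
                    "end_minus": minus_iv.end,
                    "start_plus": plus_iv.start,
                    "end_plus": plus_iv.end,
                    "mark": Mark.H3AC.value,
                    "klass": "common",
                    "direction": direction,
                    "gene_id": g.gene_id,
                }
            )
        if has_cpg:
            isl = GenomicInterval(
                g.seq_id,
                max(0, g.tss_pos - config.cpg_island_len // 2),
                g.tss_pos + config.cpg_island_len // 2,
            )
            cpg_islands.append(isl)
        add_promoter_mark(g, s5p_status, s5p_minus, s5p_plus)
        add_promoter_mark(g, sp1_status, sp1_minus, sp1_plus)

        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "seq_id": g.seq_id,
                "tss_pos": g.tss_pos,
                "strand": g.strand.value,
                "regulation": reg,
                "group": grp,
                "h3ac_common": has_h3ac,
                "extension": direction,
                "s5p_status": s5p_status,
                "sp1_status": sp1_status,
                "cpg": has_cpg,
                "tata": has_tata,
            }
        )

    # ---- intragenic stimulation-unique peaks -----------------------------
    if config.n_intragenic_unique:
        open_hosts = [i for i in range(config.n_genes) if gene_rows[i]["h3ac_common"]]
        closed_hosts = [
            i for i in range(config.n_genes) if not gene_rows[i]["h3ac_common"]
        ]
        n_open = int(round(config.frac_intragenic_in_open * config.n_intragenic_unique))
        n_closed = config.n_intragenic_unique - n_open
        if n_open > len(open_hosts) or n_closed > len(closed_hosts):
            raise ConfigError(
                "not enough host genes for the requested intragenic unique peaks"
            )
        half = int(0.6 * config.mean_peak_len_minus)
        ext = int(math.ceil((config.widen_factor - 1.0) * 1.2 * config.mean_peak_len_minus))
        offset = half + ext + 1000  # downstream of any planted promoter peak
        plen = 400
        if offset + plen > config.gene_length - 100:
            raise ConfigError(
                "gene_length too small to host intragenic unique peaks "
                f"(need > {offset + plen + 100})"
            )
        hosts = [(i, True) for i in open_hosts[:n_open]] + [
            (i, False) for i in closed_hosts[:n_closed]
        ]
        for gi, in_open in hosts:
            g = genes[gi]
            if g.strand is Strand.PLUS:
                start = g.tss_pos + offset
            else:
                start = g.tss_pos - offset - plen
            iv = GenomicInterval(g.seq_id, start, start + plen)
            h3ac_plus.append(iv)
            peak_rows.append(
                {
                    "seq_id": g.seq_id,
                    "start_minus": -1,
                    "end_minus": -1,
                    "start_plus": iv.start,
                    "end_plus": iv.end,
                    "mark": Mark.H3AC.value,
                    "klass": "intragenic_unique_plus",
                    "direction": EXTENSION_NONE,
                    "gene_id": g.gene_id,
                }
            )

    # ---- background peaks on a gene-free sequence ------------------------
    seq_lengths = {f"chr{i + 1}": config.seq_length for i in range(config.n_sequences)}
    if config.n_background_peaks:
        ext_max = int(
            math.ceil((config.widen_factor - 1.0) * 1.2 * config.mean_peak_len_minus)
        )
        gap = config._max_peak_len + 2 * ext_max + 1000
        bg_seq = "chrBG"
        pos = 1000 + ext_max
        classes = rng.choice(
            ["common", "unique_minus", "unique_plus"],
            size=config.n_background_peaks,
            p=[config.frac_common, config.frac_unique_minus, config.frac_unique_plus],
        )
        for klass in classes:
            L = int(
                np.clip(
                    rng.normal(config.mean_peak_len_minus, 0.1 * config.mean_peak_len_minus),
                    0.8 * config.mean_peak_len_minus,
                    1.2 * config.mean_peak_len_minus,
                )
            )
            base = GenomicInterval(bg_seq, pos, pos + L)
            direction = EXTENSION_NONE
            row = {
                "seq_id": bg_seq,
                "start_minus": -1,
                "end_minus": -1,
                "start_plus": -1,
                "end_plus": -1,
                "mark": Mark.H3AC.value,
                "klass": klass,
                "direction": direction,
                "gene_id": "",
            }
            if klass == "common":
                # direction recorded in +-strand convention (no gene anchor)
                direction = _draw_direction(rng, config.extension_direction_mix)
                plus_iv = _widen(base, direction, Strand.PLUS, config.widen_factor)
                h3ac_minus.append(base)
                h3ac_plus.append(plus_iv)
                row.update(
                    start_minus=base.start, end_minus=base.end,
                    start_plus=plus_iv.start, end_plus=plus_iv.end,
                    direction=direction,
                )
            elif klass == "unique_minus":
                h3ac_minus.append(base)
                row.update(start_minus=base.start, end_minus=base.end)
            else:
                h3ac_plus.append(base)
                row.update(start_plus=base.start, end_plus=base.end)
            peak_rows.append(row)
            pos += L + gap
        seq_lengths[bg_seq] = pos + config._max_peak_len
    # ---- genome sequence -------------------------------------------------
    genome: dict[str, np.ndarray] = {
        sid: rng.integers(0, 4, size=L) for sid, L in seq_lengths.items()
    }
    # cosmetic CpG enrichment inside islands
    for isl in cpg_islands:
        n = isl.length
        pattern = np.tile([1, 2], n // 2 + 1)[:n]  # C,G alternation
        genome[isl.seq_id][isl.start : isl.end] = pattern
    # plant TATA consensus in class-1 core windows (sense strand)
    matrices = default_tata_matrices()
    motif_idx = np.array([("ACGT".index(c)) for c in TATA_CONSENSUS])
    for gi, g in enumerate(genes):
        if not gene_rows[gi]["tata"]:
            continue
        if g.strand is Strand.PLUS:
            start = g.tss_pos + config.tata_offset
            genome[g.seq_id][start : start + len(motif_idx)] = motif_idx
        else:
            # sense-strand motif maps to the reverse complement genomically
            rc = reverse_complement(TATA_CONSENSUS)
            rc_idx = np.array([("ACGT".index(c)) for c in rc])
            end = g.tss_pos - config.tata_offset + 1
            genome[g.seq_id][end - len(rc_idx) : end] = rc_idx
    # scrub accidental TATA-like matches from every non-planted core window
    cutoff = config.tata_matrix_similarity_target
    for gi, g in enumerate(genes):
        if gene_rows[gi]["tata"]:
            continue
        if g.strand is Strand.PLUS:
            w0 = g.tss_pos - config.tata_window_up
            w1 = g.tss_pos + config.tata_window_down
        else:
            w0 = g.tss_pos - config.tata_window_down + 1
            w1 = g.tss_pos + config.tata_window_up + 1
        for _ in range(200):
            frag = "".join(_BASES[genome[g.seq_id][w0:w1]])
            sense = frag if g.strand is Strand.PLUS else reverse_complement(frag)
            if not scan_sequence(sense, matrices, cutoff):
                break
            genome[g.seq_id][w0:w1] = rng.integers(0, 4, size=w1 - w0)
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigError(f"could not scrub TATA matches from {g.gene_id}")

    # ---- expression matrix -----------------------------------------------
    n_rep = config.n_replicates
    baselines = rng.uniform(4.0, 10.0, size=config.n_genes)
    mean_minus = baselines.copy()
    mean_plus = baselines.copy()
    for gi in range(config.n_genes):
        if regulation[gi] == "up":
            d = math.log2(config.fc_up) / 2
        elif regulation[gi] == "down":
            d = -math.log2(config.fc_down) / 2
        else:
            d = 0.0
        mean_minus[gi] -= d
        mean_plus[gi] += d
    noise = rng.normal(0.0, 1.0, size=(config.n_genes, 2 * n_rep))
    values = np.empty((config.n_genes, 2 * n_rep))
    values[:, :n_rep] = mean_minus[:, None] + config.replicate_sd * noise[:, :n_rep]
    values[:, n_rep:] = mean_plus[:, None] + config.replicate_sd * noise[:, n_rep:]
    samples = [f"minus_{r + 1}" for r in range(n_rep)] + [
        f"plus_{r + 1}" for r in range(n_rep)
    ]
    expr = ExpressionMatrix(
        gene_ids=[g.gene_id for g in genes],
        sample_labels=samples,
        condition_of_sample={
            s: (Condition.MINUS if s.startswith("minus") else Condition.PLUS)
            for s in samples
        },
        values=values,
    )

    # ---- write everything ------------------------------------------------
    files: dict[str, Path] = {}

    def bed(name: str, ivs: list[GenomicInterval]) -> Path:
        p = outdir / name
        format_io.write_bed(sorted(ivs), p)
        return p

    files["genome"] = outdir / "genome.fa"
    format_io.write_fasta(
        {sid: "".join(_BASES[arr]) for sid, arr in genome.items()}, files["genome"]
    )
    files["genes"] = outdir / "genes.tsv"
    format_io.write_gene_models(genes, files["genes"])
    files["cpg"] = bed("cpg.bed", cpg_islands)
    files["h3ac_minus"] = bed("peaks_H3Ac_minus.bed", h3ac_minus)
    files["h3ac_plus"] = bed("peaks_H3Ac_plus.bed", h3ac_plus)
    files["s5p_minus"] = bed("peaks_S5P_minus.bed", s5p_minus)
    files["s5p_plus"] = bed("peaks_S5P_plus.bed", s5p_plus)
    files["sp1_minus"] = bed("peaks_Sp1_minus.bed", sp1_minus)
    files["sp1_plus"] = bed("peaks_Sp1_plus.bed", sp1_plus)
    files["expression"] = outdir / "expression.tsv"
    files["samples"] = outdir / "samples.tsv"
    format_io.write_expression(expr, files["expression"], files["samples"])

    genes_df = pd.DataFrame(gene_rows)
    peaks_df = pd.DataFrame(
        peak_rows,
        columns=[
            "seq_id", "start_minus", "end_minus", "start_plus", "end_plus",
            "mark", "klass", "direction", "gene_id",
        ],
    )
    files["truth_genes"] = outdir / "truth_genes.tsv"
    files["truth_peaks"] = outdir / "truth_peaks.tsv"
    genes_df.to_csv(files["truth_genes"], sep="\t", index=False)
    peaks_df.to_csv(files["truth_peaks"], sep="\t", index=False)
    seq_len_df = pd.DataFrame(
        sorted(seq_lengths.items()), columns=["seq_id", "length"]
    )
    files["seq_lengths"] = outdir / "seq_lengths.tsv"
    seq_len_df.to_csv(files["seq_lengths"], sep="\t", index=False)

    return GroundTruth(genes=genes_df, peaks=peaks_df, files=files, config=config)
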