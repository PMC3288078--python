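"""End-to-end pipeline orchestration.

Reads a YAML config that either names all input files or contains a
``simulate`` block, runs compare → annotate → scan → diffexpr →
integrate, and writes summary tables (peak-class summaries per mark,
cross-mark co-localization, the per-TSS feature table) plus a run log.
The same config and seed give byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotate, format_io
from .diffexpr import differential_expression, summarize_de, write_de_table
from .genomic_model import (
    Condition,
    GenomicInterval,
    Mark,
    PeakSet,
    TssRecord,
    make_promoter_window,
)
from .integrate import (
    TssFeatureProfile,
    build_profile,
    colocalization_summary,
    consistency_score,
    gene_rollup,
    intragenic_unique_analysis,
)
from .motif_scan import default_tata_matrices, read_matrix_file, scan_tata
from .peak_compare import ComparisonResult, compare_conditions, length_summary
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "upstream_bp": 2000,
    "downstream_bp": 1000,
    "tata_window_up": 150,
    "tata_window_down": 50,
    "tata_cutoff": 0.9,
    "fc_threshold": 2.0,
    "alpha": 0.05,
    "test": "student",
    "min_extension_bp": 200,
}

_MARK_KEYS = {
    Mark.H3AC: ("h3ac_minus", "h3ac_plus"),
    Mark.S5P: ("s5p_minus", "s5p_plus"),
    Mark.SP1: ("sp1_minus", "sp1_plus"),
}

REQUIRED_INPUTS = [
    "genes", "genome", "cpg", "expression", "samples",
    "h3ac_minus", "h3ac_plus", "s5p_minus", "s5p_plus",
    "sp1_minus", "sp1_plus",
]


class PipelineError(RuntimeError):
    pass


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.4g}"
    return str(x)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "simulate" not in cfg and "inputs" not in cfg:
        raise PipelineError("config needs a 'simulate' or an 'inputs' section")
    cfg.setdefault("params", {})
    for k, v in DEFAULT_PARAMS.items():
        cfg["params"].setdefault(k, v)
    return cfg


def _simulation_config(block: dict) -> SimulationConfig:
    valid = {f.name for f in dc_fields(SimulationConfig)}
    unknown = set(block) - valid
    if unknown:
        raise PipelineError(f"unknown simulate keys: {sorted(unknown)}")
    return SimulationConfig(**block)


def write_summary(result: ComparisonResult, cpg, promoters, genes, path: Path) -> None:
    """Peak-class summary: counts, mean lengths, promoter %, CpG splits."""
    summ = length_summary(result)
    classes = {
        "all_minus": result.all_peaks(Condition.MINUS),
        "all_plus": result.all_peaks(Condition.PLUS),
        "common_minus_members": result.common_minus_peaks,
        "common_plus_members": result.common_plus_peaks,
        "unique_minus": list(result.unique_minus.intervals),
        "unique_plus": list(result.unique_plus.intervals),
    }
    with path.open("w") as fh:
        fh.write(
            "class\tn_peaks\tmean_length\tpct_promoter\t"
            "n_high_cpg\tn_low_cpg\n"
        )
        for name, ivs in classes.items():
            mean_len = (sum(i.length for i in ivs) / len(ivs)) if ivs else None
            pct = annotate.promoter_fraction(ivs, promoters, genes)
            ps = PeakSet(result.mark, Condition.MINUS, ivs)
            high, low = annotate.cpg_split(ps, cpg)
            fh.write(
                f"{name}\t{len(ivs)}\t{_fmt(mean_len)}\t{_fmt(pct)}\t"
                f"{len(high)}\t{len(low)}\n"
            )
        fh.write(f"n_components\t{summ['n_components']}\t\t\t\t\n")
        fh.write(f"widening_ratio\t{_fmt(summ['widening_ratio'])}\t\t\t\t\n")


def run_pipeline(config_path: str | Path, outdir: str | Path) -> dict[str, Path]:
    """Run every stage; returns a name → path map of the report files."""
    cfg = load_config(config_path)
    params = cfg["params"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    log_lines: list[str] = [f"chromintegrate {__version__}", f"params: {params}"]

    if "simulate" in cfg:
        sim_cfg = _simulation_config(cfg["simulate"] or {})
        truth = simulate(sim_cfg, outdir / "sim")
        inputs = {k: str(truth.files[k]) for k in REQUIRED_INPUTS}
        inputs["seq_lengths"] = str(truth.files["seq_lengths"])
        log_lines.append(f"simulate: seed={sim_cfg.seed} n_genes={sim_cfg.n_genes}")
    else:
        inputs = cfg["inputs"]
        missing = [k for k in REQUIRED_INPUTS if k not in inputs]
        if missing:
            raise PipelineError(f"missing input keys: {missing}")

    try:
        genes = format_io.read_gene_models(inputs["genes"])
        genome = format_io.read_fasta(inputs["genome"])
        cpg = list(
            format_io.read_bed(inputs["cpg"], Mark.H3AC, Condition.MINUS).intervals
        )
        expr = format_io.read_expression(inputs["expression"], inputs["samples"])
        tracks: dict[Mark, dict[Condition, PeakSet]] = {}
        for mark, (km, kp) in _MARK_KEYS.items():
            tracks[mark] = {
                Condition.MINUS: format_io.read_bed(inputs[km], mark, Condition.MINUS),
                Condition.PLUS: format_io.read_bed(inputs[kp], mark, Condition.PLUS),
            }
    except FileNotFoundError as exc:
        raise PipelineError(f"missing input file: {exc.filename}") from exc

    seq_lengths = {sid: len(s) for sid, s in genome.items()}
    promoters = [
        make_promoter_window(
            g, params["upstream_bp"], params["downstream_bp"],
            seq_lengths.get(g.seq_id),
        )
        for g in genes
    ]

    # --- condition comparison per mark ------------------------------------
    comparisons: dict[Mark, ComparisonResult] = {}
    for mark in Mark:
        res = compare_conditions(
            tracks[mark][Condition.MINUS], tracks[mark][Condition.PLUS]
        )
        comparisons[mark] = res
        name = {Mark.H3AC: "h3ac", Mark.S5P: "s5p", Mark.SP1: "sp1"}[mark]
        p = outdir / f"summary_{name}.tsv"
        write_summary(res, cpg, promoters, genes, p)
        outputs[f"summary_{name}"] = p
        s = length_summary(res)
        log_lines.append(
            f"compare[{mark.value}]: components={s['n_components']} "
            f"unique-={s['n_unique_minus']} unique+={s['n_unique_plus']}"
        )

    # --- co-localization (S5P classes vs H3Ac) ----------------------------
    coloc = colocalization_summary(
        comparisons[Mark.S5P], comparisons[Mark.H3AC], promoters
    )
    p = outdir / "coloc.tsv"
    with p.open("w") as fh:
        fh.write("class\tn\tn_overlapping\tfrac_overlapping\t"
                 "frac_overlapping_in_promoter\n")
        for name, row in coloc.items():
            fh.write(
                f"{name}\t{row['n']}\t{row['n_overlapping']}\t"
                f"{_fmt(row['frac_overlapping'])}\t"
                f"{_fmt(row['frac_overlapping_in_promoter'])}\n"
            )
    outputs["coloc"] = p

    # --- TATA scan --------------------------------------------------------
    matrices = (
        [read_matrix_file(m) for m in params["tata_matrices"]]
        if params.get("tata_matrices")
        else default_tata_matrices()
    )
    tata_by_tss: dict[tuple[str, int], bool] = {}
    hit_rows = []
    for g in genes:
        found, hits = scan_tata(
            g, genome,
            params["tata_window_up"], params["tata_window_down"],
            params["tata_cutoff"], matrices,
        )
        tata_by_tss[(g.gene_id, g.tss_pos)] = found
        for h in hits:
            hit_rows.append(
                {
                    "gene_id": g.gene_id,
                    "tss_pos": g.tss_pos,
                    "matrix": h.matrix_name,
                    "offset": h.offset,
                    "similarity": round(h.similarity, 4),
                    "matched": h.matched,
                }
            )
    p = outdir / "tata_hits.tsv"
    pd.DataFrame(
        hit_rows,
        columns=["gene_id", "tss_pos", "matrix", "offset", "similarity", "matched"],
    ).to_csv(p, sep="\t", index=False)
    outputs["tata_hits"] = p
    log_lines.append(f"scan-tata: {sum(tata_by_tss.values())}/{len(tata_by_tss)} "
                     "TSS windows with a hit")

    # --- differential expression ------------------------------------------
    de_results = differential_expression(
        expr, params["fc_threshold"], params["alpha"], params["test"]
    )
    de_by_gene = {r.gene_id: r for r in de_results}
    p = outdir / "de.tsv"
    write_de_table(de_results, p)
    outputs["de"] = p
    n_up, n_down = summarize_de(de_results)
    log_lines.append(f"diffexpr: up={n_up} down={n_down}")

    # --- per-TSS integration ----------------------------------------------
    profiles: list[TssFeatureProfile] = []
    for g in genes:
        profiles.append(
            build_profile(
                g,
                comparisons[Mark.H3AC],
                s5p_minus=tracks[Mark.S5P][Condition.MINUS],
                s5p_plus=tracks[Mark.S5P][Condition.PLUS],
                sp1_minus=tracks[Mark.SP1][Condition.MINUS],
                sp1_plus=tracks[Mark.SP1][Condition.PLUS],
                cpg_islands=cpg,
                tata=tata_by_tss[(g.gene_id, g.tss_pos)],
                de=de_by_gene.get(g.gene_id),
                upstream_bp=params["upstream_bp"],
                downstream_bp=params["downstream_bp"],
                seq_length=seq_lengths.get(g.seq_id),
                min_extension_bp=params["min_extension_bp"],
            )
        )
    p = outdir / "feature_table.tsv"
    format_io.write_feature_table(profiles, p)
    outputs["feature_table"] = p

    rollup = gene_rollup(profiles)
    p = outdir / "gene_groups.tsv"
    with p.open("w") as fh:
        fh.write("gene_id\tgroup\tconsistency\n")
        for prof in profiles:
            if prof.group == "unassigned":
                continue
            fh.write(
                f"{prof.gene_id}\t{rollup[prof.gene_id]}\t"
                f"{_fmt(consistency_score(prof))}\n"
            )
    outputs["gene_groups"] = p

    n_qual, n_open = intragenic_unique_analysis(
        comparisons[Mark.H3AC], genes, promoters, cpg
    )
    log_lines.append(f"intragenic-unique: qualifying={n_qual} in_open_genes={n_open}")

    log_path = outdir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_path
    return outputs
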