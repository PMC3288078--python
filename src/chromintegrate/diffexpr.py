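"""Differential expression calls on a replicated log2 matrix.

A gene is called up when its signed linear fold change is >= the
threshold and its two-sided t-test p-value is < alpha; down for the
mirrored criterion.  Fold changes use the signed convention
``+2^d`` for d >= 0 and ``-2^(-d)`` otherwise (d = difference of log2
group means), so |FC| >= 1 always.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .format_io import ExpressionMatrix
from .genomic_model import Condition

logger = logging.getLogger(__name__)

__all__ = ["DEResult", "differential_expression", "summarize_de"]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_delta: float
    fold_change: float  # signed linear scale, |FC| >= 1
    p_value: float
    call: str  # up | down | null


def _signed_fc(delta: float) -> float:
    return float(2.0 ** delta) if delta >= 0 else float(-(2.0 ** (-delta)))


def differential_expression(
    m: ExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "student",
    bh_correct: bool = False,
) -> list[DEResult]:
    """Per-gene two-sided t-test plus signed fold-change thresholding.

    ``test`` is ``student`` (equal-variance, the default) or ``welch``.
    When both groups have zero variance the t statistic is undefined:
    p is reported as 0 when the means differ and 1 when they coincide
    (logged).  ``bh_correct`` applies Benjamini-Hochberg to the
    p-values before calling.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    idx_minus = m.samples_of(Condition.MINUS)
    idx_plus = m.samples_of(Condition.PLUS)
    x_minus = m.values[:, idx_minus]
    x_plus = m.values[:, idx_plus]
    deltas = x_plus.mean(axis=1) - x_minus.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(
            x_plus, x_minus, axis=1, equal_var=(test == "student")
        )
    degenerate = np.isnan(pvals)
    if degenerate.any():
        logger.info(
            "differential_expression: %d genes with zero variance in both groups",
            int(degenerate.sum()),
        )
        pvals = np.where(degenerate, np.where(deltas != 0, 0.0, 1.0), pvals)

    if bh_correct:
        pvals = _benjamini_hochberg(pvals)

    results = []
    for gid, d, p in zip(m.gene_ids, deltas, pvals):
        fc = _signed_fc(float(d))
        if p < alpha and fc >= fc_threshold:
            call = "up"
        elif p < alpha and fc <= -fc_threshold:
            call = "down"
        else:
            call = "null"
        results.append(DEResult(gid, float(d), fc, float(p), call))
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def summarize_de(results: list[DEResult]) -> tuple[int, int]:
    """(n_up, n_down)."""
    n_up = sum(1 for r in results if r.call == "up")
    n_down = sum(1 for r in results if r.call == "down")
    return n_up, n_down


def write_de_table(results: list[DEResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2_delta\tfold_change\tp_value\tcall\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.log2_delta:.6g}\t{r.fold_change:.6g}\t"
                f"{r.p_value:.6g}\t{r.call}\n"
            )
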