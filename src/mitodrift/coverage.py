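"""mtDNA copy-number estimation from sequencing coverage.

Relative copy number for a line is its mean per-site mitochondrial coverage
(AT-rich control region masked) divided by the unweighted mean of the mean
coverages of three single-copy nuclear genes. Because every nuclear locus is
present at two copies per diploid genome regardless of line, this ratio is a
relative per-cell mitogenome count, comparable across lines and sequencing
depths (it is invariant under rescaling all coverages).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import line_coverage_stats
from .genome import RegionMask
from .pileup import SitePileup

__all__ = [
    "CopyNumberSummary",
    "normalized_copy_number",
    "fold_change",
    "summarize_line",
    "copy_number_table",
]


@dataclass(frozen=True)
class CopyNumberSummary:
    """One line's coverage summary (one row of a copy-number report)."""

    line: str
    mt_mean_coverage: float
    mt_sd_coverage: float
    nuclear_gene_means: dict[str, float]
    single_copy_mean: float
    normalized_copy_number: float


def normalized_copy_number(mt_mean: float, gene_means: Sequence[float]) -> float:
    """mt mean coverage / unweighted mean of single-copy nuclear gene means."""
    gene_means = list(gene_means)
    if not gene_means:
        raise ValueError("no nuclear gene means supplied")
    single_copy = float(np.mean(gene_means))
    if single_copy <= 0:
        raise ZeroDivisionError("nuclear single-copy mean coverage must be > 0")
    return mt_mean / single_copy


def fold_change(
    ma_values: Sequence[float], progenitor_value: float
) -> tuple[float, tuple[float, float]]:
    """Mean MA copy number over the progenitor's, plus the per-line range."""
    if len(ma_values) == 0:
        raise ValueError("no MA values supplied")
    if progenitor_value <= 0:
        raise ZeroDivisionError("progenitor value must be > 0")
    per_line = np.asarray(ma_values, dtype=float) / progenitor_value
    return float(per_line.mean()), (float(per_line.min()), float(per_line.max()))


def summarize_line(
    line: str,
    pileups: Sequence[SitePileup],
    nuclear_gene_means: Mapping[str, float],
    mask: RegionMask | None = None,
) -> CopyNumberSummary:
    """Build a line's copy-number summary from its mitochondrial pileups and
    pre-computed nuclear per-gene mean coverages.

    The mask (AT-rich region) applies to the mitochondrial mean/SD only.
    """
    mt_mean, mt_sd = line_coverage_stats(pileups, mask)
    gene_means = dict(nuclear_gene_means)
    single_copy = float(np.mean(list(gene_means.values())))
    return CopyNumberSummary(
        line=line,
        mt_mean_coverage=mt_mean,
        mt_sd_coverage=mt_sd,
        nuclear_gene_means=gene_means,
        single_copy_mean=single_copy,
        normalized_copy_number=normalized_copy_number(mt_mean, list(gene_means.values())),
    )


def copy_number_table(summaries: Sequence[CopyNumberSummary]) -> pd.DataFrame:
    """Copy-number report, one row per line."""
    rows = []
    for s in summaries:
        row = {
            "line": s.line,
            "avg_mtdna_cov": s.mt_mean_coverage,
            "sd_mtdna_cov": s.mt_sd_coverage,
            "norm_mtdna": s.normalized_copy_number,
            "avg_single_copy": s.single_copy_mean,
        }
        for gene, mean in s.nuclear_gene_means.items():
            row[f"avg_{gene}_cov"] = mean
        rows.append(row)
    return pd.DataFrame(rows)
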