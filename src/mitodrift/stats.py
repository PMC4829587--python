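"""Nonparametric statistics for copy-number comparisons across lines.

Normalized per-region copy-number values (one value per mitochondrial gene
or rRNA region per line) typically violate normality and homoscedasticity,
so group comparisons use Levene's test for variance heterogeneity, the
tie-corrected Kruskal-Wallis H test for location, and Dunn's rank-sum z
tests (on the pooled ranking, with multiplicity adjustment) for post-hoc
pairwise contrasts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "levene_test",
    "kruskal_wallis",
    "pairwise_posthoc",
    "per_generation_rate",
]

Groups = Mapping[str, Sequence[float]] | Sequence[Sequence[float]]


def _as_groups(groups: Groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups)
        values = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        values = [np.asarray(g, dtype=float) for g in groups]
        labels = [str(i) for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for g in values:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    return labels, values


def levene_test(groups: Groups) -> tuple[float, float]:
    """Classic mean-centered Levene W with its F reference distribution."""
    _, values = _as_groups(groups)
    if all(np.ptp(g) == 0 for g in values):
        return 0.0, 1.0
    w, p = sps.levene(*values, center="mean")
    return float(w), float(p)


def kruskal_wallis(groups: Groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-squared (k-1 df) reference."""
    _, values = _as_groups(groups)
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*values)
    return float(h), float(p)


def pairwise_posthoc(groups: Groups, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's post-hoc z tests on the pooled ranking.

    For groups i and j with midrank means R_i, R_j over N pooled values,

        z_ij = (R_i - R_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),

    where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties. Two-sided
    normal p-values are adjusted jointly across all pairs (Benjamini-
    Hochberg by default; any statsmodels ``multipletests`` method name,
    e.g. "bonferroni", is accepted). Returns a long-format table with one
    row per pair: z, raw and adjusted p.
    """
    labels, values = _as_groups(groups)
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction from pooled midranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in values:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    rows = []
    for i in range(len(values)):
        for j in range(i + 1, len(values)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": labels[i], "group2": labels[j], "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p_raw"].to_numpy(), method=adjust)[1]
    return table


def per_generation_rate(fold: float, generations: int, model: str = "geometric") -> float:
    """Percent change in copy number per generation implied by a fold change.

    linear: 100 * (fold - 1) / generations (constant absolute increments);
    geometric: 100 * (fold^(1/generations) - 1) (constant multiplicative
    growth). The two diverge strongly for large folds over few generations.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if model == "linear":
        return 100.0 * (fold - 1.0) / generations
    if model == "geometric":
        return 100.0 * (fold ** (1.0 / generations) - 1.0)
    raise ValueError(f"unknown model {model!r}")
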