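"""Bundled worked example: printed summary tables from a published
C. elegans mutation-accumulation resequencing experiment.

Twelve L1-stage samples — a wild-type (N2) progenitor with five MA lines
bottlenecked for 250 generations, and a backcrossed ETC-mutant (gas-1)
progenitor with five MA lines bottlenecked for ~43 generations — were
resequenced; the published report prints per-line sequencing/coverage
summaries, heteroplasmic SNP and indel records with read counts, and a
site-by-line frequency matrix. Those printed values are transcribed here as
plain data so the package's arithmetic (variant frequencies, normalized
copy number, record counts, fold changes) can be exercised end-to-end
against published numbers without any raw-read download.

Values are as printed, including the report's internal inconsistencies
(e.g. the N2 progenitor's normalized copy number does not recompute from
its own printed coverages); nothing here is adjusted.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "sequencing_summary",
    "snp_records",
    "indel_records",
    "site_frequency_matrix",
    "NUCLEAR_GENES",
    "MA_GENERATIONS",
]

NUCLEAR_GENES = ("ama-1", "ego-1", "efl-3")

#: bottleneck generations per strain background (N2 lines ran far longer)
MA_GENERATIONS = {"N2": 250, "gas-1": 43}

# line, strain, role, total_reads, pct_mapping,
# nuc_mean, nuc_sd, mt_mean, mt_sd, norm_mtdna (printed), single_copy (printed),
# ama1_mean, ama1_sd, ego1_mean, ego1_sd, efl3_mean, efl3_sd
_SEQ_ROWS = [
    ("Progenitor-N2", "N2", "progenitor", 12474086, 87.7, 27.3, 54.7, 330.7, 128.0, 9.4, 37.0, 36.3, 13.7, 39.0, 11.4, 35.7, 14.2),
    ("MA523", "N2", "MA", 8162820, 92.7, 11.3, 15.1, 241.6, 62.8, 19.8, 12.2, 10.4, 3.3, 13.1, 3.5, 13.1, 3.1),
    ("MA526", "N2", "MA", 6698142, 89.5, 8.9, 13.1, 636.2, 85.7, 71.1, 9.0, 7.4, 2.7, 9.3, 3.4, 10.2, 4.4),
    ("MA529", "N2", "MA", 6799824, 93.0, 9.4, 12.2, 414.2, 52.8, 42.4, 9.8, 8.9, 3.2, 10.1, 3.2, 10.3, 3.0),
    ("MA553", "N2", "MA", 7846166, 92.0, 10.7, 15.9, 569.1, 74.1, 51.4, 11.1, 9.1, 3.6, 12.1, 4.6, 12.0, 4.5),
    ("MA574", "N2", "MA", 6271490, 93.2, 8.7, 12.4, 449.5, 67.9, 50.1, 9.0, 7.1, 3.3, 9.2, 4.3, 10.7, 4.1),
    ("Progenitor-gas-1", "gas-1", "progenitor", 10725726, 88.6, 23.7, 36.9, 221.3, 86.2, 7.2, 30.8, 26.2, 9.6, 35.0, 9.2, 31.2, 11.2),
    ("MA412", "gas-1", "MA", 7558954, 83.4, 15.6, 14.5, 324.5, 79.9, 18.0, 18.1, 13.8, 5.5, 20.3, 5.8, 20.1, 7.3),
    ("MA419", "gas-1", "MA", 6843258, 82.5, 14.0, 13.7, 308.9, 99.9, 28.3, 10.9, 10.6, 4.3, 14.9, 4.2, 7.3, 5.9),
    ("MA429", "gas-1", "MA", 7351108, 86.8, 15.9, 12.3, 498.8, 74.2, 29.1, 17.2, 11.7, 5.0, 20.0, 6.8, 19.8, 6.2),
    ("MA431", "gas-1", "MA", 6896562, 80.6, 13.7, 13.7, 286.6, 98.4, 19.4, 14.8, 10.9, 4.2, 17.4, 4.5, 15.9, 6.8),
    ("MA438", "gas-1", "MA", 6998936, 83.4, 14.4, 17.4, 259.6, 100.1, 17.1, 15.2, 11.1, 4.8, 17.3, 5.6, 17.1, 6.4),
]


def sequencing_summary() -> pd.DataFrame:
    """Per-line run statistics and copy-number normalization inputs.

    ``norm_mtdna`` and ``single_copy`` are the PRINTED values; recomputing
    them from the per-gene columns is the worked example exercised in tests.
    """
    cols = [
        "line", "strain", "role", "total_reads", "pct_mapping",
        "nuc_mean", "nuc_sd", "mt_mean", "mt_sd", "norm_mtdna", "single_copy",
        "ama-1_mean", "ama-1_sd", "ego-1_mean", "ego-1_sd", "efl-3_mean", "efl-3_sd",
    ]
    return pd.DataFrame(_SEQ_ROWS, columns=cols)


# line, strain, pos, gene, ref, ref_count, var, var_count, printed freq,
# ref_codon, ref_aa, var_codon, var_aa, effect
_SNP_ROWS = [
    ("Progenitor-N2", "N2", 8274, "COX-I", "G", 495, "A", 21, 0.041, "GGG", "Gly", "GAG", "Glu", "Non-Syn"),
    ("MA523", "N2", 8731, "COX-I", "C", 292, "A", 18, 0.058, "GCT", "Ala", "GAT", "Asp", "Non-Syn"),
    ("Progenitor-gas-1", "gas-1", 8439, "COX-I", "G", 344, "T", 18, 0.050, "GTG", "Val", "TTG", "Leu", "Non-Syn"),
    ("MA412", "gas-1", 8439, "COX-I", "G", 259, "T", 155, 0.374, "GTG", "Val", "TTG", "Leu", "Non-Syn"),
    ("MA431", "gas-1", 211, "NAD-6", "A", 238, "T", 9, 0.036, "CTA", "Leu", "CTT", "Leu", "Syn"),
    ("MA431", "gas-1", 450, "NAD-6", "A", 140, "T", 6, 0.041, "CTA", "Leu", "CTT", "Leu", "Syn"),
    ("MA431", "gas-1", 5422, "Cyt-b", "A", 261, "T", 7, 0.026, "ACC", "Thr", "ACT", "Thr", "Syn"),
    ("MA431", "gas-1", 7176, "NAD-4", "T", 312, "C", 36, 0.103, "TTA", "Leu", "TCA", "Ser", "Non-Syn"),
    ("MA431", "gas-1", 11965, "NAD-5", "T", 203, "A", 6, 0.029, "CTA", "Leu", "CAA", "Gln", "Non-Syn"),
    ("MA438", "gas-1", 211, "NAD-6", "A", 252, "T", 6, 0.023, "CTA", "Leu", "CTT", "Leu", "Syn"),
    ("MA438", "gas-1", 8439, "COX-I", "G", 0, "T", 447, 1.000, "GTG", "Val", "TTG", "Leu", "Non-Syn"),
]


def snp_records() -> pd.DataFrame:
    """Heteroplasmic single-nucleotide records with read counts and codons."""
    cols = [
        "line", "strain", "pos", "gene", "ref", "ref_count", "var", "var_count",
        "var_freq", "ref_codon", "ref_aa", "var_codon", "var_aa", "effect",
    ]
    return pd.DataFrame(_SNP_ROWS, columns=cols)


# line, strain, pos, gene, ref allele, ref_count, var allele, var_count,
# printed freq, homopolymer run length, type
_INDEL_ROWS = [
    ("MA523", "N2", 3235, "ATP6", "A", 211, "-", 11, 0.0495, 11, "Deletion"),
    ("MA523", "N2", 11721, "NAD-5", "-", 193, "T", 13, 0.063, 8, "Insertion"),
    ("MA526", "N2", 3235, "ATP6", "A", 113, "-", 441, 0.796, 11, "Deletion"),
    ("MA526", "N2", 8653, "COX-I", "-", 611, "A", 11, 0.018, 2, "Insertion"),
    ("MA529", "N2", 3235, "ATP6", "A", 372, "-", 15, 0.0388, 11, "Deletion"),
    ("MA553", "N2", 3235, "ATP6", "A", 493, "-", 21, 0.041, 11, "Deletion"),
    ("MA574", "N2", 3235, "ATP6", "A", 255, "-", 136, 0.348, 11, "Deletion"),
    ("MA574", "N2", 11721, "NAD-5", "-", 236, "T", 152, 0.392, 8, "Insertion"),
    ("Progenitor-gas-1", "gas-1", 9954, "tRNA-C", "T", 235, "-", 11, 0.0447, 2, "Deletion"),
    ("MA419", "gas-1", 3235, "ATP6", "A", 370, "-", 11, 0.029, 11, "Deletion"),
    ("MA429", "gas-1", 3235, "ATP6", "A", 502, "-", 25, 0.047, 11, "Deletion"),
    ("MA431", "gas-1", 3235, "ATP6", "A", 375, "-", 17, 0.043, 11, "Deletion"),
    ("MA438", "gas-1", 3235, "ATP6", "A", 321, "-", 11, 0.033, 11, "Deletion"),
]


def indel_records() -> pd.DataFrame:
    """Heteroplasmic indel records; frequencies as printed (some at 4 dp)."""
    cols = [
        "line", "strain", "pos", "gene", "ref", "ref_count", "var", "var_count",
        "var_freq", "homopoly_len", "type",
    ]
    return pd.DataFrame(_INDEL_ROWS, columns=cols)


_MATRIX_LINES = [
    "Progenitor-N2", "MA523", "MA526", "MA529", "MA553", "MA574",
    "Progenitor-gas-1", "MA412", "MA419", "MA429", "MA431", "MA438",
]

# site -> 12 frequencies in _MATRIX_LINES order; significant (bold) cells
_MATRIX_ROWS = {
    211: (0.008, 0.003, 0.004, 0.006, 0.002, 0.002, 0.000, 0.011, 0.020, 0.018, 0.036, 0.023),
    450: (0.000, 0.000, 0.000, 0.008, 0.000, 0.000, 0.007, 0.000, 0.006, 0.002, 0.041, 0.007),
    5422: (0.000, 0.000, 0.008, 0.004, 0.000, 0.002, 0.006, 0.008, 0.009, 0.004, 0.026, 0.013),
    8274: (0.041, 0.000, 0.001, 0.002, 0.000, 0.000, 0.000, 0.000, 0.008, 0.000, 0.002, 0.000),
    8439: (0.002, 0.000, 0.000, 0.000, 0.000, 0.000, 0.050, 0.374, 0.000, 0.000, 0.000, 1.000),
    8731: (0.001, 0.060, 0.002, 0.000, 0.000, 0.002, 0.000, 0.000, 0.000, 0.002, 0.000, 0.000),
    3235: (0.021, 0.050, 0.796, 0.038, 0.041, 0.348, 0.013, 0.021, 0.029, 0.047, 0.043, 0.033),
    8653: (0.001, 0.003, 0.018, 0.000, 0.000, 0.000, 0.003, 0.002, 0.000, 0.000, 0.002, 0.000),
    9954: (0.002, 0.000, 0.000, 0.000, 0.000, 0.000, 0.045, 0.000, 0.000, 0.000, 0.000, 0.002),
    11721: (0.000, 0.063, 0.090, 0.002, 0.000, 0.392, 0.000, 0.000, 0.003, 0.002, 0.004, 0.000),
}

_MATRIX_SIGNIFICANT = {
    211: ("MA431", "MA438"),
    450: ("MA431",),
    5422: ("MA431",),
    8274: ("Progenitor-N2",),
    8439: ("Progenitor-gas-1", "MA412", "MA438"),
    8731: ("MA523",),
    3235: ("MA523", "MA526", "MA529", "MA553", "MA574", "MA419", "MA431", "MA438"),
    8653: ("MA526",),
    9954: ("Progenitor-gas-1",),
    11721: ("MA523", "MA574"),
}


def site_frequency_matrix() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site-by-line variant-frequency matrix and its significance mask.

    Returns (frequencies, significant): both indexed by site position with
    one column per line; ``significant`` marks the cells the report accepted
    as heteroplasmies (printed in bold).
    """
    freq = pd.DataFrame.from_dict(_MATRIX_ROWS, orient="index", columns=_MATRIX_LINES)
    freq = freq.sort_index()
    sig = pd.DataFrame(False, index=freq.index, columns=freq.columns)
    for site, lines in _MATRIX_SIGNIFICANT.items():
        for line in lines:
            sig.loc[site, line] = True
    return freq, sig
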