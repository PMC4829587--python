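"""Report emission: VCF 4.2 and the tab-separated variant/copy-number/fate
tables mirroring the layouts conventionally printed for MA heteroplasmy
studies."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import EffectAnnotation
from .detect import HeteroplasmyCall
from .genome import ReferenceGenome
from .inheritance import FateMatrix

__all__ = ["write_vcf", "snp_table", "indel_table", "write_fate_tsv"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele frequency">
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNP/insertion/deletion)">
##INFO=<ID=RC,Number=1,Type=Integer,Description="Reference-supporting read count">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total site coverage">
##INFO=<ID=LINE,Number=1,Type=String,Description="MA line">
##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene or intergenic">
##INFO=<ID=REFC,Number=1,Type=String,Description="Reference codon">
##INFO=<ID=VARC,Number=1,Type=String,Description="Variant codon">
##INFO=<ID=EFF,Number=1,Type=String,Description="Syn/Non-Syn/non-coding/frameshift">
##INFO=<ID=HPL,Number=1,Type=Integer,Description="Homopolymer run length at anchor">
##FILTER=<ID=min_count,Description="Fewer than the minimum variant-supporting reads">
##FILTER=<ID=cov_window,Description="Site coverage outside the line coverage window">
##FILTER=<ID=vf_thresh,Description="Frequency not above the line background threshold">
##FILTER=<ID=baseline,Description="Allele fixed in a baseline (progenitor/lab) profile">
"""


def _vcf_alleles(call: HeteroplasmyCall, genome: ReferenceGenome) -> tuple[int, str, str]:
    """Left-anchored POS/REF/ALT per VCF convention for indels."""
    if call.variant_type == "SNP":
        return call.position, call.ref_allele, call.var_allele
    if call.position > 1:
        anchor_pos = call.position - 1
        anchor = genome.base(anchor_pos)
        if call.variant_type == "deletion":
            return anchor_pos, anchor + call.ref_allele, anchor
        return anchor_pos, anchor, anchor + call.var_allele
    anchor = genome.base(call.position)
    if call.variant_type == "deletion":
        # deletion at position 1 anchors on the following base
        nxt = genome.base(call.position + 1)
        return call.position, call.ref_allele + nxt, nxt
    return call.position, anchor, call.var_allele + anchor


def write_vcf(
    calls: Sequence[tuple[HeteroplasmyCall, EffectAnnotation | None]],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Write calls (optionally annotated) as a VCF 4.2 text file."""
    lines = [_VCF_HEADER + f"##contig=<ID={genome.id},length={genome.length}>"]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = sorted(calls, key=lambda ca: (ca[0].position, ca[0].line))
    for call, eff in ordered:
        pos, ref, alt = _vcf_alleles(call, genome)
        depth = (
            int(round(call.var_count / call.frequency))
            if call.frequency > 0
            else call.ref_count
        )
        info = [
            f"AF={call.frequency:.6g}",
            f"VC={call.variant_type}",
            f"RC={call.ref_count}",
            f"DP={depth}",
            f"LINE={call.line}",
        ]
        if eff is not None:
            info.append(f"GENE={eff.gene}")
            if eff.ref_codon:
                info.append(f"REFC={eff.ref_codon};VARC={eff.var_codon}")
            info.append(f"EFF={eff.effect}")
            if eff.homopolymer_length is not None:
                info.append(f"HPL={eff.homopolymer_length}")
        lines.append(
            f"{genome.id}\t{pos}\t.\t{ref}\t{alt}\t.\t{call.filter_label}\t"
            + ";".join(info)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def snp_table(
    calls: Sequence[tuple[HeteroplasmyCall, EffectAnnotation | None]],
) -> pd.DataFrame:
    """SNP report with codon/amino-acid columns (printed-table layout)."""
    rows = []
    for call, eff in calls:
        if call.variant_type != "SNP":
            continue
        rows.append(
            {
                "line": call.line,
                "pos": call.position,
                "gene": eff.gene if eff else "",
                "ref": call.ref_allele,
                "ref_count": call.ref_count,
                "var": call.var_allele,
                "var_count": call.var_count,
                "var_freq": round(call.frequency, 3),
                "ref_codon": eff.ref_codon if eff else None,
                "ref_aa": eff.ref_aa if eff else None,
                "var_codon": eff.var_codon if eff else None,
                "var_aa": eff.var_aa if eff else None,
                "effect": eff.effect if eff else None,
                "filter": call.filter_label,
            }
        )
    return pd.DataFrame(rows)


def indel_table(
    calls: Sequence[tuple[HeteroplasmyCall, EffectAnnotation | None]],
) -> pd.DataFrame:
    """Indel report with homopolymer context (printed-table layout)."""
    rows = []
    for call, eff in calls:
        if call.variant_type == "SNP":
            continue
        rows.append(
            {
                "line": call.line,
                "pos": call.position,
                "gene": eff.gene if eff else "",
                "ref": call.ref_allele,
                "ref_count": call.ref_count,
                "var": call.var_allele,
                "var_count": call.var_count,
                "var_freq": round(call.frequency, 3),
                "homopoly_len": eff.homopolymer_length if eff else None,
                "type": call.variant_type.capitalize(),
                "filter": call.filter_label,
            }
        )
    return pd.DataFrame(rows)


def write_fate_tsv(fate: FateMatrix, path: str | Path) -> None:
    """Fate matrix as TSV: sites as rows, lines as columns; PASS cells are
    marked with a trailing '*'."""
    out = fate.frequencies.copy().astype(object)
    for pos in out.index:
        for line in out.columns:
            val = f"{fate.frequencies.loc[pos, line]:.3f}"
            if fate.passed.loc[pos, line]:
                val += "*"
            out.loc[pos, line] = val
    out.index.name = "site"
    out.to_csv(path, sep="\t")
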