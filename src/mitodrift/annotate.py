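"""Functional annotation of heteroplasmy calls.

CDS single-base variants are translated under the invertebrate mitochondrial
genetic code (NCBI translation table 5 by default: AGA/AGG encode Ser, ATA
Met, TGA Trp) and classified synonymous / non-synonymous. Variants in tRNA,
rRNA or intergenic sequence are non-coding. Indels are annotated with the
length of the homopolymer run containing their anchor position, since
homopolymeric stretches are the dominant indel mutational hotspot in
nematode mtDNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Data import CodonTable

from .detect import HeteroplasmyCall
from .genome import (
    GeneAnnotation,
    ReferenceGenome,
    codon_at,
    homopolymer_length,
    reverse_complement,
)

__all__ = [
    "GeneticCode",
    "EffectAnnotation",
    "translate_codon",
    "annotate_call",
    "AA3",
]

# one-letter -> three-letter amino-acid names, as printed in variant reports
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

# annotation priority when features overlap at the anchor position
_KIND_PRIORITY = {"CDS": 0, "tRNA": 1, "rRNA": 2, "other": 3}


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon table keyed by NCBI translation table id."""

    table_id: int = 5

    @property
    def forward_table(self) -> dict[str, str]:
        ncbi = CodonTable.unambiguous_dna_by_id[self.table_id]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        return table

    @property
    def start_codons(self) -> frozenset[str]:
        return frozenset(CodonTable.unambiguous_dna_by_id[self.table_id].start_codons)


INVERTEBRATE_MT = GeneticCode(5)


def translate_codon(codon: str, code: GeneticCode = INVERTEBRATE_MT) -> str:
    """One-letter amino acid (or '*' for stop) for a codon; table lookup."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"untranslatable codon {codon!r}")
    return code.forward_table[codon]


@dataclass(frozen=True)
class EffectAnnotation:
    gene: str  # gene name or "intergenic"
    effect: str  # Syn | Non-Syn | non-coding
    ref_codon: str | None = None
    var_codon: str | None = None
    ref_aa: str | None = None  # three-letter
    var_aa: str | None = None
    homopolymer_length: int | None = None  # indels only


def _feature_at(position: int, annotations: Sequence[GeneAnnotation]) -> GeneAnnotation | None:
    hits = [a for a in annotations if a.contains(position)]
    if not hits:
        return None
    return min(hits, key=lambda a: _KIND_PRIORITY[a.kind])


def annotate_call(
    call: HeteroplasmyCall,
    genome: ReferenceGenome,
    annotations: Sequence[GeneAnnotation],
    code: GeneticCode = INVERTEBRATE_MT,
) -> EffectAnnotation:
    """Attach gene, codon change and effect (or homopolymer context) to a call.

    The variant is annotated by the feature containing its anchor position;
    ties between overlapping features break CDS > tRNA > rRNA > other.
    """
    feature = _feature_at(call.position, annotations)
    gene = feature.gene if feature is not None else "intergenic"
    if call.variant_type != "SNP":
        in_cds = feature is not None and feature.kind == "CDS"
        return EffectAnnotation(
            gene=gene,
            effect="frameshift" if in_cds else "non-coding",
            homopolymer_length=homopolymer_length(genome, call.position),
        )
    if feature is None or feature.kind != "CDS":
        return EffectAnnotation(gene=gene, effect="non-coding")
    ref_codon, _, offset = codon_at(genome, feature, call.position)
    var_base = call.var_allele
    if feature.strand == "-":
        var_base = reverse_complement(var_base)
    var_codon = ref_codon[:offset] + var_base + ref_codon[offset + 1 :]
    ref_aa = translate_codon(ref_codon, code)
    var_aa = translate_codon(var_codon, code)
    return EffectAnnotation(
        gene=gene,
        effect="Syn" if ref_aa == var_aa else "Non-Syn",
        ref_codon=ref_codon,
        var_codon=var_codon,
        ref_aa=AA3[ref_aa],
        var_aa=AA3[var_aa],
    )
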