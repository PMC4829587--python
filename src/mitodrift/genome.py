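"""Reference mitogenome model: sequence, gene annotations, region masks and
sequence-context utilities.

Coordinates are 1-based inclusive throughout the package, matching the
positions conventionally printed for animal mitochondrial genomes
(e.g. "position 8439"). BED input is converted from its native 0-based
half-open convention on read.

The mitogenome is circular; homopolymer runs may wrap the origin, but gene
features may not (in the standard rotation of the C. elegans mitogenome no
gene spans the origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "GeneAnnotation",
    "RegionMask",
    "GenomeFormatError",
    "load_reference",
    "load_annotations",
    "homopolymer_length",
    "codon_at",
]

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")


class GenomeFormatError(ValueError):
    """Raised for malformed FASTA/GFF3/BED input or out-of-bounds features."""


@dataclass(frozen=True)
class ReferenceGenome:
    """A single circular (or linear) reference sequence, uppercase ACGTN."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise GenomeFormatError("reference sequence is empty")
        bad = set(seq) - _DNA
        if bad:
            raise GenomeFormatError(f"non-DNA characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        self._check(position)
        return self.sequence[position - 1]

    def _check(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside genome of length {self.length}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """One feature on the mitogenome, 1-based inclusive coordinates.

    ``frame_offset`` shifts the reading frame start within the feature (0-2);
    it is almost always 0 for complete mitochondrial CDSs.
    """

    gene: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeFormatError(f"unknown strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise GenomeFormatError(f"unknown feature kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise GenomeFormatError(
                f"bad interval [{self.start}, {self.end}] for {self.gene}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise GenomeFormatError("frame_offset must be 0-2")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class RegionMask:
    """Excluded intervals (1-based inclusive), e.g. the AT-rich control region.

    Intervals are normalized (sorted, merged) on construction. A wrapping
    interval on a circular genome is supplied as two pieces.
    """

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivals = sorted((int(a), int(b)) for a, b in self.intervals)
        for a, b in ivals:
            if a > b or a < 1:
                raise GenomeFormatError(f"bad mask interval ({a}, {b})")
        merged: list[tuple[int, int]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.intervals = merged

    def __contains__(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.intervals)

    def unmasked_positions(self, length: int) -> list[int]:
        return [p for p in range(1, length + 1) if p not in self]


def load_reference(path: str | Path, circular: bool = True) -> ReferenceGenome:
    """Read a single-record FASTA into a :class:`ReferenceGenome`.

    The sequence is uppercased; more than one record is a contract violation
    (the package models one mitogenome at a time).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeFormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise GenomeFormatError(
            f"expected a single reference record, found {len(records)} in {path}"
        )
    rec = records[0]
    return ReferenceGenome(id=rec.id, sequence=str(rec.seq), circular=circular)


def _parse_gff3(lines: Iterable[str]) -> list[GeneAnnotation]:
    out = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise GenomeFormatError(f"malformed GFF3 line: {line!r}")
        ftype = cols[2]
        kind = ftype if ftype in FEATURE_KINDS else "other"
        attrs = cols[8] if len(cols) > 8 else ""
        name = ""
        for kv in attrs.split(";"):
            if "=" in kv:
                k, v = kv.split("=", 1)
                if k.strip() in ("Name", "gene", "ID"):
                    name = v.strip()
                    if k.strip() in ("Name", "gene"):
                        break
        frame = cols[7]
        out.append(
            GeneAnnotation(
                gene=name or ftype,
                start=int(cols[3]),
                end=int(cols[4]),
                strand=cols[6],
                kind=kind,
                frame_offset=int(frame) if frame in "012" else 0,
            )
        )
    return out


def _parse_bed(lines: Iterable[str]) -> list[GeneAnnotation]:
    out = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise GenomeFormatError(f"malformed BED line: {line!r}")
        start0, end0 = int(cols[1]), int(cols[2])
        name = cols[3] if len(cols) > 3 else "feature"
        strand = cols[5] if len(cols) > 5 else "+"
        kind = cols[6] if len(cols) > 6 and cols[6] in FEATURE_KINDS else "CDS"
        # BED is 0-based half-open; internal coordinates are 1-based inclusive.
        out.append(
            GeneAnnotation(gene=name, start=start0 + 1, end=end0, strand=strand, kind=kind)
        )
    return out


def load_annotations(path: str | Path, genome: ReferenceGenome) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or BED (chosen by file extension).

    Features must lie within the genome; wrap-around (origin-spanning) gene
    features are rejected.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if path.suffix.lower() in (".bed",):
        anns = _parse_bed(lines)
    else:
        anns = _parse_gff3(lines)
    for ann in anns:
        if ann.end > genome.length:
            raise GenomeFormatError(
                f"feature {ann.gene} [{ann.start}, {ann.end}] exceeds genome "
                f"length {genome.length}"
            )
    return anns


def homopolymer_length(genome: ReferenceGenome, position: int) -> int:
    """Length of the maximal run of identical bases containing ``position``.

    On a circular genome the run may wrap the origin. N breaks a run (and a
    run of N itself is reported as length 1 per N site — N is not a base).
    """
    genome._check(position)
    seq = genome.sequence
    n = genome.length
    base = seq[position - 1]
    if base == "N":
        return 1
    i = position - 1
    if genome.circular and n > 1:
        # Scan on the doubled string so runs can cross the origin, but never
        # past one full genome length (an all-identical genome is one run).
        left = 0
        while left < n - 1 and seq[(i - left - 1) % n] == base:
            left += 1
        right = 0
        while left + right < n - 1 and seq[(i + right + 1) % n] == base:
            right += 1
        return left + right + 1
    left = i
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = i
    while right < n - 1 and seq[right + 1] == base:
        right += 1
    return right - left + 1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codon_at(
    genome: ReferenceGenome, ann: GeneAnnotation, position: int
) -> tuple[str, int, int]:
    """Return (codon, codon_index, offset_in_codon) for a CDS position.

    The codon is read 5'->3' on the coding strand; for minus-strand genes the
    gene sequence is reverse-complemented before the frame walk. codon_index
    counts codons from the gene's frame start (0-based).
    """
    if ann.kind != "CDS":
        raise ValueError(f"{ann.gene} is {ann.kind}, not coding")
    if not ann.contains(position):
        raise ValueError(
            f"position {position} outside {ann.gene} [{ann.start}, {ann.end}]"
        )
    gene_seq = genome.sequence[ann.start - 1 : ann.end]
    if ann.strand == "+":
        idx = position - ann.start
        coding = gene_seq
    else:
        coding = reverse_complement(gene_seq)
        idx = ann.end - position
    idx_in_frame = idx - ann.frame_offset
    if idx_in_frame < 0:
        raise ValueError(f"position {position} precedes the reading frame")
    codon_index = idx_in_frame // 3
    offset = idx_in_frame % 3
    codon = coding[ann.frame_offset + 3 * codon_index : ann.frame_offset + 3 * codon_index + 3]
    if len(codon) < 3:
        raise ValueError(f"incomplete terminal codon at position {position}")
    return codon, codon_index, offset
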