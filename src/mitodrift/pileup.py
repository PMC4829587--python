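"""Per-site allele-count containers and the canonical pileup TSV dialect.

A :class:`SitePileup` is the atom of all detection arithmetic: counts of
reads supporting each base, each deletion allele and each insertion allele
at one reference position. Site coverage is the sum of every allele count
(each read counted once; an insertion-bearing read counts under its
insertion allele, not additionally under a base).

Canonical TSV: header ``pos ref A C G T del:<seq>... ins:<seq>...``, one row
per site, tab-separated, positions ascending. This plain-text table is the
bit-exact interchange format between the simulator and the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = ["SitePileup", "site_coverage", "write_pileup_tsv", "read_pileup_tsv"]

BASES = ("A", "C", "G", "T")


@dataclass
class SitePileup:
    position: int
    ref_base: str
    base_counts: dict[str, int] = field(default_factory=dict)
    deletion_counts: dict[str, int] = field(default_factory=dict)
    insertion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        self.base_counts = {b: int(self.base_counts.get(b, 0)) for b in BASES}
        for table in (self.base_counts, self.deletion_counts, self.insertion_counts):
            for allele, count in table.items():
                if count < 0:
                    raise ValueError(f"negative count for allele {allele!r}")

    @property
    def ref_count(self) -> int:
        return self.base_counts[self.ref_base]

    def coverage(self) -> int:
        return (
            sum(self.base_counts.values())
            + sum(self.deletion_counts.values())
            + sum(self.insertion_counts.values())
        )

    def alt_alleles(self) -> list[tuple[str, str, int]]:
        """All observed non-reference alleles as (type, allele, count).

        type is "SNP", "deletion" or "insertion"; deletion alleles are the
        deleted sequence, insertion alleles the inserted sequence.
        """
        out = []
        for b in BASES:
            if b != self.ref_base and self.base_counts[b] > 0:
                out.append(("SNP", b, self.base_counts[b]))
        for seq, c in sorted(self.deletion_counts.items()):
            if c > 0:
                out.append(("deletion", seq, c))
        for seq, c in sorted(self.insertion_counts.items()):
            if c > 0:
                out.append(("insertion", seq, c))
        return out


def site_coverage(pileup: SitePileup) -> int:
    """Total reads at the site: bases + deletion + insertion-bearing reads."""
    return pileup.coverage()


def write_pileup_tsv(pileups: Iterable[SitePileup], path: str | Path) -> None:
    pileups = sorted(pileups, key=lambda p: p.position)
    del_alleles = sorted({a for p in pileups for a in p.deletion_counts})
    ins_alleles = sorted({a for p in pileups for a in p.insertion_counts})
    header = (
        ["pos", "ref", *BASES]
        + [f"del:{a}" for a in del_alleles]
        + [f"ins:{a}" for a in ins_alleles]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for p in pileups:
            row = [str(p.position), p.ref_base]
            row += [str(p.base_counts[b]) for b in BASES]
            row += [str(p.deletion_counts.get(a, 0)) for a in del_alleles]
            row += [str(p.insertion_counts.get(a, 0)) for a in ins_alleles]
            fh.write("\t".join(row) + "\n")


def read_pileup_tsv(path: str | Path) -> list[SitePileup]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["pos", "ref", *BASES]:
            raise ValueError(f"unexpected pileup header in {path}: {header[:6]}")
        del_cols = [(i, h[4:]) for i, h in enumerate(header) if h.startswith("del:")]
        ins_cols = [(i, h[4:]) for i, h in enumerate(header) if h.startswith("ins:")]
        out = []
        last_pos = 0
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            pos = int(cols[0])
            if pos <= last_pos:
                raise ValueError(f"positions not ascending at {pos} in {path}")
            last_pos = pos
            out.append(
                SitePileup(
                    position=pos,
                    ref_base=cols[1],
                    base_counts={b: int(cols[2 + i]) for i, b in enumerate(BASES)},
                    deletion_counts={a: int(cols[i]) for i, a in del_cols if int(cols[i])},
                    insertion_counts={a: int(cols[i]) for i, a in ins_cols if int(cols[i])},
                )
            )
    return out
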