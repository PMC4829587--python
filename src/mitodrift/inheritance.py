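"""Trans-generational fate of heteroplasmies and the Phred-based Sanger
trace screen.

A heteroplasmy present in a progenitor can, after generations of
single-individual bottlenecks, be lost, still segregating, or fixed in each
descendant line; a variant absent from the progenitor but passing the filter
in a line is gained. The fate matrix tabulates every variant site against
every line with the observed frequency (sub-threshold frequencies included,
so near-zero background values remain visible) and a per-cell PASS flag.

The Sanger screen classifies a trace at a known variant position by
comparing the site's Phred score with the mean score of the flanking 50 bp
on each side: a mixed (heteroplasmic) template produces overlapping peaks
and a locally depressed Phred score, while a clean base call at flank-level
quality is scored absent or fixed by its identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .detect import HeteroplasmyCall

__all__ = [
    "SangerTrace",
    "FateMatrix",
    "classify_fate",
    "build_fate_matrix",
    "classify_sanger_site",
]

FATES = ("lost", "segregating", "fixed", "gained", "absent")


@dataclass(frozen=True)
class SangerTrace:
    """Base calls plus per-base Phred scores for one sequencing trace."""

    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")
        if any(not 0 <= q <= 93 for q in self.qualities):
            raise ValueError("Phred scores must be in [0, 93]")

    @classmethod
    def from_record(cls, record: SeqRecord) -> "SangerTrace":
        return cls(
            bases=str(record.seq),
            qualities=tuple(record.letter_annotations["phred_quality"]),
        )


def classify_fate(
    progenitor_freq: float,
    line_freq: float,
    line_pass: bool = True,
    detection_floor: float = 0.01,
    fixed_floor: float = 0.99,
) -> str:
    """Fate of a variant in one line relative to its progenitor.

    Progenitor-present variants: below the detection floor (or failing the
    line's filters) -> lost; at or above the fixed floor -> fixed; otherwise
    segregating. Progenitor-absent variants: gained when detected and
    passing, else absent.
    """
    for f in (progenitor_freq, line_freq):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    in_progenitor = progenitor_freq >= detection_floor
    detected = line_pass and line_freq >= detection_floor
    if in_progenitor:
        if not detected:
            return "lost"
        if line_freq >= fixed_floor:
            return "fixed"
        return "segregating"
    return "gained" if detected else "absent"


@dataclass
class FateMatrix:
    """Site x line frequency grid with per-cell PASS flags and fates."""

    frequencies: pd.DataFrame  # index = positions, columns = lines
    passed: pd.DataFrame  # same shape, boolean
    fates: pd.DataFrame  # same shape, strings from FATES (MA lines only)
    progenitor: str

    def record_count(self, lines: Sequence[str] | None = None) -> int:
        """Per-record heteroplasmy count: one per PASS cell, parallel events
        in several lines counted once per line."""
        cols = list(lines) if lines is not None else list(self.passed.columns)
        return int(self.passed[cols].to_numpy().sum())

    def unique_event_count(self, lines: Sequence[str]) -> int:
        """Unique-event convention: a variant present (PASS) in the
        progenitor counts once however many lines inherit it; a
        progenitor-absent variant counts once per line showing it."""
        total = 0
        for pos in self.passed.index:
            in_prog = bool(self.passed.loc[pos, self.progenitor])
            n_lines = int(self.passed.loc[pos, list(lines)].sum())
            total += 1 if in_prog else n_lines
        return total


def build_fate_matrix(
    calls_by_line: Mapping[str, Iterable[HeteroplasmyCall]],
    progenitor: str,
    detection_floor: float = 0.01,
    fixed_floor: float = 0.99,
) -> FateMatrix:
    """Assemble the union of variant sites across lines into a fate matrix.

    Frequencies are filled from the calls of every line at every site in the
    union (0 where a line shows no reads for the variant), whether or not
    the call passed — printed matrices keep sub-threshold values visible.
    """
    calls_by_line = {line: list(calls) for line, calls in calls_by_line.items()}
    if progenitor not in calls_by_line:
        raise ValueError(f"progenitor {progenitor!r} missing from calls")
    # union over sites that PASS somewhere, keyed by (position, alleles)
    ref_at: dict[int, str] = {}
    for line, calls in calls_by_line.items():
        for c in calls:
            prev = ref_at.setdefault(c.position, c.ref_allele)
            if prev != c.ref_allele:
                raise ValueError(
                    f"conflicting reference alleles at {c.position}: {prev} vs {c.ref_allele}"
                )
    sites = sorted(
        {c.position for calls in calls_by_line.values() for c in calls if c.passed}
    )
    lines = list(calls_by_line)
    freq = pd.DataFrame(0.0, index=sites, columns=lines)
    passed = pd.DataFrame(False, index=sites, columns=lines)
    for line, calls in calls_by_line.items():
        best: dict[int, HeteroplasmyCall] = {}
        for c in calls:
            if c.position in sites:
                cur = best.get(c.position)
                if cur is None or (c.passed, c.frequency) > (cur.passed, cur.frequency):
                    best[c.position] = c
        for pos, c in best.items():
            freq.loc[pos, line] = c.frequency
            passed.loc[pos, line] = c.passed
    ma_lines = [ln for ln in lines if ln != progenitor]
    fates = pd.DataFrame("", index=sites, columns=ma_lines)
    for pos in sites:
        prog_f = float(freq.loc[pos, progenitor])
        for line in ma_lines:
            fates.loc[pos, line] = classify_fate(
                prog_f,
                float(freq.loc[pos, line]),
                bool(passed.loc[pos, line]),
                detection_floor,
                fixed_floor,
            )
    return FateMatrix(frequencies=freq, passed=passed, fates=fates, progenitor=progenitor)


def classify_sanger_site(
    trace: SangerTrace | SeqRecord,
    site_index: int,
    ref_base: str,
    var_base: str,
    flank: int = 50,
    delta: float = 15.0,
) -> str:
    """Classify a trace at a focal site as absent / segregating / fixed.

    The site's Phred score is compared with the mean score of up to ``flank``
    bases on each side (truncated at the trace ends, focal site excluded).
    A score more than ``delta`` below the flank mean marks a mixed template
    (segregating); otherwise the base identity decides.
    """
    if isinstance(trace, SeqRecord):
        trace = SangerTrace.from_record(trace)
    n = len(trace.bases)
    if not 0 <= site_index < n:
        raise IndexError(f"site_index {site_index} outside trace of length {n}")
    lo = max(0, site_index - flank)
    hi = min(n, site_index + flank + 1)
    flank_scores = [
        trace.qualities[i] for i in range(lo, hi) if i != site_index
    ]
    if not flank_scores:
        raise ValueError("no flanking bases available")
    flank_mean = float(np.mean(flank_scores))
    site_q = trace.qualities[site_index]
    if site_q < flank_mean - delta:
        return "segregating"
    call = trace.bases[site_index]
    if call == var_base:
        return "fixed"
    if call == ref_base:
        return "absent"
    raise ValueError(
        f"ambiguous high-quality call {call!r} (neither {ref_base} nor {var_base})"
    )
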