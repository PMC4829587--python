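"""Heteroplasmy detection: per-site variant frequencies and the three-rule
count/coverage/frequency filter with progenitor and lab-strain baseline
exclusion.

A candidate allele at a site is accepted as a heteroplasmy when

  (a) it is supported by at least ``min_var_count`` reads (default 6),
  (b) the site's coverage lies within ``cov_sd_window`` sample standard
      deviations of the line's per-site mean coverage (default 1, two-sided,
      inclusive),
  (c) its frequency strictly exceeds the line's mean per-site non-reference
      frequency plus ``vf_sd_multiple`` standard deviations (default 2), and
  (d) the allele is not already fixed (frequency >= ``baseline_fixed_cutoff``,
      default 0.95) in any baseline profile (the lab strain / progenitor),
      which removes strain-level differences from the reference rather than
      true de novo heteroplasmies.

Rules (b) and (c) are calibrated per line: the coverage rule excludes sites
in artifact-prone regions whose coverage is atypical for the line, and the
frequency rule turns the line's own background mismatch rate (sequencing
error) into the detection floor. Non-passing candidates are retained with
per-rule failure flags so that sub-threshold frequencies can still be
reported in fate matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import RegionMask
from .pileup import SitePileup, site_coverage

__all__ = [
    "LineProfile",
    "FilterThresholds",
    "HeteroplasmyCall",
    "site_variant_frequency",
    "per_site_nonref_frequency",
    "line_variant_stats",
    "line_coverage_stats",
    "call_heteroplasmies",
    "classify_variant",
    "baseline_frequency",
]

FILTER_NAMES = ("min_count", "cov_window", "vf_thresh", "baseline")


@dataclass(frozen=True)
class FilterThresholds:
    min_var_count: int = 6
    cov_sd_window: float = 1.0
    vf_sd_multiple: float = 2.0
    baseline_fixed_cutoff: float = 0.95

    def __post_init__(self) -> None:
        if (
            self.min_var_count < 0
            or self.cov_sd_window < 0
            or self.vf_sd_multiple < 0
            or self.baseline_fixed_cutoff < 0
        ):
            raise ValueError("thresholds must be non-negative")


@dataclass
class HeteroplasmyCall:
    line: str
    position: int
    variant_type: str  # SNP | insertion | deletion
    ref_allele: str
    var_allele: str
    ref_count: int
    var_count: int
    frequency: float
    filter_flags: dict[str, bool] = field(default_factory=dict)
    baseline_excluded: bool = False

    @property
    def passed(self) -> bool:
        return all(self.filter_flags.get(name, False) for name in FILTER_NAMES)

    @property
    def filter_label(self) -> str:
        """VCF-style FILTER value: PASS or the first failing rule."""
        for name in FILTER_NAMES:
            if not self.filter_flags.get(name, True):
                return name
        return "PASS"


def site_variant_frequency(pileup: SitePileup, var_allele: str, variant_type: str = "SNP") -> float:
    """Variant reads divided by total site coverage (all alleles)."""
    cov = site_coverage(pileup)
    if cov == 0:
        raise ZeroDivisionError(f"zero coverage at position {pileup.position}")
    if variant_type == "SNP":
        if var_allele == pileup.ref_base:
            raise ValueError("var_allele equals the reference base")
        count = pileup.base_counts.get(var_allele, 0)
    elif variant_type == "deletion":
        count = pileup.deletion_counts.get(var_allele, 0)
    elif variant_type == "insertion":
        count = pileup.insertion_counts.get(var_allele, 0)
    else:
        raise ValueError(f"unknown variant_type {variant_type!r}")
    return count / cov


def per_site_nonref_frequency(pileup: SitePileup) -> float:
    """1 - ref reads / coverage: the site's total non-reference frequency."""
    cov = site_coverage(pileup)
    if cov == 0:
        raise ZeroDivisionError(f"zero coverage at position {pileup.position}")
    return 1.0 - pileup.ref_count / cov


def _unmasked(pileups: Sequence[SitePileup], mask: RegionMask | None) -> list[SitePileup]:
    if mask is None:
        return list(pileups)
    return [p for p in pileups if p.position not in mask]


def line_coverage_stats(
    pileups: Sequence[SitePileup], mask: RegionMask | None = None
) -> tuple[float, float]:
    """Mean and sample SD (n-1) of site coverage over unmasked sites."""
    covs = np.array([site_coverage(p) for p in _unmasked(pileups, mask)], dtype=float)
    if covs.size < 2:
        raise ValueError("need at least two unmasked sites for coverage stats")
    return float(covs.mean()), float(covs.std(ddof=1))


def line_variant_stats(
    pileups: Sequence[SitePileup], mask: RegionMask | None = None
) -> tuple[float, float]:
    """Mean and sample SD of per-site non-reference frequency.

    Computed over ALL unmasked covered sites (zero-variant sites included),
    so with no true variants the mean estimates the per-base error rate.
    """
    freqs = np.array(
        [
            per_site_nonref_frequency(p)
            for p in _unmasked(pileups, mask)
            if site_coverage(p) > 0
        ],
        dtype=float,
    )
    if freqs.size < 2:
        raise ValueError("need at least two unmasked covered sites for variant stats")
    return float(freqs.mean()), float(freqs.std(ddof=1))


@dataclass
class LineProfile:
    """One line's pileups plus the per-line filter baselines."""

    line: str
    pileups: list[SitePileup]
    role: str = "MA"  # progenitor | MA
    generations: int = 0
    mask: RegionMask | None = None
    cov_mean: float = field(default=math.nan)
    cov_sd: float = field(default=math.nan)
    vf_mean: float = field(default=math.nan)
    vf_sd: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.role not in ("progenitor", "MA"):
            raise ValueError("role must be 'progenitor' or 'MA'")
        if math.isnan(self.cov_mean):
            self.cov_mean, self.cov_sd = line_coverage_stats(self.pileups, self.mask)
        if math.isnan(self.vf_mean):
            self.vf_mean, self.vf_sd = line_variant_stats(self.pileups, self.mask)
        self._by_pos = {p.position: p for p in self.pileups}

    def pileup_at(self, position: int) -> SitePileup | None:
        return self._by_pos.get(position)


def classify_variant(ref_allele: str, var_allele: str) -> str:
    """SNP for equal-length single bases; longer var = insertion; shorter =
    deletion. '-' denotes the empty allele."""
    ref = "" if ref_allele == "-" else ref_allele
    var = "" if var_allele == "-" else var_allele
    if ref == var:
        raise ValueError("alleles are identical")
    if len(ref) == 1 and len(var) == 1:
        return "SNP"
    if len(var) > len(ref):
        return "insertion"
    if len(var) < len(ref):
        return "deletion"
    raise ValueError(f"unsupported multi-base substitution {ref_allele}>{var_allele}")


def baseline_frequency(
    profile: LineProfile, position: int, variant_type: str, var_allele: str
) -> float:
    """Frequency of an allele in a baseline profile (0 if site absent/empty)."""
    pile = profile.pileup_at(position)
    if pile is None or site_coverage(pile) == 0:
        return 0.0
    return site_variant_frequency(pile, var_allele, variant_type)


def call_heteroplasmies(
    profile: LineProfile,
    thresholds: FilterThresholds = FilterThresholds(),
    baseline_profiles: Iterable[LineProfile] = (),
) -> list[HeteroplasmyCall]:
    """Evaluate every observed alternate allele in a line against the filter.

    Each alternate allele at each unmasked site yields one call carrying
    per-rule pass/fail flags; callers can keep PASS calls only or report the
    full set (fate matrices print sub-threshold frequencies too).
    """
    baseline_profiles = list(baseline_profiles)
    calls: list[HeteroplasmyCall] = []
    for pile in _unmasked(profile.pileups, profile.mask):
        cov = site_coverage(pile)
        if cov == 0:
            continue
        cov_ok = abs(cov - profile.cov_mean) <= thresholds.cov_sd_window * profile.cov_sd
        vf_floor = profile.vf_mean + thresholds.vf_sd_multiple * profile.vf_sd
        for variant_type, allele, count in pile.alt_alleles():
            freq = count / cov
            fixed_in_baseline = any(
                baseline_frequency(bp, pile.position, variant_type, allele)
                >= thresholds.baseline_fixed_cutoff
                for bp in baseline_profiles
            )
            flags = {
                "min_count": count >= thresholds.min_var_count,
                "cov_window": cov_ok,
                "vf_thresh": freq > vf_floor,
                "baseline": not fixed_in_baseline,
            }
            if variant_type == "SNP":
                ref_allele, var_allele = pile.ref_base, allele
            elif variant_type == "deletion":
                ref_allele, var_allele = allele, "-"
            else:
                ref_allele, var_allele = "-", allele
            calls.append(
                HeteroplasmyCall(
                    line=profile.line,
                    position=pile.position,
                    variant_type=variant_type,
                    ref_allele=ref_allele,
                    var_allele=var_allele,
                    ref_count=pile.ref_count,
                    var_count=count,
                    frequency=freq,
                    filter_flags=flags,
                    baseline_excluded=fixed_in_baseline,
                )
            )
    return calls
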