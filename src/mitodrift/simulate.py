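"""Synthetic data generation: reference mitogenomes, bottlenecked
heteroplasmy transmission, per-line pileups and Sanger-style traces.

Every generator is a pure function of (config, seed): identical seeds give
byte-identical outputs. The generator emulates a mutation-accumulation (MA)
design — lines propagated through single-individual bottlenecks each
generation — with heteroplasmies planted at chosen founder frequencies and
transmitted by neutral Wright-Fisher resampling of a small number of mtDNA
segregating units.

Coverage model
--------------
Per-site coverage is negative-binomial (variance = mean + dispersion *
mean^2; dispersion 0 recovers Poisson) around the line mean. A small
configurable fraction of "artifact" sites additionally receives a
log-uniform dip (0.05-0.5x) or spike (2-5x) multiplier, emulating the
localized coverage anomalies (repeat collapse and pile-up, homopolymer
margins, control-region edges) that dominate the site-to-site coverage SD
in real short-read mitogenome data. With the defaults the total coverage
CV is ~0.3 — inside the 0.13-0.39 range of per-line mitochondrial coverage
CVs observed in MA resequencing — while ordinary sites stay near-Poisson,
which is what lets a one-SD coverage window exclude artifact-prone sites
without discarding typical ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneAnnotation, ReferenceGenome, RegionMask
from .pileup import BASES, SitePileup

__all__ = [
    "PlantedVariant",
    "SimulationConfig",
    "simulate_reference",
    "simulate_transmission",
    "simulate_transmission_many",
    "simulate_pileups",
    "simulate_sanger_trace",
]

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PlantedVariant:
    """A heteroplasmy to plant: '-' in ref marks an insertion, '-' in alt a
    deletion (the deleted base is the reference base at the position)."""

    position: int
    ref: str
    alt: str
    founder_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.founder_frequency <= 1.0:
            raise ValueError("founder_frequency must be in [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.ref != "-" and self.alt != "-":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SNP alleles must be single bases")
            if self.ref not in "ACGT" or self.alt not in "ACGT":
                raise ValueError("SNP alleles must be A/C/G/T")

    @property
    def variant_type(self) -> str:
        if self.ref == "-":
            return "insertion"
        if self.alt == "-":
            return "deletion"
        return "SNP"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for a synthetic MA cohort.

    Defaults emulate a five-line nematode MA experiment: a ~13.8 kb circular
    mitogenome, ~43 single-worm generations per line, a germline bottleneck
    of 10 mtDNA segregating units per transmission (the true nematode value
    is unknown; 10 makes a 5% founder heteroplasmy reach absorption within
    the experiment, as observed), mean mitochondrial coverage ~380 reads
    with overdispersion, and a per-base miscall rate of 1e-3.
    """

    genome_length: int = 13794
    homopolymer_spec: tuple[tuple[int, str, int], ...] = ()
    gene_layout: tuple[GeneAnnotation, ...] = ()
    at_rich: tuple[int, int] | None = None
    n_lines: int = 5
    generations: int = 43
    bottleneck_N: int = 10
    planted_variants: tuple[PlantedVariant, ...] = ()
    coverage_mean: float = 380.0
    coverage_dispersion: float = 0.003
    artifact_fraction: float = 0.03
    artifact_dip_range: tuple[float, float] = (0.05, 0.5)
    artifact_spike_range: tuple[float, float] = (2.0, 5.0)
    error_rate: float = 1e-3
    homopolymer_indel_error: float = 3e-3
    homopolymer_min_run: int = 5
    nuclear_mean_coverage: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.bottleneck_N < 1:
            raise ValueError("bottleneck_N must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        for p in (self.error_rate, self.homopolymer_indel_error, self.artifact_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.coverage_dispersion < 0:
            raise ValueError("coverage_dispersion must be >= 0")


def _rng(seed, *salt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, salt)])


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, list[GeneAnnotation], RegionMask]:
    """Random genome with the requested homopolymer runs embedded verbatim.

    Flanks of each embedded run are forced to a different base so the run
    length equals the requested length exactly.
    """
    n = config.genome_length
    runs = sorted(config.homopolymer_spec)
    occupied: list[tuple[int, int]] = []
    for pos, base, length in runs:
        if length > n:
            raise ValueError(f"run of length {length} exceeds genome length {n}")
        if not 1 <= pos and pos + length - 1 <= n:
            raise ValueError(f"run at {pos} (length {length}) outside genome")
        iv = (pos - 1, pos + length)  # 0-based, including one flank each side
        for a, b in occupied:
            if iv[0] <= b and a <= iv[1]:
                raise ValueError("overlapping homopolymer specs")
        occupied.append(iv)
    rng = _rng(config.seed, 1)
    seq = rng.choice(list("ACGT"), size=n)
    for pos, base, length in runs:
        seq[pos - 1 : pos + length - 1] = base
        other = "C" if base != "C" else "G"
        if pos >= 2:
            seq[pos - 2] = other
        if pos + length - 1 < n:
            seq[pos + length - 1] = other
    # the reference must carry each planted variant's stated ref allele
    for pv in config.planted_variants:
        if pv.ref != "-":
            seq[pv.position - 1] = pv.ref
    genome = ReferenceGenome(id="mt_sim", sequence="".join(seq), circular=True)
    mask = RegionMask([config.at_rich]) if config.at_rich else RegionMask([])
    return genome, list(config.gene_layout), mask


def simulate_transmission(
    founder_frequency: float,
    bottleneck_N: int,
    generations: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One Wright-Fisher heteroplasmy trajectory.

    f(t+1) = Binomial(N, f(t)) / N, with absorbing boundaries at 0 and 1.
    Returns the length-(generations+1) frequency series including the founder.
    """
    return simulate_transmission_many(
        founder_frequency, bottleneck_N, generations, 1, seed
    )[:, 0]


def simulate_transmission_many(
    founder_frequency: float,
    bottleneck_N: int,
    generations: int,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Replicated trajectories, shape (generations + 1, n_replicates)."""
    if not 0.0 <= founder_frequency <= 1.0:
        raise ValueError("founder_frequency must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 2)
    traj = np.empty((generations + 1, n_replicates))
    f = np.full(n_replicates, founder_frequency)
    traj[0] = f
    for g in range(1, generations + 1):
        f = rng.binomial(bottleneck_N, f) / bottleneck_N
        traj[g] = f
    return traj


def _planted_by_position(
    config: SimulationConfig,
) -> dict[int, PlantedVariant]:
    out: dict[int, PlantedVariant] = {}
    for pv in config.planted_variants:
        if not 1 <= pv.position <= config.genome_length:
            raise ValueError(f"planted variant position {pv.position} out of bounds")
        if pv.position in out:
            raise ValueError(f"two planted variants at position {pv.position}")
        out[pv.position] = pv
    return out


def _site_coverage_draw(
    config: SimulationConfig,
    n_sites: int,
    rng: np.random.Generator,
    protected: Sequence[int] = (),
) -> np.ndarray:
    """Per-site coverage: NB everywhere, dip/spike artifact anomalies at a
    random site fraction. Each artifact site's mean is multiplied by a
    log-uniform dip (repeat collapse / unmappable context) or spike
    (repeat pile-up), equiprobably. ``protected`` positions (1-based; the
    planted variant sites, whose allele counts are modeled as clean
    samples) never fall on artifact sites — an artifact site's counts
    would be mapping-corrupted, which this generator does not model."""
    mean = np.full(n_sites, float(config.coverage_mean))
    if config.artifact_fraction > 0:
        artifact = rng.random(n_sites) < config.artifact_fraction
        for pos in protected:
            artifact[pos - 1] = False
        k = int(artifact.sum())
        spike = rng.random(k) < 0.5
        lo_d, hi_d = config.artifact_dip_range
        lo_s, hi_s = config.artifact_spike_range
        mult = np.where(
            spike,
            np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), k)),
            np.exp(rng.uniform(np.log(lo_d), np.log(hi_d), k)),
        )
        mean[artifact] *= mult
    if config.coverage_dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / config.coverage_dispersion
    # NB as gamma-mixed Poisson keeps the per-site mean exact
    lam = rng.gamma(size, mean / size)
    return rng.poisson(lam)


def simulate_pileups(
    config: SimulationConfig,
    line_frequencies: Mapping[int, float],
    line_index: int = 0,
    genome: ReferenceGenome | None = None,
    homopolymer_runs: Sequence[int] | None = None,
) -> list[SitePileup]:
    """Pileups for one line given its per-position planted-variant frequencies.

    ``line_frequencies`` maps a planted variant's position to that line's
    frequency (e.g. a transmission-trajectory endpoint). Every key must match
    a configured planted variant. Sequencing error spreads uniformly over the
    three non-reference bases; homopolymer sites (runs >= homopolymer_min_run)
    additionally receive single-base deletion errors at a higher rate.
    """
    planted = _planted_by_position(config)
    for pos in line_frequencies:
        if pos not in planted:
            raise ValueError(f"frequency supplied for unknown position {pos}")
    if genome is None:
        genome, _, _ = simulate_reference(config)
    n = genome.length
    rng = _rng(config.seed, 3, line_index)
    coverage = _site_coverage_draw(config, n, rng, protected=list(line_frequencies))

    ref_idx = np.fromiter((_BASE_IDX[b] for b in genome.sequence), dtype=np.int64, count=n)
    counts = np.zeros((n, 4), dtype=np.int64)

    # start with every read supporting the true allele mixture
    var_reads = np.zeros(n, dtype=np.int64)
    for pos, freq in line_frequencies.items():
        var_reads[pos - 1] = rng.binomial(coverage[pos - 1], freq)
    ref_reads = coverage - var_reads

    # homopolymer deletion errors consume reference reads at hot sites
    del_err = np.zeros(n, dtype=np.int64)
    if config.homopolymer_indel_error > 0:
        if homopolymer_runs is None:
            homopolymer_runs = _run_lengths(genome.sequence)
        hot = np.asarray(homopolymer_runs) >= config.homopolymer_min_run
        hot &= ref_reads > 0
        del_err[hot] = rng.binomial(ref_reads[hot], config.homopolymer_indel_error)
        ref_reads = ref_reads - del_err

    # base miscalls: each remaining ref read flips to a uniform other base
    if config.error_rate > 0:
        miscalled = rng.binomial(ref_reads, config.error_rate)
        ref_reads = ref_reads - miscalled
        split = rng.multinomial(miscalled, [1 / 3] * 3)
    else:
        miscalled = np.zeros(n, dtype=np.int64)
        split = np.zeros((n, 3), dtype=np.int64)
    counts[np.arange(n), ref_idx] = ref_reads
    for j in range(3):
        # the j-th non-reference base in base order for each site
        alt_idx = np.array(
            [[b for b in range(4) if b != r][j] for r in range(4)], dtype=np.int64
        )[ref_idx]
        counts[np.arange(n), alt_idx] += split[:, j]

    pileups: list[SitePileup] = []
    for i in range(n):
        pos = i + 1
        ref_base = genome.sequence[i]
        base_counts = {b: int(counts[i, k]) for b, k in _BASE_IDX.items()}
        deletions: dict[str, int] = {}
        insertions: dict[str, int] = {}
        if del_err[i]:
            deletions[ref_base] = int(del_err[i])
        pv = planted.get(pos)
        if pv is not None and pos in line_frequencies and var_reads[i]:
            v = int(var_reads[i])
            if pv.variant_type == "SNP":
                base_counts[pv.alt] += v
            elif pv.variant_type == "deletion":
                deletions[pv.ref] = deletions.get(pv.ref, 0) + v
            else:
                insertions[pv.alt] = insertions.get(pv.alt, 0) + v
        pileups.append(
            SitePileup(
                position=pos,
                ref_base=ref_base,
                base_counts=base_counts,
                deletion_counts=deletions,
                insertion_counts=insertions,
            )
        )
    return pileups


def _run_lengths(sequence: str) -> np.ndarray:
    """Homopolymer run length containing each position (circular)."""
    n = len(sequence)
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    lengths = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and arr[j] == arr[i]:
            j += 1
        lengths[i:j] = j - i
        i = j
    # merge the wrap-around run on circular sequences
    if n > 1 and arr[0] == arr[-1] and lengths[0] < n:
        first = lengths[0]
        last = lengths[-1]
        total = first + last
        lengths[:first] = total
        lengths[n - last :] = total
    return lengths


def simulate_sanger_trace(
    state: str,
    site_index: int,
    read_length: int = 200,
    flank_quality: float = 50.0,
    seed: int = 0,
    ref_base: str = "C",
    var_base: str = "A",
    heteroplasmy_quality_drop: float = 25.0,
) -> SeqRecord:
    """A FASTQ-style trace read with the focal site in a given state.

    absent: reference base at ~flank quality. fixed: variant base at ~flank
    quality. segregating: mixed template — either base may be called, with
    the Phred score depressed >= 20 below the flanking mean (the classic
    double-peak signature of a heteroplasmic position in an
    electropherogram).
    """
    if state not in ("absent", "segregating", "fixed"):
        raise ValueError(f"unknown state {state!r}")
    if not 0 <= site_index < read_length:
        raise ValueError("site_index must lie within the read")
    rng = _rng(seed, 4)
    bases = rng.choice(list("ACGT"), size=read_length)
    quals = np.clip(rng.normal(flank_quality, 1.5, read_length), 0, 93)
    if state == "absent":
        bases[site_index] = ref_base
    elif state == "fixed":
        bases[site_index] = var_base
    else:
        bases[site_index] = ref_base if rng.random() < 0.5 else var_base
        drop = max(20.0, heteroplasmy_quality_drop + rng.normal(0, 2))
        quals[site_index] = max(0.0, flank_quality - drop)
    rec = SeqRecord(
        Seq("".join(bases)),
        id=f"trace_{state}_{seed}",
        description=f"synthetic Sanger trace, focal site {site_index} {state}",
    )
    rec.letter_annotations["phred_quality"] = [int(round(q)) for q in quals]
    return rec
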