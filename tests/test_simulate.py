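"""Synthetic cohort generators: determinism, embedding, transmission
martingale, pileup count laws, Sanger trace construction."""

import numpy as np
import pytest

from mitodrift import (
    PlantedVariant,
    SimulationConfig,
    simulate_pileups,
    simulate_reference,
    simulate_sanger_trace,
    simulate_transmission,
    simulate_transmission_many,
)


class TestSimulateReference:
    def test_requested_run_embedded_verbatim(self):
        cfg = SimulationConfig(genome_length=50, homopolymer_spec=((10, "A", 11),), seed=5)
        genome, _, _ = simulate_reference(cfg)
        assert genome.sequence[9:20] == "A" * 11
        # flanks differ so the run length is exactly as requested
        assert genome.sequence[8] != "A" and genome.sequence[20] != "A"

    def test_same_seed_same_genome(self):
        cfg = SimulationConfig(genome_length=300, seed=9)
        g1, _, _ = simulate_reference(cfg)
        g2, _, _ = simulate_reference(cfg)
        assert g1.sequence == g2.sequence

    def test_run_longer_than_genome_rejected(self):
        cfg = SimulationConfig(genome_length=10, homopolymer_spec=((1, "A", 11),))
        with pytest.raises(ValueError, match="exceeds"):
            simulate_reference(cfg)

    def test_overlapping_runs_rejected(self):
        cfg = SimulationConfig(
            genome_length=60, homopolymer_spec=((10, "A", 8), (15, "C", 8))
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_reference(cfg)

    def test_planted_ref_alleles_written_into_sequence(self):
        cfg = SimulationConfig(
            genome_length=80, planted_variants=(PlantedVariant(30, "G", "T", 0.1),), seed=2
        )
        genome, _, _ = simulate_reference(cfg)
        assert genome.base(30) == "G"


class TestTransmission:
    def test_absorbing_boundaries(self):
        assert (simulate_transmission(0.0, 10, 20, seed=1) == 0).all()
        assert (simulate_transmission(1.0, 10, 20, seed=1) == 1).all()

    def test_frequencies_stay_in_unit_interval_and_absorb(self):
        traj = simulate_transmission_many(0.3, 8, 60, 500, seed=3)
        assert ((traj >= 0) & (traj <= 1)).all()
        # once absorbed, a trajectory never leaves the boundary
        hit0 = np.minimum.accumulate(np.where(traj == 0, 0, 1), axis=0)
        assert (traj[1:][hit0[:-1] == 0] == 0).all()

    def test_mean_frequency_is_conserved_across_generations(self):
        # neutral drift is a martingale: E[f_t] = f_0 for every t
        traj = simulate_transmission_many(0.2, 12, 40, 20000, seed=4)
        se = np.sqrt(0.2 * 0.8 / 20000)
        assert abs(traj[-1].mean() - 0.2) < 4 * se
        assert np.all(np.abs(traj.mean(axis=1) - 0.2) < 5 * se)


def _cfg(**kw):
    base = dict(
        genome_length=200,
        coverage_mean=300.0,
        coverage_dispersion=0.0,
        artifact_fraction=0.0,
        error_rate=0.0,
        homopolymer_indel_error=0.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulatePileups:
    def test_error_free_variant_free_lines_are_pure_reference(self):
        cfg = _cfg()
        genome, _, _ = simulate_reference(cfg)
        for p in simulate_pileups(cfg, {}, genome=genome):
            assert p.ref_count == p.coverage() > 0
            assert p.alt_alleles() == []

    def test_planted_frequency_recovered_at_deep_coverage(self):
        cfg = _cfg(
            coverage_mean=10000.0,
            planted_variants=(PlantedVariant(50, "G", "T", 0.5),),
        )
        genome, _, _ = simulate_reference(cfg)
        piles = simulate_pileups(cfg, {50: 0.5}, genome=genome)
        p = piles[49]
        assert abs(p.base_counts["T"] / p.coverage() - 0.5) < 0.02

    def test_counts_sum_to_drawn_coverage_with_indels(self):
        cfg = _cfg(
            error_rate=1e-3,
            homopolymer_indel_error=0.05,
            homopolymer_spec=((100, "A", 8),),
            planted_variants=(PlantedVariant(50, "A", "-", 0.3),),
        )
        genome, _, _ = simulate_reference(cfg)
        piles = simulate_pileups(cfg, {50: 0.2}, genome=genome)
        dels = sum(sum(p.deletion_counts.values()) for p in piles)
        assert dels > 0  # homopolymer deletion errors and the planted allele
        for p in piles:
            counts = (
                sum(p.base_counts.values())
                + sum(p.deletion_counts.values())
                + sum(p.insertion_counts.values())
            )
            assert counts == p.coverage()

    def test_poisson_limit_variance_matches_mean(self):
        cfg = _cfg(genome_length=10000, coverage_mean=100.0)
        genome, _, _ = simulate_reference(cfg)
        covs = np.array([p.coverage() for p in simulate_pileups(cfg, {}, genome=genome)])
        assert abs(covs.var() / covs.mean() - 1.0) < 0.05

    def test_overdispersion_raises_variance(self):
        cfg = _cfg(genome_length=5000, coverage_dispersion=0.02)
        genome, _, _ = simulate_reference(cfg)
        covs = np.array([p.coverage() for p in simulate_pileups(cfg, {}, genome=genome)])
        # variance/mean for NB: 1 + dispersion * mean = 7
        assert covs.var() / covs.mean() > 3.0

    def test_byte_identical_given_seed(self):
        cfg = _cfg(error_rate=1e-3, planted_variants=(PlantedVariant(50, "G", "T", 0.1),))
        genome, _, _ = simulate_reference(cfg)
        a = simulate_pileups(cfg, {50: 0.1}, genome=genome)
        b = simulate_pileups(cfg, {50: 0.1}, genome=genome)
        assert a == b

    def test_frequency_for_unknown_position_rejected(self):
        cfg = _cfg()
        with pytest.raises(ValueError, match="unknown position"):
            simulate_pileups(cfg, {10: 0.5})


class TestSangerTrace:
    def test_absent_state_is_reference_at_flank_quality(self):
        rec = simulate_sanger_trace("absent", 100, seed=0, ref_base="C", var_base="A")
        quals = rec.letter_annotations["phred_quality"]
        flank = np.mean([q for i, q in enumerate(quals) if i != 100])
        assert rec.seq[100] == "C"
        assert abs(quals[100] - flank) < 6

    def test_fixed_state_is_variant_at_flank_quality(self):
        rec = simulate_sanger_trace("fixed", 100, seed=0, ref_base="C", var_base="A")
        assert rec.seq[100] == "A"

    def test_segregating_state_depresses_phred_at_least_20(self):
        for seed in range(20):
            rec = simulate_sanger_trace("segregating", 80, seed=seed)
            quals = rec.letter_annotations["phred_quality"]
            flank = np.mean([q for i, q in enumerate(quals) if i != 80])
            assert quals[80] <= flank - 20 + 1  # integer rounding slack
            assert rec.seq[80] in "CA"

    def test_site_outside_read_rejected(self):
        with pytest.raises(ValueError):
            simulate_sanger_trace("absent", 500, read_length=200)
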