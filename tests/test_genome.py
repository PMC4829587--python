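"""Reference model: loaders, homopolymer scanning, codon arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitodrift import (
    GeneAnnotation,
    GenomeFormatError,
    ReferenceGenome,
    codon_at,
    homopolymer_length,
    load_annotations,
    load_reference,
)
from mitodrift.genome import reverse_complement

from conftest import write_fasta


def brute_force_run(sequence: str, position: int, circular: bool) -> int:
    """Independent oracle: scan left/right on the (doubled) string."""
    n = len(sequence)
    i = position - 1
    base = sequence[i]
    if base == "N":
        return 1
    if circular:
        doubled = sequence * 3
        i += n
        seq = doubled
    else:
        seq = sequence
    left = i
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = i
    while right < len(seq) - 1 and seq[right + 1] == base:
        right += 1
    return min(right - left + 1, n)


class TestLoadReference:
    def test_reads_single_record_and_uppercases(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", [("mt", "acgt")])
        g = load_reference(path)
        assert (g.id, g.sequence, g.length) == ("mt", "ACGT", 4)

    def test_multi_record_rejected(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", [("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(GenomeFormatError, match="single"):
            load_reference(path)

    @pytest.mark.parametrize("seq", ["", "ACGU", "ACGX"])
    def test_bad_sequences_rejected(self, tmp_path, seq):
        path = write_fasta(tmp_path / "r.fa", [("mt", seq)])
        with pytest.raises(GenomeFormatError):
            load_reference(path)


class TestLoadAnnotations:
    def test_bed_is_converted_to_one_based_inclusive(self, tmp_path, toy_genome):
        (tmp_path / "g.bed").write_text("mt\t0\t9\tg1\t.\t+\n")
        (ann,) = load_annotations(tmp_path / "g.bed", toy_genome)
        assert (ann.start, ann.end, ann.gene) == (1, 9, "g1")

    def test_gff3_used_as_is(self, tmp_path, toy_genome):
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\nmt\t.\tCDS\t3\t11\t.\t+\t0\tID=c1;Name=g1\n"
        )
        (ann,) = load_annotations(tmp_path / "g.gff3", toy_genome)
        assert (ann.start, ann.end, ann.kind, ann.gene) == (3, 11, "CDS", "g1")
        assert len(ann) == 9

    def test_same_feature_in_both_dialects_agrees(self, tmp_path, toy_genome):
        (tmp_path / "g.bed").write_text("mt\t2\t11\tg1\t.\t-\tCDS\n")
        (tmp_path / "g.gff3").write_text("mt\t.\tCDS\t3\t11\t.\t-\t0\tName=g1\n")
        bed, gff = (
            load_annotations(tmp_path / f"g.{ext}", toy_genome)[0]
            for ext in ("bed", "gff3")
        )
        assert (bed.start, bed.end, bed.strand, bed.kind) == (
            gff.start, gff.end, gff.strand, gff.kind,
        )

    def test_out_of_bounds_feature_rejected(self, tmp_path, toy_genome):
        (tmp_path / "g.gff3").write_text("mt\t.\tCDS\t3\t99\t.\t+\t0\tName=g1\n")
        with pytest.raises(GenomeFormatError, match="exceeds"):
            load_annotations(tmp_path / "g.gff3", toy_genome)

    def test_unknown_strand_rejected(self, tmp_path, toy_genome):
        (tmp_path / "g.gff3").write_text("mt\t.\tCDS\t3\t9\t.\t?\t0\tName=g1\n")
        with pytest.raises(GenomeFormatError):
            load_annotations(tmp_path / "g.gff3", toy_genome)


class TestHomopolymerLength:
    def test_eleven_base_run(self):
        g = ReferenceGenome("mt", "GGAAAAAAAAAAAGG", circular=False)
        assert homopolymer_length(g, 5) == 11

    def test_singleton(self):
        g = ReferenceGenome("mt", "ACGT", circular=False)
        assert homopolymer_length(g, 2) == 1

    def test_run_wraps_origin_when_circular(self):
        g = ReferenceGenome("mt", "AAGCAA", circular=True)
        assert homopolymer_length(g, 1) == 4
        assert homopolymer_length(g, 6) == 4
        assert homopolymer_length(ReferenceGenome("mt", "AAGCAA", circular=False), 1) == 2

    def test_n_breaks_runs(self):
        g = ReferenceGenome("mt", "AANAA", circular=False)
        assert homopolymer_length(g, 1) == 2
        assert homopolymer_length(g, 3) == 1

    def test_out_of_bounds(self, toy_genome):
        with pytest.raises(IndexError):
            homopolymer_length(toy_genome, 0)

    @settings(max_examples=25, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=2, max_size=60),
        circular=st.booleans(),
        data=st.data(),
    )
    def test_matches_brute_force_scan(self, seq, circular, data):
        g = ReferenceGenome("mt", seq, circular=circular)
        pos = data.draw(st.integers(1, len(seq)))
        assert homopolymer_length(g, pos) == brute_force_run(seq, pos, circular)

    def test_thousand_random_positions_match_oracle(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        g = ReferenceGenome("mt", seq, circular=True)
        for pos in rng.integers(1, 2001, size=1000):
            assert homopolymer_length(g, int(pos)) == brute_force_run(seq, int(pos), True)


class TestCodonAt:
    def test_plus_strand_frame_walk(self, toy_genome, plus_cds):
        # toy genome begins ATGGTG
        assert codon_at(toy_genome, plus_cds, 4) == ("GTG", 1, 0)
        assert codon_at(toy_genome, plus_cds, 1) == ("ATG", 0, 0)
        assert codon_at(toy_genome, plus_cds, 6) == ("GTG", 1, 2)

    def test_minus_strand_matches_revcomp_oracle(self):
        g = ReferenceGenome("mt", "CACCAT", circular=False)
        ann = GeneAnnotation(gene="g-", start=1, end=6, strand="-", kind="CDS")
        coding = reverse_complement(g.sequence)  # ATGGTG
        for pos in range(1, 7):
            codon, idx, off = codon_at(g, ann, pos)
            i = 6 - pos  # coding-strand index of the physical base
            assert codon == coding[3 * (i // 3) : 3 * (i // 3) + 3]
            assert (idx, off) == (i // 3, i % 3)

    def test_position_outside_gene_rejected(self, toy_genome, plus_cds):
        with pytest.raises(ValueError, match="outside"):
            codon_at(toy_genome, plus_cds, 7)

    def test_non_cds_rejected(self, toy_genome):
        trna = GeneAnnotation(gene="t", start=1, end=6, strand="+", kind="tRNA")
        with pytest.raises(ValueError, match="not coding"):
            codon_at(toy_genome, trna, 3)

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_substitution_round_trip(self, data):
        # mutating the base at offset_in_codon changes exactly that codon slot
        seq = data.draw(st.text(alphabet="ACGT", min_size=9, max_size=30))
        n_codons = len(seq) // 3
        ann = GeneAnnotation("g", 1, 3 * n_codons, data.draw(st.sampled_from("+-")), "CDS")
        g = ReferenceGenome("mt", seq, circular=False)
        pos = data.draw(st.integers(1, 3 * n_codons))
        codon, idx, off = codon_at(g, ann, pos)
        new_base = data.draw(st.sampled_from("ACGT"))
        mutated = seq[: pos - 1] + new_base + seq[pos:]
        codon2, idx2, off2 = codon_at(ReferenceGenome("mt", mutated, circular=False), ann, pos)
        assert (idx2, off2) == (idx, off)
        expected = reverse_complement(new_base) if ann.strand == "-" else new_base
        assert codon2 == codon[:off] + expected + codon[off + 1 :]
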