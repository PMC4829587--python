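import pytest

from mitodrift import GeneAnnotation, ReferenceGenome


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    # 24 bp circular toy mitogenome: one 5-A run, assorted context
    return ReferenceGenome(id="mt", sequence="ATGGTGCCAAAAAGTTACGCTTGA", circular=True)


@pytest.fixture
def plus_cds() -> GeneAnnotation:
    return GeneAnnotation(gene="g+", start=1, end=6, strand="+", kind="CDS")


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path
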