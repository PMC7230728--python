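"""Shared fixtures: small synthetic genomes generated at test time."""

import pytest

from halomotif.simulate import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def plain_genome_10kb():
    """10 kb order-1 genome at 57% G+C, no CDS, no TDR, nothing avoided."""
    return generate_genome(
        SyntheticGenomeSpec(
            length_bp=10000, gc=0.57, markov_order=1, avoided_motifs=(),
            tdr_length=0, n_cds=0, cxxc_plant=(0, 0), seed=101, name="plain10k",
        )
    )


@pytest.fixture(scope="session")
def avoided_genome_10kb():
    """10 kb genome with GATC and CTAG fully avoided on both strands."""
    return generate_genome(
        SyntheticGenomeSpec(
            length_bp=10000, gc=0.57, markov_order=1,
            avoided_motifs=("GATC", "CTAG"), tdr_length=0, n_cds=0,
            cxxc_plant=(0, 0), seed=102, name="avoided10k",
        )
    )


@pytest.fixture(scope="session")
def annotated_genome_20kb():
    """20 kb genome with 12 CDS, 5 of them CxxC proteins (3 micro)."""
    return generate_genome(
        SyntheticGenomeSpec(
            length_bp=20000, gc=0.56, markov_order=1, avoided_motifs=(),
            tdr_length=0, n_cds=12, cxxc_plant=(5, 3), seed=103, name="annot20k",
        )
    )
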