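import numpy as np
import pytest

from mutmapkit.simdata import SimulationConfig, simulate_dataset, simulate_genome
from mutmapkit.variants import GeneModel


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Small genome for unit tests: 2 x 600 kb, causal mid-chromosome-1."""
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=600_000,
        causal_pos=300_000,
        ems_rate=1e-4,
        seed=11,
    )


@pytest.fixture(scope="session")
def dataset(fast_config):
    return simulate_dataset(fast_config)


@pytest.fixture(scope="session")
def shared_genome(fast_config):
    return simulate_genome(fast_config)


TOY_CDS = "ATGTCTGCTAAACCCGGGTATCATTAA"  # 9 codons: M S A K P G Y H *


@pytest.fixture()
def toy_gene_plus() -> tuple[GeneModel, dict[str, str]]:
    """A 3-exon plus-strand gene on a tiny hand-made chromosome.

    CDS spans exons (11,22), (31,39), (51,56): 12+9+6 = 27 bp = 9 codons.
    """
    exons = ((11, 22), (31, 39), (51, 56))
    model = GeneModel(gene_id="toy", chrom="c", strand="+", exons=exons, cds=exons)
    exon1, exon2, exon3 = TOY_CDS[:12], TOY_CDS[12:21], TOY_CDS[21:]
    intron1 = "GTCCCCAG"  # 8 bp, positions 23-30
    intron2 = "GTTTTTTTTAG"  # 11 bp, positions 40-50
    seq = "A" * 10 + exon1 + intron1 + exon2 + intron2 + exon3 + "A" * 20
    assert seq[10:22] == exon1 and seq[30:39] == exon2 and seq[50:56] == exon3
    reference = {"c": seq}
    return model, reference
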