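import numpy as np
import pytest

from sumtwas.datatypes import GeneAnnotation, ReferencePanel, SnpRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gene():
    return GeneAnnotation(gene_id="GENE1", chrom="1", tss=2_000_000, tes=2_010_000)


def make_panel(genotypes, snp_ids=None, pos_start=1_500_000, spacing=1000, alleles=None, cm=None):
    """Build a small reference panel from a genotype matrix."""
    g = np.asarray(genotypes, dtype=np.float32)
    n, p = g.shape
    snp_ids = snp_ids or [f"rs{i+1}" for i in range(p)]
    alleles = alleles or [("A", "G")] * p
    records = [
        SnpRecord(
            snp_id=snp_ids[i],
            chrom="1",
            pos=pos_start + i * spacing,
            ref_allele=alleles[i][0],
            alt_allele=alleles[i][1],
            cm=None if cm is None else float(cm[i]),
        )
        for i in range(p)
    ]
    return ReferencePanel(
        sample_ids=[f"s{i+1}" for i in range(n)], genotypes=g, records=records
    )


@pytest.fixture
def small_panel(rng):
    """20 samples x 5 polymorphic SNPs."""
    g = rng.integers(0, 3, size=(20, 5)).astype(np.float32)
    # guarantee polymorphism
    g[0] = 0
    g[1] = 2
    return make_panel(g)
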