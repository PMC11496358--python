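import numpy as np
import pytest

from mhcdepth import (
    GeneFamily,
    GeneRegion,
    Genotype,
    GenotypeMatrix,
    SiteRecord,
    default_config,
    simulate_truth,
)


@pytest.fixture
def toy_region() -> GeneRegion:
    return GeneRegion(
        gene_id="G1",
        chrom="chr1",
        exons=((100, 160), (200, 263)),
        family=GeneFamily.MHC_I,
        strand="+",
        frame_offsets=(0, 0),
    )


@pytest.fixture
def tlr_region() -> GeneRegion:
    return GeneRegion(
        gene_id="TLRx",
        chrom="chr1",
        exons=((1000, 1900),),
        family=GeneFamily.TLR,
        single_copy_reference=True,
    )


def make_matrix(
    calls,
    individuals=None,
    depth=None,
    allele_depths=None,
    region_labels=None,
    qual=500.0,
    mq=60.0,
    chrom="chr1",
    start_pos=101,
):
    """Build a GenotypeMatrix from a (sites x individuals) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_i = calls.shape
    individuals = individuals or [f"K{j + 1}" for j in range(n_i)]
    sites = [
        SiteRecord(chrom=chrom, pos=start_pos + i, ref="A", alt="G", qual=qual, mq=mq)
        for i in range(n_s)
    ]
    return GenotypeMatrix(
        sites=sites,
        individuals=individuals,
        calls=calls,
        depth=depth,
        allele_depths=allele_depths,
        region_labels=region_labels,
    )


@pytest.fixture
def small_truth():
    cfg = default_config(seed=11, n_regions=3, n_individuals_per_region=8)
    return simulate_truth(cfg)
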