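import numpy as np
import pandas as pd
import pytest

from sweepscan import SimulationConfig, PhenotypeConfig, simulate_cohort
from sweepscan.simulate import tile_genes, write_fixture_bundle


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort (default study conditions) shared across tests."""
    config = SimulationConfig(seed=11)
    table, manifest = simulate_cohort(config)
    return config, table, manifest


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A written fixture bundle (VCF/GFF/lists/tables) on disk."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=11, snp_density=0.0005)  # small for file I/O tests
    paths = write_fixture_bundle(config, PhenotypeConfig(), str(outdir))
    return config, paths


@pytest.fixture()
def toy_genes():
    from sweepscan import GeneRecord

    return [
        GeneRecord("gA", "chr1", 140_000, 160_000),
        GeneRecord("gB", "chr1", 150_001, 160_000),
        GeneRecord("gC", "chr1", 95_000, 105_000),
        GeneRecord("gD", "chr2", 100, 200),
    ]


def make_site(genotypes, chrom="chr1", pos=100, info=None, gq=None, dp=None, ad=None):
    from sweepscan import VariantSite

    genotypes = np.asarray(genotypes, dtype=np.int8)
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        genotypes=genotypes,
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        ad=None if ad is None else np.asarray(ad, dtype=np.int32),
        info=info or {},
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tT\t500\t.\tQD=20;FS=1.5\tGT:AD:DP:GQ\t0/0:10,0:10:99\t0/1:5,5:10:99\t1/1:0,9:9:80
chr1\t200\t.\tG\tC\t500\t.\tQD=25;FS=0.5\tGT:AD:DP:GQ\t./.:.:.:.\t0/1:6,4:10:45\t0/0:8,0:8:70
chr1\t300\t.\tT\tA\t500\t.\tQD=30;FS=2\tGT:AD:DP:GQ\t1/1:0,12:12:90\t1/1:1,11:12:88\t0/1:7,5:12:91
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)
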