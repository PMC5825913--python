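import numpy as np
import pandas as pd
import pytest

import supergs as sg


@pytest.fixture(scope="session")
def small_panel():
    """Single-population panel: 80 genotypes × 300 markers."""
    gm, Q, P = sg.simulate_genotypes(n=80, m=300, K=1, seed=42)
    return gm


@pytest.fixture(scope="session")
def structured_panel():
    """Two well-separated populations with admixture: 120 × 600."""
    return sg.simulate_genotypes(
        n=120, m=600, K=2, alpha_admix=0.1, fst=0.35, seed=7
    )


@pytest.fixture(scope="session")
def trial(small_panel):
    """Balanced 3-site × 3-rep trial with spatial trends and G×E."""
    pheno, truth = sg.simulate_trait(
        small_panel, n_qtl=20, h2_plot=0.4, n_sites=3, n_reps=3,
        prop_ge=0.3, spatial_sd=0.4, seed=11,
    )
    return pheno, truth


@pytest.fixture()
def toy_vcf(tmp_path):
    """5 samples × 4 SNPs; one monomorphic site (MAF 0)."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5
chr1\t100\tsnp1\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\t0/0\t1/1\t0/0
chr1\t200\tsnp2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0
chr1\t300\tsnp3\tG\tA\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0\t0/0\t0/1
chr2\t150\tsnp4\tT\tC\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\t0/0\t1/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return str(path)


@pytest.fixture()
def gff_file(tmp_path):
    """3 genes (one deliberately unsorted) and 2 mRNA features."""
    text = """##gff-version 3
chr1\tsrc\tgene\t5000\t6000\t.\t+\t.\tID=geneB;Name=geneB
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA;description=first gene
chr1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=mrnaA;Parent=geneA
chr2\tsrc\tgene\t300\t900\t.\t-\t.\tID=geneC
chr2\tsrc\tmRNA\t300\t900\t.\t-\t.\tID=mrnaC;Parent=geneC
"""
    path = tmp_path / "genes.gff3"
    path.write_text(text)
    return str(path)
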