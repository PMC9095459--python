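"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import binburden as bb
from binburden.variants import Gene, GeneModel


@pytest.fixture(scope="session")
def grch38_bins() -> bb.GenomicBinIndex:
    return bb.build_bins(bb.GenomeBuild.grch38(), 5_000_000)


@pytest.fixture(scope="session")
def small_cohort() -> bb.SyntheticCohort:
    """A small planted-signal cohort reused across read-only tests."""
    config = bb.make_config("strong", n_cases=60, n_controls=60, seed=7)
    return bb.generate_cohort(config)


def make_toy_gene_model() -> GeneModel:
    """One plus-strand coding gene with a split CDS, one ncRNA gene.

    Coding gene on chr1: span [1001, 1060], exons [1001,1030]+[1041,1060],
    CDS [1011,1030]+[1041,1048] (28 bp... adjusted to 27 bp, 9 codons),
    5' UTR [1001,1010], 3' UTR [1049,1060], intron [1031,1040].
    """
    # CDS: [1011, 1030] (20 bp) + [1041, 1047] (7 bp) = 27 bp = 9 codons
    cds_seq = "ATG" + "GCT" + "CGA" + "TAT" + "GGT" + "AAA" + "CCC" + "GGG" + "TTT"
    coding = Gene(
        name="TOY1",
        chrom="chr1",
        strand="+",
        start=1001,
        end=1060,
        exons=[(1001, 1030), (1041, 1060)],
        cds=[(1011, 1030), (1041, 1047)],
        coding=True,
        cds_seq=cds_seq,
    )
    nc = Gene(
        name="TOYNC",
        chrom="chr1",
        strand="+",
        start=2001,
        end=2500,
        exons=[(2001, 2500)],
        coding=False,
    )
    return GeneModel([coding, nc])


@pytest.fixture()
def toy_gene_model() -> GeneModel:
    return make_toy_gene_model()


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t0/0
chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
chr1\t400\t.\tA\tC,T\t.\tPASS\t.\tGT\t1/2\t0/1\t0/2
chr1\t500\t.\tT\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t0/0
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
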