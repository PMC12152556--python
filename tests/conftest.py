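"""Shared fixtures: hand-built gene models and simulated datasets."""

from __future__ import annotations

import pytest

from snortools.annotations import (
    HostGeneModel,
    IntronRecord,
    SnoRNARecord,
    TranscriptModel,
)
from snortools.intervals import GenomicInterval
from snortools.read_model import ReadAlignment
from snortools.simulator import make_fixture


def make_read(blocks, gaps=(), chrom="chr1", strand="+", read_id="r1"):
    return ReadAlignment(
        read_id,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in blocks],
        [GenomicInterval(chrom, s, e, strand) for s, e in gaps],
    )


def make_host_gene(strand="+", coding=True, box_class="CD", canonical=True):
    """Three-exon host gene with the snoRNA in the second intron.

    Exons [100,200), [500,600), [900,1000); introns [200,500) and
    [600,900); snoRNA at [700,800).
    """
    chrom = "chr1"
    exons = [
        GenomicInterval(chrom, 100, 200, strand),
        GenomicInterval(chrom, 500, 600, strand),
        GenomicInterval(chrom, 900, 1000, strand),
    ]
    tx_exons = exons if strand == "+" else exons[::-1]
    tx = TranscriptModel(
        "tx1", "geneA", tx_exons, cds=list(tx_exons) if coding else None
    )
    sno = SnoRNARecord(
        "snoA", "geneA", GenomicInterval(chrom, 700, 800, strand), box_class, canonical
    )
    gene = HostGeneModel(
        "geneA", GenomicInterval(chrom, 100, 1000, strand), [tx]
    )
    gene.introns = [
        IntronRecord("geneA", GenomicInterval(chrom, 200, 500, strand)),
        IntronRecord(
            "geneA",
            GenomicInterval(chrom, 600, 900, strand),
            hosts_snorna=True,
            snorna_id="snoA",
        ),
    ]
    gene.snornas = [sno]
    gene.category = "CDS_INTERNAL" if coding else "NONCODING"
    return gene


@pytest.fixture
def plus_gene():
    return make_host_gene("+")


@pytest.fixture
def minus_gene():
    return make_host_gene("-")


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    return make_fixture("tiny", tmp_path_factory.mktemp("tiny"))


@pytest.fixture(scope="session")
def mirror_dataset(tmp_path_factory):
    return make_fixture("mirror", tmp_path_factory.mktemp("mirror"))


@pytest.fixture(scope="session")
def noisy_dataset(tmp_path_factory):
    return make_fixture("noisy", tmp_path_factory.mktemp("noisy"))
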