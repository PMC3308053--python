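"""Shared fixtures: small hand-built gene models with known sequences."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from exomefunnel.variants import GeneModelSet, TranscriptModel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toygene() -> GeneModelSet:
    """Single-exon plus-strand gene, CDS ``ATGTATTGA`` (M Y *) at 11-19."""
    seq = "A" * 10 + "ATGTATTGA" + "C" * 11  # length 30
    t = TranscriptModel(
        transcript_id="toy1",
        gene_name="toygene",
        chrom="chr1",
        strand="+",
        exons=((11, 19),),
        cds=((11, 19),),
    )
    return GeneModelSet([t], {"chr1": seq}).validate()


@pytest.fixture(scope="session")
def minusgene() -> GeneModelSet:
    """Minus-strand gene whose transcript CDS is ``ATGTATTGA``.

    The genomic plus strand carries the reverse complement ``TCAATACAT`` at
    31-39; transcript codon 2 (TAT) corresponds to the genomic triplet ATA at
    34-36, so a genomic T>C change at 35 reads TAT>TGT (Tyr>Cys) in the
    transcript.
    """
    seq = "G" * 30 + "TCAATACAT" + "G" * 11  # length 50
    t = TranscriptModel(
        transcript_id="minus1",
        gene_name="minusgene",
        chrom="chr2",
        strand="-",
        exons=((31, 39),),
        cds=((31, 39),),
    )
    return GeneModelSet([t], {"chr2": seq}).validate()


# Multi-exon gene, plus strand, with UTRs and one intron:
#   1-10   pad            AAAAAAAAAA
#   11-15  5' UTR         GGGGG
#   16-25  CDS part 1     ATGTATTGGC          (codons: ATG TAT TGG C..)
#   26-55  intron (30)    GT ...26 bases... AG
#   56-63  CDS part 2     AATGCTGA            (..AA TGC TGA)
#   64-75  3' UTR         TTTTTTTTTTTT
#   76-85  pad            AAAAAAAAAA
# CDS = ATG TAT TGG CAA TGC TGA -> protein M Y W Q C *
_INTRON = "GT" + "ACGTACGTACGTACGTACGTACGTAC" + "AG"
SPLICEGENE_SEQ = (
    "A" * 10 + "GGGGG" + "ATGTATTGGC" + _INTRON + "AATGCTGA" + "T" * 12 + "A" * 10
)


@pytest.fixture(scope="session")
def splicegene() -> GeneModelSet:
    assert len(_INTRON) == 30
    t = TranscriptModel(
        transcript_id="spl1",
        gene_name="splicegene",
        chrom="chr3",
        strand="+",
        exons=((11, 25), (56, 75)),
        cds=((16, 25), (56, 63)),
    )
    nc = TranscriptModel(
        transcript_id="nc1",
        gene_name="ncgene",
        chrom="chr3",
        strand="+",
        exons=((80, 84),),
        cds=(),
        biotype="noncoding",
    )
    return GeneModelSet([t, nc], {"chr3": SPLICEGENE_SEQ}).validate()
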