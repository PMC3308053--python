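"""Codon-aware consequence classification, checked against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from exomefunnel.consequence import (
    SEVERITY_ORDER,
    annotate,
    annotate_indel,
    annotate_snv,
    severity_rank,
)
from exomefunnel.errors import CoordinateError, DataError
from exomefunnel.variants import (
    GeneModelSet,
    TranscriptModel,
    VariantCall,
    reverse_complement,
)


def snv(chrom, pos, ref, alt, **kw):
    return VariantCall(chrom, pos, ref, alt, kw.pop("genotype", "het"), **kw)


class TestCodingSnvs:
    def test_missense_tyrosine_to_cysteine(self, toygene):
        # CDS base 5 (A>G): codon TAT -> TGT
        a = annotate_snv(snv("chr1", 15, "A", "G"), toygene)
        assert a.category == "nonsynonymous"
        assert a.consequence.detail == "Y:C" and a.consequence.residue == 2
        assert a.gene_name == "toygene"

    def test_minus_strand_missense_matches_transcript_orientation(self, minusgene):
        # genomic T>C at the middle of plus-strand triplet ATA -> transcript TAT>TGT
        a = annotate_snv(snv("chr2", 35, "T", "C"), minusgene)
        assert a.category == "nonsynonymous"
        assert a.consequence.detail == "Y:C" and a.consequence.residue == 2

    def test_stop_gained(self, toygene):
        # CDS base 6 (T>A): codon TAT -> TAA
        a = annotate_snv(snv("chr1", 16, "T", "A"), toygene)
        assert a.category == "stop_gained"
        assert a.consequence.detail == "Y:*"

    def test_stop_retaining_change_is_synonymous(self, splicegene):
        # final codon TGA at 61-63; G>A gives TAA: still a stop
        a = annotate_snv(snv("chr3", 62, "G", "A"), splicegene)
        assert a.category == "synonymous"

    def test_stop_lost(self, splicegene):
        # TGA -> TCA (Ser)
        a = annotate_snv(snv("chr3", 62, "G", "C"), splicegene)
        assert a.category == "stop_lost"

    def test_codon_spanning_intron(self, splicegene):
        # codon 4 = CAA split across exons (25 | 56,57); C>T gives TAA
        a = annotate_snv(snv("chr3", 25, "C", "T"), splicegene)
        assert a.category == "stop_gained"

    def test_reference_mismatch_is_an_error(self, toygene):
        with pytest.raises(DataError, match="REF"):
            annotate_snv(snv("chr1", 15, "C", "G"), toygene)

    def test_position_beyond_reference_is_an_error(self, toygene):
        with pytest.raises(CoordinateError):
            annotate_snv(snv("chr1", 4000, "A", "G"), toygene)


class TestNoncodingSnvs:
    @pytest.mark.parametrize(
        "pos,category",
        [
            (26, "essential_splice_site"),  # intron base 1
            (27, "essential_splice_site"),  # intron base 2
            (28, "intronic"),               # intron base 3
            (54, "essential_splice_site"),  # last-but-one intron base
            (55, "essential_splice_site"),  # last intron base
            (53, "intronic"),
            (12, "utr5"),
            (70, "utr3"),
            (82, "noncoding_transcript"),
            (5, "intergenic"),
        ],
    )
    def test_region_classification(self, splicegene, pos, category):
        ref = splicegene.sequence("chr3")[pos - 1]
        alt = "A" if ref != "A" else "C"
        assert annotate_snv(snv("chr3", pos, ref, alt), splicegene).category == category

    def test_every_transcript_position_gets_exactly_one_label(self, splicegene):
        """Region labels partition the transcript span."""
        (t, _) = splicegene.transcripts
        lo, hi = t.span
        counts = {"cds": 0, "utr5": 0, "utr3": 0, "splice": 0, "intron": 0}
        for pos in range(lo, hi + 1):
            counts[t.classify_position(pos)] += 1
        assert counts["cds"] == t.cds_length == 18
        assert counts["utr5"] == 5 and counts["utr3"] == 12
        assert counts["splice"] == 4 and counts["intron"] == 26
        assert sum(counts.values()) == hi - lo + 1


class TestIndels:
    def test_coding_1bp_insertion_is_frameshift(self, splicegene):
        seq = splicegene.sequence("chr3")
        a = annotate_indel(VariantCall("chr3", 17, seq[16], seq[16] + "G", "het"), splicegene)
        assert a.category == "frameshift"

    def test_inframe_insertion_encoding_stop(self, splicegene):
        # TAA inserted at the codon boundary after CDS base 3
        seq = splicegene.sequence("chr3")
        a = annotate_indel(VariantCall("chr3", 18, seq[17], seq[17] + "TAA", "het"), splicegene)
        assert a.category == "stop_gained"

    def test_inframe_benign_insertion(self, splicegene):
        seq = splicegene.sequence("chr3")
        a = annotate_indel(VariantCall("chr3", 18, seq[17], seq[17] + "GGG", "het"), splicegene)
        assert a.category == "inframe_indel"

    def test_inframe_codon_deletion(self, splicegene):
        seq = splicegene.sequence("chr3")
        a = annotate_indel(
            VariantCall("chr3", 18, seq[17:21], seq[17], "het"), splicegene
        )
        assert a.category == "inframe_indel"

    def test_intron_interior_deletion_is_intronic(self, splicegene):
        seq = splicegene.sequence("chr3")
        a = annotate_indel(VariantCall("chr3", 39, seq[38:40], seq[38], "het"), splicegene)
        assert a.category == "intronic"

    def test_deletion_of_splice_base(self, splicegene):
        seq = splicegene.sequence("chr3")
        a = annotate_indel(VariantCall("chr3", 25, seq[24:26], seq[24], "het"), splicegene)
        assert a.category == "essential_splice_site"

    def test_intergenic_indel(self, splicegene):
        seq = splicegene.sequence("chr3")
        a = annotate_indel(VariantCall("chr3", 2, seq[1:3], seq[1], "het"), splicegene)
        assert a.category == "intergenic"


class TestSeverityOrder:
    @pytest.mark.parametrize(
        "more,less",
        [
            ("stop_gained", "nonsynonymous"),
            ("stop_lost", "essential_splice_site"),
            ("frameshift", "essential_splice_site"),
            ("essential_splice_site", "nonsynonymous"),
            ("nonsynonymous", "inframe_indel"),
            ("inframe_indel", "synonymous"),
            ("synonymous", "utr5"),
            ("utr3", "noncoding_transcript"),
            ("noncoding_transcript", "intronic"),
            ("essential_splice_site", "intronic"),
            ("intronic", "intergenic"),
        ],
    )
    def test_relative_order(self, more, less):
        assert severity_rank(more) < severity_rank(less)

    def test_intergenic_is_least_severe(self):
        assert severity_rank("intergenic") == max(severity_rank(c) for c in SEVERITY_ORDER)

    def test_unknown_category_rejected(self):
        with pytest.raises(DataError):
            severity_rank("missense")


# ---------------------------------------------------------------------------
# Brute-force oracle over random single-exon genes
# ---------------------------------------------------------------------------

def _random_single_exon_models(rng, n_codons=80, pad=25):
    codons = ["ATG"]
    sense = [
        a + b + c
        for a in "ACGT" for b in "ACGT" for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    codons += [sense[i] for i in rng.integers(0, len(sense), n_codons - 2)]
    codons.append(("TAA", "TAG", "TGA")[int(rng.integers(0, 3))])
    cds = "".join(codons)
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, pad))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, pad))
    seq = left + cds + right
    t = TranscriptModel(
        "rt1", "rgene", "chrR", "+", ((pad + 1, pad + len(cds)),), ((pad + 1, pad + len(cds)),)
    )
    return GeneModelSet([t], {"chrR": seq}).validate(), pad, cds


def _oracle(cds: str, cds_index: int, alt: str):
    """Rebuild the whole mutant CDS, translate both, diff the proteins."""
    mutant = cds[:cds_index] + alt + cds[cds_index + 1 :]
    p0, p1 = str(Seq(cds).translate()), str(Seq(mutant).translate())
    if p0 == p1:
        return "synonymous", None
    diffs = [i for i, (a, b) in enumerate(zip(p0, p1)) if a != b]
    (i,) = diffs
    if p0[i] == "*":
        return "stop_lost", f"{p0[i]}:{p1[i]}"
    if p1[i] == "*":
        return "stop_gained", f"{p0[i]}:{p1[i]}"
    return "nonsynonymous", f"{p0[i]}:{p1[i]}"


def test_snv_annotation_agrees_with_bruteforce_translation_oracle():
    """>= 1000 random coding SNVs on random single-exon genes match a
    full-CDS rebuild-and-translate oracle, category and amino-acid detail."""
    rng = np.random.default_rng(20240901)
    checked = 0
    for _ in range(6):
        models, pad, cds = _random_single_exon_models(rng)
        for _ in range(250):
            idx = int(rng.integers(0, len(cds)))
            ref = cds[idx]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            v = snv("chrR", pad + 1 + idx, ref, alt)
            got = annotate_snv(v, models)
            want_cat, want_detail = _oracle(cds, idx, alt)
            assert got.category == want_cat, (idx, ref, alt)
            if want_detail:
                assert got.consequence.detail == want_detail
            checked += 1
    assert checked >= 1000


# ---------------------------------------------------------------------------
# Strand symmetry
# ---------------------------------------------------------------------------

def _mirror_models(models: GeneModelSet) -> GeneModelSet:
    """Reverse-complement every chromosome and flip all coordinates/strands."""
    ref = {c: reverse_complement(s) for c, s in models.reference.items()}
    flipped = []
    for t in models.transcripts:
        L = len(models.reference[t.chrom])
        flip = lambda iv: tuple(sorted((L - e + 1, L - s + 1) for s, e in iv))
        flipped.append(
            TranscriptModel(
                t.transcript_id, t.gene_name, t.chrom,
                "-" if t.strand == "+" else "+",
                flip(t.exons), flip(t.cds), t.biotype,
            )
        )
    return GeneModelSet(flipped, ref).validate()


def test_strand_symmetry_of_snv_annotation(splicegene):
    """Mirroring the genome (revcomp + coordinate flip) leaves every SNV's
    category and amino-acid detail unchanged."""
    mirrored = _mirror_models(splicegene)
    L = len(splicegene.sequence("chr3"))
    seq = splicegene.sequence("chr3")
    rng = np.random.default_rng(7)
    for pos in range(1, L + 1):
        ref = seq[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        a = annotate_snv(snv("chr3", pos, ref, alt), splicegene)
        b = annotate_snv(
            snv("chr3", L - pos + 1, reverse_complement(ref), reverse_complement(alt)),
            mirrored,
        )
        assert a.category == b.category, pos
        assert a.consequence.detail == b.consequence.detail


def test_annotate_dispatches_on_variant_class(toygene):
    assert annotate(snv("chr1", 5, "A", "G"), toygene).category == "intergenic"
    ins = VariantCall("chr1", 5, "A", "AT", "het")
    assert annotate(ins, toygene).category == "intergenic"
    with pytest.raises(DataError):
        annotate_snv(ins, toygene)
    with pytest.raises(DataError):
        annotate_indel(snv("chr1", 5, "A", "G"), toygene)
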