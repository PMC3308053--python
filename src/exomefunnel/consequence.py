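"""Codon-aware consequence classification of SNVs and short indels.

For coding SNVs the affected codon is extracted in transcript orientation
(reverse-complemented for minus-strand transcripts), mutated, translated with
the standard nuclear genetic code and compared with the reference amino acid.
Essential splice sites are the first or last two bases of an intron; splice
classification takes precedence over plain intronic placement. In-frame coding
indels are re-translated to detect introduced stop codons.

Each variant receives the most severe consequence across all overlapping
transcripts under a fixed severity order; ties are broken by lexicographic
transcript id so annotation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

from .errors import CoordinateError, DataError
from .variants import (
    GeneModelSet,
    TranscriptModel,
    VariantCall,
    reverse_complement,
)

#: Fixed severity order, most severe first. The ranking is this package's
#: choice: the underlying selection rule only distinguishes "selected"
#: (stop gain/loss, amino-acid change, essential splice site) from everything
#: else, but reporting one consequence per variant needs a total order.
SEVERITY_ORDER: tuple[str, ...] = (
    "stop_gained",
    "stop_lost",
    "frameshift",
    "essential_splice_site",
    "nonsynonymous",
    "inframe_indel",
    "synonymous",
    "utr5",
    "utr3",
    "noncoding_transcript",
    "intronic",
    "intergenic",
)

_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

#: Categories that change or could change the protein product.
CODING_CATEGORIES = frozenset(
    {"stop_gained", "stop_lost", "frameshift", "nonsynonymous", "inframe_indel", "synonymous"}
)

#: Categories kept by the candidate-selection step of the funnel.
SELECTED_CATEGORIES = frozenset(
    {"stop_gained", "stop_lost", "nonsynonymous", "essential_splice_site"}
)


def severity_rank(category_or_consequence) -> int:
    """Position in the fixed severity order (lower = more severe)."""
    cat = getattr(category_or_consequence, "category", category_or_consequence)
    try:
        return _RANK[cat]
    except KeyError:
        raise DataError(f"unknown consequence category {cat!r}") from None


@dataclass(frozen=True)
class Consequence:
    """A consequence category plus the amino-acid change when coding.

    ``detail`` is ``"X:Y"`` (reference:variant amino acid, ``*`` for stop) and
    ``residue`` the 1-based residue index, for codon-level categories; both are
    empty otherwise.
    """

    category: str
    detail: str = ""
    residue: int | None = None


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call joined to its most severe consequence."""

    variant: VariantCall
    consequence: Consequence
    transcript_id: str | None = None
    gene_name: str | None = None

    @property
    def category(self) -> str:
        return self.consequence.category


def _translate(codons: str) -> str:
    return str(Seq(codons).translate())


_NONCODING_MAP = {
    "splice": "essential_splice_site",
    "utr5": "utr5",
    "utr3": "utr3",
    "noncoding_exon": "noncoding_transcript",
    "intron": "intronic",
}


def _noncoding_category(labels: Iterable[str]) -> str | None:
    cats = [_NONCODING_MAP[l] for l in labels if l in _NONCODING_MAP]
    if not cats:
        return None
    return min(cats, key=severity_rank)


def _aa_change(ref_aa: str, alt_aa: str, residue: int) -> Consequence:
    detail = f"{ref_aa}:{alt_aa}"
    if ref_aa == alt_aa:
        return Consequence("synonymous", detail, residue)
    if ref_aa == "*":
        return Consequence("stop_lost", detail, residue)
    if alt_aa == "*":
        return Consequence("stop_gained", detail, residue)
    return Consequence("nonsynonymous", detail, residue)


def _snv_consequence(
    v: VariantCall, t: TranscriptModel, models: GeneModelSet
) -> Consequence | None:
    label = t.classify_position(v.pos)
    if label == "outside":
        return None
    if label != "cds":
        return Consequence(_NONCODING_MAP[label])

    seq = models.sequence(v.chrom)
    if seq[v.pos - 1].upper() != v.ref.upper():
        raise DataError(
            f"{v.chrom}:{v.pos}: REF {v.ref} does not match reference base {seq[v.pos - 1]}"
        )
    idx = t.cds_index(v.pos)
    codon_i, within = divmod(idx, 3)
    cds = models.coding_sequence(t)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_base = v.alt if t.strand == "+" else reverse_complement(v.alt)
    mutant = codon[:within] + alt_base.upper() + codon[within + 1 :]
    return _aa_change(_translate(codon), _translate(mutant), codon_i + 1)


def _indel_footprint(v: VariantCall) -> list[int]:
    """Genomic positions whose interpretation the indel changes.

    Deletions: the deleted bases. Insertions: the two bases flanking the
    insertion point (the anchor and its right neighbour).
    """
    if v.variant_class == "deletion":
        return list(range(v.pos + 1, v.pos + len(v.ref)))
    return [v.pos, v.pos + 1]


def _mutant_cds(v: VariantCall, t: TranscriptModel, models: GeneModelSet) -> str:
    """Spliced CDS with the indel applied, in transcript orientation."""
    positions = t.cds_positions
    index_of = {p: i for i, p in enumerate(positions)}
    seq = models.sequence(v.chrom)
    plus_cds = [seq[p - 1] for p in positions]  # ascending genomic order
    if v.variant_class == "deletion":
        for p in range(v.pos + 1, v.pos + len(v.ref)):
            plus_cds[index_of[p]] = ""
    else:
        plus_cds[index_of[v.pos]] += v.alt[1:]
    s = "".join(plus_cds).upper()
    return reverse_complement(s) if t.strand == "-" else s


def _indel_consequence(
    v: VariantCall, t: TranscriptModel, models: GeneModelSet
) -> Consequence | None:
    footprint = _indel_footprint(v)
    labels = [t.classify_position(p) for p in footprint]
    if all(l == "outside" for l in labels):
        return None

    # Anything touching the first/last two bases of an intron disrupts
    # splicing regardless of what else it touches.
    if "splice" in labels:
        return Consequence("essential_splice_site")

    wholly_coding = all(l == "cds" for l in labels)
    if not wholly_coding:
        if "cds" in labels and v.variant_class == "deletion":
            # A deletion reaching over a CDS boundary (into a UTR) removes
            # coding bases; the frame shifts when their number is not a
            # multiple of three. No re-translation is attempted here.
            n_coding = sum(1 for l in labels if l == "cds")
            return Consequence("frameshift" if n_coding % 3 else "inframe_indel")
        # A boundary insertion sits between codons and the neighbouring
        # region; classify by the non-coding side.
        cat = _noncoding_category(labels)
        return Consequence(cat) if cat else None

    delta = len(v.alt) - len(v.ref)
    if delta % 3 != 0:
        return Consequence("frameshift")

    protein = _translate(models.coding_sequence(t))
    mutant_protein = _translate(_mutant_cds(v, t, models))
    stop_at = mutant_protein.find("*")
    if 0 <= stop_at < len(mutant_protein) - 1:
        ref_aa = protein[stop_at] if stop_at < len(protein) else "-"
        return Consequence("stop_gained", f"{ref_aa}:*", stop_at + 1)
    if "*" not in mutant_protein and protein.endswith("*"):
        return Consequence("stop_lost", f"*:{mutant_protein[-1]}", len(mutant_protein))
    return Consequence("inframe_indel")


def _best(
    v: VariantCall,
    models: GeneModelSet,
    per_transcript,
) -> AnnotatedVariant:
    seq = models.sequence(v.chrom)
    if v.pos > len(seq):
        raise CoordinateError(
            f"{v.chrom}:{v.pos} beyond reference length {len(seq)}"
        )
    best: tuple[int, str, Consequence, TranscriptModel] | None = None
    for t in models.overlapping(v.chrom, v.pos):
        cons = per_transcript(v, t, models)
        if cons is None:
            continue
        entry = (severity_rank(cons), t.transcript_id, cons, t)
        if best is None or entry[:2] < best[:2]:
            best = entry
    if best is None:
        return AnnotatedVariant(v, Consequence("intergenic"))
    _, _, cons, t = best
    return AnnotatedVariant(v, cons, t.transcript_id, t.gene_name)


def annotate_snv(v: VariantCall, models: GeneModelSet) -> AnnotatedVariant:
    """Classify a single-nucleotide variant against all overlapping transcripts."""
    if v.variant_class != "snv":
        raise DataError(f"annotate_snv requires an SNV, got {v.variant_class}")
    return _best(v, models, _snv_consequence)


def annotate_indel(v: VariantCall, models: GeneModelSet) -> AnnotatedVariant:
    """Classify a short insertion or deletion.

    Coding indels whose length change is not a multiple of three are
    frameshifts; in-frame indels are re-translated and become ``stop_gained``
    when they introduce a premature stop, ``inframe_indel`` otherwise. Indels
    not wholly inside a CDS are classified like SNVs from the bases they touch
    (splice before intronic, UTRs, noncoding, intergenic).
    """
    if v.variant_class == "snv":
        raise DataError("annotate_indel requires an insertion or deletion")
    return _best(v, models, _indel_consequence)


def annotate(v: VariantCall, models: GeneModelSet) -> AnnotatedVariant:
    """Dispatch on variant class."""
    if v.variant_class == "snv":
        return annotate_snv(v, models)
    return annotate_indel(v, models)


def annotate_variants(
    calls: Iterable[VariantCall], models: GeneModelSet
) -> list[AnnotatedVariant]:
    return [annotate(v, models) for v in calls]


ANNOTATION_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "transcript", "category", "detail")


def annotations_frame(annotated: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    rows = [
        {
            "chrom": a.variant.chrom,
            "pos": a.variant.pos,
            "ref": a.variant.ref,
            "alt": a.variant.alt,
            "gene": a.gene_name or "",
            "transcript": a.transcript_id or "",
            "category": a.category,
            "detail": a.consequence.detail,
        }
        for a in annotated
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def write_annotations(annotated: Iterable[AnnotatedVariant], path: str | Path) -> None:
    annotations_frame(annotated).to_csv(path, sep="\t", index=False)
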