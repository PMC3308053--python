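"""Linkage exclusion: rule out alternative causal changes near the candidate.

A confirmed candidate could in principle be a linked marker rather than the
causal change, so every private call on the candidate's chromosome is
enumerated and classified, split into a physical-distance window around the
candidate (absolute distance, so the window is two-sided) and the remainder
of the chromosome, with protein-disrupting entries highlighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .consequence import CODING_CATEGORIES, AnnotatedVariant, annotate
from .variants import GeneModelSet, VariantCall, variant_key

DEFAULT_WINDOW_BP = 10_000_000

_LOCATION_LABELS = {
    "essential_splice_site": "Splice site (intronic)",
    "utr5": "5' UTR",
    "utr3": "3' UTR",
    "noncoding_transcript": "Noncoding (retained intron)",
    "intronic": "Intronic",
    "intergenic": "Intergenic",
}


def location_label(category: str) -> str:
    """Human-readable location column (coding categories print as Exonic)."""
    if category in CODING_CATEGORIES:
        return "Exonic"
    return _LOCATION_LABELS.get(category, category)


def _note(a: AnnotatedVariant) -> str:
    cat = a.category
    if cat == "frameshift":
        return "Frameshift leading to truncation of protein"
    if cat == "stop_gained" and a.variant.variant_class != "snv":
        return "Gain of stop codon leading to truncation of protein"
    if cat == "stop_lost":
        return "Loss of stop codon"
    if cat == "inframe_indel":
        return "In-frame indel"
    return ""


@dataclass(frozen=True)
class LinkageEntry:
    gene: str
    pos: int
    variant_class: str
    zygosity: str
    category: str
    location: str
    note: str

    @property
    def coding(self) -> bool:
        return self.category in CODING_CATEGORIES


@dataclass
class LinkageReport:
    """All classified same-chromosome calls, split by distance to the candidate."""

    candidate_key: tuple[str, int, str]
    window_bp: int
    in_window: list[LinkageEntry]
    rest_of_chromosome: list[LinkageEntry]

    @property
    def coding_in_window(self) -> list[LinkageEntry]:
        return [e for e in self.in_window if e.coding]

    @property
    def coding_in_rest(self) -> list[LinkageEntry]:
        return [e for e in self.rest_of_chromosome if e.coding]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for where, entries in (
            ("in_window", self.in_window),
            ("rest_of_chromosome", self.rest_of_chromosome),
        ):
            for e in entries:
                rows.append(
                    {
                        "region": where,
                        "gene": e.gene,
                        "pos": e.pos,
                        "type": e.variant_class,
                        "location": e.location,
                        "zygosity": e.zygosity,
                        "consequence": e.note if e.coding else "",
                        "category": e.category,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "region", "gene", "pos", "type", "location",
                "zygosity", "consequence", "category",
            ],
        )


def build_linkage_report(
    candidate: AnnotatedVariant | VariantCall,
    calls: Sequence[VariantCall],
    models: GeneModelSet,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> LinkageReport:
    """Classify every other call on the candidate's chromosome.

    ``calls`` should be post-subtraction survivors (private to the mutant),
    including indels. Entries within ``window_bp`` of the candidate (absolute
    distance) land in the window partition, all others in the remainder.
    """
    v = candidate.variant if isinstance(candidate, AnnotatedVariant) else candidate
    ckey = variant_key(v)
    in_window: list[LinkageEntry] = []
    rest: list[LinkageEntry] = []
    for call in sorted(calls, key=lambda c: (int(c.pos), c.alt)):
        if str(call.chrom) != str(v.chrom) or variant_key(call) == ckey:
            continue
        ann = annotate(call, models)
        entry = LinkageEntry(
            gene=ann.gene_name or "",
            pos=call.pos,
            variant_class=call.variant_class,
            zygosity=call.genotype,
            category=ann.category,
            location=location_label(ann.category),
            note=_note(ann),
        )
        if abs(call.pos - v.pos) <= window_bp:
            in_window.append(entry)
        else:
            rest.append(entry)
    return LinkageReport(ckey, window_bp, in_window, rest)


def count_candidates_on_chromosome(
    candidates: Sequence[AnnotatedVariant | VariantCall], chrom: str
) -> int:
    """Number of final candidates on the stated chromosome."""
    n = 0
    for c in candidates:
        v = c.variant if isinstance(c, AnnotatedVariant) else c
        n += str(v.chrom) == str(chrom)
    return n
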