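"""The causal-candidate filtration cascade, with per-step survivor accounting.

The funnel mirrors the analysis that reduced the raw exome call sets of an
ENU mutant and its un-mutagenized background strain to a single confirmed
candidate: subtract calls shared with the background strain, subtract
known-variant panels (pre-existing strain polymorphisms), apply quality
thresholds, annotate consequences, drop intronic/intergenic calls, keep
stop/nonsynonymous/essential-splice SNVs, and (optionally) confront the
survivors with independent validation genotypes. Indels are excluded from the
candidate list but preserved in a side channel for linkage exclusion, and
candidates sitting close to an indel call are flagged as likely alignment
artifacts — the dominant false-positive mode of this kind of screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .consequence import (
    SELECTED_CATEGORIES,
    AnnotatedVariant,
    annotate_variants,
    annotations_frame,
)
from .errors import ParameterError, ValidationCompletenessError
from .variants import (
    GeneModelSet,
    ValidationGenotype,
    VariantCall,
    read_gene_models,
    read_validation_genotypes,
    read_variant_calls,
    variant_key,
)


@dataclass(frozen=True)
class QualityThresholds:
    """Numeric limits of the two quality-filter stages.

    Stage A keeps calls with SNP quality >= ``min_snp_quality`` (inclusive:
    a "lower limit"); stage B further requires mapping quality strictly
    greater than ``min_mapping_quality`` and read depth strictly greater than
    ``min_read_depth``. Consensus quality is never filtered on (it is carried
    through for reporting only). Calls with a missing metric fail the relevant
    stage unless ``missing_fails`` is switched off.
    """

    min_snp_quality: float = 20.0
    min_mapping_quality: float = 45.0
    min_read_depth: int = 10
    missing_fails: bool = True

    def __post_init__(self) -> None:
        if min(self.min_snp_quality, self.min_mapping_quality, self.min_read_depth) < 0:
            raise ParameterError("quality thresholds must be non-negative")

    def _missing(self) -> bool:
        """Truth value a missing metric contributes to a filter."""
        return not self.missing_fails

    def passes_stage_a(self, v: VariantCall) -> bool:
        if v.snp_quality is None:
            return self._missing()
        return v.snp_quality >= self.min_snp_quality

    def passes_stage_b(self, v: VariantCall) -> bool:
        if v.mapping_quality is None or v.read_depth is None:
            if v.mapping_quality is None and not self._missing():
                return False
            if v.read_depth is None and not self._missing():
                return False
        ok_mq = True if v.mapping_quality is None else v.mapping_quality > self.min_mapping_quality
        ok_dp = True if v.read_depth is None else v.read_depth > self.min_read_depth
        return ok_mq and ok_dp


@dataclass(frozen=True)
class IndelProximityFlag:
    """Distance from a candidate to the nearest raw indel call."""

    candidate_key: tuple[str, int, str]
    nearest_indel_key: tuple[str, int, str] | None
    distance: int | None
    window: int

    @property
    def flagged(self) -> bool:
        return self.distance is not None and self.distance <= self.window


REJECTION_REASONS = (
    "identical_to_background",
    "indel_misalignment",
    "miscalled_zygosity",
    "missing_data",
)


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of confronting one candidate with its validation genotypes."""

    candidate: AnnotatedVariant
    confirmed: bool
    reason: str | None  # one of REJECTION_REASONS when not confirmed


# ---------------------------------------------------------------------------
# Individual funnel steps
# ---------------------------------------------------------------------------

def subtract_shared(
    mutant: Sequence[VariantCall], background: Iterable[VariantCall]
) -> list[VariantCall]:
    """Remove mutant calls whose key also occurs in the background strain."""
    bg = {variant_key(v) for v in background}
    return [v for v in mutant if variant_key(v) not in bg]


def subtract_known(
    calls: Sequence[VariantCall], panels: Iterable[Iterable[VariantCall]]
) -> list[VariantCall]:
    """Remove calls present in any known-variant panel (position + allele)."""
    known: set[tuple[str, int, str]] = set()
    for panel in panels:
        known.update(variant_key(v) for v in panel)
    return [v for v in calls if variant_key(v) not in known]


def apply_quality_filters(
    calls: Sequence[VariantCall], thresholds: QualityThresholds | None = None
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Two-stage quality filter; returns (stage-A survivors, stage-B survivors)."""
    thresholds = thresholds or QualityThresholds()
    stage_a = [v for v in calls if thresholds.passes_stage_a(v)]
    stage_b = [v for v in stage_a if thresholds.passes_stage_b(v)]
    return stage_a, stage_b


def remove_noncoding(annotated: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Drop intronic and intergenic calls; essential splice sites are kept
    despite their intronic coordinates."""
    return [a for a in annotated if a.category not in ("intronic", "intergenic")]


def select_candidates(annotated: Sequence[AnnotatedVariant]) -> list[AnnotatedVariant]:
    """Keep SNVs predicted to gain/lose a stop, change an amino acid, or hit
    an essential splice site. Indels and milder categories are excluded here
    (indels are carried separately for linkage exclusion)."""
    return [
        a
        for a in annotated
        if a.variant.variant_class == "snv" and a.category in SELECTED_CATEGORIES
    ]


def flag_indel_proximal(
    candidates: Sequence[AnnotatedVariant | VariantCall],
    indel_calls: Sequence[VariantCall],
    window_bp: int = 20,
) -> list[IndelProximityFlag]:
    """Flag candidates lying within ``window_bp`` of any raw indel call.

    SNVs called either side of a small indel are the dominant false-positive
    mode; distance is measured between anchored positions.
    """
    flags = []
    for c in candidates:
        v = c.variant if isinstance(c, AnnotatedVariant) else c
        nearest: VariantCall | None = None
        best: int | None = None
        for ind in indel_calls:
            if str(ind.chrom) != str(v.chrom):
                continue
            d = abs(int(ind.pos) - int(v.pos))
            if best is None or d < best:
                best, nearest = d, ind
        flags.append(
            IndelProximityFlag(
                candidate_key=variant_key(v),
                nearest_indel_key=variant_key(nearest) if nearest else None,
                distance=best,
                window=window_bp,
            )
        )
    return flags


def confirm_with_validation(
    candidates: Sequence[AnnotatedVariant],
    validation: Sequence[ValidationGenotype],
) -> list[ValidationResult]:
    """Confront candidates with independent (capillary-style) genotypes.

    A candidate is confirmed iff the mutant re-genotype contains the alternate
    allele, the background re-genotype does not, and neither call is symbolic
    (deletion/insertion/missing). Everything else is labelled a false positive
    with a reason code.
    """
    index = {r.key: r for r in validation}
    results = []
    for c in candidates:
        v = c.variant if isinstance(c, AnnotatedVariant) else c
        rec = index.get(variant_key(v))
        if rec is None:
            raise ValidationCompletenessError(
                f"candidate {v.chrom}:{v.pos} {v.ref}>{v.alt} has no validation record"
            )
        calls = (rec.background_call, rec.mutant_call)
        if any(call in ("deletion", "insertion") for call in calls):
            results.append(ValidationResult(c, False, "indel_misalignment"))
        elif any(call == "missing" for call in calls):
            results.append(ValidationResult(c, False, "missing_data"))
        elif rec.mutant_has_alt() and not rec.background_has_alt():
            results.append(ValidationResult(c, True, None))
        elif rec.mutant_call == rec.background_call:
            results.append(ValidationResult(c, False, "identical_to_background"))
        else:
            results.append(ValidationResult(c, False, "miscalled_zygosity"))
    return results


def confirmed_candidates(results: Iterable[ValidationResult]) -> list[AnnotatedVariant]:
    return [r.candidate for r in results if r.confirmed]


def count_heterozygous(candidates: Sequence[AnnotatedVariant | VariantCall]) -> int:
    """Number of candidates called heterozygous in the mutant sample —
    the genotype a dominant induced mutation is expected to show."""
    n = 0
    for c in candidates:
        v = c.variant if isinstance(c, AnnotatedVariant) else c
        n += v.genotype == "het"
    return n


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------

STEP_NAMES = (
    "mutant calls",
    "not shared with background",
    "not in known panels",
    "snp quality filter",
    "mapping quality and depth filter",
    "coding, UTR or splice region",
    "candidate SNVs (stop/nonsynonymous/splice)",
    "confirmed by validation",
)


@dataclass
class FunnelReport:
    """Ordered per-step survivor counts plus the final candidate list."""

    steps: list[tuple[str, int]]
    candidates: list[AnnotatedVariant]
    indel_side_channel: list[AnnotatedVariant] = field(default_factory=list)
    proximity_flags: list[IndelProximityFlag] = field(default_factory=list)
    validation: list[ValidationResult] | None = None

    def __post_init__(self) -> None:
        counts = [n for _, n in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ParameterError(f"funnel counts are not non-increasing: {counts}")
        final = self.steps[-1][1]
        expect = len(self.confirmed) if self.validation is not None else len(self.candidates)
        if final != expect:
            raise ParameterError("final survivor count disagrees with candidate list")

    @property
    def confirmed(self) -> list[AnnotatedVariant]:
        return confirmed_candidates(self.validation or [])

    def steps_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "count"])

    def candidates_frame(self) -> pd.DataFrame:
        flagged = {f.candidate_key for f in self.proximity_flags if f.flagged}
        status = {}
        if self.validation is not None:
            for r in self.validation:
                key = variant_key(r.candidate.variant)
                status[key] = "confirmed" if r.confirmed else r.reason
        rows = []
        for a in self.candidates:
            v = a.variant
            key = variant_key(v)
            rows.append(
                {
                    "gene": a.gene_name or "",
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "category": a.category,
                    "detail": a.consequence.detail,
                    "genotype": v.genotype,
                    "consensus_quality": v.consensus_quality,
                    "snp_quality": v.snp_quality,
                    "mapping_quality": v.mapping_quality,
                    "read_depth": v.read_depth,
                    "indel_proximal": key in flagged,
                    "validation": status.get(key, ""),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "chrom", "pos", "ref", "alt", "category", "detail",
                "genotype", "consensus_quality", "snp_quality",
                "mapping_quality", "read_depth", "indel_proximal", "validation",
            ],
        )

    def to_tsv(self) -> str:
        """Deterministic serialization (steps, candidates, indel channel)."""
        parts = [
            self.steps_frame().to_csv(sep="\t", index=False),
            self.candidates_frame().to_csv(sep="\t", index=False),
            annotations_frame(self.indel_side_channel).to_csv(sep="\t", index=False),
        ]
        return "\n".join(parts)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.steps_frame().to_csv(out / "funnel_report.tsv", sep="\t", index=False)
        self.candidates_frame().to_csv(out / "candidates.tsv", sep="\t", index=False)
        annotations_frame(self.indel_side_channel).to_csv(
            out / "indels.tsv", sep="\t", index=False
        )

    def summary(self) -> str:
        lines = ["funnel survivor counts:"]
        for name, n in self.steps:
            lines.append(f"  {name:<42s} {n}")
        lines.append(f"heterozygous candidates: {count_heterozygous(self.candidates)}")
        if self.validation is not None:
            lines.append(f"confirmed candidates: {len(self.confirmed)}")
        return "\n".join(lines)


def run_funnel_calls(
    mutant_calls: Sequence[VariantCall],
    background_calls: Sequence[VariantCall],
    panels: Sequence[Sequence[VariantCall]],
    models: GeneModelSet,
    thresholds: QualityThresholds | None = None,
    validation: Sequence[ValidationGenotype] | None = None,
    indel_window: int = 20,
) -> FunnelReport:
    """Run the full cascade on in-memory call sets."""
    thresholds = thresholds or QualityThresholds()
    steps: list[tuple[str, int]] = [(STEP_NAMES[0], len(mutant_calls))]

    private = subtract_shared(mutant_calls, background_calls)
    steps.append((STEP_NAMES[1], len(private)))

    unknown = subtract_known(private, panels)
    steps.append((STEP_NAMES[2], len(unknown)))

    stage_a, stage_b = apply_quality_filters(unknown, thresholds)
    steps.append((STEP_NAMES[3], len(stage_a)))
    steps.append((STEP_NAMES[4], len(stage_b)))

    annotated = annotate_variants(stage_b, models)
    regioned = remove_noncoding(annotated)
    steps.append((STEP_NAMES[5], len(regioned)))

    candidates = select_candidates(regioned)
    steps.append((STEP_NAMES[6], len(candidates)))

    indel_channel = [a for a in annotated if a.variant.variant_class != "snv"]
    raw_indels = [
        v
        for v in list(mutant_calls) + list(background_calls)
        if v.variant_class != "snv"
    ]
    flags = flag_indel_proximal(candidates, raw_indels, indel_window)

    results = None
    if validation is not None:
        results = confirm_with_validation(candidates, validation)
        steps.append((STEP_NAMES[7], len(confirmed_candidates(results))))

    return FunnelReport(
        steps=steps,
        candidates=candidates,
        indel_side_channel=indel_channel,
        proximity_flags=flags,
        validation=results,
    )


def run_funnel(
    mutant_vcf: str | Path,
    background_vcf: str | Path,
    panel_vcfs: Sequence[str | Path],
    gff_path: str | Path,
    fasta_path: str | Path,
    thresholds: QualityThresholds | None = None,
    validation_tsv: str | Path | None = None,
    indel_window: int = 20,
) -> FunnelReport:
    """Load the inputs from disk and run the cascade."""
    mutant = read_variant_calls(mutant_vcf)
    background = read_variant_calls(background_vcf)
    panels = [read_variant_calls(p) for p in panel_vcfs]
    models = read_gene_models(gff_path, fasta_path)
    validation = (
        read_validation_genotypes(validation_tsv) if validation_tsv is not None else None
    )
    return run_funnel_calls(
        mutant, background, panels, models, thresholds, validation, indel_window
    )
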