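"""Published results of the dearisch (*Isl1*, Drsh) exome screen, as data.

The dearisch mouse is an ENU-induced mutant with low-penetrance otitis media
on a C3HeB/FeJ background whose causal change — a heterozygous Tyr-to-Cys
missense SNV in *Isl1* on chromosome 13 (13:117098488, T>C) — was found by
exome resequencing without linkage mapping. Three published summary tables
are packaged here so the downstream statistics can be recomputed exactly:

* the 23 candidate SNVs that survived the filtration funnel, with both
  samples' call qualities and the capillary re-sequencing genotypes used to
  adjudicate them;
* all private chromosome-13 calls (SNVs and indels) used for linkage
  exclusion, with their published location labels;
* the colony segregation table (genotype x hearing class per cross), which
  is expanded back into one record per animal. Hearing classes map to
  representative click thresholds (20 / 40 / 65 dB SPL) that reproduce the
  published class boundaries; one published sex split (37 animals printed as
  23 m / 15 f) is internally inconsistent and is expanded as 23 m / 14 f.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consequence import AnnotatedVariant, Consequence
from .variants import CohortRecord, ValidationGenotype, VariantCall, normalize_call

#: chromosome and position of the confirmed causal missense change
ISL1_CHROM = "13"
ISL1_POS = 117_098_488


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("exomefunnel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str}, keep_default_na=False)


def dearisch_candidates() -> pd.DataFrame:
    """The 23 filtered candidate SNVs with both samples' quality metrics,
    capillary re-genotyping calls and adjudication comments."""
    return _read_table("dearisch_candidates.tsv")


def dearisch_candidate_calls() -> list[AnnotatedVariant]:
    """The candidates as annotated variant calls (mutant-sample metrics)."""
    out = []
    for row in dearisch_candidates().itertuples(index=False):
        v = VariantCall(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            genotype=row.mut_genotype,
            consensus_quality=float(row.mut_consensus_quality),
            snp_quality=float(row.mut_snp_quality),
            mapping_quality=float(row.mut_mapping_quality),
            read_depth=int(row.mut_read_depth),
        )
        out.append(
            AnnotatedVariant(
                variant=v,
                consequence=Consequence(row.category, row.aa_change or ""),
                gene_name=row.gene,
            )
        )
    return out


def dearisch_validation() -> list[ValidationGenotype]:
    """Capillary re-genotyping of the 23 candidate sites in both DNA samples."""
    out = []
    for row in dearisch_candidates().itertuples(index=False):
        out.append(
            ValidationGenotype(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                background_call=normalize_call(row.cap_background),
                mutant_call=normalize_call(row.cap_mutant),
            )
        )
    return out


def dearisch_chr13_calls() -> pd.DataFrame:
    """All private chromosome-13 calls (SNVs and indels) with published
    location labels, used for the linkage-exclusion analysis around *Isl1*."""
    return _read_table("dearisch_chr13_calls.tsv")


# Colony segregation table: {cross: {genotype: {class: (n, n_male)}}}
_CROSS_COUNTS = {
    "het_x_het": {
        "wt": {"unaffected": (37, 23), "intermediate": (2, 1), "affected": (0, 0)},
        "het": {"unaffected": (32, 25), "intermediate": (21, 13), "affected": (19, 13)},
        "hom": {"unaffected": (0, 0), "intermediate": (0, 0), "affected": (0, 0)},
    },
    "het_x_wt": {
        "wt": {"unaffected": (35, 19), "intermediate": (1, 1), "affected": (0, 0)},
        "het": {"unaffected": (27, 15), "intermediate": (13, 8), "affected": (9, 6)},
        "hom": {"unaffected": (0, 0), "intermediate": (0, 0), "affected": (0, 0)},
    },
}

_CLASS_THRESHOLD = {"unaffected": 20.0, "intermediate": 40.0, "affected": 65.0}


def dearisch_cohort() -> list[CohortRecord]:
    """The colony cohort expanded to one record per animal.

    Each animal gets the representative click threshold of its hearing class,
    so re-tabulating the cohort reproduces the published counts exactly.
    """
    records = []
    i = 0
    for cross, by_genotype in _CROSS_COUNTS.items():
        for genotype, by_class in by_genotype.items():
            for cls, (n, n_male) in by_class.items():
                for k in range(n):
                    i += 1
                    records.append(
                        CohortRecord(
                            animal_id=f"drsh{i:04d}",
                            cross_type=cross,
                            genotype=genotype,
                            sex="m" if k < n_male else "f",
                            click_threshold=_CLASS_THRESHOLD[cls],
                        )
                    )
    return records
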