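"""Seeded generators for every input the pipeline consumes, with truth labels.

The scenario generator emulates the statistical structure of an ENU-mutant
exome screen at desk scale: a large stratum of variants shared by the mutant
and its un-mutagenized background strain against the reference genome,
known-panel polymorphisms, low-quality calls, private-but-benign calls
(noncoding, synonymous), clusters of artifact SNVs flanking small indels (the
dominant false-positive mode of short-read SNV calling around indels), and a
single planted heterozygous causal missense SNV with high quality metrics.
Every mutant call carries a truth label so recovery can be scored exactly.

The cohort generator emulates segregation of a dominant, partially penetrant
allele with homozygote lethality: genotypes drawn per cross, and a bimodal
click-threshold distribution whose class mixture is genotype-dependent. The
distribution parameters are this package's choices, constrained only by the
qualitative shape of real colony data (a normal-hearing peak below 30 dB SPL
and a spread of raised thresholds between 50 and 80 dB SPL).

All randomness in a generator flows from a single seed through a splittable
seed sequence; outputs are byte-identical per seed, and emitted files record
the seed in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ConfigError, DataError
from .variants import (
    CohortRecord,
    GeneModelSet,
    TranscriptModel,
    ValidationGenotype,
    VariantCall,
    reverse_complement,
    variant_key,
    write_validation_genotypes,
    write_variant_calls,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Variant-scenario generator settings (counts per truth stratum)."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 60_000
    n_genes: int = 14
    noncoding_gene_fraction: float = 0.15
    n_shared_variants: int = 120
    n_panel_variants: int = 40
    n_panels: int = 2
    n_panel_only: int = 10  # per panel, sites absent from the mutant
    n_background_private: int = 25
    n_low_quality: int = 12
    n_noncoding: int = 10
    n_synonymous: int = 6
    n_indel_clusters: int = 3
    n_flanking_artifacts: int = 2  # artifact SNVs per indel cluster
    artifact_spacing: int = 8  # bp from indel anchor to each artifact SNV
    causal_gene: str | None = None  # auto-selected when None
    causal_target: str = "Y:C"  # preferred amino-acid change
    causal_genotype: str = "het"
    # consensus, SNP, mapping quality and read depth of the planted causal call
    causal_qualities: tuple[float, float, float, int] = (199.0, 228.0, 60.0, 66)

    def validate(self) -> "ScenarioConfig":
        numeric = (
            self.n_chromosomes, self.chromosome_length, self.n_genes,
            self.n_shared_variants, self.n_panel_variants, self.n_panels,
            self.n_panel_only, self.n_background_private, self.n_low_quality,
            self.n_noncoding, self.n_synonymous, self.n_indel_clusters,
            self.n_flanking_artifacts, self.artifact_spacing,
        )
        if any(x < 0 for x in numeric):
            raise ConfigError("scenario counts must be non-negative")
        if self.n_chromosomes < 1 or self.chromosome_length < 2_000:
            raise ConfigError("need at least one chromosome of >= 2 kb")
        if self.causal_genotype not in ("het", "hom_alt"):
            raise ConfigError(f"bad causal genotype {self.causal_genotype!r}")
        return self


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings.

    ``pi_affected``/``pi_intermediate`` are the true class probabilities for
    heterozygotes; wild types leak into the intermediate class with a small
    probability (a few real wild types sit just above the unaffected cut).
    Thresholds are drawn per class: unaffected ~ Normal(22, 4) truncated to
    [0, 30] dB SPL, affected ~ Normal(65, 9) truncated to [50, 97], and
    intermediate ~ Uniform(31, 49), so draws respect the class boundaries.
    """

    seed: int = 0
    n_het_x_het: int = 111
    n_het_x_wt: int = 85
    pi_affected: float = 0.231
    pi_intermediate: float = 0.28
    hom_viability: float = 0.0
    wt_intermediate_leak: float = 0.04
    mu_unaffected: float = 22.0
    sd_unaffected: float = 4.0
    unaffected_range: tuple[float, float] = (0.0, 30.0)
    mu_affected: float = 65.0
    sd_affected: float = 9.0
    affected_range: tuple[float, float] = (50.0, 97.0)
    intermediate_range: tuple[float, float] = (31.0, 49.0)

    def validate(self) -> "CohortConfig":
        if self.pi_affected < 0 or self.pi_intermediate < 0:
            raise ConfigError("class probabilities must be non-negative")
        if self.pi_affected + self.pi_intermediate > 1.0:
            raise ConfigError("pi_affected + pi_intermediate must be <= 1")
        if not 0.0 <= self.hom_viability <= 1.0:
            raise ConfigError("hom_viability must be in [0, 1]")
        if not 0.0 <= self.wt_intermediate_leak <= 1.0:
            raise ConfigError("wt_intermediate_leak must be in [0, 1]")
        return self


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

@dataclass
class _BuiltGene:
    """A gene region in local 1-based coordinates (already strand-oriented)."""

    region_seq: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    strand: str
    biotype: str


def _split_lengths(
    rng: np.random.Generator, total: int, pieces: int, min_len: int = 6
) -> list[int]:
    if total < pieces * min_len:
        raise ConfigError(f"cannot split {total} bases into {pieces} exons")
    extra = rng.multinomial(total - pieces * min_len, [1.0 / pieces] * pieces)
    return [min_len + int(e) for e in extra]


def _flip_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return sorted((length - e + 1, length - s + 1) for s, e in intervals)


def _build_gene(
    rng: np.random.Generator,
    *,
    strand: str,
    biotype: str = "protein_coding",
    n_codons: int = 60,
    n_exons: int = 3,
    utr5_len: int = 25,
    utr3_len: int = 25,
    intron_len_range: tuple[int, int] = (30, 80),
    force_tyr: bool = False,
) -> _BuiltGene:
    """Assemble one gene region: UTRs, a CDS that is a multiple of 3 with
    proper start/stop and no internal stop, split over ``n_exons`` exons with
    GT..AG introns. Built in transcript orientation, then mirrored for minus
    strand genes."""
    if biotype == "protein_coding":
        if n_codons < 3:
            raise ConfigError("need at least start + 1 + stop codons")
        body = [
            _SENSE_CODONS[i]
            for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
        ]
        if force_tyr and n_codons >= 4:
            body[int(rng.integers(1, len(body)))] = "TAT"
        cds_seq = "ATG" + "".join(body) + _STOPS[int(rng.integers(0, 3))]
        exonic = _random_seq(rng, utr5_len) + cds_seq + _random_seq(rng, utr3_len)
        cds_lo, cds_hi = utr5_len + 1, utr5_len + 3 * n_codons
    else:
        exonic = _random_seq(rng, utr5_len + 3 * n_codons + utr3_len)
        cds_lo = cds_hi = 0

    pieces = _split_lengths(rng, len(exonic), n_exons)
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    piece_map: list[tuple[int, int, int]] = []  # exonic start/end, region start
    pos = 1
    exonic_cursor = 0
    for i, plen in enumerate(pieces):
        exons.append((pos, pos + plen - 1))
        piece_map.append((exonic_cursor + 1, exonic_cursor + plen, pos))
        parts.append(exonic[exonic_cursor : exonic_cursor + plen])
        exonic_cursor += plen
        pos += plen
        if i < n_exons - 1:
            ilen = int(rng.integers(*intron_len_range))
            parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
            pos += ilen
    region = "".join(parts)

    cds: list[tuple[int, int]] = []
    if cds_hi:
        for ex_s, ex_e, reg_s in piece_map:
            lo, hi = max(ex_s, cds_lo), min(ex_e, cds_hi)
            if lo <= hi:
                cds.append((reg_s + lo - ex_s, reg_s + hi - ex_s))

    if strand == "-":
        length = len(region)
        return _BuiltGene(
            region_seq=reverse_complement(region),
            exons=_flip_intervals(exons, length),
            cds=_flip_intervals(cds, length),
            strand=strand,
            biotype=biotype,
        )
    return _BuiltGene(region, exons, cds, strand, biotype)


class _GenomeBuilder:
    """Accumulates chromosomes as mutable base lists and placed transcripts."""

    def __init__(self) -> None:
        self.sequences: dict[str, list[str]] = {}
        self.transcripts: list[TranscriptModel] = []
        self._counter = 0

    def new_chromosome(self, name: str, rng: np.random.Generator, length: int) -> None:
        self.sequences[name] = list(_random_seq(rng, length))

    def place(self, chrom: str, offset: int, built: _BuiltGene, gene_name: str | None = None) -> TranscriptModel:
        """Paste a built gene region at 1-based ``offset``."""
        seq = self.sequences[chrom]
        region = built.region_seq
        if offset < 1 or offset - 1 + len(region) > len(seq):
            raise ConfigError(
                f"gene of {len(region)} bp does not fit at {chrom}:{offset}"
            )
        seq[offset - 1 : offset - 1 + len(region)] = list(region)
        self._counter += 1
        shift = offset - 1
        t = TranscriptModel(
            transcript_id=f"tx{self._counter:03d}",
            gene_name=gene_name or f"G{self._counter:03d}",
            chrom=chrom,
            strand=built.strand,
            exons=tuple((s + shift, e + shift) for s, e in built.exons),
            cds=tuple((s + shift, e + shift) for s, e in built.cds),
            biotype=built.biotype,
        )
        self.transcripts.append(t)
        return t

    def finish(self) -> GeneModelSet:
        reference = {name: "".join(seq) for name, seq in self.sequences.items()}
        return GeneModelSet(list(self.transcripts), reference).validate()


def generate_reference_and_genes(config: ScenarioConfig) -> GeneModelSet:
    """Random reference with ORF-bearing multi-exon genes on both strands.

    Deterministic per seed; every CDS is a positive multiple of 3 with proper
    start/stop, so the result always passes gene-model validation. The first
    protein-coding gene is guaranteed to contain an interior tyrosine codon so
    a Tyr->Cys causal change can always be planted.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    builder = _GenomeBuilder()
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    first_coding_placed = False
    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        builder.new_chromosome(chrom, rng, config.chromosome_length)
        cursor = int(rng.integers(300, 800))
        for _ in range(per_chrom[ci]):
            coding = rng.random() >= config.noncoding_gene_fraction
            built = _build_gene(
                rng,
                strand="+" if rng.random() < 0.5 else "-",
                biotype="protein_coding" if coding else "noncoding",
                n_codons=int(rng.integers(40, 81)),
                n_exons=int(rng.integers(2, 5)),
                utr5_len=int(rng.integers(15, 41)),
                utr3_len=int(rng.integers(15, 41)),
                force_tyr=coding and not first_coding_placed,
            )
            if coding:
                first_coding_placed = True
            builder.place(chrom, cursor, built)  # raises ConfigError when full
            cursor += len(built.region_seq) + int(rng.integers(250, 900))
    return builder.finish()


# ---------------------------------------------------------------------------
# Codon-level placement helpers
# ---------------------------------------------------------------------------

def _codon_genomic_positions(t: TranscriptModel, codon_i: int) -> list[int]:
    """Genomic positions (ascending transcript order) of codon ``codon_i``."""
    positions = t.cds_positions
    idxs = range(3 * codon_i, 3 * codon_i + 3)
    if t.strand == "+":
        return [positions[i] for i in idxs]
    n = len(positions)
    return [positions[n - 1 - i] for i in idxs]


def _transcript_base(models: GeneModelSet, t: TranscriptModel, gpos: int) -> str:
    base = models.sequence(t.chrom)[gpos - 1]
    return reverse_complement(base) if t.strand == "-" else base


def _genomic_allele(t: TranscriptModel, base_transcript_orient: str) -> str:
    return (
        reverse_complement(base_transcript_orient)
        if t.strand == "-"
        else base_transcript_orient
    )


def _find_codons(models: GeneModelSet, t: TranscriptModel, targets: set[str]) -> list[int]:
    """Interior codon indices (not start, not stop) whose codon is in targets."""
    cds = models.coding_sequence(t)
    out = []
    for i in range(1, len(cds) // 3 - 1):
        if cds[3 * i : 3 * i + 3] in targets:
            out.append(i)
    return out


def _aa_changing_alt(
    models: GeneModelSet,
    t: TranscriptModel,
    gpos: int,
    rng: np.random.Generator,
    *,
    want_stop: bool | None = False,
) -> str | None:
    """A genomic ALT base at CDS position ``gpos`` that changes the amino acid.

    ``want_stop=False`` additionally avoids creating a stop codon;
    ``want_stop=None`` accepts any amino-acid change.
    """
    idx = t.cds_index(gpos)
    codon_i, within = divmod(idx, 3)
    cds = models.coding_sequence(t)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    ref_aa = _translate(codon)
    for b in rng.permutation(list(_BASES)):
        if b == codon[within]:
            continue
        mutant = codon[:within] + b + codon[within + 1 :]
        alt_aa = _translate(mutant)
        if alt_aa == ref_aa:
            continue
        if want_stop is False and alt_aa == "*":
            continue
        if want_stop is True and alt_aa != "*":
            continue
        return _genomic_allele(t, b)
    return None


def _synonymous_site(
    models: GeneModelSet, t: TranscriptModel, rng: np.random.Generator
) -> tuple[int, str] | None:
    """A (genomic position, genomic alt) pair giving a synonymous change."""
    cds = models.coding_sequence(t)
    n_codons = len(cds) // 3
    for codon_i in rng.permutation(np.arange(1, n_codons - 1)):
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        aa = _translate(codon)
        for b in rng.permutation(list(_BASES)):
            if b == codon[2]:
                continue
            if _translate(codon[:2] + b) == aa:
                gpos = _codon_genomic_positions(t, int(codon_i))[2]
                return gpos, _genomic_allele(t, b)
    return None


# ---------------------------------------------------------------------------
# Variant scenario
# ---------------------------------------------------------------------------

TRUTH_LABELS = (
    "shared",
    "panel",
    "low_quality",
    "noncoding",
    "synonymous",
    "indel",
    "indel_artifact",
    "causal",
)


@dataclass
class Scenario:
    """A generated screen: call sets, panels, gene models and truth labels."""

    config: ScenarioConfig
    models: GeneModelSet
    mutant_calls: list[VariantCall]
    background_calls: list[VariantCall]
    panels: list[list[VariantCall]]
    truth: pd.DataFrame  # columns chrom, pos, ref, alt, label

    @property
    def causal(self) -> VariantCall:
        row = self.truth[self.truth["label"] == "causal"].iloc[0]
        key = (str(row["chrom"]), int(row["pos"]), row["alt"])
        for v in self.mutant_calls:
            if variant_key(v) == key:
                return v
        raise DataError("causal call missing from mutant list")  # pragma: no cover

    def truth_label(self, v: VariantCall) -> str:
        key = variant_key(v)
        m = self.truth[
            (self.truth["chrom"] == key[0])
            & (self.truth["pos"] == key[1])
            & (self.truth["alt"] == key[2])
        ]
        if m.empty:
            raise DataError(f"no truth label for {key}")
        return str(m.iloc[0]["label"])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, VCFs, truth and validation TSVs; byte-identical
        per seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seed_line = f"##scenario_seed={self.config.seed}"
        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "genes.gff3",
            "mutant": out / "mutant.vcf",
            "background": out / "background.vcf",
            "truth": out / "truth.tsv",
            "validation": out / "validation.tsv",
        }
        write_fasta(self.models.reference, paths["fasta"], seed=self.config.seed)
        write_gff3(self.models, paths["gff3"], seed=self.config.seed)
        write_variant_calls(
            self.mutant_calls, paths["mutant"],
            reference=self.models.reference, sample="mutant",
            extra_header=[seed_line],
        )
        write_variant_calls(
            self.background_calls, paths["background"],
            reference=self.models.reference, sample="background",
            extra_header=[seed_line],
        )
        for i, panel in enumerate(self.panels, start=1):
            p = out / f"panel_{i}.vcf"
            paths[f"panel_{i}"] = p
            write_variant_calls(
                panel, p, reference=self.models.reference,
                sample=f"panel{i}", extra_header=[seed_line],
            )
        with open(paths["truth"], "w") as fh:
            fh.write(f"# seed={self.config.seed}\n")
            self.truth.to_csv(fh, sep="\t", index=False)
        write_validation_genotypes(
            generate_validation_genotypes(self), paths["validation"]
        )
        return paths


class _PositionLedger:
    """Tracks occupied positions and exclusion zones around planted indels."""

    def __init__(self) -> None:
        self.used: dict[str, set[int]] = {}
        self.zones: list[tuple[str, int, int]] = []

    def free(self, chrom: str, pos: int, *, respect_zones: bool = True) -> bool:
        if pos in self.used.get(chrom, ()):
            return False
        if respect_zones:
            for zc, lo, hi in self.zones:
                if zc == chrom and lo <= pos <= hi:
                    return False
        return True

    def take(self, chrom: str, pos: int) -> None:
        self.used.setdefault(chrom, set()).add(pos)

    def add_zone(self, chrom: str, lo: int, hi: int) -> None:
        self.zones.append((chrom, lo, hi))


def _good_qualities(rng: np.random.Generator) -> dict:
    return {
        "consensus_quality": float(rng.integers(30, 200)),
        "snp_quality": float(rng.integers(25, 150)),
        "mapping_quality": float(rng.integers(46, 61)),
        "read_depth": int(rng.integers(11, 101)),
    }


def _low_qualities(rng: np.random.Generator) -> dict:
    q = _good_qualities(rng)
    mode = ("snp_quality", "mapping_quality", "read_depth")[int(rng.integers(0, 3))]
    if mode == "snp_quality":
        q["snp_quality"] = float(rng.integers(0, 20))
        q["consensus_quality"] = float(rng.integers(0, 20))
    elif mode == "mapping_quality":
        q["mapping_quality"] = float(rng.integers(10, 46))
    else:
        q["read_depth"] = int(rng.integers(0, 11))
    return q


def generate_variant_scenario(
    config: ScenarioConfig, models: GeneModelSet | None = None
) -> Scenario:
    """Generate mutant/background/panel call sets with a planted causal SNV."""
    config.validate()
    variant_ss = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(variant_ss)
    if models is None:
        models = generate_reference_and_genes(config)

    ledger = _PositionLedger()
    mutant: list[VariantCall] = []
    background: list[VariantCall] = []
    panels: list[list[VariantCall]] = [[] for _ in range(config.n_panels)]
    truth_rows: list[dict] = []
    chroms = sorted(models.reference, key=str)

    def ref_base(chrom: str, pos: int) -> str:
        return models.sequence(chrom)[pos - 1]

    def add_mutant(call: VariantCall, label: str) -> None:
        mutant.append(call)
        ledger.take(call.chrom, call.pos)
        truth_rows.append(
            {"chrom": call.chrom, "pos": call.pos, "ref": call.ref,
             "alt": call.alt, "label": label}
        )

    coding = [
        t for t in models.transcripts if t.biotype == "protein_coding" and t.cds
    ]
    if not coding and (config.n_indel_clusters or config.n_synonymous):
        raise ConfigError("scenario needs protein-coding genes")

    # --- planted causal SNV ------------------------------------------------
    causal_call: VariantCall | None = None
    candidates_t = coding
    if config.causal_gene is not None:
        candidates_t = [t for t in coding if t.gene_name == config.causal_gene]
        if not candidates_t:
            raise ConfigError(f"causal gene {config.causal_gene!r} not found")
    tyr = {"TAT", "TAC"} if config.causal_target == "Y:C" else set()
    placed = False
    for t in candidates_t:
        hits = _find_codons(models, t, tyr) if tyr else []
        if hits:
            codon_i = hits[int(rng.integers(0, len(hits)))]
            gpos = _codon_genomic_positions(t, codon_i)[1]  # middle base
            alt = _genomic_allele(t, "G")  # TAT->TGT / TAC->TGC: Tyr->Cys
            placed = True
            break
    if not placed:
        # fall back to any amino-acid-changing site in the first usable gene
        for t in candidates_t:
            cds_len = len(models.coding_sequence(t))
            for codon_i in rng.permutation(np.arange(1, cds_len // 3 - 1)):
                gpos = _codon_genomic_positions(t, int(codon_i))[1]
                alt_maybe = _aa_changing_alt(models, t, gpos, rng)
                if alt_maybe is not None:
                    alt = alt_maybe
                    placed = True
                    break
            if placed:
                break
    if not placed:
        raise ConfigError("gene set too short to place the causal variant")
    cq, sq, mq, dp = config.causal_qualities
    causal_call = VariantCall(
        chrom=t.chrom, pos=gpos, ref=ref_base(t.chrom, gpos), alt=alt,
        genotype=config.causal_genotype,
        consensus_quality=cq, snp_quality=sq, mapping_quality=mq, read_depth=dp,
    )
    add_mutant(causal_call, "causal")
    causal_transcript = t
    ledger.add_zone(t.chrom, gpos - 25, gpos + 25)

    # --- indel clusters with flanking artifact SNVs ------------------------
    spacing = config.artifact_spacing
    cluster_hosts = [
        (t2, (s, e))
        for t2 in coding
        if t2.gene_name != causal_transcript.gene_name
        for s, e in t2.cds
        if e - s + 1 >= 2 * spacing + 6
    ]
    if config.n_indel_clusters and not cluster_hosts:
        raise ConfigError("no CDS interval long enough for indel clusters")
    for k in range(config.n_indel_clusters):
        t2, (s, e) = cluster_hosts[int(rng.integers(0, len(cluster_hosts)))]
        chrom = t2.chrom
        center = int(rng.integers(s + spacing + 2, e - spacing - 1))
        if not ledger.free(chrom, center):
            continue
        seq = models.sequence(chrom)
        indel = VariantCall(
            chrom=chrom, pos=center,
            ref=seq[center - 1 : center + 1], alt=seq[center - 1],
            genotype="het" if rng.random() < 0.5 else "hom_alt",
            **_good_qualities(rng),
        )
        add_mutant(indel, "indel")
        # flanking miscalled SNVs inside the same CDS interval
        n_flank = min(config.n_flanking_artifacts, 2)
        offsets = ([-spacing, spacing] if n_flank == 2 else [spacing])
        for off in offsets:
            p = center + off
            alt2 = None
            for nudge in (0, -1, 1, -2, 2):
                q = p + nudge
                if not (s <= q <= e) or abs(q - center) > spacing or q == center:
                    continue
                if not ledger.free(chrom, q, respect_zones=False):
                    continue
                alt2 = _aa_changing_alt(models, t2, q, rng, want_stop=None)
                if alt2 is not None:
                    p = q
                    break
            if alt2 is None:
                continue
            add_mutant(
                VariantCall(
                    chrom=chrom, pos=p, ref=ref_base(chrom, p), alt=alt2,
                    genotype="het" if rng.random() < 0.7 else "hom_alt",
                    **_good_qualities(rng),
                ),
                "indel_artifact",
            )
        ledger.add_zone(chrom, center - 25, center + 25)

    # --- random free positions for the bulk strata -------------------------
    def random_free_position(*, respect_zones: bool = True) -> tuple[str, int]:
        for _ in range(10_000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, len(models.sequence(chrom)) + 1))
            if ledger.free(chrom, pos, respect_zones=respect_zones):
                return chrom, pos
        raise ConfigError("could not find a free genome position")  # pragma: no cover

    def random_snv(chrom: str, pos: int, qualities: dict, genotype=None) -> VariantCall:
        ref = ref_base(chrom, pos)
        alt_choices = [b for b in _BASES if b != ref]
        alt2 = alt_choices[int(rng.integers(0, 3))]
        if genotype is None:
            genotype = "het" if rng.random() < 0.5 else "hom_alt"
        return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt2,
                           genotype=genotype, **qualities)

    # shared strain-vs-reference variants: in both call sets, same key
    for _ in range(config.n_shared_variants):
        chrom, pos = random_free_position()
        call = random_snv(chrom, pos, _good_qualities(rng))
        add_mutant(call, "shared")
        background.append(
            VariantCall(
                chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
                genotype="het" if rng.random() < 0.5 else "hom_alt",
                **_good_qualities(rng),
            )
        )

    # known-panel polymorphisms present in the mutant
    for i in range(config.n_panel_variants):
        chrom, pos = random_free_position()
        call = random_snv(chrom, pos, _good_qualities(rng))
        add_mutant(call, "panel")
        panels[i % config.n_panels].append(
            VariantCall(chrom=chrom, pos=pos, ref=call.ref, alt=call.alt,
                        genotype="het", **_good_qualities(rng))
        )
    # panel-only sites, never in the mutant
    for panel in panels:
        for _ in range(config.n_panel_only):
            chrom, pos = random_free_position()
            ledger.take(chrom, pos)
            panel.append(random_snv(chrom, pos, _good_qualities(rng), genotype="het"))

    # low-quality artifact calls (each fails one quality stage)
    for _ in range(config.n_low_quality):
        chrom, pos = random_free_position()
        add_mutant(random_snv(chrom, pos, _low_qualities(rng)), "low_quality")

    # private calls in intronic or intergenic space
    placed_nc = 0
    for _ in range(50_000):
        if placed_nc >= config.n_noncoding:
            break
        chrom, pos = random_free_position()
        labels = {t3.classify_position(pos) for t3 in models.overlapping(chrom, pos)}
        if labels <= {"intron", "outside"}:
            add_mutant(random_snv(chrom, pos, _good_qualities(rng)), "noncoding")
            placed_nc += 1
    if placed_nc < config.n_noncoding:
        raise ConfigError("could not place requested noncoding variants")

    # private synonymous coding changes
    for _ in range(config.n_synonymous):
        for _attempt in range(100):
            t4 = coding[int(rng.integers(0, len(coding)))]
            site = _synonymous_site(models, t4, rng)
            if site is None:
                continue
            gpos2, alt3 = site
            if ledger.free(t4.chrom, gpos2):
                add_mutant(
                    VariantCall(
                        chrom=t4.chrom, pos=gpos2, ref=ref_base(t4.chrom, gpos2),
                        alt=alt3, genotype="het" if rng.random() < 0.5 else "hom_alt",
                        **_good_qualities(rng),
                    ),
                    "synonymous",
                )
                break

    # background-private noise (never in the mutant)
    for _ in range(config.n_background_private):
        chrom, pos = random_free_position()
        ledger.take(chrom, pos)
        background.append(random_snv(chrom, pos, _good_qualities(rng)))

    order = lambda v: (str(v.chrom), int(v.pos), v.alt)
    mutant.sort(key=order)
    background.sort(key=order)
    for panel in panels:
        panel.sort(key=order)
    truth = (
        pd.DataFrame(truth_rows, columns=["chrom", "pos", "ref", "alt", "label"])
        .sort_values(["chrom", "pos", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )
    return Scenario(config, models, mutant, background, panels, truth)


def generate_validation_genotypes(scenario: Scenario) -> list[ValidationGenotype]:
    """Derive capillary-style validation genotypes from the truth table.

    The causal call re-genotypes as background hom-ref / mutant het; SNVs
    flanking planted indels re-genotype as Deletion/Deletion (the re-read
    reveals the indel); low-quality false calls re-genotype identical to the
    background; genuine private and shared calls reproduce their call.
    """
    out: list[ValidationGenotype] = []
    for v in scenario.mutant_calls:
        label = scenario.truth_label(v)
        anchor_ref = v.ref[0]
        hom_ref = (anchor_ref, anchor_ref)
        het = tuple(sorted((anchor_ref, v.alt[0] if len(v.alt) > 1 else v.alt)))
        hom_alt = (v.alt, v.alt)
        if label == "causal":
            bg, mut = hom_ref, (
                tuple(sorted((anchor_ref, v.alt))) if v.genotype == "het" else hom_alt
            )
        elif label in ("indel", "indel_artifact"):
            bg = mut = "deletion" if label == "indel_artifact" or v.variant_class == "deletion" else "insertion"
        elif label == "low_quality":
            bg = mut = hom_ref
        elif label in ("shared", "panel"):
            bg = mut = het if v.genotype == "het" else hom_alt
        else:  # noncoding, synonymous: genuine private calls
            bg = hom_ref
            mut = tuple(sorted((anchor_ref, v.alt))) if v.genotype == "het" else hom_alt
        out.append(
            ValidationGenotype(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                background_call=bg, mutant_call=mut,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncnorm(rng, mu, sd, lo, hi, size):
    from scipy.stats import truncnorm

    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig) -> list[CohortRecord]:
    """Simulate a colony cohort with genotype-dependent hearing thresholds.

    Observed offspring genotypes are drawn per cross from the Mendelian prior
    conditioned on homozygote survival (het x het: 1 : 2 : viability/…,
    het x wt: 1 : 1), then a hearing class is drawn per genotype and a click
    threshold per class. Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    records: list[CohortRecord] = []

    def class_for(genotype: str) -> str:
        if genotype == "wt":
            return (
                "intermediate"
                if rng.random() < config.wt_intermediate_leak
                else "unaffected"
            )
        pa, pi = config.pi_affected, config.pi_intermediate
        u = rng.random()
        if u < pa:
            return "affected"
        if u < pa + pi:
            return "intermediate"
        return "unaffected"

    def threshold_for(cls: str) -> float:
        if cls == "unaffected":
            lo, hi = config.unaffected_range
            return float(
                _truncnorm(rng, config.mu_unaffected, config.sd_unaffected, lo, hi, 1)[0]
            )
        if cls == "affected":
            lo, hi = config.affected_range
            return float(
                _truncnorm(rng, config.mu_affected, config.sd_affected, lo, hi, 1)[0]
            )
        lo, hi = config.intermediate_range
        return float(rng.uniform(lo, hi))

    plans = (
        ("het_x_het", config.n_het_x_het, np.array([1.0, 2.0, config.hom_viability])),
        ("het_x_wt", config.n_het_x_wt, np.array([1.0, 1.0, 0.0])),
    )
    counter = 0
    for cross, n, weights in plans:
        probs = weights / weights.sum()
        for _ in range(n):
            counter += 1
            genotype = ("wt", "het", "hom")[int(rng.choice(3, p=probs))]
            cls = class_for(genotype)
            records.append(
                CohortRecord(
                    animal_id=f"a{counter:04d}",
                    cross_type=cross,
                    genotype=genotype,
                    sex="m" if rng.random() < 0.5 else "f",
                    click_threshold=round(threshold_for(cls), 1),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Replica of the chromosome-wide linkage-exclusion layout (scaled down)
# ---------------------------------------------------------------------------

@dataclass
class LinkageReplica:
    models: GeneModelSet
    candidate: VariantCall
    calls: list[VariantCall]
    window_bp: int


def _first_intron(t: TranscriptModel) -> tuple[int, int]:
    introns = t.introns
    if not introns:
        raise ConfigError(f"{t.transcript_id} has no introns")
    return introns[0]


def _interval_with_room(intervals, room: int) -> tuple[int, int]:
    for s, e in intervals:
        if e - s + 1 >= room:
            return s, e
    raise ConfigError("no interval long enough")


def linkage_replica(seed: int = 0, window_bp: int = 12_000) -> LinkageReplica:
    """A scaled-down chromosome-wide exclusion layout around a causal SNV.

    One synthetic chromosome carries the candidate missense SNV near its
    middle; within ``window_bp`` of it sit four non-coding indels (a
    splice-site deletion, 3' UTR and 5' UTR deletions, and a splice-site
    insertion), while the chromosome remainder carries protein-disrupting
    indels (a 1-bp frameshift insertion and an in-frame stop-gaining
    insertion) plus further non-coding changes. The expected report shows no
    coding entry inside the window and flags the coding entries outside it.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91]))
    chrom = "13"
    length = 120_000
    builder = _GenomeBuilder()
    builder.new_chromosome(chrom, rng, length)

    def gene(offset, strand="+", biotype="protein_coding", force_tyr=False, name=None):
        built = _build_gene(
            rng, strand=strand, biotype=biotype, n_codons=60, n_exons=3,
            utr5_len=30, utr3_len=30, force_tyr=force_tyr,
        )
        return builder.place(chrom, offset, built, gene_name=name)

    g_far1 = gene(10_000, name="FarA")          # frameshift host
    g_far2 = gene(30_000, name="FarB")          # stop-gain host
    g_near1 = gene(52_000, name="NearA")        # splice deletion + 3' UTR deletion
    g_cand = gene(58_000, force_tyr=True, name="Cand")
    g_near2 = gene(64_000, name="NearB")        # 5' UTR deletion + splice insertion
    g_far3 = gene(100_000, name="FarC")         # non-coding rest entries
    models = builder.finish()
    seq = models.sequence(chrom)

    def base(p: int) -> str:
        return seq[p - 1]

    # candidate: Tyr->Cys missense in the central gene
    codon_i = _find_codons(models, g_cand, {"TAT", "TAC"})[0]
    gpos = _codon_genomic_positions(g_cand, codon_i)[1]
    candidate = VariantCall(
        chrom=chrom, pos=gpos, ref=base(gpos), alt=_genomic_allele(g_cand, "G"),
        genotype="het", consensus_quality=199, snp_quality=228,
        mapping_quality=60, read_depth=66,
    )

    q = _good_qualities
    calls: list[VariantCall] = []

    # --- four non-coding indels inside the window --------------------------
    s1, _ = _first_intron(g_near1)  # intron first base
    calls.append(VariantCall(chrom, s1 - 1, seq[s1 - 2 : s1], base(s1 - 1), "het", **q(rng)))
    u3s, u3e = _interval_with_room(g_near1.utr_intervals[1], 3)
    calls.append(VariantCall(chrom, u3s, seq[u3s - 1 : u3s + 1], base(u3s), "het", **q(rng)))
    u5s, u5e = _interval_with_room(g_near2.utr_intervals[0], 3)
    calls.append(VariantCall(chrom, u5s, seq[u5s - 1 : u5s + 1], base(u5s), "hom_alt", **q(rng)))
    s2, _ = _first_intron(g_near2)  # insertion inside the donor dinucleotide
    calls.append(VariantCall(chrom, s2, base(s2), base(s2) + "T", "het", **q(rng)))

    # --- rest of the chromosome --------------------------------------------
    fs, fe = _interval_with_room(g_far1.cds, 6)
    p = fs + 1
    calls.append(VariantCall(chrom, p, base(p), base(p) + "G", "het", **q(rng)))  # frameshift
    # in-frame TAA insertion at a codon boundary of a plus-strand gene
    host = g_far2 if g_far2.strand == "+" else g_far1
    positions = host.cds_positions
    boundary = None
    for i in range(2, len(positions) - 3, 3):
        if positions[i] + 1 == positions[i + 1]:  # codon end with intra-exon neighbour
            boundary = positions[i]
            break
    if boundary is None:
        raise ConfigError("no codon boundary found for stop-gain insertion")
    calls.append(
        VariantCall(chrom, boundary, base(boundary), base(boundary) + "TAA", "hom_alt", **q(rng))
    )
    s3, _ = _first_intron(g_far3)
    calls.append(VariantCall(chrom, s3 - 1, seq[s3 - 2 : s3], base(s3 - 1), "hom_alt", **q(rng)))
    u3s2, _ = _interval_with_room(g_far3.utr_intervals[1], 3)
    alt = "A" if base(u3s2) != "A" else "C"
    calls.append(VariantCall(chrom, u3s2, base(u3s2), alt, "het", **q(rng)))  # 3' UTR SNV

    return LinkageReplica(models, candidate, calls, window_bp)


# ---------------------------------------------------------------------------
# File emitters (plain-text FASTA / GFF3)
# ---------------------------------------------------------------------------

def write_fasta(
    reference: dict[str, str], path: str | Path, *, seed: int | None = None, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference, key=str):
            desc = f" scenario_seed={seed}" if seed is not None else ""
            fh.write(f">{name}{desc}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: GeneModelSet, path: str | Path, *, seed: int | None = None) -> None:
    lines = ["##gff-version 3"]
    if seed is not None:
        lines.append(f"# scenario_seed={seed}")
    for name in sorted(models.reference, key=str):
        lines.append(f"##sequence-region {name} 1 {len(models.reference[name])}")
    for t in models.transcripts:
        lo, hi = t.span
        gene_id = f"gene:{t.transcript_id}"
        attrs_gene = f"ID={gene_id};Name={t.gene_name}"
        lines.append(
            f"{t.chrom}\texomefunnel\tgene\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs_gene}"
        )
        attrs_t = (
            f"ID={t.transcript_id};Parent={gene_id};"
            f"gene_name={t.gene_name};biotype={t.biotype}"
        )
        lines.append(
            f"{t.chrom}\texomefunnel\tmRNA\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs_t}"
        )
        for s, e in t.exons:
            lines.append(
                f"{t.chrom}\texomefunnel\texon\t{s}\t{e}\t.\t{t.strand}\t.\tParent={t.transcript_id}"
            )
        for s, e in t.cds:
            lines.append(
                f"{t.chrom}\texomefunnel\tCDS\t{s}\t{e}\t.\t{t.strand}\t.\tParent={t.transcript_id}"
            )
        utr5, utr3 = t.utr_intervals
        for kind, intervals in (("five_prime_UTR", utr5), ("three_prime_UTR", utr3)):
            for s, e in intervals:
                lines.append(
                    f"{t.chrom}\texomefunnel\t{kind}\t{s}\t{e}\t.\t{t.strand}\t.\tParent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")
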