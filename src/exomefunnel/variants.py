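"""Domain types and readers/writers for variant calls, gene models and cohort tables.

Coordinates are 1-based and inclusive throughout (VCF/GFF3 convention). Indels
are stored VCF-style, anchored on the reference base immediately before the
inserted or deleted sequence, so that ``(chrom, pos, alt)`` is an unambiguous
key for set subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    CoordinateError,
    DataError,
    GeneModelError,
    VariantFormatError,
)

GENOTYPES = ("hom_ref", "het", "hom_alt")
VARIANT_CLASSES = ("snv", "insertion", "deletion")

_DNA = frozenset("ACGTN")


def _check_allele(allele: str, what: str) -> None:
    if not allele:
        raise VariantFormatError(f"{what} allele is empty")
    if not set(allele.upper()) <= _DNA:
        raise VariantFormatError(f"{what} allele {allele!r} is not plain DNA")


@dataclass(frozen=True)
class VariantCall:
    """One called difference from the reference: the atom of the funnel.

    Quality metrics that are absent from the source file are ``None`` and, by
    default, fail quality filters closed (see
    :class:`exomefunnel.funnel.QualityThresholds`).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    consensus_quality: float | None = None
    snp_quality: float | None = None
    mapping_quality: float | None = None
    read_depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantFormatError(f"position {self.pos} < 1")
        _check_allele(self.ref, "ref")
        _check_allele(self.alt, "alt")
        if self.ref == self.alt:
            raise VariantFormatError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if len(self.ref) == len(self.alt) and len(self.ref) != 1:
            raise VariantFormatError(
                f"block substitution {self.ref}>{self.alt} at {self.chrom}:{self.pos} "
                "is not supported (alleles must be an SNV or a simple indel)"
            )
        if self.genotype not in GENOTYPES:
            raise VariantFormatError(f"unknown genotype {self.genotype!r}")
        for name in ("consensus_quality", "snp_quality", "mapping_quality"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise VariantFormatError(f"{name} {val} < 0")
        if self.read_depth is not None and self.read_depth < 0:
            raise VariantFormatError(f"read_depth {self.read_depth} < 0")

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def key(self) -> tuple[str, int, str]:
        return variant_key(self)


def variant_key(v: VariantCall) -> tuple[str, int, str]:
    """Deterministic matching key used by all set-subtraction steps.

    Genotype and quality metrics are deliberately excluded: two samples share a
    variant when they share position and alternate allele, however confidently
    or in whatever zygosity each was called.
    """
    return (str(v.chrom), int(v.pos), v.alt)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TranscriptModel:
    """One transcript: exon/CDS structure on a chromosome.

    ``exons`` and ``cds`` are sorted lists of 1-based inclusive genomic
    intervals; ``strand`` is ``"+"`` or ``"-"``. Introns are the gaps between
    consecutive exons.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        self.cds = tuple((int(s), int(e)) for s, e in self.cds)
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.transcript_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @cached_property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @cached_property
    def cds_positions(self) -> tuple[int, ...]:
        """All CDS genomic positions, ascending."""
        out: list[int] = []
        for s, e in self.cds:
            out.extend(range(s, e + 1))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @cached_property
    def utr_intervals(self) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
        """(5' UTR, 3' UTR) genomic intervals: exonic sequence outside the CDS."""
        if not self.cds:
            return ((), ())
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        left: list[tuple[int, int]] = []
        right: list[tuple[int, int]] = []
        for s, e in self.exons:
            if e < cds_lo:
                left.append((s, e))
            elif s < cds_lo:
                left.append((s, cds_lo - 1))
            if s > cds_hi:
                right.append((s, e))
            elif e > cds_hi:
                right.append((cds_hi + 1, e))
        if self.strand == "+":
            return (tuple(left), tuple(right))
        return (tuple(right), tuple(left))

    def classify_position(self, pos: int) -> str:
        """Region label for a genomic position relative to this transcript.

        One of ``cds``, ``utr5``, ``utr3``, ``splice`` (first/last two bases of
        an intron), ``intron``, ``noncoding_exon`` or ``outside``. Labels
        partition the transcript span.
        """
        lo, hi = self.span
        if pos < lo or pos > hi:
            return "outside"
        for s, e in self.exons:
            if s <= pos <= e:
                if self.biotype != "protein_coding" or not self.cds:
                    return "noncoding_exon"
                for cs, ce in self.cds:
                    if cs <= pos <= ce:
                        return "cds"
                cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
                if pos < cds_lo:
                    return "utr5" if self.strand == "+" else "utr3"
                return "utr3" if self.strand == "+" else "utr5"
        for s, e in self.introns:
            if s <= pos <= e:
                if pos <= s + 1 or pos >= e - 1:
                    return "splice"
                return "intron"
        return "outside"  # pragma: no cover - spans are exon-bounded

    def cds_index(self, pos: int) -> int:
        """0-based index of a CDS genomic position in transcript orientation."""
        positions = self.cds_positions
        # positions are ascending; binary search
        import bisect

        i = bisect.bisect_left(positions, pos)
        if i == len(positions) or positions[i] != pos:
            raise CoordinateError(f"{self.transcript_id}: {pos} is not a CDS position")
        return i if self.strand == "+" else len(positions) - 1 - i


@dataclass
class GeneModelSet:
    """Transcript structures plus the reference sequence they live on."""

    transcripts: list[TranscriptModel]
    reference: dict[str, str]
    _cds_cache: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> "GeneModelSet":
        for t in self.transcripts:
            tid = t.transcript_id
            if t.chrom not in self.reference:
                raise GeneModelError(f"{tid}: chromosome {t.chrom!r} not in reference")
            seqlen = len(self.reference[t.chrom])
            prev_end = 0
            for s, e in t.exons:
                if s > e or s < 1 or e > seqlen:
                    raise GeneModelError(f"{tid}: exon ({s},{e}) outside sequence of length {seqlen}")
                if s <= prev_end:
                    raise GeneModelError(f"{tid}: exons overlap or are unsorted at ({s},{e})")
                prev_end = e
            exon_pos = set()
            for s, e in t.exons:
                exon_pos.update(range(s, e + 1))
            for s, e in t.cds:
                if not set(range(s, e + 1)) <= exon_pos:
                    raise GeneModelError(f"{tid}: CDS ({s},{e}) not contained in exons")
            if t.biotype == "protein_coding" and t.cds:
                n = t.cds_length
                if n <= 0 or n % 3 != 0:
                    raise GeneModelError(f"{tid}: CDS length {n} is not a positive multiple of 3")
        return self

    def sequence(self, chrom: str) -> str:
        try:
            return self.reference[chrom]
        except KeyError:
            raise CoordinateError(f"chromosome {chrom!r} not in reference") from None

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        out = []
        for t in self.transcripts:
            if t.chrom != chrom:
                continue
            lo, hi = t.span
            if lo <= pos <= hi:
                out.append(t)
        return out

    def coding_sequence(self, t: TranscriptModel) -> str:
        """Spliced CDS of ``t`` in transcript orientation (cached)."""
        cached = self._cds_cache.get(t.transcript_id)
        if cached is not None:
            return cached
        seq = self.sequence(t.chrom)
        s = "".join(seq[a - 1 : b] for a, b in t.cds)
        if t.strand == "-":
            s = reverse_complement(s)
        self._cds_cache[t.transcript_id] = s
        return s


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Validation genotypes and cohort records
# ---------------------------------------------------------------------------

SYMBOLIC_CALLS = ("deletion", "insertion", "missing")


def normalize_call(raw: str) -> tuple[str, ...] | str:
    """Normalize a capillary-style genotype string.

    Allele order never matters (``"C/T"`` and ``"T/C"`` are identical); a
    single base means a homozygous call; ``Deletion``/``Insertion`` and
    missing markers (``NA``, empty, ``.``) map to symbolic values distinct
    from any concrete call.
    """
    s = str(raw).strip()
    low = s.lower()
    if low in ("", "na", "nan", ".", "none", "missing"):
        return "missing"
    if low in ("deletion", "del"):
        return "deletion"
    if low in ("insertion", "ins"):
        return "insertion"
    alleles = [a.strip().upper() for a in s.split("/") if a.strip()]
    if not alleles:
        return "missing"
    if len(alleles) == 1:
        alleles = alleles * 2
    if len(alleles) != 2 or not all(set(a) <= _DNA for a in alleles):
        raise DataError(f"cannot interpret genotype call {raw!r}")
    return tuple(sorted(alleles))


@dataclass(frozen=True)
class ValidationGenotype:
    """Independent re-genotyping of one candidate site in both DNA samples."""

    chrom: str
    pos: int
    ref: str
    alt: str
    background_call: tuple[str, ...] | str
    mutant_call: tuple[str, ...] | str

    @property
    def key(self) -> tuple[str, int, str]:
        return (str(self.chrom), int(self.pos), self.alt)

    @staticmethod
    def _contains(call: tuple[str, ...] | str, allele: str) -> bool:
        return isinstance(call, tuple) and allele.upper() in call

    def mutant_has_alt(self) -> bool:
        return self._contains(self.mutant_call, self.alt)

    def background_has_alt(self) -> bool:
        return self._contains(self.background_call, self.alt)


CROSS_TYPES = ("het_x_het", "het_x_wt")
COHORT_GENOTYPES = ("wt", "het", "hom")
SEXES = ("m", "f", "unknown")


@dataclass(frozen=True)
class CohortRecord:
    """One animal: cross of origin, genotype at the candidate locus, hearing."""

    animal_id: str
    cross_type: str
    genotype: str
    sex: str
    click_threshold: float

    def __post_init__(self) -> None:
        if self.cross_type not in CROSS_TYPES:
            raise DataError(f"{self.animal_id}: unknown cross_type {self.cross_type!r}")
        if self.genotype not in COHORT_GENOTYPES:
            raise DataError(f"{self.animal_id}: unknown genotype {self.genotype!r}")
        if self.sex not in SEXES:
            raise DataError(f"{self.animal_id}: unknown sex {self.sex!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _rounded(x, ndigits: int = 4):
    # htslib stores INFO floats as float32; round away the representation noise
    return None if x is None else round(float(x), ndigits)


def read_variant_calls(path: str | Path) -> list[VariantCall]:
    """Read a VCF into a list of :class:`VariantCall`.

    Emits one call per ALT allele per record, with the genotype taken from the
    first sample's GT field; hom-ref records contribute nothing (a variant
    list contains only differences from the reference). Qualities are carried
    as QUAL = SNP quality and INFO keys ``CQ`` (consensus quality), ``MQ``
    (RMS mapping quality) and ``DP`` (read depth); absent keys become ``None``.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VariantFormatError(f"{path}: cannot parse VCF ({exc})") from exc
    if len(vcf.samples) < 1:
        raise VariantFormatError(f"{path}: VCF has no sample column (GT required)")

    calls: list[VariantCall] = []
    for i, rec in enumerate(vcf, start=1):
        where = f"{path}: record {i} ({rec.CHROM}:{rec.POS})"
        gts = rec.genotypes
        if not gts:
            raise VariantFormatError(f"{where}: missing GT")
        gt = gts[0]
        alleles = gt[:-1]  # last element is the phasing flag
        if len(alleles) != 2:
            raise VariantFormatError(f"{where}: GT ploidy {len(alleles)} is not diploid")
        if all(a <= 0 for a in alleles):
            continue  # hom-ref or no-call: not a difference from reference
        cq = _rounded(rec.INFO.get("CQ"))
        mq = _rounded(rec.INFO.get("MQ"))
        dp = rec.INFO.get("DP")
        dp = None if dp is None else int(dp)
        sq = _rounded(rec.QUAL)
        for k, alt in enumerate(rec.ALT, start=1):
            n_copies = sum(1 for a in alleles if a == k)
            if n_copies == 0:
                continue
            genotype = "hom_alt" if n_copies == 2 else "het"
            try:
                calls.append(
                    VariantCall(
                        chrom=str(rec.CHROM),
                        pos=int(rec.POS),
                        ref=rec.REF,
                        alt=alt,
                        genotype=genotype,
                        consensus_quality=cq,
                        snp_quality=sq,
                        mapping_quality=mq,
                        read_depth=dp,
                    )
                )
            except VariantFormatError as exc:
                raise VariantFormatError(f"{where}: {exc}") from exc
    return calls


def _fmt_num(x) -> str:
    if x is None:
        return "."
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(round(xf, 4))


def write_variant_calls(
    calls: Iterable[VariantCall],
    path: str | Path,
    *,
    reference: dict[str, str] | None = None,
    sample: str = "SAMPLE",
    extra_header: Sequence[str] = (),
) -> None:
    """Write calls as a minimal single-sample VCF 4.2 (one record per call)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CQ,Number=1,Type=Float,Description="Consensus quality (phred)">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines.extend(extra_header)
    if reference:
        for name, seq in reference.items():
            lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for v in calls:
        info_parts = []
        if v.consensus_quality is not None:
            info_parts.append(f"CQ={_fmt_num(v.consensus_quality)}")
        if v.mapping_quality is not None:
            info_parts.append(f"MQ={_fmt_num(v.mapping_quality)}")
        if v.read_depth is not None:
            info_parts.append(f"DP={v.read_depth}")
        info = ";".join(info_parts) or "."
        gt = "1/1" if v.genotype == "hom_alt" else "0/1"
        lines.append(
            "\t".join(
                [
                    str(v.chrom),
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    _fmt_num(v.snp_quality),
                    ".",
                    info,
                    "GT",
                    gt,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(gff_path: str | Path, fasta_path: str | Path) -> GeneModelSet:
    """Read GFF3 gene models plus their FASTA reference into a validated set."""
    import gffutils

    reference = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not reference:
        raise DataError(f"{fasta_path}: no sequences")

    text = Path(gff_path).read_text()
    has_features = any(
        line.strip() and not line.startswith("#") for line in text.splitlines()
    )
    transcripts: list[TranscriptModel] = []
    if has_features:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
        for ttype in ("mRNA", "transcript", "ncRNA"):
            for t in db.features_of_type(ttype):
                exons = sorted(
                    (f.start, f.end) for f in db.children(t, featuretype="exon")
                )
                cds = sorted((f.start, f.end) for f in db.children(t, featuretype="CDS"))
                gene_name = t.attributes.get("gene_name", [None])[0]
                if gene_name is None:
                    parents = list(db.parents(t, featuretype="gene"))
                    if parents:
                        gene_name = parents[0].attributes.get("Name", [parents[0].id])[0]
                biotype = t.attributes.get(
                    "biotype", ["protein_coding" if cds else "noncoding"]
                )[0]
                transcripts.append(
                    TranscriptModel(
                        transcript_id=t.id,
                        gene_name=gene_name or t.id,
                        chrom=str(t.seqid),
                        strand=t.strand,
                        exons=tuple(exons) if exons else ((t.start, t.end),),
                        cds=tuple(cds),
                        biotype=biotype,
                    )
                )
    transcripts.sort(key=lambda t: (t.chrom, t.span, t.transcript_id))
    return GeneModelSet(transcripts, reference).validate()


def read_validation_genotypes(path: str | Path) -> list[ValidationGenotype]:
    """Read a validation-genotype TSV (chrom, pos, ref, alt, background_call, mutant_call)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"chrom", "pos", "ref", "alt", "background_call", "mutant_call"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ValidationGenotype(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                background_call=normalize_call(row.background_call),
                mutant_call=normalize_call(row.mutant_call),
            )
        )
    return out


def write_validation_genotypes(records: Iterable[ValidationGenotype], path: str | Path) -> None:
    def fmt(call) -> str:
        if isinstance(call, tuple):
            return "/".join(call)
        return call.capitalize() if call != "missing" else "NA"

    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "background_call": fmt(r.background_call),
            "mutant_call": fmt(r.mutant_call),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(
    path: str | Path, *, plausible_range: tuple[float, float] = (0.0, 100.0)
) -> list[CohortRecord]:
    """Read a cohort TSV (animal_id, cross_type, genotype, sex, click_threshold)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"animal_id", "cross_type", "genotype", "sex", "click_threshold"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    lo, hi = plausible_range
    out = []
    for row in df.itertuples(index=False):
        thr = float(row.click_threshold)
        if not (lo <= thr <= hi):
            raise DataError(
                f"{path}: {row.animal_id}: click_threshold {thr} outside [{lo}, {hi}] dB SPL"
            )
        out.append(
            CohortRecord(
                animal_id=str(row.animal_id),
                cross_type=row.cross_type,
                genotype=row.genotype,
                sex=row.sex,
                click_threshold=thr,
            )
        )
    return out


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "cross_type": r.cross_type,
            "genotype": r.genotype,
            "sex": r.sex,
            "click_threshold": r.click_threshold,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
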