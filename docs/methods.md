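# Methods

This note documents the models, conventions and numerical choices behind
`exomefunnel`, and what the synthetic data do and do not establish.

## Coordinates, keys and genotypes

All coordinates are 1-based inclusive (VCF/GFF3 convention). Indels are
stored VCF-style, anchored on the reference base before the event, and
`variant_class` is derived from allele lengths (equal length 1 → SNV; longer
ALT → insertion; longer REF → deletion). Same-length multi-base substitutions
are rejected by the reader: block substitutions are outside the model.

Every subtraction step matches on the key `(chrom, pos, alt)` — genotype and
qualities are deliberately excluded, so a variant is "shared" or "known"
whenever the same alternate allele was called at the same site, however
confidently and in whatever zygosity. Position-only matching (ignoring the
allele) would be more aggressive; position+allele was chosen because it can
only under-subtract, and the funnel's philosophy is to prefer false
positives over false negatives. Heterozygous genotype strings in validation
tables are normalized so allele order never matters ("C/T" ≡ "T/C"); a
single base means a homozygous call; `Deletion`, `Insertion` and missing
markers are symbolic values distinct from any concrete call.

Quality metrics absent from an input default to "unknown" and fail quality
filters closed (a call that cannot demonstrate its quality is not promoted);
`QualityThresholds(missing_fails=False)` switches to fail-open.

## Quality filtering

Two stages mirror the original cascade's printed semantics: SNP quality is a
"lower limit", hence inclusive (≥ 20); mapping quality and read depth are
printed as strict inequalities (> 45, > 10) and implemented as such.
Consensus quality is carried through for reporting but never filtered on.
The original pipeline's first quality step was a caller-specific filter
whose exact heuristics are not recoverable; here it is realized as the SNP
quality rule alone, which is why desk-scale funnels have one fewer degree of
freedom than the original and full-scale survivor counts are not a
reproduction target.

## Consequence annotation

For a coding SNV the affected codon is located through the spliced CDS in
transcript orientation (reverse-complemented for minus-strand transcripts),
mutated, and translated with the standard nuclear code; the reference and
mutant amino acids give the category (synonymous, nonsynonymous, stop
gained, stop lost) and the detail string `X:Y` with the 1-based residue
index. Changes at a stop codon that preserve a stop (e.g. TGA→TAA) are
synonymous. Essential splice sites are the first or last two bases of any
intron, including UTR introns, and take precedence over plain intronic
placement. Noncoding-biotype transcripts annotate as `noncoding_transcript`
(their ORFs are never translated — pseudogene ORF translation is
deliberately not attempted). Positions outside every transcript are
intergenic.

Indels wholly inside a CDS are frameshifts when the length change is not a
multiple of three; in-frame indels are re-translated (the spliced CDS is
rebuilt with the edit applied) and become `stop_gained` when a premature
stop appears, `stop_lost` when the terminal stop disappears, otherwise
`inframe_indel`. An indel touching the first/last two intron bases is an
essential-splice disruption regardless of what else it touches; a deletion
reaching over a CDS/UTR boundary shifts the frame iff the number of deleted
coding bases is not a multiple of three (no re-translation across the
boundary is attempted); a boundary insertion classifies by its non-coding
side. Insertions are classified from the two bases flanking the insertion
point; deletions from the deleted bases.

One variant gets one consequence: the most severe across overlapping
transcripts under the fixed order

```
stop_gained = stop_lost = frameshift > essential_splice_site > nonsynonymous
  > inframe_indel > synonymous > utr5/utr3 > noncoding_transcript
  > intronic > intergenic
```

with ties broken by lexicographic transcript id. The order itself is a
package choice — the selection rule only needs the boundary between
"selected" (stop/missense/splice) and everything else — but a total order
makes reporting deterministic.

## Funnel contract

Survivor counts are recorded after every step and are non-increasing by
construction; `FunnelReport` refuses to build otherwise. Candidate selection
keeps only SNVs; indels surviving the quality stages are preserved in a side
channel (they feed linkage exclusion but are never candidates). Candidate
confirmation requires the mutant validation call to contain the alternate
allele, the background call not to, and neither call to be symbolic;
failures are labelled `indel_misalignment` (symbolic call present —
checked first, since an indel under the site explains any residual
disagreement), `missing_data`, `identical_to_background`, or
`miscalled_zygosity` (the remainder). Homozygous candidates are retained
through selection: the dominant-inheritance expectation informs reporting
(the heterozygote count), not filtering.

Indel-proximity flagging measures the distance between anchored positions
against raw indel calls from either sample, window 20 bp by default; it
annotates, never removes.

## Linkage exclusion

The window is a closed two-sided interval of ±10 Mb (physical distance; no
recombination model) around the candidate. Each same-chromosome private call
is annotated and printed with the conventional location labels ("Exonic",
"Splice site (intronic)", "5'/3' UTR", "Noncoding (retained intron)");
protein-disrupting entries (frameshift, stop gain/loss, missense) are
highlighted with a truncation note. The packaged chromosome-13 call list
reproduces the published layout: 4 entries within 10 Mb of the candidate,
none coding. The synthetic replica used by tests and the acceptance script
recreates that structure at reduced scale — a 120 kb chromosome with a
±12 kb window — because the property checked (no coding change inside the
window; coding frameshift/stop entries confined to the remainder) is
invariant to the physical scale.

## Segregation and penetrance

Hearing classes partition the click-threshold axis: affected ≥ 50 dB SPL,
unaffected ≤ 30 dB SPL, intermediate the open interval (30, 50) — both
endpoints belong to the outer classes, so the "30 to 50" column of a printed
cross table is the open interval. Cross-table percentages are proportions of
the cross grand total rounded to one decimal.

Penetrance is numerator/denominator over carriers of the stated genotype,
pooled across cross types by default (the published 23.1% and 51.2% both
equal the pooled 28/121 and 62/121, so pooling is adopted); per-cross
estimates are available via `cross_types`. The 95% CI is a Wilson score
interval (good small-sample behaviour, never escapes [0, 1]; the source
analysis reported no interval, so the choice is this package's).

The homozygote-deficit test is the one-sided exact binomial tail
P(X ≤ n_hom) at the Mendelian expectation (0.25 for an intercross); with
0/111 homozygotes this is 0.75¹¹¹ ≈ 1.35 × 10⁻¹⁴. The Mendelian-ratio test
is an exact multinomial test (summing outcome probabilities no larger than
the observed outcome's, with a 10⁻⁹ relative tolerance for pmf ties) when
the total count is ≤ 200 and the outcome space is enumerable, falling back
to chi-square goodness of fit otherwise. Sex is recorded and reported but
never tested.

## Synthetic data: what it emulates, and what it does not

The scenario generator plants, per seed: a single heterozygous causal
missense SNV (Tyr→Cys where a tyrosine codon is available — the generator
guarantees one in the first coding gene — otherwise any amino-acid change)
with quality metrics defaulting to the confirmed candidate's published
values (CQ 199, SQ 228, MQ 60, DP 66); 120 variants shared with the
background strain; 40 known-panel hits (plus panel-only sites); 12
low-quality calls, each failing exactly one quality stage; 10 deep-intronic
or intergenic calls; 6 synonymous third-base changes; and 3 one-base
deletions inside CDS intervals, each flanked by 2 amino-acid-changing SNVs
within 8 bp — the artifact clusters whose validation genotypes read
Deletion/Deletion. Panel and shared sites are drawn disjoint from the causal
site by construction (panel subtraction must never remove the planted
mutation). Every mutant call carries a truth label, and label soundness
(no "shared" call survives background subtraction, no "panel" call survives
panel subtraction) is tested directly.

Genes are random ORFs: ATG + 38–78 sense codons + stop, split over 2–4
exons with GT..AG introns of 30–79 bp, 15–40 bp UTRs, on both strands, ~15%
noncoding biotype. Chromosomes default to 2 × 60 kb with 14 genes — large
enough to give every consequence category sampling room, small enough that
a hundred seeded end-to-end funnels run in seconds.

The cohort generator draws observed genotypes from the Mendelian prior
conditioned on homozygote survival (viability 0 by default), a hearing
class per genotype (heterozygotes: affected 0.231, intermediate 0.28;
wild types leak into the intermediate class with probability 0.04,
mirroring the few real wild types just above the unaffected cut), and a
threshold per class: unaffected ~ N(22, 4²) truncated to [0, 30], affected
~ N(65, 9²) truncated to [50, 97], intermediate ~ U(31, 49) dB SPL.
The class probabilities come from the published cross table; the threshold
distributions are package choices constrained only by the qualitative
bimodality of real colony data (a normal-hearing peak below 30 dB and a
spread of raised thresholds between 50 and 80 dB), and thresholds are
continuous rather than snapped to the 3-dB measurement grid of a real ABR
rig. Simulated intercross heterozygote class counts are
chi-square-compatible with the published row in ≥ 95% of seeds.

What passing tests therefore show: the funnel's set logic, threshold
semantics, annotation and adjudication are correct, and the statistics
reproduce published values exactly on the published tables. What they do
not show: performance on real alignment artifacts (the generator plants
clean, labelled artifact clusters; real misalignment is messier), on
multi-sample or structurally variant genomes, or at the multi-million-call
scale of a real exome, whose first-stage caller heuristics are not
reproduced here.

## Determinism

All generator randomness flows from one seed through a splittable
`numpy.random.SeedSequence` (one child for the genome, one for variants);
emitted files record the seed in their headers and are byte-identical per
seed. Re-running the funnel on identical inputs yields a byte-identical
serialized report. The acceptance script derives scenario seeds as
`seed·1000 + i (mod 2³¹)`.

## Known limitations

No BAM/CRAM or read-level handling; first sample's GT only; selenocysteine
and ambiguity codes unsupported; no splice-strength scoring or
protein-structure impact; no realignment around indels (flagging only); no
recombination-distance modelling; exact multinomial testing is skipped for
outcome spaces that cannot be enumerated cheaply.
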