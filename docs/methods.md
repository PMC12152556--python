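# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the genome, with strand
carried on every interval. GFF3 (1-based inclusive) and the snoRNA TSV
(1-based inclusive, stated in its header) are converted at the parsing
boundary. "Transcript orientation" means genomic left-to-right on `+`
genes and right-to-left on `-` genes; the 5′ end of a read is its leftmost
aligned base on `+` and its rightmost on `-`.

## Host-gene model and categories

Introns are derived per transcript as the gaps between consecutive exons,
then deduplicated per gene by exact coordinates. A span that is intronic
in one transcript but exonic in another is kept as an intron and flagged
`ambiguous`; when nested introns both contain a snoRNA, the smallest
containing intron wins. Each host gene is categorized by the context of
its snoRNA intron:

* `CDS_INTERNAL` — in at least one coding transcript, both exons flanking
  the snoRNA intron overlap CDS. Any such transcript decides the gene:
  this is the configuration in which 5′ cut points are cleanly measurable,
  so it is the most informative label when transcripts disagree.
* `UTR` — flanking exonic context is untranslated in every coding
  transcript containing the intron.
* `NONCODING` — no transcript of the gene has CDS.
* `UNRESOLVED` — none of the above applies (e.g. no coding transcript
  contains the intron between two of its exons). Ambiguity is absorbed
  here rather than raised as an error, since overlapping alternative
  transcripts are common at snoRNA host loci.

The `canonical` flag (snoRNA has at least one annotated RNA target) is
taken verbatim from the input table; no database is queried.

## Read model

Aligned blocks and splice gaps come from the CIGAR: `M`/`=`/`X` extend a
block, `N` ends a block and records a gap, `D` ends a block without
recording a gap. Deletions never count as splicing regardless of length —
ONT aligners encode indel noise as `D` and introns as `N`, and conflating
them would create false spliced calls. Defaults: primary alignments only,
MAPQ ≥ 10 (suppresses multi-mapped host-gene paralogs; the threshold is a
package choice, configurable). Read strand is the alignment strand bit,
assuming stranded cDNA alignment.

Per intron, a read is `SPLICED` when some gap matches both intron
boundaries within a junction tolerance of ±5 nt (long-read aligners wobble
at splice sites; tolerance 0 recovers exact matching and widening the
tolerance can only grow the spliced set); `RETAINED` when blocks cover at
least `min_interior_cov = 0.9` of the intron, no gap overlaps the intron,
and the read has aligned bases on both flanks; `PARTIAL` otherwise.
Interior coverage of 0.9 reflects that a retained intron should be
near-completely present in the read, while tolerating small deletions.

## snoRT calling

Containment is reference-coordinate coverage of the snoRNA interval by the
read's aligned blocks (default ≥ 0.9). This is deterministic and
aligner-consistent; an optional sequence-verification mode
(`sequence_identity_check`: local alignment of the snoRNA reference inside
the read sequence, ≥ 80 % identity over ≥ 90 % of the snoRNA length) is
available when basecalls are trusted less than coordinates.

A snoRT read must additionally align to at least one exonic base
downstream (transcript orientation) of the snoRNA intron. The 3′-snoRT is
a polyadenylated fragment running toward the transcript 3′ end; this
requirement excludes mature-snoRNA-only fragments. It can be disabled
(`require_downstream_exon=False`).

The upstream extent is `max(0, −offset)` where `offset` is the signed
distance from the read 5′ end to the snoRNA 5′ start. Classification uses
`T = 10` nt: more than ten nucleotides upstream → FL, ten or fewer → 3′.
`T` is exposed on the CLI (`--threshold`). Reads whose 5′ end lies more
than half the snoRNA length inside the snoRNA body remain `THREE_PRIME`
but are flagged `LOW_CONFIDENCE`; no hard lower bound is imposed.
Strand-mismatched reads are excluded from classification (flagged). Reads
with duplicate ids are counted once per (gene, snoRNA) pair.

Per-gene relative abundances are FL and 3′ counts over all primary
strand-matched reads overlapping the gene span; a display flag marks genes
where either form reaches 1 % of host-gene expression. Calls are emitted
for all gene categories; the category tag lets downstream users filter to
`CDS_INTERNAL` genes, where cut points are best defined.

## Statistics

* Group comparison: two-sided unpaired t-test on per-intron retention
  frequencies — introns are the sampling units, each intron's frequency
  built from its individual read events. Welch (unequal variances) is the
  default because intron groups differ strongly in depth and variance;
  Student's pooled-variance variant is available (`--test-variant
  student`). Frequencies are not transformed. Introns with no informative
  reads are excluded listwise. Fold change is the ratio of group means.
  Implemented via `scipy.stats.ttest_ind`; the test suite checks it to
  1e-10 against a from-scratch evaluation of the formulas.
* Canonical comparison: retained/spliced events pooled across the
  snoRNA-hosting introns of canonical vs non-canonical snoRNAs, then a
  chi-square with Yates' continuity correction
  (Σ(|O−E|−0.5)²/E, correction floored so |O−E| < 0.5 contributes 0;
  `scipy.stats.chi2_contingency(correction=True)` implements exactly this,
  verified against a hand evaluation). Zero marginals are an error.
* Intron depth weighting is not applied in the t-test; unweighted
  per-intron frequencies are the analysis unit. Depth weighting would be a
  straightforward extension.

## ddPCR deconvolution

Inputs are instrument-reported absolute concentrations (copies/µL) for the
three nested primer sets; no droplet-level Poisson modeling is done.
`fl = c_fl`, `three_prime = c_snort − c_fl`, `snorna = c_all − c_snort`.
Without clamping the three outputs sum to `c_all` exactly and the map is
scale-equivariant. Droplet noise can make a raw difference negative; by
default such values are clamped to 0 and flagged
(`NEG_3PRIME_CLAMPED` / `NEG_SNORNA_CLAMPED`). Replicates are aggregated
as median ± SD per (sample, target); relative fractions are computed from
the medians and sum to 1 when the total is positive. Concentrations are
reported as measured, without normalization to cDNA input mass.

## Simulator

Each gene is a random multi-exon locus (defaults: 4 exons of 120–300 nt,
introns of 250–600 nt) on its own chromosome, with one snoRNA (70–140 nt)
placed ≥ 20 nt inside an internal intron. Genes are coding with CDS
spanning all exons (`CDS_INTERNAL`) unless `noncoding_frac` makes them
non-coding; the `UTR` category is exercised with hand-built annotations in
the unit tests instead. Molecules are drawn from `isoform_props`
(default 0.5 spliced / 0.2 FL / 0.3 3′): spliced molecules remove all
introns, FL molecules retain the snoRNA intron full-length, 3′ molecules
start at `snoRNA start + class offset + round(N(0, jitter_sd))` — offset 0
for C/D, −2 for H/ACA, jitter default 3 nt (the spread is a package choice
for testing; it is not a measured value) — and run to the transcript 3′
end. Other introns are independently retained at a background rate
(default 1e-4); a spliced molecule retaining one is labelled `OTHER_IR`.

Substitutions/insertions/deletions are injected per base at configurable
rates with the CIGAR updated accordingly; indels are suppressed within
5 nt of block boundaries so noise can never silently convert one truth
label into another. Alignments are written directly as a coordinate-sorted
indexed BAM — no aligner is run, so truth labels are exact and outputs are
byte-for-byte reproducible for a given config. Molecule identity draws use
a fixed-width RNG stream separate from error injection; the `mirror`
fixture exploits this to build a reverse-complemented twin locus with
read-for-read identical isoforms, the basis of the strand-symmetry tests.

What the simulator does not emulate: ONT signal-level error structure,
poly(A) tails and their soft-clipping, PCR length bias against short
3′-snoRTs, truncated/chimeric reads from library artefacts, expression
variation across genes, and overlapping alternative transcripts. Passing
tests therefore demonstrate the correctness of the calling logic and
statistics under idealized alignments, not robustness to every real ONT
artefact; the MAPQ, coverage and junction-tolerance knobs exist for that
real-data messiness.

For the retention statistics, count-level generators
(`simulate_retention_summaries`, `simulate_canonical_events`) draw
per-intron binomial counts directly: the t-test and chi-square consume
only per-intron totals, so materializing millions of reads would add cost
without information.

## Problem sizes and numerical choices

The bundled checks run at desk scale, chosen so the whole suite finishes
in well under a minute: mixtures of 2 000–10 000 reads for recovery
checks, 500 3′ reads per box class for cut-point medians, 300 introns ×
5 000 informative reads per group at rates 0.006 vs 0.0001 for the
enrichment comparison (true fold change 60), and 1 000 replicates of
20 000 events per class for type-I calibration of the Yates test (at
these depths the continuity correction is small enough that the test is
calibrated near the nominal 5 %; at much lower counts it is conservative,
which is expected behaviour, not a defect). Stochastic assertions use
3-standard-error bands around the generating values. Ties in medians are
handled by `numpy.median` (mean of central order statistics). Degenerate
inputs — zero informative reads, zero gene totals, zero ddPCR totals —
yield flagged, defined outputs rather than exceptions wherever a
downstream aggregate remains meaningful.
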