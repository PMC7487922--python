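# Methods

## Scope and data model

`editome` operates on *site evidence*: one record per supporting read per
genomic position, carrying the observed base, its Phred quality, the
offsets of the position from both read ends, and the library strand of a
strand-specific (dUTP-style) protocol. This abstraction sits downstream of
alignment and duplicate marking, which are deliberately out of scope: the
package consumes either the bundled TSV dialect or anything a caller
converts into it. All coordinates are 0-based half-open in memory;
GTF/VCF writers and readers use the standard 1-based dialects, BED stays
0-based. Reference data are carried in a single `ReferenceBundle`: genome
sequences, transcript models (exons, CDS, strand-resolved UTRs derived as
exon-minus-CDS), repeat intervals, known-SNP positions and WGS genotype
classes.

## Detection model

A position becomes a candidate RNA–DNA difference when, pooling
quality-passing reads (Phred ≥ 25, the threshold is inclusive) across all
samples, exactly two allele types remain, one of them is the genomic
reference, and the other is supported by at least 3 reads. Pooling across
samples maximizes detection power; per-sample counts are retained so the
per-sample interpretation can be audited downstream. Note a consequence of
the strict two-allele rule: a single high-quality error read of a third
base vetoes a site, so under a realistic per-base error rate (default
1e-3) a few percent of true sites are rejected — visible in the worked
example and intentional.

Five filters then flag candidates; each filter is a pure predicate that
only adds flags, so the cascade is order-independent and the attrition
counts reconcile exactly (`candidates = surviving + flagged`):

1. **Genomic variation.** Positions genotyped heterozygous *or*
   homozygous-alternative in WGS, and positions present in the known-SNP
   catalogue, are flagged. Hom-alt is included although only
   heterozygosity is strictly a confounder: a hom-alt call means the
   reference base is wrong and the site would masquerade as 100% editing.
   The catalogue is matched by position only (stricter than
   allele-matching; the catalogue is a position set).
2. **Splice proximity.** Intronic positions whose distance to the nearest
   exon–intron boundary is ≤ 4 bp are flagged (the first intronic base has
   distance 1). Exonic positions are never flagged by this filter.
3. **Homopolymers.** Positions inside a maximal run of ≥ 5 identical
   reference bases. The run length of 5 is a common convention for this
   artifact class; it is configurable.
4. **Read ends.** Alternative-allele reads with an offset ≤ 6 bp from the
   5′ *or* the 3′ end of their read are removed from the supporting
   counts; the site is flagged when fewer than 3 survive. The "either
   end" reading reflects the artifact mechanism (errors concentrate at
   both read extremities); requiring both offsets to be small
   simultaneously would be vacuous for 150 bp reads.
5. **Multi-mapping.** The ±25 bp window around the call is aligned
   (semi-global edit distance, via `edlib`) against the whole genome with
   the window's own locus masked, and against the reverse complement of
   every contig. The site is flagged when the best other locus reaches
   95% of the self-alignment identity. This is an exhaustive
   local-uniqueness check, practical at the genome sizes this package
   targets; at full mammalian scale the same predicate would be driven by
   an external aligner producing the identical flag.

The transcribed strand is the strand of the single overlapping gene;
overlapping genes on both strands leave it unknown (such calls are
excluded from the mismatch-type tally), and intergenic calls take the
majority library strand of their covering reads, ties unknown. Mismatch
types are reported on the transcribed strand, giving the 12-type spectrum;
unflagged A-to-G calls are the accepted A-to-I sites.

## Quantification

Per-site, per-sample editing level: `nG / (nA + nG)` over reads with
quality ≥ 25, where A/G are counted in transcribed-strand sense (genomic
T/C for minus-strand sites). The level is undefined when A+G coverage
< 10 or fewer than 3 G reads support the edited form — including truly
unedited site/sample pairs, which therefore drop out of level matrices
rather than appearing as zeros. The per-sample *overall* editing rate
pools `Σ nG / Σ(nA+nG)` across all accepted sites with no coverage
criterion; per-stage values are unweighted means over replicates (the
pooled-read alternative is a one-liner on the same counts and both are
written by the pipeline). RPKM is provided for regulator-expression
context: `reads / (exon_kb) / (mapped_reads/1e6)`.

Estimation accuracy is evaluated on the stage-pooled estimator (summed
counts over the replicates of a stage, compared with the mean realized
replicate level). This is the estimator a stage-level claim rests on; a
single-replicate estimate at 100× coverage carries an irreducible binomial
noise floor (sd ≈ 0.03–0.04 at intermediate levels) that no implementation
can beat, while the pooled estimator's error reflects implementation
correctness. Bias is checked per sample at 1000× where the binomial floor
is negligible.

## Differential editing

Sites with at least two defined levels per group enter a two-sided
equal-variance Student's *t*-test (Welch is available by config); sites
failing eligibility are excluded from the Benjamini–Hochberg denominator.
A site is differentially edited (DES) when BH-adjusted q ≤ 0.05 *and*
|Δ| ≥ 0.1, with Δ = mean(later) − mean(earlier), so "up" means editing
rises in the later stage. Degenerate zero-variance/equal-mean sites get
p = 1 rather than NaN. BH is the (unnamed in most method sections) FDR
procedure of choice and is swappable. Sample clustering uses
1 − Pearson correlation over sites defined in every sample, average
linkage, with columns sorted by name first so the tree is invariant to
input order; the tree is exported as Newick. Gene-level integration calls
a gene differentially edited when it hosts ≥ 1 DES, intersects those
genes with a user-supplied DEG list, and tests term over-representation
with a one-sided hypergeometric tail plus BH across terms — a generic
replacement for web-service enrichment tools.

## miRNA binding

For a 3′-UTR site, the ±50 bp genomic flank is taken in transcribed-strand
orientation (truncation at contig edges is recorded), and the edited
variant substitutes G at the center. Each mature miRNA is reversed and
locally aligned (Gotoh affine gaps) against the flank with
complementarity scoring: Watson–Crick +5, G:U wobble +1, mismatch −3, gap
open −9, extend −4, substitution scores doubled at miRNA positions 2–8
(the seed). One best hit per miRNA is kept (ties leftmost); hits require
score ≥ 140 and duplex energy ≤ −7 kcal/mol. The energy model is a
simplified nearest-neighbor sum — one constant per stack class
(G:C/G:C −3.3, mixed −2.1, A:U/A:U −1.1, any G:U −0.5 kcal/mol) plus
+4.1 per interior unpaired stretch; it is deterministic and monotone in
pairing quality, which is what gained/lost/ΔE-sign classification needs.
Numeric parity with any particular external scanner binary is a non-goal.
Per (site, miRNA): *gained* = hit on the edited flank only, *lost* =
reference only, *energy_changed* = both with ΔE ≠ 0, else *unchanged*;
energy distributions are compared with a two-sided Wilcoxon rank-sum.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
exercised:

* **Design.** Three stages × three replicates by default, with stage mean
  editing levels 0.1663 / 0.2087 / 0.1886 — the overall editing rates of
  infancy, puberty and adulthood in the developmental study this package
  models — and 150 bp reads.
* **Genome.** ~50 kb with six genes (alternating strands; four coding
  with 5′-UTR/CDS/3′-UTR/introns, one lincRNA, one novel lncRNA),
  diverged copies of a 180 nt SINE-like consensus ("SINE/tRNA:
  Pre0_SS-like") in introns and 3′-UTRs, planted homopolymer tracts
  (A×7) inside transcribed regions, and one ~400 bp segment duplicated
  into intergenic space. Repeat copies carry 15% random substitutions
  from the consensus — old-SINE-like divergence that keeps distinct
  copies below the 95% multi-mapping threshold. The duplicated copy is
  mutated at a fixed 60 bp spacing, which *guarantees* every 51 bp window
  stays ≥ 50/51 identical between copies, so mismap artifacts are flagged
  deterministically.
* **Truth.** 500 editing sites on transcribed-strand adenosines, 80%
  inside repeats; per-site level = stage mean + a site offset uniform in
  ±0.08 (shared across stages), clipped to [0,1]. Per-replicate levels
  add truncated Normal(0, 0.02) noise — small enough for n = 3 *t*-tests
  to have power at Δ ≥ 0.1; the within-stage variance of real studies is
  not reported anywhere authoritative, so this is an exposed SimConfig
  parameter, chosen once. Sites avoid the filter-trigger zones (runs ≥ 5,
  ≤ 6 bp from exon boundaries, the duplicated segment), because the
  planted *artifacts* are the designated filter violators: 50 read-end
  artifacts (all alternative reads within 6 bp of a read end), 50
  homopolymer artifacts (centers of planted tracts), 50 mismap artifacts
  (adenosines inside the duplicated segment), each at editing-like level
  0.3. 50 heterozygous SNPs appear in RNA at ~50% alternative allele and
  in the WGS VCF as 0/1 genotypes; the known-SNP catalogue lists the same
  positions. 200 background positions contribute pure-reference reads.
* **Reads.** Per site/sample coverage ~ Poisson(mean, floor 1); edited
  read counts ~ Binomial(coverage, replicate level); non-artifact read
  offsets uniform over internal positions; base errors at rate 1e-3
  substitute a uniform other base and draw quality from 10–30 (so roughly
  half the errors survive the quality filter — the mechanism behind the
  two-allele veto noted above). Library strand equals the transcribed
  strand, recorded explicitly.
* **miRNAs.** Engineered against planted 3′-UTR sites in three cycling
  classes — perfect complements of the edited flank (seed over the edited
  base ⇒ gained), of the reference flank (⇒ lost), and complements
  pairing the site outside the seed (⇒ hit kept, energy changed). The
  class is encoded in the miRNA id.

Identical configurations (including the seed) produce byte-identical
files. What the generator does *not* emulate: alignment errors beyond the
duplicated-segment class, PCR duplicates, coverage autocorrelation along
transcripts, hyper-edited read clusters, and allele-specific expression.
Passing tests therefore demonstrate the correctness of the statistical
machinery under the stated generative model, not performance on real
libraries.

## Numerical choices and edge cases

* Quality thresholds are inclusive (≥ 25) everywhere.
* Feature precedence CDS > 3′-UTR > 5′-UTR > ncRNA exon > intron >
  intergenic resolves overlapping transcripts; every site receives
  exactly one label.
* Neighbor preferences are raw frequencies over −1/+1 bases on the edited
  strand; contig-edge sites are skipped per affected column; columns sum
  to 1.
* Majority-strand ties and opposite-strand gene overlaps leave the strand
  unknown; such calls survive filters but are excluded from typing.
* BH q-values come from `statsmodels` and are verified in tests against a
  direct step-up implementation; *t* statistics are verified against the
  pooled-variance formula to 1e-9.
* Clustering requires ≥ 2 sites defined in all samples and fails loudly
  otherwise; the correlation matrix is symmetrized and clipped before
  linkage.
* The alignment tie-break (strictly-greater best-cell update) makes hit
  positions leftmost-deterministic; a duplex with a single base pair has
  zero stacks and energy 0; a duplex with no paired column has undefined
  energy and is never reported as a hit.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
recovery sweeps use ten (tests) or five (script) seeds of the default
500-site study at 50× with the error rate at zero; estimation uses 500
sites at 100× and 200 sites at 1000×; null/power differential checks use
150–200 sites over 10–20 seeds at 30–50×; strand-symmetry and pipeline
checks use a 60-site study. These sizes were chosen so the full stack is
exercised end-to-end in a few minutes on one CPU while keeping every
statistical assertion comfortably powered.

## Known limitations

* The strict two-allele rule discards sites co-occurring with any second
  variant signal; hyper-editing rescue is not implemented.
* The exhaustive multi-mapping check scales linearly with genome size per
  candidate and is not intended for full mammalian genomes without an
  external-aligner adapter.
* The duplex-energy model ranks stability classes correctly but does not
  reproduce experimental ΔG values; gained/lost calls are
  threshold-dependent in the same way as the scanner they emulate.
* miRNA scanning keeps one best hit per miRNA per flank; multiple
  independent sites for the same miRNA on one 101 nt flank are not
  enumerated.
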