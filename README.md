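# editome

Detection and analysis of adenosine-to-inosine (A-to-I) RNA editing from
strand-specific RNA-seq evidence with matched whole-genome genotypes.

A-to-I editing — catalyzed by the ADAR enzyme family — deaminates adenosine
to inosine, which sequencers read as guanosine. An editing site therefore
appears as an A→G mismatch between RNA reads and the genomic DNA, and the
central analytical problem is separating genuine editing from everything
else that produces such mismatches: genomic SNPs, sequencing errors near
read ends, misalignment around splice junctions and homopolymer runs, and
reads placed at the wrong copy of a near-duplicated locus. `editome`
implements the full analysis stack used in developmental editome studies:

* **detection** — candidate RNA–DNA differences from per-read site
  evidence (base quality ≥ 25, exactly two allele types, minor allele
  supported by ≥ 3 reads), followed by five independent filters: WGS
  het/hom-alt genotypes and known-SNP positions; intronic sites within 4 bp
  of splice junctions; homopolymer runs ≥ 5 nt; alternative reads within
  6 bp of either read end; and flanking windows that align elsewhere in the
  genome at ≥ 95% of their self-alignment identity. Mismatch types are
  resolved on the transcribed strand (genomic T→C in a minus-strand gene is
  A-to-G), so the strand-specific library protocol is used rather than
  guessed.
* **quantification** — per-site editing level `nG / (nA + nG)` over
  quality-passing reads (undefined below 10× A+G coverage or 3 supporting
  G reads), and the per-sample overall editing rate
  `Σ nG / Σ (nA + nG)` pooled across all sites with no coverage cutoff.
* **characterization** — genomic feature (CDS > 3′-UTR > 5′-UTR > ncRNA
  exon > intron > intergenic), codon recoding (synonymous vs
  nonsynonymous, e.g. AAT→AGT, Asn→Ser), repeat family/subfamily overlap,
  and −1/+1 neighbor-nucleotide preferences.
* **differential editing** — per-site two-sided Student's *t*-test between
  stage groups, Benjamini–Hochberg FDR within each comparison, and the
  joint call FDR ≤ 0.05 with |Δlevel| ≥ 0.1; plus 1 − Pearson
  average-linkage sample clustering, DEG-overlap, and a hypergeometric
  over-representation test for functional terms.
* **miRNA binding** — a Miranda-style scanner (match +5, G:U wobble +1,
  mismatch −3, gaps −9/−4, seed positions 2–8 doubled) on ±50 bp reference
  vs edited 3′-UTR flanks, a nearest-neighbor duplex-energy model, and
  classification of each miRNA–target pair as gained, lost,
  energy-changed or unchanged upon editing.
* **synthetic studies** — a first-class generator that emulates the data
  structure of a 3-stage × 3-replicate pineal-gland-style study: a small
  annotated genome with genes on both strands, a diverged SINE-like repeat
  family hosting most editing sites, heterozygous SNPs, and planted
  artifacts that each violate exactly one filter. Every pipeline stage is
  testable without any external download.

## Worked example

```python
from pathlib import Path
from editome.config import SimConfig
from editome.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir=Path("run1"), seed=1,
    sim=SimConfig(n_true_sites=120, n_het_snps=15,
                  n_read_end_artifacts=10, n_homopolymer_artifacts=10,
                  n_mismap_artifacts=10, n_background_sites=50,
                  coverage_mean=40.0),
)
report = run_pipeline(cfg)
print(report["n_candidates"], report["n_editing_sites"])
print(report["overall_rate_per_stage"])
print(report["mirna_effects"]["pairs"])
```

prints (exact values for this seed):

```
162 117
{'Y180': 0.215574, 'Y30': 0.172916, 'Y300': 0.191169}
{'energy_changed': 8, 'unchanged': 20, 'lost': 7, 'gained': 6}
```

162 positions passed candidate calling; 117 survived all five filters, and
all 117 are A-to-G on the transcribed strand — exactly the planted truth
minus sites lost to stray sequencing errors that create a third allele
type. The per-stage overall editing rates track the generator's stage
means (16.63% / 20.87% / 18.86%: puberty above infancy and adulthood), and
among the engineered miRNAs the scanner finds binding sites created by the
edit (gained), destroyed by it (lost), and kept with a shifted duplex
energy. The same run writes per-stage tables, annotated site lists, DES
tables, a sample-clustering tree and miRNA hit/effect tables under
`run1/`, plus `run1/report.json` with the full summary. The pipeline is
also exposed as a CLI (`editome run|simulate|detect|profile|diff|mirna`).

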