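# codonmnv

Haplotype-aware re-annotation of **in-codon multi-nucleotide variants
(MNVs)** from GATK-phased multi-sample VCFs.

## The problem

Variant effect predictors annotate each SNP against the reference
sequence as if it were the only change in its codon. When two (or
three) SNPs fall inside the *same codon* and travel on the *same
haplotype*, the codon that is actually translated carries all of the
alternative alleles at once, and its consequence can differ sharply
from any single-SNP prediction. The canonical failure mode is the
**rescued stop-gained**: one SNP alone turns CGA (arginine) into TGA
(stop), but on the haplotype where it always co-occurs with a second,
individually "synonymous" SNP, the codon is TGC (cysteine) — a missense,
not a truncation. In an RNA-seq cohort of 382 chickens this affected
~95% of apparent stop-gained codons, and overall 41.1% of in-codon MNVs
changed annotation once the haplotype was considered.

`codonmnv` re-implements that analysis: it reads a genome FASTA, a GTF
with CDS features, and a multi-sample VCF carrying GATK
HaplotypeCaller's physical-phasing FORMAT fields (`PGT`, phased
genotype; `PID`, phase-set identifier); groups biallelic coding SNPs by
(transcript, codon); decides per sample whether the alternative alleles
are in **cis** (same `PID`, same `PGT` side, or homozygous-alt) or in
**trans**; calls an MNV when at least one individual carries the full
haplotype; re-translates the haplotype codon; and classifies the
re-annotation **flux** — *eased*, *equal* or *aggravated* — against the
most severe constituent-SNP consequence, using the severity order

```
stop_gained > stop_lost > start_lost > missense > stop_retained > synonymous
```

It ships a first-class synthetic-data generator that plants MNV truth
(designed consequence triples found by exhaustive search over the
standard genetic code) into toy cohorts, so every step is testable
against a machine-readable manifest.

## Worked example

```
$ python analysis/04_rescued_stop_example.py --seed 1
four haplotype codons (coding strand) and their consequences:
  reference      CGA  -> R
  SNP1 alone     TGA  -> *
  SNP2 alone     CGC  -> R
  MNV haplotype  TGC  -> C
SNP-level (most severe constituent): stop_gained
MNV-level re-annotation:             missense (R -> C)
flux: eased; rescued stop-gained: True
cis carriers: 12 of 24 samples
```

The gene sits on the reverse strand, so the VCF alleles are the
complements of the coding-strand bases shown; the pipeline handles the
strand flip, splice junctions and the phase bookkeeping internally.

The other analysis scripts follow the same pattern:
`analysis/01_simulate_cohort.py` writes a 40-sample toy cohort with 20
planted cis MNVs, 3 trans-only pairs and 4 singleton errors;
`analysis/02_detect_and_reannotate.py` runs detection on it and reports
precision/recall 1.000/1.000 against the manifest;
`analysis/03_published_flux_reanalysis.py` recomputes the published
cohort percentages (95.6% rescued stop-gained, 37.3% novel-amino-acid
missense, 41.1% changed impact, 86% stop-gained decline, twofold
synonymous growth, 31% singletons) from the shipped count matrix through
the ordinary summarize path.

There is also a CLI for running on your own files:

```
codonmnv detect --vcf calls.vcf --gtf genes.gtf --fasta genome.fa \
    --outdir out/ --min-carriers 5
codonmnv simulate --outdir fixture/ --seed 7
codonmnv summarize --flux out/flux.tsv --outdir summary/
```

`detect` writes per-SNP annotations, the per-MNV table (with carrier
counts and optional per-population counts), the trans-pair side table,
the per-MNV flux table, the flux summary matrix across carrier
thresholds, and the headline statistics.

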