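# Methods

## Model and procedure

An in-codon MNV is defined as 2–3 biallelic SNPs that (i) map to the
same codon of the same transcript and (ii) are carried in cis — on one
haplotype — by at least one individual. The pipeline is a deterministic
sequence of steps:

1. **Codon assignment.** Each biallelic SNP (1 bp REF, single 1 bp ALT;
   indels and multi-allelic sites are skipped with a logged count) is
   mapped into the spliced, frame-trimmed CDS of every usable transcript
   that contains it. Coordinates are 1-based inclusive at every module
   boundary (matching VCF `POS` and GTF `start`/`end`); on the `-`
   strand the CDS is read from the highest genomic coordinate downward
   and VCF alleles are complemented onto the coding strand. Codons
   spanning splice junctions are handled by the spliced representation.
2. **Consequence classification.** The reference and alternative codons
   are translated with the standard genetic code (table 1, via
   Biopython) and classified into six categories by ordered rules:
   start_lost (codon 1, reference ATG, alternative ≠ ATG);
   stop_retained (stop → stop); stop_lost (stop → non-stop); stop_gained
   (non-stop → stop); synonymous (same amino acid); else missense.
   Severity ranks them stop_gained (1) … synonymous (6), and the
   SNP-level annotation of a codon group is its most severe constituent
   call, ties resolved by codon-offset order.
3. **Phase interpretation.** Per candidate and sample:
   any site without the alternative allele (or no-call) → non-carrier;
   all sites homozygous-alt → cis carrier (phase is logically forced);
   heterozygous sites all sharing one `PID` with their alt alleles on
   the same `PGT` side (remaining sites hom-alt) → cis carrier; shared
   `PID` but opposite sides → trans; any het lacking `PGT`/`PID`,
   differing `PID`s, or a `PGT` inconsistent with the `GT` → unphasable.
   A sample hom-alt at one site and *unphased*-het at the other is
   deliberately unphasable, not a carrier: the conservative reading when
   read-based phasing provides no evidence.
4. **Calling and support filtering.** A candidate with ≥ 1 cis carrier
   becomes an MNV call; trans-only groups go to a side table and are
   never MNVs. Calls are filtered at a minimum carrier count
   (default 5); carrier-count-1 calls are flagged as likely sequencing
   errors. 3-SNP groups are detected and called but excluded from the
   default flux analysis (`include_three_snp` opts in).
5. **Flux classification.** The haplotype codon substitutes all
   alternative alleles simultaneously; its consequence is compared with
   the SNP-level one: eased when strictly less severe, aggravated when
   strictly more severe, else equal. For missense → missense with *all*
   constituents missense, the subtype is `novel_aa` when the MNV amino
   acid differs from every constituent prediction, else `shared_aa`.
   `changed_impact` is true when the category changes or the subtype is
   novel. The rescued-stop flag marks SNP-level stop_gained that the
   MNV does not preserve.
6. **Summaries.** The flux summary is the count matrix of
   (SNP-level → MNV-level) transitions across a carrier-threshold ladder
   (default 1, 2, 3, 4, 5, 10, 15, 20, 30, 50, 100); each column counts
   MNVs at or above that threshold, so columns sum to the per-threshold
   totals and are monotone non-increasing. Headline statistics at one
   threshold are derived entirely from the matrix plus the novel-aa
   count: rescued-stop share, missense→synonymous and novel-aa shares of
   initial missense, overall changed-impact fraction, stop-gained
   decline, synonymous fold change and the singleton share (drop from
   the threshold-1 to threshold-2 total). Zero denominators report
   `None` ("undefined"), never 0.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_carriers` | 5 | minimum cis carriers for a reliable MNV (individuals) |
| `thresholds` | 1…100 ladder | columns of the flux summary matrix |
| `include_three_snp` | off | admit 3-SNP codon groups into flux analysis |
| rounding | half away from zero | percentages printed to 1 decimal; decline and singleton shares to integers |

## Published-cohort reanalysis

The (transition × threshold) count matrix and the novel-amino-acid count
(1,038 at the ≥5 threshold) reported by a 382-chicken, 11-population
RNA-seq survey are shipped as input data (`reference_counts.py`). The
cumulative matrix is differenced into carrier-count bins and inflated to
a record-level table (records in bin [tᵢ, tᵢ₊₁) get carrier count tᵢ;
the within-bin distribution is unknowable and irrelevant at the
published thresholds), which the ordinary summarize path re-aggregates.
All quoted percentages are therefore recomputed, not transcribed; this
also pins the headline formulas, e.g. the changed-impact fraction is
(all off-diagonal cells + novel-aa count) / total, which reproduces the
published 41.1% exactly.

## Synthetic cohorts

The generator emulates the *structure* of the real cohort at toy scale:
a small three-chromosome genome; one single-transcript protein-coding
gene per planted codon group, with 1–3 CDS exons, 20 bp introns, ≥ 30 bp
intergenic padding (so planted truth is the only truth) and roughly half
the genes on the reverse strand; 40 samples labeled round-robin with 11
population names. Designed (snp1, snp2, mnv) consequence triples are
realized by exhaustive search over the genetic code (the rescued-stop
design prefers the canonical CGA + T@1/C@3 triple); unrealizable designs
— e.g. synonymous + synonymous → stop_gained, or any
synonymous + synonymous → missense, which the code table cannot produce
— fail loudly at plan time. Terminal-stop designs (stop_lost,
stop_retained) are placed in the annotated terminal codon, which the
generator includes inside the CDS span; start_lost designs occupy
codon 1.

The default panel plants 16 cis MNVs with 2–25 carriers (including
reverse-strand and splice-junction-spanning cases and carriers realized
as phased het/het, hom-alt/hom-alt and mixed hom-alt + phased-het), 4
singleton errors, 3 trans-only pairs, ~5% unphased-het samples per
group, and two genes with a lone coding SNP (which must never yield a
candidate). Everything derives from one `numpy` generator seeded by the
config, and identical (config, seed) produce identical output bytes.

What the generator does *not* emulate: read-level errors, realistic
allele-frequency spectra, linkage beyond the planted codon pair,
multi-isoform genes sharing codons, or phase sets broken by read length.
Passing the planted-truth tests therefore demonstrates correctness of
the coordinate, phase and classification logic — not robustness to
upstream calling artifacts, which enter a real analysis through the VCF.

## Numerical and edge-case choices

- Transcripts are dropped (logged) when the frame-trimmed CDS length is
  not divisible by 3, or when the reference translation contains an
  internal stop; a queried codon overlapping an `N` skips that
  transcript for that SNP.
- start_lost requires the annotated first codon to be ATG; alternative
  start codons are out of scope. stop_retained can only arise where the
  reference codon is a stop, i.e. the terminal codon of a clean model.
- `PGT` orientation is evaluated on the strings as written (GATK keeps
  orientation consistent within one `PID` group); a `PGT` whose alleles
  disagree with the `GT` is warned about and treated as unphasable.
- MNV identity for counting is (transcript, codon index, alt alleles);
  a genomic-level deduplicated count (chrom, positions, alleles) is also
  logged, since isoforms may share a codon.
- Percentages round half away from zero to match conventional reporting;
  byte-stable TSV output makes summaries reproducible verbatim.

## Scale of the shipped analyses

The analysis scripts and acceptance checks run on the 40-sample default
cohort (23 planted groups, 48 SNPs) and on the exhaustive codon spaces
(576 single- and 1,728 two-substitution cases); each completes in
seconds. These sizes were chosen as the smallest cohorts that exercise
every planted scenario class simultaneously; the library itself streams
per-record and has no fixed scale assumptions.

## Known limitations

- Only in-codon MNVs are considered; gnomAD-style multi-codon window
  MNVs, indels and UTR/splice-region consequences are out of scope.
- Phasing is consumed, never inferred: codon pairs whose sites were not
  phased by the caller (e.g. split across reads) fall to unphasable and
  are invisible, mirroring the read-based-phasing limit of the original
  analysis.
- One consolidated VCF is assumed; merging per-tissue VCFs and
  reconciling duplicate sites is upstream of this package.
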