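# Methods

## Scope and data model

`minivar` analyses the population variability of minimotif instances — short
(2–15 aa) contiguous peptides with an experimentally assigned molecular
function — in a diploid cohort. Inputs are a reference genome (FASTA),
transcript models (TSV with exon blocks, strand and frame), a simplified VCF
genotype panel with an `AA=` ancestral-allele INFO key, a minimotif table
(protein coordinates, activity class, optional `mmod` critical-residue
position), per-site GERP/SLR/PhyloP score tables, a BED3 high-confidence mask
and a sample→population→continent panel.

Coordinate conventions: genomic intervals are 0-based half-open internally;
VCF and score positions are 1-based; protein residues are 1-based inclusive.
All conversions pass through `minivar.coords`.

## Personalized proteomes and the match matrix

The reference proteome is translated from the transcript models (standard
nuclear code; minus-strand exons reverse-complemented; translation stops at
the first stop codon; a CDS with an internal stop is excluded and logged).
Predicted reference proteins are accepted against an external reference only
if residues 2–15 match exactly, the lengths are identical and overall
positionwise identity is ≥ 90%; for proteins shorter than 15 residues the
first rule uses the available 2..L overlap. This validation is deliberately
*not* repeated for personal proteomes — a person's variant may legitimately
change residues 2–15.

Personal proteomes substitute each sample's two alleles into two haplotype
genomes before translation. Unphased heterozygotes place the alternate allele
on haplotype 2; this is an arbitrary non-contract choice, since every
downstream quantity depends on allele dosage only. Missing genotypes
substitute N (translating to an `X` residue that carries no match-matrix
weight); stop gains truncate the haplotype protein.

The match matrix assigns each person total weight 1, 0.5 per haplotype, with
a denominator fixed at the cohort size. Missing data therefore reduces a
column's sum rather than shrinking the denominator — the simplest convention
consistent with a fixed-N normalizer, and the one asserted by the
column-stochasticity tests. Positions past a stop-gain truncation are treated
as missing the same way.

## Classification

Each motif residue maps to three genomic coordinates in translation order
(descending on the minus strand; codons may straddle exon junctions). A
variant hitting a motif yields one record per overlapping motif instance —
tallies count motif instances, as a motif database enumerates them — while the
distinct-SNP summary row deduplicates shared variants.

* **Effect**: translation of reference vs alternate codon. Nonsense hits are
  folded into the missense tallies but flagged.
* **Position kind**: critical iff the altered residue equals the motif's
  `mmod` position.
* **Ser↔Thr exception**: a critical S↔T substitution in a phosphorylation
  motif is reported separately and is never a LOFM (dual-specificity kinases
  phosphorylate both residues).
* **LOFM/DM**: restricted to autosomal variants with a known ancestral allele
  (elsewhere `unknown_ancestral`). Ancestral = reference allele ⇒ the motif is
  ancestral and the derived allele destroys it (LOFM); ancestral = alternate
  allele ⇒ the motif residue is newly derived (DM). An ancestral base matching
  neither allele is logged and treated as unknown.
* **MAF class**: minor-allele count 1 ⇒ singleton; MAF < 1% (strict) ⇒ rare;
  otherwise common. Singleton takes precedence over rare. The rare cutoff is
  configurable (`maf_rare_cutoff`). The per-site denominator is called
  chromosomes, so missing genotypes shrink it.

## Selection metrics

* **Substitution rate**: `n_segments` fixed-length segments (default 12 bp,
  the motif-scale window) are drawn uniformly *with replacement* from all
  placements fully inside one interval of a mask-intersected region class;
  the replicate rate is covered variant sites (counted once per covering
  segment) per sampled base. Sampling with replacement keeps the estimator's
  expectation equal to the region's per-bp variant density; replicate variance
  shrinks as 1/`n_segments` (tested). Defaults: 50 000 segments × 5
  replicates.
* **Replicate comparison**: a two-sided Welch t-test on the replicate rates.
  The underlying study never names its test; Welch is the conservative default
  for 5-replicate mean comparison. Two zero-variance equal-mean vectors give
  p = 1 by convention.
* **GERP**: scores > 2 are constrained; scores exactly 0 are omitted from both
  numerator and denominator of any constrained fraction; absent scores are
  excluded.
* **SLR**: three-way thresholding at −3 (negative selection) and +3 (positive
  selection), strict inequalities, boundary values neutral. The published
  figure legend's alternative (4/6) thresholds contradict the accompanying
  text; the text's −3/+3 are the defaults and any pair is reachable via
  configuration.
* **PhyloP** is summarized descriptively (median, mean, n); no threshold class
  is defined for it.

Stratified runs (per activity, or any tagged gene subset such as histones)
reuse the identical operations on a restricted variant set; recombining
stratum compositions reproduces the pooled composition exactly (tested).

## Population differentiation

The derived allele is the one differing from the ancestral base; DAF is the
derived dosage over called chromosomes. A continent's DAF is the **unweighted
mean** of its populations' DAFs — mirroring summaries built from
per-population values — with populations flagged admixed excluded under the
default `strict` policy (they remain available at population level and can be
included with `lenient`; chromosome pooling is deliberately not the default).
ΔDAF is the absolute DAF difference, symmetric and invariant to ref/alt
relabeling while the ancestral allele is fixed. Intercontinental pairs are
restricted to {AFR, EUR, ASN}. The high-ΔDAF extraction considers DMs and
LOFMs only, keeps alleles whose maximal intercontinental ΔDAF exceeds the
threshold (default 0.5) and reports them signed (`+` DM, `−` LOFM), sorted
descending.

## The synthetic cohort

The generator emulates the *shape* of the real study inputs, not their
population-genetic fine structure. What it does model:

* random multi-exon genes on both strands, with exon boundaries at arbitrary
  transcript offsets (codons straddle junctions) and a third of genes carrying
  a nonzero frame offset — the geometry the proteome code must survive;
* motif instances of length uniform in [2, 15]; PTM-class motifs carry an
  `mmod` residue, and phosphorylation motifs are placed around an existing
  Ser/Thr; activities follow a configurable mix defaulting to a
  phosphorylation-dominated database-like composition;
* planted SNVs: a configurable fraction (default 0.15) on `mmod` codons, of
  which a fraction (default 0.05, echoing how much rarer derived motifs are
  than losses) get ancestral = alternate allele; the remainder on random
  unused codons (one variant per codon) and a fraction (default 0.10) in
  intergenic space; stop gains and edits of the terminal stop codon are never
  planted so personal proteomes stay length-aligned;
* allele frequencies per site from a Beta(0.2, 2) minor-allele distribution
  (strongly rare-skewed, most MAFs below 10%), with optional per-continent
  divergence and small per-population jitter (default 0.01); genotypes are
  binomial per sample over a 1000-Genomes-like panel of 10 populations × 12
  diploids across AFR/EUR/ASN, one admixed. An optional two-point SFS
  (`sfs_two_point`) places the rare mass far from the 1% boundary so that
  rare-mass recovery experiments are well-posed at finite sample size;
* optional planted high-divergence sites: critical, autosomal,
  known-ancestral variants whose continental frequencies differ by a
  configured gap (default 0.8);
* conservation scores drawn per variant from class-conditional normals, the
  latent class following a configurable mixture (default 60/38/2
  negative/neutral/positive). SLR values are truncated to their class's
  interval so the planted composition is recoverable by thresholding; GERP is
  clipped to the empirically observed range [−12.3, 6.2].

What it does **not** model: linkage disequilibrium, recombination,
coalescent genealogies, realistic phasing, sequencing error, or the real
covariance between conservation scores and allele frequency. Variants are also
planted preferentially inside motifs (to exercise the classifier), so the
synthetic ordering of region substitution rates does not reproduce the real
data's ordering. Passing tests therefore demonstrate that the *computations*
are correct and their estimators unbiased on controlled input — not that the
synthetic cohort reproduces real-cohort summary statistics.

Randomness uses a single root seed with deterministically spawned per-stage
child streams; a fixed seed yields byte-identical output files.

## Numerical and rendering choices

Percentages are rendered round-half-even at 3 significant figures (2 for the
coarser phosphorylation-summary table), trailing zeros kept, zero counts
printed as `0`. Totals rows are always the column sums of the printed
per-activity counts — the renderer enforces the consistency that hand-built
tables sometimes lose. Counts in the human report are space-grouped
("18 542"); machine TSVs never group. Composition fractions are asserted to
sum to 1 within 1e-12.

## Problem sizes

The default synthetic study — 200 genes, 2 000 motifs, 5 000 variants, 120
diploid samples — was chosen as the smallest cohort at which every downstream
stratum (per-activity tables, DM/LOFM grids, ΔDAF tables) is well populated;
the full pipeline including the match matrix completes in well under a minute
on one core, and the statistical acceptance checks use 3-sd tolerances at
these sizes. Estimator experiments use 5 000 segments × 5 replicates
(substitution rate) and 5 000 variants (rare mass, SLR mixture).

## Known limitations

* The VCF reader supports the analysis subset only: GT-first FORMAT, biallelic
  SNV extraction, `AA=` ancestral key; no structural variants or additional
  FORMAT fields.
* Validation rule (c) uses positionwise identity of equal-length sequences;
  there is no alignment, selenocysteine handling, or alternative codon table.
* Half-calls arising from multi-allelic splitting contribute only their called
  allele; the affected sample's other allele is treated as missing for that
  biallelic record.
* X-chromosome variants are excluded from LOFM/DM assignment (the ancestral
  comparison is defined for autosomes) but participate in every other metric.
* Whether admixed populations belong in continental aggregates is genuinely
  ambiguous in practice; both behaviors are exposed (`strict`/`lenient`) with
  `strict` as default.
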