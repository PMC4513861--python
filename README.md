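# minivar

Population variability of **minimotifs** (short linear motifs, SLiMs): a
pipeline for asking how often the 2–15-residue functional peptides of a
proteome — phosphorylation sites, cleavage sites, binding elements — are
polymorphic in a sequenced cohort, which variants destroy or create motif
function, and how those alleles are distributed across populations.

Minimotifs are short enough that a single missense SNV can eliminate a
function (mutating the serine of a phosphosite) or create one. `minivar`
builds personalized proteomes from a diploid genotype panel, quantifies
per-residue variability as a cohort match-fraction matrix, classifies each
motif × variant pair, and measures selection and geographic differentiation.

## The core quantities

**Match-fraction matrix.** For a cohort of *N* diploid individuals aligned to
the reference proteome, the matrix entry for amino acid *k* at proteome
position *j* is

```
M[k, j] = (1/N) Σ_i  I(X_{i,j} = k)
```

where person *i* contributes weight 1, split 0.5 per haplotype — a
heterozygote Ala/Gly site reports 0.5 for each residue. Columns sum to 1
wherever every haplotype carries a standard residue; missing genotypes and
positions beyond a stop-gain truncation reduce the column sum.

**Variant classification.** Each SNV inside a motif is classified by codon
translation (synonymous / missense / nonsense), by position (a *critical* hit
alters the covalently modified `mmod` residue; anything else is *degenerate*),
and — for critical missense hits with a known autosomal ancestral allele — by
the ancestral state: if the ancestral allele encodes the motif residue the
variant is a **loss-of-function minimotif (LOFM)**; if the motif residue is
the derived state it is a **derived minimotif (DM)**. Ser↔Thr substitutions at
phosphosites are functionally tolerated by dual-specificity kinases and are
reported separately, never as LOFMs.

**Selection metrics.** Substitution rates are estimated by drawing fixed-length
(12 bp) segments uniformly with replacement from a high-confidence region
class and counting covered variant sites per base, replicated for a Welch
t-test between region classes; rare-variant fractions use singleton / rare
(MAF < 1%) / common classes; GERP scores > 2 are called constrained (exact
zeros omitted); SLR scores are thresholded at −3/+3 into negative selection,
neutral drift and positive selection.

**ΔDAF geography.** Derived allele frequencies are computed per population,
averaged (unweighted) over a continent's non-admixed populations, and compared
pairwise; DM/LOFM alleles whose maximal intercontinental ΔDAF exceeds 50% are
extracted into a signed table (`+` DM, `−` LOFM).

Because the real inputs (a 1000-genomes-scale panel plus a curated motif
database) are far beyond desk scale, the package ships a first-class
synthetic-cohort generator (`minivar.simulate`) that emits every input format
with ground-truth labels for each downstream call, so the whole pipeline is
validated by exact truth recovery and planted-parameter recovery.

## Worked example

```python
from minivar import CohortSpec, PipelineConfig, run_pipeline

config = PipelineConfig(
    simulate=CohortSpec(n_genes=60, n_minimotifs=400, n_variants=1200,
                        n_high_ddaf_sites=2),
    seed=7, outdir="demo_run", n_segments=5000,
)
manifest = run_pipeline(config)
print(open("demo_run/report.txt").read())
```

The report for this run ends with:

```
DM / LOFM minimotifs (autosomal, known ancestral allele)
--------------------------------------------------------
Activity         DMs  LOFMs
Acetylation      0    20
Glycosylation    0    7
Phosphorylation  6    81
Proteolysis      1    20
Ubiquitination   1    27
Total            8    155
```

i.e. of the 400 simulated motifs, 163 suffered a critical-residue missense
SNP; 155 of those with a known autosomal ancestral allele destroy an ancestral
motif (LOFMs) and 8 are newly derived motif alleles (DMs). The two planted
high-divergence sites surface in `demo_run/high_ddaf.tsv` with intercontinental
ΔDAF of 0.88 and 0.74 (both `−`, i.e. LOFMs), and
`demo_run/selection_composition.tsv` recovers the planted SLR mixture
(60% negative / 38% neutral / 2% positive) within sampling error.

The same stages are available from a shell:

```sh
minivar simulate --seed 7 --out inputs/
minivar run-all --config config.yaml --out run/
minivar report --run run/
```

Re-running any command with the same seed produces byte-identical outputs.

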