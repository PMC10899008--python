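# regmk

Inference of *cis*-regulatory selection on a degenerating Y chromosome:
polarized X/Y substitution rates in accessible chromatin regions (ACRs),
GC-matched intergenic permutation nulls, pooled and per-gene
McDonald–Kreitman (MK) tests, filtered nucleotide diversity, and
allele-specific-expression association — with a synthetic-data generator
that provides exact ground truth for every stage.

## The problem

After recombination stops between a young X and Y, the Y accumulates
substitutions. Whether the substitutions piling up in Y-linked
*regulatory* sequence (open-chromatin regions that act as enhancers and
promoters) are driven by positive selection — e.g. selection to silence
gametologs that carry deleterious coding mutations — or merely by
inefficient purifying selection is a population-genetics question:
positive selection predicts divergence *above* the neutral intergenic
rate together with a *deficit* of segregating polymorphism.

The package implements the full inferential chain for that question, for
anyone with (i) three-way alignments of X gametolog regions, their Y
homologs and an outgroup autosome standing in for the ancestral state,
(ii) ACR intervals, (iii) population genotypes from hemizygous males,
and (iv) allele-resolved expression counts.

## Core statistics

* **Polarization.** In an aligned column (X, Y, O) with outgroup O:
  X ≠ O = Y is an X-branch substitution, Y ≠ O = X a Y-branch
  substitution; X = Y ≠ O is fixed between species (predates the sex
  chromosomes, ignored), and three distinct states are ambiguous
  (excluded). Per-region rates are d_X = n_X / L and d_Y = n_Y / L over
  the L columns assayable in all three sequences.
* **Permutation null.** For each ACR, random intergenic regions of equal
  length and GC content within ±2 percentage points are drawn; over
  n sets the empirical p-value of the observed mean ACR divergence is
  (r + 1)/(n + 1), r the number of null means at least as extreme.
* **Noncoding MK test.** With divergence D and polymorphism P pooled over
  ACRs (focal) and matched intergenic sequence (neutral):
  NI = (P_ACR/P_INT)/(D_ACR/D_INT), α = 1 − NI, significance by 2×2
  chi-square (Pearson and Yates variants), dispersion by bootstrap over
  regions. NI < 1 indicates positive selection. The coding MK test is the
  same table with nonsynonymous/synonymous site counts classified per
  codon against the outgroup. Gene-level tables use
  NI_Haldane = ln[((PN+½)/(PS+½)) / ((DN+½)/(DS+½))], finite for zero
  counts, with classes: purifying > 0.25, positive < −0.25, relaxed
  in between.
* **Diversity.** Per-site π = c_ref·c_alt / C(n,2); hemizygous
  compartments reject heterozygous calls, depth outside half-to-double
  the chromosome median is discarded; 10-kb window averages and
  region/autosome ratios against the neutral expectations (Y 25 %,
  X 75 %).
* **Expression association.** ASE = log2(mean X counts / mean Y counts);
  Spearman rank correlation against mean assigned-ACR divergence with a
  percentile bootstrap CI, Fisher-Z comparison of two correlations, and
  a randomized down-sampling significance test.

## Worked example

The MK machinery applied to a published pooled noncoding table row
(Y chromosome, oldest stratum, testis ACRs):

```python
>>> from regmk.selection_tests import MKTable
>>> t = MKTable(d_focal=739, d_neutral=555, p_focal=18, p_neutral=46)
>>> round(t.ni, 3), round(t.alpha, 3), round(t.chi2, 2)
(0.294, 0.706, 20.77)
```

NI = 0.294 < 1: ACRs carry 3.4× less polymorphism per unit divergence
than intergenic sequence — an excess of fixed differences consistent
with positive selection; α estimates that ~71 % of ACR substitutions
were fixed adaptively, and the chi-square (20.77, p < 0.001) rejects
neutrality.

The full synthetic study runs as numbered drivers:

```bash
python analysis/01_simulate_cohort.py      # cohort -> results/sim/
python analysis/02_acr_divergence.py       # polarized rates + class contrast
python analysis/03_permutation_null.py     # GC-matched permutation p-values
python analysis/04_mk_tests.py             # pooled noncoding + per-gene coding MK
python analysis/05_diversity.py            # filtered pi, windows, ratios
python analysis/06_expression_association.py
```

On the default cohort (seed 7: 60 ACRs across three strata, Y rates 3×
elevated inside ACRs with a 0.3× polymorphism deficit, 12 hemizygous
males) the drivers print, among others:

```
S1: H = 29.34, p = 6.06e-08, letters {'acr': 'b', 'intergenic': 'a'}
S1  Y  observed_mean 0.1145  null_mean 0.02327  p_greater 0.0005
pi per bp: chrX 0.000585, chrY 0.000037, chrA 0.001128
Y/autosome ratio 0.033 (neutral expectation 0.25, deviation -0.217)
Y-branch divergence vs log2(X/Y): rho = 0.200 (95% CI -0.057..0.434, p = 0.1262, n = 60)
```

Stratum-1 Y-branch ACR divergence (0.115/bp) sits far above the
GC-matched intergenic null (0.023 ± 0.004), the Y carries 3 % of
autosomal diversity against the 25 % neutral expectation, and the
divergence–expression correlation is positive (the generator's latent
correlation is 0.40; individual 60-gene cohorts scatter around it with
SD ≈ 0.10, and this cohort's bootstrap CI covers it).

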