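# Methods

This note documents the models, numerical conventions and design
choices behind `regmk`, and what the synthetic cohorts do and do not
establish about real data.

## Coordinates and intervals (`genome_io`)

All coordinates are 0-based half-open internally. BED/narrowPeak are
consumed as-is; GFF3 (1-based inclusive) is converted at the parsing
boundary. Intergenic space is the complement, within the chromosome, of
the union of genes, repeats and ACRs. ACRs are assigned to the gene
whose TSS (start on `+`, end−1 on `-`) is nearest, within 50 kb. The
ACR anchor is its midpoint by default; a nearest-edge anchor is
available (`anchor="edge"`) because the 50-kb convention in the
literature does not fix the ACR-side reference point. Equidistant TSSs
are broken deterministically by lower coordinate, then lexicographic
gene id. Strata are attached to intervals from the stratum of the
interval midpoint given a plain-text boundary table.

## Polarized divergence (`divergence`)

Each alignment column of (X, Y, outgroup) is classified by outgroup
parsimony: a substitution is assigned to the branch whose sequence
differs from the outgroup while the other gametolog matches it.
Columns where X = Y ≠ outgroup predate recombination suppression and
are excluded from both branch rates; columns with three states are
ambiguous and also excluded — exclusion, rather than majority
assignment, is conservative and keeps the rates interpretable as
branch-specific lower bounds. Columns with a gap or N anywhere are
removed from the denominator, so rates stay ≤ 1 in gapped alignments;
a raw-length denominator is not offered because it is not comparable
across alignments of different quality. Flank columns (±50 bp
extraction padding, used as alignment anchors) are excluded from the
denominator by default and can be included with `include_flanks=True`.

Class comparisons use the Kruskal–Wallis omnibus (scipy) and a
hand-rolled Dunn's post hoc: normal approximation on mean rank
differences with the standard tie correction, Bonferroni-adjusted over
all pairs within a stratum, summarized by an insert-and-absorb compact
letter display. When all pooled observations are identical the omnibus
is reported as (0, 1) directly, since the rank test is undefined there.

## Permutation null (`permutation_null`)

GC content is (G+C)/(A+C+G+T), N excluded from both terms. For each
ACR, control starts are drawn uniformly over every intergenic placement
that can hold the ACR's length, and accepted when the control GC is
within an absolute tolerance (default ±2 percentage points) of the
ACR's; the retry budget is 1,000 candidate draws per ACR per set, and
an ACR that cannot be matched is flagged and excluded from every set so
set sizes stay equal. Draws are with replacement by default; options
disallow repeated starts within a set (`with_replacement=False`) or any
within-set overlap (`non_overlapping=True`). The non-overlap option
exists because overlapping control windows double-count sites and
overdisperse pooled MK counts — count-based tests downstream of the
sampler should use it, as driver 04 does; the divergence-mean null of
driver 03 does not need it.

Empirical p-values use the add-one estimator p = (r+1)/(n+1) with
non-strict exceedance, so p = 0 is never reported; `two_sided` doubles
the smaller one-sided value, capped at 1. One-sided tails in both
directions are reported alongside it because elevated and depressed
divergence are both of interest.

## MK tests (`selection_tests`)

NI = (P_f/P_n)/(D_f/D_n) and α = 1 − NI exactly; negative α is reported
as-is (adaptive fixation rate indistinguishable from zero). The 2×2
chi-square is provided in both the Pearson and the Yates-corrected
variant and every report carries both, because published tables mix the
two variants row by row; neither is declared canonical. NI_Haldane adds
0.5 to each cell before the log odds ratio; the natural log is used, and
the gene-classification thresholds (±0.25) are applied on that scale,
with boundary values assigned to the relaxed class. A site counts as
divergence only when the population sample is monomorphic for the
derived allele; a biallelic segregating site counts as polymorphism.
Codon-context classification substitutes the focal allele into the
outgroup codon and compares translations (standard code, via
Biopython); sites with N, codons with alignment gaps, sites with
missing genotypes, and non-biallelic sites are omitted with recorded
reasons, and a premature stop in the outgroup frame flags the gene and
omits that codon.

The bootstrap resamples whole regions (or genes) with replacement
within each factor, re-pools, and recomputes NI/α per replicate —
resampling the region, not the site, preserves within-region
correlation. Replicates with an undefined NI are dropped and counted;
more than 50 % undefined flags the interval unstable.

## Diversity (`diversity`)

Per-site π = c_ref·c_alt / C(n,2) over called alleles (haploid calls
contribute one allele, diploid two; mixed ploidy at a site is
rejected). Filters: biallelic only; no heterozygous call in hemizygous
(noncrossover) compartments; per-site mean depth across samples within
half-to-double the per-chromosome median (defaults 3.5–14 for the sex
chromosomes, 6.5–26 for the autosome). The half-integer bounds act as
strict interval membership on the mean depth. Filters are conjunctive
and therefore order-independent.

Windows tile the chromosome at 10 kb. Two window denominators are
implemented because the convention differs by use: `"sites"` (mean π
per segregating site — informative about allele-frequency shape,
insensitive to θ) and `"length"` (summed site π per bp — the scale on
which chromosome-level diversity and region/autosome ratios are
quoted). Chromosome summaries exclude empty windows by default and can
include them as zeros, which is the correct choice under the per-bp
denominator. Neutral expectations for hemizygous compartments are Y =
25 % and X = 75 % of autosomal diversity (equal sex ratio).

## Expression association (`expression_assoc`)

ASE is log2 of the ratio of replicate-mean counts, X over Y; no
cross-library normalization is applied because counts are only compared
within a gene. Transcripts with all-zero counts are removed; genes with
one silent allele have an infinite ratio and are excluded by default
(an explicit pseudocount option, +0.5 to both means, retains them) —
exclusion avoids an arbitrary constant dominating the tail of the
distribution. Spearman's rho uses scipy; the 95 % CI is a percentile
bootstrap over gene pairs (row-vectorized rank correlation).
Correlations are compared with the Fisher Z transformation on the
correlation coefficients. The down-sampling test subsamples pairs
without replacement and evaluates Spearman significance with the
t approximation; it answers "would a smaller cohort still have seen
this?".

## Synthetic cohorts (`synthetic_data`)

The generator emulates the statistical structure the inference
machinery assumes, not the biology that produced it:

* The ancestor is drawn with a piecewise-linear GC field (control
  points every 10 kb, constant within each kb, default range
  0.35–0.55), split evenly G/C and A/T — so GC matching is exercised
  against real heterogeneity.
* X and Y derive from the ancestor by independent per-site
  substitution at stratum rates (defaults d_X = 0.010/0.006/0.004 and
  d_Y = 0.040/0.020/0.010 for the oldest to youngest stratum),
  multiplied inside ACRs by per-chromosome factors (default Y ×3,
  X ×1). The outgroup is the ancestor itself. There are no indels, so
  alignments are gap-free and the truth table of injected
  lineage-specific substitutions is exact — the polarization stage is
  checked to the site, every seed. Gap handling is tested on hand-built
  alignments instead.
* Selection on ACRs is phenomenological: a divergence multiplier plus a
  polymorphism-deficit multiplier, not a forward simulation. The
  artifact tests the inference machinery, not coalescent realism; in
  particular linked selection, recombination within strata, and
  demography are absent, so passing calibrations here do not certify
  behaviour under those forces.
* Polymorphism arises per bp at θ (defaults θ_X = 0.0019,
  θ_Y = 0.0001, θ_auto = 0.0043, matching the per-bp diversity scale of
  the system emulated), derived-allele counts follow the 1/k neutral
  spectrum, all 12 males are hemizygous on noncrossover compartments,
  and read depths are Poisson around the compartment median (7 sex,
  13 autosome) with a 2 % fraction of 3×/0.2× outlier sites so the
  depth filters bite.
* Expression: each gene's assigned Y ACR divergence (mean over ACRs
  within 50 kb of its TSS) is standardized across genes; the true log2
  ratio is slope·z + Gaussian noise, with negative-binomial replicate
  counts. The defaults (slope 0.457, noise SD 0.98, baseline 200,
  dispersion 50) put the latent divergence–ASE Spearman correlation at
  0.40 — the association strength the machinery is expected to
  resolve; individual ~50-gene cohorts scatter around it with SD ≈ 0.1.

Determinism: every operation derives its own stream from
(seed, stage-index), so simulate/polymorphism/expression are
individually reproducible and written files are byte-identical across
runs with equal parameters.

## Problem sizes in the test suite

The statistical acceptance checks run at sizes chosen so Monte-Carlo
error is well inside the asserted bands: permutation-null uniformity
over 500 cohorts of 50 ACRs (199 sets each) and power over 100 cohorts
of 200 ACRs; pooled-NI convergence on one cohort of 2,000 regions of
500 bp with θ = 0.015 (expected counts ≥ 15,000 per cell, so the NI
sampling SD is ≈ 0.017 against the ±0.05 band); chi-square type-I over
1,000 neutral cohorts with non-overlapping controls; CI coverage over
500 expression cohorts of 51 genes with 1,000-replicate bootstraps.
Calibration scenarios use a single stratum and uniform rates so ACRs
and controls are exchangeable by construction.

## Known limitations

* The polarization model has no multiple-hit correction; at the default
  divergence scale (≤ 5 %) the bias is second-order, but rates from
  deeply diverged strata are underestimates.
* `sample_matched_controls` matches GC and length only — not
  dinucleotide content, repeat context, or mappability.
* The coding MK path consumes pre-aligned, frame-annotated sequence; it
  does not align, and it treats the outgroup codon as the ancestral
  context for both fixed and segregating variants.
* Asymptotic-MK extrapolation of α over frequency classes, two-outgroup
  polarized MK, and DFE estimation are out of scope.
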