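# Methods

This note documents the models and procedures implemented in `mozevo`, the
assumptions behind them, the tunable parameters, what the synthetic-data
generators do and do not emulate, and the numerical and design choices made
where the design was genuinely open.

## Codon-counting dN/dS

The estimator is the classical counting approach (Nei–Gojobori style) rather
than a maximum-likelihood codon model. It was chosen because it is
deterministic and verifiable by exhaustive enumeration at desk scale; output
rows carry a `method` label (`NG-counting+JC`) so a likelihood backend could
be added behind the same interface without changing consumers.

- **Site counts.** For each codon position, the synonymous fraction of the
  three single-nucleotide neighbors is computed under the standard genetic
  code (translation table 1, hard-coded and cross-checked against Biopython
  in the tests). Neighbors that create stop codons are excluded from both
  numerator and denominator at that position, so `s_sites + n_sites = 3`
  exactly for every sense codon. This differs from variants of the counting
  method that treat stop-creating changes as nonsynonymous; the exclusion
  convention is applied consistently in both the estimator and the sequence
  generator, so the two sides agree by construction.
- **Differences.** Between two codons, synonymous/nonsynonymous steps are
  averaged over all minimal single-step pathways with equal weights;
  pathways through a stop codon are excluded unless every pathway hits a
  stop (then all are kept, so the count is never undefined). `sd + nd`
  always equals the Hamming distance.
- **Aggregation.** Codons containing a gap, an ambiguous base, or a stop in
  either row are excluded pairwise from both site and difference counts.
  S and N are the mean of the two rows' site totals. No
  transition/transversion or codon-frequency weighting is applied
  (a deliberate non-goal).
- **Correction.** pS and pN are Jukes–Cantor corrected:
  d = −(3/4)·ln(1 − 4p/3). p ≥ 3/4 is reported as saturated (status flag),
  and ω with dS = 0 is reported as undefined with status `dS_zero` — never
  as infinity. Note that very short alignments can sit exactly on the
  saturation boundary (e.g. a single synonymous difference in a 3-codon
  alignment gives pS = 0.75); ω is then undefined by construction.

**Sliding window.** 34 codons (102 nt) stepping 31 codons (3-codon overlap
between consecutive windows). Windows start at codon 0; when the last
regular window does not reach the end of the alignment, a final window
anchored at `L − 34` is appended so no codon is silently dropped. Windows
with undefined ω are reported as missing rather than removed, which keeps
the track's coordinates complete for plotting.

**Percentiles.** All percentile ranks in the package use the midpoint tie
rule, `100·(#below + 0.5·#equal)/N`, which is stable under duplicated
values; genes with undefined ω are excluded from the ranking and reported
separately.

## McDonald–Kreitman test

Classification walks codon columns that are clean (no gap/N/stop in any
ingroup haplotype or the outgroup). Within a codon:

- each segregating nucleotide position contributes one polymorphism per
  non-major allele, classified by substituting that allele into the
  ingroup major-allele codon context;
- each position where the ingroup is monomorphic but differs from the
  outgroup contributes one divergence, classified by substituting the
  outgroup base into the ingroup codon;
- positions that are simultaneously polymorphic and divergent count as
  polymorphism only (the ingroup major allele defines the lineage state) —
  the standard conservative convention.

Two deterministic tie-breaks: major-allele ties break lexicographically, and
a substitution that would create a stop codon in context is classified
nonsynonymous (it alters the protein). Multiple segregating positions within
one codon are classified independently against the major-allele context,
keeping counts integral. No frequency cutoff is applied inside this module;
whether low-frequency polymorphisms were removed upstream is the caller's
choice. α = 1 − (Ds·Pn)/(Dn·Ps) requires Dn > 0 and Ps > 0 and raises a
descriptive error (carrying the table) otherwise; the pipeline reports such
genes with α = NA.

**Fisher's exact test** is implemented from scratch with exact rational
arithmetic (`fractions.Fraction` over `math.comb`), using the two-sided
probability-mass rule: sum the hypergeometric probabilities of all tables
with the observed margins whose probability is at most that of the observed
table, with 1e-7 relative slack on the comparison so float-boundary ties are
included. A zero row or column margin yields p = 1 with a flag. The tests
check it against an independent `scipy.stats.hypergeom` enumeration (1e-12)
and against `scipy.stats.fisher_exact`.

## Variant filtering and allele frequencies

The module consumes called genotypes (VCF 4.x via pysam); read alignment and
calling are out of scope. Multiallelic records are split one-per-alternate
(bcftools `norm -m -` semantics): genotype alleles matching neither the
reference nor the record's alternate become missing. Only diploid calls are
accepted; haploid genotypes raise an error rather than being silently
reinterpreted.

Per population, AN counts called alleles and AC alternate alleles, so a
half-missing call contributes one allele; AF = AC/AN is missing when AN = 0.
The three filters, applied in this order with first-match tallying:

1. **missingness** — dropped if, in *any* population, the fraction of
   individuals whose genotype is fully missing exceeds 0.9 (strict). The
   per-population reading follows the stated design; a site-wide F_MISSING
   reading would be weaker.
2. **quality** — dropped if QUAL < 30 (a QUAL of exactly 30 is kept).
3. **frequency** — dropped if AF < 0.05 in *every* population with a
   defined AF (AF exactly 0.05 anywhere is kept).

Filtering is idempotent. Variants map to genes by 1-based inclusive
`[start, end]` spans from a TSV; a variant inside overlapping genes is
assigned to the first interval in file order.

## Environment association

Per-variant Pearson correlations use pairwise deletion of missing values and
require ≥ 3 complete pairs and non-constant vectors; the two-tailed p comes
from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. Variants with
undefined correlations are excluded from both the observed statistics and
the permutation pool, and counted.

The gene-level metric is −log₁₀ of the **raw** harmonic mean p-value of the
gene's variants (equal weights). The HMP's asymptotically exact multiplicity
adjustment — the upper tail of a Landau distribution (stable α = 1, β = 1,
location ln L + 0.874, scale π/2, S0 parameterization, evaluated with
`scipy.stats.levy_stable`) at 1/HMP — is reported alongside in
`combined_p_adjusted`; no additional genome-wide FDR is layered on top. For
a single variant both equal that variant's p. Zero p-values are clamped to
the smallest positive float with a warning.

**Permutation test.** The "mean gene-wide correlation" statistic is the mean
of |r| across the gene's variants for one variable (direction-agnostic;
matches ranking by correlation strength). The null resamples the gene's
variant count without replacement from the pool of all usable variants,
independently per replicate; p = (1 + #{T_null ≥ T_obs})/(1 + B), the
add-one form that cannot return zero. Given (seed, B, pool order) the result
is bit-exact reproducible; an explicit seed is mandatory for every
stochastic operation. Percentiles are computed per variable, and the
top-decile flag is percentile ≥ 90.

## Sequence composition

GC content is 100·(G+C)/(A+C+G+T) on the sequence as supplied (gene span vs
CDS is the caller's choice); N residues are excluded from numerator and
denominator, and an all-N sequence is an error. Amino-acid composition is
computed per protein on the mature sequence (signal peptide removed by the
supplied cleavage index), normalized to 100 per protein, then averaged
unweighted across proteins — mean-of-percents, not pooled counts, so short
and long proteins weigh equally. The minimum-length filter (default 60
residues) applies to the mature sequence, since that is what is averaged.
All 20 standard residues appear in the output with explicit zeros; X is
tracked as its own category when present but excluded from the 20-letter
normalization check.

## Synthetic data: what it emulates, and what it does not

The generators plant the statistical structure each stage assumes; they are
not population-genetic simulations (no coalescent, recombination, linkage,
or demography — deliberate non-goals).

- **Coding pairs** (`simulate_coding_pair`): a random stop-free CDS is
  mutated by uniformly proposed single-nucleotide changes; synonymous
  proposals are accepted with probability min(1, 1/ω) and nonsynonymous
  with min(1, ω), so the realized rate ratio equals ω for any ω ≥ 0 —
  including ω > 1, which a scheme accepting all synonymous proposals could
  not produce. Stop-creating proposals are rejected. Mutation stops when 5%
  of nucleotide sites differ (default), keeping multiple hits rare enough
  that the counting estimator recovers ω within a few percent at 2000
  codons.
- **Population alignments** (`simulate_population_cds`): divergences and
  polymorphisms are planted at distinct codons; each event's class is
  Bernoulli with the configured nonsynonymous proportion (so Fisher-test
  calibration sees real sampling noise), or exact counts can be planted via
  `exact_table` for exact-recovery tests. Derived-allele counts are uniform
  on 1..n−1. Because events occupy distinct codons and avoid stops, the
  planted table is recovered exactly when classes are fixed. Defaults (20
  haplotypes, 150+150 events in 400 codons, equal class proportions of 0.5)
  give the strict-neutrality condition used for calibration.
- **Environment datasets** (`simulate_env_dataset`): defaults follow the
  study design — 25 populations, 40 called alleles per population (2 × 20
  diploid genomes), 200 genes × 20 variants, 5% signal genes with a
  logit-scale effect of 1.5 on the first ecological variable, variant
  intercepts a ~ Normal(−1, 0.5) (baseline AF ≈ 0.27), three ecological
  variables sharing a latent factor with loading 0.5 to mimic correlated
  Bioclim variables. Counts are AC ~ Binomial(AN, AF). Per-gene random
  streams are keyed by (seed, gene index), so enlarging the gene set leaves
  earlier genes' data unchanged.

Passing tests on these data show that the statistics are implemented
correctly and calibrated under their own assumptions. They do not show
robustness to features of real resequencing data that the generators omit:
linkage between variants within a gene, population structure and shared
demographic history (which inflate genotype–environment correlations),
alignment error, or variant-calling artifacts. Headline numbers from the
original full-scale study (e.g. per-gene α values or GC percentiles of
specific loci) depend on those data and on upstream alignment/filter
choices, and are not reproduced at desk scale.

## Problem sizes and runtime choices

The shipped analyses and the acceptance script use desk-scale sizes chosen
to give stable estimates in seconds to tens of seconds on one CPU: 50
replicate pairs of 2000 codons per ω for dN/dS recovery; 500 neutral MK
replicates (events ~150+150 per replicate); 1000 repetitions at B = 999 for
permutation type-I error; B = 1000 for the power analysis (the full-scale
analysis would use B = 10 000; the add-one p-value makes the smaller B
strictly conservative at the 0.05 threshold, 0.049 attainable resolution).

## Known limitations

- Counting dN/dS has no transition/transversion or codon-usage correction
  and will differ from likelihood (YN-style) estimates, particularly at
  high divergence; percentile ranks are more comparable than raw ω.
- The MK implementation does not polarize by parsimony, handle singletons
  specially, or implement asymptotic-MK extensions.
- The association test assumes exchangeable variants under the null; with
  strong linkage the variant-count-matched permutation null is optimistic.
- The HMP adjustment is asymptotic in L and approximate for very small
  numbers of variants; the raw HMP is always reported alongside.
- Only the standard genetic code is supported, and ploidy is fixed at 2.
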