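# Methods

## Study design being modeled

The pipeline analyzes paired lake–stream contrasts ("systems") of
threespine stickleback within a single lake basin: per-individual
life-history phenotypes (calendar-year age class from otolith rings,
landmark-based centroid size, mass, fecundity, clutch dry mass, lateral
plate morph), diploid microsatellite genotypes at eight loci
(Stn28–Stn200), and a 305-bp mitochondrial D-loop alignment. One lake
sampling site may serve as the lake member of two adjacent stream
pairs; such a record carries both system labels (comma-separated) and
enters each per-system contrast.

## Permutation inference

All tests shuffle the response over the predictor without replacement.
With B permutations and ties counted as extreme, the reported p-value
is (n_extreme + 1)/(B + 1). This add-one convention is deliberately
(slightly) conservative and makes the attainable floor exactly
1/(B + 1); the suite verifies both the floor and that the null p-value
distribution is never anti-conservative.

Design choices where the procedure was genuinely open:

- **Sidedness.** Group-difference statistics (mean age, mean size,
  fecundity, egg size, variance of population means) are compared
  two-sided via |T|; the direction of divergence is read off the sign
  of the observed statistic separately. Chi-square and ANOVA F are
  non-negative and one-sided.
- **Permutation unit.** For the body-size-variability comparison
  across populations the habitat label attaches to a population, so
  the unit permuted is the population mean, not the individual. All
  other tests permute individuals.
- **Pooling.** Fecundity and egg-size tests pool individuals across
  sites within each habitat (sample sizes per site are small); a
  per-system option exists but is off by default.
- **Ages** are compared as integer calendar-year classes via the mean
  difference.
- **RNG.** One master seed; every test derives an independent
  substream via SHA-256 of (seed, test name, system), so adding or
  reordering tests never perturbs another test's draws.

Missing responses are dropped before testing; a constant response
yields p = 1 with a warning rather than an error.

## Centroid size

CS = scale × sqrt(Σ‖x_i − centroid‖²), the standard geometric-
morphometrics size measure, in mm via the TPS SCALE factor (defaulting
to 1 with a warning when absent). No Procrustes superimposition is
performed — only size, not shape, is analyzed. Coincident landmarks
give exactly 0; fewer than three landmarks is a degenerate-
configuration error. Egg size is clutch dry mass / egg count (mg per
egg), undefined at zero fecundity.

## Weir–Cockerham θ and standardized F′_ST

θ̂ uses the 1984 variance-component estimator for r = 2 populations,
per locus and per allele, from (n_i, p_i, h_i) with n̄, n_c, p̄, s²
and h̄ as defined there. Numerical conventions:

- **Ratio of sums**: θ̂ = Σa / Σ(a + b + c) over all loci and alleles
  (the 1984 recommendation), never an average of per-locus ratios.
- **Monomorphic loci** (across both populations) are skipped from both
  numerator and denominator; loci untyped in either population are
  skipped for that pair; a pair with all loci skipped raises an
  undefined-θ signal (NaN in matrix assembly).
- **Negative θ̂** values are reported as computed (unbiased-estimator
  behaviour), truncated only for two-decimal display.
- Pairwise matrices are computed pair by pair on the two populations
  only.

Permutation P-values reassign whole multilocus individuals between the
two populations (preserving sample sizes and within-individual
linkage), one-sided on θ̂, B = 999 by default (floor 0.001).

F′_ST: alleles are recoded per locus with a within-population bijection
onto labels disjoint between the two populations, which preserves each
population's frequency spectrum and heterozygosity exactly while
maximizing differentiation; θ̂_max on the recoded pair divides θ̂.
Recoding is pairwise (per population pair), missing calls stay
missing, and θ̂_max ≤ 0 raises an undefined-standardization signal.

## Haplotypes and network

Haplotype identity merges sequences that agree at every mutually
non-missing column (N and gaps are missing; first-match assignment in
input order; an exact-string policy is available). Segregating sites
are columns with ≥ 2 observed bases among {A,C,G,T}; coordinates are
1-based. The genealogy is a minimum-spanning tree over pairwise
Hamming distances (missing columns excluded), with ties broken by
lexicographic haplotype order, hence fully deterministic. For a
handful of SNPs an MST recovers the same topology class a
maximum-likelihood genealogy would, while being exactly checkable
against exhaustive spanning-tree enumeration; likelihood tree search
and model selection are deliberately out of scope.

## Synthetic study conditions

The generators' defaults are the study conditions, fixed up front:

- **Ages**: lake P(2,3,4) = (0.1, 0.8, 0.1); stream (0.9, 0.1, 0.0) —
  lake fish mostly in their third calendar year, stream fish annual.
- **Centroid size per age**: means 61.2 / 81.35 / 92.0 mm (SD 5 mm)
  for ages 2/3/4, solved so the habitat age mixtures give pooled means
  of 80.4 mm (lake) and 63.2 mm (stream). Within-age SDs are free
  parameters (no published value) chosen once as field-realistic.
- **Mass**: allometric, 2.76·10⁻⁶ g·mm⁻³·¹³ · CS³·¹³ with lognormal
  noise (σ = 0.1), the curve through 2.53 g at 80.4 mm and 1.19 g at
  63.2 mm.
- **Fecundity** (females only): round(max(0, −604.2 + 11.05·CS + ε)),
  ε ~ N(0, 25²) — the line through 284 eggs at 80.4 mm and 94 at
  63.2 mm. The zero-floor makes the realized slope slightly shallower
  near the truncation region; estimation checks therefore run away
  from it.
- **Egg size**: 0.4 mg dry mass per egg in both habitats (lognormal
  σ = 0.05) — egg size deliberately does *not* diverge.
- **Plate morphs**: lake (full, partial, low) = (0.90, 0.08, 0.02);
  stream (0.40, 0.30, 0.30).
- **Sites**: nine samples with the survey's sample sizes (22–33), the
  COS lake sample shared between the COS1 and COS2 pairs.
- **Microsatellites**: Balding–Nichols island model — ancestral
  frequencies symmetric-Dirichlet per locus, population frequencies
  Dirichlet(p(1 − F)/F), Hardy–Weinberg within populations; defaults
  8 loci × 10 alleles × 25 diploids × 11 populations. The model's one
  parameter is exactly the quantity the popgen module estimates,
  giving a clean recovery target (mean θ̂ within ±0.02 of F over 200
  replicates).
- **D-loop**: a random 305-bp backbone with n_snp = 6 single-
  substitution haplotypes (star topology by default, chain optional),
  sampled per population from a frequency vector with one dominant
  haplotype.
- **Diet**: per-individual totals ~ Poisson(20), compositions ~
  Dirichlet-multinomial (concentration 3) around the published
  site-mean compositions over seven prey classes (normalized to sum
  to one); zero-weight classes are never sampled.

What the generators do **not** emulate: linkage between loci, mutation
processes (no stepwise-mutation allele-size structure), within-habitat
ecological covariates, measurement error in ageing, or reticulate
mtDNA genealogies. Passing tests therefore demonstrate correctness of
the estimators and the engine under the assumed sampling models, not
robustness to those real-data complications.

## Problem sizes and numerical conventions

The test suite runs the calibration at 1000 null datasets with B = 199
(discreteness of the p-grid at 1/200 is negligible at α = 0.05), the
island-model recovery at 200 replicates per F, and the exhaustive
oracles on 3v3 / 4v4 (20 / 70 arrangements) and 2v2 (6 splits)
instances; the acceptance script uses the same sizes with B = 9999 for
the headline phenotype tests. Monte-Carlo-vs-exhaustive comparisons
use a 4·SE + 2/B band around the exact expectation
(B·p_exact + 1)/(B + 1).

Floating-point ties in |T*| vs |T_obs| count as extreme (≥). Allele
labels are positive integers with 0 as the missing sentinel; GENEPOP
export uses 3-digit codes by default (2-digit dialect available).
All writers are byte-deterministic; floats round-trip via `repr`.

## Known limitations

- The equal-at-non-missing haplotype merge is order-dependent in rare
  chained-ambiguity cases (A≈B, B≈C, A≠C); with few SNPs and few Ns
  this does not arise, and the exact-string policy avoids it entirely.
- θ̂ is the two-population estimator throughout; a global
  k-population θ, locus bootstraps and R_ST are out of scope.
- The MST is a visualization genealogy; it does not attempt
  median-joining reticulations or likelihood inference.
- The F′_ST recoding is pairwise; dataset-wide recoding would give
  slightly different standardized values.
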