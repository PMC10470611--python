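# Methods

## The assembly model

The package treats each leaf-surface sample as a local community assembled
from a shared metacommunity (the pool of airborne and garden bacteria).
Neutral assembly is modelled in the Sloan tradition: for a taxon at
relative frequency *p* in the source pool, dispersal and drift leave its
local relative abundance *x* approximately Beta-distributed,

    x ~ Beta(N·m·p, N·m·(1−p)),

where *N* is the community size (operationally, the read depth) and *m*
the migration parameter — the probability that a death in the local
community is replaced by an immigrant rather than a local birth. Small
*N·m* means weak coupling to the pool and high between-sample variance;
*m* → 1 collapses every sample onto the pool composition.

A taxon is scored as present when at least one of the *N* reads is
assigned to it. Two detection kernels are implemented:

- **threshold**: occupancy = P(x > d), the classical sharp cutoff with
  detection limit d (default 1/N, one read at depth N). This is the form
  used by the standard fitting code in the field and is kept exactly, as
  `predict_occupancy`.
- **exact** (fitter default): occupancy = E[1 − (1−x)^N]
  = 1 − B(a, b+N)/B(a, b), the beta-binomial probability of at least one
  read. On count data the sharp threshold is biased: rare taxa with
  x slightly below 1/N are still sampled often, so observed occupancies
  sit above the threshold curve and the least-squares m̂ inflates —
  measured at +12% to +39% over m ∈ [0.02, 0.3] on tables drawn from the
  package's own generator, versus within ±5% for the exact kernel. When
  m itself is the quantity of interest the exact kernel is the right
  default; the threshold kernel remains available for comparability with
  published fits.

`fit_neutral` minimises the occupancy SSE over m ∈ (10⁻⁶, 1] with a
50-point log-spaced grid multistart followed by bounded scalar
minimisation (the SSE surface flattens for large N·m, so a single local
search can stall on the plateau). R² is 1 − SSE/SST about the mean
observed occupancy and can be negative. The envelope around the fitted
curve is a Wilson score interval at the realised number of samples,
evaluated at the predicted occupancy; taxa outside it are classed
above/below (candidates for positive selection / dispersal limitation).
Taxa with p = 0, p = 1 or zero occupancy are excluded from the fit but
retained in reports. N defaults to the rarefaction depth when the table
has equal column sums, else the mean depth; both are recorded on the fit.

## The synthetic study generator

`simulate_study` is the generative dual of the fit: per sample, effective
source q = normalize(p × boost^strength × plant jitter), independent Beta
draws per taxon (renormalised — independent Betas rather than a Dirichlet,
matching the taxon-wise model being fitted), then one multinomial of
`reads_per_sample` reads. Defaults emulate a single botanical-garden
survey: 24 plant species × 3 individuals × 2 leaf sides (144 samples),
500 taxa with lognormal(σ = 2) pool abundances, 14,000 reads per sample
before rarefaction to 4,000.

The two leaf sides differ in two planted ways:

- **Dispersal**: m_upper = 0.15 > m_lower = 0.05 — upper surfaces
  intercept more airborne immigrants.
- **Host filtering**: multiplicative boosts on the source pool, applied
  before the neutral draw so selection and dispersal are independently
  tunable. Each species' filter boosts a shared "plant-associated" core
  (20 taxa from the abundant pool ranks, ×5) and a private endemic set
  (12 of the rarest pool taxa per species, disjoint across species, boost
  solved per species so the endemic set makes up 10% of the filtered
  pool). The lower side applies the filter at full strength; the upper
  side at strength 0.5 (boost^0.5) — filtering acts on both surfaces but
  roughly twice as strongly below, which is what leaf-leachate chemistry
  suggests. Strength 0 (no upper filtering) is available and is used in
  null designs.

Endemic taxa are drawn from the rarest pool ranks deliberately: host
specificity is only observable if a taxon is too rare in the shared pool
to be detected on other hosts. An `endemic_exclusive` switch additionally
zeroes each endemic set in all other species' filters, which drives the
recovered endemism degree to its maximum (n_species−1)/n_species and is
used as a generator check.

Covariates mirror field measurements: per-leaf pH with the lower surface
0.21 units more acidic on average (Gaussian noise sd 0.15, clipped to the
plausible leaf range 4.89–7.16), stomata almost exclusively on the lower
surface, coordinates jittered in a ~0.14 km² frame, leaf hardness /
pubescence / area as inert extra columns. A lognormal per-plant jitter
(sd 0.12) on the source pool gives individual plants their own signature.

Effect-size calibration: the field study this design emulates reports
directions and variance partitions, not effect sizes, so the boost
magnitudes and jitter were fixed once, at design time, to put the planted
contrasts at realistic magnitudes — host plant species the largest
PERMANOVA term (R² ≈ 0.3) with a clear side × species interaction, core
taxa a large minority-to-majority share of reads, endemism a two-to-four
fold side contrast — and then frozen. What passing tests show is that the
analysis recovers known structure of this kind; they do not certify
behaviour on real tables with, e.g., taxon correlations, sequencing-run
batch effects or contamination, none of which the generator emulates.

## Filters, rarefaction, diversity

- Low-count denoising zeroes any per-sample count ≤ 2 (per-entry reading
  of the "two or fewer reads in any given sample" rule; a `max_anywhere`
  mode drops taxa never exceeding the threshold instead). Idempotent by
  construction; taxa left with all-zero rows are dropped.
- The total-relative-abundance filter removes taxa strictly below 0.1% of
  the grand total (strict "less than": a taxon exactly at the threshold
  stays).
- Rarefaction is a single multivariate-hypergeometric draw per sample
  (without replacement) to exactly the target depth; shallower samples
  are dropped and reported; the seed is a required, logged parameter.
- Alpha diversity (observed richness, inverse Simpson) is computed on the
  rarefied table only; the functions refuse unequal column sums unless
  forced. Bray–Curtis runs on within-sample relative abundances via scipy;
  geographic distances are haversine with Earth radius 6,371 km (the
  study frame is far too small for projection choice to matter).

## Core selection

Taxa are ranked by occupancy, ties broken by mean relative abundance then
taxon ID (the "spatial" variant of the abundance-occupancy method — no
time series exists here, so no temporal grouping enters the index). For
each prefix of the ranking, the contribution to beta diversity is the
mean over sample pairs of the prefix's share of the pair's Bray–Curtis
numerator over the full-composition denominator. This prefix-restricted
numerator / full denominator convention makes the curve non-decreasing,
bounded by 1, and exactly 1 at the full ranking — the invariants the
selection rule needs. (The alternative convention that also restricts the
denominator to the prefix can exceed 1 and is non-monotone; it was
rejected for that reason. A consequence of compositional closure is that
a single taxon's contribution can reach but never exceed 0.5.) The core
is the shortest prefix after which the relative gain stays below the 2%
threshold (configurable); a flat curve falls back to the smallest prefix
with nonzero contribution. Pairs with zero full dissimilarity are
skipped.

## Endemism

Degrees of endemism are computed on the filtered, unrarefied table
(detection = count > 0) after excluding taxa seen in at most one sample,
whose host range a single record cannot establish. Species with fewer
sampled individuals weigh equally in the proportion. Weighted endemism
renormalises relative abundances over the retained taxa; samples with no
retained-taxon reads get W = NaN and a warning. The log transform uses
the natural log with zero-W samples floored at half the smallest positive
W (configurable). "Optimising" the regression means backward elimination
at α = 0.05 per term (worst dummy p per categorical term); the full
pre-elimination model is always reported alongside. Note that with three
near-independent terms this procedure retains the empty model in only
about 0.95³ ≈ 86% of pure-noise datasets — per-term type-I control, not
familywise.

## PERMANOVA and Mantel

The PERMANOVA Gower-centres −½D² and decomposes tr(HG) sequentially over
an ordered term list (Type I, the adonis2 `by = "terms"` convention):
each term's SS is the increment in the trace when its dummy columns join
the cumulative design, with ranks computed by SVD so aliased columns cost
no degrees of freedom. Nesting is encoded by entering concatenated
parent:child labels after the parent term; the side × species interaction
is the product coding, entered last. Significance uses free permutation
of sample identities, observed statistic included in the null set
(p = (#{F* ≥ F} + 1)/(n_perm + 1)); an `exhaustive` mode enumerates all
n! relabelings for exact small-n checks. Free (unrestricted) permutation
matches the default of the standard implementation; a restricted scheme
for the repeated-measures structure is deliberately out of scope, so
p-values for the nested individual term are approximate. The Mantel test
correlates lower-triangle entries (Spearman by default, ranks computed
once and permuted with the matrix) under simultaneous row/column
permutation of the second matrix, two-sided.

Numerical conventions throughout: permutation p-values can never be
below 1/(n_perm+1); degenerate paired tests (all differences zero) return
p = 1; all-zero samples and empty tables raise rather than propagate
NaNs; every stochastic step takes an explicit seed, and the pipeline
derives per-stage seeds from one master seed.

## Pipeline problem sizes

The default pipeline run simulates 144 samples × 500 taxa, rarefies to
4,000 reads, uses 9,999 permutations for PERMANOVA/Mantel and 199
sign-flip permutations for the R² gap test. The test suite validates the
same machinery at reduced frames (8–12 species, 150–300 taxa, 39–199
permutations) chosen so each property is still comfortably detectable;
the calibration study behind the null-specificity check uses 50
replicates.

## Known limitations

- The neutral fit is least-squares on occupancies, not likelihood-based;
  confidence in m̂ comes from the envelope and permutation contrasts, not
  an asymptotic SE.
- m̂ is a descriptive parameter when the community is not actually
  neutral: host filtering and between-plant heterogeneity bias it (they
  widen the occupancy–abundance cloud), which is why per-side comparisons
  of fit quality, not absolute m̂, carry the inference.
- The generator draws taxa independently given the pool; it does not
  emulate taxon–taxon interactions, temporal succession, or
  phage–bacteria dynamics.
- No phylogenetic metrics (UniFrac, phylogenetic endemism): no tree is in
  scope.
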