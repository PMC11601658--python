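# Methods

This note records the models the package implements, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the problem sizes at which the simulation-based checks run.

## The POPout test

The test takes a per-individual table of a quantitative trait `y` and a
polygenic score `p`, both standardised to mean 0 and SD 1 within the
analysed sample.  (The centering is required: the effect formula compares
absolute values, which only encode "distance from the population mean" when
the mean is zero.)  A least-squares line `f(y) = a + b·y` is fitted on all
rows; tail membership is rank-based — the `floor(q·N)` smallest and largest
trait values (default q = 0.01), ties broken by stable input order.  Within
a tail the effect is `mean(|f(yᵢ)| − |pᵢ|)`, and significance comes from a
two-sided one-sample t-test of the tail residuals `pᵢ − f(yᵢ)` with tail-only
variance and n − 1 degrees of freedom.  Under uniform polygenicity the
conditional mean of the score is linear in the trait, so tail residuals
center on zero; rare un-scored alleles in a tail pull the observed score
toward the mean, making the effect positive.

Numerical choices and degenerate cases:

- A perfectly predicted score (residual SD below 1e-10) would make the
  t-statistic 0/0; such tails report t = 0, p = 1 with a
  `zero-variance-residuals` flag, and the QC screen passes vacuously.
- A negative trait-score slope is diagnostic of mismatched inputs but leaves
  the formula well defined: the test warns and proceeds.
- The QC screen ranks rows into 100 equal-count bins (remainder rows going
  to the lowest-index bins), t-tests the residual mean of centiles 11–90,
  and fails a trait when min p ≤ 0.05/80.  A linear score–trait relation in
  the bulk is a precondition for interpreting tail residuals.
- BH-FDR q-values are computed jointly across all trait-tails of a run
  (statsmodels' step-up implementation).

One behaviour worth knowing: a *strong* single-tail enrichment (e.g. 1% of
individuals carrying a +3 SD un-scored effect) tilts the global regression
slope downward, which produces a modest negative effect in the opposite,
un-enriched tail and can trip the centile QC screen.  This is the method
working as designed — the global linear fit is the polygenic null model,
and data violating it that grossly are flagged by QC.  At milder, more
realistic enrichment levels the opposite tail stays within noise of zero
and QC passes.

### Case/control prediction emulation

To show what tail architecture does to clinical use of a score, the trait
is dichotomised at a quantile (default 0.75 or 0.99; mirrored quantiles for
lower-tail outcomes), the score is cut into equal-count bins, and each
bin's odds ratio against the bin containing the median score is reported
with 95% Wald CIs.  For a single binary bin indicator the logistic MLE
equals the 2×2-table odds ratio, so the table form is computed directly;
zero cells get the Haldane 0.5 correction and a flag.  The matched
baseline simulates `T = √r²·PRS + E`, `E ~ N(0, 1−r²)` at the same r² and
sample size — the curve a uniformly polygenic trait would give.

### Replication power

`bootstrap_power` draws subsets without replacement (a replication-cohort
analogy), reruns the tail test, and reports the fraction of
full-data-significant tails (FDR 5%) replicating at nominal p < 0.05 plus
the correlation between subset and full-data effects.  Subsets too small to
hold the per-tail floor are skipped with a warning.

## Sibling-based tests (STANDout)

Under the infinitesimal model with heritability h², the trait of a sibling
conditional on their co-sibling's value `s₁` is
`N(s₁h²/2, 1 − h⁴/4)`.  Everything in this module derives from that
distribution:

- **h² estimation** maximises
  `−n·log(1 − h⁴/4) − Σ(s₂ − s₁h²/2)²/(1 − h⁴/4)` over h² ∈ [0, 1].  The
  residual sum collapses onto three sufficient statistics, so the profile
  is evaluated densely (201 points) and refined by bounded scalar
  minimisation to 1e-6.  Both orderings of each unordered pair enter (the
  likelihood is directional; doubling symmetrises it).  Boundary optima are
  flagged, not errors.
- **Mendelian test**: each unordered pair enters once, through its
  designated index sibling (the `s1` column; in real data the column
  assignment should be arbitrary with respect to the trait).  Index
  siblings in the empirical q-mass tail form A_q; `r` counts pairs whose
  conditional sibling is also in the tail; the null concordance probability
  π₀ averages, over index siblings, the conditional tail mass beyond the
  *theoretical* threshold Φ⁻¹(q) (lower) / Φ⁻¹(1−q) (upper).  The statistic
  is `z = (r − nπ₀)/√(nπ₀(1−π₀))`, one-sided for excess concordance.
  Letting both orderings serve as index entries may look like it doubles
  the information, but a doubly-extreme pair then contributes r += 2
  deterministically, doubling Var(r) relative to the Bernoulli model in
  the denominator and inflating the null rejection rate — single
  orientation keeps the score test exactly calibrated.
- **De novo test**: `z = Σ(s₂ − s₁h²/2)/√(n(1−h⁴/4))` over tail index
  siblings; upper tail tests H₁: z < 0 (conditional sibs fall below the
  polygenic expectation), lower tail mirrors to H₁: z > 0; one-sided normal
  p-values (the statistic is already standardised).
- **STANDout** Fisher-combines the two one-sided p-values:
  `χ²₄ = −2(ln p_M + ln p_D)`; p-values are floored at the smallest
  positive double before logging (flagged when hit).  h² is re-estimated
  from the full pair set unless pinned by the caller.

Calibration, verified by simulation over polygenic-null replicates
(h² = 0.5, 50,000 pairs): the Mendelian and de novo p-values are each
uniform (KS).  The *combined* STANDout p is valid but conservative — the
two statistics are computed on the same tail pairs and are positively
correlated under the null (corr(z_M, z_D) ≈ 0.4 at these settings), which
makes their one-sided p-values negatively correlated, so the Fisher χ²₄
combination concentrates below its nominal distribution and rejects at
≈2% for a nominal 5% level.  The combination is kept in its standard χ²₄
form: it controls the type-I error (conservatively) and the power of the
omnibus test against Mendelian and de novo alternatives is driven by the
component in play.  Users wanting exact combined calibration under the
polygenic null can simulate the null with `gen_sibling_pairs` at the
estimated h² and calibrate the χ² empirically.

## Selection inference from reproductive success

Relative lifetime reproductive success divides each individual's offspring
count by their birth-cohort mean (cohort means of the output are exactly 1;
cohorts with non-positive mean counts are an error naming the cohort).
The regression `Y = β₀ + βz + γz²` is fitted by least squares for the four
intercept-containing submodels, compared by the Gaussian profile BIC
`n·ln(RSS/n) + k·ln(n)` (constant terms cancel across candidates), and the
winner is classified: intercept-only → none; linear-only → sign of β;
quadratic-only → stabilising (γ < 0) or disruptive (γ > 0); both terms →
sign of β gives the direction.  An exact fit (RSS = 0) short-circuits
selection toward the most parsimonious perfect candidate and is flagged.

Tail-effect contrasts group traits into four categories (none;
non-directional quadratic, i.e. stabilising with disruptive folded in;
positive-direction; negative-direction) and Welch-t-test significant lower
vs upper tail effects within each group — directional selection predicts
the selected-against tail carries the larger effect.  Fitness-proxy
associations compute, per trait, the mean proxy value among tail
individuals and Spearman-correlate these tail means with the matching tail
effects across traits.

## Wright–Fisher simulator

A population of N diploids (default 10,000) with a 100 kb genome evolves
with per-bp mutation rate 2.36e-8 and crossover rate 1e-8 per generation.
Mutation effects are gamma-distributed (shape 0.186, mean 0.01026) with a
random sign, the trait is the sum of carried effects over both haplotypes
(h² = 1), and fitness is 1 during burn-in (10N generations).  At selection
onset the trait mean and SD are frozen as the optimum μ and width σ of the
Gaussian fitness `1 + (k/√(2πσ²))·exp(−(x−μ)²/2σ²)`, and selection runs
for 1N generations; parents are drawn with probability proportional to
fitness, independently with replacement (incidental selfing allowed, as in
the standard model).

Implementation: the population is a boolean genotype matrix over
segregating sites in pre-allocated double buffers; a numba kernel fuses the
gamete copy (including crossover parity switching) with per-site carrier
counting, so exact segregating-site logs are free every generation.
Mutations take uniformly drawn unoccupied bp positions (collisions redrawn:
approximate infinite sites; the collision probability at ~10³ segregating
sites over 10⁵ bp is negligible).  Lost columns are compacted away every 4
generations; a column that fixes stays fixed, so deferred handling is
exact — on compaction its effect moves into a scalar baseline as 2e per
diploid, preserving phenotypes.  Per-haplotype trait scores are maintained
incrementally and re-derived from the matrix every 512 generations to bound
float drift; fixed-seed runs are bit-reproducible.

Snapshot analyses:

- **Centile summaries** rank individuals into 100 equal-count trait bins
  and count carried alleles by class: rare (MAF < 1%), very rare
  (MAF < 0.05%), common (MAF ≥ 1%), with "large effects" the top 10% of
  |effect| among segregating mutations.  MAF comes from all 2N haplotypes.
  The common-variant PRS is the effect-weighted count of carried common
  alleles (true effects as weights: heritability is 1 and no GWAS is
  simulated), standardised; the POPout-like effect per centile is
  `mean(|f(trait)| − |PRS|)` with f the population-wide least-squares fit.
- **Enrichment log-OR**: per replicate and allele class,
  `(rare_sel/common_sel)/(rare_neu/common_neu)` over the tail centiles,
  each replicate's neutral control being its own end-of-burn-in snapshot;
  Haldane correction on zero cells; one-sample t-test of the mean log-OR
  against zero.
- **Extreme-tail carrier fraction**: a tail individual counts as a carrier
  if they harbour a rare allele whose signed effect points toward the tail
  and whose magnitude is at least their distance from the tail boundary —
  removing it would move them out of the tail.  The alternative reading
  (rare AND top-decile effect) is available as `criterion="large_effect"`;
  which operationalisation matches the published percentages is genuinely
  ambiguous, and the two differ most under weak selection.

### Rescaling and problem sizes

Configs may scale N down and mutation/recombination up by the same factor,
keeping θ = 4NμL (here 94.4) and running generations proportional to N.
The selection multiplier k is deliberately **not** rescaled, so absolute
fitness differences are preserved while drift strengthens — rescaled runs
reproduce qualitative contrasts, not the full-scale percentages.

The shipped checks use, as their study conditions:

- neutral-equilibrium checks (Watterson segregating-site count, 1/i site
  frequency spectrum): N = 1,000, rates ×10, 20 replicates.  The 1/i law
  is the coalescent small-sample limit, so the spectrum is scored on
  50-haplotype subsamples; the whole-population spectrum of the exact
  discrete chain has a genuine singleton excess (≈ +12% when observed
  after mutation, reproduced by an independent allele-count Markov-chain
  oracle), which is neutral-theory fine print, not simulator error;
- selection contrasts (enrichment ordering across k ∈ {0, 1, 100},
  POPout-like centile effects, carrier fractions): N = 500, rates ×20,
  100 replicates, with the three selection phases forked from one shared
  burn-in per replicate (a paired design that isolates k).  N = 500 is the
  smallest rescale at which k = 1 remains meaningfully weaker than k = 100;
  at N = 200 the two regimes collapse into each other because the
  unrescaled multiplier is already effectively strong against the reduced
  population.  The very-rare class (MAF < 0.05%) needs ≥ 4,000 haplotypes
  to be populated at all and is reported but not asserted at desk scale.
- the full-scale configuration (N = 10,000, 10N burn-in, 100 replicates)
  behind the published extreme-tail carrier percentages (~1% neutral, ~28%
  strong selection) is provided as `scripts/full_scale_carrier_fractions.py`
  and takes days of CPU; desk-scale runs assert the qualitative contrast
  (selection ≫ neutral) instead.

## Synthetic-data generators

The generators produce exactly the structure the tests assume, which is
what makes them useful for calibration and what limits them as models of
real data:

- `gen_trait_prs`: `T = √r²·PRS + rare + E` with a point-mass rare
  component (carrier probability, fixed signed effect) per tail.  This is
  the minimal structure producing tail regression-to-the-mean; it does not
  model LD, polygenic rare variation, or genotype-level noise.
- `gen_sibling_pairs`: shared-plus-independent genetic components matching
  the conditional model exactly, with optional family-segregating
  (parent carrier, transmission probability 1/2 to each sib) or
  single-sibling de novo overlays; outputs standardised jointly.
- `gen_fecundity`: Poisson counts with mean `max(ε, c(1 + βz + γz²))`,
  c = 2 offspring by default; the truncation means coefficient recovery is
  documented for small |β|, |γ| (≲ 0.2) where the clip is rarely active.

Passing tests on these generators demonstrates internal consistency and
statistical calibration of the methods under their stated null and
alternative models — not robustness to ascertainment, measurement error,
assortative mating, shared sibling environment or population structure,
none of which the generators emulate.

## Seeding

All randomness flows through `numpy.random.default_rng` from explicit
seeds; library functions that simulate take a `seed` argument, and the CLI
exposes a global `--seed`.  Fixed seeds reproduce byte-identical outputs.
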