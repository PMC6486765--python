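# Methods

## Model

The simulator tracks an infinite, diploid, randomly mating population as a
frequency distribution over multilocus genotypes. A drive architecture is a
chain length *n*, a target map (locus *i* cuts wild-type alleles at locus
*i*+1 for a daisy chain; a standard self-propagating drive is a single
self-targeting locus), a homing efficiency *H* ∈ [0, 1], and a cut
probability κ restricted to {0, 1}. The κ = 0 case is the Mendelian
comparator used for inundative releases; intermediate cut probabilities are
rejected rather than silently interpreted, because partial cutting would
require a model of iterated cut-and-repair cycles that the present germline
rule does not define.

Germline conversion transforms the diploid genotype at a targeted locus
before segregation — WW → RR, WR → RR, WD → DD w.p. *H* else DR; D/R pairs
are immune — whenever the driving locus carries at least one D allele.
Activation is dominant and trans-acting (a single D on either haplotype
suffices), on the rationale that the nuclease and guide RNAs are diffusible
in the germline cell. Note conversion never changes whether a locus carries
a D, so conversion at one locus cannot create or destroy the activation
signal for the next; the per-locus rules are therefore order-independent.

Fitness is multiplicative across loci with complete dominance: 1 − *c_i*
per locus carrying ≥1 D, and 1 − *s* if the cargo locus carries ≥1 R.
Default parameter conventions follow the studied scenarios: upstream
(guide-RNA-only) element costs *d* = 10⁻⁴, cargo costs *c* of 0.08–0.10,
and dominant-lethal cargo resistance *s* = 1. All rates are proportions
internally; the config loader accepts `units: percent` for captions quoted
in percent.

## Lifecycle and bookkeeping

One generation is, in order: viability selection → gamete production →
random union (allowing selfing, as is standard for infinite-population
recursions) → release injection replacing a fraction ρ of the zygote pool
with engineered homozygotes. Selection precedes reproduction because the
lethal cargo-resistance cost acts on inheriting zygotes. Generation 0 of a
trajectory is the census immediately after the initial release, so
"time to 99%" counts generations elapsed since release. Recorded censuses
are pre-selection zygote frequencies.

Continuous release is implemented as frequency replacement,
(1 − ρ)·offspring + ρ·release, the simplest mass-conserving reading of a
constant-rate release into a fixed-size population.

In the metapopulation, migration mixes zygote-pool frequencies after
reproduction and local release: x_i′ = (1 − Σ_j m_ij)·x_i + Σ_j m_ij·x_j,
with m_ij the fraction of population *i*'s pool drawn from *j*. The
alternative ordering (migration before reproduction) was checked on the
five-population containment scenario and changes the second- and
third-population cargo peaks by less than 0.02; post-reproduction mixing is
the default. Populations are equal-sized and constant. A population whose
mean fitness reaches zero is frozen at its last state (still exporting
migrants) with a warning, rather than aborting the run.

## Numerical engine

The state is a dense 3ⁿ × 3ⁿ array over ordered haplotype pairs. The
population gamete pool is computed by contracting the parental-genotype
tensor locus by locus: because a daisy locus is coupled only to the locus
driving it, the sum over parental genotypes factorises into a chain of small
tensor contractions carrying a single "driver D present" bit between
neighbours. This is exact (no truncation or pruning of rare genotype
classes) and makes six- and seven-locus chains cheap: a 100-generation
six-locus run takes ~2 s, and the five-population, 500-generation chain
scenario ~1 s. Architectures outside the chain/self-targeting family fall
back to an explicit per-genotype sum. Fitness lookups use a Kronecker
product of per-locus cost factors. Allele frequencies are clipped to [0, 1]
to shave off float residue at fixation; probability-conservation tolerances
are 10⁻⁹ on distributions and 10⁻¹² on single-genotype gamete vectors.

A consequence of double precision worth knowing: an allele driven below
~10⁻³⁰⁸ underflows to exactly zero and cannot recover. In strong-drive
scenarios the wild-type cargo allele can be eliminated outright, after which
the cargo persists at fixation indefinitely. This matches the qualitative
regime claim (resistance costlier than cargo ⇒ indefinite persistence) but
means very-long-horizon recovery times of ultra-rare alleles are not
meaningful.

## Stochastic cross-validation

The Wright–Fisher simulator draws, for each of N offspring, two parents
with probability proportional to fitness and one gamete per parent from
that parent's germline distribution; releases replace ⌊ρN⌋ random
individuals with engineered homozygotes. Conditional on the realized
population at one generation, each of the 2N transmitted allele copies is
an independent draw from the pool predicted by one deterministic step
applied to the realized genotype distribution, so the next census is
binomial with standard error √(p(1−p)/2N) around that prediction. The
equivalence test uses exactly this conditional comparison at five standard
errors per locus, allele and generation.

Marginal (whole-trajectory) deviations are *not* binomial: during the
spread phase, selection and homing amplify early fluctuations
multiplicatively — empirically ~5-fold over 20 generations at N = 10⁴ in
the strong-drive scenario — so an additive accumulation of binomial
variances understates the spread of a single replicate. The additive
envelope (`drift_envelope`) is therefore used only in the neutral Mendelian
limit, where the per-generation map has unit slope and it is exact.

The simulator validates the deterministic engine, never substitutes for it:
all reported results come from the deterministic recursion.

## Scenario presets and open choices

Presets encode the studied parameter sets (three-element chains at H = 0.95
and 0.60 with 2%/15% releases; six-element chains at H = 0.95 with 1%
single or continuous releases; the five-population daisy/standard/inundative
comparators at H = 0.8, c = 0.1, 15% release, m = 0.01). Choices the source
scenarios leave open, resolved here:

- **Standard-drive comparator.** Multi-gRNA targeting of an essential gene
  is approximated by a single self-targeting locus with dominant-lethal
  resistance (s = 1): end-joining products disrupt the essential gene and
  are removed each generation, so no functional resistant class
  accumulates. This reproduces the intended behaviour (fixation in all
  connected populations) without per-gRNA allele bookkeeping.
- **Persistence-sweep base point** (`s4_persistence`): n = 3, H = 0.95,
  c = 0.1, d = 10⁻⁴, s = 1, 20% release, 500 generations — chosen so the
  cargo clears 50% across swept neighbourhoods of every parameter.
- **Persistence dichotomy test point.** The qualitative regime split at
  s = c expresses itself only when enough resistant alleles are generated
  during the spread (moderate homing): at H = 0.6, 15% release, c = 0.1,
  an s = 0.15 cargo stays above 50% through a 500-generation horizon while
  s = 0.05 collapses to resistant-allele fixation. Strong-homing, large-
  release scenarios fix the cargo absolutely regardless of s (see the
  underflow note above), which is why the dichotomy is probed at moderate
  homing.
- **`persistence_above`** counts all generations above threshold, not the
  longest contiguous run; for this model's rise-then-fall trajectories the
  two coincide.

## Known limitations

Loci are unlinked and autosomal; inheritance is sex-symmetric; there is no
maternal nuclease deposition, no partial dominance of costs, no standing
resistant variation at release, no de novo mutation, and no demography
(constant population sizes, no suppression dynamics). The deterministic
engine ignores drift entirely — threshold-adjacent outcomes in small real
populations will differ. Passing tests show the recursion and its couplings
are implemented exactly as specified above; they do not show that real
release programmes behave this way.
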