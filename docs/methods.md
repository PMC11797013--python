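# Methods

## Scope and model structure

`drivesim` models a single CRISPR homing gene drive locus in a closed,
randomly mating population of constant size *n*, with discrete,
non-overlapping generations.  Three alleles are tracked: the drive allele,
the wild-type allele, and one conversion-resistant allele (the machinery in
`drivesim.core` accepts any number of resistant alleles; the scenario layer
uses one).  The state of the system is the allele-frequency vector *p*;
each generation expands it into diploid genotype frequencies, applies
conversion and selection to the drive-carrying genotypes, collapses back to
allele frequencies, and resamples the gamete pool.

The per-generation module order is

    zygote formation → [post-zygotic: conversion] → selection
    → [pre-zygotic: conversion] → collapse to alleles → drift

Pre- and post-zygotic drives differ only in where conversion sits.  In a
pre-zygotic drive, homing happens in the germline of surviving adults, so
selection acts on heterozygous parents before their gametes are biased.  In
a post-zygotic drive the zygote is converted first, so selection sees
(mostly) drive homozygotes — which is why post-zygotic drives are less
tolerant of fitness costs and reach equilibrium more rarely.

## Parameters

| parameter | symbol | range | default | meaning |
|---|---|---|---|---|
| conversion | c | [0, 1] | — | probability a wild-type allele in a drive heterozygote is converted, per generation |
| resistance level | R | [0, c] | 0 | conversion rate of the drive on the resistant allele; 0 = fully immune |
| resistance frequency | p_R | [0, 0.4] | 0 | initial resistant-allele frequency (resistant alleles are minor alleles) |
| fitness cost | s | [0, 1] | 0 | selection coefficient against drive carriers |
| exposure | e | [0, 1] | 1 | fraction of the population exposed to selection each generation |
| dominance | d | [0, 1] | 0.5 | weight of the cost in drive heterozygotes (0 recessive, 0.5 additive, 1 dominant) |
| inbreeding | F | [0, 1] | 0 | excess homozygosity at zygote formation |
| population size | n | ≥ 1 | 10⁶ | constant; sets the magnitude of all sampling noise |
| generations | T | ≥ 1 | 500 | trajectory length (plus the generation-0 state) |
| initial drive frequency | p₀ | (0, 1) | 0.001 | release frequency |

All rates are per generation and unitless.  The drive homozygote always
pays the full cost *s*; dominance scales the cost of any genotype
heterozygous for the drive, including drive/resistant.  This choice — full
cost in homozygotes — is what produces the characteristic dominance sweep
(equilibrium → temporary → fixation as *d* rises under the
`dominance-switch` preset): raising *d* makes selection kill
drive/resistant heterozygotes, which removes resistant alleles as a side
effect and ultimately clears the drive's path to fixation.  The alternative
reading (homozygote cost also scaled by *d*) collapses recessive-cost
dynamics to neutral and is grossly inconsistent with the outcome
frequencies this model is meant to produce.

### Stochastic semantics

Each stochastic module draws binomial counts at population size *n*:

- conversion: `x ~ Binomial(n, c_j · G_Dj)`, converted mass `min(x/n, G_Dj)`
  (the draw can overshoot the available heterozygote mass with small
  probability; it is clamped);
- selection: killed mass `x/n` with `x ~ Binomial(round(e · G_ij · n), d_eff · s)`.
  Drawing deaths with probability `d_eff·s` is distributionally complementary
  to drawing survivors with probability `1 − d_eff·s`, and has the property
  that a neutral drive (s = 0) is exactly untouched;
- drift: per-allele `x_i ~ Binomial(2n, p_i)`, `p_i' = x_i / 2n`, then the
  vector is renormalized to sum to 1 (independent per-allele draws do not
  conserve mass).  A joint multinomial gamete draw — classical
  Wright–Fisher, mass-conserving by construction — is available via
  `drift_method="multinomial"`.  The renormalized per-allele scheme has
  somewhat lower variance on any single allele than the multinomial (down
  to ~0.5× at two-allele states); outcome frequencies are insensitive to
  the choice (differences well under one standard error at 5,000 draws).

Deterministic mode replaces every draw by its expectation, giving the exact
recursion used for closed-form validation: with s = 0, p_R = 0, F = 0 the
drive obeys `p' = p + c·p(1 − p)`, and for c = 1 the wild-type fraction
squares each generation, `1 − p_t = (1 − p₀)^(2^t)`.

## Numerical choices

- **Mass renormalization.** Allele frequencies are renormalized to sum to
  exactly 1 at the collapse step of every generation.  This is not
  cosmetic: the quadratic zygote-formation step amplifies any deviation of
  the total from 1 by a factor ≈ (1 + p_drive) per generation, which
  explodes within ~100 generations near interior equilibria.
- **Absorbing states.** Drive frequency exactly 0 (and exactly 1) is
  absorbing — there is no mutation or reintroduction — so simulations are
  frozen there and the remaining trajectory entries filled with the frozen
  value.  This is purely an optimization; semantics are unchanged.
- **Whole-population kill.** If selection would remove the entire
  population (drive fixed under a fully exposed lethal cost), survivor
  frequencies are undefined and the state is left unchanged.
- **Fractional trials.** `e·G·n` is rounded to the nearest integer before
  the selection draw; unbiased to first order.
- **Empty gamete pool.** At very small *n* the per-allele binomial draws
  can all return 0; the pre-drift pool is kept in that case.

## Outcome classification

A trajectory is summarized by max frequency, first generation attaining
it, final frequency, and the gradient over the last 20 generations,
estimated as the mean per-generation change `(p_T − p_{T−20}) / 20`
(a least-squares slope over the last 21 points is available via
`gradient_method="slope"`; the two differ by <10% in sampling noise).  The
difference form makes the 10⁻⁴ equilibrium threshold commensurate with
drift noise at n = 10⁶: a plateau's 20-generation mean change has standard
deviation ≈ 8×10⁻⁵ at mid frequencies, so genuine plateaus mostly classify
as equilibrium while moving trajectories do not.

The five categories partition the summary space (verified by brute-force
enumeration): comparisons are strict except the lower equilibrium bound, so
values exactly on a threshold are unclassified.  "Between 0.10 and 0.90" is
read as the half-open interval [0.10, 0.90); a final frequency of exactly
0.90 is neither fixation nor equilibrium.

## Monte Carlo design-space exploration

The sampler draws conversion, fitness cost, exposure, dominance and
inbreeding uniformly on [0, 1]; resistance frequency uniformly on [0, 0.4]
(resistance as standing minor variation); and the resistance level as an
independent U(0, 1) fraction of the drawn conversion, so resistance can
never exceed conversion.  Run settings are fixed at n = 10⁶, 500
generations, p₀ = 0.001.  These defaults are the study conditions; the
acceptance script and tests use them unchanged.

Simulation is vectorized across scenarios in fixed-size chunks (default
4,096); each chunk's variable draws and binomial noise come from generators
seeded by `(root_seed, timing, chunk_index)`, so any batch is exactly
reproducible from its root seed.  Pre- and post-zygotic tables are built
from independent batches.  Unclassified simulations stay in outcome-table
denominators (the classified total is below 100%) but are excluded from
balanced samples and regressions.

The balanced sampler keeps drawing fresh scenarios until every classified
outcome has its quota, discarding the surplus; equilibrium, at roughly 2%
of pre-zygotic draws, dominates the cost (≈ 40× the quota in total draws).
Within-outcome effects are estimated by ordinary least squares of a
dynamics metric (time to maximum, final frequency, or maximum frequency) on
the seven variables, unstandardized, with an intercept and no interactions.
Problem sizes used by the shipped tests and acceptance script: 5,000
simulations per timing for outcome tables, 2,000 records per outcome for
regressions — large enough that every reported comparison is made at 3
binomial (or coefficient) standard errors.

## What the generator does and does not emulate

The sampler emulates a sensitivity analysis over drive design and
population parameters, not any particular organism.  Not modelled: spatial
structure and migration, overlapping generations, changing population size
(no suppression demography — the drive is a replacement drive), de novo
resistance generation by NHEJ or mutation (resistance is standing variation
only), sex-specific inheritance, and more than one resistant allele class
in the scenario layer.  Passing tests therefore demonstrate correctness of
the single-locus, constant-size dynamics and of the downstream statistics,
not field-level predictions for any real release.

## Known limitations

- The equilibrium outcome is by far the most sensitive statistic in the
  whole pipeline: it depends on a threshold (10⁻⁴ per generation) applied
  to a noisy tail estimate, so its share responds to estimator and noise
  details that leave the other three outcomes essentially unchanged.  Loss,
  fixation and temporary shares, the rarity ordering, the
  pre-versus-post-zygotic equilibrium contrast, and all within-outcome
  regression effects are robust across seeds, drift schemes and gradient
  estimators; the absolute equilibrium percentage (~2–3% pre-zygotic,
  ~0.5–0.7% post-zygotic under the defaults) should be read with that
  sensitivity in mind.
- Interior equilibria here are deterministic fixed points of the
  three-allele recursion; at n = 10⁶ drift perturbs them only slightly. At
  much smaller population sizes the classifier thresholds would need
  rescaling, since drift noise grows as 1/√n.
- The OLS coefficient magnitudes depend on the sampled ensemble
  (they are averages over a strongly nonlinear response surface); signs and
  relative magnitudes are the meaningful output.
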