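# drivesim

Stochastic, allele-level simulation of CRISPR homing gene drive frequency
dynamics, for researchers designing drives with *intermediate* outcomes —
drives that neither sweep to fixation nor vanish, but plateau at an
equilibrium frequency or establish only temporarily.  The package simulates
a single drive locus forward in time, classifies each trajectory into
fixation / loss / temporary / equilibrium, and explores the seven-variable
design space with a Monte Carlo sensitivity framework.

## Model

The population carries three alleles at the drive locus — the drive allele
*D*, the wild-type allele *W* and a conversion-resistant allele *R* — and
cycles through discrete, non-overlapping generations at constant population
size *n* (default 10⁶).  Each generation:

1. **Zygote formation.** Gamete frequencies *p* form diploid genotypes at
   Hardy–Weinberg proportions with excess homozygosity from inbreeding *F*:
   `G_ii = p_i² + F p_i (1 − p_i)`, `G_ij = 2 (1 − F) p_i p_j`.
2. **Homing conversion.** Drive heterozygotes become drive homozygotes:
   the converted mass is `x/n` with `x ~ Binomial(n, c_j G_Dj)`, where the
   susceptibility `c_j` is the conversion efficiency *c* for *W* and the
   (lower) resistance level for *R*.
3. **Selection.** Drive carriers exposed to selection (fraction *e* of the
   population) pay a fitness cost *s*, weighted by the dominance *d* in
   heterozygotes (drive homozygotes pay the full cost):
   killed mass `x/n` with `x ~ Binomial(round(e G_ij n), d_eff s)`;
   genotype frequencies are then rescaled to sum to 1.
4. **Drift.** Wright–Fisher binomial resampling of the gamete pool:
   `p_i' = x_i / 2n`, `x_i ~ Binomial(2n, p_i)`, renormalized.

A *pre-zygotic* drive converts during gametogenesis (after selection on the
parents); a *post-zygotic* drive converts the newly formed zygotes (before
selection).  Every module also has a deterministic expectation-propagation
flavour used for closed-form validation.

After 500 generations a trajectory is summarized by its maximum frequency,
time to maximum, final frequency and gradient (mean per-generation change
over the last 20 generations), and classified: **fixation** (final > 0.90),
**loss** (max < 0.10), **temporary** (max > 0.30 and final < 0.10),
**equilibrium** (final in [0.10, 0.90) and |gradient| < 10⁻⁴), else
unclassified.

## Worked example

Simulate an efficient pre-zygotic drive (conversion 0.95) with a strong but
recessive, half-exposed fitness cost (s = 0.8, e = 0.5, d = 0) against a
weakly convertible resistant allele (resistance level 0.1, initial
frequency 0.1):

```console
$ drivesim simulate --preset equilibrium --mode deterministic --out traj.csv
outcome: equilibrium (max 0.8206 at generation 14, final 0.2500)
equilibrium
```

The drive surges to 82% within 14 generations as wild-type alleles are
converted, then recedes as selection against drive homozygotes balances the
slow conversion of resistant alleles, settling at the interior equilibrium
frequency 0.25.  `traj.csv` holds the per-generation allele frequencies and
`traj.json` the summary statistics, outcome and full scenario echo.

Sample the whole design space (all seven variables uniform, resistance
level a uniform fraction of conversion, resistance frequency on [0, 0.4]):

```console
$ drivesim montecarlo --n-sims 2000 --seed 1 --out records.csv
Loss           51.35
Fixation       34.85
Temporary       6.30
Equilibrium     2.55
Total          95.05
```

Roughly half of all sampled pre-zygotic drives are lost, a third fix, and
the intermediate outcomes are rare — equilibrium rarest of all, requiring
low dominance and low inbreeding.  `records.csv` has one row per simulation
(the sampled variables, the derived selection pressure s·e, the summary
statistics and the outcome), ready for downstream multivariate analysis;
`--balanced N` collects N records of each outcome instead, and `--regress`
adds within-outcome least-squares tables of the dynamics metrics on the
variables.

## Layout

- `drivesim.core` — life-cycle operations and single-scenario simulation
- `drivesim._engine` — vectorized batch engine used by the Monte Carlo driver
- `drivesim.outcomes` — summary statistics and outcome classification
- `drivesim.montecarlo` — design-space sampling, outcome tables, balanced
  sampling, within-outcome OLS
- `drivesim.cli` / `drivesim.config` / `drivesim.presets` — command line,
  YAML configs, named fixture scenarios

See `docs/methods.md` for modelling assumptions, parameter semantics,
numerical choices and known limitations.
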