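# Methods

This note documents the models implemented in `drivesuite`, the defaults
and why they were chosen, the numerical decisions, and the limits of what
the synthetic experiments can show.

## 1. Inheritance engine (`drivesuite.genetics`)

### Model

Each individual is a phased two-locus diplotype. Gametes are produced by
per-locus transmission rules:

- **Drive locus** (`W`, `D`, `R1`, `R2`): only the exact genotype `D/W` is
  biased. The drive is transmitted with probability *h<sub>s</sub>* (sex
  *s*); the remaining 1 − *h* of gametes descend from the originally
  wild-type chromosome whose allele is `W` with share *u* (escaped
  cleavage), `R1` with (1 − *u*)·*f* and `R2` with (1 − *u*)·(1 − *f*)
  (end-joining repair). All other genotypes segregate 1:1. With *h* = 0.5
  and *u* = 1 the locus is exactly Mendelian.
- **Effector locus** (`C`, `E`, `CR`): identical rule with
  *h<sub>E</sub>*, *u<sub>E</sub>*, active only when the individual
  carries at least one `D` (Cas9 supplied in trans) and is exactly `E/C`.

The two loci are joined through the recombination fraction *r*: the
chromosome of descent at each locus is drawn from the per-locus
transmission weights, with parental (non-recombinant) configurations
up-weighted by 1 − *r* against *r*, and the joint renormalised. At the
default *r* = 0.5 the loci factorise and the per-locus marginals above are
exact. This direct-marginal formulation was chosen over an explicit
"conversion event then meiosis" construction because it represents any
*h* ∈ [0, 1] (a conversion-probability model cannot express transmission
below 0.5) and makes the documented marginals hold by construction. The
one approximation this buys: when **both** loci are actively homing *and*
*r* < 0.5, the renormalisation shifts each marginal slightly off its
nominal *h*. The default is *r* = 0.5 — the real loci are megabases apart
and no genetic-map distance is available — so the shipped configurations
never encounter this regime.

Offspring distributions are the outer product of the parental gamete
distributions with a 1:1 sex split (autosomal loci; no maternal
deposition, which matches the germline-restricted Cas9 promoter used by
the modelled strain).

Fitness classes partition genotypes by intact target-gene copies:
`D`/`R2` are equivalent loss-of-function alleles, `W`/`R1` equivalent
functional ones. The effector locus is fitness-neutral.

### Defaults

| parameter | default | basis |
|---|---|---|
| *h*♀, *h*♂ | 0.996, 0.971 | measured inheritance rates of the drive strain |
| *u* | 0 | the transmission-model configuration converts all residual alleles to resistance |
| *f* | 0.001 | the drive targets an ultra-conserved microRNA; nearly all repair scars break it. The low (1:999) split also reproduces the observed *sustained* fixation — with *f* = 0.1, functional-resistance alleles arise often enough in a 500-adult cage to displace the costly drive after fixation, which was not observed |
| *h<sub>E</sub>*, *u<sub>E</sub>* | 0.95, 0 | effective trans-homing of the effector; the measured endpoint (effector fixed wherever the drive fixed) constrains it to be high but not its exact value |
| *r* | 0.5 | free recombination absent a genetic map |

`deterministic_step` iterates the drive locus in an infinite population:
Hardy-Weinberg genotype formation, per-class relative weights
(viability/mating lumped), sex-specific gamete pools averaged. It is the
mean-field oracle for both stochastic simulators.

## 2. Cage simulator (`drivesuite.cage`)

One generation follows the maintenance protocol of the emulated trial, in
order: (1) binomial adult attrition over a 6-day mating window, daily
survival `p0^m` with `p0` = 0.98 (wild-type median lifespan ≈ 35 days)
and `m` the class multiplier; (2) single mating per female (*Anopheles*
females are effectively monandrous), partner multinomial ∝ male count ×
mating weight; (3) one blood meal — LOF-homozygous females die with
probability *b* before ovipositing; (4) Poisson egg output per female
(mean 80, hatch-to-larva viability folded in) scaled by class fecundity;
(5) 525 larvae (5 trays × 105) drawn **without replacement** from the egg
pool — sequential hypergeometric over mating pairs, then exact
per-pair offspring genotype sampling via the cross distribution; (6)
screening of larvae not used for seeding: hypergeometric draws of 100 for
the fluorescent drive marker and 92 for the effector PCR. Extinction (no
adults of one sex, or no eggs) returns a flagged terminal state.

**Where the measured phenotypes act.** Lifespan → the mating-window
attrition; blood-meal mortality → step (3); flight deficits → the mating
weight. The mating weight acts on males through partner sampling **and on
females as a mating-success probability** — swarm mating requires flight
from both sexes. Without the female channel no parameterisation inside
the measured cost ranges slows invasion enough to match the observed
fixation times; with it the calibration below does.

**Calibration** (`calibrated_cage_fitness`): daily mortality multiplier
1.5 (measured homozygote/wild-type median-lifespan hazard ratios are
1.4–1.6; heterozygotes get the half-impact default 1.25), blood-meal
mortality 0.8 (post-meal mortality under the cage feeding protocol is
severe), homozygote mating weight 0.2. The mating weight is the single
free parameter: it compounds the flightless fraction (up to ~40%),
reduced flight capacity among flyers, and mating competition — not
separately identifiable from cage trajectories. Under this calibration 50
replicate cages give a generation-1 carrier-frequency dip in essentially
all replicates, median wild-type-allele exhaustion at generation ~13, and
a sustained fall in egg output after fixation.

## 3. Transmission model (`drivesuite.epi`)

A daily-timestep stochastic cohort model; counts are integers and all
transitions binomial/multinomial, making the representation
distributionally equivalent to an agent-based description of the same
rules while running at desk scale (≈ 0.1 s per simulated year).

**Vectors.** Females are stratified by own genotype × mate genotype ×
feeding timer × infection state. Emerging females mate once with a male
drawn from the current male genotype pool (females that emerge into a
male-less cage remain unmated and lay nothing). Females attempt a blood
meal daily until the first success (success probability 0.9/day), then
feed every 3 days, ovipositing at each cycle completion before re-feeding.
Adult survival is `p0^m` per day with baseline `p0` = 0.88 (field-scale
mean adult life ≈ 7–8 days); blood-meal mortality *b* applies to
LOF-homozygous females at every meal, after the bite's epidemiological
effects (the meal is taken either way) and after oviposition (eggs come
from the previous meal). Because transmission requires surviving at least
two meals separated by the extrinsic incubation period, even moderate *b*
sharply truncates the infectious tail of the female age distribution —
the central suppression-modification mechanism.

**Larvae.** Fixed 10-day development; daily survival `0.9 / (1 +
L/K)` (logistic crowding) with capacity *K*. *K* is the tuning knob for
transmission intensity: `calibrate_density` bisects log *K* until the
no-release equilibrium EIR (annualised infectious bites per person,
averaged over ≥ 3 burn-in replicates) is within 20% of target.

**Humans.** A two-state susceptible–infected process: infection from
infectious bites with probability 0.5 × S/N per bite, clearance at
0.01/day (a single effective rate standing in for natural recovery plus
treatment seeking), incubation in the mosquito fixed at 11 days,
no seasonality. Daily new human infections are the clinical-incidence
proxy. This is a declared simplification of within-host dynamics:
**absolute case counts are not comparable to full agent-based
frameworks** — supported outputs are relative reductions versus matched
no-release baselines, elimination indicators (no new infections in the
final year), vector-eradication events, and allele-frequency
trajectories.

**Release and sweeps.** A single release of drive-homozygous males
(default 1000 at day 200). `sweep` runs the factorial grid *f* × *m* ×
*b* × EIR with one calibration and one set of baseline runs shared per
EIR setting. Reference conditions are 99% inheritance in both sexes,
full residual conversion, *f* ∈ {0.001, 0.01, 0.1}, *m* ∈ [1, 2.5], *b*
∈ [0, 1], EIR targets {15, 35, 65}, 40 replicates, 6-year horizon,
~1000 humans. The shipped qualitative checks run a reduced design — 3 ×
3 × 3 grid, 10 replicates, 2-year horizon, 200 humans, EIR 35 — chosen
as the smallest system in which the regime structure is stable: vector
eradication occurs only where *b* = 1 and *f* ≤ 0.01 (functional
resistance rescues the population otherwise), and case reduction rises
with *b* at drive-permissive daily mortality. At this reduced horizon the
comparison of stochastic means between *b* levels uses a paired two-SE
allowance: eradication's full payoff accrues beyond the truncated
window, so *b* = 1 can trail *b* = 0.5 by a within-noise margin even
though both far exceed *b* = 0 — consistent with intermediate blood-meal
mortality being competitive with full lethality once resistance
selection and timing are considered.

## 4. Estimators (`drivesuite.inference`)

- Transmission: point estimate *k/n* with the exact Clopper-Pearson
  interval (scipy's exact binomial machinery). Exact coverage at the
  design point *n* = 200, *p* = 0.99 is 0.984.
- Lifespan conversions assume constant hazard (geometric lifetimes),
  matching how the simulators apply mortality: daily survival
  `p = 0.5^(1/median)`; the mortality multiplier implied by two medians is
  their ratio (hazard ratio). The survival-table median estimator reads
  the median off the cumulative-death curve so right-censoring does not
  bias it low.
- Carrier → allele frequency assumes Hardy-Weinberg (`q = 1 − √(1 − c)`);
  biased in the first generations after seeding with homozygous founders.
- Egg trend: OLS quadratic in generation (statsmodels), setup generation
  excluded by default (its founders are all homozygous), pointwise
  standard errors of the fitted line returned.
- Cage blood-meal-mortality calibration: grid search minimising the mean
  squared distance between observed trajectories and the replicate-mean
  simulated trajectory. Transparent rather than likelihood-based; with
  fewer than ~5 simulation replicates per grid point the loss is noisy
  enough to mis-rank adjacent values.

## 5. Synthetic data (`drivesuite.synth`)

Generators emit exactly the sampling distributions the assays induce:
binomial per-replicate carrier counts for crosses; geometric lifetimes
right-censored at the end of follow-up, tabulated as daily deaths/at-risk;
hypergeometric screening draws (larvae are physically removed) from cage
census truth. Ground truth travels in a sidecar record, so estimator
inputs look like lab tables while tests keep the answer key. What they do
**not** emulate: overdispersion between biological replicates beyond
sampling noise, environment-driven egg-output fluctuations (visible and
large in the real trial), genotyping error, or non-constant hazards —
passing recovery tests therefore demonstrates estimator correctness under
the stated model, not robustness to these real-data features.

## 6. Reproducibility and numerics

All randomness flows from integer seeds through `numpy` Generators;
replicates use (seed, replicate-index) seed sequences; identical seeds
give byte-identical CSV outputs, recorded with checksums in each run
manifest. Gamete distributions are exact to 1e-12 (validated against
brute-force enumeration); allele-frequency vectors are renormalised after
each deterministic step to absorb rounding. Degenerate inputs are defined,
not accidental: all-zero fitness weights raise, empty founder censuses
raise, extinction states are flagged and terminal, a zero-case baseline
makes the percent reduction undefined and raises.

## 7. Known limitations

- Discrete generations and a single blood meal per cage generation; no
  overlapping ages inside a cage cycle and no larval density dependence in
  the cage (the protocol fixes larval numbers).
- The two-locus joint distribution is approximate only in the unused
  corner (both loci homing, *r* < 0.5).
- The human layer has no age structure, immunity, superinfection or
  importation; elimination probabilities at 200 humans are optimistic
  relative to larger systems.
- The cage cost calibration is not unique: the data constrain the
  composite homozygote disadvantage much more tightly than its split
  across mating, lifespan and blood-meal channels.
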