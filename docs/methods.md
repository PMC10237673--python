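# Methods

## The guarding model

Male *Drosophila melanogaster* shorten their copulations after sexual
experience (shorter-mating-duration, SMD). Because most of the variation in
mating duration lies in the post-ejaculatory phase, the behavior is modelled
as a patch-residence problem: mate guarding secures eggs at a diminishing
rate while its costs (predation exposure, forgone matings and foraging)
accrue steadily, and the marginal value theorem picks the duration at which
the marginal benefit falls to the marginal cost.

`mateguard.guarding` uses

    B(t) = (1/alpha) * (1 - exp(-beta * t))        benefit (eggs secured)
    C(t) = (gamma / e) * t                         cost (egg-equivalents)
    N(t) = B(t) - C(t)                             maximised over t in [0, t_max]

with three parameters:

| parameter | meaning | units | default regime used in analyses |
|-----------|---------|-------|---------------------------------|
| `alpha` (> 0) | inverse of the total securable clutch; larger alpha means fewer eggs in total | 1/eggs | 1.0 |
| `beta` (> 0) | benefit-accrual rate; 1/beta is the benefit time constant | 1/time | 1.0 |
| `gamma` (>= 0) | cost parameter; the marginal cost rate is gamma/e, the 1/e gauge chosen so that the regime boundaries sit at beta/alpha and e*beta/alpha | eggs/time (composite) | swept |

The interior optimum is `t* = (1/beta) * ln(e*beta/(alpha*gamma))`, clamped
to `[0, t_max]` with `t_max = 10/beta` by default (several benefit time
constants, enough to capture saturation without unbounded search). Three
qualitative regimes follow directly:

* `gamma <= beta/alpha` — cheap guarding; the male guards at least one full
  benefit time constant (`t* >= 1/beta`), and with `gamma = 0` the payoff is
  monotone so the optimum is the horizon itself (`corner_max`);
* `beta/alpha < gamma < e*beta/alpha` — marginal guarding; the interior
  optimum shrinks from `1/beta` to zero as gamma rises across the window;
* `gamma >= e*beta/alpha` — guarding never pays and the optimum is the
  corner at zero (`corner_zero`).

The boundary `gamma = e*beta/alpha` is therefore both the classifier's C/D
boundary and the point where the optimum's character changes, which is what
the boundary-detection analysis verifies numerically. Exact equality at a
boundary classifies into the lower-labelled regime, keeping the strict
inequalities deterministic.

These functional forms are the package's own model definition, kept behind a
single seam (`benefit`, `cost`, `net_payoff`) so an alternative form can be
substituted without touching the solver. They were chosen as the simplest
pair satisfying every property the analyses require: no accrual at zero,
concave saturating benefit whose total scales as 1/alpha, cost linear in t,
homogeneous of degree one in gamma and identically zero at gamma = 0.

### Scenario predictions and a structural limitation

Four single-parameter shifts can favour shorter guarding in experienced
males: a larger `alpha` (fewer eggs securable in total), a smaller `beta`
(slower accrual), a larger `gamma` inside the middle window (costlier
guarding) and — per the stated regime condition — a smaller `gamma` when
`gamma > e*beta/alpha`. The first three hold in this model and are verified
against a brute-force grid oracle.

The fourth cannot hold in this model class, and the package reports it
honestly rather than forcing it. For any objective `B(t) - gamma*g(t)` with
`B` concave and `g` increasing — which is exactly the class pinned down by
the requirements above — implicit differentiation at an interior maximum
gives `dt*/dgamma = g'(t*)/N''(t*) < 0`: the optimum is strictly decreasing
in gamma wherever it is interior, and pinned at zero in the
`gamma > e*beta/alpha` regime. A decrease of gamma within that regime
therefore leaves the optimum unchanged at zero (`delta_t_star = 0`), and
`predict_smd` reports no SMD for scenario D. The corresponding acceptance
test is left failing by design; making it pass would require a cost that is
non-monotone in gamma, for which we see no biological justification.

### Solvers

`closed_form` evaluates the analytic optimum with corner handling.
`grid_search` takes the argmax over a uniform grid (10,000 points by
default, at least 1,000) and refines the bracketing interval by
golden-section search to a tolerance of 1e-8 in t; the payoff is concave in
t so the refinement is safe, and the two methods agree to 10x the tolerance
on random interior parameter sets. All real-valued comparisons use a
relative tolerance of 1e-9 unless stated.

## Synthetic assay data

`mateguard.simulate` generates the datasets the statistical pipeline
consumes. It emulates the distributional structure the analyses assume, not
the biology that produces it:

* **Mating durations** are normal per group (the study reports normality of
  its duration data), truncated at a 60 s floor and rounded to the 10 s
  recording accuracy. The experienced-group mean is the naive mean scaled by
  `1 - percent_reduction/100`. Defaults: naive mean 1260 s (21 min, typical
  for the species), sd 240 s, 36 males per group (the study's minimum), and
  per-strain reductions taken from the reported values (CS 15.7, WT-Berlin
  15.8, Oregon-R 15.7, w1118 12.4 percent) where a strain is named.
* **Copulation latency** is lognormal (right-skewed, positive; mean 900 s,
  sd 700 s), so a small fraction of males exceeds the one-hour window and
  exercises the inclusion filter. Courtship latency is lognormal
  (60 +/- 45 s); courtship index is clipped normal on [0, 1] (0.6 +/- 0.15);
  climbing velocity is normal (8 +/- 2 mm/s).
* **Exposure time** maps hours with females to the percent reduction: zero
  at 6 h or less, the full effect at 12 h or more, linear between — the
  study's qualitative threshold without inventing intermediate values.
* **Fecundity**: eggs per female per 24 h are Poisson (negative-binomial
  optional via an overdispersion parameter), progeny binomial given eggs.
  Defaults: 50 eggs, survival 0.85, 24 females per arm, and an
  experienced-arm survival multiplier of 0.7 so the generator reproduces the
  reported pattern (comparable eggs, fewer progeny).
* **Two-sire crosses**: brood sizes Poisson(40) over 20 females; each
  progeny is sired by the first male with probability `first_sire_share`
  (default 0.2, matching typical last-male sperm precedence of ~0.8), and
  eye colour follows recessive single-locus genetics of the sepia marker:
  with an se/se mother, sepia-eyed progeny are the se/se sire's.
* **CaLexA fluorescence**: lognormal GFP and autofluorescence intensities
  per tarsal segment and condition; the default puts an effect only in T5
  (100 -> 250 a.u.), mirroring the reported contrast structure.

Every generator is a pure function of (design, seed), with per-generator
substreams derived from the one seed, so partial runs reproduce exactly.

What passing tests on these data do **not** show: the generators contain no
courtship micro-structure, no strain-specific variances (the study reports
none), no correlation between metrics within a fly, and no real measurement
artefacts beyond rounding and the inclusion window. Recovery of a configured
effect therefore validates the estimators and plumbing, not any claim about
the deposited raw data — in particular, the w1118 effect-size recomputation
runs on a synthetic stand-in parameterised at the printed 12.4 %.

## Statistics

* **Student's t** is the classic pooled-variance unpaired test
  (df = n1 + n2 - 2), matching the test the study names; Welch's variant is
  available as an option. Zero pooled variance follows fixed conventions:
  equal means give t = 0, p = 1; unequal means give p = 0 with a degeneracy
  flag.
* **Normality** uses the one-sample KS statistic against a normal law with
  estimated mean and sd, with the Lilliefors correction (statsmodels); the
  naive fully specified KS is available but anticonservative here. A
  lognormality mode tests the log-transformed sample. Constant samples are
  rejected as undefined rather than given an arbitrary p.
* **Kruskal-Wallis** (scipy, tie-corrected) gates **Dunn's multiple
  comparison test**: pairwise z on joint mean ranks with the tie term
  `sum(t^3 - t)/(12(N-1))`, two-sided normal p, Bonferroni-adjusted over the
  comparisons performed — control-vs-all by default, matching the
  internal-control design; all-pairs optional. Hash marks flag adjusted
  p < 0.05, stars use the strict conventional thresholds (0.05/0.01/0.001).
* **Estimation statistics**: the unpaired mean difference with a bootstrap
  CI from 5,000 independent within-group resamples; percentile interval by
  default (simplest to verify against an oracle), BCa with jackknife
  acceleration as an option. Calibration is checked at the study's group
  size of 36, where the percentile interval's small-sample undercoverage is
  within the stated band.
* **Inclusion** keeps males with copulation latency <= 3600 s (the boundary
  read inclusively, fixed for determinism). Percent reduction uses the naive
  group mean as denominator; with the deposited raw data unavailable, this
  reading could not be cross-checked against the printed 12.4 % and is
  documented as the package's convention.

## Problem sizes

Calibration experiments use 10,000 null replicates for the t test, 1,000
datasets for bootstrap coverage and 1,000 replicates at n = 500 for KS level
and power; effect-size recoveries use 1,000 flies per group, 2,000 females
per fecundity arm and ~12,000 progeny for paternity. These sizes put the
Monte-Carlo error well inside the assertion bands while keeping the whole
suite desk-scale.

## Known limitations

* Scenario D, as discussed above, is structurally outside the model class.
* The Dunn adjustment family and the KS correction used by the original
  analyses are not stated there; both choices here are documented defaults
  with the alternative available.
* Generator defaults for quantities the study never reports (variances,
  latency distributions, brood sizes) are conventional choices, not fits.
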