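# Methods

## Cohort definitions and filtering

A *term* birth is one at gestational age ≥ 259 days (37+0 weeks); the
exclusion filter removes multiple pregnancies (plurality > 1), preterm
births (< 259 days) and congenital anomalies, tallying each exclusion once
by the first matching reason in that order. Epoch assignment is by birth
date against a configured policy cut date, half-open: dates on or after the
cut date are "after". *Undiagnosed breech* means a term breech birth with no
antenatal diagnosis whose labour onset was spontaneous labour, prelabour
rupture of membranes, or induction — i.e. the breech was first discovered
when intrapartum options had already narrowed. Any antenatal scan finding
breech marks the record diagnosed; no look-back window is applied.

Pregnancies delivered by planned cesarean for a diagnosed breech never
labour, so they are removed from the denominators of all outcomes *except*
the four neonatal outcomes (Apgar < 7 at 5 min, neonatal-unit admission,
HIE, perinatal death), where the newborn's outcome remains informative.
Records missing a field an outcome requires (e.g. Apgar) are dropped from
that outcome's denominator only, with the count logged.

## Bayesian log-binomial risk-ratio model

Events per epoch are binomial with log-linear risk:
`log p₁ = α`, `log p₂ = α + β`, so `exp(β)` is the after-vs-before risk
ratio. The log link forces the support constraint `α ≤ 0`, `α + β ≤ 0`,
enforced by assigning zero posterior mass outside it.

**Priors.** `β ~ Normal(μ, σ)`. For informative analyses, (μ, σ) are
elicited from a published point estimate and 95% CI via
`μ = ln RR₀`, `σ = (ln CI_hi − ln CI_lo)/(2·1.959964)`; the constant
1.959964 (not 1.96) is fixed throughout for reproducibility of the
round-trip `exp(μ ± 1.959964 σ)`. The weakly informative default, used for
the "flat-prior" sensitivity analysis, is `Normal(0, 10)` — essentially
flat over any plausible risk ratio; a truly improper constant prior is
available behind a flag and gives near-identical results at these sample
sizes. The intercept prior is `Student-t(df = 3, location, scale = 2.5)`
with the location defaulting to the log pooled risk
`ln((a + c + ½)/(n₁ + n₂ + 1))`; both are configurable. If a published
source estimate has a zero cell, or the data do, the single-event
correction replaces each zero event count with 1 (denominator unchanged)
and flags the summary.

**Sampler.** Adaptive random-walk Metropolis with component-wise Gaussian
proposals on (α, β), alternating coordinate updates each sweep.
Per-coordinate proposal scales (default 0.4) adapt every 50 burn-in sweeps
toward ~35% acceptance by a multiplicative rule, and are frozen after
burn-in so the sampling phase satisfies detailed balance; component-wise
adaptation keeps mixing correct even under near-degenerate priors
(σ → 0 pins β at μ). Defaults follow the standard settings used for this
analysis: 2 chains × 1,500 retained sweeps after 500 burn-in, pooled.
Chains are initialised at a jittered moment estimate
(`α₀ = ln((a+½)/(n₁+1))`, `β₀` from the crude log-RR, clipped into the
prior's ±3σ bulk), projected into the support. Each chain's random stream
derives from (seed, chain index); identical inputs give bit-identical
output. Diagnostics: split R-hat on β across chains (warning above 1.05)
and post-burn-in acceptance rate (warning outside [0.1, 0.6]).

**Summaries.** Point estimate: posterior median of `exp(β)` (medians are
invariant to the exp transform and robust to the skew of small-count
posteriors); interval: equal-tailed 2.5/97.5 percentiles. The posterior
probability of reduction is Φ(−m/s) where (m, s) are the moments of the
pooled β draws — a normal density fitted to the log-RR posterior — which
agrees with the empirical tail fraction to < 2% in testing but is smooth
in the tails where the draw count is limiting.

**Grid oracle.** An independent validation path evaluates the unnormalised
log posterior on an 801 × 801 lattice, centred on a precision-weighted
normal approximation (likelihood moments combined with the prior) and
spanning ±12 approximate posterior SDs, normalises by summation, and reads
the marginal quantiles of `exp(β)` and P(β < 0) off the marginal CDF. The
sampler is required (and tested) to agree with the oracle within
Monte-Carlo error on randomized small tables; the oracle shares no code
path with the sampler beyond the log-posterior definition.

## Number needed to scan

`NNS = ⌈1/RD⌉` with `RD = a/n₁ − c/n₂` computed on whole-population
denominators (all term singleton births, not just breech). The 95% CI
inverts the Wald interval `RD ± 1.959964·SE`,
`SE = √(p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂)`. The point estimate always rounds up
(a partial woman cannot be scanned); interval endpoints round to the
nearest integer by default — outward rounding (floor/ceil, giving an
interval never narrower than the exact one) is available as an option, and
the two conventions differ by at most 1. `RD ≤ 0` leaves the NNS
undefined and is signalled rather than reported.

## Descriptive comparisons

Continuous variables: Welch's unequal-variance t-test (mean ± sd) or the
two-sided Mann-Whitney rank-sum test (median, IQR). A "signed-rank" test is
not applicable to independent epochs, so the rank-sum test is the
independent-groups interpretation used here. Binary variables: Pearson
chi-squared on the 2×2 table without Yates continuity correction — the
simpler convention, fixed and documented because published descriptive
p-values of this kind are not always reproducible from printed counts under
either convention. Two identical constant samples under the t-test return
p = 1 by convention (logged). No multiplicity adjustment is applied; rows
are reported as independent descriptive comparisons.

## Interrupted time series

Term breech records are binned into consecutive calendar months (explicit
zero bins for empty months; partial first/last months keep their true
exposures) with undiagnosed counts and breech-birth exposures. The default
model is ordinary least squares of monthly counts on a natural cubic
spline in month index (df = 4, knots at quantiles; the spline basis spans
the constant) plus a post-policy indicator; the policy effect is the
F-test comparing the models with and without the indicator, mirroring the
ANCOVA-style interrupted-time-series test common in applied policy
analysis. A Poisson GLM with log link and log-exposure offset is the
configurable alternative (likelihood-ratio test, 1 df), which is the
appropriate likelihood for the 0–4 events/month counts typical at a single
hospital. Its type-I error is calibrated at study scale (~0.04 at nominal
0.05 over 500 null simulations).

**Power limitation.** With ~46 pre-policy and ~21 post-policy months, the
epoch step is strongly collinear with any smooth secular trend (R² of the
indicator on the trend basis: 0.65 for a linear trend, 0.88 at spline
df = 4). Trend-adjusted detection of even a large step (14.2% → 2.8% at
~12–13 breech births/month) at p < 0.001 therefore succeeds only in a
minority-to-moderate fraction of replicates (Gaussian df = 4 ≈ 5%; Poisson
with linear trend ≈ 67%, where it does detect the step in the majority of
replicates). Users should treat the ITS p-value as confirmatory of the
primary two-group Bayesian analysis, not as a powerful standalone test;
a single observed series can still yield p < 0.001 when the realised step
is sharp.

## Synthetic cohort generator

One seeded stream per cohort drives, per epoch: uniform birth dates over
the configured months; independent Bernoulli draws for multiple pregnancy
(1.5%), preterm (6%), anomaly (2%), breech (3.4%); an epoch-dependent
undiagnosed fraction among breech (defaults 14.2% before, 2.8% after — the
study-scale rates); planned cesarean in 70% of diagnosed breeches; and
adverse outcomes conditional on (breech, diagnosed): e.g. Apgar < 7 risk
0.008 if diagnosed vs 0.08 if undiagnosed, against a 0.004 background.
The conditional outcome risks are simulation knobs (chosen so rare events
are observable at test sample sizes with the risk ordering
undiagnosed > diagnosed > background), not published quantities.
Demographics (age with an epoch shift, BMI, parity, ethnicity, IMD) come
from simple parametric families and never drive outcome risk, matching the
unadjusted two-group models downstream. The generator returns a truth
tally of every planted count, and the pipeline's aggregation is tested to
reproduce it exactly.

What the generator does *not* emulate: within-epoch secular trends or
seasonality, spontaneous version dynamics and external cephalic version
pathways, correlated outcomes within a birth, site mixtures, or
missingness (optional but defaulted off). Passing tests therefore
demonstrate correctness of the estimators under the assumed two-epoch
conditional-Bernoulli structure, not robustness to confounding or drift in
real maternity data.

## Problem sizes used in testing

Tests exercise the sampler against the grid oracle on 20 randomized small
tables (2 × 20,000 retained sweeps each, so tail quantiles carry < 2%
Monte-Carlo error), parameter recovery on 100 replicates × 3 planted risk
ratios at 500 breech pregnancies/epoch, generator calibration on 200
replicates at 5,000 births/epoch, and ITS calibration on 500 null
series of 67 months. The full suite runs in well under a minute on one
CPU.

## Known limitations

- The log-binomial support constraint makes the posterior boundary-aware;
  for risks near 1 the random-walk sampler mixes slowly (not a regime that
  occurs with rare outcomes).
- The normal-density posterior probability understates nothing at these
  effect sizes but can differ from the empirical tail for strongly skewed
  posteriors with very few events.
- Informative-prior analyses are only as good as the elicited source
  estimate; the elicitation assumes the source CI is a symmetric normal
  interval on the log scale.
- The ITS module fits a level change at a known date only; no slope-change
  or unknown change-point estimation, and no autocorrelation-robust
  variance (monthly rare-event counts show negligible serial correlation
  in the simulated regime).
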