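# Methods

## The population and the question

McKenzie River spring Chinook salmon — the strongest remaining wild
population of the Upper Willamette River ESU — emigrate seaward through
the lower Willamette River, where the Portland Harbor Superfund reach
holds legacy PCBs and DDTs. One juvenile life-history type, the spring
subyearling (on average 18% of outmigrants), rears in this reach long
enough to accumulate contaminants. The package quantifies what removing
contaminant-attributable mortality from that cohort would do to adult
abundance and quasi-extinction risk over a century.

## Contaminant loss model

Three mortality pathways combine into one annual loss for spring
subyearlings:

* **West-bank lethality (acute).** Tissue DDT burdens at the west-bank
  hotspot (site T02, 14,832 ng/g lipid) are an order of magnitude above
  all other sites and above the 6,000 ng/g lipid effect threshold, and
  comparably burdened fish are absent downstream; west-bank migrants
  (fraction 0.5 of the cohort) are therefore treated as lost
  (loss = 1.0).
* **Immunosuppression (delayed).** Disease-challenge studies support a
  7% delayed mortality for exposed east-bank migrants.
* **Reduced growth (delayed).** Growth deficits map to estuary survival
  through the logistic link below; the 0.35 and 2.21 percentage-point
  decrements from the two documented length reductions average to ≈1%
  delayed mortality.

Immune and growth losses are summed (treated as mutually exclusive); an
independent-event combination, 1 − (1 − a)(1 − b), is available but not
default. The combined loss is

`L = w·l_w + (1 − w)·(l_i + l_g)` = 0.5 + 0.5 × 0.08 = **0.54**,

converted to a survival multiplier of **1 + L = 1.54** on
spring-subyearling lower-river survival. The additive convention (1.54,
not the compensatory 1/(1 − 0.54) ≈ 2.17) is used because the sensitivity
design range 1.00–1.54 fixes that convention; the compensatory form is
available behind an option. Whether baseline lower-river survival already
embeds contaminant mortality is unknowable from the available evidence;
the multiplier is applied as a relative improvement.

## Growth–survival link

Estuary survival is `expit(α + βΔℓ)` with β = 0.0329 per mm of fork
length. The intercept is calibrated so that survival at Δℓ = 0 equals
the population-scale base value 0.66 × 0.18 = 0.1188, giving
α = logit(0.1188) = −2.003. Subyearlings in the harbor reach run 50–80 mm
(mean 65 mm); length reductions of 1.6% and 10.8% give Δℓ = −1.04 mm and
−7.02 mm and survival decrements of 0.35 and 2.21 percentage points.
The logistic is evaluated with `scipy.special.expit` (numerically stable
at extreme arguments); exact evaluation of the 10.8% case gives 2.2143
points, reported to two decimals.

## Life cycle model

Annual census with stages: spawners → fry (Beverton–Holt,
`pS/(1 + pS/c_fry)` with fry capacity `c_fry = p × c_adult`) → above/below
dam rearing (fraction 0.30 above Cougar Dam passes at 0.60 and survives
the reservoir at 0.55; below-dam fry survive at 0.65) → three-way pathway
split (0.18/0.13/0.69) → pathway-specific lower-river survival → estuary
entry with survival `expit(−2.003 − 1.12·PDO_May + 0.70·Up_May +
0.56·Up_Sept + 0.0329·Δℓ)` → ocean ages 1–5 with annual survival 0.80 and
maturation 0.30/0.60/1.00 at ages 3/4/5 → prespawn survival
`expit(4.935 − 0.45·T + 2.0·W)` (T late-summer temperature °C, W wild
fraction). Spawning is semelparous. The remediation multiplier scales
spring-subyearling lower-river survival only, clipped at 1; fall
subyearlings and yearlings move through the harbor too quickly to accrue
contaminant effects and receive none.

**Stochasticity.** Fry production is Poisson about the Beverton–Holt
mean; every survival transition is binomial and the pathway split
multinomial. All draws use inverse-CDF sampling from a fixed number of
uniforms per year. Because the binomial/Poisson quantile function is
monotone in the underlying uniform, in n and in p, two projections with
the same seed and different multipliers are pathwise ordered — the basis
of the common-random-number monotonicity guarantees. An expected-value
mode (no RNG) runs the same recursions on continuous counts; in that
density-independent limit the model is linear and its growth rate equals
the dominant eigenvalue of the corresponding projection matrix (verified
in tests).

**Initialization.** Projections start from 650 spawners with the ocean
pipeline filled at the deterministic stationary age structure, avoiding a
spurious collapse while the first cohorts age at sea.

## Parameter provenance and calibration

Quantities fixed by the study design: pathway proportions (0.18, 0.13,
0.69); estuary logit intercept −2.003 (survival 0.1188 at average ocean
conditions); growth slope 0.0329/mm; quasi-extinction threshold 250
adults; horizon 100 years; 1000 runs per ensemble; multiplier range
1.00–1.54.

The remaining demographic rates and covariate coefficients are the
package's own calibration, chosen once, within biologically plausible
bounds for McKenzie spring Chinook (productivity 215 fry per spawner ≈
4,500 eggs × 50% females × ~10% egg-to-fry survival; adult-equivalent
capacity 900 above Cougar Dam; lower-river survival ~0.5 per pathway;
ocean survival 0.8/yr; prespawn survival ≈ 0.34 at average conditions —
within the wide observed range of Willamette prespawn mortality), so that
the **baseline** model reproduces the published baseline behaviour of
life cycle assessments of this population: median-centred per-run mean spawner
abundance ~500–600 with a wide interquartile spread (roughly −45% to
+50% of the median) and a quasi-extinction risk near 0.2 at the 250-adult
threshold. The treated-arm outcomes (median change ≈ +25%, risk ≈ 0.1)
are emergent predictions of that calibrated baseline, not fitted targets.
Under this calibration the baseline spread remains right-lighter than the
published quartiles (+50% vs +123% at the 75th percentile); matching that
tail while holding the risk and median-change levels was not achievable
with this noise structure and is recorded as a known limitation.

## Synthetic environment

Each covariate (May PDO, May/September upwelling, late-summer
temperature, wild fraction) is an independent stationary AR(1) process
with a 100-step burn-in: standardized indices (mean 0, sd 1) with lag-1
autocorrelation 0.7 for PDO (regime-like persistence) and 0.5 for
upwelling; temperature 16 ± 1 °C (φ = 0.5); wild fraction 0.80 ± 0.08
(φ = 0.3), clipped to [0, 1]. These are stand-ins with the right
qualitative structure, not reconstructions of the historical series: they
lack cross-covariate correlation (PDO and upwelling are correlated in
reality), trends, and observed regime timing. Passing tests therefore
demonstrate the machinery and the calibrated model's behaviour, not a
hindcast of the real ocean.

## Ensembles and summaries

Each ensemble spawns one `SeedSequence` child per run (two grandchildren:
environment and demography), so runs are independent and insensitive to
ensemble size or order. A run is summarized by its mean spawner abundance
over the horizon. Scenario effects: per-run change relative to the
*baseline median* (hence baseline median change is 0 by construction);
quasi-extinction risk is the fraction of runs whose mean is below 250
(an `any_year` mode scores any single-year dip instead; results label the
mode). Baseline and treated arms use independent seeds by default,
matching the two-sample design; a paired common-random-numbers mode
supports variance-reduced comparisons and the monotonicity tests.

## Sensitivity analysis

1000 draws, each parameter uniform over its range: multiplier 1.00–1.54;
pathway components (0.10–0.33, 0.40–0.65, 0.10–0.30) renormalized to a
unit sum after sampling (the per-component bounds do not themselves sum
to 1); prespawn logit intercept 3.94–5.94; capacity 1,500–4,000 was
rescaled to 750–1,800 to bracket the calibrated 900; fry survival below
dam 0.50–0.80; dam passage 0.40–0.80; reservoir survival 0.40–0.70;
estuary intercept −2.40 to −1.60. One stochastic projection per draw
yields the response (mean spawner abundance). The regression uses
additive log-ratio coordinates for the composition, with the yearling
proportion as reference (the alr variant is a package choice; centered
log-ratio is switchable). Influence = (coefficient/SE) scaled by the
largest absolute value; the top parameter scores ±1. No published numeric
influence values exist, so the qualitative ordering (prespawn survival
most influential) is logged as a soft diagnostic rather than asserted.

## Numerical choices and edge cases

* Logistic links via `expit`; calibration via `logit`; both stable.
* Compositions must be strictly positive; log-ratio transforms reject
  zero components and renormalize sums within 1e-6 of 1.
* Survival probabilities scaled by the multiplier are clipped at 1.
* Zero population is absorbing; NaN at any stage raises an error naming
  the stage.
* Exact binomial/Poisson quantiles are used at every population size;
  the cost (~0.1 ms/draw) keeps a 1000-run ensemble near 2–4 minutes on
  one CPU. Tests use reduced ensembles (40–200 runs, 15–50 years) except
  the full-scale two-arm experiment.

## Problem sizes used

Full experiment: 2 ensembles × 1000 runs × 100 years. Sensitivity: 1000
draws × 1 run each (examples use 300 × 50 years). Unit and property
tests: 5–200 runs, 9–45 years, 10,000-sample distributional checks.

## Known limitations

* Exact demographic point estimates for this population live in agency
  reports and model appendices not reproduced here; the calibration above
  stands in for them, so absolute abundances are indicative, not
  predictive.
* The baseline upper quartile of run-to-run spread is lighter than
  published (+50% vs +123%); heavier environmental tails (e.g.,
  correlated covariates, fatter innovation distributions) would be the
  natural extension.
* One response per draw makes the sensitivity regression noisy at small
  draw counts; influence rankings stabilize near the full 1000 draws.
* No density dependence outside fry recruitment; no harvest; hatchery
  influence enters only through the wild-fraction covariate.
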