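# chinook-pva

Population viability analysis of Upper Willamette River spring Chinook
salmon (*Oncorhynchus tshawytscha*) under legacy-contaminant mortality and
its remediation.

Juvenile "spring subyearling" Chinook from the McKenzie River feed and
grow for weeks in the Portland Harbor Superfund reach of the lower
Willamette River, where legacy PCBs and DDTs accumulate in their tissues.
This package implements a population-scale account of that exposure for
conservation practitioners and ecotoxicologists: it combines acute and
delayed contaminant mortality into a single annual loss for the exposed
cohort, embeds that loss in a stochastic stage-structured life cycle
model, and asks what a cleanup would buy the population over a century.

## The model

**Contaminant loss calculus.** Spring subyearlings split evenly between
river banks. West-bank migrants encounter a DDT hotspot and are assumed
lost (50% of the cohort); east-bank migrants carry delayed mortality from
immunosuppression (7%) and reduced growth (1%), giving a combined annual
loss

L = 0.5 × 1.0 + 0.5 × (0.07 + 0.01) = 0.54,

expressed as a survival multiplier of 1 + L = 1.54 on spring-subyearling
lower-river survival when remediation removes the loss.

**Growth–survival link.** Estuary survival follows a logistic in the
change of mean fork length Δℓ (mm),

s(Δℓ) = logit⁻¹(α + 0.0329 Δℓ),

with α = logit(0.66 × 0.18) = −2.003 so that s(0) = 0.1188. Documented
growth reductions of 1.6% and 10.8% of the 65 mm mean length translate to
survival decrements of 0.35 and 2.21 percentage points.

**Life cycle.** Spawners produce fry through Beverton–Holt recruitment
(productivity p, capacity c), fry pass or rear below Cougar Dam, split
into three juvenile pathways (spring subyearling 18%, fall subyearling
13%, spring yearling 69%), survive the lower river at pathway-specific
rates, enter the ocean through a covariate-driven estuary survival
(May PDO, May/September coastal upwelling), age at sea with annual
survival and a maturation schedule over ocean ages 3–5, and return to
spawn after temperature- and wild-fraction-driven prespawn mortality.
Demographic stochasticity uses Poisson/binomial/multinomial draws coupled
through inverse-CDF sampling, so paired seeds give pathwise-monotone
common-random-number comparisons.

**Experiments.** Monte Carlo ensembles (1000 runs × 100 years) compare
baseline and remediation arms by the distribution of per-run mean spawner
abundance and by quasi-extinction risk (fraction of runs averaging below
250 adults); a global sensitivity analysis ranks parameters by
standardized regression coefficients, with the compositional pathway
proportions handled through additive log-ratio coordinates.

## Worked example

```python
import chinook_pva as cp

loss = cp.combine_losses()              # 0.54
mult = cp.survival_multiplier(loss)     # 1.54

params = cp.default_parameters().evolve(n_runs=500)
result = cp.run_table2(params, seed=42)
for label, row in result["rows"].items():
    print(label, round(row["median_change_pct"]),
          round(row["quasi_extinction_risk"], 2))
```

prints (seed 42, 500 runs per arm):

```
baseline 0 0.2
treated 27 0.11
```

Baseline relative change is 0% by construction (each arm is compared to
the baseline median). The treated arm — spring-subyearling survival
multiplied by 1.54 — raises median spawner abundance by roughly a
quarter and cuts the probability of a century-long trajectory averaging
below 250 adults by about half. The `examples/` scripts walk through each
capability: the loss calculus, the growth–survival link, the
tissue-residue evidence, the projection experiment, and the sensitivity
ranking.

## Command line

A thin CLI mirrors the library:

```sh
pva scenario combine --west-fraction 0.5 --west-loss 1.0 --immune 0.07 --growth 0.01
pva experiment --runs 200 --multiplier 1.54 --seed 42 --out summary.json
pva sensitivity --draws 300 --seed 11 --out influence.csv
pva synth env --years 100 --series 5 --seed 3 --out env.csv
```

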