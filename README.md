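# genlife

Estimating adult lifespan and lifespan inequality from genealogy-style
microdata — and diagnosing when such estimates can be trusted.

Crowdsourced online genealogies record millions of individual lifespans
across centuries, but they are not random samples: coverage of the real
population is thin in early periods, and socially visible elites are
heavily overrepresented. `genlife` implements the full estimation chain
used in historical mortality research on such data, together with the
representativeness diagnostics that reveal when a genealogy-derived
series is tracking an elite subpopulation rather than the general one.
It is aimed at demographers and quantitative historians working with
individual-level vital records (one row per person: id, sex, birth and
death dates of mixed precision, places).

## What it computes

**Mortality estimation.** Individual lifelines are cleaned (territory
assignment, duplicate removal, death ages > 100 y dropped as
transcription errors, deaths after a cutoff year excluded) and tabulated
into a Lexis grid of death counts `D` and person-year exposures `E` by
5-y age group × calendar period, with optional left truncation at an
entry age (scholars enter observation at first appointment). The death
rate surface is smoothed with two-dimensional P-splines — a penalized
Poisson model

    D_ij ~ Poisson(E_ij · exp(η_ij)),   η = B_a Θ B_p'

with cubic B-spline bases and order-2 difference penalties in age and
period, fitted by penalized IRLS, smoothing weights selected by BIC.
Abridged period life tables (5-y groups, open interval 80+) follow the
standard chain `q_x = n·m_x / (1 + (n − a_x)·m_x)`, with the average
time lived by those dying in an interval (`a_x`) taken from the observed
deaths when tabulating microdata. From each table the package reports

* `e30` — remaining life expectancy at age 30, `T(30)/l(30)`;
* `G(30)` — the Gini coefficient of remaining lifespan,
  `E|X₁−X₂| / (2·E X)`, computed by the exact double sum over the
  table's discrete death distribution.

**Uncertainty.** 95% intervals come from Monte Carlo resampling of death
counts as binomials, `D*_x ~ Binomial(N_x, q̂_x)` with
`N_x = round(D_x/q̂_x)`, rebuilding the life table per replicate
(1,000 replicates by default) and taking percentile bounds.

**Representativeness.** Coverage (persons alive in the sample ÷
interpolated true population size, per year), elite oversampling (elite
share in sample ÷ elite share in population, per period, with elites
located by fuzzy record linkage on birth/death year, month and place),
and the correlation of each driver with how closely the sample's e30
resembles the elite's.

**Synthetic worlds.** A first-class generator draws populations from
Gompertz–Makeham hazards (`μ(x) = c + a·e^{bx}`, elites' hazard scaled
by a ratio < 1) by exact inverse-CDF sampling, then applies a
configurable ascertainment model (time-varying inclusion, elite
multiplier, duplicates, age-inflation errors, year-only dates) so every
stage can be validated against known truth.

## Worked example

```bash
python analysis/01_simulate_world.py
python analysis/02_run_pipeline.py
python analysis/03_representativeness.py
python analysis/04_validation_experiments.py
```

The first script builds a 120,000-person synthetic world (2% elite,
elite hazard ratio 0.6) and samples a biased genealogy from it; the rest
of the chain then behaves exactly as it would on a real export:

```
sample:     15918 records (13.3% of the population)
...
cleaning report:
n_input                       15918
n_duplicates_removed            384
n_age_gt_max_removed             92
n_after_period_removed         1715
n_output                      13727
...
median 95% CI width: 2.67 y
```

The diagnostics then quantify the distortion and the method's accuracy:

```
coverage: mean 0.105, 0 anomalous years (> 1)
matched 1140/2235 roster scholars (1095 unmatched)
oversampling: 3.74-4.68 across 13 periods
...
binomial MC interval: empirical coverage 0.940 (nominal 0.95, 200 datasets)
scholar e30: wLT error -0.02 y, woLT bias +0.76 y
bias worlds: corr(coverage, resemblance) -0.89, corr(oversampling, resemblance) +0.92
```

Read: the genealogy holds ~10% of the population but ~4–5× its fair
share of scholars; the left-truncated scholar estimator is unbiased
while ignoring truncation overstates elite longevity; and across
replicate worlds with rising coverage, the sample's e30 reliably drifts
from the elite value toward the general one — better coverage means
*less* resemblance to the elite (negative correlation), stronger elite
oversampling means more (positive correlation).

A `genlife` console script exposes the same steps
(`genlife simulate | run | lifetable | represent`).

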