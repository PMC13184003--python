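# famliab

Familial co-aggregation and liability-threshold ACE modelling of binary
register phenotypes.

## The problem

National health registers record lifetime diagnoses for millions of
related individuals. Given one exposure phenotype (here: borderline
personality disorder, BPD, ascertained from ICD-9 codes 301D/301J and
ICD-10 code F60.3) and a panel of psychiatric, somatic and behavioral
outcome phenotypes, two families of questions arise:

1. **Co-aggregation** — how much more likely is a diagnosis in a person,
   or in a relative of a diagnosed person, across relative types of
   decreasing genetic relatedness (MZ/DZ twins, full siblings, maternal
   and paternal half-siblings, parents, aunts/uncles, first cousins)?
2. **Etiology** — how much of the phenotypic overlap is attributable to
   shared additive-genetic factors (A), shared family environment (C)
   and unique environment (E)?

The real register data are access-restricted, so `famliab` pairs the
full analysis machinery with a synthetic-registry generator whose latent
structure matches the model the estimators assume. Every stage is
verified by closed-form oracles and parameter-recovery simulation, and
worked examples reproduce the published cohort's descriptive statistics
from its printed counts.

## The model

Each binary trait arises from a latent standard-normal liability
`x` with threshold `tau`: diagnosed iff `x > tau`. The liability
decomposes as

    x_t = a_t A + c_t C + e_t E,      a_t^2 + c_t^2 + e_t^2 = 1

A relative pair of kinship *g* shares a fraction `alpha_g` of A
(1 for MZ twins, 1/2 for full siblings/DZ twins, 1/4 for half-siblings,
1/8 for cousins) and `gamma_g` of C (1 for siblings raised by the same
mother, 0 for paternal half-siblings). For two traits with factor
correlations `rA`, `rC`, `rE` the implied latent correlations are

    same trait, pair:    alpha_g * a_t^2 + gamma_g * c_t^2
    cross trait, pair:   alpha_g * a1 a2 rA + gamma_g * c1 c2 rC
    cross trait, person: r_ph = a1 a2 rA + c1 c2 rC + e1 e2 rE

Observed tetrachoric correlations per kinship group are fitted by
diagonal weighted least squares (correlated-factors parameterization,
loadings constrained non-negative, multi-start SLSQP), and the
phenotypic correlation is decomposed into path shares

    bivA = a1 a2 rA / r_ph,   bivC = c1 c2 rC / r_ph,   bivE = e1 e2 rE / r_ph

which sum to 1 and may individually be negative. Co-aggregation odds
ratios come from logistic models fitted by maximum likelihood with
cluster-robust (family-level) sandwich variances — the independence-
working-correlation GEE — adjusted for sex and a natural cubic spline
(5 df) of birth year, with double-entered within-generation pairs.

## Worked example

The analysis chain lives in `analysis/` (each script is a thin driver
over the library and writes under `results/`):

```bash
python analysis/01_simulate_registry.py     # synthetic registries
python analysis/02_build_cohort.py          # cohort + relative pairs
python analysis/03_descriptives_coaggregation.py
python analysis/04_fit_ace_models.py
python analysis/05_recovery_study.py
```

`03_descriptives_coaggregation.py` first recomputes the published
cohort's descriptives from its printed counts:

```
exposure prevalence: 0.9%
female share among cases: 85.8%
depressive disorder: 76.6% of cases vs 8.3% of non-cases
unadjusted within-individual OR (depressive disorder): 36.17
```

i.e. 24,073 of 2,665,478 cohort members carried the exposure diagnosis
(0.9%), 85.8% of them female, and the depressive-disorder cross-product
ratio from the same counts is 36.17. It then prints OR estimates on the
synthetic cohort. `05_recovery_study.py` verifies the bivariate model at
the design point (a² = 0.5, c² = 0.05, rA = 0.74):

```
single 50,000-pair study: rA = 0.776 (SE 0.040), truth 0.74, z = 0.90
100 replicates at 20000 pairs/kinship: median |rA error| = 0.043,
MC SD = 0.057, mean reported SE = 0.060, 95% CI coverage = 97%
```

so the genetic correlation is recovered within sampling error, the
reported standard errors match the Monte-Carlo spread, and the Wald
intervals attain near-nominal coverage.

A `famliab` console command exposes the same pipeline
(`famliab simulate | build-cohort | coaggregate | ace-fit | report |
run-all`); see `famliab --help`.

## Layout

- `src/famliab/` — the library: `simulate` (pedigrees, gene-dropping,
  registry emission), `registry` (cohort, ascertainment, pairs),
  `splines`/`gee` (covariate basis, cluster-robust logistic GEE),
  `bvn`/`tetrachoric` (quadrant probabilities, latent correlations),
  `ace` (WLS SEM fits, decomposition, screening), `recovery`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers.
- `docs/methods.md` — modelling and numerical details.
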