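# Methods

## Scope and design

`famliab` implements a register-style family analysis of binary lifetime
phenotypes: cohort and relative-pair construction, within-individual and
familial co-aggregation odds ratios, and liability-threshold ACE
structural-equation models over full and half-sibling pairs. Because
real register data are restricted, a synthetic-data generator emulates
the registers' schema and the latent statistical structure the
estimators assume; all validation is against closed-form oracles, an
independent reference implementation where one exists (R's
`splines::ns`, statsmodels GEE), and parameter-recovery simulation.

## Synthetic registry generator

**Pedigrees.** Families are drawn from a configurable mix: two full
siblings, maternal or paternal half-siblings (re-partnering), MZ/DZ
twins, or first-cousin structures (grandparents, two full-sib parents,
one child each). Children's birth years are uniform over 1973–2001;
parents sit 20–32 years earlier. Sex is Bernoulli(1/2).

**Liabilities.** Bivariate additive-genetic values are gene-dropped:
founders are N(0, R_A) with R_A the 2×2 matrix with off-diagonal rA;
each child receives the mid-parental vector plus segregation noise with
covariance R_A/2 (no inbreeding, founders unrelated); MZ co-twins share
one genetic draw. Common-environment vectors (correlation rC) are drawn
once per household — defined as all children of one mother, so maternal
half-siblings share C and paternal half-siblings do not, matching the
sharing assumption of the ACE design. Unique-environment vectors
(correlation rE) are independent per person. With loadings
(a, c, e) = (√a², √c², √e²) per trait, liabilities have unit marginal
variance and the implied pair correlations are `alpha·a² + gamma·c²`
(same trait) and `alpha·a1a2·rA + gamma·c1c2·rC` (cross trait). A
closed-form 4-variate sampler (`simulate_pair_liabilities`) draws
sibling pairs directly from this distribution for large recovery
studies; a test verifies it matches the gene-dropped pedigree moments.

**Registry emission.** Binary diagnoses arise by thresholding. The base
threshold is calibrated (Brent root-find) so the population-average
prevalence equals the target after probit-scale covariate shifts: a
female shift (default −0.6 for the exposure trait, which yields ≈86%
female cases at 0.9% overall prevalence, matching the register cohort's
sex skew) and an optional linear birth-year drift. Event dates are
uniform over the follow-up window; events before 1997 carry ICD-9 codes,
later ones ICD-10, from the configured code sets. Death and emigration
are exponential censoring from age 18. Default conditions follow the
emulated cohort: exposure prevalence 0.9%, outcome 8.3%, ACE truth
(a², c²) = (0.5, 0.05) per trait with rA = 0.74, rC = 0.5, rE = 0.2.
All randomness flows from one config seed through per-stage child
streams, so each stage is independently reproducible and registry
output is byte-identical across reruns.

**What the generator does not emulate.** Realistic demography and
family-size distributions, assortative mating, dominance, age-of-onset
hazards, diagnostic drift beyond a linear probit trend, and
three-quarter-sibling or adoption structures. Passing tests therefore
certify the estimators under the model's own assumptions, not the
behaviour of real register data.

## Cohort, ascertainment and pairs

The cohort keeps persons born 1973-01-01..2001-12-31 with a known
mother, no malformation flag, and neither death nor first emigration
before the 18th birthday (exact calendar arithmetic). Phenotypes are
lifetime indicators: a diagnosis matches when its code starts with a
configured prefix for the event's revision era (ICD-9 through 1996,
ICD-10 from 1997); cause-of-death phenotypes (suicide) match only
cause-of-death rows; female-only phenotypes are unascertainable (NaN)
for males. Follow-up runs from max(birth, first immigration,
1987-01-01) to min(first emigration, first matching diagnosis, death,
2020-12-31); intervals are closed, and a start-date diagnosis counts.

Relative pairs are classified from parent links (shared mother+father =
full sib, mother only = maternal half, father only = paternal half),
twins split MZ/DZ by the zygosity table (unknown-zygosity twins are
excluded from twin sets but stay eligible as full siblings), cousins as
children of full-sib parents, and parent-child/aunt-uncle as
between-generation pairs restricted to older relatives born ≥ 1933 and
emitted once, older member on the exposure side. Within-generation
pairs are double-entered (both orientations). Psychiatric phenotypes
are analyzed only for within-generation pairs via a definition flag.

For the SEM stage, one pair per sibling kinship type is selected per
independent family cluster — defined as a connected component of the
full/half-sibling graph — by (1) smallest birth-date gap, (2) earliest
birth of the older member, (3) a seeded uniform draw.

## Co-aggregation GEE

Point estimates are ordinary logistic maximum likelihood (statsmodels
GLM); with an independence working correlation the GEE estimating
equations coincide with the likelihood score, so only the variance
differs. The covariance is the sandwich with scores summed within
family clusters (connected components over all relative-pair edges, so
double-entered and overlapping pairs share a cluster); with singleton
clusters it reduces exactly to the observation-wise robust (HC0)
covariance, and a test confirms agreement with statsmodels' GEE.
Models adjust for sex (both members' sexes for pair models; only the
exposure-side sex for female-only outcomes) and natural cubic splines
(5 df) of birth year. The spline basis follows the R `splines::ns`
construction — boundary knots at the data range, interior knots at
equally spaced quantiles, natural constraints imposed via the QR null
space of the boundary second derivatives, linear extrapolation outside —
and a test shows its column span matches R's to 1e-8. Estimates with
any exposure-outcome cell under 5 observations are suppressed and
rendered "NA". Wald 95% intervals use the conventional 1.96. Separation
is flagged when any |log-odds| exceeds 15.

## Latent correlations

Bivariate-normal quadrant probabilities use a vectorized port of the
Drezner–Wesolowsky/Genz deterministic quadrature (20-point
Gauss–Legendre on the arcsine-transformed integral for |rho| ≤ 0.925, a
tail expansion above), accurate to ~1e-15 and exact against the
closed form P(X>0,Y>0) = 1/4 + arcsin(rho)/2π.

Estimation is two-step. Per-trait thresholds come from a marginal
probit regression on sex and the birth-year spline; the person-specific
threshold is minus the linear predictor, which keeps the binary
likelihood exact under covariate adjustment (no residualization). The
latent correlation for each moment is then profiled by bounded ML over
per-pair rectangle probabilities with thresholds held fixed.

Per kinship group, four moments are estimated: cross-person same-trait
(two), cross-person cross-trait (both orientations of each pair stacked,
which equals the symmetrized estimate), and within-person cross-trait
(both members pooled). For the stacked estimates the SE is a
pair-clustered sandwich — per-row scores summed within the originating
pair — so the two orientations are never counted as independent. The
full covariance of each group's moment vector is assembled from
influence functions (per-pair score sums divided by the observed
information); groups use disjoint pairs, so the overall moment
covariance is block-diagonal. A delete-one-block jackknife over pairs
is the fallback when the information is degenerate (boundary estimates).

## ACE model fitting

**Univariate.** `r_g = alpha_g a² + gamma_g c²` is linear in (a², c²),
solved in closed form by inverse-variance-weighted least squares over
the three sibling groups, unconstrained (negative shares are reported
as such, as is conventional for unconstrained variance-component fits).

**Bivariate.** The correlated-factors model is fitted by minimizing the
inverse-variance-weighted squared discrepancy between the 12 observed
moments (4 per sibling group) and their implied values over
θ = (a1, c1, a2, c2, rA, rC, rE), with e_t = √(1 − a_t² − c_t²) derived
(unit liability variance), loadings bounded in [0, 1] with
a_t² + c_t² ≤ 1, and factor correlations in [−1, 1]. Weights are
diagonal: stable at small counts, and the loss relative to full-matrix
WLS is measurable in the recovery study. Optimization is 8
deterministic SLSQP multi-starts (grid over the rA sign and loading
magnitudes) with the best objective kept, followed by a bounded
trust-region least-squares polish when the variance constraint is
inactive; noiseless structures are inverted to ~1e-13. Direct bound
constraints (rather than a squared-parameter reparameterization) make
boundary solutions such as c = 0 exact and flaggable. When the free fit
fails to converge and both c loadings are near zero, the model is
automatically re-fitted with the C paths fixed to zero (`fixed_c`),
dropping rC — mirroring the standard fallback when univariate C is
estimated at ~0.

**Uncertainty.** The parameter covariance is the WLS sandwich
(JᵀWJ)⁻¹ JᵀW Σ W J (JᵀWJ)⁻¹ with J the moment Jacobian at the optimum
and W the diagonal weights. Σ is the *full* influence-function
covariance of the moment vector rather than its diagonal: moments of
one kinship group are computed from the same pairs and co-vary
positively, and ignoring that covariance inflates the rA standard error
by ~40% and pushes interval coverage to ~100%. With the full Σ the
95% Wald coverage for rA is ≈95–97% over 100 replicates and the mean
reported SE matches the Monte-Carlo SD. Derived quantities — r_ph, the
path shares bivA/bivC/bivE, per-trait variance shares — get delta-method
SEs; intervals are deliberately not truncated to [−1, 1] or [0, 1], so
an rA near 1 can carry an upper bound above 1.

**Screening.** A phenotype enters the bivariate stage iff its pooled
within-person tetrachoric correlation with the exposure is ≥ 0.1 and
there are ≥ 5 concordant and ≥ 5 discordant sibling pairs (pooled over
kinship groups; boundaries inclusive). Exclusions carry reason codes.

## Problem sizes and numerical choices

The recovery design point is per-trait (a², c²) = (0.5, 0.05) with
rA = 0.74 and trait prevalence 0.20 — representative of the common
phenotypes (8–38% lifetime prevalence) that dominate register panels;
rarer traits give proportionally noisier tetrachorics. The headline
study uses 50,000 pairs per kinship type; calibration uses 100
replicates at 20,000 pairs. End-to-end pipeline runs and tests use
4,000–8,000 families, with 5%/8.3% prevalences for the SEM stage so the
sibling 2×2 tables stay off the boundary at that scale; at the emulated
registry prevalence of 0.9% the SEM stage needs register-scale pair
counts, exactly as in the real study. Quadrant probabilities are exact
to ~1e-15; tetrachoric ML uses bounded Brent iterations to xatol 1e-10
with boundary flagging at |rho| ≥ 1 − 1e-6; probit and logistic fits run
to tolerance 1e-10; numerical derivatives use central differences
(h = 1e-5 for information, 1e-6 for Jacobians).

## Known limitations

Asymptotic (Wald) inference throughout — no profile or bootstrap
intervals; boundary fits (c = 0, |rA| = 1) make the local sandwich
covariance unreliable and are flagged rather than corrected; the
generator's household model equates C-sharing with maternal
co-residence; female-only phenotypes are handled in the co-aggregation
stage but the SEM stage simply drops pairs with unascertainable
members; and the pair-count screen is applied pooled rather than per
kinship group (both interpretations are defensible; pooled is the
default here).
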