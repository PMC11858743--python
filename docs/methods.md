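# Methods

This note documents the models, the estimators, the numerical choices and
the simulator behind `sexdem`, and states what the bundled synthetic data
can and cannot show about real census data.

## Study system and data model

The package targets census data from a long-term study of group-living
red-fronted lemurs: individually marked animals followed by near-daily
censuses, with immigrant males assigned estimated ages on arrival.  The
unit records are

* **individuals** — sex, natal/immigrant status, entry age, exit age, and
  an exit cause in {death, emigration, eviction, unknown, censored};
* **pregnancies** — mother, birth date, offspring sex as observed
  (infants cannot be sexed visually before ~3 months; early losses stay
  `unknown`);
* **hormone samples** — maternal faecal oestrone (E1C, ng/g) time series.

All departures are pooled into one absorbing **disappearance** event.
This is deliberate: the scientific question is whether *sex* predicts
leaving the observed population, whatever the route (death, male
dispersal, female eviction).  Cause labels are carried through the I/O
schema for realism but never enter the estimators.

## Prenatal hormonal sexing

Only mothers carrying a male fetus show markedly elevated E1C in the last
six weeks (42 days) of gestation.  The classifier therefore:

1. averages each pregnancy's samples with
   `birth_date − 42 d ≤ sample_date < birth_date`;
2. derives a threshold = mean + *k*·s.d. (*k* = 2, s.d. with *n*−1) over
   the late-gestation means of **female-carrying** mothers — the anchor
   group is configurable, as is *k*;
3. calls a pregnancy male iff its mean exceeds the threshold strictly;
   ties go to female (with real, well-separated clusters ties never
   arise; a deterministic rule is still required).

Validation is leave-one-out: the threshold is re-derived without the
held-out pregnancy, which is then classified.  Note an intrinsic edge of
any +2 s.d. rule under leave-one-out: the most extreme female-carrying
mean sits near its own class's 97.7th percentile, so even with fully
separated clusters a single borderline female call can occur at some
seeds; the full-sample threshold (the dashed-line construction) separates
the simulated clusters completely under the default hormone parameters.

## Birth sex ratio

`BSR = N_male / (N_male + N_female)` over sexed births; unknown-sex
offspring are excluded from the ratio but reported.  Visual and hormonal
calls are merged per pregnancy: a hormonal call fills a visual unknown,
agreement keeps the visual label, and disagreements are reported as
conflicts and counted as unknown rather than silently resolved.

The confidence interval is a **parametric bootstrap**: binomial
resampling with n = sexed births at p = point estimate, 1000 replicates
by default, percentile interval.  Percentile intervals were chosen as the
standard pairing with a parametric bootstrap of a proportion; at n ≈ 167
their empirical coverage is ~94–95% (verified by simulation in the test
suite).

## Event-history analysis

**Time scale.**  Age, not time-on-study: the scientific quantity is
age-specific disappearance, and immigrants with estimated entry ages are
handled correctly by delayed entry (left truncation) — an episode
(start, stop] is at risk at age *t* iff start < *t* ≤ stop.

**Episodes.**  Lifetimes are split at the changepoint (default 8 years)
so the two-level age term is time-varying; the event flag sits only on
the terminal episode.

**Identifiability.**  On the age scale the 'young' indicator is constant
within every risk set (everyone at risk below the changepoint is young),
so its main effect is absorbed by the nonparametric baseline hazard and
is *not estimable* — its information is exactly zero.  The fitted model
is therefore `sex + sex:young`: the sex contrast above the changepoint
and its change below it, which together carry all identifiable
structure.  Toolkits that report a large, apparently significant main
age-term coefficient are implicitly working on a different time scale
(e.g. time-on-study), where the term is identified but conflated with
entry-age composition.

**Estimation.**  The Cox partial likelihood with the **Efron** correction
for ties (near-daily censuses make day-scale ties real) is maximized by
Newton–Raphson with step-halving: start at 0, max 50 iterations,
convergence when the relative log-likelihood change < 1e-9.  The
variance is the inverse observed information; LR, Wald and per-term
normal tests are reported.  Failure modes are explicit: no events, a
singular information matrix, non-convergence (gradient norm reported)
and monotone likelihood/separation (flagged when the converged
coefficient exceeds 10 in absolute value).  The implementation is
vectorized over risk sets via suffix sums in stop/start order; at the
optimum the gradient norm is < 1e-6 (asserted in tests), and the fit
agrees with an independent counting-process implementation (lifelines)
to ~1e-8 and with brute-force maximization of the written-out Efron
likelihood on small instances to 1e-6.

**Product-limit curves.**  Kaplan–Meier on the age scale with the same
delayed-entry risk sets; ties are removed simultaneously.

**Proportional-hazards diagnostic.**  Grambsch–Therneau score test on
Schoenfeld residuals (Efron-adjusted within tie groups): with residuals
r_k at event times t_k, transform g, and observed information I,
U = Σ(g_k − ḡ) r_k and T = d·UᵀI⁻¹U / Σ(g_k − ḡ)², per term and
globally.  The default transform is the Kaplan–Meier transform
g(t) = 1 − Ŝ(t); identity, rank and log are available.  The statistic
reproduces lifelines' `proportional_hazard_test` to 1e-6.  When the
model includes the age split, the interaction covariate is identically
zero above the changepoint and its residuals vanish there, which makes
the averaged-variance approximation conservative for that term — the
diagnostic then rejects less often than the nominal 5% under a correct
model.

## Two-sex projection and ASR sensitivity

Four classes: juvenile female, adult female, juvenile male, adult male,
with adulthood at 30 months (2.5 years).  Four stage classes cannot tile
a ~25-year lifespan as single-year ages, so juveniles carry a self-loop
with maturation probability γ = 1/2.5 per year, making the mean juvenile
residence equal the age at maturity.  Projection matrix (column = source
class):

```
juvenile-F:  s_jf(1−γ)      f_f           0            0
adult-F:     s_jf·γ         s_af          0            0
juvenile-M:  0              f_m           s_jm(1−γ)    0
adult-M:     0              0             s_jm·γ       s_am
```

Births are attributed to adult females only (female-dominant two-sex
model — the standard resolution absent a mating function), split into
daughters (f_f) and sons (f_m) per adult-female-year; f_m/(f_f+f_m)
equals the BSR used for the split.

**Rates from data.**  Class survival is the geometric-mean annual
survival over the class's age span read from the sex-specific
Kaplan–Meier curve: juveniles over [0, 2.5), adults over [2.5, A] with A
the last observed event age capped at 20 years (beyond the cap the risk
sets are too small to inform an annual rate).  Fecundities are sexed
births divided by adult-female-years of observed exposure.

**Asymptotics.**  Dominant eigenpair by `numpy.linalg.eig`, cross-checked
against power iteration (tolerance 1e-12); the two must agree to 1e-8 or
the state is refused.  A matrix without a strictly dominant eigenvalue
(modulus gap ≤ 1e-9) is rejected — e.g. a scaled identity.  ASR = stable
adult-male share / (adult-male + adult-female shares).  Under
sex-symmetric rates the male classes mirror the female classes in the
stable structure, so ASR = 0.5 to numerical precision (a property test
sweeps admissible rates).

**Sensitivity.**  For each of the eight non-structurally-zero elements,
central differences (δ = 0.01 absolute by default):
(ASR(a+δ) − ASR(a−δ))/2δ, with survival-type entries clipped to [0, 1]
(clipping reported, the quotient uses the realized perturbation) and
elements whose perturbation destroys dominance flagged.  Estimates
converge at O(δ²) (Richardson check in the tests); exact antisymmetries
of the limit (e.g. ∂ASR/∂s_am = −∂ASR/∂s_af under symmetric rates) hold
up to that O(δ²) error.  The ranking orders elements by signed effect.

## The simulator: what it emulates, and what it does not

Defaults are the study conditions: 7 founder groups seeded with 3 adult
females and 3 adult males each, 27 years of annual census steps, true
BSR 0.5, annual birth probability 0.8 per adult female (≈4.8 lifetime
births given the default hazards, matching the species' reported
lifetime reproduction), immigrant males arriving at 0.4 per group-year
(≈80 over the study) with entry ages uniform on [2.5, 7.5], and
disappearance hazards per year of 0.22 (female) vs 0.11 (male) below age
8 and 0.18 for both sexes above — a female-biased young-age excess that
qualitatively reproduces the observed survivor curves; the study itself
reports no rates.  Late-gestation E1C is log-normal with natural-scale
mean ± s.d. of 200 ± 50 ng/g (female fetus) vs 600 ± 150 (male), i.e.
the male mean sits > 6 female s.d. above the female mean; each pregnancy
receives 3–6 samples dated within the final 42 days of a 120-day
gestation.  Waiting times are exact inverse-CDF draws from the two-piece
constant hazard (no time discretization); infants disappearing before
0.25 years remain unsexed, which reproduces a realistic fraction of
unknown-sex births.

Calibration studies in the acceptance tests use a plain birth cohort
(`simulate_cohort`, n = 500, 200 replicates) with hazards 0.16/0.08
below the changepoint and 0.28 for both sexes above it, so that both age
segments carry substantial numbers of events (~200 above age 8 per
replicate) — the condition under which interval coverage and the power
of the PH diagnostic are informative.

Not emulated: group-level social structure, spatial arrangement,
paternity, density dependence, environmental stochasticity in vital
rates, assay error in hormone measurements, and mortality–dispersal
distinctions.  Passing tests therefore demonstrate that the estimators
recover known truths under the assumed statistical structure (piecewise
hazards, log-normal hormones, binomial sexes); they do not validate
those structural assumptions for any real population.

## Known limitations

* The 'young' main effect is intrinsically inestimable on the age scale
  (above); results styled after a fixed-covariate age term are not
  comparable without knowing the time scale used.
* Annualized adult survival compresses age-varying hazards (young-adult
  vs post-changepoint) into one rate per sex; the projection is a
  stage-classed approximation, not an age-structured life table.
* The bootstrap resamples offspring, not mothers; litter/maternal
  clustering would widen a mother-resampled interval.
* The PH diagnostic is conservative for covariates that vanish over part
  of the time axis (interaction terms with episode splitting).
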