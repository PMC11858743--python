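# sexdem — sex-ratio demography of a wild group-living lemur population

`sexdem` is a tested re-implementation of a sex-ratio-dynamics analysis for
long-term census data on a wild population of red-fronted lemurs
(*Eulemur rufifrons*), a group-living Malagasy primate in which the adult
sex ratio is male-biased — the reverse of the female-biased ratios typical
of non-monogamous mammals.  The package answers, on census-style data, the
chain of questions that explains such a pattern:

1. **What is the birth sex ratio (BSR)?**  Infants of this sexually
   dichromatic species cannot be sexed visually before ~3 months, but
   maternal faecal oestrone conjugates (E1C) in late gestation are markedly
   elevated only when the fetus is male.  A threshold at the mean of
   female-carrying mothers' late-gestation E1C means plus 2 s.d. classifies
   fetal sex prenatally.  The BSR is then
   `BSR = N_male / (N_male + N_female)` over sexed births (visual calls
   completed by hormonal calls), with a 1000-replicate parametric-bootstrap
   percentile confidence interval.
2. **Which sex disappears faster, and when?**  All departures (death, male
   emigration, female eviction, unknown) form one absorbing "disappearance"
   event.  On the age scale, with delayed entry for immigrants of estimated
   age, the package estimates product-limit (Kaplan–Meier) survivor curves
   by sex and fits a Cox proportional-hazards model — Efron tie handling,
   Newton–Raphson on the partial likelihood, written from first principles
   — with a time-varying '<8 / ≥8 years' age term implemented by episode
   splitting.  A scaled-Schoenfeld-residual score test (Grambsch–Therneau,
   Kaplan–Meier time transform) diagnoses non-proportionality.
3. **What does that imply for the adult sex ratio (ASR)?**  Class-specific
   survival and sex-specific fecundities parameterize a 4×4 two-sex
   stage-classed projection matrix (juvenile/adult × female/male).  Its
   dominant eigenpair gives the asymptotic growth rate λ and the stable
   structure, hence the asymptotic ASR = adult males / adults; numerical
   central-difference sensitivities rank how strongly each matrix element
   moves the ASR.

Because the real census tables are not bundled, the package ships an
individual-based simulator (`sexdem.simulate`) that generates census
histories, pregnancy records and hormone profiles with the statistical
structure the analyses assume — annual single births by philopatric adult
females, sex-specific piecewise-constant disappearance hazards with a
changepoint at age 8, immigrant males entering at estimated ages,
right-censoring at the study end, and sex-dependent late-gestation E1C.

Intended users: behavioural ecologists and biodemographers analysing
individual-based census data, and anyone needing a transparent, tested
reference implementation of left-truncated survival analysis plus two-sex
matrix projection.

## Worked example

```bash
sexdem run-all --seed 3 --out-dir demo
```

prints

```
BSR = 0.533, ASR = 0.595, lambda = 1.050 -> demo/summary.json
```

meaning: among sexed simulated births 53.3% were male (the simulator's
true BSR is 0.50; the bootstrap interval in `demo/bsr.csv` contains it);
the population grows ~5% per year at its stable structure; and although
births are even, the asymptotic adult sex ratio is male-biased (0.595)
because female disappearance exceeds male disappearance before age 8.

The same run from Python, with the intermediate objects:

```python
from sexdem import (SimulationConfig, simulate_population,
                    fit_disappearance_model, estimate_vital_rates,
                    build_leslie, asymptotic_state, asr_sensitivity)

individuals, pregnancies = simulate_population(SimulationConfig(seed=7))
fit, ph = fit_disappearance_model(individuals, changepoint=8.0)
print(fit.summary())
#          term  coefficient        se         p
# 0         sex    -0.048...  0.206...  0.815...
# 1   sex:young    -0.793...  0.245...  0.001...
rates = estimate_vital_rates(individuals, pregnancies, adult_age=2.5)
state = asymptotic_state(build_leslie(rates))
print(round(state.lam, 4), round(state.asr, 3))   # 1.0357 0.603
print(asr_sensitivity(build_leslie(rates)).ranking[0])
# adult-male -> adult-male (survival)
```

The negative `sex:young` coefficient says males below age 8 disappear at
roughly half the female rate (`exp(-0.79) ≈ 0.45`), while the
near-zero `sex` main effect says the sexes are at par above 8; the PH test
(in `ph`) no longer rejects once the age split is in the model.  The
sensitivity ranking shows adult male survival as the element with the
greatest positive effect on the ASR.

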