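"""Two-sex stage-classed projection: rates, eigenstructure, ASR sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexdem.projection import (
    LeslieModel,
    VitalRates,
    asr_sensitivity,
    asymptotic_state,
    build_leslie,
    estimate_vital_rates,
)
from sexdem.simulate import simulate_cohort
from sexdem import SimulationConfig, simulate_population


def _symmetric(s_j, s_a, f):
    return VitalRates(s_jf=s_j, s_jm=s_j, s_af=s_a, s_am=s_a, f_f=f, f_m=f)


# ---------------------------------------------------------------------------
# vital-rate estimation


def test_constant_hazard_gives_exponential_annual_survival():
    """With a single constant hazard h the annualized class survival is
    e^(-h) (closed-form check, both sexes and both stages)."""
    h = 0.15
    inds = simulate_cohort(4000, h, h, h, h, censor_age=30.0, seed=1)
    rates = estimate_vital_rates(inds, [], adult_age=2.5)
    for s in (rates.s_jf, rates.s_jm, rates.s_af, rates.s_am):
        assert s == pytest.approx(np.exp(-h), abs=0.02)
    assert rates.f_f == 0.0 and rates.f_m == 0.0


def test_fecundity_split_matches_birth_probability():
    """true_bsr 0.5 and birth probability 0.8 give f_f ~ f_m ~ 0.4 within
    3 s.e. of the binomial/Poisson sampling error."""
    cfg = SimulationConfig(n_founder_groups=40, years=30.0, seed=2)
    individuals, pregnancies = simulate_population(cfg)
    rates = estimate_vital_rates(individuals, pregnancies, adult_age=cfg.adult_age)
    n_births = sum(p.observed_sex in ("male", "female") for p in pregnancies)
    se = 0.4 * 3 / np.sqrt(n_births)  # conservative Poisson-scale s.e.
    assert rates.f_f == pytest.approx(0.4, abs=3 * se + 0.03)
    assert rates.f_m == pytest.approx(0.4, abs=3 * se + 0.03)
    assert rates.bsr == pytest.approx(0.5, abs=0.05)


def test_vital_rates_reject_empty_classes():
    inds = simulate_cohort(50, 0.2, 0.2, 0.2, 0.2, seed=3, prop_male=1.0)
    with pytest.raises(ValueError):
        estimate_vital_rates(inds, [], adult_age=2.5)


# ---------------------------------------------------------------------------
# matrix assembly and asymptotic state


def test_fecundity_only_matrix_has_zero_growth():
    rates = VitalRates(0.0, 0.0, 0.0, 0.0, 0.4, 0.4)
    A = build_leslie(rates).matrix
    assert np.allclose(np.linalg.eigvals(A), 0.0)


def test_structural_zeros_and_reproduction_placement():
    model = build_leslie(_symmetric(0.8, 0.9, 0.35))
    A = model.matrix
    assert A[0, 1] == 0.35 and A[2, 1] == 0.35  # births only from adult females
    assert A[:, 2].tolist()[0] == 0 and A[0, 3] == 0  # no male column births
    assert np.all(A[model.structural_zero] == 0)


def test_symmetric_rates_give_asr_half_and_reduction_oracle():
    """Sex-symmetric rates give ASR exactly 0.5, and the two-sex dominant
    eigenvalue equals that of the female-only 2x2 submodel."""
    rates = _symmetric(0.85, 0.9, 0.4)
    model = build_leslie(rates)
    state = asymptotic_state(model)
    assert state.asr == pytest.approx(0.5, abs=1e-10)
    gamma = 1.0 / rates.adult_age
    female_block = np.array(
        [[rates.s_jf * (1 - gamma), rates.f_f], [rates.s_jf * gamma, rates.s_af]]
    )
    lam_female = max(np.linalg.eigvals(female_block).real)
    assert state.lam == pytest.approx(lam_female, rel=1e-12)


def test_male_survival_advantage_biases_asr_above_half():
    rates = VitalRates(0.85, 0.85, 0.80, 0.92, 0.4, 0.4)
    assert asymptotic_state(build_leslie(rates)).asr > 0.5


def test_long_run_projection_matches_eigenvector():
    model = build_leslie(VitalRates(0.8, 0.9, 0.82, 0.88, 0.45, 0.42))
    state = asymptotic_state(model)
    v = np.array([1.0, 2.0, 0.5, 3.0])
    for _ in range(500):
        v = model.matrix @ v
        v /= v.sum()
    assert np.abs(v - state.stable_structure).max() < 1e-8


@settings(derandomize=True, max_examples=60)
@given(
    s_j=st.floats(0.2, 0.95),
    s_a=st.floats(0.2, 0.95),
    f=st.floats(0.1, 1.0),
)
def test_symmetry_property_sweep(s_j, s_a, f):
    state = asymptotic_state(build_leslie(_symmetric(s_j, s_a, f)))
    assert state.asr == pytest.approx(0.5, abs=1e-10)


def test_asr_invariant_under_matrix_scaling():
    model = build_leslie(VitalRates(0.8, 0.85, 0.8, 0.9, 0.4, 0.45))
    base = asymptotic_state(model).asr
    scaled = LeslieModel(matrix=2.7 * model.matrix)
    assert asymptotic_state(scaled).asr == pytest.approx(base, abs=1e-12)


def test_degenerate_matrix_without_dominance_is_rejected():
    with pytest.raises(ValueError):
        asymptotic_state(LeslieModel(matrix=0.9 * np.eye(4)))


def test_rates_validation():
    with pytest.raises(ValueError):
        VitalRates(1.2, 0.8, 0.8, 0.8, 0.4, 0.4)
    with pytest.raises(ValueError):
        VitalRates(0.8, 0.8, 0.8, 0.8, -0.1, 0.4)


# ---------------------------------------------------------------------------
# sensitivity


def test_sensitivity_antisymmetric_under_sex_symmetry():
    delta = 0.005
    sens = asr_sensitivity(build_leslie(_symmetric(0.85, 0.9, 0.4)), delta=delta)
    by_label = {e["label"]: e["dASR_dElement"] for e in sens.entries}
    am = by_label["adult-male -> adult-male (survival)"]
    af = by_label["adult-female -> adult-female (survival)"]
    # antisymmetry holds in the limit; central differences add O(delta^2)
    assert am == pytest.approx(-af, abs=20 * delta**2)
    assert am > 0 > af


def test_sensitivity_richardson_convergence():
    """Central differences are second order: halving delta moves the
    estimates by < 1% relative."""
    model = build_leslie(VitalRates(0.8, 0.85, 0.8, 0.9, 0.4, 0.45))
    s1 = asr_sensitivity(model, delta=0.01)
    s2 = asr_sensitivity(model, delta=0.005)
    for e1, e2 in zip(s1.entries, s2.entries):
        assert e1["dASR_dElement"] == pytest.approx(e2["dASR_dElement"], rel=0.01)


def test_sensitivity_reports_clipping_at_survival_bounds():
    model = build_leslie(VitalRates(0.8, 0.85, 0.8, 0.995, 0.4, 0.45))
    sens = asr_sensitivity(model, delta=0.02)
    am = next(e for e in sens.entries if e["label"] == "adult-male -> adult-male (survival)")
    assert am["clipped"]
    assert am["delta_used"] < 0.04


def test_sensitivity_ranking_is_permutation_of_entries():
    sens = asr_sensitivity(build_leslie(VitalRates(0.8, 0.85, 0.8, 0.9, 0.4, 0.45)))
    assert sorted(sens.ranking) == sorted(e["label"] for e in sens.entries)
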