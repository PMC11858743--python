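"""Individual-based simulator of census histories and maternal hormone profiles.

The simulator produces the three data streams the downstream analyses
consume:

* individual life histories — natal animals entering at age 0, immigrant
  males entering at estimated adult ages (left truncation), a single
  absorbing "disappearance" event per individual drawn from sex-specific
  piecewise-constant hazards with a changepoint, and right-censoring at the
  end of the study window;
* pregnancy records — annual single births by adult females with fetal sex
  drawn Bernoulli(true_bsr); infants that disappear within their first
  three months remain visually unsexed, mimicking the delay before coat
  colour reveals sex in this species;
* late-gestation maternal E1C samples — log-normal concentrations whose
  mean is markedly elevated when the fetus is male.

Exit-cause labels (death / emigration / eviction / unknown) are generated
only for schema realism: every non-censored exit is the same absorbing
event in the survival analyses.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import SimulationConfig

__all__ = [
    "Individual",
    "PregnancyRecord",
    "HormoneSample",
    "simulate_population",
    "simulate_cohort",
    "simulate_hormone_profiles",
    "piecewise_exponential",
]

#: age (years) below which an infant cannot yet be sexed visually
VISUAL_SEXING_AGE = 0.25

_STUDY_START_YEAR = 1996


@dataclass
class Individual:
    id: str
    sex: str  # "female" | "male" | "unknown"
    natal: bool
    entry_age: float  # 0 for natal animals, estimated age for immigrants
    exit_age: float
    exit_cause: str  # "death" | "emigration" | "eviction" | "unknown" | "censored"
    birth_year: int

    @property
    def event(self) -> int:
        """1 if the individual disappeared, 0 if right-censored."""
        return 0 if self.exit_cause == "censored" else 1

    def __post_init__(self) -> None:
        if self.exit_age < self.entry_age:
            raise ValueError(
                f"{self.id}: exit_age {self.exit_age} < entry_age {self.entry_age}"
            )
        if self.natal and self.entry_age != 0:
            raise ValueError(f"{self.id}: natal individuals enter at age 0")


@dataclass
class PregnancyRecord:
    mother_id: str
    birth_date: _dt.date
    true_fetal_sex: str  # "female" | "male"
    observed_sex: str  # "female" | "male" | "unknown"
    sexing_mode: str  # "visual" | "hormonal" | "none"


@dataclass
class HormoneSample:
    mother_id: str
    sample_date: _dt.date
    e1c: float  # immunoreactive oestrone, ng/g faeces


def piecewise_exponential(
    rng: np.random.Generator,
    entry_age: float,
    hazard_young: float,
    hazard_old: float,
    changepoint: float,
) -> float:
    """Exact waiting-time draw from a two-piece constant hazard.

    Returns the age at the event, conditional on survival to ``entry_age``
    (memorylessness within each piece makes the conditioning exact).  An
    all-zero hazard returns ``inf``.
    """
    e = rng.exponential()
    if entry_age < changepoint:
        h_to_cp = hazard_young * (changepoint - entry_age)
        if e < h_to_cp:  # implies hazard_young > 0
            return entry_age + e / hazard_young
        if hazard_old <= 0:
            return np.inf
        return changepoint + (e - h_to_cp) / hazard_old
    if hazard_old <= 0:
        return np.inf
    return entry_age + e / hazard_old


def _draw_exit_cause(rng: np.random.Generator, sex: str) -> str:
    # cosmetic labels only; all causes are the same absorbing event
    if sex == "male":
        return rng.choice(["emigration", "death", "unknown"], p=[0.55, 0.10, 0.35])
    return rng.choice(["eviction", "death", "unknown"], p=[0.30, 0.10, 0.60])


def simulate_population(
    config: SimulationConfig,
) -> tuple[list[Individual], list[PregnancyRecord]]:
    """Simulate a multi-group census history under ``config``.

    Founder adults (both sexes) seed each group at time 0; thereafter, each
    adult female gives birth once per year with probability
    ``annual_birth_prob``, and immigrant males arrive per group as a
    Poisson process with rate ``immigrant_rate``.  Every exit time is an
    exact draw from the sex-specific piecewise-exponential hazard;
    individuals alive at ``years`` are censored there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    individuals: list[Individual] = []
    pregnancies: list[PregnancyRecord] = []

    hazards = {
        "female": (config.hazard_female_young, config.hazard_female_old),
        "male": (config.hazard_male_young, config.hazard_male_old),
    }

    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:05d}"

    # (entry_time, sex, current exit-time bookkeeping) of living females for births
    # We track (id, sex, entry_time, entry_age, exit_time) per animal.
    living: list[dict] = []

    def add_individual(
        prefix: str, sex: str, natal: bool, entry_time: float, entry_age: float
    ) -> dict:
        hy, ho = hazards[sex]
        exit_age = piecewise_exponential(rng, entry_age, hy, ho, config.changepoint_age)
        exit_time = entry_time + (exit_age - entry_age)
        rec = {
            "id": next_id(prefix),
            "sex": sex,
            "natal": natal,
            "entry_time": entry_time,
            "entry_age": entry_age,
            "exit_time": exit_time,
            "exit_age": exit_age,
        }
        living.append(rec)
        return rec

    # founders: a small adult core per group, modelled like immigrants
    for _ in range(config.n_founder_groups):
        for sex, n in (("female", 3), ("male", 3)):
            for _ in range(n):
                age = rng.uniform(config.adult_age, config.adult_age + 5.0)
                add_individual("F", sex, natal=False, entry_time=0.0, entry_age=age)

    for year in range(int(np.ceil(config.years))):
        t = float(year)
        if t >= config.years:
            break
        # annual births by living adult females
        for rec in list(living):
            if rec["sex"] != "female":
                continue
            age_now = rec["entry_age"] + (t - rec["entry_time"])
            if age_now < config.adult_age or rec["exit_time"] <= t:
                continue
            if rng.uniform() >= config.annual_birth_prob:
                continue
            fetal_sex = "male" if rng.uniform() < config.true_bsr else "female"
            birth_time = t + rng.uniform(0.6, 0.9)  # birth season late in the year
            child = add_individual(
                "N", fetal_sex, natal=True, entry_time=birth_time, entry_age=0.0
            )
            child["birth_time"] = birth_time
            age_at_exit = min(child["exit_age"], config.years - birth_time)
            visually_sexed = age_at_exit > VISUAL_SEXING_AGE
            pregnancies.append(
                PregnancyRecord(
                    mother_id=rec["id"],
                    birth_date=_time_to_date(birth_time),
                    true_fetal_sex=fetal_sex,
                    observed_sex=fetal_sex if visually_sexed else "unknown",
                    sexing_mode="visual" if visually_sexed else "none",
                )
            )
        # immigrant males, per group
        n_imm = rng.poisson(config.immigrant_rate * config.n_founder_groups)
        for _ in range(n_imm):
            age = rng.uniform(config.adult_age, config.adult_age + 5.0)
            add_individual(
                "I", "male", natal=False, entry_time=t + rng.uniform(), entry_age=age
            )

    for rec in living:
        censored = rec["exit_time"] > config.years
        exit_age = (
            rec["entry_age"] + (config.years - rec["entry_time"])
            if censored
            else rec["exit_age"]
        )
        if exit_age <= rec["entry_age"]:
            # entered essentially at the final census; give it a token sliver
            exit_age = rec["entry_age"] + 1e-6
        birth_time = rec["entry_time"] - rec["entry_age"]
        sex = rec["sex"]
        # infants lost (or last seen) before visual sexing age stay unsexed
        if rec["natal"] and exit_age <= VISUAL_SEXING_AGE:
            sex = "unknown"
        individuals.append(
            Individual(
                id=rec["id"],
                sex=sex,
                natal=rec["natal"],
                entry_age=rec["entry_age"],
                exit_age=float(exit_age),
                exit_cause="censored" if censored else _draw_exit_cause(rng, rec["sex"]),
                birth_year=_STUDY_START_YEAR + int(np.floor(birth_time)),
            )
        )
    return individuals, pregnancies


def simulate_cohort(
    n: int,
    hazard_female_young: float,
    hazard_male_young: float,
    hazard_female_old: float,
    hazard_male_old: float,
    changepoint: float = 8.0,
    censor_age: float = 25.0,
    prop_male: float = 0.5,
    seed: int = 0,
) -> list[Individual]:
    """Simulate a simple birth cohort (no staggered entry, no immigration).

    Useful for calibration studies of the survival machinery where the full
    population bookkeeping of :func:`simulate_population` is unnecessary.
    Individuals enter at age 0 and are censored at ``censor_age``.
    """
    rng = np.random.default_rng(seed)
    out: list[Individual] = []
    n_male = int(round(n * prop_male))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    for i, sex in enumerate(sexes):
        hy, ho = (
            (hazard_male_young, hazard_male_old)
            if sex == "male"
            else (hazard_female_young, hazard_female_old)
        )
        t = piecewise_exponential(rng, 0.0, hy, ho, changepoint)
        censored = t > censor_age
        out.append(
            Individual(
                id=f"C{i:05d}",
                sex=sex,
                natal=True,
                entry_age=0.0,
                exit_age=float(min(t, censor_age)),
                exit_cause="censored" if censored else "unknown",
                birth_year=_STUDY_START_YEAR,
            )
        )
    return out


def simulate_hormone_profiles(
    pregnancies: Sequence[PregnancyRecord],
    config: SimulationConfig,
    samples_per_pregnancy: tuple[int, int] = (3, 6),
) -> list[HormoneSample]:
    """Draw late-gestation E1C samples for each pregnancy.

    Each pregnancy receives between ``samples_per_pregnancy`` faecal
    samples, uniformly dated within the last ``late_window_days`` before
    birth.  Concentrations are log-normal with natural-scale mean and s.d.
    given by the sex-specific config parameters, so male-carrying mothers
    show the elevated oestrogen signature that the threshold classifier
    exploits.
    """
    config.validate()
    lo, hi = samples_per_pregnancy
    if not 1 <= lo <= hi:
        raise ValueError("samples_per_pregnancy must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(config.seed + 1)
    out: list[HormoneSample] = []
    for preg in pregnancies:
        if preg.birth_date is None:
            raise ValueError(f"pregnancy of {preg.mother_id} lacks a birth date")
        mean, sd = (
            (config.e1c_male_mean, config.e1c_male_sd)
            if preg.true_fetal_sex == "male"
            else (config.e1c_female_mean, config.e1c_female_sd)
        )
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        n_samples = int(rng.integers(lo, hi + 1))
        days_before = np.sort(rng.uniform(1.0, config.late_window_days, n_samples))
        values = rng.lognormal(mu, np.sqrt(sigma2), n_samples)
        for d, v in zip(days_before, values):
            out.append(
                HormoneSample(
                    mother_id=preg.mother_id,
                    sample_date=preg.birth_date - _dt.timedelta(days=float(np.ceil(d))),
                    e1c=float(v),
                )
            )
    return out


def _time_to_date(t: float) -> _dt.date:
    """Continuous study time (years since study start) -> calendar date."""
    year = int(np.floor(t))
    day = int(np.floor((t - year) * 365.0))
    return _dt.date(_STUDY_START_YEAR + year, 1, 1) + _dt.timedelta(days=day)
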