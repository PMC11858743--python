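"""Two-sex stage-classed population projection and ASR sensitivity.

The population is projected with a 4 x 4 non-negative matrix over the
classes (juvenile female, adult female, juvenile male, adult male), where
"adult" means at least ``adult_age`` years old (30 months by default).
Because four classes cannot tile a ~25-year lifespan as single-year age
classes, juveniles carry a self-loop and mature with probability
gamma = 1 / adult_age per year, so the mean juvenile residence time equals
the age at maturity.  Births are attributed to adult females only (a
female-dominant two-sex model); the adult-female column carries the
sex-specific fecundities into the two juvenile rows.

The adult sex ratio (ASR) is the proportion of adult males among adults in
the stable stage structure (dominant right eigenvector).  Sensitivities of
the ASR to individual matrix elements are numerical central differences,
the analogue of classical eigenvalue sensitivities but for a nonlinear
functional of the eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .simulate import Individual, PregnancyRecord
from .survival import build_episodes, km_estimate

__all__ = [
    "VitalRates",
    "LeslieModel",
    "AsymptoticState",
    "SensitivityResult",
    "estimate_vital_rates",
    "build_leslie",
    "asymptotic_state",
    "asr_sensitivity",
    "CLASS_LABELS",
]

CLASS_LABELS = ("juvenile-female", "adult-female", "juvenile-male", "adult-male")


@dataclass
class VitalRates:
    """Annual survival per age-sex class and per-capita fecundity.

    ``f_f`` and ``f_m`` are the mean numbers of female and male offspring
    produced per adult female per year; their ratio encodes the birth sex
    ratio used to split reproduction between the sexes.
    """

    s_jf: float
    s_jm: float
    s_af: float
    s_am: float
    f_f: float
    f_m: float
    adult_age: float = 2.5

    def __post_init__(self) -> None:
        for name in ("s_jf", "s_jm", "s_af", "s_am"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.f_f < 0 or self.f_m < 0:
            raise ValueError("fecundities must be >= 0")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be > 0")

    @property
    def bsr(self) -> float:
        tot = self.f_f + self.f_m
        return self.f_m / tot if tot > 0 else float("nan")


@dataclass
class LeslieModel:
    matrix: np.ndarray
    class_labels: tuple = CLASS_LABELS
    rates: VitalRates | None = None

    #: (row, col) entries that are structurally zero in this model
    @property
    def structural_zero(self) -> np.ndarray:
        mask = np.ones((4, 4), dtype=bool)
        for r, c, _ in _NONZERO_ENTRIES:
            mask[r, c] = False
        return mask


# entries: (row, col, kind); kind "survival" entries are clipped to [0, 1]
_NONZERO_ENTRIES = [
    (0, 0, "survival"),  # juvenile-female persistence
    (1, 0, "survival"),  # juvenile-female maturation
    (1, 1, "survival"),  # adult-female survival
    (0, 1, "fecundity"),  # daughters per adult female
    (2, 1, "fecundity"),  # sons per adult female
    (2, 2, "survival"),  # juvenile-male persistence
    (3, 2, "survival"),  # juvenile-male maturation
    (3, 3, "survival"),  # adult-male survival
]


@dataclass
class AsymptoticState:
    lam: float
    stable_structure: np.ndarray  # proportions over CLASS_LABELS, sums to 1
    asr: float


@dataclass
class SensitivityResult:
    entries: list  # dicts: row, col, label, delta_used, dASR_dElement, clipped
    ranking: list = field(default_factory=list)  # entry labels by signed effect, desc


def estimate_vital_rates(
    individuals: Iterable[Individual],
    pregnancies: Iterable[PregnancyRecord],
    adult_age: float = 2.5,
    max_age: float = 20.0,
) -> VitalRates:
    """Annualized class survival from product-limit curves, plus fecundity.

    Survival is the geometric-mean annual survival over the class's age
    span, read off the sex-specific Kaplan-Meier curve: juveniles over
    [0, adult_age), adults over [adult_age, A] with A the smaller of
    ``max_age`` and the last observed event age.  Fecundities are sexed
    births per adult-female-year of observed exposure, split by offspring
    sex.
    """
    individuals = list(individuals)
    pregnancies = list(pregnancies)
    if adult_age <= 0:
        raise ValueError("adult_age must be > 0")
    episodes = build_episodes(individuals, changepoint=adult_age, split=True)
    surv = {}
    for sex, flag in (("female", 0), ("male", 1)):
        sub = [e for e in episodes if e.sex_male == flag]
        if not sub:
            raise ValueError(f"no {sex} episodes: cannot estimate survival")
        curve = km_estimate(sub)
        s_at_adult = curve.at(adult_age)
        if s_at_adult <= 0:
            raise ValueError(f"{sex} survival reaches 0 before adulthood")
        upper = min(max_age, curve.times.max()) if curve.times.size else max_age
        if upper <= adult_age:
            raise ValueError(f"no {sex} exposure beyond adult_age")
        s_upper = max(curve.at(upper), 1e-12)
        surv[sex] = (
            s_at_adult ** (1.0 / adult_age),
            (s_upper / s_at_adult) ** (1.0 / (upper - adult_age)),
        )

    # adult-female exposure years
    af_years = 0.0
    for ind in individuals:
        if ind.sex != "female":
            continue
        af_years += max(0.0, ind.exit_age - max(ind.entry_age, adult_age))
    if af_years <= 0:
        raise ValueError("no adult-female exposure")
    n_f = sum(p.observed_sex == "female" for p in pregnancies)
    n_m = sum(p.observed_sex == "male" for p in pregnancies)
    return VitalRates(
        s_jf=surv["female"][0],
        s_jm=surv["male"][0],
        s_af=surv["female"][1],
        s_am=surv["male"][1],
        f_f=n_f / af_years,
        f_m=n_m / af_years,
        adult_age=adult_age,
    )


def build_leslie(rates: VitalRates) -> LeslieModel:
    """Assemble the 4 x 4 projection matrix from vital rates."""
    gamma = 1.0 / rates.adult_age
    gamma = min(gamma, 1.0)
    A = np.zeros((4, 4))
    A[0, 0] = rates.s_jf * (1.0 - gamma)
    A[1, 0] = rates.s_jf * gamma
    A[1, 1] = rates.s_af
    A[0, 1] = rates.f_f
    A[2, 1] = rates.f_m
    A[2, 2] = rates.s_jm * (1.0 - gamma)
    A[3, 2] = rates.s_jm * gamma
    A[3, 3] = rates.s_am
    return LeslieModel(matrix=A, rates=rates)


def _power_iteration(A: np.ndarray, tol: float = 1e-12, max_iter: int = 200_000):
    v = np.full(A.shape[0], 1.0 / A.shape[0])
    lam = 0.0
    for _ in range(max_iter):
        w = A @ v
        norm = w.sum()
        if norm <= 0:
            raise ValueError("projection collapsed: no positive growth path")
        w /= norm
        if np.abs(w - v).max() < tol and abs(norm - lam) < tol * max(1.0, lam):
            return norm, w
        v, lam = w, norm
    raise ValueError("power iteration did not converge (dominance too weak)")


def asymptotic_state(model: LeslieModel, tol: float = 1e-12) -> AsymptoticState:
    """Dominant eigenpair -> growth rate, stable structure, asymptotic ASR.

    Power iteration (tolerance ``tol``) cross-checked against a direct
    eigendecomposition; raises if the matrix lacks a strictly dominant
    eigenvalue (e.g. a scaled identity).
    """
    A = model.matrix
    if np.any(A < 0):
        raise ValueError("projection matrix must be non-negative")
    eigvals, eigvecs = np.linalg.eig(A)
    mods = np.abs(eigvals)
    order = np.argsort(mods)[::-1]
    if mods[order[0]] <= 0:
        raise ValueError("no positive dominant eigenvalue")
    gap = mods[order[0]] - mods[order[1]]
    if gap <= 1e-9 * max(1.0, mods[order[0]]):
        raise ValueError(
            "no strictly dominant eigenvalue: asymptotic structure undefined"
        )
    lam = float(np.real(eigvals[order[0]]))
    v = np.real(eigvecs[:, order[0]])
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9):
        raise ValueError("dominant eigenvector is not non-negative")
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    lam_p, v_p = _power_iteration(A, tol=tol)
    if abs(lam_p - lam) > 1e-8 * max(1.0, lam) or np.abs(v_p - v).max() > 1e-8:
        raise ValueError("power iteration and eigendecomposition disagree")
    adults = v[1] + v[3]
    if adults <= 0:
        raise ValueError("no adults in the stable structure")
    return AsymptoticState(lam=lam, stable_structure=v, asr=float(v[3] / adults))


def asr_sensitivity(model: LeslieModel, delta: float = 0.01) -> SensitivityResult:
    """Central-difference sensitivity of the ASR to each matrix element.

    Each non-structurally-zero element is perturbed by +/- ``delta``;
    survival-type entries are clipped to [0, 1] and any clipping is
    reported (the difference quotient uses the realized perturbation).
    Entries whose perturbation destroys eigenvalue dominance are flagged.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    A = model.matrix
    entries = []
    for r, c, kind in _NONZERO_ENTRIES:
        a = A[r, c]
        hi, lo = a + delta, a - delta
        clipped = False
        if kind == "survival":
            hi_c, lo_c = min(hi, 1.0), max(lo, 0.0)
            clipped = (hi_c != hi) or (lo_c != lo)
            hi, lo = hi_c, lo_c
        else:
            lo_c = max(lo, 0.0)
            clipped = lo_c != lo
            lo = lo_c
        label = f"{CLASS_LABELS[c]} -> {CLASS_LABELS[r]} ({kind})"
        if hi <= lo:
            entries.append(
                dict(row=r, col=c, label=label, delta_used=0.0,
                     dASR_dElement=np.nan, clipped=True, degenerate=True)
            )
            continue
        try:
            Ap = A.copy(); Ap[r, c] = hi
            Am = A.copy(); Am[r, c] = lo
            asr_hi = asymptotic_state(LeslieModel(Ap, model.class_labels)).asr
            asr_lo = asymptotic_state(LeslieModel(Am, model.class_labels)).asr
        except ValueError:
            entries.append(
                dict(row=r, col=c, label=label, delta_used=hi - lo,
                     dASR_dElement=np.nan, clipped=clipped, degenerate=True)
            )
            continue
        entries.append(
            dict(
                row=r,
                col=c,
                label=label,
                delta_used=hi - lo,
                dASR_dElement=(asr_hi - asr_lo) / (hi - lo),
                clipped=clipped,
                degenerate=False,
            )
        )
    ok = [e for e in entries if not e["degenerate"]]
    ranking = [e["label"] for e in sorted(ok, key=lambda e: -e["dASR_dElement"])]
    ranking += [e["label"] for e in entries if e["degenerate"]]
    return SensitivityResult(entries=entries, ranking=ranking)
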