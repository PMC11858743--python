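"""Prenatal fetal sexing from maternal late-gestation oestrogen (E1C).

In this species only mothers carrying a male fetus show markedly elevated
faecal oestrone during the last weeks of gestation, so fetal sex can be
called from the mean late-gestation concentration with a simple threshold:
the mean of female-carrying mothers' means plus ``k`` sample standard
deviations (default k = 2).  Values strictly above the threshold are called
male; ties and everything below are called female.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import HormoneSample, PregnancyRecord

__all__ = [
    "PregnancyHormoneSummary",
    "SexThreshold",
    "summarize_late_gestation",
    "derive_threshold",
    "classify_fetal_sex",
    "loo_accuracy",
]


@dataclass
class PregnancyHormoneSummary:
    mother_id: str
    birth_date: _dt.date
    mean_late_e1c: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("summary requires at least one sample")
        if self.mean_late_e1c < 0:
            raise ValueError("mean E1C must be non-negative")


@dataclass
class SexThreshold:
    female_mean: float
    female_sd: float
    k: float = 2.0

    @property
    def threshold(self) -> float:
        return self.female_mean + self.k * self.female_sd


def summarize_late_gestation(
    samples: Iterable[HormoneSample],
    pregnancies: Iterable[PregnancyRecord],
    window_days: float = 42.0,
) -> tuple[list[PregnancyHormoneSummary], list[PregnancyRecord]]:
    """Per-pregnancy mean E1C over the late-gestation window.

    A sample contributes to a pregnancy when
    ``birth_date - window_days <= sample_date < birth_date``.  Returns the
    summaries plus the pregnancies that had no in-window samples (omitted
    from the summaries, reported to the caller).
    """
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    by_mother: dict[str, list[HormoneSample]] = {}
    for s in samples:
        by_mother.setdefault(s.mother_id, []).append(s)

    summaries: list[PregnancyHormoneSummary] = []
    unsampled: list[PregnancyRecord] = []
    for preg in pregnancies:
        if preg.birth_date is None:
            raise ValueError(f"pregnancy of {preg.mother_id} lacks a birth date")
        lo = preg.birth_date - _dt.timedelta(days=window_days)
        vals = [
            s.e1c
            for s in by_mother.get(preg.mother_id, [])
            if lo <= s.sample_date < preg.birth_date
        ]
        if not vals:
            unsampled.append(preg)
            continue
        summaries.append(
            PregnancyHormoneSummary(
                mother_id=preg.mother_id,
                birth_date=preg.birth_date,
                mean_late_e1c=float(np.mean(vals)),
                n_samples=len(vals),
            )
        )
    return summaries, unsampled


def derive_threshold(
    female_training_means: Sequence[float], k: float = 2.0
) -> SexThreshold:
    """Threshold anchored on female-carrying mothers: mean + k * s.d. (n-1)."""
    vals = np.asarray(list(female_training_means), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 female training values")
    if k <= 0:
        raise ValueError("k must be > 0")
    return SexThreshold(
        female_mean=float(vals.mean()), female_sd=float(vals.std(ddof=1)), k=k
    )


def classify_fetal_sex(
    summary: PregnancyHormoneSummary, threshold: SexThreshold
) -> str:
    """Male iff the late-gestation mean is strictly above the threshold."""
    return "male" if summary.mean_late_e1c > threshold.threshold else "female"


def loo_accuracy(
    summaries: Sequence[PregnancyHormoneSummary],
    true_sexes: Sequence[str],
    k: float = 2.0,
) -> float:
    """Leave-one-out accuracy of the threshold rule on labelled pregnancies.

    For each pregnancy, the threshold is re-derived from the remaining
    female-carrying mothers' means, the held-out pregnancy is classified,
    and the fraction of correct calls is returned.
    """
    if len(summaries) != len(true_sexes):
        raise ValueError("summaries and labels must align")
    if len(summaries) < 3:
        raise ValueError("need at least 3 labelled pregnancies")
    if sum(s == "female" for s in true_sexes) < 2:
        raise ValueError("need at least 2 female-carrying pregnancies")
    correct = 0
    for i, (summ, truth) in enumerate(zip(summaries, true_sexes)):
        training = [
            s.mean_late_e1c
            for j, (s, lab) in enumerate(zip(summaries, true_sexes))
            if j != i and lab == "female"
        ]
        if len(training) >= 2:
            thr = derive_threshold(training, k=k)
        else:
            # degenerate fold (held-out was one of only two females)
            thr = SexThreshold(female_mean=training[0], female_sd=0.0, k=k)
        if classify_fetal_sex(summ, thr) == truth:
            correct += 1
    return correct / len(summaries)
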