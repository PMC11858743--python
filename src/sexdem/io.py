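"""CSV schemas and round-trip readers/writers for all pipeline tables.

All tables are plain UTF-8 CSV with fixed, documented headers; dates are
ISO-8601 (YYYY-MM-DD).  Schema violations are reported with the offending
row number (1-based, excluding the header).

Tables
------
individuals.csv : id, sex, natal, entry_age, exit_age, event, exit_cause, birth_year
pregnancies.csv : mother_id, birth_date, true_fetal_sex, observed_sex, sexing_mode
hormones.csv    : mother_id, sample_date, e1c
episodes.csv    : id, start_age, stop_age, event, sex_male, young
sexing.csv      : mother_id, birth_date, mean_late_e1c, n_samples, call, threshold_used
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Sequence

import pandas as pd

from .simulate import HormoneSample, Individual, PregnancyRecord
from .survival import Episode

__all__ = [
    "SchemaError",
    "write_individuals",
    "read_individuals",
    "write_pregnancies",
    "read_pregnancies",
    "write_hormones",
    "read_hormones",
    "write_episodes",
    "read_episodes",
]

_SEXES = {"female", "male", "unknown"}
_CAUSES = {"death", "emigration", "eviction", "unknown", "censored"}


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_date(v, path, row) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(v))
    except ValueError as exc:
        raise SchemaError(f"{path}: row {row}: bad date {v!r}") from exc


# -- individuals ------------------------------------------------------------

INDIVIDUAL_COLUMNS = [
    "id", "sex", "natal", "entry_age", "exit_age", "event", "exit_cause", "birth_year",
]


def write_individuals(individuals: Sequence[Individual], path) -> None:
    pd.DataFrame(
        [
            {
                "id": i.id,
                "sex": i.sex,
                "natal": int(i.natal),
                "entry_age": round(i.entry_age, 6),
                "exit_age": round(i.exit_age, 6),
                "event": i.event,
                "exit_cause": i.exit_cause,
                "birth_year": i.birth_year,
            }
            for i in individuals
        ],
        columns=INDIVIDUAL_COLUMNS,
    ).to_csv(path, index=False)


def read_individuals(path) -> list[Individual]:
    df = pd.read_csv(path)
    _check_columns(df, INDIVIDUAL_COLUMNS, path)
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.sex not in _SEXES:
            raise SchemaError(f"{path}: row {row}: unknown sex {rec.sex!r}")
        if rec.exit_cause not in _CAUSES:
            raise SchemaError(f"{path}: row {row}: unknown exit_cause {rec.exit_cause!r}")
        if rec.entry_age < 0 or rec.exit_age < 0:
            raise SchemaError(f"{path}: row {row}: negative age")
        if rec.exit_age < rec.entry_age:
            raise SchemaError(f"{path}: row {row}: exit_age < entry_age")
        expected_event = 0 if rec.exit_cause == "censored" else 1
        if int(rec.event) != expected_event:
            raise SchemaError(
                f"{path}: row {row}: event flag inconsistent with exit_cause"
            )
        out.append(
            Individual(
                id=str(rec.id),
                sex=rec.sex,
                natal=bool(rec.natal),
                entry_age=float(rec.entry_age),
                exit_age=float(rec.exit_age),
                exit_cause=rec.exit_cause,
                birth_year=int(rec.birth_year),
            )
        )
    return out


# -- pregnancies ------------------------------------------------------------

PREGNANCY_COLUMNS = [
    "mother_id", "birth_date", "true_fetal_sex", "observed_sex", "sexing_mode",
]


def write_pregnancies(pregnancies: Sequence[PregnancyRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "mother_id": p.mother_id,
                "birth_date": p.birth_date.isoformat(),
                "true_fetal_sex": p.true_fetal_sex,
                "observed_sex": p.observed_sex,
                "sexing_mode": p.sexing_mode,
            }
            for p in pregnancies
        ],
        columns=PREGNANCY_COLUMNS,
    ).to_csv(path, index=False)


def read_pregnancies(path) -> list[PregnancyRecord]:
    df = pd.read_csv(path)
    _check_columns(df, PREGNANCY_COLUMNS, path)
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        for col in ("true_fetal_sex", "observed_sex"):
            if getattr(rec, col) not in _SEXES:
                raise SchemaError(f"{path}: row {row}: bad {col}")
        out.append(
            PregnancyRecord(
                mother_id=str(rec.mother_id),
                birth_date=_parse_date(rec.birth_date, path, row),
                true_fetal_sex=rec.true_fetal_sex,
                observed_sex=rec.observed_sex,
                sexing_mode=rec.sexing_mode,
            )
        )
    return out


# -- hormones ---------------------------------------------------------------

HORMONE_COLUMNS = ["mother_id", "sample_date", "e1c"]


def write_hormones(samples: Sequence[HormoneSample], path) -> None:
    pd.DataFrame(
        [
            {
                "mother_id": s.mother_id,
                "sample_date": s.sample_date.isoformat(),
                "e1c": round(s.e1c, 6),
            }
            for s in samples
        ],
        columns=HORMONE_COLUMNS,
    ).to_csv(path, index=False)


def read_hormones(path) -> list[HormoneSample]:
    df = pd.read_csv(path)
    _check_columns(df, HORMONE_COLUMNS, path)
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.e1c < 0:
            raise SchemaError(f"{path}: row {row}: negative concentration")
        out.append(
            HormoneSample(
                mother_id=str(rec.mother_id),
                sample_date=_parse_date(rec.sample_date, path, row),
                e1c=float(rec.e1c),
            )
        )
    return out


# -- episodes ---------------------------------------------------------------

EPISODE_COLUMNS = ["id", "start_age", "stop_age", "event", "sex_male", "young"]


def write_episodes(episodes: Sequence[Episode], path) -> None:
    pd.DataFrame(
        [
            {
                "id": e.id,
                "start_age": round(e.start_age, 6),
                "stop_age": round(e.stop_age, 6),
                "event": e.event,
                "sex_male": e.sex_male,
                "young": e.young,
            }
            for e in episodes
        ],
        columns=EPISODE_COLUMNS,
    ).to_csv(path, index=False)


def read_episodes(path) -> list[Episode]:
    df = pd.read_csv(path)
    _check_columns(df, EPISODE_COLUMNS, path)
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        if rec.start_age < 0:
            raise SchemaError(f"{path}: row {row}: negative age")
        if rec.stop_age <= rec.start_age:
            raise SchemaError(f"{path}: row {row}: stop_age <= start_age")
        out.append(
            Episode(
                id=str(rec.id),
                start_age=float(rec.start_age),
                stop_age=float(rec.stop_age),
                event=int(rec.event),
                sex_male=int(rec.sex_male),
                young=int(rec.young),
            )
        )
    return out
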