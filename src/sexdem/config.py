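"""Simulation configuration for the individual-based census simulator.

The defaults describe the study system the package emulates: a small
population of group-living, sexually dichromatic lemurs followed by
near-daily censuses over ~27 years.  Philopatric females mature in their
third year of life and usually produce a single infant annually; males
disperse between groups and females can be evicted, both of which count as
"disappearance" events alongside death.  Maternal faecal oestrone (E1C)
rises markedly in late gestation only when the fetus is male, which is what
makes prenatal hormonal sexing possible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["SimulationConfig"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic census / hormone simulation.

    Hazards are per-year rates of the composite "disappearance" event
    (death, male emigration, female eviction, or unknown), piecewise
    constant with a changepoint at ``changepoint_age``.  E1C parameters are
    the mean and s.d. (natural scale, ng/g) of late-gestation maternal
    oestrone by fetal sex; samples are drawn log-normally with matching
    first two moments.
    """

    n_founder_groups: int = 7
    years: float = 27.0
    true_bsr: float = 0.5
    hazard_female_young: float = 0.22
    hazard_male_young: float = 0.11
    hazard_female_old: float = 0.18
    hazard_male_old: float = 0.18
    changepoint_age: float = 8.0
    adult_age: float = 2.5
    annual_birth_prob: float = 0.8
    immigrant_rate: float = 0.4
    e1c_female_mean: float = 200.0
    e1c_female_sd: float = 50.0
    e1c_male_mean: float = 600.0
    e1c_male_sd: float = 150.0
    gestation_days: float = 120.0
    late_window_days: float = 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "seed":
                if not isinstance(v, (int,)) or isinstance(v, bool):
                    raise ValueError("seed must be an integer")
                continue
            if not math.isfinite(float(v)):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
        for name in ("true_bsr", "annual_birth_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "hazard_female_young",
            "hazard_male_young",
            "hazard_female_old",
            "hazard_male_old",
            "immigrant_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_founder_groups < 0:
            raise ValueError("n_founder_groups must be >= 0")
        if self.years <= 0:
            raise ValueError("years must be > 0")
        if not self.changepoint_age > self.adult_age > 0:
            raise ValueError("need changepoint_age > adult_age > 0")
        for name in ("e1c_female_mean", "e1c_male_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("e1c_female_sd", "e1c_male_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gestation_days <= 0 or self.late_window_days <= 0:
            raise ValueError("gestation_days and late_window_days must be > 0")
        if self.late_window_days > self.gestation_days:
            raise ValueError("late_window_days cannot exceed gestation_days")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
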