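"""Birth sex ratio (BSR) estimation with parametric-bootstrap intervals.

The BSR is the proportion of male offspring among sexed births,

    BSR = N_male / (N_male + N_female),

with unknown-sex offspring excluded from the ratio but retained in the
counts for reporting.  The confidence interval is a parametric bootstrap:
binomial resampling of the sexed-birth count at the point estimate, with a
percentile interval over the replicate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .simulate import PregnancyRecord

__all__ = ["SexCounts", "BSREstimate", "compute_bsr", "bootstrap_ci", "merge_sexings"]


@dataclass
class SexCounts:
    n_male: int = 0
    n_female: int = 0
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if min(self.n_male, self.n_female, self.n_unknown) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_sexed(self) -> int:
        return self.n_male + self.n_female


@dataclass
class BSREstimate:
    bsr: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.bsr <= self.ci_high <= 1.0:
            raise ValueError("interval must satisfy 0 <= low <= bsr <= high <= 1")


def compute_bsr(counts: SexCounts) -> float:
    """Proportion male among sexed offspring; unknowns are excluded."""
    if counts.n_sexed == 0:
        raise ValueError("no sexed offspring: BSR undefined")
    return counts.n_male / counts.n_sexed


def bootstrap_ci(
    counts: SexCounts,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> BSREstimate:
    """Parametric-bootstrap percentile interval for the BSR.

    Draws ``n_boot`` binomial replicates with n = sexed births and
    p = point BSR, recomputes the ratio per replicate, and takes the
    percentile interval at ``level``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    p_hat = compute_bsr(counts)
    n = counts.n_sexed
    rng = np.random.default_rng(seed)
    reps = rng.binomial(n, p_hat, size=n_boot) / n
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    # the percentile interval can exclude p_hat only through Monte Carlo
    # discreteness at extreme p; clip so the estimate object stays valid
    lo = min(float(lo), p_hat)
    hi = max(float(hi), p_hat)
    return BSREstimate(
        bsr=p_hat, ci_low=lo, ci_high=hi, n_boot=n_boot, level=level, seed=seed
    )


@dataclass
class MergeResult:
    counts: SexCounts
    conflicts: list = field(default_factory=list)  # (key, visual, hormonal)


def merge_sexings(
    visual: Sequence[PregnancyRecord],
    hormonal: Mapping[tuple, str] | None = None,
) -> MergeResult:
    """Combine visually and hormonally determined offspring sexes.

    ``hormonal`` maps pregnancy keys ``(mother_id, birth_date)`` to a sex
    call.  A hormonal call fills in records whose visual sex is unknown;
    when both exist and agree the visual label stands; disagreements are
    reported as conflicts and excluded from the sexed counts.
    """
    hormonal = dict(hormonal or {})
    seen: set[tuple] = set()
    counts = {"male": 0, "female": 0, "unknown": 0}
    conflicts: list[tuple] = []
    for rec in visual:
        key = (rec.mother_id, rec.birth_date)
        if key in seen:
            raise ValueError(f"duplicate pregnancy key {key}")
        seen.add(key)
        call = rec.observed_sex
        horm = hormonal.pop(key, None)
        if horm is not None:
            if call == "unknown":
                call = horm
            elif call != horm:
                conflicts.append((key, call, horm))
                counts["unknown"] += 1
                continue
        counts[call] += 1
    # hormonally confirmed pregnancies without a demographic record
    for key, horm in hormonal.items():
        if key in seen:
            continue
        counts[horm] += 1
    return MergeResult(
        counts=SexCounts(
            n_male=counts["male"],
            n_female=counts["female"],
            n_unknown=counts["unknown"],
        ),
        conflicts=conflicts,
    )
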