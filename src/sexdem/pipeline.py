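"""End-to-end pipeline: simulate/load -> sex -> BSR -> survival -> projection.

Every run writes its outputs under one directory, each carrying the
config hash and seed, and aggregates the headline quantities — BSR with
bootstrap interval, the Cox fit and proportional-hazards diagnostics, the
population growth rate, the asymptotic adult sex ratio and the sensitivity
ranking — into a single ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sdio
from .config import SimulationConfig
from .hormones import (
    classify_fetal_sex,
    derive_threshold,
    summarize_late_gestation,
)
from .projection import asr_sensitivity, asymptotic_state, build_leslie, estimate_vital_rates
from .sexratio import bootstrap_ci, merge_sexings
from .simulate import simulate_hormone_profiles, simulate_population
from .survival import build_episodes, fit_disappearance_model, km_estimate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("sexdem")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Either a simulation config or paths to the three input tables."""

    out_dir: str | Path = "sexdem_out"
    simulation: SimulationConfig | None = None
    individuals_csv: str | Path | None = None
    pregnancies_csv: str | Path | None = None
    hormones_csv: str | Path | None = None
    seed: int = 0
    changepoint: float = 8.0
    adult_age: float = 2.5
    window_days: float = 42.0
    threshold_k: float = 2.0
    n_boot: int = 1000
    level: float = 0.95
    sensitivity_delta: float = 0.01
    stages: tuple = ("sexing", "bsr", "survival", "projection", "sensitivity")

    def __post_init__(self) -> None:
        have_paths = self.individuals_csv is not None
        if have_paths == (self.simulation is not None):
            raise ValueError(
                "supply exactly one of: a simulation config, or input CSV paths"
            )
        if have_paths and self.pregnancies_csv is None:
            raise ValueError("pregnancies_csv required alongside individuals_csv")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = None  # the output location does not define the run
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        individuals, pregnancies = simulate_population(cfg.simulation)
        hormones = simulate_hormone_profiles(pregnancies, cfg.simulation)
        return individuals, pregnancies, hormones
    individuals = sdio.read_individuals(cfg.individuals_csv)
    pregnancies = sdio.read_pregnancies(cfg.pregnancies_csv)
    hormones = (
        sdio.read_hormones(cfg.hormones_csv) if cfg.hormones_csv is not None else []
    )
    return individuals, pregnancies, hormones


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages; returns (and writes) the summary dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_id = {"config_hash": cfg.hash(), "seed": cfg.seed}
    summary: dict = {"run": run_id}

    individuals, pregnancies, hormones = _load_inputs(cfg)
    sdio.write_individuals(individuals, out_dir / "individuals.csv")
    sdio.write_pregnancies(pregnancies, out_dir / "pregnancies.csv")
    sdio.write_hormones(hormones, out_dir / "hormones.csv")
    summary["n_individuals"] = len(individuals)
    summary["n_pregnancies"] = len(pregnancies)

    hormonal_calls: dict = {}
    if "sexing" in cfg.stages:
        hormonal_calls = _stage_sexing(cfg, out_dir, pregnancies, hormones, summary)
    if "bsr" in cfg.stages:
        _stage_bsr(cfg, out_dir, pregnancies, hormonal_calls, summary)
    if "survival" in cfg.stages:
        _stage_survival(cfg, out_dir, individuals, summary)
    model = None
    if "projection" in cfg.stages:
        model = _stage_projection(cfg, out_dir, individuals, pregnancies, summary)
    if "sensitivity" in cfg.stages:
        if model is None:
            raise PipelineError(
                "sensitivity", ValueError("sensitivity requires the projection stage")
            )
        _stage_sensitivity(cfg, out_dir, model, summary)

    (out_dir / "summary.json").write_text(_to_json(summary))
    return summary


@_stage("sexing")
def _stage_sexing(cfg, out_dir, pregnancies, hormones, summary):
    if not hormones:
        raise ValueError("hormonal sexing enabled but no hormone samples supplied")
    summaries, unsampled = summarize_late_gestation(
        hormones, pregnancies, window_days=cfg.window_days
    )
    by_key = {(p.mother_id, p.birth_date): p for p in pregnancies}
    training = [
        s.mean_late_e1c
        for s in summaries
        if by_key[(s.mother_id, s.birth_date)].observed_sex == "female"
    ]
    thr = derive_threshold(training, k=cfg.threshold_k)
    calls = {
        (s.mother_id, s.birth_date): classify_fetal_sex(s, thr) for s in summaries
    }
    import pandas as pd

    pd.DataFrame(
        [
            {
                "mother_id": s.mother_id,
                "birth_date": s.birth_date.isoformat(),
                "mean_late_e1c": round(s.mean_late_e1c, 6),
                "n_samples": s.n_samples,
                "call": calls[(s.mother_id, s.birth_date)],
                "threshold_used": round(thr.threshold, 6),
            }
            for s in summaries
        ],
        columns=[
            "mother_id", "birth_date", "mean_late_e1c",
            "n_samples", "call", "threshold_used",
        ],
    ).to_csv(out_dir / "sexing.csv", index=False)
    summary["sexing"] = {
        "threshold": thr.threshold,
        "k": cfg.threshold_k,
        "n_classified": len(calls),
        "n_without_samples": len(unsampled),
    }
    return calls


@_stage("bsr")
def _stage_bsr(cfg, out_dir, pregnancies, hormonal_calls, summary):
    merged = merge_sexings(pregnancies, hormonal_calls)
    est = bootstrap_ci(merged.counts, n_boot=cfg.n_boot, level=cfg.level, seed=cfg.seed)
    summary["bsr"] = {
        "n_male": merged.counts.n_male,
        "n_female": merged.counts.n_female,
        "n_unknown": merged.counts.n_unknown,
        "n_conflicts": len(merged.conflicts),
        "bsr": est.bsr,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_boot": est.n_boot,
        "level": est.level,
    }
    import pandas as pd

    pd.DataFrame([summary["bsr"]]).to_csv(out_dir / "bsr.csv", index=False)


@_stage("survival")
def _stage_survival(cfg, out_dir, individuals, summary):
    episodes = build_episodes(individuals, changepoint=cfg.changepoint)
    sdio.write_episodes(episodes, out_dir / "episodes.csv")
    import pandas as pd

    for label, flag in (("female", 0), ("male", 1)):
        curve = km_estimate(episodes, group=lambda e, f=flag: e.sex_male == f)
        pd.DataFrame(
            {
                "age": curve.times,
                "survival": curve.survival,
                "n_at_risk": curve.n_at_risk,
                "n_events": curve.n_events,
            }
        ).to_csv(out_dir / f"km_{label}.csv", index=False)
    fit, ph = fit_disappearance_model(individuals, changepoint=cfg.changepoint)
    fit_report = {
        "terms": fit.terms,
        "coefficients": fit.coef.tolist(),
        "se": fit.se.tolist(),
        "p": fit.p_values.tolist(),
        "loglik_null": fit.loglik_null,
        "loglik_fit": fit.loglik_fit,
        "lr_stat": fit.lr_stat,
        "wald_stat": fit.wald_stat,
        "df": fit.df,
        "n_events": fit.n_events,
    }
    ph_report = {
        "terms": ph.terms,
        "chi2": ph.chi2.tolist(),
        "p": ph.p.tolist(),
        "global_chi2": ph.global_chi2,
        "global_df": ph.global_df,
        "global_p": ph.global_p,
    }
    (out_dir / "cox_fit.json").write_text(_to_json(fit_report))
    (out_dir / "ph_test.json").write_text(_to_json(ph_report))
    summary["survival"] = {"cox": fit_report, "ph_test": ph_report}


@_stage("projection")
def _stage_projection(cfg, out_dir, individuals, pregnancies, summary):
    rates = estimate_vital_rates(individuals, pregnancies, adult_age=cfg.adult_age)
    model = build_leslie(rates)
    state = asymptotic_state(model)
    import pandas as pd

    pd.DataFrame(model.matrix, columns=model.class_labels).to_csv(
        out_dir / "leslie.csv", index=False
    )
    report = {
        "rates": dataclasses.asdict(rates),
        "lambda": state.lam,
        "stable_structure": dict(zip(model.class_labels, state.stable_structure)),
        "asr": state.asr,
    }
    (out_dir / "asymptotic.json").write_text(_to_json(report))
    summary["projection"] = report
    return model


@_stage("sensitivity")
def _stage_sensitivity(cfg, out_dir, model, summary):
    sens = asr_sensitivity(model, delta=cfg.sensitivity_delta)
    import pandas as pd

    pd.DataFrame(sens.entries).to_csv(out_dir / "sensitivity.csv", index=False)
    summary["sensitivity"] = {
        "delta": cfg.sensitivity_delta,
        "ranking": sens.ranking,
        "entries": sens.entries,
    }


def _to_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    return json.dumps(obj, indent=2, sort_keys=True, default=default)
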