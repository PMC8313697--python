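"""End-to-end orchestration: simulate, analyse behavior and EMG, infer.

``run_full_pipeline`` ties the stages into one deterministic run: a
synthetic population is generated (or participant-level data ingested),
each participant's session yields an SSRT and each pulse block a mean CSP,
the five screening criteria drop outlier participants, and the retained
sample enters the correlation stage (Pearson family, skipped Pearson for
the CSP-SSRT pair, leave-one-out cross-validation with a permutation
null).  The report carries provenance (config hash, seed) so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .emg_csp import CSPConfig, extract_trial_features, summarize_participant
from .errors import AnalysisError, StopCSPError
from .sst_analysis import apply_exclusion_criteria, choice_error_rate, summarize_session
from .stats_inference import loocv_permutation_test, pearson_family, skipped_pearson
from .synthetic_data import (
    ParticipantBehaviorModel,
    ParticipantData,
    PopulationParams,
    SessionDesign,
    SyntheticEMGParams,
    generate_population,
)

__all__ = ["RunConfig", "run_full_pipeline", "report_to_json"]

log = logging.getLogger("stopcsp")


def _build(cls, data: dict | None):
    """Construct a (possibly nested) config dataclass from plain dicts."""
    data = dict(data or {})
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data.pop(f.name)
        if isinstance(value, dict) and f.name in _NESTED:
            value = _build(_NESTED[f.name], value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    if data:
        raise StopCSPError(f"unknown {cls.__name__} field(s): {', '.join(sorted(data))}")
    return cls(**kwargs)


_NESTED = {
    "design": SessionDesign,
    "behavior_defaults": ParticipantBehaviorModel,
    "emg_defaults": SyntheticEMGParams,
    "population": PopulationParams,
    "csp_config": CSPConfig,
}


@dataclass
class RunConfig:
    population: PopulationParams = field(default_factory=PopulationParams)
    csp_config: CSPConfig = field(default_factory=CSPConfig)
    n_boot: int = 2000
    n_perm: int = 5000
    alpha: float = 0.05
    #: minimum fraction of non-rejected TMS pulses for a participant's CSP
    #: mean to be considered measurable; below it the participant is
    #: dropped alongside the behaviorally excluded
    min_valid_pulse_frac: float = 0.5
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _participant_record(data: ParticipantData, csp_config: CSPConfig) -> dict:
    summary = summarize_session(data.trials)
    cer = choice_error_rate(data.trials)
    exclusion = apply_exclusion_criteria(summary, cer)
    mvc_rms_uv = data.emg_params.mvc_rms * 1000.0
    feats = [extract_trial_features(tr, csp_config, mvc_rms_uv) for tr in data.sweeps]
    emg = summarize_participant(feats)
    return {
        "participant_id": data.participant_id,
        "ssrt_ms": summary.ssrt,
        "mean_ssd_ms": summary.mean_ssd,
        "go_rt_ms": summary.go_rt,
        "p_respond_signal": summary.p_respond_signal,
        "s_rt_ms": summary.s_rt,
        "miss": summary.miss,
        "acc": summary.acc,
        "choice_error_rate": cer,
        "csp_ms": emg["csp_ms"],
        "mep_amp_mv": emg["mep_amp_mv"],
        "mep_dur_ms": emg["mep_dur_ms"],
        "rmt_pct": data.rmt,
        "n_pulses_rejected": emg["n_rejected"],
        "n_pulses": emg["n_pulses"],
        "excluded": exclusion.excluded,
        "exclusion_flags": exclusion.flags,
    }


def _mean_sd(series: pd.Series) -> dict:
    return {"mean": float(series.mean()), "sd": float(series.std(ddof=1))}


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole synthetic study and return the report dict.

    Stages: generate -> per-participant behavior/EMG analysis -> exclusion
    screening -> correlation inference on the retained sample.  Any stage
    failure is re-raised with a stage tag.  Fully deterministic per seed.
    """
    try:
        population = generate_population(config.population, config.seed)
    except StopCSPError as exc:
        raise StopCSPError(f"[generate] {exc}") from exc
    log.info("generated %d participants", len(population))

    try:
        records = [_participant_record(p, config.csp_config) for p in population]
    except StopCSPError as exc:
        raise StopCSPError(f"[participant-analysis] {exc}") from exc
    table = pd.DataFrame.from_records(records)
    # a participant with too few valid pulses has no reliable CSP and
    # cannot enter inference; count them with the excluded
    valid_frac = 1.0 - table["n_pulses_rejected"] / table["n_pulses"]
    dropped = (
        table["excluded"]
        | table["csp_ms"].isna()
        | (valid_frac < config.min_valid_pulse_frac)
    )
    usable = table[~dropped]
    n_excluded = int(dropped.sum())
    log.info(
        "exclusions: %d of %d participants dropped; %d pulses rejected in total",
        n_excluded, len(table), int(table["n_pulses_rejected"].sum()),
    )

    if len(usable) < 4:
        raise StopCSPError("[inference] fewer than 4 analysable participants")
    y = usable["ssrt_ms"].to_numpy()
    predictors = {
        "csp_ms": usable["csp_ms"].to_numpy(),
        "rmt_pct": usable["rmt_pct"].to_numpy(),
        "mep_amp_mv": usable["mep_amp_mv"].to_numpy(),
        "mep_dur_ms": usable["mep_dur_ms"].to_numpy(),
    }
    try:
        family = pearson_family(predictors, y, alpha=config.alpha)
        skipped = skipped_pearson(
            predictors["csp_ms"], y, n_boot=config.n_boot, seed=config.seed
        )
        loocv = loocv_permutation_test(
            predictors["csp_ms"], y, n_perm=config.n_perm, seed=config.seed
        )
    except AnalysisError as exc:
        raise StopCSPError(f"[inference] {exc}") from exc
    log.info(
        "inference: skipped r=%.3f, loocv r=%.3f p=%.4f",
        skipped.r, loocv.r_pred_obs, loocv.p_perm,
    )

    group_cols = [
        "ssrt_ms", "mean_ssd_ms", "go_rt_ms", "p_respond_signal", "s_rt_ms",
        "miss", "acc", "csp_ms", "mep_amp_mv", "mep_dur_ms", "rmt_pct",
    ]
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_generated": len(table),
            "n_excluded": n_excluded,
            "n_analyzed": int(len(usable)),
        },
        "participants": records,
        "group_descriptives": {c: _mean_sd(usable[c]) for c in group_cols},
        "pearson": [
            {
                "predictor": c.name,
                "r": c.r,
                "n": c.n,
                "p": c.p,
                "alpha_adjusted": c.alpha_adjusted,
                "significant": c.significant,
            }
            for c in family
        ],
        "skipped_pearson": {
            "r": skipped.r,
            "n": skipped.n,
            "p": skipped.p,
            "ci": list(skipped.ci) if skipped.ci is not None else None,
            "outlier_indices": skipped.outlier_indices,
            "n_boot": skipped.n_boot,
        },
        "loocv": {
            "r_pred_obs": loocv.r_pred_obs,
            "p_perm": loocv.p_perm,
            "n_perm": loocv.n_perm,
            "predictions": [float(v) for v in loocv.predictions],
        },
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON serialisation of a run report."""

    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if is_dataclass(obj):
            return asdict(obj)
        raise TypeError(f"unserialisable {type(obj)!r}")

    def _clean(obj):
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [_clean(v) for v in obj]
        return obj

    return json.dumps(_clean(json.loads(json.dumps(report, default=_default))), indent=1)
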