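"""Stop-signal-task descriptives, integration-method SSRT, exclusions.

The stop signal reaction time (SSRT) is estimated with the integration
method: under the independent race model, the stop process finishes at the
p(respond|signal) quantile of the go RT distribution, so

    SSRT = Q_go(p(respond|signal)) - mean SSD

where the go RT set includes choice-error responses and every go omission
replaced by the maximum observed go RT.  The quantile is the nth smallest
go RT with n = round(p · N_go), rounded half away from zero and clamped to
[1, N_go].

Participant-level screening applies five criteria (strict inequalities):
(1) p(respond|signal) outside (0.40, 0.60); (2) go omissions > 25%;
(3) choice errors on go trials > 10%; (4) race-model violation (mean RT on
unsuccessful stop trials exceeding mean go RT); (5) SSRT below 50 ms
(which subsumes negative estimates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, EstimationError

__all__ = [
    "SSTSummary",
    "ExclusionReport",
    "summarize_session",
    "estimate_ssrt_integration",
    "apply_exclusion_criteria",
    "choice_error_rate",
]


@dataclass
class SSTSummary:
    """The seven session descriptives plus trial counts.

    ssrt, mean_ssd, go_rt, s_rt in ms; p_respond_signal, miss, acc are
    probabilities.  ``s_rt`` is NaN when no stop trial drew a response;
    ``ssrt_unreliable`` flags estimates at p(respond|signal) of exactly
    0 or 1, where the integration quantile degenerates.
    """

    ssrt: float
    mean_ssd: float
    go_rt: float
    p_respond_signal: float
    s_rt: float
    miss: float
    acc: float
    n_go: int
    n_stop: int
    ssrt_unreliable: bool = False


@dataclass
class ExclusionReport:
    flags: dict[str, bool] = field(default_factory=dict)
    excluded: bool = False
    values_checked: dict[str, float] = field(default_factory=dict)


def _experimental(trials: pd.DataFrame) -> pd.DataFrame:
    if "phase" in trials.columns:
        return trials[trials["phase"] == "experimental"]
    return trials


def _split(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    exp = _experimental(trials)
    go = exp[exp["trial_type"] == "go"]
    stop = exp[exp["trial_type"] == "stop"]
    if len(stop) == 0:
        raise AnalysisError("no experimental stop trials in table")
    if len(go) == 0:
        raise AnalysisError("no experimental go trials in table")
    return go, stop


def estimate_ssrt_integration(trials: pd.DataFrame) -> tuple[float, bool]:
    """Integration-method SSRT with go-omission replacement.

    Returns ``(ssrt_ms, unreliable)``; ``unreliable`` is True when
    p(respond|signal) is exactly 0 or 1.

    Raises
    ------
    EstimationError
        If no go trial carries a response (the go distribution is empty).
    """
    go, stop = _split(trials)
    responded_go = go["response"] != "none"
    if responded_go.sum() == 0:
        raise EstimationError("no responded go trials: go RT distribution is empty")
    rts = go["rt_ms"].to_numpy(dtype=float)
    max_rt = np.nanmax(rts[responded_go.to_numpy()])
    rts = np.where(responded_go.to_numpy(), rts, max_rt)  # omission replacement
    rts.sort()
    n_go = rts.size
    p_respond = float((stop["response"] != "none").mean())
    # nth smallest go RT, n = round-half-away-from-zero(p*N) clamped to [1, N]
    nth = int(min(max(math.floor(p_respond * n_go + 0.5), 1), n_go))
    mean_ssd = float(stop["ssd_ms"].mean())
    unreliable = p_respond in (0.0, 1.0)
    if unreliable:
        warnings.warn(
            "p(respond|signal) is 0 or 1; integration-method SSRT is unreliable",
            stacklevel=2,
        )
    return float(rts[nth - 1] - mean_ssd), unreliable


def summarize_session(trials: pd.DataFrame) -> SSTSummary:
    """Session descriptives over experimental trials only.

    Mean go RT is taken over all responded go trials, choice errors
    included; ``miss`` is the fraction of go trials with no response;
    ``acc`` the fraction of responded go trials in the correct direction;
    ``mean_ssd`` is averaged over all stop trials.
    """
    go, stop = _split(trials)
    responded_go = go[go["response"] != "none"]
    responded_stop = stop[stop["response"] != "none"]
    ssrt, unreliable = estimate_ssrt_integration(trials)
    return SSTSummary(
        ssrt=ssrt,
        mean_ssd=float(stop["ssd_ms"].mean()),
        go_rt=float(responded_go["rt_ms"].mean()) if len(responded_go) else float("nan"),
        p_respond_signal=float((stop["response"] != "none").mean()),
        s_rt=float(responded_stop["rt_ms"].mean()) if len(responded_stop) else float("nan"),
        miss=float((go["response"] == "none").mean()),
        acc=float((responded_go["correct"] == 1).mean()) if len(responded_go) else float("nan"),
        n_go=int(len(go)),
        n_stop=int(len(stop)),
        ssrt_unreliable=unreliable,
    )


def choice_error_rate(trials: pd.DataFrame) -> float:
    """Fraction of go trials answered in the wrong direction."""
    go, _ = _split(trials)
    responded = go[go["response"] != "none"]
    if len(go) == 0:
        return float("nan")
    wrong = (responded["response"] != responded["direction"]).sum()
    return float(wrong / len(go))


def apply_exclusion_criteria(summary: SSTSummary, choice_error_rate: float) -> ExclusionReport:
    """Screen one participant against the five outlier-rejection criteria.

    All comparisons are strict, so boundary values (e.g. p(respond|signal)
    exactly 0.40) are retained.  A missing s_rt (no responses on stop
    trials) cannot violate the race-model check.
    """
    c4 = bool(
        not (math.isnan(summary.s_rt) or math.isnan(summary.go_rt))
        and summary.s_rt > summary.go_rt
    )
    flags = {
        "c1": summary.p_respond_signal < 0.40 or summary.p_respond_signal > 0.60,
        "c2": summary.miss > 0.25,
        "c3": choice_error_rate > 0.10,
        "c4": c4,
        "c5": summary.ssrt < 50.0,
    }
    return ExclusionReport(
        flags=flags,
        excluded=any(flags.values()),
        values_checked={
            "p_respond_signal": summary.p_respond_signal,
            "miss": summary.miss,
            "choice_error_rate": choice_error_rate,
            "s_rt": summary.s_rt,
            "go_rt": summary.go_rt,
            "ssrt": summary.ssrt,
        },
    )
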