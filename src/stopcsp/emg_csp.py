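"""Cortical silent period (CSP) and motor evoked potential (MEP) extraction.

Surface EMG is recorded from a tonically contracted hand muscle (first
dorsal interosseous at ~30% of maximal voluntary contraction, MVC) while a
single suprathreshold TMS pulse is delivered over the contralateral motor
cortex.  The pulse evokes an MEP followed by a suppression of the voluntary
EMG — the cortical silent period, a marker of GABA_B-mediated intracortical
inhibition.  The *absolute* CSP is the interval from MEP offset to the
return of EMG activity to its pre-stimulus level.

All landmark detection operates on the smoothed rectified envelope of the
sweep, with thresholds expressed relative to pre-stimulus baseline
statistics (mean ± k·SD of the envelope), so every measure is invariant to
overall signal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DetectionError, ParameterError

__all__ = [
    "EMGTrace",
    "CSPConfig",
    "BaselineStats",
    "EMGTrialFeatures",
    "MVCResult",
    "compute_envelope",
    "baseline_stats",
    "compute_mvc",
    "detect_mep",
    "detect_csp",
    "extract_trial_features",
    "summarize_participant",
]

MVC_WINDOW_MS = 500.0  # peak-to-peak is taken per 500 ms window of each MVC trial


@dataclass
class EMGTrace:
    """One stimulus-locked EMG sweep.

    Parameters
    ----------
    samples : array of mV values
    fs : sampling rate in Hz
    stim_time : time of the TMS pulse within the sweep, ms
    metadata : free-form recording metadata (participant / pulse ids,
        stimulation intensity in % rMT, rMT in % maximum stimulator output).
        Carried through unchanged; never used by the detectors.
    """

    samples: np.ndarray
    fs: float
    stim_time: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not 0 <= self.stim_time <= self.duration_ms:
            raise ParameterError("stim_time must lie within the sweep")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.fs * 1000.0

    def times_ms(self) -> np.ndarray:
        """Sample times in ms from sweep start."""
        return np.arange(self.n_samples) / self.fs * 1000.0

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to the sweep)."""
        return int(np.clip(round(t_ms / 1000.0 * self.fs), 0, self.n_samples - 1))


@dataclass
class CSPConfig:
    """Detection settings for MEP/CSP landmark extraction.

    baseline_window : ms pair relative to the stimulus over which the
        pre-stimulus envelope mean/SD and raw RMS are computed.
    smoothing_window : width (ms) of the centred moving average applied to
        the rectified signal.
    k_sd : threshold multiplier; thresholds are baseline mean ± k_sd·SD.
    artifact_blank : ms after the stimulus excluded from MEP search.
    mep_search_window : ms pair after the stimulus in which the MEP onset
        must occur.
    offset_dwell : ms the envelope must stay below threshold for the MEP
        offset to be accepted (guards against the mid-MEP zero crossing).
    sustain : ms the envelope must stay at/above the return threshold for
        the silent period to be considered terminated.
    floor_frac : lower bound on the return threshold as a fraction of the
        baseline envelope mean.  The nominal threshold mean − k_sd·SD can
        fall to (or below) the residual level of the silenced signal when
        the SD estimate is large, which would terminate the silent period
        instantly; the relative floor keeps the threshold meaningful.
    contraction_band : admissible pre-stimulus RMS as a fraction of the MVC
        reference level; trials outside it are rejected.
    """

    baseline_window: tuple[float, float] = (-110.0, -10.0)
    smoothing_window: float = 5.0
    k_sd: float = 2.0
    artifact_blank: float = 5.0
    mep_search_window: tuple[float, float] = (10.0, 60.0)
    offset_dwell: float = 2.0
    sustain: float = 10.0
    floor_frac: float = 0.1
    contraction_band: tuple[float, float] = (0.2, 0.4)

    def __post_init__(self) -> None:
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ParameterError("baseline_window must be an increasing pair")
        if self.baseline_window[1] > 0:
            raise ParameterError("baseline_window must be entirely pre-stimulus")
        if self.smoothing_window <= 0:
            raise ParameterError("smoothing_window must be positive")
        if self.k_sd <= 0:
            raise ParameterError("k_sd must be positive")
        if self.mep_search_window[0] >= self.mep_search_window[1]:
            raise ParameterError("mep_search_window must be an increasing pair")
        if self.sustain < 0 or self.offset_dwell < 0 or self.artifact_blank < 0:
            raise ParameterError("durations must be non-negative")
        if not 0 <= self.floor_frac < 1:
            raise ParameterError("floor_frac must be in [0, 1)")
        lo, hi = self.contraction_band
        if not 0 <= lo < hi:
            raise ParameterError("contraction_band must be ordered and non-negative")


class BaselineStats(NamedTuple):
    mean: float  # envelope mean, mV
    sd: float  # envelope SD, mV
    rms: float  # raw-signal RMS, mV
    n_samples: int


@dataclass
class EMGTrialFeatures:
    """Per-pulse measures; NaN where a landmark could not be determined."""

    mep_amp_pp: float = np.nan  # peak-to-peak amplitude, mV
    mep_onset: float = np.nan  # ms within sweep
    mep_offset: float = np.nan
    mep_duration: float = np.nan  # ms
    csp_end: float = np.nan  # ms within sweep
    csp_abs: float = np.nan  # absolute CSP = csp_end - mep_offset, ms
    baseline_mean: float = np.nan
    baseline_sd: float = np.nan
    prestim_rms: float = np.nan
    rejected: bool = False
    reason: str = ""


@dataclass
class MVCResult:
    """Maximal-voluntary-contraction reference level.

    ``mvc`` is the mean peak-to-peak amplitude (µV) across trials, each
    trial summarised as the mean peak-to-peak over its 500 ms windows.
    ``rms`` is the corresponding mean raw RMS (µV), the quantity against
    which tonic pre-stimulus contraction is normalised.
    """

    mvc: float
    per_trial: list[float]
    rms: float


def _smoothing_size(fs: float, smoothing_window: float) -> int:
    return max(1, int(round(smoothing_window / 1000.0 * fs)))


def compute_envelope(trace: EMGTrace, config: CSPConfig) -> np.ndarray:
    """Rectified, centred-moving-average envelope of the sweep (mV)."""
    size = _smoothing_size(trace.fs, config.smoothing_window)
    if size > trace.n_samples:
        raise ParameterError(
            f"smoothing window ({size} samples) longer than sweep ({trace.n_samples})"
        )
    return uniform_filter1d(np.abs(trace.samples), size=size, mode="nearest")


def baseline_stats(
    trace: EMGTrace, config: CSPConfig, envelope: np.ndarray | None = None
) -> BaselineStats:
    """Pre-stimulus envelope mean/SD and raw RMS within ``baseline_window``."""
    if envelope is None:
        envelope = compute_envelope(trace, config)
    t0 = trace.stim_time + config.baseline_window[0]
    t1 = trace.stim_time + config.baseline_window[1]
    if t0 < 0:
        raise ParameterError("baseline window starts before the sweep")
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    if i1 <= i0:
        raise ParameterError("baseline window is empty")
    seg_env = envelope[i0:i1]
    seg_raw = trace.samples[i0:i1]
    return BaselineStats(
        mean=float(seg_env.mean()),
        sd=float(seg_env.std()),
        rms=float(np.sqrt(np.mean(seg_raw**2))),
        n_samples=i1 - i0,
    )


def compute_mvc(traces: Sequence[EMGTrace]) -> MVCResult:
    """MVC reference from maximal-contraction trials.

    Each trial is split into non-overlapping 500 ms windows; the
    peak-to-peak amplitude is taken per window and averaged within the
    trial; the MVC is the mean across trials, reported in µV.
    """
    if len(traces) == 0:
        raise ParameterError("compute_mvc requires at least one trace")
    per_trial: list[float] = []
    per_trial_rms: list[float] = []
    for k, tr in enumerate(traces):
        win = int(round(MVC_WINDOW_MS / 1000.0 * tr.fs))
        n_win = tr.n_samples // win
        if n_win == 0:
            raise ParameterError(f"MVC trial {k} shorter than one {MVC_WINDOW_MS:g} ms window")
        segs = tr.samples[: n_win * win].reshape(n_win, win)
        p2p = segs.max(axis=1) - segs.min(axis=1)
        per_trial.append(float(p2p.mean()) * 1000.0)  # mV -> µV
        per_trial_rms.append(float(np.sqrt(np.mean(tr.samples**2))) * 1000.0)
    return MVCResult(
        mvc=float(np.mean(per_trial)),
        per_trial=per_trial,
        rms=float(np.mean(per_trial_rms)),
    )


def _first_sustained(above: np.ndarray, start: int, n_required: int) -> int | None:
    """First index >= start where ``above`` holds for ``n_required`` samples."""
    if n_required <= 1:
        idx = np.flatnonzero(above[start:])
        return int(idx[0]) + start if idx.size else None
    a = above[start:].astype(np.int32)
    if a.size < n_required:
        return None
    # windowed sum over a sliding window of length n_required
    c = np.concatenate(([0], np.cumsum(a)))
    sums = c[n_required:] - c[:-n_required]
    hits = np.flatnonzero(sums == n_required)
    return int(hits[0]) + start if hits.size else None


def detect_mep(
    trace: EMGTrace,
    config: CSPConfig,
    envelope: np.ndarray | None = None,
    baseline: BaselineStats | None = None,
) -> tuple[float, float, float, float]:
    """Locate the MEP and measure it.

    Returns ``(onset_ms, offset_ms, amp_pp_mv, duration_ms)``.  Onset is the
    first time within the search window (after the artifact blank) at which
    the envelope exceeds baseline mean + k_sd·SD; offset is the first time
    after the envelope peak at which it stays below that threshold for
    ``offset_dwell`` ms.  Peak-to-peak amplitude is taken on the raw signal
    between onset and offset.

    Raises
    ------
    DetectionError
        If no suprathreshold excursion exists in the search window, or the
        envelope never returns below threshold ("no MEP detected").
    """
    if envelope is None:
        envelope = compute_envelope(trace, config)
    if baseline is None:
        baseline = baseline_stats(trace, config, envelope)
    thr = baseline.mean + config.k_sd * baseline.sd
    t_lo = trace.stim_time + max(config.artifact_blank, config.mep_search_window[0])
    t_hi = trace.stim_time + config.mep_search_window[1]
    i_lo, i_hi = trace.index_at(t_lo), trace.index_at(t_hi)
    win = envelope[i_lo:i_hi]
    over = np.flatnonzero(win > thr)
    if over.size == 0:
        raise DetectionError("no MEP detected: envelope never exceeds threshold in search window")
    onset_idx = i_lo + int(over[0])
    # envelope peak within a generous post-onset span (MEP fully contained)
    peak_hi = min(trace.n_samples, onset_idx + int(round(0.100 * trace.fs)))
    peak_idx = onset_idx + int(np.argmax(envelope[onset_idx:peak_hi]))
    dwell = max(1, int(round(config.offset_dwell / 1000.0 * trace.fs)))
    off_idx = _first_sustained(envelope <= thr, peak_idx, dwell)
    if off_idx is None:
        raise DetectionError("no MEP detected: envelope never returns below threshold")
    onset_ms = onset_idx / trace.fs * 1000.0
    offset_ms = off_idx / trace.fs * 1000.0
    seg = trace.samples[onset_idx : off_idx + 1]
    amp_pp = float(seg.max() - seg.min())
    return onset_ms, offset_ms, amp_pp, offset_ms - onset_ms


def detect_csp(
    trace: EMGTrace,
    config: CSPConfig,
    mep_offset: float,
    envelope: np.ndarray | None = None,
    baseline: BaselineStats | None = None,
) -> tuple[float, float]:
    """End of the silent period after ``mep_offset`` (ms within sweep).

    The silent period terminates at the first time >= mep_offset at which
    the envelope is at or above baseline mean − k_sd·SD (never below
    ``floor_frac`` × baseline mean, and never negative) continuously for
    ``sustain`` ms.  Returns ``(csp_end_ms, csp_abs_ms)``.

    Raises
    ------
    DetectionError
        If EMG activity does not return before the end of the sweep
        ("unterminated CSP").
    """
    if envelope is None:
        envelope = compute_envelope(trace, config)
    if baseline is None:
        baseline = baseline_stats(trace, config, envelope)
    thr = max(baseline.mean - config.k_sd * baseline.sd, config.floor_frac * baseline.mean, 0.0)
    start = trace.index_at(mep_offset)
    n_req = max(1, int(round(config.sustain / 1000.0 * trace.fs)))
    idx = _first_sustained(envelope >= thr, start, n_req)
    if idx is None:
        raise DetectionError("unterminated CSP: EMG does not return to baseline before sweep end")
    csp_end = idx / trace.fs * 1000.0
    return csp_end, csp_end - mep_offset


def extract_trial_features(
    trace: EMGTrace, config: CSPConfig, mvc: MVCResult | float
) -> EMGTrialFeatures:
    """Full per-pulse feature extraction with non-fatal rejection.

    ``mvc`` is either a :class:`MVCResult` or the MVC RMS reference in µV.
    The trial is rejected (never raising) when the pre-stimulus contraction
    falls outside ``contraction_band`` × MVC, or when either detector fails.
    """
    mvc_rms_uv = mvc.rms if isinstance(mvc, MVCResult) else float(mvc)
    if mvc_rms_uv <= 0:
        raise ParameterError("MVC reference must be positive")
    envelope = compute_envelope(trace, config)
    base = baseline_stats(trace, config, envelope)
    feats = EMGTrialFeatures(
        baseline_mean=base.mean, baseline_sd=base.sd, prestim_rms=base.rms
    )
    ratio = base.rms * 1000.0 / mvc_rms_uv
    lo, hi = config.contraction_band
    if not lo <= ratio <= hi:
        feats.rejected = True
        feats.reason = "contraction out of band"
        return feats
    try:
        onset, offset, amp, dur = detect_mep(trace, config, envelope, base)
    except DetectionError:
        feats.rejected = True
        feats.reason = "no MEP detected"
        return feats
    feats.mep_onset, feats.mep_offset = onset, offset
    feats.mep_amp_pp, feats.mep_duration = amp, dur
    try:
        csp_end, csp_abs = detect_csp(trace, config, offset, envelope, base)
    except DetectionError:
        feats.rejected = True
        feats.reason = "unterminated CSP"
        return feats
    feats.csp_end, feats.csp_abs = csp_end, csp_abs
    return feats


def summarize_participant(features: Sequence[EMGTrialFeatures]) -> dict:
    """Participant-level means over non-rejected pulses.

    Returns mean CSP duration, MEP amplitude and duration plus rejection
    bookkeeping; order of the input pulses is irrelevant.
    """
    kept = [f for f in features if not f.rejected]
    out = {
        "n_pulses": len(features),
        "n_rejected": len(features) - len(kept),
        "csp_ms": np.nan,
        "mep_amp_mv": np.nan,
        "mep_dur_ms": np.nan,
    }
    if kept:
        out["csp_ms"] = float(np.mean([f.csp_abs for f in kept]))
        out["mep_amp_mv"] = float(np.mean([f.mep_amp_pp for f in kept]))
        out["mep_dur_ms"] = float(np.mean([f.mep_duration for f in kept]))
    return out
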