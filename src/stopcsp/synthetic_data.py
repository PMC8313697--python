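"""Synthetic stop-signal-task sessions and TMS-EMG sweeps with known truth.

The behavioral generator implements the independent horse-race model of
response inhibition: on every trial a go process (ex-Gaussian finish time)
races a stop process (truncated-Gaussian latency, started at the stop
signal delay); a response is emitted on a stop trial iff the go process
finishes first.  The stop signal delay (SSD) follows the standard 1-up
1-down 50 ms staircase, which drives the probability of responding on a
stop trial towards 0.5.

The EMG synthesizer produces a stimulus-locked sweep of band-limited
Gaussian tonic activity with a deterministic biphasic MEP inserted at a
fixed latency, followed by a near-complete suppression of the tonic signal
(the silent period) and a linear recovery ramp.  Ground truth for every
injected landmark is returned alongside, enabling parameter-recovery tests
of the detectors.

The population generator couples the per-participant true CSP duration and
the true stop-process latency through a shared latent trait, so that the
expected correlation between the two equals ``coupling_rho`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emg_csp import EMGTrace
from .errors import ParameterError

__all__ = [
    "SessionDesign",
    "ParticipantBehaviorModel",
    "SyntheticEMGParams",
    "PopulationParams",
    "GroundTruth",
    "ParticipantData",
    "staircase_update",
    "simulate_session",
    "synthesize_emg_trial",
    "generate_population",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "block",
    "trial",
    "phase",
    "trial_type",
    "direction",
    "ssd_ms",
    "response",
    "rt_ms",
    "correct",
]


@dataclass
class SessionDesign:
    """Structure of one stop-signal-task session.

    Defaults give a 32-trial practice block (8 stop) followed by five
    96-trial experimental blocks (24 stop each, i.e. 25% stop trials), a
    1000 ms response deadline, and a staircased SSD starting at 250 ms
    moving in 50 ms steps.  ``iti`` is carried as metadata only.
    """

    n_practice_trials: int = 32
    n_practice_stop: int = 8
    n_blocks: int = 5
    trials_per_block: int = 96
    stop_per_block: int = 24
    max_rt: float = 1000.0
    ssd_start: float = 250.0
    ssd_step: float = 50.0
    ssd_bounds: tuple[float, float] = (0.0, 900.0)
    iti: float = 4000.0

    def __post_init__(self) -> None:
        if self.stop_per_block > self.trials_per_block:
            raise ParameterError("stop_per_block must not exceed trials_per_block")
        if self.n_practice_stop > self.n_practice_trials:
            raise ParameterError("n_practice_stop must not exceed n_practice_trials")
        if not self.ssd_bounds[0] <= self.ssd_start <= self.ssd_bounds[1]:
            raise ParameterError("ssd_start must lie within ssd_bounds")
        if self.ssd_step <= 0:
            raise ParameterError("ssd_step must be positive")
        if self.max_rt <= 0:
            raise ParameterError("max_rt must be positive")

    @property
    def n_experimental_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_experimental_stop(self) -> int:
        return self.n_blocks * self.stop_per_block


@dataclass
class ParticipantBehaviorModel:
    """Latent race-model parameters for one participant.

    The go finish time is ex-Gaussian with mean ``go_mu + go_tau`` and SD
    ``sqrt(go_sigma² + go_tau²)``; defaults give ~546 ± 105 ms.  The stop
    latency is Gaussian truncated at zero (mean 215 ms).  ``p_omission``
    models trials on which the go process fails entirely; responses slower
    than the deadline also count as omissions.  ``p_trigger_failure`` is
    the probability that the stop process never starts on a stop trial.
    """

    go_mu: float = 456.0
    go_sigma: float = 54.0
    go_tau: float = 90.0
    stop_mu: float = 215.0
    stop_sigma: float = 20.0
    p_omission: float = 0.02
    p_choice_error: float = 0.004
    p_trigger_failure: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_omission", "p_choice_error", "p_trigger_failure"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.go_sigma < 0 or self.stop_sigma < 0 or self.go_tau < 0:
            raise ParameterError("scale parameters must be non-negative")


@dataclass
class SyntheticEMGParams:
    """Construction parameters for one synthetic TMS-EMG sweep.

    Amplitudes are in mV; all times in ms.  ``tonic_rms`` is the RMS of the
    band-limited tonic EMG (30% MVC by default, so the MVC reference RMS is
    ``tonic_rms / 0.3``).  ``silence_floor`` is the multiplicative gain of
    the tonic signal during the silent period.
    """

    fs: float = 8000.0
    duration: float = 600.0
    stim_time: float = 200.0
    tonic_rms: float = 0.05
    mvc_rms: float | None = None  # defaults to tonic_rms / 0.3
    band: tuple[float, float] = (20.0, 250.0)
    mep_amp_pp: float = 0.49
    mep_duration: float = 35.0
    mep_latency: float = 22.0
    csp_duration: float = 106.0
    silence_floor: float = 0.02
    recovery_ramp: float = 10.0

    def __post_init__(self) -> None:
        if self.mvc_rms is None:
            self.mvc_rms = self.tonic_rms / 0.3
        if self.fs <= 2 * self.band[1]:
            raise ParameterError("fs must exceed twice the upper band edge")
        for name in ("duration", "mep_duration", "csp_duration", "recovery_ramp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.stim_time + self.mep_latency + self.mep_duration + self.csp_duration >= self.duration:
            raise ParameterError("MEP + silent period must end before the sweep does")
        if self.silence_floor < 0:
            raise ParameterError("silence_floor must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs / 1000.0))


@dataclass
class PopulationParams:
    """Study-level generator settings: 27 participants, 20 TMS pulses each,
    CSP 106 ± 26 ms and stop latency 215 ± 21 ms across participants, with
    a tunable latent correlation ``coupling_rho`` between the two.
    ``go_mu_sd`` is the between-subject SD of the ex-Gaussian go location,
    which reproduces the between-subject spread of mean go RT (~105 ms)
    and, through staircase tracking, of mean SSD."""

    n_participants: int = 27
    csp_mean: float = 106.0
    csp_sd: float = 26.0
    stoplat_mean: float = 215.0
    stoplat_sd: float = 21.0
    coupling_rho: float = 0.6
    pulses_per_participant: int = 20
    csp_pulse_jitter_sd: float = 8.0
    go_mu_sd: float = 100.0
    rmt_mean: float = 55.0
    rmt_sd: float = 4.0
    rmt_range: tuple[float, float] = (48.0, 61.0)
    mep_amp_mean: float = 0.49
    mep_amp_sd: float = 0.29
    mep_dur_mean: float = 35.0
    mep_dur_sd: float = 2.0
    behavior_defaults: ParticipantBehaviorModel = field(default_factory=ParticipantBehaviorModel)
    design: SessionDesign = field(default_factory=SessionDesign)
    emg_defaults: SyntheticEMGParams = field(default_factory=SyntheticEMGParams)

    def __post_init__(self) -> None:
        if abs(self.coupling_rho) > 1:
            raise ParameterError("coupling_rho must lie in [-1, 1]")
        if self.n_participants < 3:
            raise ParameterError("n_participants must be at least 3 (correlation undefined below)")
        if self.csp_sd < 0 or self.stoplat_sd < 0:
            raise ParameterError("population SDs must be non-negative")


@dataclass
class GroundTruth:
    """Injected quantities the detectors and estimators should recover."""

    true_csp: float | np.ndarray | None = None  # ms (per pulse)
    true_mep_onset: float | None = None  # ms within sweep
    true_mep_offset: float | None = None
    true_stop_latency_mean: float | None = None  # ms
    latent_trait: float | None = None  # z-score


@dataclass
class ParticipantData:
    """Everything generated for one synthetic participant."""

    participant_id: str
    trials: pd.DataFrame
    sweeps: list[EMGTrace]
    pulse_truths: list[GroundTruth]
    truth: GroundTruth
    behavior: ParticipantBehaviorModel
    emg_params: SyntheticEMGParams
    rmt: float
    mep_amp: float
    mep_dur: float


def staircase_update(ssd: float, responded_on_stop: bool, design: SessionDesign) -> float:
    """One step of the 1-up 1-down SSD staircase.

    The SSD increases by one step after a successful stop (no response,
    stopping made harder) and decreases after an unsuccessful stop
    (response emitted, stopping made easier), clamped to ``ssd_bounds``.
    """
    lo, hi = design.ssd_bounds
    if not lo <= ssd <= hi:
        raise ParameterError(f"ssd {ssd} outside bounds [{lo}, {hi}]")
    nxt = ssd - design.ssd_step if responded_on_stop else ssd + design.ssd_step
    return float(min(max(nxt, lo), hi))


def _sample_stop_latency(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Gaussian stop latency truncated at zero (rejection sampling)."""
    if sigma == 0:
        return max(mu, 0.0)
    while True:
        s = rng.normal(mu, sigma)
        if s >= 0:
            return s


def _block_plan(n_trials: int, n_stop: int, rng: np.random.Generator) -> np.ndarray:
    is_stop = np.zeros(n_trials, dtype=bool)
    is_stop[rng.choice(n_trials, size=n_stop, replace=False)] = True
    return is_stop


def simulate_session(
    design: SessionDesign,
    behavior: ParticipantBehaviorModel,
    seed: int | np.random.SeedSequence,
    participant_id: str = "P00",
) -> pd.DataFrame:
    """Simulate one full session (practice + experimental blocks).

    Returns a trial table with one row per trial.  Stop-trial positions are
    randomised within each block at the design's stop fraction; the SSD
    staircase runs continuously from the first practice trial onward.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    blocks: list[tuple[int, str, int, int]] = []
    if design.n_practice_trials > 0:
        blocks.append((0, "practice", design.n_practice_trials, design.n_practice_stop))
    for b in range(1, design.n_blocks + 1):
        blocks.append((b, "experimental", design.trials_per_block, design.stop_per_block))

    ssd = float(design.ssd_start)
    rows: list[tuple] = []
    for block_idx, phase, n_trials, n_stop in blocks:
        is_stop = _block_plan(n_trials, n_stop, rng)
        for t in range(n_trials):
            direction = "left" if rng.random() < 0.5 else "right"
            t_go = rng.normal(behavior.go_mu, behavior.go_sigma) + rng.exponential(behavior.go_tau)
            omitted = rng.random() < behavior.p_omission
            choice_error = rng.random() < behavior.p_choice_error
            resp_dir = ("right" if direction == "left" else "left") if choice_error else direction
            if is_stop[t]:
                trig_fail = rng.random() < behavior.p_trigger_failure
                s_lat = _sample_stop_latency(rng, behavior.stop_mu, behavior.stop_sigma)
                go_wins = trig_fail or (t_go < ssd + s_lat)
                responded = go_wins and (t_go <= design.max_rt) and not omitted
                rows.append(
                    (
                        participant_id, block_idx, t, phase, "stop", direction, ssd,
                        resp_dir if responded else "none",
                        t_go if responded else np.nan,
                        0 if responded else 1,
                    )
                )
                ssd = staircase_update(ssd, responded, design)
            else:
                responded = (t_go <= design.max_rt) and not omitted
                correct = int(responded and resp_dir == direction)
                rows.append(
                    (
                        participant_id, block_idx, t, phase, "go", direction, np.nan,
                        resp_dir if responded else "none",
                        t_go if responded else np.nan,
                        correct,
                    )
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@lru_cache(maxsize=8)
def _bandpass_sos(fs: float, band: tuple[float, float]):
    return sps.butter(4, band, btype="band", fs=fs, output="sos")


def _tonic_noise(rng: np.random.Generator, n: int, fs: float, band, rms: float) -> np.ndarray:
    # pad before filtering and crop the interior: the zero-phase filter's
    # edge transients would otherwise make the sweep non-stationary
    pad = int(round(0.1 * fs))
    x = sps.sosfiltfilt(_bandpass_sos(fs, band), rng.standard_normal(n + 2 * pad))
    x = x[pad : pad + n]
    s = x.std()
    return x * (rms / s) if s > 0 else x


def mep_waveform(n_samples: int, amp_pp: float) -> np.ndarray:
    """Deterministic biphasic MEP: a positive then a larger negative lobe.

    Each lobe is a half-sine raised to the power 0.5, which gives the
    compact support, fast rise/decay at the edges and brisk central zero
    crossing seen in real compound muscle potentials; peak-to-peak
    amplitude is normalised to ``amp_pp`` exactly.
    """
    if n_samples < 4:
        return np.zeros(n_samples)
    n1 = int(round(0.45 * n_samples))
    n2 = n_samples - n1
    v1 = np.linspace(0.0, 1.0, n1, endpoint=False)
    v2 = np.linspace(0.0, 1.0, n2, endpoint=True)
    lobe = lambda v: np.sin(np.pi * v) ** 0.5  # noqa: E731
    w = np.concatenate([0.45 * lobe(v1), -0.55 * lobe(v2)])
    span = w.max() - w.min()
    return w * (amp_pp / span)


def synthesize_emg_trial(
    params: SyntheticEMGParams,
    seed: int | np.random.SeedSequence,
    metadata: dict | None = None,
) -> tuple[EMGTrace, GroundTruth]:
    """One stimulus-locked sweep plus its injected ground truth.

    Construction: band-limited Gaussian tonic EMG scaled to ``tonic_rms``;
    a gain profile that drops to ``silence_floor`` from MEP onset (the
    compound potential interrupts voluntary drive rather than summing with
    it) until exactly ``csp_duration`` ms after the MEP offset, then ramps
    linearly back over ``recovery_ramp`` ms; the deterministic MEP
    waveform added on top.
    """
    rng = np.random.default_rng(seed)
    n = params.n_samples
    fs = params.fs
    noise = _tonic_noise(rng, n, fs, params.band, params.tonic_rms)

    ms = lambda t: int(round(t / 1000.0 * fs))  # noqa: E731
    mep_on = params.stim_time + params.mep_latency
    mep_off = mep_on + params.mep_duration
    csp_end = mep_off + params.csp_duration

    gain = np.ones(n)
    i_off, i_end = ms(mep_off), ms(csp_end)
    gain[ms(mep_on):i_end] = params.silence_floor
    n_ramp = ms(params.recovery_ramp)
    ramp_stop = min(i_end + n_ramp, n)
    if ramp_stop > i_end:
        gain[i_end:ramp_stop] = np.linspace(
            params.silence_floor, 1.0, ramp_stop - i_end, endpoint=False
        )
    samples = noise * gain
    i_on = ms(mep_on)
    n_mep = ms(mep_off) - i_on
    samples[i_on : i_on + n_mep] += mep_waveform(n_mep, params.mep_amp_pp)

    trace = EMGTrace(
        samples=samples, fs=fs, stim_time=params.stim_time, metadata=dict(metadata or {})
    )
    truth = GroundTruth(
        true_csp=params.csp_duration, true_mep_onset=mep_on, true_mep_offset=mep_off
    )
    return trace, truth


def sample_latent_traits(
    pop: PopulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (latent z, true CSP, true stop latency) for every participant.

    Both observables load on a shared standard-normal trait z with loading
    λ = sqrt(|coupling_rho|) (the sign of the coupling applied to the stop
    side), plus independent residuals, so corr(CSP, stop latency) equals
    ``coupling_rho`` in expectation.
    """
    n = pop.n_participants
    lam = math.sqrt(abs(pop.coupling_rho))
    sgn = 1.0 if pop.coupling_rho >= 0 else -1.0
    resid = math.sqrt(1.0 - lam**2)
    z = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    u = rng.standard_normal(n)
    true_csp = pop.csp_mean + pop.csp_sd * (lam * z + resid * eps)
    true_stop = pop.stoplat_mean + pop.stoplat_sd * (sgn * lam * z + resid * u)
    return z, np.maximum(true_csp, 0.0), np.maximum(true_stop, 0.0)


def generate_population(
    pop: PopulationParams, seed: int | np.random.SeedSequence
) -> list[ParticipantData]:
    """Generate the full synthetic study: one session plus a block of TMS
    pulses per participant, coupled through the latent trait.

    The master seed is split deterministically per participant, so any
    participant's data can be regenerated independently of the others.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    top_rng = np.random.default_rng(master.spawn(1)[0])
    z, true_csp, true_stop = sample_latent_traits(pop, top_rng)
    rmt = np.clip(
        top_rng.normal(pop.rmt_mean, pop.rmt_sd, pop.n_participants), *pop.rmt_range
    )
    mep_amp = np.clip(
        top_rng.normal(pop.mep_amp_mean, pop.mep_amp_sd, pop.n_participants), 0.05, None
    )
    mep_dur = np.clip(
        top_rng.normal(pop.mep_dur_mean, pop.mep_dur_sd, pop.n_participants), 5.0, None
    )
    go_mu = pop.behavior_defaults.go_mu + pop.go_mu_sd * top_rng.standard_normal(
        pop.n_participants
    )

    out: list[ParticipantData] = []
    child_seeds = master.spawn(pop.n_participants)
    for i in range(pop.n_participants):
        pid = f"P{i:02d}"
        kids = child_seeds[i].spawn(pop.pulses_per_participant + 2)
        behavior = replace(
            pop.behavior_defaults, stop_mu=float(true_stop[i]), go_mu=float(go_mu[i])
        )
        trials = simulate_session(pop.design, behavior, kids[0], participant_id=pid)
        pulse_rng = np.random.default_rng(kids[1])
        sweeps: list[EMGTrace] = []
        pulse_truths: list[GroundTruth] = []
        for k in range(pop.pulses_per_participant):
            pulse_csp = max(
                float(true_csp[i] + pulse_rng.normal(0.0, pop.csp_pulse_jitter_sd)), 0.0
            )
            pulse_amp = float(mep_amp[i] * max(pulse_rng.normal(1.0, 0.05), 0.2))
            emg_params = replace(
                pop.emg_defaults,
                csp_duration=pulse_csp,
                mep_amp_pp=pulse_amp,
                mep_duration=float(mep_dur[i]),
            )
            meta = {
                "participant_id": pid,
                "pulse_index": k,
                "stim_intensity_pct_rmt": 120.0,
                "rmt_pct_mso": float(rmt[i]),
            }
            trace, truth = synthesize_emg_trial(emg_params, kids[2 + k], metadata=meta)
            sweeps.append(trace)
            pulse_truths.append(truth)
        out.append(
            ParticipantData(
                participant_id=pid,
                trials=trials,
                sweeps=sweeps,
                pulse_truths=pulse_truths,
                truth=GroundTruth(
                    true_csp=float(true_csp[i]),
                    true_stop_latency_mean=float(true_stop[i]),
                    latent_trait=float(z[i]),
                ),
                behavior=behavior,
                emg_params=pop.emg_defaults,
                rmt=float(rmt[i]),
                mep_amp=float(mep_amp[i]),
                mep_dur=float(mep_dur[i]),
            )
        )
    return out
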