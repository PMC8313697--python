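"""EMG feature extraction: envelope, baseline, MVC, MEP and silent-period
detectors, with brute-force oracles and ground-truth recovery."""

import numpy as np
import pytest

from stopcsp import (
    CSPConfig,
    DetectionError,
    EMGTrace,
    ParameterError,
    SyntheticEMGParams,
    baseline_stats,
    compute_envelope,
    compute_mvc,
    detect_csp,
    detect_mep,
    extract_trial_features,
    summarize_participant,
    synthesize_emg_trial,
)


def csp_end_oracle(envelope, fs, thr, start_idx, sustain_ms):
    """Sample-by-sample scan: first index >= start where the envelope stays
    at/above thr for sustain_ms.  Independent of the vectorised detector."""
    n_req = max(1, int(round(sustain_ms / 1000.0 * fs)))
    above = envelope >= thr
    for i in range(start_idx, len(envelope) - n_req + 1):
        ok = True
        for j in range(i, i + n_req):
            if not above[j]:
                ok = False
                break
        if ok:
            return i
    return None


class TestEnvelope:
    def test_constant_negative_signal(self, csp_config):
        trace = EMGTrace(samples=np.full(4000, -0.3), fs=8000, stim_time=200)
        env = compute_envelope(trace, csp_config)
        assert np.allclose(env, 0.3)

    def test_zero_signal(self, csp_config):
        trace = EMGTrace(samples=np.zeros(4000), fs=8000, stim_time=100)
        assert np.all(compute_envelope(trace, csp_config) == 0)

    def test_rectified_sine_mean_level(self, csp_config):
        """A rectified fast sine averages to 2/pi of its amplitude."""
        t = np.arange(8000) / 8000
        # frequency incommensurate with fs so samples cover all phases
        trace = EMGTrace(samples=np.sin(2 * np.pi * 773 * t), fs=8000, stim_time=500)
        env = compute_envelope(trace, csp_config)
        assert env[100:-100].mean() == pytest.approx(2 / np.pi, rel=0.02)

    def test_window_longer_than_sweep_rejected(self):
        trace = EMGTrace(samples=np.ones(10), fs=8000, stim_time=0.5)
        with pytest.raises(ParameterError):
            compute_envelope(trace, CSPConfig(smoothing_window=50.0))


class TestBaseline:
    def test_constant_signal(self, csp_config):
        trace = EMGTrace(samples=np.full(4000, 0.2), fs=8000, stim_time=300)
        stats = baseline_stats(trace, csp_config)
        assert stats.mean == pytest.approx(0.2)
        assert stats.sd == pytest.approx(0.0)
        assert stats.rms == pytest.approx(0.2)

    def test_sample_count(self, csp_config):
        trace = EMGTrace(samples=np.zeros(4800), fs=8000, stim_time=300)
        assert baseline_stats(trace, csp_config).n_samples == 800  # 100 ms at 8 kHz

    def test_synthetic_tonic_level(self, emg_params, csp_config):
        rms = [
            baseline_stats(synthesize_emg_trial(emg_params, seed=s)[0], csp_config).rms
            for s in range(20)
        ]
        assert np.mean(rms) == pytest.approx(0.05, rel=0.10)


class TestMVC:
    def test_hand_computed_sinusoids(self):
        t = np.arange(24000) / 8000
        traces = [
            EMGTrace(samples=amp * np.sin(2 * np.pi * 50 * t), fs=8000, stim_time=0)
            for amp in (0.050, 0.060, 0.070)  # mV == 50/60/70 µV amplitude
        ]
        res = compute_mvc(traces)
        assert res.per_trial == pytest.approx([100, 120, 140], rel=1e-3)
        assert res.mvc == pytest.approx(120, rel=1e-3)

    def test_zero_trace(self):
        trace = EMGTrace(samples=np.zeros(8000), fs=8000, stim_time=0)
        assert compute_mvc([trace]).mvc == 0.0

    def test_short_trace_rejected(self):
        trace = EMGTrace(samples=np.zeros(1000), fs=8000, stim_time=0)
        with pytest.raises(ParameterError):
            compute_mvc([trace])


class TestDetectMEP:
    def test_amplitude_and_duration_recovery(self, emg_params, csp_config):
        amps, durs = [], []
        for s in range(50):
            trace, _ = synthesize_emg_trial(emg_params, seed=s)
            _, _, amp, dur = detect_mep(trace, csp_config)
            amps.append(amp)
            durs.append(dur)
        assert np.mean(amps) == pytest.approx(0.49, rel=0.05)
        assert np.mean(durs) == pytest.approx(35, abs=3)

    def test_no_mep_is_an_error(self, csp_config):
        params = SyntheticEMGParams(mep_amp_pp=0.0)
        trace, _ = synthesize_emg_trial(params, seed=1)
        with pytest.raises(DetectionError, match="no MEP"):
            detect_mep(trace, csp_config)

    def test_onset_offset_bracket_truth(self, emg_params, csp_config):
        trace, truth = synthesize_emg_trial(emg_params, seed=4)
        onset, offset, _, _ = detect_mep(trace, csp_config)
        assert onset == pytest.approx(truth.true_mep_onset, abs=4)
        assert offset == pytest.approx(truth.true_mep_offset, abs=4)


class TestDetectCSP:
    def test_injected_silence_recovered(self, csp_config):
        params = SyntheticEMGParams(silence_floor=0.0, csp_duration=120.0)
        trace, truth = synthesize_emg_trial(params, seed=6)
        _, offset, _, _ = detect_mep(trace, csp_config)
        _, csp_abs = detect_csp(trace, csp_config, offset)
        detected_end = offset + csp_abs
        assert detected_end == pytest.approx(
            truth.true_mep_offset + 120.0, abs=csp_config.smoothing_window
        )

    def test_matches_bruteforce_scan_oracle(self, emg_params, csp_config):
        """Exact sample-index agreement with the per-sample oracle scan."""
        for s in range(30):
            trace, _ = synthesize_emg_trial(emg_params, seed=200 + s)
            env = compute_envelope(trace, csp_config)
            base = baseline_stats(trace, csp_config, env)
            _, offset, _, _ = detect_mep(trace, csp_config, env, base)
            csp_end, _ = detect_csp(trace, csp_config, offset, env, base)
            thr = max(
                base.mean - csp_config.k_sd * base.sd,
                csp_config.floor_frac * base.mean,
                0.0,
            )
            oracle_idx = csp_end_oracle(
                env, trace.fs, thr, trace.index_at(offset), csp_config.sustain
            )
            assert trace.index_at(csp_end) == oracle_idx

    def test_unterminated_csp_is_an_error(self, csp_config):
        params = SyntheticEMGParams(duration=400.0, stim_time=150.0, csp_duration=150.0)
        trace, _ = synthesize_emg_trial(params, seed=3)
        # chop the sweep before the silent period can end (~357 ms)
        short = EMGTrace(
            samples=trace.samples[: trace.index_at(330.0)],
            fs=trace.fs,
            stim_time=trace.stim_time,
        )
        _, offset, _, _ = detect_mep(short, csp_config)
        with pytest.raises(DetectionError, match="unterminated"):
            detect_csp(short, csp_config, offset)

    def test_scale_equivariance(self, emg_params, csp_config):
        """Thresholds are baseline-relative, so amplitude scaling must not
        move any temporal landmark."""
        trace, _ = synthesize_emg_trial(emg_params, seed=9)
        scaled = EMGTrace(
            samples=trace.samples * 7.3, fs=trace.fs, stim_time=trace.stim_time
        )
        on1, off1, amp1, _ = detect_mep(trace, csp_config)
        on2, off2, amp2, _ = detect_mep(scaled, csp_config)
        assert (on1, off1) == (on2, off2)
        assert amp2 == pytest.approx(7.3 * amp1)
        end1, _ = detect_csp(trace, csp_config, off1)
        end2, _ = detect_csp(scaled, csp_config, off2)
        assert end1 == end2


class TestExtractFeatures:
    def test_nominal_sweep_complete(self, emg_params, csp_config):
        trace, _ = synthesize_emg_trial(emg_params, seed=12)
        f = extract_trial_features(trace, csp_config, emg_params.mvc_rms * 1000)
        assert not f.rejected
        assert f.csp_abs > 0
        assert f.mep_offset > f.mep_onset
        assert f.csp_end >= f.mep_offset

    def test_weak_contraction_rejected(self, emg_params, csp_config):
        trace, _ = synthesize_emg_trial(emg_params, seed=13)
        # same sweep against an MVC reference ten times larger -> ~3% MVC
        f = extract_trial_features(trace, csp_config, emg_params.mvc_rms * 10000)
        assert f.rejected
        assert f.reason == "contraction out of band"

    def test_missing_mep_rejected_not_raised(self, csp_config):
        params = SyntheticEMGParams(mep_amp_pp=0.0)
        trace, _ = synthesize_emg_trial(params, seed=1)
        f = extract_trial_features(trace, csp_config, params.mvc_rms * 1000)
        assert f.rejected
        assert f.reason == "no MEP detected"

    def test_participant_summary_order_invariant(self, emg_params, csp_config):
        feats = []
        for s in range(8):
            trace, _ = synthesize_emg_trial(emg_params, seed=40 + s)
            feats.append(extract_trial_features(trace, csp_config, emg_params.mvc_rms * 1000))
        fwd = summarize_participant(feats)
        rev = summarize_participant(list(reversed(feats)))
        assert fwd == rev

    def test_ground_truth_recovery(self, csp_config):
        """Median CSP error across pulses stays within the smoothing scale,
        and detected-vs-true CSP is close to the identity line."""
        rng = np.random.default_rng(0)
        errors, det, tru = [], [], []
        for k in range(60):
            true_csp = float(rng.uniform(50, 200))
            params = SyntheticEMGParams(csp_duration=true_csp)
            trace, truth = synthesize_emg_trial(params, seed=600 + k)
            f = extract_trial_features(trace, csp_config, params.mvc_rms * 1000)
            if f.rejected:
                continue
            errors.append(f.csp_abs - true_csp)
            det.append(f.csp_abs)
            tru.append(true_csp)
        assert len(errors) > 45
        assert np.median(np.abs(errors)) <= 5
        slope = np.polyfit(tru, det, 1)[0]
        assert 0.95 <= slope <= 1.05
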