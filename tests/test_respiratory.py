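import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somnostage.io_core import AudioRecording, EpochGrid
from somnostage.respiratory import (
    BreathSeries,
    EnvelopeSeries,
    bandpass_breath,
    detect_breaths,
    envelope,
    estimate_noise_template,
    respiratory_feature_block,
    respiratory_features,
    spectral_subtract,
)

FS = 5000


def tone(freq, seconds=10.0, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return AudioRecording(amp * np.sin(2 * np.pi * freq * t), fs)


def rms(x):
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestEnvelope:
    def test_constant_signal(self):
        a = AudioRecording(np.full(FS * 2, 2.0), FS)
        e = envelope(a, 0.2, 0.05)
        np.testing.assert_allclose(e.values, 2.0)

    def test_sine_closed_form(self):
        # window of integer periods: RMS of A*sin = A/sqrt(2)
        e = envelope(tone(10, amp=3.0), 0.2, 0.05)
        np.testing.assert_allclose(e.values, 3.0 / np.sqrt(2), rtol=1e-9)

    def test_zero_signal(self):
        e = envelope(AudioRecording(np.zeros(FS), FS), 0.2, 0.05)
        assert np.all(e.values == 0.0)

    def test_length_formula(self):
        a = AudioRecording(np.ones(FS * 3 + 17), FS)
        e = envelope(a, 0.2, 0.05)
        win, hop = int(0.2 * FS), int(0.05 * FS)
        assert len(e) == (a.samples.size - win) // hop + 1

    def test_mean_abs_variant(self):
        a = AudioRecording(np.full(FS, -1.5), FS)
        e = envelope(a, 0.2, 0.05, kind="mean_abs")
        np.testing.assert_allclose(e.values, 1.5)

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            envelope(AudioRecording(np.ones(100), FS), 0.2, 0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.01, 100.0, allow_nan=False),
        sign=st.sampled_from([-1.0, 1.0]),
        seed=st.integers(0, 100),
    )
    def test_scale_equivariance(self, lam, sign, seed):
        x = np.random.default_rng(seed).standard_normal(FS)
        e1 = envelope(AudioRecording(x + 10, FS), 0.2, 0.05).values
        # envelope(lam * x) = |lam| * envelope(x)
        e2 = envelope(AudioRecording(sign * lam * (x + 10), FS), 0.2, 0.05).values
        np.testing.assert_allclose(e2, lam * e1, rtol=1e-7)


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = bandpass_breath(tone(1000))
        mid = out.samples[FS:-FS]
        assert rms(mid) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_stopband_tone_attenuated(self):
        out = bandpass_breath(tone(50))
        atten = 20 * np.log10(rms(out.samples[FS:-FS]) / (1 / np.sqrt(2)))
        assert atten <= -40

    def test_zero_in_zero_out(self):
        out = bandpass_breath(AudioRecording(np.zeros(FS), FS))
        assert np.all(out.samples == 0.0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_breath(AudioRecording(np.zeros(1000), 3000))

    def test_group_delay_compensated(self):
        # an impulse-like click must stay at its original time
        x = np.zeros(FS)
        x[2500] = 1.0
        out = bandpass_breath(AudioRecording(x, FS))
        assert abs(int(np.argmax(np.abs(out.samples))) - 2500) <= 2


class TestSpectralSubtraction:
    def test_zero_template_identity(self):
        x = np.random.default_rng(0).standard_normal(FS * 40) * 0.1
        a = AudioRecording(x, FS)
        out = spectral_subtract(a, np.zeros(513))
        np.testing.assert_allclose(out.samples, x, atol=1e-6)

    def test_matched_noise_suppressed(self):
        x = np.random.default_rng(1).standard_normal(FS * 40) * 0.1
        a = AudioRecording(x, FS)
        out = spectral_subtract(a, estimate_noise_template(a))
        assert np.mean(out.samples**2) <= 0.05 * np.mean(x**2)

    def test_tone_survives_matched_noise(self):
        rng = np.random.default_rng(2)
        noise = rng.standard_normal(FS * 40) * 0.05
        sig = tone(500, 40).samples
        a = AudioRecording(sig + noise, FS)
        tmpl = estimate_noise_template(AudioRecording(noise, FS))
        out = spectral_subtract(a, tmpl)
        # compare power in the tone band before and after
        from scipy import signal as sg

        f, p_in = sg.periodogram(sig, FS)
        _, p_out = sg.periodogram(out.samples, FS)
        band = (f > 480) & (f < 520)
        assert p_out[band].sum() == pytest.approx(p_in[band].sum(), rel=0.2)

    def test_template_size_mismatch(self):
        with pytest.raises(ValueError, match="bins"):
            spectral_subtract(tone(500, 40), np.zeros(100))


class TestNoiseTemplate:
    def test_white_noise_flat(self):
        x = np.random.default_rng(3).standard_normal(FS * 60)
        tmpl = estimate_noise_template(AudioRecording(x, FS))
        inner = tmpl[5:-5]  # edge bins carry half-width
        assert np.std(inner) / np.mean(inner) < 0.3

    def test_silence_zero_template(self):
        tmpl = estimate_noise_template(AudioRecording(np.zeros(FS * 40), FS))
        assert np.all(tmpl == 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_template(AudioRecording(np.zeros(FS * 10), FS))

    def test_bursts_excluded_from_floor(self):
        rng = np.random.default_rng(4)
        noise = rng.standard_normal(FS * 60) * 0.05
        with_bursts = noise.copy()
        for t0 in range(5, 55, 10):  # sparse loud bursts
            with_bursts[t0 * FS : t0 * FS + FS] += rng.standard_normal(FS) * 1.0
        tmpl_clean = estimate_noise_template(AudioRecording(noise, FS))
        tmpl_burst = estimate_noise_template(AudioRecording(with_bursts, FS))
        # template tracks the floor: bursts must not inflate it much
        assert tmpl_burst.mean() <= 1.5 * tmpl_clean.mean()


def brute_force_runs(values, thr, hop, min_s, max_s):
    """Independent oracle: exhaustive scan for threshold runs."""
    events = []
    i = 0
    n = len(values)
    while i < n:
        if values[i] > thr:
            j = i
            while j < n and values[j] > thr:
                j += 1
            dur = (j - i) * hop
            if min_s <= dur <= max_s:
                events.append((i, max(values[i:j])))
            i = j
        else:
            i += 1
    return events


class TestDetectBreaths:
    def _env(self, values, hop=0.05):
        return EnvelopeSeries(np.asarray(values, float), 0.2, hop)

    def test_rectangular_bursts(self):
        hop = 0.05
        v = np.zeros(240)  # 12 s
        for t0 in (0, 4, 8):
            v[int(t0 / hop) : int((t0 + 1.0) / hop)] = 1.0
        env = self._env(v)
        br = detect_breaths(env, threshold_factor=1.2)
        onsets = br.onset_times + env.window_seconds / 2  # window-center grid
        np.testing.assert_allclose(onsets, [0.1, 4.1, 8.1], atol=0.06)
        np.testing.assert_allclose(br.bb_intervals, [4.0, 4.0], atol=1e-9)

    def test_all_below_threshold(self):
        br = detect_breaths(self._env(np.ones(300)))
        assert br.n_breaths == 0  # constant envelope: nothing above 1.2x median

    def test_short_blip_rejected(self):
        v = np.zeros(300)
        v[100:102] = 5.0  # 100 ms < 0.3 s minimum
        assert detect_breaths(self._env(v)).n_breaths == 0

    def test_empty_envelope_rejected(self):
        with pytest.raises(ValueError):
            detect_breaths(self._env(np.array([])))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_matches_exhaustive_run_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.abs(rng.standard_normal(rng.integers(201, 1000)))
        env = self._env(v)
        br = detect_breaths(env, 1.2, 0.3, 10.0)
        thr = 1.2 * np.median(v)
        oracle = brute_force_runs(v, thr, 0.05, 0.3, 10.0)
        assert br.n_breaths == len(oracle)
        for (i, amp), onset, a in zip(oracle, br.onset_times, br.amplitudes):
            assert onset == pytest.approx(env.times[i] - 0.1, abs=1e-9)
            assert a == pytest.approx(amp)


class TestRespiratoryFeatures:
    def _breaths(self, onsets, amps=None):
        onsets = np.asarray(onsets, float)
        if amps is None:
            amps = np.ones_like(onsets)
        return BreathSeries(onsets, np.asarray(amps, float), threshold=0.5)

    def _env(self, seconds=150):
        n = int(seconds / 0.05)
        return EnvelopeSeries(np.ones(n), 0.2, 0.05)

    def test_periodic_breathing(self):
        onsets = np.arange(0, 150, 4.0)
        f, flag = respiratory_features(self._breaths(onsets), self._env(), EpochGrid(5), 2)
        assert not flag
        assert f[0] == pytest.approx(15.0)  # 4 s BB -> 15 breaths/min
        assert f[1] == pytest.approx(4.0)
        assert f[2] == pytest.approx(0.0)
        assert f[3] == pytest.approx(0.0)
        assert f[6] == 0.0  # autocorrelation of a constant series -> 0

    def test_alternating_bb(self):
        onsets = np.cumsum([0] + [3.0, 5.0] * 18)
        f, _ = respiratory_features(self._breaths(onsets), self._env(), EpochGrid(5), 2)
        assert f[1] == pytest.approx(4.0, rel=0.01)
        assert f[4] == pytest.approx(2.0, rel=0.01)  # RMSSD of +-2 jumps

    def test_epoch_without_breaths_flagged_and_imputed(self):
        onsets = np.arange(0.0, 30.0, 4.0)  # breaths only in epoch 0
        blk, flags = respiratory_feature_block(
            self._breaths(onsets), self._env(150), EpochGrid(5)
        )
        assert flags[4]  # far epoch has no breaths in context
        from somnostage.staging import assemble_features

        mat = assemble_features(blk, np.zeros((5, 13)), np.zeros((5, 4)), EpochGrid(5))
        assert np.isfinite(mat.values).all()
        assert mat.imputed_flags[4, :7].any()
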