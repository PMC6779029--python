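"""Filtering, spatial filtering, channel gating, demodulation, segmentation."""
import numpy as np
import pytest
from scipy import signal as sps

from myocoupling.preprocess import (
    ChannelSelectionError,
    bandpass_filter,
    compute_double_differential,
    compute_envelope,
    estimate_cc_cv,
    kinematic_summary,
    segment_cycles,
    select_channel,
)
from myocoupling.records import ChannelQuality, KinematicRecording, RawArrayRecording
from myocoupling.synthetic import SubjectConfig, gen_cycle_durations, gen_kinematics

FS = 2048.0


def _rec(x):
    return RawArrayRecording("ECR", np.vstack([x, x]), fs=FS)


class TestBandpass:
    def test_stopband_and_passband_tones(self):
        t = np.arange(0, 10, 1 / FS)
        low = bandpass_filter(_rec(np.sin(2 * np.pi * 5 * t)))
        mid = bandpass_filter(_rec(np.sin(2 * np.pi * 100 * t)))
        # steady-state amplitude, away from the edges
        sl = slice(int(FS), int(9 * FS))
        att_low = np.max(np.abs(low.channels[0][sl]))
        assert 20 * np.log10(att_low) < -20
        amp_mid = np.max(np.abs(mid.channels[0][sl]))
        assert abs(20 * np.log10(amp_mid)) < 1.0

    def test_white_noise_matches_butterworth_magnitude(self, rng):
        x = rng.standard_normal(int(60 * FS))
        y = bandpass_filter(_rec(x)).channels[0]
        f, pxx = sps.welch(x, fs=FS, nperseg=8192)
        f, pyy = sps.welch(y, fs=FS, nperseg=8192)
        gain = pyy / pxx
        b, a = sps.butter(4, [20, 350], btype="bandpass", fs=FS)
        _, h = sps.freqz(b, a, worN=f, fs=FS)
        # forward-backward doubles the magnitude response in power: |H|^4
        expected = np.abs(h) ** 4
        band = (f > 10) & (f < 500) & (expected > 1e-4)
        assert np.allclose(gain[band], expected[band], rtol=0.35, atol=0.02)

    def test_too_short_raises_with_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            bandpass_filter(_rec(np.zeros(100)))


class TestDoubleDifferential:
    def test_identical_channels_cancel(self, rng):
        x = rng.standard_normal(5000)
        rec = RawArrayRecording("ECR", np.vstack([x] * 7), fs=FS)
        dd = compute_double_differential(rec)
        assert dd.n_channels == 6
        assert np.all(dd.channels == 0)

    def test_linear_ramp_gives_constant(self):
        c = 0.37
        rec = RawArrayRecording("ECR", np.vstack([i * c * np.ones(1000) for i in range(7)]), fs=FS)
        dd = compute_double_differential(rec)
        assert np.allclose(dd.channels, c)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            RawArrayRecording("ECR", np.zeros((1, 100)), fs=FS)


class TestCCCV:
    def test_identity_gives_unit_cc_invalid_cv(self, rng):
        a = rng.standard_normal(4096)
        r = estimate_cc_cv(a, a, FS, 0.005)
        assert r.cc == pytest.approx(1.0, abs=1e-6)
        assert not r.cv_valid

    def test_fractional_delay_recovers_cv(self, rng):
        from myocoupling.synthetic import _biphasic_wavelet, _fractional_delay

        n = int(10 * FS)
        train = np.zeros(n)
        idx = rng.integers(0, n, 2000)
        train[idx] = rng.uniform(0.6, 1.4, len(idx))
        a = sps.fftconvolve(train, _biphasic_wavelet(FS), mode="same")
        b = _fractional_delay(a, 2.56)
        r = estimate_cc_cv(a, b, FS, 0.005)
        # 0.005 m / (2.56 / 2048 s) = 4.0 m/s
        assert r.cv == pytest.approx(4.0, abs=0.3)
        assert r.cc > 0.95

    def test_independent_noise_low_cc(self, rng):
        r = estimate_cc_cv(rng.standard_normal(20480), rng.standard_normal(20480), FS, 0.005)
        assert abs(r.cc) < 0.2

    def test_amplitude_scale_invariance(self, rng):
        from myocoupling.synthetic import _fractional_delay

        a = sps.lfilter([1], [1, -0.9], rng.standard_normal(8192))
        b = _fractional_delay(a, 2.0)
        r1 = estimate_cc_cv(a, b, FS, 0.005)
        r2 = estimate_cc_cv(5.0 * a, 0.2 * b, FS, 0.005)
        assert r1.cc == pytest.approx(r2.cc, abs=1e-9)
        assert r1.cv == pytest.approx(r2.cv, rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            estimate_cc_cv(np.zeros(100), np.ones(100), FS, 0.005)


class TestSelectChannel:
    def _dd(self, k=3):
        return RawArrayRecording("ECR", np.random.default_rng(0).standard_normal((k, 100)), fs=FS)

    def test_highest_cc_wins(self):
        q = [ChannelQuality(0, 0.9, 4.5), ChannelQuality(1, 0.8, 5.0)]
        _, best, _ = select_channel(self._dd(), q)
        assert best.dd_index == 0

    def test_cv_gate_excludes_high_cc(self):
        q = [ChannelQuality(0, 0.95, 9.0), ChannelQuality(1, 0.75, 4.0)]
        _, best, _ = select_channel(self._dd(), q)
        assert best.dd_index == 1

    def test_no_qualifying_channel_raises_with_reasons(self):
        q = [ChannelQuality(0, 0.65, 4.0)]
        with pytest.raises(ChannelSelectionError, match="CC"):
            select_channel(self._dd(), q)

    def test_artifact_flag_excludes(self):
        q = [ChannelQuality(0, 0.95, 4.0, artifact_flag=True),
             ChannelQuality(1, 0.8, 4.5)]
        _, best, _ = select_channel(self._dd(), q)
        assert best.dd_index == 1


class TestEnvelope:
    def test_zero_mean_unit_variance(self, rng):
        env = compute_envelope(rng.standard_normal(int(30 * FS)), FS)
        assert abs(env.values.mean()) < 1e-9
        assert abs(env.values.var() - 1.0) < 1e-9

    def test_moving_average_of_constant(self):
        from myocoupling.preprocess import _centered_moving_average

        out = _centered_moving_average(np.full(5000, 3.5), 819)
        assert np.allclose(out[500:-500], 3.5)

    def test_am_noise_recovers_modulator(self, rng):
        t = np.arange(0, 20, 1 / FS)
        mod = 1 + 0.9 * np.sin(2 * np.pi * 0.5 * t)
        env = compute_envelope(mod * rng.standard_normal(len(t)), FS)
        te = np.arange(len(env.values)) / env.fs_env
        ref = 1 + 0.9 * np.sin(2 * np.pi * 0.5 * te)
        assert np.corrcoef(env.raw, ref)[0, 1] > 0.95

    def test_scale_invariance_after_normalisation(self, rng):
        x = rng.standard_normal(int(5 * FS))
        e1 = compute_envelope(x, FS)
        e3 = compute_envelope(3.0 * x, FS)
        assert np.allclose(e1.values, e3.values, atol=1e-10)
        assert e3.std == pytest.approx(3.0 * e1.std, rel=1e-9)

    def test_constant_zero_errors(self):
        with pytest.raises(ValueError):
            compute_envelope(np.zeros(int(2 * FS)), FS)


class TestSegmentCycles:
    def test_pure_sine_counts_cycles(self):
        fs = 100.0
        t = np.arange(0, 94.5, 1 / fs)
        kin = KinematicRecording(np.sin(2 * np.pi * t / 2.1), np.zeros_like(t),
                                 np.zeros_like(t), fs=fs)
        ct = segment_cycles(kin)
        assert ct.n_cycles == 45
        assert ct.mean_duration == pytest.approx(2.1, rel=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generator_truth_recovered(self, seed):
        cfg = SubjectConfig(seed=seed, n_cycles=30)
        r = np.random.default_rng(seed)
        dur = gen_cycle_durations(cfg, r)
        kin = gen_kinematics(cfg, dur, r)
        ct = segment_cycles(kin)
        assert ct.n_cycles == 30
        assert ct.mean_duration == pytest.approx(dur.mean(), rel=0.01)

    def test_no_crossings_errors(self):
        kin = KinematicRecording(np.ones(1000), np.zeros(1000), np.zeros(1000), fs=100)
        with pytest.raises(ValueError):
            segment_cycles(kin)

    def test_few_cycles_warns(self):
        fs = 100.0
        t = np.arange(0, 10.5, 1 / fs)
        kin = KinematicRecording(np.sin(2 * np.pi * t / 2.1), np.zeros_like(t),
                                 np.zeros_like(t), fs=fs)
        with pytest.warns(UserWarning, match="cycles"):
            segment_cycles(kin)


class TestKinematicSummary:
    def _subject(self, seed=0, **kw):
        cfg = SubjectConfig(seed=seed, n_cycles=25, **kw)
        r = np.random.default_rng(seed)
        dur = gen_cycle_durations(cfg, r)
        kin = gen_kinematics(cfg, dur, r)
        return kin, segment_cycles(kin)

    def test_torque_ratio_matches_programmed_decay(self):
        kin, ct = self._subject(torque_final_frac=0.3)
        s = kinematic_summary(kin, ct)["summary"]
        assert s["torque_final_initial"] == pytest.approx(0.3, abs=0.07)

    def test_constant_torque_gives_unit_ratio(self):
        kin, ct = self._subject(torque_final_frac=1.0)
        s = kinematic_summary(kin, ct)["summary"]
        assert s["torque_final_initial"] == pytest.approx(1.0, abs=0.07)

    def test_velocity_plateaus_recovered(self):
        kin, ct = self._subject()
        s = kinematic_summary(kin, ct)["summary"]
        assert s["vel_extension_mean"] == pytest.approx(60.0, abs=2.0)
        assert s["vel_flexion_mean"] == pytest.approx(180.0, abs=5.0)
        assert s["range_mean"] == pytest.approx(70.0, abs=3.0)
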