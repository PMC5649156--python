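"""GFP and Morlet time-frequency log power."""

import numpy as np
import pytest

from bromeg.sensorlevel import (SensorAnalysisError, baseline_correct,
                                default_freqs, global_field_power,
                                gfp_window_contrast, morlet_tf,
                                spectral_bootstrap, tf_trial_mean,
                                tf_trial_mean_continuous)

from bromeg.preprocess import bandpass

SFREQ = 200.0
DELTA = (0.5, 4.0)


class TestGFP:
    def test_identical_channels_zero(self):
        avg = np.tile(np.sin(np.linspace(0, 10, 400)), (8, 1))
        gfp = global_field_power(avg, SFREQ, band=None)
        assert np.allclose(gfp, 0.0)

    def test_closed_form_pattern_scaling(self, rng):
        """channels = common drift c(t) + pattern p × s(t) gives
        GFP(t) = |s(t)| · SD(p)."""
        n_ch, n_t = 12, 300
        c = rng.standard_normal(n_t)
        p = rng.standard_normal(n_ch)
        s = rng.standard_normal(n_t)
        avg = c[None, :] + p[:, None] * s[None, :]
        gfp = global_field_power(avg, SFREQ, band=None)
        assert np.allclose(gfp, np.abs(s) * p.std(), atol=1e-12)

    def test_matches_brute_force_spatial_sd(self, rng):
        avg = rng.standard_normal((10, 250))
        gfp = global_field_power(avg, SFREQ, band=None)
        brute = np.array([np.sqrt(np.mean((avg[:, i] - avg[:, i].mean()) ** 2))
                          for i in range(250)])
        assert np.allclose(gfp, brute, atol=1e-12)

    def test_offset_invariance(self, rng):
        avg = rng.standard_normal((10, 250))
        common = rng.standard_normal(250)
        g1 = global_field_power(avg, SFREQ, band=None)
        g2 = global_field_power(avg + common[None, :], SFREQ, band=None)
        assert np.max(np.abs(g1 - g2)) < 1e-12

    def test_variance_convention_is_square(self, rng):
        avg = rng.standard_normal((6, 100))
        sd = global_field_power(avg, SFREQ, band=None, stat="sd")
        var = global_field_power(avg, SFREQ, band=None, stat="var")
        assert np.allclose(var, sd ** 2)

    def test_single_channel_rejected(self):
        with pytest.raises(SensorAnalysisError):
            global_field_power(np.ones((1, 100)), SFREQ)


class TestGFPWindowContrast:
    times = np.arange(-1.5, 1.5 + 1 / SFREQ, 1 / SFREQ)

    def test_identical_windows_give_null(self, rng):
        gfp = np.tile(rng.uniform(1, 2, size=(6, 1)), (1, len(self.times)))
        res, post, pre = gfp_window_contrast(gfp, self.times)
        assert res.t == 0.0 and res.p == 1.0
        assert np.allclose(post, pre)

    def test_window_outside_epoch_rejected(self, rng):
        gfp = rng.standard_normal((6, len(self.times)))
        with pytest.raises(SensorAnalysisError):
            gfp_window_contrast(gfp, self.times, post_win=(1.4, 1.9))


class TestMorlet:
    def test_tone_peaks_at_its_frequency(self):
        t = np.arange(0, 6, 1 / SFREQ)
        sig = np.sin(2 * np.pi * 3.0 * t)
        freqs = default_freqs()
        lp = morlet_tf(sig, SFREQ, freqs)
        mid = slice(len(t) // 3, 2 * len(t) // 3)
        assert freqs[np.argmax(lp[:, mid].mean(axis=1))] == pytest.approx(3.0)

    def test_amplitude_doubling_adds_log10_four(self, rng):
        sig = rng.standard_normal((2, 3, 600))
        lp1 = morlet_tf(sig, SFREQ)
        lp2 = morlet_tf(2.0 * sig, SFREQ)
        assert np.allclose(lp2 - lp1, np.log10(4.0), atol=1e-9)

    def test_short_epoch_raises_when_strict(self):
        sig = np.zeros(200)  # 1 s epoch, 0.5 Hz wavelet needs far more
        with pytest.raises(SensorAnalysisError):
            morlet_tf(sig, SFREQ, np.array([0.5]), on_short="raise")

    def test_invalid_frequencies(self):
        with pytest.raises(SensorAnalysisError):
            morlet_tf(np.zeros(400), SFREQ, np.array([150.0]))
        with pytest.raises(SensorAnalysisError):
            morlet_tf(np.zeros(400), SFREQ, np.array([3.0]), n_cycles=2)

    def test_matches_mne_reference(self):
        """Cross-check against the established Morlet TFR implementation on
        a frequency whose wavelet fits the epoch."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(0)
        epochs = rng.standard_normal((3, 2, 1200))  # 6 s at 200 Hz
        freqs = np.array([4.0, 5.0])
        ours = morlet_tf(epochs, SFREQ, freqs, n_cycles=6)
        power = mne.time_frequency.tfr_array_morlet(
            epochs, SFREQ, freqs, n_cycles=6, output="power", zero_mean=True)
        # away from epoch edges the two differ only by the wavelet
        # normalization convention: log-power ratio is a constant
        sl = slice(300, 900)
        dev = ours[..., sl] - np.log10(power[..., sl])
        dev = dev - np.median(dev)
        assert np.quantile(np.abs(dev), 0.95) < 0.05


class TestBaselineCorrect:
    times = np.arange(-1.5, 1.5 + 1 / SFREQ, 1 / SFREQ)

    def test_baseline_window_mean_is_zero(self, rng):
        lp = rng.standard_normal((4, 3, 5, len(self.times)))
        out = baseline_correct(lp, self.times, (-1.5, -0.5))
        mask = (self.times >= -1.5) & (self.times <= -0.5)
        assert np.allclose(out[..., mask].mean(axis=-1), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        lp = rng.standard_normal((2, 2, 3, len(self.times)))
        once = baseline_correct(lp, self.times)
        twice = baseline_correct(once, self.times)
        assert np.allclose(once, twice, atol=1e-12)

    def test_stationary_noise_stays_flat(self, rng):
        """White-noise epochs: after baseline correction, mean log power over
        any window is within 3 SE of zero."""
        epochs = rng.standard_normal((30, 4, len(self.times)))
        lp = tf_trial_mean(epochs, SFREQ, self.times,
                           freqs=np.array([3.0, 4.0]), base_win=(-1.5, -0.5))
        mask = (self.times >= 0.5) & (self.times <= 1.0)
        vals = lp[..., mask].mean(axis=-1).ravel()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 0.02

    def test_window_outside_epoch_rejected(self, rng):
        lp = rng.standard_normal((2, 2, 3, len(self.times)))
        with pytest.raises(SensorAnalysisError):
            baseline_correct(lp, self.times, (-2.5, -2.0))


class TestContinuousTF:
    def test_agrees_with_epoch_path_away_from_edges(self, rng):
        """Continuous-CWT trial means match the per-epoch transform in the
        epoch center, where wavelet truncation does not bite."""
        data = rng.standard_normal((3, 8000))
        centers = np.array([2000, 4000, 6000])
        times = np.arange(-301, 302) / SFREQ
        freqs = np.array([4.0, 6.0])
        cont = tf_trial_mean_continuous(data, SFREQ, centers, times, freqs,
                                        base_win=(-1.0, -0.5))
        rel = np.arange(-301, 302)
        epochs = np.stack([data[:, c + rel] for c in centers])
        ep = tf_trial_mean(epochs, SFREQ, times, freqs, base_win=(-1.0, -0.5))
        mid = slice(250, 350)
        assert np.allclose(cont[..., mid], ep[..., mid], atol=0.02)

    def test_centers_near_edges_rejected(self, rng):
        data = rng.standard_normal((2, 2000))
        times = np.arange(-301, 302) / SFREQ
        with pytest.raises(SensorAnalysisError):
            tf_trial_mean_continuous(data, SFREQ, np.array([100]), times)


class TestGFPLatencyRecovery:
    @pytest.mark.parametrize("latency", [0.15, 0.35])
    def test_planted_latency_recovered_within_30_ms(self, latency):
        """Single artifact-free subject: the delta-band GFP of the blink
        average peaks within ±30 ms of the planted response latency."""
        from bromeg.blinks import detect_blinks
        from bromeg.preprocess import epoch_blink
        from bromeg.simulate import (BlinkWaveformParams, RecordingConfig,
                                     blink_waveform, generate_recording)

        cfg = RecordingConfig.desk_scale(n_chan=24, ocular_moment=0.0,
                                         neural_latency=latency)
        rec, gt = generate_recording(cfg, seed=17)
        veog = bandpass(rec.veog * 1e6, cfg.sfreq, 0.1, 30.0)
        ev = detect_blinks(veog, blink_waveform(BlinkWaveformParams(),
                                                cfg.sfreq), cfg.sfreq)
        meg = bandpass(rec.meg, cfg.sfreq, *DELTA)
        ep = epoch_blink(meg, cfg.sfreq, ev)
        gfp = global_field_power(ep.average(), cfg.sfreq, band=None)
        peak = ep.times[np.argmax(gfp)]
        assert abs(peak - latency) <= 0.030


class TestSpectralBootstrap:
    def test_degenerate_null(self, rng):
        tf = rng.standard_normal((6, 3, 4, 601))
        tf = np.concatenate([tf, tf], axis=-1)[:, :, :, :601]
        times = np.arange(-300, 301) / SFREQ
        # symmetric windows on identical content -> observed ~ 0
        obs, p = spectral_bootstrap(tf, np.array([1.0, 2.0, 3.0, 4.0]), times,
                                    pre_win=(-1.0, -0.8), post_win=(-1.0, -0.8),
                                    n_perm=500, seed=0)
        assert obs == pytest.approx(0.0)
        assert p > 0.4
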