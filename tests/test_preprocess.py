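"""Filters, epoching, ICA artifact removal, and the power-ratio statistic."""

import numpy as np
import pandas as pd
import pytest

from bromeg.blinks import BlinkEvents
from bromeg.preprocess import (PreprocessingError, bandpass,
                               compare_power_ratios, epoch_blink, epoch_control,
                               identify_ocular_components, notch_filter,
                               power_ratio, remove_components, run_ica)

SFREQ = 200.0


def events_at(seconds, sfreq=SFREQ):
    s = np.asarray([int(t * sfreq) for t in seconds])
    return BlinkEvents(t0_samples=s, scores=np.ones(len(s)))


class TestFilters:
    def test_passband_amplitude_preserved(self):
        t = np.arange(0, 30, 1 / SFREQ)
        x = np.sin(2 * np.pi * 3.0 * t)
        y = bandpass(x, SFREQ, 0.5, 45.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        ratio = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        assert abs(ratio - 1.0) < 0.02

    def test_notch_attenuates_line_frequency(self):
        sfreq = 600.0
        t = np.arange(0, 20, 1 / sfreq)
        x = np.sin(2 * np.pi * 60.0 * t)
        y = notch_filter(x, sfreq, 60.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        atten = 20 * np.log10(np.sqrt(np.mean(x[mid] ** 2))
                              / np.sqrt(np.mean(y[mid] ** 2) + 1e-300))
        assert atten >= 20.0

    def test_zero_phase_keeps_pulse_latency(self):
        t = np.arange(0, 20, 1 / SFREQ)
        x = np.exp(-0.5 * ((t - 10.0) / 0.3) ** 2)
        y = bandpass(x, SFREQ, 0.5, 45.0)
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1

    def test_invalid_band(self):
        with pytest.raises(PreprocessingError):
            bandpass(np.zeros(100), SFREQ, 50.0, 40.0)
        with pytest.raises(PreprocessingError):
            bandpass(np.zeros(100), SFREQ, 0.5, 150.0)


class TestEpoching:
    def test_blink_epoch_indexing_identity(self, rng):
        data = rng.standard_normal((4, int(600 * SFREQ) // 10))
        ev = events_at([30.0])
        ep = epoch_blink(data, SFREQ, ev)
        assert ep.n_trials == 1
        i0 = ep.time_index(0.0)
        assert np.array_equal(ep.data[0, :, i0], data[:, int(30.0 * SFREQ)])
        assert ep.times[0] == pytest.approx(-1.5)
        assert ep.times[-1] == pytest.approx(1.5)

    def test_edge_events_dropped_and_counted(self, rng):
        data = rng.standard_normal((2, int(20 * SFREQ)))
        ep = epoch_blink(data, SFREQ, events_at([0.5, 10.0, 19.6]))
        assert ep.n_trials == 1
        assert ep.n_dropped == 2

    def test_control_block_centered_nonoverlapping(self, rng):
        data = rng.standard_normal((2, int(600 * SFREQ)))
        ep = epoch_control(data, SFREQ, n_trials=10)
        assert ep.n_trials == 10
        centers = ep.centers
        assert np.all(np.diff(centers) == len(ep.times))
        block_mid = (centers[0] + centers[-1]) / 2
        assert abs(block_mid - data.shape[-1] // 2) <= len(ep.times)

    def test_control_matches_blink_trial_count(self, rng):
        data = rng.standard_normal((2, int(300 * SFREQ)))
        ev = events_at([50.0, 100.0, 200.0])
        epb = epoch_blink(data, SFREQ, ev)
        epc = epoch_control(data, SFREQ, epb.n_trials, ev)
        assert epc.n_trials == epb.n_trials
        assert epc.data.shape == epb.data.shape

    def test_control_not_blink_locked(self, small_recording):
        rec, gt = small_recording
        ep = epoch_control(rec.meg, rec.sfreq, 20)
        zeros = ep.centers / rec.sfreq
        offsets = np.array([np.min(np.abs(gt.blink_times - z)) for z in zeros])
        assert offsets.std() > 0.1  # non-degenerate distribution

    def test_too_short_recording(self, rng):
        data = rng.standard_normal((2, int(10 * SFREQ)))
        with pytest.raises(PreprocessingError):
            epoch_control(data, SFREQ, n_trials=10)

    def test_strict_mode_excludes_blink_adjacent_epochs(self, rng):
        data = rng.standard_normal((2, int(600 * SFREQ)))
        mid = data.shape[-1] // 2
        ev = events_at([mid / SFREQ])  # a blink exactly at the block center
        strict = epoch_control(data, SFREQ, n_trials=9, events=ev, strict=True)
        loose = epoch_control(data, SFREQ, n_trials=9, events=ev)
        assert loose.n_trials == 9
        assert strict.n_trials < 9
        assert all(abs(c - mid) > 1.5 * SFREQ for c in strict.centers)


class TestICA:
    @pytest.fixture(scope="class")
    def mixture(self):
        """3-source mixture: ocular-like train + alpha + broadband noise."""
        rng = np.random.default_rng(5)
        n = 40000
        t = np.arange(n) / SFREQ
        ocular = np.zeros(n)
        for s in range(8, 195, 6):
            i = int(s * SFREQ)
            ocular[i:i + 80] += np.hanning(80)
        alpha = np.sin(2 * np.pi * 10 * t) * (1 + 0.3 * np.sin(2 * np.pi * 0.1 * t))
        noise = rng.standard_normal((6, n)) * 0.3
        A = rng.standard_normal((6, 2))
        data = A[:, :1] @ ocular[None] * 10.0 + A[:, 1:] @ alpha[None] + noise
        return data, ocular, alpha

    def test_full_rank_reconstruction(self, mixture):
        data, *_ = mixture
        ica = run_ica(data, n_components=6, seed=0)
        err = np.linalg.norm(data - ica.reconstruct()) / np.linalg.norm(data)
        assert err < 1e-6

    def test_planted_source_recovered(self, mixture):
        data, ocular, _ = mixture
        ica = run_ica(data, n_components=6, seed=0)
        best = max(abs(np.corrcoef(s, ocular)[0, 1]) for s in ica.sources)
        assert best > 0.95

    def test_seed_determinism_after_canonicalization(self, mixture):
        data, ocular, _ = mixture
        a = run_ica(data, n_components=4, seed=3, veog=ocular)
        b = run_ica(data, n_components=4, seed=3, veog=ocular)
        assert np.array_equal(a.sources, b.sources)
        assert np.array_equal(a.mixing, b.mixing)

    def test_identify_flags_injected_veog(self, rng):
        # band-limited ocular reference, injected verbatim as a component
        veog = bandpass(rng.standard_normal(8000), SFREQ, 0.5, 30.0)
        sources = np.vstack([rng.standard_normal(8000), veog])
        flagged = identify_ocular_components(sources, veog, SFREQ,
                                             corr_thresh=0.7)
        assert 1 in flagged and 0 not in flagged

    def test_white_noise_not_flagged(self, rng):
        veog = rng.standard_normal(20000)
        sources = rng.standard_normal((5, 20000))
        flagged = identify_ocular_components(sources, veog, SFREQ,
                                             corr_thresh=0.5)
        assert len(flagged) == 0

    def test_remove_nothing_is_identity(self, mixture):
        data, *_ = mixture
        ica = run_ica(data, n_components=4, seed=0)
        out = remove_components(ica, np.array([], dtype=int), data=data)
        assert np.allclose(out, data, atol=1e-12)

    def test_removal_linear_in_data_for_fixed_unmixing(self, mixture):
        data, *_ = mixture
        ica = run_ica(data, n_components=6, seed=0)
        flagged = np.array([0])
        out1 = remove_components(ica, flagged)
        # reconstruct-from-kept equals input minus flagged contribution
        direct = data - ica.mixing[:, :1] @ ica.sources[:1]
        assert np.allclose(out1, direct, atol=1e-6 * np.abs(data).max())

    def test_all_flagged_rejected(self, mixture):
        data, *_ = mixture
        ica = run_ica(data, n_components=3, seed=0)
        with pytest.raises(PreprocessingError):
            remove_components(ica, np.arange(3))


class TestPowerRatio:
    times = np.linspace(-1.5, 1.5, 301)

    def make_erf(self, y, x):
        erf = np.zeros((len(y), len(self.times)))
        iy = np.argmin(np.abs(self.times - 0.0))
        ix = np.argmin(np.abs(self.times - (-1.0)))
        erf[:, iy] = y
        erf[:, ix] = x
        return erf

    def test_identical_latencies_give_unity(self, rng):
        v = rng.standard_normal(10)
        erf = self.make_erf(v, v)
        assert power_ratio(erf, self.times) == pytest.approx(1.0)

    def test_doubled_deviations_give_four(self, rng):
        x = rng.standard_normal(10)
        y = x.mean() + 2.0 * (x - x.mean())
        erf = self.make_erf(y, x)
        assert power_ratio(erf, self.times) == pytest.approx(4.0)

    def test_invariant_to_channel_common_offset(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        r1 = power_ratio(self.make_erf(y, x), self.times)
        r2 = power_ratio(self.make_erf(y + 5.0, x - 3.0), self.times)
        assert r1 == pytest.approx(r2)

    def test_zero_denominator_rejected(self):
        erf = self.make_erf(np.arange(5.0), np.ones(5))
        with pytest.raises(PreprocessingError):
            power_ratio(erf, self.times)

    def test_latency_outside_epoch_rejected(self, rng):
        erf = rng.standard_normal((5, len(self.times)))
        with pytest.raises(PreprocessingError):
            power_ratio(erf, self.times, t_base=-2.0)


class TestComparePowerRatios:
    def make_table(self, post_shift=0.0, n_subj=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            for region in ("frontal", "central", "parietal", "temporal",
                           "occipital"):
                pre = 5.0 + rng.normal(0, 1)
                rows.append(dict(subject=f"s{s}", region=region,
                                 condition="blink", stage="pre", ratio=pre))
                rows.append(dict(subject=f"s{s}", region=region,
                                 condition="blink", stage="post",
                                 ratio=pre - post_shift + rng.normal(0, 0.3)))
        return pd.DataFrame(rows)

    def test_identical_stages_give_t_zero_p_one(self):
        table = self.make_table()
        table.loc[table.stage == "post", "ratio"] = \
            table.loc[table.stage == "pre", "ratio"].to_numpy()
        res = compare_power_ratios(table)
        assert np.allclose(res["ttests"]["t"], 0.0)
        assert np.allclose(res["ttests"]["p_bonferroni"], 1.0)

    def test_bonferroni_is_five_times_raw(self):
        res = compare_power_ratios(self.make_table(post_shift=0.5))
        t = res["ttests"]
        assert np.allclose(t["p_bonferroni"],
                           np.minimum(1.0, 5.0 * t["p_raw"]))

    def test_known_shift_matches_reference_ttest(self):
        """Per-region t agrees with the scipy paired t-test to 1e-10."""
        from scipy.stats import ttest_rel

        table = self.make_table(post_shift=1.0, seed=3)
        res = compare_power_ratios(table)
        for _, row in res["ttests"].iterrows():
            grp = table[table.region == row.region]
            wide = grp.pivot(index="subject", columns="stage", values="ratio")
            ref = ttest_rel(wide["pre"], wide["post"])
            assert row.t == pytest.approx(ref.statistic, abs=1e-10)
            assert row.p_raw == pytest.approx(ref.pvalue, abs=1e-10)

    def test_anova_reported_per_stage(self):
        res = compare_power_ratios(self.make_table(post_shift=0.5))
        anova = res["anova"]
        assert set(anova["stage"]) == {"pre", "post"}
        assert np.all(anova["F"] >= 0)
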