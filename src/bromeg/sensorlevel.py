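"""Sensor-space statistics: global field power and Morlet time-frequency.

GFP is the spatial standard deviation across all sensors at each time point
(the classical reference-free field-strength summary); it is computed on
trial-averaged, delta-band (0.5–4 Hz) filtered data.  Window contrasts
compare mean GFP in a post-event window (default 150–350 ms, spanning the
blink-locked GFP peak) against a pre-event baseline window (−1300 to
−1100 ms) with a paired t-test across subjects.

Time-frequency log power uses a continuous Morlet wavelet transform (six
cycles), log10 of the squared coefficient magnitude, baseline-corrected per
trial by subtracting the mean log power in a −1500 to −500 ms window.  The
group-level spectral test is a paired sign-flip permutation on the
per-subject (post − pre) band power.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import bandpass
from .stats import PairedTResult, paired_t, sign_flip_test

DELTA_BAND = (0.5, 4.0)


class SensorAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# global field power
# ---------------------------------------------------------------------------

def global_field_power(avg_epochs: np.ndarray, sfreq: float,
                       band: tuple[float, float] | None = DELTA_BAND,
                       stat: str = "sd") -> np.ndarray:
    """Per-time-point spatial dispersion across channels of trial-averaged
    data, optionally band-filtered first.

    ``stat`` selects the classical standard-deviation convention ("sd") or
    spatial variance ("var").  Invariant to channel-common offsets.
    """
    avg = np.atleast_2d(np.asarray(avg_epochs, dtype=float))
    if avg.shape[0] < 2:
        raise SensorAnalysisError("GFP needs at least 2 channels")
    if band is not None:
        avg = bandpass(avg, sfreq, band[0], band[1])
    var = avg.var(axis=0)
    if stat == "sd":
        return np.sqrt(var)
    if stat == "var":
        return var
    raise SensorAnalysisError("stat must be 'sd' or 'var'")


def window_mean(values: np.ndarray, times: np.ndarray,
                win: tuple[float, float]) -> float | np.ndarray:
    if win[0] < times[0] - 1e-9 or win[1] > times[-1] + 1e-9:
        raise SensorAnalysisError(f"window {win} outside the epoch")
    mask = (times >= win[0]) & (times <= win[1])
    if not np.any(mask):
        raise SensorAnalysisError("empty window")
    return np.asarray(values)[..., mask].mean(axis=-1)


def gfp_window_contrast(gfp: np.ndarray, times: np.ndarray,
                        post_win: tuple[float, float] = (0.150, 0.350),
                        pre_win: tuple[float, float] = (-1.300, -1.100),
                        ) -> tuple[PairedTResult, np.ndarray, np.ndarray]:
    """Paired t between mean GFP in the post and pre windows.

    ``gfp`` is (n_subjects, n_time).  Returns the test plus the per-subject
    post and pre window means.
    """
    gfp = np.atleast_2d(np.asarray(gfp, dtype=float))
    if gfp.shape[0] < 2:
        raise SensorAnalysisError("need at least 2 subjects")
    post = np.array([window_mean(g, times, post_win) for g in gfp])
    pre = np.array([window_mean(g, times, pre_win) for g in gfp])
    return paired_t(post, pre), post, pre


# ---------------------------------------------------------------------------
# Morlet time-frequency
# ---------------------------------------------------------------------------

def morlet_wavelet(freq: float, sfreq: float, n_cycles: float = 6.0,
                   max_duration: float | None = None) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized; sigma_t = n_cycles/(2π f).

    Support is ±5 sigma_t, truncated to ``max_duration`` seconds when that
    is shorter (long low-frequency wavelets in short epochs).
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = 5.0 * sigma_t
    if max_duration is not None:
        half = min(half, max_duration / 2.0)
    t = np.arange(-half, half + 1.0 / sfreq, 1.0 / sfreq)
    wav = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    wav -= wav.mean()  # zero-mean correction for short wavelets
    return wav / np.linalg.norm(wav)


def default_freqs(lo: float = 0.5, hi: float = 6.0, step: float = 0.25) -> np.ndarray:
    """Analysis frequencies concentrated on the delta band."""
    return np.arange(lo, hi + step / 2, step)


def morlet_tf(epochs: np.ndarray, sfreq: float,
              freqs: np.ndarray | None = None, n_cycles: float = 6.0,
              on_short: str = "truncate") -> np.ndarray:
    """Per-trial, per-channel Morlet log power: log10 |CWT|².

    ``epochs`` is (n_trials, n_chan, n_time) (trial/channel axes may be
    absent); returns (n_trials, n_chan, n_freq, n_time).  When the epoch is
    shorter than a wavelet's nominal support, the wavelet is truncated to
    the epoch length (``on_short='truncate'``) or an error is raised
    (``on_short='raise'``).
    """
    epochs = np.asarray(epochs, dtype=float)
    squeeze = 3 - epochs.ndim
    epochs = epochs.reshape((1,) * squeeze + epochs.shape)
    n_tr, n_ch, n_time = epochs.shape
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= sfreq / 2):
        raise SensorAnalysisError("frequencies must lie in (0, Nyquist)")
    if n_cycles < 3:
        raise SensorAnalysisError("n_cycles must be at least 3")
    epoch_dur = n_time / sfreq
    out = np.empty((n_tr, n_ch, len(freqs), n_time))
    for fi, f in enumerate(freqs):
        support = 2 * 5.0 * n_cycles / (2.0 * np.pi * f)
        if support > epoch_dur and on_short == "raise":
            raise SensorAnalysisError(
                f"epoch ({epoch_dur:.2f} s) shorter than the {f} Hz wavelet "
                f"support ({support:.2f} s)")
        wav = morlet_wavelet(f, sfreq, n_cycles, max_duration=epoch_dur)
        # reflect-pad by half the wavelet so edge samples see a full window;
        # otherwise log power is biased low near the epoch edges, which the
        # pre-event windows sit closest to
        pad = min(len(wav) // 2, n_time - 1)
        padded = np.concatenate([epochs[..., pad:0:-1], epochs,
                                 epochs[..., -2:-2 - pad:-1]], axis=2)
        coef = fftconvolve(padded, wav[None, None, :], mode="same", axes=2)
        power = np.abs(coef[..., pad:pad + n_time]) ** 2
        out[:, :, fi, :] = np.log10(np.maximum(power, 1e-300))
    return out[(0,) * squeeze] if squeeze else out


def baseline_correct(log_power: np.ndarray, times: np.ndarray,
                     base_win: tuple[float, float] = (-1.5, -0.5)) -> np.ndarray:
    """Subtract per (trial, channel, frequency) the mean log power over the
    baseline window."""
    if base_win[0] < times[0] - 1e-9 or base_win[1] > times[-1] + 1e-9:
        raise SensorAnalysisError("baseline window outside the epoch")
    mask = (times >= base_win[0]) & (times <= base_win[1])
    if not np.any(mask):
        raise SensorAnalysisError("empty baseline window")
    base = log_power[..., mask].mean(axis=-1, keepdims=True)
    return log_power - base


def tf_trial_mean(epochs: np.ndarray, sfreq: float, times: np.ndarray,
                  freqs: np.ndarray | None = None, n_cycles: float = 6.0,
                  base_win: tuple[float, float] = (-1.5, -0.5)) -> np.ndarray:
    """Trial-averaged baseline-corrected log power, (n_chan, n_freq, n_time).

    Streams over trials so full (trials × channels × freqs × time) arrays
    are never held in memory.
    """
    epochs = np.asarray(epochs, dtype=float)
    n_tr = epochs.shape[0]
    acc = None
    for tr in range(n_tr):
        lp = morlet_tf(epochs[tr], sfreq, freqs, n_cycles)
        lp = baseline_correct(lp, times, base_win)
        acc = lp if acc is None else acc + lp
    return acc / n_tr


def tf_trial_mean_continuous(data: np.ndarray, sfreq: float,
                             centers, times: np.ndarray,
                             freqs: np.ndarray | None = None,
                             n_cycles: float = 6.0,
                             base_win: tuple[float, float] = (-1.5, -0.5)):
    """Trial-averaged baseline-corrected log power from a continuous CWT.

    The wavelet transform is computed on the continuous recording and the
    log power epoched afterwards at the ``centers`` samples — every epoch
    sample then sees the full wavelet, so there is no epoch-boundary
    attenuation (which would otherwise bias windows near the epoch edges).

    ``centers`` may be one array of epoch-zero samples, or a dict of them
    (e.g. blink and control conditions) to amortize the transform.  Returns
    (n_chan, n_freq, n_time), or a dict of such arrays.
    """
    from scipy.fft import fft, ifft, next_fast_len

    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    half = int(round(-times[0] * sfreq))
    rel = np.arange(len(times)) - half
    center_sets = centers if isinstance(centers, dict) else {"_": centers}
    idx = {}
    for key, c in center_sets.items():
        c = np.asarray(c, dtype=int)
        if np.any(c + rel[0] < 0) or np.any(c + rel[-1] >= n_samp):
            raise SensorAnalysisError("epoch centers too close to the record edges")
        idx[key] = c[:, None] + rel[None, :]
    bmask = (times >= base_win[0]) & (times <= base_win[1])
    if not np.any(bmask):
        raise SensorAnalysisError("empty baseline window")

    wavs = [morlet_wavelet(f, sfreq, n_cycles) for f in freqs]
    nfft = next_fast_len(n_samp + max(len(w) for w in wavs) - 1)
    data_f = fft(data, nfft, axis=1)  # one forward transform, reused per freq
    acc = {key: np.zeros((n_ch, len(freqs), len(times))) for key in idx}
    for fi, wav in enumerate(wavs):
        wav_f = fft(wav, nfft)
        coef = ifft(data_f * wav_f[None, :], axis=1)
        shift = (len(wav) - 1) // 2   # align "same"-mode convolution
        coef = coef[:, shift:shift + n_samp]
        lp = np.log10(np.maximum(np.abs(coef) ** 2, 1e-300))
        for key, ix in idx.items():
            ep = lp[:, ix]                           # (n_ch, n_trials, n_time)
            ep = ep - ep[..., bmask].mean(axis=-1, keepdims=True)
            acc[key][:, fi, :] = ep.mean(axis=1)
    return acc if isinstance(centers, dict) else acc["_"]


def band_window_power(tf_mean: np.ndarray, freqs: np.ndarray,
                      times: np.ndarray, band: tuple[float, float],
                      win: tuple[float, float]) -> float:
    """Mean (over channels, band frequencies, and window samples) of the
    trial-averaged log power."""
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    tmask = (times >= win[0]) & (times <= win[1])
    if not np.any(fmask) or not np.any(tmask):
        raise SensorAnalysisError("empty band or window")
    return float(tf_mean[..., fmask, :][..., tmask].mean())


def spectral_bootstrap(tf_means: np.ndarray, freqs: np.ndarray,
                       times: np.ndarray,
                       pre_win: tuple[float, float] = (-1.300, -1.100),
                       post_win: tuple[float, float] = (0.150, 0.350),
                       band: tuple[float, float] = DELTA_BAND,
                       n_perm: int = 5000, seed: int = 0,
                       alternative: str = "greater") -> tuple[float, float]:
    """Group-level paired sign-flip permutation on (post − pre) band power.

    ``tf_means`` is (n_subjects, n_chan, n_freq, n_time) of trial-averaged
    baseline-corrected log power.  Returns (observed mean difference, p),
    one-sided for an increase by default.
    """
    import warnings as _w
    if n_perm < 100:
        _w.warn("n_perm < 100 gives a very coarse permutation p-value")
    deltas = np.array([
        band_window_power(tf, freqs, times, band, post_win)
        - band_window_power(tf, freqs, times, band, pre_win)
        for tf in tf_means])
    return sign_flip_test(deltas, n_perm=n_perm, seed=seed,
                          alternative=alternative)
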