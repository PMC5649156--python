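"""Filtering, epoching, ICA ocular-artifact removal, and power-ratio checks.

The blink condition epochs the continuous record in 3-s windows centered on
each blink maximum T0; the control condition takes an equal number of
consecutive, non-overlapping 3-s epochs from the middle of the run, so its
epoch zeros are pseudo-random with respect to blinks.  Ocular contamination
is removed by linear ICA: components whose time course correlates with the
(0.1–30 Hz filtered) vEOG beyond a threshold are projected out.

The blink-to-baseline power ratio quantifies residual ocular signal per
sensor region: the across-channel demeaned power of the event-related field
at the blink latency (0 ms) divided by the same at a pre-blink baseline
latency (−1000 ms, clear of blink-related saccades).  Ratios near 1 mean no
blink-locked excess power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import pearsonr
from sklearn.decomposition import FastICA

from .blinks import BlinkEvents
from .stats import paired_t

REGIONS = ("frontal", "central", "parietal", "temporal", "occipital")


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filters (4th-order Butterworth, forward-backward => zero phase)
# ---------------------------------------------------------------------------

def bandpass(data: np.ndarray, sfreq: float, lo: float, hi: float,
             order: int = 4, axis: int = -1) -> np.ndarray:
    if not 0 < lo < hi < sfreq / 2:
        raise PreprocessingError(f"invalid band ({lo}, {hi}) at sfreq={sfreq}")
    sos = signal.butter(order, [lo, hi], btype="band", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=axis)


def lowpass(data: np.ndarray, sfreq: float, hi: float, order: int = 4,
            axis: int = -1) -> np.ndarray:
    if not 0 < hi < sfreq / 2:
        raise PreprocessingError("invalid cutoff")
    sos = signal.butter(order, hi, btype="low", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=axis)


def notch_filter(data: np.ndarray, sfreq: float, freq: float = 60.0,
                 quality: float = 30.0, axis: int = -1) -> np.ndarray:
    """Zero-phase IIR notch (power-line removal)."""
    if not 0 < freq < sfreq / 2:
        raise PreprocessingError("notch frequency outside (0, Nyquist)")
    b, a = signal.iirnotch(freq, quality, fs=sfreq)
    return signal.filtfilt(b, a, data, axis=axis)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Trials × channels × time, with the time axis relative to epoch zero.

    ``centers`` holds each trial's epoch-zero sample in the continuous
    recording, so analyses needing continuous context (e.g. boundary-free
    wavelet transforms) can re-index the raw data.
    """

    data: np.ndarray
    times: np.ndarray
    condition: str
    subject: str | None = None
    n_dropped: int = 0
    centers: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def average(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def time_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))


def _epoch_times(sfreq: float, half_width: float) -> tuple[int, np.ndarray]:
    half = int(round(half_width * sfreq))
    return half, np.arange(-half, half + 1) / sfreq


def epoch_blink(data: np.ndarray, sfreq: float, events: BlinkEvents,
                half_width: float = 1.5, subject: str | None = None) -> EpochSet:
    """3-s epochs centered at each T0; edge-violating events are dropped."""
    half, times = _epoch_times(sfreq, half_width)
    n_samp = data.shape[-1]
    trials, kept, dropped = [], [], 0
    for t0 in events.t0_samples:
        if t0 - half < 0 or t0 + half + 1 > n_samp:
            dropped += 1
            continue
        trials.append(data[..., t0 - half:t0 + half + 1])
        kept.append(int(t0))
    if not trials:
        raise PreprocessingError("no blink epochs inside the recording")
    return EpochSet(data=np.asarray(trials), times=times, condition="blink",
                    subject=subject, n_dropped=dropped,
                    centers=np.asarray(kept))


def epoch_control(data: np.ndarray, sfreq: float, n_trials: int,
                  events: BlinkEvents | None = None, half_width: float = 1.5,
                  subject: str | None = None, strict: bool = False) -> EpochSet:
    """Consecutive non-overlapping epochs centered on the recording midpoint.

    Trial count matches the blink condition; epoch zeros are pseudo-random
    with respect to blinks.  With ``strict=True`` epochs whose zero falls
    within ``half_width`` of any detected T0 are excluded (and the block is
    extended to keep the trial count, when possible).
    """
    half, times = _epoch_times(sfreq, half_width)
    epoch_len = 2 * half + 1
    n_samp = data.shape[-1]
    mid = n_samp // 2
    first_center = mid - (n_trials - 1) * epoch_len // 2
    centers = [first_center + k * epoch_len for k in range(n_trials)]
    if strict and events is not None and len(events):
        t0s = events.t0_samples
        centers = [c for c in centers
                   if np.min(np.abs(t0s - c)) > half_width * sfreq]
    if centers and (centers[0] - half < 0 or centers[-1] + half + 1 > n_samp):
        raise PreprocessingError("recording too short for the control block")
    if len(centers) < n_trials and not strict:
        raise PreprocessingError("recording too short for the control block")
    trials = [data[..., c - half:c + half + 1] for c in centers]
    return EpochSet(data=np.asarray(trials), times=times, condition="control",
                    subject=subject, n_dropped=n_trials - len(centers),
                    centers=np.asarray(centers))


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    mixing: np.ndarray    # (n_chan, n_comp)
    sources: np.ndarray   # (n_comp, n_samp)
    mean: np.ndarray      # (n_chan,)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        if keep is None:
            keep = np.arange(self.n_components)
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


def run_ica(data: np.ndarray, n_components: int | None = None, seed: int = 0,
            veog: np.ndarray | None = None, max_iter: int = 500,
            decim: int = 1) -> ICADecomposition:
    """FastICA unmixing of the MEG rows, canonicalized for determinism.

    Components are ordered by |correlation| with ``veog`` (descending) when
    it is given, else by explained variance; signs are fixed so the vEOG
    correlation (or the largest-magnitude sample) is positive.  Data with
    rank below ``n_components`` are decomposed at their actual rank, with a
    warning.  ``decim`` > 1 fits the unmixing on every ``decim``-th sample
    (the mixing model is time-invariant) and applies it to the full data.
    """
    n_chan = data.shape[0]
    if n_components is None:
        n_components = min(n_chan, 20)
    if n_components > n_chan:
        raise PreprocessingError("more components than channels")
    rank = np.linalg.matrix_rank(data @ data.T / data.shape[1])
    if rank < n_components:
        warnings.warn(f"rank-deficient data: reducing components to {rank}")
        n_components = int(rank)
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=max_iter, tol=1e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are tolerable
        ica.fit(data[:, ::decim].T)
        sources = ica.transform(data.T).T
    mixing = ica.mixing_
    mean = ica.mean_

    if veog is not None:
        r = np.array([np.corrcoef(s, veog)[0, 1] for s in sources])
        r = np.nan_to_num(r)
        order = np.argsort(-np.abs(r))
        signs = np.sign(r[order])
    else:
        var = np.array([np.var(mixing[:, k]) * np.var(sources[k])
                        for k in range(n_components)])
        order = np.argsort(-var)
        signs = np.array([np.sign(s[np.argmax(np.abs(s))]) for s in sources[order]])
    signs[signs == 0] = 1.0
    sources = sources[order] * signs[:, None]
    mixing = mixing[:, order] * signs[None, :]
    return ICADecomposition(mixing=mixing, sources=sources, mean=mean)


def identify_ocular_components(sources: np.ndarray, veog: np.ndarray,
                               sfreq: float, corr_thresh: float = 0.7,
                               veog_band: tuple[float, float] = (0.5, 30.0)
                               ) -> np.ndarray:
    """Indices of components with |Pearson r| >= threshold against the
    band-filtered vEOG.  May be empty.

    The reference vEOG is filtered to the band shared with the analyzed MEG
    (default 0.5–30 Hz): sub-band mismatch otherwise dilutes the correlation
    of a genuinely ocular component.
    """
    hi = min(veog_band[1], 0.99 * sfreq / 2)
    veog_f = bandpass(veog, sfreq, veog_band[0], hi)
    flagged = []
    for k, s in enumerate(sources):
        r, _ = pearsonr(s, veog_f)
        if np.abs(r) >= corr_thresh:
            flagged.append(k)
    return np.asarray(flagged, dtype=int)


def remove_components(ica: ICADecomposition, flagged: np.ndarray,
                      data: np.ndarray | None = None) -> np.ndarray:
    """Sensor data with the flagged components projected out.

    With ``data`` given, the flagged components' contribution
    ``A_f @ S_f`` is subtracted from it — this keeps the variance outside
    the ICA subspace (essential when n_components < n_chan).  Without
    ``data`` the non-flagged components are reconstructed directly.
    """
    flagged = np.asarray(flagged, dtype=int)
    keep = np.setdiff1d(np.arange(ica.n_components), flagged)
    if keep.size == 0:
        raise PreprocessingError("all components flagged — nothing left")
    if data is not None:
        if flagged.size == 0:
            return data.copy()
        return data - ica.mixing[:, flagged] @ ica.sources[flagged]
    return ica.reconstruct(keep)


# ---------------------------------------------------------------------------
# blink-to-baseline power ratio
# ---------------------------------------------------------------------------

def power_ratio(erf: np.ndarray, times: np.ndarray, t_blink: float = 0.0,
                t_base: float = -1.0) -> float:
    """Across-channel demeaned power at the blink latency over the same at
    baseline: ratio = Σ(y_i − ȳ)² / Σ(x_i − x̄)² over a region's channels."""
    erf = np.atleast_2d(erf)
    if erf.shape[0] < 2:
        raise PreprocessingError("power ratio needs at least 2 channels")
    for t in (t_blink, t_base):
        if t < times[0] or t > times[-1]:
            raise PreprocessingError(f"latency {t} s outside the epoch")
    iy = int(np.argmin(np.abs(times - t_blink)))
    ix = int(np.argmin(np.abs(times - t_base)))
    y, x = erf[:, iy], erf[:, ix]
    denom = np.sum((x - x.mean()) ** 2)
    if denom == 0:
        raise PreprocessingError("zero baseline power across channels")
    return float(np.sum((y - y.mean()) ** 2) / denom)


def regional_power_ratios(erf: np.ndarray, times: np.ndarray,
                          regions: np.ndarray, t_blink: float = 0.0,
                          t_base: float = -1.0) -> dict[str, float]:
    out = {}
    for region in REGIONS:
        idx = np.flatnonzero(regions == region)
        if len(idx) >= 2:
            out[region] = power_ratio(erf[idx], times, t_blink, t_base)
    return out


def compare_power_ratios(table: pd.DataFrame) -> dict:
    """Pre- vs post-ICA statistics on the power-ratio table.

    ``table`` columns: subject, region, condition, stage ('pre'|'post'),
    ratio.  Returns per-(condition, region) paired t-tests with Bonferroni
    adjustment over the regions, and a one-way repeated-measures ANOVA
    across regions per (condition, stage).
    """
    from statsmodels.stats.anova import AnovaRM

    if table["subject"].nunique() < 2:
        raise PreprocessingError("need at least 2 subjects")
    n_regions = table["region"].nunique()
    rows = []
    for (cond, region), grp in table.groupby(["condition", "region"]):
        wide = grp.pivot(index="subject", columns="stage", values="ratio")
        res = paired_t(wide["pre"].to_numpy(), wide["post"].to_numpy())
        rows.append({"condition": cond, "region": region, "t": res.t,
                     "p_raw": res.p,
                     "p_bonferroni": min(1.0, n_regions * res.p)})
    ttests = pd.DataFrame(rows)
    anova_rows = []
    for (cond, stage), grp in table.groupby(["condition", "stage"]):
        res = AnovaRM(grp, depvar="ratio", subject="subject",
                      within=["region"]).fit()
        f = float(res.anova_table["F Value"].iloc[0])
        p = float(res.anova_table["Pr > F"].iloc[0])
        anova_rows.append({"condition": cond, "stage": stage, "F": f, "p": p})
    return {"ttests": ttests, "anova": pd.DataFrame(anova_rows)}
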