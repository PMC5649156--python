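"""Blink detection and morphology on the vertical EOG.

Blinks are found by template matching: the vEOG trace is scanned with a
sliding-window Pearson correlation against a blink template, candidate
matches are amplitude-thresholded, and any blink closer than a temporal
threshold (default 3 s) to a neighbor is excluded — both members of a close
pair are dropped, since each is contaminated by the other.  The blink
maximum T0 (complete eye closure) is the vEOG peak inside the matched
window.

Morphology features of the trial-averaged blink:

* M1 — positive peak amplitude (µV)
* M2 — width of the positive lobe between its bounding zero crossings (s)
* M3 — negative trough amplitude after the positive lobe (µV)
* M4 — trough latency relative to T0 (s)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks


class DetectionError(ValueError):
    pass


@dataclass
class BlinkEvents:
    """Detected blink maxima (sample indices) with template-match scores."""

    t0_samples: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.t0_samples)

    def times(self, sfreq: float) -> np.ndarray:
        return self.t0_samples / sfreq


@dataclass
class Morphology:
    m1: float   # µV (or the trace's amplitude unit)
    m2: float   # s
    m3: float   # µV
    m4: float   # s

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.m3, self.m4])

    @property
    def defined(self) -> bool:
        return not np.any(np.isnan(self.as_array()))


def sliding_correlation(trace: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of every length-m window of ``trace`` with
    ``template`` (valid windows only; scale- and offset-invariant)."""
    m = len(template)
    if m > len(trace):
        raise DetectionError("template longer than trace")
    tz = template - template.mean()
    tnorm = np.linalg.norm(tz)
    if tnorm == 0:
        raise DetectionError("flat template (zero variance)")
    tz = tz / tnorm
    # numerator: since tz is zero-mean, sum(tz * (x - x̄)) = sum(tz * x)
    num = fftconvolve(trace, tz[::-1], mode="valid")
    csum = np.concatenate([[0.0], np.cumsum(trace)])
    csum2 = np.concatenate([[0.0], np.cumsum(trace * trace)])
    wsum = csum[m:] - csum[:-m]
    wsum2 = csum2[m:] - csum2[:-m]
    ssx = np.maximum(wsum2 - wsum * wsum / m, 0.0)
    denom = np.sqrt(ssx)
    corr = np.zeros_like(num)
    ok = denom > 0
    corr[ok] = num[ok] / denom[ok]
    return np.clip(corr, -1.0, 1.0)


def detect_blinks(veog: np.ndarray, template: np.ndarray, sfreq: float,
                  match_thresh: float = 0.7, min_gap: float = 3.0,
                  amp_frac: float = 0.5, merge_window: float = 0.5) -> BlinkEvents:
    """Template-matching blink detector.

    1. sliding Pearson correlation of the trace with the template;
    2. local correlation maxima above ``match_thresh`` become candidates,
       candidates within ``merge_window`` s collapse to the best-scoring one;
    3. the candidate's vEOG peak must reach ``amp_frac`` times the template
       peak (amplitude threshold);
    4. temporal threshold: each member of any pair of surviving blinks less
       than ``min_gap`` s apart is removed;
    5. T0 is the vEOG maximum within the matched window.
    """
    veog = np.asarray(veog, dtype=float)
    if veog.size == 0:
        raise DetectionError("empty trace")
    if not 0 < match_thresh < 1:
        raise DetectionError("match_thresh must lie in (0, 1)")
    if min_gap < 0:
        raise DetectionError("min_gap must be non-negative")
    m = len(template)
    corr = sliding_correlation(veog, template)
    starts, props = find_peaks(corr, height=match_thresh,
                               distance=max(int(merge_window * sfreq), 1))
    scores = props["peak_heights"]

    peak_amp = np.max(template)
    t0s, kept_scores = [], []
    for s, sc in zip(starts, scores):
        window = veog[s:s + m]
        t0 = s + int(np.argmax(window))
        if veog[t0] >= amp_frac * peak_amp:
            t0s.append(t0)
            kept_scores.append(sc)
    t0s = np.asarray(t0s, dtype=int)
    kept_scores = np.asarray(kept_scores, dtype=float)
    if len(t0s) > 1:  # collapse duplicate T0 from adjacent windows
        order = np.argsort(t0s)
        t0s, kept_scores = t0s[order], kept_scores[order]
        uniq = np.concatenate([[True], np.diff(t0s) > merge_window * sfreq])
        t0s, kept_scores = t0s[uniq], kept_scores[uniq]

    # temporal threshold: drop BOTH members of any close pair
    if len(t0s) > 1 and min_gap > 0:
        gaps = np.diff(t0s) / sfreq
        too_close_prev = np.concatenate([[False], gaps < min_gap])
        too_close_next = np.concatenate([gaps < min_gap, [False]])
        keep = ~(too_close_prev | too_close_next)
        t0s, kept_scores = t0s[keep], kept_scores[keep]
    return BlinkEvents(t0_samples=t0s, scores=kept_scores)


def _interp_crossing(x: np.ndarray, i: int, j: int) -> float:
    """Fractional index where x crosses zero between samples i and j."""
    if x[i] == x[j]:
        return float(i)
    return i + (0.0 - x[i]) / (x[j] - x[i]) * (j - i)


def extract_morphology(avg_blink: np.ndarray, sfreq: float,
                       t0_index: int | None = None) -> Morphology:
    """M1–M4 from a trial-averaged blink trace time-locked at its maximum.

    Features without a defining landmark (e.g. no zero crossing bounding the
    positive lobe, no trough after it) are returned as NaN.
    """
    x = np.asarray(avg_blink, dtype=float)
    if t0_index is None:
        t0_index = int(np.argmax(x))
    m1 = float(x[t0_index])
    if m1 <= 0:
        raise DetectionError("trace maximum is not positive")

    # crossing search uses a tiny relative threshold so float-epsilon values
    # at the lobe boundary do not shift the detected crossing by a sample
    zero = 1e-6 * m1
    below_left = np.flatnonzero(x[:t0_index] <= zero)
    below_right = t0_index + 1 + np.flatnonzero(x[t0_index + 1:] <= zero)
    if len(below_left) == 0 or len(below_right) == 0:
        m2 = math.nan
        right_edge = t0_index
    else:
        li = below_left[-1]
        ri = below_right[0]
        left = _interp_crossing(x, li, li + 1)
        right = _interp_crossing(x, ri - 1, ri)
        m2 = (right - left) / sfreq
        right_edge = ri
    after = x[right_edge:]
    if len(after) == 0 or np.min(after) >= 0:
        m3, m4 = math.nan, math.nan
    else:
        k = right_edge + int(np.argmin(after))
        m3 = float(x[k])
        m4 = (k - t0_index) / sfreq
    return Morphology(m1=m1, m2=m2, m3=m3, m4=m4)


def normalized_average(subject_epochs: list[np.ndarray]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject blink averages normalized to their own maxima, plus the
    grand average across subjects.

    Each element of ``subject_epochs`` is (n_epochs, n_time) for one
    subject.  Normalizing before grand-averaging stops large-amplitude
    subjects from dominating the group waveform.
    """
    per_subject = []
    for ep in subject_epochs:
        ep = np.atleast_2d(np.asarray(ep, dtype=float))
        avg = ep.mean(axis=0)
        peak = np.max(np.abs(avg))
        if peak == 0:
            raise DetectionError("zero-amplitude subject average")
        per_subject.append(avg / np.max(avg))
    per_subject = np.asarray(per_subject)
    return per_subject, per_subject.mean(axis=0)


@dataclass
class SplitHalfResult:
    mean_rho: np.ndarray      # per feature
    n_dropped: np.ndarray     # undefined-correlation repetitions per feature
    consistent: bool          # all features above the consistency criterion


def split_half_reliability(values: np.ndarray, n_reps: int = 1000,
                           seed: int = 0, criterion: float = 0.8
                           ) -> SplitHalfResult:
    """Sorted split-half consistency of per-subject feature values.

    Per repetition the subjects are randomly split into two equal halves
    (odd n: one subject dropped at random), the values in each half are
    sorted, and the sorted vectors correlated (Pearson).  The mean
    correlation per feature over ``n_reps`` is returned; repetitions with a
    constant half (undefined correlation) are excluded from the mean.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim == 1:
        values = values[:, None]
    n_subj, n_feat = values.shape
    if n_subj < 4:
        raise DetectionError("need at least 4 subjects for split-half")
    rng = np.random.default_rng(seed)
    sums = np.zeros(n_feat)
    counts = np.zeros(n_feat, dtype=int)
    for _ in range(n_reps):
        perm = rng.permutation(n_subj)
        if n_subj % 2:
            perm = perm[:-1]
        half = len(perm) // 2
        a = np.sort(values[perm[:half]], axis=0)
        b = np.sort(values[perm[half:]], axis=0)
        for f in range(n_feat):
            sa, sb = a[:, f].std(), b[:, f].std()
            if sa == 0 or sb == 0:
                continue
            rho = np.corrcoef(a[:, f], b[:, f])[0, 1]
            sums[f] += rho
            counts[f] += 1
    mean_rho = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_dropped = n_reps - counts
    consistent = bool(np.all(mean_rho > criterion))
    return SplitHalfResult(mean_rho=mean_rho, n_dropped=n_dropped,
                           consistent=consistent)
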