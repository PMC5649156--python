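"""Shared statistics: paired t, bootstrap CIs, permutation cluster test.

The cluster test compares two paired sets of time courses with a pointwise
paired t-test; contiguous runs of samples beyond the two-sided critical t
form clusters (positive and negative separately, so deflection signs are
reportable).  The null distribution of the maximum cluster size is built by
randomly swapping the two conditions within subjects; a cluster's p-value is
the fraction of null maxima at least as large, with the observed statistic
included in the null (so p >= 1/(n_perm+1), never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class PairedTResult:
    t: float
    p: float
    df: int
    zero_variance: bool = False


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTResult:
    """Two-sided paired t-test; zero-variance differences give t=0, p=1
    (flagged) rather than NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise StatsError("paired t needs two equal-length vectors, n >= 2")
    d = x - y
    df = len(d) - 1
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTResult(t=0.0, p=1.0, df=df, zero_variance=True)
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return PairedTResult(t=float(t), p=float(p), df=df)


def bonferroni(p: float | np.ndarray, m: int) -> np.ndarray:
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


def bootstrap_ci(series: np.ndarray, level: float = 0.95, n_boot: int = 1000,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI of the across-subject mean, per time point.

    ``series`` is (n_subjects, n_time); returns (lo, hi) arrays.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_subj = series.shape[0]
    if n_subj < 4:
        raise StatsError("need at least 4 subjects for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    means = series[idx].mean(axis=1)          # (n_boot, n_time)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(means, alpha, axis=0)
    hi = np.quantile(means, 1.0 - alpha, axis=0)
    return lo, hi


# ---------------------------------------------------------------------------
# max-suprathreshold-cluster permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: float      # s (or sample index when no time axis is given)
    end: float
    size: int         # samples
    sign: int         # +1 / -1
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max_sizes: np.ndarray
    t_values: np.ndarray
    t_critical: float

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _pointwise_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t per time point from difference time courses (n_subj, n_time)."""
    n = diffs.shape[0]
    sd = diffs.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return diffs.mean(axis=0) / (sd / np.sqrt(n))


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of contiguous True runs."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Maximum contiguous-True run length per row of a boolean matrix.

    Vectorized: within-row cumulative counts minus the cumulative count at
    the last False give the current run length at every position.
    """
    masks = np.atleast_2d(masks)
    s = np.cumsum(masks, axis=1)
    base = np.maximum.accumulate(np.where(masks, 0, s), axis=1)
    return (s - base).max(axis=1)


def cluster_permutation(ts_a: np.ndarray, ts_b: np.ndarray,
                        times: np.ndarray | None = None,
                        t_thresh_alpha: float = 0.05, n_perm: int = 5000,
                        seed: int = 0) -> ClusterResult:
    """Max-cluster permutation test between paired condition time courses.

    ``ts_a``/``ts_b`` are (n_subjects, n_time).  Cluster mass is the sample
    count.  Within-subject condition labels are swapped at random per
    permutation; the null records the maximum suprathreshold cluster size
    over the |t| mask.
    """
    ts_a = np.atleast_2d(np.asarray(ts_a, dtype=float))
    ts_b = np.atleast_2d(np.asarray(ts_b, dtype=float))
    if ts_a.shape != ts_b.shape:
        raise StatsError("condition arrays must have identical shape")
    n_subj, n_time = ts_a.shape
    if n_subj < 4:
        raise StatsError("need at least 4 subjects")
    if n_perm < 100:
        raise StatsError("n_perm must be at least 100")
    diffs = ts_a - ts_b
    t_crit = float(sps.t.ppf(1.0 - t_thresh_alpha / 2.0, n_subj - 1))
    t_obs = _pointwise_t(diffs)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # vectorized permuted t: mean and sd of sign-flipped diffs
    m = flips @ diffs / n_subj                               # (n_perm, n_time)
    ex2 = np.mean(diffs * diffs, axis=0)[None, :]            # flips square away
    var = (ex2 - m * m) * n_subj / (n_subj - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[sd == 0] = np.inf
    t_null = m / (sd / np.sqrt(n_subj))
    # null max cluster size, with positive and negative clusters formed
    # separately (same definition as the observed clusters)
    null_max = np.maximum(_max_run_lengths(t_null > t_crit),
                          _max_run_lengths(t_null < -t_crit))

    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_obs) > t_crit
        for a, b in _clusters_from_mask(mask):
            size = b - a
            p = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
            if times is not None:
                start, end = float(times[a]), float(times[b - 1])
            else:
                start, end = float(a), float(b - 1)
            clusters.append(Cluster(start=start, end=end, size=size,
                                    sign=sign, p=float(p)))
    clusters.sort(key=lambda c: c.start)
    return ClusterResult(clusters=clusters, null_max_sizes=null_max,
                         t_values=t_obs, t_critical=t_crit)


def sign_flip_test(deltas: np.ndarray, n_perm: int = 5000, seed: int = 0,
                   alternative: str = "greater") -> tuple[float, float]:
    """Paired sign-flip permutation test on per-subject differences.

    Statistic: the group mean difference.  Returns (observed, p) with the
    observed statistic included in the null.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if n < 4:
        raise StatsError("need at least 4 subjects")
    rng = np.random.default_rng(seed)
    if n_perm >= 2 ** n:  # exhaustive enumeration is cheaper and exact
        signs = np.array(np.meshgrid(*([[-1.0, 1.0]] * n))).reshape(n, -1).T
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    observed = float(deltas.mean())
    null = signs @ deltas / n
    if alternative == "greater":
        p = (1.0 + np.sum(null >= observed)) / (len(null) + 1.0)
    elif alternative == "two-sided":
        p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (len(null) + 1.0)
    else:
        raise StatsError("alternative must be 'greater' or 'two-sided'")
    return observed, float(p)
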