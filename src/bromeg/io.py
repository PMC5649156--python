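"""On-disk formats: HDF5 recordings, CSV event files, TOML configuration.

HDF5 layout for a recording::

    /data          (n_rows, n_samp) float64 — MEG rows in T, EOG rows in V
    /times         (n_samp,) s
    /sfreq         scalar
    /channels/labels, /channels/types        fixed-length strings
    /channels/positions, /channels/orientations  (n_meg, 3)
    /channels/regions                        fixed-length strings
    /geometry/*    duplicate of the /channels geometry datasets

Event files are CSV with columns ``t0_sample,t0_seconds,score``, sorted by
sample.  Cohort manifests are CSV with columns ``subject,recording,events``
(the events path may be empty to request in-pipeline detection).
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .blinks import BlinkEvents
from .headmodel import SensorArray
from .simulate import Recording


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    meg_rows = [i for i, t in enumerate(rec.types) if t == "meg"]
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("times", data=rec.times)
        f.create_dataset("sfreq", data=float(rec.sfreq))
        ch = f.create_group("channels")
        ch.create_dataset("labels", data=np.array(rec.labels, dtype="S32"))
        ch.create_dataset("types", data=np.array(rec.types, dtype="S8"))
        ch.create_dataset("positions", data=rec.array.positions)
        ch.create_dataset("orientations", data=rec.array.orientations)
        ch.create_dataset("regions", data=np.array(rec.array.regions, dtype="S16"))
        ch.create_dataset("baseline", data=float(rec.array.baseline))
        geo = f.create_group("geometry")
        for name in ("positions", "orientations", "regions"):
            geo[name] = ch[name]
        assert len(meg_rows) == rec.array.n_chan


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        for ds in ("data", "times", "sfreq", "channels"):
            if ds not in f:
                raise FormatError(f"missing dataset /{ds} in {path}")
        sfreq = float(f["sfreq"][()])
        if sfreq <= 0:
            raise FormatError("/sfreq must be positive")
        data = f["data"][()]
        ch = f["channels"]
        labels = [s.decode() for s in ch["labels"][()]]
        types = [s.decode() for s in ch["types"][()]]
        array = SensorArray(positions=ch["positions"][()],
                            orientations=ch["orientations"][()],
                            baseline=float(ch["baseline"][()]),
                            labels=[l for l, t in zip(labels, types) if t == "meg"],
                            regions=np.array([s.decode() for s in ch["regions"][()]]))
    return Recording(data=data, sfreq=sfreq, array=array, labels=labels,
                     types=types)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def write_events(events: BlinkEvents, sfreq: float, path) -> None:
    df = pd.DataFrame({"t0_sample": events.t0_samples,
                       "t0_seconds": events.t0_samples / sfreq,
                       "score": events.scores})
    df.to_csv(path, index=False)


def read_events(path) -> BlinkEvents:
    df = pd.read_csv(path)
    for col in ("t0_sample", "t0_seconds", "score"):
        if col not in df.columns:
            raise FormatError(f"events file missing column {col}")
    t0 = df["t0_sample"].to_numpy(dtype=int)
    if len(t0) > 1 and (np.any(np.diff(t0) <= 0)):
        raise FormatError("event samples must be sorted and unique")
    return BlinkEvents(t0_samples=t0, scores=df["score"].to_numpy(dtype=float))


def write_ground_truth(blink_times: np.ndarray, path) -> None:
    pd.DataFrame({"t0_seconds": blink_times}).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("subject", "recording"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col}")
    if df["subject"].duplicated().any():
        raise FormatError("manifest subject ids must be unique")
    if "events" not in df.columns:
        df["events"] = ""
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Analysis tunables.  Defaults are the canonical BRO protocol values:
    3-s epochs, 3-s blink exclusion, 0.5-45 Hz broadband, 0.5-4 Hz delta,
    six-cycle wavelets, 150-350 ms / -1300..-1100 ms contrast windows,
    -1500..-500 ms log-power baseline, 1000 split-half repetitions, 5000
    cluster permutations, 8 mm smoothing, 5 mm VOIs."""

    meg_band: tuple[float, float] = (0.5, 45.0)   # broadband MEG filter, Hz
    eog_band: tuple[float, float] = (0.1, 30.0)   # vEOG filter for detection, Hz
    notch_hz: float = 60.0                        # power-line notch (0 = off)
    match_thresh: float = 0.7                     # template-correlation threshold
    amp_frac: float = 0.5                         # amplitude threshold vs template peak
    min_gap: float = 3.0                          # s, exclude blinks closer than this
    merge_window: float = 0.5                     # s, collapse duplicate matches
    epoch_half_width: float = 1.5                 # s (3-s epochs)
    ratio_blink_latency: float = 0.0              # s, power-ratio numerator latency
    ratio_base_latency: float = -1.0              # s, power-ratio baseline latency
    ica_components: int = 20
    ica_corr_thresh: float = 0.7                  # |r| vs vEOG to flag a component
    delta_band: tuple[float, float] = (0.5, 4.0)  # Hz
    tf_freq_range: tuple[float, float] = (0.5, 6.0)
    tf_freq_step: float = 0.25
    n_cycles: float = 6.0                         # Morlet cycles
    post_win: tuple[float, float] = (0.150, 0.350)    # s, spans the GFP peak
    pre_win: tuple[float, float] = (-1.300, -1.100)   # s, pre-event baseline
    tf_base_win: tuple[float, float] = (-1.5, -0.5)   # s, log-power baseline
    split_half_reps: int = 1000
    n_perm_spectral: int = 5000
    n_perm_cluster: int = 5000                    # VOI cluster permutations
    n_perm_fwe: int = 1000
    cluster_alpha: float = 0.05                   # cluster-forming threshold
    lam: float = 0.05                             # relative Tikhonov regularization
    smooth_fwhm: float = 0.008                    # m (8 mm)
    voi_radius: float = 0.005                     # m (5 mm)
    voi_names: tuple[str, ...] = ("precuneus_left", "precuneus_right")
    grid_spacing: float = 0.01                    # m, source-shell spacing

    def tf_freqs(self) -> np.ndarray:
        lo, hi = self.tf_freq_range
        return np.arange(lo, hi + self.tf_freq_step / 2, self.tf_freq_step)

    def hash(self) -> str:
        payload = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


_TUPLE_FIELDS = {"meg_band", "eog_band", "delta_band", "tf_freq_range",
                 "post_win", "pre_win", "tf_base_win", "voi_names"}


def load_config(path) -> Config:
    """Read a TOML config; unknown keys are rejected."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS else v for k, v in raw.items()}
    cfg = Config(**kwargs)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Config) -> None:
    for name in ("meg_band", "eog_band", "delta_band", "tf_freq_range"):
        lo, hi = getattr(cfg, name)
        if not 0 <= lo < hi:
            raise FormatError(f"invalid band {name}={lo, hi}")
    if not 0 < cfg.match_thresh < 1:
        raise FormatError("match_thresh must lie in (0, 1)")
    if cfg.min_gap < 0 or cfg.epoch_half_width <= 0:
        raise FormatError("min_gap/epoch_half_width out of range")
    for name in ("n_perm_spectral", "n_perm_cluster", "n_perm_fwe",
                 "split_half_reps"):
        if getattr(cfg, name) < 1:
            raise FormatError(f"{name} must be positive")
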