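"""Synthetic MEG + vEOG generator with planted ground truth.

Emulates a resting fixation recording from an axial-gradiometer helmet:

* spontaneous blinks as a refractory Poisson process (default 11.3/min,
  minimum gap 3 s),
* a vertical-EOG channel carrying a biphasic blink waveform (positive peak
  43.70 µV, 0.329 s wide, followed by a −10.07 µV trough 0.399 s after the
  peak) plus pink noise,
* an ocular artifact dipole anterior-inferior in the conductor whose time
  course follows the blink train, producing a frontally concentrated field,
* background activity: per-channel 1/f noise, a posterior 10 Hz (alpha)
  source with a slowly varying envelope, and white sensor noise,
* a blink-locked delta-band cortical response planted at the left/right
  precuneus-proxy grid points, peaking ``neural_latency`` (default 250 ms)
  after each blink maximum.

All randomness flows from one master seed through named substreams, spawned
in a fixed order: (0) blink times, (1) vEOG noise, (2) background 1/f,
(3) alpha source, (4) sensor white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .headmodel import (SensorArray, SourceGrid, _tangent_basis,
                        build_sensor_array, build_source_grid,
                        gradiometer_output)


class InvalidParamsError(ValueError):
    """Waveform or generator parameters outside their valid domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BlinkWaveformParams:
    """Biphasic vEOG blink morphology (generator-side M1–M4).

    pos_amp : positive peak amplitude, µV (M1)
    pos_width : zero-crossing width of the positive lobe, s (M2)
    neg_amp : negative trough amplitude, µV (M3, < 0)
    neg_time : trough latency after the positive peak, s (M4)
    """

    pos_amp: float = 43.70
    pos_width: float = 0.329
    neg_amp: float = -10.07
    neg_time: float = 0.399

    def validate(self) -> None:
        if self.pos_amp <= 0 or self.neg_amp >= 0 or self.neg_time <= 0:
            raise InvalidParamsError("need pos_amp > 0, neg_amp < 0, neg_time > 0")
        if self.neg_time <= self.pos_width / 2:
            raise InvalidParamsError("trough latency lies inside the positive lobe")


@dataclass
class RecordingConfig:
    """Study conditions for one synthetic subject (defaults = full scale)."""

    n_chan: int = 151
    sfreq: float = 1200.0
    duration: float = 600.0          # s (10 min runs)
    helmet_radius: float = 0.11      # m
    conductor_radius: float = 0.09   # m
    baseline: float = 0.05           # m, gradiometer coil separation
    shell_radius: float = 0.07       # m, source shell
    grid_spacing: float = 0.01       # m
    blink_rate: float = 11.3         # per minute
    refractory: float = 3.0          # s, minimum inter-blink gap
    blink_margin: float = 1.6        # s, keep blinks clear of recording edges
    waveform: BlinkWaveformParams = field(default_factory=BlinkWaveformParams)
    veog_noise_uv: float = 3.0       # pink-noise RMS on the vEOG channel
    ocular_moment: float = 2.0e-7    # A·m, artifact dipole at blink peak
    neural_moment: float = 2.5e-8    # A·m, planted response at source peak
    neural_latency: float = 0.25     # s after blink maximum
    background_rms: float = 250e-15  # T, per-channel 1/f noise
    alpha_rms: float = 120e-15       # T, posterior 10 Hz rhythm at sensors
    sensor_noise_rms: float = 40e-15  # T, white noise per channel

    @classmethod
    def desk_scale(cls, **overrides) -> "RecordingConfig":
        """Reduced problem size for desk-scale cohorts: fewer channels, lower
        sample rate, shorter run (still ~60 usable blinks at the default
        rate), coarser source grid.  Signal/noise levels are unchanged."""
        cfg = cls(n_chan=32, sfreq=200.0, duration=480.0, grid_spacing=0.02)
        return replace(cfg, **overrides)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sfreq))


@dataclass
class Recording:
    """Continuous multichannel data: MEG rows in T, the vEOG row in V."""

    data: np.ndarray                 # (n_chan + 1, n_samp)
    sfreq: float
    array: SensorArray
    labels: list[str]
    types: list[str]                 # 'meg' or 'eog' per row

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    @property
    def meg(self) -> np.ndarray:
        idx = [i for i, t in enumerate(self.types) if t == "meg"]
        return self.data[idx]

    @property
    def veog(self) -> np.ndarray:
        idx = [i for i, t in enumerate(self.types) if t == "eog"]
        return self.data[idx[0]]


@dataclass
class GroundTruth:
    """What was planted: blink instants and the hidden source structure."""

    blink_times: np.ndarray          # s, sorted, gaps >= refractory
    ocular_gain: np.ndarray          # (n_chan,) field of the artifact dipole
    ocular_timecourse: np.ndarray    # (n_samp,) unit-peak artifact drive
    neural_source_indices: list[int]
    neural_latency: float
    neural_moment: float
    neural_kernel: np.ndarray        # unit-peak response, relative to T0
    neural_kernel_times: np.ndarray
    grid: SourceGrid


# ---------------------------------------------------------------------------
# blink timing and waveforms
# ---------------------------------------------------------------------------

def generate_blink_times(duration: float, rate: float = 11.3,
                         refractory: float = 3.0, seed: int | None = 0,
                         margin: float = 1.6,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Homogeneous Poisson blink instants, thinned to a minimum gap.

    Candidate events are drawn at ``rate`` per minute on
    (margin, duration - margin); any candidate closer than ``refractory`` to
    the previously accepted blink is discarded (dead-time thinning).
    """
    if duration <= 0:
        raise InvalidParamsError("duration must be positive")
    if rate < 0 or refractory < 0:
        raise InvalidParamsError("rate and refractory must be non-negative")
    if rate == 0:
        return np.array([])
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = rate / 60.0
    lo, hi = margin, duration - margin
    if hi <= lo:
        return np.array([])
    n = rng.poisson(lam * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, size=n))
    kept: list[float] = []
    for t in cand:
        if not kept or t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def blink_waveform(params: BlinkWaveformParams, sfreq: float,
                   margin: float = 0.1) -> np.ndarray:
    """Biphasic vEOG blink template, µV, with ``margin`` s of zeros around it.

    Positive lobe: half-cosine of amplitude ``pos_amp`` spanning exactly
    ``pos_width`` between its zero crossings, peak at T0 (the array argmax).
    Negative lobe: smooth squared-sine dip starting at the trailing zero
    crossing, with its trough ``neg_time`` after T0 and depth ``neg_amp``.
    """
    params.validate()
    half = params.pos_width / 2.0
    neg_width = 2.0 * (params.neg_time - half)
    t = np.arange(-margin - half, half + neg_width + margin + 1.0 / sfreq,
                  1.0 / sfreq)
    y = np.zeros_like(t)
    pos = np.abs(t) < half
    y[pos] = params.pos_amp * np.cos(np.pi * t[pos] / params.pos_width)
    neg = (t >= half) & (t <= half + neg_width)
    y[neg] = params.neg_amp * np.sin(np.pi * (t[neg] - half) / neg_width) ** 2
    return y


def neural_response_kernel(sfreq: float, latency: float = 0.25
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak delta-band response kernel relative to the blink maximum.

    Triphasic Hann-lobe waveform: the main positive deflection (0.4 s wide)
    peaks at ``latency``; the dominant trailing negativity (0.5 s wide,
    −0.52 relative amplitude) troughs 0.45 s later (~700 ms post-blink at
    the default latency); a small leading negativity (0.4 s wide, −0.35)
    precedes it.  Amplitudes are chosen so the kernel integrates to zero
    and ≥95% of its power lies in the delta band (0.5–4 Hz).
    """
    lobes = [(latency, 0.4, 1.0),
             (latency - 0.35, 0.4, -0.35),
             (latency + 0.45, 0.5, -0.52)]
    t_lo = latency - 0.35 - 0.2 - 0.05
    t_hi = latency + 0.45 + 0.25 + 0.05
    t = np.arange(t_lo, t_hi + 1.0 / sfreq, 1.0 / sfreq)
    y = np.zeros_like(t)
    for center, width, amp in lobes:
        m = np.abs(t - center) < width / 2
        y[m] += amp * np.cos(np.pi * (t[m] - center) / width) ** 2
    return y, t


def _event_train(n_samp: int, sfreq: float, event_times: np.ndarray,
                 kernel: np.ndarray, kernel_start: float) -> np.ndarray:
    """Sum of kernels; kernel sample 0 lands ``kernel_start`` s after each
    event time (nearest sample).  Parts falling outside the record are cut."""
    out = np.zeros(n_samp)
    starts = np.round((event_times + kernel_start) * sfreq).astype(int)
    m = len(kernel)
    for s in starts:
        a, b = max(s, 0), min(s + m, n_samp)
        if a < b:
            out[a:b] += kernel[a - s:b - s]
    return out


def _pink_noise(rng: np.random.Generator, n_chan: int, n_samp: int,
                sfreq: float, rms: float, f_floor: float = 0.1) -> np.ndarray:
    """1/f-spectrum noise, independent per channel, normalized to ``rms``."""
    white = rng.standard_normal((n_chan, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    shape = 1.0 / np.sqrt(np.maximum(f, f_floor))
    shape[0] = 0.0
    spec *= shape
    out = np.fft.irfft(spec, n=n_samp, axis=1)
    scale = out.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return out / scale * rms


# ---------------------------------------------------------------------------
# full recording
# ---------------------------------------------------------------------------

def generate_recording(config: RecordingConfig | None = None, seed: int = 0,
                       array: SensorArray | None = None,
                       grid: SourceGrid | None = None,
                       ) -> tuple[Recording, GroundTruth]:
    """One synthetic subject: continuous MEG + vEOG plus its ground truth.

    Pass a prebuilt ``array``/``grid`` to share geometry (and its lead-field
    computation) across a cohort.
    """
    if config is None:
        config = RecordingConfig()
    ss = np.random.SeedSequence(seed)
    rng_blinks, rng_veog, rng_bg, rng_alpha, rng_sensor = \
        [np.random.default_rng(s) for s in ss.spawn(5)]

    if array is None:
        array = build_sensor_array(config.n_chan, config.helmet_radius,
                                   config.baseline, seed=0)
    if grid is None:
        grid = build_source_grid(config.grid_spacing, config.shell_radius,
                                 config.conductor_radius)
    n_samp = config.n_samples
    sfreq = config.sfreq

    blink_times = generate_blink_times(config.duration, config.blink_rate,
                                       config.refractory, margin=config.blink_margin,
                                       rng=rng_blinks)

    # --- vEOG channel (µV internally, stored in V) ---------------------------
    wave = blink_waveform(config.waveform, sfreq)
    wave_start = -(int(np.argmax(wave)) / sfreq)  # template peak sits at T0
    veog_clean = _event_train(n_samp, sfreq, blink_times, wave, wave_start)
    veog = veog_clean + _pink_noise(rng_veog, 1, n_samp, sfreq,
                                    config.veog_noise_uv)[0]

    # --- ocular artifact dipole ----------------------------------------------
    ocular_pos = 0.91 * config.conductor_radius * \
        np.array([0.9, 0.15, -0.35]) / np.linalg.norm([0.9, 0.15, -0.35])
    ocular_dir = _tangent_basis(ocular_pos[None])[0, 1]  # vertical-ish tangent
    ocular_gain = gradiometer_output(array, ocular_pos, ocular_dir)
    ocular_tc = _event_train(n_samp, sfreq, blink_times,
                             wave / wave.max(), wave_start)
    meg = config.ocular_moment * np.outer(ocular_gain, ocular_tc)

    # --- planted blink-locked neural response --------------------------------
    kernel, kernel_t = neural_response_kernel(sfreq, config.neural_latency)
    neural_tc = _event_train(n_samp, sfreq, blink_times, kernel, kernel_t[0])
    src_indices = [grid.names["precuneus_left"], grid.names["precuneus_right"]]
    for j in src_indices:
        direction = _tangent_basis(grid.coords[j][None])[0, 0]
        gain = gradiometer_output(array, grid.coords[j], direction)
        meg += config.neural_moment * np.outer(gain, neural_tc)

    # --- background: 1/f + posterior alpha + sensor white noise --------------
    meg += _pink_noise(rng_bg, array.n_chan, n_samp, sfreq, config.background_rms)
    alpha_pos = config.shell_radius * \
        np.array([-0.85, 0.0, 0.35]) / np.linalg.norm([-0.85, 0.0, 0.35])
    alpha_dir = _tangent_basis(alpha_pos[None])[0, 0]
    alpha_gain = gradiometer_output(array, alpha_pos, alpha_dir)
    phase = rng_alpha.uniform(0, 2 * np.pi)
    envelope = np.abs(_pink_noise(rng_alpha, 1, n_samp, sfreq, 1.0, f_floor=0.5)[0])
    alpha_tc = envelope * np.sin(2 * np.pi * 10.0 * np.arange(n_samp) / sfreq + phase)
    gain_rms = np.sqrt(np.mean(alpha_gain**2))
    alpha_tc *= config.alpha_rms / (gain_rms * alpha_tc.std() + 1e-300)
    meg += np.outer(alpha_gain, alpha_tc)
    meg += rng_sensor.standard_normal((array.n_chan, n_samp)) * config.sensor_noise_rms

    data = np.vstack([meg, veog[None] * 1e-6])
    labels = list(array.labels) + ["vEOG"]
    types = ["meg"] * array.n_chan + ["eog"]
    rec = Recording(data=data, sfreq=sfreq, array=array, labels=labels, types=types)
    gt = GroundTruth(blink_times=blink_times, ocular_gain=ocular_gain,
                     ocular_timecourse=ocular_tc,
                     neural_source_indices=src_indices,
                     neural_latency=config.neural_latency,
                     neural_moment=config.neural_moment,
                     neural_kernel=kernel, neural_kernel_times=kernel_t,
                     grid=grid)
    return rec, gt
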