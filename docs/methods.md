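# Methods

`bromeg` implements a complete analysis chain for blink-related oscillations
(BROs) in MEG: spontaneous blinks are detected on a vertical EOG channel,
ocular artifact is removed by ICA, and the blink-locked delta-band (0.5–4 Hz)
brain response is characterized at the sensor level (global field power,
Morlet time-frequency) and at the source level (minimum-norm inverse,
permutation familywise-error maps, virtual-electrode time courses). A
synthetic MEG + vEOG generator with planted ground truth provides the test
bed: every statistical claim the package makes is validated against data
whose true structure is known.

## Forward model and geometry

The head is a single homogeneous sphere. For MEG this loses essentially
nothing: the magnetic field outside a spherically symmetric conductor is
independent of the conductivity profile, and radial ("silent") sources
produce no field at all. Fields are computed with the closed-form solution
for a current dipole in a sphere; sensors are axial gradiometers — two
coaxial coils separated by a 5 cm baseline along the radial direction —
modeled as a two-point difference of the radial field, and arranged
quasi-uniformly (golden-angle spiral) on an upper spherical cap of radius
0.11 m around a conductor of radius 0.09 m.

Channels are partitioned into frontal / central / parietal / temporal /
occipital regions by fixed azimuth–elevation sectors in the helmet frame
(+x anterior, +y left, +z superior): low lateral sensors are temporal, low
anterior frontal, low posterior occipital, and the superior crown splits
into central (anterior) and parietal (posterior).

Sources live on a spherical shell of radius 0.07 m, cut below half the shell
radius (MEG has no sensitivity, and there is no cortex, far below the
helmet), with two tangential orientations per point (the radial orientation
is magnetically silent and excluded by construction). Default shell spacing
is 10 mm. Two named proxy points for the left and right precuneus are
registered by scaling the MNI directions [−8, −68, 49] and [7, −68, 39] mm
onto the shell; no real anatomy is involved — only relative geometry matters
here.

## Synthetic data

One simulated subject is a continuous multichannel recording (defaults: 151
channels at 1200 Hz for 10 min) containing:

* **Blinks** — a homogeneous Poisson process at 11.3 blinks/min thinned to a
  3 s minimum gap (dead time), clear of the recording edges by 1.6 s.
* **vEOG** — each blink contributes a biphasic waveform with positive peak
  43.70 µV, positive-lobe zero-crossing width 0.329 s, trailing trough
  −10.07 µV at 0.399 s after the peak (the M1–M4 morphology parameters),
  plus 3 µV RMS pink noise.
* **Ocular artifact** — an equivalent dipole anterior–inferior in the
  conductor whose moment follows the blink train (200 nA·m at the blink
  peak), yielding the frontally concentrated artifact topography.
* **Blink-locked neural response** — a triphasic delta-band kernel planted
  at both precuneus proxies (25 nA·m peak): the main positive deflection
  peaks 250 ms after the blink maximum, the dominant trailing negativity
  troughs near 700 ms, and a small leading negativity precedes the peak.
  The kernel integrates to zero and ≥95% of its power lies in 0.5–4 Hz.
* **Background** — per-channel 1/f noise (250 fT RMS), a posterior 10 Hz
  source with a slowly varying envelope (120 fT RMS at the sensors), and
  40 fT white sensor noise. These levels put the single-trial blink-locked
  delta response around −10 dB, so the effect emerges only after averaging
  on the order of 60 trials — the regime the pipeline is designed for.

All randomness derives from one master seed through fixed-order substreams
(blink times, vEOG noise, background, alpha, sensor noise), so components
can be switched off (e.g. a null cohort with zero ocular and neural
amplitude) without perturbing the others.

What the generator does **not** emulate: head movement, saccades and cardiac
artifact, correlated sensor noise, inter-subject anatomical variability, and
non-stationary background. Passing tests therefore demonstrate that the
pipeline recovers a known blink-locked delta source under realistic SNR —
not that it is robust to every artifact class in real recordings.

`RecordingConfig.desk_scale()` is the reduced preset used by the test suite
and the acceptance script: 32 channels at 200 Hz for 480 s (~60 usable
blinks at the default rate) with 20 mm source spacing. Signal and noise
*levels* are unchanged; only the problem size shrinks.

## Blink detection and morphology

The vEOG is band-passed to 0.1–30 Hz and scanned with a sliding-window
Pearson correlation against a blink template (default: the canonical
waveform above; a subject-specific template may be supplied). Correlation is
scale- and offset-invariant, so one threshold (default 0.7) works across
subjects. Candidate matches within 0.5 s collapse to the best-scoring one;
a candidate must also reach half the template's peak amplitude. T0 — the
blink maximum, taken as full eye closure — is the vEOG peak inside the
matched window. Finally, *both* members of any pair of blinks closer than
3 s are discarded, since each contaminates the other's epoch.

Morphology features of the trial-averaged blink: M1 = positive peak
amplitude, M2 = width of the positive lobe between its bounding zero
crossings (the width definition is configurable; zero-crossing width is the
default), M3 = trough amplitude after the positive lobe, M4 = trough latency
from T0. Per-subject averages are normalized to their own maxima before
grand averaging so large-amplitude subjects do not dominate. Group
consistency uses the sorted split-half correlation: subjects are repeatedly
(default 1000×) split into halves, each half's values sorted, and the sorted
vectors correlated; repetitions with a constant half are dropped from the
mean rather than scored as zero. With an odd subject count one subject is
dropped at random per repetition.

## Preprocessing

Filters are 4th-order Butterworth applied forward–backward (zero phase);
the broadband MEG band is 0.5–45 Hz with an optional 60 Hz notch. Epochs are
3 s: the *blink* condition is centered on each T0, and the *control*
condition takes the same number of consecutive non-overlapping 3-s epochs
from the middle of the run — pseudo-random with respect to blinks, same
data, same trial count, so it shares the noise budget but not the time
locking. Control epochs are not purged of blinks (an optional strict mode
excludes epochs whose zero falls near a T0).

ICA uses FastICA with 20 components (fit on a decimated copy when the
recording is long; the mixing model is time-invariant). Components are
canonicalized — ordered by |correlation| with the vEOG, signs fixed positive
— so identical seeds give identical decompositions. A component is flagged
as ocular when its |Pearson r| against the vEOG, filtered to the band shared
with the MEG data (0.5–30 Hz), reaches 0.7. Band matching matters: the
planted ocular component correlates ≈0.8 with the band-matched reference but
only ≈0.75 against a 0.1–30 Hz reference, because the sub-0.5 Hz vEOG
content has no counterpart in the 0.5–45 Hz MEG. The null level (next-best
component) is ≈0.09, so 0.7 separates the two regimes with wide margins.
Flagged components are removed by subtracting their contribution from the
data (`X − A_f S_f`), which preserves the variance outside the 20-component
ICA subspace.

Cleanup effectiveness is quantified by the blink-to-baseline power ratio per
sensor region: the across-channel demeaned power of the trial-averaged ERF
at the blink latency (0 ms) divided by the same at −1000 ms (a baseline
latency chosen clear of blink-related saccades). Ratios ≫ 1 indicate
blink-locked ocular power; ≈1 indicates none. Pre- vs post-ICA ratios are
compared per region with paired t-tests (Bonferroni ×5) and across regions
with a one-way repeated-measures ANOVA. Note the post-cleanup ratio at a
single latency is a noise-power ratio — approximately F-distributed with
degrees of freedom set by the region's channel count — so individual-subject
values scatter widely around 1 even for perfect cleanup; group means are the
meaningful summary.

## Sensor-level analysis

GFP is the per-time-point spatial standard deviation across channels
(classical convention; spatial variance available) of trial-averaged
delta-band data. Window statistics compare mean GFP in a 200 ms post-blink
window spanning the group GFP peak (150–350 ms) against a pre-blink baseline
window (−1300 to −1100 ms) with a paired t-test across subjects, separately
per condition. Bootstrap 95% CIs (percentile, over subjects) are computed
per time point of the grand-averaged GFP.

Time-frequency log power uses a six-cycle complex Morlet CWT over
0.5–6 Hz in 0.25 Hz steps, log10 of the squared magnitude, baseline-corrected
per trial by the mean log power in −1500 to −500 ms. The group spectral test
is a paired sign-flip permutation on the per-subject (post − pre) delta band
power, one-sided for an increase (configurable two-sided); the observed
statistic is included in its own null, so p ≥ 1/(n_perm+1).

**Boundary handling.** All band-limited quantities are computed on the
continuous recording and epoched afterwards: the delta-band filter and the
wavelet transform are applied to the full record, not to 3-s snippets.
Filtering and trial-averaging commute, so the estimator is unchanged — but
filtering short epochs leaks edge transients into the pre-event windows
(measured as a t ≈ −6.5 spurious control-condition GFP contrast over 20 null
subjects before the change, and a spurious spectral increase from wavelet
truncation near the left epoch edge). The per-epoch operations remain
available in the API (`global_field_power` with a band, `morlet_tf` on
epochs); wavelets longer than an epoch are truncated by default, with
`on_short="raise"` as the strict alternative.

## Source-level analysis

The inverse is the classical minimum-norm estimate
`s = Lᵀ(LLᵀ + λI)⁻¹ b` with λ expressed relative to the mean sensor-space
eigenvalue (λ_eff = λ·trace(LLᵀ)/n_chan, default λ = 0.05); a
discrepancy-principle helper chooses λ from the pre-event noise floor when
preferred. At λ = 0 a rank-deficient system falls back to the pseudo-inverse
with a warning. The inverse is linear, so delta-band source time courses are
obtained by inverting the continuously-filtered averaged epochs (identical
to filtering the source time courses, without epoch-boundary transients).

Per-subject contrast images are the voxelwise difference of mean delta-band
source power (orientation-summed) between the post and pre windows, smoothed
along the shell with an 8 mm FWHM Gaussian (each voxel spreads unit mass, so
total image mass is preserved exactly). Group inference is a one-sample t
per voxel with FWE control by max-|t| sign-flip permutation (exhaustive
enumeration when 2^n_subjects does not exceed the permutation budget). Four
contrasts are evaluated: Bpost>Bpre, Bpre>Bpost, Cpost>Cpre, Cpre>Cpost —
under correct operation only the first shows suprathreshold voxels, and they
include the precuneus proxies.

Virtual electrodes average estimated dipole moments over a 5 mm-radius VOI,
projected onto the VOI's dominant orientation (first principal direction of
the trial-averaged moments); the sign convention makes the post-blink
deflection positive, since an inverse solution's dipole polarity is
arbitrary. Per-trial VOI time courses are delta-filtered and averaged, and
blink vs control compared with a max-cluster permutation test: pointwise
paired t, two-sided cluster-forming threshold α = 0.05, positive and
negative clusters formed separately (so deflection signs are reportable),
cluster mass = sample count (configurable to summed |t|), null = maximum
cluster size over within-subject condition swaps, 5000 permutations by
default. On strongly autocorrelated (delta-band) series the size statistic
calibrates accurately; on white-noise-like series it is tie-heavy and
conservative — never anticonservative.

## Numerical and design choices

* Blink exclusion near the 3 s boundary: gaps are measured on detected T0
  samples, so planted pairs within T0-jitter of exactly 3 s may legitimately
  be excluded; detector recovery is therefore assessed with ±50 ms matching,
  pooled over subjects.
* Permutation p-values always include the observed statistic in the null.
* ICA determinism is secured by seeding plus canonicalization; the spectral
  bootstrap, FWE, cluster and split-half procedures take explicit seeds.
* Degenerate inputs fail loudly: flat templates, zero-amplitude averages,
  zero baseline power, empty VOIs, all-components-flagged removals, filters
  outside (0, Nyquist), windows outside the epoch.
* Desk-scale problem sizes used throughout the tests (12 subjects, 32
  channels, 200 Hz, 480 s, ~60 blinks, 20 mm grids, 500–1000 permutations)
  are the package's validation preset; the defaults remain the full-scale
  study conditions.

## Known limitations

* The spherical single-shell model has no anatomy; "precuneus" points are
  geometric proxies, and localization accuracy is only meaningful within the
  helmet-covered region (sources below the coverage rim mislocalize, as in
  real MEG).
* Minimum-norm estimates are depth-biased toward the sensors; the
  single-shell source space sidesteps rather than solves this.
* The control condition is a timing control, not a separate recording;
  inference about non-blink activity is limited accordingly.
* The ICA criterion assumes the vEOG records the dominant ocular source;
  saccadic or cardiac components without a vEOG signature would not be
  flagged automatically.
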