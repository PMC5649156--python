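"""End-to-end orchestration: subject processing, group statistics, report.

Per subject: blink detection on the vEOG, morphology, broadband filtering,
ICA ocular-artifact removal with pre/post power-ratio bookkeeping, blink and
control epoching, delta-band GFP, Morlet band power in the pre/post windows,
minimum-norm contrast images, and virtual-electrode VOI time courses.

At the group level: blink behavior (counts, rate, morphology with split-half
consistency), power-ratio t-tests/ANOVA, GFP window contrasts with bootstrap
CIs, the spectral sign-flip test, max-statistic FWE source maps for the four
contrasts (Bpost>Bpre, Bpre>Bpost, Cpost>Cpre, Cpre>Cpost), and VOI cluster
permutation tests of blink versus control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import blinks as bl
from . import preprocess as pp
from . import sensorlevel as sl
from . import sourcelevel as src
from .headmodel import LeadField, SourceGrid, build_source_grid, compute_leadfield
from .io import Config
from .simulate import (BlinkWaveformParams, Recording, RecordingConfig,
                       blink_waveform, generate_recording)
from .stats import ClusterResult, bootstrap_ci, cluster_permutation, sign_flip_test

logger = logging.getLogger("bromeg")


class PipelineError(RuntimeError):
    pass


@dataclass
class SubjectResult:
    subject: str
    n_blinks: int
    blink_rate: float                   # per minute
    scores: np.ndarray
    morphology: bl.Morphology
    avg_blink_veog: np.ndarray          # µV, trial-averaged
    ratio_rows: list[dict]
    epoch_times: np.ndarray
    gfp: dict[str, np.ndarray]          # condition -> (n_time,)
    band_power: dict[str, dict[str, float]]  # condition -> {pre, post}
    contrast_img: dict[str, np.ndarray]      # condition -> (n_vox,)
    voi_tc: dict[str, dict[str, np.ndarray]]  # voi -> condition -> (n_time,)
    n_trials: int


@dataclass
class GroupResult:
    subjects: list[str]
    grand_blink_waveform: np.ndarray   # peak-normalized, µV/µV
    blink_table: pd.DataFrame
    split_half: bl.SplitHalfResult
    ratio_table: pd.DataFrame
    ratio_stats: dict
    epoch_times: np.ndarray
    grand_gfp: dict[str, np.ndarray]
    gfp_ci: dict[str, tuple[np.ndarray, np.ndarray]]
    gfp_tests: dict[str, object]        # condition -> PairedTResult
    gfp_peak_latency: float             # s, blink-condition grand GFP argmax
    spectral: dict[str, tuple[float, float]]  # condition -> (observed, p)
    fwe: dict[str, src.GroupFWEResult]  # contrast -> result
    voi_clusters: dict[str, ClusterResult]
    grid: SourceGrid
    config_hash: str
    seed: int


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

def process_subject(rec: Recording, config: Config, subject: str = "s00",
                    seed: int = 0, leadfield: LeadField | None = None,
                    template: np.ndarray | None = None) -> SubjectResult:
    """Run the full single-subject analysis on one continuous recording."""
    sfreq = rec.sfreq
    veog_uv = rec.veog * 1e6
    veog_f = pp.bandpass(veog_uv, sfreq, *config.eog_band)
    if template is None:
        template = blink_waveform(BlinkWaveformParams(), sfreq)
    events = bl.detect_blinks(veog_f, template, sfreq,
                              match_thresh=config.match_thresh,
                              min_gap=config.min_gap,
                              amp_frac=config.amp_frac,
                              merge_window=config.merge_window)
    if len(events) < 2:
        raise PipelineError(f"subject {subject}: too few blinks detected")
    duration_min = rec.n_samples / sfreq / 60.0

    veog_epochs = pp.epoch_blink(veog_f, sfreq, events,
                                 config.epoch_half_width, subject)
    avg_blink = veog_epochs.average()
    morph = bl.extract_morphology(avg_blink, sfreq,
                                  t0_index=veog_epochs.time_index(0.0))

    meg = rec.meg
    if config.notch_hz:
        meg = pp.notch_filter(meg, sfreq, config.notch_hz)
    meg = pp.bandpass(meg, sfreq, *config.meg_band)

    # ICA ocular cleanup, with power ratios before and after
    decim = max(1, meg.shape[1] // 30000)  # ICA mixing is time-invariant
    ica = pp.run_ica(meg, n_components=min(config.ica_components, meg.shape[0]),
                     seed=seed, veog=veog_f, decim=decim)
    overlap = (max(config.eog_band[0], config.meg_band[0]),
               min(config.eog_band[1], config.meg_band[1]))
    flagged = pp.identify_ocular_components(ica.sources, veog_uv, sfreq,
                                            config.ica_corr_thresh,
                                            veog_band=overlap)
    logger.info("subject %s: %d blinks, %d ocular component(s) removed",
                subject, len(events), len(flagged))
    cleaned = pp.remove_components(ica, flagged, data=meg)

    regions = rec.array.regions
    ratio_rows = []
    epochs = {}
    for stage, data in (("pre", meg), ("post", cleaned)):
        ep_b = pp.epoch_blink(data, sfreq, events, config.epoch_half_width, subject)
        ep_c = pp.epoch_control(data, sfreq, ep_b.n_trials, events,
                                config.epoch_half_width, subject)
        epochs[stage] = {"blink": ep_b, "control": ep_c}
        for cond, ep in (("blink", ep_b), ("control", ep_c)):
            for region, ratio in pp.regional_power_ratios(
                    ep.average(), ep.times, regions,
                    config.ratio_blink_latency, config.ratio_base_latency).items():
                ratio_rows.append({"subject": subject, "region": region,
                                   "condition": cond, "stage": stage,
                                   "ratio": ratio})

    ep_blink = epochs["post"]["blink"]
    ep_control = epochs["post"]["control"]
    times = ep_blink.times
    n_trials = ep_blink.n_trials

    # delta-band data are filtered on the CONTINUOUS record, then epoched:
    # band-filtering a 3-s average instead would put filter edge transients
    # into the pre-event windows (filtering and trial-averaging commute)
    delta_cont = pp.bandpass(cleaned, sfreq, *config.delta_band)
    ep_delta = {cond: pp.epoch_blink(delta_cont, sfreq, events,
                                     config.epoch_half_width, subject)
                if cond == "blink" else
                pp.epoch_control(delta_cont, sfreq, n_trials, events,
                                 config.epoch_half_width, subject)
                for cond in ("blink", "control")}

    gfp = {}
    band_power = {}
    freqs = config.tf_freqs()
    tf_means = sl.tf_trial_mean_continuous(
        cleaned, sfreq, {"blink": ep_blink.centers, "control": ep_control.centers},
        times, freqs, config.n_cycles, config.tf_base_win)
    for cond in ("blink", "control"):
        gfp[cond] = sl.global_field_power(ep_delta[cond].average(), sfreq,
                                          band=None)
        band_power[cond] = {
            "pre": sl.band_window_power(tf_means[cond], freqs, times,
                                        config.delta_band, config.pre_win),
            "post": sl.band_window_power(tf_means[cond], freqs, times,
                                         config.delta_band, config.post_win)}

    if leadfield is None:
        grid = build_source_grid(config.grid_spacing)
        leadfield = compute_leadfield(rec.array, grid)
    K = src.inverse_operator(leadfield, config.lam)
    contrast_img = {}
    for cond in ("blink", "control"):
        est = src.minimum_norm(ep_delta[cond].average(), leadfield,
                               config.lam, K=K)
        contrast_img[cond] = src.source_contrast(
            est, times, sfreq, config.post_win, config.pre_win,
            band=None, fwhm=config.smooth_fwhm)

    voi_tc: dict[str, dict[str, np.ndarray]] = {}
    for name in config.voi_names:
        center = leadfield.grid.coords[leadfield.grid.names[name]]
        voi_tc[name] = {}
        for cond in ("blink", "control"):
            avg, _ = src.virtual_electrode(ep_delta[cond].data, leadfield,
                                           center, sfreq, times,
                                           config.voi_radius, config.lam,
                                           band=None,
                                           polarity_win=config.post_win)
            voi_tc[name][cond] = avg

    return SubjectResult(subject=subject, n_blinks=len(events),
                         blink_rate=len(events) / duration_min,
                         scores=events.scores, morphology=morph,
                         avg_blink_veog=avg_blink, ratio_rows=ratio_rows,
                         epoch_times=times, gfp=gfp, band_power=band_power,
                         contrast_img=contrast_img, voi_tc=voi_tc,
                         n_trials=n_trials)


# ---------------------------------------------------------------------------
# group level
# ---------------------------------------------------------------------------

def group_analysis(results: list[SubjectResult], config: Config,
                   grid: SourceGrid, seed: int = 0) -> GroupResult:
    if len(results) < 2:
        raise PipelineError("group analysis needs at least 2 subjects")
    rng = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(8)]
    times = results[0].epoch_times

    blink_table = pd.DataFrame(
        {"subject": [r.subject for r in results],
         "n_blinks": [r.n_blinks for r in results],
         "rate_per_min": [r.blink_rate for r in results],
         "M1_uV": [r.morphology.m1 for r in results],
         "M2_s": [r.morphology.m2 for r in results],
         "M3_uV": [r.morphology.m3 for r in results],
         "M4_s": [r.morphology.m4 for r in results]})
    feats = blink_table[["M1_uV", "M2_s", "M3_uV", "M4_s"]].to_numpy()
    split_half = bl.split_half_reliability(feats, config.split_half_reps,
                                           seed=seeds[0])
    # grand blink waveform: each subject average normalized to its own peak
    _, grand_blink = bl.normalized_average(
        [r.avg_blink_veog[None] for r in results])

    ratio_table = pd.DataFrame([row for r in results for row in r.ratio_rows])
    ratio_stats = pp.compare_power_ratios(ratio_table)

    grand_gfp, gfp_ci, gfp_tests = {}, {}, {}
    for cond in ("blink", "control"):
        stack = np.array([r.gfp[cond] for r in results])
        grand_gfp[cond] = stack.mean(axis=0)
        gfp_ci[cond] = bootstrap_ci(stack, 0.95, n_boot=1000, seed=seeds[1])
        gfp_tests[cond], _, _ = sl.gfp_window_contrast(
            stack, times, config.post_win, config.pre_win)
    gfp_peak_latency = float(times[np.argmax(grand_gfp["blink"])])

    spectral = {}
    for cond in ("blink", "control"):
        deltas = np.array([r.band_power[cond]["post"] - r.band_power[cond]["pre"]
                           for r in results])
        spectral[cond] = sign_flip_test(deltas, n_perm=config.n_perm_spectral,
                                        seed=seeds[2])

    fwe = {}
    contrast_defs = {"Bpost>Bpre": ("blink", 1.0), "Bpre>Bpost": ("blink", -1.0),
                     "Cpost>Cpre": ("control", 1.0), "Cpre>Cpost": ("control", -1.0)}
    for k, (name, (cond, sign)) in enumerate(contrast_defs.items()):
        images = np.array([sign * r.contrast_img[cond] for r in results])
        fwe[name] = src.group_fwe(images, n_perm=config.n_perm_fwe,
                                  seed=seeds[3] + k)

    voi_clusters = {}
    for k, name in enumerate(config.voi_names):
        ts_b = np.array([r.voi_tc[name]["blink"] for r in results])
        ts_c = np.array([r.voi_tc[name]["control"] for r in results])
        voi_clusters[name] = cluster_permutation(
            ts_b, ts_c, times, config.cluster_alpha,
            n_perm=config.n_perm_cluster, seed=seeds[4] + k)

    return GroupResult(subjects=[r.subject for r in results],
                       grand_blink_waveform=grand_blink,
                       blink_table=blink_table, split_half=split_half,
                       ratio_table=ratio_table, ratio_stats=ratio_stats,
                       epoch_times=times, grand_gfp=grand_gfp, gfp_ci=gfp_ci,
                       gfp_tests=gfp_tests, gfp_peak_latency=gfp_peak_latency,
                       spectral=spectral, fwe=fwe, voi_clusters=voi_clusters,
                       grid=grid, config_hash=config.hash(), seed=seed)


# ---------------------------------------------------------------------------
# cohort helpers and the file-based entry point
# ---------------------------------------------------------------------------

def simulate_and_process_cohort(n_subjects: int, sim_config: RecordingConfig,
                                config: Config, seed: int = 0,
                                keep_truth: bool = False):
    """Generate and analyze a seeded cohort entirely in memory.

    Geometry (sensor array, grid, lead field) is shared across subjects;
    per-subject seeds derive from the master seed.  Returns
    (GroupResult, [SubjectResult], [GroundTruth or None]).
    """
    from .headmodel import build_sensor_array

    array = build_sensor_array(sim_config.n_chan, sim_config.helmet_radius,
                               sim_config.baseline, seed=0)
    grid = build_source_grid(config.grid_spacing, sim_config.shell_radius,
                             sim_config.conductor_radius)
    lf = compute_leadfield(array, grid, sim_config.conductor_radius)
    subject_seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)
    results, truths = [], []
    for i, s_seed in enumerate(subject_seeds):
        rec, gt = generate_recording(sim_config, int(s_seed), array=array, grid=grid)
        res = process_subject(rec, config, subject=f"sim{i:02d}",
                              seed=int(s_seed), leadfield=lf)
        results.append(res)
        truths.append(gt if keep_truth else None)
        logger.info("processed subject %d/%d", i + 1, n_subjects)
    group = group_analysis(results, config, grid, seed=seed)
    return group, results, truths


def run_pipeline(manifest: pd.DataFrame, config: Config, out_dir,
                 seed: int = 0) -> GroupResult:
    """File-based cohort run: read each recording, analyze, write the report."""
    from pathlib import Path

    from .io import read_events, read_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    lf = None
    grid = None
    for _, row in manifest.iterrows():
        subject = str(row["subject"])
        try:
            rec = read_recording(row["recording"])
            if lf is None:
                grid = build_source_grid(config.grid_spacing)
                lf = compute_leadfield(rec.array, grid)
            template = None
            if row.get("events", ""):
                # externally supplied events are honored by rebuilding a
                # subject-specific template from their average
                ev = read_events(row["events"])
                veog_uv = rec.veog * 1e6
                ep = pp.epoch_blink(veog_uv, rec.sfreq, ev, 1.0)
                template = ep.average()
            results.append(process_subject(rec, config, subject=subject,
                                           leadfield=lf, template=template))
        except Exception as exc:  # annotate failures with the subject id
            raise PipelineError(f"stage failure for subject {subject}: {exc}") from exc
    group = group_analysis(results, config, grid, seed=seed)
    write_report(group, out, config)
    return group


def write_report(group: GroupResult, out_dir, config: Config) -> None:
    """Human-readable report plus the cohort-level CSV tables."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    group.blink_table.to_csv(out / "blink_stats.csv", index=False)
    group.ratio_table.to_csv(out / "power_ratios.csv", index=False)
    group.ratio_stats["ttests"].to_csv(out / "power_ratio_tests.csv", index=False)

    lines = [
        "Blink-related oscillation analysis report",
        "=" * 45,
        f"config hash: {group.config_hash}   master seed: {group.seed}",
        f"subjects: {len(group.subjects)}",
        "",
        "Blink behavior",
        "-" * 30,
    ]
    bt = group.blink_table
    n = len(bt)
    lines.append(f"blinks per subject: {bt.n_blinks.mean():.1f} ± "
                 f"{bt.n_blinks.std(ddof=1):.1f}")
    lines.append(f"blink rate: {bt.rate_per_min.mean():.1f} ± "
                 f"{bt.rate_per_min.std(ddof=1):.1f} /min")
    for col, rho in zip(("M1_uV", "M2_s", "M3_uV", "M4_s"),
                        group.split_half.mean_rho):
        m, se = bt[col].mean(), bt[col].std(ddof=1) / np.sqrt(n)
        lines.append(f"{col}: {m:.3f} ± {se:.3f} (SE), split-half ρ = {rho:.3f}")
    lines.append(f"split-half consistency criterion met: "
                 f"{group.split_half.consistent}")

    lines += ["", "Artifact removal (power ratios, pre vs post ICA)", "-" * 30]
    for _, row in group.ratio_stats["ttests"].iterrows():
        lines.append(f"{row.condition:8s} {row.region:10s} t={row.t:7.2f}  "
                     f"p_bonf={row.p_bonferroni:.4g}")

    lines += ["", "Sensor space (delta GFP and spectral power)", "-" * 30]
    for cond in ("blink", "control"):
        t = group.gfp_tests[cond]
        obs, p = group.spectral[cond]
        lines.append(f"{cond:8s} GFP post vs pre: t={t.t:.2f} p={t.p:.4g}; "
                     f"spectral Δlog-power={obs:.4f} p={p:.4g}")
    lines.append(f"blink grand GFP peak latency: "
                 f"{1e3 * group.gfp_peak_latency:.0f} ms")

    lines += ["", "Source space (max-statistic FWE, α=0.05)", "-" * 30]
    for name, res in group.fwe.items():
        supra = res.suprathreshold(0.05)
        lines.append(f"{name}: {len(supra)} suprathreshold voxel(s)")
    for name, cres in group.voi_clusters.items():
        sig = cres.significant(0.05)
        desc = "; ".join(f"{'+' if c.sign > 0 else '-'}cluster "
                         f"[{c.start * 1e3:.0f},{c.end * 1e3:.0f}] ms p={c.p:.4g}"
                         for c in sig) or "none"
        lines.append(f"VOI {name}: significant clusters: {desc}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
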