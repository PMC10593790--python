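"""End-to-end assay orchestration, configuration, and worked summaries.

Each ``run_*`` function chains the module operations for one assay
(open-field locomotion, rotarod, ephys, closed-loop) on synthetic inputs or
files written by the generators, returns a results bundle, and optionally
writes tidy CSV outputs plus a JSON run log carrying the seed and a config
hash so reruns are reproducible byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aligned_stats, closedloop, ephys, kinematics, photometry, synthdata
from .errors import InvalidConfigError, InvalidInputError

ANALYSIS_FS = 100.0  # Hz — common grid for photometry/behavior alignment

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {
        "duration_s": 600.0,
        "fs_photometry": 101.73,
        "fs_video": 30.0,
        "transient_rate": 0.8,
        "coupling_gain": 1.0,
        "artifact_gain": 0.5,
        "noise_sd": 0.3,
        "bout_period_s": 60.0,
        "bout_s": 8.0,
        "bout_peak_speed": 10.0,
    },
    "photometry": {
        "downsample_factor": 1,
        "trim_s": 180.0,
        "min_prominence": 0.5,
        "min_separation_s": 0.2,
        "percentile_window_s": 30.0,
    },
    "kinematics": {
        "smooth_window_s": 2.0,
        "bout_enter": 5.0,
        "bout_sustain": 3.0,
        "likelihood_interp_thresh": 0.9,
        "jump_likelihood_thresh": 0.95,
        "loco_thresh": 4.5,
        "still_thresh": 0.8,
        "border_cm": 10.0,
    },
    "aligned": {
        "pre_s": 5.0,
        "post_s": 5.0,
        "max_lag_s": 5.0,
        "n_shuffle": 1000,
    },
    "rotarod": {
        "trim_s": 0.0,
        "pre_s": 120.0,
        "run_s": 120.0,
        "post_s": 120.0,
        "jump_period_s": 1.2,
        "jump_period_jitter": 0.25,
        "edge_exclude_s": 10.0,
    },
    "ephys": {
        "stim_durations_ms": [0, 250, 500, 1000],
        "n_sweeps": 10,
        "n_units": 50,
        "sal_inhibition_depth": 0.7,
        "cno_inhibition_depth": 0.05,
        "baseline_rate_hz": 30.0,
    },
    "closedloop": {
        "window_s": 120.0,
        "lowpass_hz": 1.0,
        "z_target": 2.0,
        "sustain_s": 0.25,
        "latency_s": 0.2,
        "refractory_s": 10.0,
        "rest_required_s": 5.0,
        "iti_s": 360.0,
        "max_trials": 5,
    },
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _deep_update(base: dict, new: dict) -> dict:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merged run configuration: defaults <- YAML file <- dotted overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            _deep_update(cfg, yaml.safe_load(fh) or {})
    for key, value in (overrides or {}).items():
        node = cfg
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(cfg: dict, **extra) -> synthdata.SimConfig:
    s = cfg["synth"]
    schedule = synthdata.default_bout_schedule(
        s["duration_s"], s["bout_period_s"], s["bout_s"], s["bout_peak_speed"])
    kw = dict(seed=cfg["seed"], duration_s=s["duration_s"],
              fs_photometry=s["fs_photometry"], fs_video=s["fs_video"],
              transient_rate=s["transient_rate"],
              coupling_gain=s["coupling_gain"], artifact_gain=s["artifact_gain"],
              noise_sd=s["noise_sd"], bout_schedule=schedule)
    kw.update(extra)
    return synthdata.SimConfig(**kw)


# ---------------------------------------------------------------------------
# Worked example: tracing count summaries
# ---------------------------------------------------------------------------

@dataclass
class CountSummary:
    """A printed count with its percentage (one decimal, half away from zero)."""

    numerator: int
    denominator: int
    percent: float


def summarize_tracing_counts(numerator: int, denominator: int) -> CountSummary:
    """Percentage of a printed cell count, rounded to one decimal.

    Rounding is half-away-from-zero (the convention of printed figure
    legends), not banker's rounding.
    """
    if denominator <= 0:
        raise InvalidInputError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise InvalidInputError("numerator must lie in [0, denominator]")
    raw = 1000.0 * numerator / denominator
    percent = np.floor(raw + 0.5) / 10.0
    return CountSummary(numerator, denominator, float(percent))


# ---------------------------------------------------------------------------
# Assay runners
# ---------------------------------------------------------------------------

def run_open_field(cfg: dict, out_dir=None) -> dict:
    """Open-field assay: photometry -> kinematics -> aligned statistics.

    Produces bout events, bout-aligned z matrices, motor-state fractions,
    the speed/dFF lagged correlation, and its phase-shuffle surrogate test.
    """
    sim = _sim_config(cfg)
    table, truth = synthdata.simulate_tracking(sim)
    kin = cfg["kinematics"]
    table = kinematics.interpolate_low_likelihood(
        table, kin["likelihood_interp_thresh"])
    table = kinematics.calibrate_and_upsample(
        table, synthdata.ARENA_CM, synthdata.ARENA_PX, target_fs=None)
    speed = kinematics.compute_speed(table, kin["smooth_window_s"])
    bouts = kinematics.detect_locomotor_bouts(
        speed, kin["bout_enter"], kin["bout_sustain"])
    states = kinematics.classify_motor_state(
        table, speed, kin["loco_thresh"], kin["still_thresh"], kin["border_cm"])

    # photometry driven by the same ground-truth speed profile
    session, _ = synthdata.simulate_photometry(sim)
    pho = cfg["photometry"]
    trace = photometry.process_session(session, pho["downsample_factor"],
                                       pho["trim_s"])
    trace = photometry.resample_trace(trace, ANALYSIS_FS)

    al = cfg["aligned"]
    onset_matrix = aligned_stats.align_to_events(
        trace, bouts.times("bout_onset"), al["pre_s"], al["post_s"])
    # speed/dFF correlation on the common grid and span
    t0, t1 = trace.time_s[0], trace.time_s[-1]
    sel = (speed.time_s >= t0) & (speed.time_s <= t1)
    v = np.interp(trace.time_s, speed.time_s[sel], speed.speed_cm_s[sel])
    corr = aligned_stats.lagged_pearson(v, trace.z, ANALYSIS_FS, al["max_lag_s"])
    rng = np.random.default_rng([cfg["seed"], 97])
    surrogate = aligned_stats.shuffle_correlation_test(
        [v], [trace.z], ANALYSIS_FS, n_shuffle=al["n_shuffle"], rng=rng,
        max_lag_s=al["max_lag_s"])

    bundle = {"bouts": bouts, "states": states, "trace": trace, "speed": speed,
              "onset_matrix": onset_matrix, "speed_dff_corr": corr,
              "surrogate": surrogate, "truth": truth}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_df(bouts.table, out / "bout_events.csv")
        _write_df(pd.DataFrame({"time_s": states.time_s, "label": states.label,
                                "zone": states.zone}), out / "motor_states.csv")
        _write_df(pd.DataFrame(
            {"lag_s": corr.lags_s, "r": corr.r_by_lag}), out / "speed_dff_lags.csv")
        report = pd.DataFrame([{"best_r": corr.best_r,
                                "best_lag_s": corr.best_lag_s,
                                "surrogate_p": surrogate.p_value,
                                "n_shuffle": surrogate.n_shuffle}])
        _write_df(report, out / "correlation_report.csv")
        _write_log(cfg, out, dropped_trials=onset_matrix.n_dropped)
    return bundle


def _rotarod_epochs(cfg: dict) -> dict:
    r = cfg["rotarod"]
    t1 = r["pre_s"]
    t2 = t1 + r["run_s"]
    t3 = t2 + r["post_s"]
    e = r["edge_exclude_s"]
    return {"pre": (0.0 + e, t1 - e), "during": (t1 + e, t2 - e),
            "post": (t2 + e, t3 - e)}


def run_rotarod(cfg: dict, out_dir=None) -> dict:
    """Rotarod assay: jump segmentation, epoch metrics, jump-aligned
    calcium, duration coupling, and epoch-wise inter-site correlation.

    The synthetic session has a pre/run/post structure; calcium transients
    are driven by the jump cycle during the run epoch, and the isosbestic
    fit and percentile baseline use the rest (pre/post) epochs only.
    """
    r = cfg["rotarod"]
    total = r["pre_s"] + r["run_s"] + r["post_s"]
    sim = _sim_config(cfg, duration_s=total, bout_schedule=())
    run_span = (r["pre_s"], r["pre_s"] + r["run_s"])

    rod_cfg = synthdata.SimConfig(seed=cfg["seed"], duration_s=r["run_s"],
                                  fs_video=sim.fs_video)
    rod, rod_truth = synthdata.simulate_rotarod_tracking(
        rod_cfg, r["jump_period_s"], period_jitter=r["jump_period_jitter"])
    jump_truth = rod_truth.true_jumps.shifted(run_span[0])

    # both sites share the jump-locked transient source, independent noise
    onsets = jump_truth.times("jump_onset")
    gpe_sess, _ = synthdata.simulate_photometry(sim, transient_times=onsets)
    snr_sim = synthdata.SimConfig(**{**sim.__dict__, "seed": sim.seed + 1})
    snr_sess, _ = synthdata.simulate_photometry(snr_sim, transient_times=onsets)

    pho = cfg["photometry"]
    epochs = _rotarod_epochs(cfg)

    def rest_mask(t):
        return (t < run_span[0]) | (t >= run_span[1])

    traces = {}
    for name, sess in (("gpe", gpe_sess), ("snr", snr_sess)):
        tr = photometry.process_session(sess, pho["downsample_factor"],
                                        r["trim_s"], baseline_mask_fn=rest_mask)
        tr.z = photometry.moving_average(tr.z, 0.5, tr.fs)
        traces[name] = photometry.resample_trace(tr, ANALYSIS_FS)

    # epoch transient metrics on the GPe trace
    metrics = {}
    g = traces["gpe"]
    for name, (t0, t1) in epochs.items():
        sel = (g.time_s >= t0) & (g.time_s < t1)
        metrics[name] = photometry.detect_transients(
            g.z[sel], g.fs, pho["min_prominence"], pho["min_separation_s"],
            baseline_window_s=pho["percentile_window_s"])

    rod_cal = kinematics.calibrate_and_upsample(
        rod, synthdata.ROD_HEIGHT_CM, synthdata.ROD_HEIGHT_PX,
        target_fs=None)
    jumps = kinematics.detect_jumps(rod_cal, part="lower_body").shifted(
        run_span[0])

    al = cfg["aligned"]
    jump_matrix = aligned_stats.align_to_events(
        g, jumps.times("jump_onset"), al["pre_s"], al["post_s"],
        baseline_window=(-5.0, -1.0))
    run_metrics = metrics["during"]
    peak_times = run_metrics.peak_times_s + epochs["during"][0]
    try:
        jd, td, dur_r, dur_p = aligned_stats.transient_duration_and_event_duration(
            peak_times, jumps)
    except Exception:
        jd = td = np.array([])
        dur_r = dur_p = float("nan")
    site_corr = aligned_stats.epoch_correlation(traces["gpe"], traces["snr"],
                                                epochs, al["max_lag_s"])

    bundle = {"traces": traces, "jumps": jumps, "jump_truth": jump_truth,
              "epoch_metrics": metrics, "jump_matrix": jump_matrix,
              "duration_pairs": (jd, td), "duration_r": dur_r,
              "duration_p": dur_p, "site_corr": site_corr}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_df(jumps.table, out / "jump_events.csv")
        rows = [{"epoch": k, "peak_frequency_hz": m.peak_frequency_hz,
                 "auc_per_s": m.auc_per_s, "baseline_level": m.baseline_level,
                 "mean_ipi_s": float(np.mean(m.interpeak_intervals_s))
                 if m.interpeak_intervals_s.size else float("nan")}
                for k, m in metrics.items()]
        _write_df(pd.DataFrame(rows), out / "epoch_metrics.csv")
        corr_rows = [{"epoch": k, "best_r": v.best_r, "best_lag_s": v.best_lag_s}
                     for k, v in site_corr.items()]
        _write_df(pd.DataFrame(corr_rows), out / "site_correlations.csv")
        _write_log(cfg, out, duration_r=dur_r)
    return bundle


def run_ephys(cfg: dict, out_dir=None) -> dict:
    """Ephys assay: PSTHs, both unit classifications, population tables.

    Simulates a saline cohort with strong stimulus-locked inhibition and a
    CNO cohort in which terminal release (hence inhibition) is suppressed,
    then contrasts inhibited proportions per stimulation duration with
    Fisher's exact test.
    """
    e = cfg["ephys"]
    if e["n_units"] < 1:
        raise InvalidInputError("ephys.n_units must be at least 1")
    units = []
    truth = {}
    for i, (drug, depth) in enumerate(
            (("SAL", e["sal_inhibition_depth"]), ("CNO", e["cno_inhibition_depth"]))):
        sim = synthdata.SimConfig(seed=cfg["seed"] + i,
                                  baseline_rate_hz=e["baseline_rate_hz"],
                                  inhibition_depth=depth)
        us, tr = synthdata.simulate_spike_trains(
            sim, e["stim_durations_ms"], e["n_sweeps"], n_units=e["n_units"],
            drug=drug)
        for u in us:
            u.unit_id = f"{drug}_{u.unit_id}"
        units.extend(us)
        truth.update({f"{drug}_{k}": v for k, v in tr.true_unit_class.items()})
    classifications = [ephys.classify_unit(u) for u in units]
    counts, tests = ephys.population_summary(classifications)
    bundle = {"units": units, "classifications": classifications,
              "counts": counts, "tests": tests, "truth": truth}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cls_df = pd.DataFrame([c.__dict__ for c in classifications])
        _write_df(cls_df, out / "unit_classifications.csv")
        _write_df(counts, out / "population_counts.csv")
        _write_df(tests, out / "population_tests.csv")
        _write_log(cfg, out, n_units=len(units))
    return bundle


def run_closed_loop(cfg: dict, out_dir=None) -> dict:
    """Closed-loop assay: online dFF, both trigger rules, trial schedule."""
    sim = _sim_config(cfg)
    cl = cfg["closedloop"]
    session, _ = synthdata.simulate_photometry(sim)
    online = closedloop.online_dff_stream(session, cl["window_s"],
                                          cl["lowpass_hz"])
    thr = closedloop.threshold_from_zscore(online, cl["z_target"])
    ca_rule = closedloop.TriggerRule("calcium_peak", threshold=thr,
                                     sustain_s=cl["sustain_s"],
                                     latency_s=cl["latency_s"],
                                     refractory_s=cl["refractory_s"])
    ca_log = closedloop.calcium_peak_trigger(online, ca_rule)

    table, _ = synthdata.simulate_tracking(sim)
    kin = cfg["kinematics"]
    table = kinematics.interpolate_low_likelihood(
        table, kin["likelihood_interp_thresh"])
    table = kinematics.calibrate_and_upsample(
        table, synthdata.ARENA_CM, synthdata.ARENA_PX, target_fs=None)
    speed = kinematics.compute_speed(table, kin["smooth_window_s"])
    sp_rule = closedloop.TriggerRule("speed", refractory_s=cl["refractory_s"],
                                     rest_required_s=cl["rest_required_s"])
    sp_log = closedloop.speed_trigger(speed, sp_rule)
    rng = np.random.default_rng([cfg["seed"], 131])
    trials = closedloop.trial_scheduler(sp_log, cl["max_trials"], cl["iti_s"],
                                        assignment="random", rng=rng)
    bundle = {"online": online, "threshold": thr, "calcium_log": ca_log,
              "speed_log": sp_log, "trials": trials}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_df(pd.DataFrame({"trigger_time_s": ca_log.trigger_times_s,
                                "cause": ["calcium_peak"] * len(ca_log)}),
                  out / "calcium_triggers.csv")
        _write_df(pd.DataFrame({"trigger_time_s": sp_log.trigger_times_s,
                                "cause": ["speed"] * len(sp_log)}),
                  out / "speed_triggers.csv")
        _write_df(trials, out / "scheduled_trials.csv")
        _write_log(cfg, out, threshold=thr)
    return bundle


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def _write_df(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _write_log(cfg: dict, out: Path, **extras) -> None:
    log = {"seed": cfg["seed"], "config_hash": config_hash(cfg)}
    log.update({k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in extras.items()})
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
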