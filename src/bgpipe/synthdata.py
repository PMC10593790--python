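"""Seeded synthetic photometry, tracking, and spike-train generators.

Every downstream stage of the pipeline is exercised against signals whose
ground truth is known by construction:

* photometry — GCaMP-like transients (difference-of-exponentials kernel)
  whose event rate is kinetically coupled to locomotor speed, riding on a
  shared exponential photobleaching drift, with a common motion artifact
  injected into both the 465 nm signal and 405 nm control channels plus
  independent sensor noise per channel;
* open-field tracking — a body-center trajectory whose speed follows a
  smooth trapezoid per scheduled locomotor bout, carried by eight body
  parts in a rigid, heading-aligned geometry, with a configurable fraction
  of likelihood dropouts;
* rotarod tracking — a lower-body vertical position oscillating between
  the rod base (0 cm) and top (3 cm) with a fixed jump period;
* spike trains — homogeneous Poisson units whose rate is scaled down
  (inhibited), up (excited), or unchanged inside the stimulation window.

One integer seed drives everything through per-component substreams, so
identical configurations are bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .errors import InvalidConfigError
from .events import EventSet
from .ephys import UnitRecording
from .kinematics import TrackingTable
from .photometry import PhotometrySession

SPEED_REF_CM_S = 5.0          # speed scale for dimensionless coupling_gain
ARENA_CM = 42.0               # open-field side length
ARENA_PX = 420.0              # image-side pixels -> 0.1 cm/px
ROD_HEIGHT_CM = 3.0
ROD_HEIGHT_PX = 30.0

_STREAMS = {"photometry": 0, "tracking": 1, "spikes": 2, "rotation": 3,
            "noise465": 4, "noise405": 5, "artifact": 6}

# body-frame part offsets (cm): +x is the heading direction, +y the left side
_PART_OFFSETS = {
    "snout": (2.5, 0.0), "left_ear": (1.8, 0.8), "right_ear": (1.8, -0.8),
    "body_center": (0.0, 0.0), "left_side": (0.0, 1.2),
    "right_side": (0.0, -1.2), "tail_base": (-2.5, 0.0), "tail_end": (-5.0, 0.0),
}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[component]])


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults matching its design.

    ``coupling_gain`` scales how strongly the transient rate follows body
    speed (0 = independent); ``artifact_gain`` sets the SD (a.u.) of the
    shared motion term on both channels; ``bout_schedule`` lists
    ``(onset_s, offset_s, peak_speed_cm_s)`` locomotor bouts;
    ``amp_mean``/``amp_cv`` parameterize the lognormal single-transient
    amplitude distribution (a.u. of raw fluorescence).
    """

    seed: int = 0
    duration_s: float = 600.0
    fs_photometry: float = 101.73
    fs_video: float = 30.0
    transient_rate: float = 0.8          # events/s at reference speed
    tau_rise: float = 0.07               # s, GCaMP-like kernel
    tau_decay: float = 0.8               # s
    bleach_tau: float = 2000.0           # s; inf disables bleaching
    noise_sd: float = 0.3                # a.u. per channel
    coupling_gain: float = 1.0
    artifact_gain: float = 0.5
    bout_schedule: tuple = ()
    ramp_s: float = 1.0                  # trapezoid rise/fall time
    baseline_speed: float = 0.5          # cm/s between bouts
    speed_noise_sd: float = 0.0          # cm/s jitter on the speed profile
    dropout_fraction: float = 0.02       # tracking likelihood dropouts
    jitter_px: float = 0.0               # tracking coordinate noise
    amp_mean: float = 5.0
    amp_cv: float = 0.3
    inhibition_depth: float = 0.8        # fraction of rate removed in stim
    baseline_rate_hz: float = 30.0
    excitation_gain: float = 2.0

    def __post_init__(self) -> None:
        self.bout_schedule = tuple(tuple(b) for b in self.bout_schedule)
        self.validate()

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        for name in ("fs_photometry", "fs_video", "tau_rise", "tau_decay",
                     "bleach_tau", "baseline_rate_hz", "ramp_s"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in ("transient_rate", "noise_sd", "speed_noise_sd",
                     "artifact_gain", "amp_mean", "amp_cv", "jitter_px",
                     "baseline_speed", "excitation_gain"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.inhibition_depth <= 1.0:
            raise InvalidConfigError("inhibition_depth must lie in [0, 1]")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise InvalidConfigError("dropout_fraction must lie in [0, 1]")
        prev_end = -math.inf
        for onset, offset, peak in self.bout_schedule:
            if not 0.0 <= onset < offset <= self.duration_s:
                raise InvalidConfigError(
                    f"bout ({onset}, {offset}) outside the session or reversed")
            if onset < prev_end:
                raise InvalidConfigError("bout intervals overlap")
            if offset - onset <= 2 * self.ramp_s:
                raise InvalidConfigError("bout shorter than its two speed ramps")
            if peak <= 0:
                raise InvalidConfigError("bout peak speed must be positive")
            prev_end = offset


def default_bout_schedule(duration_s: float, period_s: float = 60.0,
                          bout_s: float = 8.0,
                          peak_speed: float = 8.0) -> tuple:
    """Evenly spaced locomotor bouts: one ``bout_s`` bout per ``period_s``."""
    onsets = np.arange(period_s / 2.0, duration_s - bout_s, period_s)
    return tuple((float(o), float(o + bout_s), peak_speed) for o in onsets)


@dataclass
class GroundTruth:
    """What the generator actually put into the signals."""

    true_bouts: EventSet | None = None
    true_jumps: EventSet | None = None
    true_lag_s: float = 0.0
    true_coupling: float = 0.0
    true_unit_class: dict = field(default_factory=dict)
    transient_times_s: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.transient_times_s = np.asarray(self.transient_times_s, dtype=float)


# ---------------------------------------------------------------------------
# Speed profile shared by tracking and photometry
# ---------------------------------------------------------------------------

def trapezoid_speed(t, schedule, baseline: float, ramp_s: float) -> np.ndarray:
    """Piecewise-linear speed: baseline -> peak over ``ramp_s``, plateau,
    back down, per scheduled bout.  ``schedule`` entries are
    (onset_s, offset_s, peak); the rise starts at onset and the descent
    ends at offset."""
    t = np.asarray(t, dtype=float)
    v = np.full_like(t, float(baseline))
    for onset, offset, peak in schedule:
        up = (t >= onset) & (t < onset + ramp_s)
        v[up] = baseline + (peak - baseline) * (t[up] - onset) / ramp_s
        flat = (t >= onset + ramp_s) & (t < offset - ramp_s)
        v[flat] = peak
        down = (t >= offset - ramp_s) & (t < offset)
        v[down] = baseline + (peak - baseline) * (offset - t[down]) / ramp_s
    return v


def schedule_truth(schedule, ramp_s: float) -> EventSet:
    """Ground-truth bout events: onset = start of the speed rise, offset =
    start of the descent (the last sample at peak speed)."""
    if not schedule:
        return EventSet()
    onsets = [b[0] for b in schedule]
    offsets = [b[1] - ramp_s for b in schedule]
    return EventSet.from_pairs(onsets, offsets, kind="bout")


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

def gcamp_kernel(tau_rise: float, tau_decay: float, fs: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak."""
    if tau_decay <= tau_rise:
        raise InvalidConfigError("tau_decay must exceed tau_rise")
    t = np.arange(0.0, tau_decay * 8.0, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def kernel_peak_s(tau_rise: float, tau_decay: float) -> float:
    """Time from transient onset to kernel peak (closed form)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


def simulate_photometry(cfg: SimConfig, speed=None, transient_times=None
                        ) -> tuple[PhotometrySession, GroundTruth]:
    """Simulate a two-channel photometry session.

    The 465 nm channel carries bleach drift + kernel-convolved transients
    (rate modulated by ``coupling_gain`` x speed) + shared motion artifact
    + noise; the 405 nm control carries the same drift and artifact but no
    transients.  ``speed`` (sampled at ``fs_video``) overrides the profile
    implied by ``bout_schedule``; ``transient_times`` bypasses the event
    draw entirely (used to build dual-site recordings sharing one source).
    """
    cfg.validate()
    fs = cfg.fs_photometry
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    if speed is not None:
        speed = np.asarray(speed, dtype=float)
        t_video = np.arange(speed.size) / cfg.fs_video
        speed_p = np.interp(t, t_video, speed)
    else:
        speed_p = trapezoid_speed(t, cfg.bout_schedule, cfg.baseline_speed,
                                  cfg.ramp_s)

    rng = _rng(cfg.seed, "photometry")
    if transient_times is None:
        rate = cfg.transient_rate * np.clip(
            1.0 + cfg.coupling_gain * speed_p / SPEED_REF_CM_S, 0.0, None)
        rate_max = float(rate.max())
        if rate_max > 0:
            n_cand = rng.poisson(rate_max * cfg.duration_s)
            cand = np.sort(rng.uniform(0.0, cfg.duration_s, n_cand))
            accept = rng.uniform(0.0, 1.0, n_cand) < \
                np.interp(cand, t, rate) / rate_max
            transient_times = cand[accept]
        else:
            transient_times = np.array([])
    else:
        transient_times = np.sort(np.asarray(transient_times, dtype=float))

    impulses = np.zeros(n)
    idx = np.round(transient_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    if idx.size:
        sigma = math.log1p(cfg.amp_cv ** 2) ** 0.5
        mu = math.log(cfg.amp_mean) - 0.5 * sigma ** 2 if cfg.amp_mean > 0 else 0.0
        amps = rng.lognormal(mu, sigma, idx.size) if cfg.amp_mean > 0 else \
            np.zeros(idx.size)
        np.add.at(impulses, idx, amps)
    transients = fftconvolve(impulses, gcamp_kernel(cfg.tau_rise, cfg.tau_decay,
                                                    fs))[:n] if idx.size else \
        np.zeros(n)

    bleach = np.ones(n) if math.isinf(cfg.bleach_tau) else \
        np.exp(-t / cfg.bleach_tau)
    if cfg.artifact_gain > 0:
        white = _rng(cfg.seed, "artifact").standard_normal(n)
        art = gaussian_filter1d(white, sigma=max(1.0, 0.1 * fs))
        art = cfg.artifact_gain * art / art.std()
    else:
        art = np.zeros(n)
    noise465 = _rng(cfg.seed, "noise465").standard_normal(n) * cfg.noise_sd
    noise405 = _rng(cfg.seed, "noise405").standard_normal(n) * cfg.noise_sd

    f465 = 100.0 * bleach + transients + art + noise465
    f405 = 80.0 * bleach + art + noise405
    session = PhotometrySession(t, f465, f405, fs=fs)
    truth = GroundTruth(true_bouts=schedule_truth(cfg.bout_schedule, cfg.ramp_s),
                        true_lag_s=kernel_peak_s(cfg.tau_rise, cfg.tau_decay),
                        true_coupling=cfg.coupling_gain,
                        transient_times_s=transient_times)
    return session, truth


# ---------------------------------------------------------------------------
# Open-field tracking
# ---------------------------------------------------------------------------

def simulate_tracking(cfg: SimConfig) -> tuple[TrackingTable, GroundTruth]:
    """Open-field tracking table whose body-center speed follows the
    scheduled trapezoids, with 8 body parts in a rigid heading-aligned
    geometry, image-pixel coordinates (y down), and likelihood dropouts."""
    cfg.validate()
    fs = cfg.fs_video
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    rng = _rng(cfg.seed, "tracking")

    v = trapezoid_speed(t, cfg.bout_schedule, cfg.baseline_speed, cfg.ramp_s)
    if cfg.speed_noise_sd > 0:
        v = np.clip(v + rng.normal(0.0, cfg.speed_noise_sd, n), 0.0, None)

    # smoothly turning heading (circling run path, ~1 rad/s plus drift) so
    # the realized body-center speed carries no wall-collision artifacts
    dt = 1.0 / fs
    turn = 1.0 * dt + gaussian_filter1d(rng.normal(0.0, 0.02, n), sigma=fs)
    heading = np.cumsum(turn)
    hx, hy = np.cos(heading), np.sin(heading)
    x = ARENA_CM / 2.0 + np.concatenate([[0.0], np.cumsum(v[1:] * hx[1:] * dt)])
    y = ARENA_CM / 2.0 + np.concatenate([[0.0], np.cumsum(v[1:] * hy[1:] * dt)])
    np.clip(x, 1.0, ARENA_CM - 1.0, out=x)
    np.clip(y, 1.0, ARENA_CM - 1.0, out=y)

    cm_per_px = ARENA_CM / ARENA_PX
    cols = {}
    for part, (fwd, left) in _PART_OFFSETS.items():
        px_cm = x + fwd * hx - left * hy
        py_cm = y + fwd * hy + left * hx
        x_px = px_cm / cm_per_px
        y_px = (ARENA_CM - py_cm) / cm_per_px  # image y points down
        if cfg.jitter_px > 0:
            x_px = x_px + rng.normal(0.0, cfg.jitter_px, n)
            y_px = y_px + rng.normal(0.0, cfg.jitter_px, n)
        like = np.full(n, 0.99)
        if cfg.dropout_fraction > 0:
            drop = rng.uniform(0.0, 1.0, n) < cfg.dropout_fraction
            like[drop] = rng.uniform(0.1, 0.85, int(drop.sum()))
        cols[(part, "x")] = x_px
        cols[(part, "y")] = y_px
        cols[(part, "likelihood")] = like
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["bodyparts", "coords"])
    table = TrackingTable(df, t, fs_video=fs)
    truth = GroundTruth(true_bouts=schedule_truth(cfg.bout_schedule, cfg.ramp_s),
                        true_coupling=cfg.coupling_gain)
    return table, truth


def simulate_rotarod_tracking(cfg: SimConfig, period_s: float,
                              dropout_fraction: float | None = None,
                              period_jitter: float = 0.0
                              ) -> tuple[TrackingTable, GroundTruth]:
    """Rotarod variant: lower-body y oscillates 0 -> 3 cm as a triangle wave.

    With ``period_jitter`` = 0 jump onsets (position minima) fall exactly at
    integer multiples of ``period_s``, offsets (maxima) half a period later.
    A positive jitter draws each cycle's period uniformly from
    ``period_s * (1 +/- period_jitter)`` (rounded to the frame grid), which
    gives the jump durations the trial-to-trial variability needed for
    duration-coupling analyses.  Output is in image pixels (y down) so the
    standard calibrate-then-detect path applies.  The first cycle's onset
    sits on the trace edge and is excluded from the ground truth.
    """
    cfg.validate()
    if period_s <= 0:
        raise InvalidConfigError("period_s must be positive")
    if not 0.0 <= period_jitter < 1.0:
        raise InvalidConfigError("period_jitter must lie in [0, 1)")
    fs = cfg.fs_video
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    rng_p = _rng(cfg.seed, "rotation")
    y_cm = np.empty(0)
    starts, halves = [], []
    while y_cm.size < n:
        period = period_s * (1.0 + period_jitter * rng_p.uniform(-1.0, 1.0))
        h = max(1, int(round(period * fs / 2.0)))
        i = np.arange(2 * h)
        cycle = ROD_HEIGHT_CM * np.where(i <= h, i / h, (2.0 * h - i) / h)
        starts.append(y_cm.size)
        halves.append(h)
        y_cm = np.concatenate([y_cm, cycle])
    y_cm = y_cm[:n]
    cm_per_px = ROD_HEIGHT_CM / ROD_HEIGHT_PX
    y_px = (ROD_HEIGHT_CM - y_cm) / cm_per_px + 50.0
    x_px = np.full(n, 120.0)
    frac = cfg.dropout_fraction if dropout_fraction is None else dropout_fraction
    like = np.full(n, 0.99)
    if frac > 0:
        rng = _rng(cfg.seed, "tracking")
        drop = rng.uniform(0.0, 1.0, n) < frac
        like[drop] = rng.uniform(0.1, 0.9, int(drop.sum()))
    df = pd.DataFrame({("lower_body", "x"): x_px, ("lower_body", "y"): y_px,
                       ("lower_body", "likelihood"): like,
                       ("tail_base", "x"): x_px - 10.0,
                       ("tail_base", "y"): y_px,
                       ("tail_base", "likelihood"): np.full(n, 0.99)})
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["bodyparts", "coords"])
    table = TrackingTable(df, t, fs_video=fs)

    pairs_on, pairs_off = [], []
    for start, h in zip(starts[1:], halves[1:]):
        if start + h < n:
            pairs_on.append(start / fs)
            pairs_off.append((start + h) / fs)
    truth = GroundTruth(true_jumps=EventSet.from_pairs(pairs_on, pairs_off,
                                                       kind="jump"))
    return table, truth


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def simulate_spike_trains(cfg: SimConfig, stim_durations_ms=(0, 250, 500, 1000),
                          n_sweeps: int = 10, n_units: int = 1,
                          labels=None, region: str = "GPe", drug: str = "SAL"
                          ) -> tuple[list[UnitRecording], GroundTruth]:
    """Poisson units with stimulus-locked rate changes.

    Outside stimulation the rate is ``baseline_rate_hz``; inside it the
    rate is multiplied by ``1 - inhibition_depth`` for inhibited units and
    by ``excitation_gain`` for excited units.  One :class:`UnitRecording`
    is produced per unit per stimulation duration; the true label of every
    unit is recorded in the ground truth.
    """
    cfg.validate()
    if n_sweeps < 1:
        raise InvalidConfigError("n_sweeps must be at least 1")
    if n_units < 1:
        raise InvalidConfigError("n_units must be at least 1")
    durations = [float(d) for d in stim_durations_ms]
    if any(d < 0 for d in durations):
        raise InvalidConfigError("stimulation durations must be non-negative")
    if labels is None:
        labels = ["inhibited" if cfg.inhibition_depth > 0 else "none"] * n_units
    if len(labels) != n_units:
        raise InvalidConfigError("labels must match n_units")
    rng = _rng(cfg.seed, "spikes")
    rate_ms = cfg.baseline_rate_hz / 1000.0
    factors = {"inhibited": 1.0 - cfg.inhibition_depth,
               "excited": cfg.excitation_gain, "none": 1.0}
    units, truth_labels = [], {}
    for u in range(n_units):
        label = labels[u]
        if label not in factors:
            raise InvalidConfigError(f"unknown unit label {label!r}")
        for dur in durations:
            segments = [(-1000.0, 0.0, rate_ms)]
            if dur > 0:
                segments += [(0.0, dur, rate_ms * factors[label]),
                             (dur, 2000.0, rate_ms)]
            else:
                segments += [(0.0, 2000.0, rate_ms)]
            sweeps = []
            for _ in range(n_sweeps):
                parts = []
                for a, b, r in segments:
                    k = rng.poisson(r * (b - a))
                    parts.append(rng.uniform(a, b, k))
                sweeps.append(np.sort(np.concatenate(parts)))
            uid = f"u{u:03d}"
            units.append(UnitRecording(uid, sweeps, dur, region=region,
                                       drug=drug))
            truth_labels[uid] = label
    return units, GroundTruth(true_unit_class=truth_labels)


# ---------------------------------------------------------------------------
# Rotation trajectory
# ---------------------------------------------------------------------------

def simulate_rotation_trajectory(angular_velocity_dps: float, duration_s: float,
                                 fs_video: float, radius_cm: float = 2.5
                                 ) -> TrackingTable:
    """Snout revolving around a fixed lower-body point at constant angular
    velocity (counter-clockwise positive).  The table is emitted already
    calibrated (cm, y-up), endpoint included, so the cumulative rotation
    over ``duration_s`` is exactly ``angular_velocity_dps * duration_s``."""
    if fs_video <= 0 or duration_s <= 0:
        raise InvalidConfigError("fs_video and duration_s must be positive")
    n = int(round(duration_s * fs_video)) + 1
    t = np.arange(n) / fs_video
    theta = np.radians(angular_velocity_dps) * t
    cx, cy = 21.0, 21.0
    ones = np.full(n, 0.99)
    df = pd.DataFrame({
        ("snout", "x"): cx + radius_cm * np.cos(theta),
        ("snout", "y"): cy + radius_cm * np.sin(theta),
        ("snout", "likelihood"): ones,
        ("lower_body", "x"): np.full(n, cx),
        ("lower_body", "y"): np.full(n, cy),
        ("lower_body", "likelihood"): ones,
    })
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["bodyparts", "coords"])
    return TrackingTable(df, t, fs_video=fs_video, cm_per_px=1.0, y_up=True)
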