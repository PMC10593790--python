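"""Offline replay of the online closed-loop trigger rules.

The online dFF estimate differs from the offline pipeline: each channel is
baselined against a trailing 120 s sliding mean Fo and the control channel
is subtracted, ``dff = [(F-Fo)/Fo]_465 - [(F-Fo)/Fo]_405``, then low-passed
at 1 Hz with a causal one-pole filter.  No output sample depends on future
input (verified by mutation testing), so replaying recorded sessions
reproduces exactly what an online implementation would have seen.

Two trigger rules are simulated:

* calcium-peak — fire when the online dFF has stayed above threshold for a
  sustain period (250 ms) and a local peak occurred, then add the mean
  compute latency (200 ms);
* speed — fire after a rest period below the floor threshold, followed by
  a rise above the mobility threshold that is sustained (never dropping
  below the floor) for 5 s; the trigger lands at the end of the sustain
  window.

A trial scheduler turns accepted triggers into laser-on / laser-off trials
under inter-trial-interval and per-condition caps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DivisionGuardError, InvalidConfigError
from .kinematics import SpeedTrace
from .photometry import PhotometrySession, moving_average


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class OnlineDff:
    """Causal online dFF stream; NaN during the baseline warm-up."""

    time_s: np.ndarray
    dff: np.ndarray
    fs: float
    window_s: float
    lowpass_hz: float


@dataclass
class TriggerRule:
    """Parameters of one online trigger rule.

    Speed thresholds are in the units of the input trace (cm/s throughout
    this package; the published 0.08 / 0.03 m/s correspond to 8 / 3 cm/s).
    """

    kind: str                       # 'calcium_peak' | 'speed'
    threshold: float = 0.0          # calcium: online-dFF units
    sustain_s: float = 0.25
    latency_s: float = 0.2
    refractory_s: float = 0.0
    rest_required_s: float = 5.0    # speed rule: rest before the bout
    rise_thresh: float = 8.0        # cm/s
    floor_thresh: float = 3.0       # cm/s
    avg_window_s: float = 1.0       # trailing mean applied before comparison
    strict_peak: bool = True        # calcium rule: require a local maximum

    def __post_init__(self) -> None:
        if self.kind not in ("calcium_peak", "speed"):
            raise InvalidConfigError("kind must be 'calcium_peak' or 'speed'")
        if self.sustain_s < 0 or self.latency_s < 0 or self.refractory_s < 0:
            raise InvalidConfigError("sustain, latency and refractory must be >= 0")


@dataclass
class TriggerLog:
    """Times at which a rule fired, with per-trigger cause records."""

    trigger_times_s: np.ndarray
    causes: list = field(default_factory=list)
    rule: TriggerRule | None = None

    def __post_init__(self) -> None:
        self.trigger_times_s = np.asarray(self.trigger_times_s, dtype=float)
        if self.rule is not None and self.trigger_times_s.size > 1:
            gaps = np.diff(self.trigger_times_s)
            if np.any(gaps < self.rule.refractory_s - 1e-9):
                raise InvalidConfigError("triggers violate the refractory period")

    def __len__(self) -> int:
        return self.trigger_times_s.size


# ---------------------------------------------------------------------------
# Online dFF
# ---------------------------------------------------------------------------

def _trailing_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Mean over the past ``w`` samples (inclusive); NaN before warm-up."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(x.size, np.nan)
    idx = np.arange(w - 1, x.size)
    out[idx] = (c[idx + 1] - c[idx + 1 - w]) / w
    return out


def online_dff_stream(session: PhotometrySession, window_s: float = 120.0,
                      lowpass_hz: float = 1.0, shrink: bool = False) -> OnlineDff:
    """Causal online dFF: trailing-mean baseline per channel, control
    subtraction, and a one-pole low-pass.  With ``shrink`` the baseline uses
    a growing window during warm-up instead of emitting NaN."""
    fs = session.fs
    w = int(round(window_s * fs))
    if session.time_s.size <= w and not shrink:
        raise InvalidConfigError("session shorter than the baseline window")

    def chan(f: np.ndarray) -> np.ndarray:
        fo = _trailing_mean(f, w)
        if shrink:
            warm = np.arange(min(w - 1, f.size))
            fo[warm] = np.cumsum(f[:warm.size]) / (warm + 1)
        valid = ~np.isnan(fo)
        if np.any(fo[valid] <= 0):
            raise DivisionGuardError(np.flatnonzero(valid & (fo <= 0)))
        return (f - fo) / fo

    raw = chan(session.f465) - chan(session.f405)
    out = np.full(raw.size, np.nan)
    valid = np.flatnonzero(~np.isnan(raw))
    if valid.size:
        a = math.exp(-2.0 * math.pi * lowpass_hz / fs)
        y = 0.0
        started = False
        for i in valid:
            y = raw[i] if not started else (1.0 - a) * raw[i] + a * y
            started = True
            out[i] = y
    return OnlineDff(session.time_s, out, fs, window_s, lowpass_hz)


def threshold_from_zscore(o: OnlineDff, z_target: float = 2.0,
                          calibration_span: tuple | None = None) -> float:
    """Convert a robust-z target into online-dFF units on a calibration epoch.

    The published peak threshold is stated post hoc in z-score units; the
    online signal is in raw dFF units, so the threshold is mapped through
    the median/MAD of the online stream over the calibration span.
    """
    d = o.dff
    if calibration_span is not None:
        sel = (o.time_s >= calibration_span[0]) & (o.time_s < calibration_span[1])
        d = d[sel]
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise InvalidConfigError("calibration span has no online samples")
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        raise InvalidConfigError("calibration span has zero MAD")
    return float(med + z_target * mad / 0.6745)


# ---------------------------------------------------------------------------
# Trigger rules
# ---------------------------------------------------------------------------

def calcium_peak_trigger(o: OnlineDff, rule: TriggerRule) -> TriggerLog:
    """Fire on sustained supra-threshold online dFF containing a peak.

    Detection happens at the first sample where the signal has been above
    ``rule.threshold`` continuously for ``sustain_s`` and (with
    ``strict_peak``) a local maximum has occurred since the crossing; the
    logged trigger time adds the fixed compute latency.  One trigger per
    supra-threshold excursion; the refractory interval is enforced between
    consecutive triggers.
    """
    if rule.kind != "calcium_peak":
        raise InvalidConfigError("rule.kind must be 'calcium_peak'")
    v = o.dff
    t = o.time_s
    n = v.size
    sustain = int(round(rule.sustain_s * o.fs))
    times, causes = [], []
    last_trig = -math.inf
    i = 0
    while i < n:
        if not (not np.isnan(v[i]) and v[i] > rule.threshold):
            i += 1
            continue
        start = i
        peak_at = None
        fired = False
        while i < n and not np.isnan(v[i]) and v[i] > rule.threshold:
            # causal peak flag: the signal turned down at sample i
            if peak_at is None and i >= start + 2 and \
                    v[i] < v[i - 1] and v[i - 1] >= v[i - 2]:
                peak_at = i - 1
            if not fired and i - start >= sustain and \
                    (not rule.strict_peak or peak_at is not None):
                trig = t[i] + rule.latency_s
                if trig - last_trig >= rule.refractory_s:
                    times.append(trig)
                    causes.append({"cause": "calcium_peak",
                                   "cross_time_s": float(t[start]),
                                   "peak_time_s": None if peak_at is None
                                   else float(t[peak_at])})
                    last_trig = trig
                    fired = True
            i += 1
    return TriggerLog(np.asarray(times), causes, rule)


def speed_trigger(speed: SpeedTrace, rule: TriggerRule,
                  bout_sustain_s: float = 5.0) -> TriggerLog:
    """Rest-then-mobility trigger on the (trailing-averaged) speed trace.

    Sequence per trigger: speed below ``floor_thresh`` for
    ``rest_required_s``; then a rise above ``rise_thresh``; then
    ``bout_sustain_s`` during which speed never drops below the floor.  The
    trigger lands at the end of the sustain window.
    """
    if rule.kind != "speed":
        raise InvalidConfigError("rule.kind must be 'speed'")
    v = speed.speed_cm_s
    if rule.avg_window_s > 0:
        w = max(1, int(round(rule.avg_window_s * speed.fs)))
        c = np.concatenate([[0.0], np.cumsum(v)])
        idx = np.arange(v.size)
        lo = np.maximum(0, idx + 1 - w)
        v = (c[idx + 1] - c[lo]) / (idx + 1 - lo)   # trailing, shrinking start
    t = speed.time_s
    fs = speed.fs
    rest_n = int(round(rule.rest_required_s * fs))
    sustain_n = int(round(bout_sustain_s * fs))
    times, causes = [], []
    last_trig = -math.inf
    rest_run = 0
    rested = False
    i = 0
    n = v.size
    while i < n:
        if v[i] < rule.floor_thresh:
            rest_run += 1
            if rest_run >= rest_n:
                rested = True
        else:
            rest_run = 0
        if rested and v[i] > rule.rise_thresh:
            j = i + sustain_n
            if j < n and np.all(v[i:j + 1] >= rule.floor_thresh):
                trig = t[j]
                if trig - last_trig >= rule.refractory_s:
                    times.append(trig)
                    causes.append({"cause": "speed", "rise_time_s": float(t[i])})
                    last_trig = trig
                    rested = False
                    rest_run = 0
                    i = j
            else:
                rested = False
                rest_run = 0
        i += 1
    return TriggerLog(np.asarray(times), causes, rule)


# ---------------------------------------------------------------------------
# Trial scheduling
# ---------------------------------------------------------------------------

def trial_scheduler(log: TriggerLog, max_trials: int = 5, iti_s: float = 360.0,
                    session_cap_s: float = math.inf, trial_s: float = 30.0,
                    assignment: str = "alternate",
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Accept triggers into laser-on / laser-off trials.

    A trigger is accepted when the inter-trial interval has elapsed, the
    session cap is not exceeded, and the assigned condition still has room
    (``max_trials`` per condition).  Assignment alternates on/off or is a
    seeded random draw from the remaining slots.
    """
    if iti_s < 0:
        raise InvalidConfigError("iti_s must be non-negative")
    if assignment not in ("alternate", "random"):
        raise InvalidConfigError("assignment must be 'alternate' or 'random'")
    if assignment == "random" and rng is None:
        rng = np.random.default_rng()
    remaining = {"on": max_trials, "off": max_trials}
    rows = []
    last = -math.inf
    nxt = "on"
    for trig in log.trigger_times_s:
        if trig > session_cap_s:
            break
        if trig - last < iti_s:
            continue
        if assignment == "alternate":
            cond = nxt if remaining[nxt] > 0 else (
                "off" if nxt == "on" else "on")
        else:
            pool = [c for c in ("on", "off") for _ in range(remaining[c])]
            if not pool:
                break
            cond = pool[rng.integers(len(pool))]
        if remaining[cond] == 0:
            continue
        remaining[cond] -= 1
        rows.append({"trial_time_s": float(trig), "condition": cond,
                     "trial_duration_s": trial_s})
        last = trig
        nxt = "off" if cond == "on" else "on"
        if remaining["on"] == 0 and remaining["off"] == 0:
            break
    return pd.DataFrame(rows, columns=["trial_time_s", "condition",
                                       "trial_duration_s"])
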