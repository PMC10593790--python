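"""Pose-tracking ingestion, cleaning, and behavior segmentation.

Input is DeepLabCut-dialect CSV (three header rows: scorer / bodyparts /
coords, one ``x, y, likelihood`` triplet per body part).  The module cleans
low-likelihood points, converts pixels to centimetres (flipping to a y-up
convention once, at calibration), upsamples to the photometry analysis
grid, and segments behavior into locomotor bouts, rotarod jumps,
frame-wise motor states, arena zones, and signed body rotations.

Speed-threshold bout segmentation follows a hysteresis rule: a bout is
opened when smoothed body-center speed breaks 5 cm/s, its onset refined to
the last local minimum before the upward 3 cm/s crossing, and its offset to
the last local maximum before the downward 5 cm/s crossing; the epoch ends
when speed falls back below 3 cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks

from .errors import (
    CalibrationError,
    DegenerateScaleError,
    InvalidConfigError,
    MalformedInputError,
    PartUnusableError,
    SessionExcludedError,
)
from .events import EventSet
from .photometry import MAD_SCALE, moving_average

OPEN_FIELD_PARTS = ("snout", "left_ear", "right_ear", "body_center",
                    "left_side", "right_side", "tail_base", "tail_end")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrackingTable:
    """Per-frame body-part coordinates with likelihoods.

    ``data`` has a two-level column index ``(bodypart, coord)`` with coords
    ``x``, ``y``, ``likelihood``.  Raw tables are in image pixels with y
    increasing downward; after :func:`calibrate_and_upsample` coordinates
    are in cm with y increasing upward (``y_up`` records which).
    """

    data: pd.DataFrame
    time_s: np.ndarray
    fs_video: float
    cm_per_px: float | None = None
    y_up: bool = False
    scorer: str = "bgpipe-synthetic"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.size != len(self.data):
            raise InvalidConfigError("time axis length must match frame count")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise InvalidConfigError("frame times must be strictly increasing")
        like = self.data.xs("likelihood", axis=1, level=1)
        if ((like.to_numpy() < 0) | (like.to_numpy() > 1)).any():
            raise InvalidConfigError("likelihood values must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def part(self, name: str) -> pd.DataFrame:
        if name not in self.bodyparts:
            raise InvalidConfigError(f"body part {name!r} not in table")
        return self.data[name]

    def xy(self, name: str) -> np.ndarray:
        p = self.part(name)
        return np.column_stack([p["x"].to_numpy(), p["y"].to_numpy()])


@dataclass
class SpeedTrace:
    """Body-center speed (cm/s) with per-part speeds and smoothing metadata."""

    time_s: np.ndarray
    speed_cm_s: np.ndarray            # body center, smoothed
    raw_speed_cm_s: np.ndarray        # body center, unsmoothed
    part_speeds: pd.DataFrame         # per-part, unsmoothed
    fs: float
    smooth_window_s: float

    @property
    def smoothed(self) -> bool:
        return self.smooth_window_s > 0


@dataclass
class MotorStateFrames:
    """Exhaustive per-frame motor-state and arena-zone labels."""

    time_s: np.ndarray
    label: np.ndarray   # 'locomotion' | 'motionless' | 'other_movement'
    zone: np.ndarray    # 'center' | 'periphery'

    def fractions(self) -> dict[str, float]:
        n = self.label.size
        return {k: float(np.mean(self.label == k))
                for k in ("locomotion", "motionless", "other_movement")} if n else {}

    def zone_fractions(self) -> dict[str, float]:
        return {k: float(np.mean(self.zone == k)) for k in ("center", "periphery")}


@dataclass
class RotationRecord:
    """Signed per-frame body rotation and cumulative degrees from a reference."""

    time_s: np.ndarray
    angle_deg: np.ndarray       # per consecutive-frame pair, aligned to frame i+1
    cumulative_deg: np.ndarray  # running sum from the reference event onward
    reference_s: float
    skipped_frames: np.ndarray = field(default_factory=lambda: np.array([], int))


# ---------------------------------------------------------------------------
# I/O — DeepLabCut CSV dialect
# ---------------------------------------------------------------------------

def write_tracking(table: TrackingTable, path) -> None:
    """Write the three-header-row (scorer / bodyparts / coords) CSV dialect."""
    cols = pd.MultiIndex.from_tuples(
        [(table.scorer, part, coord) for part, coord in table.data.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out = table.data.copy()
    out.columns = cols
    out.index.name = None
    out.to_csv(path)


def read_tracking(path, fs_video: float | None = None,
                  timestamps=None) -> TrackingTable:
    """Read a DeepLabCut-dialect CSV.

    Frame times come from ``timestamps`` (array of per-frame seconds) when
    given, otherwise from ``fs_video``.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise MalformedInputError(f"cannot parse tracking CSV: {exc}") from exc
    if df.columns.nlevels != 3:
        raise MalformedInputError("expected three header rows (scorer/bodyparts/coords)")
    coords = df.columns.get_level_values(2)
    if not set(coords) <= {"x", "y", "likelihood"}:
        raise MalformedInputError(
            "third header row must contain x/y/likelihood coords "
            "(header rows may be out of order)"
        )
    scorer = str(df.columns.get_level_values(0)[0])
    df.columns = pd.MultiIndex.from_arrays(
        [df.columns.get_level_values(1), coords], names=["bodyparts", "coords"]
    )
    for part in df.columns.get_level_values(0).unique():
        have = set(df[part].columns)
        if have != {"x", "y", "likelihood"}:
            raise MalformedInputError(f"body part {part!r} missing columns "
                                      f"{sorted({'x', 'y', 'likelihood'} - have)}")
    df = df.astype(float).reset_index(drop=True)
    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
        if fs_video is None:
            fs_video = 1.0 / float(np.median(np.diff(t)))
    else:
        if fs_video is None:
            raise InvalidConfigError("either fs_video or timestamps is required")
        t = np.arange(len(df)) / fs_video
    return TrackingTable(df, t, fs_video=fs_video, scorer=scorer)


# ---------------------------------------------------------------------------
# Cleaning and calibration
# ---------------------------------------------------------------------------

def interpolate_low_likelihood(table: TrackingTable,
                               threshold: float = 0.9) -> TrackingTable:
    """Replace sub-threshold coordinates by interpolation over valid frames.

    Interior gaps use shape-preserving piecewise-cubic (PCHIP)
    interpolation; gaps at the edges are filled with the nearest valid
    value.  Likelihoods are preserved unchanged for audit.
    """
    out = table.data.copy()
    idx = np.arange(len(out))
    for part in table.bodyparts:
        like = out[(part, "likelihood")].to_numpy()
        valid = like >= threshold
        if valid.sum() < 2:
            raise PartUnusableError(f"part {part!r}: fewer than 2 frames with "
                                    f"likelihood >= {threshold}")
        if valid.all():
            continue
        for coord in ("x", "y"):
            v = out[(part, coord)].to_numpy(dtype=float)
            interp = PchipInterpolator(idx[valid], v[valid], extrapolate=False)
            filled = v.copy()
            filled[~valid] = interp(idx[~valid])
            # edge gaps: clamp to nearest valid sample
            first, last = idx[valid][0], idx[valid][-1]
            filled[:first] = v[first]
            filled[last + 1:] = v[last]
            out[(part, coord)] = filled
    return replace(table, data=out)


def calibrate_and_upsample(table: TrackingTable, known_distance_cm: float,
                           known_distance_px: float,
                           target_fs: float | None = 100.0) -> TrackingTable:
    """Convert pixels to cm, flip to y-up, and resample to ``target_fs``.

    The image convention has y increasing downward; calibration flips once
    to y-up (about the largest y in the table) so all downstream geometry —
    rotation sign, rotarod "height above the rod base" — uses a fixed
    mathematical convention.  ``target_fs=None`` keeps the native frame
    rate (calibration only).
    """
    if known_distance_px <= 0 or known_distance_cm <= 0:
        raise CalibrationError("known distance must be positive in px and cm")
    cm_per_px = known_distance_cm / known_distance_px
    data = table.data.copy()
    if not table.y_up:
        y_cols = [c for c in data.columns if c[1] == "y"]
        y_ref = data[y_cols].to_numpy().max()
        for c in y_cols:
            data[c] = y_ref - data[c]
    for c in data.columns:
        if c[1] in ("x", "y"):
            data[c] = data[c] * cm_per_px

    if target_fs is None:
        return TrackingTable(data, table.time_s, fs_video=table.fs_video,
                             cm_per_px=cm_per_px, y_up=True,
                             scorer=table.scorer)
    t0, t1 = table.time_s[0], table.time_s[-1]
    n = int(np.floor((t1 - t0) * target_fs)) + 1
    t_new = t0 + np.arange(n) / target_fs
    resampled = {}
    for c in data.columns:
        resampled[c] = np.interp(t_new, table.time_s, data[c].to_numpy(dtype=float))
    new = pd.DataFrame(resampled)
    new.columns = pd.MultiIndex.from_tuples(new.columns,
                                            names=["bodyparts", "coords"])
    return TrackingTable(new, t_new, fs_video=target_fs, cm_per_px=cm_per_px,
                         y_up=True, scorer=table.scorer)


# ---------------------------------------------------------------------------
# Speed and bout segmentation
# ---------------------------------------------------------------------------

def compute_speed(table: TrackingTable, smooth_window_s: float = 2.0,
                  center_part: str = "body_center") -> SpeedTrace:
    """Frame-to-frame displacement speeds; body-center speed smoothed.

    Speed is per-frame displacement over the frame interval (the first
    frame repeats the second so lengths match).  Requires a calibrated
    (cm) table so speeds come out in cm/s.
    """
    if table.cm_per_px is None:
        raise CalibrationError("compute_speed requires a calibrated (cm) table")
    if len(table.data) < 2:
        raise InvalidConfigError("need at least 2 frames to compute speed")
    t = table.time_s
    dt = np.diff(t)
    speeds = {}
    for part in table.bodyparts:
        xy = table.xy(part)
        step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1])) / dt
        speeds[part] = np.concatenate([step[:1], step])
    part_speeds = pd.DataFrame(speeds)
    if center_part not in part_speeds.columns:
        raise InvalidConfigError(f"center part {center_part!r} not tracked")
    raw = part_speeds[center_part].to_numpy()
    smoothed = (moving_average(raw, smooth_window_s, table.fs_video)
                if smooth_window_s > 0 else raw.copy())
    return SpeedTrace(t, smoothed, raw, part_speeds, fs=table.fs_video,
                      smooth_window_s=smooth_window_s)


def _last_near_min(x: np.ndarray, tol: float) -> int:
    """Latest sample within ``tol`` of the window minimum."""
    return int(np.flatnonzero(x <= x.min() + tol)[-1])


def _last_near_max(x: np.ndarray, tol: float) -> int:
    return int(np.flatnonzero(x >= x.max() - tol)[-1])


def detect_locomotor_bouts(speed: SpeedTrace, enter: float = 5.0,
                           sustain: float = 3.0, lookback_s: float = 2.0,
                           flat_tol: float = 1e-3) -> EventSet:
    """Hysteresis bout segmentation on smoothed body-center speed.

    Candidate epochs are maximal spans with speed > ``sustain`` that reach
    ``enter`` at least once.  The onset is the last local minimum (with
    prominence above ``flat_tol`` cm/s) in the ``lookback_s`` window before
    the upward ``sustain`` crossing; on a flat pre-bout baseline, where no
    such minimum exists, it falls back to the latest sample within
    ``flat_tol`` of the window minimum, i.e. the foot of the rise.  The
    offset is symmetric: the last local maximum before the final downward
    ``enter`` crossing.  A session already above ``enter`` at its first
    frame opens a censored bout at frame 0.
    """
    v = speed.speed_cm_s
    n = v.size
    fs = speed.fs
    if n == 0 or not np.any(v > enter):
        return EventSet()
    look = max(1, int(round(lookback_s * fs)))
    above = v > sustain
    # contiguous spans where speed stays above the sustain threshold
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)
    onsets, offsets, censored = [], [], []
    for i0, i1 in zip(starts, ends):
        seg = v[i0:i1]
        if seg.max() <= enter:
            continue
        # onset: look back from the upward sustain-crossing
        if i0 == 0:
            onset, cens = 0, True
        else:
            w0 = max(0, i0 - look)
            window = v[w0:i0 + 1]
            mins, _ = find_peaks(-window, prominence=flat_tol)
            onset = w0 + (mins[-1] if mins.size else
                          _last_near_min(window, flat_tol))
            cens = False
        # offset: last local max before the final downward enter-crossing
        above_enter = np.flatnonzero(seg > enter)
        j_cross = i0 + above_enter[-1]          # last sample above `enter`
        w0 = max(i0, j_cross - look)
        window = v[w0:j_cross + 1]
        maxs, _ = find_peaks(window, prominence=flat_tol)
        offset = w0 + (maxs[-1] if maxs.size else
                       _last_near_max(window, flat_tol))
        if offset <= onset:
            offset = j_cross
        onsets.append(speed.time_s[onset])
        offsets.append(speed.time_s[offset])
        censored.append(cens)
    if not onsets:
        return EventSet()
    return EventSet.from_pairs(onsets, offsets, kind="bout",
                               extra={"censored": censored})


# ---------------------------------------------------------------------------
# Rotarod jumps
# ---------------------------------------------------------------------------

def detect_jumps(table: TrackingTable, part: str = "lower_body",
                 like_thresh: float = 0.95, min_valid_fraction: float = 0.5,
                 min_gap_s: float = 1.0, prominence: float = 0.5) -> EventSet:
    """Detect rotarod jump cycles from the vertical (y-up) position of a part.

    Quality gate: sessions with fewer than ``min_valid_fraction`` of frames
    at likelihood > ``like_thresh`` are excluded outright; individual
    sub-threshold frames are dropped, and runs of them lasting at least
    ``min_gap_s`` split the trace into independent segments.  The y
    position is robust-z-scored, jump onsets are the minima (peaks of the
    inverted z), offsets the maxima.
    """
    if table.cm_per_px is None or not table.y_up:
        raise CalibrationError("detect_jumps requires a calibrated y-up table")
    p = table.part(part)
    like = p["likelihood"].to_numpy()
    y = p["y"].to_numpy(dtype=float)
    valid = like > like_thresh
    if valid.mean() < min_valid_fraction:
        raise SessionExcludedError(
            f"only {100 * valid.mean():.1f}% of frames above likelihood "
            f"{like_thresh}; session excluded"
        )
    med = np.median(y[valid])
    mad = np.median(np.abs(y[valid] - med))
    if mad == 0:
        raise DegenerateScaleError("y position has zero MAD; jumps undefined")
    z = MAD_SCALE * (y - med) / mad

    # segments separated by long low-likelihood runs; short gaps interpolated
    long_gap = np.zeros(valid.size, dtype=bool)
    gap_len = max(1, int(round(min_gap_s * table.fs_video)))
    inv = ~valid
    edges = np.diff(inv.astype(int))
    g_starts = list(np.flatnonzero(edges == 1) + 1)
    g_ends = list(np.flatnonzero(edges == -1) + 1)
    if inv.size and inv[0]:
        g_starts.insert(0, 0)
    if inv.size and inv[-1]:
        g_ends.append(inv.size)
    for g0, g1 in zip(g_starts, g_ends):
        if g1 - g0 >= gap_len:
            long_gap[g0:g1] = True
        else:
            idx = np.arange(len(z))
            z[g0:g1] = np.interp(idx[g0:g1], idx[valid], z[valid])

    onsets, offsets = [], []
    seg_bounds = _segments(~long_gap)
    for s0, s1 in seg_bounds:
        seg = z[s0:s1]
        if seg.size < 3:
            continue
        mins, _ = find_peaks(-seg, prominence=prominence)
        maxs, _ = find_peaks(seg, prominence=prominence)
        onsets.extend(table.time_s[s0 + mins])
        offsets.extend(table.time_s[s0 + maxs])
    onsets = np.sort(np.asarray(onsets))
    offsets = np.sort(np.asarray(offsets))
    # pair each onset with the first offset before the next onset
    pairs_on, pairs_off = [], []
    for k, on in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < onsets.size else np.inf
        cand = offsets[(offsets > on) & (offsets < nxt)]
        if cand.size:
            pairs_on.append(on)
            pairs_off.append(cand[0])
    if not pairs_on:
        return EventSet()
    return EventSet.from_pairs(pairs_on, pairs_off, kind="jump")


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) spans where ``mask`` is True."""
    if mask.size == 0:
        return []
    edges = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def inter_jump_intervals(jumps: EventSet) -> np.ndarray:
    """Intervals between consecutive jump onsets (seconds)."""
    return np.diff(jumps.times("jump_onset"))


# ---------------------------------------------------------------------------
# Motor states, rotations, relative speed
# ---------------------------------------------------------------------------

def classify_motor_state(table: TrackingTable, speed: SpeedTrace,
                         loco_thresh: float = 4.5, still_thresh: float = 0.8,
                         border_cm: float = 10.0, arena_cm: float = 42.0,
                         center_part: str = "body_center") -> MotorStateFrames:
    """Label each frame locomotion / motionless / other_movement plus zone.

    Locomotion: body-center speed > ``loco_thresh``.  Motionless: the speed
    of *every* tracked part <= ``still_thresh``.  Everything else is
    other (non-locomotor) movement.  Zone is periphery inside the outermost
    ``border_cm`` band of the square arena, else center.
    """
    if center_part not in speed.part_speeds.columns:
        raise InvalidConfigError(f"center part {center_part!r} missing")
    body = speed.speed_cm_s
    all_slow = (speed.part_speeds.to_numpy() <= still_thresh).all(axis=1)
    label = np.full(body.size, "other_movement", dtype=object)
    label[all_slow] = "motionless"
    label[body > loco_thresh] = "locomotion"

    xy = table.xy(center_part)
    lo, hi = border_cm, arena_cm - border_cm
    periph = ((xy[:, 0] < lo) | (xy[:, 0] > hi) |
              (xy[:, 1] < lo) | (xy[:, 1] > hi))
    zone = np.where(periph, "periphery", "center").astype(object)
    return MotorStateFrames(speed.time_s, label.astype(str), zone.astype(str))


def rotation_angles(snout_xy, lower_xy, time_s,
                    reference_event_s: float = 0.0,
                    eps: float = 1e-12) -> RotationRecord:
    """Signed body-rotation angles from the lower-body -> snout vector.

    For consecutive frames with body vectors v1, v2 the turn is
    ``atan2(x1*y2 - y1*x2, x1*x2 + y1*y2)`` (counter-clockwise positive in
    y-up coordinates), converted to degrees; the cumulative sum runs from
    the reference event (stimulation onset).  Frames where snout and
    lower-body coincide are skipped (zero contribution) and reported.
    """
    snout = np.asarray(snout_xy, dtype=float)
    lower = np.asarray(lower_xy, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    v = snout - lower
    norm = np.hypot(v[:, 0], v[:, 1])
    degenerate = norm < eps
    x1, y1 = v[:-1, 0], v[:-1, 1]
    x2, y2 = v[1:, 0], v[1:, 1]
    ang = np.degrees(np.arctan2(x1 * y2 - y1 * x2, x1 * x2 + y1 * y2))
    bad = degenerate[:-1] | degenerate[1:]
    ang[bad] = 0.0
    after_ref = time_s[1:] > reference_event_s
    cum = np.cumsum(np.where(after_ref, ang, 0.0))
    return RotationRecord(time_s[1:], ang, cum, reference_event_s,
                          skipped_frames=np.flatnonzero(degenerate))


def relative_speed(speed: SpeedTrace, stim_onsets,
                   baseline: tuple[float, float] = (-60.0, -5.0),
                   window: tuple[float, float] = (-60.0, 30.0)):
    """Per-trial speed minus that trial's pre-stimulation baseline mean.

    Trials whose baseline window is not fully inside the recording are
    dropped.  Returns ``(rel_time_s, matrix, kept_onsets, n_dropped)``.
    """
    t = speed.time_s
    fs = speed.fs
    rel = np.arange(int(round(window[0] * fs)), int(round(window[1] * fs)) + 1) / fs
    rows, kept = [], []
    dropped = 0
    for onset in np.asarray(stim_onsets, dtype=float):
        if onset + baseline[0] < t[0] or onset + window[1] > t[-1]:
            dropped += 1
            continue
        i = int(round((onset - t[0]) * fs))
        idx = i + np.round(rel * fs).astype(int)
        trial = speed.speed_cm_s[idx]
        bmask = (rel >= baseline[0]) & (rel <= baseline[1])
        rows.append(trial - trial[bmask].mean())
        kept.append(onset)
    mat = np.vstack(rows) if rows else np.empty((0, rel.size))
    return rel, mat, np.asarray(kept), dropped
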