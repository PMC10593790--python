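"""Two-channel fiber-photometry processing.

The processing chain mirrors standard practice for GCaMP photometry with an
isosbestic control channel: raw 465/405 nm streams are decimated and
trimmed, the 405 nm (calcium-independent) channel is linearly fitted to the
465 nm channel to form the baseline F0, the fractional change
``dFF = 100 * (F - F0) / F0`` is computed, and traces are standardized with
a median/MAD robust z-score ``z = 0.6745 * (dFF - median) / MAD`` so that
sessions and animals share a common scale.  Transients are then detected as
prominent local maxima and summarized per epoch (peak frequency, amplitude
relative to the preceding local minimum, interpeak interval, and
time-normalized area under the curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    DegenerateFitError,
    DegenerateScaleError,
    DivisionGuardError,
    EmptySessionError,
    InvalidConfigError,
    InvalidWindowError,
)
from .events import EventSet

MAD_SCALE = 0.6745  # scales MAD to estimate sigma of a normal distribution


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PhotometrySession:
    """Raw two-channel fluorescence on a uniform time grid.

    ``f465`` carries the calcium-dependent signal, ``f405`` the isosbestic
    control.  ``events`` holds trial/laser marks on the same clock.
    """

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float
    events: EventSet = field(default_factory=EventSet)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        n = self.time_s.size
        if self.f465.size != n or self.f405.size != n:
            raise InvalidConfigError("channel lengths must match the time axis")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise InvalidConfigError("time axis must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
                raise InvalidConfigError("time axis must be uniform")

    @property
    def duration_s(self) -> float:
        if self.time_s.size < 2:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0]) + 1.0 / self.fs


@dataclass
class ControlFit:
    """Least-squares mapping of the 405 nm channel onto the 465 nm channel."""

    slope: float
    intercept: float
    residual_rms: float


@dataclass
class DffTrace:
    """Processed fluorescence: baseline F0, dFF (%), and robust z."""

    time_s: np.ndarray
    f0: np.ndarray
    dff: np.ndarray
    z: np.ndarray
    fs: float
    events: EventSet = field(default_factory=EventSet)


@dataclass
class TransientMetrics:
    """Per-epoch summary of detected calcium transients (z units)."""

    peak_times_s: np.ndarray
    peak_amplitudes: np.ndarray
    interpeak_intervals_s: np.ndarray
    peak_frequency_hz: float
    auc_per_s: float
    baseline_level: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def downsample_and_trim(session: PhotometrySession, factor: int = 10,
                        trim_s: float = 180.0) -> PhotometrySession:
    """Block-mean decimate by ``factor`` then drop the first ``trim_s``.

    Block averaging acts as a crude anti-alias filter; naive subsampling
    would fold high-frequency noise into the decimated band.  Event
    timestamps are absolute and therefore unchanged; events falling in the
    trimmed span are dropped.
    """
    if factor < 1 or int(factor) != factor:
        raise InvalidConfigError("factor must be a positive integer")
    factor = int(factor)
    n = session.time_s.size
    n_blocks = n // factor
    if n_blocks == 0:
        raise EmptySessionError("session shorter than one decimation block")

    def block(x: np.ndarray) -> np.ndarray:
        return x[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)

    t = block(session.time_s)
    f465 = block(session.f465)
    f405 = block(session.f405)
    keep = t >= session.time_s[0] + trim_s
    if not np.any(keep):
        raise EmptySessionError("trim_s removes the entire session")
    ev = session.events.table
    ev = ev[ev["time_s"] >= t[keep][0]].reset_index(drop=True)
    return PhotometrySession(t[keep], f465[keep], f405[keep],
                             fs=session.fs / factor, events=EventSet(ev))


def fit_isosbestic(f465, f405, baseline_mask=None) -> tuple[ControlFit, np.ndarray]:
    """Fit ``f0 = slope * f405 + intercept`` by least squares.

    ``baseline_mask`` restricts the samples used for the fit (rotarod
    sessions fit on the pre/post rest periods only); the fitted line is then
    evaluated on the full series.
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f465.size != f405.size or f465.size < 2:
        raise InvalidConfigError("channels must have equal length >= 2")
    if baseline_mask is None:
        xs, ys = f405, f465
    else:
        baseline_mask = np.asarray(baseline_mask, dtype=bool)
        xs, ys = f405[baseline_mask], f465[baseline_mask]
        if xs.size < 2:
            raise InvalidConfigError("baseline mask selects fewer than 2 samples")
    if np.ptp(xs) == 0:
        raise DegenerateFitError("control channel is constant; fit undefined")
    slope, intercept = np.polyfit(xs, ys, 1)
    f0 = slope * f405 + intercept
    resid = ys - (slope * xs + intercept)
    return ControlFit(float(slope), float(intercept),
                      float(np.sqrt(np.mean(resid ** 2)))), f0


def compute_dff(f, f0) -> np.ndarray:
    """dFF (%) = 100 * (F - F0) / F0, guarded against non-positive F0."""
    f = np.asarray(f, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise DivisionGuardError(bad)
    return 100.0 * (f - f0) / f0


def robust_zscore(x) -> np.ndarray:
    """Modified z-score ``0.6745 * (x - median) / MAD``.

    The MAD here is the raw median absolute deviation (unscaled); the
    0.6745 factor makes the result comparable to a standard z-score for
    Gaussian data.  By construction the output has median exactly zero.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateScaleError("MAD is zero; modified z-score undefined")
    return MAD_SCALE * (x - med) / mad


def moving_average(x, width_s: float, fs: float) -> np.ndarray:
    """Centered boxcar mean with truncated (shrinking) edge windows."""
    x = np.asarray(x, dtype=float)
    w = int(round(width_s * fs))
    if w < 1:
        w = 1
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def baseline_correct_percentile(x, window_s: float, fs: float, q: float = 8.0,
                                baseline_mask=None) -> np.ndarray:
    """Subtract a moving ``q``-th percentile baseline.

    With ``baseline_mask`` (rotarod mode) the running percentile is computed
    on the masked rest samples only and linearly interpolated across the run
    span, so the running epoch itself does not deform the baseline.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    if window_s <= 0 or w < 3:
        raise InvalidWindowError("percentile window must span >= 3 samples")
    if baseline_mask is None:
        base = _running_percentile(x, w, q)
    else:
        baseline_mask = np.asarray(baseline_mask, dtype=bool)
        if baseline_mask.sum() < 3:
            raise InvalidWindowError("baseline mask selects fewer than 3 samples")
        idx = np.flatnonzero(baseline_mask)
        base_on_mask = _running_percentile(x[idx], w, q)
        base = np.interp(np.arange(x.size), idx, base_on_mask)
    return x - base


def _running_percentile(x: np.ndarray, w: int, q: float) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(w, center=True, min_periods=1).quantile(q / 100.0).to_numpy()


def running_percentile(x, window_s: float, fs: float, q: float = 8.0) -> np.ndarray:
    """Moving ``q``-th percentile with truncated edge windows."""
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    if window_s <= 0 or w < 3:
        raise InvalidWindowError("percentile window must span >= 3 samples")
    return _running_percentile(x, w, q)


def detect_transients(z, fs: float, min_prominence: float = 0.5,
                      min_separation_s: float = 0.2,
                      baseline_window_s: float = 30.0) -> TransientMetrics:
    """Detect calcium transients as prominent local maxima.

    Peak amplitude is measured against the nearest preceding local minimum
    (falling back to the lowest sample before the first peak).  AUC is the
    trapezoidal integral divided by the epoch duration; ``baseline_level``
    is the mean of the moving 8th-percentile baseline.
    """
    z = np.asarray(z, dtype=float)
    if z.size <= 2:
        raise InvalidConfigError("series too short for peak detection")
    duration = (z.size - 1) / fs  # span of the trapezoid grid
    distance = max(1, int(round(min_separation_s * fs)))
    peaks, _ = find_peaks(z, prominence=min_prominence, distance=distance)
    minima, _ = find_peaks(-z)
    amplitudes = np.empty(peaks.size)
    for i, p in enumerate(peaks):
        prior = minima[minima < p]
        ref = z[prior[-1]] if prior.size else z[: p + 1].min()
        amplitudes[i] = z[p] - ref
    times = peaks / fs
    ipi = np.diff(times)
    w = min(z.size, max(3, int(round(baseline_window_s * fs))))
    baseline = float(np.mean(_running_percentile(z, w, 8.0)))
    auc = float(np.trapezoid(z, dx=1.0 / fs) / duration)
    return TransientMetrics(times, amplitudes, ipi,
                            peak_frequency_hz=peaks.size / duration,
                            auc_per_s=auc, baseline_level=baseline)


# ---------------------------------------------------------------------------
# Convenience chain and I/O
# ---------------------------------------------------------------------------

def process_session(session: PhotometrySession, factor: int = 10,
                    trim_s: float = 180.0, baseline_mask_fn=None) -> DffTrace:
    """Run decimation, isosbestic fit, dFF and robust z in one call.

    ``baseline_mask_fn`` maps the decimated time axis to a boolean mask
    restricting the isosbestic fit (rotarod pre/post rest periods).
    """
    ds = downsample_and_trim(session, factor=factor, trim_s=trim_s)
    mask = baseline_mask_fn(ds.time_s) if baseline_mask_fn is not None else None
    _, f0 = fit_isosbestic(ds.f465, ds.f405, baseline_mask=mask)
    dff = compute_dff(ds.f465, f0)
    z = robust_zscore(dff)
    return DffTrace(ds.time_s, f0, dff, z, fs=ds.fs, events=ds.events)


def write_photometry_csv(session: PhotometrySession, path) -> None:
    pd.DataFrame({"time_s": session.time_s, "f465": session.f465,
                  "f405": session.f405}).to_csv(path, index=False)


def read_photometry_csv(path, fs: float | None = None,
                        events: EventSet | None = None) -> PhotometrySession:
    df = pd.read_csv(path)
    for col in ("time_s", "f465", "f405"):
        if col not in df.columns:
            raise InvalidConfigError(f"photometry table missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise InvalidConfigError("cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    return PhotometrySession(t, df["f465"].to_numpy(dtype=float),
                             df["f405"].to_numpy(dtype=float), fs=fs,
                             events=events or EventSet())


def resample_trace(trace: DffTrace, target_fs: float) -> DffTrace:
    """Linear-interpolate a processed trace onto a uniform ``target_fs`` grid."""
    t0, t1 = trace.time_s[0], trace.time_s[-1]
    n = int(np.floor((t1 - t0) * target_fs)) + 1
    t = t0 + np.arange(n) / target_fs
    interp = lambda y: np.interp(t, trace.time_s, y)
    return replace(trace, time_s=t, f0=interp(trace.f0), dff=interp(trace.dff),
                   z=interp(trace.z), fs=target_fs)
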