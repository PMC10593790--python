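"""Event-aligned photometry metrics and surrogate correlation statistics.

Traces are aligned to behavioral events into trial x time matrices with an
optional pre-event baseline subtraction.  Relationships between the
calcium signal and behavior (or between two recording sites) are measured
with a lagged Pearson correlation — the trace pair is shifted sample by
sample and the strongest correlation (by magnitude) is reported with its
lag — and tested against a phase-randomized surrogate null: surrogates
preserve the Fourier amplitude spectrum (hence power spectrum and
autocorrelation) of one variable while destroying its phase alignment, and
the population of real best-correlations is compared with the surrogate
population by a two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import mannwhitneyu, pearsonr

from .errors import (
    InsufficientDataError,
    InvalidConfigError,
    UndefinedCorrelationError,
)
from .events import EventSet
from .photometry import DffTrace


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EventMatrix:
    """Trial x time matrix of a trace aligned to events."""

    data: np.ndarray
    rel_time_s: np.ndarray
    event_times_s: np.ndarray
    fs: float
    baseline_window: tuple | None = None
    n_dropped: int = 0


@dataclass
class LaggedCorrelation:
    """Pearson r across integer-sample lags; the strongest |r| is 'best'."""

    lags_s: np.ndarray
    r_by_lag: np.ndarray
    best_r: float
    best_lag_s: float
    n_samples: int


@dataclass
class SurrogateTest:
    """Real vs phase-shuffled best-correlation populations."""

    real_values: np.ndarray
    surrogate_values: np.ndarray
    n_shuffle: int
    p_value: float
    test: str = "two-sided rank-sum"


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_to_events(trace, events, pre_s: float, post_s: float,
                    baseline_window: tuple | None = None,
                    channel: str = "z", fs: float | None = None,
                    time_s=None) -> EventMatrix:
    """Slice a trace around each event time.

    ``trace`` may be a :class:`~bgpipe.photometry.DffTrace` (``channel``
    selects ``z`` or ``dff``) or a plain array with ``time_s``/``fs``
    supplied.  ``events`` is an EventSet kind-array or a plain array of
    times.  Events whose window exceeds the trace are dropped (counted in
    ``n_dropped``); if ``baseline_window`` (rel. seconds, e.g. (-5, -1)) is
    given, each row has its baseline mean subtracted.
    """
    if isinstance(trace, DffTrace):
        x = getattr(trace, channel)
        time_s = trace.time_s
        fs = trace.fs
    else:
        x = np.asarray(trace, dtype=float)
        if time_s is None or fs is None:
            raise InvalidConfigError("plain-array traces need time_s and fs")
        time_s = np.asarray(time_s, dtype=float)
    if isinstance(events, EventSet):
        raise InvalidConfigError("pass a specific event-kind array, e.g. "
                                 "events.times('bout_onset')")
    event_times = np.asarray(events, dtype=float)
    npre = int(round(pre_s * fs))
    npost = int(round(post_s * fs))
    rel = np.arange(-npre, npost + 1) / fs
    rows, kept = [], []
    dropped = 0
    for ev in event_times:
        i = int(round((ev - time_s[0]) * fs))
        if i - npre < 0 or i + npost >= x.size:
            dropped += 1
            continue
        row = x[i - npre: i + npost + 1].astype(float).copy()
        if baseline_window is not None:
            m = (rel >= baseline_window[0]) & (rel <= baseline_window[1])
            if not m.any():
                raise InvalidConfigError("baseline window outside the matrix")
            row -= row[m].mean()
        rows.append(row)
        kept.append(ev)
    if not rows:
        raise InsufficientDataError("no event window fits inside the trace")
    return EventMatrix(np.vstack(rows), rel, np.asarray(kept), fs,
                       baseline_window=baseline_window, n_dropped=dropped)


def post_event_extremum(m: EventMatrix, search_window=(0.0, 5.0),
                        mode: str = "max"):
    """Per-trial local extremum nearest the event inside ``search_window``.

    Returns ``(values, latencies_s, flagged)``; rows with no interior
    extremum fall back to the window boundary value and are flagged.
    """
    if mode not in ("min", "max"):
        raise InvalidConfigError("mode must be 'min' or 'max'")
    sel = (m.rel_time_s >= search_window[0]) & (m.rel_time_s <= search_window[1])
    if not sel.any():
        raise InvalidConfigError("search window outside the matrix window")
    rel = m.rel_time_s[sel]
    vals = np.empty(m.data.shape[0])
    lats = np.empty(m.data.shape[0])
    flagged = np.zeros(m.data.shape[0], dtype=bool)
    for i, row in enumerate(m.data):
        seg = row[sel] if mode == "max" else -row[sel]
        peaks, _ = find_peaks(seg)
        if peaks.size:
            j = peaks[np.argmin(np.abs(rel[peaks]))]
        else:
            j = int(np.argmax(seg))
            flagged[i] = True
        vals[i] = row[sel][j]
        lats[i] = rel[j]
    return vals, lats, flagged


def amplitude_change(m: EventMatrix, rule: str = "bout",
                     offsets_rel_s=None, search_s: float = 5.0) -> np.ndarray:
    """Per-trial amplitude delta across a bout or opto epoch.

    ``bout`` rule: (local maximum near the bout end) minus (local minimum
    near the onset); ``offsets_rel_s`` gives each trial's offset relative
    to the aligned event.  ``opto`` rule: trace value at opto offset minus
    value at opto onset.  Trials whose reference points fall outside the
    matrix are dropped (NaN in the output).
    """
    n_trials = m.data.shape[0]
    if offsets_rel_s is None:
        raise InvalidConfigError("offsets_rel_s (scalar or per-trial) required")
    offs = np.broadcast_to(np.asarray(offsets_rel_s, dtype=float), (n_trials,))
    deltas = np.full(n_trials, np.nan)
    for i, (row, off) in enumerate(zip(m.data, offs)):
        if off > m.rel_time_s[-1] or off < m.rel_time_s[0]:
            continue
        if rule == "opto":
            j0 = int(np.argmin(np.abs(m.rel_time_s)))
            j1 = int(np.argmin(np.abs(m.rel_time_s - off)))
            deltas[i] = row[j1] - row[j0]
        elif rule == "bout":
            sub = EventMatrix(row[None, :], m.rel_time_s, m.event_times_s[i:i + 1],
                              m.fs)
            vmin, _, _ = post_event_extremum(sub, (-search_s, search_s), "min")
            end = EventMatrix(row[None, :], m.rel_time_s - off,
                              m.event_times_s[i:i + 1], m.fs)
            vmax, _, _ = post_event_extremum(end, (-search_s, search_s), "max")
            deltas[i] = vmax[0] - vmin[0]
        else:
            raise InvalidConfigError("rule must be 'bout' or 'opto'")
    return deltas


def transient_duration_and_event_duration(transient_peak_times_s, jumps,
                                          max_offset_s: float = 2.0):
    """Pair jump-bout durations with calcium-transient durations.

    Jump duration is the peak-to-peak interval between consecutive jump
    onsets; transient duration the interval between the corresponding
    consecutive dFF peaks (each jump onset matched to its nearest peak
    within ``max_offset_s``).  Returns ``(jump_dur, transient_dur, r, p)``.
    """
    peaks = np.sort(np.asarray(transient_peak_times_s, dtype=float))
    jump_times = jumps.times("jump_onset") if isinstance(jumps, EventSet) \
        else np.sort(np.asarray(jumps, dtype=float))
    matched = np.full(jump_times.size, np.nan)
    for i, jt in enumerate(jump_times):
        if peaks.size == 0:
            break
        k = int(np.argmin(np.abs(peaks - jt)))
        if abs(peaks[k] - jt) <= max_offset_s:
            matched[i] = peaks[k]
    jd, td = [], []
    for i in range(jump_times.size - 1):
        if np.isnan(matched[i]) or np.isnan(matched[i + 1]):
            continue
        if matched[i + 1] <= matched[i]:
            continue
        jd.append(jump_times[i + 1] - jump_times[i])
        td.append(matched[i + 1] - matched[i])
    if len(jd) < 3:
        raise InsufficientDataError("fewer than 3 paired jump/transient durations")
    jd = np.asarray(jd)
    td = np.asarray(td)
    r, p = pearsonr(jd, td)
    return jd, td, float(r), float(p)


# ---------------------------------------------------------------------------
# Lagged correlation and surrogate testing
# ---------------------------------------------------------------------------

def lagged_pearson(x, y, fs: float, max_lag_s: float = 5.0,
                   step: int = 1, min_overlap: int = 30) -> LaggedCorrelation:
    """Pearson r of ``x[t]`` against ``y[t + lag]`` over integer-sample lags.

    r is computed on the overlapping (shift-trimmed) span at every lag in
    +/-``max_lag_s``; the result reports the signed r of the lag with the
    largest \\|r\\|.  Lags with a zero-variance overlap yield NaN; if all
    lags are degenerate an error is raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidConfigError("series must share one grid")
    n = x.size
    max_lag = int(round(max_lag_s * fs))
    lags = np.arange(-max_lag, max_lag + 1, step)
    # center once (Pearson is translation invariant) to avoid catastrophic
    # cancellation in the moment sums of high-offset fluorescence traces
    x = x - x.mean()
    y = y - y.mean()
    # windowed first/second moments from cumulative sums; the cross term is
    # a dot product per lag, so a full scan is O(n_lags * n)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    r = np.full(lags.size, np.nan)
    for i, k in enumerate(lags):
        m = n - abs(int(k))
        if m < min_overlap:
            continue
        if k >= 0:
            a, b = x[:m], y[k: k + m]
            sx, sxx = cx[m], cxx[m]
            sy, syy = cy[n] - cy[k], cyy[n] - cyy[k]
        else:
            a, b = x[-k: -k + m], y[:m]
            sx, sxx = cx[n] - cx[-k], cxx[n] - cxx[-k]
            sy, syy = cy[m], cyy[m]
        var_x = m * sxx - sx * sx
        var_y = m * syy - sy * sy
        if var_x <= 0 or var_y <= 0:
            continue
        r[i] = (m * np.dot(a, b) - sx * sy) / np.sqrt(var_x * var_y)
    if np.all(np.isnan(r)):
        raise UndefinedCorrelationError(
            "no lag had a valid (non-degenerate) overlap")
    best = int(np.nanargmax(np.abs(r)))
    k = lags[best]
    n_ov = n - abs(int(k))
    return LaggedCorrelation(lags / fs, r, float(r[best]), float(k / fs), n_ov)


def phase_shuffle(x, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate with the amplitude spectrum preserved.

    Phases of all non-DC, non-Nyquist rFFT bins are replaced by independent
    uniform draws; conjugate symmetry is implicit in the inverse rFFT, so
    the output is real with exactly the original \\|FFT\\| per bin.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise InvalidConfigError("phase shuffling needs at least 4 samples")
    spec = np.fft.rfft(x)
    hi = spec.size - 1 if n % 2 == 0 else spec.size
    phases = rng.uniform(0.0, 2.0 * np.pi, hi - 1)
    spec[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


def shuffle_correlation_test(x_per_subject, y_per_subject, fs: float,
                             n_shuffle: int = 1000,
                             rng: np.random.Generator | None = None,
                             max_lag_s: float = 5.0,
                             mode: str = "pooled") -> SurrogateTest:
    """Real vs phase-shuffled best-correlation populations.

    For every subject the real best \\|r\\| (lagged Pearson) is computed;
    ``n_shuffle`` surrogates phase-shuffle the x variable (cycling through
    subjects in ``pooled`` mode) and rescan the lags.  The two populations
    are compared with a two-sided Mann-Whitney rank-sum test.  In
    ``per_subject`` mode surrogate populations are kept per subject and a
    pooled p-value is still reported for the combined populations.
    """
    if n_shuffle < 1:
        raise InvalidConfigError("n_shuffle must be at least 1")
    if mode not in ("pooled", "per_subject"):
        raise InvalidConfigError("mode must be 'pooled' or 'per_subject'")
    if rng is None:
        rng = np.random.default_rng()
    xs = [np.asarray(x, dtype=float) for x in x_per_subject]
    ys = [np.asarray(y, dtype=float) for y in y_per_subject]
    if len(xs) != len(ys) or not xs:
        raise InvalidConfigError("need matching non-empty subject lists")
    real = np.array([abs(lagged_pearson(x, y, fs, max_lag_s).best_r)
                     for x, y in zip(xs, ys)])
    if mode == "pooled":
        subj = [i % len(xs) for i in range(n_shuffle)]
    else:
        subj = [i // n_shuffle for i in range(n_shuffle * len(xs))]
    surr = np.empty(len(subj))
    for i, s in enumerate(subj):
        xs_sh = phase_shuffle(xs[s], rng)
        surr[i] = abs(lagged_pearson(xs_sh, ys[s], fs, max_lag_s).best_r)
    _, p = mannwhitneyu(real, surr, alternative="two-sided")
    return SurrogateTest(real, surr, n_shuffle, float(p))


def epoch_correlation(gpe: DffTrace, snr: DffTrace, epochs: dict,
                      max_lag_s: float = 5.0, min_overlap: int = 30,
                      channel: str = "z") -> dict:
    """Lagged Pearson correlation between two sites, per task epoch.

    ``epochs`` maps names (e.g. pre/during/post) to ``(t0, t1)`` spans in
    seconds on the shared clock.  Epochs that are too short or degenerate
    are skipped (absent from the result).
    """
    if gpe.time_s.size != snr.time_s.size or \
            abs(gpe.time_s[0] - snr.time_s[0]) > 0.5 / gpe.fs:
        raise InvalidConfigError("traces must share one time grid")
    x = getattr(gpe, channel)
    y = getattr(snr, channel)
    out = {}
    for name, (t0, t1) in epochs.items():
        sel = (gpe.time_s >= t0) & (gpe.time_s < t1)
        if sel.sum() < min_overlap:
            continue
        try:
            out[name] = lagged_pearson(x[sel], y[sel], gpe.fs, max_lag_s,
                                       min_overlap=min_overlap)
        except UndefinedCorrelationError:
            continue
    return out
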