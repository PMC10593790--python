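"""Peri-stimulus time histograms and opto-response unit classification.

Single units are recorded as per-sweep spike-time lists relative to laser
onset.  PSTHs use 1 ms bins spanning -1000 to +2000 ms, with spike counts
summed across sweeps and converted to firing rate (Hz).  Two published
criteria classify a unit's response to optogenetic stimulation:

* thirds rule — inhibited if the stimulation-window mean rate falls to
  <= 2/3 of the 1000 ms pre-stimulation baseline, excited if it rises to
  >= 4/3 of it;
* z-score rule — ``z = (mean_stim - mean_baseline) / SD_baseline`` with
  cut-offs at -2 / +2, where SD_baseline is taken across the 1000 one-ms
  baseline bins of the summed PSTH.

For the 0 ms (no-light) control condition both rules evaluate a 1000 ms
post-onset window.  An optional first-50-ms analysis window isolates the
earliest, most likely monosynaptic part of the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import InvalidInputError

PSTH_PRE_MS = 1000
PSTH_POST_MS = 2000
BIN_MS = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class UnitRecording:
    """Per-sweep spike times (ms, relative to laser onset) for one unit."""

    unit_id: str
    sweeps: list
    stim_duration_ms: float
    region: str = "GPe"
    drug: str = "SAL"

    def __post_init__(self) -> None:
        self.sweeps = [np.sort(np.asarray(s, dtype=float)) for s in self.sweeps]
        for s in self.sweeps:
            if s.size and (s.min() < -PSTH_PRE_MS or s.max() >= PSTH_POST_MS):
                raise InvalidInputError(
                    f"unit {self.unit_id}: spike outside the "
                    f"({-PSTH_PRE_MS}, {PSTH_POST_MS}) ms analysis window"
                )

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


@dataclass
class PSTH:
    """Sweep-summed 1 ms-bin rate histogram with baseline statistics."""

    bin_edges_ms: np.ndarray
    rate_hz: np.ndarray
    n_sweeps: int
    stim_duration_ms: float
    baseline_mean_hz: float
    baseline_sd_hz: float
    unit_id: str = ""

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


@dataclass
class UnitClassification:
    """Both criteria for one unit under one analysis window."""

    unit_id: str
    stim_duration_ms: float
    region: str
    drug: str
    norm_rate: float
    zscore: float
    label_thirds: str | None
    label_z: str | None
    analysis_window: str = "full_stim"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_psth(u: UnitRecording) -> PSTH:
    """Histogram spikes into 1 ms bins and convert to Hz.

    Per-bin rate = total count across sweeps / (n_sweeps * bin width).
    Bins are half-open ``[t, t+1)`` ms.  Baseline mean/SD are computed over
    the 1000 pre-stimulation bins (sample SD across bins).
    """
    if u.n_sweeps < 1:
        raise InvalidInputError("PSTH requires at least one sweep")
    edges = np.arange(-PSTH_PRE_MS, PSTH_POST_MS + BIN_MS, BIN_MS, dtype=float)
    spikes = np.concatenate(u.sweeps) if u.sweeps else np.array([])
    counts, _ = np.histogram(spikes, bins=edges)
    rate = counts / (u.n_sweeps * BIN_MS * 1e-3)
    base = rate[:PSTH_PRE_MS]
    return PSTH(edges, rate, u.n_sweeps, u.stim_duration_ms,
                baseline_mean_hz=float(base.mean()),
                baseline_sd_hz=float(base.std(ddof=1)),
                unit_id=u.unit_id)


def _stim_window_bins(p: PSTH, window: str) -> slice:
    if window == "first_50ms":
        dur = 50.0
    elif window == "full_stim":
        dur = p.stim_duration_ms if p.stim_duration_ms > 0 else 1000.0
    else:
        raise InvalidInputError(f"unknown analysis window {window!r}")
    i0 = PSTH_PRE_MS  # bin starting at 0 ms
    return slice(i0, i0 + int(round(dur / BIN_MS)))


def normalized_rate(p: PSTH, window: str = "full_stim") -> float:
    """Stimulation-window mean rate divided by the baseline mean.

    Returns NaN (unit unanalyzable) when the baseline mean is zero.
    """
    if p.baseline_mean_hz == 0:
        return float("nan")
    stim = p.rate_hz[_stim_window_bins(p, window)]
    return float(stim.mean() / p.baseline_mean_hz)


def classify_thirds(p: PSTH, window: str = "full_stim") -> str | None:
    """Inhibited / excited by a one-third change from baseline; else 'none'.

    Returns None for unanalyzable units (zero baseline).
    """
    nr = normalized_rate(p, window)
    if np.isnan(nr):
        return None
    if nr <= 2.0 / 3.0:
        return "inhibited"
    if nr >= 4.0 / 3.0:
        return "excited"
    return "none"


def classify_zscore(p: PSTH, window: str = "full_stim") -> tuple[float, str | None]:
    """z = (mean_stim - mean_baseline) / SD_baseline with cut-offs at +/-2."""
    if p.baseline_sd_hz == 0:
        return float("nan"), None
    stim = p.rate_hz[_stim_window_bins(p, window)]
    z = float((stim.mean() - p.baseline_mean_hz) / p.baseline_sd_hz)
    if z <= -2.0:
        return z, "inhibited"
    if z >= 2.0:
        return z, "excited"
    return z, "none"


def basal_rate(p: PSTH) -> float:
    """Mean firing rate (Hz) over the 1000 ms pre-stimulation window."""
    return p.baseline_mean_hz


def classify_unit(u: UnitRecording, window: str = "full_stim") -> UnitClassification:
    p = build_psth(u)
    z, lz = classify_zscore(p, window)
    return UnitClassification(u.unit_id, u.stim_duration_ms, u.region, u.drug,
                              norm_rate=normalized_rate(p, window), zscore=z,
                              label_thirds=classify_thirds(p, window), label_z=lz,
                              analysis_window=window)


def population_summary(classifications, criterion: str = "thirds",
                       contrast: tuple[str, str] = ("SAL", "CNO")):
    """Inhibited vs non-inhibited contingency tables per region x duration.

    ``classifications`` is an iterable of :class:`UnitClassification`.
    For each (region, stim_duration) cell a 2x2 Fisher exact test compares
    the inhibited proportion between the two drug groups.  Unanalyzable
    units (label None) are counted separately and excluded from the test.
    Returns ``(counts, tests)`` tidy DataFrames.
    """
    rows = []
    for c in classifications:
        label = c.label_thirds if criterion == "thirds" else c.label_z
        rows.append({"unit_id": c.unit_id, "region": c.region, "drug": c.drug,
                     "stim_duration_ms": c.stim_duration_ms,
                     "label": "unanalyzable" if label is None else label})
    if not rows:
        raise InvalidInputError("no unit classifications provided")
    df = pd.DataFrame(rows)
    counts = (df.groupby(["region", "stim_duration_ms", "drug", "label"])
                .size().rename("n").reset_index())
    tests = []
    for (region, dur), grp in df.groupby(["region", "stim_duration_ms"]):
        grp = grp[grp["label"] != "unanalyzable"]
        tab = np.zeros((2, 2), dtype=int)
        for j, drug in enumerate(contrast):
            sub = grp[grp["drug"] == drug]
            tab[j, 0] = int((sub["label"] == "inhibited").sum())
            tab[j, 1] = int((sub["label"] != "inhibited").sum())
        if tab.sum(axis=1).min() == 0:
            continue  # one drug group empty in this cell
        _, p = fisher_exact(tab, alternative="two-sided")
        tests.append({"region": region, "stim_duration_ms": dur,
                      f"inhibited_{contrast[0]}": tab[0, 0],
                      f"total_{contrast[0]}": tab[0].sum(),
                      f"inhibited_{contrast[1]}": tab[1, 0],
                      f"total_{contrast[1]}": tab[1].sum(),
                      "fisher_p": float(p)})
    return counts, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# I/O — plain-text spike lists
# ---------------------------------------------------------------------------

def write_spikes(units, spikes_path, metadata_path) -> None:
    """Write per-sweep spike lists and a unit metadata table."""
    rows = []
    meta = []
    for u in units:
        meta.append({"unit_id": u.unit_id, "region": u.region, "drug": u.drug,
                     "stim_duration_ms": u.stim_duration_ms,
                     "n_sweeps": u.n_sweeps})
        for sweep_id, s in enumerate(u.sweeps):
            for t in s:
                rows.append((u.unit_id, u.stim_duration_ms, sweep_id, t))
    pd.DataFrame(rows, columns=["unit_id", "stim_duration_ms", "sweep_id",
                                "spike_time_ms"]) \
        .to_csv(spikes_path, index=False)
    pd.DataFrame(meta).to_csv(metadata_path, index=False)


def read_spikes(spikes_path, metadata_path) -> list[UnitRecording]:
    """One recording per (unit, stimulation duration) metadata row."""
    spk = pd.read_csv(spikes_path)
    meta = pd.read_csv(metadata_path)
    units = []
    for _, m in meta.iterrows():
        sub = spk[(spk["unit_id"] == m["unit_id"])
                  & (spk["stim_duration_ms"] == m["stim_duration_ms"])]
        sweeps = [sub.loc[sub["sweep_id"] == k, "spike_time_ms"].to_numpy()
                  for k in range(int(m["n_sweeps"]))]
        units.append(UnitRecording(str(m["unit_id"]), sweeps,
                                   float(m["stim_duration_ms"]),
                                   region=str(m["region"]), drug=str(m["drug"])))
    if not units:
        raise InvalidInputError("empty unit metadata table")
    return units
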