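"""Typed behavioral event containers.

An :class:`EventSet` stores point events (bout/jump onsets and offsets,
trigger times) on a common time axis, with onset/offset pairing kept
explicit so downstream alignment can iterate over whole bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("bout_onset", "bout_offset", "jump_onset", "jump_offset", "trigger")


@dataclass
class EventSet:
    """Sorted, typed point events with optional onset/offset pairing.

    ``table`` has columns ``kind`` (one of :data:`KINDS`), ``time_s`` and
    ``pair_id`` (integer linking an onset with its offset; -1 when unpaired).
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            {"kind": pd.Series(dtype=str),
             "time_s": pd.Series(dtype=float),
             "pair_id": pd.Series(dtype=int)}
        )
    )

    def __post_init__(self) -> None:
        t = self.table
        bad = set(t["kind"]) - set(KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        self.table = t.sort_values("time_s", kind="stable").reset_index(drop=True)
        for prefix in ("bout", "jump"):
            on, off = self.pairs(prefix)
            if np.any(off < on):
                raise ValueError(f"{prefix} offset precedes its onset")

    @classmethod
    def from_pairs(cls, onsets, offsets, kind: str = "bout",
                   extra: dict | None = None) -> "EventSet":
        onsets = np.asarray(onsets, dtype=float)
        offsets = np.asarray(offsets, dtype=float)
        if onsets.shape != offsets.shape:
            raise ValueError("onsets and offsets must pair one-to-one")
        n = onsets.size
        df = pd.DataFrame({
            "kind": [f"{kind}_onset"] * n + [f"{kind}_offset"] * n,
            "time_s": np.concatenate([onsets, offsets]),
            "pair_id": np.concatenate([np.arange(n)] * 2),
        })
        if extra:
            for key, vals in extra.items():
                df[key] = np.concatenate([np.asarray(vals)] * 2)
        return cls(df)

    @classmethod
    def from_times(cls, times, kind: str = "trigger") -> "EventSet":
        times = np.asarray(times, dtype=float)
        return cls(pd.DataFrame({
            "kind": [kind] * times.size,
            "time_s": times,
            "pair_id": np.full(times.size, -1, dtype=int),
        }))

    def times(self, kind: str) -> np.ndarray:
        return self.table.loc[self.table["kind"] == kind, "time_s"].to_numpy()

    def pairs(self, prefix: str = "bout") -> tuple[np.ndarray, np.ndarray]:
        """Return (onsets, offsets) matched by pair_id for ``prefix`` events."""
        on = self.table[self.table["kind"] == f"{prefix}_onset"]
        off = self.table[self.table["kind"] == f"{prefix}_offset"]
        merged = on.merge(off, on="pair_id", suffixes=("_on", "_off"))
        merged = merged.sort_values("time_s_on")
        return merged["time_s_on"].to_numpy(), merged["time_s_off"].to_numpy()

    def shifted(self, dt_s: float) -> "EventSet":
        out = self.table.copy()
        out["time_s"] = out["time_s"] + dt_s
        return EventSet(out)

    def __len__(self) -> int:
        return len(self.table)
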