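"""Tabular containers for behavioral events and spike times.

Both tables round-trip through tab-delimited text with a JSON sidecar that
documents the columns, so artifacts stay greppable and diffable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = ["TrialEvents", "EventTable", "SpikeTable"]


@dataclass
class TrialEvents:
    """Tap and stimulus times for a single trial.

    Times are in milliseconds from trial start.  Tap times must be strictly
    increasing; stimulus times may be empty (e.g. the continuation phase).
    """

    trial_id: int
    condition: str
    target_interval_ms: float
    tap_times_ms: np.ndarray
    stimulus_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.tap_times_ms = np.asarray(self.tap_times_ms, dtype=float)
        self.stimulus_times_ms = np.asarray(self.stimulus_times_ms, dtype=float)
        if self.tap_times_ms.size >= 2 and np.any(np.diff(self.tap_times_ms) <= 0):
            raise ValueError(
                f"trial {self.trial_id}: tap times must be strictly increasing"
            )

    @property
    def produced_intervals_ms(self) -> np.ndarray:
        return np.diff(self.tap_times_ms)

    @property
    def n_segments(self) -> int:
        return max(len(self.tap_times_ms) - 1, 0)


class EventTable:
    """Collection of per-trial tap/stimulus event records."""

    def __init__(self, trials: Iterable[TrialEvents] = ()) -> None:
        self._trials: dict[int, TrialEvents] = {}
        for t in trials:
            self.add(t)

    def add(self, trial: TrialEvents) -> None:
        if trial.trial_id in self._trials:
            raise ValueError(f"duplicate trial_id {trial.trial_id}")
        self._trials[trial.trial_id] = trial

    def __len__(self) -> int:
        return len(self._trials)

    def __iter__(self) -> Iterator[TrialEvents]:
        return iter(self._trials.values())

    def __getitem__(self, trial_id: int) -> TrialEvents:
        return self._trials[trial_id]

    @property
    def trial_ids(self) -> list[int]:
        return list(self._trials)

    def extend(self, other: "EventTable") -> "EventTable":
        for t in other:
            self.add(t)
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self:
            for k, tm in enumerate(t.tap_times_ms):
                rows.append((t.trial_id, t.condition, t.target_interval_ms, "tap", k, tm))
            for k, tm in enumerate(t.stimulus_times_ms):
                rows.append(
                    (t.trial_id, t.condition, t.target_interval_ms, "stimulus", k, tm)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "trial_id",
                "condition",
                "target_interval_ms",
                "kind",
                "event_index",
                "time_ms",
            ],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        table = cls()
        for trial_id, grp in df.groupby("trial_id", sort=True):
            taps = grp.loc[grp["kind"] == "tap"].sort_values("event_index")
            stims = grp.loc[grp["kind"] == "stimulus"].sort_values("event_index")
            table.add(
                TrialEvents(
                    trial_id=int(trial_id),
                    condition=str(grp["condition"].iloc[0]),
                    target_interval_ms=float(grp["target_interval_ms"].iloc[0]),
                    tap_times_ms=taps["time_ms"].to_numpy(),
                    stimulus_times_ms=stims["time_ms"].to_numpy(),
                )
            )
        return table

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        _write_sidecar(
            path,
            {
                "format": "event-table",
                "columns": {
                    "trial_id": "integer trial identifier",
                    "condition": "task condition label (SC, CC, ST, SRTT, ...)",
                    "target_interval_ms": "instructed interval in ms",
                    "kind": "tap or stimulus",
                    "event_index": "ordinal position within the trial",
                    "time_ms": "event time in ms from trial start",
                },
            },
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EventTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


class SpikeTable:
    """Spike times per (trial, neuron), stored as a long-format frame."""

    COLUMNS = ["trial_id", "neuron_id", "time_ms"]

    def __init__(self, df: pd.DataFrame | None = None) -> None:
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"spike table missing columns: {sorted(missing)}")
        if len(df) and (df["time_ms"] < 0).any():
            raise ValueError("spike times must be nonnegative")
        self.df = df.sort_values(self.COLUMNS, kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def neuron_ids(self) -> np.ndarray:
        return np.sort(self.df["neuron_id"].unique())

    @property
    def trial_ids(self) -> np.ndarray:
        return np.sort(self.df["trial_id"].unique())

    def spikes(self, trial_id: int, neuron_id: int) -> np.ndarray:
        mask = (self.df["trial_id"] == trial_id) & (self.df["neuron_id"] == neuron_id)
        return self.df.loc[mask, "time_ms"].to_numpy()

    def concat(self, other: "SpikeTable") -> "SpikeTable":
        frames = [df for df in (self.df, other.df) if len(df)]
        if not frames:
            return SpikeTable()
        return SpikeTable(pd.concat(frames, ignore_index=True))

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        _write_sidecar(
            path,
            {
                "format": "spike-table",
                "columns": {
                    "trial_id": "integer trial identifier",
                    "neuron_id": "integer unit identifier",
                    "time_ms": "spike time in ms from trial start",
                },
            },
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SpikeTable":
        return cls(pd.read_csv(path, sep="\t"))


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
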