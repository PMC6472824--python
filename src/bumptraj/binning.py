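"""Event time normalization, binning and rate normalization.

Two time frames are used throughout:

UTND (unit-time-normalized data)
    Every inter-tap segment is divided into exactly 50 bins, so trials at
    different tempos have the same number of columns.
TIND (target-interval-normalized data)
    Bin count per segment is ``round(target / 20 ms)`` (half-up), so bin
    duration stays near 20 ms of real time and longer intervals contribute
    more bins.

Bins are half-open ``[start, end)``: a spike exactly at a tap belongs to
the following segment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import PopulationActivity
from .tables import EventTable, SpikeTable, TrialEvents

__all__ = [
    "UTND_BINS_PER_SEGMENT",
    "RAW_BIN_MS",
    "BinnedPopulation",
    "time_normalize_events",
    "tind_bin_count",
    "bin_spikes",
    "bin_population_activity",
    "concat_binned",
    "normalize_rates",
    "resample_segments",
    "behavior_metrics",
]

UTND_BINS_PER_SEGMENT = 50
RAW_BIN_MS = 20.0

BIN_META_COLUMNS = [
    "trial_id",
    "condition",
    "target_interval_ms",
    "repetition",
    "segment",
    "bin_in_segment",
    "normalized_time",
    "time_ms",
    "bin_width_ms",
]


def time_normalize_events(
    event_times_ms: np.ndarray, tap_times_ms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map event times onto the tap-anchored normalized axis.

    For an event in the segment between taps ``k`` and ``k+1`` the value is
    ``(event - tap_{k+1}) / produced_interval + (k+1)``, so tap ``k`` maps
    exactly to the integer ``k`` and a full seven-tap trial spans [0, 6].
    Events outside the tap span are extrapolated with the nearest segment
    and flagged ``False`` in the second return value.
    """
    events = np.asarray(event_times_ms, dtype=float)
    taps = np.asarray(tap_times_ms, dtype=float)
    if taps.size < 2:
        raise ValueError("need at least two taps")
    if np.any(np.diff(taps) <= 0):
        raise ValueError("tap times must be strictly increasing")
    # segment index for each event; events before the first tap use segment
    # 0 and events at/after the last tap use the final segment
    seg = np.clip(np.searchsorted(taps, events, side="right") - 1, 0, taps.size - 2)
    produced = np.diff(taps)[seg]
    values = (events - taps[seg + 1]) / produced + (seg + 1)
    in_span = (events >= taps[0]) & (events <= taps[-1])
    return values, in_span


def tind_bin_count(target_interval_ms: float, bin_ms: float = RAW_BIN_MS) -> int:
    """Bins per segment in the TIND frame (round half up: 450/20 -> 23)."""
    return int(np.floor(target_interval_ms / bin_ms + 0.5))


@dataclass
class BinnedPopulation:
    """Neurons-by-bins rate matrix with per-bin metadata.

    ``X[i, j]`` is the rate of ``neuron_ids[i]`` in bin ``j``; the ``bins``
    frame describes each column (trial, segment, normalized time, real
    time, width).  ``max_rates`` is populated by :func:`normalize_rates`.
    """

    X: np.ndarray
    neuron_ids: np.ndarray
    bins: pd.DataFrame
    mode: str
    max_rates: np.ndarray | None = None
    silent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.X.shape[0] != len(self.neuron_ids):
            raise ValueError("X rows must match neuron_ids")
        if self.X.shape[1] != len(self.bins):
            raise ValueError("X columns must match bin metadata rows")

    @property
    def n_neurons(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]

    @property
    def is_normalized(self) -> bool:
        return self.max_rates is not None

    def segment_keys(self) -> pd.DataFrame:
        """Unique (trial, segment) combinations, in column order."""
        return (
            self.bins[["trial_id", "repetition", "target_interval_ms", "condition", "segment"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def segment_mask(self, trial_id: int, segment: int) -> np.ndarray:
        return (
            (self.bins["trial_id"] == trial_id) & (self.bins["segment"] == segment)
        ).to_numpy()

    def select_neurons(self, neuron_ids: Sequence) -> "BinnedPopulation":
        index = {n: i for i, n in enumerate(self.neuron_ids)}
        rows = [index[n] for n in neuron_ids]
        return replace(
            self,
            X=self.X[rows],
            neuron_ids=np.asarray(list(neuron_ids)),
            max_rates=None if self.max_rates is None else self.max_rates[rows],
            silent=None if self.silent is None else self.silent[rows],
        )


def _segment_edges(tap_a: float, tap_b: float, n_bins: int) -> np.ndarray:
    return np.linspace(tap_a, tap_b, n_bins + 1)


def _bins_for_trial(trial: TrialEvents, mode: str, bin_ms: float) -> list[tuple]:
    """Per-bin (segment, bin_in_segment, start, end) tuples for one trial."""
    out = []
    taps = trial.tap_times_ms
    for k in range(len(taps) - 1):
        if mode == "utnd":
            nb = UTND_BINS_PER_SEGMENT
        elif mode == "tind":
            nb = tind_bin_count(trial.target_interval_ms, bin_ms)
        elif mode == "raw":
            nb = max(int(np.floor((taps[k + 1] - taps[k]) / bin_ms)), 1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        edges = _segment_edges(taps[k], taps[k + 1], nb)
        for j in range(nb):
            out.append((k, j, edges[j], edges[j + 1]))
    return out


def _bin_meta_row(trial: TrialEvents, seg: int, j: int, a: float, b: float, repetition: int):
    taps = trial.tap_times_ms
    width = b - a
    center = (a + b) / 2.0
    norm = seg + (center - taps[seg]) / (taps[seg + 1] - taps[seg])
    return (
        trial.trial_id,
        trial.condition,
        trial.target_interval_ms,
        repetition,
        seg,
        j,
        norm,
        center,
        width,
    )


def bin_spikes(
    spikes: SpikeTable,
    events: EventTable,
    mode: str,
    bin_ms: float = RAW_BIN_MS,
    neuron_ids: Sequence | None = None,
    repetition: int = 0,
) -> BinnedPopulation:
    """Bin spike counts into rates (spikes/s) on the requested time frame.

    Trials with fewer than two taps are skipped with a warning.  Neurons
    default to the union observed in the spike table; pass ``neuron_ids``
    to fix the row order (absent neurons become silent rows).
    """
    if neuron_ids is None:
        neuron_ids = spikes.neuron_ids
    neuron_ids = np.asarray(neuron_ids)
    index = {n: i for i, n in enumerate(neuron_ids)}

    cols: list[np.ndarray] = []
    meta_rows: list[tuple] = []
    for trial in events:
        if len(trial.tap_times_ms) < 2:
            warnings.warn(f"trial {trial.trial_id} has < 2 taps; skipped")
            continue
        tdf = spikes.df[spikes.df["trial_id"] == trial.trial_id]
        by_neuron = {
            n: g["time_ms"].to_numpy() for n, g in tdf.groupby("neuron_id", sort=False)
        }
        for seg, j, a, b in _bins_for_trial(trial, mode, bin_ms):
            col = np.zeros(len(neuron_ids))
            width_s = (b - a) / 1000.0
            for n, times in by_neuron.items():
                if n in index:
                    col[index[n]] = (
                        np.count_nonzero((times >= a) & (times < b)) / width_s
                    )
            cols.append(col)
            meta_rows.append(_bin_meta_row(trial, seg, j, a, b, repetition))
    X = np.column_stack(cols) if cols else np.zeros((len(neuron_ids), 0))
    bins = pd.DataFrame(meta_rows, columns=BIN_META_COLUMNS)
    return BinnedPopulation(X=X, neuron_ids=neuron_ids, bins=bins, mode=mode)


def bin_population_activity(
    pop: PopulationActivity,
    mode: str,
    bin_ms: float = RAW_BIN_MS,
    trial_id: int = 0,
) -> BinnedPopulation:
    """Average a dense 1-ms rate matrix into UTND/TIND/raw bins."""
    trial = TrialEvents(
        trial_id=trial_id,
        condition=pop.condition,
        target_interval_ms=pop.target_interval_ms,
        tap_times_ms=pop.tap_times_ms,
    )
    cols = []
    meta_rows = []
    n_samples = pop.rates.shape[1]
    for seg, j, a, b in _bins_for_trial(trial, mode, bin_ms):
        i0 = int(round(a)) - pop.t0_ms
        i1 = int(round(b)) - pop.t0_ms
        i0, i1 = max(i0, 0), min(max(i1, i0 + 1), n_samples)
        cols.append(pop.rates[:, i0:i1].mean(axis=1))
        meta_rows.append(_bin_meta_row(trial, seg, j, a, b, pop.repetition))
    X = np.column_stack(cols)
    bins = pd.DataFrame(meta_rows, columns=BIN_META_COLUMNS)
    return BinnedPopulation(X=X, neuron_ids=pop.neuron_ids.copy(), bins=bins, mode=mode)


def bin_fixed_windows(
    pop: PopulationActivity, bin_ms: float = RAW_BIN_MS, trial_id: int = 0
) -> BinnedPopulation:
    """Fixed-width bins over the full simulated range (margins included).

    Unlike the tap-anchored frames this covers activity before the first
    and after the last tap; segment indices outside the tap span are -1 /
    n_segments.  Used for decoding tap times from continuous output.
    """
    n_samples = pop.rates.shape[1]
    n_bins = int(n_samples // bin_ms)
    taps = pop.tap_times_ms
    cols, meta_rows = [], []
    for j in range(n_bins):
        i0, i1 = int(j * bin_ms), int((j + 1) * bin_ms)
        cols.append(pop.rates[:, i0:i1].mean(axis=1))
        center = pop.t0_ms + (i0 + i1) / 2.0
        seg = int(np.searchsorted(taps, center, side="right") - 1)
        norm, _ = time_normalize_events(np.array([center]), taps)
        meta_rows.append(
            (
                trial_id,
                pop.condition,
                pop.target_interval_ms,
                pop.repetition,
                seg,
                j,
                float(norm[0]),
                center,
                float(bin_ms),
            )
        )
    X = np.column_stack(cols)
    bins = pd.DataFrame(meta_rows, columns=BIN_META_COLUMNS)
    return BinnedPopulation(X=X, neuron_ids=pop.neuron_ids.copy(), bins=bins, mode="raw")


def concat_binned(parts: Iterable[BinnedPopulation]) -> BinnedPopulation:
    """Concatenate along bins, expanding to the union of neuron ids.

    Neurons missing from a part are zero (silent) in its columns — a unit
    not recruited for a condition simply does not fire there.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to concatenate")
    modes = {p.mode for p in parts}
    if len(modes) > 1:
        raise ValueError(f"cannot mix binning modes: {sorted(modes)}")
    union: list = []
    seen = set()
    for p in parts:
        for n in p.neuron_ids:
            if n not in seen:
                seen.add(n)
                union.append(n)
    union_arr = np.asarray(union)
    index = {n: i for i, n in enumerate(union_arr)}
    X = np.zeros((len(union_arr), sum(p.n_bins for p in parts)))
    offset = 0
    for p in parts:
        rows = [index[n] for n in p.neuron_ids]
        X[rows, offset : offset + p.n_bins] = p.X
        offset += p.n_bins
    bins = pd.concat([p.bins for p in parts], ignore_index=True)
    return BinnedPopulation(X=X, neuron_ids=union_arr, bins=bins, mode=parts[0].mode)


def normalize_rates(binned: BinnedPopulation) -> BinnedPopulation:
    """Scale each neuron by its maximum rate over all bins.

    Silent neurons (max 0) are left at zero and flagged.  Idempotent: the
    maxima of an already-normalized matrix are 1.
    """
    max_rates = binned.X.max(axis=1) if binned.n_bins else np.zeros(binned.n_neurons)
    silent = max_rates <= 0
    scale = np.where(silent, 1.0, max_rates)
    return replace(
        binned,
        X=binned.X / scale[:, None],
        max_rates=max_rates,
        silent=silent,
    )


def resample_segments(binned: BinnedPopulation, n_bins: int = 30) -> BinnedPopulation:
    """Linearly resample every segment to ``n_bins`` columns."""
    cols = []
    meta_rows = []
    keys = binned.segment_keys()
    for _, key in keys.iterrows():
        mask = (binned.bins["trial_id"] == key["trial_id"]) & (
            binned.bins["segment"] == key["segment"]
        )
        idx = np.flatnonzero(mask.to_numpy())
        sub = binned.X[:, idx]
        old = np.arange(len(idx))
        new = np.linspace(0, len(idx) - 1, n_bins)
        res = np.vstack([np.interp(new, old, row) for row in sub])
        cols.append(res)
        seg = int(key["segment"])
        meta = binned.bins.iloc[idx[0]]
        t0 = binned.bins.iloc[idx[0]]["time_ms"]
        t1 = binned.bins.iloc[idx[-1]]["time_ms"]
        centers = np.linspace(t0, t1, n_bins)
        width = (t1 - t0) / max(n_bins - 1, 1)
        for j in range(n_bins):
            meta_rows.append(
                (
                    meta["trial_id"],
                    meta["condition"],
                    meta["target_interval_ms"],
                    meta["repetition"],
                    seg,
                    j,
                    seg + (j + 0.5) / n_bins,
                    centers[j],
                    width,
                )
            )
    X = np.hstack(cols)
    bins = pd.DataFrame(meta_rows, columns=BIN_META_COLUMNS)
    return BinnedPopulation(
        X=X, neuron_ids=binned.neuron_ids.copy(), bins=bins, mode=binned.mode
    )


def behavior_metrics(events: EventTable) -> pd.DataFrame:
    """Constant error, within-trial temporal variability and asynchronies.

    Constant error is ``mean(produced - target)``; temporal variability is
    the mean over trials of the SD of produced intervals within a trial;
    asynchrony is tap time minus nearest metronome stimulus (NaN without
    stimuli).
    """
    rows = []
    for trial in events:
        produced = trial.produced_intervals_ms
        if produced.size == 0:
            continue
        if trial.stimulus_times_ms.size:
            asyncs = [
                t - trial.stimulus_times_ms[np.argmin(np.abs(trial.stimulus_times_ms - t))]
                for t in trial.tap_times_ms[: len(trial.stimulus_times_ms)]
            ]
            mean_async = float(np.mean(asyncs))
        else:
            mean_async = np.nan
        rows.append(
            {
                "condition": trial.condition,
                "target_interval_ms": trial.target_interval_ms,
                "trial_id": trial.trial_id,
                "mean_produced_ms": float(produced.mean()),
                "constant_error_ms": float(produced.mean() - trial.target_interval_ms),
                "within_trial_sd_ms": float(produced.std(ddof=1)) if produced.size > 1 else 0.0,
                "mean_asynchrony_ms": mean_async,
            }
        )
    per_trial = pd.DataFrame(rows)
    if per_trial.empty:
        return per_trial
    summary = (
        per_trial.groupby(["condition", "target_interval_ms"], as_index=False)
        .agg(
            constant_error_ms=("constant_error_ms", "mean"),
            temporal_variability_ms=("within_trial_sd_ms", "mean"),
            mean_asynchrony_ms=("mean_asynchrony_ms", "mean"),
            n_trials=("trial_id", "nunique"),
        )
        .sort_values(["condition", "target_interval_ms"])
        .reset_index(drop=True)
    )
    return summary
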