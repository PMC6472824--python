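"""Poisson surprise-index detection of single-unit activation periods.

A window holding ``n`` spikes in ``T`` seconds is scored against a
homogeneous Poisson process at the unit's whole-recording mean rate ``r``:

    P = exp(-rT) * sum_{i>=n} (rT)^i / i!        SI = -log(P)

Windows are grown greedily from each spike while the surprise increases,
trimmed from the left the same way, then thresholded and pruned to a
non-overlapping set (highest surprise first).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = [
    "SurpriseQuery",
    "ActivationPeriod",
    "BumpSummary",
    "poisson_surprise",
    "detect_activation_periods",
    "summarize_bump",
]

DEFAULT_SI_THRESHOLD = 4.6  # ~= -ln(0.01)
DEFAULT_MIN_SPIKES = 3
DEFAULT_MIN_DURATION_MS = 20.0


@dataclass
class SurpriseQuery:
    """Inputs of one Poisson-tail evaluation."""

    rate_hz: float
    duration_s: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.n_spikes < 0 or int(self.n_spikes) != self.n_spikes:
            raise ValueError("spike count must be a nonnegative integer")


@dataclass
class ActivationPeriod:
    """A detected above-chance activation window of one unit."""

    neuron_id: int
    onset_ms: float
    offset_ms: float
    surprise: float
    n_spikes: int
    mean_rate_hz: float
    peak_time_ms: float
    target_interval_ms: float = np.nan
    segment: int = -1

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class BumpSummary:
    """Per-condition moving-bump statistics."""

    n_cells: int
    mean_duration_ms: float
    recruitment_lapses_ms: np.ndarray
    mean_in_period_rate_hz: float
    condition: tuple = ()

    @property
    def mean_lapse_ms(self) -> float:
        return float(np.mean(self.recruitment_lapses_ms)) if self.recruitment_lapses_ms.size else np.nan


def poisson_surprise(query: SurpriseQuery, log_base: float = np.e) -> float:
    """Surprise index of a spike-count query, evaluated in log space.

    Uses the regularized upper-incomplete-gamma form of the Poisson tail,
    so extreme tails do not underflow.  ``n = 0`` gives 0; a positive count
    at zero baseline rate returns ``inf``.
    """
    n, mu = int(query.n_spikes), query.rate_hz * query.duration_s
    if n == 0:
        return 0.0
    if mu == 0:
        return float("inf")
    log_p = poisson.logsf(n - 1, mu)  # log P(N >= n)
    si = -float(log_p)
    if log_base != np.e:
        si /= np.log(log_base)
    return max(si, 0.0)


def _window_surprise(times: np.ndarray, i: int, j: int, rate_hz: float) -> float:
    """Surprise of the window spanned by spikes i..j.

    Both window endpoints are spikes by construction, so only the interior
    count (n - 2) is scored against the spanned duration; scoring all n
    would overstate the surprise of windows that hug their spikes and
    break the false-positive calibration.
    """
    from scipy.special import pdtrc

    duration_s = max(times[j] - times[i], 1e-3) / 1000.0
    n_interior = j - i - 1
    if n_interior <= 0:
        return 0.0
    mu = rate_hz * duration_s
    p = pdtrc(n_interior - 1, mu)  # P(N >= n_interior)
    if p <= 0:  # underflow: fall back to the stable log form
        return poisson_surprise(SurpriseQuery(rate_hz, duration_s, n_interior))
    return -float(np.log(p))


def detect_activation_periods(
    spike_times_ms: np.ndarray,
    mean_rate_hz: float,
    si_threshold: float = DEFAULT_SI_THRESHOLD,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    min_duration_ms: float = DEFAULT_MIN_DURATION_MS,
    neuron_id: int = -1,
) -> list[ActivationPeriod]:
    """Greedy surprise-maximizing window detection on one spike train.

    Each spike seeds a window of ``min_spikes`` spikes that is extended to
    the right while the surprise increases, then trimmed from the left the
    same way.  Candidates below the surprise threshold, the spike-count
    floor or the minimum duration are dropped; surviving windows are kept
    highest-surprise-first without overlap.
    """
    times = np.sort(np.asarray(spike_times_ms, dtype=float))
    n = len(times)
    if n < min_spikes:
        return []
    if mean_rate_hz <= 0:
        raise ValueError("mean_rate_hz must be positive")

    lookahead = 3  # tolerate locally non-improving steps during growth
    candidates: list[tuple[float, int, int]] = []
    for i in range(n - min_spikes + 1):
        j = i + min_spikes - 1
        si = _window_surprise(times, i, j, mean_rate_hz)
        while j + 1 < n:
            step = None
            for k in range(1, lookahead + 1):
                if j + k >= n:
                    break
                nxt = _window_surprise(times, i, j + k, mean_rate_hz)
                if nxt > si:
                    step, si = k, nxt
                    break
            if step is None:
                break
            j += step
        i2 = i
        while i2 + 1 <= j - min_spikes + 1:
            step = None
            for k in range(1, lookahead + 1):
                if i2 + k > j - min_spikes + 1:
                    break
                nxt = _window_surprise(times, i2 + k, j, mean_rate_hz)
                if nxt > si:
                    step, si = k, nxt
                    break
            if step is None:
                break
            i2 += step
        duration = times[j] - times[i2]
        if si >= si_threshold and (j - i2 + 1) >= min_spikes and duration >= min_duration_ms:
            candidates.append((si, i2, j))

    candidates.sort(key=lambda c: -c[0])
    chosen: list[tuple[float, int, int]] = []
    taken = np.zeros(n, dtype=bool)
    for si, i, j in candidates:
        if taken[i : j + 1].any():
            continue
        # boundary completion: the surprise-maximal core tends to trim the
        # first/last spikes of a burst, so attach adjacent spikes whose
        # gaps look like in-burst intervals
        if j > i:
            med_isi = float(np.median(np.diff(times[i : j + 1])))
            while i > 0 and not taken[i - 1] and times[i] - times[i - 1] <= 2 * med_isi:
                i -= 1
            while j < n - 1 and not taken[j + 1] and times[j + 1] - times[j] <= 2 * med_isi:
                j += 1
        taken[i : j + 1] = True
        chosen.append((si, i, j))

    periods = []
    for si, i, j in sorted(chosen, key=lambda c: c[1]):
        window = times[i : j + 1]
        duration_s = max(window[-1] - window[0], 1e-3) / 1000.0
        periods.append(
            ActivationPeriod(
                neuron_id=neuron_id,
                onset_ms=float(window[0]),
                offset_ms=float(window[-1]),
                surprise=float(si),
                n_spikes=j - i + 1,
                mean_rate_hz=(j - i + 1) / duration_s,
                peak_time_ms=float(np.mean(window)),
            )
        )
    return periods


def summarize_bump(
    periods: Sequence[ActivationPeriod], population_size: int
) -> BumpSummary:
    """Moving-bump statistics from one condition's detected periods.

    Counts units with at least one period, averages durations and in-period
    rates, and measures recruitment lapses as peak-time differences between
    consecutively activated units (one period per unit: its strongest).
    """
    if population_size < 0:
        raise ValueError("population_size must be >= 0")
    if not periods:
        return BumpSummary(
            n_cells=0,
            mean_duration_ms=np.nan,
            recruitment_lapses_ms=np.empty(0),
            mean_in_period_rate_hz=np.nan,
        )
    best: dict[int, ActivationPeriod] = {}
    for p in periods:
        if p.neuron_id not in best or p.surprise > best[p.neuron_id].surprise:
            best[p.neuron_id] = p
    n_cells = len(best)
    if n_cells > population_size:
        raise ValueError("more active cells than population size")
    peaks = np.sort([p.peak_time_ms for p in best.values()])
    lapses = np.diff(peaks)
    return BumpSummary(
        n_cells=n_cells,
        mean_duration_ms=float(np.mean([p.duration_ms for p in periods])),
        recruitment_lapses_ms=lapses,
        mean_in_period_rate_hz=float(np.mean([p.mean_rate_hz for p in periods])),
    )


def periods_to_frame(periods: Sequence[ActivationPeriod]) -> pd.DataFrame:
    """Long-format table of detected periods (for TSV export)."""
    return pd.DataFrame(
        [
            {
                "neuron_id": p.neuron_id,
                "target_interval_ms": p.target_interval_ms,
                "segment": p.segment,
                "onset_ms": p.onset_ms,
                "offset_ms": p.offset_ms,
                "duration_ms": p.duration_ms,
                "surprise": p.surprise,
                "n_spikes": p.n_spikes,
                "mean_rate_hz": p.mean_rate_hz,
                "peak_time_ms": p.peak_time_ms,
            }
            for p in periods
        ]
    )
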