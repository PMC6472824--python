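"""Synthetic moving-bump population activity, tapping behavior and controls.

The central object is a population of units that activate sequentially
within each produced interval and repeat the pattern cyclically.  Each
unit's activation waveform is a sum of random gamma-density components on a
unit support, stretched to the interval-specific activation duration.  Unit
recruitment (peak-time placement) follows a truncated Gaussian centered at
mid-interval, so the population rate rises and falls within the interval
with slow tails near the taps.

Two regimes are provided:

``expanding``
    Neuron count and activation duration both grow with the target
    interval (defaults: 108..182 neurons, 197..257 ms).
``static``
    A temporal-scaling null: constant neuron count and constant duty
    cycle, i.e. the same population pattern stretched in time.  Under this
    regime trajectories share a common loop traversed at interval-dependent
    speed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import truncnorm

from .tables import EventTable, SpikeTable, TrialEvents

__all__ = [
    "EXPANDING_NEURON_COUNTS",
    "EXPANDING_ACTIVATION_MS",
    "STATIC_NEURON_COUNT",
    "STATIC_ACTIVATION_MS",
    "STATIC_REFERENCE_INTERVAL_MS",
    "SimulationConfig",
    "BehaviorConfig",
    "GammaProfileSpec",
    "ActivationProfile",
    "PopulationActivity",
    "simulate_activation_profile",
    "simulate_moving_bump",
    "extend_bump_population",
    "simulate_experiment",
    "generate_behavior",
    "simulate_reactive_control",
    "sample_spikes",
]

log = logging.getLogger(__name__)

DEFAULT_INTERVALS_MS: tuple[int, ...] = (450, 550, 650, 850, 1000)

EXPANDING_NEURON_COUNTS: dict[int, int] = {450: 108, 550: 120, 650: 130, 850: 170, 1000: 182}
EXPANDING_ACTIVATION_MS: dict[int, float] = {450: 197.0, 550: 205.0, 650: 213.0, 850: 233.0, 1000: 257.0}

STATIC_NEURON_COUNT = 130
STATIC_ACTIVATION_MS = 213.0
STATIC_REFERENCE_INTERVAL_MS = 650


@dataclass
class SimulationConfig:
    """Parameters of a moving-bump population simulation."""

    target_intervals_ms: tuple[int, ...] = DEFAULT_INTERVALS_MS
    n_neurons_by_interval: dict[int, int] | None = None
    activation_ms_by_interval: dict[int, float] | None = None
    n_intervals_per_trial: int = 3
    n_repetitions: int = 5
    regime: str = "expanding"
    recruitment_shape: str = "gaussian"
    recruitment_sd_fraction: float = 0.25
    insert_quantile_range: tuple[float, float] = (0.15, 0.85)
    n_gamma_components: int = 20
    noise_sd: float = 0.05
    fresh_population_per_repetition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("expanding", "static"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.recruitment_shape != "gaussian":
            raise ValueError(f"unknown recruitment shape {self.recruitment_shape!r}")
        if self.n_neurons_by_interval is None:
            if self.regime == "expanding":
                self.n_neurons_by_interval = {
                    t: EXPANDING_NEURON_COUNTS[t] for t in self.target_intervals_ms
                }
            else:
                self.n_neurons_by_interval = {
                    t: STATIC_NEURON_COUNT for t in self.target_intervals_ms
                }
        if self.activation_ms_by_interval is None:
            if self.regime == "expanding":
                self.activation_ms_by_interval = {
                    t: EXPANDING_ACTIVATION_MS[t] for t in self.target_intervals_ms
                }
            else:
                # constant duty cycle: the 650-ms value stretched per interval
                duty = STATIC_ACTIVATION_MS / STATIC_REFERENCE_INTERVAL_MS
                self.activation_ms_by_interval = {
                    t: duty * t for t in self.target_intervals_ms
                }
        for t in self.target_intervals_ms:
            if t not in self.n_neurons_by_interval:
                raise ValueError(f"missing neuron count for interval {t}")
            if t not in self.activation_ms_by_interval:
                raise ValueError(f"missing activation duration for interval {t}")
            if t <= 0 or self.n_neurons_by_interval[t] <= 0:
                raise ValueError("intervals and neuron counts must be positive")
            if self.activation_ms_by_interval[t] <= 0:
                raise ValueError("activation durations must be positive")
        if self.n_intervals_per_trial < 1 or self.n_repetitions < 1:
            raise ValueError("counts must be strictly positive")
        lo, hi = self.insert_quantile_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("insert_quantile_range must satisfy 0 <= lo < hi <= 1")


@dataclass
class BehaviorConfig:
    """Tapping-behavior noise model: scalar (Weber) variability plus a
    small signed bias of the produced interval."""

    weber_fraction: float = 0.05
    constant_error_ms: float = -10.0
    n_trials: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class GammaProfileSpec:
    """Shape parameters of a gamma-sum waveform on a unit support.

    ``modes`` are component peak positions as fractions of the activation
    window; evaluating at a duration rescales the whole profile in time, so
    a unit keeps its canonical shape across target intervals.
    """

    shapes: np.ndarray
    modes: np.ndarray
    amplitudes: np.ndarray

    @classmethod
    def draw(cls, rng: np.random.Generator, n_components: int = 20) -> "GammaProfileSpec":
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        return cls(
            shapes=rng.uniform(2.0, 8.0, n_components),
            modes=rng.uniform(0.0, 1.0, n_components),
            amplitudes=rng.uniform(0.0, 1.0, n_components) + 1e-12,
        )

    def waveform(self, duration_ms: float) -> np.ndarray:
        """Evaluate the peak-normalized waveform at 1-ms resolution."""
        if duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        n = int(round(duration_ms))
        t = np.arange(n, dtype=float)
        w = np.zeros(n)
        for k, m, a in zip(self.shapes, self.modes, self.amplitudes):
            mode_ms = max(m * duration_ms, 1.0)
            scale = mode_ms / (k - 1.0)
            peak = gamma_dist.pdf(mode_ms, a=k, scale=scale)
            if peak > 0:
                w += a * gamma_dist.pdf(t, a=k, scale=scale) / peak
        peak = w.max()
        if peak <= 0:
            raise RuntimeError("degenerate all-zero waveform")
        return w / peak


@dataclass
class ActivationProfile:
    """A single unit's activation waveform within one produced interval."""

    neuron_id: int
    onset_ms: float
    duration_ms: float
    waveform: np.ndarray

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if np.any(self.waveform < 0):
            raise ValueError("waveform must be nonnegative")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms

    @property
    def peak_time_ms(self) -> float:
        return self.onset_ms + float(np.argmax(self.waveform))


@dataclass
class PopulationActivity:
    """Dense population rates (1-ms resolution) with tap landmarks.

    ``rates[i, j]`` is the rate of ``neuron_ids[i]`` at time
    ``t0_ms + j`` milliseconds; taps are at ``tap_times_ms``.
    """

    rates: np.ndarray
    t0_ms: int
    tap_times_ms: np.ndarray
    target_interval_ms: float
    condition: str
    neuron_ids: np.ndarray
    peak_times_ms: np.ndarray
    activation_ms: float
    noise_sd: float = 0.0
    repetition: int = 0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.tap_times_ms = np.asarray(self.tap_times_ms, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.peak_times_ms = np.asarray(self.peak_times_ms, dtype=float)
        if self.rates.shape[0] != len(self.neuron_ids):
            raise ValueError("rates rows must match neuron_ids")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.rates.shape[1])

    def population_rate(self) -> np.ndarray:
        return self.rates.sum(axis=0)

    def cycle_correlation(self, first: int = 0, second: int = 1) -> float:
        """Pearson correlation of the population pattern between two cycles."""
        T = int(round(self.target_interval_ms))
        a = self._cycle_slab(first, T).ravel()
        b = self._cycle_slab(second, T).ravel()
        return float(np.corrcoef(a, b)[0, 1])

    def _cycle_slab(self, cycle: int, T: int) -> np.ndarray:
        start = int(self.tap_times_ms[cycle]) - self.t0_ms
        return self.rates[:, start : start + T]


def simulate_activation_profile(
    duration_ms: float,
    n_components: int = 20,
    rng: np.random.Generator | None = None,
    spec: GammaProfileSpec | None = None,
    neuron_id: int = -1,
) -> ActivationProfile:
    """Build a smooth nonnegative waveform supported on [0, duration_ms].

    The waveform is the sum of ``n_components`` gamma densities with random
    shapes in [2, 8], peak positions uniform over the window and uniform
    amplitudes, peak-normalized to 1.  Pass ``spec`` to fix the gamma
    parameters explicitly (``n_components`` is then ignored).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if spec is None:
        rng = np.random.default_rng() if rng is None else rng
        spec = GammaProfileSpec.draw(rng, n_components)
    return ActivationProfile(
        neuron_id=neuron_id,
        onset_ms=0.0,
        duration_ms=float(duration_ms),
        waveform=spec.waveform(duration_ms),
    )


def _recruitment_bounds(interval_ms: float, activation_ms: float) -> tuple[float, float]:
    # peaks may fall slightly before the start tap and after the end tap so
    # the first units activate before the interval begins and the last ones
    # finish after it ends
    return -activation_ms / 4.0, interval_ms + activation_ms / 4.0


def recruitment_distribution(
    interval_ms: float, activation_ms: float, sd_fraction: float = 0.25
):
    """Truncated Gaussian of unit peak times within one produced interval."""
    lo, hi = _recruitment_bounds(interval_ms, activation_ms)
    loc, scale = interval_ms / 2.0, sd_fraction * interval_ms
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm(a, b, loc=loc, scale=scale)


def _render_cyclic(
    peaks_ms: np.ndarray,
    waveforms: list[np.ndarray],
    interval_ms: int,
    n_cycles: int,
    margin_ms: int,
) -> tuple[np.ndarray, int]:
    """Accumulate cyclically repeated waveforms into a rate matrix."""
    t0 = -margin_ms
    n_samples = n_cycles * interval_ms + 2 * margin_ms
    rates = np.zeros((len(peaks_ms), n_samples))
    for i, (p, w) in enumerate(zip(peaks_ms, waveforms)):
        pk = int(np.argmax(w))
        for c in range(n_cycles):
            onset = int(round(p - pk + c * interval_ms)) - t0
            s0, s1 = max(onset, 0), min(onset + len(w), n_samples)
            if s1 > s0:
                rates[i, s0:s1] += w[s0 - onset : s1 - onset]
    return rates, t0


def _add_rate_noise(rates: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return rates
    return np.clip(rates + rng.normal(0.0, sd, rates.shape), 0.0, None)


def simulate_moving_bump(
    config: SimulationConfig,
    interval_ms: int,
    rng: np.random.Generator,
    peaks_ms: np.ndarray | None = None,
    profile_specs: Sequence[GammaProfileSpec] | None = None,
    neuron_ids: np.ndarray | None = None,
    noise_sd: float | None = None,
    repetition: int = 0,
    condition: str | None = None,
) -> PopulationActivity:
    """Simulate one trial of cyclic moving-bump population activity.

    Unit peak times follow the truncated-Gaussian recruitment profile and
    the pattern repeats for ``config.n_intervals_per_trial`` produced
    intervals; taps sit at exact multiples of the interval.
    """
    if interval_ms not in config.n_neurons_by_interval:
        raise ValueError(f"interval {interval_ms} not configured")
    n = config.n_neurons_by_interval[interval_ms]
    if n < 2:
        raise ValueError("need at least 2 neurons")
    duration = config.activation_ms_by_interval[interval_ms]
    if peaks_ms is None:
        peaks_ms = recruitment_distribution(
            interval_ms, duration, config.recruitment_sd_fraction
        ).rvs(size=n, random_state=rng)
    peaks_ms = np.asarray(peaks_ms, dtype=float)
    if profile_specs is None:
        profile_specs = [
            GammaProfileSpec.draw(rng, config.n_gamma_components) for _ in range(len(peaks_ms))
        ]
    if neuron_ids is None:
        neuron_ids = np.arange(len(peaks_ms))
    waveforms = [spec.waveform(duration) for spec in profile_specs]
    margin = int(np.ceil(duration))
    rates, t0 = _render_cyclic(
        peaks_ms, waveforms, int(interval_ms), config.n_intervals_per_trial, margin
    )
    sd = config.noise_sd if noise_sd is None else noise_sd
    rates = _add_rate_noise(rates, sd, rng)
    taps = np.arange(config.n_intervals_per_trial + 1, dtype=float) * interval_ms
    return PopulationActivity(
        rates=rates,
        t0_ms=t0,
        tap_times_ms=taps,
        target_interval_ms=float(interval_ms),
        condition=condition or f"SIM-{config.regime}",
        neuron_ids=np.asarray(neuron_ids),
        peak_times_ms=peaks_ms,
        activation_ms=float(duration),
        noise_sd=sd,
        repetition=repetition,
    )


def extend_bump_population(
    base: PopulationActivity, extra_n: int, rng: np.random.Generator
) -> PopulationActivity:
    """Insert ``extra_n`` units at intermediate peak-time positions.

    New peaks are drawn from the recruitment Gaussian restricted to the
    open interval between the earliest and latest base peaks, so base units
    keep their relative activation order and insertions are interior.
    """
    if extra_n < 0:
        raise ValueError("extra_n must be >= 0")
    if extra_n == 0:
        return replace(base)
    T = base.target_interval_ms
    lo, hi = float(base.peak_times_ms.min()), float(base.peak_times_ms.max())
    dist = recruitment_distribution(T, base.activation_ms)
    u_lo, u_hi = dist.cdf(lo), dist.cdf(hi)
    eps = 1e-9 * max(hi - lo, 1.0)
    new_peaks = dist.ppf(rng.uniform(u_lo, u_hi, extra_n))
    new_peaks = np.clip(new_peaks, lo + eps, hi - eps)
    specs = [GammaProfileSpec.draw(rng, 20) for _ in range(extra_n)]
    waveforms = [s.waveform(base.activation_ms) for s in specs]
    n_cycles = len(base.tap_times_ms) - 1
    margin = -base.t0_ms
    new_rates, _ = _render_cyclic(new_peaks, waveforms, int(T), n_cycles, margin)
    new_rates = _add_rate_noise(new_rates, base.noise_sd, rng)
    next_id = int(np.max(base.neuron_ids)) + 1
    return replace(
        base,
        rates=np.vstack([base.rates, new_rates]),
        neuron_ids=np.concatenate([base.neuron_ids, np.arange(next_id, next_id + extra_n)]),
        peak_times_ms=np.concatenate([base.peak_times_ms, new_peaks]),
    )


def _draw_population(config: SimulationConfig, rng: np.random.Generator):
    """Draw shared unit quantiles, canonical profiles and nested active sets.

    Units shared between intervals keep the same recruitment quantile, so
    their peak ranks are preserved across intervals; units added for longer
    intervals take quantiles from the intermediate range.
    """
    counts = sorted({config.n_neurons_by_interval[t] for t in config.target_intervals_ms})
    n_base, n_max = counts[0], counts[-1]
    u = np.empty(n_max)
    u[:n_base] = np.sort(rng.uniform(size=n_base))
    lo, hi = config.insert_quantile_range
    u[n_base:] = rng.uniform(lo, hi, n_max - n_base)
    u = np.clip(u, 1e-9, 1.0 - 1e-9)
    extra_order = n_base + rng.permutation(n_max - n_base)
    active = {
        c: np.sort(np.concatenate([np.arange(n_base), extra_order[: c - n_base]])).astype(int)
        for c in counts
    }
    specs = [GammaProfileSpec.draw(rng, config.n_gamma_components) for _ in range(n_max)]
    return u, specs, active


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[PopulationActivity]:
    """Run the full multi-interval, multi-repetition simulation.

    Within a repetition every interval shares the unit registry: a unit
    active in several intervals keeps its canonical waveform (stretched to
    the interval's activation duration) and its recruitment quantile, so
    relative peak order is preserved across intervals.  By default each
    repetition is an independent simulation (fresh random draws); set
    ``fresh_population_per_repetition=False`` to share one population
    across repetitions with only the additive rate noise varying.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    shared = None
    if not config.fresh_population_per_repetition:
        shared = _draw_population(config, rng)
    out: list[PopulationActivity] = []
    for rep in range(config.n_repetitions):
        u, specs, active = shared if shared is not None else _draw_population(config, rng)
        for T in config.target_intervals_ms:
            ids = active[config.n_neurons_by_interval[T]]
            duration = config.activation_ms_by_interval[T]
            dist = recruitment_distribution(T, duration, config.recruitment_sd_fraction)
            peaks = dist.ppf(u[ids])
            out.append(
                simulate_moving_bump(
                    config,
                    T,
                    rng,
                    peaks_ms=peaks,
                    profile_specs=[specs[i] for i in ids],
                    neuron_ids=ids.copy(),
                    repetition=rep,
                )
            )
    return out


def generate_behavior(
    behavior_config: BehaviorConfig,
    target_interval_ms: float,
    n_taps: int = 7,
    condition: str = "SCT",
    rng: np.random.Generator | None = None,
    n_metronome_stimuli: int | None = None,
) -> EventTable:
    """Generate tapping trials with Weber-scaled interval noise.

    Produced intervals are Gaussian with mean ``target + constant_error``
    and SD ``weber_fraction * target`` (negative draws are resampled).  For
    SCT trials metronome stimuli cover the first four taps; for ST they
    cover all taps; continuation-only trials carry none.
    """
    if n_taps < 2:
        raise ValueError("n_taps must be >= 2")
    rng = np.random.default_rng(behavior_config.seed) if rng is None else rng
    mean = target_interval_ms + behavior_config.constant_error_ms
    sd = behavior_config.weber_fraction * target_interval_ms
    if mean <= 0:
        raise ValueError("constant error drives produced intervals nonpositive")
    table = EventTable()
    n_resampled = 0
    for trial in range(behavior_config.n_trials):
        intervals = np.empty(n_taps - 1)
        for i in range(n_taps - 1):
            draw = rng.normal(mean, sd) if sd > 0 else mean
            while draw <= 0:
                n_resampled += 1
                draw = rng.normal(mean, sd)
            intervals[i] = draw
        taps = np.concatenate([[0.0], np.cumsum(intervals)])
        if condition == "SCT":
            n_stim = 4 if n_metronome_stimuli is None else n_metronome_stimuli
        elif condition == "ST":
            n_stim = n_taps if n_metronome_stimuli is None else n_metronome_stimuli
        else:
            n_stim = 0 if n_metronome_stimuli is None else n_metronome_stimuli
        stims = np.arange(min(n_stim, n_taps)) * target_interval_ms
        table.add(
            TrialEvents(
                trial_id=trial,
                condition=condition,
                target_interval_ms=float(target_interval_ms),
                tap_times_ms=taps,
                stimulus_times_ms=stims,
            )
        )
    if n_resampled:
        log.info("resampled %d negative produced intervals", n_resampled)
    return table


def simulate_reactive_control(
    intervals_pool: Sequence[float],
    n_stimuli: int,
    response_latency_ms: float,
    rng: np.random.Generator,
    n_neurons: int = 130,
    transient_ms: float = 200.0,
    latency_jitter_ms: float = 0.0,
    onset_spread_ms: float = 150.0,
    noise_sd: float = 0.05,
    n_gamma_components: int = 20,
    trial_id: int = 0,
) -> tuple[EventTable, PopulationActivity]:
    """Reactive (SRTT-like) control: stimulus-locked transients at random
    interstimulus intervals, taps trailing each stimulus by a reaction
    latency.  There is no periodic structure to entrain to."""
    pool = np.asarray(list(intervals_pool), dtype=float)
    if pool.size == 0:
        raise ValueError("intervals_pool must be non-empty")
    isi = rng.choice(pool, size=n_stimuli - 1) if n_stimuli > 1 else np.empty(0)
    stim_times = np.concatenate([[0.0], np.cumsum(isi)])
    jitter = (
        rng.normal(0.0, latency_jitter_ms, n_stimuli) if latency_jitter_ms > 0 else 0.0
    )
    taps = stim_times + response_latency_ms + jitter

    specs = [GammaProfileSpec.draw(rng, n_gamma_components) for _ in range(n_neurons)]
    waveforms = [s.waveform(transient_ms) for s in specs]
    lags = rng.uniform(0.0, onset_spread_ms, n_neurons)
    margin = int(np.ceil(transient_ms + onset_spread_ms + response_latency_ms))
    t0 = 0
    n_samples = int(np.ceil(stim_times[-1])) + margin
    rates = np.zeros((n_neurons, n_samples))
    for i, w in enumerate(waveforms):
        for s in stim_times:
            onset = int(round(s + lags[i]))
            s0, s1 = onset, min(onset + len(w), n_samples)
            if s1 > s0:
                rates[i, s0:s1] += w[: s1 - s0]
    rates = _add_rate_noise(rates, noise_sd, rng)

    events = EventTable(
        [
            TrialEvents(
                trial_id=trial_id,
                condition="SRTT",
                target_interval_ms=float(np.mean(pool)),
                tap_times_ms=taps,
                stimulus_times_ms=stim_times,
            )
        ]
    )
    activity = PopulationActivity(
        rates=rates,
        t0_ms=t0,
        tap_times_ms=taps,
        target_interval_ms=float(np.mean(pool)),
        condition="SRTT",
        neuron_ids=np.arange(n_neurons),
        peak_times_ms=lags + transient_ms / 2.0,
        activation_ms=float(transient_ms),
        noise_sd=noise_sd,
    )
    return events, activity


def sample_spikes(
    pop: PopulationActivity,
    peak_rate_hz: float,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> SpikeTable:
    """Draw Poisson spikes from the rate matrix (``peak_rate_hz`` maps a
    normalized rate of 1 to spikes/s).  Times are shifted so the first tap
    is at ``-t0_ms``; i.e. spike times are nonnegative."""
    import pandas as pd

    lam = np.clip(pop.rates, 0.0, None) * (peak_rate_hz / 1000.0)
    counts = rng.poisson(lam)
    neuron_idx, sample_idx = np.nonzero(counts)
    reps = counts[neuron_idx, sample_idx]
    neuron_idx = np.repeat(neuron_idx, reps)
    sample_idx = np.repeat(sample_idx, reps)
    times = sample_idx + rng.uniform(0.0, 1.0, len(sample_idx))
    df = pd.DataFrame(
        {
            "trial_id": trial_id,
            "neuron_id": pop.neuron_ids[neuron_idx],
            "time_ms": times,
        }
    )
    return SpikeTable(df)
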