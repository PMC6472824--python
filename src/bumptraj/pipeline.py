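"""End-to-end orchestration: simulate, normalize, project, quantify, decode.

The stage helpers here are plain functions over the library types so tests
and the acceptance report can call them directly; :func:`run_pipeline`
wires them together with config, logging, per-stage seeds and text/JSON
artifacts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import activation as act
from . import binning, decoding, dpca, geometry
from .simulate import (
    BehaviorConfig,
    PopulationActivity,
    SimulationConfig,
    generate_behavior,
    sample_spikes,
    simulate_experiment,
)

__all__ = [
    "RunConfig",
    "GeometryExperimentResult",
    "normalize_pair",
    "run_geometry_experiment",
    "run_dpca_analysis",
    "run_activation_analysis",
    "run_interval_decoding",
    "run_tap_decoding",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# shared helpers


def normalize_pair(
    utnd: binning.BinnedPopulation, tind: binning.BinnedPopulation
) -> tuple[binning.BinnedPopulation, binning.BinnedPopulation]:
    """Normalize both frames by one per-neuron maximum over all conditions."""
    if list(utnd.neuron_ids) != list(tind.neuron_ids):
        raise ValueError("frames must share the neuron axis")
    max_rates = np.maximum(
        utnd.X.max(axis=1) if utnd.n_bins else 0.0,
        tind.X.max(axis=1) if tind.n_bins else 0.0,
    )
    silent = max_rates <= 0
    scale = np.where(silent, 1.0, max_rates)
    u = dataclasses.replace(utnd, X=utnd.X / scale[:, None], max_rates=max_rates, silent=silent)
    t = dataclasses.replace(tind, X=tind.X / scale[:, None], max_rates=max_rates, silent=silent)
    return u, t


def bin_experiment(
    sims: list[PopulationActivity], mode: str
) -> binning.BinnedPopulation:
    """Bin and concatenate a list of simulated trials (union neuron axis).

    Trial ids encode (repetition, interval index) so segment grouping stays
    unambiguous.
    """
    parts = []
    for k, pop in enumerate(sims):
        parts.append(binning.bin_population_activity(pop, mode, trial_id=k))
    return binning.concat_binned(parts)


@dataclass
class GeometryExperimentResult:
    """Radius/variability/speed of one simulated regime, with regressions."""

    regime: str
    segments: pd.DataFrame  # per (rep, interval, segment)
    summary: pd.DataFrame  # per (rep, interval)
    regressions: dict  # metric -> scipy linregress result

    def regression_row(self, metric: str) -> dict:
        r = self.regressions[metric]
        return {
            "slope": r.slope,
            "intercept": r.intercept,
            "r_squared": r.rvalue**2,
            "p_value": r.pvalue,
        }


def _geometry_one_repetition(
    sims_rep: list[PopulationActivity],
    radius_components,
    speed_components,
    n_retained: int,
    smooth: bool,
) -> pd.DataFrame:
    utnd = bin_experiment(sims_rep, "utnd")
    tind = bin_experiment(sims_rep, "tind")
    utnd, tind = normalize_pair(utnd, tind)
    coeffs = geometry.fit_coefficients(utnd, n_retained=n_retained)
    traj = geometry.project(coeffs, tind, smooth=smooth)
    geoms, table = geometry.geometry_table(traj, radius_components, speed_components)
    by_key = {}
    for g in geoms:
        by_key.setdefault(g.target_interval_ms, []).append(g)
    var_rows = {
        t: geometry.radius_variability(gs, expected_segments=1) for t, gs in by_key.items()
    }
    table["variability"] = table["target_interval_ms"].map(var_rows)
    return table


def run_geometry_experiment(
    config: SimulationConfig,
    radius_components=geometry.DEFAULT_RADIUS_COMPONENTS,
    speed_components=geometry.DEFAULT_SPEED_COMPONENTS,
    n_retained: int = 8,
    smooth: bool = False,
) -> GeometryExperimentResult:
    """Simulate a regime and regress segment geometry on target interval.

    The loading matrix is fit per repetition (each repetition is an
    independent simulation by default); regressions pool the per-(rep,
    interval) means, mirroring a 5-repetition-per-interval design.
    """
    sims = simulate_experiment(config)
    tables = []
    for rep in range(config.n_repetitions):
        sims_rep = [s for s in sims if s.repetition == rep]
        t = _geometry_one_repetition(
            sims_rep, radius_components, speed_components, n_retained, smooth
        )
        t["repetition"] = rep
        tables.append(t)
    segments = pd.concat(tables, ignore_index=True)
    summary = (
        segments.groupby(["repetition", "target_interval_ms"], as_index=False)
        .agg(
            radius=("radius", "mean"),
            speed=("speed", "mean"),
            variability=("variability", "mean"),
        )
        .sort_values(["repetition", "target_interval_ms"])
        .reset_index(drop=True)
    )
    regressions = {
        m: stats.linregress(summary["target_interval_ms"], summary[m])
        for m in ("radius", "variability", "speed")
    }
    return GeometryExperimentResult(
        regime=config.regime, segments=segments, summary=summary, regressions=regressions
    )


# --------------------------------------------------------------------------
# dPCA


def run_dpca_analysis(
    config: SimulationConfig,
    n_components: int = 5,
    n_bins: int = 30,
    reference_interval_ms: float | None = None,
) -> dict:
    """Demixed decomposition plus cross-tempo distance profiles.

    Uses a shared population across repetitions so trials can be pooled
    into one decomposition.  Distance profiles between the reference
    interval and every other interval are computed twice — from ordinary
    components 1-3 and from the first interval-demixed component — and
    compared with a two-sample KS test.
    """
    cfg = dataclasses.replace(config, fresh_population_per_repetition=False)
    sims = simulate_experiment(cfg)
    utnd = bin_experiment(sims, "utnd")
    tind = bin_experiment(sims, "tind")
    utnd, tind = normalize_pair(utnd, tind)
    marg = dpca.condition_average(tind, n_bins=n_bins)
    model = dpca.fit_dpca(marg, n_components=n_components)

    coeffs = geometry.fit_coefficients(utnd)
    traj = geometry.project(coeffs, tind)
    targets = sorted(tind.bins["target_interval_ms"].unique())
    ref = reference_interval_ms if reference_interval_ms is not None else targets[0]

    ref_mean = geometry.condition_mean_trajectory(traj, ref, n_bins=n_bins)
    # demixed trajectory: first interval component per condition
    interval_scores = model.scores["interval"][0].reshape(len(marg.condition_labels), n_bins)

    rows = []
    for t in targets:
        other_mean = geometry.condition_mean_trajectory(traj, t, n_bins=n_bins)
        dists, _ = geometry.distance_profile(ref_mean, other_mean, components=(0, 1, 2), n_bins=n_bins)
        ref_idx = list(marg.condition_labels).index(ref)
        t_idx = list(marg.condition_labels).index(t)
        d_dpca = np.abs(interval_scores[t_idx] - interval_scores[ref_idx])
        rows.append(
            {
                "target_interval_ms": t,
                "mean_distance_pca": float(np.mean(dists)),
                "sd_distance_pca": float(np.std(dists)),
                "mean_distance_dpca": float(np.mean(d_dpca)),
                "sd_distance_dpca": float(np.std(d_dpca)),
            }
        )
    profiles = pd.DataFrame(rows)
    # shape agreement across targets: compare the scale-normalized
    # mean-distance-vs-interval profiles of the two decompositions
    pca_prof = profiles["mean_distance_pca"].to_numpy()
    dpca_prof = profiles["mean_distance_dpca"].to_numpy()
    pca_prof = pca_prof / (pca_prof.mean() or 1.0)
    dpca_prof = dpca_prof / (dpca_prof.mean() or 1.0)
    ks = stats.ks_2samp(pca_prof, dpca_prof)
    return {
        "model": model,
        "profiles": profiles,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


# --------------------------------------------------------------------------
# activation periods


def run_activation_analysis(
    config: SimulationConfig,
    rng: np.random.Generator,
    peak_rate_hz: float = 60.0,
    si_threshold: float = act.DEFAULT_SI_THRESHOLD,
    min_spikes: int = act.DEFAULT_MIN_SPIKES,
) -> tuple[list[act.ActivationPeriod], pd.DataFrame]:
    """Sample spikes from simulated rates and detect activation periods.

    Detection runs per (unit, segment) against the unit's whole-recording
    mean rate; the summary aggregates counts, durations, recruitment
    lapses and in-period rates per (interval, repetition).
    """
    sims = simulate_experiment(config)
    all_periods: list[act.ActivationPeriod] = []
    rows = []
    for k, pop in enumerate(sims):
        spikes = sample_spikes(pop, peak_rate_hz, rng, trial_id=k)
        total_s = pop.rates.shape[1] / 1000.0
        taps_on_spike_clock = pop.tap_times_ms - pop.t0_ms
        trial_periods: list[act.ActivationPeriod] = []
        for n_id, grp in spikes.df.groupby("neuron_id", sort=False):
            times = grp["time_ms"].to_numpy()
            mean_rate = len(times) / total_s
            if mean_rate <= 0:
                continue
            for seg in range(len(taps_on_spike_clock) - 1):
                a, b = taps_on_spike_clock[seg], taps_on_spike_clock[seg + 1]
                seg_times = times[(times >= a) & (times < b)]
                for p in act.detect_activation_periods(
                    seg_times, mean_rate, si_threshold=si_threshold, min_spikes=min_spikes,
                    neuron_id=int(n_id),
                ):
                    p.target_interval_ms = pop.target_interval_ms
                    p.segment = seg
                    trial_periods.append(p)
        all_periods.extend(trial_periods)
        for seg in range(len(taps_on_spike_clock) - 1):
            seg_periods = [p for p in trial_periods if p.segment == seg]
            summ = act.summarize_bump(seg_periods, pop.n_neurons)
            rows.append(
                {
                    "target_interval_ms": pop.target_interval_ms,
                    "repetition": pop.repetition,
                    "segment": seg,
                    "n_cells": summ.n_cells,
                    "mean_duration_ms": summ.mean_duration_ms,
                    "mean_lapse_ms": summ.mean_lapse_ms,
                    "mean_in_period_rate_hz": summ.mean_in_period_rate_hz,
                }
            )
    return all_periods, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# decoding


def _pooled_trajectory(config: SimulationConfig, smooth: bool = False):
    cfg = dataclasses.replace(config, fresh_population_per_repetition=False)
    sims = simulate_experiment(cfg)
    utnd = bin_experiment(sims, "utnd")
    tind = bin_experiment(sims, "tind")
    utnd, tind = normalize_pair(utnd, tind)
    coeffs = geometry.fit_coefficients(utnd)
    traj = geometry.project(coeffs, tind, smooth=smooth)
    return sims, tind, coeffs, traj


def run_interval_decoding(
    config: SimulationConfig,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
    candidates=(0, 1, 2),
    ablate: bool = True,
) -> dict:
    """Second-layer cloud, best-component SVM accuracy and ablation curve."""
    _, tind, coeffs, traj = _pooled_trajectory(config)
    best, comp_accs = decoding.best_component(traj, candidates=candidates, seed=seed)
    cloud = decoding.build_segment_cloud(traj, component=best)
    mean, sd, _ = decoding.classify_interval(cloud, repeats=repeats, folds=folds, seed=seed)
    out = {
        "best_component": best,
        "component_accuracies": comp_accs,
        "accuracy_mean": mean,
        "accuracy_sd": sd,
        "n_classes": len(np.unique(cloud.targets)),
    }
    if ablate:
        sched = decoding.ablation_schedule(coeffs, best)
        out["ablation"] = decoding.ablate_and_classify(
            tind, coeffs, sched, repeats=repeats, folds=folds, seed=seed
        )
    return out


def run_tap_decoding(
    config: SimulationConfig,
    folds: int = 5,
    seed: int = 0,
    component: int = 0,
    bin_ms: float = 20.0,
) -> dict:
    """Train/evaluate the tap decoder on simulated component-1 series.

    Series use fixed 20-ms bins over the full trial range (margins before
    the first and after the last tap included), so every tap has causal
    history and is an interior sample of the output.
    """
    cfg = dataclasses.replace(config, fresh_population_per_repetition=False)
    sims = simulate_experiment(cfg)
    utnd = bin_experiment(sims, "utnd")
    full = binning.concat_binned(
        [binning.bin_fixed_windows(pop, bin_ms, trial_id=k) for k, pop in enumerate(sims)]
    )
    utnd, full = normalize_pair(utnd, full)
    coeffs = geometry.fit_coefficients(utnd)
    traj = geometry.project(coeffs, full)
    series_list, taps_list = [], []
    for k, pop in enumerate(sims):
        idx = np.flatnonzero((traj.bins["trial_id"] == k).to_numpy())
        series_list.append(traj.Y[idx, component])
        taps_list.append(pop.tap_times_ms - pop.t0_ms)
    decoder, report = decoding.train_tap_decoder(
        series_list, taps_list, folds=folds, seed=seed, bin_ms=bin_ms
    )
    frac = report["n_correct"].sum() / max(report["n_true_taps"].sum(), 1)
    return {
        "decoder": decoder,
        "report": report,
        "fraction_correct": float(frac),
        "mean_error_ms": float(report["mean_error_ms"].mean()),
    }


# --------------------------------------------------------------------------
# full pipeline


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "runs/latest"
    seed: int = 1
    regimes: tuple[str, ...] = ("expanding", "static")
    stages: dict = field(
        default_factory=lambda: {
            "behavior": True,
            "geometry": True,
            "dpca": True,
            "activations": True,
            "decode_interval": True,
            "decode_taps": True,
        }
    )
    n_repetitions: int = 5
    n_intervals_per_trial: int = 3
    noise_sd: float = 0.05
    smooth: bool = False
    weber_fraction: float = 0.05
    constant_error_ms: float = -10.0
    behavior_trials: int = 20
    svm_repeats: int = 10
    svm_folds: int = 5
    tap_folds: int = 5
    si_threshold: float = act.DEFAULT_SI_THRESHOLD
    peak_rate_hz: float = 60.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "regimes" in d:
            d["regimes"] = tuple(d["regimes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = self.to_dict()
        d["regimes"] = list(d["regimes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def simulation_config(self, regime: str, seed_offset: int = 0) -> SimulationConfig:
        return SimulationConfig(
            regime=regime,
            n_repetitions=self.n_repetitions,
            n_intervals_per_trial=self.n_intervals_per_trial,
            noise_sd=self.noise_sd,
            seed=self.seed + seed_offset,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages, writing artifacts under ``out_dir``.

    Outputs are deterministic for a fixed config (all stage seeds derive
    from ``config.seed``).  On stage failure the run halts with a
    stage-named error; artifacts of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"config_hash": config.config_hash(), "stages": {}}
    timings: dict[str, float] = {}

    def run_stage(name, fn):
        if not config.stages.get(name, False):
            log.info("stage %s disabled", name)
            return
        log.info("stage %s ...", name)
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            _write_json(out / "report.json", report)
            raise StageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.1fs", name, timings[name])

    def behavior_stage():
        rows = []
        tables = []
        for t in (450, 550, 650, 850, 1000):
            bc = BehaviorConfig(
                weber_fraction=config.weber_fraction,
                constant_error_ms=config.constant_error_ms,
                n_trials=config.behavior_trials,
                seed=config.seed + t,
            )
            ev = generate_behavior(bc, t)
            tables.append(ev)
            rows.append(binning.behavior_metrics(ev))
        merged = EventTableMerge(tables)
        merged.table.write_tsv(out / "behavior_events.tsv")
        metrics = pd.concat(rows, ignore_index=True)
        metrics.to_csv(out / "behavior_metrics.tsv", sep="\t", index=False)
        reg = stats.linregress(
            metrics["target_interval_ms"], metrics["temporal_variability_ms"]
        )
        report["stages"]["behavior"] = {
            "variability_slope": reg.slope,
            "variability_p": reg.pvalue,
            "mean_constant_error_ms": float(metrics["constant_error_ms"].mean()),
        }

    def geometry_stage():
        for i, regime in enumerate(config.regimes):
            res = run_geometry_experiment(
                config.simulation_config(regime, seed_offset=i), smooth=config.smooth
            )
            res.segments.to_csv(out / f"geometry_segments_{regime}.tsv", sep="\t", index=False)
            res.summary.to_csv(out / f"geometry_summary_{regime}.tsv", sep="\t", index=False)
            report["stages"][f"geometry_{regime}"] = {
                m: res.regression_row(m) for m in ("radius", "variability", "speed")
            }

    def dpca_stage():
        res = run_dpca_analysis(config.simulation_config("expanding"))
        res["profiles"].to_csv(out / "dpca_profiles.tsv", sep="\t", index=False)
        report["stages"]["dpca"] = {
            "ks_statistic": res["ks_statistic"],
            "ks_pvalue": res["ks_pvalue"],
            "interval_component_variance": res["model"].explained_variance["interval"][:3],
        }

    def activations_stage():
        rng = np.random.default_rng(config.seed + 7)
        periods, summary = run_activation_analysis(
            config.simulation_config("expanding"),
            rng,
            peak_rate_hz=config.peak_rate_hz,
            si_threshold=config.si_threshold,
        )
        act.periods_to_frame(periods).to_csv(out / "activation_periods.tsv", sep="\t", index=False)
        summary.to_csv(out / "activation_summary.tsv", sep="\t", index=False)
        per_interval = summary.groupby("target_interval_ms")["n_cells"].mean()
        report["stages"]["activations"] = {
            "n_cells_by_interval": per_interval.to_dict(),
            "n_periods": len(periods),
        }

    def decode_interval_stage():
        res = run_interval_decoding(
            config.simulation_config("expanding"),
            repeats=config.svm_repeats,
            folds=config.svm_folds,
            seed=config.seed,
        )
        res["ablation"].to_csv(out / "ablation_curve.tsv", sep="\t", index=False)
        report["stages"]["decode_interval"] = {
            "best_component": res["best_component"],
            "accuracy_mean": res["accuracy_mean"],
            "accuracy_sd": res["accuracy_sd"],
        }

    def decode_taps_stage():
        res = run_tap_decoding(
            config.simulation_config("expanding"),
            folds=config.tap_folds,
            seed=config.seed,
        )
        res["report"].to_csv(out / "tap_decoding.tsv", sep="\t", index=False)
        report["stages"]["decode_taps"] = {
            "fraction_correct": res["fraction_correct"],
            "mean_error_ms": res["mean_error_ms"],
        }

    run_stage("behavior", behavior_stage)
    run_stage("geometry", geometry_stage)
    run_stage("dpca", dpca_stage)
    run_stage("activations", activations_stage)
    run_stage("decode_interval", decode_interval_stage)
    run_stage("decode_taps", decode_taps_stage)

    report["timings_s"] = timings
    _write_json(out / "report.json", report)
    return report


class EventTableMerge:
    """Merge event tables with per-table trial-id offsets."""

    def __init__(self, tables):
        from .tables import EventTable, TrialEvents

        self.table = EventTable()
        offset = 0
        for t in tables:
            for trial in t:
                self.table.add(
                    TrialEvents(
                        trial_id=trial.trial_id + offset,
                        condition=trial.condition,
                        target_interval_ms=trial.target_interval_ms,
                        tap_times_ms=trial.tap_times_ms,
                        stimulus_times_ms=trial.stimulus_times_ms,
                    )
                )
            offset += max((tr.trial_id for tr in t), default=-1) + 1
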