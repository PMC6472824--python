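import numpy as np
import pytest
from scipy import stats
from scipy.stats import gamma as gamma_dist

from bumptraj.binning import behavior_metrics
from bumptraj.simulate import (
    BehaviorConfig,
    GammaProfileSpec,
    SimulationConfig,
    extend_bump_population,
    generate_behavior,
    recruitment_distribution,
    sample_spikes,
    simulate_activation_profile,
    simulate_experiment,
    simulate_moving_bump,
    simulate_reactive_control,
)


def lag_autocorr(x, lag):
    x = x - x.mean()
    return float(np.corrcoef(x[:-lag], x[lag:])[0, 1])


class TestActivationProfile:
    def test_support_and_peak(self):
        prof = simulate_activation_profile(257.0, rng=np.random.default_rng(0))
        assert len(prof.waveform) == 257
        assert prof.waveform.max() == pytest.approx(1.0)
        assert prof.waveform.min() >= 0.0

    def test_deterministic_under_seed(self):
        a = simulate_activation_profile(200.0, rng=np.random.default_rng(42))
        b = simulate_activation_profile(200.0, rng=np.random.default_rng(42))
        assert np.array_equal(a.waveform, b.waveform)

    def test_single_gamma_matches_closed_form(self):
        # n_components=1 with fixed parameters must be proportional to the
        # gamma density itself (oracle: direct density evaluation)
        spec = GammaProfileSpec(
            shapes=np.array([4.0]), modes=np.array([0.4]), amplitudes=np.array([1.0])
        )
        duration = 250.0
        prof = simulate_activation_profile(duration, spec=spec)
        t = np.arange(250, dtype=float)
        mode_ms = 0.4 * duration
        expected = gamma_dist.pdf(t, a=4.0, scale=mode_ms / 3.0)
        expected = expected / expected.max()
        assert np.allclose(prof.waveform, expected, atol=1e-12)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            simulate_activation_profile(0.0, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_activation_profile(-5.0, rng=np.random.default_rng(0))

    def test_rescaling_preserves_shape(self):
        spec = GammaProfileSpec.draw(np.random.default_rng(3), 20)
        short = spec.waveform(100.0)
        long = spec.waveform(400.0)
        # same canonical shape stretched: compare on a common support
        resampled = np.interp(np.linspace(0, 399, 100), np.arange(400), long)
        assert np.corrcoef(short, resampled)[0, 1] > 0.98


class TestMovingBump:
    def test_printed_parameter_maps(self):
        cfg = SimulationConfig()
        assert cfg.n_neurons_by_interval[450] == 108
        assert cfg.n_neurons_by_interval[1000] == 182
        assert cfg.activation_ms_by_interval[450] == 197.0
        assert cfg.activation_ms_by_interval[1000] == 257.0

    def test_neuron_counts_realized(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,), n_repetitions=1)
        pop = simulate_moving_bump(cfg, 450, rng)
        assert pop.n_neurons == 108
        assert pop.activation_ms == 197.0

    def test_unknown_interval_rejected(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,))
        with pytest.raises(ValueError, match="not configured"):
            simulate_moving_bump(cfg, 500, rng)

    def test_too_few_neurons_rejected(self, rng):
        cfg = SimulationConfig(
            target_intervals_ms=(450,),
            n_neurons_by_interval={450: 1},
            activation_ms_by_interval={450: 197.0},
        )
        with pytest.raises(ValueError, match="at least 2"):
            simulate_moving_bump(cfg, 450, rng)

    def test_peak_times_follow_recruitment_gaussian(self, rng):
        cfg = SimulationConfig(
            target_intervals_ms=(450,),
            n_neurons_by_interval={450: 500},
            activation_ms_by_interval={450: 197.0},
            noise_sd=0.0,
        )
        pop = simulate_moving_bump(cfg, 450, rng)
        dist = recruitment_distribution(450, 197.0)
        assert stats.kstest(pop.peak_times_ms, dist.cdf).pvalue > 0.01

    def test_recruitment_distribution_at_large_n(self, rng):
        # sampling-distribution check at the spec's pooled n
        dist = recruitment_distribution(450, 197.0)
        draws = dist.rvs(size=10_000, random_state=rng)
        assert stats.kstest(draws, dist.cdf).pvalue > 0.01

    def test_activity_spans_past_taps(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,), noise_sd=0.0)
        pop = simulate_moving_bump(cfg, 450, rng)
        margin = -pop.t0_ms
        n_cycles = len(pop.tap_times_ms) - 1
        # first cells activate before the interval-start tap ...
        assert pop.rates[:, :margin].max() > 0
        # ... and the last cells finish after the final tap
        assert pop.rates[:, margin + n_cycles * 450 :].max() > 0

    def test_cycle_correlation_noise_free(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(650,), noise_sd=0.0)
        pop = simulate_moving_bump(cfg, 650, rng)
        assert pop.cycle_correlation(0, 1) > 0.95
        assert pop.cycle_correlation(1, 2) > 0.95

    def test_cyclicity_autocorrelation(self, rng):
        cfg = SimulationConfig(
            target_intervals_ms=(650,), n_intervals_per_trial=5, noise_sd=0.0
        )
        pop = simulate_moving_bump(cfg, 650, rng)
        rate = pop.population_rate()
        at_period = lag_autocorr(rate, 650)
        off_lags = [300, 450, 500, 800, 975]
        assert all(at_period > lag_autocorr(rate, lag) for lag in off_lags)


class TestExtendBumpPopulation:
    def test_zero_extra_is_identity(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,))
        pop = simulate_moving_bump(cfg, 450, rng)
        same = extend_bump_population(pop, 0, rng)
        assert np.array_equal(same.rates, pop.rates)
        assert np.array_equal(same.neuron_ids, pop.neuron_ids)

    def test_insertion_preserves_base_and_is_interior(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,))
        base = simulate_moving_bump(cfg, 450, rng)
        ext = extend_bump_population(base, 74, rng)
        assert ext.n_neurons == 182
        # base peaks (and hence their rank order) are untouched
        assert np.array_equal(ext.peak_times_ms[:108], base.peak_times_ms)
        new = ext.peak_times_ms[108:]
        assert np.all(new > base.peak_times_ms.min())
        assert np.all(new < base.peak_times_ms.max())

    def test_negative_extra_rejected(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,))
        pop = simulate_moving_bump(cfg, 450, rng)
        with pytest.raises(ValueError):
            extend_bump_population(pop, -1, rng)


class TestExperiment:
    def test_conservation_of_profile_counts(self, small_config):
        sims = simulate_experiment(small_config)
        assert len(sims) == 3 * 3
        for pop in sims:
            expected = small_config.n_neurons_by_interval[int(pop.target_interval_ms)]
            assert pop.n_neurons == expected

    def test_shared_units_keep_peak_order_across_intervals(self, small_config):
        sims = simulate_experiment(small_config)
        rep0 = [s for s in sims if s.repetition == 0]
        short = min(rep0, key=lambda s: s.target_interval_ms)
        long = max(rep0, key=lambda s: s.target_interval_ms)
        shared = np.intersect1d(short.neuron_ids, long.neuron_ids)
        p_short = [short.peak_times_ms[list(short.neuron_ids).index(n)] for n in shared]
        p_long = [long.peak_times_ms[list(long.neuron_ids).index(n)] for n in shared]
        assert np.array_equal(np.argsort(p_short), np.argsort(p_long))

    def test_seeded_determinism(self):
        cfg = SimulationConfig(target_intervals_ms=(450, 650), n_repetitions=2, seed=9)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.rates, y.rates)

    def test_static_regime_constant_duty(self):
        cfg = SimulationConfig(regime="static")
        duties = {
            t: cfg.activation_ms_by_interval[t] / t for t in cfg.target_intervals_ms
        }
        assert np.allclose(list(duties.values()), 213.0 / 650.0)
        assert all(n == 130 for n in cfg.n_neurons_by_interval.values())


class TestBehavior:
    def test_degenerate_noise_exact(self):
        bc = BehaviorConfig(weber_fraction=0.0, constant_error_ms=0.0, n_trials=3)
        ev = generate_behavior(bc, 650.0)
        for trial in ev:
            assert np.allclose(trial.produced_intervals_ms, 650.0)

    def test_weber_sd_recovered(self):
        bc = BehaviorConfig(weber_fraction=0.05, constant_error_ms=0.0, n_trials=200, seed=4)
        ev = generate_behavior(bc, 1000.0, n_taps=7)
        produced = np.concatenate([t.produced_intervals_ms for t in ev])
        assert len(produced) >= 1000
        se = 50.0 / np.sqrt(2 * len(produced))
        assert abs(produced.std(ddof=1) - 50.0) < 3 * se

    def test_default_constant_error_negative(self):
        for target in (450.0, 1000.0):
            ev = generate_behavior(BehaviorConfig(n_trials=100, seed=1), target)
            metrics = behavior_metrics(ev)
            assert (metrics["constant_error_ms"] < 0).all()

    def test_metronome_conventions(self):
        ev_sct = generate_behavior(BehaviorConfig(n_trials=1), 500.0, condition="SCT")
        assert len(next(iter(ev_sct)).stimulus_times_ms) == 4
        ev_st = generate_behavior(BehaviorConfig(n_trials=1), 500.0, n_taps=6, condition="ST")
        assert len(next(iter(ev_st)).stimulus_times_ms) == 6

    def test_scalar_property_slope_recovery(self):
        # regression of produced-interval SD on target recovers the weber
        # fraction within 10% at n >= 500 intervals per target
        weber = 0.05
        targets = np.array([450.0, 550.0, 650.0, 850.0, 1000.0])
        sds = []
        for i, t in enumerate(targets):
            bc = BehaviorConfig(weber_fraction=weber, constant_error_ms=0.0,
                                n_trials=100, seed=50 + i)
            ev = generate_behavior(bc, t, n_taps=7)
            produced = np.concatenate([tr.produced_intervals_ms for tr in ev])
            assert len(produced) >= 500
            sds.append(produced.std(ddof=1))
        slope = stats.linregress(targets, sds).slope
        assert abs(slope - weber) / weber < 0.10


class TestReactiveControl:
    def test_random_isis_and_exact_latency(self, rng):
        events, _ = simulate_reactive_control(
            [450, 550, 650, 750, 850, 950], 6, 300.0, rng, n_neurons=20, noise_sd=0.0
        )
        trial = next(iter(events))
        isis = np.diff(trial.stimulus_times_ms)
        assert len(np.unique(isis)) > 1
        assert np.allclose(trial.tap_times_ms - trial.stimulus_times_ms, 300.0)

    def test_no_periodic_structure_vs_bump(self, rng):
        cfg = SimulationConfig(
            target_intervals_ms=(650,), n_intervals_per_trial=5, noise_sd=0.0
        )
        bump = simulate_moving_bump(cfg, 650, rng)
        _, reactive = simulate_reactive_control(
            [450, 550, 650, 750, 850, 950], 6, 300.0, rng, n_neurons=130, noise_sd=0.0
        )
        bump_rate = bump.population_rate()
        reactive_rate = reactive.population_rate()
        assert lag_autocorr(bump_rate, 650) > 0.8
        for lag in (450, 550, 650, 750, 850, 950):
            assert lag_autocorr(reactive_rate, lag) < 0.5


class TestSampleSpikes:
    def test_rate_scaling(self, rng):
        cfg = SimulationConfig(target_intervals_ms=(450,), noise_sd=0.0)
        pop = simulate_moving_bump(cfg, 450, rng)
        spikes = sample_spikes(pop, 100.0, rng)
        expected = pop.rates.sum() * 0.1  # rate_sum * (100 Hz / 1000 ms)
        assert abs(len(spikes) - expected) < 5 * np.sqrt(expected)
        assert (spikes.df["time_ms"] >= 0).all()


class TestConfigValidation:
    def test_missing_map_entry(self):
        with pytest.raises(ValueError, match="missing"):
            SimulationConfig(
                target_intervals_ms=(450, 650),
                n_neurons_by_interval={450: 10},
                activation_ms_by_interval={450: 100.0, 650: 100.0},
            )

    def test_nonpositive_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                target_intervals_ms=(450,),
                n_neurons_by_interval={450: 0},
                activation_ms_by_interval={450: 100.0},
            )
        with pytest.raises(ValueError):
            SimulationConfig(regime="bogus")
        with pytest.raises(ValueError):
            SimulationConfig(insert_quantile_range=(0.9, 0.1))
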