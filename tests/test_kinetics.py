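"""Dissociation-rate spectra: survival functions, inversion, clustering."""

import numpy as np
import pytest

from morphotrack import synthetic
from morphotrack.kinetics import (
    RATE_GRID,
    RateSpectrum,
    SurvivalCondition,
    SurvivalData,
    cluster_spectrum,
    event_to_state_spectrum,
    invert_spectrum,
    resample_spectrum,
    survival_distribution,
)


class TestSurvival:
    def test_step_function_for_identical_durations(self):
        cond = SurvivalCondition(
            cycle_time=0.1, durations=np.full(200, 0.2), min_frames=3
        )
        t, s, _ = cond.survival()
        assert s[0] == 1.0
        assert np.all(s == 1.0)  # every event lasts exactly t_min

    def test_survival_non_increasing_and_normalized(self):
        rng = np.random.default_rng(0)
        durations = 0.1 * rng.integers(2, 40, size=500)
        cond = SurvivalCondition(cycle_time=0.1, durations=durations)
        t, s, _ = cond.survival()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_censored_events_counted_in_survival(self):
        cond = SurvivalCondition(
            cycle_time=0.1,
            durations=np.full(50, 0.2),
            n_censored=50,
            censor_time=1.0,
        )
        t, s, _ = cond.survival()
        # half the events survive to the censoring time
        assert s[-1] == pytest.approx(0.5)

    def test_low_count_condition_warns(self):
        with pytest.warns(UserWarning):
            survival_distribution({0.058: np.full(10, 0.116)})


class TestEventStateConversion:
    def test_direct_arithmetic(self):
        s = event_to_state_spectrum(np.array([0.5, 0.5]), np.array([0.1, 1.0]))
        assert np.allclose(s, [10 / 11, 1 / 11])

    def test_single_component(self):
        amps = np.zeros(40)
        amps[7] = 1.0
        assert event_to_state_spectrum(amps).sum() == pytest.approx(1.0)
        assert event_to_state_spectrum(amps)[7] == pytest.approx(1.0)

    def test_negative_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            event_to_state_spectrum(np.array([-0.1, 1.1]), np.array([0.1, 1.0]))


class TestInversion:
    def test_single_rate_no_bleach_localized_on_grid(self):
        data, _ = synthetic.generate_survival(
            rates=np.array([0.1]),
            state_fractions=np.array([1.0]),
            n_events=10_000,
            bleach_per_frame=0.0,
            seed=1,
        )
        spec = invert_spectrum(data)
        target = np.argmin(np.abs(np.log(RATE_GRID) - np.log(0.1)))
        window = spec.event_amplitudes[max(target - 1, 0) : target + 2]
        assert window.sum() >= 0.9
        assert spec.bleaching_per_frame < 0.03

    def test_two_rates_with_bleaching_recovered(self):
        data, truth = synthetic.generate_survival(
            rates=np.array([0.1, 2.0]),
            state_fractions=np.array([0.6, 0.4]),
            n_events=10_000,
            bleach_per_frame=0.1,
            seed=2,
        )
        spec = invert_spectrum(data)
        assert abs(spec.bleaching_per_frame - 0.1) / 0.1 < 0.2
        cl = cluster_spectrum(spec, boundaries=[0.5])
        # both populations land in the right rate bands; exact values are
        # noise-limited at this event count
        assert cl.residence_times[0] == pytest.approx(10.0, rel=0.6)
        assert cl.residence_times[1] == pytest.approx(0.5, rel=0.6)

    def test_zero_durations_rejected(self):
        conds = [
            SurvivalCondition(cycle_time=0.1, durations=np.zeros(100)),
            SurvivalCondition(cycle_time=1.0, durations=np.zeros(100)),
        ]
        with pytest.raises(ValueError):
            invert_spectrum(SurvivalData(conds))

    def test_single_condition_rejected(self):
        cond = SurvivalCondition(cycle_time=0.1, durations=np.full(100, 0.5))
        with pytest.raises(ValueError):
            invert_spectrum(SurvivalData([cond]))

    def test_inversion_invariant_to_event_order(self):
        data, _ = synthetic.generate_survival(
            rates=np.array([0.5]),
            state_fractions=np.array([1.0]),
            n_events=3000,
            bleach_per_frame=0.05,
            seed=3,
        )
        shuffled = SurvivalData(
            [
                SurvivalCondition(
                    cycle_time=c.cycle_time,
                    durations=np.random.default_rng(0).permutation(c.durations),
                    n_censored=c.n_censored,
                    censor_time=c.censor_time,
                    min_frames=c.min_frames,
                )
                for c in data.conditions
            ]
        )
        a = invert_spectrum(data)
        b = invert_spectrum(shuffled)
        assert np.allclose(a.event_amplitudes, b.event_amplitudes)

    def test_nnls_route_runs_and_normalizes(self):
        data, _ = synthetic.generate_survival(
            rates=np.array([0.2]),
            state_fractions=np.array([1.0]),
            n_events=5000,
            bleach_per_frame=0.1,
            seed=4,
        )
        spec = invert_spectrum(data, method="nnls")
        assert np.isclose(spec.event_amplitudes.sum(), 1.0)
        assert np.isfinite(spec.regularization)


class TestClustering:
    def test_single_cluster_covers_everything(self):
        amps = np.zeros(40)
        amps[5:9] = 0.25
        spec = RateSpectrum(RATE_GRID, amps, 0.0)
        cl = cluster_spectrum(spec, boundaries=np.array([]))
        assert cl.n_clusters == 1
        assert cl.state_fractions[0] == pytest.approx(1.0)

    def test_residence_time_inverse_identity(self):
        rates = RATE_GRID.copy()
        rates[10] = 1 / 16.2
        amps = np.zeros(40)
        amps[10] = 1.0
        spec = RateSpectrum(rates, amps, 0.0)
        cl = cluster_spectrum(spec, boundaries=[0.15])
        assert cl.residence_times[0] == pytest.approx(16.2)
        assert cl.state_fractions[0] == pytest.approx(1.0)
        assert np.isnan(cl.residence_times[1])  # empty fast cluster

    def test_empty_cluster_zero_fraction(self):
        amps = np.zeros(40)
        amps[30] = 1.0  # fast only
        spec = RateSpectrum(RATE_GRID, amps, 0.0)
        cl = cluster_spectrum(spec, boundaries=[0.15])
        assert cl.state_fractions[0] == 0.0
        assert np.isnan(cl.residence_times[0])

    def test_fractions_partition_unity(self):
        rng = np.random.default_rng(5)
        amps = rng.dirichlet(np.ones(40))
        spec = RateSpectrum(RATE_GRID, amps, 0.0)
        cl = cluster_spectrum(spec, boundaries=[0.1, 1.0, 10.0])
        assert cl.state_fractions.sum() == pytest.approx(1.0)
        assert cl.event_fractions.sum() == pytest.approx(1.0)


class TestResampling:
    def test_reproducible_under_seed(self):
        data, _ = synthetic.generate_survival(
            rates=np.array([0.3]),
            state_fractions=np.array([1.0]),
            n_events=2000,
            bleach_per_frame=0.1,
            seed=6,
        )
        env1, _ = resample_spectrum(data, n_reps=3, seed=11)
        env2, _ = resample_spectrum(data, n_reps=3, seed=11)
        assert np.array_equal(env1, env2)

    def test_cluster_summary_from_replicates(self):
        data, _ = synthetic.generate_survival(
            rates=np.array([0.1, 2.0]),
            state_fractions=np.array([0.5, 0.5]),
            n_events=4000,
            bleach_per_frame=0.1,
            seed=7,
        )
        env, summary = resample_spectrum(
            data, n_reps=4, seed=12, boundaries=[0.5]
        )
        assert env.shape == (40,)
        assert summary is not None
        assert summary.sd_residence is not None
        assert np.isfinite(summary.residence_times[0])
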