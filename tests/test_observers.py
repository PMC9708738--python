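"""Generative observer model: reproduction, discrimination, control tasks."""

import numpy as np
import pytest
from scipy.stats import norm

from centend import observers as obs
from centend.central_tendency import summarize
from centend.observers import ObserverParams
from centend.schedules import default_reproduction_schedule


class TestParams:
    def test_requires_exactly_one_noise_model(self):
        with pytest.raises(ValueError, match="exactly one"):
            ObserverParams(sigma_s=1.0, weber_coeff=0.1)
        with pytest.raises(ValueError, match="exactly one"):
            ObserverParams()

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            ObserverParams(w_prior=1.2, sigma_s=1.0)
        with pytest.raises(ValueError):
            ObserverParams(sigma_s=-1.0)
        with pytest.raises(ValueError):
            ObserverParams(sigma_s=1.0, lapse=0.7)

    def test_scalar_noise_grows_with_magnitude(self):
        p = ObserverParams(weber_coeff=0.1)
        np.testing.assert_allclose(p.sensory_sd([1.0, 2.0]), [0.1, 0.2])


class TestReproduction:
    def test_veridical_observer_reproduces_stimuli_exactly(
        self, veridical_observer, space_schedule
    ):
        s, r = obs.simulate_reproduction(veridical_observer, space_schedule, seed=0)
        np.testing.assert_array_equal(s, r)
        assert summarize((s, r)).regression_index == pytest.approx(0.0, abs=1e-12)

    def test_pure_prior_observer_always_answers_the_mean(
        self, pure_prior_observer, space_schedule
    ):
        s, r = obs.simulate_reproduction(pure_prior_observer, space_schedule, seed=0)
        np.testing.assert_allclose(r, space_schedule.mean_level)
        assert summarize((s, r)).regression_index == pytest.approx(1.0, abs=1e-12)

    def test_regression_index_recovers_prior_weight(self, space_schedule):
        # static-mean linear model: E[slope] = 1 - w, so E[RI] = w
        p = ObserverParams(w_prior=0.5, sigma_s=0.05 * space_schedule.mean_level)
        ris = []
        for i in range(25):
            s, r = obs.simulate_reproduction(p, space_schedule, seed=100 + i)
            ris.append(summarize((s, r)).regression_index)
        assert np.mean(ris) == pytest.approx(0.5, abs=0.01)

    def test_running_mean_prior_tracks_measurement_history(self, space_schedule):
        p = ObserverParams(w_prior=1.0, prior_mode="running_mean", sigma_s=0.0)
        s, r = obs.simulate_reproduction(p, space_schedule, seed=0)
        assert r[0] == s[0]  # first trial: prior is the current measurement
        np.testing.assert_allclose(
            r[1:], np.cumsum(s)[:-1] / np.arange(1, s.size), atol=1e-12
        )

    def test_clipping_warns_and_counts(self, space_schedule):
        p = ObserverParams(w_prior=0.0, sigma_s=0.0, sigma_m=0.0, bias=-50.0)
        with pytest.warns(UserWarning, match="clipped"):
            _, r = obs.simulate_reproduction(p, space_schedule, seed=0)
        assert np.all(r == 0.0)

    def test_rejects_non_reproduction_schedule(self, veridical_observer, space_schedule):
        from centend.schedules import StimulusSchedule

        bad = StimulusSchedule(
            condition="space", task="discrimination", levels=(10.0,),
            trials=((0, 10.0),), units="cm", seed=0,
        )
        with pytest.raises(ValueError, match="reproduction"):
            obs.simulate_reproduction(veridical_observer, bad, seed=0)


class TestDiscriminationChoice:
    def test_equal_magnitudes_are_a_coin_flip(self):
        p = ObserverParams(sigma_s=0.0, sigma_d=1.0, lapse=0.0)
        assert obs.discrimination_choice_probability(p, 10, 10) == pytest.approx(0.5)
        # deterministic observer resolves an exact tie the same way
        p0 = ObserverParams(sigma_s=0.0, sigma_d=0.0, lapse=0.1)
        assert obs.discrimination_choice_probability(p0, 10, 10) == pytest.approx(0.5)

    def test_step_observer_limit(self):
        p = ObserverParams(sigma_s=0.0, sigma_d=0.0, lapse=0.1)
        assert obs.discrimination_choice_probability(p, 10, 100) == pytest.approx(0.95)
        assert obs.discrimination_choice_probability(p, 10, 1) == pytest.approx(0.05)

    def test_choice_frequency_matches_normal_cdf(self):
        # standard 10, comparison 11, sigma_d 1 -> P = Phi(1)
        p = ObserverParams(sigma_s=0.0, sigma_d=1.0, lapse=0.0)
        rng = np.random.default_rng(123)
        n = 100_000
        hits = sum(obs.simulate_discrimination_choice(p, 10.0, 11.0, rng) for _ in range(n))
        expected = norm.cdf(1.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se


class TestControlTasks:
    def test_noiseless_pointing_hits_the_target(self):
        p = ObserverParams(sigma_s=0.0, sigma_m=0.0)
        targets, touches = obs.simulate_pointing(p, 12, seed=0)
        np.testing.assert_array_equal(targets, touches)

    def test_five_trials_use_each_position_once(self):
        p = ObserverParams(sigma_s=0.0, sigma_m=0.0)
        targets, _ = obs.simulate_pointing(p, 5, seed=0)
        assert {tuple(t) for t in targets} == set(obs.POINTING_POSITIONS)

    def test_mean_radial_error_is_rayleigh(self):
        # isotropic unit noise -> mean radial error sqrt(pi/2)
        p = ObserverParams(sigma_s=0.0, sigma_m=1.0)
        targets, touches = obs.simulate_pointing(p, 20_000, seed=5)
        radial = np.hypot(*(touches - targets).T)
        assert np.mean(radial) == pytest.approx(np.sqrt(np.pi / 2), abs=0.02)

    def test_noiseless_rhythm_is_perfectly_regular(self):
        from centend.control import rhythm_variability

        p = ObserverParams(sigma_s=0.0, sigma_m=0.0)
        intervals = obs.simulate_rhythm(p, n_intervals=10, target_interval=1.0, seed=0)
        np.testing.assert_allclose(intervals, 1.0)
        assert rhythm_variability(intervals) == 0.0

    def test_rhythm_variability_estimates_noise_scale(self):
        from centend.control import rhythm_variability

        p = ObserverParams(sigma_s=0.0, sigma_m=0.1)
        intervals = obs.simulate_rhythm(p, n_intervals=20_000, target_interval=1.0, seed=7)
        assert rhythm_variability(intervals) == pytest.approx(0.1, abs=0.005)


class TestCohort:
    def test_group_sizes_respected(self, tiny_cohort):
        assert tiny_cohort["reproduction"]["participant"].nunique() == 4
        assert set(tiny_cohort["reproduction"]["group"]) == {"YA", "OA"}

    def test_reproduction_has_66_trials_per_participant_condition(self, tiny_cohort):
        counts = tiny_cohort["reproduction"].groupby(["participant", "condition"]).size()
        assert (counts == 66).all()

    def test_discrimination_sessions_at_least_50_trials(self, tiny_cohort):
        counts = tiny_cohort["discrimination"].groupby(["participant", "condition"]).size()
        assert (counts >= 50).all()

    def test_same_seed_reproduces_dataset(self, tiny_cohort_spec, tiny_cohort):
        again = obs.simulate_cohort(tiny_cohort_spec, seed=17)
        for task, df in tiny_cohort.items():
            assert again[task].equals(df), task

    def test_malformed_spec_names_offending_field(self):
        spec = {"groups": [{"name": "G", "n": 1, "space": {"w_prior": 0.5}}]}
        with pytest.raises(ValueError, match="time"):
            obs.simulate_cohort(spec, seed=0)
        spec2 = {
            "groups": [{"name": "G", "n": 1,
                        "space": {"bogus_field": 1, "sigma_s": 1},
                        "time": {"weber_coeff": 0.1}}]
        }
        with pytest.raises(ValueError, match="bogus_field"):
            obs.simulate_cohort(spec2, seed=0)

    def test_adding_a_group_does_not_perturb_existing_participants(self, tiny_cohort_spec):
        import copy

        bigger = copy.deepcopy(tiny_cohort_spec)
        bigger["groups"][1]["n"] += 1
        a = obs.simulate_cohort(tiny_cohort_spec, seed=17)["reproduction"]
        b = obs.simulate_cohort(bigger, seed=17)["reproduction"]
        first = a["participant"] < 4
        assert b[b["participant"] < 4].reset_index(drop=True).equals(
            a[first].reset_index(drop=True)
        )
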