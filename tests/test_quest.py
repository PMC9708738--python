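"""QUEST staircase: prior, Bayes updates, placement, stopping, sessions."""

import numpy as np
import pytest
from scipy.stats import norm

from centend import quest
from centend.observers import ObserverParams


@pytest.fixture
def space_cfg():
    return quest.default_config("space")


@pytest.fixture
def time_cfg():
    return quest.default_config("time")


class TestInit:
    def test_fresh_space_posterior_peaks_at_prior_mean(self, space_cfg):
        state = quest.quest_init(space_cfg)
        assert quest.quest_recommend(state, space_cfg) == pytest.approx(12.0)

    def test_fresh_time_posterior_peaks_at_prior_mean(self, time_cfg):
        state = quest.quest_init(time_cfg)
        assert quest.quest_recommend(state, time_cfg) == pytest.approx(1.7)

    def test_posterior_normalized(self, space_cfg):
        state = quest.quest_init(space_cfg)
        assert state.posterior().sum() == pytest.approx(1.0, abs=1e-9)

    def test_flat_prior_limit(self):
        cfg = quest.QuestConfig(
            guess=10.0, prior_sd=1e9, grid_min=5.0, grid_max=15.0, grid_n=11
        )
        p = quest.quest_init(cfg).posterior()
        np.testing.assert_allclose(p, 1.0 / 11, rtol=1e-6)

    def test_guess_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="inside the grid"):
            quest.QuestConfig(guess=30.0, prior_sd=1.0, grid_min=5.0, grid_max=15.0)


class TestUpdate:
    def test_update_renormalizes_and_appends_history(self, space_cfg):
        state = quest.quest_init(space_cfg)
        state = quest.quest_update(state, 11.0, True, space_cfg)
        assert state.posterior().sum() == pytest.approx(1.0, abs=1e-9)
        assert state.n_trials == 1
        assert state.history == ((11.0, True),)

    def test_updates_commute(self, space_cfg):
        s0 = quest.quest_init(space_cfg)
        a = quest.quest_update(quest.quest_update(s0, 11.0, True, space_cfg), 9.0, False, space_cfg)
        b = quest.quest_update(quest.quest_update(s0, 9.0, False, space_cfg), 11.0, True, space_cfg)
        np.testing.assert_allclose(a.posterior(), b.posterior(), atol=1e-12)

    def test_single_update_matches_hand_multiplied_grid(self):
        # brute-force oracle on a 3-point grid
        cfg = quest.QuestConfig(
            guess=10.0, prior_sd=2.0, grid_min=8.0, grid_max=12.0, grid_n=3,
            beta=0.5, gamma=0.05, delta=0.1,
        )
        state = quest.quest_update(quest.quest_init(cfg), 11.0, True, cfg)
        grid = np.array([8.0, 10.0, 12.0])
        prior = np.exp(-0.5 * ((grid - 10.0) / 2.0) ** 2)
        psi = 0.05 + 0.85 * norm.cdf(0.5 * (11.0 - grid))
        expect = prior * psi
        expect /= expect.sum()
        np.testing.assert_allclose(state.posterior(), expect, atol=1e-12)

    def test_nonfinite_or_off_grid_intensity_rejected(self, space_cfg):
        state = quest.quest_init(space_cfg)
        with pytest.raises(ValueError):
            quest.quest_update(state, np.nan, True, space_cfg)
        with pytest.raises(ValueError):
            quest.quest_update(state, 100.0, True, space_cfg)


class TestRecommend:
    def test_recommendation_always_on_grid(self, space_cfg):
        state = quest.quest_init(space_cfg)
        rng = np.random.default_rng(0)
        for _ in range(30):
            x = quest.quest_recommend(state, space_cfg)
            assert x in space_cfg.grid
            state = quest.quest_update(state, x, bool(rng.random() < 0.5), space_cfg)

    def test_longer_responses_above_threshold_pull_recommendation_down(self, space_cfg):
        state = quest.quest_init(space_cfg)
        recs = [quest.quest_recommend(state, space_cfg)]
        for _ in range(20):
            state = quest.quest_update(state, 12.0, True, space_cfg)
            recs.append(quest.quest_recommend(state, space_cfg))
        assert recs[-1] < recs[0]

    def test_mean_and_quantile_rules(self):
        cfg = quest.QuestConfig(
            guess=10.0, prior_sd=1.0, grid_min=5.0, grid_max=15.0, grid_n=101,
            recommendation_rule="mean",
        )
        state = quest.quest_init(cfg)
        assert quest.quest_recommend(state, cfg) == pytest.approx(10.0, abs=0.11)
        cfg_q = quest.QuestConfig(
            guess=10.0, prior_sd=1.0, grid_min=5.0, grid_max=15.0, grid_n=101,
            recommendation_rule="quantile", quantile=0.5,
        )
        assert quest.quest_recommend(state, cfg_q) == pytest.approx(10.0, abs=0.11)


class TestStopping:
    def _state_with_n(self, cfg, n):
        state = quest.quest_init(cfg)
        for _ in range(n):
            state = quest.quest_update(state, cfg.guess, True, cfg)
        return state

    def test_never_stops_before_the_50_trial_floor(self, time_cfg):
        state = self._state_with_n(time_cfg, 49)
        assert not quest.quest_should_stop(state, time_cfg)

    def test_stops_at_ceiling(self, time_cfg):
        state = self._state_with_n(time_cfg, time_cfg.max_trials)
        assert quest.quest_should_stop(state, time_cfg)

    def test_min_equals_max_stops_exactly_there(self):
        cfg = quest.QuestConfig(
            guess=10.0, prior_sd=1.0, grid_min=5.0, grid_max=15.0,
            min_trials=50, max_trials=50,
        )
        assert not quest.quest_should_stop(self._state_with_n(cfg, 49), cfg)
        assert quest.quest_should_stop(self._state_with_n(cfg, 50), cfg)

    def test_posterior_sd_stopping_rule(self):
        cfg = quest.QuestConfig(
            guess=10.0, prior_sd=1.0, grid_min=5.0, grid_max=15.0,
            min_trials=2, max_trials=500, sd_stop=0.9,
        )
        state = self._state_with_n(cfg, 2)
        # prior sd 1.0, two consistent updates shrink it below 0.9
        assert state.posterior_sd(cfg) <= 0.9
        assert quest.quest_should_stop(state, cfg)


class TestSession:
    def test_default_session_runs_at_least_50_trials(self, time_cfg):
        observer = ObserverParams(sigma_s=0.0, sigma_d=0.25, lapse=0.02)
        log = quest.run_discrimination_session(time_cfg, observer, 1.535, seed=1)
        assert len(log) >= 50

    def test_same_seed_identical_session(self, space_cfg):
        observer = ObserverParams(sigma_s=0.0, sigma_d=1.0)
        a = quest.run_discrimination_session(space_cfg, observer, 10.0, seed=9)
        b = quest.run_discrimination_session(space_cfg, observer, 10.0, seed=9)
        assert a.equals(b)

    def test_posterior_converges_toward_standard_for_sharp_observer(self, space_cfg):
        observer = ObserverParams(sigma_s=0.0, sigma_d=0.05)
        log = quest.run_discrimination_session(space_cfg, observer, 10.0, seed=2)
        state = quest.quest_init(space_cfg)
        for _, row in log.iterrows():
            state = quest.quest_update(
                state, row["comparison"], bool(row["comparison_judged_longer"]), space_cfg
            )
        mode = space_cfg.grid[np.argmax(state.posterior())]
        # for a near-step observer, any threshold within the placement
        # offset window is response-consistent; that window is the
        # identifiable resolution
        assert abs(mode - 10.0) <= max(space_cfg.placement_offsets) + 0.1

    def test_choice_column_consistent_with_position(self, space_cfg):
        observer = ObserverParams(sigma_s=0.0, sigma_d=1.0)
        log = quest.run_discrimination_session(space_cfg, observer, 10.0, seed=4)
        judged = log["comparison_judged_longer"].astype(bool)
        assert (log.loc[judged, "choice"] == log.loc[judged, "comparison_position"]).all()
        assert (log.loc[~judged, "choice"] == 3 - log.loc[~judged, "comparison_position"]).all()
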