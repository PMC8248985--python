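import numpy as np
import pytest

from etype_sync import rl
from etype_sync.synthetic import gen_session


class TestUpdateValues:
    def test_full_learning_rate_jumps_to_outcome(self):
        V = np.full(6, 0.2)
        out = rl.update_values(V, [0, 2, 4], [1, 3, 5], 1.0, rl.RlParams(1.0, 0.0, 1.0))
        assert np.allclose(out[[0, 2, 4]], 1.0)

    def test_zero_decay_leaves_unchosen_untouched(self):
        V = np.full(6, 0.4)
        out = rl.update_values(V, [0, 2, 4], [1, 3, 5], 0.0, rl.RlParams(0.5, 0.0, 1.0))
        assert np.allclose(out[[1, 3, 5]], 0.4)

    def test_half_learning_rate_arithmetic(self):
        V = np.full(6, 0.4)
        out = rl.update_values(V, [0], [1], 0.0, rl.RlParams(0.5, 0.0, 1.0))
        assert out[0] == pytest.approx(0.2)

    def test_decay_shrinks_unchosen(self):
        V = np.full(6, 0.8)
        out = rl.update_values(V, [0], [1], 1.0, rl.RlParams(0.1, 0.25, 1.0))
        assert out[1] == pytest.approx(0.6)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            rl.update_values(np.zeros(6), [0, 1], [1, 2], 1.0, rl.RlParams(0.5, 0.2, 1.0))

    def test_fixed_point_reached_geometrically(self):
        V = np.full(6, 0.5)
        p = rl.RlParams(0.3, 0.0, 1.0)
        for t in range(1, 6):
            V = rl.update_values(V, [0], [1], 1.0, p)
            assert 1.0 - V[0] == pytest.approx(0.5 * 0.7**t)


class TestChoiceProbs:
    def test_equal_sums_split_evenly(self):
        V = np.full(6, 0.3)
        p = rl.choice_probs(V, [[0, 2, 4], [1, 3, 5]], beta=7.0)
        assert np.allclose(p, 0.5)

    def test_zero_beta_is_uniform(self):
        V = np.array([1.0, 0.0, 0.5, 0.5, 0.5, 0.5])
        p = rl.choice_probs(V, [[0, 2, 4], [1, 3, 5]], beta=0.0)
        assert np.allclose(p, 0.5)

    def test_closed_form_value(self):
        V = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        p = rl.choice_probs(V, [[0, 2, 4], [1, 3, 5]], beta=2.0)
        assert p[0] == pytest.approx(np.exp(2) / (np.exp(2) + 1))

    def test_additive_constant_invariance(self):
        V = np.array([0.9, 0.1, 0.4, 0.6, 0.2, 0.8])
        p1 = rl.choice_probs(V, [[0, 2, 4], [1, 3, 5]], beta=3.0)
        p2 = rl.choice_probs(V + 0.37, [[0, 2, 4], [1, 3, 5]], beta=3.0)
        assert np.allclose(p1, p2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rl.choice_probs(np.zeros(6), [[], [1]], beta=1.0)


class TestLikelihood:
    def test_nll_matches_bruteforce_recomputation(self, agent_session):
        params, trials = agent_session
        sub = trials.iloc[:100]
        nll = rl.negative_log_likelihood(sub, params)
        # independent per-trial recomputation with explicit updates
        V = np.full(6, rl.V0)
        total = 0.0
        for _, row in sub.iterrows():
            c = int(row.chosen_color)
            ci = [c, 2 + int(row.chosen_location), 4 + int(row.chosen_direction)]
            ui = [1 - c, 2 + 1 - int(row.chosen_location), 4 + 1 - int(row.chosen_direction)]
            p = rl.choice_probs(V, [ci, ui], params.beta)[0]
            total -= np.log(p)
            V = rl.update_values(V, ci, ui, float(row.reward), params)
        assert nll == pytest.approx(total, abs=1e-9)

    def test_random_chooser_fits_near_chance(self):
        trials, _ = gen_session(rl.RlParams(0.5, 0.2, 1e-3), n_blocks=10, seed=30)
        params, nll = rl.fit(trials, n_starts=4, seed=1)
        assert nll / len(trials) == pytest.approx(np.log(2), abs=0.01)
        assert params.beta < 1.0

    def test_too_few_trials_rejected(self):
        trials, _ = gen_session(rl.RlParams(0.5, 0.2, 5.0), n_blocks=1, seed=0)
        with pytest.raises(ValueError):
            rl.fit(trials.iloc[:50])


class TestCrossValidation:
    def test_heldout_nll_exceeds_training_on_average(self, agent_session):
        _, trials = agent_session
        cv = rl.cross_validate(trials, n_rep=6, seed=2, n_starts=2)
        assert (cv["test_nll_per_trial"] - cv["train_nll_per_trial"]).mean() > -0.01

    def test_generating_model_beats_no_decay_null(self, agent_session):
        _, trials = agent_session
        full = rl.cross_validate(trials, n_rep=8, seed=3, n_starts=2)
        null = rl.cross_validate(trials, n_rep=8, seed=3, n_starts=2, fix_omega=0.0)
        wins = (full["test_nll_per_trial"].to_numpy() < null["test_nll_per_trial"].to_numpy()).sum()
        assert wins >= 5

    def test_degenerate_fraction_rejected(self, agent_session):
        _, trials = agent_session
        with pytest.raises(ValueError):
            rl.cross_validate(trials, frac=1.0)


class TestTrialVariables:
    def test_first_trial_is_maximally_uncertain(self, agent_session):
        params, trials = agent_session
        tr = rl.trial_variables(trials, params)
        assert tr.p_choice[0] == pytest.approx(0.5)
        if trials["reward"].iloc[0] == 1:
            assert tr.rpe_pos[0] == pytest.approx(1.0 - rl.V0)

    def test_rpe_defined_only_on_rewarded_trials(self, agent_session):
        params, trials = agent_session
        tr = rl.trial_variables(trials, params)
        rewarded = trials["reward"].to_numpy() == 1
        assert np.all(np.isfinite(tr.rpe_pos[rewarded]))
        assert np.all(np.isnan(tr.rpe_pos[~rewarded]))

    def test_late_block_trials_more_certain_than_early(self, agent_session):
        params, trials = agent_session
        tr = rl.trial_variables(trials, params)
        early = trials["trial_in_block"] <= 3
        late = trials["trial_in_block"] >= 20
        assert tr.p_choice[late.to_numpy()].mean() > tr.p_choice[early.to_numpy()].mean()


class TestLearningTrial:
    def test_all_correct_block_learns_at_trial_one(self):
        lc = rl.learning_trial(np.ones(20))
        assert lc.learning_trial == 1

    def test_all_error_block_never_learns(self):
        lc = rl.learning_trial(np.zeros(20))
        assert lc.learning_trial is None

    def test_bounds_bracket_the_estimate(self):
        rng = np.random.default_rng(4)
        out = (rng.random(40) < 0.8).astype(int)
        lc = rl.learning_trial(out)
        assert np.all(lc.lower <= lc.p_correct + 1e-12)
        assert np.all(lc.p_correct <= lc.upper + 1e-12)

    def test_step_change_detected_near_the_step(self):
        rng = np.random.default_rng(5)
        detected = []
        for _ in range(60):
            out = np.r_[rng.random(9) < 0.5, rng.random(31) < 0.95].astype(int)
            lc = rl.learning_trial(out)
            detected.append(lc.learning_trial or 41)
        assert 10 <= np.median(detected) <= 16

    def test_chance_blocks_rarely_flag_learning(self):
        rng = np.random.default_rng(6)
        none_count = 0
        for _ in range(60):
            out = (rng.random(40) < 0.5).astype(int)
            if rl.learning_trial(out).learning_trial is None:
                none_count += 1
        assert none_count / 60 >= 0.9

    def test_short_blocks_rejected(self):
        with pytest.raises(ValueError):
            rl.learning_trial([1, 0, 1])


class TestParamValidation:
    @pytest.mark.parametrize("eta,omega,beta", [(-0.1, 0, 1), (0.5, 1.5, 1), (0.5, 0.2, 0)])
    def test_invalid_params_rejected(self, eta, omega, beta):
        with pytest.raises(ValueError):
            rl.RlParams(eta, omega, beta)
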