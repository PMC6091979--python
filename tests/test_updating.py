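import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intertrial as it
from intertrial.updating import UpdateRuleSpec
from conftest import make_trials

E1 = "exp1_detection_blocked"
E3 = "exp3_detection_mixed"


class TestLogPriorOdds:
    def test_symmetry_point(self):
        assert it.log_prior_odds(0.5) == 0.0

    def test_closed_form(self):
        assert it.log_prior_odds(0.75) == pytest.approx(np.log(3), abs=1e-12)

    @pytest.mark.parametrize("p", np.arange(0.1, 0.95, 0.1))
    def test_antisymmetry(self, p):
        assert it.log_prior_odds(1 - p) == pytest.approx(-it.log_prior_odds(p))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            it.log_prior_odds(1.0)


class TestBeliefState:
    def test_initial_expectation_is_half(self):
        for beta0 in (0.5, 1.0, 3.0):
            assert it.BeliefState.create(beta0).p_hat == pytest.approx(0.5, abs=1e-12)

    def test_full_memory_predict_is_identity(self):
        st_ = it.BeliefState.create(1.0, alpha=1.0)
        st_ = it.belief_observe(st_, "u1")
        before = st_.w.copy()
        after = it.belief_predict(st_)
        assert np.allclose(after.w, before)

    def test_zero_alpha_predict_resets_to_initial(self):
        st_ = it.BeliefState.create(2.0, alpha=0.0)
        for _ in range(5):
            st_ = it.belief_observe(st_, "u1")
        st_ = it.belief_predict(st_)
        assert st_.p_hat == pytest.approx(0.5, abs=1e-12)

    def test_partial_forgetting_mixes_expectations(self):
        # posterior shaped Beta(3,1) (p_hat 0.75) mixed 50/50 with the
        # uniform initial prior (p_hat 0.5) -> 0.625
        st_ = it.BeliefState.create(1.0, alpha=0.5)
        st_ = it.belief_observe(it.belief_observe(st_, "u1"), "u1")
        assert st_.p_hat == pytest.approx(0.75, abs=1e-3)
        st_ = it.belief_predict(st_)
        assert st_.p_hat == pytest.approx(0.625, abs=1e-3)

    def test_single_observation_matches_conjugate_beta(self):
        st_ = it.belief_observe(it.BeliefState.create(1.0), "u1")
        assert st_.p_hat == pytest.approx(2 / 3, abs=1e-3)

    def test_opposite_observations_cancel(self):
        st_ = it.BeliefState.create(1.0)
        st_ = it.belief_observe(it.belief_observe(st_, "u1"), "u2")
        assert st_.p_hat == pytest.approx(0.5, abs=1e-3)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_grid_matches_laplace_rule_over_random_sequences(self, seq):
        """With a uniform hyperprior and full memory, the grid posterior
        mean must match the conjugate closed form (k+1)/(n+2)."""
        st_ = it.BeliefState.create(1.0, alpha=1.0)
        for success in seq:
            st_ = it.belief_observe(st_, "u1" if success else "u2")
        k, n = sum(seq), len(seq)
        assert st_.p_hat == pytest.approx((k + 1) / (n + 2), abs=1e-3)

    def test_weights_always_normalized(self):
        st_ = it.BeliefState.create(0.5, alpha=0.3)
        for i in range(50):
            st_ = it.belief_predict(st_)
            st_ = it.belief_observe(st_, "u1" if i % 3 else "u2")
            assert st_.w.sum() == pytest.approx(1.0, abs=1e-12)
            assert 0.0 < st_.p_hat < 1.0


class TestRateRules:
    def test_binary_repeat_switch_and_first_trial(self):
        st_ = it.RateState.create("binary", kappa0=0.8)
        s, st_ = it.rate_step_binary(st_, "u1")
        assert s == 1.0                     # no predecessor
        s, st_ = it.rate_step_binary(st_, "u1")
        assert s == 1.0                     # repeat
        s, st_ = it.rate_step_binary(st_, "u2")
        assert s == 0.8                     # switch

    def test_binary_absent_trial_clears_predecessor(self):
        st_ = it.RateState.create("binary", kappa0=0.8)
        _, st_ = it.rate_step_binary(st_, "u1")
        _, st_ = it.rate_step_binary(st_, None)   # target-absent
        s, st_ = it.rate_step_binary(st_, "u2")
        assert s == 1.0

    def test_decay_accumulates_delta_over_repeats(self):
        # full memory: scaling sequence over u,u,u,u is 1, 1, 1.1, 1.2
        st_ = it.RateState.create("decay", alpha=1.0, delta=0.1)
        scalings = []
        for _ in range(4):
            s, st_ = it.rate_step_decay(st_, "u1", True)
            scalings.append(round(s, 10))
        assert scalings == [1.0, 1.0, 1.1, 1.2]

    def test_decay_zero_alpha_pins_scaling_at_one(self):
        st_ = it.RateState.create("decay", alpha=0.0, delta=0.3)
        for uv in ["u1", "u2", "u2", "u1"]:
            s, st_ = it.rate_step_decay(st_, uv, True)
            assert s == 1.0

    def test_decay_forgetting_only_step_on_absent_trial(self):
        st_ = it.RateState.create("decay", alpha=0.5, delta=0.1)
        st_.kappa = 1.4
        st_.last_uv = "u1"
        s, st_ = it.rate_step_decay(st_, None, False)
        assert s == 1.4
        assert st_.kappa == pytest.approx(1.2)  # 0.5*1.4 + 0.5, no +-delta
        assert st_.last_uv == "u1"

    def test_weighted_single_trial_moves_resource(self):
        st_ = it.RateState.create("weighted", alpha=1.0, delta=0.1)
        (k1, k2), st_ = it.rate_step_weighted(st_, "u1", True)
        assert (k1, k2) == (1.0, 1.0)           # scaling read before update
        assert (st_.kappa1, st_.kappa2) == (1.1, 0.9)

    def test_weighted_zero_alpha_stays_at_unity(self):
        st_ = it.RateState.create("weighted", alpha=0.0, delta=0.4)
        for uv in ["u1", "u1", "u2"]:
            (k1, k2), st_ = it.rate_step_weighted(st_, uv, True)
            assert (k1, k2) == (1.0, 1.0)

    def test_weighted_conservation_over_random_sequence(self):
        rng = np.random.default_rng(0)
        st_ = it.RateState.create("weighted", alpha=0.9, delta=0.1)
        for _ in range(500):
            uv = rng.choice(["u1", "u2", None])
            _, st_ = it.rate_step_weighted(st_, uv, uv is not None)
            assert st_.kappa1 + st_.kappa2 == pytest.approx(2.0, abs=1e-12)


def _all_present_exp1(n=20, feat="green"):
    return make_trials([("p1", E1, 0, 0, i, feat, 0.45, True)
                        for i in range(n)])


class TestApplyRules:
    def no_update(self, scope):
        return UpdateRuleSpec("no_update", scope)

    def test_no_update_gives_neutral_modulations(self, exp1_synthetic):
        _, _, df = exp1_synthetic
        s0, kappa = it.apply_rules(self.no_update("RDF"), self.no_update("TDD"), df)
        assert (s0 == 0).all() and (kappa == 1).all()

    def test_s0_grows_under_repeated_identical_outcomes(self):
        df = _all_present_exp1()
        rdf = UpdateRuleSpec("s0_decay", "RDF", {"alpha": 0.9, "beta0": 1.0})
        s0, _ = it.apply_rules(rdf, self.no_update("TDD"), df)
        assert (np.diff(s0[:5]) > 0).all()

    def test_tdd_binary_requires_immediately_preceding_present_trial(self):
        df = make_trials([
            ("p1", E3, 0, 0, 0, "green", 0.45, True),
            ("p1", E3, 0, 0, 1, "tilt_left", 0.45, True),   # dim switch
            ("p1", E3, 0, 0, 2, "green", 0.45, True),       # dim switch
            ("p1", E3, 0, 0, 3, "absent", 0.45, True),
            ("p1", E3, 0, 0, 4, "tilt_left", 0.45, True),   # after absent
        ])
        tdd = UpdateRuleSpec("rate_binary", "TDD", {"kappa0": 0.8})
        _, kappa = it.apply_rules(self.no_update("RDF"), tdd, df)
        assert list(kappa) == [1.0, 0.8, 0.8, 1.0, 1.0]

    def test_rdf_and_tdd_rate_scalings_multiply(self):
        df = make_trials([
            ("p1", E3, 0, 0, 0, "green", 0.45, True),
            ("p1", E3, 0, 0, 1, "tilt_left", 0.45, True),
        ])
        rdf = UpdateRuleSpec("rate_binary", "RDF", {"kappa0": 0.9})
        tdd = UpdateRuleSpec("rate_binary", "TDD", {"kappa0": 0.8})
        _, kappa = it.apply_rules(rdf, tdd, df)
        # trial 2: RDF repeats (present->present, scaling 1) while the
        # dimension switches (0.8)
        assert kappa[1] == pytest.approx(0.8)

    def test_tdd_s0_contributes_only_on_present_trials(self):
        df = make_trials([
            ("p1", E3, 0, 0, 0, "green", 0.45, True),
            ("p1", E3, 0, 0, 1, "absent", 0.45, True),
            ("p1", E3, 0, 0, 2, "green", 0.45, True),
            ("p1", E3, 0, 0, 3, "purple", 0.45, True),
        ])
        tdd = UpdateRuleSpec("s0_decay", "TDD", {"alpha": 1.0, "beta0": 1.0})
        s0, _ = it.apply_rules(self.no_update("RDF"), tdd, df)
        assert s0[0] == pytest.approx(0.0, abs=1e-9)  # neutral prior
        assert s0[1] == 0.0                           # absent trial
        # before trial 3 the color prior saw color, not-color, color:
        # Laplace mean (2+1)/(3+2) = 0.6 -> log odds log(1.5)
        assert s0[3] == pytest.approx(np.log(0.6 / 0.4), abs=1e-3)

    def test_alpha_zero_levels_collapse_to_no_update(self, exp1_synthetic):
        _, _, df = exp1_synthetic
        base_s0, base_k = it.apply_rules(self.no_update("RDF"),
                                         self.no_update("TDD"), df)
        for rdf in (UpdateRuleSpec("s0_decay", "RDF", {"alpha": 0.0, "beta0": 2.0}),
                    UpdateRuleSpec("rate_decay", "RDF", {"alpha": 0.0, "delta": 0.3}),
                    UpdateRuleSpec("rate_weighted", "RDF", {"alpha": 0.0, "delta": 0.3})):
            s0, kappa = it.apply_rules(rdf, self.no_update("TDD"), df)
            assert np.allclose(s0, base_s0, atol=1e-12)
            assert np.allclose(kappa, base_k, atol=1e-12)

    def test_alpha_one_decay_equals_full_memory(self, exp1_synthetic):
        _, _, df = exp1_synthetic
        decay = UpdateRuleSpec("s0_decay", "RDF", {"alpha": 1.0, "beta0": 2.0})
        full = UpdateRuleSpec("s0_full_memory", "RDF", {"beta0": 2.0})
        s0_d, _ = it.apply_rules(decay, self.no_update("TDD"), df)
        s0_f, _ = it.apply_rules(full, self.no_update("TDD"), df)
        assert np.allclose(s0_d, s0_f, atol=1e-12)

    def test_trajectories_are_recorded(self):
        df = _all_present_exp1(10)
        rdf = UpdateRuleSpec("s0_decay", "RDF", {"alpha": 0.9, "beta0": 1.0})
        tdd = UpdateRuleSpec("rate_weighted", "TDD", {"alpha": 0.9, "delta": 0.1})
        s0, kappa, traj = it.apply_rules(rdf, tdd, df, record_trajectories=True)
        assert len(traj["rdf_p_hat"]) == 10
        assert np.allclose(traj["kappa"], kappa)
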