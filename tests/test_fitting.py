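import numpy as np
import pandas as pd
import pytest

import intertrial as it
from intertrial.fitting import FitResult
from intertrial.trials import TrialMask

E1 = "exp1_detection_blocked"
NOUP = it.ModelSpec.from_string("LATER+nd/rdf=no_update/tdd=no_update")


def _noup_params(t_er=0.15):
    tp = it.default_true_params(NOUP, E1)
    tp["t_er"] = t_er
    return tp


@pytest.fixture(scope="module")
def iid_trials():
    cfg = it.GeneratorConfig(E1, NOUP, _noup_params(), n_participants=1,
                             lapse_rate=0.02, seed=21)
    return it.simulate_participant(cfg, 77, "p00")


class TestNegloglik:
    def test_masking_one_trial_removes_exactly_its_term(self, iid_trials):
        df = iid_trials
        params = _noup_params()
        mask = it.modeling_outlier_mask(df)
        full = it.negloglik(NOUP, params, df, mask)
        i = int(np.flatnonzero(mask.include_in_likelihood)[5])
        cls = "absent" if not df.loc[i, "target_present"] \
            else df.loc[i, "target_dimension"]
        term = -it.later_logpdf(
            np.array([df.loc[i, "rt"]]),
            it.LaterParams(params[f"{cls}:D"], params[f"{cls}:mu"],
                           params[f"{cls}:sigma"], params["t_er"]))[0]
        less = TrialMask(mask.include_in_likelihood.copy(),
                         mask.include_in_descriptives)
        less.include_in_likelihood[i] = False
        assert it.negloglik(NOUP, params, df, less) == pytest.approx(
            full - term, abs=1e-9)

    def test_doubling_trials_doubles_the_objective(self, iid_trials):
        df = iid_trials
        params = _noup_params()
        single = it.negloglik(NOUP, params, df)
        doubled_df = pd.concat([df, df], ignore_index=True)
        doubled = it.negloglik(NOUP, params, doubled_df)
        assert doubled == pytest.approx(2 * single, rel=1e-9)

    def test_rt_at_or_below_t_er_gives_infinite_objective(self, iid_trials):
        df = iid_trials.copy()
        params = _noup_params(t_er=float(df["rt"].min()) + 0.01)
        mask = TrialMask.all_true(len(df))
        mask.include_in_descriptives[:] = True
        assert np.isinf(it.negloglik(NOUP, params, df, mask))

    def test_generating_params_dominate_perturbed_params(self):
        """On i.i.d. LATER data the likelihood at the generating parameters
        should beat a +-20% perturbation nearly always."""
        rng = np.random.default_rng(5)
        wins = 0
        n_rep = 100
        base = _noup_params()
        cfg = it.GeneratorConfig(E1, NOUP, base, n_participants=1,
                                 lapse_rate=0.0, seed=0)
        for rep in range(n_rep):
            df = it.simulate_participant(cfg, 1000 + rep, "p00")
            df = df.iloc[:200].reset_index(drop=True)
            pert = dict(base)
            for k in pert:
                if ":" in k:
                    pert[k] *= rng.choice([0.8, 1.2])
            mask = it.modeling_outlier_mask(df)
            if it.negloglik(NOUP, base, df, mask) <= \
                    it.negloglik(NOUP, pert, df, mask):
                wins += 1
        assert wins >= 95


class TestFit:
    def test_aic_identity_and_bookkeeping(self, iid_trials):
        fr = it.fit(NOUP, iid_trials, options=it.FitOptions(n_restarts=1))
        assert fr.aic == pytest.approx(2 * fr.n_params - 2 * fr.loglik)
        assert fr.n_params == 10  # 9 inner + t_er
        mask = it.modeling_outlier_mask(iid_trials)
        assert fr.n_included == mask.include_in_likelihood.sum()

    def test_refit_from_recovered_params_is_a_fixed_point(self, iid_trials):
        opts = it.FitOptions(n_restarts=1, seed=0)
        fr1 = it.fit(NOUP, iid_trials, options=opts)
        nll = it.negloglik(NOUP, fr1.params, iid_trials)
        assert -nll == pytest.approx(fr1.loglik, abs=1e-6)
        fr2 = it.fit(NOUP, iid_trials, options=opts)
        assert fr2.loglik == pytest.approx(fr1.loglik, abs=1e-3)

    def test_recovered_baselines_close_to_truth(self, iid_trials):
        fr = it.fit(NOUP, iid_trials, options=it.FitOptions(n_restarts=1))
        truth = _noup_params()
        for cls in ("absent", "color", "orientation"):
            assert fr.params[f"{cls}:mu"] == pytest.approx(
                truth[f"{cls}:mu"], rel=0.15)
        assert abs(fr.params["t_er"] - truth["t_er"]) < 0.1

    def test_nesting_consistency_alpha_zero_never_beats_no_update(self, iid_trials):
        """s0_decay with alpha = 0 is the no-update model; its best fit can
        exceed the no-update fit's likelihood only by optimizer slack."""
        opts = it.FitOptions(n_restarts=1, seed=0)
        fr_noup = it.fit(NOUP, iid_trials, options=opts)
        decay = it.ModelSpec.from_string("LATER+nd/rdf=s0_decay/tdd=no_update")
        params = dict(fr_noup.params)
        params.update({"rdf_alpha": 0.0, "rdf_beta0": 2.0})
        nll = it.negloglik(decay, params, iid_trials)
        assert -nll <= fr_noup.loglik + 1e-6


class TestCompare:
    def _fr(self, pid, spec, aic):
        return FitResult(spec=spec, params={}, loglik=0.0, n_params=0,
                         aic=aic, n_included=0, converged=True, seed=0,
                         participant_id=pid)

    def test_relative_aic_single_participant(self):
        a = it.ModelSpec.from_string("LATER+nd/rdf=no_update/tdd=no_update")
        b = it.ModelSpec.from_string("DDM+nd/rdf=no_update/tdd=no_update")
        table = it.compare([self._fr("p1", a, 100.0), self._fr("p1", b, 110.0)])
        assert table.winner == a.to_string()
        rel = dict(zip(table.table["spec"], table.table["mean_relative_aic"]))
        assert rel[a.to_string()] == 0.0
        assert rel[b.to_string()] == 10.0

    def test_winner_mean_relative_aic_is_zero_by_construction(self):
        rng = np.random.default_rng(0)
        specs = [it.ModelSpec("with", "later", lv, "no_update")
                 for lv in ("no_update", "s0_decay", "rate_binary")]
        fits = [self._fr(f"p{i}", s, float(100 + rng.normal(0, 5)))
                for i in range(4) for s in specs]
        table = it.compare(fits)
        win_row = table.table[table.table["spec"] == table.winner]
        assert win_row["mean_relative_aic"].iloc[0] == pytest.approx(0.0)

    def test_missing_cell_raises(self):
        a = it.ModelSpec.from_string("LATER+nd/rdf=no_update/tdd=no_update")
        b = it.ModelSpec.from_string("DDM+nd/rdf=no_update/tdd=no_update")
        fits = [self._fr("p1", a, 100.0), self._fr("p1", b, 101.0),
                self._fr("p2", a, 90.0)]
        with pytest.raises(ValueError, match="missing fit"):
            it.compare(fits)


class TestPredictCellMeans:
    def test_history_blind_model_predicts_flat_intertrial_cells(self, iid_trials):
        fr = it.fit(NOUP, iid_trials, options=it.FitOptions(n_restarts=1))
        cells = it.predict_cell_means(fr, iid_trials, n_draws=200, seed=1)
        assert (cells["predicted"] > fr.params["t_er"]).all()
        # within each (frequency, condition), repeat and switch predictions
        # agree up to Monte-Carlo error
        for _, grp in cells.groupby(["frequency", "condition"]):
            if len(grp) == 2:
                assert abs(grp["predicted"].diff().iloc[-1]) < 0.02

    def test_generating_spec_predictions_track_observed_means(self, exp1_synthetic):
        # under starting-point updating the frequency conditions produce
        # systematic cell-mean differences the fitted model should track
        spec, _, df = exp1_synthetic
        fr = it.fit(spec, df, options=it.FitOptions(n_restarts=1))
        cells = it.predict_cell_means(fr, df, n_draws=200, seed=2)
        r = np.corrcoef(cells["observed"], cells["predicted"])[0, 1]
        assert r**2 > 0.5
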