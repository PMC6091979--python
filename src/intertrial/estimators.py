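"""scikit-learn-style estimator wrapping the nested MLE fit.

``AccumulatorModel`` fits one model spec to one participant's tidy trial
frame; fitted quantities live in trailing-underscore attributes and the
estimator composes with sklearn's clone/get_params machinery. The model
spec string selects the factorial cell, e.g.
``"LATER+nd/rdf=s0_decay/tdd=rate_weighted"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import accumulators as acc
from .fitting import FitOptions, FitResult, _class_labels, fit, negloglik
from .model_space import ModelSpec, rule_specs
from .trials import validate_trials
from .updating import apply_rules


class AccumulatorModel(BaseEstimator):
    """Maximum-likelihood accumulator model with history updating.

    Parameters
    ----------
    spec : str
        Factorial model spec string (accumulator, optional ``+nd``
        non-decision time, RDF and TDD updating levels).
    n_restarts : int
        Multi-start count of the outer bounded search.
    seed : int
        Seed for restart sampling and any simulation-based prediction.
    inner_maxfev, outer_maxfev : int
        Function-evaluation budgets of the inner/outer Powell searches.
    """

    def __init__(self, spec: str = "LATER+nd/rdf=no_update/tdd=no_update",
                 n_restarts: int = 3, seed: int = 0,
                 inner_maxfev: int = 300, outer_maxfev: int = 400):
        self.spec = spec
        self.n_restarts = n_restarts
        self.seed = seed
        self.inner_maxfev = inner_maxfev
        self.outer_maxfev = outer_maxfev

    def _spec(self) -> ModelSpec:
        return (self.spec if isinstance(self.spec, ModelSpec)
                else ModelSpec.from_string(self.spec))

    def _options(self) -> FitOptions:
        return FitOptions(n_restarts=self.n_restarts, seed=self.seed,
                          inner_maxfev=self.inner_maxfev,
                          outer_maxfev=self.outer_maxfev)

    def fit(self, X: pd.DataFrame, y=None) -> "AccumulatorModel":
        """Fit to one participant's trial frame (the likelihood mask is
        derived internally from the modelling outlier rule)."""
        validate_trials(X)
        if X["participant_id"].nunique() != 1:
            raise ValueError("fit expects a single participant's trials")
        result: FitResult = fit(self._spec(), X.reset_index(drop=True),
                                options=self._options())
        self.result_ = result
        self.params_ = result.params
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.n_params_ = result.n_params
        self.n_included_ = result.n_included
        self.converged_ = result.converged
        return self

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per included trial at the fitted parameters."""
        check_is_fitted(self, "params_")
        from .trials import modeling_outlier_mask
        mask = modeling_outlier_mask(X)
        nll = negloglik(self._spec(), self.params_, X.reset_index(drop=True))
        return -nll / max(int(mask.include_in_likelihood.sum()), 1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted typical RT per trial: the closed-form median for
        LATER, a seeded Monte-Carlo mean for the DDM."""
        check_is_fitted(self, "params_")
        spec = self._spec()
        params = self.params_
        X = X.reset_index(drop=True)
        t_er = params.get("t_er", 0.0)
        rdf_spec, tdd_spec = rule_specs(spec, params)
        s0, kappa = apply_rules(rdf_spec, tdd_spec, X)
        labels = _class_labels(X)
        out = np.empty(len(X))
        rng = np.random.default_rng(self.seed)
        for cls in np.unique(labels):
            sel = labels == cls
            if spec.accumulator == "later":
                d_eff = np.maximum(params[f"{cls}:D"] - s0[sel], acc.EPS_D)
                out[sel] = t_er + d_eff / (kappa[sel] * params[f"{cls}:mu"])
            else:
                a, v, s = (params[f"{cls}:a"], params[f"{cls}:v"],
                           params[f"{cls}:s"])
                m = int(sel.sum())
                reps = 50
                z = np.clip(a / 2.0 + np.tile(s0[sel], reps),
                            acc.EPS_Z, a - acc.EPS_Z)
                _, draws = acc.sample_ddm_arrays(
                    rng, np.full(m * reps, a), np.tile(kappa[sel], reps) * v,
                    np.full(m * reps, s), t_er, z)
                out[sel] = draws.reshape(reps, m).mean(axis=0)
        return out
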