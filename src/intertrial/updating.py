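"""Trial-by-trial updating rules for the starting point and the rate.

Six factor levels, applied in two scopes: the response-defining feature
(RDF; target presence in the detection tasks, target dimension in the
discrimination task) and the target-defining dimension (TDD).

Starting-point levels maintain a discretized hyperprior over the Bernoulli
rate ``p`` of the two UV values (a symmetric Beta(beta0, beta0) initially),
updated by Bayes' rule after every trial. The decay variant mixes the
posterior back toward the initial prior with weight ``1 - alpha`` before
each trial (Dynamic-Belief-Model forgetting); ``alpha = 1`` is full memory,
``alpha = 0`` is no updating. The starting point contribution is the log
prior odds of the trial's correct response class.

Rate levels scale the mean accumulation rate:

* binary — scale by ``kappa0`` when the UV switched from the previous
  trial, 1 when it repeated;
* decay — a single kappa, +Delta on repeats, -Delta on switches, with the
  same forgetting-toward-1 mixture;
* weighted — one kappa per UV value sharing a fixed resource
  (``kappa1 + kappa2 = 2``): +Delta to the observed value's kappa, -Delta
  to the other, with forgetting.

Updating consumes stimulus truth (never responses) and sees every trial,
errors and outliers included. Per-trial order: forget -> read s0/kappa ->
observe / rate step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import beta as beta_dist

from .trials import rdf_values

GRID_N = 401
EPS_K = 1e-3

LEVELS = ("no_update", "s0_full_memory", "s0_decay",
          "rate_binary", "rate_decay", "rate_weighted")

#: Free parameters contributed by each level (Table-1 arities).
LEVEL_PARAMS = {
    "no_update": (),
    "s0_full_memory": ("beta0",),
    "s0_decay": ("alpha", "beta0"),
    "rate_binary": ("kappa0",),
    "rate_decay": ("alpha", "delta"),
    "rate_weighted": ("alpha", "delta"),
}

S0_LEVELS = ("s0_full_memory", "s0_decay")
RATE_LEVELS = ("rate_binary", "rate_decay", "rate_weighted")


@dataclass(frozen=True)
class UpdateRuleSpec:
    """One factor level with its scope and parameter values."""
    level: str
    scope: str  # "RDF" or "TDD"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.scope not in ("RDF", "TDD"):
            raise ValueError("scope must be RDF or TDD")
        need = set(LEVEL_PARAMS[self.level])
        got = set(self.params)
        if need != got:
            raise ValueError(
                f"level {self.level} needs params {sorted(need)}, got {sorted(got)}")


def log_prior_odds(p_hat: float) -> float:
    """log(p / (1-p)); domain error outside (0, 1)."""
    p_hat = float(p_hat)
    if not 0.0 < p_hat < 1.0:
        raise ValueError("p_hat must lie in (0, 1)")
    return float(np.log(p_hat / (1.0 - p_hat)))


def _beta_grid_weights(beta0: float, n: int = GRID_N):
    p = (np.arange(n) + 0.5) / n
    w = beta_dist.pdf(p, beta0, beta0)
    return p, w / w.sum()


@dataclass
class BeliefState:
    """Discretized hyperprior over a Bernoulli rate p."""
    grid: np.ndarray
    w: np.ndarray
    w0: np.ndarray
    beta0: float
    alpha: float

    @classmethod
    def create(cls, beta0: float, alpha: float = 1.0, n: int = GRID_N):
        if beta0 <= 0 or not 0.0 <= alpha <= 1.0:
            raise ValueError("require beta0 > 0 and alpha in [0, 1]")
        p, w = _beta_grid_weights(beta0, n)
        return cls(p, w.copy(), w, beta0, alpha)

    @property
    def p_hat(self) -> float:
        return float(self.grid @ self.w)


def belief_predict(state: BeliefState) -> BeliefState:
    """Forgetting step: mix the current posterior with the initial prior."""
    w = state.alpha * state.w + (1.0 - state.alpha) * state.w0
    return replace(state, w=w / w.sum())


def belief_observe(state: BeliefState, outcome: str) -> BeliefState:
    """Bayes step with a Bernoulli likelihood (outcome 'u1' or 'u2')."""
    lik = state.grid if outcome == "u1" else 1.0 - state.grid
    w = state.w * lik
    return replace(state, w=w / w.sum())


@dataclass
class RateState:
    """State of a rate-scaling rule."""
    mode: str                      # binary | decay | weighted
    kappa0: float = 0.8            # binary
    delta: float = 0.0             # decay / weighted
    alpha: float = 1.0
    kappa: float = 1.0             # decay
    kappa1: float = 1.0            # weighted, UV value u1
    kappa2: float = 1.0            # weighted, UV value u2
    last_uv: str | None = None

    @classmethod
    def create(cls, mode: str, **params):
        if mode == "binary":
            k0 = params["kappa0"]
            if not 0.0 < k0 < 1.0:
                raise ValueError("kappa0 must lie in (0, 1)")
            return cls(mode="binary", kappa0=k0)
        if mode in ("decay", "weighted"):
            a, d = params["alpha"], params["delta"]
            if not 0.0 <= a <= 1.0 or d < 0:
                raise ValueError("require alpha in [0, 1] and delta >= 0")
            return cls(mode=mode, alpha=a, delta=d)
        raise ValueError(f"unknown rate mode {mode!r}")


def rate_step_binary(state: RateState, uv_n: str | None):
    """One-trial-back rule: scaling kappa0 on a UV switch, 1 on a repeat
    or when no immediately-preceding UV is defined. Passing ``uv_n=None``
    (a TDD-scope target-absent trial) clears the predecessor, so the next
    present trial is unscaled."""
    if uv_n is None:
        return 1.0, replace(state, last_uv=None)
    if state.last_uv is None or uv_n == state.last_uv:
        scaling = 1.0
    else:
        scaling = state.kappa0
    return scaling, replace(state, last_uv=uv_n)


def rate_step_decay(state: RateState, uv_n: str | None, uv_applies: bool = True):
    """Single-kappa rule with +-Delta steps and forgetting toward 1.

    ``uv_applies=False`` (TDD scope, target-absent trial) runs only the
    forgetting step; the returned scaling is then not applied by the
    caller. Repeat/switch is judged against the last trial on which the UV
    was defined."""
    scaling = state.kappa
    k_u = state.kappa
    last = state.last_uv
    if uv_applies and uv_n is not None:
        if last is not None:
            k_u = state.kappa + (state.delta if uv_n == last else -state.delta)
        last = uv_n
    k_next = state.alpha * k_u + (1.0 - state.alpha)
    k_next = max(k_next, EPS_K)
    return scaling, replace(state, kappa=k_next, last_uv=last)


def rate_step_weighted(state: RateState, uv_n: str | None, uv_applies: bool = True):
    """Shared-resource rule: kappa1 + kappa2 = 2 at every step. The
    observed UV value's kappa gains Delta, the other loses Delta, then both
    forget toward 1 (which preserves the sum)."""
    scaling = (state.kappa1, state.kappa2)
    k1u, k2u = state.kappa1, state.kappa2
    if uv_applies and uv_n is not None:
        sign = 1.0 if uv_n == "u1" else -1.0
        k1u = state.kappa1 + sign * state.delta
        k2u = state.kappa2 - sign * state.delta
    k1 = state.alpha * k1u + (1.0 - state.alpha)
    k2 = state.alpha * k2u + (1.0 - state.alpha)
    k1, k2 = max(k1, EPS_K), max(k2, EPS_K)
    return scaling, replace(state, kappa1=k1, kappa2=k2)


# ---------------------------------------------------------------------------
# Orchestration over a trial sequence

def _grid_predict_inplace(w, w0, alpha):
    w *= alpha
    w += (1.0 - alpha) * w0
    w /= w.sum()


def _grid_observe_inplace(w, lik):
    w *= lik
    w /= w.sum()


class _S0Tracker:
    """Fast in-place belief tracker for one scope."""

    def __init__(self, beta0, alpha, dims=None):
        self.grid, self.w0 = _beta_grid_weights(beta0)
        self.alpha = alpha
        # one belief per dimension for TDD scope, a single one for RDF
        self.keys = dims if dims is not None else ("_rdf",)
        self.w = {k: self.w0.copy() for k in self.keys}
        self.lik_u1 = self.grid
        self.lik_u2 = 1.0 - self.grid

    def forget(self):
        for k in self.keys:
            _grid_predict_inplace(self.w[k], self.w0, self.alpha)

    def p_hat(self, key="_rdf"):
        return float(self.grid @ self.w[key])

    def observe(self, key, outcome_u1: bool):
        _grid_observe_inplace(self.w[key], self.lik_u1 if outcome_u1 else self.lik_u2)


def apply_rules(spec_rdf: UpdateRuleSpec, spec_tdd: UpdateRuleSpec,
                trials, record_trajectories: bool = False):
    """Run both updating rules over a participant's trial sequence.

    Returns ``(s0, kappa)`` arrays of per-trial modulations and, when
    requested, a dict of state trajectories. ``s0`` is the summed log-
    prior-odds contribution toward the trial's correct response class;
    ``kappa`` is the product of the active rate scalings (RDF x TDD).
    Updating is driven by stimulus truth and runs across block and section
    boundaries; every trial participates, errors and outliers included.
    """
    if spec_rdf.scope != "RDF" or spec_tdd.scope != "TDD":
        raise ValueError("specs must carry scopes (RDF, TDD) in that order")
    n = len(trials)
    rdf_u1 = rdf_values(trials) == "u1"
    present = trials["target_present"].to_numpy(bool)
    dim = trials["target_dimension"].to_numpy(object)

    s0 = np.zeros(n)
    kappa = np.ones(n)
    traj: dict[str, list] = {}

    # --- RDF scope -------------------------------------------------------
    rlevel, rp = spec_rdf.level, spec_rdf.params
    rdf_belief = rdf_rate = None
    if rlevel in S0_LEVELS:
        alpha = 1.0 if rlevel == "s0_full_memory" else rp["alpha"]
        rdf_belief = _S0Tracker(rp["beta0"], alpha)
    elif rlevel in RATE_LEVELS:
        rdf_rate = RateState.create(rlevel.removeprefix("rate_"), **rp)

    # --- TDD scope -------------------------------------------------------
    tlevel, tp = spec_tdd.level, spec_tdd.params
    tdd_belief = tdd_rate = None
    if tlevel in S0_LEVELS:
        alpha = 1.0 if tlevel == "s0_full_memory" else tp["alpha"]
        tdd_belief = _S0Tracker(tp["beta0"], alpha, dims=("color", "orientation"))
    elif tlevel in RATE_LEVELS:
        tdd_rate = RateState.create(tlevel.removeprefix("rate_"), **tp)

    if record_trajectories:
        if rdf_belief is not None:
            traj["rdf_p_hat"] = []
        if tdd_belief is not None:
            traj["tdd_p_color"] = []
            traj["tdd_p_orientation"] = []
        if rdf_rate is not None or tdd_rate is not None:
            traj["kappa"] = []

    for i in range(n):
        # (a) forgetting / predictive step
        if rdf_belief is not None:
            rdf_belief.forget()
        if tdd_belief is not None:
            tdd_belief.forget()

        # (b) read the trial's modulation
        if rdf_belief is not None:
            p = rdf_belief.p_hat()
            s0[i] += log_prior_odds(p) if rdf_u1[i] else log_prior_odds(1.0 - p)
            if record_trajectories:
                traj["rdf_p_hat"].append(p)
        if tdd_belief is not None:
            if present[i]:
                s0[i] += log_prior_odds(tdd_belief.p_hat(dim[i]))
            if record_trajectories:
                traj["tdd_p_color"].append(tdd_belief.p_hat("color"))
                traj["tdd_p_orientation"].append(tdd_belief.p_hat("orientation"))

        # (c) rate scalings + state steps
        if rdf_rate is not None:
            uv = "u1" if rdf_u1[i] else "u2"
            if rdf_rate.mode == "binary":
                scale, rdf_rate = rate_step_binary(rdf_rate, uv)
            elif rdf_rate.mode == "decay":
                scale, rdf_rate = rate_step_decay(rdf_rate, uv, True)
            else:
                (k1, k2), rdf_rate = rate_step_weighted(rdf_rate, uv, True)
                scale = k1 if uv == "u1" else k2
            kappa[i] *= scale
        if tdd_rate is not None:
            uv = None if not present[i] else ("u1" if dim[i] == "color" else "u2")
            if tdd_rate.mode == "binary":
                scale, tdd_rate = rate_step_binary(tdd_rate, uv)
            elif tdd_rate.mode == "decay":
                scale, tdd_rate = rate_step_decay(tdd_rate, uv, uv is not None)
                if uv is None:
                    scale = 1.0  # rate only scaled on target-present trials
            else:
                (k1, k2), tdd_rate = rate_step_weighted(tdd_rate, uv, uv is not None)
                scale = 1.0 if uv is None else (k1 if uv == "u1" else k2)
            kappa[i] *= scale

        # (d) Bayes step with the trial's true stimulus values
        if rdf_belief is not None:
            rdf_belief.observe("_rdf", rdf_u1[i])
        if tdd_belief is not None:
            tdd_belief.observe("color", present[i] and dim[i] == "color")
            tdd_belief.observe("orientation", present[i] and dim[i] == "orientation")

        if record_trajectories and "kappa" in traj:
            traj["kappa"].append(kappa[i])

    kappa = np.maximum(kappa, EPS_K)
    if record_trajectories:
        return s0, kappa, {k: np.asarray(v) for k, v in traj.items()}
    return s0, kappa
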