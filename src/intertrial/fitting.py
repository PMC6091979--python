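"""Nested maximum-likelihood fitting, AIC, and factorial comparison.

One fit = one model spec x one participant's trial sequence. The updating
rules run over *all* trials (errors and outliers included) to produce
per-trial modulations; the likelihood sums only over included trials.

The optimizer is nested, mirroring the inner/outer structure of the
parameter space: the outer bounded multi-start search runs over the
non-decision time and updating-rule parameters; for every outer candidate
the inner accumulator parameters are optimized. Because, given the outer
parameters, the likelihood factorizes over stimulus classes, the 9 (or 6)
inner parameters are fitted as independent per-class 3-parameter bounded
problems (Powell, moment-based starts, warm-started across outer
iterations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import accumulators as acc
from .model_space import (ModelSpec, ParamLayout, param_layout, rule_specs,
                          stimulus_classes)
from .trials import TrialMask, modeling_outlier_mask
from .updating import apply_rules


@dataclass
class FitOptions:
    n_restarts: int = 3
    seed: int = 0
    inner_maxfev: int = 300
    inner_ftol: float = 1e-6
    outer_maxfev: int = 400
    outer_xtol: float = 1e-4


@dataclass
class FitResult:
    spec: ModelSpec
    params: dict
    loglik: float
    n_params: int
    aic: float
    n_included: int
    converged: bool
    seed: int
    experiment: str = ""
    participant_id: str = ""


def _class_labels(trials) -> np.ndarray:
    present = trials["target_present"].to_numpy(bool)
    dim = trials["target_dimension"].to_numpy(object)
    return np.where(present, dim, "absent")


def _class_logpdf(accumulator, triple, rts, s0, kappa, t_er):
    if accumulator == "later":
        D, mu, sigma = triple
        return acc.later_logpdf_arrays(rts, D, mu, sigma, t_er, s0, kappa)
    a, v, s = triple
    return acc.ddm_logpdf_correct_arrays(rts, a, v, s, t_er, s0, kappa)


def negloglik(spec: ModelSpec, params: dict, trials,
              mask: TrialMask | None = None) -> float:
    """Negative log-likelihood over included trials at named parameters.

    Any included trial with ``rt <= t_er`` yields +inf (an impossible
    datum under the model), which drives the optimizer away rather than
    raising.
    """
    if mask is None:
        mask = modeling_outlier_mask(trials)
    include = mask.include_in_likelihood
    t_er = params.get("t_er", 0.0)
    rdf_spec, tdd_spec = rule_specs(spec, params)
    s0, kappa = apply_rules(rdf_spec, tdd_spec, trials)
    labels = _class_labels(trials)
    rts = trials["rt"].to_numpy(float)
    total = 0.0
    for cls in stimulus_classes(trials["experiment"].iloc[0]):
        sel = include & (labels == cls)
        if not sel.any():
            continue
        triple = (params[f"{cls}:D"], params[f"{cls}:mu"], params[f"{cls}:sigma"]) \
            if spec.accumulator == "later" else \
            (params[f"{cls}:a"], params[f"{cls}:v"], params[f"{cls}:s"])
        lp = _class_logpdf(spec.accumulator, triple, rts[sel], s0[sel],
                           kappa[sel], t_er)
        if not np.all(np.isfinite(lp)):
            return np.inf
        total -= lp.sum()
    return float(total)


# ---------------------------------------------------------------------------
# Inner (per-class) optimization

def _inner_start(accumulator, rts, s0, kappa, t_er, layout, cls):
    td = np.maximum(rts - t_er, 1e-3)
    if accumulator == "later":
        D0 = 1.0
        r = np.maximum(D0 - s0, acc.EPS_D) / td / np.maximum(kappa, 1e-3)
        mu0 = float(np.clip(np.median(r), *layout.bounds(f"{cls}:mu")))
        sig0 = float(np.clip(r.std() + 1e-3, *layout.bounds(f"{cls}:sigma")))
        return np.array([D0, mu0, sig0])
    a0 = 2.0
    dist = np.maximum(a0 / 2.0 - s0, acc.EPS_Z)
    v0 = float(np.clip(np.median(dist / td / np.maximum(kappa, 1e-3)),
                       *layout.bounds(f"{cls}:v")))
    return np.array([a0, v0, 1.0])


def _fit_class(accumulator, rts, s0, kappa, t_er, layout, cls, opts,
               warm=None):
    names = [f"{cls}:{p}" for p in
             (("D", "mu", "sigma") if accumulator == "later" else ("a", "v", "s"))]
    bounds = [layout.bounds(nm) for nm in names]

    def obj(x):
        lp = _class_logpdf(accumulator, x, rts, s0, kappa, t_er)
        if not np.all(np.isfinite(lp)):
            return 1e12
        return -lp.sum()

    if warm is not None:
        starts = [warm]  # warm-started across neighbouring outer iterates
    else:
        starts = [_inner_start(accumulator, rts, s0, kappa, t_er, layout, cls)]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(obj, x0, method="Powell", bounds=bounds,
                       options={"maxfev": opts.inner_maxfev,
                                "ftol": opts.inner_ftol, "xtol": 1e-5})
        if best is None or res.fun < best.fun:
            best = res
    return best.x, float(best.fun)


# ---------------------------------------------------------------------------
# Outer optimization

def _default_outer_starts(layout: ParamLayout, t_er_max: float) -> list[np.ndarray]:
    """Two deterministic starts: mid-range, and t_er near its cap (fits
    with a non-decision time usually end up close to the fastest RT)."""
    starts = []
    for t_er0 in (0.5 * t_er_max, 0.9 * t_er_max):
        defaults = {"t_er": t_er0, "alpha": 0.7, "beta0": 2.0,
                    "delta": 0.1, "kappa0": 0.8}
        starts.append(np.array([
            defaults[nm.removeprefix("rdf_").removeprefix("tdd_")]
            for nm in layout.outer_names]))
    return starts


def _is_log_scaled(name: str) -> bool:
    # beta0 spans orders of magnitude; search it on a log axis
    return name.endswith("beta0")


def fit(spec: ModelSpec, trials, mask: TrialMask | None = None,
        options: FitOptions | None = None) -> FitResult:
    """Fit one model spec to one participant's trials by nested MLE."""
    opts = options or FitOptions()
    if mask is None:
        mask = modeling_outlier_mask(trials)
    include = mask.include_in_likelihood
    n_included = int(include.sum())
    experiment = trials["experiment"].iloc[0]
    layout = param_layout(spec, experiment)
    rts = trials["rt"].to_numpy(float)
    min_rt = rts[include].min()
    t_er_max = 0.95 * min_rt
    labels = _class_labels(trials)
    classes = stimulus_classes(experiment)
    class_sel = {cls: include & (labels == cls) for cls in classes}

    mod_cache: dict[tuple, tuple] = {}
    warm: dict[str, np.ndarray] = {}

    def modulations(outer_named):
        key = tuple(sorted((k, round(v, 12)) for k, v in outer_named.items()
                           if k != "t_er"))
        if key not in mod_cache:
            full = dict(outer_named)
            rdf_spec, tdd_spec = rule_specs(spec, full)
            mod_cache[key] = apply_rules(rdf_spec, tdd_spec, trials)
        return mod_cache[key]

    tracker = {"fun": np.inf, "x": None, "inner": None}

    def outer_obj(x):
        outer_named = dict(zip(layout.outer_names, x))
        t_er = outer_named.get("t_er", 0.0)
        s0, kappa = modulations(outer_named)
        total = 0.0
        inner = {}
        for cls in classes:
            sel = class_sel[cls]
            if not sel.any():
                continue
            xbest, f = _fit_class(spec.accumulator, rts[sel], s0[sel],
                                  kappa[sel], t_er, layout, cls, opts,
                                  warm.get(cls))
            warm[cls] = xbest
            inner[cls] = xbest
            total += f
        if total < tracker["fun"]:
            tracker.update(fun=total, x=np.array(x), inner=dict(inner))
        return total

    rng = np.random.default_rng(opts.seed)
    n_outer = layout.n_outer

    if n_outer == 0:
        outer_obj(np.empty(0))
        best_named, success = {}, True
    else:
        # the optimizer works in a scaled space: log10 axis for beta0
        log_scaled = np.array([_is_log_scaled(nm) for nm in layout.outer_names])

        def to_scaled(x):
            x = np.array(x, float)
            x[log_scaled] = np.log10(x[log_scaled])
            return x

        def from_scaled(u):
            u = np.array(u, float)
            u[log_scaled] = 10.0 ** u[log_scaled]
            return u

        obounds = [layout.bounds(nm, t_er_max) for nm in layout.outer_names]
        sbounds = [(np.log10(lo), np.log10(hi)) if sc else (lo, hi)
                   for sc, (lo, hi) in zip(log_scaled, obounds)]
        starts = _default_outer_starts(layout, t_er_max)[:max(1, opts.n_restarts)]
        for _ in range(max(0, opts.n_restarts - len(starts))):
            starts.append(np.array([rng.uniform(lo, hi) for lo, hi in obounds]))
        success = False
        for x0 in starts:
            x0 = np.clip(x0, [b[0] for b in obounds], [b[1] for b in obounds])
            res = minimize(lambda u: outer_obj(from_scaled(u)), to_scaled(x0),
                           method="Powell", bounds=sbounds,
                           options={"maxfev": opts.outer_maxfev,
                                    "xtol": opts.outer_xtol, "ftol": 1e-4})
            success = success or bool(res.success)
        best_named = dict(zip(layout.outer_names, tracker["x"]))

    best_fun = float(tracker["fun"])
    best_inner = tracker["inner"]

    if not np.isfinite(best_fun):
        bad = int(np.flatnonzero(include)[0])
        raise RuntimeError(
            f"no finite likelihood found; first included trial index {bad}")

    params = dict(best_named)
    inner_names = (("D", "mu", "sigma") if spec.accumulator == "later"
                   else ("a", "v", "s"))
    for cls in classes:
        if cls in best_inner:
            for nm, val in zip(inner_names, best_inner[cls]):
                params[f"{cls}:{nm}"] = float(val)
        else:  # class absent from the data; pin at the start values
            for nm, val in zip(inner_names,
                               _inner_start(spec.accumulator, rts[include],
                                            0.0, 1.0, 0.0, layout, cls)):
                params[f"{cls}:{nm}"] = float(val)

    loglik = -best_fun
    k = layout.n_params
    return FitResult(spec=spec, params=params, loglik=loglik, n_params=k,
                     aic=2.0 * k - 2.0 * loglik, n_included=n_included,
                     converged=success, seed=opts.seed,
                     experiment=experiment,
                     participant_id=str(trials["participant_id"].iloc[0]))


# ---------------------------------------------------------------------------
# Factorial comparison

@dataclass
class ComparisonTable:
    """Per-spec mean relative AIC (relative to the overall winner)."""
    per_cell: pd.DataFrame    # participant_id, spec, aic, rel_aic
    table: pd.DataFrame       # spec, mean_relative_aic, sd, n_participants
    winner: str


def compare(fits) -> ComparisonTable:
    """Aggregate (participant, spec) fits into mean relative AICs.

    The overall winner is the spec with the lowest mean AIC across
    participants; for each participant, that spec's AIC is subtracted from
    every spec's AIC before averaging.
    """
    rows = []
    for item in fits:
        if isinstance(item, FitResult):
            rows.append((item.participant_id, item.spec.to_string(), item.aic))
        else:
            pid, fr = item
            rows.append((str(pid), fr.spec.to_string(), fr.aic))
    cells = pd.DataFrame(rows, columns=["participant_id", "spec", "aic"])
    pivot = cells.pivot_table(index="participant_id", columns="spec",
                              values="aic")
    if pivot.isna().any().any():
        missing = pivot.stack(future_stack=True)
        missing = missing[missing.isna()].index[0]
        raise ValueError(f"missing fit for (participant, spec) = {missing}")
    winner = pivot.mean(axis=0).idxmin()
    rel = pivot.sub(pivot[winner], axis=0)
    cells = rel.stack(future_stack=True).rename("rel_aic").reset_index().merge(
        cells, on=["participant_id", "spec"])
    table = (rel.agg(["mean", "std"]).T
             .rename(columns={"mean": "mean_relative_aic", "std": "sd"})
             .assign(n_participants=len(pivot))
             .sort_values("mean_relative_aic")
             .rename_axis("spec").reset_index())
    return ComparisonTable(per_cell=cells, table=table, winner=winner)


def predict_cell_means(fit_result: FitResult, trials, n_draws: int = 100,
                       seed: int = 0) -> pd.DataFrame:
    """Predicted vs observed mean RT per (frequency x target condition x
    inter-trial condition) cell, by simulating the fitted model over the
    participant's actual stimulus sequence."""
    from .reporting import label_trials
    from .trials import descriptive_outlier_mask

    params = fit_result.params
    spec = fit_result.spec
    t_er = params.get("t_er", 0.0)
    rdf_spec, tdd_spec = rule_specs(spec, params)
    s0, kappa = apply_rules(rdf_spec, tdd_spec, trials)
    labels = _class_labels(trials)
    n = len(trials)
    rng = np.random.default_rng(seed)

    pred = np.zeros(n)
    for cls in np.unique(labels):
        sel = labels == cls
        m = int(sel.sum())
        s0_t = np.tile(s0[sel], n_draws)
        kp_t = np.tile(kappa[sel], n_draws)
        if spec.accumulator == "later":
            D, mu, sg = (params[f"{cls}:D"], params[f"{cls}:mu"],
                         params[f"{cls}:sigma"])
            draws = acc.sample_later_arrays(
                rng, np.full(m * n_draws, D), np.full(m * n_draws, mu),
                np.full(m * n_draws, sg), t_er, s0_t, kp_t)
        else:
            a, v, s = (params[f"{cls}:a"], params[f"{cls}:v"],
                       params[f"{cls}:s"])
            z = np.clip(a / 2.0 + s0_t, acc.EPS_Z, a - acc.EPS_Z)
            _, draws = acc.sample_ddm_arrays(
                rng, np.full(m * n_draws, a), kp_t * v,
                np.full(m * n_draws, s), t_er, z)
        pred[sel] = draws.reshape(n_draws, m).mean(axis=0)

    lab = label_trials(trials)
    keep = descriptive_outlier_mask(trials).include_in_descriptives \
        & lab["intertrial"].notna().to_numpy()
    out = lab.loc[keep, ["frequency", "condition", "intertrial"]].copy()
    out["observed"] = trials["rt"].to_numpy(float)[keep]
    out["predicted"] = pred[keep]
    return (out.groupby(["frequency", "condition", "intertrial"], dropna=False)
            .agg(observed=("observed", "mean"), predicted=("predicted", "mean"),
                 n=("observed", "size"))
            .reset_index())
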