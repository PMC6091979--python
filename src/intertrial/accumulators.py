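"""RT likelihoods and samplers for the LATER and drift-diffusion models.

LATER
-----
Evidence rises linearly from the starting point to a single boundary at
distance ``D`` (the start-to-boundary separation at a neutral prior). The
rate is constant within a trial but varies across trials,
``R ~ Normal(mu, sigma)`` truncated to ``R > 0`` and renormalized, so

    T = t_er + D_eff / R,
    f(t) = [D_eff / (t - t_er)^2] * phi((D_eff/(t - t_er) - mu_eff)/sigma)
           / sigma / Phi(mu_eff/sigma),

the "recinormal" density. A trial-wise starting-point offset ``s0`` (log
prior odds toward the correct boundary) shrinks the separation,
``D_eff = D - s0``; a trial-wise rate scaling ``kappa`` multiplies the mean
rate, ``mu_eff = kappa * mu``.

DDM
---
A Wiener process with boundary separation ``a``, diffusion scale ``s``,
drift ``v`` toward the correct (upper) boundary, starting at
``z = a/2 + s0`` (clamped inside the boundaries). The likelihood of a
correct response at time ``t`` is the *defective* first-passage density at
the upper boundary, evaluated with the exact series expansion with
automatic small-time / large-time regime selection (truncation error
``1e-7`` by default).

All densities are vectorized over trials; ``rt <= t_er`` yields ``-inf``
(an impossible datum), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

EPS_D = 1e-3   # floor on the effective LATER separation
EPS_Z = 1e-3   # clamp of the DDM start away from either boundary
SERIES_ERR = 1e-7
_MAX_K = 80


@dataclass(frozen=True)
class LaterParams:
    """Baseline LATER parameters for one stimulus class."""
    D: float          # start-to-boundary separation at neutral prior
    mu: float         # mean accumulation rate (evidence units / s)
    sigma: float      # across-trial SD of the rate
    t_er: float = 0.0  # non-decision time, shared across classes

    def __post_init__(self):
        if self.D <= 0 or self.sigma <= 0 or self.t_er < 0:
            raise ValueError("require D > 0, sigma > 0, t_er >= 0")


@dataclass(frozen=True)
class DdmParams:
    """Baseline DDM parameters for one stimulus class."""
    a: float          # boundary separation
    v: float          # drift toward the correct boundary
    s: float          # diffusion scale (evidence units / sqrt(s))
    t_er: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.s <= 0 or self.t_er < 0:
            raise ValueError("require a > 0, s > 0, t_er >= 0")


@dataclass(frozen=True)
class TrialModulation:
    """Per-trial history modulation: starting-point offset and rate scaling."""
    s0: float = 0.0
    kappa: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


# ---------------------------------------------------------------------------
# LATER

def later_logpdf_arrays(rt, D, mu, sigma, t_er, s0=0.0, kappa=1.0):
    """Vectorized LATER log-density; any argument may be an array."""
    rt = np.asarray(rt, float)
    t = rt - t_er
    d_eff = np.maximum(D - np.asarray(s0, float), EPS_D)
    mu_eff = np.asarray(kappa, float) * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        r = d_eff / t
        zscore = (r - mu_eff) / sigma
        logf = (
            np.log(d_eff) - 2.0 * np.log(np.where(t > 0, t, 1.0))
            - 0.5 * zscore**2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
            - log_ndtr(mu_eff / sigma)
        )
    return np.where(t > 0, logf, -np.inf)


def later_logpdf(rt, p: LaterParams, m: TrialModulation = TrialModulation()):
    return later_logpdf_arrays(rt, p.D, p.mu, p.sigma, p.t_er, m.s0, m.kappa)


def later_sample(n: int, p: LaterParams,
                 m: TrialModulation = TrialModulation(), seed=None):
    """Draw n LATER RTs by rejection-sampling the rate to R > 0."""
    rng = np.random.default_rng(seed)
    return sample_later_arrays(rng, np.full(n, p.D), np.full(n, p.mu),
                               np.full(n, p.sigma), p.t_er,
                               np.full(n, m.s0), np.full(n, m.kappa))


def sample_later_arrays(rng, D, mu, sigma, t_er, s0, kappa):
    """Per-trial LATER sampler with trial-wise modulation arrays."""
    d_eff = np.maximum(D - s0, EPS_D)
    mu_eff = kappa * mu
    r = rng.normal(mu_eff, sigma)
    bad = r <= 0
    while bad.any():
        r[bad] = rng.normal(mu_eff[bad] if np.ndim(mu_eff) else mu_eff,
                            sigma[bad] if np.ndim(sigma) else sigma)
        bad = r <= 0
    return t_er + d_eff / r


# ---------------------------------------------------------------------------
# DDM: Wiener first-passage time density (exact series, s = 1 internally)

def _fpt_lower_unit(u, w, err=SERIES_ERR):
    """Density of first passage at the LOWER boundary for a zero-drift
    Wiener process with unit separation, start fraction w, at normalized
    time u = t / a^2 (diffusion 1). Small/large-time series selected per
    element by the number of terms each needs for truncation error err."""
    u = np.asarray(u, float)
    w = np.broadcast_to(np.asarray(w, float), u.shape).copy()
    out = np.zeros_like(u)
    ok = u > 0
    uu, ww = u[ok], w[ok]

    # terms needed by each expansion
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_l = np.pi * uu * err
        kl = np.where(arg_l < 1,
                      np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0)
                              / (np.pi**2 * uu)),
                      0.0)
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(uu)))
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * uu) * err
        ks = np.where(arg_s < 1,
                      2.0 + np.sqrt(np.maximum(
                          -2.0 * uu * np.log(np.maximum(arg_s, 1e-300)), 0)),
                      2.0)
        ks = np.maximum(ks, np.sqrt(uu) + 1.0)

    small = ks < kl
    f = np.zeros_like(uu)

    if small.any():
        us, wsf = uu[small], ww[small]
        K = int(min(_MAX_K, np.ceil(ks[small].max() / 2.0) + 1))
        k = np.arange(-K, K + 1)
        terms = (wsf[:, None] + 2.0 * k[None, :]) * np.exp(
            -((wsf[:, None] + 2.0 * k[None, :]) ** 2) / (2.0 * us[:, None]))
        f[small] = terms.sum(axis=1) / np.sqrt(2.0 * np.pi * us**3)

    large = ~small
    if large.any():
        ul, wl = uu[large], ww[large]
        K = int(min(_MAX_K, np.ceil(kl[large].max())))
        k = np.arange(1, K + 1)
        terms = k[None, :] * np.exp(-(k[None, :] ** 2) * np.pi**2 * ul[:, None] / 2.0) \
            * np.sin(k[None, :] * np.pi * wl[:, None])
        f[large] = np.pi * terms.sum(axis=1)

    out[ok] = np.maximum(f, 0.0)
    return out


def wfpt_logpdf_lower(t, v, a, w, err=SERIES_ERR):
    """Log defective density of first passage at the lower boundary at
    decision time t, for drift v, separation a, start fraction w = z/a,
    diffusion 1."""
    t = np.asarray(t, float)
    v = np.broadcast_to(np.asarray(v, float), t.shape)
    w = np.broadcast_to(np.asarray(w, float), t.shape)
    u = t / a**2
    f = _fpt_lower_unit(u, w, err)
    with np.errstate(divide="ignore"):
        logf = np.log(np.where(f > 0, f, np.nan)) - 2.0 * np.log(a) \
            - v * a * w - v**2 * t / 2.0
    logf = np.where((t > 0) & (f > 0), logf, -np.inf)
    return logf


def ddm_logpdf_correct_arrays(rt, a, v, s, t_er, s0=0.0, kappa=1.0,
                              err=SERIES_ERR):
    """Vectorized log defective density of a correct (upper-boundary)
    response. Rescaled internally to unit diffusion: a' = a/s, v' = v/s."""
    rt = np.asarray(rt, float)
    td = rt - t_er
    z = np.clip(a / 2.0 + np.asarray(s0, float), EPS_Z, a - EPS_Z)
    v_eff = np.asarray(kappa, float) * v
    # upper-boundary passage == lower-boundary passage of the mirrored process
    logf = wfpt_logpdf_lower(np.where(td > 0, td, 1.0),
                             -v_eff / s, a / s, 1.0 - z / a, err)
    return np.where(td > 0, logf, -np.inf)


def ddm_logpdf_correct(rt, p: DdmParams, m: TrialModulation = TrialModulation(),
                       err=SERIES_ERR):
    return ddm_logpdf_correct_arrays(rt, p.a, p.v, p.s, p.t_er, m.s0, m.kappa,
                                     err)


def ddm_hit_probability_upper(a, v, z, s=1.0):
    """Closed-form probability of absorption at the upper boundary."""
    if v == 0:
        return z / a
    e = 2.0 * v / s**2
    return (1.0 - np.exp(-e * z)) / (1.0 - np.exp(-e * a))


def ddm_sample(n: int, p: DdmParams, m: TrialModulation = TrialModulation(),
               dt: float = 1e-3, seed=None, t_max: float = 10.0):
    """Euler-Maruyama paths; returns (boundary, rt) with boundary +1 for
    the upper (correct) boundary, -1 for the lower, 0 for paths censored
    at t_max."""
    rng = np.random.default_rng(seed)
    z = float(np.clip(p.a / 2.0 + m.s0, EPS_Z, p.a - EPS_Z))
    boundary, rt = sample_ddm_arrays(
        rng, np.full(n, p.a), np.full(n, m.kappa * p.v), np.full(n, p.s),
        p.t_er, np.full(n, z), dt, t_max)
    return boundary, rt


def sample_ddm_arrays(rng, a, v, s, t_er, z, dt=1e-3, t_max=10.0):
    """Vectorized EM simulation with per-trial drift/start arrays."""
    n = len(a)
    x = z.astype(float).copy()
    boundary = np.zeros(n, int)
    rt = np.full(n, np.nan)
    active = np.arange(n)
    sq = np.sqrt(dt)
    n_steps = int(np.ceil(t_max / dt))
    for step in range(1, n_steps + 1):
        x[active] += v[active] * dt + s[active] * sq * rng.standard_normal(len(active))
        hit_up = x[active] >= a[active]
        hit_lo = x[active] <= 0.0
        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            boundary[idx] = np.where(hit_up[done], 1, -1)
            rt[idx] = t_er + step * dt
            active = active[~done]
        if len(active) == 0:
            break
    # censored paths keep boundary 0 and rt = t_er + t_max
    rt[active] = t_er + t_max
    return boundary, rt
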