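# Methods

## Scope and data model

The package models per-trial reaction times in three pop-out search
designs. The unit of analysis is one participant's complete trial
sequence, a tidy frame with stimulus truth (target presence, dimension,
feature), the response, correctness and the RT in seconds. Two attributes
drive history effects:

* **RDF** (response-defining feature): target presence vs. absence in the
  detection tasks, target dimension (color vs. orientation) in the
  discrimination task. Coded `u1`/`u2` (present/color = `u1`).
* **TDD** (target-defining dimension): color vs. orientation, defined only
  on target-present trials.

Stimulus classes for likelihood purposes are `absent`, `color`,
`orientation` in the detection experiments and `color`, `orientation` in
the discrimination experiment; each class carries its own accumulator
parameter triple. The `absent`/`color`/`orientation` split is kept even in
the blocked design (where dimensions alternate between blocks) so that the
parameter count is constant across the detection experiments.

## Accumulators

**LATER.** Decision time is `D_eff / R` with `R ~ N(mu_eff, sigma)`
truncated to `R > 0` and renormalized; the truncated-normal correction
term `Phi(mu_eff/sigma)` is included in the density, so it stays a proper
density even at low rate signal-to-noise. RT adds a non-decision time
`t_er` (0 when the model's non-decision factor level is "without").

**DDM.** Wiener process, boundary separation `a`, diffusion scale `s`,
drift `v` toward the correct (upper) boundary, start `z = a/2 + S0`. The
likelihood of a correct RT is the defective upper-boundary first-passage
density. It is evaluated by rescaling to unit diffusion and using the
exact series expansions with per-point regime selection (small-time vs
large-time, whichever needs fewer terms for truncation error `1e-7`,
capped at 80 terms). Error responses are not modelled in the likelihood
(error trials are excluded from it), so the correct-boundary defective
density is used as-is rather than conditioned on correctness.

**History modulation.** A trial's starting-point offset `S0` (log prior
odds toward the correct boundary) *reduces the effective separation*:
`D_eff = max(D - S0, 1e-3)` for LATER and `z = clip(a/2 + S0, 1e-3,
a - 1e-3)` for the DDM. A trial's rate scaling `kappa` multiplies the mean
rate only (`mu` or `v`), not the dispersion; `kappa` is floored at `1e-3`.
These clamps keep the likelihood finite when the optimizer explores
extreme updating parameters.

## Updating rules

The hyperprior over the Bernoulli rate `p` of the two UV values is
discretized on a uniform grid of 401 points over (0, 1) (half-bin offset,
open interval), initialized to Beta(`beta0`, `beta0`). Discretization is
needed because the forgetting step (posterior mixed with the initial prior,
weight `1 - alpha`) leaves the conjugate family. At 401 points the grid
posterior mean matches conjugate closed forms (Laplace rule etc.) to
better than `1e-3`, which the tests check.

Per-trial order of operations: **forget → read `S0`/`kappa` → observe**.
The forgetting step implements the predictive prior for the upcoming
trial; the Bayes/rate step consumes the trial's true stimulus (never the
response), and runs on every trial including errors and outliers.
Updating runs continuously across block and section boundaries.

Scope conventions:

* RDF starting-point levels learn a single `p = P(u1)`; the trial's
  contribution is `+log(p/(1-p))` for `u1` trials and the negative for
  `u2` trials.
* TDD starting-point levels learn one prior per dimension, each tracking
  "target in this dimension vs. not"; both priors observe every trial
  (absent trials count as "not" for both) but contribute to `S0` only on
  target-present trials. In the discrimination design (every trial has a
  target) this reduces exactly to the single-prior treatment.
* TDD rate levels: the binary rule scales only target-present trials whose
  *immediately preceding* trial was target-present with the other
  dimension (an intervening absent trial clears the predecessor). The
  decay and weighted rules run their forgetting step on every trial but
  take no ±`Delta` step (and apply no scaling) on absent trials; for the
  decay rule, repeat/switch on a present trial is judged against the last
  present trial's dimension.
* When both scopes use rate rules their scalings compose multiplicatively.
* First trial: no predecessor, so the binary and decay rules skip their
  ±`Delta`/switch logic; the weighted rule (which compares the trial's UV
  against each value directly, not against the predecessor) updates from
  its first applicable trial. Scaling factors start at 1.
* The TDD full-memory starting-point level is constructible but excluded
  from the default enumeration (`enumerate_models(False)`, 120 specs;
  `True` restores all 144): with a dimension prior that never forgets,
  heavily unbalanced histories push the log odds to extremes and fits
  degenerate.

## Trial filtering

Two rules, both computed per participant over correct trials:

* **Modelling mask** — excluded from the likelihood: errors, RT > 2 s, and
  RT below `mean - 1.5 IQR`. The mean and IQR are computed over correct
  trials at most 2 s long (over-long trials are excluded anyway and a
  single multi-second RT would drag the mean in small samples). If
  IQR = 0 the lower-tail rule is not applied.
* **Descriptive mask** — excluded from mean-RT summaries: errors and
  trials whose inverse RT is more than 3 SD from the participant's mean
  inverse RT (no exclusion when SD = 0). Computed per participant across
  all conditions.

Masks only gate sums; they never change the sequence the updating rules
see (a tested invariant).

## Fitting

Maximum likelihood with a nested search, mirroring the inner/outer
parameter split:

* **Outer parameters** (0–5): `t_er` (bounded by 0.95 x the fastest
  included RT) plus the updating-rule parameters with bounds
  `alpha ∈ [0,1]`, `beta0 ∈ [0.01, 100]` (searched on a log10 axis),
  `delta ∈ [0, 1]`, `kappa0 ∈ (0.001, 0.999)`. Bounded Powell search,
  `xtol 1e-4`, from two deterministic starts (mid-range; `t_er` near its
  cap) plus uniform random restarts; the best point seen across all
  evaluations is kept, which also guards against non-monotone line-search
  excursions on this rugged objective.
* **Inner parameters**: given the outer candidate, the likelihood
  factorizes over stimulus classes, so the 9 (or 6) accumulator
  parameters are fitted as independent per-class 3-parameter bounded
  Powell problems (`ftol 1e-6`), started from moment heuristics
  (`D = 1`, `mu`/`v` from median effective rates, `sigma` from their
  spread) and warm-started between neighbouring outer iterations.
  Bounds: `D, a ∈ [0.1, 10]`, `mu, v ∈ [0.1, 50]`, `sigma ∈ [0.01, 20]`,
  `s ∈ [0.01, 10]`.

Per-trial modulations depend only on the updating parameters, so they are
cached across outer iterations that vary only `t_er`. AIC is
`2k - 2 logL` with `k` = inner + outer count. Model comparison subtracts,
per participant, the AIC of the spec with the lowest mean AIC across
participants ("overall winner"), then averages; the winner's mean relative
AIC is 0 by construction.

## Synthetic data generator

The generator reproduces the study conditions of the three designs:

* Exps 1–2: 3 sections x 10 blocks x 40 trials with section ratios
  75/50/25% (printed order by default; configurable permutation), exact
  per-block counts (a fixed multiset is shuffled, so block proportions are
  exact rather than binomial), features uniform within dimension, Exp-1
  blocks alternating color/orientation starting with color.
* Exp 3: 65-trial blocks from a random linear order-2 De Bruijn sequence
  over 8 labels (4 target types + 4 absent placeholders), sampled by a
  seeded random Eulerian circuit on the complete 8-vertex digraph; 18
  blocks (1170 trials) by default, matching the ~1200-trial sessions of
  the other designs.

RTs are sampled from the chosen accumulator with the same per-trial
modulations the fitting code would compute. The single-boundary LATER
model cannot produce errors, so errors arise from a lapse process (default
rate 2%; the per-design configs use 1.5/2.5/3.3% to emulate the observed
error rates; lapse RTs uniform on [0.15, 2.0] s). Under the DDM, errors
arise naturally at the wrong boundary. Updating always proceeds across
error trials. Default accumulator baselines (`D = 1, mu = 3.3,
sigma = 0.66, t_er = 0.15`; `a = 2, v = 5, s = 1.5`) put median correct
RTs near 0.45 s and natural DDM error rates near 1–3%, the ranges the
designs are meant to emulate.

What the generator does *not* emulate: post-error slowing, fatigue and
practice trends, feature-level (within-dimension) priming, inter-trial
interval jitter, and response-conditioned updating. Passing recovery
tests therefore show that the estimation machinery is consistent under
the model's own assumptions, not that real data satisfy them.

## Recovery designs and problem sizes

* *Parameter recovery*: 10 simulated blocked-detection participants
  (1200 trials each) per generating configuration, one fit restart.
  Piloted tolerances: `alpha` ±0.15, `t_er` ±0.1, `kappa0` ±0.1,
  `delta` ±0.05, each required in ≥ 8/10 participants.
* *Model recovery* (reduced design): 5 replicates of 3 mixed-detection
  participants x 6 blocks (390 trials), candidate set of 6 LATER specs
  crossing {no-update, starting-point-decay} x {no-update, binary-rate,
  weighted-rate}; the generating spec (decay x weighted) must win the
  mean-relative-AIC comparison in ≥ 4/5 replicates.
* *Qualitative signatures*: 12 simulated participants per condition;
  starting-point updating must produce the frequency effect and the
  response repeat/switch benefit, weighted-rate updating the dimension
  repetition benefit, and the no-update model neither.

## Numerical and degenerate-input conventions

* LATER density at `rt <= t_er` returns `-inf` (impossible datum), never
  raises; an included trial with `rt <= t_er` makes the objective `+inf`.
* Wiener series truncation error `1e-7`; series value floored at 0 before
  the log.
* Grid weights renormalized after every predict/observe step; belief
  expectations therefore stay strictly inside (0, 1).
* Exact-count randomization makes all design ratios exact in every block.
* Repeat/switch labels never cross block boundaries (blocks are separated
  by feedback screens; in the blocked design, cross-block pairs would mix
  the dimension manipulation into the inter-trial contrast). The first
  trial of each block is unlabelled.
* The two-back dimension contrast pairs trial `n` with `n-2` when both are
  target-present in the same block, regardless of the intervening trial.
* Empirical frequency labels are computed from the realized section
  composition (exact by construction), not from a config file.

## Known limitations

* No trial-to-trial variability of non-decision time or drift within the
  DDM, and no error-RT likelihood; accuracy is modelled only through the
  lapse mechanism of the generator.
* Participants are fitted independently; no hierarchical pooling.
* The inner/outer Powell search is a local method with a small number of
  restarts; for specs with 4–5 outer parameters on short sequences the
  outer landscape can be flat, and the recovered `beta0` in particular is
  weakly identified when `alpha` is small (forgetting erases the
  hyperprior's shape).
* Rate scalings of concurrently active RDF and TDD rules compose
  multiplicatively by convention; the factorial comparison never requires
  another choice, but it is a modelling assumption.
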