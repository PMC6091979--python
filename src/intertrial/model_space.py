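"""The 2 x 2 x 6 x 6 factorial model space and parameter bookkeeping.

Factors: non-decision time (without/with), accumulator (DDM/LATER),
RDF-based updating level, TDD-based updating level. Inner parameters are
the accumulator's own, one triple per stimulus class (absent / color /
orientation for the detection experiments, color / orientation for the
discrimination experiment); outer parameters are the non-decision time
plus the updating-rule parameters (0 to 5 in total).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .updating import LEVEL_PARAMS, LEVELS, UpdateRuleSpec

ACCUMULATORS = ("ddm", "later")
ND_TIME = ("without", "with")

LATER_INNER = ("D", "mu", "sigma")
DDM_INNER = ("a", "v", "s")

#: Bounds for every parameter kind (t_er's upper bound is data-dependent).
PARAM_BOUNDS = {
    "D": (0.1, 10.0), "mu": (0.1, 50.0), "sigma": (0.01, 20.0),
    "a": (0.1, 10.0), "v": (0.1, 50.0), "s": (0.01, 10.0),
    "t_er": (0.0, 1.0),
    "alpha": (0.0, 1.0), "beta0": (0.01, 100.0),
    "kappa0": (1e-3, 1.0 - 1e-3), "delta": (0.0, 1.0),
}


class ParamBoundsError(ValueError):
    """A parameter value lies outside its admissible range."""


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the factorial space."""
    nd_time: str = "with"
    accumulator: str = "later"
    rdf_level: str = "no_update"
    tdd_level: str = "no_update"

    def __post_init__(self):
        if self.nd_time not in ND_TIME:
            raise ValueError(f"nd_time must be one of {ND_TIME}")
        if self.accumulator not in ACCUMULATORS:
            raise ValueError(f"accumulator must be one of {ACCUMULATORS}")
        for lv in (self.rdf_level, self.tdd_level):
            if lv not in LEVELS:
                raise ValueError(f"unknown updating level {lv!r}")

    def to_string(self) -> str:
        acc = self.accumulator.upper()
        nd = "+nd" if self.nd_time == "with" else ""
        return f"{acc}{nd}/rdf={self.rdf_level}/tdd={self.tdd_level}"

    @classmethod
    def from_string(cls, s: str) -> "ModelSpec":
        head, rdf, tdd = s.split("/")
        nd = "with" if head.endswith("+nd") else "without"
        acc = head.removesuffix("+nd").lower()
        return cls(nd, acc, rdf.removeprefix("rdf="), tdd.removeprefix("tdd="))

    def __str__(self) -> str:
        return self.to_string()


def enumerate_models(include_tdd_full_memory: bool = False) -> list[ModelSpec]:
    """Full Cartesian product of the four factors (144 specs; 120 when the
    TDD full-memory level is dropped, as in the reference comparison where
    it was excluded after fit degeneracies)."""
    tdd_levels = [lv for lv in LEVELS
                  if include_tdd_full_memory or lv != "s0_full_memory"]
    return [ModelSpec(nd, acc, rdf, tdd)
            for nd, acc, rdf, tdd in itertools.product(
                ND_TIME, ACCUMULATORS, LEVELS, tdd_levels)]


def stimulus_classes(experiment: str) -> tuple[str, ...]:
    if experiment == "exp2_dimension_discrimination":
        return ("color", "orientation")
    return ("absent", "color", "orientation")


@dataclass(frozen=True)
class ParamLayout:
    """Named flat layout: inner accumulator params per stimulus class, then
    outer params (t_er and updating-rule parameters)."""
    spec: ModelSpec
    experiment: str
    inner_names: tuple[str, ...]   # "<class>:<param>"
    outer_names: tuple[str, ...]   # "t_er", "rdf_<param>", "tdd_<param>"

    @property
    def names(self) -> tuple[str, ...]:
        return self.inner_names + self.outer_names

    @property
    def n_inner(self) -> int:
        return len(self.inner_names)

    @property
    def n_outer(self) -> int:
        return len(self.outer_names)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def bounds(self, name: str, t_er_max: float | None = None):
        base = name.split(":")[-1]
        base = base.removeprefix("rdf_").removeprefix("tdd_")
        lo, hi = PARAM_BOUNDS[base]
        if base == "t_er" and t_er_max is not None:
            hi = t_er_max
        return lo, hi


def param_layout(spec: ModelSpec, experiment: str) -> ParamLayout:
    inner_kind = LATER_INNER if spec.accumulator == "later" else DDM_INNER
    inner = tuple(f"{cls}:{p}" for cls in stimulus_classes(experiment)
                  for p in inner_kind)
    outer = []
    if spec.nd_time == "with":
        outer.append("t_er")
    outer += [f"rdf_{p}" for p in LEVEL_PARAMS[spec.rdf_level]]
    outer += [f"tdd_{p}" for p in LEVEL_PARAMS[spec.tdd_level]]
    return ParamLayout(spec, experiment, inner, tuple(outer))


def pack(layout: ParamLayout, params: dict, t_er_max: float | None = None) -> np.ndarray:
    """Named params -> flat bounded vector; raises on a missing or
    out-of-bounds entry, naming the parameter."""
    vec = np.empty(layout.n_params)
    for i, name in enumerate(layout.names):
        if name not in params:
            raise ParamBoundsError(f"missing parameter {name!r}")
        val = float(params[name])
        lo, hi = layout.bounds(name, t_er_max)
        if not lo <= val <= hi:
            raise ParamBoundsError(
                f"parameter {name!r} = {val} outside [{lo}, {hi}]")
        vec[i] = val
    return vec


def unpack(layout: ParamLayout, vector, t_er_max: float | None = None) -> dict:
    vector = np.asarray(vector, float)
    if vector.shape != (layout.n_params,):
        raise ParamBoundsError(
            f"expected vector of length {layout.n_params}, got {vector.shape}")
    params = {}
    for i, name in enumerate(layout.names):
        lo, hi = layout.bounds(name, t_er_max)
        if not lo <= vector[i] <= hi:
            raise ParamBoundsError(
                f"parameter {name!r} = {vector[i]} outside [{lo}, {hi}]")
        params[name] = float(vector[i])
    return params


def rule_specs(spec: ModelSpec, params: dict) -> tuple[UpdateRuleSpec, UpdateRuleSpec]:
    """Build the two UpdateRuleSpecs from a named parameter dict."""
    rdf = UpdateRuleSpec(spec.rdf_level, "RDF",
                         {p: params[f"rdf_{p}"] for p in LEVEL_PARAMS[spec.rdf_level]})
    tdd = UpdateRuleSpec(spec.tdd_level, "TDD",
                         {p: params[f"tdd_{p}"] for p in LEVEL_PARAMS[spec.tdd_level]})
    return rdf, tdd
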