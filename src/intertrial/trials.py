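"""Trial-level data model, CSV I/O, and trial-filtering rules.

The canonical in-memory container is a tidy :class:`pandas.DataFrame` with one
row per search trial, ordered by presentation (participant, section, block,
trial). Two boolean masks gate which trials enter likelihood sums and
descriptive RT averages; the belief/rate updating rules always see the full
trial sequence, errors and outliers included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EXPERIMENTS = (
    "exp1_detection_blocked",
    "exp2_dimension_discrimination",
    "exp3_detection_mixed",
)
DIMENSIONS = ("color", "orientation", "none")
FEATURES = ("green", "purple", "tilt_left", "tilt_right", "none")
RESPONSES = ("present", "absent", "color", "orientation")

FEATURE_DIMENSION = {
    "green": "color",
    "purple": "color",
    "tilt_left": "orientation",
    "tilt_right": "orientation",
    "none": "none",
}

#: Column order of the on-disk CSV schema.
CSV_COLUMNS = (
    "participant_id", "experiment", "section", "block", "trial",
    "target_present", "target_dimension", "target_feature",
    "response", "correct", "rt_s",
)

#: Internal frame columns (0-based indices, rt in seconds).
FRAME_COLUMNS = (
    "participant_id", "experiment", "section", "block", "trial",
    "target_present", "target_dimension", "target_feature",
    "response", "correct", "rt",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A trial row violates a structural invariant."""


@dataclass(frozen=True)
class TrialRecord:
    """One visual-search trial: stimulus truth, response, correctness, RT."""

    participant_id: str
    experiment: str
    section: int
    block: int
    trial: int
    target_present: bool
    target_dimension: str
    target_feature: str
    response: str
    correct: bool
    rt: float


@dataclass
class TrialMask:
    """Boolean gates for likelihood and descriptive sums.

    Masking never removes trials from the sequence the updating rules see;
    it only decides which RT terms enter a likelihood or a cell mean.
    """

    include_in_likelihood: np.ndarray
    include_in_descriptives: np.ndarray

    def __post_init__(self):
        self.include_in_likelihood = np.asarray(self.include_in_likelihood, bool)
        self.include_in_descriptives = np.asarray(self.include_in_descriptives, bool)

    @classmethod
    def all_true(cls, n: int) -> "TrialMask":
        return cls(np.ones(n, bool), np.ones(n, bool))

    def combine(self, other: "TrialMask") -> "TrialMask":
        return TrialMask(
            self.include_in_likelihood & other.include_in_likelihood,
            self.include_in_descriptives & other.include_in_descriptives,
        )


def correct_response(experiment: str, target_present, target_dimension):
    """Task-appropriate response for the stimulus truth (vectorized)."""
    present = np.asarray(target_present, bool)
    if experiment == "exp2_dimension_discrimination":
        return np.asarray(target_dimension, object)
    return np.where(present, "present", "absent")


def validate_trials(df: pd.DataFrame) -> None:
    """Check every structural invariant; raise ValidationError with row number."""
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return

    present = df["target_present"].to_numpy(bool)
    dim = df["target_dimension"].to_numpy(object)
    feat = df["target_feature"].to_numpy(object)
    resp = df["response"].to_numpy(object)
    corr = df["correct"].to_numpy(bool)
    rt = df["rt"].to_numpy(float)

    def _fail(rows, msg):
        idx = int(np.flatnonzero(rows)[0])
        raise ValidationError(f"row {idx}: {msg}")

    bad = ~np.isin(df["experiment"].to_numpy(object), EXPERIMENTS)
    if bad.any():
        _fail(bad, "unknown experiment label")
    bad = ~np.isin(dim, DIMENSIONS)
    if bad.any():
        _fail(bad, "unknown target_dimension")
    bad = ~np.isin(feat, FEATURES)
    if bad.any():
        _fail(bad, "unknown target_feature")
    bad = ~np.isin(resp, RESPONSES)
    if bad.any():
        _fail(bad, "unknown response")

    # absent <=> dimension none <=> feature none
    bad = present != (dim != "none")
    if bad.any():
        _fail(bad, "target_present inconsistent with target_dimension")
    bad = present != (feat != "none")
    if bad.any():
        _fail(bad, "target_present inconsistent with target_feature")
    feat_dim = np.array([FEATURE_DIMENSION[f] for f in feat], object)
    bad = feat_dim != dim
    if bad.any():
        _fail(bad, "target_feature inconsistent with target_dimension")

    bad = (df["experiment"].to_numpy(object) == "exp2_dimension_discrimination") & ~present
    if bad.any():
        _fail(bad, "exp2 trials must always have a target present")

    expected = np.array(
        [correct_response(e, p, d)
         for e, p, d in zip(df["experiment"], present, dim)], object
    )
    bad = corr != (resp == expected)
    if bad.any():
        _fail(bad, "correct flag inconsistent with response and stimulus truth")

    bad = ~(rt > 0) | ~np.isfinite(rt)
    if bad.any():
        _fail(bad, "rt must be a positive real")


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["participant_id", "section", "block", "trial"], kind="stable"
    ).reset_index(drop=True)


def read_trials(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a trials CSV into the validated internal frame.

    Parameters
    ----------
    path : file path
    schema : optional mapping from the expected CSV column names to the
        names actually used in the file.

    The CSV carries 1-based ``block``/``trial`` columns for human
    readability; they are converted to 0-based indices here.
    """
    raw = pd.read_csv(path)
    colmap = {c: (schema or {}).get(c, c) for c in CSV_COLUMNS}
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    df = pd.DataFrame({
        "participant_id": raw[colmap["participant_id"]].astype(str),
        "experiment": raw[colmap["experiment"]].astype(str),
        "section": raw[colmap["section"]].astype(int),
        "block": raw[colmap["block"]].astype(int) - 1,
        "trial": raw[colmap["trial"]].astype(int) - 1,
        "target_present": raw[colmap["target_present"]].astype(int).astype(bool),
        "target_dimension": raw[colmap["target_dimension"]].astype(str),
        "target_feature": raw[colmap["target_feature"]].astype(str),
        "response": raw[colmap["response"]].astype(str),
        "correct": raw[colmap["correct"]].astype(int).astype(bool),
        "rt": raw[colmap["rt_s"]].astype(float),
    })
    df = _sorted(df)
    validate_trials(df)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the internal frame to the CSV schema (1-based block/trial)."""
    validate_trials(df)
    out = pd.DataFrame({
        "participant_id": df["participant_id"],
        "experiment": df["experiment"],
        "section": df["section"],
        "block": df["block"] + 1,
        "trial": df["trial"] + 1,
        "target_present": df["target_present"].astype(int),
        "target_dimension": df["target_dimension"],
        "target_feature": df["target_feature"],
        "response": df["response"],
        "correct": df["correct"].astype(int),
        "rt_s": df["rt"],
    })
    out.to_csv(path, index=False)


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=FRAME_COLUMNS)
    df = _sorted(df)
    validate_trials(df)
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    return [TrialRecord(**{k: row[k] for k in FRAME_COLUMNS})
            for _, row in df.iterrows()]


def rdf_values(df: pd.DataFrame) -> np.ndarray:
    """Response-defining feature per trial, coded 'u1'/'u2'.

    Detection tasks (Exps 1 & 3): target presence is response-defining
    (present -> u1, absent -> u2). The discrimination task (Exp 2): the
    target dimension is response-defining (color -> u1, orientation -> u2).
    """
    exp = df["experiment"].to_numpy(object)
    present = df["target_present"].to_numpy(bool)
    dim = df["target_dimension"].to_numpy(object)
    is_exp2 = exp == "exp2_dimension_discrimination"
    u1 = np.where(is_exp2, dim == "color", present)
    return np.where(u1, "u1", "u2")


def rdf_value(t: TrialRecord) -> str:
    """Scalar counterpart of :func:`rdf_values` for one trial."""
    if t.experiment == "exp2_dimension_discrimination":
        return "u1" if t.target_dimension == "color" else "u2"
    return "u1" if t.target_present else "u2"


def _per_participant(df, values, func):
    out = np.empty(len(df))
    for _, idx in df.groupby("participant_id", sort=False).indices.items():
        out[idx] = func(values[idx], idx)
    return out


def modeling_outlier_mask(df: pd.DataFrame) -> TrialMask:
    """Likelihood mask used by model fitting.

    Excluded from the likelihood: error trials, RTs longer than 2 s, and
    RTs more than 1.5 interquartile ranges below the participant's mean.
    Location statistics are computed per participant over correct trials
    at most 2 s long (errors and over-long trials are excluded anyway and
    would distort the location estimate). Degenerate samples (IQR = 0)
    get no lower-tail exclusion.
    """
    if len(df) == 0:
        raise ValueError("empty trial table")
    rt = df["rt"].to_numpy(float)
    corr = df["correct"].to_numpy(bool)
    include = corr & (rt <= 2.0)
    for _, idx in df.groupby("participant_id", sort=False).indices.items():
        c = corr[idx] & (rt[idx] <= 2.0)
        if c.sum() < 4:
            raise ValueError("need >= 4 correct trials per participant for IQR")
        sample = rt[idx][c]
        q75, q25 = np.percentile(sample, [75, 25])
        iqr = q75 - q25
        if iqr > 0:
            lo = sample.mean() - 1.5 * iqr
            include[idx] &= rt[idx] >= lo
    return TrialMask(include, np.ones(len(df), bool))


def descriptive_outlier_mask(df: pd.DataFrame) -> TrialMask:
    """Mask for mean-RT analyses: errors, and trials whose inverse RT lies
    more than 3 SD from the participant's mean inverse RT (statistics over
    correct trials). SD = 0 samples get no outlier exclusion."""
    if len(df) < 2:
        raise ValueError("need >= 2 trials")
    rt = df["rt"].to_numpy(float)
    corr = df["correct"].to_numpy(bool)
    include = corr.copy()
    inv = 1.0 / rt
    for _, idx in df.groupby("participant_id", sort=False).indices.items():
        sample = inv[idx][corr[idx]]
        sd = sample.std(ddof=0)
        if sd > 0:
            z = np.abs(inv[idx] - sample.mean()) / sd
            include[idx] &= z <= 3.0
    return TrialMask(np.ones(len(df), bool), include)
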