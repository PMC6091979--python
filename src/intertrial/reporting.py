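"""Descriptive repeat/switch summaries of trial sequences.

Each summary emits a tidy per-participant cell table: mean correct RT,
SEM, trial count and error rate per cell. RT statistics use only trials
passing the descriptive mask; error rates use all trials in the cell.

Inter-trial labels never cross block boundaries: the first trial of each
block carries no repeat/switch label (blocks are separated by feedback
screens, and the blocked designs make cross-block pairs anomalous).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trials import TrialMask, descriptive_outlier_mask, rdf_values


def _same_stream(df: pd.DataFrame) -> np.ndarray:
    """True where trial i-1 belongs to the same participant and block."""
    same = np.zeros(len(df), bool)
    pid = df["participant_id"].to_numpy(object)
    sec = df["section"].to_numpy()
    blk = df["block"].to_numpy()
    same[1:] = (pid[1:] == pid[:-1]) & (sec[1:] == sec[:-1]) & (blk[1:] == blk[:-1])
    return same


def label_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial cell labels: target condition, inter-trial condition, and
    the empirical frequency of the trial's response class in its section.

    condition: 'absent' or the target dimension. intertrial: 'repeat' /
    'switch' of the target condition vs the previous trial, NaN on the
    first trial of a block. frequency: fraction of the participant-section
    trials sharing the trial's response-defining value (so the 75%-present
    section labels present trials 0.75 and absent trials 0.25).
    """
    present = df["target_present"].to_numpy(bool)
    dim = df["target_dimension"].to_numpy(object)
    condition = np.where(present, dim, "absent")

    same = _same_stream(df)
    prev_cond = np.roll(condition, 1)
    intertrial = np.where(condition == prev_cond, "repeat", "switch")
    intertrial = np.where(same, intertrial, None)

    rdf = rdf_values(df)
    freq = np.empty(len(df))
    for _, idx in df.groupby(["participant_id", "section"], sort=False).indices.items():
        u1_share = (rdf[idx] == "u1").mean()
        freq[idx] = np.where(rdf[idx] == "u1", u1_share, 1.0 - u1_share)
    freq = np.round(freq, 2)

    return pd.DataFrame({"condition": condition, "intertrial": intertrial,
                         "frequency": freq}, index=df.index)


def _cell_table(df, mask, cells: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    keep_rt = mask.include_in_descriptives
    work = cells.copy()
    work["participant_id"] = df["participant_id"].to_numpy(object)
    work["rt"] = np.where(keep_rt, df["rt"].to_numpy(float), np.nan)
    work["error"] = (~df["correct"].to_numpy(bool)).astype(float)
    grouped = work.groupby(["participant_id"] + by, dropna=True)
    out = grouped.agg(
        mean_rt=("rt", "mean"),
        sem_rt=("rt", lambda x: x.std(ddof=1) / np.sqrt(max(x.notna().sum(), 1))),
        n_trials=("rt", "size"),
        error_rate=("error", "mean"),
    ).reset_index()
    return out


def intertrial_summary(df: pd.DataFrame, mask: TrialMask | None = None) -> pd.DataFrame:
    """Mean correct RT for repeat vs switch of the target condition, per
    participant, target condition and frequency condition."""
    if mask is None:
        mask = descriptive_outlier_mask(df)
    cells = label_trials(df)
    cells = cells[["frequency", "condition", "intertrial"]]
    return _cell_table(df, mask, cells, ["frequency", "condition", "intertrial"])


def dimension_repetition_summary(df: pd.DataFrame,
                                 mask: TrialMask | None = None,
                                 lag: int = 1) -> pd.DataFrame:
    """Dimension repeat/switch contrast among target-present trials whose
    trial n-lag (same block) was also target-present; per dimension.

    ``lag=1`` is the consecutive-pair contrast; ``lag=2`` probes the
    repetition benefit from two trials back.
    """
    if mask is None:
        mask = descriptive_outlier_mask(df)
    present = df["target_present"].to_numpy(bool)
    dim = df["target_dimension"].to_numpy(object)
    pid = df["participant_id"].to_numpy(object)
    sec = df["section"].to_numpy()
    blk = df["block"].to_numpy()
    n = len(df)

    ok = np.zeros(n, bool)
    rep = np.empty(n, object)
    idx = np.arange(lag, n)
    same = (pid[idx] == pid[idx - lag]) & (sec[idx] == sec[idx - lag]) \
        & (blk[idx] == blk[idx - lag])
    pair = same & present[idx] & present[idx - lag]
    ok[idx] = pair
    rep[idx[pair]] = np.where(dim[idx[pair]] == dim[idx[pair] - lag],
                              "repeat", "switch")

    cells = pd.DataFrame({
        "dimension": np.where(ok, dim, None),
        "dimension_transition": rep,
    }, index=df.index)
    if not ok.any():
        return pd.DataFrame(columns=["participant_id", "dimension",
                                     "dimension_transition", "mean_rt",
                                     "sem_rt", "n_trials", "error_rate"])
    sub_mask = TrialMask(mask.include_in_likelihood[ok],
                         mask.include_in_descriptives[ok])
    return _cell_table(df.loc[ok], sub_mask, cells.loc[ok],
                       ["dimension", "dimension_transition"])


def feature_repetition_summary(df: pd.DataFrame,
                               mask: TrialMask | None = None) -> pd.DataFrame:
    """Feature repeat/switch contrast among consecutive target-present
    pairs in which the target dimension stayed the same; per dimension."""
    if mask is None:
        mask = descriptive_outlier_mask(df)
    present = df["target_present"].to_numpy(bool)
    dim = df["target_dimension"].to_numpy(object)
    feat = df["target_feature"].to_numpy(object)
    same = _same_stream(df)
    n = len(df)

    ok = np.zeros(n, bool)
    ok[1:] = same[1:] & present[1:] & present[:-1] & (dim[1:] == dim[:-1])
    rep = np.empty(n, object)
    rep[1:][ok[1:]] = np.where(feat[1:][ok[1:]] == feat[:-1][ok[1:]],
                               "repeat", "switch")

    cells = pd.DataFrame({"dimension": np.where(ok, dim, None),
                          "feature_transition": rep}, index=df.index)
    if not ok.any():
        return pd.DataFrame(columns=["participant_id", "dimension",
                                     "feature_transition", "mean_rt",
                                     "sem_rt", "n_trials", "error_rate"])
    sub_mask = TrialMask(mask.include_in_likelihood[ok],
                         mask.include_in_descriptives[ok])
    return _cell_table(df.loc[ok], sub_mask, cells.loc[ok],
                       ["dimension", "feature_transition"])
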