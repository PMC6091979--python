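import numpy as np
import pandas as pd
import pytest

import intertrial as it


def make_trials(rows):
    """Build a validated trial frame from compact tuples:
    (participant, experiment, section, block, trial, feature_or_absent, rt,
     correct)."""
    recs = []
    for pid, exp, sec, blk, tri, feat, rt, correct in rows:
        present = feat != "absent"
        dim = it.trials.FEATURE_DIMENSION[feat] if present else "none"
        truth = ("present" if present else "absent") \
            if exp != "exp2_dimension_discrimination" else dim
        if correct:
            resp = truth
        else:
            resp = {"present": "absent", "absent": "present",
                    "color": "orientation", "orientation": "color"}[truth]
        recs.append(dict(participant_id=pid, experiment=exp, section=sec,
                         block=blk, trial=tri, target_present=present,
                         target_dimension=dim,
                         target_feature=feat if present else "none",
                         response=resp, correct=correct, rt=rt))
    df = pd.DataFrame(recs)
    it.validate_trials(df)
    return df


@pytest.fixture(scope="session")
def exp1_synthetic():
    """One simulated blocked-detection participant under starting-point
    updating with forgetting (LATER, non-decision time 0.15 s)."""
    spec = it.ModelSpec.from_string("LATER+nd/rdf=s0_decay/tdd=no_update")
    tp = it.default_true_params(spec, "exp1_detection_blocked",
                                {"rdf_alpha": 0.8, "rdf_beta0": 2.0})
    cfg = it.GeneratorConfig("exp1_detection_blocked", spec, tp,
                             n_participants=1, lapse_rate=0.02, seed=3)
    df = it.simulate_participant(cfg, 42, "p00")
    return spec, tp, df


@pytest.fixture(scope="session")
def exp3_synthetic_group():
    """Twelve simulated mixed-detection participants with both
    starting-point and weighted-rate updating."""
    spec = it.ModelSpec.from_string("LATER+nd/rdf=s0_decay/tdd=rate_weighted")
    tp = it.default_true_params(
        spec, "exp3_detection_mixed",
        {"rdf_alpha": 0.8, "rdf_beta0": 2.0,
         "tdd_alpha": 0.9, "tdd_delta": 0.1})
    cfg = it.GeneratorConfig("exp3_detection_mixed", spec, tp,
                             n_participants=12, lapse_rate=0.033, seed=7)
    return spec, tp, it.simulate_experiment(cfg)
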