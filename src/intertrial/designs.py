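"""Trial-sequence generators for the three experiment designs.

Stimulus schedules only, no RTs. All three designs share the same stimulus
set: a singleton target that is either a color singleton (green or purple)
or an orientation singleton (tilt_left or tilt_right), or no target.

* Exp 1 (blocked detection): 3 sections x 10 blocks x 40 trials; the
  target-present proportion varies across sections (75/50/25%); blocks
  alternate color-only and orientation-only targets.
* Exp 2 (dimension discrimination): same structure, a target on every
  trial; the color-target proportion varies across sections.
* Exp 3 (mixed detection): 65-trial blocks built from a linear order-2
  De Bruijn sequence over 8 trial labels (4 target types + 4 target-absent
  placeholders), giving a perfect census of all ordered label pairs.

Per-block stimulus counts are exact (a fixed multiset is shuffled), so the
stated proportions hold in every single block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RATIOS = (0.75, 0.50, 0.25)
COLOR_FEATURES = ("green", "purple")
ORIENT_FEATURES = ("tilt_left", "tilt_right")

# De Bruijn alphabet for Exp 3: four target types + four absent placeholders.
DEBRUIJN_TARGETS = ("green", "purple", "tilt_left", "tilt_right")
N_LABELS = 8


@dataclass(frozen=True)
class SectionSpec:
    """Stimulus ratio of one section (u1 = present for Exp 1, color for Exp 2)."""
    ratio_u1: float

    def __post_init__(self):
        if not 0.0 < self.ratio_u1 < 1.0:
            raise ValueError("ratio must be in (0, 1)")


@dataclass(frozen=True)
class ExperimentDesign:
    experiment: str
    sections: tuple
    trials_per_block: int
    blocks_per_section: int


def exp1_design(section_order=RATIOS) -> ExperimentDesign:
    return ExperimentDesign("exp1_detection_blocked",
                            tuple(SectionSpec(r) for r in section_order), 40, 10)


def exp2_design(section_order=RATIOS) -> ExperimentDesign:
    return ExperimentDesign("exp2_dimension_discrimination",
                            tuple(SectionSpec(r) for r in section_order), 40, 10)


def exp3_design(n_blocks: int = 18) -> ExperimentDesign:
    return ExperimentDesign("exp3_detection_mixed",
                            (SectionSpec(0.5),), 65, n_blocks)


def _schedule_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["section", "block", "trial",
                       "target_present", "target_dimension", "target_feature"],
    )


def _features(rng, dimension, n):
    pool = COLOR_FEATURES if dimension == "color" else ORIENT_FEATURES
    return rng.choice(pool, size=n)


def generate_exp1_schedule(seed: int, section_order=RATIOS,
                           first_dimension: str = "color") -> pd.DataFrame:
    """Blocked-detection schedule: exact per-block present counts, blocks
    alternating color-only / orientation-only targets."""
    rng = np.random.default_rng(seed)
    rows = []
    dims = ("color", "orientation")
    start = 0 if first_dimension == "color" else 1
    block_global = 0
    for s, ratio in enumerate(section_order):
        n_present = round(ratio * 40)
        for b in range(10):
            dim = dims[(start + block_global) % 2]
            present = np.zeros(40, bool)
            present[:n_present] = True
            rng.shuffle(present)
            feats = _features(rng, dim, int(present.sum()))
            fi = 0
            for t in range(40):
                if present[t]:
                    rows.append((s, block_global, t, True, dim, feats[fi]))
                    fi += 1
                else:
                    rows.append((s, block_global, t, False, "none", "none"))
            block_global += 1
    return _schedule_frame(rows)


def generate_exp2_schedule(seed: int, section_order=RATIOS) -> pd.DataFrame:
    """Discrimination schedule: a target on every trial; exact per-block
    color-target counts at the section ratio."""
    rng = np.random.default_rng(seed)
    rows = []
    block_global = 0
    for s, ratio in enumerate(section_order):
        n_color = round(ratio * 40)
        for _ in range(10):
            is_color = np.zeros(40, bool)
            is_color[:n_color] = True
            rng.shuffle(is_color)
            for t in range(40):
                dim = "color" if is_color[t] else "orientation"
                feat = _features(rng, dim, 1)[0]
                rows.append((s, block_global, t, True, dim, feat))
            block_global += 1
    return _schedule_frame(rows)


def _random_eulerian_circuit(rng) -> list[int]:
    """Random Eulerian circuit on the complete digraph (with self-loops)
    over the 8 trial labels; Hierholzer with seeded edge order."""
    succ = {v: list(rng.permutation(N_LABELS)) for v in range(N_LABELS)}
    start = int(rng.integers(N_LABELS))
    stack, circuit = [start], []
    while stack:
        v = stack[-1]
        if succ[v]:
            stack.append(int(succ[v].pop()))
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit  # 65 vertices; 64 edges = every ordered pair once


def generate_exp3_block(seed: int) -> pd.DataFrame:
    """One 65-trial Exp-3 block from a linear order-2 De Bruijn sequence.

    Labels 0-3 are the four target types; labels 4-7 all map to the
    target-absent stimulus. Every ordered pair of the 8 labels occurs
    exactly once among consecutive trials, so each target type is followed
    exactly once by every label — hence equally often by each target type
    (itself included) and equally often by target-present as by
    target-absent trials.
    """
    rng = np.random.default_rng(seed)
    labels = _random_eulerian_circuit(rng)
    rows = []
    for t, lab in enumerate(labels):
        if lab < 4:
            feat = DEBRUIJN_TARGETS[lab]
            dim = "color" if feat in COLOR_FEATURES else "orientation"
            rows.append((0, 0, t, True, dim, feat))
        else:
            rows.append((0, 0, t, False, "none", "none"))
    return _schedule_frame(rows)


def generate_exp3_schedule(seed: int, n_blocks: int = 18) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    blocks = []
    for b in range(n_blocks):
        blk = generate_exp3_block(int(rng.integers(2**31 - 1)))
        blk["block"] = b
        blocks.append(blk)
    return pd.concat(blocks, ignore_index=True)


def generate_schedule(experiment: str, seed: int, **kwargs) -> pd.DataFrame:
    """Dispatch on experiment label; returns a stimulus schedule frame."""
    if experiment == "exp1_detection_blocked":
        return generate_exp1_schedule(seed, **kwargs)
    if experiment == "exp2_dimension_discrimination":
        return generate_exp2_schedule(seed, **kwargs)
    if experiment == "exp3_detection_mixed":
        return generate_exp3_schedule(seed, **kwargs)
    raise ValueError(f"unknown experiment: {experiment}")
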