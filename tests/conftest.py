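"""Shared fixtures and independent straight-loop reference implementations.

The oracles here deliberately use plain Python loops over the full trial
list, independent of the package's vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from distractor_learn import ExperimentDesign, TrialSequence, generate_sequence
from distractor_learn.models import RL_INITIAL_PREDICTION

N_LOC = 6


# ---------------------------------------------------------------------------
# straight-loop oracles


def _trial_tuples(seq: TrialSequence):
    f = seq.frame
    return list(zip(f["block"], f["distractor_present"] == 1,
                    f["distractor_location"]))


def oracle_accumulator(seq, b_distractor: float, reset: bool) -> list[float]:
    """1 - exp(-b * count) at the distractor's location, before updating."""
    counts = [0] * N_LOC
    preds, last_block = [], None
    for block, present, dloc in _trial_tuples(seq):
        if reset and block != last_block:
            counts = [0] * N_LOC
        last_block = block
        if present:
            preds.append(1.0 - math.exp(-b_distractor * counts[dloc]))
            counts[dloc] += 1
    return preds


def oracle_rl(seq, alpha: float, reset: bool) -> list[float]:
    """Delta-rule prediction at the distractor's location, before updating."""
    p = [RL_INITIAL_PREDICTION] * N_LOC
    preds, last_block = [], None
    for block, present, dloc in _trial_tuples(seq):
        if reset and block != last_block:
            p = [RL_INITIAL_PREDICTION] * N_LOC
        last_block = block
        if present:
            preds.append(p[dloc])
            for l in range(N_LOC):
                p[l] = p[l] + alpha * ((1.0 if l == dloc else 0.0) - p[l])
    return preds


def oracle_categorical(seq, reset: bool) -> list[float]:
    """1 iff the distractor is at a maximal-count location (ties included)."""
    counts = [0] * N_LOC
    preds, last_block = [], None
    for block, present, dloc in _trial_tuples(seq):
        if reset and block != last_block:
            counts = [0] * N_LOC
        last_block = block
        if present:
            preds.append(1.0 if counts[dloc] == max(counts) else 0.0)
            counts[dloc] += 1
    return preds


def make_sequence(trials, hp_location: int = 0,
                  trials_per_block: int | None = None) -> TrialSequence:
    """Hand-build a TrialSequence from (block, distractor_loc_or_None,
    target_loc) tuples, bypassing the generator's quota checks."""
    rows = []
    per_block: dict[int, int] = {}
    for g, (block, dloc, tloc) in enumerate(trials, start=1):
        per_block[block] = per_block.get(block, 0) + 1
        present = dloc is not None
        cond = ("ABS" if not present
                else ("HP" if dloc == hp_location else "LP"))
        rows.append({
            "block": block, "trial_in_block": per_block[block],
            "trial_global": g, "distractor_present": int(present),
            "distractor_location": dloc if present else -1,
            "target_location": tloc, "hp_location": hp_location,
            "singleton_color": "red", "condition": cond,
        })
    frame = pd.DataFrame(rows)
    design = ExperimentDesign(n_blocks=int(frame["block"].max()),
                              trials_per_block=trials_per_block
                              or int(frame["trial_in_block"].max()),
                              hp_location=hp_location)
    return TrialSequence(design=design, subject_id="hand", frame=frame)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def exp1_design():
    return ExperimentDesign.exp1(seed=123)


@pytest.fixture(scope="session")
def exp1_sequence(exp1_design):
    return generate_sequence(exp1_design, "s01")


@pytest.fixture(scope="session")
def one_block_design():
    return ExperimentDesign(n_blocks=1, trials_per_block=60, seed=7)


@pytest.fixture(scope="session")
def one_block_sequence(one_block_design):
    return generate_sequence(one_block_design, "s01")


@pytest.fixture(scope="session")
def two_block_sequence():
    return generate_sequence(
        ExperimentDesign(n_blocks=2, trials_per_block=60, seed=11), "s01")


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
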