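"""Per-subject behavioral data: a trial sequence plus RTs and accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign, TrialSequence


@dataclass
class SubjectData:
    """One subject's trial sequence with observed (or simulated) behavior.

    ``rt_ms`` are reaction times in milliseconds, NaN where unavailable;
    ``accuracy`` is a 0/1 flag per trial. Lengths match the sequence.
    """

    sequence: TrialSequence
    rt_ms: np.ndarray
    accuracy: np.ndarray

    def __post_init__(self):
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=int)
        n = self.sequence.n_trials
        if len(self.rt_ms) != n or len(self.accuracy) != n:
            raise ValueError(
                f"rt_ms/accuracy length must match the {n}-trial sequence")
        observed = self.rt_ms[np.isfinite(self.rt_ms)]
        if observed.size and (observed.min() <= 0 or observed.max() > 2000):
            raise ValueError("observed RTs must lie in (0, 2000] ms")

    @property
    def subject_id(self) -> str:
        return self.sequence.subject_id

    def to_frame(self) -> pd.DataFrame:
        return self.sequence.to_frame(rt_ms=self.rt_ms, accuracy=self.accuracy)


def read_trials_csv(path, design: ExperimentDesign | None = None) -> list[SubjectData]:
    """Load one or more subjects from the tidy trial CSV schema."""
    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("trial_global").reset_index(drop=True)
        seq = TrialSequence.from_frame(g, design=design)
        rt = pd.to_numeric(g.get("rt_ms"), errors="coerce").to_numpy(float)
        acc = pd.to_numeric(g.get("accuracy"), errors="coerce")
        acc = acc.fillna(1).to_numpy(int) if acc is not None else np.ones(len(g), int)
        out.append(SubjectData(sequence=seq, rt_ms=rt, accuracy=acc))
    return out


def write_trials_csv(path, subjects) -> None:
    frames = [s.to_frame() for s in subjects]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
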