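"""Synthetic behavioral datasets with the statistical structure the GLM assumes.

Subject-level parameters are independent Normal draws around a raw-space
group mean; RTs on the fitted (distractor-present, included) trials are the
model's linear prediction plus Gaussian noise, clipped to the task's
[200, 2000] ms response window. Accuracy labels are i.i.d. Bernoulli (the
task yields ~94-98% accuracy) unless a template is supplied.

Simulation builds the design matrix through the same code path as fitting —
including the per-subject z-scoring over included trials — so that fitting a
noise-free simulation recovers the generating coefficients exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SubjectData
from .design import ExperimentDesign, TrialSequence, generate_sequence
from .models import MODEL_SPECS, DesignBuilder, ParameterVector

RT_FLOOR_MS = 200.0
RT_CEIL_MS = 2000.0
DEFAULT_ACCURACY = 0.95


@dataclass(frozen=True)
class GroupSpec:
    """Raw-space group distribution generating one model's subjects."""

    model_id: int
    group_mean: np.ndarray
    group_sd: np.ndarray
    n_subjects: int = 17

    def __post_init__(self):
        object.__setattr__(self, "group_mean",
                           np.asarray(self.group_mean, float))
        object.__setattr__(self, "group_sd", np.asarray(self.group_sd, float))
        d = MODEL_SPECS[self.model_id].n_params
        if self.group_mean.shape != (d,) or self.group_sd.shape != (d,):
            raise ValueError(f"model {self.model_id} takes {d} raw parameters")
        if np.any(self.group_sd < 0):
            raise ValueError("group_sd must be non-negative")

    def to_dict(self) -> dict:
        return {"model_id": self.model_id,
                "group_mean": self.group_mean.tolist(),
                "group_sd": self.group_sd.tolist(),
                "n_subjects": self.n_subjects}

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSpec":
        return cls(model_id=int(d["model_id"]),
                   group_mean=d["group_mean"], group_sd=d["group_sd"],
                   n_subjects=int(d.get("n_subjects", 17)))


@dataclass(frozen=True)
class NoiseSpec:
    """Trial-noise standard deviations: one fixed value, or a pool assigned
    to subjects by sampling without replacement."""

    mode: str = "fixed"  # "fixed" | "per_subject"
    sd_ms: float | tuple[float, ...] = 50.0

    def __post_init__(self):
        if self.mode not in ("fixed", "per_subject"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        sds = np.atleast_1d(np.asarray(self.sd_ms, float))
        if np.any(sds <= 0):
            raise ValueError("noise SDs must be positive")
        if self.mode == "per_subject":
            object.__setattr__(self, "sd_ms", tuple(float(s) for s in sds))

    def subject_sds(self, n_subjects: int,
                    rng: np.random.Generator) -> np.ndarray:
        if self.mode == "fixed":
            return np.full(n_subjects, float(self.sd_ms))
        pool = np.asarray(self.sd_ms, float)
        if len(pool) < n_subjects:
            raise ValueError(
                f"noise pool has {len(pool)} values for {n_subjects} subjects")
        return rng.permutation(pool)[:n_subjects]


@dataclass
class SimulatedDataset:
    subjects: list[SubjectData]
    generating_model: int
    generating_params: np.ndarray  # subjects x params, raw space
    seed: int | None = None


def draw_subject_params(spec: GroupSpec,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None) -> np.ndarray:
    """Independent Normal(group_mean, group_sd^2) raw draws per subject."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return spec.group_mean + spec.group_sd * rng.standard_normal(
        (spec.n_subjects, len(spec.group_mean)))


def simulate_rts(model_id: int, raw, seq: TrialSequence,
                 noise_sd_ms: float = 50.0,
                 accuracy_rate: float = DEFAULT_ACCURACY,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None,
                 accuracy=None) -> SubjectData:
    """Simulate one subject's RTs from a model on a trial sequence.

    Distractor-present included trials get mu = X @ beta plus Gaussian noise;
    everything is clipped to [200, 2000] ms. Distractor-absent and excluded
    trials receive placeholder RTs from the intercept (plus the global-decay
    term where the model has one); they never enter fitting.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pv = ParameterVector(model_id, raw)
    nat = pv.natural
    n = seq.n_trials
    if accuracy is None:
        accuracy = (rng.random(n) < accuracy_rate).astype(int)
    else:
        accuracy = np.asarray(accuracy, int)

    builder = DesignBuilder(model_id, seq, rt_ms=None, accuracy=accuracy)
    dm = builder.matrix(nat)
    mu = dm.X @ pv.betas  # seconds

    rt_s = np.empty(n)
    base = nat["beta_intercept"]
    if "global_decay" in dm.columns:
        # decay level at any trial: exp(-b * number of past present trials),
        # standardized with the included-row statistics
        present = seq.frame["distractor_present"].to_numpy() == 1
        n_past_present = np.cumsum(present) - present
        level = np.exp(-nat["b_global"] * n_past_present)
        m, sd = dm.z_stats["global_decay"]
        z = (level - m) / sd if sd > 0 else level - m
        rt_s[:] = base + nat["beta_global_decay"] * z
    else:
        rt_s[:] = base
    rt_s[dm.included] = mu
    rt_s += rng.normal(0.0, noise_sd_ms / 1000.0, size=n)
    rt_ms = np.clip(rt_s * 1000.0, RT_FLOOR_MS, RT_CEIL_MS)
    return SubjectData(sequence=seq, rt_ms=rt_ms, accuracy=accuracy)


def simulate_group(spec: GroupSpec, design: ExperimentDesign,
                   noise: "NoiseSpec | float" = 50.0,
                   accuracy_rate: float = DEFAULT_ACCURACY,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None,
                   subject_prefix: str = "sim") -> SimulatedDataset:
    """Draw a group of subjects from ``spec``, give each a fresh trial
    sequence from ``design``, and simulate their RTs."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if not isinstance(noise, NoiseSpec):
        noise = NoiseSpec("fixed", float(noise))
    params = draw_subject_params(spec, rng)
    sds = noise.subject_sds(spec.n_subjects, rng)
    subjects = []
    for i in range(spec.n_subjects):
        sid = f"{subject_prefix}{i + 1:02d}"
        seq = generate_sequence(design, subject_id=sid, rng=rng.spawn(1)[0])
        subjects.append(simulate_rts(spec.model_id, params[i], seq,
                                     noise_sd_ms=sds[i],
                                     accuracy_rate=accuracy_rate, rng=rng))
    return SimulatedDataset(subjects=subjects, generating_model=spec.model_id,
                            generating_params=params, seed=seed)
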