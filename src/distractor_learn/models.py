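"""Candidate learning models of distractor suppression and their trial-level GLM.

Each model turns a trial sequence into a design matrix over the
distractor-present trials and predicts RT (in seconds) as a linear
combination of its regressors, with i.i.d. Gaussian residuals whose standard
deviation is profiled out at its maximum-likelihood value.

The nine models:

====  ==========================================================
 1    frequency accumulator with saturating decay, + global decay
 2    Rescorla-Wagner (delta-rule) prediction, + global decay
 3    categorical (argmax-of-counts) suppression, + global decay
 4-6  block-reset variants of 1-3
 7    trial-by-trial priming only (no learning), + global decay
 8/9  models 1/4 without the global decay regressor
====  ==========================================================

All learning states update on every distractor-present trial (GLM row
exclusions are measurement filters, not experience filters), and the
prediction entering trial *i*'s regressor reflects state through trial
*i − 1* only. The global-decay index counts distractor-present trials and
never resets across blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .design import TrialSequence

RL_INITIAL_PREDICTION = 0.16667  # uniform 1/6 starting estimate per location
PRIOR_MEAN = 0.0
PRIOR_VAR = 6.25  # raw-space Gaussian prior for every free parameter


class DegenerateDesignError(ValueError):
    """Too few included trials to fit the model's design matrix."""


class DegenerateLikelihoodError(ValueError):
    """Residuals identically zero; the Gaussian likelihood is unbounded."""


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    state: str | None       # "accumulator" | "rl" | None
    regressor: str | None   # "graded" | "categorical" | None
    reset_per_block: bool
    global_decay: bool
    repetition: bool = False

    @property
    def columns(self) -> tuple[str, ...]:
        cols = ["intercept"]
        if self.global_decay:
            cols.append("global_decay")
        if self.regressor == "graded":
            cols.append("distractor_prediction")
        elif self.regressor == "categorical":
            cols.append("categorical")
        cols.append("prev_absent")
        if self.repetition:
            cols.append("repetition")
        return tuple(cols)

    @property
    def nonlinear_names(self) -> tuple[str, ...]:
        names = []
        if self.global_decay:
            names.append("b_global")
        # the categorical regressor is parameter-free: the argmax of the
        # counts is invariant to the accumulator's decay rate
        if self.regressor == "graded":
            if self.state == "accumulator":
                names.append("b_distractor")
            elif self.state == "rl":
                names.append("alpha")
        return tuple(names)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.nonlinear_names + tuple(f"beta_{c}" for c in self.columns)

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, "accumulator", "graded", False, True),
    2: ModelSpec(2, "rl", "graded", False, True),
    3: ModelSpec(3, "accumulator", "categorical", False, True),
    4: ModelSpec(4, "accumulator", "graded", True, True),
    5: ModelSpec(5, "rl", "graded", True, True),
    6: ModelSpec(6, "accumulator", "categorical", True, True),
    7: ModelSpec(7, None, None, False, True, repetition=True),
    8: ModelSpec(8, "accumulator", "graded", False, False),
    9: ModelSpec(9, "accumulator", "graded", True, False),
}

MODEL_IDS = tuple(MODEL_SPECS)


def n_free_params(model_id: int) -> int:
    return MODEL_SPECS[model_id].n_params


@dataclass(frozen=True)
class ParameterVector:
    """Raw (unconstrained) parameters for one model.

    Raw order: nonlinear parameters (see ``ModelSpec.nonlinear_names``)
    followed by the GLM coefficients in column order. Transforms to natural
    space: rates ``b_* = exp(raw)``, learning rate ``alpha = logistic(raw)``,
    betas are identity (units: seconds).
    """

    model_id: int
    raw: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        spec = MODEL_SPECS[self.model_id]
        if self.raw.shape != (spec.n_params,):
            raise ValueError(
                f"model {self.model_id} takes {spec.n_params} raw parameters "
                f"({', '.join(spec.parameter_names)}); got {self.raw.shape}")

    @property
    def spec(self) -> ModelSpec:
        return MODEL_SPECS[self.model_id]

    @property
    def natural(self) -> dict[str, float]:
        spec = self.spec
        out: dict[str, float] = {}
        for name, v in zip(spec.nonlinear_names, self.raw):
            out[name] = float(np.exp(v)) if name.startswith("b_") else float(expit(v))
        for name, v in zip(spec.columns, self.raw[len(spec.nonlinear_names):]):
            out[f"beta_{name}"] = float(v)
        return out

    @property
    def betas(self) -> np.ndarray:
        return self.raw[len(self.spec.nonlinear_names):]

    @classmethod
    def from_natural(cls, model_id: int, natural: dict) -> "ParameterVector":
        spec = MODEL_SPECS[model_id]
        raw = []
        for name in spec.nonlinear_names:
            v = float(natural[name])
            raw.append(np.log(v) if name.startswith("b_")
                       else np.log(v / (1.0 - v)))
        raw += [float(natural[f"beta_{c}"]) for c in spec.columns]
        return cls(model_id, np.array(raw))


# ---------------------------------------------------------------------------
# per-sequence caches of parameter-free structure


class PresentTrials:
    """Parameter-free quantities over the distractor-present trials of one
    sequence, from which every model's regressors are cheap to assemble."""

    def __init__(self, seq: TrialSequence):
        f = seq.frame
        present = f["distractor_present"].to_numpy() == 1
        self.n_locations = seq.design.n_locations
        self.index_global = np.flatnonzero(present)
        self.loc = f["distractor_location"].to_numpy()[present]
        self.block = f["block"].to_numpy()[present]
        self.trial_in_block = f["trial_in_block"].to_numpy()[present]
        self.n = len(self.loc)

        dloc_all = f["distractor_location"].to_numpy()
        prev_present = np.concatenate([[False], present[:-1]])
        prev_loc = np.concatenate([[-9], dloc_all[:-1]])
        # first trial overall carries no previous-trial label; it is excluded
        # from fitting anyway (first trial of its block)
        self.prev_absent = (~prev_present)[present].astype(float)
        self.repetition = (prev_present[present]
                           & (prev_loc[present] == self.loc)).astype(float)

        onehot = (self.loc[:, None] == np.arange(self.n_locations)).astype(np.int64)
        counts_after = np.cumsum(onehot, axis=0)
        self.counts_before = counts_after - onehot  # counts through trial i-1
        # block-reset counts: subtract the running count at each block start
        starts = np.flatnonzero(np.concatenate(
            [[True], self.block[1:] != self.block[:-1]]))
        self.block_starts = starts
        base = np.repeat(self.counts_before[starts], np.diff(
            np.append(starts, self.n)), axis=0)
        self.counts_before_reset = self.counts_before - base
        self.onehot = onehot.astype(float)
        self._rows = np.arange(self.n)
        self._reset_segs = np.append(starts, self.n)

    def c_prev(self, reset: bool) -> np.ndarray:
        C = self.counts_before_reset if reset else self.counts_before
        return C[np.arange(self.n), self.loc]

    def categorical(self, reset: bool) -> np.ndarray:
        C = self.counts_before_reset if reset else self.counts_before
        own = C[np.arange(self.n), self.loc]
        return (own == C.max(axis=1)).astype(float)

    def rl_own_prediction(self, alpha: float, reset: bool,
                          with_grad: bool = False):
        """Delta-rule prediction at each trial's distractor location, using
        state through the previous present trial; all locations start at
        ``RL_INITIAL_PREDICTION`` (reset variants re-initialize per block).

        With ``with_grad`` also returns the derivative of the prediction with
        respect to the learning rate (the recursion
        ds_i = (1 - alpha) * ds_{i-1} + (Dist_i - pDist_{i-1}))."""
        onehot = self.onehot
        segs = self._reset_segs if reset else np.array([0, self.n])
        before = np.empty((self.n, self.n_locations))
        a_coef = [1.0, -(1.0 - alpha)]
        for s, e in zip(segs[:-1], segs[1:]):
            zi = np.full((1, self.n_locations),
                         (1.0 - alpha) * RL_INITIAL_PREDICTION)
            out, _ = lfilter([alpha], a_coef, onehot[s:e], axis=0, zi=zi)
            before[s] = RL_INITIAL_PREDICTION
            before[s + 1:e] = out[:-1]
        pred = before[self._rows, self.loc]
        if not with_grad:
            return pred
        dbefore = np.empty_like(before)
        for s, e in zip(segs[:-1], segs[1:]):
            w = onehot[s:e] - before[s:e]
            out, _ = lfilter([1.0], a_coef, w, axis=0,
                             zi=np.zeros((1, self.n_locations)))
            dbefore[s] = 0.0
            dbefore[s + 1:e] = out[:-1]
        return pred, dbefore[self._rows, self.loc]


def _z_score(col: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = col.mean()
    sd = col.std()
    if sd < 1e-12:
        # constant column: leave it centered rather than dividing by ~0
        return col - m, m, 0.0
    return (col - m) / sd, m, sd


# ---------------------------------------------------------------------------
# public regressor operations


def global_decay_regressor(n_present: int, b_global: float) -> np.ndarray:
    """exp(-b_global * (i - 1)) over 1-based present-trial indices i;
    equals 1 on the first distractor-present trial."""
    if n_present < 1:
        raise ValueError("need at least one distractor-present trial")
    return np.exp(-b_global * np.arange(n_present, dtype=float))


def accumulator_predictions(seq: TrialSequence, b_distractor: float,
                            reset_per_block: bool = False) -> np.ndarray:
    """Saturating frequency prediction 1 - exp(-b * count) at each present
    trial's distractor location, counts through the previous trial."""
    pt = PresentTrials(seq)
    return 1.0 - np.exp(-b_distractor * pt.c_prev(reset_per_block))


def rl_predictions(seq: TrialSequence, alpha: float,
                   reset_per_block: bool = False) -> np.ndarray:
    """Delta-rule prediction at each present trial's distractor location."""
    pt = PresentTrials(seq)
    return pt.rl_own_prediction(alpha, reset_per_block)


def categorical_regressor(seq: TrialSequence,
                          reset_per_block: bool = False) -> np.ndarray:
    """1 when the distractor sits at a location of maximal accumulated count
    (ties included), else 0. Parameter-free: the argmax of the counts equals
    the argmax of any monotone transform of them."""
    pt = PresentTrials(seq)
    return pt.categorical(reset_per_block)


def priming_regressors(seq: TrialSequence) -> tuple[np.ndarray, np.ndarray]:
    """(prev_absent, repetition) dummies over distractor-present trials."""
    pt = PresentTrials(seq)
    return pt.prev_absent.copy(), pt.repetition.copy()


# ---------------------------------------------------------------------------
# design matrix & likelihood


@dataclass
class DesignMatrix:
    """Standardized regressor matrix over the included present trials."""

    model_id: int
    X: np.ndarray
    columns: tuple[str, ...]
    included: np.ndarray        # global trial indices of the rows
    present_index: np.ndarray   # 1-based present-trial index of the rows
    z_stats: dict[str, tuple[float, float]]
    inclusion_mask: np.ndarray  # over all trials


class DesignBuilder:
    """Assembles a model's design matrix for one subject, caching everything
    that does not depend on the free parameters. Used both for fitting and
    for simulation so the two are exact inverses."""

    def __init__(self, model_id: int, seq: TrialSequence,
                 rt_ms: np.ndarray | None = None,
                 accuracy: np.ndarray | None = None):
        self.model_id = model_id
        self.spec = MODEL_SPECS[model_id]
        self.seq = seq
        self.pt = PresentTrials(seq)
        pt = self.pt

        keep = pt.trial_in_block > 1  # first trial of each block
        if accuracy is not None:
            keep &= np.asarray(accuracy)[pt.index_global].astype(bool)
        if rt_ms is not None:
            rt = np.asarray(rt_ms, float)[pt.index_global]
            keep &= np.isfinite(rt) & (rt >= 200.0)
        self.keep = keep
        self.included = pt.index_global[keep]
        self.present_index = np.flatnonzero(keep) + 1  # 1-based over present
        n_rows, n_cols = int(keep.sum()), len(self.spec.columns)
        if n_rows < n_cols + 2:
            raise DegenerateDesignError(
                f"model {model_id}: {n_rows} included trials for "
                f"{n_cols} regressors")
        self.n_rows = n_rows

        # parameter-free columns, already sliced to included rows
        self._fixed: dict[str, np.ndarray] = {
            "intercept": np.ones(n_rows),
            "prev_absent": pt.prev_absent[keep],
        }
        if self.spec.repetition:
            self._fixed["repetition"] = pt.repetition[keep]
        if self.spec.regressor == "categorical":
            self._fixed["categorical"] = pt.categorical(
                self.spec.reset_per_block)[keep]
        if self.spec.state == "accumulator" and self.spec.regressor == "graded":
            self._c_prev = pt.c_prev(self.spec.reset_per_block)[keep]
        self._decay_exponent = np.arange(pt.n, dtype=float)[keep]

        mask = np.zeros(seq.n_trials, dtype=bool)
        mask[self.included] = True
        self.inclusion_mask = mask

        # preallocated matrix with the fixed columns already in place
        self._X = np.empty((n_rows, n_cols))
        self._dynamic: list[tuple[int, str]] = []
        for j, name in enumerate(self.spec.columns):
            if name in self._fixed:
                self._X[:, j] = self._fixed[name]
            else:
                self._dynamic.append((j, name))

    def matrix_values(self, natural: dict[str, float],
                      z_stats: dict | None = None) -> np.ndarray:
        """Fill and return the design-matrix array for the given natural
        parameters. The returned buffer is reused across calls."""
        spec = self.spec
        X = self._X
        for j, name in self._dynamic:
            if name == "global_decay":
                raw = np.exp(-natural["b_global"] * self._decay_exponent)
            elif spec.state == "accumulator":
                raw = 1.0 - np.exp(-natural["b_distractor"] * self._c_prev)
            else:
                raw = self.pt.rl_own_prediction(
                    natural["alpha"], spec.reset_per_block)[self.keep]
            z, m, sd = _z_score(raw)
            if z_stats is not None:
                z_stats[name] = (m, sd)
            X[:, j] = z
        return X

    def matrix_values_grad(self, natural: dict[str, float]
                           ) -> tuple[np.ndarray, dict]:
        """Design matrix plus, for each parameter-dependent column, the
        derivative of the (standardized) column with respect to its natural
        parameter, keyed by ``natural_name -> (column_index, dcol)``."""
        spec = self.spec
        X = self._X
        grads: dict[str, tuple[int, np.ndarray]] = {}
        n = self.n_rows
        for j, name in self._dynamic:
            if name == "global_decay":
                x = np.exp(-natural["b_global"] * self._decay_exponent)
                dx = -self._decay_exponent * x
                nat_name = "b_global"
            elif spec.state == "accumulator":
                e = np.exp(-natural["b_distractor"] * self._c_prev)
                x = 1.0 - e
                dx = self._c_prev * e
                nat_name = "b_distractor"
            else:
                x, dx = self.pt.rl_own_prediction(
                    natural["alpha"], spec.reset_per_block, with_grad=True)
                x, dx = x[self.keep], dx[self.keep]
                nat_name = "alpha"
            m = x.mean()
            c = x - m
            sd = np.sqrt(c @ c / n)
            dc = dx - dx.mean()
            if sd < 1e-12:
                z, dz = c, dc
            else:
                z = c / sd
                dz = (dc - z * (z @ dc / n)) / sd
            X[:, j] = z
            grads[nat_name] = (j, dz)
        return X, grads

    def matrix(self, natural: dict[str, float]) -> DesignMatrix:
        z_stats: dict[str, tuple[float, float]] = {}
        X = self.matrix_values(natural, z_stats).copy()
        return DesignMatrix(self.model_id, X, self.spec.columns,
                            self.included, self.present_index, z_stats,
                            self.inclusion_mask)


def build_design_matrix(params: ParameterVector, seq: TrialSequence,
                        rt_ms=None, accuracy=None) -> DesignMatrix:
    """Model's design matrix over the included distractor-present trials.

    Rows exclude the first trial of each block and (when ``rt_ms`` /
    ``accuracy`` are given) inaccurate trials and RTs below 200 ms. The
    global-decay and graded-prediction columns are z-scored over the included
    rows; dummy columns are left as 0/1.
    """
    return DesignBuilder(params.model_id, seq, rt_ms, accuracy).matrix(
        params.natural)


def predict_rt(X, betas) -> np.ndarray:
    """Linear predictor mu = X @ beta, in seconds."""
    if isinstance(X, DesignMatrix):
        X = X.X
    X = np.asarray(X, float)
    betas = np.asarray(betas, float)
    if X.shape[1] != betas.shape[0]:
        raise ValueError(f"design has {X.shape[1]} columns but "
                         f"{betas.shape[0]} coefficients were given")
    return X @ betas


def log_likelihood(y, mu) -> tuple[float, float]:
    """Gaussian log-likelihood with the residual SD profiled at its MLE.

    sigma_hat = sqrt(RSS / n);
    LL = -(n/2) * (1 + ln(2*pi)) - n * ln(sigma_hat).
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if y.shape != mu.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and mu must be equal-length vectors, n >= 2")
    n = len(y)
    rss = float(np.sum((y - mu) ** 2))
    if rss <= 0.0:
        raise DegenerateLikelihoodError("all residuals are zero")
    sigma_hat = np.sqrt(rss / n)
    ll = -(n / 2.0) * (1.0 + np.log(2.0 * np.pi)) - n * np.log(sigma_hat)
    return float(ll), float(sigma_hat)
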