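"""Descriptive behavioral summaries of real or simulated datasets.

RT summaries use accurate trials with RT >= 200 ms only; accuracy summaries
use all trials. All functions are pure: rerunning on the same data yields
identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SubjectData
from .design import circular_distance


class NotApplicableError(ValueError):
    """Analysis requires a schedule feature the dataset does not have."""


def _table(data: SubjectData) -> pd.DataFrame:
    f = data.sequence.frame.copy()
    f["rt_ms"] = data.rt_ms
    f["accuracy"] = data.accuracy
    f["rt_ok"] = (f["accuracy"] == 1) & np.isfinite(f["rt_ms"]) \
        & (f["rt_ms"] >= 200.0)
    f["distance"] = circular_distance(
        f["distractor_location"], f["hp_location"],
        data.sequence.design.n_locations)
    return f


def _mean(s: pd.Series) -> float:
    return float(s.mean()) if len(s) else float("nan")


@dataclass
class ConditionSummary:
    """Per-subject condition means. RT fields in ms; missing cells are NaN."""

    subject_id: str
    rt_mean: dict        # condition -> mean RT (HP / LP / ABS)
    accuracy_mean: dict  # condition -> mean accuracy, over all trials
    rt_by_distance: dict  # LP distance (1-3) -> mean RT
    rt_target_at_hp_absent: float
    rt_target_at_lp_absent: float
    rt_target_at_hp_lp_trials: float
    rt_target_at_lp_lp_trials: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subject_id": self.subject_id, "measure": "rt",
                 "condition": c, "value": v} for c, v in self.rt_mean.items()]
        rows += [{"subject_id": self.subject_id, "measure": "accuracy",
                  "condition": c, "value": v}
                 for c, v in self.accuracy_mean.items()]
        rows += [{"subject_id": self.subject_id, "measure": "rt",
                  "condition": f"LP-{d}", "value": v}
                 for d, v in self.rt_by_distance.items()]
        rows += [{"subject_id": self.subject_id, "measure": "rt",
                  "condition": c, "value": v} for c, v in [
                     ("target_at_HP_absent", self.rt_target_at_hp_absent),
                     ("target_at_LP_absent", self.rt_target_at_lp_absent),
                     ("target_at_HP_lp", self.rt_target_at_hp_lp_trials),
                     ("target_at_LP_lp", self.rt_target_at_lp_lp_trials)]]
        return pd.DataFrame(rows)


def condition_means(data: SubjectData) -> ConditionSummary:
    """Mean RT and accuracy per distractor condition, LP means by distance
    from the HP location, and target-position means."""
    f = _table(data)
    ok = f[f["rt_ok"]]
    rt_mean = {c: _mean(ok.loc[ok["condition"] == c, "rt_ms"])
               for c in ("HP", "LP", "ABS")}
    accuracy_mean = {c: _mean(f.loc[f["condition"] == c, "accuracy"])
                     for c in ("HP", "LP", "ABS")}
    lp = ok[ok["condition"] == "LP"]
    rt_by_distance = {d: _mean(lp.loc[lp["distance"] == d, "rt_ms"])
                      for d in (1, 2, 3)}
    absent = ok[ok["condition"] == "ABS"]
    at_hp = absent["target_location"] == absent["hp_location"]
    lp_at_hp = lp["target_location"] == lp["hp_location"]
    return ConditionSummary(
        subject_id=data.subject_id,
        rt_mean=rt_mean,
        accuracy_mean=accuracy_mean,
        rt_by_distance=rt_by_distance,
        rt_target_at_hp_absent=_mean(absent.loc[at_hp, "rt_ms"]),
        rt_target_at_lp_absent=_mean(absent.loc[~at_hp, "rt_ms"]),
        rt_target_at_hp_lp_trials=_mean(lp.loc[lp_at_hp, "rt_ms"]),
        rt_target_at_lp_lp_trials=_mean(lp.loc[~lp_at_hp, "rt_ms"]),
    )


def gradient_slope(data: SubjectData) -> float:
    """Least-squares slope (ms per step) of the LP condition means over
    distance 1-3 from the HP location; NaN if any distance bin is empty."""
    means = condition_means(data).rt_by_distance
    y = np.array([means[1], means[2], means[3]])
    if not np.all(np.isfinite(y)):
        return float("nan")
    return float(np.polyfit([1.0, 2.0, 3.0], y, 1)[0])


def previous_trial_means(data: SubjectData) -> dict:
    """HP-trial RT means grouped by the preceding trial's condition.

    Excludes the first trial of each block and trials whose target location
    repeats the preceding trial's target (target repetitions are not equated
    across preceding conditions under the probability manipulation).
    """
    f = _table(data)
    prev_cond = f["condition"].shift()
    prev_target = f["target_location"].shift()
    keep = (f["rt_ok"] & (f["condition"] == "HP") & (f["trial_in_block"] > 1)
            & (f["target_location"] != prev_target))
    g = f[keep]
    pc = prev_cond[keep]
    return {c: _mean(g.loc[(pc == c).to_numpy(), "rt_ms"])
            for c in ("HP", "LP", "ABS")}


def last_hp_means(data: SubjectData) -> dict:
    """Changing schedule only: RT means for distractors at the current HP
    location vs the most recent previous HP location.

    Excludes the first epoch (no previous HP yet exists), distractors at
    locations never yet associated with high probability, and locations whose
    HP association predates the most recent previous epoch.
    """
    seq = data.sequence
    if seq.design.schedule != "changing":
        raise NotApplicableError("last-HP analysis requires a changing schedule")
    f = _table(data)
    hp = f["hp_location"].to_numpy()
    change = np.flatnonzero(np.concatenate([[True], hp[1:] != hp[:-1]]))
    epoch = np.cumsum(np.isin(np.arange(len(f)), change)) - 1
    epoch_hp = hp[change]  # HP location of each epoch in order
    prev_hp = np.full(len(f), -1)
    for e in range(1, len(change)):
        lo = change[e]
        hi = change[e + 1] if e + 1 < len(change) else len(f)
        prev_hp[lo:hi] = epoch_hp[e - 1]
    ok = f["rt_ok"].to_numpy() & (f["distractor_present"].to_numpy() == 1) \
        & (epoch >= 1)
    dloc = f["distractor_location"].to_numpy()
    cur = ok & (dloc == hp)
    last = ok & (dloc == prev_hp)
    rt = f["rt_ms"].to_numpy()
    return {"current_hp": _mean(pd.Series(rt[cur])),
            "last_hp": _mean(pd.Series(rt[last]))}


def bin_by_prediction(data: SubjectData, predictions,
                      n_bins: int = 4) -> pd.DataFrame:
    """Mean RT per quantile bin of model-derived distractor predictions.

    ``predictions`` align with the model's included distractor-present
    trials. Bins are rank-based with near-equal occupancy (differing by at
    most one trial); tied prediction values are assigned in trial order, so
    earlier trials fall in the lower bin. All-equal predictions collapse to a
    single bin with a warning.
    """
    from .models import DesignBuilder  # local import to avoid cycle

    pred = np.asarray(predictions, float)
    builder = DesignBuilder(1, data.sequence, rt_ms=data.rt_ms,
                            accuracy=data.accuracy)
    idx = builder.included
    if len(pred) != len(idx):
        raise ValueError(f"{len(pred)} predictions for {len(idx)} included "
                         "trials")
    if len(pred) < n_bins:
        raise ValueError(f"need at least {n_bins} included trials")
    rt = data.rt_ms[idx]
    if np.ptp(pred) == 0:
        warnings.warn("all predictions equal; returning a single bin")
        return pd.DataFrame({"bin": [1], "mean_rt_ms": [float(rt.mean())],
                             "n_trials": [len(rt)]})
    order = np.argsort(pred, kind="stable")
    ranks = np.empty(len(pred), dtype=int)
    ranks[order] = np.arange(len(pred))
    bins = (ranks * n_bins) // len(pred) + 1
    out = (pd.DataFrame({"bin": bins, "rt": rt})
           .groupby("bin")["rt"].agg(["mean", "size"]).reset_index())
    out.columns = ["bin", "mean_rt_ms", "n_trials"]
    return out


def summarize_dataset(subjects) -> dict[str, pd.DataFrame]:
    """Tidy per-subject tables for a list of subjects: condition means,
    gradient slopes, and previous-trial means (plus last-HP means when the
    schedule changes)."""
    cond = pd.concat([condition_means(s).to_frame() for s in subjects],
                     ignore_index=True)
    slopes = pd.DataFrame([{"subject_id": s.subject_id,
                            "slope_ms_per_step": gradient_slope(s)}
                           for s in subjects])
    prev = pd.DataFrame([{"subject_id": s.subject_id, **{
        f"prev_{k}": v for k, v in previous_trial_means(s).items()}}
        for s in subjects])
    out = {"condition_means": cond, "gradient_slopes": slopes,
           "previous_trial_means": prev}
    if subjects and subjects[0].sequence.design.schedule == "changing":
        out["last_hp_means"] = pd.DataFrame(
            [{"subject_id": s.subject_id, **last_hp_means(s)}
             for s in subjects])
    return out
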