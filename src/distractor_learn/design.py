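"""Trial-sequence generation for the additional-singleton distractor paradigm.

A search display has six locations on an imaginary ring. The target (a shape
singleton) appears at every location equally often within a block. On half of
the trials one non-target item is a color singleton (the distractor); on 2/3
of those trials the distractor occupies a single *high-probability* (HP)
location, with the remaining distractor-present trials split equally over the
five *low-probability* (LP) locations. Target position is counterbalanced so
that target-location repetitions cannot mimic the probability manipulation:
on HP-distractor trials the target never sits at the HP location, and on
exactly half of LP-distractor trials the target is placed *at* the HP
location in compensation.

Two schedules are supported: ``constant`` (one HP location throughout) and
``changing`` (the HP location moves every ``change_interval_trials`` trials so
that each location serves as HP exactly once).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

N_LOCATIONS = 6

CSV_COLUMNS = [
    "subject_id", "block", "trial_in_block", "trial_global",
    "distractor_present", "distractor_location", "target_location",
    "hp_location", "condition", "rt_ms", "accuracy",
]


class DesignError(ValueError):
    """An experiment design whose quotas cannot be realized exactly."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Counts and probabilities defining one subject's trial structure.

    Defaults reproduce the 8-block constant-probability experiment
    (480 trials; 240 distractor present, 160 of those at the HP location).
    """

    n_blocks: int = 8
    trials_per_block: int = 60
    p_present: float = 0.5
    p_high_given_present: float = 2.0 / 3.0
    schedule: str = "constant"  # "constant" | "changing"
    change_interval_trials: int | None = None
    #: constant schedule: HP location index. Changing schedule: explicit
    #: epoch->location order, or None for a seeded random order.
    hp_location: int | tuple[int, ...] | None = 0
    lp_target_mapping: str = "predefined"  # "predefined" | "random"
    seed: int = 0
    n_locations: int = N_LOCATIONS

    # -- convenience constructors ------------------------------------------
    @classmethod
    def exp1(cls, hp_location: int = 0, seed: int = 0) -> "ExperimentDesign":
        """Constant schedule, 8 blocks of 60, predefined LP target mapping."""
        return cls(n_blocks=8, trials_per_block=60, hp_location=hp_location,
                   seed=seed)

    @classmethod
    def exp2_constant(cls, hp_location: int = 0, seed: int = 0) -> "ExperimentDesign":
        """Constant schedule, 18 blocks of 60, randomized LP target mapping."""
        return cls(n_blocks=18, trials_per_block=60, hp_location=hp_location,
                   lp_target_mapping="random", seed=seed)

    @classmethod
    def exp2_changing(cls, seed: int = 0,
                      hp_order: Sequence[int] | None = None) -> "ExperimentDesign":
        """Changing schedule: HP location moves every 180 trials (3 blocks)."""
        return cls(n_blocks=18, trials_per_block=60, schedule="changing",
                   change_interval_trials=180,
                   hp_location=tuple(hp_order) if hp_order is not None else None,
                   lp_target_mapping="random", seed=seed)

    # -- derived counts ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def block_quotas(self) -> dict[str, int]:
        """Exact per-block counts; raises DesignError naming any violated
        integrality constraint."""
        tpb = self.trials_per_block
        L = self.n_locations

        def _integral(x: float, name: str) -> int:
            if abs(x - round(x)) > 1e-9:
                raise DesignError(f"{name} = {x} is not an integer")
            return int(round(x))

        if tpb % L:
            raise DesignError(
                f"trials_per_block = {tpb} not divisible by n_locations = {L}")
        n_present = _integral(self.p_present * tpb,
                              "p_present * trials_per_block")
        n_hp = _integral(self.p_high_given_present * n_present,
                         "p_high_given_present * present trials")
        n_lp = n_present - n_hp
        n_abs = tpb - n_present
        if n_abs % L:
            raise DesignError(f"absent-trial count {n_abs} not divisible by {L}")
        if n_hp % (L - 1):
            raise DesignError(
                f"HP-distractor count {n_hp} not divisible by {L - 1} "
                "(target balance on HP trials)")
        if n_lp % (2 * (L - 1)):
            raise DesignError(
                f"LP-distractor count {n_lp} not divisible by {2 * (L - 1)} "
                "(half target-at-HP, rest balanced over LP locations)")
        target_per_loc = tpb // L
        # target bookkeeping must close exactly
        if n_abs // L + n_lp // 2 != target_per_loc:
            raise DesignError("target count at the HP location does not balance")
        if n_abs // L + n_hp // (L - 1) + n_lp // (2 * (L - 1)) != target_per_loc:
            raise DesignError("target count at LP locations does not balance")
        return {
            "n_present": n_present, "n_hp": n_hp, "n_lp": n_lp,
            "n_absent": n_abs, "per_lp": n_lp // (L - 1),
            "target_per_loc": target_per_loc,
        }

    def validate(self) -> None:
        if self.schedule not in ("constant", "changing"):
            raise DesignError(f"unknown schedule {self.schedule!r}")
        if self.lp_target_mapping not in ("predefined", "random"):
            raise DesignError(
                f"unknown lp_target_mapping {self.lp_target_mapping!r}")
        self.block_quotas()
        if self.schedule == "constant":
            if not isinstance(self.hp_location, (int, np.integer)):
                raise DesignError("constant schedule requires an integer hp_location")
            if not 0 <= self.hp_location < self.n_locations:
                raise DesignError(f"hp_location {self.hp_location} out of range")
        else:
            iv = self.change_interval_trials
            if iv is None:
                raise DesignError("changing schedule requires change_interval_trials")
            if iv % self.trials_per_block:
                raise DesignError(
                    "change_interval_trials must be a whole number of blocks")
            if self.n_trials != self.n_locations * iv:
                raise DesignError(
                    "changing schedule requires n_blocks*trials_per_block == "
                    f"{self.n_locations} * change_interval_trials so every "
                    "location is HP exactly once")
            if self.hp_location is not None:
                order = tuple(self.hp_location)
                if sorted(order) != list(range(self.n_locations)):
                    raise DesignError(
                        "hp_location epoch order must be a permutation of all "
                        "locations")

    def to_dict(self) -> dict:
        d = {
            "n_blocks": self.n_blocks,
            "trials_per_block": self.trials_per_block,
            "p_present": self.p_present,
            "p_high_given_present": self.p_high_given_present,
            "schedule": self.schedule,
            "change_interval_trials": self.change_interval_trials,
            "hp_location": (list(self.hp_location)
                            if isinstance(self.hp_location, tuple)
                            else self.hp_location),
            "lp_target_mapping": self.lp_target_mapping,
            "seed": self.seed,
            "n_locations": self.n_locations,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        hp = d.get("hp_location")
        if isinstance(hp, list):
            d["hp_location"] = tuple(hp)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise DesignError(f"unknown design fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrialSequence:
    """An ordered set of trials for one subject, as a tidy DataFrame.

    Columns: block, trial_in_block, trial_global (all 1-based),
    distractor_present (0/1), distractor_location (0-5, -1 when absent),
    target_location, hp_location, singleton_color, condition (HP/LP/ABS).
    """

    design: ExperimentDesign
    subject_id: str
    frame: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def to_frame(self, rt_ms=None, accuracy=None) -> pd.DataFrame:
        """Trial CSV schema; distractor_location is NA on absent trials."""
        f = self.frame
        out = pd.DataFrame({
            "subject_id": self.subject_id,
            "block": f["block"],
            "trial_in_block": f["trial_in_block"],
            "trial_global": f["trial_global"],
            "distractor_present": f["distractor_present"],
            "distractor_location": f["distractor_location"].where(
                f["distractor_present"] == 1).astype("Int64"),
            "target_location": f["target_location"],
            "hp_location": f["hp_location"],
            "condition": f["condition"],
            "rt_ms": np.asarray(rt_ms, float) if rt_ms is not None else np.nan,
            "accuracy": (pd.array(np.asarray(accuracy, int), dtype="Int64")
                         if accuracy is not None else pd.NA),
        })
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   design: ExperimentDesign | None = None) -> "TrialSequence":
        subject_id = str(df["subject_id"].iloc[0]) if "subject_id" in df else "s"
        f = pd.DataFrame({
            "block": df["block"].astype(int),
            "trial_in_block": df["trial_in_block"].astype(int),
            "trial_global": df["trial_global"].astype(int),
            "distractor_present": df["distractor_present"].astype(int),
            "distractor_location": pd.to_numeric(
                df["distractor_location"], errors="coerce").fillna(-1).astype(int),
            "target_location": df["target_location"].astype(int),
            "hp_location": df["hp_location"].astype(int),
            "singleton_color": df.get("singleton_color", "red"),
            "condition": df["condition"],
        }).reset_index(drop=True)
        if design is None:
            schedule = ("changing" if f["hp_location"].nunique() > 1 else "constant")
            n_blocks = int(f["block"].max())
            tpb = int(f["trial_in_block"].max())
            if schedule == "constant":
                design = ExperimentDesign(n_blocks=n_blocks, trials_per_block=tpb,
                                          hp_location=int(f["hp_location"].iloc[0]))
            else:
                runs = f["hp_location"].ne(f["hp_location"].shift()).cumsum()
                interval = int(f.groupby(runs).size().iloc[0])
                order = tuple(f["hp_location"][runs.ne(runs.shift()).fillna(True)])
                design = ExperimentDesign(
                    n_blocks=n_blocks, trials_per_block=tpb, schedule="changing",
                    change_interval_trials=interval, hp_location=order,
                    lp_target_mapping="random")
        return cls(design=design, subject_id=subject_id, frame=f)


# ---------------------------------------------------------------------------
# generation


def _subject_seed(design_seed: int, subject_id: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([design_seed, zlib.crc32(str(subject_id).encode())])


def _derangement(items: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of ``items`` with no fixed point."""
    while True:
        p = rng.permutation(items)
        if np.all(p != items):
            return p


def _lp_target_permutation(lp_locs: np.ndarray, mapping: str,
                           rng: np.random.Generator) -> dict[int, int]:
    """Distractor->target assignment for the LP trials whose target is not at
    the HP location: a derangement of the LP locations, so each LP location
    receives exactly one target and the target never coincides with the
    distractor."""
    if mapping == "predefined":
        targets = np.roll(lp_locs, -1)  # fixed cyclic shift
    else:
        targets = _derangement(lp_locs, rng)
    return dict(zip(lp_locs.tolist(), targets.tolist()))


def generate_sequence(design: ExperimentDesign, subject_id: str = "s01",
                      rng: np.random.Generator | None = None) -> TrialSequence:
    """Generate one subject's trial sequence satisfying all count quotas.

    Reproducible: the RNG stream is derived from ``design.seed`` and
    ``subject_id`` unless an explicit generator is supplied.
    """
    design.validate()
    q = design.block_quotas()
    L = design.n_locations
    if rng is None:
        rng = np.random.default_rng(_subject_seed(design.seed, subject_id))

    # epoch -> HP location
    if design.schedule == "constant":
        hp_of_block = [int(design.hp_location)] * design.n_blocks
    else:
        if design.hp_location is None:
            order = rng.permutation(L)
        else:
            order = np.asarray(design.hp_location)
        blocks_per_epoch = design.change_interval_trials // design.trials_per_block
        hp_of_block = [int(order[b // blocks_per_epoch])
                       for b in range(design.n_blocks)]

    records: list[tuple] = []
    for b in range(1, design.n_blocks + 1):
        hp = hp_of_block[b - 1]
        lp_locs = np.array([l for l in range(L) if l != hp])
        rows: list[tuple[int, int]] = []  # (distractor_location or -1, target)
        for loc in range(L):
            rows += [(-1, loc)] * (q["n_absent"] // L)
        for t in lp_locs:
            rows += [(hp, int(t))] * (q["n_hp"] // (L - 1))
        m = q["n_lp"] // (2 * (L - 1))  # LP trials per location with target at HP
        for d in lp_locs:
            rows += [(int(d), hp)] * m
        for _ in range(m):
            perm = _lp_target_permutation(lp_locs, design.lp_target_mapping, rng)
            rows += [(int(d), perm[int(d)]) for d in lp_locs]
        assert len(rows) == design.trials_per_block
        order_idx = rng.permutation(len(rows))
        for j, idx in enumerate(order_idx, start=1):
            dloc, tloc = rows[idx]
            records.append((b, j, (b - 1) * design.trials_per_block + j,
                            int(dloc >= 0), dloc, tloc, hp))

    f = pd.DataFrame(records, columns=[
        "block", "trial_in_block", "trial_global", "distractor_present",
        "distractor_location", "target_location", "hp_location"])
    f["singleton_color"] = np.where(rng.random(len(f)) < 0.5, "red", "blue")
    f["condition"] = np.select(
        [f["distractor_present"] == 0, f["distractor_location"] == f["hp_location"]],
        ["ABS", "HP"], default="LP")
    return TrialSequence(design=design, subject_id=str(subject_id), frame=f)


# ---------------------------------------------------------------------------
# validation & labeling


def validate_sequence(seq: TrialSequence) -> list[str]:
    """Check every sequence invariant; return a report of violations
    (empty when the sequence is valid). Each entry names the block, the
    constraint, and observed vs expected counts."""
    design = seq.design
    try:
        q = design.block_quotas()
    except DesignError as e:
        return [f"design: {e}"]
    L = design.n_locations
    f = seq.frame
    report: list[str] = []

    coll = f[(f["distractor_present"] == 1)
             & (f["distractor_location"] == f["target_location"])]
    for t in coll["trial_global"]:
        report.append(f"trial {t}: distractor and target share a location")

    bad_hp = f[(f["condition"] == "HP")
               & (f["target_location"] == f["hp_location"])]
    for t in bad_hp["trial_global"]:
        report.append(f"trial {t}: target at the HP location on an HP trial")

    expect_cond = np.select(
        [f["distractor_present"] == 0,
         f["distractor_location"] == f["hp_location"]],
        ["ABS", "HP"], default="LP")
    for t in f.loc[f["condition"] != expect_cond, "trial_global"]:
        report.append(f"trial {t}: condition label inconsistent with locations")

    for b, g in f.groupby("block"):
        n_present = int((g["distractor_present"] == 1).sum())
        if n_present != q["n_present"]:
            report.append(f"block {b}: distractor-present count "
                          f"{n_present} != {q['n_present']}")
        n_hp = int((g["condition"] == "HP").sum())
        if n_hp != q["n_hp"]:
            report.append(f"block {b}: HP-distractor count {n_hp} != {q['n_hp']}")
        hp = int(g["hp_location"].iloc[0])
        lp = g[g["condition"] == "LP"]
        for l in range(L):
            if l == hp:
                continue
            c = int((lp["distractor_location"] == l).sum())
            if c != q["per_lp"]:
                report.append(f"block {b}: LP-distractor count at location {l} "
                              f"{c} != {q['per_lp']}")
        tc = g["target_location"].value_counts()
        for l in range(L):
            c = int(tc.get(l, 0))
            if c != q["target_per_loc"]:
                report.append(f"block {b}: target count at location {l} "
                              f"{c} != {q['target_per_loc']}")
        at_hp = int((lp["target_location"] == g["hp_location"].iloc[0]).sum())
        if 2 * at_hp != len(lp):
            report.append(f"block {b}: target-at-HP on LP trials {at_hp} != "
                          f"{len(lp) // 2} (half of {len(lp)})")

    if design.schedule == "changing":
        counts = f["hp_location"].value_counts()
        for l in range(L):
            c = int(counts.get(l, 0))
            if c != design.change_interval_trials:
                report.append(f"schedule: location {l} is HP on {c} trials != "
                              f"{design.change_interval_trials}")
    return report


def circular_distance(a, b, n_locations: int = N_LOCATIONS):
    """Minimal step count between two ring locations (0..n//2)."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % n_locations
    return np.minimum(d, n_locations - d)


def label_conditions(seq: TrialSequence) -> pd.DataFrame:
    """Per-trial condition label and distractor distance from the HP location
    (0 = HP, 1-3 = LP distances, NaN on absent trials)."""
    f = seq.frame
    dist = circular_distance(f["distractor_location"], f["hp_location"],
                             seq.design.n_locations).astype(float)
    dist[f["distractor_present"] == 0] = np.nan
    return pd.DataFrame({
        "trial_global": f["trial_global"],
        "condition": f["condition"],
        "distance_from_hp": dist,
    })
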