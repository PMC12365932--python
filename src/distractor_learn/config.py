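"""Pipeline configuration and the end-to-end run: design -> simulate -> fit
-> compare -> recover -> summarize, with one global seed deriving every
stage's randomness and every output stamped with the config hash and seed."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import write_trials_csv
from .design import ExperimentDesign
from .inference import fit_hierarchical
from .behavior import summarize_dataset
from .recovery import RecoveryConfig, run_recovery, summarize_recovery
from .simulate import GroupSpec, NoiseSpec, simulate_group

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A pipeline configuration field is missing or invalid."""


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_round_floats(payload), indent=1,
                                     default=_json_default) + "\n")


@dataclass
class PipelineConfig:
    design: ExperimentDesign
    models: tuple[int, ...]
    group_spec: GroupSpec
    noise: NoiseSpec = NoiseSpec("fixed", 50.0)
    n_recovery_simulations: int = 0   # 0 disables the recovery stage
    recovery_generating_models: tuple[int, ...] = ()
    recovery_group_specs: dict[int, GroupSpec] = field(default_factory=dict)
    max_hbi_iterations: int = 50
    n_restarts: int = 2
    exceedance_draws: int = 10 ** 5
    seed: int = 0

    def validate(self) -> None:
        from .models import MODEL_SPECS
        self.design.validate()
        for m in self.models:
            if m not in MODEL_SPECS:
                raise ConfigError(f"models: unknown model id {m}")
        if self.group_spec.model_id not in MODEL_SPECS:
            raise ConfigError(
                f"group_spec.model_id: unknown model id "
                f"{self.group_spec.model_id}")
        if self.n_recovery_simulations:
            for m in self.recovery_generating_models:
                if m not in self.recovery_group_specs:
                    raise ConfigError(
                        f"recovery_group_specs: no spec for model {m}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            design = ExperimentDesign.from_dict(d["design"])
            models = tuple(int(m) for m in d["models"])
            group_spec = GroupSpec.from_dict(d["group_spec"])
        except KeyError as e:
            raise ConfigError(f"missing required field {e.args[0]!r}") from e
        noise = d.get("noise", {"mode": "fixed", "sd_ms": 50.0})
        noise = NoiseSpec(noise.get("mode", "fixed"), noise.get("sd_ms", 50.0))
        rec_specs = {int(k): GroupSpec.from_dict(v)
                     for k, v in d.get("recovery_group_specs", {}).items()}
        cfg = cls(design=design, models=models, group_spec=group_spec,
                  noise=noise,
                  n_recovery_simulations=int(
                      d.get("n_recovery_simulations", 0)),
                  recovery_generating_models=tuple(
                      int(m) for m in d.get("recovery_generating_models", ())),
                  recovery_group_specs=rec_specs,
                  max_hbi_iterations=int(d.get("max_hbi_iterations", 50)),
                  n_restarts=int(d.get("n_restarts", 2)),
                  exceedance_draws=int(d.get("exceedance_draws", 10 ** 5)),
                  seed=int(d.get("seed", 0)))
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "models": list(self.models),
            "group_spec": self.group_spec.to_dict(),
            "noise": {"mode": self.noise.mode,
                      "sd_ms": (list(self.noise.sd_ms)
                                if isinstance(self.noise.sd_ms, tuple)
                                else self.noise.sd_ms)},
            "n_recovery_simulations": self.n_recovery_simulations,
            "recovery_generating_models": list(self.recovery_generating_models),
            "recovery_group_specs": {str(k): v.to_dict()
                                     for k, v in
                                     self.recovery_group_specs.items()},
            "max_hbi_iterations": self.max_hbi_iterations,
            "n_restarts": self.n_restarts,
            "exceedance_draws": self.exceedance_draws,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir,
                 seed: int | None = None) -> dict:
    """Execute all pipeline stages, writing CSV/JSON artifacts to
    ``out_dir``. Returns a manifest of stage outputs and timings."""
    config.validate()
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": seed}
    root = np.random.SeedSequence(seed)
    manifest: dict = dict(stamp)
    manifest["stages"] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)
        return time.perf_counter()

    try:
        t0 = _stage("simulate")
        sim_rng = np.random.default_rng(root.spawn(1)[0])
        ds = simulate_group(config.group_spec, config.design,
                            noise=config.noise, rng=sim_rng)
        write_trials_csv(out / "simulated_trials.csv", ds.subjects)
        manifest["stages"]["simulate"] = {
            "file": "simulated_trials.csv",
            "n_subjects": len(ds.subjects),
            "elapsed_s": time.perf_counter() - t0}

        t0 = _stage("fit")
        fit_rng = np.random.default_rng(root.spawn(1)[0])
        fit = fit_hierarchical(config.models, ds.subjects,
                               max_iterations=config.max_hbi_iterations,
                               n_restarts=config.n_restarts,
                               exceedance_draws=config.exceedance_draws,
                               rng=fit_rng)
        write_json(out / "fit.json", {**stamp, **fit.to_dict()})
        manifest["stages"]["fit"] = {
            "file": "fit.json", "converged": fit.converged,
            "n_iterations": fit.n_iterations,
            "elapsed_s": time.perf_counter() - t0}

        if config.n_recovery_simulations:
            t0 = _stage("recover")
            rc = RecoveryConfig(
                generating_models=config.recovery_generating_models,
                candidate_models=config.models,
                group_specs=config.recovery_group_specs,
                design=config.design,
                n_simulations=config.n_recovery_simulations,
                noise=config.noise,
                max_hbi_iterations=config.max_hbi_iterations,
                n_restarts=config.n_restarts,
                exceedance_draws=config.exceedance_draws)
            rec_rng = np.random.default_rng(root.spawn(1)[0])
            rr = run_recovery(rc, rng=rec_rng)
            summarize_recovery(rr.confusion).to_csv(
                out / "confusion.csv", index=False)
            manifest["stages"]["recover"] = {
                "file": "confusion.csv",
                "elapsed_s": time.perf_counter() - t0}

        t0 = _stage("summarize")
        for name, frame in summarize_dataset(ds.subjects).items():
            frame.to_csv(out / f"{name}.csv", index=False)
        manifest["stages"]["summarize"] = {
            "elapsed_s": time.perf_counter() - t0}
    except Exception as e:
        manifest["failed_stage"] = getattr(e, "stage", type(e).__name__)
        write_json(out / "manifest.json", manifest)
        raise

    write_json(out / "manifest.json", manifest)
    return manifest
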