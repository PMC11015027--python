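"""Run configuration, presets, checkpointing and the end-to-end ``run``.

A run is a pure function of (config, master seed) up to floating-point
reproducibility: every stochastic component draws from a named sub-stream of
the master seed (see :func:`snnl2l.utils.seed_stream`).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import training

__all__ = ["RunConfig", "PRESETS", "load_config", "run",
           "save_checkpoint", "load_checkpoint"]

_EXPERIMENTS = {
    "sinusoid": training.SinusoidExperiment,
    "arm": training.ArmExperiment,
    "pattern": training.PatternExperiment,
    "maze": training.MazeExperiment,
}


@dataclass
class RunConfig:
    """Declarative description of one outer-loop training run.

    ``experiment_kwargs`` are forwarded to the experiment constructor and
    therefore follow each task's parameter list (network size, SFA fraction,
    tau_a range, batch, learning rate, ...).
    """

    task: str = "sinusoid"
    iterations: int = 100
    seed: int = 0
    eval_episodes: int = 20
    checkpoint_every: int = 0
    out_dir: str | None = None
    experiment_kwargs: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.task not in _EXPERIMENTS:
            raise ValueError(f"unknown task {self.task!r}; "
                             f"choose from {sorted(_EXPERIMENTS)}")
        if self.iterations < 0 or self.eval_episodes < 0:
            raise ValueError("iterations and eval_episodes must be >= 0")
        if not isinstance(self.experiment_kwargs, dict):
            raise ValueError("experiment_kwargs must be a mapping")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig(**yaml.safe_load(Path(path).read_text())).validate()


#: the four full-scale reference configurations plus small desk-scale variants
PRESETS: dict[str, RunConfig] = {
    "sinusoid-full": RunConfig(task="sinusoid", iterations=5000, experiment_kwargs=dict(
        n_neurons=100, sfa_fraction=0.4, beta=1.6, tau_a_range=[1.0, 3000.0],
        n_steps=500, step_ms=20, batch=100, lr=1e-3, gamma=0.3)),
    "arm-full": RunConfig(task="arm", iterations=5000, experiment_kwargs=dict(
        n_neurons=600, sfa_fraction=0.5, beta=1.7, tau_a_range=[1.0, 600.0],
        episode_ms=30000, batch=80, lr=1e-3, gamma=0.3)),
    "maze-full": RunConfig(task="maze", iterations=20000, experiment_kwargs=dict(
        n_exc_lif=200, n_inh_lif=80, n_sfa=120, beta=1.7, tau_a=1200.0,
        connectivity=0.2, k_episodes=10, t_steps=2000, lr=0.01,
        lr_halving_every=5000, gamma=0.3)),
    "pattern-full": RunConfig(task="pattern", iterations=100000, experiment_kwargs=dict(
        n_neurons=300, sfa_fraction=0.5, beta=1.7, tau_a_range=[1.0, 1000.0],
        item_ms=100, batch=100, lr=1e-3, gamma=0.3)),
    "sinusoid-desk": RunConfig(task="sinusoid", iterations=200, experiment_kwargs=dict(
        n_neurons=80, sfa_fraction=0.4, beta=1.6, tau_a_range=[1.0, 3000.0],
        n_steps=100, step_ms=20, batch=20, lr=0.03, gamma=0.3)),
    "arm-desk": RunConfig(task="arm", iterations=5, experiment_kwargs=dict(
        n_neurons=100, sfa_fraction=0.5, beta=1.7, tau_a_range=[1.0, 600.0],
        episode_ms=1000, batch=4, lr=1e-3, gamma=0.3)),
    "maze-desk": RunConfig(task="maze", iterations=3, experiment_kwargs=dict(
        n_exc_lif=30, n_inh_lif=12, n_sfa=18, beta=1.7, tau_a=1200.0,
        connectivity=0.2, k_episodes=3, t_steps=200, lr=0.01, gamma=0.3)),
    "pattern-desk": RunConfig(task="pattern", iterations=5, experiment_kwargs=dict(
        n_neurons=60, sfa_fraction=0.5, beta=1.7, tau_a_range=[1.0, 1000.0],
        item_ms=50, batch=8, lr=1e-3, gamma=0.3)),
}


def load_config(preset: str | None = None, path=None, **overrides) -> RunConfig:
    if preset is not None:
        cfg = dataclasses.replace(PRESETS[preset])
        cfg.experiment_kwargs = dict(cfg.experiment_kwargs)
    elif path is not None:
        cfg = RunConfig.from_yaml(path)
    else:
        cfg = RunConfig()
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, v)
    return cfg.validate()


def build_experiment(cfg: RunConfig):
    return _EXPERIMENTS[cfg.task](seed=cfg.seed, **cfg.experiment_kwargs)


def save_checkpoint(path, experiment, iteration: int) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        experiment.model.weights.save(f.create_group("weights"))
        if experiment.model.nu is not None:
            f.create_dataset("nu", data=experiment.model.nu)
        f.attrs["iteration"] = iteration
        f.attrs["rng_states"] = json.dumps({
            name: getattr(experiment, name).bit_generator.state
            for name in ("rng_data", "rng_noise", "rng_eval")})
        opt = f.create_group("optimizer")
        st = experiment.optimizer.state_dict()
        opt.attrs["t"], opt.attrs["lr"] = st["t"], st["lr"]
        for slot in ("m", "v"):
            g = opt.create_group(slot)
            for k, arr in st[slot].items():
                g.create_dataset(k, data=arr)


def load_checkpoint(path, experiment) -> int:
    import h5py
    from .connectivity import WeightSet
    with h5py.File(path, "r") as f:
        ws = WeightSet.load(f["weights"])
        experiment.model.weights = ws
        if "nu" in f:
            experiment.model.nu = f["nu"][()]
        opt = f["optimizer"]
        experiment.optimizer.load_state_dict({
            "t": opt.attrs["t"], "lr": opt.attrs["lr"],
            "m": {k: opt["m"][k][()] for k in opt["m"]},
            "v": {k: opt["v"][k][()] for k in opt["v"]},
        })
        for name, state in json.loads(f.attrs["rng_states"]).items():
            getattr(experiment, name).bit_generator.state = state
        it = int(f.attrs["iteration"])
    experiment.iteration_count = it
    return it


def run(cfg: RunConfig, resume: bool = False) -> dict:
    """Train per config; write metrics (CSV + JSONL) and checkpoints if
    ``out_dir`` is set; returns the final metrics and evaluation."""
    import pandas as pd
    cfg.validate()
    exp = build_experiment(cfg)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    ckpt = out_dir / "checkpoint.h5" if out_dir else None
    start = 0
    if resume and ckpt is not None and ckpt.exists():
        start = load_checkpoint(ckpt, exp)
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out_dir / "config.yaml")
    jsonl = (out_dir / "metrics.jsonl").open("a") if out_dir else None
    for i in range(start, cfg.iterations):
        metrics = training.adam_outer_iteration(exp, exp.history)
        if jsonl:
            jsonl.write(json.dumps(metrics, default=float) + "\n")
        if (out_dir and cfg.checkpoint_every
                and (i + 1) % cfg.checkpoint_every == 0):
            save_checkpoint(ckpt, exp, i + 1)
    if jsonl:
        jsonl.close()
    evaluation = exp.evaluate(cfg.eval_episodes) if cfg.eval_episodes else {}
    evaluation = {k: v for k, v in evaluation.items() if np.isscalar(v)}
    if out_dir:
        if exp.history:
            pd.DataFrame(exp.history).to_csv(out_dir / "metrics.csv", index=False)
        save_checkpoint(ckpt, exp, cfg.iterations)
        (out_dir / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    final = exp.history[-1] if exp.history else {}
    return {"final_metrics": final, "evaluation": evaluation, "experiment": exp}
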