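"""Analysis instruments: internal-model probing and the linear baseline.

The internal-model probe visualizes what a frozen network state "believes"
the target function to be: from a stored mid-episode snapshot, each grid
input x is presented for one 20 ms step to a *copy* of the state and the
decoded output recorded — the resumable state is never touched.  The linear
baseline fits an ordinary least-squares line to the first half of each
sinusoid episode's analog (x, y) pairs and scores it on the second half.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import coding, tasks
from .neurons import NetworkState, simulate

__all__ = ["ProbeResult", "internal_model_probe", "linear_baseline",
           "linear_fit_predict", "evaluate_task"]


@dataclass
class ProbeResult:
    x_grid: np.ndarray
    y_probe: np.ndarray
    snapshot_id: int | None = None


def internal_model_probe(snapshot: NetworkState, experiment, x_grid=None,
                         feedback_value: float = 0.0,
                         rng: np.random.Generator | None = None,
                         snapshot_id: int | None = None) -> ProbeResult:
    """Decode the network's current input-output mapping without advancing it.

    ``snapshot`` must be a single-episode state (batch 1).  Each grid value
    is presented for one 20 ms step alongside ``feedback_value`` on the
    feedback channel; outputs are decoded exactly as in the task.  The
    snapshot is copied per grid point, so probing is free of side effects.
    """
    if x_grid is None:
        x_grid = np.linspace(-5.0, 5.0, 101)
    x_grid = np.asarray(x_grid, dtype=np.float64)
    rng = rng or np.random.default_rng(0)
    G = x_grid.size
    rep = NetworkState(
        v=np.repeat(snapshot.v, G, axis=0),
        a=np.repeat(snapshot.a, G, axis=0),
        refrac=np.repeat(snapshot.refrac, G, axis=0),
        x_buf=np.repeat(snapshot.x_buf, G, axis=1),
        z_buf=np.repeat(snapshot.z_buf, G, axis=1),
    )
    values = np.stack([x_grid, np.full(G, feedback_value)], axis=-1)[None]
    x_spikes = coding.encode_values(values, experiment.specs,
                                    experiment.step_ms, 1.0, rng)
    record = simulate(experiment.model.weights, experiment.model.neuron,
                      experiment.model.adapt, x_spikes, state=rep)
    y, _ = coding.mean_rate_decode(record.z, experiment.model.weights.w_out,
                                   experiment.model.weights.b_out,
                                   experiment.step_ms)
    return ProbeResult(x_grid=x_grid, y_probe=y[0, :, 0], snapshot_id=snapshot_id)


def linear_fit_predict(x: np.ndarray, y: np.ndarray,
                       x_test: np.ndarray) -> np.ndarray | None:
    """OLS slope + intercept fit; returns predictions or None if degenerate."""
    var = np.var(x)
    if var < 1e-300:
        return None
    slope = np.cov(x, y, bias=True)[0, 1] / var
    intercept = y.mean() - slope * x.mean()
    return slope * x_test + intercept


def linear_baseline(n_episodes: int = 5000,
                    seed: int | np.random.Generator = 0,
                    n_steps: int = 500) -> float:
    """Family-mean test MSE of the per-episode OLS baseline.

    Per episode: fit on the first half of the (x, y) pairs (analog values,
    no spike coding), mean squared error on the second half; average across
    episodes.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    half = n_steps // 2
    mses = []
    for _ in range(n_episodes):
        ep = tasks.regression_episode(tasks.sample_sinusoid_task(rng), rng, n_steps)
        pred = linear_fit_predict(ep["x"][:half], ep["target"][:half],
                                  ep["x"][half:])
        if pred is None:
            warnings.warn("degenerate episode skipped (constant inputs)")
            continue
        mses.append(np.mean((ep["target"][half:] - pred) ** 2))
    return float(np.mean(mses))


def evaluate_task(experiment, n_eval: int = 10,
                  rng: np.random.Generator | None = None) -> dict:
    """Family-appropriate held-out metrics for any trained experiment."""
    return experiment.evaluate(n_eval, rng) if not hasattr(
        experiment, "collect") else experiment.evaluate(rng=rng)
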