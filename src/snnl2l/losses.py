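"""Outer-loop loss functions and their readout-level gradients.

All losses are expectations over a batch of inner-loop episodes,
approximated by the batch mean.  The firing-rate regularizer
``coeff * (f_avg - f0)^2`` (f_avg = total spikes / (neurons * episode
seconds)) pushes networks toward sparse firing at the target rate f0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig", "PPOConfig",
    "firing_regularizer", "firing_regularizer_grad",
    "regression_loss", "arm_loss", "pattern_loss",
    "discounted_return", "gaussian_log_prob", "gaussian_entropy",
    "ppo_loss", "noisy_current",
]


@dataclass
class LossConfig:
    """Coefficients of the task losses and the firing regularizer."""

    lambda_reg: float = 30.0
    f0: float = 20.0
    mu_v: float = 1.0
    mu_e: float = 0.001
    mu_firing: float = 100.0

    def __post_init__(self) -> None:
        if min(self.lambda_reg, self.mu_v, self.mu_e, self.mu_firing) < 0:
            raise ValueError("loss coefficients must be non-negative")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


@dataclass
class PPOConfig:
    """Clipped-surrogate policy optimization settings for the maze task."""

    epsilon: float = 0.2
    eta: float = 0.99
    k_episodes: int = 10
    t_steps: int = 2000
    nu_init: float = 0.03

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise ValueError("discount eta must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("clip epsilon must be positive")


def _f_avg(z: np.ndarray, delta_t: float) -> np.ndarray:
    """Average firing rate (Hz) per episode; z is (T, B, n)."""
    T, B, n = z.shape
    duration_s = T * delta_t * 1e-3
    return z.sum(axis=(0, 2)) / (n * duration_s)


def firing_regularizer(z: np.ndarray, f0: float, coefficient: float,
                       delta_t: float = 1.0) -> float:
    """coeff * (f_avg - f0)^2, averaged over the batch."""
    return float(np.mean(coefficient * (_f_avg(z, delta_t) - f0) ** 2))


def firing_regularizer_grad(z: np.ndarray, f0: float, coefficient: float,
                            delta_t: float = 1.0) -> np.ndarray:
    """dL/dz for the batch-mean firing regularizer; shape of z."""
    T, B, n = z.shape
    duration_s = T * delta_t * 1e-3
    per_spike = 2.0 * coefficient * (_f_avg(z, delta_t) - f0) / (n * duration_s * B)
    return np.broadcast_to(per_spike[None, :, None], z.shape).copy()


def regression_loss(predictions: np.ndarray, targets: np.ndarray,
                    spikes: np.ndarray | None, cfg: LossConfig,
                    delta_t: float = 1.0) -> float:
    """Sum of squared per-step errors plus the firing term, batch-averaged.

    predictions (K, B) or (K, B, 1); targets (K, B).
    """
    pred = np.asarray(predictions)
    if pred.ndim == 3:
        pred = pred[..., 0]
    mse = np.sum((targets - pred) ** 2, axis=0).mean()
    reg = 0.0 if spikes is None else firing_regularizer(
        spikes, cfg.f0, cfg.lambda_reg, delta_t)
    return float(mse + reg)


def arm_loss(predicted: np.ndarray, true: np.ndarray,
             delta_t: float = 1.0) -> float:
    """Time-integral of the squared joint-angle error (sum over 1 ms steps).

    predicted / true: (T, B, 2); batch-averaged.
    """
    return float(np.sum((true - predicted) ** 2, axis=(0, 2)).mean() * delta_t)


def discounted_return(rewards: np.ndarray, eta: float,
                      t: int | None = None) -> np.ndarray | float:
    """R(t) = sum_{t' > t} eta^(t'-t) r(t') (strictly future rewards).

    rewards: (T,) or (T, B); returns the full array, or the value at ``t``.
    """
    r = np.asarray(rewards, dtype=np.float64)
    out = np.zeros_like(r)
    acc = np.zeros(r.shape[1:])
    for s in range(r.shape[0] - 2, -1, -1):
        acc = eta * (r[s + 1] + acc)
        out[s] = acc
    return out if t is None else out[t]


def gaussian_log_prob(a: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Diagonal-Gaussian log density, summed over the trailing axis."""
    return np.sum(-0.5 * ((a - mu) ** 2 / var + np.log(2.0 * np.pi * var)), axis=-1)


def gaussian_entropy(var: np.ndarray) -> np.ndarray:
    """Entropy 0.5 ln(2 pi e var) per coordinate, summed over the trailing axis."""
    return np.sum(0.5 * np.log(2.0 * np.pi * np.e * var), axis=-1)


def ppo_loss(actions: np.ndarray, mu: np.ndarray, var: np.ndarray,
             value: np.ndarray, log_prob_old: np.ndarray, returns: np.ndarray,
             value_old: np.ndarray, spikes: np.ndarray | None,
             ppo: PPOConfig, cfg: LossConfig, delta_t: float = 1.0,
             with_grads: bool = False):
    """Clipped-surrogate PPO loss over a trajectory buffer (time, episode).

    Advantage is R(t,k) - V_old(t,k) with finite-horizon discounted returns
    (no bootstrapping, no GAE); the value head is regressed onto the same
    returns; the entropy bonus uses the closed-form diagonal-Gaussian
    entropy.  With ``with_grads=True`` also returns dL/dy for the five
    readout channels, shape (T, B, 5).
    """
    log_prob = gaussian_log_prob(actions, mu, var)
    ratio = np.exp(log_prob - log_prob_old)
    adv = returns - value_old
    clipped = np.clip(ratio, 1.0 - ppo.epsilon, 1.0 + ppo.epsilon)
    surrogate = np.minimum(ratio * adv, clipped * adv)
    value_err = returns - value
    entropy = gaussian_entropy(var)
    loss = float(np.mean(-surrogate + cfg.mu_v * value_err ** 2 - cfg.mu_e * entropy))
    reg = 0.0 if spikes is None else firing_regularizer(
        spikes, cfg.f0, cfg.mu_firing, delta_t)
    loss += reg
    if not with_grads:
        return loss

    n_el = ratio.size
    active = (ratio * adv <= clipped * adv)
    g_ratio = np.where(active, -adv, 0.0) / n_el
    g_logp = g_ratio * ratio
    g_mu = g_logp[..., None] * (actions - mu) / var
    g_var = g_logp[..., None] * 0.5 * ((actions - mu) ** 2 / var ** 2 - 1.0 / var)
    g_var += -cfg.mu_e * (0.5 / var) / n_el
    g_value = 2.0 * cfg.mu_v * (value - returns) / n_el
    g_y = np.empty(mu.shape[:-1] + (5,))
    g_y[..., :2] = g_mu * (1.0 - mu ** 2)            # tanh'
    g_y[..., 2:4] = g_var * var * (1.0 - var)        # sigmoid'
    g_y[..., 4] = g_value
    return loss, g_y


def pattern_loss(probabilities: np.ndarray, targets: np.ndarray,
                 spikes: np.ndarray | None, cfg: LossConfig,
                 lambda_reg: float = 5.0, delta_t: float = 1.0,
                 eps: float = 1e-12) -> float:
    """Mean bitwise binary cross-entropy over phases B and D plus firing term.

    probabilities / targets: (n_items, ..., n_bits) covering both phases;
    the item mean is taken over the leading axes, the bit mean over the last.
    """
    p = np.clip(probabilities, eps, 1.0 - eps)
    y = targets
    ce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean(axis=-1)
    reg = 0.0 if spikes is None else firing_regularizer(
        spikes, cfg.f0, lambda_reg, delta_t)
    return float(ce.mean() + reg)


def noisy_current(drive: np.ndarray, nu: np.ndarray,
                  rng: np.random.Generator, r_m: float = 1.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Add per-step Gaussian current noise of std nu_j / R_m to each neuron.

    ``drive`` is the voltage-valued R_m * I, so the injected voltage noise has
    std nu_j.  Returns (noisy drive, unit-variance draws eps) so the noise
    path stays differentiable with respect to nu.
    """
    eps = rng.standard_normal(drive.shape)
    return drive + np.asarray(nu) * eps, eps
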