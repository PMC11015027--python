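"""Conversions between analog / bit / reward signals and spike trains.

Analog values are encoded with Gaussian population rate codes
(r_i = r_max exp(-(m_i - value)^2 / (2 sigma^2)) over evenly spaced preferred
values m_i) and sampled as independent Bernoulli spikes per 1 ms bin.
Decoders are linear readouts on either per-step mean firing rates (20 ms
windows), exponentially filtered spike traces, or non-spiking leaky
integrator "readout membrane potentials" (navigation task).  Each decoder
exposes the vector-Jacobian products needed by the outer-loop BPTT.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationCodeSpec",
    "population_rates",
    "rates_to_spikes",
    "encode_values",
    "bit_pattern_spikes",
    "reward_spikes",
    "mean_rate_decode",
    "mean_rate_decode_vjp",
    "trace_decode",
    "trace_decode_vjp",
    "leaky_readout",
    "leaky_readout_vjp",
    "policy_decode",
    "sample_action",
]


@dataclass
class PopulationCodeSpec:
    """Gaussian tuning-curve array for one analog channel."""

    n_neurons: int = 100
    value_min: float = -5.0
    value_max: float = 5.0
    r_max: float = 200.0
    sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.value_min >= self.value_max:
            raise ValueError("value_min must be below value_max")
        if self.r_max <= 0 or self.sigma <= 0:
            raise ValueError("r_max and sigma must be positive")

    @property
    def preferred(self) -> np.ndarray:
        return np.linspace(self.value_min, self.value_max, self.n_neurons)

    @staticmethod
    def maze_position() -> "PopulationCodeSpec":
        # rate = 500 * exp(-100 (xi_i - xi)^2)  <=>  sigma = 1/sqrt(200)
        return PopulationCodeSpec(n_neurons=40, value_min=-1.0, value_max=1.0,
                                  r_max=500.0, sigma=1.0 / np.sqrt(200.0))


def population_rates(value, spec: PopulationCodeSpec) -> np.ndarray:
    """Firing rate (Hz) per tuning neuron; ``value`` may carry batch axes.

    Out-of-range values are encoded by the same Gaussian (rates just decay);
    the code is translation-covariant in (value, centers).
    """
    value = np.asarray(value, dtype=np.float64)
    m = spec.preferred
    diff = m - value[..., None]
    return spec.r_max * np.exp(-(diff * diff) / (2.0 * spec.sigma**2))


def rates_to_spikes(rates: np.ndarray, duration_steps: int, delta_t: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Bernoulli spike sampling, p = min(rate * dt, 1) per bin.

    Returns (duration_steps, *rates.shape); deterministic given the
    generator state.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    p = np.minimum(rates * (delta_t * 1e-3), 1.0)
    return (rng.random((duration_steps,) + rates.shape) < p).astype(np.float64)


def encode_values(values: np.ndarray, specs, steps_per_value: int,
                  delta_t: float, rng: np.random.Generator) -> np.ndarray:
    """Encode a (K, batch, n_channels) value stream into (K*steps, batch, n_in) spikes.

    ``specs`` is one PopulationCodeSpec per channel; channel codes are
    concatenated along the neuron axis.
    """
    values = np.asarray(values, dtype=np.float64)
    K, B, C = values.shape
    rates = np.concatenate(
        [population_rates(values[:, :, c], specs[c]) for c in range(C)], axis=-1)
    spikes = rates_to_spikes(rates, steps_per_value, delta_t, rng)  # (S, K, B, n)
    return np.ascontiguousarray(
        np.moveaxis(spikes, 0, 1).reshape(K * steps_per_value, B, -1))


def bit_pattern_spikes(bits: np.ndarray, duration_steps: int,
                       rng: np.random.Generator, neurons_per_bit: int = 5,
                       rate_on: float = 200.0, rate_off: float = 2.0,
                       delta_t: float = 1.0) -> np.ndarray:
    """Binary vector -> spikes: 5 neurons per bit at 200 Hz (1) or 2 Hz (0)."""
    bits = np.asarray(bits)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be binary")
    rates = np.repeat(np.where(bits > 0, rate_on, rate_off), neurons_per_bit)
    return rates_to_spikes(rates, duration_steps, delta_t, rng)


def reward_spikes(reward: float, group_size: int = 40) -> np.ndarray:
    """Reward channel: group 1 fires in synchrony on +1, group 2 on -0.02."""
    out = np.zeros(2 * group_size)
    if reward == 1:
        out[:group_size] = 1.0
    elif reward == -0.02:
        out[group_size:] = 1.0
    elif reward != 0:
        raise ValueError(f"unexpected reward value {reward}")
    return out


# -- decoders -------------------------------------------------------------

def mean_rate_decode(z: np.ndarray, w_out: np.ndarray, b_out: np.ndarray,
                     window: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Per-window readout of mean firing rates.

    z: (T, B, n) with T = K * window.  Features are spike counts / window;
    returns (outputs (K, B, n_out), features (K, B, n)).
    """
    T, B, n = z.shape
    if T % window:
        raise ValueError("episode length must be a multiple of the step window")
    feats = z.reshape(T // window, window, B, n).sum(axis=1) / window
    return feats @ w_out.T + b_out, feats


def mean_rate_decode_vjp(g_y: np.ndarray, feats: np.ndarray, w_out: np.ndarray,
                         window: int = 20) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """VJP of mean_rate_decode: returns (g_z (T,B,n), g_w_out, g_b_out)."""
    K, B, n = feats.shape
    g_feats = g_y @ w_out                               # (K, B, n)
    g_z = np.repeat(g_feats / window, window, axis=0)
    g_w = np.einsum("kbo,kbn->on", g_y, feats)
    return g_z, g_w, g_y.sum(axis=(0, 1))


def trace_decode(z: np.ndarray, tau_trace: float, w_out: np.ndarray,
                 b_out: np.ndarray, delta_t: float = 1.0,
                 trace0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Readout on exponentially filtered spikes.

    trace(t) = trace(t - dt) * exp(-dt/tau) + z(t); returns
    (outputs (T, B, n_out), traces (T, B, n)).
    """
    kappa = np.exp(-delta_t / tau_trace)
    T = z.shape[0]
    traces = np.empty_like(z)
    prev = np.zeros(z.shape[1:]) if trace0 is None else trace0
    for t in range(T):
        prev = kappa * prev + z[t]
        traces[t] = prev
    return traces @ w_out.T + b_out, traces


def trace_decode_vjp(g_y: np.ndarray, traces: np.ndarray, tau_trace: float,
                     w_out: np.ndarray, delta_t: float = 1.0,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """VJP of trace_decode: reverse-filter the readout gradient onto spikes."""
    kappa = np.exp(-delta_t / tau_trace)
    g_tr = g_y @ w_out
    g_z = np.empty_like(g_tr)
    acc = np.zeros(g_tr.shape[1:])
    for t in range(g_tr.shape[0] - 1, -1, -1):
        acc = kappa * acc + g_tr[t]
        g_z[t] = acc
    g_w = np.einsum("tbo,tbn->on", g_y, traces)
    return g_z, g_w, g_y.sum(axis=(0, 1))


def leaky_readout(z: np.ndarray, w_out: np.ndarray, b_out: np.ndarray,
                  tau_out: float = 20.0, delta_t: float = 1.0,
                  ) -> np.ndarray:
    """Non-spiking leaky-integrator readout membrane potentials.

    y(t) = alpha_o y(t-dt) + (1 - alpha_o) (W_out z(t) + b), no reset.
    """
    alpha_o = np.exp(-delta_t / tau_out)
    drive = z @ w_out.T + b_out
    y = np.empty_like(drive)
    prev = np.zeros(drive.shape[1:])
    for t in range(drive.shape[0]):
        prev = alpha_o * prev + (1.0 - alpha_o) * drive[t]
        y[t] = prev
    return y


def leaky_readout_vjp(g_y: np.ndarray, z: np.ndarray, w_out: np.ndarray,
                      tau_out: float = 20.0, delta_t: float = 1.0,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """VJP of leaky_readout: returns (g_z, g_w_out, g_b_out)."""
    alpha_o = np.exp(-delta_t / tau_out)
    T = g_y.shape[0]
    u = np.empty_like(g_y)
    acc = np.zeros(g_y.shape[1:])
    for t in range(T - 1, -1, -1):
        acc = alpha_o * acc + g_y[t]
        u[t] = acc
    g_drive = (1.0 - alpha_o) * u
    g_z = g_drive @ w_out
    g_w = np.einsum("tbo,tbn->on", g_drive, z)
    return g_z, g_w, g_drive.sum(axis=(0, 1))


# -- policy head ----------------------------------------------------------

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def policy_decode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Readout potentials (..., 5) -> (action mean (...,2), variances (...,2), value).

    mu = tanh(y1, y2); variances phi = sigmoid(y3, y4); value = y5.
    """
    y = np.asarray(y, dtype=np.float64)
    return np.tanh(y[..., :2]), _sigmoid(y[..., 2:4]), y[..., 4]


def sample_action(mu: np.ndarray, var: np.ndarray, rng: np.random.Generator,
                  a_scale: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Sample a ~ N(mu, var) coordinate-wise; returns (action, velocity).

    velocity = a_scale * a, clipped to Euclidean norm <= a_scale.
    """
    a = mu + np.sqrt(var) * rng.standard_normal(mu.shape)
    vel = a_scale * a
    norm = np.linalg.norm(vel, axis=-1, keepdims=True)
    scale = np.where(norm > a_scale, a_scale / np.maximum(norm, 1e-300), 1.0)
    return a, vel * scale
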