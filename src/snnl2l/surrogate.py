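"""Reverse-mode differentiation of the unrolled spiking simulation.

The spike nonlinearity z = H(V - A) is non-differentiable; during the
backward pass it is assigned the dampened pseudo-derivative

    dz/dv_norm = gamma * max(0, 1 - |v_norm|),   v_norm = (V - A) / A,

applied wherever z appears in the graph (including the subtractive reset
term, which is the same Heaviside node).  The adaptation recursion
a(t+dt) = rho a(t) + (1-rho) z(t) is linear in its hidden variable and is
differentiated exactly — no dampening on the rho path.  The refractory
countdown is treated as a non-differentiable constant gate.

The backward pass consumes the forward :class:`~snnl2l.neurons.EpisodeRecord`
plus per-step direct loss gradients and returns gradients for W_in, W_rec
(and the per-neuron noise scale nu when a noise drive was injected).
Gradients with respect to readout weights are produced by the decoders that
own them (see :mod:`snnl2l.coding`), since readout features are plain
functions of the recorded spikes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neurons import AdaptationParams, EpisodeRecord, NeuronParams

__all__ = ["SurrogateConfig", "pseudo_derivative", "backward", "EpisodeGradients"]


@dataclass
class SurrogateConfig:
    """Dampening factor for backpropagation through spikes."""

    gamma: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")


def pseudo_derivative(v_norm: np.ndarray, gamma: float) -> np.ndarray:
    """Triangular surrogate gamma * max(0, 1 - |v_norm|)."""
    return gamma * np.maximum(0.0, 1.0 - np.abs(v_norm))


@dataclass
class EpisodeGradients:
    """Gradient container for one batched episode (summed over the batch)."""

    w_in: np.ndarray
    w_rec: np.ndarray
    nu: np.ndarray | None = None


def backward(record: EpisodeRecord, weights, params: NeuronParams,
             adapt: AdaptationParams, g_z: np.ndarray | None,
             gamma: float = 0.3, g_v: np.ndarray | None = None,
             noise_eps: np.ndarray | None = None) -> EpisodeGradients:
    """Exact reverse-mode pass over the recorded episode.

    Parameters
    ----------
    g_z, g_v
        Direct loss gradients dL/dz(t) and dL/dV(t), shape (T, batch, n)
        (either may be ``None`` for zero).
    noise_eps
        Unit-variance noise draws (T, batch, n) if the forward drive included
        nu * eps; enables the gradient with respect to nu.

    Notes
    -----
    With lamV(t) = dL/dV(t) and lam_a(t) = dL/da(t) the reverse recursion is

        psi(t)  = g_z(t) - v_th lamV(t+1) + (1 - rho) lam_a(t+1)
                  + sum_d [(1-alpha) W_rec o (d_rec = d)]^T lamV(t+d+1)
        lamV(t) = alpha lamV(t+1) + psi(t) pd(t)/A(t) + g_v(t)
        lam_a(t) = rho lam_a(t+1) - psi(t) pd(t) beta V(t)/A(t)^2

    where pd(t) is the refractory-gated pseudo-derivative.  Weight gradients
    then accumulate lamV against the appropriately delayed spike histories.
    """
    z, v, a, gate = record.z, record.v, record.a, record.gate
    if v is None:
        raise ValueError("episode must be recorded with record=True")
    T, B, n = z.shape
    alpha = np.broadcast_to(np.asarray(params.alpha, dtype=np.float64), (n,))
    rho = np.broadcast_to(np.asarray(adapt.rho, dtype=np.float64), (n,))
    beta = np.broadcast_to(np.asarray(adapt.beta, dtype=np.float64), (n,))
    v_th = params.v_th

    A = v_th + beta * a
    v_norm = (v - A) / A
    pd = gate * pseudo_derivative(v_norm, gamma)
    dz_dv = pd / A
    dz_da = -pd * beta * v / (A * A)

    d_in, d_rec = weights.delay_arrays()
    d_max = int(max(d_in.max(), d_rec.max()))
    w_rec_d = [(int(d), np.ascontiguousarray((weights.w_rec * (d_rec == d)) * (1.0 - alpha)[:, None]))
               for d in np.unique(d_rec)]

    lam_v = np.zeros((T + d_max + 1, B, n))
    lam_a = np.zeros((B, n))
    for t in range(T - 1, -1, -1):
        psi = -v_th * lam_v[t + 1] + (1.0 - rho) * lam_a
        if g_z is not None:
            psi = psi + g_z[t]
        for d, w in w_rec_d:
            psi += lam_v[t + d + 1] @ w
        lam_v[t] = alpha * lam_v[t + 1] + psi * dz_dv[t]
        if g_v is not None:
            lam_v[t] += g_v[t]
        lam_a = rho * lam_a + psi * dz_da[t]
    if not np.all(np.isfinite(lam_v)):
        raise FloatingPointError("non-finite gradient in BPTT backward pass")

    # weight gradients; histories are extended by the carried-in buffers so
    # pre-episode spikes reaching the weights through delays contribute too
    one_m_alpha = 1.0 - alpha
    x_ext = record.x if record.x_pre is None else np.concatenate(
        [record.x_pre, record.x], axis=0)
    z_ext = z if record.z_pre is None else np.concatenate(
        [record.z_pre, z], axis=0)
    pre_x = x_ext.shape[0] - T
    pre_z = z_ext.shape[0] - T

    def _accumulate(d, hist, pre):
        lo = max(pre - d, 0)
        steps = hist.shape[0] - lo
        lv = lam_v[1 + (lo - pre + d):1 + (lo - pre + d) + steps]
        lv = lv.reshape(steps * B, n) * one_m_alpha
        return lv.T @ hist[lo:].reshape(steps * B, -1)

    g_w_in = np.zeros_like(weights.w_in)
    for d in np.unique(d_in):
        g_w_in += _accumulate(int(d), x_ext, pre_x) * (d_in == d)
    g_w_rec = np.zeros_like(weights.w_rec)
    for d, _ in w_rec_d:
        g_w_rec += _accumulate(int(d), z_ext, pre_z) * (d_rec == d)
    np.fill_diagonal(g_w_rec, 0.0)
    if weights.mask_in is not None:
        g_w_in *= weights.mask_in
    if weights.mask_rec is not None:
        g_w_rec *= weights.mask_rec

    g_nu = None
    if noise_eps is not None:
        g_nu = np.einsum("tbj,tbj,j->j", lam_v[1:1 + T], noise_eps, one_m_alpha)
    return EpisodeGradients(w_in=g_w_in, w_rec=g_w_rec, nu=g_nu)
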