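"""Independent oracles used by the test suite.

``forward_mode_grad`` re-implements the surrogate computation graph of the
spiking network as a forward-mode (tangent) propagation: the primal recursion
is duplicated here from first principles and a tangent is carried through
every operation, with the spike Heaviside assigned the same dampened
pseudo-derivative.  It shares no code with the package's reverse-mode pass,
so agreement between the two is a genuine two-route check of the Jacobian.
"""
from __future__ import annotations

import numpy as np


def _pseudo(v_norm, gamma):
    return gamma * np.maximum(0.0, 1.0 - np.abs(v_norm))


def forward_primal_and_tangent(weights, neuron, adapt, x, gamma,
                               dw_in, dw_rec):
    """Propagate (z, dz) through the unrolled simulation for one tangent
    direction (dw_in, dw_rec).  Returns (z (T,B,n), dz (T,B,n))."""
    T, B, n_in = x.shape
    n = weights.w_rec.shape[0]
    alpha = np.broadcast_to(np.asarray(neuron.alpha, dtype=float), (n,))
    rho = np.broadcast_to(np.asarray(adapt.rho, dtype=float), (n,))
    beta = np.broadcast_to(np.asarray(adapt.beta, dtype=float), (n,))
    v_th, n_ref = neuron.v_th, neuron.n_ref_steps
    d_in, d_rec = weights.delay_arrays()

    V = np.zeros((B, n)); a = np.zeros((B, n)); refrac = np.zeros((B, n), int)
    dV = np.zeros((B, n)); da = np.zeros((B, n))
    zs = np.zeros((T, B, n)); dzs = np.zeros((T, B, n))
    for t in range(T):
        A = v_th + beta * a
        free = refrac == 0
        z = (free & (V > A)).astype(float)
        pd = free * _pseudo((V - A) / A, gamma)
        dz = pd * (dV / A - V * (beta * da) / A**2)
        refrac = np.where(z > 0, n_ref, np.maximum(refrac - 1, 0))
        drive = np.zeros((B, n)); ddrive = np.zeros((B, n))
        for d in np.unique(d_in):
            if t - d >= 0:
                drive += x[t - d] @ (weights.w_in * (d_in == d)).T
                ddrive += x[t - d] @ (dw_in * (d_in == d)).T
        for d in np.unique(d_rec):
            if t - d >= 0:
                wd = weights.w_rec * (d_rec == d)
                drive += zs[t - d] @ wd.T
                ddrive += zs[t - d] @ (dw_rec * (d_rec == d)).T + dzs[t - d] @ wd.T
        dV = alpha * dV + (1.0 - alpha) * ddrive - v_th * dz
        V = alpha * V + (1.0 - alpha) * drive - v_th * z
        da = rho * da + (1.0 - rho) * dz
        a = rho * a + (1.0 - rho) * z
        zs[t] = z; dzs[t] = dz
    return zs, dzs


def forward_mode_grad(weights, neuron, adapt, x, gamma, loss_tangent,
                      coords_in=(), coords_rec=()):
    """Full gradient entries by one tangent propagation per coordinate.

    ``loss_tangent(z, dz)`` maps the primal spikes and their tangent to the
    scalar directional derivative of the loss.  Returns two dicts
    {(j, i): dL/dW[j, i]}.
    """
    g_in, g_rec = {}, {}
    for j, i in coords_in:
        dwi = np.zeros_like(weights.w_in); dwi[j, i] = 1.0
        z, dz = forward_primal_and_tangent(weights, neuron, adapt, x, gamma,
                                           dwi, np.zeros_like(weights.w_rec))
        g_in[(j, i)] = loss_tangent(z, dz)
    for j, i in coords_rec:
        dwr = np.zeros_like(weights.w_rec); dwr[j, i] = 1.0
        z, dz = forward_primal_and_tangent(weights, neuron, adapt, x, gamma,
                                           np.zeros_like(weights.w_in), dwr)
        g_rec[(j, i)] = loss_tangent(z, dz)
    return g_in, g_rec


def reference_adam(grads_seq, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
    """Textbook Adam recursion on a scalar gradient sequence; returns the
    cumulative parameter displacement after each step."""
    m = v = 0.0
    theta = 0.0
    out = []
    for t, g in enumerate(grads_seq, start=1):
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        theta -= lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)
        out.append(theta)
    return np.array(out)
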