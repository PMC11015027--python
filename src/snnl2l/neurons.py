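"""Discrete-time recurrent networks of LIF neurons with spike-frequency adaptation.

The membrane potential of neuron j follows, in steps of ``delta_t``,

    V_j(t + dt) = alpha * V_j(t) + (1 - alpha) * R_m * I_j(t) - v_th * z_j(t)

with ``alpha = exp(-dt / tau_m)`` and a *subtractive* reset of fixed magnitude
``v_th`` (also for adapting neurons; see docs/methods.md).  The spike variable
is ``z_j(t) = H(V_j(t) - A_j(t))`` gated by a refractory countdown, where the
firing threshold

    A_j(t) = v_th + beta * a_j(t),
    a_j(t + dt) = rho * a_j(t) + (1 - rho) * z_j(t),   rho = exp(-dt / tau_a)

adapts with every spike (spike-frequency adaptation, SFA).  ``beta = 0``
recovers the plain LIF neuron.  Synaptic currents are weighted sums of delayed
binary spikes; delays are integer multiples of ``delta_t`` and at least 1, so
a spike emitted at step t can influence other neurons at step t + d at the
earliest — there is no same-step recurrence.

Weights are expressed as voltage-valued drive (the ``w0 = 1 Volt / R_m * dt``
convention makes R_m drop out of the update); thresholds are in mV.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "NeuronParams",
    "AdaptationParams",
    "NetworkState",
    "synaptic_current",
    "membrane_step",
    "threshold_step",
    "spike_and_refractory",
    "network_step",
    "simulate",
    "EpisodeRecord",
    "spikes_to_events",
]


@dataclass
class NeuronParams:
    """Membrane parameters, shared or per neuron.

    tau_m, tau_ref and delta_t are in ms, v_th in mV, r_m in GOhm.  ``alpha``
    is recomputed from tau_m/delta_t on every access so the invariant
    0 < alpha < 1 cannot go stale.
    """

    tau_m: float | np.ndarray = 20.0
    v_th: float = 30.0
    tau_ref: float = 5.0
    r_m: float = 1.0
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.tau_m) <= 0):
            raise ValueError("tau_m must be positive")
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(-self.delta_t / np.asarray(self.tau_m, dtype=np.float64))

    @property
    def n_ref_steps(self) -> int:
        return int(np.ceil(self.tau_ref / self.delta_t))


@dataclass
class AdaptationParams:
    """Adaptive-threshold parameters; ``beta = 0`` disables SFA per neuron."""

    beta: float | np.ndarray = 0.0
    tau_a: float | np.ndarray = 1000.0
    delta_t: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.beta) < 0):
            raise ValueError("beta must be non-negative")
        if np.any(np.asarray(self.tau_a) <= 0):
            raise ValueError("tau_a must be positive")

    @property
    def rho(self) -> np.ndarray:
        return np.exp(-self.delta_t / np.asarray(self.tau_a, dtype=np.float64))

    @staticmethod
    def mixed(n: int, sfa_fraction: float, beta: float, tau_a_range, rng) -> "AdaptationParams":
        """Population with the trailing ``sfa_fraction`` of neurons adapting.

        tau_a of adapting neurons is spread uniformly over ``tau_a_range``
        (a (lo, hi) pair, or a scalar for a common constant).
        """
        betas = np.zeros(n)
        taus = np.full(n, 1000.0)
        n_sfa = int(round(sfa_fraction * n))
        if n_sfa > 0:
            betas[n - n_sfa:] = beta
            lo, hi = (tau_a_range, tau_a_range) if np.isscalar(tau_a_range) else tau_a_range
            taus[n - n_sfa:] = np.linspace(lo, hi, n_sfa) if lo != hi else lo
        return AdaptationParams(beta=betas, tau_a=taus)


@dataclass
class NetworkState:
    """Per-neuron dynamic variables plus delayed-spike ring buffers.

    ``x_buf[d-1]`` / ``z_buf[d-1]`` hold the input / recurrent spikes from
    ``d`` steps ago (most recent first); buffers are exactly as deep as the
    maximum synaptic delay.  All arrays carry a leading batch axis.
    """

    v: np.ndarray
    a: np.ndarray
    refrac: np.ndarray
    x_buf: np.ndarray
    z_buf: np.ndarray

    @staticmethod
    def zeros(batch: int, n: int, n_in: int, max_delay_in: int = 1,
              max_delay_rec: int = 1) -> "NetworkState":
        return NetworkState(
            v=np.zeros((batch, n)),
            a=np.zeros((batch, n)),
            refrac=np.zeros((batch, n), dtype=np.int64),
            x_buf=np.zeros((max_delay_in, batch, n_in)),
            z_buf=np.zeros((max_delay_rec, batch, n)),
        )

    def copy(self) -> "NetworkState":
        return NetworkState(self.v.copy(), self.a.copy(), self.refrac.copy(),
                            self.x_buf.copy(), self.z_buf.copy())


def _delayed_sum(w: np.ndarray, buf: np.ndarray, delays) -> np.ndarray:
    """sum_i W[j,i] * s_i(t - d[j,i]) from a most-recent-first buffer."""
    if delays is None or np.isscalar(delays):
        d = 1 if delays is None else int(delays)
        if d > buf.shape[0]:
            raise ValueError(f"delay {d} exceeds buffer depth {buf.shape[0]}")
        return buf[d - 1] @ w.T
    delays = np.asarray(delays)
    if delays.max(initial=1) > buf.shape[0]:
        raise ValueError("requested delay exceeds buffer depth")
    out = np.zeros((buf.shape[1], w.shape[0]))
    for d in np.unique(delays):
        out += buf[int(d) - 1] @ (w * (delays == d)).T
    return out


def synaptic_current(state: NetworkState, weights, t: int | None = None) -> np.ndarray:
    """Voltage-valued drive I_j(t) from buffered (strictly past) spikes."""
    return (_delayed_sum(weights.w_in, state.x_buf, weights.d_in)
            + _delayed_sum(weights.w_rec, state.z_buf, weights.d_rec))


def membrane_step(v: np.ndarray, drive: np.ndarray, params: NeuronParams,
                  z: np.ndarray) -> np.ndarray:
    """One Euler-exponential membrane update with subtractive reset.

    ``drive`` is R_m * I in mV; ``z`` the spikes emitted at the current step.
    """
    v_next = params.alpha * v + (1.0 - params.alpha) * drive - params.v_th * z
    if not np.all(np.isfinite(v_next)):
        raise FloatingPointError("non-finite membrane potential")
    return v_next


def threshold_step(a: np.ndarray, z: np.ndarray, adapt: AdaptationParams,
                   v_th: float) -> tuple[np.ndarray, np.ndarray]:
    """Advance the adaptation variable; return (a_next, A_next)."""
    a_next = adapt.rho * a + (1.0 - adapt.rho) * z
    return a_next, v_th + adapt.beta * a_next


def spike_and_refractory(v: np.ndarray, threshold: np.ndarray, refrac: np.ndarray,
                         params: NeuronParams) -> tuple[np.ndarray, np.ndarray]:
    """Strict-Heaviside spike decision gated by the refractory countdown."""
    free = refrac == 0
    z = (free & (v > threshold)).astype(np.float64)
    refrac_next = np.where(z > 0, params.n_ref_steps, np.maximum(refrac - 1, 0))
    return z, refrac_next


def network_step(state: NetworkState, x_t: np.ndarray, weights,
                 params: NeuronParams, adapt: AdaptationParams,
                 extra_drive: np.ndarray | None = None) -> tuple[NetworkState, np.ndarray]:
    """Advance the network by one step; returns (new state, spikes emitted).

    Order: threshold comparison at the current potentials, refractory gating,
    synaptic currents from buffered past spikes, membrane + adaptation update,
    then the new spikes and ``x_t`` are pushed into the buffers (so they act
    with delay >= 1).  Mutates nothing; returns a fresh state.
    """
    if x_t.shape[-1] != state.x_buf.shape[-1]:
        raise ValueError("input width mismatch")
    threshold = params.v_th + np.asarray(adapt.beta) * state.a
    z, refrac = spike_and_refractory(state.v, threshold, state.refrac, params)
    drive = synaptic_current(state, weights)
    if extra_drive is not None:
        drive = drive + extra_drive
    v = membrane_step(state.v, drive, params, z)
    a, _ = threshold_step(state.a, z, adapt, params.v_th)
    x_buf = np.concatenate([x_t[None], state.x_buf[:-1]], axis=0)
    z_buf = np.concatenate([z[None], state.z_buf[:-1]], axis=0)
    return NetworkState(v, a, refrac, x_buf, z_buf), z


@dataclass
class EpisodeRecord:
    """Forward trace of one (batched) episode, sufficient for exact BPTT.

    Shapes: time-major ``(T, batch, n)``.  ``v``/``a``/``gate`` are the values
    *at* each step (pre-update, i.e. the ones the spike decision saw).
    """

    x: np.ndarray
    z: np.ndarray
    v: np.ndarray
    a: np.ndarray
    gate: np.ndarray
    final_state: NetworkState
    extra_drive: np.ndarray | None = None
    #: pre-episode buffered spikes (oldest first), needed so weight gradients
    #: include the paths through carried-in delayed spikes; None means zeros
    x_pre: np.ndarray | None = None
    z_pre: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def simulate(weights, params: NeuronParams, adapt: AdaptationParams,
             x: np.ndarray, state: NetworkState | None = None,
             extra_drive: np.ndarray | None = None,
             record: bool = True) -> EpisodeRecord:
    """Run the network over input spikes ``x`` of shape (T, batch, n_in).

    ``extra_drive`` (T, batch, n) is an optional voltage-valued current per
    step (noise injection, test drive).  Implements the same recursion as
    ``network_step`` with full-history indexing for speed; equivalence is
    covered by the test suite.
    """
    x = np.asarray(x, dtype=np.float64)
    T, B, n_in = x.shape
    n = weights.w_rec.shape[0]
    d_in, d_rec = weights.delay_arrays()
    din_max, drec_max = int(d_in.max()), int(d_rec.max())
    if state is None:
        state = NetworkState.zeros(B, n, n_in, din_max, drec_max)
    alpha = np.asarray(params.alpha)
    rho = np.asarray(adapt.rho)
    beta = np.asarray(adapt.beta)
    v_th, n_ref = params.v_th, params.n_ref_steps

    # full history with `pre` slots holding the carried-in buffers
    xs = np.concatenate([state.x_buf[::-1], x], axis=0)          # (din_max+T, B, n_in)
    zs = np.zeros((drec_max + T, B, n))
    zs[:drec_max] = state.z_buf[::-1]
    v_rec = np.empty((T, B, n)) if record else None
    a_rec = np.empty((T, B, n)) if record else None
    gate_rec = np.empty((T, B, n), dtype=bool) if record else None

    w_in_d = [(int(d), np.ascontiguousarray((weights.w_in * (d_in == d)).T))
              for d in np.unique(d_in)]
    w_rec_d = [(int(d), np.ascontiguousarray((weights.w_rec * (d_rec == d)).T))
               for d in np.unique(d_rec)]

    v, a, refrac = state.v.copy(), state.a.copy(), state.refrac.copy()
    for t in range(T):
        free = refrac == 0
        z = (free & (v > v_th + beta * a)).astype(np.float64)
        if record:
            v_rec[t], a_rec[t], gate_rec[t] = v, a, free
        refrac = np.where(z > 0, n_ref, np.maximum(refrac - 1, 0))
        drive = np.zeros((B, n))
        for d, wT in w_in_d:
            drive += xs[din_max + t - d] @ wT
        for d, wT in w_rec_d:
            drive += zs[drec_max + t - d] @ wT
        if extra_drive is not None:
            drive += extra_drive[t]
        v = alpha * v + (1.0 - alpha) * drive - v_th * z
        a = rho * a + (1.0 - rho) * z
        zs[drec_max + t] = z
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite membrane potential")

    # buffers carry the last max-delay steps, most recent first
    final = NetworkState(
        v=v, a=a, refrac=refrac,
        x_buf=xs[T:T + din_max][::-1].copy(),
        z_buf=zs[T:T + drec_max][::-1].copy(),
    )
    return EpisodeRecord(
        x=x, z=zs[drec_max:].copy(), v=v_rec, a=a_rec, gate=gate_rec,
        final_state=final, extra_drive=extra_drive,
        x_pre=xs[:din_max].copy(), z_pre=zs[:drec_max].copy(),
    )


def spikes_to_events(z: np.ndarray, delta_t: float = 1.0) -> np.ndarray:
    """Dense (T, n) raster -> (time_ms, neuron_id) event list (float array)."""
    t_idx, n_idx = np.nonzero(z)
    return np.column_stack([t_idx * delta_t, n_idx]).astype(np.float64)
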