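"""Outer-loop (learning-to-learn) training.

The inner loop is one task episode simulated with frozen weights — all
adaptation happens in the network dynamics.  The outer loop samples a batch
of tasks per iteration, accumulates surrogate-gradient BPTT gradients across
the batch (a mean over episodes), and applies one Adam step; the navigation
task instead collects K full episodes under frozen parameters and applies
one Adam step of the clipped-surrogate PPO loss, with DEEP R rewiring
keeping connectivity and Dale signs fixed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coding, losses, tasks
from .coding import PopulationCodeSpec
from .connectivity import (RewiringConfig, WeightSet, init_dale,
                           init_unconstrained, sparsify)
from .losses import LossConfig, PPOConfig
from .neurons import (AdaptationParams, EpisodeRecord, NetworkState,
                      NeuronParams, simulate)
from .surrogate import backward
from .utils import seed_stream

__all__ = [
    "Adam", "RSNNModel",
    "SinusoidExperiment", "ArmExperiment", "PatternExperiment", "MazeExperiment",
    "adam_outer_iteration",
]


class Adam(object):
    """Adam optimizer over a dict of named arrays (default torch-style
    hyperparameters: beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def direction(self, grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Advance moments and return the update (to be *added* to params)."""
        self.t += 1
        out = {}
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            m_hat = m / (1.0 - self.beta1 ** self.t)
            v_hat = v / (1.0 - self.beta2 ** self.t)
            out[k] = -self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return out

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        for k, upd in self.direction(grads).items():
            params[k] += upd

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state.get("lr", self.lr))
        self.m = {k: np.asarray(v) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v) for k, v in state["v"].items()}


@dataclass
class RSNNModel:
    """A spiking network with its neuron parameters and surrogate setting."""

    weights: WeightSet
    neuron: NeuronParams
    adapt: AdaptationParams
    gamma: float = 0.3
    nu: np.ndarray | None = None

    def param_dict(self) -> dict[str, np.ndarray]:
        out = {"w_in": self.weights.w_in, "w_rec": self.weights.w_rec,
               "w_out": self.weights.w_out, "b_out": self.weights.b_out}
        if self.nu is not None:
            out["nu"] = self.nu
        return out


def adam_outer_iteration(experiment, log: list | None = None) -> dict:
    """One outer-loop iteration of any experiment; logs and returns metrics."""
    metrics = experiment.iteration()
    if log is not None:
        log.append(metrics)
    return metrics


class _ExperimentBase:
    """Shared outer-loop driver: seeding streams, training loop, history."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.rng_init = seed_stream(seed, "init")
        self.rng_data = seed_stream(seed, "data")
        self.rng_noise = seed_stream(seed, "noise")
        self.rng_eval = seed_stream(seed, "eval")
        self.history: list[dict] = []
        self.iteration_count = 0

    def train(self, n_iterations: int, callback=None) -> list[dict]:
        for _ in range(n_iterations):
            metrics = self.iteration()
            self.history.append(metrics)
            if callback is not None:
                callback(metrics)
        return self.history


class SinusoidExperiment(_ExperimentBase):
    """Meta-regression on the family y = A sin(phi + x).

    Inputs per 20 ms step: the query x^k and the delayed feedback y^{k-1},
    each through a 100-neuron Gaussian population code over [-5, 5]; readout
    is linear in the per-step mean firing rates.  Loss: summed squared error
    over the K steps plus the firing regularizer (lambda=30, f0=20 Hz).
    """

    def __init__(self, n_neurons: int = 100, sfa_fraction: float = 0.4,
                 beta: float = 1.6, tau_a_range=(1.0, 3000.0),
                 n_steps: int = 500, step_ms: int = 20, batch: int = 100,
                 lr: float = 1e-3, gamma: float = 0.3,
                 code_sigma: float = 0.1, code_neurons: int = 100,
                 seed: int = 0):
        super().__init__(seed)
        self.n_steps, self.step_ms, self.batch = n_steps, step_ms, batch
        self.loss_cfg = LossConfig(lambda_reg=30.0, f0=20.0)
        self.specs = [PopulationCodeSpec(code_neurons, -5.0, 5.0, 200.0, code_sigma),
                      PopulationCodeSpec(code_neurons, -5.0, 5.0, 200.0, code_sigma)]
        n_in = 2 * code_neurons
        self.model = RSNNModel(
            weights=WeightSet(
                w_in=init_unconstrained(n_neurons, n_in, seed=self.rng_init),
                w_rec=init_unconstrained(n_neurons, n_neurons, seed=self.rng_init),
                w_out=init_unconstrained(1, n_neurons, w0=1.0, seed=self.rng_init),
            ),
            neuron=NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0),
            adapt=AdaptationParams.mixed(n_neurons, sfa_fraction, beta,
                                         tau_a_range, self.rng_init),
            gamma=gamma,
        )
        self.optimizer = Adam(lr=lr)

    # -- episode plumbing --------------------------------------------------
    def episode_batch(self, rng: np.random.Generator, batch: int) -> dict:
        eps = [tasks.regression_episode(tasks.sample_sinusoid_task(rng), rng,
                                        self.n_steps) for _ in range(batch)]
        values = np.stack([np.stack([e["x"], e["feedback"]], axis=-1)
                           for e in eps], axis=1)          # (K, B, 2)
        targets = np.stack([e["target"] for e in eps], axis=1)
        return {"values": values, "targets": targets, "episodes": eps}

    def forward(self, data: dict, rng: np.random.Generator,
                state: NetworkState | None = None) -> dict:
        x_spikes = coding.encode_values(data["values"], self.specs,
                                        self.step_ms, 1.0, rng)
        record = simulate(self.model.weights, self.model.neuron,
                          self.model.adapt, x_spikes, state=state)
        y, feats = coding.mean_rate_decode(record.z, self.model.weights.w_out,
                                           self.model.weights.b_out, self.step_ms)
        return {"record": record, "y": y[..., 0], "feats": feats}

    def iteration(self) -> dict:
        data = self.episode_batch(self.rng_data, self.batch)
        fwd = self.forward(data, self.rng_data)
        record, y = fwd["record"], fwd["y"]
        loss = losses.regression_loss(y, data["targets"], record.z, self.loss_cfg)

        g_y = (2.0 * (y - data["targets"]) / self.batch)[..., None]
        g_z, g_w_out, g_b_out = coding.mean_rate_decode_vjp(
            g_y, fwd["feats"], self.model.weights.w_out, self.step_ms)
        g_z = g_z + losses.firing_regularizer_grad(
            record.z, self.loss_cfg.f0, self.loss_cfg.lambda_reg)
        eg = backward(record, self.model.weights, self.model.neuron,
                      self.model.adapt, g_z, self.model.gamma)
        self.optimizer.step(self.model.param_dict(), {
            "w_in": eg.w_in, "w_rec": eg.w_rec, "w_out": g_w_out, "b_out": g_b_out})
        np.fill_diagonal(self.model.weights.w_rec, 0.0)
        self.iteration_count += 1
        f_avg = record.z.mean() * 1000.0
        mse_step = float(np.mean((y - data["targets"]) ** 2))
        return {"iteration": self.iteration_count, "loss": loss,
                "f_avg_hz": float(f_avg), "mse_per_step": mse_step}

    def evaluate(self, n_episodes: int = 20,
                 rng: np.random.Generator | None = None) -> dict:
        """Held-out test MSE per step over the second half of each episode."""
        rng = rng or self.rng_eval
        data = self.episode_batch(rng, n_episodes)
        fwd = self.forward(data, rng)
        half = self.n_steps // 2
        err = (fwd["y"] - data["targets"])[half:]
        return {"test_mse": float(np.mean(err ** 2)),
                "test_mse_full": float(np.mean((fwd["y"] - data["targets"]) ** 2))}


class ArmExperiment(_ExperimentBase):
    """One-shot adaptation of a two-link-arm forward model.

    Inputs per 1 ms step: the two joint torques and the two joint angles fed
    back with a 100 ms delay (zero for the first 100 ms), each through a
    100-neuron population code; readout is linear in 50 ms exponential spike
    traces; loss is the time-integrated squared angle error.
    """

    def __init__(self, n_neurons: int = 600, sfa_fraction: float = 0.5,
                 beta: float = 1.7, tau_a_range=(1.0, 600.0),
                 episode_ms: int = 30000, batch: int = 80, lr: float = 1e-3,
                 gamma: float = 0.3, torque_bound: float = 5.0,
                 code_neurons: int = 100, seed: int = 0):
        super().__init__(seed)
        self.episode_ms, self.batch = episode_ms, batch
        self.torque_bound = torque_bound
        self.delay_ms = 100
        self.tau_trace = 50.0
        self.specs = [
            PopulationCodeSpec(code_neurons, -torque_bound, torque_bound, 200.0,
                               2.0 * torque_bound / 1000.0),
            PopulationCodeSpec(code_neurons, -torque_bound, torque_bound, 200.0,
                               2.0 * torque_bound / 1000.0),
            PopulationCodeSpec(code_neurons, -np.pi, np.pi, 200.0, 2.0 * np.pi / 1000.0),
            PopulationCodeSpec(code_neurons, -np.pi, np.pi, 200.0, 2.0 * np.pi / 1000.0),
        ]
        n_in = 4 * code_neurons
        self.model = RSNNModel(
            weights=WeightSet(
                w_in=init_unconstrained(n_neurons, n_in, seed=self.rng_init),
                w_rec=init_unconstrained(n_neurons, n_neurons, seed=self.rng_init),
                w_out=init_unconstrained(2, n_neurons, w0=1.0, seed=self.rng_init),
            ),
            neuron=NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0),
            adapt=AdaptationParams.mixed(n_neurons, sfa_fraction, beta,
                                         tau_a_range, self.rng_init),
            gamma=gamma,
        )
        self.optimizer = Adam(lr=lr)

    def episode_batch(self, rng: np.random.Generator, batch: int) -> dict:
        vals, angles, arms = [], [], []
        for _ in range(batch):
            task = tasks.sample_arm_task(rng)
            torques = tasks.torque_sequence(rng, self.episode_ms,
                                            bound=self.torque_bound)
            states = tasks.simulate_arm(task, torques)[1:]       # (T, 4)
            phi = states[:, :2]
            fb = np.zeros_like(phi)
            fb[self.delay_ms:] = phi[:-self.delay_ms]
            wrapped = np.mod(fb + np.pi, 2.0 * np.pi) - np.pi
            vals.append(np.concatenate([torques, wrapped], axis=1))
            angles.append(phi)
            arms.append(task)
        return {"values": np.stack(vals, axis=1),
                "targets": np.stack(angles, axis=1),             # (T, B, 2)
                "tasks": arms}

    def forward(self, data: dict, rng: np.random.Generator) -> dict:
        x_spikes = coding.encode_values(data["values"], self.specs, 1, 1.0, rng)
        record = simulate(self.model.weights, self.model.neuron,
                          self.model.adapt, x_spikes)
        y, traces = coding.trace_decode(record.z, self.tau_trace,
                                        self.model.weights.w_out,
                                        self.model.weights.b_out)
        return {"record": record, "y": y, "traces": traces}

    def iteration(self) -> dict:
        data = self.episode_batch(self.rng_data, self.batch)
        fwd = self.forward(data, self.rng_data)
        loss = losses.arm_loss(fwd["y"], data["targets"])
        g_y = 2.0 * (fwd["y"] - data["targets"]) / self.batch
        g_z, g_w_out, g_b_out = coding.trace_decode_vjp(
            g_y, fwd["traces"], self.tau_trace, self.model.weights.w_out)
        eg = backward(fwd["record"], self.model.weights, self.model.neuron,
                      self.model.adapt, g_z, self.model.gamma)
        self.optimizer.step(self.model.param_dict(), {
            "w_in": eg.w_in, "w_rec": eg.w_rec, "w_out": g_w_out, "b_out": g_b_out})
        np.fill_diagonal(self.model.weights.w_rec, 0.0)
        self.iteration_count += 1
        return {"iteration": self.iteration_count, "loss": loss,
                "f_avg_hz": float(fwd["record"].z.mean() * 1000.0)}

    def evaluate(self, n_episodes: int = 10,
                 rng: np.random.Generator | None = None) -> dict:
        """Joint-angle RMSE (rad) and its error-versus-time curve."""
        rng = rng or self.rng_eval
        data = self.episode_batch(rng, n_episodes)
        fwd = self.forward(data, rng)
        err = fwd["y"] - data["targets"]

        def tip(phi, task):
            x = task.l1 * np.sin(phi[..., 0]) \
                + task.l2 * np.sin(phi[..., 0] + phi[..., 1])
            y = -task.l1 * np.cos(phi[..., 0]) \
                - task.l2 * np.cos(phi[..., 0] + phi[..., 1])
            return np.stack([x, y], axis=-1)

        tip_sq = [np.mean((tip(fwd["y"][:, b], t) - tip(data["targets"][:, b], t)) ** 2)
                  for b, t in enumerate(data["tasks"])]
        return {"rmse_rad": float(np.sqrt(np.mean(err ** 2))),
                "rmse_tip_m": float(np.sqrt(np.mean(tip_sq))),
                "rmse_vs_time": np.sqrt(np.mean(err ** 2, axis=(1, 2)))}


class PatternExperiment(_ExperimentBase):
    """One-shot pattern store / complete / delete.

    Four phases (A: store three 25-bit patterns, B: complete partial cues,
    C: delete-by-index cue, D: complete again honouring the deletion); 140
    input neurons (5 per pattern bit + 5 per cue bit, 200/2 Hz), readout on
    100 ms spike traces squashed to bitwise probabilities; mean bitwise
    cross-entropy over phases B and D plus firing regularizer (lambda=5).
    """

    def __init__(self, n_neurons: int = 300, sfa_fraction: float = 0.5,
                 beta: float = 1.7, tau_a_range=(1.0, 1000.0),
                 item_ms: int = 100, batch: int = 100, lr: float = 1e-3,
                 gamma: float = 0.3, seed: int = 0):
        super().__init__(seed)
        self.item_ms, self.batch = item_ms, batch
        self.tau_trace = 100.0
        self.loss_cfg = LossConfig(lambda_reg=5.0, f0=20.0)
        self.n_bits, self.n_patterns = 25, 3
        n_in = 5 * (self.n_bits + 3)
        self.model = RSNNModel(
            weights=WeightSet(
                w_in=init_unconstrained(n_neurons, n_in, seed=self.rng_init),
                w_rec=init_unconstrained(n_neurons, n_neurons, seed=self.rng_init),
                w_out=init_unconstrained(self.n_bits, n_neurons, w0=1.0, seed=self.rng_init),
            ),
            neuron=NeuronParams(tau_m=20.0, v_th=30.0, tau_ref=5.0),
            adapt=AdaptationParams.mixed(n_neurons, sfa_fraction, beta,
                                         tau_a_range, self.rng_init),
            gamma=gamma,
        )
        self.optimizer = Adam(lr=lr)

    @property
    def phase_layout(self) -> list[tuple[str, int]]:
        """(phase, item) per 100 ms slot: A,A,A, B,B,B, C, D,D,D."""
        out = [("A", i) for i in range(3)] + [("B", i) for i in range(3)]
        return out + [("C", 0)] + [("D", i) for i in range(3)]

    def episode_batch(self, rng: np.random.Generator, batch: int) -> dict:
        eps = [tasks.build_pattern_episode(rng) for _ in range(batch)]
        T = len(self.phase_layout) * self.item_ms
        x = np.zeros((T, batch, 5 * (self.n_bits + 3)))
        for b, ep in enumerate(eps):
            for s, (phase, item) in enumerate(self.phase_layout):
                bits25 = {"A": ep.patterns[item], "B": ep.partials[item],
                          "C": np.zeros(self.n_bits, dtype=np.int64),
                          "D": ep.partials[item]}[phase]
                cue = np.zeros(3, dtype=np.int64)
                if phase == "C":
                    cue[ep.delete_index] = 1
                bits = np.concatenate([bits25, cue])
                sl = slice(s * self.item_ms, (s + 1) * self.item_ms)
                x[sl, b] = coding.bit_pattern_spikes(bits, self.item_ms, rng)
        targets = np.stack([np.concatenate([ep.targets_b, ep.targets_d])
                            for ep in eps], axis=1)      # (6, B, 25)
        return {"x": x, "targets": targets.astype(np.float64), "episodes": eps}

    def _target_slots(self) -> list[int]:
        return [i for i, (ph, _) in enumerate(self.phase_layout) if ph in "BD"]

    def forward(self, data: dict) -> dict:
        record = simulate(self.model.weights, self.model.neuron,
                          self.model.adapt, data["x"])
        y, traces = coding.trace_decode(record.z, self.tau_trace,
                                        self.model.weights.w_out,
                                        self.model.weights.b_out)
        slots = self._target_slots()
        T = y.shape[0]
        y_items = y.reshape(T // self.item_ms, self.item_ms, *y.shape[1:]).mean(axis=1)
        logits = y_items[slots]                          # (6, B, 25)
        probs = 1.0 / (1.0 + np.exp(-logits))
        return {"record": record, "y": y, "traces": traces,
                "logits": logits, "probs": probs}

    def iteration(self) -> dict:
        data = self.episode_batch(self.rng_data, self.batch)
        fwd = self.forward(data)
        loss = losses.pattern_loss(fwd["probs"], data["targets"],
                                   fwd["record"].z, self.loss_cfg,
                                   lambda_reg=self.loss_cfg.lambda_reg)
        n_items, B = fwd["probs"].shape[:2]
        g_logits = (fwd["probs"] - data["targets"]) / (self.n_bits * n_items * B)
        g_y = np.zeros_like(fwd["y"])
        for j, s in enumerate(self._target_slots()):
            sl = slice(s * self.item_ms, (s + 1) * self.item_ms)
            g_y[sl] = g_logits[j] / self.item_ms
        g_z, g_w_out, g_b_out = coding.trace_decode_vjp(
            g_y, fwd["traces"], self.tau_trace, self.model.weights.w_out)
        g_z = g_z + losses.firing_regularizer_grad(
            fwd["record"].z, self.loss_cfg.f0, self.loss_cfg.lambda_reg)
        eg = backward(fwd["record"], self.model.weights, self.model.neuron,
                      self.model.adapt, g_z, self.model.gamma)
        self.optimizer.step(self.model.param_dict(), {
            "w_in": eg.w_in, "w_rec": eg.w_rec, "w_out": g_w_out, "b_out": g_b_out})
        np.fill_diagonal(self.model.weights.w_rec, 0.0)
        self.iteration_count += 1
        acc = float(np.mean((fwd["probs"] > 0.5) == (data["targets"] > 0.5)))
        return {"iteration": self.iteration_count, "loss": loss, "accuracy": acc,
                "f_avg_hz": float(fwd["record"].z.mean() * 1000.0)}

    def evaluate(self, n_episodes: int = 20,
                 rng: np.random.Generator | None = None) -> dict:
        """Bitwise completion accuracies in phases B and D and their mean."""
        rng = rng or self.rng_eval
        data = self.episode_batch(rng, n_episodes)
        fwd = self.forward(data)
        correct = (fwd["probs"] > 0.5) == (data["targets"] > 0.5)
        acc_b = float(np.mean(correct[:3]))
        acc_d = float(np.mean(correct[3:]))
        return {"accuracy_b": acc_b, "accuracy_d": acc_d,
                "accuracy_mean": 0.5 * (acc_b + acc_d)}


class MazeExperiment(_ExperimentBase):
    """Meta-reinforcement learning in the circular water maze.

    A Dale-constrained sparse network (default 400 = 200 excitatory + 80
    inhibitory LIF + 120 excitatory SFA neurons at 20% global connectivity,
    delays 1-10 ms) receives place-cell position coding (2 x 40 neurons) and
    reward spikes (2 x 40), drives a Gaussian policy through five leaky
    readout integrators, and is trained with one Adam step of the clipped
    PPO loss per iteration; DEEP R rewiring preserves connectivity and
    signs.  Per-neuron current noise (scale nu, trainable) supports learned
    exploration.
    """

    def __init__(self, n_exc_lif: int = 200, n_inh_lif: int = 80,
                 n_sfa: int = 120, beta: float = 1.7, tau_a: float = 1200.0,
                 connectivity: float = 0.2, k_episodes: int = 10,
                 t_steps: int = 2000, lr: float = 0.01, gamma: float = 0.3,
                 lr_halving_every: int = 5000, seed: int = 0):
        super().__init__(seed)
        n = n_exc_lif + n_inh_lif + n_sfa
        self.n = n
        self.ppo_cfg = PPOConfig(k_episodes=k_episodes, t_steps=t_steps)
        self.loss_cfg = LossConfig(f0=10.0, mu_v=1.0, mu_e=0.001, mu_firing=100.0)
        self.rewiring = RewiringConfig(connectivity=connectivity)
        self.lr_halving_every = lr_halving_every
        self.base_lr = lr
        self.task = tasks.MazeTask(episode_steps=t_steps)
        self.pos_spec = PopulationCodeSpec.maze_position()
        n_in = 2 * 40 + 2 * 40

        sign = np.concatenate([np.ones(n_exc_lif), -np.ones(n_inh_lif),
                               np.ones(n_sfa)]).astype(np.int64)
        w_rec, _ = init_dale(n, n, seed=self.rng_init, sign=sign)
        w_in, sign_in = init_dale(n, n_in, frac_excitatory=0.8, seed=self.rng_init)
        w_out, _ = init_dale(5, n, w0=1.0, seed=self.rng_init, sign=sign)
        mask_rec = sparsify(w_rec, connectivity, self.rng_init, exclude_diagonal=True)
        mask_in = sparsify(w_in, connectivity, self.rng_init)
        mask_out = sparsify(w_out, connectivity, self.rng_init)
        self.sign_in = sign_in
        tau_m = self.rng_init.uniform(15.0, 30.0, n)
        betas = np.concatenate([np.zeros(n_exc_lif + n_inh_lif), np.full(n_sfa, beta)])
        taus = np.concatenate([np.full(n_exc_lif + n_inh_lif, 1000.0),
                               np.full(n_sfa, tau_a)])
        self.model = RSNNModel(
            weights=WeightSet(
                w_in=w_in, w_rec=w_rec, w_out=w_out, sign=sign,
                d_in=self.rng_init.integers(1, 11, w_in.shape),
                d_rec=self.rng_init.integers(1, 11, w_rec.shape),
                mask_in=mask_in, mask_rec=mask_rec, mask_out=mask_out,
            ),
            neuron=NeuronParams(tau_m=tau_m, v_th=30.0, tau_ref=3.0),
            adapt=AdaptationParams(beta=betas, tau_a=taus),
            gamma=gamma,
            nu=np.full(n, self.ppo_cfg.nu_init),
        )
        self.optimizer = Adam(lr=lr, eps=1e-5)

    @property
    def lr(self) -> float:
        return self.base_lr * 0.5 ** (self.iteration_count // self.lr_halving_every)

    def _encode_step(self, positions: np.ndarray, rewards: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        """(B, 2) positions + (B,) previous rewards -> (B, 160) input spikes."""
        rates = np.concatenate(
            [coding.population_rates(positions[:, 0], self.pos_spec),
             coding.population_rates(positions[:, 1], self.pos_spec)], axis=-1)
        pos_spikes = coding.rates_to_spikes(rates, 1, 1.0, rng)[0]
        rew_spikes = np.stack([coding.reward_spikes(r) for r in rewards])
        return np.concatenate([pos_spikes, rew_spikes], axis=-1)

    def collect(self, rng: np.random.Generator) -> dict:
        """Roll out K episodes under the current (frozen) parameters."""
        K, T = self.ppo_cfg.k_episodes, self.ppo_cfg.t_steps
        m, n = self.model, self.n
        d_in, d_rec = m.weights.delay_arrays()
        state = NetworkState.zeros(K, n, 160, int(d_in.max()), int(d_rec.max()))
        goals = np.stack([tasks.sample_goal(rng, self.task) for _ in range(K)])
        pos = np.stack([tasks.random_arena_position(rng, self.task)
                        for _ in range(K)])
        buf = {k: [] for k in ("x", "z", "v", "a", "gate", "eps", "actions",
                               "mu", "var", "value", "rewards", "y")}
        prev_rewards = np.zeros(K)
        y_readout = np.zeros((K, 5))
        alpha_o = np.exp(-1.0 / 20.0)
        from .neurons import network_step
        for _ in range(T):
            x_t = self._encode_step(pos, prev_rewards, rng)
            eps = rng.standard_normal((K, n))
            drive_noise = m.nu * eps
            buf["v"].append(state.v.copy())
            buf["a"].append(state.a.copy())
            buf["gate"].append(state.refrac == 0)
            state, z = network_step(state, x_t, m.weights, m.neuron, m.adapt,
                                    extra_drive=drive_noise)
            y_readout = alpha_o * y_readout + (1.0 - alpha_o) * (
                z @ m.weights.w_out.T + m.weights.b_out)
            mu, var, value = coding.policy_decode(y_readout)
            actions, vel = coding.sample_action(mu, var, rng, self.task.a_scale)
            rewards = np.empty(K)
            for k in range(K):
                pos_k, r_k, _ = tasks.maze_step(pos[k], vel[k], goals[k],
                                                rng, self.task)
                pos[k], rewards[k] = pos_k, r_k
            for key, val in (("x", x_t), ("z", z), ("eps", eps),
                             ("actions", actions), ("mu", mu), ("var", var),
                             ("value", value), ("rewards", rewards),
                             ("y", y_readout)):
                buf[key].append(val.copy() if hasattr(val, "copy") else val)
            prev_rewards = rewards
        out = {k: np.stack(v) for k, v in buf.items()}
        out["log_prob_old"] = losses.gaussian_log_prob(
            out["actions"], out["mu"], out["var"])
        out["returns"] = losses.discounted_return(out["rewards"], self.ppo_cfg.eta)
        out["goals"] = goals
        out["record"] = EpisodeRecord(
            x=out["x"], z=out["z"], v=out["v"], a=out["a"], gate=out["gate"],
            final_state=state)
        return out

    def iteration(self) -> dict:
        self.optimizer.lr = self.lr
        traj = self.collect(self.rng_data)
        loss, g_y = losses.ppo_loss(
            traj["actions"], traj["mu"], traj["var"], traj["value"],
            traj["log_prob_old"], traj["returns"], traj["value"],
            traj["z"], self.ppo_cfg, self.loss_cfg, with_grads=True)
        g_z, g_w_out, g_b_out = coding.leaky_readout_vjp(
            g_y, traj["z"], self.model.weights.w_out, tau_out=20.0)
        g_z = g_z + losses.firing_regularizer_grad(
            traj["z"], self.loss_cfg.f0, self.loss_cfg.mu_firing)
        eg = backward(traj["record"], self.model.weights, self.model.neuron,
                      self.model.adapt, g_z, self.model.gamma,
                      noise_eps=traj["eps"])
        grads = {"w_in": eg.w_in, "w_rec": eg.w_rec, "w_out": g_w_out,
                 "b_out": g_b_out, "nu": eg.nu}
        self._constrained_update(grads)
        self.iteration_count += 1
        reward_sum = float(traj["rewards"].sum() / self.ppo_cfg.k_episodes)
        goals_hit = float((traj["rewards"] == 1.0).sum() / self.ppo_cfg.k_episodes)
        return {"iteration": self.iteration_count, "loss": loss,
                "reward_per_episode": reward_sum, "goals_per_episode": goals_hit,
                "f_avg_hz": float(traj["z"].mean() * 1000.0)}

    def _constrained_update(self, grads: dict) -> None:
        """Adam direction + DEEP R: L1 shrinkage, sign-flip disconnection and
        uniform reconnection with a *global* connection budget over w_in,
        w_rec and w_out."""
        upd = self.optimizer.direction(grads)
        w = self.model.weights
        w.b_out += upd["b_out"]
        self.model.nu += upd["nu"]
        parts = [("w_in", w.w_in, w.mask_in, self.sign_in, False),
                 ("w_rec", w.w_rec, w.mask_rec, w.sign, True),
                 ("w_out", w.w_out, w.mask_out, w.sign, False)]
        lr = self.optimizer.lr
        rng = self.rng_noise
        flips = []
        for name, mat, mask, sign, excl in parts:
            active = mask > 0
            col_sign = np.broadcast_to(np.asarray(sign)[None, :], mat.shape)
            mat[active] += upd[name][active] - lr * self.rewiring.l1 * col_sign[active]
            flipped = active & (col_sign * mat < 0)
            mat[flipped] = 0.0
            mask[flipped] = 0.0
            flips.append(int(flipped.sum()))
        n_flip = sum(flips)
        if n_flip:
            free_coords = []
            for idx, (name, mat, mask, sign, excl) in enumerate(parts):
                eligible = mask == 0
                if excl:
                    np.fill_diagonal(eligible, False)
                for flat in np.flatnonzero(eligible):
                    free_coords.append((idx, flat))
            chosen = rng.choice(len(free_coords), size=min(n_flip, len(free_coords)),
                                replace=False)
            for c in chosen:
                idx, flat = free_coords[c]
                parts[idx][2].flat[flat] = 1.0
                parts[idx][1].flat[flat] = 0.0

    def evaluate(self, n_iterations: int = 1,
                 rng: np.random.Generator | None = None) -> dict:
        """Accumulated reward and goal count per episode under frozen weights."""
        rng = rng or self.rng_eval
        traj = self.collect(rng)
        return {"reward_per_episode": float(traj["rewards"].sum()
                                            / self.ppo_cfg.k_episodes),
                "goals_per_episode": float((traj["rewards"] == 1.0).sum()
                                           / self.ppo_cfg.k_episodes)}
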