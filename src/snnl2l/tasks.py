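"""The four task families: sinusoid meta-regression, two-link-arm forward
model, water-maze navigation, and one-shot pattern store/complete/delete.

Every generator is a pure function of its random generator / seed, so the
same objects double as reproducible test fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SinusoidTask", "sample_sinusoid_task", "regression_episode",
    "ArmTask", "sample_arm_task", "torque_sequence", "arm_dynamics_step",
    "simulate_arm", "arm_energy",
    "MazeTask", "maze_step", "random_arena_position", "sample_goal",
    "PatternTask", "build_pattern_episode", "closest_kept_pattern",
]

GRAVITY = 9.81


# -- sinusoid meta-regression ---------------------------------------------

@dataclass
class SinusoidTask:
    """One target function y = A sin(phi + x) over x in [-5, 5]."""

    A: float
    phi: float
    x_min: float = -5.0
    x_max: float = 5.0

    def __call__(self, x):
        return self.A * np.sin(self.phi + np.asarray(x, dtype=np.float64))


def sample_sinusoid_task(rng: np.random.Generator) -> SinusoidTask:
    """A ~ U[0.1, 5], phi ~ U[0, pi]."""
    return SinusoidTask(A=float(rng.uniform(0.1, 5.0)),
                        phi=float(rng.uniform(0.0, np.pi)))


def regression_episode(task: SinusoidTask, rng: np.random.Generator,
                       n_steps: int = 500) -> dict:
    """i.i.d. inputs x^k ~ U[-5,5]; feedback is the previous step's target.

    Returns arrays ``x`` (K,), ``target`` (K,) with y^k = f(x^k), and
    ``feedback`` (K,) where feedback[k] = y^{k-1} and feedback[0] = 0.
    """
    x = rng.uniform(task.x_min, task.x_max, n_steps)
    y = task(x)
    feedback = np.concatenate([[0.0], y[:-1]])
    return {"x": x, "target": y, "feedback": feedback, "task": task}


# -- two-link arm ---------------------------------------------------------

@dataclass
class ArmTask:
    """Planar two-link arm under gravity; point masses at the link ends.

    phi1 is the angle of the proximal link from the downward vertical, phi2
    the relative angle of the distal link (both links hanging straight down
    is (0, 0), a stable equilibrium).  Masses in kg, lengths in m.
    """

    m1: float = 1.0
    m2: float = 1.0
    l1: float = 1.0
    l2: float = 1.0
    feedback_delay_ms: float = 100.0
    episode_ms: float = 30000.0
    torque_block_ms: float = 10.0
    gravity: float = GRAVITY


def sample_arm_task(rng: np.random.Generator) -> ArmTask:
    """Masses and lengths i.i.d. uniform in [0.5, 2]."""
    m1, m2, l1, l2 = rng.uniform(0.5, 2.0, 4)
    return ArmTask(m1=float(m1), m2=float(m2), l1=float(l1), l2=float(l2))


def torque_sequence(rng: np.random.Generator, duration_ms: float = 30000.0,
                    block_ms: float = 10.0, bound: float = 5.0) -> np.ndarray:
    """Piecewise-constant joint torques, one U[-bound, bound]^2 draw per block.

    Returns (n_steps, 2) at 1 ms resolution with block boundaries at exact
    multiples of block_ms.
    """
    n_steps = int(round(duration_ms))
    n_blocks = int(np.ceil(n_steps / block_ms))
    blocks = rng.uniform(-bound, bound, (n_blocks, 2))
    return np.repeat(blocks, int(round(block_ms)), axis=0)[:n_steps]


def _arm_accel(state: np.ndarray, torque: np.ndarray, p: ArmTask) -> np.ndarray:
    """Rigid-body accelerations; state = (phi1, phi2, w1, w2)."""
    phi1, phi2, w1, w2 = state
    c2, s2 = np.cos(phi2), np.sin(phi2)
    m11 = (p.m1 + p.m2) * p.l1**2 + p.m2 * p.l2**2 + 2.0 * p.m2 * p.l1 * p.l2 * c2
    m12 = p.m2 * p.l2**2 + p.m2 * p.l1 * p.l2 * c2
    m22 = p.m2 * p.l2**2
    h = p.m2 * p.l1 * p.l2 * s2
    cor = np.array([-h * (2.0 * w1 * w2 + w2 * w2), h * w1 * w1])
    g1 = (p.m1 + p.m2) * p.gravity * p.l1 * np.sin(phi1) \
        + p.m2 * p.gravity * p.l2 * np.sin(phi1 + phi2)
    g2 = p.m2 * p.gravity * p.l2 * np.sin(phi1 + phi2)
    rhs = np.asarray(torque) - cor - np.array([g1, g2])
    det = m11 * m22 - m12 * m12
    acc1 = (m22 * rhs[0] - m12 * rhs[1]) / det
    acc2 = (m11 * rhs[1] - m12 * rhs[0]) / det
    return np.array([w1, w2, acc1, acc2])


def arm_dynamics_step(state: np.ndarray, torque: np.ndarray, params: ArmTask,
                      dt_physics: float = 1.0) -> np.ndarray:
    """One explicit RK4 step of the equations of motion (dt in ms).

    Angles are unwrapped (radians); torque is held constant over the step.
    """
    dt = dt_physics * 1e-3
    s = np.asarray(state, dtype=np.float64)
    k1 = _arm_accel(s, torque, params)
    k2 = _arm_accel(s + 0.5 * dt * k1, torque, params)
    k3 = _arm_accel(s + 0.5 * dt * k2, torque, params)
    k4 = _arm_accel(s + dt * k3, torque, params)
    out = s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite arm state")
    return out


def simulate_arm(task: ArmTask, torques: np.ndarray,
                 state0: np.ndarray | None = None,
                 dt_physics: float = 1.0) -> np.ndarray:
    """Integrate the arm over a (n_steps, 2) torque sequence; returns states
    (n_steps + 1, 4) including the initial state."""
    state = np.zeros(4) if state0 is None else np.asarray(state0, dtype=np.float64)
    n_sub = max(1, int(round(1.0 / dt_physics)))
    out = np.empty((len(torques) + 1, 4))
    out[0] = state
    for t, tau in enumerate(torques):
        for _ in range(n_sub):
            state = arm_dynamics_step(state, tau, task, dt_physics)
        out[t + 1] = state
    return out


def arm_energy(state: np.ndarray, p: ArmTask) -> float:
    """Total mechanical energy (J); conserved under zero torque."""
    phi1, phi2, w1, w2 = state
    v1sq = (p.l1 * w1)**2
    v2sq = v1sq + (p.l2 * (w1 + w2))**2 \
        + 2.0 * p.l1 * p.l2 * w1 * (w1 + w2) * np.cos(phi2)
    kinetic = 0.5 * p.m1 * v1sq + 0.5 * p.m2 * v2sq
    potential = -(p.m1 + p.m2) * p.gravity * p.l1 * np.cos(phi1) \
        - p.m2 * p.gravity * p.l2 * np.cos(phi1 + phi2)
    return float(kinetic + potential)


# -- water maze -----------------------------------------------------------

@dataclass
class MazeTask:
    """Circular arena of radius 1; goal disk of radius 0.3 centred on the
    circle of radius 0.85; one episode is T steps of 1 ms."""

    goal: np.ndarray = field(default_factory=lambda: np.array([0.85, 0.0]))
    arena_radius: float = 1.0
    goal_radius: float = 0.3
    goal_center_radius: float = 0.85
    a_scale: float = 0.02
    episode_steps: int = 2000
    reward_goal: float = 1.0
    reward_wall: float = -0.02


def sample_goal(rng: np.random.Generator, task: MazeTask | None = None) -> np.ndarray:
    """Goal centre uniform on the circle of radius 0.85."""
    t = task or MazeTask()
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return t.goal_center_radius * np.array([np.cos(theta), np.sin(theta)])


def random_arena_position(rng: np.random.Generator,
                          task: MazeTask | None = None) -> np.ndarray:
    """Uniform-by-area position inside the arena."""
    t = task or MazeTask()
    r = t.arena_radius * np.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return r * np.array([np.cos(theta), np.sin(theta)])


def maze_step(position: np.ndarray, velocity: np.ndarray, goal: np.ndarray,
              rng: np.random.Generator, task: MazeTask | None = None,
              ) -> tuple[np.ndarray, float, bool]:
    """Advance the agent; returns (new position, reward, relocated?).

    Wall crossings pay -0.02 and project the step onto the border (the
    intersection of the movement segment with the unit circle); entering the
    goal disk pays +1 (replacing any wall penalty in the same step) and
    relocates the agent uniformly in the arena.
    """
    t = task or MazeTask()
    p = np.asarray(position, dtype=np.float64)
    v = np.asarray(velocity, dtype=np.float64)
    new = p + v
    reward = 0.0
    if np.linalg.norm(new) > t.arena_radius:
        reward = t.reward_wall
        new = _border_intersection(p, v, t.arena_radius)
    relocated = False
    if np.linalg.norm(new - goal) <= t.goal_radius:
        reward = t.reward_goal
        new = random_arena_position(rng, t)
        relocated = True
    return new, reward, relocated


def _border_intersection(p: np.ndarray, v: np.ndarray, radius: float) -> np.ndarray:
    """First intersection of the segment p -> p + v with the circle |x| = radius."""
    a = v @ v
    if a == 0.0:
        return p
    b = 2.0 * (p @ v)
    c = p @ p - radius * radius
    disc = max(b * b - 4.0 * a * c, 0.0)
    s = (-b + np.sqrt(disc)) / (2.0 * a)
    s = min(max(s, 0.0), 1.0)
    out = p + s * v
    # guard against rounding pushing the point outside
    norm = np.linalg.norm(out)
    if norm > radius:
        out = out * (radius / norm)
    return out


# -- one-shot pattern store / complete / delete ---------------------------

@dataclass
class PatternTask:
    """One episode of the four-phase 25-bit pattern task.

    Phase A shows the three full patterns (no targets), phase B their
    partial versions (targets = full patterns), phase C a one-hot delete
    cue, and phase D the partials again with the deleted pattern's target
    replaced by the closest kept pattern (Hamming distance, lower index on
    ties).
    """

    patterns: np.ndarray          # (3, 25)
    partials: np.ndarray          # (3, 25)
    delete_index: int             # in {0, 1, 2}
    targets_b: np.ndarray = None  # (3, 25)
    targets_d: np.ndarray = None  # (3, 25)
    n_bits: int = 25
    item_ms: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.delete_index < len(self.patterns):
            raise ValueError("delete_index out of range")
        if np.any(self.partials > self.patterns):
            raise ValueError("a partial pattern contains a 1 absent from its source")
        if self.targets_b is None:
            self.targets_b = self.patterns.copy()
        if self.targets_d is None:
            self.targets_d = self.patterns.copy()
            self.targets_d[self.delete_index] = self.patterns[
                closest_kept_pattern(self.patterns, self.delete_index)]


def closest_kept_pattern(patterns: np.ndarray, delete_index: int) -> int:
    """Index of the kept pattern with minimal Hamming distance to the deleted
    one; ties resolved toward the lower index."""
    deleted = patterns[delete_index]
    best, best_d = None, None
    for i, p in enumerate(patterns):
        if i == delete_index:
            continue
        d = int(np.sum(p != deleted))
        if best_d is None or d < best_d:
            best, best_d = i, d
    return best


def build_pattern_episode(rng: np.random.Generator, n_patterns: int = 3,
                          n_bits: int = 25, drop_prob: float = 0.4) -> PatternTask:
    """Sample one episode: i.i.d. Bernoulli(0.5) bits; partials zero each
    1-bit independently with probability ``drop_prob``; random delete index."""
    patterns = (rng.random((n_patterns, n_bits)) < 0.5).astype(np.int64)
    keep = rng.random((n_patterns, n_bits)) >= drop_prob
    partials = patterns * keep
    delete_index = int(rng.integers(n_patterns))
    return PatternTask(patterns=patterns, partials=partials,
                       delete_index=delete_index, n_bits=n_bits)
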