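# Methods

This note documents the models, parameter conventions and numerical choices
behind `snnl2l`, and what the synthetic task generators do and do not
emulate.

## Neuron model and units

Neurons are discrete-time leaky integrate-and-fire units, step δt = 1 ms:

    V(t+δt) = α V(t) + (1−α) R_m I(t) − v_th z(t),   α = e^(−δt/τ_m),
    z(t)    = H(V(t) − A(t)) gated by a refractory countdown,
    A(t)    = v_th + β a(t),   a(t+δt) = ρ a(t) + (1−ρ) z(t),  ρ = e^(−δt/τ_a).

Conventions and edge decisions:

* **Units.** Potentials/thresholds in mV (v_th = 30 mV), time in ms.
  Synaptic weights are stored as voltage-valued drive (R_m · I), with the
  weight scale w0 = 1 Volt/R_m · δt = 1000 mV; initial weights are
  w0/√n_in · N(0,1), n_in = number of afferents.  This makes R_m (1 GΩ)
  drop out of the update.
* **Reset.** Subtractive, always of fixed magnitude v_th — *not* the current
  adaptive threshold A(t).  The governing update is defined for the plain LIF
  neuron; the adapting neuron reuses it unchanged.
  The membrane continues to integrate during the refractory period; only the
  spike is gated.  The spike test is strict (V > A; equality does not fire).
* **Refractoriness.** A spike at step t starts a countdown of ⌈τ_ref/δt⌉
  steps; the neuron can fire again at t + τ_ref/δt + 1 at the earliest.
  τ_ref = 5 ms everywhere except the navigation task (3 ms).
* **Delays.** Integer ≥ 1 step per synapse; a spike emitted at t first
  reaches a target's current at t + d, so there is no same-step recurrence.
  All tasks use d = 1 ms except the navigation task (d uniform on 1–10 ms,
  frozen at initialization).
* **Initial conditions.** V = a = 0, empty (zero) delay buffers, no
  refractory carry-over.
* **SFA population.** A configured fraction of neurons receives β > 0
  (1.6–1.7 mV by task) with adaptation time constants spread uniformly over
  the task's τ_a range; the rest are plain LIF (β = 0), which is bit-exactly
  equivalent to removing the adaptation variable.

## Surrogate-gradient BPTT

Outer-loop gradients are exact reverse-mode derivatives of the unrolled
simulation in which every occurrence of the spike Heaviside — including the
reset term, which is the same computational node — carries the dampened
pseudo-derivative γ · max(0, 1 − |v|), with v = (V − A)/A normalized by the
*current* adaptive threshold and γ = 0.3.  The adaptation recursion is linear
in its hidden state and is differentiated exactly (no dampening on the ρ
path).  The refractory gate is treated as a non-differentiable constant:
while the countdown is active the spike (and its derivative) is zero.

The engine is written directly in numpy (reverse accumulation over the
recorded forward trace; no truncation — episodes are unrolled in full).
Two independent routes validate it in the test suite: central finite
differences in a regime where the graph is provably smooth (no spikes and
the membrane outside the surrogate's active window), and a forward-mode
tangent propagation of the identical surrogate graph written separately in
the tests.  Gradients also flow through spikes buffered in a carried-in
network state, so mid-episode gradient computation is exact.

Readouts own their weight gradients: per-step mean-rate features (20 ms
windows), exponential spike traces (τ = 50 ms arm / 100 ms pattern), or
non-spiking leaky integrators (τ_out = 20 ms, no reset) for the navigation
policy head.  Readout weights are initialized at scale 1/√n *without* the w0
factor: w0 converts binary spikes into mV-scale currents, whereas the
readout maps dimensionless rate/trace features to output units.

## Task families (synthetic generators)

All generators are pure functions of named seed streams derived from the run
seed, so every fixture is regenerable bit-exactly.

**Sinusoid meta-regression.** Tasks y = A sin(φ + x), A ~ U[0.1, 5],
φ ~ U[0, π]; per episode K = 500 steps of 20 ms, inputs x^k ~ U[−5, 5]
i.i.d., feedback channel carries y^(k−1) (0 at the first step).  Both
channels use a 100-neuron Gaussian population code (r_max = 200 Hz) over
[−5, 5].  The tuning width for this task is σ = (range)/100 = 0.1 — i.e.
roughly the spacing of the preferred values, the canonical overlapping
population code.  (The arm task's much narrower σ = range/1000 would leave ~70 %
of inputs encoded by silence and, at desk scale, prevents the inner loop
from receiving x at all; the tuning width for this task is therefore a
package decision.)
Loss: Σ_k (y^k − ŷ^k)² + λ (f_avg − f0)², λ = 30, f0 = 20 Hz.

**Two-link arm.** Planar rigid two-link pendulum under gravity
(g = 9.81 m/s²), point masses at the link ends, no friction — the standard
manipulator equations M(φ)φ̈ + C(φ, φ̇) + G(φ) = τ with φ1 measured from the
downward vertical and φ2 relative to link 1.  Masses and lengths
~ U[0.5, 2] per episode; torques piecewise constant over 10 ms blocks,
each block ~ U[−5, 5] N·m per joint (a zero-mean bounded law; the
bound is exposed in config).  Integration is
explicit RK4 at 1 ms; with zero torque the integrator conserves mechanical
energy to better than 1e−6 relative over 1 s (verified in the tests).  Over
tens of seconds the double pendulum is chaotic, so step-halving agreement is
asserted over short horizons only.  Inputs: torques and 100 ms-delayed
joint angles (zero for the first 100 ms; angles wrapped to [−π, π] for
encoding), each via a 100-neuron code with σ = range/1000;
output: trace readout of both angles; loss: time-integrated squared angle
error (no firing term).

**Water maze.** Unit-radius arena; goal disk radius 0.3 centred uniformly
on the circle of radius 0.85; episodes T = 2000 steps of 1 ms.  Action: a
Gaussian policy over a velocity of norm ≤ a_scale = 0.02 (tanh means,
sigmoid variances from five leaky readout potentials; the fifth readout is
the value estimate).  Wall crossings pay −0.02 and project the step onto
the border (segment–circle intersection); entering the goal pays +1,
*replacing* a wall penalty incurred in the same step, and relocates the agent uniformly by area.
Inputs: 2 × 40 place-cell-like neurons (rate 500 · e^(−100 Δ²) Hz) plus
2 × 40 reward-event neurons firing in synchrony on +1 / −0.02.  The
network is Dale-constrained (200 excitatory + 80 inhibitory LIF, 120
excitatory SFA with τ_a = 1200 ms), 20 % connectivity governed *globally*
by DEEP R across input, recurrent and readout matrices, τ_m ~ U[15, 30] ms,
trainable per-neuron current-noise scales ν (init 0.03) for learned
exploration.  Training: K = 10 episodes collected under frozen parameters,
then one Adam step (lr 0.01 halved every 5000 iterations, Adam ε = 1e−5) of
the clipped-surrogate objective (ε = 0.2, discount η = 0.99, finite-horizon
returns of strictly future rewards, advantage = return − value under the
collecting parameters; no GAE, no extra epochs, no advantage normalization)
plus value (μ_v = 1), entropy (μ_e = 0.001) and firing (μ_firing = 100,
f0 = 10 Hz) terms.  Trajectories are conditioned on the recorded noise
draws, so ν receives exact gradients through the noise path.

**Pattern store/complete/delete.** Three 25-bit Bernoulli(0.5) patterns per
episode; partial cues zero each 1-bit with probability 0.4.  Phases (100 ms
per item): A — show the three patterns; B — show partials, targets are the
full patterns; C — 3-bit one-hot delete cue; D — partials again, the
deleted index's target is the kept pattern closest in Hamming distance
(ties → lower index).  Inputs use 5 neurons per bit at 200/2 Hz; outputs
are logistic-squashed trace readouts, with each item's prediction taken as
the mean readout over its 100 ms window.  Loss: mean bitwise binary
cross-entropy over phases B and D (the standard "+" form) + λ (f_avg − f0)², λ = 5.
Phase A/C carry no targets.

## Initialization and rewiring

Sign-free networks: Gaussian w0/√n_in.  Dale-constrained networks: per-neuron
sign κ ~ Bernoulli(frac_exc) over {−1, +1} (or an explicit E/I layout),
magnitudes |N(0, 1)| column-signed by κ, per-row zero-sum balancing, spectral
normalization (divide by the largest |eigenvalue|; non-square matrices are
subselected from a larger square one), then w0.  The balancing constant is
added only to the sign class whose magnitudes must grow (excess excitation →
inhibitory entries become more negative, and vice versa): a single constant
applied to *every* entry would flip the sign of roughly a third of the
entries at realistic E/I ratios, violating the sign constraint the same
construction is meant to guarantee.  Rows with a single sign class are left
unbalanced with a warning.

DEEP R keeps sparse networks sign-consistent at a fixed connection count:
active weights take the optimizer step plus a constant L1 shrinkage
lr · l1 · sign(w) (l1 = 0.01; the stochastic-exploration temperature is 0,
so the only randomness is reconnection sampling); any active weight pushed
across zero against its owner's sign is disconnected, and for each removal
one uniformly sampled free coordinate is activated at magnitude 0 with the
owner's sign.  In the navigation task the connection budget is global over
W_in, W_rec and W_out; recurrent, readout and input columns all inherit
their presynaptic neuron's sign the same way.

## Analysis instruments

The **internal-model probe** snapshots the full dynamic state mid-episode
(potentials, adaptation variables, refractory counters, delay buffers),
presents each grid input (101 points over [−5, 5], one 20 ms step each,
alongside a caller-chosen feedback value) to a *copy*, and decodes the
output.  The resumable state is bit-identical afterwards; the test suite
verifies that a probed-and-resumed episode equals an unprobed control run
exactly.

The **linear baseline** fits slope + intercept per episode to the first half
of the analog (x, y) pairs and reports the mean squared error on the second
half, averaged over episodes (≥ 5000 at full scale; two disjoint 2500-episode
batches agree within 2 %).  Degenerate episodes (constant inputs) are skipped
with a warning.

## Desk-scale study sizes

The validation suite runs everything on one CPU: the L2L learning signature
uses the sinusoid family with 80 neurons, episodes of 100 × 20 ms steps,
batch 20 and 200 Adam iterations at lr = 0.03 (the full-scale lr of 1e−3 is
matched to 5000-iteration runs; at the mV weight scale it moves weights by
only ~0.3 % in 200 iterations, so the short desk protocol scales the step
size up accordingly — with it, held-out prediction beats the per-episode
OLS baseline on every seed tried).  The gradient oracles use 3-neuron, 20-step networks; rewiring
invariants run 1000 steps on 40-neuron matrices; the navigation and pattern
machinery is exercised at reduced sizes (tens of neurons, hundreds of steps).
The shipped `*-full` presets carry the full-scale reference configurations
unchanged; they are cluster-scale and are not executed by the test suite.

## What the generators do not emulate

Synthetic episodes capture the statistical structure of the task families,
not biological recordings: there is no sensory noise beyond the
Bernoulli spike sampling, the arm has point-mass links and no friction or
motor noise, the maze has no visual input (place-cell coding is the designed
interface), and pattern bits are i.i.d.  Passing tests therefore
demonstrate correctness of the dynamics, gradients and protocols, and
desk-scale learnability — not quantitative reproduction of the full-scale
endpoints, which require the shipped paper presets on cluster budgets.

## Known limitations

* Forward traces are held in memory for BPTT (no checkpoint/recompute), so
  full-scale arm episodes (30 s × 600 neurons × batch 80) need a
  large-memory machine; desk scales are unaffected.
* The clipped surrogate is implemented in its simplest form (one
  optimizer step per data collection); with a single step the clipping is
  inactive at the point of linearization and acts only as a safeguard.
* Time-rescaling (δt ≠ 1 ms) is exposed for verification of the integrator
  only; all task protocols assume 1 ms.
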