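"""Loss functions, the Adam recursion, PPO bookkeeping, and the frozen-
weight contract of the inner loop."""
import numpy as np
import pytest

from snnl2l import Adam, LossConfig, PPOConfig, discounted_return
from snnl2l.losses import (arm_loss, firing_regularizer,
                           firing_regularizer_grad, gaussian_entropy,
                           gaussian_log_prob, noisy_current, pattern_loss,
                           ppo_loss, regression_loss)
from snnl2l.training import (MazeExperiment, PatternExperiment,
                             SinusoidExperiment)

from _reference import reference_adam


class TestFiringRegularizer:
    def test_on_target_is_zero(self):
        z = np.zeros((1000, 1, 10))
        z[::50] = 1.0  # 20 Hz exactly
        assert firing_regularizer(z, 20.0, 30.0) == pytest.approx(0.0)

    def test_silent_network_value(self):
        """Silent network at f0 = 20 Hz, lambda = 30 -> 30 * 400 = 12000."""
        z = np.zeros((1000, 1, 50))
        assert firing_regularizer(z, 20.0, 30.0) == pytest.approx(12000.0)

    def test_quadratic_scaling(self):
        z1 = np.zeros((1000, 1, 10)); z1[::100] = 1.0   # 10 Hz, dev 10
        z2 = np.zeros((1000, 1, 10))                    # 0 Hz, dev 20
        r1 = firing_regularizer(z1, 20.0, 1.0)
        r2 = firing_regularizer(z2, 20.0, 1.0)
        assert r2 == pytest.approx(4 * r1)

    def test_grad_matches_finite_difference(self):
        z = np.zeros((100, 2, 5)); z[::10] = 1.0
        g = firing_regularizer_grad(z, 20.0, 30.0)
        h = 1.0  # one extra spike
        z2 = z.copy(); z2[3, 1, 2] += h
        fd = firing_regularizer(z2, 20.0, 30.0) - firing_regularizer(z, 20.0, 30.0)
        # first-order term dominates; compare within the quadratic correction
        assert g[3, 1, 2] == pytest.approx(fd, rel=0.05)


class TestTaskLosses:
    def test_perfect_regression_at_target_rate_is_zero(self):
        z = np.zeros((1000, 1, 10)); z[::50] = 1.0
        pred = np.ones((50, 1)); targ = np.ones((50, 1))
        assert regression_loss(pred, targ, z, LossConfig()) == pytest.approx(0.0)

    def test_single_step_error(self):
        pred = np.zeros((10, 1)); targ = np.zeros((10, 1)); targ[3] = 2.0
        assert regression_loss(pred, targ, None, LossConfig()) == pytest.approx(4.0)

    def test_regression_batch_mean_oracle(self, rng):
        pred = rng.normal(size=(20, 3)); targ = rng.normal(size=(20, 3))
        expected = np.mean([np.sum((targ[:, b] - pred[:, b])**2) for b in range(3)])
        assert regression_loss(pred, targ, None, LossConfig()) == pytest.approx(expected)

    def test_arm_loss_oracle(self, rng):
        pred = rng.normal(size=(30, 2, 2)); targ = rng.normal(size=(30, 2, 2))
        expected = np.mean([np.sum((targ[:, b] - pred[:, b])**2) for b in range(2)])
        assert arm_loss(pred, targ) == pytest.approx(expected)

    def test_pattern_loss_chance_level(self):
        p = np.full((6, 1, 25), 0.5); y = np.zeros((6, 1, 25))
        assert pattern_loss(p, y, None, LossConfig()) == pytest.approx(np.log(2))

    def test_pattern_loss_perfect_prediction(self):
        y = (np.random.default_rng(0).random((6, 1, 25)) < 0.5).astype(float)
        assert pattern_loss(y, y, None, LossConfig()) == pytest.approx(0.0, abs=1e-9)

    def test_pattern_loss_hand_computed_toy(self):
        p = np.array([[[0.9, 0.2, 0.6]]]); y = np.array([[[1.0, 0.0, 1.0]]])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.6)) / 3
        assert pattern_loss(p, y, None, LossConfig()) == pytest.approx(expected)


class TestDiscountedReturn:
    def test_zero_rewards(self):
        assert np.all(discounted_return(np.zeros(10), 0.99) == 0.0)

    def test_single_future_reward(self):
        r = np.zeros(5); r[3] = 1.0
        out = discounted_return(r, 0.99)
        assert out[2] == pytest.approx(0.99)
        assert out[3] == 0.0  # strictly future

    def test_two_rewards_geometric(self):
        r = np.zeros(6); r[1] = 1.0; r[3] = 1.0
        assert discounted_return(r, 0.99)[0] == pytest.approx(0.99 + 0.99**3)

    def test_batched(self):
        r = np.zeros((4, 2)); r[2, 1] = 1.0
        out = discounted_return(r, 0.5)
        assert out[0, 1] == pytest.approx(0.25) and np.all(out[:, 0] == 0)


class TestPPO:
    def _buffer(self, seed=0, T=50, B=4):
        g = np.random.default_rng(seed)
        mu = np.tanh(g.normal(size=(T, B, 2)))
        var = 1 / (1 + np.exp(-g.normal(size=(T, B, 2))))
        actions = mu + np.sqrt(var) * g.standard_normal((T, B, 2))
        value = g.normal(size=(T, B))
        rewards = (g.random((T, B)) < 0.02).astype(float)
        returns = discounted_return(rewards, 0.99)
        return actions, mu, var, value, returns

    def test_ratio_one_at_old_params(self):
        actions, mu, var, value, returns = self._buffer()
        lp_old = gaussian_log_prob(actions, mu, var)
        loss = ppo_loss(actions, mu, var, value, lp_old, returns, value,
                        None, PPOConfig(), LossConfig())
        # at theta = theta_old the surrogate reduces to the mean advantage
        adv = returns - value
        expected = float(np.mean(-adv + 1.0 * (returns - value)**2
                                 - 0.001 * gaussian_entropy(var)))
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_clipping_caps_large_ratios(self):
        """ratio = 1 + 2 eps with positive advantage clips at (1+eps)*adv."""
        cfg = PPOConfig(epsilon=0.2)
        actions = np.zeros((1, 1, 2)); mu = np.zeros((1, 1, 2))
        var = np.full((1, 1, 2), 0.5)
        value = np.zeros((1, 1)); returns = np.ones((1, 1))  # advantage +1
        lp = gaussian_log_prob(actions, mu, var)
        lp_old = lp - np.log(1.4)  # ratio = 1.4 = 1 + 2 eps
        lcfg = LossConfig(mu_v=0.0, mu_e=0.0)
        loss = ppo_loss(actions, mu, var, value, lp_old, returns, value,
                        None, cfg, lcfg)
        assert loss == pytest.approx(-1.2)

    def test_entropy_closed_form_against_scipy(self):
        from scipy.stats import norm
        var = np.array([0.3, 0.7])
        expected = sum(norm(scale=np.sqrt(v)).entropy() for v in var)
        assert gaussian_entropy(var) == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_difference_on_readouts(self):
        """The analytic dL/dy of the policy head agrees with numerics."""
        from snnl2l.coding import policy_decode
        g = np.random.default_rng(1)
        T, B = 10, 2
        y = g.normal(size=(T, B, 5))
        actions = g.normal(scale=0.5, size=(T, B, 2))
        rewards = (g.random((T, B)) < 0.1).astype(float)
        returns = discounted_return(rewards, 0.99)
        mu0, var0, val0 = policy_decode(y)
        lp_old = gaussian_log_prob(actions, mu0, var0) + 0.05
        cfg, lcfg = PPOConfig(), LossConfig()

        def f(yy):
            mu, var, val = policy_decode(yy)
            return ppo_loss(actions, mu, var, val, lp_old, returns, val0,
                            None, cfg, lcfg)

        _, g_y = ppo_loss(actions, mu0, var0, val0, lp_old, returns, val0,
                          None, cfg, lcfg, with_grads=True)
        h = 1e-6
        for idx in [(0, 0, 0), (3, 1, 2), (5, 0, 3), (7, 1, 4), (2, 0, 1)]:
            yp = y.copy(); yp[idx] += h
            ym = y.copy(); ym[idx] -= h
            fd = (f(yp) - f(ym)) / (2 * h)
            assert g_y[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)


class TestNoiseAndAdam:
    def test_zero_noise_scale_is_identity(self, rng):
        drive = rng.normal(size=(10, 2, 5))
        out, _ = noisy_current(drive, np.zeros(5), rng)
        np.testing.assert_array_equal(out, drive)

    def test_noise_std_matches_nu(self):
        rng = np.random.default_rng(0)
        drive = np.zeros((100000, 1, 1))
        out, eps = noisy_current(drive, np.array([0.03]), rng)
        assert np.std(out) == pytest.approx(0.03, rel=0.02)

    def test_noise_reproducible_under_seed(self):
        d = np.zeros((100, 1, 3))
        o1, _ = noisy_current(d, np.full(3, 0.03), np.random.default_rng(5))
        o2, _ = noisy_current(d, np.full(3, 0.03), np.random.default_rng(5))
        np.testing.assert_array_equal(o1, o2)

    def test_adam_matches_reference_recursion(self):
        """Driving a single parameter with an arbitrary gradient sequence
        reproduces the textbook Adam trajectory to 1e-12."""
        g = np.random.default_rng(2)
        grads = g.normal(size=30)
        opt = Adam(lr=0.01)
        theta = {"w": np.zeros(1)}
        traj = []
        for gr in grads:
            opt.step(theta, {"w": np.array([gr])})
            traj.append(theta["w"][0])
        np.testing.assert_allclose(traj, reference_adam(grads, lr=0.01),
                                   atol=1e-12)

    def test_zero_lr_keeps_weights(self):
        exp = SinusoidExperiment(n_neurons=20, n_steps=5, batch=2, lr=0.0,
                                 code_neurons=10, seed=0)
        before = exp.model.weights.state_hash()
        metrics = exp.iteration()
        assert exp.model.weights.state_hash() == before
        assert np.isfinite(metrics["loss"])


class TestInnerLoopContracts:
    def test_weights_frozen_within_episode(self):
        """Simulating an inner-loop episode must not touch the weights."""
        exp = SinusoidExperiment(n_neurons=20, n_steps=10, batch=2,
                                 code_neurons=10, seed=3)
        before = exp.model.weights.state_hash()
        data = exp.episode_batch(exp.rng_data, 2)
        exp.forward(data, exp.rng_data)
        assert exp.model.weights.state_hash() == before

    def test_batch_of_identical_tasks_mean_reduction(self):
        """Gradient over a batch of identical episodes equals the
        single-episode gradient (the batch mean of equal terms)."""
        import snnl2l.coding as coding
        from snnl2l.losses import firing_regularizer_grad
        from snnl2l.surrogate import backward
        exp = SinusoidExperiment(n_neurons=15, n_steps=8, batch=1,
                                 code_neurons=8, seed=4)
        data = exp.episode_batch(exp.rng_data, 1)

        def grads_for(reps):
            d = {"values": np.repeat(data["values"], reps, axis=1),
                 "targets": np.repeat(data["targets"], reps, axis=1)}
            rng = np.random.default_rng(9)
            x = coding.encode_values(d["values"][:, :1], exp.specs,
                                     exp.step_ms, 1.0, rng)
            x = np.repeat(x, reps, axis=1)  # identical spikes per episode
            from snnl2l.neurons import simulate
            rec = simulate(exp.model.weights, exp.model.neuron,
                           exp.model.adapt, x)
            y, feats = coding.mean_rate_decode(rec.z, exp.model.weights.w_out,
                                               exp.model.weights.b_out, 20)
            g_y = (2.0 * (y[..., 0] - d["targets"]) / reps)[..., None]
            g_z, g_w_out, _ = coding.mean_rate_decode_vjp(
                g_y, feats, exp.model.weights.w_out, 20)
            g_z = g_z + firing_regularizer_grad(rec.z, 20.0, 30.0)
            eg = backward(rec, exp.model.weights, exp.model.neuron,
                          exp.model.adapt, g_z, 0.3)
            return eg.w_rec
        np.testing.assert_allclose(grads_for(1), grads_for(3), rtol=1e-9)

    def test_maze_collect_under_frozen_params_has_unit_ppo_ratio(self):
        exp = MazeExperiment(n_exc_lif=10, n_inh_lif=4, n_sfa=6,
                             k_episodes=2, t_steps=40, seed=0)
        traj = exp.collect(exp.rng_data)
        lp = gaussian_log_prob(traj["actions"], traj["mu"], traj["var"])
        np.testing.assert_allclose(np.exp(lp - traj["log_prob_old"]), 1.0,
                                   rtol=1e-12)

    def test_maze_training_preserves_connectivity_and_signs(self):
        exp = MazeExperiment(n_exc_lif=10, n_inh_lif=4, n_sfa=6,
                             k_episodes=2, t_steps=60, seed=1)
        w = exp.model.weights
        count0 = sum(int(m.sum()) for m in (w.mask_in, w.mask_rec, w.mask_out))
        for _ in range(3):
            exp.iteration()
        count1 = sum(int(m.sum()) for m in (w.mask_in, w.mask_rec, w.mask_out))
        assert count0 == count1
        for mat, sign in ((w.w_rec, w.sign), (w.w_out, w.sign),
                          (w.w_in, exp.sign_in)):
            cs = np.broadcast_to(sign[None, :], mat.shape)
            assert np.all((mat == 0) | (np.sign(mat) == cs))
        assert np.all(np.diag(w.mask_rec) == 0)

    def test_pattern_iteration_runs_and_reports_chance_accuracy(self):
        exp = PatternExperiment(n_neurons=40, item_ms=30, batch=3, seed=2)
        m = exp.iteration()
        assert 0.3 < m["accuracy"] < 0.7
        assert np.isfinite(m["loss"])
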