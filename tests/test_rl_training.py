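"""GAE, the PPO surrogate, advantage normalization, behavioral cloning."""

import numpy as np
import pytest

from vmatrl.nn import Tensor
from vmatrl.training import (AdvantageSet, TrainConfig, compute_gae,
                             normalize_advantages, ppo_loss)


def gae_double_sum(rewards, values, dones, gamma, lam):
    """Direct-summation oracle: A_t = sum_l (gamma*lam)^l delta_{t+l},
    truncated at the terminal step."""
    n = len(rewards)
    v_next = np.append(values[1:], 0.0)
    delta = rewards + gamma * (1 - dones) * v_next - values
    adv = np.zeros(n)
    for t in range(n):
        acc = 0.0
        for l in range(n - t):
            acc += (gamma * lam) ** l * delta[t + l]
            if dones[t + l]:
                break
        adv[t] = acc
    return adv


class TestComputeGae:
    def test_single_step_episode_reduces_to_reward(self):
        out = compute_gae(([2.5], [0.0], [1.0]), gamma=0.99, lam=0.95)
        assert out.advantages[0] == pytest.approx(2.5)
        assert out.returns[0] == pytest.approx(2.5)

    def test_two_step_closed_form_with_published_constants(self):
        # zero values, rewards (0, 1): A_0 = gamma*lam * 1 = 0.9405
        out = compute_gae(([0.0, 1.0], [0.0, 0.0], [0.0, 1.0]),
                          gamma=0.99, lam=0.95)
        assert out.advantages[0] == pytest.approx(0.99 * 0.95)
        assert out.advantages[1] == pytest.approx(1.0)

    def test_recursion_equals_double_sum_on_random_trajectories(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(1, 51))
            rewards = rng.normal(size=n)
            values = rng.normal(size=n)
            dones = np.zeros(n)
            dones[-1] = 1.0
            got = compute_gae((rewards, values, dones), 0.99, 0.95).advantages
            expect = gae_double_sum(rewards, values, dones, 0.99, 0.95)
            worst = max(worst, np.abs(got - expect).max())
        assert worst < 1e-10

    def test_returns_are_advantage_plus_value(self):
        rng = np.random.default_rng(0)
        rewards, values = rng.normal(size=10), rng.normal(size=10)
        dones = np.zeros(10)
        dones[-1] = 1.0
        out = compute_gae((rewards, values, dones), 0.99, 0.95)
        assert np.allclose(out.returns, out.advantages + values, atol=1e-14)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            compute_gae(([], [], []), 0.99, 0.95)


class TestNormalizeAdvantages:
    def test_batch_mean_zero_std_one(self):
        rng = np.random.default_rng(3)
        adv, mu, sd = normalize_advantages(rng.normal(3.0, 2.0, size=200))
        assert abs(adv.mean()) < 1e-8
        assert abs(adv.std() - 1.0) < 1e-6

    def test_tiny_batches_do_not_divide_by_zero(self):
        adv, _, sd = normalize_advantages(np.array([5.0]))
        assert np.isfinite(adv).all() and sd == 1.0


def _loss_oracle(lp_new, lp_old, adv, v_new, returns, log_std, cfg):
    """Scalar-loop evaluation of the clipped surrogate."""
    n = len(adv)
    l_clip = l_vf = ent = 0.0
    for i in range(n):
        r = np.exp(lp_new[i] - lp_old[i])
        l_clip += min(r * adv[i],
                      min(max(r, 1 - cfg.clip_eps), 1 + cfg.clip_eps) * adv[i])
        l_vf += (v_new[i] - returns[i]) ** 2
        ent += sum(0.5 * np.log(2 * np.pi * np.e) + s for s in log_std[i])
    l_clip, l_vf, ent = l_clip / n, l_vf / n, ent / n
    return l_clip - cfg.c1 * l_vf + cfg.c2 * ent


class TestPpoLoss:
    def _random_batch(self, rng, n=16, d=5):
        lp_old = rng.normal(size=n)
        lp_new = lp_old + rng.normal(scale=0.3, size=n)
        adv = rng.normal(size=n)
        v_new = rng.normal(size=n)
        returns = rng.normal(size=n)
        log_std = rng.normal(scale=0.4, size=(n, d))
        return lp_new, lp_old, adv, v_new, returns, log_std

    def test_identical_policies_and_perfect_critic(self):
        cfg = TrainConfig()
        rng = np.random.default_rng(1)
        lp = rng.normal(size=12)
        adv = rng.normal(size=12)
        returns = rng.normal(size=12)
        log_std = rng.normal(size=(12, 4))
        from vmatrl.policies import policy_entropy
        ent = policy_entropy(Tensor(log_std))
        obj, comps = ppo_loss(Tensor(lp), lp, adv, Tensor(returns), returns,
                              ent, cfg)
        assert comps["l_vf"] == pytest.approx(0.0, abs=1e-14)
        expect = adv.mean() + cfg.c2 * float(ent.mean().data)
        assert comps["objective"] == pytest.approx(expect, abs=1e-12)

    def test_clip_boundary_with_published_epsilon(self):
        # A = 1, R = 1.3, eps = 0.15: the clipped branch wins at 1.15
        cfg = TrainConfig()
        lp_old = np.array([0.0])
        lp_new = np.array([np.log(1.3)])
        obj, comps = ppo_loss(Tensor(lp_new), lp_old, np.array([1.0]),
                              Tensor(np.array([0.0])), np.array([0.0]),
                              Tensor(np.array([0.0])), cfg)
        assert comps["l_clip"] == pytest.approx(1.15)

    def test_matches_scalar_loop_oracle_on_random_batches(self):
        cfg = TrainConfig()
        rng = np.random.default_rng(7)
        from vmatrl.policies import policy_entropy
        worst = 0.0
        for _ in range(100):
            lp_new, lp_old, adv, v_new, returns, log_std = self._random_batch(rng)
            ent = policy_entropy(Tensor(log_std))
            _, comps = ppo_loss(Tensor(lp_new), lp_old, adv, Tensor(v_new),
                                returns, ent, cfg)
            expect = _loss_oracle(lp_new, lp_old, adv, v_new, returns, log_std, cfg)
            worst = max(worst, abs(comps["objective"] - expect))
        assert worst < 1e-10

    def test_clip_gradient_is_inactive_inside_and_active_outside(self):
        cfg = TrainConfig()
        adv = np.array([1.0])
        for ratio, expect_grad in ((1.05, True), (1.30, False)):
            lp_new = Tensor(np.array([np.log(ratio)]), requires_grad=True)
            obj, _ = ppo_loss(lp_new, np.array([0.0]), adv,
                              Tensor(np.array([0.0])), np.array([0.0]),
                              Tensor(np.array([0.0])), cfg)
            obj.backward()
            has_grad = bool(np.abs(lp_new.grad).max() > 1e-12)
            assert has_grad is expect_grad

    def test_nan_components_abort(self):
        cfg = TrainConfig()
        with pytest.raises(FloatingPointError):
            ppo_loss(Tensor(np.array([np.nan])), np.array([0.0]), np.array([1.0]),
                     Tensor(np.array([0.0])), np.array([0.0]),
                     Tensor(np.array([0.0])), cfg)


class TestTrainConfig:
    def test_published_constants_are_the_defaults(self):
        cfg = TrainConfig()
        assert (cfg.gamma, cfg.lam) == (0.99, 0.95)
        assert cfg.clip_eps == 0.15
        assert (cfg.c1, cfg.c2) == (0.45, 0.005)
        assert cfg.mu_steps == 8

    def test_invalid_discount_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(gamma=1.5)
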