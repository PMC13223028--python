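"""Reinforced representation learning: encoder, policy, rewards, advantages
and the actor-critic updates against small closed-form oracles."""

import numpy as np
import pytest

from rehabprog import rrl_core
from rehabprog._autograd import Tensor, backward
from rehabprog.rrl_core import (EncoderConfig, Trajectory, advantage_estimates,
                                actor_critic_update, build_trajectories,
                                discounted_return, encode_frames,
                                gaussian_log_density, init_encoder_params,
                                init_policy, policy_sample, refine_embedding,
                                reward_signals, step_reward)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def test_encoder_shape_contract(rng):
    cfg = EncoderConfig(n_features=12, kernel=3, channels=(4, 4),
                        embedding_dim=6)
    params = init_encoder_params(cfg, rng, dtype=np.float64)
    z = encode_frames(rng.standard_normal((10, 12)), params, cfg)
    assert z.data.shape == (10, 6)
    zb = encode_frames(rng.standard_normal((3, 10, 12)), params, cfg)
    assert zb.data.shape == (3, 10, 6)
    with pytest.raises(ValueError):
        encode_frames(rng.standard_normal((10, 13)), params, cfg)


def test_encoder_zero_weights_zero_output(rng):
    cfg = EncoderConfig(n_features=5, kernel=3, channels=(2, 2),
                        embedding_dim=3, activation="tanh")
    params = init_encoder_params(cfg, rng)
    for p in params.values():
        p.data = np.zeros_like(p.data)
    z = encode_frames(rng.standard_normal((7, 5)), params, cfg)
    np.testing.assert_array_equal(z.data, 0.0)


def test_encoder_gradient_matches_finite_differences(rng):
    cfg = EncoderConfig(n_features=6, kernel=3, channels=(3, 3),
                        embedding_dim=4)
    params = init_encoder_params(cfg, rng, dtype=np.float64)
    x = rng.standard_normal((5, 6))
    w = rng.standard_normal(4)

    def readout():
        z = encode_frames(x, params, cfg)
        return (z @ Tensor(w.reshape(-1, 1))).sum()

    loss = readout()
    backward(loss)
    h = 1e-5
    for name, p in params.items():
        flat = p.data.reshape(-1)
        grad = p.grad.reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp = float(readout().data)
            flat[i] = orig - h
            lm = float(readout().data)
            flat[i] = orig
            fd = (lp - lm) / (2 * h)
            assert abs(fd - grad[i]) < 1e-4 * max(abs(fd), abs(grad[i]), 1.0), name


# ---------------------------------------------------------------------------
# policy
# ---------------------------------------------------------------------------

def test_policy_deterministic_mode_returns_mean(rng):
    policy = init_policy(3, 2, rng)
    s = rng.standard_normal(3)
    a, _ = policy_sample(s, policy, deterministic=True)
    np.testing.assert_allclose(a, s @ policy.W_mean + policy.b_mean)


def test_standard_normal_log_density():
    lp = gaussian_log_density(np.zeros(1), np.zeros(1), np.zeros(1))
    assert lp == pytest.approx(-0.5 * np.log(2 * np.pi))


def test_policy_sample_mean_monte_carlo(rng):
    policy = init_policy(3, 2, rng)
    s = rng.standard_normal(3)
    mean = s @ policy.W_mean + policy.b_mean
    draws, _ = policy_sample(np.tile(s, (200_000, 1)), policy, rng)
    se = np.exp(policy.log_std) / np.sqrt(draws.shape[0])
    assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)


def test_policy_rejects_bad_state(rng):
    policy = init_policy(2, 2, rng)
    with pytest.raises(ValueError):
        policy_sample(np.array([np.nan, 0.0]), policy, rng)


def test_refine_embedding_identity_saturation_and_bound(rng):
    z = rng.standard_normal(5)
    np.testing.assert_array_equal(refine_embedding(z, np.zeros(5)), z)
    np.testing.assert_allclose(refine_embedding(np.zeros(3), np.full(3, 50.0)),
                               np.ones(3), atol=1e-9)
    a = rng.standard_normal(5) * 10
    assert np.abs(refine_embedding(z, a) - z).max() <= 1.0 + 1e-12
    with pytest.raises(ValueError):
        refine_embedding(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# rewards / returns / advantages
# ---------------------------------------------------------------------------

def test_reward_signals_hand_cases(rng):
    policy = init_policy(2, 2, rng)
    # force g(s) = 0.5 via zero aux weights
    policy.W_aux[:] = 0.0
    policy.b_aux = 0.0
    acc, align = reward_signals(np.zeros((1, 2)), y=0.7, gamma=np.array([0.4]),
                                policy=policy)
    assert acc[0] == pytest.approx(0.8) and align[0] == pytest.approx(0.9)


@pytest.mark.parametrize("acc,align,alpha,beta,expected", [
    (1.0, 1.0, 0.6, 0.4, 1.0),
    (1.0, 0.0, 0.6, 0.4, 0.6),
    (0.5, 0.5, 0.3, 0.7, 0.5),
])
def test_step_reward_convex_combination(acc, align, alpha, beta, expected):
    assert step_reward(acc, align, alpha, beta) == pytest.approx(expected)


def test_step_reward_rejects_unnormalized_weights():
    with pytest.raises(ValueError):
        step_reward(1.0, 1.0, 0.6, 0.5)


def test_discounted_return_convention():
    assert discounted_return(np.array([1.0, 1, 1]), 0.5) == pytest.approx(1.75)
    assert discounted_return(np.ones(5), 1.0) == 5.0
    assert discounted_return(np.array([3.0, 9, 9]), 0.0) == 3.0


def test_advantage_td_hand_cases():
    adv = advantage_estimates(np.array([1.0]), np.array([0.0]), 0.9)
    assert adv[0] == pytest.approx(1.0)
    adv = advantage_estimates(np.array([1.0, 0.0]), np.array([1.0, 0.0]), 0.9)
    assert adv[0] == pytest.approx(0.0)  # r + ζV' − V = 1 + 0 − 1


def test_reward_bounds_property(rng):
    policy = init_policy(4, 4, rng)
    states = rng.standard_normal((50, 4))
    acc, align = reward_signals(states, y=rng.uniform(), gamma=rng.uniform(size=50),
                                policy=policy)
    r = step_reward(acc, align, 0.6, 0.4)
    assert (r >= 0).all() and (r <= 1).all()


# ---------------------------------------------------------------------------
# actor-critic learning on toy problems
# ---------------------------------------------------------------------------

def _make_traj(states, actions, rewards, values, zeta, policy):
    adv = advantage_estimates(rewards, values, zeta)
    lp = gaussian_log_density(actions, states @ policy.W_mean + policy.b_mean,
                              policy.log_std)
    return Trajectory(states=states, actions=actions, log_probs=lp,
                      rewards=rewards, values=values, advantages=adv,
                      refined=refine_embedding(states, actions))


def test_positive_advantage_increases_action_log_density(rng):
    policy = init_policy(2, 2, rng)
    policy.lr_actor = 1e-3
    s = np.ones((1, 2))
    a = np.array([[0.5, -0.3]])
    traj = Trajectory(states=s, actions=a,
                      log_probs=gaussian_log_density(
                          a, s @ policy.W_mean + policy.b_mean, policy.log_std),
                      rewards=np.array([1.0]), values=np.array([0.0]),
                      advantages=np.array([2.0]), refined=refine_embedding(s, a))
    before = gaussian_log_density(a, s @ policy.W_mean + policy.b_mean,
                                  policy.log_std)
    actor_critic_update([traj], policy)
    after = gaussian_log_density(a, s @ policy.W_mean + policy.b_mean,
                                 policy.log_std)
    assert after > before


def test_zero_advantage_leaves_actor_unchanged(rng):
    policy = init_policy(2, 2, rng)
    W0 = policy.W_mean.copy()
    s = rng.standard_normal((4, 2))
    a = rng.standard_normal((4, 2))
    traj = Trajectory(states=s, actions=a, log_probs=np.zeros(4),
                      rewards=np.zeros(4), values=np.zeros(4),
                      advantages=np.zeros(4), refined=refine_embedding(s, a))
    actor_critic_update([traj], policy)
    np.testing.assert_array_equal(policy.W_mean, W0)


def test_policy_gradient_estimator_unbiased(rng):
    """1-dim Gaussian toy with advantage Â = a: E[∇_μ log π · a] = 1."""
    mu, sigma = 0.3, 0.7
    draws = mu + sigma * rng.standard_normal(200_000)
    grads = (draws - mu) / sigma**2 * draws
    assert grads.mean() == pytest.approx(1.0, abs=0.02)


def test_two_armed_bandit_prefers_rewarding_arm(rng):
    """Arms at +1 (reward 1) and −1 (reward 0); after policy-gradient
    updates, P(choose +1) = P(a > 0) > 0.9."""
    policy = init_policy(1, 1, rng, zeta=0.0)
    policy.lr_actor = 0.05
    state = np.ones((1, 1))
    baseline = 0.5
    for _ in range(2000):
        a, _ = policy_sample(state, policy, rng)
        reward = 1.0 if a[0, 0] > 0 else 0.0
        baseline = 0.9 * baseline + 0.1 * reward
        traj = Trajectory(states=state, actions=a, log_probs=np.zeros(1),
                          rewards=np.array([reward]), values=np.array([baseline]),
                          advantages=np.array([reward - baseline]),
                          refined=refine_embedding(state, a))
        actor_critic_update([traj], policy)
    import math
    mean = float((state @ policy.W_mean + policy.b_mean).item())
    sd = float(np.exp(policy.log_std).item())
    p_right = 1.0 - 0.5 * (1 + math.erf((0 - mean) / (sd * np.sqrt(2))))
    assert abs(mean - 1.0) < abs(mean + 1.0)  # closer to the rewarding arm
    assert p_right > 0.9


def test_critic_matches_value_iteration_on_two_state_chain(rng):
    """Deterministic chain s1 -> s2 -> terminal with rewards (0.3, 0.9):
    V(s2) = 0.9, V(s1) = 0.3 + ζ·0.9."""
    zeta = 0.8
    policy = init_policy(2, 2, rng, zeta=zeta)
    policy.lr_critic = 0.2
    states = np.eye(2)
    rewards = np.array([0.3, 0.9])
    for _ in range(3000):
        values = states @ policy.W_v + policy.b_v
        traj = Trajectory(states=states, actions=np.zeros((2, 2)),
                          log_probs=np.zeros(2), rewards=rewards,
                          values=values,
                          advantages=np.zeros(2),
                          refined=states)
        actor_critic_update([traj], policy)
    V = states @ policy.W_v + policy.b_v
    v_oracle = np.array([0.3 + zeta * 0.9, 0.9])
    np.testing.assert_allclose(V, v_oracle, atol=1e-2)


def test_rollout_batch_shapes_and_determinism(rng):
    policy = init_policy(3, 3, rng)
    Z = rng.standard_normal((2, 6, 3))
    y = rng.uniform(size=2)
    gamma = rng.uniform(size=(2, 6))
    t1 = build_trajectories(Z, y, gamma, policy, np.random.default_rng(5))
    t2 = build_trajectories(Z, y, gamma, policy, np.random.default_rng(5))
    assert len(t1) == 2 and t1[0].states.shape == (6, 3)
    np.testing.assert_array_equal(t1[0].actions, t2[0].actions)
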