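"""Reinforced representation learning.

A 1-D convolutional encoder maps each frame's flattened multimodal features
to an embedding z_t; the trial is then treated as a finite-horizon Markov
decision process whose states are the embeddings (s_t = z_t) and whose
continuous actions are bounded latent refinements z*_t = z_t + tanh(a_t).

The composite per-step reward mixes two bounded terms derived from an
auxiliary per-state score head g(·) ∈ [0, 1] evaluated on the refined
state (so R(s_t, a_t) genuinely depends on the action taken):

    Acc(t)   = 1 − |g(z*_t) − y|       (per-step prediction quality)
    Align(t) = 1 − |g(z*_t) − γ_t|     (agreement with the clinical scale)
    r_t      = α·Acc(t) + β·Align(t),  α + β = 1  (defaults α=0.6, β=0.4)

A diagonal-Gaussian actor is trained by advantage-weighted policy gradients
(one-step TD advantages from a linear critic); the critic by semi-gradient
TD(0); the auxiliary head toward the label and the clinical scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor, conv1d_time, softplus

__all__ = [
    "EncoderConfig",
    "PolicyParams",
    "Trajectory",
    "init_encoder_params",
    "encode_frames",
    "init_policy",
    "policy_sample",
    "gaussian_log_density",
    "refine_embedding",
    "aux_score",
    "reward_signals",
    "step_reward",
    "discounted_return",
    "advantage_estimates",
    "build_trajectories",
    "actor_critic_update",
    "run_rl_phase",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EncoderConfig:
    """Convolutional spatiotemporal encoder: two 1-D conv stages over time
    (kernel 5) on the flattened per-frame features, then a linear map to the
    embedding space."""

    n_features: int = 275          # 11 channels x 25 joints
    kernel: int = 5
    channels: tuple[int, int] = (16, 16)
    embedding_dim: int = 16
    # softplus: smooth, non-saturating, and a natural rectifier — motion
    # *energy* (oscillation amplitude) stays linearly readable instead of
    # being clipped the way a saturating unit would clip large excursions
    activation: str = "softplus"


def init_encoder_params(cfg: EncoderConfig, rng: np.random.Generator,
                        dtype=np.float32) -> dict[str, Tensor]:
    """Scaled-normal initialisation of the encoder weights."""
    c1, c2 = cfg.channels
    k, F, m = cfg.kernel, cfg.n_features, cfg.embedding_dim

    def w(*shape):
        fan_in = int(np.prod(shape[:-1]))
        return Tensor((rng.standard_normal(shape) / np.sqrt(fan_in)).astype(dtype),
                      requires_grad=True)

    def b(n):
        return Tensor(np.zeros(n, dtype=dtype), requires_grad=True)

    return {
        "conv1_W": w(k, F, c1), "conv1_b": b(c1),
        "conv2_W": w(k, c1, c2), "conv2_b": b(c2),
        "emb_W": w(c2, m), "emb_b": b(m),
    }


def encode_frames(x, params: dict[str, Tensor], cfg: EncoderConfig) -> Tensor:
    """Encode flattened frames into embeddings.

    Parameters
    ----------
    x : array or Tensor of shape (T, F) or (B, T, F)
        Flattened per-frame features (joints-major channel layout).

    Returns a Tensor of shape (..., T, m): exactly one embedding per frame.
    """
    x = as_tensor(x)
    squeeze = x.ndim == 2
    if squeeze:
        x = x.reshape(1, *x.shape)
    if x.shape[-1] != cfg.n_features:
        raise ValueError(
            f"frame feature length {x.shape[-1]} != expected {cfg.n_features}")
    act = {"tanh": Tensor.tanh, "softplus": softplus}[cfg.activation]
    h = act(conv1d_time(x, params["conv1_W"], params["conv1_b"]))
    h = act(conv1d_time(h, params["conv2_W"], params["conv2_b"]))
    z = h @ params["emb_W"] + params["emb_b"]
    if squeeze:
        z = z[0]
    return z


# ---------------------------------------------------------------------------
# policy / critic / auxiliary head
# ---------------------------------------------------------------------------

@dataclass
class PolicyParams:
    """Actor (state → action mean + global log-std), linear critic, and
    auxiliary score head; plus the MDP scalars."""

    W_mean: np.ndarray
    b_mean: np.ndarray
    log_std: np.ndarray
    W_v: np.ndarray
    b_v: float
    W_aux: np.ndarray
    b_aux: float
    zeta: float = 0.95
    alpha: float = 0.6
    beta: float = 0.4
    lr_actor: float = 1e-3
    lr_critic: float = 1e-2
    lr_aux: float = 1e-2

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("reward weights must satisfy α, β >= 0 and α + β = 1")
        if not (0.0 <= self.zeta <= 1.0):
            raise ValueError("discount ζ must be in [0, 1]")

    def copy(self) -> "PolicyParams":
        return PolicyParams(
            W_mean=self.W_mean.copy(), b_mean=self.b_mean.copy(),
            log_std=self.log_std.copy(), W_v=self.W_v.copy(), b_v=self.b_v,
            W_aux=self.W_aux.copy(), b_aux=self.b_aux, zeta=self.zeta,
            alpha=self.alpha, beta=self.beta, lr_actor=self.lr_actor,
            lr_critic=self.lr_critic, lr_aux=self.lr_aux)


@dataclass
class Trajectory:
    """One trial's RL rollout: states, actions, rewards, values, advantages
    and the refined embedding sequence."""

    states: np.ndarray      # (T, m)
    actions: np.ndarray     # (T, m)
    log_probs: np.ndarray   # (T,)
    rewards: np.ndarray     # (T,)
    values: np.ndarray      # (T,)
    advantages: np.ndarray  # (T,)
    refined: np.ndarray     # (T, m)

    def validate(self) -> None:
        T = self.states.shape[0]
        for name in ("actions", "log_probs", "rewards", "values",
                     "advantages", "refined"):
            if getattr(self, name).shape[0] != T:
                raise ValueError(f"{name} length differs from states")
        if not np.isfinite(self.refined).all():
            raise ValueError("refined embeddings must be finite")


def init_policy(state_dim: int, action_dim: int, rng: np.random.Generator,
                zeta: float = 0.95, alpha: float = 0.6, beta: float = 0.4,
                init_log_std: float = -1.0) -> PolicyParams:
    p = PolicyParams(
        W_mean=(rng.standard_normal((state_dim, action_dim))
                / np.sqrt(state_dim) * 0.1),
        b_mean=np.zeros(action_dim),
        log_std=np.full(action_dim, init_log_std),
        W_v=np.zeros(state_dim), b_v=0.0,
        W_aux=np.zeros(state_dim), b_aux=0.0,
        zeta=zeta, alpha=alpha, beta=beta)
    p.validate()
    return p


def _mean_action(states: np.ndarray, policy: PolicyParams) -> np.ndarray:
    return states @ policy.W_mean + policy.b_mean


def gaussian_log_density(a: np.ndarray, mean: np.ndarray,
                         log_std: np.ndarray) -> np.ndarray:
    """Log density of a diagonal Gaussian, summed over action dimensions."""
    std = np.exp(log_std)
    zed = (a - mean) / std
    return -0.5 * np.sum(zed**2 + 2.0 * log_std + _LOG_2PI, axis=-1)


def policy_sample(state: np.ndarray, policy: PolicyParams,
                  rng: np.random.Generator | None = None,
                  deterministic: bool = False):
    """Draw an action from π(·|s) (or return the mean in deterministic mode)
    together with its log density."""
    state = np.asarray(state, dtype=float)
    if not np.isfinite(state).all():
        raise ValueError("state must be finite")
    mean = _mean_action(state, policy)
    if deterministic:
        return mean, gaussian_log_density(mean, mean, policy.log_std)
    if rng is None:
        raise ValueError("stochastic sampling requires an explicit rng")
    a = mean + np.exp(policy.log_std) * rng.standard_normal(mean.shape)
    return a, gaussian_log_density(a, mean, policy.log_std)


def refine_embedding(z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """z* = z + tanh(a): a residual refinement bounded by 1 per coordinate."""
    z, a = np.asarray(z), np.asarray(a)
    if z.shape != a.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {a.shape}")
    return z + np.tanh(a)


def aux_score(states: np.ndarray, policy: PolicyParams) -> np.ndarray:
    """Auxiliary per-state score g(s) ∈ (0, 1)."""
    logit = states @ policy.W_aux + policy.b_aux
    return 1.0 / (1.0 + np.exp(-logit))


def reward_signals(states: np.ndarray, y: float, gamma, policy: PolicyParams):
    """Per-step (Acc, Align) pair, both in [0, 1]."""
    g = aux_score(states, policy)
    acc = 1.0 - np.abs(g - y)
    align = 1.0 - np.abs(g - np.asarray(gamma))
    return acc, align


def step_reward(acc, align, alpha: float, beta: float):
    """r = α·Acc + β·Align with normalized weights."""
    if abs(alpha + beta - 1.0) > 1e-9:
        raise ValueError("reward weights must satisfy α + β = 1")
    return alpha * np.asarray(acc) + beta * np.asarray(align)


def discounted_return(rewards: np.ndarray, zeta: float) -> float:
    """Σ_t ζ^{t−1} r_t (first reward undiscounted)."""
    rewards = np.asarray(rewards, dtype=float)
    if not (0.0 <= zeta <= 1.0):
        raise ValueError("ζ must be in [0, 1]")
    weights = zeta ** np.arange(rewards.shape[0])
    return float(np.sum(weights * rewards))


def advantage_estimates(rewards: np.ndarray, values: np.ndarray,
                        zeta: float) -> np.ndarray:
    """One-step TD advantage Â_t = r_t + ζ·V_{t+1} − V_t with V_{T+1} = 0."""
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    if rewards.shape != values.shape:
        raise ValueError("rewards and values must have equal length")
    v_next = np.concatenate([values[1:], [0.0]])
    return rewards + zeta * v_next - values


def build_trajectories(Z: np.ndarray, y: np.ndarray, gamma: np.ndarray,
                       policy: PolicyParams, rng: np.random.Generator,
                       deterministic: bool = False) -> list[Trajectory]:
    """Roll the policy over a batch of embedded trials.

    Z: (B, T, m) embeddings; y: (B,) labels; gamma: (B, T) clinical scales.
    """
    B = Z.shape[0]
    trajectories = []
    for i in range(B):
        states = Z[i]
        actions, log_probs = policy_sample(states, policy, rng, deterministic)
        refined = refine_embedding(states, actions)
        # the reward scores the *refined* state, so R(s_t, a_t) genuinely
        # depends on the action the agent took
        acc, align = reward_signals(refined, float(y[i]), gamma[i], policy)
        rewards = step_reward(acc, align, policy.alpha, policy.beta)
        values = states @ policy.W_v + policy.b_v
        adv = advantage_estimates(rewards, values, policy.zeta)
        traj = Trajectory(states=states, actions=actions, log_probs=log_probs,
                          rewards=rewards, values=values, advantages=adv,
                          refined=refined)
        traj.validate()
        trajectories.append(traj)
    return trajectories


def actor_critic_update(trajectories: list[Trajectory], policy: PolicyParams,
                        targets: list[tuple[float, np.ndarray]] | None = None
                        ) -> dict[str, float]:
    """One advantage-weighted policy-gradient step (in place).

    Actor: ascent along E[∇ log π(a|s) · Â] with Â held constant.
    Critic: descent on the squared one-step TD error (semi-gradient).
    Auxiliary head: descent on α(g−y)² + β(g−γ)² when `targets` supplies
    per-trajectory (y, γ) pairs.

    Returns diagnostics (mean reward, mean advantage, gradient norms).
    """
    S = np.concatenate([t.states for t in trajectories], axis=0)
    A = np.concatenate([t.actions for t in trajectories], axis=0)
    Adv = np.concatenate([t.advantages for t in trajectories], axis=0)
    R = np.concatenate([t.rewards for t in trajectories], axis=0)
    V = np.concatenate([t.values for t in trajectories], axis=0)
    V_next = np.concatenate(
        [np.concatenate([t.values[1:], [0.0]]) for t in trajectories])
    n = S.shape[0]

    mean = _mean_action(S, policy)
    std = np.exp(policy.log_std)
    # ∇_mean log π = (a − mean)/σ²  (density gradient of the diagonal Gaussian)
    dmean = (A - mean) / std**2 * Adv[:, None]
    gW = S.T @ dmean / n
    gb = dmean.mean(axis=0)
    glog = np.mean(((A - mean) ** 2 / std**2 - 1.0) * Adv[:, None], axis=0)
    if not (np.isfinite(gW).all() and np.isfinite(glog).all()):
        raise FloatingPointError(
            f"non-finite actor gradient (|Adv| max {np.abs(Adv).max():.3g})")
    policy.W_mean += policy.lr_actor * gW
    policy.b_mean += policy.lr_actor * gb
    policy.log_std += policy.lr_actor * glog

    # critic: target r + ζ V' is held fixed (semi-gradient TD(0))
    delta = R + policy.zeta * V_next - V
    policy.W_v += policy.lr_critic * (S.T @ delta) / n
    policy.b_v += policy.lr_critic * float(delta.mean())

    aux_loss = np.nan
    if targets is not None:
        ys = np.concatenate([np.full(t.states.shape[0], tv[0])
                             for t, tv in zip(trajectories, targets)])
        gs = np.concatenate([np.asarray(tv[1]) for tv in targets])
        g = aux_score(S, policy)
        err = policy.alpha * (g - ys) + policy.beta * (g - gs)
        dlogit = 2.0 * err * g * (1.0 - g)
        policy.W_aux -= policy.lr_aux * (S.T @ dlogit) / n
        policy.b_aux -= policy.lr_aux * float(dlogit.mean())
        aux_loss = float(np.mean(policy.alpha * (g - ys) ** 2
                                 + policy.beta * (g - gs) ** 2))

    return {
        "mean_reward": float(R.mean()),
        "mean_advantage": float(Adv.mean()),
        "actor_grad_norm": float(np.linalg.norm(gW)),
        "td_error": float(np.mean(delta**2)),
        "aux_loss": aux_loss,
    }


def run_rl_phase(Z: np.ndarray, y: np.ndarray, gamma: np.ndarray,
                 policy: PolicyParams, rng: np.random.Generator,
                 n_updates: int = 1) -> dict[str, float]:
    """One RL refinement phase on detached embeddings (the supervised model
    is frozen during this phase)."""
    diag: dict[str, float] = {}
    for _ in range(n_updates):
        trajectories = build_trajectories(Z, y, gamma, policy, rng)
        targets = [(float(y[i]), gamma[i]) for i in range(Z.shape[0])]
        diag = actor_critic_update(trajectories, policy, targets)
    return diag
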