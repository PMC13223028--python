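"""Attention-explainable prognosis transformer.

Fuses refined frame embeddings with the clinical indicator series, adds
sinusoidal positional information plus a clinical context vector derived
from the static covariates, encodes with a multi-head self-attention
transformer, pools with temporal attention (the weights α_t are the primary
explainability artifact), and predicts the functional-recovery probability
through a sigmoid head.

Training minimises a dual objective

    L_total = L_pred + λ·H(α)

where L_pred is either the batch-mean squared error or the (soft-target)
binary cross-entropy, and H(α) is the Shannon entropy of the temporal
attention distribution.  The positive entropy penalty drives attention
toward sparse, clinically inspectable time points.

Six ablation switches reproduce the component-removal variants: no RL
refinement, no convolutional encoder, no transformer stack, single-loss
training (λ=0), uniform joint gates, and no context/positional encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import rrl_core
from ._autograd import Tensor, as_tensor, backward, layer_norm, softmax, softplus
from .rrl_core import EncoderConfig, PolicyParams

__all__ = [
    "ModelConfig",
    "LossConfig",
    "PrognosisModel",
    "AttentionRecord",
    "init_model",
    "sinusoidal_positions",
    "fuse_modalities",
    "contextual_encoding",
    "scaled_dot_attention",
    "transformer_encode",
    "temporal_attention",
    "predict_recovery",
    "prediction_loss",
    "attention_entropy_loss",
    "total_loss",
    "joint_gates",
    "forward_batch",
    "batch_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Dual supervision objective: prediction mode and entropy weight λ."""

    mode: str = "bce"     # "bce" (soft targets) or "mse"
    lam: float = 0.1      # attention-entropy regularization weight

    def validate(self) -> None:
        if self.mode not in ("bce", "mse"):
            raise ValueError("prediction mode must be 'bce' or 'mse'")
        if self.lam < 0:
            raise ValueError("λ must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Dimensions, architecture defaults and ablation switches."""

    n_joints: int = 25
    channels_per_joint: int = 11
    clinical_dim: int = 4
    static_dim: int = 3
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    d_model: int = 32
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 64
    d_attn: int = 32          # temporal-attention hidden width
    T_max: int = 512
    loss: LossConfig = field(default_factory=LossConfig)
    # ablation switches (all on = full model)
    use_drl: bool = True
    use_cnn: bool = True
    use_transformer: bool = True
    use_dual_loss: bool = True
    use_gates: bool = True
    use_context_encoding: bool = True
    dtype: str = "float32"

    @property
    def n_features(self) -> int:
        return self.n_joints * self.channels_per_joint

    @property
    def d_k(self) -> int:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        return self.d_model // self.n_heads

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def effective_lambda(self) -> float:
        return self.loss.lam if self.use_dual_loss else 0.0


@dataclass
class AttentionRecord:
    """Attention artifacts of one forward pass."""

    self_attention: list[np.ndarray]   # per layer: (B, h, T, T), rows sum to 1
    temporal: np.ndarray               # (B, T) α weights, Σ_t α_t = 1
    joint_gates: np.ndarray | None     # (B, T, J) per-frame gate distribution


@dataclass
class PrognosisModel:
    """All parameters: encoder + policy + transformer, plus input statistics."""

    config: ModelConfig
    params: dict[str, Tensor]
    policy: PolicyParams
    norm: dict[str, np.ndarray] = field(default_factory=dict)

    def trainable(self) -> dict[str, Tensor]:
        return self.params

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()


def sinusoidal_positions(T: int, d: int, dtype=np.float64) -> np.ndarray:
    """Standard sinusoidal positional matrix: even dims sine, odd cosine,
    10000-base frequencies; rows bounded in [−1, 1]."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    P = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return P.astype(dtype)


def init_model(cfg: ModelConfig, seed: int) -> PrognosisModel:
    """Seeded initialisation of every parameter group."""
    cfg.loss.validate()
    rng = np.random.default_rng(seed)
    dt = cfg.np_dtype
    m = cfg.encoder.embedding_dim
    d, k, s = cfg.d_model, cfg.clinical_dim, cfg.static_dim

    def w(*shape, scale=None):
        fan_in = shape[0] if scale is None else None
        sc = (1.0 / np.sqrt(fan_in)) if scale is None else scale
        return Tensor((rng.standard_normal(shape) * sc).astype(dt),
                      requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape, dtype=dt), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape, dtype=dt), requires_grad=True)

    params: dict[str, Tensor] = {}
    params["gate_W"] = zeros(cfg.n_features, cfg.n_joints)
    params["gate_b"] = zeros(cfg.n_joints)
    params.update(rrl_core.init_encoder_params(cfg.encoder, rng, dtype=dt))
    params["raw_W"] = w(cfg.n_features, m)
    params["raw_b"] = zeros(m)
    params["fuse_Wz"] = w(m, d)
    params["fuse_Wc"] = w(k, d)
    params["fuse_b"] = zeros(d)
    params["ctx_W"] = w(s, d, scale=0.1)
    params["ctx_b"] = zeros(d)
    for i in range(cfg.n_layers):
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            # output projections start small so each residual block begins
            # near the identity and the layer's mixing is learned, not
            # imposed by the random initialisation
            params[f"l{i}_{nm}"] = w(d, d, scale=0.02 / np.sqrt(d)) \
                if nm == "Wo" else w(d, d)
            if nm != "Wk":
                # a key bias shifts every score row by a constant and is
                # removed by the softmax; omit the redundant parameter
                params[f"l{i}_{nm}_b"] = zeros(d)
        params[f"l{i}_ln1_g"], params[f"l{i}_ln1_b"] = ones(d), zeros(d)
        params[f"l{i}_ffn_W1"], params[f"l{i}_ffn_b1"] = w(d, cfg.d_ff), zeros(cfg.d_ff)
        params[f"l{i}_ffn_W2"], params[f"l{i}_ffn_b2"] = \
            w(cfg.d_ff, d, scale=0.02 / np.sqrt(cfg.d_ff)), zeros(d)
        params[f"l{i}_ln2_g"], params[f"l{i}_ln2_b"] = ones(d), zeros(d)
    params["ta_W"] = w(d, cfg.d_attn)
    params["ta_b"] = zeros(cfg.d_attn)
    params["ta_u"] = w(cfg.d_attn, 1, scale=1.0 / np.sqrt(cfg.d_attn))
    params["out_W"] = zeros(d, 1)
    params["out_b"] = zeros(1)

    policy = rrl_core.init_policy(m, m, rng)
    return PrognosisModel(config=cfg, params=params, policy=policy)


# ---------------------------------------------------------------------------
# building blocks (spec-level operations)
# ---------------------------------------------------------------------------

def joint_gates(x: Tensor, params: dict[str, Tensor], cfg: ModelConfig):
    """Per-frame softmax gate over the joints (the spatial level of the
    hierarchical attention).

    Returns (gated features, gate distribution).  The gate distribution sums
    to 1 over joints; features are scaled by J·gate so a uniform gate is the
    identity.
    """
    J, C = cfg.n_joints, cfg.channels_per_joint
    logits = x @ params["gate_W"] + params["gate_b"]      # (B, T, J)
    g = softmax(logits, axis=-1)
    B, T = x.shape[0], x.shape[1]
    x4 = x.reshape(B, T, J, C)
    g4 = g.reshape(B, T, J, 1)
    gated = (x4 * (float(J) * g4)).reshape(B, T, J * C)
    return gated, g


def fuse_modalities(z: Tensor, c: Tensor, params: dict[str, Tensor]) -> Tensor:
    """h_t = W_z z*_t + W_c c_t + b — linear projection to the model space."""
    z, c = as_tensor(z), as_tensor(c)
    if z.shape[-1] != params["fuse_Wz"].shape[0]:
        raise ValueError("embedding dim does not match fusion weights")
    if c.shape[-1] != params["fuse_Wc"].shape[0]:
        raise ValueError("clinical dim does not match fusion weights")
    return z @ params["fuse_Wz"] + c @ params["fuse_Wc"] + params["fuse_b"]


def contextual_encoding(H: Tensor, static: Tensor, params: dict[str, Tensor],
                        cfg: ModelConfig) -> Tensor:
    """H̃ = H + P[0:T] + e_ctx with sinusoidal P and a learned linear map of
    the static covariates as the clinical context vector."""
    H = as_tensor(H)
    T = H.shape[-2]
    if T > cfg.T_max:
        raise ValueError(f"sequence length {T} exceeds T_max={cfg.T_max}")
    P = Tensor(sinusoidal_positions(cfg.T_max, cfg.d_model,
                                    dtype=H.data.dtype)[:T])
    e_ctx = as_tensor(static) @ params["ctx_W"] + params["ctx_b"]   # (B, d)
    B = e_ctx.shape[0]
    return H + P + e_ctx.reshape(B, 1, cfg.d_model)


def scaled_dot_attention(Q, K, V, d_k: int):
    """softmax(QKᵀ/√d_k)V with max-subtracted softmax.

    Returns (output, attention map); each attention row sums to 1.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    att = softmax(scores, axis=-1)
    return att @ V, att


def _split_heads(x: Tensor, B: int, T: int, h: int, d_k: int) -> Tensor:
    return x.reshape(B, T, h, d_k).swapaxes(1, 2)     # (B, h, T, d_k)


def _merge_heads(x: Tensor, B: int, T: int, d: int) -> Tensor:
    return x.swapaxes(1, 2).reshape(B, T, d)


def transformer_encode(H: Tensor, params: dict[str, Tensor], cfg: ModelConfig):
    """Post-norm transformer stack: multi-head self-attention, residual +
    layer norm, position-wise feed-forward, residual + layer norm.

    Returns (H_out, list of per-layer attention maps).
    """
    H = as_tensor(H)
    B, T, d = H.shape
    maps: list[np.ndarray] = []
    for i in range(cfg.n_layers):
        Q = _split_heads(H @ params[f"l{i}_Wq"] + params[f"l{i}_Wq_b"],
                         B, T, cfg.n_heads, cfg.d_k)
        K = _split_heads(H @ params[f"l{i}_Wk"], B, T, cfg.n_heads, cfg.d_k)
        V = _split_heads(H @ params[f"l{i}_Wv"] + params[f"l{i}_Wv_b"],
                         B, T, cfg.n_heads, cfg.d_k)
        attn_out, att = scaled_dot_attention(Q, K, V, cfg.d_k)
        if not np.isfinite(att.data).all():
            raise FloatingPointError(f"NaN attention map in layer {i}")
        maps.append(att.data)
        merged = _merge_heads(attn_out, B, T, d) @ params[f"l{i}_Wo"] \
            + params[f"l{i}_Wo_b"]
        H = layer_norm(H + merged, params[f"l{i}_ln1_g"], params[f"l{i}_ln1_b"])
        ff = (H @ params[f"l{i}_ffn_W1"] + params[f"l{i}_ffn_b1"]).tanh() \
            @ params[f"l{i}_ffn_W2"] + params[f"l{i}_ffn_b2"]
        H = layer_norm(H + ff, params[f"l{i}_ln2_g"], params[f"l{i}_ln2_b"])
    return H, maps


def temporal_attention(H_out: Tensor, params: dict[str, Tensor]):
    """α = softmax_t(uᵀ tanh(W_a h_t)), v = Σ_t α_t h_t.

    Returns (α of shape (B, T), context vector v of shape (B, d)).
    """
    H_out = as_tensor(H_out)
    B, T, d = H_out.shape
    scores = ((H_out @ params["ta_W"] + params["ta_b"]).tanh()
              @ params["ta_u"]).reshape(B, T)
    alpha = softmax(scores, axis=-1)
    v = (alpha.reshape(B, 1, T) @ H_out).reshape(B, d)
    return alpha, v


def predict_recovery(v: Tensor, params: dict[str, Tensor]):
    """ŷ = σ(W_o v + b_o); also returns the raw logit for stable losses."""
    logit = (as_tensor(v) @ params["out_W"] + params["out_b"]).reshape(-1)
    return logit.sigmoid(), logit


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def prediction_loss(yhat, y, mode: str = "bce"):
    """Batch-mean prediction loss (Tensor-aware).

    mse: mean (ŷ−y)²; bce: mean −[y ln ŷ + (1−y) ln(1−ŷ)], valid for soft
    targets y ∈ [0, 1].
    """
    yhat_t = as_tensor(yhat)
    y_t = as_tensor(y)
    if yhat_t.data.size == 0:
        raise ValueError("empty batch")
    if yhat_t.data.shape != y_t.data.shape:
        raise ValueError("ŷ and y must have equal length")
    if mode == "mse":
        diff = yhat_t - y_t
        return (diff * diff).mean()
    if mode == "bce":
        out = -(y_t * yhat_t.log() + (1.0 - y_t) * (1.0 - yhat_t).log())
        return out.mean()
    raise ValueError("prediction mode must be 'bce' or 'mse'")


def _bce_from_logits(logits: Tensor, y: Tensor) -> Tensor:
    """Numerically identical to bce on σ(logit) but overflow-safe:
    softplus(logit) − y·logit."""
    return (softplus(logits) - as_tensor(y) * logits).mean()


def attention_entropy_loss(alpha, lam: float):
    """L_exp = λ·H(α) with H(α) = −Σ α ln α (0·ln 0 := 0).

    A positive entropy penalty: minimising it sharpens the temporal
    attention toward a few key frames.
    """
    alpha_t = as_tensor(alpha)
    a = alpha_t.data
    sums = a.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-6 or a.min() < -1e-12:
        raise ValueError("α must lie on the probability simplex")
    if lam == 0.0:
        return Tensor(np.zeros((), dtype=a.dtype))
    if isinstance(alpha, Tensor) and alpha.requires_grad:
        # softmax outputs are strictly positive; log is safe
        ent = -(alpha_t * alpha_t.log()).sum(axis=-1).mean()
        return lam * ent
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(a > 0, a * np.log(a), 0.0)
    return Tensor(np.asarray(lam * float(-plogp.sum(axis=-1).mean())))


def total_loss(l_pred, l_exp):
    """L_total = L_pred + L_exp."""
    return as_tensor(l_pred) + as_tensor(l_exp)


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def encode_batch(model: PrognosisModel, X) -> np.ndarray:
    """Encoder-only forward pass (gates + spatiotemporal encoder); returns
    the detached embedding array (B, T, m) used as RL states."""
    cfg = model.config
    p = model.params
    X = as_tensor(X)
    Xg = joint_gates(X, p, cfg)[0] if cfg.use_gates else X
    if cfg.use_cnn:
        z = rrl_core.encode_frames(Xg, p, cfg.encoder)
    else:
        z = (Xg @ p["raw_W"] + p["raw_b"]).tanh()
    return z.data


def forward_batch(model: PrognosisModel, X, C, S):
    """Run the full network on a batch.

    Parameters
    ----------
    X : (B, T, F) standardized flattened frames
    C : (B, T, k) standardized clinical series
    S : (B, s) static covariates

    Returns a dict with Tensors ``yhat``, ``logits``, ``alpha``, ``z``,
    ``zstar`` and an :class:`AttentionRecord`.
    """
    cfg = model.config
    p = model.params
    X, C, S = as_tensor(X), as_tensor(C), as_tensor(S)
    B, T = X.shape[0], X.shape[1]

    gates = None
    if cfg.use_gates:
        Xg, g = joint_gates(X, p, cfg)
        gates = g.data
    else:
        Xg = X
        gates = np.full((B, T, cfg.n_joints), 1.0 / cfg.n_joints,
                        dtype=X.data.dtype)

    if cfg.use_cnn:
        z = rrl_core.encode_frames(Xg, p, cfg.encoder)
    else:
        z = (Xg @ p["raw_W"] + p["raw_b"]).tanh()

    if cfg.use_drl:
        dt = cfg.np_dtype
        W_mean = Tensor(model.policy.W_mean.astype(dt))
        b_mean = Tensor(model.policy.b_mean.astype(dt))
        zstar = z + (z @ W_mean + b_mean).tanh()
    else:
        zstar = z

    H = fuse_modalities(zstar, C, p)
    if cfg.use_context_encoding:
        H = contextual_encoding(H, S, p, cfg)
    if cfg.use_transformer:
        H_out, maps = transformer_encode(H, p, cfg)
    else:
        H_out, maps = H, []
    alpha, v = temporal_attention(H_out, p)
    yhat, logits = predict_recovery(v, p)
    record = AttentionRecord(self_attention=maps, temporal=alpha.data,
                             joint_gates=gates)
    return {"yhat": yhat, "logits": logits, "alpha": alpha, "z": z,
            "zstar": zstar, "record": record}


def batch_loss(out: dict, y, cfg: ModelConfig, lam_scale: float = 1.0):
    """Dual objective on a forward pass; returns (L_total, L_pred, L_exp).

    ``lam_scale`` supports the training-time warm-up of the entropy weight
    (evaluation always uses the full λ).
    """
    y_arr = np.asarray(y, dtype=out["logits"].data.dtype)
    if cfg.loss.mode == "bce":
        l_pred = _bce_from_logits(out["logits"], Tensor(y_arr))
    else:
        l_pred = prediction_loss(out["yhat"], Tensor(y_arr), mode="mse")
    l_exp = attention_entropy_loss(out["alpha"],
                                   cfg.effective_lambda() * lam_scale)
    return total_loss(l_pred, l_exp), l_pred, l_exp
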