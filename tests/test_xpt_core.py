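"""Transformer prognosis module: operation-level hand cases, attention laws,
the dual-loss gradient check, ablation switch semantics and training
behaviour on a tiny cohort."""

import dataclasses
import numpy as np
import pytest

from rehabprog import xpt_core
from rehabprog._autograd import Tensor, backward
from rehabprog.rrl_core import EncoderConfig
from rehabprog.training import LeakageError, TrainConfig, train_model, predict
from rehabprog.xpt_core import (LossConfig, ModelConfig, attention_entropy_loss,
                                contextual_encoding, fuse_modalities,
                                init_model, forward_batch, predict_recovery,
                                prediction_loss, scaled_dot_attention,
                                sinusoidal_positions, temporal_attention,
                                total_loss, transformer_encode)


def _tiny_cfg(**kw):
    enc = EncoderConfig(n_features=275, kernel=3, channels=(4, 4),
                        embedding_dim=5)
    defaults = dict(n_joints=25, clinical_dim=3, static_dim=3, encoder=enc,
                    d_model=8, n_heads=2, n_layers=2, d_ff=12, d_attn=8,
                    dtype="float64")
    defaults.update(kw)
    return ModelConfig(**defaults)


# ---------------------------------------------------------------------------
# fusion / positions
# ---------------------------------------------------------------------------

def test_fusion_hand_case_and_bias_only():
    params = {"fuse_Wz": Tensor(np.array([[2.0]])),
              "fuse_Wc": Tensor(np.array([[3.0]])),
              "fuse_b": Tensor(np.array([1.0]))}
    h = fuse_modalities(np.array([[0.5]]), np.array([[1.0]]), params)
    assert h.data[0, 0] == pytest.approx(5.0)
    params["fuse_Wz"] = Tensor(np.zeros((1, 1)))
    params["fuse_Wc"] = Tensor(np.zeros((1, 1)))
    h = fuse_modalities(np.array([[0.7], [0.2]]), np.array([[9.0], [3.0]]),
                        params)
    np.testing.assert_allclose(h.data, 1.0)


def test_fusion_affine_identity(rng):
    d, m, k = 4, 3, 2
    params = {"fuse_Wz": Tensor(rng.standard_normal((m, d))),
              "fuse_Wc": Tensor(rng.standard_normal((k, d))),
              "fuse_b": Tensor(rng.standard_normal(d))}
    z1, z2 = rng.standard_normal((2, m))
    c = rng.standard_normal((1, k))
    a, b = 0.7, -1.3
    lhs = fuse_modalities((a * z1 + b * z2).reshape(1, -1), c, params).data
    f1 = fuse_modalities(z1.reshape(1, -1), c, params).data
    f2 = fuse_modalities(z2.reshape(1, -1), c, params).data
    base = c @ params["fuse_Wc"].data + params["fuse_b"].data
    np.testing.assert_allclose(lhs, a * f1 + b * f2 - (a + b - 1) * base,
                               atol=1e-10)


def test_sinusoidal_position_row_zero():
    P = sinusoidal_positions(4, 6)
    np.testing.assert_allclose(P[0], [0, 1, 0, 1, 0, 1], atol=1e-12)
    assert np.abs(P).max() <= 1.0


def test_contextual_encoding_additive(rng):
    cfg = _tiny_cfg()
    model = init_model(cfg, 0)
    model.params["ctx_W"].data[:] = 0.0
    H = rng.standard_normal((2, 5, 8))
    S = np.zeros((2, 3))
    out = contextual_encoding(Tensor(H), Tensor(S), model.params, cfg).data
    np.testing.assert_allclose(out, H + sinusoidal_positions(5, 8), atol=1e-12)
    zero = contextual_encoding(Tensor(np.zeros_like(H)), Tensor(S),
                               model.params, cfg).data
    np.testing.assert_allclose(out - zero, H, atol=1e-12)
    with pytest.raises(ValueError):
        contextual_encoding(Tensor(rng.standard_normal((1, cfg.T_max + 1, 8))),
                            Tensor(S[:1]), model.params, cfg)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def test_scaled_dot_attention_hand_case():
    Q = Tensor(np.array([[1.0], [0.0]]))
    K = Tensor(np.array([[1.0], [0.0]]))
    V = Tensor(np.array([[1.0], [2.0]]))
    out, att = scaled_dot_attention(Q, K, V, d_k=1)
    e = np.e
    np.testing.assert_allclose(att.data[0], [e / (e + 1), 1 / (e + 1)],
                               atol=1e-12)
    assert out.data[0, 0] == pytest.approx(e / (e + 1) * 1 + 1 / (e + 1) * 2)
    np.testing.assert_allclose(att.data.sum(axis=-1), 1.0, atol=1e-12)


def test_attention_single_token_and_identical_keys(rng):
    v = rng.standard_normal((1, 3))
    out, att = scaled_dot_attention(Tensor(rng.standard_normal((1, 2))),
                                    Tensor(rng.standard_normal((1, 2))),
                                    Tensor(v), 2)
    assert att.data[0, 0] == 1.0
    np.testing.assert_allclose(out.data, v)
    K = Tensor(np.tile(rng.standard_normal(2), (4, 1)))
    V = Tensor(rng.standard_normal((4, 3)))
    out, att = scaled_dot_attention(Tensor(rng.standard_normal((4, 2))), K, V, 2)
    np.testing.assert_allclose(att.data, 0.25, atol=1e-12)
    np.testing.assert_allclose(out.data, np.tile(V.data.mean(axis=0), (4, 1)))
    with pytest.raises(ValueError):
        scaled_dot_attention(K, K, V, 0)


def test_transformer_shapes_rows_and_permutation_equivariance(rng):
    cfg = _tiny_cfg()
    model = init_model(cfg, 3)
    H = rng.standard_normal((2, 6, 8))
    out, maps = transformer_encode(Tensor(H), model.params, cfg)
    assert out.data.shape == (2, 6, 8) and len(maps) == cfg.n_layers
    for m in maps:
        np.testing.assert_allclose(m.sum(axis=-1), 1.0, atol=1e-6)
    # permuting timesteps (no positional encoding involved here) permutes
    # the output identically
    perm = rng.permutation(6)
    out_p, _ = transformer_encode(Tensor(H[:, perm]), model.params, cfg)
    np.testing.assert_allclose(out_p.data, out.data[:, perm], atol=1e-10)


def test_temporal_attention_uniform_and_saturated(rng):
    cfg = _tiny_cfg()
    model = init_model(cfg, 1)
    row = rng.standard_normal(8)
    H = Tensor(np.tile(row, (1, 5, 1)))
    alpha, v = temporal_attention(H, model.params)
    np.testing.assert_allclose(alpha.data, 0.2, atol=1e-12)
    np.testing.assert_allclose(v.data[0], row, atol=1e-10)
    assert alpha.data.sum() == pytest.approx(1.0, abs=1e-6)
    # one dominating score -> near one-hot attention (amplify u so the
    # bounded tanh features still yield widely separated scores)
    model.params["ta_u"].data *= 200
    H2 = Tensor(np.vstack([row * 40, -row * 40, row * 0]).reshape(1, 3, 8))
    alpha2, v2 = temporal_attention(H2, model.params)
    top = alpha2.data.argmax()
    assert alpha2.data[0, top] > 0.95
    np.testing.assert_allclose(v2.data[0], H2.data[0, top], rtol=0.2, atol=0.3)


def test_predict_recovery_sigmoid_cases():
    params = {"out_W": Tensor(np.zeros((3, 1))), "out_b": Tensor(np.zeros(1))}
    yhat, _ = predict_recovery(Tensor(np.ones((2, 3))), params)
    np.testing.assert_allclose(yhat.data, 0.5)
    params["out_b"] = Tensor(np.array([np.log(3.0)]))
    yhat, _ = predict_recovery(Tensor(np.ones((1, 3))), params)
    assert yhat.data[0] == pytest.approx(0.75)
    # monotone in the bias
    params["out_b"] = Tensor(np.array([1.5]))
    y2, _ = predict_recovery(Tensor(np.ones((1, 3))), params)
    assert y2.data[0] > 0.75


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_prediction_loss_hand_cases():
    y = np.array([1.0])
    yhat = np.array([0.5])
    assert float(prediction_loss(yhat, y, "mse").data) == pytest.approx(0.25)
    assert float(prediction_loss(yhat, y, "bce").data) == pytest.approx(np.log(2))
    same = np.array([0.2, 0.8])
    assert float(prediction_loss(same, same, "mse").data) == 0.0
    with pytest.raises(ValueError):
        prediction_loss(np.array([]), np.array([]), "mse")


def test_bce_minimized_at_soft_target():
    y = np.array([0.3])
    grid = np.linspace(0.05, 0.95, 181)
    losses = [float(prediction_loss(np.array([p]), y, "bce").data)
              for p in grid]
    assert grid[int(np.argmin(losses))] == pytest.approx(0.3, abs=0.01)


def test_attention_entropy_loss_cases():
    uniform = np.full((1, 4), 0.25)
    assert float(attention_entropy_loss(uniform, 1.0).data) == pytest.approx(np.log(4))
    onehot = np.array([[1.0, 0, 0, 0]])
    assert float(attention_entropy_loss(onehot, 1.0).data) == 0.0
    assert float(attention_entropy_loss(uniform, 0.0).data) == 0.0
    with pytest.raises(ValueError):
        attention_entropy_loss(np.array([[0.5, 0.2]]), 1.0)


def test_total_loss_sum_and_bound():
    assert float(total_loss(Tensor(0.25), Tensor(0.1)).data) == pytest.approx(0.35)
    l_pred = Tensor(np.asarray(0.4))
    l_exp = attention_entropy_loss(np.full((1, 8), 0.125), 0.3)
    assert float(total_loss(l_pred, l_exp).data) >= 0.4


def test_entropy_loss_gradient_matches_finite_differences(rng):
    logits = Tensor(rng.standard_normal((2, 6)), requires_grad=True)
    from rehabprog._autograd import softmax

    def loss():
        return attention_entropy_loss(softmax(logits, axis=-1), 0.3)

    l0 = loss()
    backward(l0)
    g = logits.grad.copy()
    h = 1e-6
    flat = logits.data.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        lp = float(loss().data)
        flat[i] = orig - h
        lm = float(loss().data)
        flat[i] = orig
        fd = (lp - lm) / (2 * h)
        assert abs(fd - g.reshape(-1)[i]) < 1e-4 * max(abs(fd), 1e-3)


def test_dual_loss_gradient_check_all_parameter_groups(rng):
    """∂L_total/∂θ vs central finite differences on a d=8, T=6 model in
    double precision, for every parameter group."""
    cfg = _tiny_cfg(loss=LossConfig(mode="bce", lam=0.1))
    model = init_model(cfg, 1)
    for k, p in model.params.items():
        if np.all(p.data == 0):
            p.data = rng.standard_normal(p.data.shape) * 0.3
    B, T = 2, 6
    X = rng.standard_normal((B, T, 275))
    C = rng.standard_normal((B, T, 3))
    S = rng.standard_normal((B, 3))
    y = rng.uniform(0.1, 0.9, B)

    def loss():
        out = forward_batch(model, X, C, S)
        return xpt_core.batch_loss(out, y, cfg)[0]

    l0 = loss()
    backward(l0)
    grads = {k: p.grad.copy() for k, p in model.params.items()
             if p.grad is not None}
    h = 1e-5
    for name, p in model.params.items():
        if name not in grads:
            continue
        flat = p.data.reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp = float(loss().data)
            flat[i] = orig - h
            lm = float(loss().data)
            flat[i] = orig
            fd = (lp - lm) / (2 * h)
            an = grads[name].reshape(-1)[i]
            assert abs(fd - an) < 1e-4 * max(abs(fd), abs(an), 1e-2), name


# ---------------------------------------------------------------------------
# ablation switches
# ---------------------------------------------------------------------------

def test_ablation_switch_semantics(rng):
    X = rng.standard_normal((2, 6, 275))
    C = rng.standard_normal((2, 6, 3))
    S = rng.standard_normal((2, 3))

    base = init_model(_tiny_cfg(), 5)
    out_full = forward_batch(base, X, C, S)

    # use_drl off: refined embeddings equal raw embeddings
    m = init_model(_tiny_cfg(use_drl=False), 5)
    out = forward_batch(m, X, C, S)
    np.testing.assert_array_equal(out["z"].data, out["zstar"].data)

    # use_transformer off: pooling applies directly to the fused encoding
    m = init_model(_tiny_cfg(use_transformer=False), 5)
    out = forward_batch(m, X, C, S)
    assert out["record"].self_attention == []

    # use_dual_loss off: entropy term contributes zero
    cfg_nd = _tiny_cfg(use_dual_loss=False)
    m = init_model(cfg_nd, 5)
    out = forward_batch(m, X, C, S)
    _, _, l_exp = xpt_core.batch_loss(out, np.full(2, 0.5), cfg_nd)
    assert float(l_exp.data) == 0.0

    # use_gates off: uniform joint gates recorded
    m = init_model(_tiny_cfg(use_gates=False), 5)
    out = forward_batch(m, X, C, S)
    np.testing.assert_allclose(out["record"].joint_gates, 1 / 25)

    # use_context_encoding off: output independent of static covariates
    m = init_model(_tiny_cfg(use_context_encoding=False), 5)
    o1 = forward_batch(m, X, C, S)
    o2 = forward_batch(m, X, C, S + 10.0)
    np.testing.assert_array_equal(o1["yhat"].data, o2["yhat"].data)

    # use_cnn off: raw linear projection path is used and runs
    m = init_model(_tiny_cfg(use_cnn=False), 5)
    out = forward_batch(m, X, C, S)
    assert out["yhat"].data.shape == (2,)


# ---------------------------------------------------------------------------
# training behaviour
# ---------------------------------------------------------------------------

def _split_tiny(tiny_arrays, rng):
    subs = sorted(set(tiny_arrays["subjects"].tolist()))
    train_s, val_s = subs[:-2], subs[-2:]
    from rehabprog.pipeline import subset
    tr = np.isin(tiny_arrays["subjects"], train_s)
    va = np.isin(tiny_arrays["subjects"], val_s)
    return subset(tiny_arrays, tr), subset(tiny_arrays, va)


def test_training_reduces_validation_prediction_loss(tiny_arrays, rng):
    train_d, val_d = _split_tiny(tiny_arrays, rng)
    cfg = ModelConfig(
        n_joints=25, clinical_dim=3, static_dim=3,
        encoder=EncoderConfig(n_features=275, kernel=3, channels=(6, 6),
                              embedding_dim=8),
        d_model=16, n_heads=2, n_layers=1, d_ff=16, d_attn=16)
    model = init_model(cfg, 2)
    model, history = train_model(model, train_d, val_d,
                                 TrainConfig(lr=2e-3, batch_size=16,
                                             patience=30, max_epochs=12,
                                             seed=3))
    val = history[history.split == "val"]
    assert val.L_pred.iloc[-1] < val.L_pred.iloc[0]


def test_training_is_deterministic(tiny_arrays, rng):
    train_d, val_d = _split_tiny(tiny_arrays, rng)
    cfg = ModelConfig(
        n_joints=25, clinical_dim=3, static_dim=3,
        encoder=EncoderConfig(n_features=275, kernel=3, channels=(4, 4),
                              embedding_dim=6),
        d_model=8, n_heads=2, n_layers=1, d_ff=8, d_attn=8)
    tc = TrainConfig(lr=1e-3, batch_size=16, patience=10, max_epochs=4, seed=9)
    _, h1 = train_model(init_model(cfg, 4), train_d, val_d, tc)
    _, h2 = train_model(init_model(cfg, 4), train_d, val_d, tc)
    assert h1.equals(h2)


def test_training_rejects_subject_leakage(tiny_arrays):
    with pytest.raises(LeakageError):
        train_model(init_model(_tiny_cfg(), 0), tiny_arrays, tiny_arrays,
                    TrainConfig())


def test_early_stopping_patience_arithmetic():
    """Validation improving through epoch 50 then flat: stop at epoch 60
    with best weights from epoch 50 (patience 10)."""
    losses = [1.0 / (e + 1) for e in range(50)] + [0.02] * 100
    best, stall, stop_epoch, best_epoch = np.inf, 0, None, None
    for epoch, v in enumerate(losses, start=1):
        if v < best - 1e-9:
            best, best_epoch, stall = v, epoch, 0
        else:
            stall += 1
            if stall >= 10:
                stop_epoch = epoch
                break
    assert best_epoch == 50 and stop_epoch == 60
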