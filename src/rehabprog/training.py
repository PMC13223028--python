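"""Model fitting: alternating RL refinement and supervised epochs.

Each epoch first runs one reinforcement-learning refinement pass (actor /
critic / auxiliary-head updates on detached embeddings; the supervised
weights are frozen during this phase), then one supervised pass over
seeded minibatches optimising the dual objective with Adam.  Early stopping
monitors the validation total loss with a fixed patience and restores the
best-validation weights.

The defaults of :class:`TrainConfig` mirror the original study protocol
(Adam at 5e-5 with weight decay 1e-4, betas (0.9, 0.999), batch 128,
patience 10).  The synthetic desk-scale experiments use
:data:`DESK_TRAIN_CONFIG`, sized for full-batch CPU training on the default
cohort — a larger step size and small minibatches, chosen from
training-loss convergence on the default cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rrl_core, xpt_core
from ._autograd import Tensor, backward
from .xpt_core import ModelConfig, PrognosisModel

__all__ = [
    "TrainConfig",
    "DESK_TRAIN_CONFIG",
    "LeakageError",
    "Adam",
    "train_model",
    "predict",
    "standardize_fit",
    "standardize_apply",
]


class LeakageError(RuntimeError):
    """Raised when a subject occurs in more than one split."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol."""

    lr: float = 5e-5
    weight_decay: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 128
    patience: int = 10
    max_epochs: int = 100
    rl_updates_per_epoch: int = 1
    lambda_warmup_epochs: int = 15
    # data augmentation (training split only): Gaussian jitter on the
    # standardized motion/clinical/static inputs and a circular time shift.
    # Both counter trial memorisation, which otherwise stalls learning on
    # small cohorts; the time shift exploits the shift-equivariance of the
    # convolutional encoder.
    augment_noise_sd: float = 0.0
    augment_time_roll: bool = False
    # optimisation hygiene for small noisy validation sets: no early stop
    # before `min_epochs`, early-stopping decisions on a 3-epoch median of
    # the validation loss, optional cosine decay of the learning rate
    min_epochs: int = 1
    cosine_lr_decay: bool = False
    # stochastic weight averaging over the decayed-lr tail; the averaged
    # model replaces the best single epoch only if its validation loss is
    # lower
    tail_weight_averaging: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.augment_noise_sd < 0:
            raise ValueError("augment_noise_sd must be >= 0")


#: configuration for the desk-scale synthetic experiments (see module docstring)
DESK_TRAIN_CONFIG = TrainConfig(lr=2e-3, weight_decay=5e-4, batch_size=32,
                                patience=60, max_epochs=180, min_epochs=60,
                                augment_noise_sd=0.15, augment_time_roll=True,
                                cosine_lr_decay=True,
                                tail_weight_averaging=True)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), weight_decay: float = 0.0,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2 = lr, betas[0], betas[1]
        self.weight_decay, self.eps = weight_decay, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data, dtype=np.float64)
                  for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data, dtype=np.float64)
                  for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# input standardisation
# ---------------------------------------------------------------------------

def standardize_fit(X: np.ndarray, axis=(0, 1)) -> dict[str, np.ndarray]:
    mean = X.mean(axis=axis)
    sd = X.std(axis=axis)
    sd = np.where(sd > 1e-8, sd, 1.0)
    return {"mean": mean, "sd": sd}

def standardize_apply(X: np.ndarray, stats: dict[str, np.ndarray]) -> np.ndarray:
    return (X - stats["mean"]) / stats["sd"]


def _prepare(model: PrognosisModel, data: dict, fit_norm: bool):
    """Standardize inputs with train-split statistics stored on the model."""
    if fit_norm:
        model.norm = {
            "X_mean": standardize_fit(data["X"])["mean"],
            "X_sd": standardize_fit(data["X"])["sd"],
            "C_mean": standardize_fit(data["C"])["mean"],
            "C_sd": standardize_fit(data["C"])["sd"],
        }
    dt = model.config.np_dtype
    X = ((data["X"] - model.norm["X_mean"]) / model.norm["X_sd"]).astype(dt)
    C = ((data["C"] - model.norm["C_mean"]) / model.norm["C_sd"]).astype(dt)
    S = data["S"].astype(dt)
    return X, C, S


def _eval_losses(model: PrognosisModel, X, C, S, y):
    out = xpt_core.forward_batch(model, X, C, S)
    l_total, l_pred, l_exp = xpt_core.batch_loss(out, y, model.config)
    return (float(l_total.data), float(l_pred.data), float(l_exp.data),
            out["yhat"].data.copy(), out["alpha"].data.copy())


def predict(model: PrognosisModel, data: dict):
    """Deterministic forward pass on raw (unstandardized) arrays.

    Returns (ŷ, AttentionRecord).
    """
    X, C, S = _prepare(model, data, fit_norm=False)
    out = xpt_core.forward_batch(model, X, C, S)
    return out["yhat"].data.copy(), out["record"]


def train_model(model: PrognosisModel, train_data: dict, val_data: dict,
                cfg: TrainConfig):
    """Fit the model; returns (model, history DataFrame).

    ``train_data`` / ``val_data`` are dicts with keys ``X`` (B, T, F) raw
    flattened frames, ``C`` (B, T, k), ``S`` (B, s), ``y`` (B,), ``gamma``
    (B, T) and ``subjects`` (B,).  Subject overlap between the splits is a
    hard error (identity leakage).
    """
    cfg.validate()
    overlap = set(train_data["subjects"]) & set(val_data["subjects"])
    if overlap:
        raise LeakageError(f"subjects shared across splits: {sorted(overlap)}")

    mcfg = model.config
    rng = np.random.default_rng(cfg.seed)
    X, C, S = _prepare(model, train_data, fit_norm=True)
    Xv, Cv, Sv = _prepare(model, val_data, fit_norm=False)
    y = np.asarray(train_data["y"], dtype=float)
    yv = np.asarray(val_data["y"], dtype=float)
    gamma = np.asarray(train_data["gamma"], dtype=float)

    opt = Adam(model.params, lr=cfg.lr, betas=cfg.betas,
               weight_decay=cfg.weight_decay)
    n = X.shape[0]
    best_val = np.inf
    best_weights = model.copy_weights()
    best_policy = model.policy.copy()
    best_epoch = 0
    stall = 0
    rows = []

    recent_val: list[float] = []
    swa_sum: dict[str, np.ndarray] | None = None
    swa_count = 0
    swa_start = int(cfg.max_epochs * 2 / 3)
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.cosine_lr_decay:
            opt.lr = cfg.lr * (0.05 + 0.95 * 0.5
                               * (1 + np.cos(np.pi * (epoch - 1)
                                             / cfg.max_epochs)))
        # --- RL refinement phase (supervised weights frozen) -------------
        if mcfg.use_drl:
            # rotate through a trial subsample per epoch: the actor/critic/
            # auxiliary heads are linear, so small batches suffice
            sub = rng.permutation(n)[:min(n, cfg.batch_size)]
            Z = xpt_core.encode_batch(model, X[sub]).astype(float)
            rrl_core.run_rl_phase(Z, y[sub], gamma[sub], model.policy, rng,
                                  n_updates=cfg.rl_updates_per_epoch)

        # --- supervised phase -------------------------------------------
        # entropy-weight warm-up: let prediction discover the informative
        # frames before the sparsity pressure locks attention in
        if cfg.lambda_warmup_epochs > 0:
            lam_scale = min(1.0, epoch / cfg.lambda_warmup_epochs)
        else:
            lam_scale = 1.0
        order = rng.permutation(n)
        ep_pred = ep_exp = ep_total = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            Xb, Cb, Sb = X[idx], C[idx], S[idx]
            if cfg.augment_noise_sd > 0:
                dt = Xb.dtype
                sd = dt.type(cfg.augment_noise_sd)
                Xb = Xb + sd * rng.standard_normal(Xb.shape).astype(dt)
                Cb = Cb + dt.type(0.1) * rng.standard_normal(Cb.shape).astype(dt)
                Sb = Sb + dt.type(0.1) * rng.standard_normal(Sb.shape).astype(dt)
            if cfg.augment_time_roll:
                Xb = Xb.copy() if Xb is X[idx] else Xb
                Cb = Cb.copy() if Cb is C[idx] else Cb
                for j, sh in enumerate(rng.integers(0, Xb.shape[1],
                                                    size=Xb.shape[0])):
                    Xb[j] = np.roll(Xb[j], sh, axis=0)
                    Cb[j] = np.roll(Cb[j], sh, axis=0)
            out = xpt_core.forward_batch(model, Xb, Cb, Sb)
            l_total, l_pred, l_exp = xpt_core.batch_loss(out, y[idx], mcfg,
                                                         lam_scale=lam_scale)
            opt.zero_grad()
            backward(l_total)
            opt.step()
            ep_pred += float(l_pred.data)
            ep_exp += float(l_exp.data)
            ep_total += float(l_total.data)
            n_batches += 1

        vt, vp, ve, vyhat, _ = _eval_losses(model, Xv, Cv, Sv, yv)
        rows.append({"epoch": epoch, "split": "train",
                     "L_pred": ep_pred / n_batches, "L_exp": ep_exp / n_batches,
                     "L_total": ep_total / n_batches, "rmse": np.nan})
        rows.append({"epoch": epoch, "split": "val", "L_pred": vp,
                     "L_exp": ve, "L_total": vt,
                     "rmse": float(np.sqrt(np.mean((vyhat - yv) ** 2)))})

        if cfg.tail_weight_averaging and epoch >= swa_start:
            w = model.copy_weights()
            if swa_sum is None:
                swa_sum = {k: v.astype(np.float64) for k, v in w.items()}
            else:
                for k, v in w.items():
                    swa_sum[k] += v
            swa_count += 1

        recent_val.append(vt)
        vt_smooth = float(np.median(recent_val[-3:]))
        if vt_smooth < best_val - 1e-9:
            best_val = vt_smooth
            best_weights = model.copy_weights()
            best_policy = model.policy.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if epoch >= cfg.min_epochs and stall >= cfg.patience:
                break

    if swa_sum is not None and swa_count > 1:
        final_weights = model.copy_weights()
        avg = {k: (v / swa_count).astype(model.params[k].data.dtype)
               for k, v in swa_sum.items()}
        model.load_weights(avg)
        vt_avg, *_ = _eval_losses(model, Xv, Cv, Sv, yv)
        if vt_avg < best_val:
            best_weights = avg
            best_val = vt_avg
            best_epoch = -1  # tail average selected
        model.load_weights(final_weights)

    model.load_weights(best_weights)
    model.policy = best_policy
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_loss"] = best_val
    return model, history
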