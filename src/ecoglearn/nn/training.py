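"""Cosine-similarity training loop with chronological validation split.

The loss is the negative mean cosine similarity between predicted and desired
directions; multiple-trajectory models average the per-step similarities.
Early stopping monitors the validation cosine similarity computed on the
chronological last fraction of the training data, and the best-validation
weights are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.01
    batch_size: int = 200
    max_epochs: int = 100
    patience: int = 10       # evaluations without improvement before stopping
    val_fraction: float = 0.1  # chronological tail held out for validation
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


def cosine_loss(pred: np.ndarray, target: np.ndarray):
    """Negative mean cosine similarity and its gradient w.r.t. ``pred``.

    ``pred`` is (n, 3) or (n, steps, 3); a (n, 3) target is broadcast over
    steps.  Zero-norm predictions contribute similarity 0 with zero gradient.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.ndim == 3 and target.ndim == 2:
        target = np.broadcast_to(target[:, None, :], pred.shape)
    pn = np.linalg.norm(pred, axis=-1)
    tn = np.linalg.norm(target, axis=-1)
    denom = pn * tn
    ok = denom > 0
    dots = np.sum(pred * target, axis=-1)
    cs = np.zeros_like(denom)
    cs[ok] = dots[ok] / denom[ok]
    count = cs.size
    loss = -float(cs.sum()) / count
    grad = np.zeros_like(pred)
    safe_pn = np.where(pn > 0, pn, 1.0)
    g = (target / np.where(denom, denom, 1.0)[..., None]
         - (cs / safe_pn ** 2)[..., None] * pred)
    grad[ok] = -g[ok] / count
    return loss, grad


def _val_cs(model, x, y, batch: int = 512) -> float:
    sims = []
    for start in range(0, x.shape[0], batch):
        pred = model.forward(x[start:start + batch], train=False)
        tgt = y[start:start + batch]
        if pred.ndim == 3:
            tgt = np.broadcast_to(tgt[:, None, :], pred.shape)
        pn = np.linalg.norm(pred, axis=-1)
        tn = np.linalg.norm(tgt, axis=-1)
        denom = pn * tn
        cs = np.zeros_like(denom)
        okm = denom > 0
        cs[okm] = np.sum(pred * tgt, axis=-1)[okm] / denom[okm]
        sims.append(cs.reshape(cs.shape[0], -1).mean(axis=1))
    return float(np.concatenate(sims).mean())


def train(model, x: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None):
    """Fit a decoder by minimizing negative mean cosine similarity.

    Returns ``(model, history)`` with the best-validation weights restored.
    ``history`` is a list of per-epoch dicts (train loss, validation CS).
    """
    if cfg is None:
        cfg = TrainConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    n_val = max(1, int(round(cfg.val_fraction * n)))
    n_train = n - n_val
    if n_train < 1:
        raise ValueError("training set too small for the validation split")
    x_train, y_train = x[:n_train], y[:n_train]
    x_val, y_val = x[n_train:], y[n_train:]

    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer(cfg.learning_rate, cfg.weight_decay)
    batch = min(cfg.batch_size, n_train)
    best_cs = -np.inf
    best_weights = model.get_weights()
    bad_evals = 0
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, batch):
            idx = order[start:start + batch]
            opt.zero_grad()
            pred = model.forward(x_train[idx], train=True)
            loss, grad = cosine_loss(pred, y_train[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_cs = _val_cs(model, x_val, y_val)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_cs": val_cs})
        if val_cs > best_cs:
            best_cs = val_cs
            best_weights = model.get_weights()
            bad_evals = 0
        else:
            bad_evals += 1
            if bad_evals >= cfg.patience:
                break
        if not all(np.all(np.isfinite(p.value)) for p in model.params()):
            raise FloatingPointError("non-finite weights during training")
    model.set_weights(best_weights)
    return model, history
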