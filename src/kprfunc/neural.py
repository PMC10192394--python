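"""The 4-layer classifier: pre-training on general propionylation sites
and meta-learning fine-tuning on the small functional-site set.

Architecture (input 300 -> hidden -> hidden -> 1): the hidden layers use
the identity ("linear unit") activation and the output neuron is a
sigmoid, so the pre-sigmoid output is affine in the input features; the
factored parameterization plus dropout acts as regularization during
training. Inputs are standardized with statistics frozen at training
time. Training minimizes binary cross-entropy with Adam; dropout is
applied to hidden activations during training only, so prediction is
deterministic.

Fine-tuning follows first-order MAML: each meta-iteration resamples
negatives at a fixed ratio per functional positive, splits the task
into stratified folds, adapts a copy of the weights on the training
folds with a few gradient steps, and applies the held-out-fold gradient
at the adapted weights as the meta-update. The mean held-out AUC across
folds is tracked and the best-scoring weights are kept; iteration stops
when that AUC plateaus.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluation import ThresholdSet, roc_auc

__all__ = [
    "NetModel",
    "TrainConfig",
    "MetaConfig",
    "pretrain",
    "maml_finetune",
    "predict_scores",
    "predict",
    "functional_auc",
    "save_net_model",
    "load_net_model",
]

_SIGMOID_CLIP = 30.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_SIGMOID_CLIP, _SIGMOID_CLIP)))


@dataclass
class NetModel:
    """Weights and metadata of the 4-layer network.

    ``params`` is [W1, b1, W2, b2, W3, b3]; feature standardization
    statistics are part of the model so prediction is self-contained.
    """

    params: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    dropout: float = 0.2
    seed: int = 0
    stage: str = "pretrained"  # or "finetuned"
    cutoffs: ThresholdSet | None = None
    history: dict = field(default_factory=dict)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (
            self.params[0].shape[0],
            self.params[0].shape[1],
            self.params[2].shape[1],
            self.params[4].shape[1],
        )

    def copy(self) -> "NetModel":
        return replace(
            self,
            params=[p.copy() for p in self.params],
            history=dict(self.history),
        )


def _init_params(sizes: Sequence[int], rng: np.random.Generator) -> list[np.ndarray]:
    params: list[np.ndarray] = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    return params


def _forward(
    params: Sequence[np.ndarray],
    Z: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass on standardized input; returns (p, cache)."""
    W1, b1, W2, b2, W3, b3 = params
    a1 = Z @ W1 + b1
    mask1 = mask2 = None
    if dropout > 0.0 and rng is not None:
        mask1 = (rng.random(a1.shape) >= dropout) / (1.0 - dropout)
        a1 = a1 * mask1
    a2 = a1 @ W2 + b2
    if dropout > 0.0 and rng is not None:
        mask2 = (rng.random(a2.shape) >= dropout) / (1.0 - dropout)
        a2 = a2 * mask2
    logit = (a2 @ W3 + b3).ravel()
    p = _sigmoid(logit)
    return p, (Z, a1, a2, mask1, mask2)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def _grads(
    params: Sequence[np.ndarray], p: np.ndarray, y: np.ndarray, cache
) -> list[np.ndarray]:
    """Backprop of mean binary cross-entropy through the linear stack."""
    W1, b1, W2, b2, W3, b3 = params
    Z, a1, a2, mask1, mask2 = cache
    n = len(y)
    d_logit = ((p - y) / n)[:, None]
    gW3 = a2.T @ d_logit
    gb3 = d_logit.sum(axis=0)
    da2 = d_logit @ W3.T
    if mask2 is not None:
        da2 = da2 * mask2
    gW2 = a1.T @ da2
    gb2 = da2.sum(axis=0)
    da1 = da2 @ W2.T
    if mask1 is not None:
        da1 = da1 * mask1
    gW1 = Z.T @ da1
    gb1 = da1.sum(axis=0)
    return [gW1, gb1, gW2, gb2, gW3, gb3]


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            params[i] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    """Pre-training hyperparameters (all overridable)."""

    hidden: tuple[int, int] = (64, 16)
    dropout: float = 0.2
    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 256
    patience: int = 10
    val_fraction: float = 0.1


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-8] = 1.0
    return mean, std


def pretrain(
    X: np.ndarray,
    y: Sequence[int],
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> NetModel:
    """Train the 4-layer network on embedded vectors (general Kpr model).

    A seeded stratified validation split monitors binary cross-entropy
    for early stopping; the best-validation weights are restored. All
    randomness (init, dropout, batching, split) flows from ``seed``.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("pretrain requires both classes present")
    if min(np.bincount(y)) < 10:
        raise ValueError("pretrain requires at least 10 items per class")
    rng = np.random.default_rng(seed)

    mean, std = _standardize_stats(X)
    Z = (X - mean) / std

    # stratified validation split
    val_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(cfg.val_fraction * idx.size)))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    vi = np.concatenate(val_idx)
    ti = np.concatenate(train_idx)
    Ztr, ytr, Zva, yva = Z[ti], y[ti], Z[vi], y[vi]

    sizes = (X.shape[1], *cfg.hidden, 1)
    params = _init_params(sizes, rng)
    opt = _Adam(params, cfg.lr)
    best_val = np.inf
    best_params = [p.copy() for p in params]
    stall = 0
    losses: list[float] = []
    n = len(ytr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            p, cache = _forward(params, Ztr[idx], cfg.dropout, rng)
            if not np.all(np.isfinite(p)):
                raise FloatingPointError("non-finite activations during training")
            loss = _bce(p, ytr[idx])
            epoch_loss += loss * len(idx)
            opt.step(params, _grads(params, p, ytr[idx], cache))
        losses.append(epoch_loss / n)
        pv, _ = _forward(params, Zva)
        val_loss = _bce(pv, yva)
        if not np.isfinite(val_loss):
            raise FloatingPointError("non-finite validation loss")
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return NetModel(
        params=best_params,
        feature_mean=mean,
        feature_std=std,
        dropout=cfg.dropout,
        seed=seed,
        stage="pretrained",
        history={"train_loss": losses, "best_val_loss": best_val},
    )


def predict_scores(model: NetModel, X: np.ndarray) -> np.ndarray:
    """Deterministic sigmoid scores in (0, 1); dropout is inactive."""
    X = np.asarray(X, dtype=float)
    Z = (X - model.feature_mean) / model.feature_std
    p, _ = _forward(model.params, Z)
    return p


@dataclass
class MetaConfig:
    """Fine-tuning scaffold: 5:1 negative sampling, 5-fold tasks."""

    ratio: int = 5
    folds: int = 5
    inner_lr: float = 0.05
    inner_steps: int = 10
    outer_lr: float = 0.01
    max_meta_iters: int = 150
    plateau_tol: float = 1e-4
    plateau_patience: int = 15
    seed: int = 0


def _stratified_folds(
    y: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, ix in enumerate(idx):
            folds[i % k].append(int(ix))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _adapt(
    params: list[np.ndarray], Z: np.ndarray, y: np.ndarray, lr: float, steps: int
) -> list[np.ndarray]:
    adapted = [p.copy() for p in params]
    for _ in range(steps):
        p, cache = _forward(adapted, Z)
        grads = _grads(adapted, p, y, cache)
        for i, g in enumerate(grads):
            adapted[i] -= lr * g
    return adapted


def functional_auc(
    model: NetModel,
    X_pos: np.ndarray,
    X_neg: np.ndarray,
) -> float:
    """AUC of a model's scores for functional positives vs. negatives."""
    scores = predict_scores(model, np.vstack([X_pos, X_neg]))
    labels = np.r_[np.ones(len(X_pos), dtype=int), np.zeros(len(X_neg), dtype=int)]
    return roc_auc(scores, labels)[0]


def maml_finetune(
    base: NetModel,
    X_func_pos: np.ndarray,
    X_neg_pool: np.ndarray,
    cfg: MetaConfig | None = None,
) -> NetModel:
    """Fine-tune a pre-trained model on a tiny functional positive set.

    Each meta-iteration samples ``ratio`` negatives per positive from
    the secondary-negative pool (known sites not annotated functional),
    builds ``folds`` stratified fold-tasks, adapts per task on the
    training folds (``inner_steps`` full-batch gradient steps at
    ``inner_lr``), and applies the average held-out gradient at the
    adapted weights through an Adam meta-update. Stops when the mean
    held-out AUC fails to improve by ``plateau_tol`` for
    ``plateau_patience`` iterations; returns the best-AUC weights.
    """
    cfg = cfg or MetaConfig()
    if base.stage not in ("pretrained", "finetuned"):
        raise ValueError(f"unexpected model stage {base.stage!r}")
    X_func_pos = np.asarray(X_func_pos, dtype=float)
    X_neg_pool = np.asarray(X_neg_pool, dtype=float)
    n_pos = len(X_func_pos)
    if n_pos < 2:
        raise ValueError("need at least 2 functional positives")
    n_neg = cfg.ratio * n_pos
    if len(X_neg_pool) == 0:
        raise ValueError("secondary negative pool is empty")
    if len(X_neg_pool) < n_neg:
        raise ValueError(
            f"negative pool of {len(X_neg_pool)} cannot supply "
            f"{cfg.ratio}:1 sampling; need at least {n_neg}"
        )
    rng = np.random.default_rng(cfg.seed)
    mean, std = base.feature_mean, base.feature_std
    Zp = (X_func_pos - mean) / std

    params = [p.copy() for p in base.params]
    opt = _Adam(params, cfg.outer_lr)
    best_auc = -np.inf
    best_params = [p.copy() for p in params]
    auc_trace: list[float] = []
    stall = 0
    for _ in range(cfg.max_meta_iters):
        pick = rng.choice(len(X_neg_pool), size=n_neg, replace=False)
        Zn = (X_neg_pool[pick] - mean) / std
        Z = np.vstack([Zp, Zn])
        y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
        folds = _stratified_folds(y, cfg.folds, rng)
        outer_grads = None
        fold_aucs: list[float] = []
        for f in range(cfg.folds):
            test = folds[f]
            train = np.concatenate([folds[g] for g in range(cfg.folds) if g != f])
            adapted = _adapt(params, Z[train], y[train], cfg.inner_lr, cfg.inner_steps)
            p_test, cache = _forward(adapted, Z[test])
            if np.unique(y[test]).size == 2:
                fold_aucs.append(roc_auc(p_test, y[test])[0])
            g = _grads(adapted, p_test, y[test], cache)
            if outer_grads is None:
                outer_grads = g
            else:
                outer_grads = [a + b for a, b in zip(outer_grads, g)]
        mean_auc = float(np.mean(fold_aucs))
        auc_trace.append(mean_auc)
        opt.step(params, [g / cfg.folds for g in outer_grads])
        if mean_auc > best_auc + cfg.plateau_tol:
            best_auc = mean_auc
            best_params = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                break
    if cfg.max_meta_iters == 0:
        best_params = [p.copy() for p in base.params]
    else:
        # deployment adaptation: the meta-weights are an initialization that
        # expects a final inner-loop fit on the full support task
        pick = rng.choice(len(X_neg_pool), size=n_neg, replace=False)
        Zn = (X_neg_pool[pick] - mean) / std
        Z = np.vstack([Zp, Zn])
        y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)]
        best_params = _adapt(best_params, Z, y, cfg.inner_lr, cfg.inner_steps)
    return NetModel(
        params=best_params,
        feature_mean=mean.copy(),
        feature_std=std.copy(),
        dropout=base.dropout,
        seed=cfg.seed,
        stage="finetuned",
        cutoffs=base.cutoffs,
        history={"functional_cv_auc": auc_trace, "best_functional_cv_auc": best_auc},
    )


def predict(
    model: NetModel,
    items,
    scoring_model,
    predictor: str | None = None,
    threshold: str = "medium",
):
    """Score PSP items and apply the calibrated threshold verdicts.

    Returns a DataFrame with the 7 service columns (accession, position,
    residue, predictor, peptide, score, cutoff) plus one boolean verdict
    column per threshold level. Cutoffs must be calibrated (or present
    on the model).
    """
    import pandas as pd

    from .embedding import embed_dataset

    if model.cutoffs is None:
        raise ValueError("model has no calibrated cutoffs; run calibration first")
    peptides = [it.peptide for it in items]
    if peptides:
        X = embed_dataset(peptides, scoring_model, leave_self_out=False)
        scores = predict_scores(model, X)
    else:
        scores = np.empty(0)
    name = predictor or ("KprFunc" if model.stage == "finetuned" else "KprFunc-i")
    rows = pd.DataFrame(
        {
            "accession": [it.source_accession for it in items],
            "position": [it.position for it in items],
            "residue": ["K"] * len(items),
            "predictor": [name] * len(items),
            "peptide": peptides,
            "score": scores,
            "cutoff": [model.cutoffs.cutoff(threshold)] * len(items),
        }
    )
    for level in ("high", "medium", "low"):
        rows[f"verdict_{level}"] = rows["score"] >= model.cutoffs.cutoff(level)
    return rows


def save_net_model(model: NetModel, path: str | Path) -> None:
    """Serialize to JSON: architecture header plus base64 float64 arrays."""

    def enc(a: np.ndarray) -> dict:
        a = np.ascontiguousarray(a, dtype="<f8")
        return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}

    doc = {
        "layer_sizes": list(model.layer_sizes),
        "dropout": model.dropout,
        "seed": model.seed,
        "stage": model.stage,
        "cutoffs": (
            None
            if model.cutoffs is None
            else {"high": model.cutoffs.high, "medium": model.cutoffs.medium, "low": model.cutoffs.low}
        ),
        "params": [enc(p) for p in model.params],
        "feature_mean": enc(model.feature_mean),
        "feature_std": enc(model.feature_std),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_net_model(path: str | Path) -> NetModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))

    def dec(d: dict) -> np.ndarray:
        return np.frombuffer(base64.b64decode(d["data"]), dtype="<f8").reshape(d["shape"]).copy()

    cut = doc.get("cutoffs")
    return NetModel(
        params=[dec(p) for p in doc["params"]],
        feature_mean=dec(doc["feature_mean"]),
        feature_std=dec(doc["feature_std"]),
        dropout=float(doc["dropout"]),
        seed=int(doc["seed"]),
        stage=doc["stage"],
        cutoffs=None if cut is None else ThresholdSet(**cut),
    )
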