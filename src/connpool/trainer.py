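"""Optimization, nested cross-validation and evaluation.

Training recipe: SGD with momentum 0.9, weight decay
1e-4, mini-batches of 8, MSE loss, He-initialized weights and a cosine
learning-rate schedule annealed from ``lr0`` to 0 over ``epochs``.  Model
selection inside each outer fold uses a 90/10 inner train/validation split
and keeps the parameters from the epoch with the best validation MAE.
Evaluation pools out-of-fold predictions across the 5 outer folds and
reports MAE, Pearson r, and the two-sided t-test p-value for r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Tensor, constant
from .connectome import CohortDataset
from .model import ModelConfig, forward_batch

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "EvalResult",
    "DivergenceError",
    "cosine_lr",
    "init_params",
    "make_folds",
    "train",
    "predict",
    "cross_validate",
    "evaluate",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainConfig:
    lr0: float = 1e-5
    momentum: float = 0.9
    epochs: int = 1000
    batch: int = 8
    weight_decay: float = 1e-4
    seed: int = 0
    folds: int = 5
    inner_val_frac: float = 0.1
    clip_norm: float | None = None  # max gradient norm; None disables clipping
    restarts: int = 1  # independent seeded inits; best kept by inner val MAE

    def __post_init__(self):
        if min(self.lr0, self.momentum, self.epochs, self.batch) <= 0 and self.momentum < 0:
            raise ValueError("training hyperparameters must be positive")
        for name in ("lr0", "epochs", "batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.inner_val_frac < 1.0):
            raise ValueError("inner_val_frac must be in (0, 1)")


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


@dataclass
class EvalResult:
    mae: float
    pearson_r: float
    p_value: float
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)

    def metrics_dict(self) -> dict:
        return {
            "mae": float(self.mae),
            "pearson_r": float(self.pearson_r),
            "p_value": float(self.p_value),
        }


def cosine_lr(t: int, total: int, lr0: float) -> float:
    """Cosine-annealed learning rate ``0.5 * (1 + cos(t*pi/T)) * lr0``."""
    if not (0 <= t <= total):
        raise ValueError(f"epoch t={t} outside [0, {total}]")
    return 0.5 * (1.0 + math.cos(t * math.pi / total)) * lr0


def _fan_in(name: str, shape: tuple[int, ...]) -> int:
    if name.startswith("e2e") or name.startswith("adj"):
        d_in, n, _ = shape
        return 2 * n * d_in  # the cross filter [r, c] spans 2n entries per map
    if name == "e2n_w":
        d_in, n, _ = shape
        return n * d_in
    return shape[0]  # GCN and MLP weights: input width


def init_params(config: ModelConfig, seed: int) -> dict[str, np.ndarray]:
    """He initialization: weights ~ N(0, 2/fan_in), biases 0."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, shape in config.param_shapes().items():
        if name.endswith("_b"):
            params[name] = np.zeros(shape)
        else:
            std = math.sqrt(2.0 / _fan_in(name, shape))
            params[name] = rng.normal(0.0, std, size=shape)
    return params


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def make_folds(subject_ids: Sequence[str], n_folds: int, seed: int,
               inner_val_frac: float = 0.1) -> list[FoldSplit]:
    """Seeded uniform shuffle into ``n_folds`` outer folds with inner 90/10.

    A deterministic function of (subject ids, seed): the outer test sets
    partition the cohort; within each outer training set a seeded shuffle
    puts ``inner_val_frac`` of subjects into the validation set.
    """
    ids = list(subject_ids)
    if len(ids) < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_chunks = np.array_split(order, n_folds)
    splits = []
    for k, test_idx in enumerate(fold_chunks):
        rest = np.concatenate([c for j, c in enumerate(fold_chunks) if j != k])
        inner = np.random.default_rng([seed, k]).permutation(len(rest))
        n_val = max(1, int(round(inner_val_frac * len(rest))))
        val_idx = rest[inner[:n_val]]
        train_idx = rest[inner[n_val:]]
        splits.append(FoldSplit(
            fold_id=k,
            train_ids=[ids[i] for i in np.sort(train_idx)],
            val_ids=[ids[i] for i in np.sort(val_idx)],
            test_ids=[ids[i] for i in np.sort(test_idx)],
        ))
    return splits


def _indices_of(ds: CohortDataset, ids: Sequence[str]) -> np.ndarray:
    lookup = {sid: i for i, sid in enumerate(ds.subject_ids)}
    return np.array([lookup[s] for s in ids], dtype=np.intp)


# ---------------------------------------------------------------------------
# SGD training
# ---------------------------------------------------------------------------

def predict(ds: CohortDataset, indices: Sequence[int],
            params: dict[str, np.ndarray], config: ModelConfig,
            batch: int = 32) -> np.ndarray:
    """Forward the model over a subset of the cohort (no gradients)."""
    stack = ds.stacked()
    out = []
    idx = np.asarray(indices, dtype=np.intp)
    for lo in range(0, len(idx), batch):
        sel = idx[lo:lo + batch]
        preds, _ = forward_batch(stack[sel], params, config)
        out.append(preds.data)
    return np.concatenate(out) if out else np.empty(0)


def _sgd_step(params, grads, velocity, lr, momentum, weight_decay, clip_norm):
    if clip_norm is not None:
        total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        if total > clip_norm:
            scale = clip_norm / total
            grads = {k: g * scale for k, g in grads.items()}
    for name in params:
        g = grads[name] + weight_decay * params[name]
        velocity[name] = momentum * velocity[name] + g
        params[name] = params[name] - lr * velocity[name]


def _train_single(ds, split, model_config, tc, restart: int):
    """One seeded training run; returns (best params, history, best val MAE)."""
    train_idx = _indices_of(ds, split.train_ids)
    val_idx = _indices_of(ds, split.val_ids)
    stack = ds.stacked()
    y = ds.targets
    params = init_params(model_config,
                         tc.seed + split.fold_id + 7919 * restart)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng([tc.seed, 1000 + split.fold_id, restart])

    best_mae = math.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    history = []
    for epoch in range(tc.epochs):
        lr = cosine_lr(epoch, tc.epochs, tc.lr0)
        perm = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        n_seen = 0
        for lo in range(0, len(perm), tc.batch):
            sel = train_idx[perm[lo:lo + tc.batch]]
            pt = {k: Tensor(v, requires_grad=True) for k, v in params.items()}
            preds, _ = forward_batch(stack[sel], pt, model_config)
            diff = preds - constant(y[sel])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            grads = {k: t.grad if t.grad is not None else np.zeros_like(t.data)
                     for k, t in pt.items()}
            _sgd_step(params, grads, velocity, lr, tc.momentum,
                      tc.weight_decay, tc.clip_norm)
            epoch_loss += float(loss.data) * len(sel)
            n_seen += len(sel)
        val_pred = predict(ds, val_idx, params, model_config)
        val_mae = float(np.mean(np.abs(val_pred - y[val_idx])))
        if val_mae < best_mae:
            best_mae = val_mae
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
        history.append({
            "epoch": epoch, "lr": lr,
            "train_loss": epoch_loss / max(n_seen, 1),
            "val_mae": val_mae,
        })
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return best_params, hist, best_mae


def train(ds: CohortDataset, split: FoldSplit, model_config: ModelConfig,
          train_config: TrainConfig) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """SGD training on one fold; returns best-validation-MAE parameters.

    Mini-batches are reshuffled every epoch with a seeded generator; the
    learning rate at epoch t is ``cosine_lr(t, epochs, lr0)``.  With
    ``restarts > 1`` the run is repeated from independent seeded
    initializations and the restart with the lowest inner-validation MAE
    is kept (model selection uses validation data only).  Raises
    :class:`DivergenceError` if the loss becomes non-finite.
    """
    best = None
    last_err: DivergenceError | None = None
    for restart in range(train_config.restarts):
        try:
            params, hist, val_mae = _train_single(ds, split, model_config,
                                                  train_config, restart)
        except DivergenceError as err:
            # a diverged restart is discarded as long as another succeeds
            last_err = err
            continue
        hist.attrs["restart"] = restart
        if best is None or val_mae < best[2]:
            best = (params, hist, val_mae)
    if best is None:
        raise last_err if last_err is not None else \
            DivergenceError("no restart completed")
    return best[0], best[1]


def cross_validate(ds: CohortDataset, model_config: ModelConfig,
                   train_config: TrainConfig,
                   keep_fold_params: bool = False) -> EvalResult:
    """Nested 5-fold cross-validation with pooled out-of-fold metrics.

    With ``keep_fold_params`` the trained parameters of every outer fold
    are attached to the result (``result.fold_params``) for downstream
    out-of-fold interpretation (saliency, CCA).
    """
    if ds.n_subjects < 10:
        raise ValueError("cross-validation needs at least 10 subjects")
    splits = make_folds(ds.subject_ids, train_config.folds, train_config.seed,
                        train_config.inner_val_frac)
    y = ds.targets
    rows = []
    per_fold = []
    fold_params = []
    for split in splits:
        params, hist = train(ds, split, model_config, train_config)
        test_idx = _indices_of(ds, split.test_ids)
        preds = predict(ds, test_idx, params, model_config)
        for sid, i, p in zip(split.test_ids, test_idx, preds):
            rows.append({"subject_id": sid, "fold": split.fold_id,
                         "observed": y[i], "predicted": p})
        fold_eval = evaluate(preds, y[test_idx])
        per_fold.append({"fold": split.fold_id, "mae": fold_eval.mae,
                         "pearson_r": fold_eval.pearson_r,
                         "best_epoch": hist.attrs["best_epoch"]})
        if keep_fold_params:
            fold_params.append(params)
    pred_df = pd.DataFrame(rows)
    result = evaluate(pred_df["predicted"].to_numpy(), pred_df["observed"].to_numpy())
    result.predictions = pred_df
    result.per_fold = pd.DataFrame(per_fold)
    if keep_fold_params:
        result.fold_params = fold_params
        result.fold_splits = splits
    return result


def evaluate(pred: np.ndarray, obs: np.ndarray) -> EvalResult:
    """MAE, Pearson r between predictions and observations, and the
    two-sided p-value from the t-transform of r with N-2 df."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D vectors of equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 observations")
    mae = float(np.mean(np.abs(pred - obs)))
    if np.std(obs) == 0.0 or np.std(pred) == 0.0:
        raise ValueError("Pearson r undefined for a constant vector")
    r, p = stats.pearsonr(pred, obs)
    return EvalResult(mae=mae, pearson_r=float(r), p_value=float(p))
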