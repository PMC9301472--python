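"""Sparse hierarchical graph network for connectome regression.

Architecture (input: one preprocessed n x n connectivity matrix ``g``):

* **feature extractor** — a stack of edge-to-edge (E2E) convolutions over
  the line graph of ``g`` followed by an edge-to-node (E2N) aggregation,
  producing an n x d node-feature matrix without any hand-chosen node
  initialization;
* **adjacency embedding** — a binary graph for the pooling stage, derived
  from the input matrix (``identity``), a learned E2E kernel on the last
  hidden edge features (``e2e``) or their per-edge average (``averaging``),
  thresholded at ``sigmoid(R) >= 0.5`` (i.e. ``R >= 0``);
* **self-attention pooling** — per layer, a 2-GCN stack scores every node,
  the top ``ceil(ratio * n_l)`` nodes survive, and features are gated
  residually as ``X' = X̂ ⊙ Ŝ + X̂``;
* **readout** — per layer ``[mean_i x_i ‖ max_i x_i]``, summed across
  pooling layers, fed to a fully connected head (128 → 64 → 1).

All layers run on :mod:`connpool.autodiff` tensors, so the same forward
pass yields parameter gradients for training and input gradients for
saliency attribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, constant, leaky_relu, sigmoid

__all__ = [
    "ModelConfig",
    "e2e_forward",
    "e2n_forward",
    "embed_adjacency",
    "gcn_forward",
    "attention_scores",
    "topk_pool",
    "readout",
    "model_forward",
    "forward_batch",
    "save_checkpoint",
    "load_checkpoint",
]

ADJACENCY_MODES = ("identity", "e2e", "averaging")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``n_e2e_layers=2``, ``l_att=2``, ``p_att=1``, ``pool_ratio=0.5`` and the
    128/64 head are the reference operating point for cohort-scale data; ``d`` (hidden feature
    maps per E2E/E2N layer, constant across layers) is free.
    """

    n: int
    d: int = 32
    n_e2e_layers: int = 2
    l_att: int = 2
    p_att: int = 1
    pool_ratio: float = 0.5
    adjacency_mode: str = "identity"
    mlp_sizes: tuple[int, ...] = (128, 64)
    leaky_slope: float = 1.0 / 3.0
    adjacency_grad: str = "straight_through"  # or "detach"

    def __post_init__(self):
        if not (0.0 < self.pool_ratio <= 1.0):
            raise ValueError("pool_ratio must be in (0, 1]")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.adjacency_mode not in ADJACENCY_MODES:
            raise ValueError(
                f"unknown adjacency_mode '{self.adjacency_mode}'; "
                f"choose from {ADJACENCY_MODES}"
            )
        if self.adjacency_grad not in ("straight_through", "detach"):
            raise ValueError("adjacency_grad must be 'straight_through' or 'detach'")

    def param_shapes(self) -> dict[str, tuple[int, ...]]:
        """Name -> shape for every trainable array."""
        n, d = self.n, self.d
        shapes: dict[str, tuple[int, ...]] = {}
        d_in = 1
        for l in range(1, self.n_e2e_layers + 1):
            shapes[f"e2e{l}_r"] = (d_in, n, d)
            shapes[f"e2e{l}_c"] = (d_in, n, d)
            d_in = d
        shapes["e2n_w"] = (d_in, n, d)
        if self.adjacency_mode == "e2e":
            shapes["adj_r"] = (d_in, n, 1)
            shapes["adj_c"] = (d_in, n, 1)
        for l in range(1, self.l_att + 1):
            shapes[f"att{l}_W0"] = (d, self.p_att)
            shapes[f"att{l}_W1"] = (self.p_att, 1)
        widths = (2 * d, *self.mlp_sizes, 1)
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:]), start=1):
            shapes[f"mlp{i}_W"] = (a, b)
            shapes[f"mlp{i}_b"] = (b,)
        return shapes

    def validate_params(self, params: dict[str, np.ndarray]) -> None:
        shapes = self.param_shapes()
        missing = sorted(set(shapes) - set(params))
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        for name, shape in shapes.items():
            got = np.asarray(params[name]).shape
            if got != shape:
                raise ValueError(f"parameter '{name}' has shape {got}, expected {shape}")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _with_batch(f) -> tuple[Tensor, bool]:
    """Promote (d, n, n) to (1, d, n, n); report whether a batch axis existed."""
    t = as_tensor(f)
    if t.ndim == 3:
        return t.reshape(1, *t.shape), False
    if t.ndim != 4:
        raise ValueError(f"edge-feature tensor must be 3- or 4-D, got ndim={t.ndim}")
    return t, True


def e2e_forward(f, r, c, slope: float = 1.0 / 3.0) -> Tensor:
    """Edge-to-edge convolution with a cross-shaped kernel.

    ``out[b][i,j] = lReLU( sum_a sum_k r[a,k,b]*f[a][i,k] + c[a,k,b]*f[a][k,j] )``

    ``f``: (B, d_in, n, n) (or unbatched); ``r``/``c``: (d_in, n, d_out).
    Returns (B, d_out, n, n).
    """
    f, batched = _with_batch(f)
    r, c = as_tensor(r), as_tensor(c)
    d_in, n, d_out = r.shape
    if f.shape[1] != d_in or f.shape[2] != n:
        raise ValueError(
            f"E2E shape mismatch: f has {f.shape[1]} maps of size {f.shape[2]}, "
            f"kernels expect {d_in} maps of length {n}"
        )
    b = f.shape[0]
    row = (f @ r).sum(axis=1)  # (B, n_i, d_out)
    col = (f.swapaxes(-1, -2) @ c).sum(axis=1)  # (B, n_j, d_out)
    pre = row.transpose(0, 2, 1).reshape(b, d_out, n, 1) + \
        col.transpose(0, 2, 1).reshape(b, d_out, 1, n)
    out = leaky_relu(pre, slope)
    return out if batched else out.reshape(d_out, n, n)


def e2n_forward(f, w, slope: float = 1.0 / 3.0) -> Tensor:
    """Edge-to-node aggregation of incident edge features.

    ``e[b][i] = lReLU( sum_a sum_k w[a,k,b]*f[a][i,k] )``; returns node
    features of shape (B, n, d_out).
    """
    f, batched = _with_batch(f)
    w = as_tensor(w)
    d_in, n, d_out = w.shape
    if f.shape[1] != d_in or f.shape[2] != n:
        raise ValueError(
            f"E2N shape mismatch: f maps {f.shape[1]}x{f.shape[2]}, "
            f"kernel expects {d_in}x{n}"
        )
    out = leaky_relu((f @ w).sum(axis=1), slope)
    return out if batched else out.reshape(n, d_out)


def _adjacency_logits(f1: Tensor, fl: Tensor, params, mode: str) -> Tensor:
    if mode == "identity":
        return f1
    if mode == "averaging":
        return fl.mean(axis=0)
    if mode == "e2e":
        r, c = as_tensor(params["adj_r"]), as_tensor(params["adj_c"])
        n = r.shape[1]
        row = (fl @ r).sum(axis=0).reshape(n, 1)
        col = (fl.swapaxes(-1, -2) @ c).sum(axis=0).reshape(1, n)
        return row + col
    raise ValueError(f"unknown adjacency mode '{mode}'")


def embed_adjacency(f1, fl, params=None, mode: str = "identity",
                    grad: str = "straight_through") -> Tensor:
    """Binarize an edge map into the pooling adjacency.

    ``A[i,j] = 1`` iff ``sigmoid(R[i,j]) >= 0.5`` (equivalently ``R >= 0``),
    symmetrized by logical OR.  The forward value is exactly binary; with
    ``grad='straight_through'`` the backward pass substitutes the smooth
    symmetrized sigmoid so upstream kernels receive gradient, with
    ``grad='detach'`` the adjacency is a constant.
    """
    f1 = as_tensor(f1)
    fl = as_tensor(fl) if fl is not None else None
    if mode in ("e2e", "averaging") and fl is None:
        raise ValueError(f"mode '{mode}' requires the last-layer edge features")
    logits = _adjacency_logits(f1, fl, params, mode)
    binary = (logits.data >= 0.0).astype(np.float64)
    binary = np.maximum(binary, binary.T)  # logical OR
    if grad == "detach" or not logits.requires_grad:
        return constant(binary)
    surrogate = sigmoid(logits)
    surrogate = (surrogate + surrogate.transpose()) * 0.5
    return surrogate + constant(binary - surrogate.data)


def gcn_forward(x, a, w) -> Tensor:
    """Symmetric-normalized graph convolution ``D̃^{-1/2} Ã D̃^{-1/2} X W``.

    ``Ã = A + I`` adds self-loops, so every degree is >= 1.
    """
    x, a, w = as_tensor(x), as_tensor(a), as_tensor(w)
    n = a.shape[0]
    a_tilde = a + constant(np.eye(n))
    dinv = a_tilde.sum(axis=1) ** -0.5
    norm = a_tilde * dinv.reshape(n, 1) * dinv.reshape(1, n)
    return norm @ x @ w


def attention_scores(x, a, w0, w1, slope: float = 1.0 / 3.0) -> Tensor:
    """Self-attention node scores ``sigmoid(GCN(lReLU(GCN(X,A;W0)),A;W1))``."""
    h = leaky_relu(gcn_forward(x, a, w0), slope)
    s = sigmoid(gcn_forward(h, a, w1))
    return s.reshape(s.shape[0])


@dataclass
class PooledGraphState:
    """Node features, binary adjacency and scores of one pooling level."""

    x: Tensor
    a: Tensor
    s: Tensor | None
    node_ids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def topk_indices(scores: np.ndarray, ratio: float) -> np.ndarray:
    """Indices of the ceil(ratio*n) highest scores; ties -> lowest index.

    Returned in increasing (original) order.
    """
    n = scores.shape[0]
    k = int(math.ceil(ratio * n))
    order = np.argsort(-scores, kind="stable")[:k]
    return np.sort(order)


def topk_pool(state: PooledGraphState, scores: Tensor, ratio: float) -> PooledGraphState:
    """Keep the top-scoring nodes and gate features residually.

    ``X' = X̂ ⊙ Ŝ + X̂`` (score broadcast over feature dims); the adjacency
    is the corresponding row+column submatrix; surviving original node ids
    keep their order.
    """
    if not (0.0 < ratio <= 1.0):
        raise ValueError("pool ratio must be in (0, 1]")
    idx = topk_indices(scores.data, ratio)
    xk = state.x.take(idx, axis=0)
    sk = scores.take(idx, axis=0)
    ak = state.a.take(idx, axis=0).take(idx, axis=1)
    x_next = xk * (sk.reshape(len(idx), 1) + 1.0)
    return PooledGraphState(x_next, ak, sk, state.node_ids[idx])


def readout(layer_states: list[PooledGraphState]) -> Tensor:
    """``z = sum_l [mean_i x_i^l ‖ max_i x_i^l]`` over pooling layers."""
    if not layer_states:
        raise ValueError("readout requires at least one layer state")
    z = None
    for st in layer_states:
        if st.n_nodes == 0:
            raise ValueError("readout on an empty node set")
        part = concatenate([st.x.mean(axis=0), st.x.max(axis=0)], axis=0)
        z = part if z is None else z + part
    return z


def _mlp(z: Tensor, params, config: ModelConfig) -> Tensor:
    h = z.reshape(1, z.shape[0]) if z.ndim == 1 else z
    n_layers = len(config.mlp_sizes) + 1
    for i in range(1, n_layers + 1):
        w = as_tensor(params[f"mlp{i}_W"])
        b = as_tensor(params[f"mlp{i}_b"])
        h = h @ w + b.reshape(1, b.shape[0])
        if i < n_layers:
            h = leaky_relu(h, config.leaky_slope)
    return h  # (B, 1)


def _as_param_tensors(params) -> dict[str, Tensor]:
    return {k: as_tensor(v) for k, v in params.items()}


# -- batched pooling path (numerically identical layer math, one graph node
#    per op across the whole mini-batch instead of per subject) -------------

def _embed_adjacency_batched(g: Tensor, f: Tensor, pt, mode: str,
                             grad: str) -> Tensor:
    b, n = g.shape[0], g.shape[1]
    if mode == "identity":
        logits = g
    elif mode == "averaging":
        logits = f.mean(axis=1)
    elif mode == "e2e":
        r, c = pt["adj_r"], pt["adj_c"]
        row = (f @ r).sum(axis=1)                      # (B, n, 1)
        col = (f.swapaxes(-1, -2) @ c).sum(axis=1)     # (B, n, 1)
        logits = row.reshape(b, n, 1) + col.reshape(b, 1, n)
    else:
        raise ValueError(f"unknown adjacency mode '{mode}'")
    binary = (logits.data >= 0.0).astype(np.float64)
    binary = np.maximum(binary, np.swapaxes(binary, 1, 2))
    if grad == "detach" or not logits.requires_grad:
        return constant(binary)
    surrogate = sigmoid(logits)
    surrogate = (surrogate + surrogate.transpose(0, 2, 1)) * 0.5
    return surrogate + constant(binary - surrogate.data)


def _gcn_batched(x: Tensor, a: Tensor, w: Tensor) -> Tensor:
    b, n = a.shape[0], a.shape[1]
    a_tilde = a + constant(np.eye(n))
    dinv = a_tilde.sum(axis=2) ** -0.5
    norm = a_tilde * dinv.reshape(b, n, 1) * dinv.reshape(b, 1, n)
    return norm @ x @ w


def _attention_scores_batched(x, a, w0, w1, slope: float) -> Tensor:
    h = leaky_relu(_gcn_batched(x, a, w0), slope)
    s = sigmoid(_gcn_batched(h, a, w1))
    return s.reshape(s.shape[0], s.shape[1])


def _topk_indices_batched(scores: np.ndarray, ratio: float) -> np.ndarray:
    """(B, k) per-sample top-k indices, ties to lowest index, sorted."""
    k = int(math.ceil(ratio * scores.shape[1]))
    order = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    return np.sort(order, axis=1)


def forward_batch(g, params, config: ModelConfig,
                  adjacency_grad: str | None = None,
                  collect: bool = False,
                  override_adjacency=None):
    """Forward pass for a (B, n, n) stack of connectivity matrices.

    Returns ``(predictions (B,), intermediates)``; ``intermediates`` is a
    dict with the shared edge/node feature tensors and, if ``collect``, the
    per-sample pooled states.  ``override_adjacency`` (one (n, n) binary
    matrix or a per-sample list) bypasses the adjacency embedding — the
    prediction is then evaluated on a *fixed* pooling graph, which is the
    differentiable branch that saliency gradients live on.
    """
    g = as_tensor(g)
    single = g.ndim == 2
    if single:
        g = g.reshape(1, *g.shape)
    b, n = g.shape[0], g.shape[1]
    if n != config.n:
        raise ValueError(f"input has {n} nodes, config expects {config.n}")
    pt = _as_param_tensors(params)
    agrad = adjacency_grad or config.adjacency_grad
    slope = config.leaky_slope

    f = g.reshape(b, 1, n, n)
    for l in range(1, config.n_e2e_layers + 1):
        f = e2e_forward(f, pt[f"e2e{l}_r"], pt[f"e2e{l}_c"], slope)
    node_feat = e2n_forward(f, pt["e2n_w"], slope)  # (B, n, d)

    if collect:
        # per-sample path: materializes PooledGraphState objects
        z, adjs, states_all = _pool_persample(
            g, f, node_feat, pt, config, agrad, override_adjacency, b, n
        )
    else:
        z, adjs = _pool_batched(
            g, f, node_feat, pt, config, agrad, override_adjacency, b, n
        )
        states_all = None
    preds = _mlp(z, pt, config).reshape(b)
    inter = {
        "edge_features": f,
        "node_features": node_feat,
        "adjacency": adjs,
        "readout": z,
        "input": g,
        "params": pt,
    }
    if collect:
        inter["pooled_states"] = states_all
    if single:
        preds = preds.reshape(1)
    return preds, inter


def _pool_batched(g, f, node_feat, pt, config: ModelConfig, agrad,
                  override_adjacency, b: int, n: int):
    if override_adjacency is not None:
        fixed = np.stack(override_adjacency) if isinstance(override_adjacency, list) \
            else np.broadcast_to(np.asarray(override_adjacency, float), (b, n, n))
        a = constant(np.array(fixed, dtype=np.float64))
    else:
        a = _embed_adjacency_batched(g, f, pt, config.adjacency_mode, agrad)
    adjs = list(a.data)
    x = node_feat
    z = None
    for l in range(1, config.l_att + 1):
        scores = _attention_scores_batched(
            x, a, pt[f"att{l}_W0"], pt[f"att{l}_W1"], config.leaky_slope
        )
        idx = _topk_indices_batched(scores.data, config.pool_ratio)
        k = idx.shape[1]
        xk = x.take_batched(idx)
        sk = scores.take_batched(idx)
        a = a.take_batched(idx).swapaxes(1, 2).take_batched(idx).swapaxes(1, 2)
        x = xk * (sk.reshape(b, k, 1) + 1.0)
        part = concatenate([x.mean(axis=1), x.max(axis=1)], axis=1)  # (B, 2d)
        z = part if z is None else z + part
    return z, adjs


def _pool_persample(g, f, node_feat, pt, config: ModelConfig, agrad,
                    override_adjacency, b: int, n: int):
    zs = []
    adjs = []
    states_all = []
    for s in range(b):
        if override_adjacency is not None:
            fixed = override_adjacency[s] if isinstance(override_adjacency, list) \
                else override_adjacency
            a = constant(np.asarray(fixed, dtype=np.float64))
        else:
            f1_s = g.take([s], axis=0).reshape(n, n)
            fl_s = f.take([s], axis=0).reshape(f.shape[1], n, n)
            a = embed_adjacency(f1_s, fl_s, pt, config.adjacency_mode, agrad)
        adjs.append(a.data)
        state = PooledGraphState(
            node_feat.take([s], axis=0).reshape(n, config.d), a, None, np.arange(n)
        )
        layer_states = []
        for l in range(1, config.l_att + 1):
            scores = attention_scores(
                state.x, state.a, pt[f"att{l}_W0"], pt[f"att{l}_W1"],
                config.leaky_slope
            )
            state = topk_pool(state, scores, config.pool_ratio)
            layer_states.append(state)
        zs.append(readout(layer_states).reshape(1, 2 * config.d))
        states_all.append(layer_states)
    return concatenate(zs, axis=0), adjs, states_all


def model_forward(g, params, config: ModelConfig, collect: bool = False):
    """Predict the severity score for a single connectivity matrix.

    Returns ``(prediction Tensor of shape (1,), intermediates dict)``.
    """
    return forward_batch(g, params, config, collect=collect)


def load_model_config(path: str | Path) -> ModelConfig:
    """Read a :class:`ModelConfig` from a YAML or JSON file.

    Any subset of fields may be given (``n`` is required); the rest take
    their defaults.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "n" not in raw:
        raise ValueError(f"{path}: expected a mapping with at least 'n'")
    if "mlp_sizes" in raw:
        raw["mlp_sizes"] = tuple(raw["mlp_sizes"])
    return ModelConfig(**raw)


# ---------------------------------------------------------------------------
# checkpointing (JSON text: config + named parameter arrays)
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, params: dict[str, np.ndarray],
                    config: ModelConfig) -> None:
    blob = {
        "config": {**asdict(config), "mlp_sizes": list(config.mlp_sizes)},
        "params": {k: np.asarray(v).tolist() for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(blob))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], ModelConfig]:
    blob = json.loads(Path(path).read_text())
    cfg_d = blob["config"]
    cfg_d["mlp_sizes"] = tuple(cfg_d["mlp_sizes"])
    config = ModelConfig(**cfg_d)
    params = {k: np.asarray(v, dtype=np.float64) for k, v in blob["params"].items()}
    config.validate_params(params)
    return params, config
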