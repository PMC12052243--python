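"""Relational-GCN + KAN node classifier for deletion evidence.

The classifier labels every graph node as background (0) or deletion
evidence (1). Its pipeline is

    conv1 (6 -> d1, ReLU) -> conv2 (d1 -> d2, ReLU) -> head -> softmax

where each conv layer is a relational graph convolution

    H_i' = ReLU( sum_r sum_{j in N_i^r} W_r H_j / C_{i,r} + W_0 H_i + b )

with one weight matrix per edge relation (ref-ref, ref-read, read-read),
a self-loop weight ``W_0``, and ``C_{i,r}`` the in-degree of node *i*
under relation *r* (a relation with no in-neighbors contributes
nothing). The default head is a KAN layer followed by a linear layer;
``fc``, ``kan`` and ``kan2`` heads are available for ablation. A KAN
layer replaces fixed activations with learnable univariate functions

    phi_{q,p}(x) = base_{q,p} * silu(x) + scale_{q,p} * sum_m c_{q,p,m} B_m(x)

summed over inputs, with ``B_m`` a cubic B-spline basis on a uniform
grid; inputs are clamped to the grid range.

Training minimizes class-weighted cross-entropy with an L2 penalty,

    Loss = -(1/N) sum_i w_{y_i} log p_{i,y_i} + (lambda/2) ||W||_2^2

with ``w`` drawn from ``[1 - weight, weight]`` by true class. The whole
network is a few hundred scalars, so forward, backward and Adam are
implemented directly in NumPy (float64) and verified against finite
differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import _bspline
from .hetgraph import (
    DEFAULT_LENGTH_SCALE,
    GraphBatch,
    ReadGraph,
    RELATIONS,
    batch_graphs,
)

EPS_LOG = 1e-12
HEADS = ("fc", "kan", "kan2", "kan_fc")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + training hyperparameters."""

    hidden1: int = 8
    hidden2: int = 4
    head: str = "kan_fc"
    grid_size: int = 5
    spline_order: int = 3
    grid_range: Tuple[float, float] = (-2.0, 2.0)
    conv_bias: bool = True
    class_weight: float = 0.9  # positive-class weight in [1-w, w]
    l2: float = 1e-4
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32  # graphs per minibatch
    length_scale: float = DEFAULT_LENGTH_SCALE

    def __post_init__(self) -> None:
        if self.head not in HEADS:
            raise ConfigError(f"unknown head {self.head!r}")
        if not (0.0 < self.class_weight < 1.0):
            raise ConfigError("class_weight must be in (0, 1)")


Params = Dict[str, np.ndarray]


def _n_bases(cfg: ModelConfig) -> int:
    return cfg.grid_size + cfg.spline_order


def init_params(cfg: ModelConfig, rng: np.random.Generator) -> Params:
    """Initialize all trainable arrays for the configured architecture."""
    p: Params = {}

    def conv(name: str, d_in: int, d_out: int) -> None:
        std = 1.0 / np.sqrt(d_in)
        for rel in RELATIONS:
            p[f"{name}.W.{rel}"] = rng.normal(0.0, std, (d_in, d_out))
        p[f"{name}.W0"] = rng.normal(0.0, std, (d_in, d_out))
        if cfg.conv_bias:
            p[f"{name}.b"] = np.zeros(d_out)

    def kan(name: str, d_in: int, d_out: int) -> None:
        p[f"{name}.base"] = rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_out, d_in))
        p[f"{name}.scale"] = np.ones((d_out, d_in))
        p[f"{name}.coef"] = rng.normal(0.0, 0.1, (d_out, d_in, _n_bases(cfg)))

    def fc(name: str, d_in: int, d_out: int) -> None:
        p[f"{name}.W"] = rng.normal(0.0, 1.0 / np.sqrt(d_in), (d_in, d_out))
        p[f"{name}.b"] = np.zeros(d_out)

    conv("conv1", 6, cfg.hidden1)
    conv("conv2", cfg.hidden1, cfg.hidden2)
    d2 = cfg.hidden2
    if cfg.head == "fc":
        fc("fc", d2, 2)
    elif cfg.head == "kan":
        kan("kan1", d2, 2)
    elif cfg.head == "kan2":
        kan("kan1", d2, d2)
        kan("kan2", d2, 2)
    else:  # kan_fc
        kan("kan1", d2, d2)
        fc("fc", d2, 2)
    return p


def count_params(params: Params) -> int:
    """Exact count of trainable scalars."""
    return int(sum(v.size for v in params.values()))


# ---------------------------------------------------------------- layers


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def _aggregate_forward(
    X: np.ndarray,
    edges: Dict[str, np.ndarray],
    Wr: Dict[str, np.ndarray],
    W0: np.ndarray,
    b: Optional[np.ndarray],
) -> Tuple[np.ndarray, dict]:
    """Pre-activation relational aggregation; returns (Z, cache)."""
    N = X.shape[0]
    Z = X @ W0
    if b is not None:
        Z = Z + b
    msgs: Dict[str, np.ndarray] = {}
    degs: Dict[str, np.ndarray] = {}
    for rel, W in Wr.items():
        E = edges.get(rel)
        if E is None or len(E) == 0:
            continue
        src, dst = E[:, 0], E[:, 1]
        if len(E) and (E.min() < 0 or E.max() >= N):
            raise IndexError(f"edge endpoint out of range for relation {rel}")
        deg = np.bincount(dst, minlength=N).astype(float)
        M = np.zeros_like(X)
        np.add.at(M, dst, X[src])
        nz = deg > 0
        M[nz] /= deg[nz, None]
        Z = Z + M @ W
        msgs[rel] = M
        degs[rel] = deg
    return Z, {"X": X, "msgs": msgs, "degs": degs, "edges": edges}


def _aggregate_backward(
    dZ: np.ndarray,
    cache: dict,
    Wr: Dict[str, np.ndarray],
    W0: np.ndarray,
    has_bias: bool,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    X = cache["X"]
    grads: Dict[str, np.ndarray] = {"W0": X.T @ dZ}
    if has_bias:
        grads["b"] = dZ.sum(axis=0)
    dX = dZ @ W0.T
    for rel, M in cache["msgs"].items():
        W = Wr[rel]
        grads[f"W.{rel}"] = M.T @ dZ
        dM = dZ @ W.T
        E = cache["edges"][rel]
        src, dst = E[:, 0], E[:, 1]
        deg = cache["degs"][rel]
        np.add.at(dX, src, dM[dst] / deg[dst, None])
    return dX, grads


def rgcn_forward(
    H: np.ndarray,
    edges_by_relation: Dict[str, np.ndarray],
    layer_params: Dict[str, np.ndarray],
) -> np.ndarray:
    """One relational graph convolution layer with ReLU.

    ``layer_params`` maps ``W.<relation>`` to the per-relation weight,
    ``W0`` to the self weight, optionally ``b`` to a bias.
    """
    Wr = {
        rel: layer_params[f"W.{rel}"]
        for rel in edges_by_relation
        if f"W.{rel}" in layer_params
    }
    edges = {
        rel: np.asarray(e, dtype=np.int64).reshape(-1, 2)
        for rel, e in edges_by_relation.items()
    }
    Z, _ = _aggregate_forward(
        np.asarray(H, dtype=float), edges, Wr, layer_params["W0"],
        layer_params.get("b"),
    )
    return np.maximum(Z, 0.0)


def _kan_forward(
    X: np.ndarray, base: np.ndarray, scale: np.ndarray, coef: np.ndarray,
    cfg: ModelConfig,
) -> Tuple[np.ndarray, dict]:
    lo, hi = cfg.grid_range
    Xc = np.clip(X, lo, hi)
    mask = ((X >= lo) & (X <= hi)).astype(float)
    N, d_in = Xc.shape
    B = _bspline.design_matrix(
        Xc.ravel(), cfg.grid_range, cfg.grid_size, cfg.spline_order
    ).reshape(N, d_in, -1)
    S = _silu(Xc)
    spl = np.einsum("npm,opm->nop", B, coef)
    Y = np.einsum("op,np->no", base, S) + np.einsum("op,nop->no", scale, spl)
    return Y, {"Xc": Xc, "mask": mask, "B": B, "S": S, "spl": spl}


def _kan_backward(
    dY: np.ndarray, cache: dict, base: np.ndarray, scale: np.ndarray,
    coef: np.ndarray, cfg: ModelConfig,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    Xc, mask, B, S, spl = (
        cache["Xc"], cache["mask"], cache["B"], cache["S"], cache["spl"],
    )
    grads = {
        "base": np.einsum("no,np->op", dY, S),
        "scale": np.einsum("no,nop->op", dY, spl),
        "coef": np.einsum("no,npm->opm", dY, B) * scale[:, :, None],
    }
    N, d_in = Xc.shape
    Bp = _bspline.design_matrix_deriv(
        Xc.ravel(), cfg.grid_range, cfg.grid_size, cfg.spline_order
    ).reshape(N, d_in, -1)
    splp = np.einsum("npm,opm->nop", Bp, coef)
    dX = np.einsum("no,op->np", dY, base) * _silu_grad(Xc)
    dX += np.einsum("no,nop->np", dY, splp * scale[None, :, :])
    return dX * mask, grads


def kan_forward(
    X: np.ndarray, kan_params: Dict[str, np.ndarray],
    cfg: Optional[ModelConfig] = None,
) -> np.ndarray:
    """Evaluate a KAN layer (``base``, ``scale``, ``coef`` arrays)."""
    cfg = cfg or ModelConfig()
    Y, _ = _kan_forward(
        np.asarray(X, dtype=float),
        kan_params["base"], kan_params["scale"], kan_params["coef"], cfg,
    )
    return Y


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    batch: GraphBatch, params: Params, cfg: ModelConfig
) -> Tuple[np.ndarray, list]:
    """Full forward pass; returns (probs, caches for backward)."""
    caches: list = []
    X = batch.X.astype(float)
    if X.shape[1] != 6:
        raise ConfigError(f"expected 6-d node features, got {X.shape[1]}")
    H = X
    for name in ("conv1", "conv2"):
        Wr = {rel: params[f"{name}.W.{rel}"] for rel in RELATIONS}
        Z, cache = _aggregate_forward(
            H, batch.edges, Wr, params[f"{name}.W0"], params.get(f"{name}.b")
        )
        H = np.maximum(Z, 0.0)
        caches.append((name, cache, Z))
    if cfg.head in ("kan", "kan2", "kan_fc"):
        Y, cache = _kan_forward(
            H, params["kan1.base"], params["kan1.scale"], params["kan1.coef"],
            cfg,
        )
        caches.append(("kan1", cache, H))
        H = Y
    if cfg.head == "kan2":
        Y, cache = _kan_forward(
            H, params["kan2.base"], params["kan2.scale"], params["kan2.coef"],
            cfg,
        )
        caches.append(("kan2", cache, H))
        H = Y
    if cfg.head in ("fc", "kan_fc"):
        caches.append(("fc", None, H))
        H = H @ params["fc.W"] + params["fc.b"]
    probs = _softmax(H)
    return probs, caches


def _backward(
    probs: np.ndarray,
    labels: np.ndarray,
    caches: list,
    params: Params,
    cfg: ModelConfig,
) -> Params:
    """Gradient of the weighted-CE part of the loss for all params."""
    N = probs.shape[0]
    w = np.where(labels == 1, cfg.class_weight, 1.0 - cfg.class_weight)
    onehot = np.zeros_like(probs)
    onehot[np.arange(N), labels] = 1.0
    dH = (probs - onehot) * w[:, None] / N  # dLoss/dlogits
    grads: Params = {}
    for name, cache, inp in reversed(caches):
        if name == "fc":
            grads["fc.W"] = inp.T @ dH
            grads["fc.b"] = dH.sum(axis=0)
            dH = dH @ params["fc.W"].T
        elif name.startswith("kan"):
            dH, g = _kan_backward(
                dH, cache,
                params[f"{name}.base"], params[f"{name}.scale"],
                params[f"{name}.coef"], cfg,
            )
            for k, v in g.items():
                grads[f"{name}.{k}"] = v
        else:  # conv layer: cache from aggregation, inp = pre-activation Z
            dH = dH * (inp > 0.0)  # ReLU
            Wr = {rel: params[f"{name}.W.{rel}"] for rel in RELATIONS}
            dH, g = _aggregate_backward(
                dH, cache, Wr, params[f"{name}.W0"], f"{name}.b" in params
            )
            for k, v in g.items():
                grads[f"{name}.{k}"] = v
    return grads


def model_forward(
    batch: GraphBatch, params: Params, cfg: Optional[ModelConfig] = None
) -> np.ndarray:
    """Class probabilities ``(N, 2)`` for every node in the batch."""
    cfg = cfg or ModelConfig()
    probs, _ = _forward(batch, params, cfg)
    return probs


def l2_norm_sq(params: Params) -> float:
    return float(sum(np.sum(v * v) for v in params.values()))


def compute_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    params: Optional[Params] = None,
    class_weight: float = 0.9,
    l2: float = 0.0,
) -> float:
    """Class-weighted cross-entropy plus (l2/2)*||W||^2."""
    labels = np.asarray(labels)
    w = np.where(labels == 1, class_weight, 1.0 - class_weight)
    p_true = np.clip(probs[np.arange(len(labels)), labels], EPS_LOG, None)
    loss = -float(np.mean(w * np.log(p_true)))
    if l2 > 0.0 and params is not None:
        loss += 0.5 * l2 * l2_norm_sq(params)
    return loss


# -------------------------------------------------------------- training


class _Adam:
    def __init__(self, params: Params, lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        for k in params:
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DeletionNodeClassifier(BaseEstimator):
    """sklearn-style node classifier over read graphs.

    ``fit`` consumes a sequence of :class:`ReadGraph` objects whose
    ``labels`` are set (see :func:`kandel.hetgraph.label_nodes`), or an
    explicit ``y`` given as a per-node array concatenated in graph
    order. ``predict``/``predict_proba`` return per-node outputs in the
    same concatenated order.
    """

    def __init__(
        self,
        hidden1: int = 8,
        hidden2: int = 4,
        head: str = "kan_fc",
        grid_size: int = 5,
        spline_order: int = 3,
        grid_range: Tuple[float, float] = (-2.0, 2.0),
        conv_bias: bool = True,
        class_weight: float = 0.9,
        l2: float = 1e-4,
        lr: float = 1e-3,
        epochs: int = 50,
        batch_size: int = 32,
        length_scale: float = DEFAULT_LENGTH_SCALE,
        seed: int = 0,
    ) -> None:
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.head = head
        self.grid_size = grid_size
        self.spline_order = spline_order
        self.grid_range = grid_range
        self.conv_bias = conv_bias
        self.class_weight = class_weight
        self.l2 = l2
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.length_scale = length_scale
        self.seed = seed

    # ------------------------------------------------------------ internals

    def _config(self) -> ModelConfig:
        return ModelConfig(
            hidden1=self.hidden1,
            hidden2=self.hidden2,
            head=self.head,
            grid_size=self.grid_size,
            spline_order=self.spline_order,
            grid_range=tuple(self.grid_range),
            conv_bias=self.conv_bias,
            class_weight=self.class_weight,
            l2=self.l2,
            lr=self.lr,
            epochs=self.epochs,
            batch_size=self.batch_size,
            length_scale=self.length_scale,
        )

    def _check_scale(self, graphs: Sequence[ReadGraph]) -> None:
        for g in graphs:
            if not np.isclose(g.length_scale, self.length_scale):
                raise ConfigError(
                    f"graph length_scale {g.length_scale} does not match "
                    f"model length_scale {self.length_scale}"
                )

    # ------------------------------------------------------------------ API

    def fit(
        self,
        graphs: Sequence[ReadGraph],
        y: Optional[np.ndarray] = None,
    ) -> "DeletionNodeClassifier":
        if not graphs:
            raise ValueError("fit requires at least one graph")
        self._check_scale(graphs)
        cfg = self._config()
        if y is not None:
            y = np.asarray(y, dtype=np.int64)
            off = 0
            graphs = list(graphs)
            for i, g in enumerate(graphs):
                g.labels = y[off : off + g.n_nodes]
                off += g.n_nodes
        labels_all = np.concatenate(
            [np.asarray(g.labels, dtype=np.int64) for g in graphs]
        )
        if len(np.unique(labels_all)) < 2:
            warnings.warn(
                "training data contains a single class; proceeding anyway",
                stacklevel=2,
            )
        rng = np.random.default_rng(self.seed)
        params = init_params(cfg, rng)
        opt = _Adam(params, cfg.lr)
        graphs = list(graphs)
        history: List[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(graphs))
            losses: List[float] = []
            for i0 in range(0, len(graphs), cfg.batch_size):
                chunk = [graphs[j] for j in order[i0 : i0 + cfg.batch_size]]
                batch = batch_graphs(chunk)
                probs, caches = _forward(batch, params, cfg)
                lab = batch.labels
                losses.append(
                    compute_loss(probs, lab, params, cfg.class_weight, cfg.l2)
                )
                grads = _backward(probs, lab, caches, params, cfg)
                if cfg.l2 > 0.0:
                    for k in params:
                        grads[k] = grads.get(k, 0.0) + cfg.l2 * params[k]
                opt.step(params, grads)
            history.append(float(np.mean(losses)))
        self.params_ = params
        self.loss_history_ = history
        self.n_params_ = count_params(params)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, graphs: Sequence[ReadGraph]) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")
        self._check_scale(graphs)
        batch = batch_graphs(list(graphs))
        return model_forward(batch, self.params_, self._config())

    def predict(self, graphs: Sequence[ReadGraph]) -> np.ndarray:
        """Hard labels; the documented tie-break at p0 == p1 is class 0."""
        probs = self.predict_proba(graphs)
        return (probs[:, 1] > probs[:, 0]).astype(np.int64)

    # ------------------------------------------------------------ persistence

    def save(self, path: str) -> None:
        """Write a self-describing JSON checkpoint (config + weights)."""
        blob = {
            "format": "kandel-checkpoint-v1",
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "params": {k: v.tolist() for k, v in self.params_.items()},
            "loss_history": getattr(self, "loss_history_", []),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "DeletionNodeClassifier":
        with open(path) as fh:
            blob = json.load(fh)
        config = dict(blob["config"])
        if "grid_range" in config:
            config["grid_range"] = tuple(config["grid_range"])
        est = cls(**config)
        est.params_ = {k: np.asarray(v) for k, v in blob["params"].items()}
        est.loss_history_ = blob.get("loss_history", [])
        est.n_params_ = count_params(est.params_)
        est.classes_ = np.array([0, 1])
        return est


# --------------------------------------------------- functional wrappers


def train_model(
    labeled_graphs: Sequence[ReadGraph],
    hyper: Optional[dict] = None,
    seed: int = 0,
) -> DeletionNodeClassifier:
    """Train a classifier on labeled graphs; thin estimator wrapper."""
    est = DeletionNodeClassifier(seed=seed, **(hyper or {}))
    return est.fit(labeled_graphs)


def predict_nodes(
    graphs: Sequence[ReadGraph], model: DeletionNodeClassifier
) -> Tuple[np.ndarray, np.ndarray]:
    """(probabilities, hard labels) for every node, concatenated."""
    probs = model.predict_proba(graphs)
    return probs, (probs[:, 1] > probs[:, 0]).astype(np.int64)


def default_param_count() -> int:
    """Trainable-scalar count of the default architecture."""
    cfg = ModelConfig()
    return count_params(init_params(cfg, np.random.default_rng(0)))
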