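"""Graph-classification harness: backbones, model assembly and training.

Builds four-layer GNN classifiers (GCN, GAT or GIN) with the topological
layer optionally substituted for one backbone layer, mean pooling and a
two-layer MLP head (hidden 32).  Training follows a fixed protocol: Adam at
learning rate 1e-3, halved whenever validation accuracy fails to improve
for 10 epochs, stopping once the learning rate drops below 1e-5 or after
200 epochs; evaluation is 10-fold cross-validation with 10% of each
training split held out for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, gather_rows, parameters_of, scatter_add_rows
from .graph import LabeledGraphDataset
from .layer import GraphBatch, Linear, MLP, TrephConfig, TrephLayer

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "Adam",
    "GraphClassifier",
    "build_model",
    "train_model",
    "train_eval",
    "MAX_DEGREE_BUCKET",
]

logger = logging.getLogger("treph")

MAX_DEGREE_BUCKET = 512  # degrees above this share one overflow embedding row


@dataclass
class ArchitectureSpec:
    """Backbone type and where (if anywhere) the topological layer sits."""

    backbone: str = "GIN"            # GCN | GAT | GIN
    n_layers: int = 4
    treph_position: int | None = None  # 1-based, None = pure backbone
    hidden: int = 64
    classifier_hidden: int = 32
    treph_variant: str = "eph"

    def __post_init__(self) -> None:
        if self.backbone not in ("GCN", "GAT", "GIN"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.treph_position is not None and not (
                1 <= self.treph_position <= self.n_layers):
            raise ValueError("treph_position out of range")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    plateau_patience: int = 10
    min_lr: float = 1e-5
    max_epochs: int = 200
    batch_size: int = 32
    n_folds: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    #: optional early stop once training accuracy reaches this level
    target_train_acc: float | None = None

    def __post_init__(self) -> None:
        if min(self.lr, self.plateau_patience, self.max_epochs,
               self.batch_size) <= 0:
            raise ValueError("training hyperparameters must be positive")


# ---------------------------------------------------------------------------
# Backbone layers
# ---------------------------------------------------------------------------

class GCNLayer:
    """Symmetric-normalized graph convolution with self-loops, ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.lin = Linear(d_in, d_out, rng)

    def forward(self, batch: GraphBatch, x: Tensor, training: bool) -> Tensor:
        xw = self.lin(x)
        deg = np.zeros(batch.n_nodes)
        np.add.at(deg, batch.edge_dst, 1.0)
        dh = 1.0 / np.sqrt(deg + 1.0)
        out = xw * Tensor((dh * dh)[:, None])  # self-loop term
        if len(batch.edge_src):
            w = dh[batch.edge_src] * dh[batch.edge_dst]
            msg = gather_rows(xw, batch.edge_src) * Tensor(w[:, None])
            out = out + scatter_add_rows(msg, batch.edge_dst, batch.n_nodes)
        return out.relu()


class GINLayer:
    """GIN-ε: ``MLP((1+ε)x + Σ_neighbors x)`` with learnable ε, ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.epsilon = Tensor(np.zeros(()), requires_grad=True)
        self.mlp = MLP([d_in, d_out, d_out], rng)

    def forward(self, batch: GraphBatch, x: Tensor, training: bool) -> Tensor:
        return self.mlp(x * (1.0 + self.epsilon) + batch.neighbor_sum(x)).relu()


class GATLayer:
    """Single-head graph attention with self-loops (LeakyReLU scores)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.lin = Linear(d_in, d_out, rng)
        a = np.sqrt(6.0 / (d_out + 1))
        self.att_src = Tensor(rng.uniform(-a, a, size=(d_out, 1)), requires_grad=True)
        self.att_dst = Tensor(rng.uniform(-a, a, size=(d_out, 1)), requires_grad=True)

    def forward(self, batch: GraphBatch, x: Tensor, training: bool) -> Tensor:
        h = self.lin(x)
        n = batch.n_nodes
        loops = np.arange(n, dtype=np.int64)
        src = np.concatenate([batch.edge_src, loops])
        dst = np.concatenate([batch.edge_dst, loops])
        score = gather_rows(h @ self.att_src, src) + gather_rows(h @ self.att_dst, dst)
        score = score.leaky_relu(0.2)
        # segment softmax over incoming edges of each dst node
        smax = np.full(n, -np.inf)
        np.maximum.at(smax, dst, score.data[:, 0])
        ex = (score - Tensor(smax[dst][:, None])).exp()
        denom = scatter_add_rows(ex, dst, n)
        alpha = ex / gather_rows(denom, dst)
        msg = gather_rows(h, src) * alpha
        return scatter_add_rows(msg, dst, n).relu()


_BACKBONES = {"GCN": GCNLayer, "GIN": GINLayer, "GAT": GATLayer}


class _TrephWrapper:
    def __init__(self, layer: TrephLayer):
        self.layer = layer

    def forward(self, batch: GraphBatch, x: Tensor, training: bool) -> Tensor:
        return self.layer.forward(batch, x, training)


class DegreeEmbedding:
    """Learnable lookup from capped node degree to a feature vector."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0, 0.1, size=(MAX_DEGREE_BUCKET + 1, dim)),
                            requires_grad=True)

    def forward(self, batch: GraphBatch, x: Tensor, training: bool) -> Tensor:
        idx = np.minimum(x.data[:, 0].astype(np.int64), MAX_DEGREE_BUCKET)
        return gather_rows(self.table, idx)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

class GraphClassifier:
    """Node-transform stack + mean pooling + MLP head producing class logits."""

    def __init__(self, layers: list, head: MLP):
        self.layers = layers
        self.head = head

    def logits(self, batch: GraphBatch, x: Tensor, training: bool = False) -> Tensor:
        for layer in self.layers:
            x = layer.forward(batch, x, training)
        return self.head(batch.mean_pool(x))

    def pooled(self, batch: GraphBatch, x: Tensor) -> np.ndarray:
        """Mean-pooled representation before the head (evaluation mode)."""
        h = x
        for layer in self.layers:
            h = layer.forward(batch, h, False)
        return batch.mean_pool(h).data

    def parameters(self) -> list[Tensor]:
        return parameters_of(self)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(spec: ArchitectureSpec, cfg: TrephConfig, n_classes: int,
                d_in: int = 1, feature_kind: str = "dense",
                seed: int = 0) -> GraphClassifier:
    """Assemble a classifier per the architecture spec.

    Layer ``spec.treph_position`` (1-based) of the backbone is replaced by
    the topological layer; the parameter count depends only on the spec and
    dims, never on graph sizes.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    if feature_kind == "degree_index":
        layers.append(DegreeEmbedding(spec.hidden, rng))
        d_prev = spec.hidden
    else:
        d_prev = d_in
    for pos in range(1, spec.n_layers + 1):
        if spec.treph_position == pos:
            lcfg = TrephConfig(d=d_prev, df=cfg.df, dv=cfg.dv,
                               d_out=spec.hidden, hidden=cfg.hidden,
                               aggregation=cfg.aggregation, residual=cfg.residual)
            layers.append(_TrephWrapper(
                TrephLayer(lcfg, rng, variant=spec.treph_variant)))
        else:
            layers.append(_BACKBONES[spec.backbone](d_prev, spec.hidden, rng))
        d_prev = spec.hidden
    head = MLP([d_prev, spec.classifier_hidden, n_classes], rng)
    return GraphClassifier(layers, head)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    z = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logp = z - z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(logp * Tensor(onehot)).sum() / len(labels)


def _accuracy(model: GraphClassifier, ds: LabeledGraphDataset,
              idx: np.ndarray) -> float:
    if len(idx) == 0:
        return float("nan")
    batch = GraphBatch([ds.graphs[i] for i in idx])
    x = Tensor(np.concatenate([ds.features[i].matrix for i in idx], axis=0))
    pred = model.logits(batch, x, training=False).data.argmax(axis=1)
    return float(np.mean(pred == np.array([ds.labels[i] for i in idx])))


def train_model(model: GraphClassifier, ds: LabeledGraphDataset,
                train_idx: np.ndarray, val_idx: np.ndarray,
                tc: TrainConfig) -> dict:
    """Train one model on one split under the plateau-halving schedule.

    Returns a history dict with per-epoch training/validation accuracy, the
    learning-rate trace and the stopping epoch.
    """
    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.parameters(), lr=tc.lr)
    best_val, since_best = -1.0, 0
    history = {"train_acc": [], "val_acc": [], "lr": [], "epochs": 0}
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), tc.batch_size):
            sel = order[start:start + tc.batch_size]
            batch = GraphBatch([ds.graphs[i] for i in sel])
            x = Tensor(np.concatenate([ds.features[i].matrix for i in sel]))
            opt.zero_grad()
            loss = _cross_entropy(model.logits(batch, x, training=True),
                                  np.array([ds.labels[i] for i in sel]))
            loss.backward()
            opt.step()
        tr_acc = _accuracy(model, ds, train_idx)
        va_acc = _accuracy(model, ds, val_idx) if len(val_idx) else tr_acc
        history["train_acc"].append(tr_acc)
        history["val_acc"].append(va_acc)
        history["lr"].append(opt.lr)
        history["epochs"] = epoch
        if va_acc > best_val:
            best_val, since_best = va_acc, 0
        else:
            since_best += 1
            if since_best >= tc.plateau_patience:
                opt.lr /= 2.0
                since_best = 0
                logger.info("epoch %d: halving lr to %g", epoch, opt.lr)
        if tc.target_train_acc is not None and tr_acc >= tc.target_train_acc:
            logger.info("epoch %d: reached target training accuracy %.3f",
                        epoch, tr_acc)
            break
        if opt.lr < tc.min_lr:
            logger.info("epoch %d: lr %g below floor, stopping", epoch, opt.lr)
            break
    return history


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::n_folds] for f in range(n_folds)]


def train_eval(make_model, ds: LabeledGraphDataset, tc: TrainConfig) -> dict:
    """K-fold cross-validation: returns per-fold test accuracies, mean, std.

    ``make_model`` is a zero-argument factory (a fresh model per fold).
    Within each training split, ``val_fraction`` of the graphs drive the
    plateau schedule.
    """
    if len(ds) < tc.n_folds or ds.n_classes < 2:
        raise ValueError("dataset too small or degenerate for cross-validation")
    rng = np.random.default_rng(tc.seed)
    folds = _fold_indices(len(ds), tc.n_folds, rng)
    accs = []
    for f, test_idx in enumerate(folds):
        train_all = np.setdiff1d(np.arange(len(ds)), test_idx)
        rng.shuffle(train_all)
        n_val = max(1, int(round(tc.val_fraction * len(train_all))))
        val_idx, train_idx = train_all[:n_val], train_all[n_val:]
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError("empty fold")
        model = make_model()
        train_model(model, ds, train_idx, val_idx, tc)
        acc = _accuracy(model, ds, test_idx)
        logger.info("fold %d/%d: test accuracy %.4f", f + 1, tc.n_folds, acc)
        accs.append(acc)
    accs = np.array(accs)
    return {"fold_accuracies": accs.tolist(),
            "mean": float(accs.mean()), "std": float(accs.std())}
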