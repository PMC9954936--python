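"""The differentiable topological layer.

The layer transforms node features ``X ∈ R^{N×d}`` of a graph batch in four
stages:

1. **Filtration** — a GIN-ε graph convolution, a concatenation skip and a
   two-layer MLP ending in a logistic sigmoid produce ``df`` learned filter
   functions per node, valued in (0, 1).
2. **Extended persistence** — each filter column is run through the exact
   reduction of :mod:`treph.eph`, one graph at a time, yielding ``4·df``
   diagrams together with the pairing and the locating map.
3. **Vectorization** — every diagram point is mapped to a ``dv``-vector by
   learnable *rational hat* coordinate functions

       ``s(p) = 1/(1 + ||p-c||_1) - 1/(1 + | |r| - ||p-c||_1 |)``

   with one set of ``dv`` functions per diagram class, shared across the
   ``df`` filtrations.
4. **Aggregation** — each point's vector is added to the nodes marking its
   birth and its death (via the locating map), the per-filtration node
   accumulators are concatenated, batch-normalized and passed through ReLU;
   a residual concatenation with the input and a fully connected layer give
   the output ``X' ∈ R^{N×d_out}``.

Because a diagram point's coordinates are the filter values at its locating
vertices, and the pairing is locally constant wherever the filters are
injective, the whole composition is differentiable there; gradients flow
from the output back into both the filtration and vectorization parameters.

Two ablation variants replace extended persistence by ordinary persistence
of ``f`` and ``-f``: ``noext`` vectorizes essential (infinite) points by
one-dimensional coordinate functions and drops their death location;
``noext_trunc`` truncates infinite deaths to the global filter extremum and
aggregates every point to its birth location only.  Both variants lose the
min-max pairing that only extended persistence carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_rows, scatter_add_rows, parameters_of
from .eph import CLASSES, Simplex, extended_persistence
from .graph import VertexFunctionGraph

__all__ = [
    "GraphBatch",
    "Linear",
    "MLP",
    "BatchNorm",
    "TrephConfig",
    "FiltrationModule",
    "VectorizationParams",
    "rational_hat",
    "vectorize",
    "TrephLayer",
    "gradcheck",
]


# ---------------------------------------------------------------------------
# Graph batching (disjoint union)
# ---------------------------------------------------------------------------

class GraphBatch:
    """A disjoint union of graphs with global node indexing.

    Message passing runs on the union; persistence is always computed per
    member graph, never across graphs.
    """

    def __init__(self, graphs: list[VertexFunctionGraph]):
        self.graphs = list(graphs)
        self.offsets = np.cumsum([0] + [g.n_vertices for g in self.graphs])
        self.n_nodes = int(self.offsets[-1])
        src, dst = [], []
        for g, off in zip(self.graphs, self.offsets):
            for (u, v) in g.edges:
                src += [u + off, v + off]
                dst += [v + off, u + off]
        self.edge_src = np.asarray(src, dtype=np.int64)
        self.edge_dst = np.asarray(dst, dtype=np.int64)
        self.node_graph = np.concatenate(
            [np.full(g.n_vertices, i, dtype=np.int64)
             for i, g in enumerate(self.graphs)]) if self.graphs else np.zeros(0, np.int64)

    @property
    def n_graphs(self) -> int:
        return len(self.graphs)

    def neighbor_sum(self, x: Tensor) -> Tensor:
        if len(self.edge_src) == 0:
            return Tensor(np.zeros_like(x.data))
        return scatter_add_rows(gather_rows(x, self.edge_src), self.edge_dst,
                                self.n_nodes)

    def mean_pool(self, x: Tensor) -> Tensor:
        counts = np.array([g.n_vertices for g in self.graphs], dtype=np.float64)
        summed = scatter_add_rows(x, self.node_graph, self.n_graphs)
        return summed * Tensor(1.0 / counts[:, None])


# ---------------------------------------------------------------------------
# Elementary trainable modules
# ---------------------------------------------------------------------------

class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        a = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-a, a, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP:
    """Fully connected stack with ReLU between layers (not after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.layers):
            x = lin(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class BatchNorm:
    """Batch normalization over the node axis with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) \
                / Tensor(np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TrephConfig:
    """Shape and wiring of the topological layer.

    ``d`` is the input feature dimension, ``df`` the number of learned filter
    functions, ``dv`` the vectorization dimension, ``d_out`` the output
    dimension (defaults to ``d`` so layers stack).  ``aggregation`` chooses
    whether per-filtration node accumulators are concatenated (default,
    output ``df·dv`` per node pre-FC) or summed (``dv``); ``residual``
    chooses concatenation of the input before the final FC (default) or a
    projected additive skip.
    """

    d: int = 64
    df: int = 8
    dv: int = 32
    d_out: int | None = None
    hidden: int | None = None
    aggregation: str = "concat"   # concat | sum
    residual: str = "concat"      # concat | add

    def __post_init__(self) -> None:
        if min(self.d, self.df, self.dv) < 1:
            raise ValueError("d, df, dv must all be >= 1")
        if self.d_out is None:
            self.d_out = self.d
        if self.hidden is None:
            self.hidden = self.d
        if self.aggregation not in ("concat", "sum"):
            raise ValueError("aggregation must be 'concat' or 'sum'")
        if self.residual not in ("concat", "add"):
            raise ValueError("residual must be 'concat' or 'add'")

    @property
    def agg_dim(self) -> int:
        return self.df * self.dv if self.aggregation == "concat" else self.dv


# ---------------------------------------------------------------------------
# Filtration module
# ---------------------------------------------------------------------------

class FiltrationModule:
    """GIN-ε convolution + concatenation skip + two-layer MLP + sigmoid.

    The GIN update is ``h_v = MLP_gin((1+ε)·x_v + Σ_{u∈N(v)} x_u)`` with a
    learnable ε initialized at 0; the head maps ``[x ‖ h]`` to ``df`` filter
    values per node, squashed into (0, 1) by the sigmoid.
    """

    def __init__(self, cfg: TrephConfig, rng: np.random.Generator):
        h = cfg.hidden
        self.epsilon = Tensor(np.zeros(()), requires_grad=True)
        self.gin_mlp = MLP([cfg.d, h, h], rng)
        self.head = MLP([cfg.d + h, h, cfg.df], rng)

    def __call__(self, batch: GraphBatch, x: Tensor) -> Tensor:
        agg = x * (1.0 + self.epsilon) + batch.neighbor_sum(x)
        hidden = self.gin_mlp(agg)
        return self.head(concat([x, hidden], axis=1)).sigmoid()


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

#: families of essential (one-coordinate) points used by the noext variant:
#: dim-0 / dim-1 essential features of f and of -f.
ONED_FAMILIES = ("f0_inf", "f1_inf", "nf0_inf", "nf1_inf")


def rational_hat(p, c, r) -> np.ndarray:
    """The rational hat coordinate function at point(s) ``p``.

    ``p`` and ``c`` may be planar points or scalars; the distance is the L1
    norm of their difference.  Peaks at ``p = c`` with value ``1 - 1/(1+|r|)``
    and decays with an inverted bump at distance ``|r|`` from ``c``.
    """
    p = np.asarray(p, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    diff = np.abs(p - c)
    dist = diff.sum(axis=-1) if (c.ndim >= 1 and c.shape[-1] == 2) else diff
    return 1.0 / (1.0 + dist) - 1.0 / (1.0 + np.abs(np.abs(r) - dist))


def _hat_t(dist: Tensor, r: Tensor) -> Tensor:
    return 1.0 / (1.0 + dist) - 1.0 / (1.0 + (r.abs() - dist).abs())


class VectorizationParams:
    """Learnable coordinate functions: ``dv`` planar rational hats per
    diagram class, plus ``dv`` one-dimensional hats per essential-point
    family (the latter only touched by the noext variant)."""

    def __init__(self, dv: int, rng: np.random.Generator):
        self.dv = dv
        self.planar = {c: (Tensor(rng.uniform(0, 1, size=(dv, 2)), requires_grad=True),
                           Tensor(rng.uniform(0.1, 1.0, size=dv), requires_grad=True))
                       for c in CLASSES}
        self.oned = {fam: (Tensor(rng.uniform(-1, 1, size=dv), requires_grad=True),
                           Tensor(rng.uniform(0.1, 1.0, size=dv), requires_grad=True))
                     for fam in ONED_FAMILIES}

    def __repr__(self) -> str:
        return f"VectorizationParams(dv={self.dv})"


def _eval_planar(vp: VectorizationParams, cls: str,
                 births: Tensor, deaths: Tensor) -> Tensor:
    c, r = vp.planar[cls]
    cb = c @ Tensor(np.array([[1.0], [0.0]]))   # (dv,1) birth centers
    cd = c @ Tensor(np.array([[0.0], [1.0]]))   # (dv,1) death centers
    dist = (births - cb.T).abs() + (deaths - cd.T).abs()   # (k, dv)
    return _hat_t(dist, r)


def _eval_oned(vp: VectorizationParams, fam: str, coords: Tensor) -> Tensor:
    c, r = vp.oned[fam]
    dist = (coords - c.reshape(1, -1)).abs()   # (k, dv)
    return _hat_t(dist, r)


def vectorize(diagrams, vp: VectorizationParams) -> dict[str, np.ndarray]:
    """Evaluate each class's coordinate functions on its diagram points.

    Convenience (non-differentiating) entry point: ``diagrams`` is an
    :class:`~treph.eph.ExtendedDiagrams`; returns per class a ``(k, dv)``
    array, one row per point instance (duplicates kept separately).
    """
    out = {}
    for cls in CLASSES:
        pts = np.asarray(diagrams[cls], dtype=np.float64).reshape(-1, 2)
        c, r = vp.planar[cls]
        if len(pts) == 0:
            out[cls] = np.zeros((0, vp.dv))
            continue
        dist = np.abs(pts[:, None, :] - c.data[None, :, :]).sum(axis=-1)
        out[cls] = 1.0 / (1.0 + dist) - 1.0 / (1.0 + np.abs(np.abs(r.data) - dist))
    return out


# ---------------------------------------------------------------------------
# The layer
# ---------------------------------------------------------------------------

@dataclass
class _Events:
    """Index bookkeeping for one (filtration, family) vectorization batch.

    Coordinates are looked up as ``sign * filter[vertex]`` so that the tape
    differentiates through them; locations are global node indices."""

    b_vertex: list[int] = field(default_factory=list)
    b_sign: list[float] = field(default_factory=list)
    d_vertex: list[int] = field(default_factory=list)
    d_sign: list[float] = field(default_factory=list)
    loc_birth: list[int] = field(default_factory=list)
    loc_death: list[int] = field(default_factory=list)   # -1: drop death location


class TrephLayer:
    """Plug-in node-representation transform ``(graph, N×d) -> (N×d_out)``.

    ``variant`` selects the full extended-persistence layer (``"eph"``) or
    the ordinary-persistence ablations (``"noext"``, ``"noext_trunc"``).
    All variants share the same parameter object, so ablations can be
    compared under identical weights.
    """

    def __init__(self, cfg: TrephConfig, rng: np.random.Generator | int = 0,
                 variant: str = "eph"):
        if variant not in ("eph", "noext", "noext_trunc"):
            raise ValueError(f"unknown variant {variant!r}")
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        self.cfg = cfg
        self.variant = variant
        self.filtration = FiltrationModule(cfg, rng)
        self.vparams = VectorizationParams(cfg.dv, rng)
        self.bn = BatchNorm(cfg.agg_dim)
        self.fc = Linear(cfg.d + cfg.agg_dim if cfg.residual == "concat"
                         else cfg.d, cfg.d_out, rng)
        if cfg.residual == "add":
            self.proj = Linear(cfg.agg_dim, cfg.d, rng)

    # -- event extraction (constant w.r.t. the tape) -----------------------
    def _collect_events(self, batch: GraphBatch, fvals: np.ndarray
                        ) -> dict[str, _Events]:
        """Run persistence per graph on one filter column; emit vectorization
        events keyed by diagram class (planar) or essential family (1-D)."""
        ev: dict[str, _Events] = {key: _Events() for key in
                                  (*CLASSES, *ONED_FAMILIES)}

        def planar(key, bv, bs, dvx, ds, lb, ld):
            e = ev[key]
            e.b_vertex.append(bv); e.b_sign.append(bs)
            e.d_vertex.append(dvx); e.d_sign.append(ds)
            e.loc_birth.append(lb); e.loc_death.append(ld)

        for g, off in zip(batch.graphs, batch.offsets):
            off = int(off)
            col = fvals[off:off + g.n_vertices]
            _, pairing, locate = extended_persistence(g, col)
            if self.variant == "noext_trunc":
                vmax = off + int(np.argmax(col))
                vmin = off + int(np.argmin(col))
            for (b, d), cls in zip(pairing.pairs, pairing.classes):
                lb, ld = off + locate[b], off + locate[d]
                if self.variant == "eph":
                    planar(cls, lb, 1.0, ld, 1.0, lb, ld)
                elif self.variant == "noext":
                    # ordinary persistence of f and -f, essential points 1-D
                    if cls in ("ord0", "rel1"):
                        planar(cls, lb, 1.0, ld, 1.0, lb, ld)
                    elif cls == "ext0":
                        e = ev["f0_inf"]
                        e.b_vertex.append(lb); e.b_sign.append(1.0)
                        e.loc_birth.append(lb)
                        e = ev["nf0_inf"]
                        e.b_vertex.append(ld); e.b_sign.append(-1.0)
                        e.loc_birth.append(ld)
                    else:  # ext1
                        e = ev["f1_inf"]
                        e.b_vertex.append(lb); e.b_sign.append(1.0)
                        e.loc_birth.append(lb)
                        e = ev["nf1_inf"]
                        e.b_vertex.append(ld); e.b_sign.append(-1.0)
                        e.loc_birth.append(ld)
                else:  # noext_trunc: all points finite, birth location only
                    if cls == "ord0":
                        planar(cls, lb, 1.0, ld, 1.0, lb, -1)
                    elif cls == "rel1":
                        # -f coordinates: (b,d) of Rel1 -> (-b,-d)
                        planar(cls, lb, -1.0, ld, -1.0, lb, -1)
                    elif cls == "ext0":
                        planar("ord0", lb, 1.0, vmax, 1.0, lb, -1)   # (min, max f)
                        planar("rel1", ld, -1.0, vmin, -1.0, ld, -1)  # (-max, max -f)
                    else:  # ext1
                        planar("ext1", lb, 1.0, vmax, 1.0, lb, -1)
                        planar("ext0", ld, -1.0, vmin, -1.0, ld, -1)
        return ev

    def _aggregate_column(self, batch: GraphBatch, col: Tensor,
                          events: dict[str, _Events]) -> Tensor:
        n, dv = batch.n_nodes, self.cfg.dv
        acc = Tensor(np.zeros((n, dv)))
        for key, e in events.items():
            if not e.loc_birth:
                continue
            b = gather_rows(col, np.asarray(e.b_vertex)) \
                * Tensor(np.asarray(e.b_sign)[:, None])
            if key in ONED_FAMILIES:
                vec = _eval_oned(self.vparams, key, b)
            else:
                d = gather_rows(col, np.asarray(e.d_vertex)) \
                    * Tensor(np.asarray(e.d_sign)[:, None])
                vec = _eval_planar(self.vparams, key, b, d)
            acc = acc + scatter_add_rows(vec, np.asarray(e.loc_birth), n)
            live = [i for i, ld in enumerate(e.loc_death) if ld >= 0] \
                if e.loc_death else []
            if live:
                sub = gather_rows(vec, np.asarray(live))
                acc = acc + scatter_add_rows(
                    sub, np.asarray([e.loc_death[i] for i in live]), n)
        return acc

    def forward(self, batch: GraphBatch, x: Tensor, training: bool = False,
                filters=None) -> Tensor:
        """Transform node features; ``filters`` (n × df) bypasses the learned
        filtration with fixed filter functions (no gradient through them)."""
        if x.data.shape != (batch.n_nodes, self.cfg.d):
            raise ValueError(
                f"expected features {(batch.n_nodes, self.cfg.d)}, got {x.data.shape}")
        if filters is None:
            filt = self.filtration(batch, x)       # (n, df), values in (0,1)
        else:
            filt = filters if isinstance(filters, Tensor) else Tensor(filters)
            if filt.data.shape != (batch.n_nodes, self.cfg.df):
                raise ValueError("filters must be n_nodes x df")
        per_k = []
        for k in range(self.cfg.df):
            sel = np.zeros((self.cfg.df, 1)); sel[k, 0] = 1.0
            col = filt @ Tensor(sel)               # (n, 1)
            events = self._collect_events(batch, col.data[:, 0])
            per_k.append(self._aggregate_column(batch, col, events))
        if self.cfg.aggregation == "concat":
            agg = concat(per_k, axis=1)
        else:
            agg = per_k[0]
            for t in per_k[1:]:
                agg = agg + t
        h = self.bn(agg, training).relu()
        if self.cfg.residual == "concat":
            return self.fc(concat([x, h], axis=1))
        return self.fc(x + self.proj(h))

    __call__ = forward

    def parameters(self) -> list[Tensor]:
        return parameters_of(self)


# ---------------------------------------------------------------------------
# Gradient checking
# ---------------------------------------------------------------------------

def gradcheck(loss_fn, params: list[Tensor], h: float = 1e-6) -> float:
    """Max relative error between tape gradients and central differences.

    ``loss_fn`` must rebuild the forward pass from the current parameter
    values and return a scalar Tensor.  The relative error per coordinate is
    ``|g_ad - g_fd| / max(1, |g_fd|)``.
    """
    for p in params:
        p.zero_grad()
    loss = loss_fn()
    loss.backward()
    analytic = [np.zeros_like(p.data) if p.grad is None else p.grad.copy()
                for p in params]
    worst = 0.0
    for p, ga in zip(params, analytic):
        flat = p.data.ravel()
        gfd = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            lp = loss_fn().data.item()
            flat[i] = orig - h
            lm = loss_fn().data.item()
            flat[i] = orig
            gfd[i] = (lp - lm) / (2 * h)
        err = np.abs(ga.ravel() - gfd) / np.maximum(1.0, np.abs(gfd))
        worst = max(worst, float(err.max(initial=0.0)))
    return worst
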