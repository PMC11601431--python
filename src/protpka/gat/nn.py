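"""A small graph-attention network in pure numpy with manual backprop.

Architecture: ``conv_layers`` single-head graph-attention convolutions of
width ``channels`` (LeakyReLU(0.2) attention logits, per-target softmax
over incoming edges incl. a self loop, ELU node update), global average
pooling, then a ReLU MLP head with inverted dropout and a linear output.
All operations are segment-reductions over flat edge arrays, so a batch of
graphs is processed as one disjoint union.  Gradients are derived by hand
and verified against finite differences in the test suite; with a fixed
seed the whole pipeline is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

LEAKY_SLOPE = 0.2


# ---------------------------------------------------------------------------
# batch assembly

def assemble_batch(graphs) -> dict:
    """Disjoint union of graphs: node matrix, directed edges + self loops,
    graph index per node."""
    feats = []
    src_all = []
    dst_all = []
    gid = []
    offset = 0
    for g_index, g in enumerate(graphs):
        n = g.node_features.shape[0]
        feats.append(np.asarray(g.node_features, dtype=np.float64))
        e = g.edges
        if e.size:
            u = e[:, 0] + offset
            v = e[:, 1] + offset
            src = np.concatenate([u, v, np.arange(offset, offset + n)])
            dst = np.concatenate([v, u, np.arange(offset, offset + n)])
        else:
            src = dst = np.arange(offset, offset + n)
        src_all.append(src)
        dst_all.append(dst)
        gid.append(np.full(n, g_index))
        offset += n
    X = np.concatenate(feats, axis=0)
    src = np.concatenate(src_all)
    dst = np.concatenate(dst_all)
    gid = np.concatenate(gid)
    n_nodes = X.shape[0]
    n_edges = src.size
    ones = np.ones(n_edges)
    eidx = np.arange(n_edges)
    # scatter matrices make the segment sums fast dense-sparse products
    dmat = sparse.csr_matrix((ones, (dst, eidx)), shape=(n_nodes, n_edges))
    smat = sparse.csr_matrix((ones, (src, eidx)), shape=(n_nodes, n_edges))
    counts = np.bincount(gid, minlength=len(graphs)).astype(float)
    pmat = sparse.csr_matrix((1.0 / counts[gid], (gid, np.arange(n_nodes))),
                             shape=(len(graphs), n_nodes))
    return {
        "X": X, "src": src, "dst": dst, "gid": gid,
        "n_graphs": len(graphs), "dmat": dmat, "smat": smat, "pmat": pmat,
    }


# ---------------------------------------------------------------------------
# parameters

def init_params(node_dim: int, channels: int = 42, conv_layers: int = 3,
                hidden: tuple[int, ...] = (32, 16),
                rng: np.random.Generator | None = None) -> dict:
    rng = rng or np.random.default_rng(0)

    def glorot(shape):
        limit = np.sqrt(6.0 / sum(shape))
        return rng.uniform(-limit, limit, size=shape)

    params: dict[str, np.ndarray] = {}
    f_in = node_dim
    for layer in range(conv_layers):
        params[f"conv{layer}_W"] = glorot((f_in, channels))
        params[f"conv{layer}_asrc"] = glorot((channels,))
        params[f"conv{layer}_adst"] = glorot((channels,))
        params[f"conv{layer}_b"] = np.zeros(channels)
        f_in = channels
    widths = (channels,) + tuple(hidden) + (1,)
    for k in range(len(widths) - 1):
        params[f"mlp{k}_W"] = glorot((widths[k], widths[k + 1]))
        params[f"mlp{k}_b"] = np.zeros(widths[k + 1])
    return params


def conv_layer_names(layer: int) -> tuple[str, ...]:
    return (f"conv{layer}_W", f"conv{layer}_asrc", f"conv{layer}_adst",
            f"conv{layer}_b")


def count_conv_layers(params: dict) -> int:
    return sum(1 for k in params if k.endswith("_W") and k.startswith("conv"))


def count_mlp_layers(params: dict) -> int:
    return sum(1 for k in params if k.endswith("_W") and k.startswith("mlp"))


# ---------------------------------------------------------------------------
# forward / backward

def _segment_softmax(e, dst, n_nodes):
    mx = np.full(n_nodes, -np.inf)
    np.maximum.at(mx, dst, e)
    ex = np.exp(e - mx[dst])
    den = np.bincount(dst, weights=ex, minlength=n_nodes)
    return ex / den[dst]


def forward(params: dict, batch: dict, dropout: float = 0.0,
            rng: np.random.Generator | None = None,
            training: bool = False) -> tuple[np.ndarray, dict]:
    """Predicted per-graph scalar and a cache for backward()."""
    X, src, dst, gid = batch["X"], batch["src"], batch["dst"], batch["gid"]
    n_nodes = X.shape[0]
    n_graphs = batch["n_graphs"]
    H = X
    layers = []
    for layer in range(count_conv_layers(params)):
        W = params[f"conv{layer}_W"]
        asrc = params[f"conv{layer}_asrc"]
        adst = params[f"conv{layer}_adst"]
        b = params[f"conv{layer}_b"]
        Z = H @ W
        s = Z @ asrc
        t = Z @ adst
        raw = s[src] + t[dst]
        e = np.where(raw > 0, raw, LEAKY_SLOPE * raw)
        alpha = _segment_softmax(e, dst, n_nodes)
        agg = batch["dmat"] @ (alpha[:, None] * Z[src])
        pre = agg + b
        H_next = np.where(pre > 0, pre, np.expm1(np.minimum(pre, 0.0)))
        layers.append({"H_in": H, "Z": Z, "raw": raw, "alpha": alpha,
                       "pre": pre})
        H = H_next
    G = batch["pmat"] @ H
    # MLP head
    mlp_cache = []
    A = G
    n_mlp = count_mlp_layers(params)
    for k in range(n_mlp):
        W = params[f"mlp{k}_W"]
        b = params[f"mlp{k}_b"]
        pre = A @ W + b
        last = k == n_mlp - 1
        if last:
            out = pre
            mask = None
        else:
            out = np.maximum(pre, 0.0)
            if training and dropout > 0:
                keep = (rng.random(out.shape) >= dropout) / (1.0 - dropout)
                out = out * keep
                mask = keep
            else:
                mask = None
        mlp_cache.append({"A_in": A, "pre": pre, "mask": mask})
        A = out
    pred = A[:, 0]
    cache = {"batch": batch, "layers": layers, "pooled_H": H, "G": G,
             "mlp": mlp_cache}
    return pred, cache


def backward(params: dict, cache: dict, dpred: np.ndarray) -> dict:
    batch = cache["batch"]
    src, dst, gid = batch["src"], batch["dst"], batch["gid"]
    n_nodes = batch["X"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dA = dpred[:, None]
    n_mlp = count_mlp_layers(params)
    for k in range(n_mlp - 1, -1, -1):
        c = cache["mlp"][k]
        if k != n_mlp - 1:
            if c["mask"] is not None:
                dA = dA * c["mask"]
            dA = dA * (c["pre"] > 0)
        grads[f"mlp{k}_W"] += c["A_in"].T @ dA
        grads[f"mlp{k}_b"] += dA.sum(axis=0)
        dA = dA @ params[f"mlp{k}_W"].T
    dG = dA
    dH = batch["pmat"].T @ dG

    for layer in range(count_conv_layers(params) - 1, -1, -1):
        c = cache["layers"][layer]
        W = params[f"conv{layer}_W"]
        asrc = params[f"conv{layer}_asrc"]
        adst = params[f"conv{layer}_adst"]
        Z, alpha, raw, pre = c["Z"], c["alpha"], c["raw"], c["pre"]
        dpre = dH * np.where(pre > 0, 1.0, np.exp(np.minimum(pre, 0.0)))
        grads[f"conv{layer}_b"] += dpre.sum(axis=0)
        # message aggregation
        dalpha = np.einsum("ij,ij->i", dpre[dst], Z[src])
        dZ = batch["smat"] @ (alpha[:, None] * dpre[dst])
        # softmax (per dst group)
        S = np.bincount(dst, weights=alpha * dalpha, minlength=n_nodes)
        de = alpha * (dalpha - S[dst])
        draw = de * np.where(raw > 0, 1.0, LEAKY_SLOPE)
        ds = np.bincount(src, weights=draw, minlength=n_nodes)
        dt = np.bincount(dst, weights=draw, minlength=n_nodes)
        grads[f"conv{layer}_asrc"] += Z.T @ ds
        grads[f"conv{layer}_adst"] += Z.T @ dt
        dZ += ds[:, None] * asrc[None, :] + dt[:, None] * adst[None, :]
        grads[f"conv{layer}_W"] += c["H_in"].T @ dZ
        dH = dZ @ W.T
    return grads


def mse_loss_grad(pred: np.ndarray, y: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    err = pred - y
    return float(np.mean(err ** 2)), 2.0 * err / err.size


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Standard Adam; parameters named in ``frozen`` are never updated."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 frozen: frozenset[str] = frozenset()):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.frozen = frozenset(frozen)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            if k in self.frozen:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
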