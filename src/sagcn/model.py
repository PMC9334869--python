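"""Self-attention graph-convolutional classifier (SA-GCN) over functional graphs.

Architecture, per branch (one branch per graph view):

    repeat `blocks` times:  H <- ReLU(D^{-1/2} (A+I) D^{-1/2} X W)      (graph conv)
                            (A, H, idx) <- SAGPool(A, H; k, theta)      (attention pool)
                            r_l <- [mean(H) || max(H)]                  (readout)
    branch embedding = sum_l r_l

The self-attention pooling scores every node with a one-channel graph
convolution z = D^{-1/2}(A+I)D^{-1/2} H theta, gates kept features by tanh(z),
and retains the ceil(k*N) highest-scoring nodes (ties broken toward the lower
node index). Branch embeddings are concatenated ("feature-level fusion") and
fed to a one-hidden-layer softmax head. Everything — including backprop and the
Adam optimiser — is implemented here in numpy: the graphs are small (tens to a
hundred ROIs) and CPU training takes seconds, so no deep-learning framework is
required.

Gradients flow through the gate and through the attention scores; the top-k
selection itself is piecewise constant and contributes no gradient, exactly as
in automatic differentiation of the same network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .graphs import Adjacency, GraphSample

logger = logging.getLogger("sagcn")


# ---------------------------------------------------------------------------
# single-graph building blocks (the algebra, unit-testable in isolation)
# ---------------------------------------------------------------------------

def normalize_adjacency(a) -> np.ndarray:
    """Symmetric normalisation D^{-1/2} (A + I) D^{-1/2} of a nonnegative adjacency."""
    vals = a.values if isinstance(a, Adjacency) else np.asarray(a, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("adjacency must be square")
    if (vals < 0).any():
        raise ValueError("adjacency entries must be nonnegative")
    ahat = vals + np.eye(vals.shape[0])
    dinv = 1.0 / np.sqrt(ahat.sum(axis=1))
    return ahat * dinv[:, None] * dinv[None, :]


def gcn_layer(a_norm: np.ndarray, x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One graph-convolution layer: ReLU(A_norm X W)."""
    if a_norm.shape[1] != x.shape[0] or x.shape[1] != w.shape[0]:
        raise ValueError(
            f"shape chain broken: A_norm {a_norm.shape} X {x.shape} W {w.shape}"
        )
    return np.maximum(a_norm @ x @ w, 0.0)


def sag_pool(a, x: np.ndarray, k: float, theta: np.ndarray):
    """Self-attention pooling: keep the ceil(k*N) nodes with highest tanh score.

    Scores are a one-channel graph convolution of ``x`` over the normalised
    adjacency. Returns (pooled adjacency, gated pooled features, kept indices
    in original node coordinates, ascending).
    """
    if not (0.0 < k <= 1.0):
        raise ValueError(f"pooling ratio must lie in (0, 1], got {k}")
    vals = a.values if isinstance(a, Adjacency) else np.asarray(a, dtype=float)
    an = normalize_adjacency(vals)
    z = an @ x @ np.asarray(theta, dtype=float).reshape(-1)
    g = np.tanh(z)
    n = vals.shape[0]
    n_keep = math.ceil(k * n)
    order = np.argsort(-g, kind="stable")[:n_keep]  # stable => lower index wins ties
    idx = np.sort(order)
    x_pooled = x[idx] * g[idx, None]
    a_pooled = vals[np.ix_(idx, idx)]
    return a_pooled, x_pooled, idx


def readout(x: np.ndarray) -> np.ndarray:
    """Graph-level embedding: column-wise mean concatenated with column-wise max."""
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("readout needs at least one node")
    return np.concatenate([x.mean(axis=0), x.max(axis=0)])


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters of the two-branch SA-GCN.

    ``view`` selects the branches: "lo", "ho" or "fused" (both, concatenated).
    ``pool=False`` removes the attention pooling entirely (plain-GCN ablation).
    """

    blocks: int = 2
    hidden_dim: int = 32
    pool_ratio: float = 0.5
    pool: bool = True
    dropout: float = 0.5
    learning_rate: float = 1e-3
    weight_decay: float = 5e-3
    epochs: int = 100
    batch_size: int = 16
    view: str = "fused"
    standardize_lo: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blocks < 1:
            raise ValueError("blocks must be >= 1")
        if not (0.0 < self.pool_ratio <= 1.0):
            raise ValueError("pool_ratio must lie in (0, 1]")
        if self.view not in {"lo", "ho", "fused"}:
            raise ValueError(f"unknown view {self.view!r}")

    @property
    def branches(self) -> tuple[str, ...]:
        return ("lo", "ho") if self.view == "fused" else (self.view,)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def init_weights(config: ModelConfig, input_dims: dict[str, int],
                 rng: np.random.Generator) -> dict:
    """Glorot-uniform initialisation of all trainable matrices."""
    params: dict = {"branches": {}, "head": {}}
    h = config.hidden_dim
    for br in config.branches:
        d_in = input_dims[br]
        stages = []
        for l in range(config.blocks):
            w = _glorot(rng, d_in if l == 0 else h, h)
            theta = _glorot(rng, h, 1).ravel()
            stages.append({"W": w, "theta": theta})
        params["branches"][br] = stages
    emb_dim = 2 * h * len(config.branches)
    params["head"] = {
        "W1": _glorot(rng, emb_dim, h), "b1": np.zeros(h),
        "W2": _glorot(rng, h, 2), "b2": np.zeros(2),
    }
    return params


def _iter_params(params):
    for br, stages in params["branches"].items():
        for l, st in enumerate(stages):
            yield f"{br}/W{l}", st, "W"
            yield f"{br}/theta{l}", st, "theta"
    for key in ("W1", "b1", "W2", "b2"):
        yield f"head/{key}", params["head"], key


# ---------------------------------------------------------------------------
# batched forward / backward kernels
# ---------------------------------------------------------------------------

def _batch_normalize(a: np.ndarray) -> np.ndarray:
    ahat = a + np.eye(a.shape[-1])[None]
    dinv = 1.0 / np.sqrt(ahat.sum(axis=-1))
    return ahat * dinv[:, :, None] * dinv[:, None, :]


def _branch_forward(a0: np.ndarray, x0: np.ndarray, stages: list[dict],
                    config: ModelConfig, trace: list | None = None):
    """Forward pass of one branch over a batch of same-size graphs.

    Returns (embedding (B, 2h), caches) where caches hold every intermediate
    needed for the hand-written backward pass.
    """
    b, n0, _ = a0.shape
    a, x = a0, x0
    orig = np.broadcast_to(np.arange(n0), (b, n0)).copy()
    emb = np.zeros((b, 2 * config.hidden_dim))
    caches = []
    bi = np.arange(b)[:, None]
    for st in stages:
        an = _batch_normalize(a)
        p = an @ x                      # (B, N, d_in)
        m = p @ st["W"]                 # (B, N, h)
        hmat = np.maximum(m, 0.0)
        cache = {"an": an, "p": p, "m": m}
        if config.pool:
            q = an @ hmat               # (B, N, h)
            z = q @ st["theta"]         # (B, N)
            g = np.tanh(z)
            n = a.shape[-1]
            n_keep = math.ceil(config.pool_ratio * n)
            order = np.argsort(-g, axis=1, kind="stable")[:, :n_keep]
            idx = np.sort(order, axis=1)
            g_k = np.take_along_axis(g, idx, axis=1)
            h_k = np.take_along_axis(hmat, idx[:, :, None], axis=1)
            # stage output is ReLU(SAGPool(GCN(...))): negatively-gated survivors
            # are zeroed, so only positively-attended nodes propagate
            xp_raw = h_k * g_k[:, :, None]
            xp = np.maximum(xp_raw, 0.0)
            a_rows = np.take_along_axis(a, idx[:, :, None], axis=1)
            ap = np.take_along_axis(a_rows, idx[:, None, :], axis=2)
            orig = np.take_along_axis(orig, idx, axis=1)
            cache.update(q=q, g=g, idx=idx, g_k=g_k, h_k=h_k, xp_raw=xp_raw, xp=xp)
        else:
            xp, ap = hmat, a
            cache.update(xp=xp)
        amax = xp.argmax(axis=1)        # (B, h)
        cache.update(amax=amax, n_pooled=xp.shape[1], h=hmat)
        emb += np.concatenate([xp.mean(axis=1), xp[bi, amax, np.arange(xp.shape[-1])[None, :]]], axis=1)
        caches.append(cache)
        a, x = ap, xp
        if trace is not None:
            trace.append(orig.copy())
    return emb, caches


def _branch_backward(demb: np.ndarray, stages: list[dict], caches: list[dict],
                     config: ModelConfig, grads: dict, prefix: str) -> None:
    """Accumulate gradients of one branch into ``grads`` (keyed like _iter_params)."""
    h_dim = config.hidden_dim
    dx_next: np.ndarray | None = None
    for l in reversed(range(len(stages))):
        st, c = stages[l], caches[l]
        b = c["xp"].shape[0]
        bi = np.arange(b)[:, None]
        cols = np.arange(c["xp"].shape[-1])[None, :]
        dxp = np.zeros_like(c["xp"])
        if dx_next is not None:
            dxp += dx_next
        dmean, dmax = demb[:, :h_dim], demb[:, h_dim:]
        dxp += dmean[:, None, :] / c["n_pooled"]
        # max-readout routes gradient to the argmax row of each column
        np.add.at(dxp, (bi, c["amax"], cols), dmax)
        if config.pool:
            dxp = dxp * (c["xp_raw"] > 0)
            dh_k = dxp * c["g_k"][:, :, None]
            dg_k = (dxp * c["h_k"]).sum(axis=-1)
            dh = np.zeros_like(c["h"])
            dh[bi, c["idx"]] = dh_k          # kept indices are unique per graph
            dg = np.zeros(c["g"].shape)
            dg[bi, c["idx"]] = dg_k
            dz = dg * (1.0 - c["g"] ** 2)
            grads[f"{prefix}/theta{l}"] += np.einsum("bnh,bn->h", c["q"], dz)
            # z = (A_norm H) theta  =>  dH += A_norm^T (dz theta^T); A_norm symmetric
            dh += c["an"] @ (dz[:, :, None] * st["theta"][None, None, :])
        else:
            dh = dxp
        dm = dh * (c["m"] > 0)
        grads[f"{prefix}/W{l}"] += np.einsum("bnd,bnh->dh", c["p"], dm)
        dx_next = c["an"] @ dm @ st["W"].T
    # gradient w.r.t. the input node features is discarded (inputs are data)


def _head_forward(emb: np.ndarray, head: dict, dropout_mask: np.ndarray | None):
    e = emb * dropout_mask if dropout_mask is not None else emb
    h1p = e @ head["W1"] + head["b1"]
    h1 = np.maximum(h1p, 0.0)
    logits = h1 @ head["W2"] + head["b2"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    probs = expd / expd.sum(axis=1, keepdims=True)
    return probs, (e, h1p, h1)


def fuse_and_classify(emb_lo: np.ndarray, emb_ho: np.ndarray | None, head: dict) -> np.ndarray:
    """Concatenate branch embeddings and apply the softmax head (single sample or batch)."""
    emb = emb_lo if emb_ho is None else np.concatenate(
        [np.atleast_2d(emb_lo), np.atleast_2d(emb_ho)], axis=1)
    emb = np.atleast_2d(emb)
    probs, _ = _head_forward(emb, head, None)
    return probs if probs.shape[0] > 1 else probs[0]


def forward_branch(graph: GraphSample, stages: list[dict], config: ModelConfig,
                   trace: list | None = None) -> np.ndarray:
    """Embed a single graph through one branch (convenience wrapper over the batch kernel)."""
    a = graph.adjacency.values[None]
    x = graph.node_features[None].astype(float)
    emb, _ = _branch_forward(a, x, stages, config, trace=trace)
    if trace is not None:
        for i, t in enumerate(trace):
            trace[i] = t[0]
    return emb[0]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    params: dict
    config: ModelConfig
    n_rois: int
    lo_stats: tuple[np.ndarray, np.ndarray] | None  # (mean, std) of Lo features
    loss_history: list[float] = field(default_factory=list)


def _stack(pairs: list[tuple[GraphSample, GraphSample]], config: ModelConfig,
           lo_stats=None):
    """Stack graph pairs into batch arrays per branch; z-score Lo features."""
    out = {}
    if "lo" in config.branches:
        a = np.stack([p[0].adjacency.values for p in pairs])
        x = np.stack([p[0].node_features for p in pairs]).astype(float)
        if config.standardize_lo:
            if lo_stats is None:
                flat = x.reshape(-1, x.shape[-1])
                mu, sd = flat.mean(axis=0), flat.std(axis=0)
                sd = np.where(sd == 0, 1.0, sd)
                lo_stats = (mu, sd)
            x = (x - lo_stats[0]) / lo_stats[1]
        out["lo"] = (a, x)
    if "ho" in config.branches:
        a = np.stack([p[1].adjacency.values for p in pairs])
        x = np.stack([p[1].node_features for p in pairs]).astype(float)
        out["ho"] = (a, x)
    labels = np.array([p[0].label for p in pairs], dtype=int)
    return out, labels, lo_stats


def _forward_all(batch: dict, params: dict, config: ModelConfig,
                 dropout_mask=None, trace: dict | None = None):
    embs, caches = [], {}
    for br in config.branches:
        tr = [] if trace is not None else None
        a, x = batch[br]
        emb, cache = _branch_forward(a, x, params["branches"][br], config, trace=tr)
        embs.append(emb)
        caches[br] = cache
        if trace is not None:
            trace[br] = tr
    fused = np.concatenate(embs, axis=1)
    probs, head_cache = _head_forward(fused, params["head"], dropout_mask)
    return probs, fused, caches, head_cache


def _loss_and_grads(batch: dict, y: np.ndarray, params: dict, config: ModelConfig,
                    dropout_mask: np.ndarray | None = None):
    """Mean cross-entropy over one minibatch and gradients for every parameter."""
    bsz = len(y)
    probs, fused, caches, (e_d, h1p, h1) = _forward_all(
        batch, params, config, dropout_mask=dropout_mask)
    loss = float(-np.log(probs[np.arange(bsz), y] + 1e-12).mean())
    grads = {name: np.zeros_like(holder[key])
             for name, holder, key in _iter_params(params)}
    dlogits = probs.copy()
    dlogits[np.arange(bsz), y] -= 1.0
    dlogits /= bsz
    head = params["head"]
    grads["head/W2"] += h1.T @ dlogits
    grads["head/b2"] += dlogits.sum(axis=0)
    dh1 = (dlogits @ head["W2"].T) * (h1p > 0)
    grads["head/W1"] += e_d.T @ dh1
    grads["head/b1"] += dh1.sum(axis=0)
    de = dh1 @ head["W1"].T
    if dropout_mask is not None:
        de = de * dropout_mask
    off = 0
    for br in config.branches:
        width = 2 * config.hidden_dim
        _branch_backward(de[:, off : off + width], params["branches"][br],
                         caches[br], config, grads, prefix=br)
        off += width
    return loss, grads, probs


def train_model(pairs: list[tuple[GraphSample, GraphSample]], config: ModelConfig,
                seed: int | None = None) -> TrainedModel:
    """Train the SA-GCN end-to-end with Adam on cross-entropy over window graphs.

    Deterministic given the seed: initialisation, shuffling and dropout masks
    all come from one ``numpy`` generator.
    """
    if not pairs:
        raise ValueError("empty training set")
    labels_all = {p[0].label for p in pairs}
    if labels_all != {0, 1}:
        raise ValueError(f"training set must contain both classes, got labels {sorted(labels_all)}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_rois = pairs[0][0].n_nodes
    input_dims = {"lo": pairs[0][0].node_features.shape[1], "ho": n_rois}
    params = init_weights(config, input_dims, rng)
    batch_all, y_all, lo_stats = _stack(pairs, config)
    n = len(pairs)
    emb_dim = params["head"]["W1"].shape[0]

    # Adam state
    state = {name: (np.zeros_like(holder[key]), np.zeros_like(holder[key]))
             for name, holder, key in _iter_params(params)}
    step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    loss_history: list[float] = []

    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = perm[start : start + config.batch_size]
            batch = {br: (batch_all[br][0][sel], batch_all[br][1][sel])
                     for br in config.branches}
            y = y_all[sel]
            bsz = len(sel)
            if config.dropout > 0:
                mask = (rng.random((bsz, emb_dim)) >= config.dropout) / (1.0 - config.dropout)
            else:
                mask = None
            loss, grads, _ = _loss_and_grads(batch, y, params, config, dropout_mask=mask)
            epoch_loss += loss * bsz

            # ---- Adam update with L2 weight decay ----
            step += 1
            for name, holder, key in _iter_params(params):
                g = grads[name] + config.weight_decay * holder[key]
                m1, m2 = state[name]
                m1 *= beta1; m1 += (1 - beta1) * g
                m2 *= beta2; m2 += (1 - beta2) * g * g
                mhat = m1 / (1 - beta1**step)
                vhat = m2 / (1 - beta2**step)
                holder[key] = holder[key] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        loss_history.append(epoch_loss / n)

    return TrainedModel(params, config, n_rois, lo_stats, loss_history)


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint weights (npz) plus config/stats sidecar (json)."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {name.replace("/", "__"): holder[key]
              for name, holder, key in _iter_params(model.params)}
    np.savez(path, **arrays)
    meta = {
        "config": model.config.__dict__,
        "n_rois": model.n_rois,
        "lo_stats": None if model.lo_stats is None else [s.tolist() for s in model.lo_stats],
        "loss_history": model.loss_history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> TrainedModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    input_dims = {"lo": 2, "ho": meta["n_rois"]}
    params = init_weights(config, input_dims, np.random.default_rng(0))
    for name, holder, key in _iter_params(params):
        holder[key] = arrays[name.replace("/", "__")]
    lo_stats = meta["lo_stats"]
    if lo_stats is not None:
        lo_stats = (np.array(lo_stats[0]), np.array(lo_stats[1]))
    return TrainedModel(params, config, meta["n_rois"], lo_stats, meta["loss_history"])


def predict_proba(model: TrainedModel, pairs: list[tuple[GraphSample, GraphSample]],
                  collect_trace: bool = False):
    """Class probabilities per window graph; optionally the pooling survivors.

    With ``collect_trace`` the return is (probs, trace) where
    ``trace[view][stage]`` is a (B, kept) array of surviving original ROI
    indices after that pooling stage.
    """
    batch, _, _ = _stack(pairs, model.config, lo_stats=model.lo_stats)
    trace: dict | None = {} if collect_trace else None
    probs, _, _, _ = _forward_all(batch, model.params, model.config, trace=trace)
    return (probs, trace) if collect_trace else probs
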