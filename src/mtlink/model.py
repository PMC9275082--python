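"""Graph-convolutional encoder with layer attention and a bilinear decoder.

The encoder stacks L graph-convolution layers on the symmetric-normalised
heterogeneous graph,

    H^(l+1) = SELU(D^{-1/2} G D^{-1/2} H^(l) W^(l)),

starting from the association-only embedding H^(0). A learned softmax
attention over the L layer embeddings produces the final representation
[H_I; H_G] = sum_l a_l H^(l), split into miRNA rows (H_I) and target rows
(H_G). The decoder scores every miRNA-target pair with a bilinear form,
A' = sigmoid(H_I W' H_G^T).

All gradients are hand-derived (dense matrix calculus) so the whole model
trains with plain numpy; `backward` returns gradients for every trainable
array and is validated against central finite differences in the test
suite.

Ablation variants are selected by ``ModelConfig.variant``:

* ``"full"`` — learned softmax attention over layers (the default);
* ``"AVE"``  — fixed uniform attention a_l = 1/L;
* ``"CON"``  — concatenate the L embeddings (decoder weight becomes Lk x Lk);
* ``"L1"``/``"L2"``/... — use only the given layer's embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .hetgraph import HeteroGraph, symmetric_degree_normalize

__all__ = [
    "ModelConfig",
    "ModelState",
    "EmbeddingStack",
    "selu",
    "sigmoid",
    "softmax",
    "gcn_layer",
    "encode",
    "attend",
    "decode",
    "forward",
    "backward",
    "predict_scores",
    "save_checkpoint",
    "load_checkpoint",
]

# SELU constants (self-normalising networks)
_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def selu(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - np.max(x))
    return z / z.sum()


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and regularisation hyperparameters.

    Defaults follow the published setting: 64-dimensional embeddings, three
    convolution layers, node and edge dropout both 0.6.
    """

    embed_dim: int = 64
    n_layers: int = 3
    node_dropout: float = 0.6
    edge_dropout: float = 0.6
    variant: str = "full"
    node_dropout_on: str = "embedding"  # or "graph": mask graph rows instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        for name in ("node_dropout", "edge_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        valid = {"full", "AVE", "CON"} | {f"L{i}" for i in range(1, self.n_layers + 1)}
        if self.variant not in valid:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {sorted(valid)}")
        if self.node_dropout_on not in ("embedding", "graph"):
            raise ValueError("node_dropout_on must be 'embedding' or 'graph'")

    @property
    def decoder_dim(self) -> int:
        return self.embed_dim * (self.n_layers if self.variant == "CON" else 1)

    def with_variant(self, variant: str) -> "ModelConfig":
        return replace(self, variant=variant)


@dataclass
class ModelState:
    """All trainable arrays: per-layer weights, attention logits, decoder."""

    W0: np.ndarray                 # (M+N) x k
    Ws: list[np.ndarray]           # (L-1) matrices, k x k
    att_logits: np.ndarray         # length L
    Wdec: np.ndarray               # k x k (Lk x Lk for CON)

    def params(self) -> dict[str, np.ndarray]:
        out = {"W0": self.W0, "att_logits": self.att_logits, "Wdec": self.Wdec}
        for i, W in enumerate(self.Ws):
            out[f"W{i + 1}"] = W
        return out

    def check_finite(self) -> None:
        for name, arr in self.params().items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in parameter {name}")


@dataclass
class EmbeddingStack:
    """Per-layer embeddings H^(1)..H^(L) and the attention-combined split."""

    layers: list[np.ndarray]
    H_I: np.ndarray
    H_G: np.ndarray
    attention: np.ndarray


def combination_weights(cfg: ModelConfig, att_logits: np.ndarray) -> np.ndarray | None:
    """Layer-mixing weights a_l for the configured variant; None for CON."""
    L = cfg.n_layers
    if cfg.variant == "full":
        return softmax(att_logits)
    if cfg.variant == "AVE":
        return np.full(L, 1.0 / L)
    if cfg.variant == "CON":
        return None
    idx = int(cfg.variant[1:]) - 1
    a = np.zeros(L)
    a[idx] = 1.0
    return a


def gcn_layer(H_prev: np.ndarray, G_norm: np.ndarray, W: np.ndarray,
              activation=selu) -> np.ndarray:
    """One propagation step: activation(G_norm @ H_prev @ W)."""
    H_prev = np.asarray(H_prev, dtype=float)
    G_norm = np.asarray(G_norm, dtype=float)
    if G_norm.shape[1] != H_prev.shape[0] or H_prev.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: G {G_norm.shape}, H {H_prev.shape}, W {W.shape}"
        )
    Z = G_norm @ (H_prev @ W)
    return activation(Z) if activation is not None else Z


@dataclass
class ForwardCache:
    """Intermediate arrays kept for the backward pass."""

    G_eff: np.ndarray
    H0: np.ndarray
    Z: list[np.ndarray]
    H: list[np.ndarray]            # post-activation, post-node-dropout
    node_masks: list[np.ndarray | None]
    a: np.ndarray | None
    C: np.ndarray
    H_I: np.ndarray
    H_G: np.ndarray
    S: np.ndarray
    scores: np.ndarray
    M: int
    N: int


def _edge_dropout(G_norm: np.ndarray, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric Bernoulli mask on non-zero entries, inverted-rescaled."""
    keep = rng.random(G_norm.shape) >= beta
    keep = np.triu(keep) | np.triu(keep, 1).T  # symmetric mask
    return np.where(G_norm != 0, G_norm * keep / (1.0 - beta), 0.0)


def forward(G_norm: np.ndarray, H0: np.ndarray, state: ModelState,
            cfg: ModelConfig, M: int, N: int, training: bool = False,
            rng: np.random.Generator | None = None) -> ForwardCache:
    """Full encoder + attention + decoder pass on dense arrays.

    In training mode, edge dropout rescales the surviving entries of the
    normalised graph and node dropout masks whole embedding rows (or graph
    rows, per config); at evaluation both are identity maps.
    """
    L = cfg.n_layers
    if training and (cfg.edge_dropout > 0 or cfg.node_dropout > 0) and rng is None:
        raise ValueError("training with dropout requires an rng")

    G_eff = G_norm
    if training and cfg.edge_dropout > 0:
        G_eff = _edge_dropout(G_norm, cfg.edge_dropout, rng)
    graph_node_dropout = training and cfg.node_dropout > 0 and cfg.node_dropout_on == "graph"
    if graph_node_dropout:
        keep = (rng.random(G_eff.shape[0]) >= cfg.node_dropout).astype(float)
        G_eff = G_eff * (keep / (1.0 - cfg.node_dropout))[:, None]

    weights = [state.W0] + list(state.Ws)
    Z_list: list[np.ndarray] = []
    H_list: list[np.ndarray] = []
    masks: list[np.ndarray | None] = []
    H_prev = H0
    for layer in range(L):
        Z = G_eff @ (H_prev @ weights[layer])
        H = selu(Z)
        mask = None
        if training and cfg.node_dropout > 0 and not graph_node_dropout:
            keep = (rng.random(H.shape[0]) >= cfg.node_dropout).astype(float)
            mask = keep / (1.0 - cfg.node_dropout)
            H = H * mask[:, None]
        Z_list.append(Z)
        H_list.append(H)
        masks.append(mask)
        H_prev = H

    a = combination_weights(cfg, state.att_logits)
    if cfg.variant == "CON":
        C = np.hstack(H_list)
    else:
        C = np.tensordot(a, np.stack(H_list), axes=1)
    H_I, H_G = C[:M], C[M:]
    S = H_I @ state.Wdec @ H_G.T
    return ForwardCache(G_eff=G_eff, H0=H0, Z=Z_list, H=H_list,
                        node_masks=masks, a=a, C=C, H_I=H_I, H_G=H_G,
                        S=S, scores=sigmoid(S), M=M, N=N)


def backward(dS: np.ndarray, cache: ForwardCache, state: ModelState,
             cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all trainables, given dLoss/dS."""
    L = cfg.n_layers
    dWdec = cache.H_I.T @ dS @ cache.H_G
    dH_I = dS @ (cache.H_G @ state.Wdec.T)
    dH_G = dS.T @ (cache.H_I @ state.Wdec)
    dC = np.vstack([dH_I, dH_G])

    datt = np.zeros(L)
    dH_layers: list[np.ndarray] = []
    if cfg.variant == "CON":
        k = cfg.embed_dim
        dH_layers = [dC[:, l * k:(l + 1) * k].copy() for l in range(L)]
    else:
        for l in range(L):
            dH_layers.append(cache.a[l] * dC)
        if cfg.variant == "full":
            da = np.array([float(np.sum(dC * cache.H[l])) for l in range(L)])
            datt = cache.a * (da - float(cache.a @ da))

    weights = [state.W0] + list(state.Ws)
    dweights: list[np.ndarray] = [np.zeros_like(w) for w in weights]
    Gt = cache.G_eff.T
    dH_next = np.zeros_like(dC)  # gradient flowing from layer l+1 into H_l
    for layer in range(L - 1, -1, -1):
        dH = dH_layers[layer] + (dH_next if layer < L - 1 else 0.0)
        if cache.node_masks[layer] is not None:
            dH = dH * cache.node_masks[layer][:, None]
        dZ = dH * selu_grad(cache.Z[layer])
        H_in = cache.H0 if layer == 0 else cache.H[layer - 1]
        GtdZ = Gt @ dZ
        dweights[layer] = H_in.T @ GtdZ
        if layer > 0:
            dH_next = GtdZ @ weights[layer].T
    grads = {"W0": dweights[0], "att_logits": datt, "Wdec": dWdec}
    for i in range(1, L):
        grads[f"W{i}"] = dweights[i]
    return grads


# ---------------------------------------------------------------------------
# high-level wrappers on HeteroGraph

def encode(graph: HeteroGraph, state: ModelState, cfg: ModelConfig,
           training: bool = False,
           rng: np.random.Generator | None = None) -> EmbeddingStack:
    """Run the encoder and attention combine on a heterogeneous graph."""
    G_norm = symmetric_degree_normalize(graph.G)
    H0 = graph.H0.toarray().astype(float)
    M, N = graph.block_sizes
    cache = forward(G_norm, H0, state, cfg, M, N, training=training, rng=rng)
    a = cache.a if cache.a is not None else np.full(cfg.n_layers, np.nan)
    return EmbeddingStack(layers=cache.H, H_I=cache.H_I, H_G=cache.H_G,
                          attention=a)


def attend(layers: list[np.ndarray], att_logits: np.ndarray,
           M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Softmax-weighted layer combination, split into miRNA/target rows."""
    a = softmax(np.asarray(att_logits, dtype=float))
    C = np.tensordot(a, np.stack(layers), axes=1)
    return C[:M], C[M:], a


def decode(H_I: np.ndarray, H_G: np.ndarray, Wdec: np.ndarray) -> np.ndarray:
    """Bilinear pair scores sigmoid(H_I @ Wdec @ H_G^T), each in (0, 1)."""
    if H_I.shape[1] != Wdec.shape[0] or H_G.shape[1] != Wdec.shape[1]:
        raise ValueError(
            f"decoder dimension mismatch: H_I {H_I.shape}, "
            f"Wdec {Wdec.shape}, H_G {H_G.shape}"
        )
    return sigmoid(H_I @ Wdec @ H_G.T)


def predict_scores(graph: HeteroGraph, state: ModelState,
                   cfg: ModelConfig) -> np.ndarray:
    """Deterministic M x N score matrix for every miRNA-target pair."""
    stack = encode(graph, state, cfg, training=False)
    return decode(stack.H_I, stack.H_G, state.Wdec)


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path: str | Path, state: ModelState, cfg: ModelConfig) -> None:
    """Single .npz archive holding all weights plus the JSON-encoded config."""
    arrays = {"W0": state.W0, "att_logits": state.att_logits, "Wdec": state.Wdec}
    for i, W in enumerate(state.Ws):
        arrays[f"Ws_{i}"] = W
    cfg_json = json.dumps({
        "embed_dim": cfg.embed_dim, "n_layers": cfg.n_layers,
        "node_dropout": cfg.node_dropout, "edge_dropout": cfg.edge_dropout,
        "variant": cfg.variant, "node_dropout_on": cfg.node_dropout_on,
        "seed": cfg.seed,
    })
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[ModelState, ModelConfig]:
    with np.load(path) as npz:
        cfg = ModelConfig(**json.loads(npz["__config__"].tobytes().decode()))
        Ws = [npz[f"Ws_{i}"] for i in range(cfg.n_layers - 1)]
        state = ModelState(W0=npz["W0"], Ws=Ws,
                           att_logits=npz["att_logits"], Wdec=npz["Wdec"])
    return state, cfg
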