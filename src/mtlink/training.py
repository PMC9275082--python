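"""Model optimisation: imbalance-weighted cross-entropy, Xavier init,
Adam with a cyclic (triangular) learning rate, and the full-batch fit loop.

The loss treats every known association as a positive (weight lambda =
|negatives| / |positives|) and every unobserved pair of the *training*
matrix as a negative:

    loss = -1/(M N) * ( lambda * sum_{(i,j) in pos} log A'_ij
                        + sum_{(i,j) in neg} log(1 - A'_ij) )

Held-out test positives are excluded from both sets by default, so a
masked pair never contributes a (false) negative signal during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import model as _model
from .hetgraph import AssociationMatrix, HeteroGraph, symmetric_degree_normalize
from .model import ModelConfig, ModelState

__all__ = [
    "LossSpec",
    "TrainConfig",
    "weighted_cross_entropy",
    "loss_gradient",
    "xavier_init",
    "init_state",
    "cyclic_lr",
    "fit",
]

_LOG_CLAMP = 1e-12


@dataclass
class LossSpec:
    """Positive/negative pair masks and the class-imbalance weight lambda."""

    pos_mask: np.ndarray          # M x N bool
    neg_mask: np.ndarray          # M x N bool
    lam: float

    def __post_init__(self) -> None:
        self.pos_mask = np.asarray(self.pos_mask, dtype=bool)
        self.neg_mask = np.asarray(self.neg_mask, dtype=bool)
        if self.pos_mask.shape != self.neg_mask.shape:
            raise ValueError("mask shapes differ")
        if not self.pos_mask.any():
            raise ValueError("empty positive set: lambda undefined")
        if not self.neg_mask.any():
            raise ValueError("empty negative set: nothing to contrast against")
        if (self.pos_mask & self.neg_mask).any():
            raise ValueError("positive and negative sets overlap")

    @property
    def n_pos(self) -> int:
        return int(self.pos_mask.sum())

    @property
    def n_neg(self) -> int:
        return int(self.neg_mask.sum())

    @classmethod
    def from_association(cls, A_train: AssociationMatrix,
                         exclude: list[tuple[int, int]] | None = None,
                         include_excluded_as_negative: bool = False) -> "LossSpec":
        """Training loss sets from a (possibly masked) association matrix.

        ``exclude`` lists held-out test positives: they are removed from the
        negative set entirely unless ``include_excluded_as_negative`` — which
        treats every unobserved pair as negative — is requested.
        """
        pos = A_train.dense().astype(bool)
        if not pos.any():
            raise ValueError("empty positive set: lambda undefined")
        neg = ~pos
        if exclude and not include_excluded_as_negative:
            rows, cols = zip(*exclude)
            neg[np.array(rows), np.array(cols)] = False
        spec = cls(pos_mask=pos, neg_mask=neg,
                   lam=float(neg.sum()) / float(pos.sum()))
        return spec


def weighted_cross_entropy(scores: np.ndarray, spec: LossSpec) -> float:
    """Imbalance-weighted cross-entropy over the pair masks.

    Log arguments are clamped at 1e-12 so a saturated sigmoid cannot produce
    an infinite loss.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != spec.pos_mask.shape:
        raise ValueError("score matrix shape does not match loss masks")
    m, n = scores.shape
    p = np.clip(scores, _LOG_CLAMP, 1.0 - _LOG_CLAMP)
    pos_term = spec.lam * np.log(p[spec.pos_mask]).sum()
    neg_term = np.log1p(-p[spec.neg_mask]).sum()
    return float(-(pos_term + neg_term) / (m * n))


def loss_gradient(scores: np.ndarray, spec: LossSpec) -> np.ndarray:
    """d loss / d S where scores = sigmoid(S); same shape as scores."""
    m, n = scores.shape
    g = np.zeros_like(scores)
    g[spec.pos_mask] = spec.lam * (scores[spec.pos_mask] - 1.0)
    g[spec.neg_mask] = scores[spec.neg_mask]
    return g / (m * n)


def xavier_init(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Glorot-uniform: U(+-sqrt(6 / (fan_in + fan_out)))."""
    fan_in, fan_out = shape[0], shape[-1]
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def init_state(graph: HeteroGraph, cfg: ModelConfig,
               rng: np.random.Generator | None = None) -> ModelState:
    """Xavier-initialise all weight matrices; attention logits start equal."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_nodes = graph.n_nodes
    k, L, dk = cfg.embed_dim, cfg.n_layers, cfg.decoder_dim
    return ModelState(
        W0=xavier_init((n_nodes, k), rng),
        Ws=[xavier_init((k, k), rng) for _ in range(L - 1)],
        att_logits=np.zeros(L),
        Wdec=xavier_init((dk, dk), rng),
    )


def cyclic_lr(step: int, total_steps: int, lr_low: float, lr_high: float,
              cycle_length: int = 100) -> float:
    """Triangular learning-rate wave: lr_low -> lr_high -> lr_low per cycle."""
    if not 0 <= step < total_steps:
        raise ValueError("step out of range")
    half = cycle_length / 2.0
    pos = step % cycle_length
    frac = pos / half if pos <= half else (cycle_length - pos) / half
    return lr_low + (lr_high - lr_low) * frac


@dataclass(frozen=True)
class TrainConfig:
    """Fit-loop hyperparameters (defaults follow the published setting)."""

    epochs: int = 500
    lr_low: float = 0.01
    lr_high: float = 0.1
    cycle_length: int = 100
    optimizer: str = "adam"        # or "sgd" (plain gradient descent)
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_low <= self.lr_high:
            raise ValueError("need 0 < lr_low <= lr_high")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.cfg = cfg

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        c = self.cfg
        self.t += 1
        for key, p in params.items():
            g = grads[key]
            self.m[key] = c.beta1 * self.m[key] + (1 - c.beta1) * g
            self.v[key] = c.beta2 * self.v[key] + (1 - c.beta2) * g * g
            mhat = self.m[key] / (1 - c.beta1 ** self.t)
            vhat = self.v[key] / (1 - c.beta2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + c.eps)


def fit(graph: HeteroGraph, loss_spec: LossSpec,
        model_cfg: ModelConfig | None = None,
        train_cfg: TrainConfig | None = None,
        seed: int | None = None) -> tuple[ModelState, pd.DataFrame]:
    """Full-batch training of the encoder-attention-decoder model.

    One optimiser step per epoch (the graph is a single instance); dropout
    masks are redrawn every epoch from a generator seeded by ``seed``.
    Returns the final state and a per-epoch history table with the loss,
    learning rate and attention weights.

    Raises
    ------
    FloatingPointError
        If the loss becomes non-finite (divergence diagnostic).
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    if seed is None:
        seed = train_cfg.seed
    rng = np.random.default_rng(seed)

    G_norm = symmetric_degree_normalize(graph.G)
    H0 = graph.H0.toarray().astype(float)
    M, N = graph.block_sizes
    state = init_state(graph, model_cfg, rng)
    params = state.params()
    opt = _Adam(params, train_cfg) if train_cfg.optimizer == "adam" else None

    records = []
    for epoch in range(train_cfg.epochs):
        cache = _model.forward(G_norm, H0, state, model_cfg, M, N,
                               training=True, rng=rng)
        loss = weighted_cross_entropy(cache.scores, loss_spec)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged: loss={loss} at epoch {epoch}"
            )
        dS = loss_gradient(cache.scores, loss_spec)
        grads = _model.backward(dS, cache, state, model_cfg)
        lr = cyclic_lr(epoch, train_cfg.epochs, train_cfg.lr_low,
                       train_cfg.lr_high, train_cfg.cycle_length)
        if opt is not None:
            opt.step(params, grads, lr)
        else:
            for key, p in params.items():
                p -= lr * grads[key]
        a = _model.combination_weights(model_cfg, state.att_logits)
        rec = {"epoch": epoch, "loss": loss, "lr": lr}
        if a is not None:
            rec.update({f"a_{i + 1}": float(w) for i, w in enumerate(a)})
        records.append(rec)
    state.check_finite()
    return state, pd.DataFrame.from_records(records)
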