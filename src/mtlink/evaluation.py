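"""Cross-validated evaluation: fold construction, negative sampling
(random / per-miRNA / per-target), and the seven-metric report.

Evaluation follows the standard protocol for bipartite association
prediction: known positives are partitioned into five folds; per fold the
test positives are masked out of the training graph, the model is trained
on the remainder, and the held-out positives are ranked against sampled
negatives at either a 1:1 ("balanced") or 1:20 ("unbalanced") ratio.

Negative-sampling strategies:

* ``random`` — uniform without replacement over all non-positive pairs;
* ``SCM`` — sampling by miRNA: each miRNA contributes as many negatives as
  it has test positives, so every miRNA with held-out links is represented;
* ``SCT`` — sampling by target, symmetric to SCM.

For the unbalanced ratio, SCM/SCT loop over the entities round-robin until
the quota is met, skipping exhausted entities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .hetgraph import AssociationMatrix, mask_test_edges, build_propagation_graph
from .model import ModelConfig, predict_scores
from .seqfeat import SimilarityMatrix
from .training import LossSpec, TrainConfig, fit

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "make_folds",
    "sample_negatives",
    "compute_metrics",
    "cross_validate",
]

Pair = tuple[int, int]


@dataclass
class FoldSplit:
    """One cross-validation fold: train/test positives plus test negatives."""

    fold_id: int
    train_pos: list[Pair]
    test_pos: list[Pair]
    test_neg: list[Pair]
    ratio: int


@dataclass
class MetricsReport:
    """Ranking (AUPR, AUC) and thresholded confusion-matrix metrics."""

    aupr: float
    auc: float
    f1: float
    accuracy: float
    recall: float
    specificity: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def make_folds(positives: list[Pair], n_folds: int = 5,
               seed: int = 0) -> list[list[Pair]]:
    """Shuffled partition of the positive pairs into near-equal folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(positives) < n_folds:
        raise ValueError(
            f"{len(positives)} positives cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds: list[list[Pair]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(positives[idx])
    return folds


def _entity_counts(pairs: list[Pair], axis: int) -> dict[int, int]:
    counts: dict[int, int] = {}
    for p in pairs:
        counts[p[axis]] = counts.get(p[axis], 0) + 1
    return counts


def sample_negatives(A: AssociationMatrix, n_needed: int,
                     strategy: str = "random", seed: int = 0,
                     exclude: set[Pair] | None = None,
                     test_pos: list[Pair] | None = None) -> list[Pair]:
    """Draw ``n_needed`` unobserved pairs under the given strategy.

    ``exclude`` defaults to all positives of ``A`` (a sampled negative must
    never be a known association); extra pairs may be added. ``test_pos``
    supplies the per-entity positive counts that drive SCM/SCT; it defaults
    to the positives of ``A``.
    """
    M, N = A.shape
    rng = np.random.default_rng(seed)
    forbidden = set(A.positive_pairs())
    if exclude:
        forbidden |= set(exclude)
    available = M * N - len(forbidden)
    if n_needed > available:
        raise ValueError(
            f"requested {n_needed} negatives but only {available} available"
        )

    if strategy == "random":
        return _sample_random(M, N, n_needed, forbidden, rng)
    if strategy in ("SCM", "SCT"):
        axis = 0 if strategy == "SCM" else 1
        counts = _entity_counts(test_pos if test_pos is not None
                                else A.positive_pairs(), axis)
        return _sample_per_entity(M, N, n_needed, forbidden, counts, axis, rng)
    raise ValueError(f"unknown sampling strategy {strategy!r}")


def _sample_random(M: int, N: int, n_needed: int, forbidden: set[Pair],
                   rng: np.random.Generator) -> list[Pair]:
    chosen: list[Pair] = []
    seen: set[Pair] = set()
    # rejection sampling with a dense fallback for tight instances
    if n_needed < 0.25 * (M * N - len(forbidden)):
        while len(chosen) < n_needed:
            i = int(rng.integers(M))
            j = int(rng.integers(N))
            if (i, j) in forbidden or (i, j) in seen:
                continue
            seen.add((i, j))
            chosen.append((i, j))
        return chosen
    pool = [(i, j) for i in range(M) for j in range(N) if (i, j) not in forbidden]
    idx = rng.choice(len(pool), size=n_needed, replace=False)
    return [pool[i] for i in idx]


def _sample_per_entity(M: int, N: int, n_needed: int, forbidden: set[Pair],
                       counts: dict[int, int], axis: int,
                       rng: np.random.Generator) -> list[Pair]:
    other = N if axis == 0 else M
    pools: dict[int, list[int]] = {}
    for e in counts:
        pool = [j for j in range(other)
                if ((e, j) if axis == 0 else (j, e)) not in forbidden]
        if not pool:
            warnings.warn(
                f"entity {e} has no available negatives; skipped",
                stacklevel=3,
            )
            continue
        rng.shuffle(pool)
        pools[e] = pool

    chosen: list[Pair] = []
    entities = sorted(pools)
    # round-robin over entities: each pass draws up to count_e per entity,
    # looping until the quota is met or every pool is exhausted
    while len(chosen) < n_needed and pools:
        progress = False
        for e in entities:
            if e not in pools:
                continue
            take = min(counts[e], len(pools[e]), n_needed - len(chosen))
            for _ in range(take):
                j = pools[e].pop()
                chosen.append((e, j) if axis == 0 else (j, e))
                progress = True
            if not pools[e]:
                del pools[e]
            if len(chosen) >= n_needed:
                break
        if not progress:
            break
    if len(chosen) < n_needed:
        # top up uniformly so the contract |neg| == n_needed holds
        extra = _sample_random(M, N, n_needed - len(chosen),
                               forbidden | set(chosen), rng)
        chosen.extend(extra)
    return chosen[:n_needed]


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricsReport:
    """Seven-metric report on a labelled score vector.

    AUC uses the midrank tie convention; AUPR is the step-wise
    precision-recall integral (average precision). The remaining five
    metrics come from the confusion matrix at ``threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return MetricsReport(
        aupr=float(average_precision_score(labels, scores)),
        auc=float(roc_auc_score(labels, scores)),
        f1=f1,
        accuracy=(tp + tn) / len(labels),
        recall=recall,
        specificity=specificity,
        precision=precision,
    )


def cross_validate(A: AssociationMatrix, Sm: SimilarityMatrix,
                   Sn: SimilarityMatrix, task: str = "balanced",
                   strategy: str = "random", n_folds: int = 5,
                   mu: float = 0.06, model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None, seed: int = 0,
                   threshold: float = 0.5,
                   ) -> tuple[pd.DataFrame, list[FoldSplit]]:
    """K-fold cross-validation of the full pipeline.

    Per fold: mask the test positives out of the association matrix,
    rebuild the propagation graph, train from scratch, then score the test
    positives against negatives sampled at the task's ratio (1:1 balanced,
    1:20 unbalanced). Returns a tidy per-fold metric table (plus mean and
    sd rows) and the fold definitions.
    """
    if task not in ("balanced", "unbalanced"):
        raise ValueError("task must be 'balanced' or 'unbalanced'")
    ratio = 1 if task == "balanced" else 20
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()

    positives = A.positive_pairs()
    folds = make_folds(positives, n_folds=n_folds, seed=seed)
    rows = []
    splits: list[FoldSplit] = []
    for fold_id, test_pos in enumerate(folds):
        A_train = mask_test_edges(A, test_pos)
        test_neg = sample_negatives(
            A, ratio * len(test_pos), strategy=strategy,
            seed=seed * n_folds + fold_id + 1, test_pos=test_pos,
        )
        graph = build_propagation_graph(A_train, Sm, Sn, mu=mu)
        spec = LossSpec.from_association(A_train, exclude=test_pos)
        state, _ = fit(graph, spec, model_cfg, train_cfg,
                       seed=seed * n_folds + fold_id + 1)
        scores_full = predict_scores(graph, state, model_cfg)
        pairs = test_pos + test_neg
        y = np.array([1] * len(test_pos) + [0] * len(test_neg))
        s = np.array([scores_full[i, j] for i, j in pairs])
        report = compute_metrics(s, y, threshold=threshold)
        rows.append({"fold": fold_id, **report.as_dict()})
        splits.append(FoldSplit(fold_id=fold_id,
                                train_pos=sorted(set(positives) - set(test_pos)),
                                test_pos=test_pos, test_neg=test_neg,
                                ratio=ratio))
    df = pd.DataFrame(rows).set_index("fold")
    summary = pd.concat([df, df.agg(["mean", "std"])])
    return summary, splits
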