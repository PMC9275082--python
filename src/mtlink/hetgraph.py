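"""Heterogeneous graph assembly for bipartite miRNA-target link prediction.

The (M+N)-node heterogeneous network combines the bipartite association
matrix A (M miRNAs x N targets) with the two normalised within-role
similarity networks S~^m and S~^n:

    A_H = [[S~^m, A], [A^T, S~^n]]

For propagation the similarity blocks are scaled by a penalty factor mu
controlling how much within-role similarity contributes relative to known
associations, and the initial node embedding carries the associations only:

    G  = [[mu S~^m, A], [A^T, mu S~^n]]
    H0 = [[0, A], [A^T, 0]]

Internally everything is 0-based block bookkeeping; ids are resolved only
at I/O boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

from .seqfeat import SimilarityMatrix

__all__ = [
    "AssociationMatrix",
    "HeteroGraph",
    "build_hetero_adjacency",
    "build_propagation_graph",
    "symmetric_degree_normalize",
    "mask_test_edges",
    "read_pairs",
    "write_pairs",
]

Pair = tuple[int, int]


@dataclass
class AssociationMatrix:
    """Sparse binary M x N matrix of known miRNA-target links."""

    matrix: sparse.csr_matrix
    mirna_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        m, n = self.matrix.shape
        if m != len(self.mirna_ids) or n != len(self.target_ids):
            raise ValueError(
                f"id lists ({len(self.mirna_ids)}, {len(self.target_ids)}) "
                f"do not match matrix shape {self.matrix.shape}"
            )
        if len(set(self.mirna_ids)) != m or len(set(self.target_ids)) != n:
            raise ValueError("duplicate ids in association matrix")
        data = self.matrix.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise ValueError("association matrix entries must be binary")
        self.matrix.eliminate_zeros()

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def n_positives(self) -> int:
        return int(self.matrix.nnz)

    def positive_pairs(self) -> list[Pair]:
        """All (miRNA index, target index) pairs with a known link."""
        coo = self.matrix.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist()))

    def dense(self) -> np.ndarray:
        return self.matrix.toarray().astype(float)

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]], mirna_ids: list[str],
                   target_ids: list[str]) -> "AssociationMatrix":
        """Build from (miRNA id, target id) string pairs against id lists."""
        mi = {r: i for i, r in enumerate(mirna_ids)}
        ti = {t: j for j, t in enumerate(target_ids)}
        rows, cols = [], []
        for r, t in pairs:
            if r not in mi:
                raise KeyError(f"unknown miRNA id {r!r} in pair list")
            if t not in ti:
                raise KeyError(f"unknown target id {t!r} in pair list")
            rows.append(mi[r])
            cols.append(ti[t])
        mat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(mirna_ids), len(target_ids)),
        )
        mat.data[:] = 1.0  # collapse duplicate pairs
        return cls(matrix=mat, mirna_ids=list(mirna_ids),
                   target_ids=list(target_ids))


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column delimited association list; '#' starts a comment line."""
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{ln}: expected two columns, got {line!r}")
            pairs.append((fields[0], fields[1]))
    return pairs


def write_pairs(pairs: list[tuple[str, str]], path: str | Path,
                header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for r, t in pairs:
            fh.write(f"{r}\t{t}\n")


@dataclass
class HeteroGraph:
    """Propagation graph G and initial embedding H0 with block bookkeeping."""

    G: sparse.csr_matrix
    H0: sparse.csr_matrix
    mu: float
    block_sizes: tuple[int, int]
    mirna_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return sum(self.block_sizes)

    def save(self, prefix: str | Path) -> None:
        """Write G and H0 as MTX triplets plus a JSON sidecar."""
        prefix = Path(prefix)
        spio.mmwrite(str(prefix) + ".G.mtx", sparse.coo_matrix(self.G))
        spio.mmwrite(str(prefix) + ".H0.mtx", sparse.coo_matrix(self.H0))
        sidecar = {
            "M": self.block_sizes[0],
            "N": self.block_sizes[1],
            "mu": self.mu,
            "mirna_ids": self.mirna_ids,
            "target_ids": self.target_ids,
        }
        Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "HeteroGraph":
        prefix = Path(prefix)
        side = json.loads(Path(str(prefix) + ".json").read_text())
        return cls(
            G=sparse.csr_matrix(spio.mmread(str(prefix) + ".G.mtx")),
            H0=sparse.csr_matrix(spio.mmread(str(prefix) + ".H0.mtx")),
            mu=side["mu"],
            block_sizes=(side["M"], side["N"]),
            mirna_ids=side["mirna_ids"],
            target_ids=side["target_ids"],
        )


def _check_blocks(A: AssociationMatrix, Sm: SimilarityMatrix,
                  Sn: SimilarityMatrix) -> tuple[int, int]:
    m, n = A.shape
    if Sm.n != m or Sn.n != n:
        raise ValueError(
            "block shape mismatch: A is "
            f"{m}x{n}, S^m is {Sm.n}x{Sm.n} (need {m}x{m}), "
            f"S^n is {Sn.n}x{Sn.n} (need {n}x{n})"
        )
    return m, n


def build_hetero_adjacency(A: AssociationMatrix, Sm: SimilarityMatrix,
                           Sn: SimilarityMatrix) -> sparse.csr_matrix:
    """Block matrix [[S~^m, A], [A^T, S~^n]]; symmetric by construction."""
    _check_blocks(A, Sm, Sn)
    return sparse.bmat(
        [[sparse.csr_matrix(Sm.matrix), A.matrix],
         [A.matrix.T, sparse.csr_matrix(Sn.matrix)]],
        format="csr",
    )


def build_propagation_graph(A: AssociationMatrix, Sm: SimilarityMatrix,
                            Sn: SimilarityMatrix, mu: float = 0.06) -> HeteroGraph:
    """Assemble G (mu-scaled similarity blocks) and H0 (association blocks)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    m, n = _check_blocks(A, Sm, Sn)
    if not (Sm.normalized and Sn.normalized):
        warnings.warn(
            "building propagation graph from un-normalised similarities",
            stacklevel=2,
        )
    G = sparse.bmat(
        [[mu * sparse.csr_matrix(Sm.matrix), A.matrix],
         [A.matrix.T, mu * sparse.csr_matrix(Sn.matrix)]],
        format="csr",
    )
    H0 = sparse.bmat(
        [[sparse.csr_matrix((m, m)), A.matrix],
         [A.matrix.T, sparse.csr_matrix((n, n))]],
        format="csr",
    )
    return HeteroGraph(G=G, H0=H0, mu=float(mu), block_sizes=(m, n),
                       mirna_ids=list(A.mirna_ids), target_ids=list(A.target_ids))


def symmetric_degree_normalize(G) -> np.ndarray:
    """D^{-1/2} G D^{-1/2} with D = diag(row sums); zero-degree rows stay zero."""
    Gd = G.toarray() if sparse.issparse(G) else np.asarray(G, dtype=float)
    if (Gd < 0).any():
        raise ValueError("graph must be non-negative")
    d = Gd.sum(axis=1)
    inv_sqrt = np.zeros_like(d)
    pos = d > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(d[pos])
    return Gd * inv_sqrt[:, None] * inv_sqrt[None, :]


def mask_test_edges(A: AssociationMatrix, test_pairs: list[Pair]) -> AssociationMatrix:
    """Copy of A with the held-out positive pairs zeroed.

    Every test pair must be a positive of A; the input is left untouched.
    """
    mat = A.matrix.tolil(copy=True)
    for i, j in test_pairs:
        if mat[i, j] != 1:
            raise ValueError(f"test pair ({i}, {j}) is not a positive in A")
        mat[i, j] = 0
    return AssociationMatrix(matrix=mat.tocsr(), mirna_ids=list(A.mirna_ids),
                             target_ids=list(A.target_ids))
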