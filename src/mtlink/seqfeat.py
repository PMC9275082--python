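"""Sequence k-mer features and pairwise similarity networks.

miRNAs (~22 nt) and their target genes are represented by binary k-mer
presence/absence vectors over the 4^k lexicographically ordered DNA k-mers.
Pairwise similarity between sequences of the same role is then computed with
the Jaccard index (default) or one of three alternative measures (cosine,
Pearson, Gaussian kernel), and symmetrically degree-normalised before it
enters the heterogeneous graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy import io as spio
from scipy import sparse

__all__ = [
    "SequenceSet",
    "FeatureMatrix",
    "SimilarityMatrix",
    "extract_kmer_features",
    "jaccard_similarity",
    "alt_similarity",
    "similarity",
    "normalize_similarity",
    "write_similarity_tsv",
    "read_similarity_tsv",
    "write_similarity_mtx",
]

_VALID = frozenset("ACGT")


class SequenceError(ValueError):
    """A sequence record violates the alphabet or length contract."""


@dataclass
class SequenceSet:
    """An ordered collection of nucleotide sequences with unique ids.

    Sequences are normalised on construction: uppercased and with U mapped
    to T, so RNA and DNA inputs are treated uniformly.

    Parameters
    ----------
    ids
        Unique record identifiers, in order.
    seqs
        Nucleotide strings, same length as ``ids``.
    role
        Either ``"miRNA"`` or ``"target"``; used only for bookkeeping.
    on_invalid
        ``"raise"`` (default) rejects records containing non-ACGT characters
        after normalisation; ``"drop"`` removes them with a warning.
    """

    ids: list[str]
    seqs: list[str]
    role: str = "miRNA"
    on_invalid: str = "raise"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise ValueError(f"duplicate sequence ids: {sorted(dupes)[:5]}")
        norm_ids, norm_seqs = [], []
        for rid, seq in zip(self.ids, self.seqs):
            s = seq.upper().replace("U", "T")
            if not s:
                raise SequenceError(f"empty sequence for id {rid!r}")
            bad = set(s) - _VALID
            if bad:
                msg = f"record {rid!r} contains non-ACGT characters {sorted(bad)}"
                if self.on_invalid == "drop":
                    warnings.warn(msg + " (dropped)", stacklevel=2)
                    continue
                raise SequenceError(msg)
            norm_ids.append(rid)
            norm_seqs.append(s)
        self.ids = norm_ids
        self.seqs = norm_seqs

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_fasta(cls, path: str | Path, role: str = "miRNA",
                   on_invalid: str = "raise") -> "SequenceSet":
        """Read a (multi-line) FASTA file; id is the first whitespace token."""
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        if not ids:
            raise SequenceError(f"no FASTA records found in {path}")
        return cls(ids=ids, seqs=seqs, role=role, on_invalid=on_invalid)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.seqs):
                fh.write(f">{rid}\n{seq}\n")


@dataclass
class FeatureMatrix:
    """Binary k-mer presence/absence matrix, one row per sequence.

    Columns enumerate all 4^k k-mers in lexicographic order (A<C<G<T).
    """

    matrix: np.ndarray
    k: int
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 ** self.k:
            raise ValueError(
                f"feature matrix must be n x 4^k = n x {4 ** self.k}, "
                f"got {self.matrix.shape}"
            )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one node role."""

    matrix: np.ndarray
    measure: str
    ids: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("similarity matrix contains non-finite values")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def kmer_vocabulary(k: int) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def extract_kmer_features(seqs: SequenceSet, k: int = 3,
                          mode: str = "binary") -> FeatureMatrix:
    """Slide a length-k window over each sequence and record its k-mers.

    ``mode="binary"`` (default) sets entry (i, m) to 1 iff k-mer m occurs at
    least once in sequence i; ``mode="frequency"`` records occurrence counts
    divided by the number of windows. Sequences shorter than k yield an
    all-zero row with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("binary", "frequency"):
        raise ValueError(f"unknown mode {mode!r}")
    index = {km: i for i, km in enumerate(kmer_vocabulary(k))}
    mat = np.zeros((len(seqs), 4 ** k))
    for i, (rid, s) in enumerate(zip(seqs.ids, seqs.seqs)):
        if len(s) < k:
            warnings.warn(
                f"sequence {rid!r} shorter than k={k}; all-zero feature row",
                stacklevel=2,
            )
            continue
        n_windows = len(s) - k + 1
        for j in range(n_windows):
            mat[i, index[s[j:j + k]]] += 1.0
        if mode == "binary":
            mat[i] = (mat[i] > 0).astype(float)
        else:
            mat[i] /= n_windows
    return FeatureMatrix(matrix=mat, k=k, row_ids=list(seqs.ids))


def jaccard_similarity(f: FeatureMatrix) -> SimilarityMatrix:
    """Intersection-over-union similarity between binary feature rows.

    S_ij = |x_i AND x_j| / |x_i OR x_j|, with the 0/0 case (two all-zero
    rows, including the self-similarity of an all-zero row) defined as 0.
    """
    x = np.asarray(f.matrix, dtype=float)
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("jaccard similarity requires a binary feature matrix")
    inter = x @ x.T
    row_sums = x.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(matrix=sim, measure="jaccard", ids=list(f.row_ids))


def alt_similarity(f: FeatureMatrix, measure: str) -> SimilarityMatrix:
    """Cosine, Pearson (centred cosine) or Gaussian-kernel similarity.

    Zero-norm rows (cosine) and constant rows (pearson) get similarity 0 to
    every other row, with a warning. The Gaussian bandwidth is set to the
    mean squared pairwise Euclidean distance over the set.
    """
    x = np.asarray(f.matrix, dtype=float)
    if measure == "cosine":
        sim = _cosine(x)
    elif measure == "pearson":
        sim = _cosine(x - x.mean(axis=1, keepdims=True))
    elif measure == "gaussian":
        sq = _sq_dists(x)
        off = sq[~np.eye(len(x), dtype=bool)]
        sigma2 = off.mean() if off.size and off.mean() > 1e-12 else 1.0
        sim = np.exp(-sq / (2.0 * sigma2))
    else:
        raise ValueError(f"unknown similarity measure {measure!r}")
    sim = (sim + sim.T) / 2.0  # enforce exact symmetry against fp noise
    return SimilarityMatrix(matrix=sim, measure=measure, ids=list(f.row_ids))


def similarity(f: FeatureMatrix, measure: str = "jaccard") -> SimilarityMatrix:
    """Dispatch to :func:`jaccard_similarity` or :func:`alt_similarity`."""
    if measure == "jaccard":
        return jaccard_similarity(f)
    return alt_similarity(f, measure)


def _cosine(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-norm rows; their similarities set to 0",
            stacklevel=3,
        )
    safe = np.where(zero, 1.0, norms)
    sim = (x @ x.T) / np.outer(safe, safe)
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    return sim


def _sq_dists(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x ** 2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    return np.maximum(d, 0.0)


def normalize_similarity(S: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric degree normalisation D^{-1/2} S D^{-1/2}.

    D = diag(row sums of S). Zero-degree rows are left zero. Negative
    entries (possible for Pearson) are clamped to 0 first, since the degree
    of a graph node must be non-negative.
    """
    if S.normalized:
        return S
    mat = np.asarray(S.matrix, dtype=float)
    if (mat < 0).any():
        warnings.warn(
            "negative similarities clamped to 0 before normalisation",
            stacklevel=2,
        )
        mat = np.maximum(mat, 0.0)
    d = mat.sum(axis=1)
    inv_sqrt = np.zeros_like(d)
    pos = d > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(d[pos])
    out = mat * inv_sqrt[:, None] * inv_sqrt[None, :]
    return SimilarityMatrix(matrix=out, measure=S.measure, ids=list(S.ids),
                            normalized=True)


# ---------------------------------------------------------------------------
# serialisation

def write_similarity_tsv(S: SimilarityMatrix, path: str | Path) -> None:
    """Labelled delimited text: header row/column are the sequence ids."""
    import pandas as pd

    ids = S.ids or [str(i) for i in range(S.n)]
    pd.DataFrame(S.matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def read_similarity_tsv(path: str | Path, measure: str = "jaccard",
                        normalized: bool = False) -> SimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(matrix=df.to_numpy(), measure=measure,
                            ids=[str(c) for c in df.columns],
                            normalized=normalized)


def write_similarity_mtx(S: SimilarityMatrix, path: str | Path) -> None:
    """Sparse MatrixMarket file plus a ``.ids`` sidecar with one id per line."""
    path = Path(path)
    spio.mmwrite(str(path), sparse.coo_matrix(S.matrix))
    ids = S.ids or [str(i) for i in range(S.n)]
    path.with_suffix(path.suffix + ".ids").write_text("\n".join(ids) + "\n")
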