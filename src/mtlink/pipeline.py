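"""Convenience glue from raw inputs (FASTA x2 + pair list) to model inputs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .hetgraph import AssociationMatrix, read_pairs
from .seqfeat import (
    SequenceSet,
    SimilarityMatrix,
    extract_kmer_features,
    normalize_similarity,
    similarity,
)

__all__ = ["Dataset", "build_dataset", "dataset_from_files"]


@dataclass
class Dataset:
    """Everything cross-validation needs: associations + normalised similarities."""

    A: AssociationMatrix
    Sm: SimilarityMatrix
    Sn: SimilarityMatrix
    mirnas: SequenceSet
    targets: SequenceSet


def build_dataset(mirnas: SequenceSet, targets: SequenceSet,
                  A: AssociationMatrix, k: int = 3,
                  measure: str = "jaccard") -> Dataset:
    """K-mer featurise both sequence sets and normalise their similarities."""
    Sm = normalize_similarity(similarity(extract_kmer_features(mirnas, k), measure))
    Sn = normalize_similarity(similarity(extract_kmer_features(targets, k), measure))
    return Dataset(A=A, Sm=Sm, Sn=Sn, mirnas=mirnas, targets=targets)


def dataset_from_files(fasta_mirna: str | Path, fasta_target: str | Path,
                       pairs_path: str | Path, k: int = 3,
                       measure: str = "jaccard") -> Dataset:
    """Read the FASTA pair-list trio and assemble a :class:`Dataset`."""
    mirnas = SequenceSet.from_fasta(fasta_mirna, role="miRNA")
    targets = SequenceSet.from_fasta(fasta_target, role="target")
    A = AssociationMatrix.from_pairs(read_pairs(pairs_path),
                                     mirnas.ids, targets.ids)
    return build_dataset(mirnas, targets, A, k=k, measure=measure)
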