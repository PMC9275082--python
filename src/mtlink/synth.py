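"""Synthetic benchmark generator with planted, recoverable block structure.

The generator emulates the shape of a real miRNA-target study — two FASTA
sequence sets plus a sparse positive pair list — under a bipartite
stochastic block model: miRNAs and targets are assigned to communities,
links are drawn Bernoulli(p_in) within a community and Bernoulli(p_out)
across, and each community seeds its members' sequences with distinctive
k-mer motifs so that sequence similarity carries community identity. This
couples the two signals the model is designed to exploit: similar miRNAs
share targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import sparse

from .hetgraph import AssociationMatrix, write_pairs
from .seqfeat import SequenceSet

__all__ = ["SynthConfig", "generate", "degenerate_fixtures", "write_bundle"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Planted-block generator parameters.

    Defaults give a 60 x 200 bipartite graph with four communities, dense
    within-community linking (p_in = 0.3) against a sparse background
    (p_out = 0.01), ~22-nt miRNAs, 60-nt targets and strongly planted
    motifs (motif_strength = 0.9: the probability that each of a block's
    motifs is written into a member sequence).
    """

    M: int = 60
    N: int = 200
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    seq_len_mirna: int = 22
    seq_len_target: int = 60
    motif_strength: float = 0.9
    motif_len: int = 5
    motifs_per_block: int = 2
    seed: int = 0

    def n_motifs(self, role: str) -> int:
        """Motif count per block, holding motif density per nucleotide
        constant across roles (longer sequences dilute a fixed number of
        motifs below the k-mer saturation floor, which would leave their
        Jaccard similarity uninformative of block identity)."""
        if role == "miRNA":
            return self.motifs_per_block
        scale = self.seq_len_target / self.seq_len_mirna
        return max(self.motifs_per_block, round(self.motifs_per_block * scale))

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_blocks > min(self.M, self.N):
            raise ValueError("more blocks than nodes on one side")
        if self.motif_len >= min(self.seq_len_mirna, self.seq_len_target):
            raise ValueError("motif longer than the sequences")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(4, size=length)])


def _assign_blocks(n: int, n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Random block labels, guaranteed non-empty via a permuted base layout."""
    labels = np.concatenate([
        np.arange(n_blocks),                       # one seat per block
        rng.integers(n_blocks, size=n - n_blocks),
    ])
    return labels[rng.permutation(n)]


def _plant(seq: str, motifs: list[str], strength: float,
           rng: np.random.Generator) -> str:
    chars = list(seq)
    for motif in motifs:
        if rng.random() < strength:
            start = int(rng.integers(len(chars) - len(motif) + 1))
            chars[start:start + len(motif)] = list(motif)
    return "".join(chars)


def generate(cfg: SynthConfig | None = None,
             ) -> tuple[SequenceSet, SequenceSet, AssociationMatrix, np.ndarray, np.ndarray]:
    """Draw one synthetic dataset.

    Returns the miRNA and target sequence sets, the association matrix, and
    the two block-label vectors (useful for diagnostics; downstream code
    only needs the first three).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    mirna_blocks = _assign_blocks(cfg.M, cfg.n_blocks, rng)
    target_blocks = _assign_blocks(cfg.N, cfg.n_blocks, rng)

    # distinct motif sets per block and role
    motifs: dict[tuple[str, int], list[str]] = {}
    for role in ("miRNA", "target"):
        for b in range(cfg.n_blocks):
            motifs[(role, b)] = [_random_seq(cfg.motif_len, rng)
                                 for _ in range(cfg.n_motifs(role))]

    mirna_seqs = [
        _plant(_random_seq(cfg.seq_len_mirna, rng),
               motifs[("miRNA", int(b))], cfg.motif_strength, rng)
        for b in mirna_blocks
    ]
    target_seqs = [
        _plant(_random_seq(cfg.seq_len_target, rng),
               motifs[("target", int(b))], cfg.motif_strength, rng)
        for b in target_blocks
    ]
    mirnas = SequenceSet(
        ids=[f"mir-{i:03d}" for i in range(cfg.M)], seqs=mirna_seqs, role="miRNA",
    )
    targets = SequenceSet(
        ids=[f"gene-{j:04d}" for j in range(cfg.N)], seqs=target_seqs, role="target",
    )

    same = mirna_blocks[:, None] == target_blocks[None, :]
    prob = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.M, cfg.N)) < prob).astype(float)
    assoc = AssociationMatrix(matrix=sparse.csr_matrix(A),
                              mirna_ids=list(mirnas.ids),
                              target_ids=list(targets.ids))
    return mirnas, targets, assoc, mirna_blocks, target_blocks


def degenerate_fixtures(seed: int = 0) -> dict[str, tuple]:
    """Edge-case datasets exercising the error paths.

    ``single_positive`` has exactly one link; ``no_motif`` carries no
    block-specific sequence signal; ``all_positive`` has every pair linked
    (so the negative set is empty); ``duplicate_sequences`` repeats one
    miRNA sequence verbatim.
    """
    out: dict[str, tuple] = {}

    small = SynthConfig(M=5, N=8, n_blocks=2, p_in=0.5, p_out=0.05,
                        seq_len_target=30, seed=seed)
    mir, tar, assoc, *_ = generate(small)

    single = sparse.csr_matrix(([1.0], ([2], [3])), shape=assoc.shape)
    out["single_positive"] = (mir, tar, AssociationMatrix(
        matrix=single, mirna_ids=list(mir.ids), target_ids=list(tar.ids)))

    mir0, tar0, assoc0, *_ = generate(
        SynthConfig(M=5, N=8, n_blocks=2, p_in=0.5, p_out=0.05,
                    seq_len_target=30, motif_strength=0.0, seed=seed))
    out["no_motif"] = (mir0, tar0, assoc0)

    dense = sparse.csr_matrix(np.ones(assoc.shape))
    out["all_positive"] = (mir, tar, AssociationMatrix(
        matrix=dense, mirna_ids=list(mir.ids), target_ids=list(tar.ids)))

    dup_seqs = list(mir.seqs)
    dup_seqs[1] = dup_seqs[0]
    dup = SequenceSet(ids=list(mir.ids), seqs=dup_seqs, role="miRNA")
    out["duplicate_sequences"] = (dup, tar, assoc)
    return out


def write_bundle(outdir: str | Path, cfg: SynthConfig | None = None) -> dict[str, Path]:
    """Write FASTA x2 + pair list + a provenance sidecar; byte-reproducible."""
    cfg = cfg or SynthConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirnas, targets, assoc, *_ = generate(cfg)
    paths = {
        "mirna_fasta": outdir / "mirnas.fasta",
        "target_fasta": outdir / "targets.fasta",
        "pairs": outdir / "pairs.tsv",
        "config": outdir / "synth_config.json",
    }
    mirnas.to_fasta(paths["mirna_fasta"])
    targets.to_fasta(paths["target_fasta"])
    id_pairs = [(assoc.mirna_ids[i], assoc.target_ids[j])
                for i, j in assoc.positive_pairs()]
    write_pairs(id_pairs, paths["pairs"], header="miRNA_id\ttarget_id")
    paths["config"].write_text(json.dumps(asdict(cfg), indent=1) + "\n")
    return paths
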