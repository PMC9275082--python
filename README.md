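# mtlink

Graph-convolutional link prediction for miRNA–target associations.

MicroRNAs regulate gene expression by binding target mRNAs, and mapping
which miRNA regulates which gene is a bottleneck in non-model organisms
(the motivating case is the tea plant, *Camellia sinensis* var.
*assamica*): experimentally validated pairs are scarce, so computational
ranking of candidate pairs guides experiments. `mtlink` treats the problem
as semi-supervised link prediction on a heterogeneous network and is aimed
at systems biologists who have two FASTA files (miRNAs and candidate
target genes) plus a list of known associations.

## The model

Sequences are featurised as binary k-mer presence/absence vectors
(default k = 3, 64 features) and pairwise similarity is the Jaccard index
S_ij = |x_i ∩ x_j| / |x_i ∪ x_j| (cosine, Pearson and Gaussian-kernel
similarity are available alternatives). With A the M×N binary association
matrix and S̃ᵐ, S̃ⁿ the degree-normalised similarity matrices
(S̃ = D^{-1/2} S D^{-1/2}), the propagation graph and initial embedding are

    G  = [[μ S̃ᵐ, A ], [Aᵀ, μ S̃ⁿ]]        H⁽⁰⁾ = [[0, A], [Aᵀ, 0]]

where μ (default 0.06) controls how much within-role similarity
contributes relative to known links. An L-layer GCN encoder (default
L = 3) propagates

    H⁽ˡ⁺¹⁾ = SELU( D^{-1/2} G D^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾ ),

a learned softmax attention combines the per-layer embeddings,
[H_I; H_G] = Σ_l a_l H⁽ˡ⁾, and a bilinear decoder scores every pair:

    A′ = sigmoid( H_I W′ H_Gᵀ ).

Training minimises the class-imbalance-weighted cross-entropy

    loss = −1/(MN) ( λ Σ_{(i,j)∈γ⁺} log A′_ij + Σ_{(i,j)∈γ⁻} log(1−A′_ij) ),

with λ = |γ⁻|/|γ⁺|, Xavier initialisation, full-batch Adam under a
triangular cyclic learning rate (0.01–0.1), and node/edge dropout
(both 0.6). Gradients are hand-derived and the whole model runs on plain
numpy. Evaluation uses 5-fold cross-validation with balanced (1:1) or
unbalanced (1:20) test sets, negatives drawn uniformly or per-entity
(SCM: by miRNA, SCT: by target), reporting AUPR, AUC, F1, accuracy,
recall, specificity and precision.

## Worked example

`examples/02_train_and_predict.py` simulates a small dataset with planted
miRNA/target communities, trains on all known links, and ranks unobserved
pairs:

```
simulated 20 miRNAs x 40 targets, 167 known associations
loss: 1.5160 (epoch 0) -> 1.4149 (epoch 199)

top 5 predicted novel associations:
  mir-004 -> gene-0009  score 0.995  (same planted block: True)
  mir-013 -> gene-0038  score 0.995  (same planted block: True)
  ...
5/5 of the top predictions lie inside a planted community, the ground
truth the generator hid.
```

The scores are decoder sigmoids in (0, 1): the model's belief that the
pair is a true association. All five top-ranked novel pairs fall inside a
planted community — exactly the signal (similar miRNAs share targets)
the architecture is built to exploit. `examples/03_cross_validation.py`
runs the balanced five-fold protocol on a simulated dataset and prints
the full seven-metric per-fold table (mean AUPR 0.790, AUC 0.812 on that
small instance); the other examples cover similarity construction,
negative-sampling strategies and the layer-attention ablations.

The same stages are scriptable from the shell:

```sh
mtlink simulate --out data/
mtlink evaluate --fasta-mirna data/mirnas.fasta \
    --fasta-target data/targets.fasta --pairs data/pairs.tsv --out eval/
```

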