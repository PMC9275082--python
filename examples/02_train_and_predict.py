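"""Simulate a small planted-block dataset, train the GCN with layer
attention on all known links, and rank the top unobserved pairs.

High-ranked unobserved pairs fall inside the planted communities — the
model recovers the block structure from the combination of link patterns
and sequence similarity.
"""

import numpy as np

from mtlink import ModelConfig, TrainConfig, build_dataset, fit
from mtlink.hetgraph import build_propagation_graph
from mtlink.model import predict_scores
from mtlink.synth import SynthConfig, generate
from mtlink.training import LossSpec

cfg = SynthConfig(M=20, N=40, n_blocks=2, p_in=0.4, p_out=0.02, seed=7)
mirnas, targets, A, mirna_blocks, target_blocks = generate(cfg)
print(f"simulated {cfg.M} miRNAs x {cfg.N} targets, "
      f"{A.n_positives} known associations")

ds = build_dataset(mirnas, targets, A)          # k-mer Jaccard similarities
graph = build_propagation_graph(ds.A, ds.Sm, ds.Sn, mu=0.06)
state, history = fit(graph, LossSpec.from_association(ds.A),
                     ModelConfig(embed_dim=32, seed=0),
                     TrainConfig(epochs=200), seed=0)
print(f"loss: {history.loss.iloc[0]:.4f} (epoch 0) -> "
      f"{history.loss.iloc[-1]:.4f} (epoch {len(history) - 1})")

scores = predict_scores(graph, state, ModelConfig(embed_dim=32, seed=0))
known = ds.A.dense().astype(bool)
candidates = [(scores[i, j], i, j)
              for i in range(cfg.M) for j in range(cfg.N) if not known[i, j]]
candidates.sort(reverse=True)

print("\ntop 5 predicted novel associations:")
hits = 0
for score, i, j in candidates[:5]:
    same = mirna_blocks[i] == target_blocks[j]
    hits += same
    print(f"  {mirnas.ids[i]} -> {targets.ids[j]}  score {score:.3f}  "
          f"(same planted block: {same})")
print(f"\n{hits}/5 of the top predictions lie inside a planted community, "
      "the ground truth the generator hid.")
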