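"""Inspect the learned layer-attention weights and the ablation variants.

The encoder produces one embedding per convolution layer; a softmax
attention combines them. Ablations replace the learned combination with a
single layer (L1/L2/L3), a uniform average (AVE), or a concatenation
(CON). On block-structured data the first layer typically dominates —
deeper layers over-smooth.
"""

from mtlink import ModelConfig, TrainConfig, build_dataset, fit
from mtlink.hetgraph import build_propagation_graph
from mtlink.model import predict_scores
from mtlink.synth import SynthConfig, generate
from mtlink.training import LossSpec

mirnas, targets, A, *_ = generate(
    SynthConfig(M=20, N=40, n_blocks=2, p_in=0.4, p_out=0.02, seed=3))
ds = build_dataset(mirnas, targets, A)
graph = build_propagation_graph(ds.A, ds.Sm, ds.Sn, mu=0.06)
spec = LossSpec.from_association(ds.A)

state, history = fit(graph, spec, ModelConfig(embed_dim=32, seed=0),
                     TrainConfig(epochs=200), seed=0)
final = history.iloc[-1]
print("learned attention weights over the three layer embeddings:")
print(f"  a_1={final.a_1:.3f}  a_2={final.a_2:.3f}  a_3={final.a_3:.3f}  "
      f"(sum {final.a_1 + final.a_2 + final.a_3:.3f})")

for variant in ("AVE", "CON", "L1"):
    cfg = ModelConfig(embed_dim=32, seed=0, variant=variant)
    st, _ = fit(graph, spec, cfg, TrainConfig(epochs=200), seed=0)
    scores = predict_scores(graph, st, cfg)
    print(f"variant {variant}: decoder weight {st.Wdec.shape}, "
          f"mean score on known links "
          f"{scores[ds.A.dense().astype(bool)].mean():.3f}")
print("\nThe first layer carries most of the signal; CON widens the "
      "decoder to act on all three embeddings stacked side by side.")
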