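"""Compare the three negative-sampling strategies used to build test sets.

Random sampling draws uniformly over unobserved pairs; SCM (sampling by
miRNA) draws, for each miRNA, as many negatives as it has test positives;
SCT does the same per target. SCM/SCT guarantee that every entity with a
held-out positive is also represented among the negatives.
"""

from collections import Counter

from mtlink import sample_negatives
from mtlink.synth import SynthConfig, generate

mirnas, targets, A, *_ = generate(
    SynthConfig(M=10, N=30, n_blocks=2, p_in=0.4, p_out=0.03,
                seq_len_target=40, seed=2))
pos = A.positive_pairs()
test_pos = pos[: len(pos) // 5]
print(f"{len(pos)} positives, {len(test_pos)} held out as test positives")

for strategy in ("random", "SCM", "SCT"):
    neg = sample_negatives(A, len(test_pos), strategy=strategy, seed=1,
                           test_pos=test_pos)
    assert not set(neg) & set(pos)          # a negative is never a known link
    by_mirna = Counter(i for i, _ in neg)
    print(f"\n{strategy}: drew {len(neg)} negatives "
          f"across {len(by_mirna)} miRNAs")
    if strategy == "SCM":
        need = Counter(i for i, _ in test_pos)
        print("  per-miRNA draws match per-miRNA test-positive counts:",
              all(by_mirna[i] == c for i, c in need.items()))

# unbalanced task: 20 negatives per positive, looping over entities
neg20 = sample_negatives(A, 20 * len(test_pos), strategy="SCM", seed=1,
                         test_pos=test_pos)
print(f"\nunbalanced draw: {len(neg20)} negatives "
      f"(= 20 x {len(test_pos)} positives)")
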