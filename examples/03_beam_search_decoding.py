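"""Beam-search decoding from a seed sequence, with exhaustive cross-check.

Uses a tiny untrained model so the exhaustive enumeration over all 4^L
extensions is feasible; the width-4^L beam must find exactly the same
best-scoring extension.
"""

import itertools
import math

import numpy as np

from gaplm import (
    ModelConfig,
    NucleotideSequence,
    PredictionConfig,
    beam_search,
    build_model,
    decode,
    encode,
)

model = build_model(ModelConfig(embedding_dim=8, recurrent_units=12), seed=1)
seed = NucleotideSequence("seed", "ACGTTGCAAC")
L = 4

top = beam_search(model, seed, PredictionConfig(prediction_length=L, beam_width=4**L))[0]

best_ext, best_score = None, -math.inf
for ext in itertools.product(range(4), repeat=L):
    ctx, score = list(encode(seed)), 0.0
    for b in ext:
        score += math.log(model.next_base_distribution(np.array(ctx))[b])
        ctx.append(b)
    if score > best_score:
        best_ext, best_score = ext, score

print(f"beam search best:  {top.bases}  log-probability {top.log_prob:.6f}")
print(f"exhaustive best:   {decode(best_ext).bases}  log-probability {best_score:.6f}")
# The two lines agree: with a full-width beam, beam search is exact.
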