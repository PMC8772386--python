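"""The alignment metrics on a controlled example.

A query built as an exact copy of a 200 bp target with 10 substitutions
aligns full-length: identity 95%, coverage 100%, correctness 95%.
"""

import numpy as np

from gaplm import NucleotideSequence, align_local, compute_metrics

rng = np.random.default_rng(0)
target = NucleotideSequence("target", "".join(rng.choice(list("ACGT"), size=200)))
mutated = list(target.bases)
for pos in rng.choice(200, size=10, replace=False):
    mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
query = NucleotideSequence("query", "".join(mutated))

aln = align_local(query, target)
m = compute_metrics(aln, query_gap_extent=len(query), target_length=len(target))

print(f"aligned columns: {aln.aligned_columns}, matches: {aln.matches}, "
      f"score: {aln.score:.0f}")
print(f"identity {m.percent_identity:.2f}%  target coverage {m.target_coverage:.2f}%")
print(f"target correctness {m.target_correctness:.2f}% "
      "(= identity x coverage / 100)")
# Correctness aggregates accuracy and completeness; it is the score the
# reference-free pass/fail rule thresholds at 70%.
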