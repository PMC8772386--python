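# Methods

## Problem and model

A scaffold gap is a run of unknown bases between two assembled flanks.
`gaplm` fills one gap at a time by treating the locus as a tiny language
modelling problem: the paired-end reads recruited to the gap's flanks are
a dense, redundant sample of the local sequence (fragments longer than the
gap bridge it), so a next-base predictor trained on those reads encodes
the gap even though the gap itself was never assembled.

The model is deliberately minimal: an index-lookup embedding of the four
bases (an index lookup is mathematically equivalent to a dense projection
of one-hot vectors), a single unidirectional LSTM whose state is zeroed at
the start of every sequence, and a dense layer mapping the final LSTM
state to 4 logits normalised by a softmax. One prediction is made per
context (the k→k+1 task); no dropout, gradient clipping, or learning-rate
schedule is used. Training minimises categorical cross-entropy with Adam.

Because no deep-learning framework is part of the dependency set, the
network is implemented directly in NumPy: forward pass, backpropagation
through time, and the Adam update. Parameters and activations are float32
with the input projection batched across timesteps into single GEMMs;
predictive distributions are emitted in float64 (softmax taken in
float64), so a model with zeroed output weights yields exactly (¼,¼,¼,¼)
and closed-form loss identities hold to near machine precision. All
randomness flows from explicit seeds; repeated runs on one machine are
bit-identical.

## Training cycle

Per iteration: sample `batch_size` reads uniformly with replacement from
the strand-augmented corpus (every read and its reverse complement); draw
k uniformly from [k_low, k_high] with k_high = (shortest sampled read
length) − 1 — the −1 makes the sampled (k+1)-mer fit exactly; take one
uniformly-positioned (k+1)-mer per read; update on predicting the final
base from the first k. Within a batch all contexts therefore have uniform
length. Reads shorter than k_low + 1 are retained in the corpus but never
sampled. One global generator seeded from the run seed drives read
choice, k, and positions, in that order.

An *epoch* is `steps_per_epoch` iterations; since sampling is with
replacement the epoch has no canonical size, the default is roughly one
pass over the strand-augmented data:
⌈2·(total read bases) / (batch_size · mean read length)⌉.

The validation loss scores the model's ability to continue the gap's own
flanks: for each of the four sequences (two flanks × two strands) of
length f, the cross-entropy of predicting base x+1 from the first x bases
is summed over x ∈ [k_low, f−1], and the grand total is divided by the sum
of the lengths of the four evaluated sequences. The denominator counts
each evaluated sequence once; this is the main numeric convention choice
in the validation loss, and an alternative divisor (scored positions) is
available via `TrainingConfig.validation_denominator`. Early stopping
halts after `patience` epochs without improvement and restores the best
epoch's parameters.

## Prediction

Beam search, seeded by the left flank (forward) or the reverse complement
of the right flank (reverse). Every surviving candidate is extended by
all four bases and scored by cumulative natural-log probability; the top
`beam_width` survive. Exactly `prediction_length` bases are emitted — the
gap's end is found later by alignment, not by a stop symbol — and each
candidate's LSTM state is carried incrementally, so the seed is consumed
once. Ties break deterministically: score, then parent rank, then base
order A<C<G<T; under a uniform model a width-1 beam returns the
lexicographically first extension. Scores are accumulated in float64 and
equal the re-scored sum of per-step log-probabilities to <1e-9.

## Validation and extraction

The reference-free pass rule aligns the first 100 bp of the reciprocal
flank (the probe; truncated with a warning if the flank is shorter) as
alignment *target* against the predicted bases as *query*, and computes
target correctness = identity × target-coverage / 100 with the probe
length as denominator. Pass requires correctness strictly over the
threshold (default 70%). The probe's query-start delimits the gap; a
probe aligning at position 0 yields a legal zero-length gap (abutting
flanks). Reverse-direction gaps are reverse-complemented so all reported
gaps are forward-strand. Between directions, a passing prediction always
beats a failing one — with local alignment a near-empty spurious hit can
carry 100% identity while covering almost none of the probe, so raw
identity alone is uninformative across statuses — then higher
reciprocal-alignment identity wins; ties prefer forward.

Local pairwise alignment uses an affine gap model (match +5, mismatch −4,
gap open −12, gap extend −4, all configurable; `gap_open` is the first
gap column's score). The dynamic programming is delegated to
Biopython's `PairwiseAligner`; determinism comes from reporting the first
optimal alignment of its fixed traversal order. The test suite verifies
scores against an independent brute-force Gotoh dynamic program.

## Synthetic data

The simulator generates what the real pipeline would extract from an
assembly: i.i.d. background sequence at a configurable GC content, a
central gap with optional tandem repeat (to make repeat-laden, hard
cases), flanks of configurable length, and paired-end reads from
normally-distributed fragments placed uniformly, with per-base
substitution errors. Recruitment is emulated by keeping read pairs whose
fragment overlaps the flank+gap window. It does **not** model indel
errors, quality-score structure, non-uniform coverage, adapter artefacts,
or genome-scale repeat families; passing tests on simulated loci
demonstrate the machinery end to end, not performance on real draft
assemblies.

## Scales and numerical choices

Shipped defaults are full-scale: embedding 128, 512 LSTM units, batch
128, ≤1000 epochs, patience 200, k_low 52, 750-base predictions at beam
width 64, 100 bp probe, 70% threshold. The test battery runs scaled-down
study conditions chosen once as a realistic desk-scale analogue:

- *End-to-end recovery*: 1.5 kb region, 30 bp gap, 200 bp flanks,
  error-free 100 bp pairs at 60×, a 32/64 model, beam width 16,
  prediction length 150.
- *Hard cases* for pass/fail discrimination add tandem repeats in the gap
  and low (8×) coverage.
- *Memorization*: a 16/32 model on one 60 bp read, 500 batches of random
  (k+1)-mers, k ∈ [52, 59].

Small models train poorly at the full-scale Adam step of 1e-3; desk-scale
configurations use 1e-2 (2e-2 for the single-read memorization check),
chosen as part of the scaled-down conditions. The learning rate is an
explicit `ModelConfig` field; all other Adam settings are the standard
defaults (β₁ 0.9, β₂ 0.999, ε 1e-8).

Degenerate inputs: flanks containing N are rejected; reads containing N
are dropped with a logged count (the model's alphabet has exactly four
letters); empty read sets and corpora with no read longer than k_low are
training errors; an empty local alignment yields all-zero metrics,
flagged by convention.

## Known limitations

Per-gap training cost dominates; the design trains one disposable model
per gap and cannot amortise across gaps. Prediction quality decays with
distance from the seed flank, so gaps approaching the read fragment
length are out of reach. Uniform-length batches bias each iteration to a
single context length. The aligner reports one optimal alignment; co-optimal
tracebacks are not enumerated.
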