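"""Shared protocols for the verification battery.

These define the scaled-down study conditions used both by the acceptance
tests and by scripts/acceptance.py: exact beam-search equivalence checks,
the independent alignment dynamic program, single-read memorization, and
end-to-end recovery of simulated gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaplm import (
    AlignmentScoring,
    ModelConfig,
    NucleotideSequence,
    PredictionConfig,
    RunConfig,
    SimulationConfig,
    TrainingConfig,
    align_local,
    beam_search,
    build_model,
    decode,
    encode,
    fill_gap,
    make_gap_case,
)
from gaplm.pipeline import evaluate_prediction


# --------------------------------------------------------------------- #
# beam search vs exhaustive enumeration
# --------------------------------------------------------------------- #
def exhaustive_best_extension(model, seed_seq, length):
    """Score ALL 4^length extensions by summed log next-base probability.

    Full breadth-first enumeration with no pruning and no tie logic: every
    extension is kept at every level and the single argmax is taken at the
    end, making this an independent oracle for beam search.
    """
    h, c = model.consume(encode(seed_seq))
    paths = np.zeros((1, 0), dtype=np.int64)
    scores = np.zeros(1)
    for _ in range(length):
        n = paths.shape[0]
        dist = model.output_distribution((h, c))
        scores = (scores[:, None] + np.log(dist)).ravel()
        paths = np.concatenate(
            [np.repeat(paths, 4, axis=0), np.tile(np.arange(4), n)[:, None]], axis=1
        )
        h = np.repeat(h, 4, axis=0)
        c = np.repeat(c, 4, axis=0)
        h, c = model.step((h, c), paths[:, -1])
    best = int(np.argmax(scores))
    return decode(paths[best]).bases, float(scores[best])


def beam_matches_exhaustive(model, seed_seq, length, tol=1e-9):
    cfg = PredictionConfig(prediction_length=length, beam_width=4**length)
    top = beam_search(model, seed_seq, cfg)[0]
    bases, score = exhaustive_best_extension(model, seed_seq, length)
    return top.bases == bases and abs(top.log_prob - score) < tol


# --------------------------------------------------------------------- #
# independent affine-gap local alignment score (Gotoh)
# --------------------------------------------------------------------- #
def bruteforce_affine_local_score(q: str, t: str, s: AlignmentScoring) -> float:
    n, m = len(q), len(t)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[:, 0] = M[0, :] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = s.match if q[i - 1] == t[j - 1] else s.mismatch
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0) + sub
            Ix[i, j] = max(M[i - 1, j] + s.gap_open, Ix[i - 1, j] + s.gap_extend)
            Iy[i, j] = max(M[i, j - 1] + s.gap_open, Iy[i, j - 1] + s.gap_extend)
            best = max(best, M[i, j], Ix[i, j], Iy[i, j])
    return best


def aligner_agreement_rate(n_pairs: int, rng: np.random.Generator) -> float:
    """Fraction of random short pairs where the aligner score equals the
    brute-force dynamic program."""
    scoring = AlignmentScoring()
    agree = 0
    for _ in range(n_pairs):
        q = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
        t = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
        expected = max(bruteforce_affine_local_score(q, t, scoring), 0.0)
        got = align_local(
            NucleotideSequence("q", q), NucleotideSequence("t", t), scoring
        ).score
        agree += abs(got - expected) < 1e-9
    return agree / n_pairs


# --------------------------------------------------------------------- #
# single-read memorization
# --------------------------------------------------------------------- #
def memorization_min_probability(read_seed: int, steps: int = 500) -> float:
    """Min next-base probability along one 60 bp read after 500 batches of
    its random (k+1)-mers, k in [52, 59]; 16/32 model, Adam 2e-2."""
    rng = np.random.default_rng(read_seed)
    read = rng.integers(0, 4, size=60)
    model = build_model(
        ModelConfig(embedding_dim=16, recurrent_units=32, learning_rate=2e-2),
        seed=5,
    )
    srng = np.random.default_rng(read_seed)
    for _ in range(steps):
        k = int(srng.integers(52, 60))
        starts = srng.integers(0, 60 - k, size=128)
        ctx = np.array([read[s : s + k] for s in starts])
        model.training_step(ctx, read[starts + k])
    dists = model.stepwise_distributions(read[np.newaxis, :-1])[0]
    return float(dists[np.arange(52, 60) - 1, read[52:]].min())


# --------------------------------------------------------------------- #
# end-to-end recovery on simulated gaps
# --------------------------------------------------------------------- #
@dataclass
class GapRun:
    """Outcome of one simulate→fill→compare run."""

    status: str
    truth_identity: float
    reciprocal_correctness: float
    gap_length: int


def easy_case_config(seed: int) -> SimulationConfig:
    """The scaled-down easy locus: error-free, well covered."""
    return SimulationConfig(
        region_length=1500, gap_length=30, flank_length=200, read_length=100,
        fragment_mean=300, fragment_sd=30.0, coverage_depth=60.0,
        substitution_error_rate=0.0, seed=seed,
    )


def hard_case_config(seed: int, kind: str) -> SimulationConfig:
    """Repeat-laden or coverage-starved loci the model should fail on."""
    if kind == "low_coverage":
        return SimulationConfig(
            region_length=1500, gap_length=30, flank_length=200,
            read_length=100, fragment_mean=300, fragment_sd=30.0,
            coverage_depth=8.0, substitution_error_rate=0.01, seed=seed,
        )
    # repeat: tandem repeat fills the gap and coverage is thin
    return SimulationConfig(
        region_length=1500, gap_length=48, flank_length=200, read_length=100,
        fragment_mean=300, fragment_sd=30.0, coverage_depth=10.0,
        substitution_error_rate=0.01, repeat_unit_length=6, repeat_copies=8,
        seed=seed,
    )


def desk_scale_run_config(seed: int, max_epochs: int) -> RunConfig:
    return RunConfig(
        model=ModelConfig(embedding_dim=32, recurrent_units=64, learning_rate=1e-2),
        training=TrainingConfig(batch_size=128, k_low=52, max_epochs=max_epochs,
                                patience=max_epochs, seed=seed),
        prediction=PredictionConfig(prediction_length=150, beam_width=16),
        seed=seed,
    )


def run_gap(sim_cfg: SimulationConfig, run_cfg: RunConfig) -> GapRun:
    """Simulate, fill, and score the extracted gap against the truth."""
    case = make_gap_case(sim_cfg)
    outcome = fill_gap(case.flanks, case.reads, run_cfg)
    result = outcome.result
    if len(result.gap_sequence) == 0 or len(case.truth_gap) == 0:
        identity = 100.0 if len(result.gap_sequence) == len(case.truth_gap) else 0.0
    else:
        identity = evaluate_prediction(
            result.gap_sequence, case.truth_gap
        ).percent_identity
    return GapRun(
        status=result.status,
        truth_identity=identity,
        reciprocal_correctness=result.reciprocal_correctness,
        gap_length=len(result.gap_sequence),
    )
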