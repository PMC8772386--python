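"""Beam-search gap prediction seeded by a flank, in both orientations.

The trained model extends a seed sequence base by base. At every step each
surviving candidate is extended by all four bases and scored by its
cumulative natural-log probability; the ``beam_width`` best extensions
survive. Exactly ``prediction_length`` bases are emitted — long enough to
cover the gap and run into the reciprocal flank, whose alignment later
delimits the gap — and the recurrent state of each candidate is carried
incrementally so the seed is consumed only once.

Ties in cumulative score are broken deterministically: higher score first,
then lower parent rank, then base order A<C<G<T. Under a uniform model a
width-1 beam therefore yields the lexicographically first extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelState
from .sequences import FlankPair, NucleotideSequence, decode, encode, reverse_complement

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class PredictionConfig:
    """Beam-search settings: bases to emit and beam width."""

    prediction_length: int = 750
    beam_width: int = 64

    def __post_init__(self) -> None:
        if self.prediction_length < 1 or self.beam_width < 1:
            raise ValueError("prediction_length and beam_width must be >= 1")


@dataclass(frozen=True)
class BeamCandidate:
    """One decoded extension (seed excluded) and its cumulative log-probability."""

    bases: str
    log_prob: float


@dataclass
class GapPrediction:
    """A directional prediction: the seed flank and the ranked beam output."""

    direction: str  # FORWARD (seeded by left flank) or REVERSE (by rc of right)
    seed: NucleotideSequence
    best: BeamCandidate
    runners_up: list[BeamCandidate] = field(default_factory=list)


def beam_search(
    model: ModelState, seed: NucleotideSequence, cfg: PredictionConfig
) -> list[BeamCandidate]:
    """Extend ``seed`` by ``cfg.prediction_length`` bases, beam-width-limited.

    Returns candidates sorted by descending cumulative log-probability.
    """
    if len(seed) == 0:
        raise ValueError("beam search requires a non-empty seed sequence")
    h, c = model.consume(encode(seed))

    W = cfg.beam_width
    A = model.config.alphabet_size
    # live beam: (n, step) base-index paths, scores, recurrent states
    paths = np.zeros((1, 0), dtype=np.int64)
    scores = np.zeros(1)
    for _ in range(cfg.prediction_length):
        n = paths.shape[0]
        dist = model.output_distribution((h, c))  # (n, 4)
        cand_scores = (scores[:, None] + np.log(dist + 1e-300)).ravel()  # n*4
        parent = np.repeat(np.arange(n), A)
        base = np.tile(np.arange(A), n)
        # primary: score desc; ties: parent rank asc, then base A<C<G<T
        order = np.lexsort((base, parent, -cand_scores))[: min(W, n * A)]
        parent, base, scores = parent[order], base[order], cand_scores[order]
        paths = np.concatenate([paths[parent], base[:, None]], axis=1)
        h, c = model.step((h[parent], c[parent]), base)

    candidates = [
        BeamCandidate(decode(paths[i]).bases, float(scores[i]))
        for i in range(paths.shape[0])
    ]
    return candidates


def predict_gap_both_directions(
    model: ModelState,
    flanks: FlankPair,
    cfg: PredictionConfig,
    keep_candidates: int = 1,
) -> tuple[GapPrediction, GapPrediction]:
    """Predict the gap seeded by each flank.

    The forward prediction continues the left flank on the forward strand;
    the reverse prediction continues the reverse complement of the right
    flank, i.e. walks into the gap from the other side on the opposite
    strand. One direction may be predicted better than the other, so both
    are returned for downstream validation and selection.
    """
    results = []
    seeds = [
        (FORWARD, flanks.left_flank),
        (REVERSE, reverse_complement(flanks.right_flank)),
    ]
    for direction, seed in seeds:
        ranked = beam_search(model, seed, cfg)
        results.append(
            GapPrediction(
                direction=direction,
                seed=seed,
                best=ranked[0],
                runners_up=ranked[1:keep_candidates],
            )
        )
    return results[0], results[1]
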