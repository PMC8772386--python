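"""Reference-free pass/fail validation, gap extraction, and best-of-two
selection.

A prediction that walked from one flank through the gap should eventually
reproduce the *reciprocal* flank — the flank on the far side of the gap.
Since both flanks are known, this gives a validation signal that needs no
reference genome: align the first ``reciprocal_prefix_length`` bases of
the reciprocal flank (the probe, as alignment target) into the predicted
bases (as query). The prediction **passes** if the probe's correctness
(identity × target coverage) is strictly greater than ``pass_threshold``.
The probe's alignment start also marks where the gap ends inside the
prediction, so the gap sequence is the prediction prefix up to that point.
Of the two directional predictions, the one whose reciprocal alignment has
the higher identity is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alignment import (
    AlignmentMetrics,
    AlignmentScoring,
    PairwiseAlignment,
    align_local,
    compute_metrics,
)
from .beam import FORWARD, REVERSE, GapPrediction
from .sequences import FlankPair, NucleotideSequence, reverse_complement

logger = logging.getLogger(__name__)

PASS = "pass"
FAIL = "fail"


@dataclass(frozen=True)
class ValidationConfig:
    """Probe length (bases of reciprocal flank) and the pass threshold (%)."""

    reciprocal_prefix_length: int = 100
    pass_threshold: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.pass_threshold <= 100):
            raise ValueError("pass_threshold must be in (0, 100]")
        if self.reciprocal_prefix_length < 1:
            raise ValueError("reciprocal_prefix_length must be >= 1")


@dataclass
class GapFillResult:
    """The validated, extracted gap for one scaffold gap (forward strand)."""

    gap_id: str
    status: str  # PASS or FAIL
    chosen_direction: str
    gap_sequence: NucleotideSequence
    reciprocal_correctness: float
    reciprocal_identity: float
    alignment: PairwiseAlignment


def reciprocal_probe(
    direction: str, flanks: FlankPair, cfg: ValidationConfig
) -> NucleotideSequence:
    """First ``reciprocal_prefix_length`` bases of the reciprocal flank,
    oriented to continue the prediction's strand."""
    if direction == FORWARD:
        recip = flanks.right_flank
    elif direction == REVERSE:
        recip = reverse_complement(flanks.left_flank)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    n = cfg.reciprocal_prefix_length
    if n > len(recip):
        logger.warning(
            "reciprocal probe (%d bp) longer than flank (%d bp); truncating",
            n,
            len(recip),
        )
        n = len(recip)
    return recip.slice(0, n, id_suffix=f":probe_{direction}")


def classify_prediction(
    pred: GapPrediction,
    flanks: FlankPair,
    cfg: ValidationConfig = ValidationConfig(),
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[str, PairwiseAlignment, AlignmentMetrics]:
    """Pass/fail the prediction by its reciprocal-flank probe alignment.

    The probe is the target, the predicted bases the query; correctness is
    computed with the probe length as the target length. Pass requires
    correctness strictly over the threshold.
    """
    if len(pred.best.bases) < 1:
        raise ValueError("prediction has no bases to validate")
    probe = reciprocal_probe(pred.direction, flanks, cfg)
    query = NucleotideSequence(f"{flanks.gap_id}:{pred.direction}", pred.best.bases)
    aln = align_local(query, probe, scoring)
    metrics = compute_metrics(
        aln, query_gap_extent=max(1, len(query)), target_length=len(probe)
    )
    status = PASS if metrics.target_correctness > cfg.pass_threshold else FAIL
    return status, aln, metrics


def extract_gap(
    pred: GapPrediction, reciprocal_alignment: PairwiseAlignment
) -> NucleotideSequence:
    """Prediction prefix up to the reciprocal-flank alignment start.

    Reverse-direction gaps are reverse-complemented so every reported gap
    sequence is on the scaffold's forward strand. A probe aligning at
    query position 0 legally yields an empty gap (abutting flanks).
    """
    if reciprocal_alignment.is_empty:
        raise ValueError("cannot extract a gap from an empty reciprocal alignment")
    end = reciprocal_alignment.query_span[0]
    if end == 0:
        logger.info("reciprocal flank aligns at prediction start: zero-length gap")
    gap = NucleotideSequence(f"{pred.seed.id}:gap", pred.best.bases[:end])
    if pred.direction == REVERSE:
        gap = reverse_complement(gap)
    return gap


def select_best(
    forward_result: "DirectionalResult", reverse_result: "DirectionalResult"
) -> "DirectionalResult":
    """Keep the better directional prediction.

    A passing direction always beats a failing one: identity alone is
    uninformative when the reciprocal alignment is a short spurious match
    (a 10-column perfect local hit scores 100% identity while covering
    almost none of the probe). Between directions of equal status the
    higher reciprocal-alignment identity wins; ties go forward.
    """
    f_key = (forward_result.status == PASS, forward_result.metrics.percent_identity)
    r_key = (reverse_result.status == PASS, reverse_result.metrics.percent_identity)
    return reverse_result if r_key > f_key else forward_result


@dataclass
class DirectionalResult:
    """One direction's classification, bundled for selection/reporting."""

    prediction: GapPrediction
    status: str
    alignment: PairwiseAlignment
    metrics: AlignmentMetrics
    gap_sequence: NucleotideSequence | None


def evaluate_direction(
    pred: GapPrediction,
    flanks: FlankPair,
    cfg: ValidationConfig = ValidationConfig(),
    scoring: AlignmentScoring = AlignmentScoring(),
) -> DirectionalResult:
    """Classify one directional prediction and extract its gap if possible."""
    status, aln, metrics = classify_prediction(pred, flanks, cfg, scoring)
    gap = extract_gap(pred, aln) if not aln.is_empty else None
    return DirectionalResult(pred, status, aln, metrics, gap)


def validate_and_select(
    forward_pred: GapPrediction,
    reverse_pred: GapPrediction,
    flanks: FlankPair,
    cfg: ValidationConfig = ValidationConfig(),
    scoring: AlignmentScoring = AlignmentScoring(),
) -> tuple[GapFillResult, DirectionalResult, DirectionalResult]:
    """Full per-gap validation: classify both directions, pick the better."""
    fwd = evaluate_direction(forward_pred, flanks, cfg, scoring)
    rev = evaluate_direction(reverse_pred, flanks, cfg, scoring)
    chosen = select_best(fwd, rev)
    gap_seq = chosen.gap_sequence
    if gap_seq is None:  # no reciprocal alignment at all: report full prediction, failed
        bases = chosen.prediction.best.bases
        gap_seq = NucleotideSequence(f"{flanks.gap_id}:gap", bases)
        if chosen.prediction.direction == REVERSE:
            gap_seq = reverse_complement(gap_seq)
    result = GapFillResult(
        gap_id=flanks.gap_id,
        status=chosen.status,
        chosen_direction=chosen.prediction.direction,
        gap_sequence=NucleotideSequence(f"{flanks.gap_id}:gap", gap_seq.bases),
        reciprocal_correctness=chosen.metrics.target_correctness,
        reciprocal_identity=chosen.metrics.percent_identity,
        alignment=chosen.alignment,
    )
    return result, fwd, rev
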