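"""Local pairwise alignment and the identity/coverage/correctness metrics.

Predictions are validated by locally aligning sequences — a prediction
against the reciprocal-flank probe, or against a reference gap — under an
affine gap model (Smith-Waterman-style), then summarising the alignment
with four percentages:

- **identity**: matches / aligned columns (gap columns included) × 100
- **target coverage**: target bases aligned / target length × 100
- **query coverage**: query bases aligned / predicted-gap extent × 100
- **correctness**: identity × coverage / 100, per side

Correctness aggregates accuracy and completeness in one number and doubles
as the confidence score of the reference-free pass/fail rule. The dynamic
programming itself is delegated to ``Bio.Align.PairwiseAligner``; the first
optimal alignment of its deterministic traversal is reported, so outputs
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .sequences import NucleotideSequence


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine local alignment scores.

    ``gap_open`` is the score of the first column of a gap, ``gap_extend``
    of each subsequent column. Defaults mimic a conventional affine
    local model (+5/−4, −12 to open, −4 to extend) and are configurable.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -12.0
    gap_extend: float = -4.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local alignment summary. Coordinates are 0-based half-open."""

    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_columns: int
    matches: int
    query_aligned: int  # query bases inside aligned blocks (gaps excluded)
    target_aligned: int
    score: float

    @property
    def is_empty(self) -> bool:
        return self.aligned_columns == 0


@dataclass(frozen=True)
class AlignmentMetrics:
    percent_identity: float
    target_coverage: float
    query_coverage: float
    target_correctness: float
    query_correctness: float


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_local(
    query: NucleotideSequence,
    target: NucleotideSequence,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseAlignment:
    """Optimal local alignment of ``query`` against ``target``.

    Returns an empty alignment (zero columns) when no positive-scoring
    local alignment exists.
    """
    if len(query) == 0 or len(target) == 0:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(scoring)
    alignments = aligner.align(target.bases, query.bases)
    empty = PairwiseAlignment(
        query.id, target.id, (0, 0), (0, 0), 0, 0, 0, 0, 0.0
    )
    if len(alignments) == 0:
        return empty
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0 or aln.score <= 0:
        return empty

    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        t_seg = target.bases[ts:te]
        q_seg = query.bases[qs:qe]
        matches += sum(a == b for a, b in zip(t_seg, q_seg))
    # internal gap columns between consecutive blocks
    for i in range(len(t_blocks) - 1):
        columns += int(t_blocks[i + 1][0] - t_blocks[i][1])
        columns += int(q_blocks[i + 1][0] - q_blocks[i][1])

    target_aligned = int(sum(te - ts for ts, te in t_blocks))
    query_aligned = int(sum(qe - qs for qs, qe in q_blocks))
    return PairwiseAlignment(
        query_id=query.id,
        target_id=target.id,
        query_span=(int(q_blocks[0][0]), int(q_blocks[-1][1])),
        target_span=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
        aligned_columns=int(columns),
        matches=int(matches),
        query_aligned=query_aligned,
        target_aligned=target_aligned,
        score=float(aln.score),
    )


def compute_metrics(
    aln: PairwiseAlignment, query_gap_extent: int, target_length: int
) -> AlignmentMetrics:
    """The four validation percentages for one alignment.

    ``target_length`` is the full reference-side length; ``query_gap_extent``
    is the number of prediction bases from the start of the predicted gap
    to its inferred end (computed by the caller from the gap and
    reciprocal-flank alignments). An empty alignment yields all zeros.
    """
    if query_gap_extent < 1 or target_length < 1:
        raise ValueError("query_gap_extent and target_length must be >= 1")
    if aln.is_empty:
        return AlignmentMetrics(0.0, 0.0, 0.0, 0.0, 0.0)
    identity = 100.0 * aln.matches / aln.aligned_columns
    target_cov = 100.0 * aln.target_aligned / target_length
    query_cov = 100.0 * aln.query_aligned / query_gap_extent
    return AlignmentMetrics(
        percent_identity=identity,
        target_coverage=target_cov,
        query_coverage=query_cov,
        target_correctness=identity * target_cov / 100.0,
        query_correctness=identity * query_cov / 100.0,
    )
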