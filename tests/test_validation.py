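"""Reference-free pass/fail heuristic, gap extraction, and selection."""

import numpy as np
import pytest

from gaplm import (
    FlankPair,
    NucleotideSequence,
    ValidationConfig,
    classify_prediction,
    extract_gap,
    reverse_complement,
    select_best,
)
from gaplm.beam import FORWARD, REVERSE, BeamCandidate, GapPrediction
from gaplm.validation import DirectionalResult, evaluate_direction, reciprocal_probe

from conftest import random_sequence


def _flanks(rng, n=120, gap_id="g"):
    return FlankPair(
        gap_id,
        random_sequence(rng, n, f"{gap_id}_left"),
        random_sequence(rng, n, f"{gap_id}_right"),
    )


def _pred(direction, bases, seed=None):
    seed = seed or NucleotideSequence("seed", "ACGT")
    return GapPrediction(direction, seed, BeamCandidate(bases, -1.0))


class TestClassify:
    def test_exact_probe_containment_passes(self):
        rng = np.random.default_rng(0)
        flanks = _flanks(rng)
        probe = flanks.right_flank.bases[:100]
        bases = random_sequence(rng, 60, "pad").bases + probe
        status, aln, metrics = classify_prediction(_pred(FORWARD, bases), flanks)
        assert status == "pass"
        assert metrics.percent_identity == 100.0
        assert metrics.target_coverage == 100.0
        assert metrics.target_correctness == 100.0
        assert aln.query_span[0] == 60

    def test_reverse_direction_probe_is_rc_of_left_flank(self):
        rng = np.random.default_rng(1)
        flanks = _flanks(rng)
        probe = reverse_complement(flanks.left_flank).bases[:100]
        bases = random_sequence(rng, 40, "pad").bases + probe
        status, aln, _ = classify_prediction(_pred(REVERSE, bases), flanks)
        assert status == "pass"
        assert aln.query_span[0] == 40

    def test_random_prediction_almost_never_passes(self):
        """Monte-Carlo: an unrelated 750-base prediction passes against a
        random 100 bp probe in well under 5% of cases."""
        passes = 0
        trials = 60
        for s in range(trials):
            rng = np.random.default_rng(1000 + s)
            flanks = _flanks(rng)
            bases = random_sequence(rng, 750, "rand").bases
            status, _, _ = classify_prediction(_pred(FORWARD, bases), flanks)
            passes += status == "pass"
        assert passes / trials < 0.05

    def test_threshold_is_strict_inequality(self):
        rng = np.random.default_rng(2)
        flanks = _flanks(rng)
        bases = "ACGT" * 15 + flanks.right_flank.bases[:100]
        cfg = ValidationConfig(pass_threshold=100.0)
        status, _, metrics = classify_prediction(_pred(FORWARD, bases), flanks, cfg)
        assert metrics.target_correctness == 100.0
        assert status == "fail"  # 100 is not strictly over 100

    def test_probe_truncated_to_short_flank(self):
        rng = np.random.default_rng(3)
        flanks = FlankPair(
            "g",
            random_sequence(rng, 120, "l"),
            random_sequence(rng, 40, "r"),
        )
        probe = reciprocal_probe(FORWARD, flanks, ValidationConfig())
        assert probe.bases == flanks.right_flank.bases

    def test_classification_uses_no_truth_sequence(self):
        import inspect

        sig = inspect.signature(classify_prediction)
        assert not any("truth" in p or "reference" in p for p in sig.parameters)


class TestExtract:
    def test_gap_is_prediction_prefix_up_to_probe_start(self):
        rng = np.random.default_rng(4)
        flanks = _flanks(rng)
        gap = random_sequence(rng, 50, "gap").bases
        bases = gap + flanks.right_flank.bases[:100] + random_sequence(rng, 20, "t").bases
        pred = _pred(FORWARD, bases)
        _, aln, _ = classify_prediction(pred, flanks)
        extracted = extract_gap(pred, aln)
        assert extracted.bases == gap

    def test_reverse_direction_gap_is_reverse_complemented(self):
        rng = np.random.default_rng(5)
        flanks = _flanks(rng)
        gap = random_sequence(rng, 50, "gap").bases
        probe = reverse_complement(flanks.left_flank).bases[:100]
        pred = _pred(REVERSE, gap + probe)
        _, aln, _ = classify_prediction(pred, flanks)
        extracted = extract_gap(pred, aln)
        assert extracted.bases == reverse_complement(NucleotideSequence("g", gap)).bases

    def test_probe_at_position_zero_gives_legal_empty_gap(self):
        rng = np.random.default_rng(6)
        flanks = _flanks(rng)
        pred = _pred(FORWARD, flanks.right_flank.bases[:100])
        _, aln, _ = classify_prediction(pred, flanks)
        assert extract_gap(pred, aln).bases == ""


class TestSelect:
    def _result(self, direction, identity, status="pass"):
        from gaplm.alignment import AlignmentMetrics, PairwiseAlignment

        return DirectionalResult(
            prediction=_pred(direction, "ACGT"),
            status=status,
            alignment=PairwiseAlignment("q", "t", (0, 4), (0, 4), 4, 4, 4, 4, 20.0),
            metrics=AlignmentMetrics(identity, 100.0, 100.0, identity, identity),
            gap_sequence=NucleotideSequence("g", "ACGT"),
        )

    @pytest.mark.parametrize(
        "fwd_id,rev_id,expected",
        [(98.0, 80.0, FORWARD), (80.0, 98.0, REVERSE), (90.0, 90.0, FORWARD)],
    )
    def test_higher_reciprocal_identity_wins_ties_forward(self, fwd_id, rev_id, expected):
        chosen = select_best(self._result(FORWARD, fwd_id), self._result(REVERSE, rev_id))
        assert chosen.prediction.direction == expected

    def test_passing_direction_beats_failing_despite_higher_identity(self):
        # a short spurious local hit can carry 100% identity; it must not
        # displace a passing full-probe alignment
        fwd = self._result(FORWARD, 96.0, status="pass")
        rev = self._result(REVERSE, 100.0, status="fail")
        assert select_best(fwd, rev).prediction.direction == FORWARD
        assert select_best(rev, fwd).prediction.direction == FORWARD


def test_evaluate_direction_bundles_gap_and_metrics():
    rng = np.random.default_rng(8)
    flanks = _flanks(rng)
    gap = random_sequence(rng, 30, "gap").bases
    pred = _pred(FORWARD, gap + flanks.right_flank.bases[:100])
    res = evaluate_direction(pred, flanks)
    assert res.status == "pass"
    assert res.gap_sequence.bases == gap
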