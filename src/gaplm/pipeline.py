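"""End-to-end per-gap workflows: fill (train → predict → validate →
extract → select) and reference-based evaluation."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AlignmentMetrics, align_local, compute_metrics
from .beam import predict_gap_both_directions
from .config import RunConfig
from .model import build_model
from .sequences import (
    FlankPair,
    NucleotideSequence,
    ReadSet,
    read_flanks,
    read_reads,
    write_fasta,
)
from .training import TrainingHistory, train
from .validation import DirectionalResult, GapFillResult, validate_and_select

logger = logging.getLogger(__name__)


@dataclass
class FillOutcome:
    result: GapFillResult
    forward: DirectionalResult
    reverse: DirectionalResult
    history: TrainingHistory


def fill_gap(flanks: FlankPair, reads: ReadSet, cfg: RunConfig) -> FillOutcome:
    """Train a fresh per-gap model and produce the validated gap sequence."""
    usable = reads.drop_ambiguous()
    if len(usable) == 0:
        raise ValueError("no usable (N-free) reads to train on")
    model = build_model(cfg.model, cfg.seed)
    rng = np.random.default_rng(cfg.training.seed or cfg.seed)
    history = train(model, usable, flanks, cfg.training, rng)
    fwd_pred, rev_pred = predict_gap_both_directions(model, flanks, cfg.prediction)
    result, fwd, rev = validate_and_select(
        fwd_pred, rev_pred, flanks, cfg.validation, cfg.scoring
    )
    return FillOutcome(result, fwd, rev, history)


def _direction_report(res: DirectionalResult) -> dict:
    return {
        "direction": res.prediction.direction,
        "status": res.status,
        "log_prob": res.prediction.best.log_prob,
        "metrics": dataclasses.asdict(res.metrics),
    }


def run_fill(
    flanks_path: str | Path,
    reads_path: str | Path,
    cfg: RunConfig,
    outdir: str | Path,
) -> FillOutcome:
    """File-based fill: read inputs, run :func:`fill_gap`, write artifacts.

    Writes ``predictions.fa`` (both directional predictions, seed +
    predicted bases), ``gap.fa`` (the selected forward-strand gap),
    ``training_log.tsv`` and ``report.json`` into ``outdir``.
    """
    flanks = read_flanks(flanks_path)
    reads = read_reads(reads_path)
    outcome = fill_gap(flanks, reads, cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    preds = []
    for res in (outcome.forward, outcome.reverse):
        p = res.prediction
        preds.append(
            NucleotideSequence(
                f"{flanks.gap_id}:{p.direction}", p.seed.bases + p.best.bases
            )
        )
    write_fasta(outdir / "predictions.fa", preds)
    write_fasta(outdir / "gap.fa", [outcome.result.gap_sequence])

    with open(outdir / "training_log.tsv", "w") as fh:
        fh.write("epoch\ttraining_loss\tvalidation_loss\tbest\n")
        h = outcome.history
        for i, (tl, vl) in enumerate(zip(h.training_loss, h.validation_loss), 1):
            fh.write(f"{i}\t{tl:.6f}\t{vl:.6f}\t{int(i == h.best_epoch)}\n")

    report = {
        "gap_id": outcome.result.gap_id,
        "status": outcome.result.status,
        "direction": outcome.result.chosen_direction,
        "gap_length": len(outcome.result.gap_sequence),
        "reciprocal_identity": outcome.result.reciprocal_identity,
        "reciprocal_correctness": outcome.result.reciprocal_correctness,
        "directions": [
            _direction_report(outcome.forward),
            _direction_report(outcome.reverse),
        ],
        "training": {
            "best_epoch": outcome.history.best_epoch,
            "stopped_epoch": outcome.history.stopped_epoch,
            "best_validation_loss": outcome.history.best_validation_loss,
        },
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return outcome


def evaluate_prediction(
    prediction: NucleotideSequence,
    truth_gap: NucleotideSequence,
    truth_reciprocal_flank: NucleotideSequence | None = None,
    scoring=None,
    probe_length: int = 100,
) -> AlignmentMetrics:
    """Reference-based metrics for one prediction.

    Aligns the prediction to the true gap sequence; the predicted-gap
    extent for query coverage ends at the furthest query position reached
    by either the gap alignment or the start of the reciprocal-flank
    alignment, when a truth flank is supplied.
    """
    from .alignment import AlignmentScoring

    scoring = scoring or AlignmentScoring()
    if len(truth_gap) == 0:
        raise ValueError("empty truth gap")
    gap_aln = align_local(prediction, truth_gap, scoring)
    extent = gap_aln.query_span[1] if not gap_aln.is_empty else len(prediction)
    if truth_reciprocal_flank is not None:
        probe = truth_reciprocal_flank.slice(0, probe_length)
        recip_aln = align_local(prediction, probe, scoring)
        if not recip_aln.is_empty:
            extent = max(extent, recip_aln.query_span[0])
    extent = max(1, extent)
    return compute_metrics(gap_aln, query_gap_extent=extent, target_length=len(truth_gap))


def run_evaluate(
    predictions_path: str | Path,
    truth_gap_path: str | Path,
    out_tsv: str | Path,
    scoring=None,
) -> list[dict]:
    """Evaluate every predicted sequence in a FASTA against a truth gap.

    Writes a TSV of the four metrics per record and returns the rows.
    """
    from Bio import SeqIO

    truth_records = list(SeqIO.parse(str(truth_gap_path), "fasta"))
    if not truth_records or len(truth_records[0].seq) == 0:
        raise ValueError(f"{truth_gap_path}: empty truth gap")
    truth = NucleotideSequence(truth_records[0].id, str(truth_records[0].seq))
    from .alignment import AlignmentScoring

    scoring = scoring or AlignmentScoring()
    rows = []
    for rec in SeqIO.parse(str(predictions_path), "fasta"):
        pred = NucleotideSequence(rec.id, str(rec.seq))
        m = evaluate_prediction(pred, truth, scoring=scoring)
        aln = align_local(pred, truth, scoring)
        rows.append(
            {
                "query": pred.id,
                "target": truth.id,
                # spans 1-based inclusive for the human-readable report
                "query_span": f"{aln.query_span[0] + 1}-{aln.query_span[1]}",
                "target_span": f"{aln.target_span[0] + 1}-{aln.target_span[1]}",
                "matches": aln.matches,
                "columns": aln.aligned_columns,
                "score": aln.score,
                **dataclasses.asdict(m),
            }
        )
    with open(out_tsv, "w") as fh:
        cols = [
            "query",
            "target",
            "query_span",
            "target_span",
            "matches",
            "columns",
            "score",
            "percent_identity",
            "target_coverage",
            "query_coverage",
            "target_correctness",
            "query_correctness",
        ]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(f"{r[c]:.3f}" if isinstance(r[c], float) else str(r[c]) for c in cols) + "\n")
    return rows
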