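"""Per-gap model training: stochastic k+1-mer batches, flank validation
loss, and early stopping.

Each training iteration (i) samples a batch of reads uniformly with
replacement from the strand-augmented corpus (every read and its reverse
complement), (ii) draws a context length k uniformly from
``[k_low, k_high]`` where ``k_high`` is one less than the shortest read
sampled into the batch (so a k+1-mer always fits), (iii) extracts one
uniformly-positioned (k+1)-mer per sampled read, and (iv) takes a gradient
step on predicting the final base of each (k+1)-mer from its first k bases.

The validation signal is how well the model predicts the gap flanks
themselves, on both strands: a model that can continue each flank base by
base is likely to have encoded enough context to continue into the gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ModelState
from .sequences import FlankPair, NucleotideSequence, ReadSet, encode, reverse_complement


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyperparameters.

    ``k_low`` is the minimum training context length in bases;
    ``k_high`` is per-batch (shortest sampled read minus one).
    ``steps_per_epoch=None`` means roughly one pass over the
    strand-augmented corpus: ``ceil(2·total read bases / (batch_size ·
    mean read length))``.
    """

    batch_size: int = 128
    k_low: int = 52
    max_epochs: int = 1000
    patience: int = 200
    steps_per_epoch: int | None = None
    seed: int = 0
    validation_denominator: str = "all_sequences"  # or "positions_scored"

    def __post_init__(self) -> None:
        if self.k_low < 1:
            raise ValueError("k_low must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingBatch:
    contexts: np.ndarray  # (batch_size, k) int
    targets: np.ndarray  # (batch_size,) int
    k: int


@dataclass
class TrainingHistory:
    training_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0

    @property
    def best_validation_loss(self) -> float:
        return self.validation_loss[self.best_epoch - 1]


def augment_with_reverse_complements(reads: ReadSet) -> list[NucleotideSequence]:
    """The strand-augmented corpus: every read plus its reverse complement."""
    out: list[NucleotideSequence] = []
    for r in reads:
        out.append(r)
        out.append(reverse_complement(r))
    return out


def sample_training_batch(
    reads: ReadSet | list[NucleotideSequence],
    cfg: TrainingConfig,
    rng: np.random.Generator,
    *,
    _encoded: list[np.ndarray] | None = None,
) -> TrainingBatch:
    """Draw one training batch of (context, target) pairs.

    One random stream drives, in order: read sampling, the choice of k,
    and the k+1-mer positions. Reads shorter than ``k_low + 1`` are
    excluded from sampling (a k+1-mer cannot fit in them).
    """
    if _encoded is None:
        pool = augment_with_reverse_complements(reads) if isinstance(reads, ReadSet) else reads
        _encoded = [encode(r) for r in pool]
    eligible = [e for e in _encoded if e.size >= cfg.k_low + 1]
    if not eligible:
        raise ValueError(
            f"corpus unusable at k_low={cfg.k_low}: no read (either strand) has "
            f"length >= {cfg.k_low + 1}"
        )
    idx = rng.integers(0, len(eligible), size=cfg.batch_size)
    sampled = [eligible[i] for i in idx]
    k_high = min(e.size for e in sampled) - 1
    k = int(rng.integers(cfg.k_low, k_high + 1))
    contexts = np.empty((cfg.batch_size, k), dtype=np.int64)
    targets = np.empty(cfg.batch_size, dtype=np.int64)
    for row, e in enumerate(sampled):
        start = int(rng.integers(0, e.size - k))  # k+1-mer start
        contexts[row] = e[start : start + k]
        targets[row] = e[start + k]
    return TrainingBatch(contexts, targets, k)


def validation_loss(
    model: ModelState,
    flanks: FlankPair,
    k_low: int,
    denominator: str = "all_sequences",
) -> float:
    """Mean cross-entropy of next-base prediction along both flanks, both strands.

    For each of the four sequences (left flank, right flank, and their
    reverse complements) of length f, every prefix of length
    x ∈ [k_low, f−1] is scored on predicting base x+1. The summed loss is
    divided by the total length of the four evaluated sequences
    (``denominator="all_sequences"``) or, alternatively, by the number of
    scored positions (``"positions_scored"``).
    """
    seqs = [
        flanks.left_flank,
        flanks.right_flank,
        reverse_complement(flanks.left_flank),
        reverse_complement(flanks.right_flank),
    ]
    total = 0.0
    denom = 0.0
    for seq in seqs:
        f = len(seq)
        if f <= k_low:
            raise ValueError(
                f"flank {seq.id!r} has length {f} <= k_low={k_low}; nothing to validate"
            )
        e = encode(seq)
        # distribution at prefix length x lives at index x-1
        dists = model.stepwise_distributions(e[np.newaxis, :-1])[0]
        positions = np.arange(k_low, f)  # predict e[x] from first x bases
        p_true = dists[positions - 1, e[positions]]
        total += float(-np.log(p_true + 1e-300).sum())
        denom += f if denominator == "all_sequences" else positions.size
    return total / denom


def default_steps_per_epoch(reads: ReadSet, batch_size: int) -> int:
    total_bases = sum(len(r) for r in reads)
    if total_bases == 0:
        raise ValueError("empty read set")
    mean_len = total_bases / len(reads)
    return max(1, math.ceil(2 * total_bases / (batch_size * mean_len)))


def train(
    model: ModelState,
    reads: ReadSet,
    flanks: FlankPair,
    cfg: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> TrainingHistory:
    """Train with early stopping on flank validation loss.

    After each epoch the validation loss is evaluated; training stops when
    it has not improved for ``patience`` consecutive epochs (or at
    ``max_epochs``), and the parameters of the best epoch are restored.
    """
    if len(reads) == 0:
        raise ValueError("cannot train on an empty read set")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    usable = reads.drop_ambiguous()
    pool = augment_with_reverse_complements(usable)
    encoded = [encode(r) for r in pool]
    steps = cfg.steps_per_epoch or default_steps_per_epoch(usable, cfg.batch_size)

    history = TrainingHistory()
    best_loss = math.inf
    best_params: dict[str, np.ndarray] | None = None
    for epoch in range(1, cfg.max_epochs + 1):
        epoch_losses = []
        for _ in range(steps):
            batch = sample_training_batch(usable, cfg, rng, _encoded=encoded)
            epoch_losses.append(model.training_step(batch.contexts, batch.targets))
        history.training_loss.append(float(np.mean(epoch_losses)))
        val = validation_loss(model, flanks, cfg.k_low, cfg.validation_denominator)
        history.validation_loss.append(val)
        if val < best_loss:
            best_loss = val
            best_params = model.snapshot()
            history.best_epoch = epoch
        history.stopped_epoch = epoch
        if epoch - history.best_epoch >= cfg.patience:
            break
    if best_params is not None:
        model.restore(best_params)
    return history
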