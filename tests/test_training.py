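"""Batch sampling, flank validation loss, and the early-stopping loop."""

import math

import numpy as np
import pytest

from gaplm import (
    FlankPair,
    ModelConfig,
    NucleotideSequence,
    ReadSet,
    TrainingConfig,
    build_model,
    decode,
    sample_training_batch,
    train,
    validation_loss,
)
from gaplm.training import augment_with_reverse_complements, default_steps_per_epoch


def _readset(rng, n, length):
    return ReadSet(
        [
            NucleotideSequence(f"r{i}", "".join(rng.choice(list("ACGT"), size=length)))
            for i in range(n)
        ]
    )


class TestBatchSampling:
    def test_k_range_and_context_shape(self):
        rng = np.random.default_rng(0)
        reads = _readset(rng, 20, 100)
        cfg = TrainingConfig(batch_size=16, k_low=52)
        for _ in range(20):
            b = sample_training_batch(reads, cfg, rng)
            assert 52 <= b.k <= 99
            assert b.contexts.shape == (16, b.k)
            assert b.targets.shape == (16,)

    def test_every_kmer_is_substring_of_read_or_rc(self):
        rng = np.random.default_rng(1)
        reads = _readset(rng, 5, 30)
        corpus = [r.bases for r in augment_with_reverse_complements(reads)]
        cfg = TrainingConfig(batch_size=8, k_low=10)
        for _ in range(25):
            b = sample_training_batch(reads, cfg, rng)
            for row in range(8):
                kmer = decode(b.contexts[row]).bases + decode([b.targets[row]]).bases
                assert any(kmer in s for s in corpus)

    def test_forced_sample_from_minimal_read(self):
        reads = ReadSet([NucleotideSequence("r", "ACGTACGTA")])  # length 9
        cfg = TrainingConfig(batch_size=4, k_low=8)
        rng = np.random.default_rng(0)
        b = sample_training_batch(reads, cfg, rng)
        assert b.k == 8
        for row in range(4):
            kmer = decode(b.contexts[row]).bases + decode([b.targets[row]]).bases
            assert kmer in ("ACGTACGTA", "TACGTACGT")

    def test_sampling_is_uniform_over_strand_augmented_reads(self):
        """Each of 10 reads (20 strand variants) appears with frequency
        0.05 within ±0.01 over many batches."""
        rng = np.random.default_rng(2)
        # distinct reads so occurrences are attributable
        reads = _readset(rng, 10, 40)
        variants = [r.bases for r in augment_with_reverse_complements(reads)]
        cfg = TrainingConfig(batch_size=8, k_low=30)
        counts = np.zeros(20)
        draws = 0
        for _ in range(2500):
            b = sample_training_batch(reads, cfg, rng)
            for row in range(8):
                kmer = decode(b.contexts[row]).bases + decode([b.targets[row]]).bases
                hits = [i for i, s in enumerate(variants) if kmer in s]
                if len(hits) == 1:  # skip ambiguous k-mers
                    counts[hits[0]] += 1
                    draws += 1
        freq = counts / draws
        assert np.all(np.abs(freq - 0.05) < 0.01)

    def test_unusable_corpus_rejected(self):
        reads = ReadSet([NucleotideSequence("r", "ACGT")])
        cfg = TrainingConfig(batch_size=4, k_low=52)
        with pytest.raises(ValueError, match="corpus unusable"):
            sample_training_batch(reads, cfg, np.random.default_rng(0))

    def test_short_reads_excluded_long_reads_used(self):
        reads = ReadSet(
            [NucleotideSequence("short", "ACGT"), NucleotideSequence("long", "A" * 30)]
        )
        cfg = TrainingConfig(batch_size=8, k_low=10)
        b = sample_training_batch(reads, cfg, np.random.default_rng(0))
        # only the poly-A read (or its poly-T reverse complement) is eligible
        for row in range(8):
            assert np.all(b.contexts[row] == 0) or np.all(b.contexts[row] == 3)


class TestValidationLoss:
    def test_uniform_model_closed_form(self, uniform_model, small_flanks):
        # 4 sequences x (100 - 52) scored positions, each -ln(1/4), over
        # the summed length of the four evaluated sequences
        expected = 4 * 48 * math.log(4) / 400
        assert validation_loss(uniform_model, small_flanks, k_low=52) == pytest.approx(
            expected, abs=1e-9
        )

    def test_matches_bruteforce_per_position_rederivation(self, tiny_model, small_flanks):
        from gaplm.sequences import encode, reverse_complement

        k_low = 52
        total = 0.0
        denom = 0
        for seq in (
            small_flanks.left_flank,
            small_flanks.right_flank,
            reverse_complement(small_flanks.left_flank),
            reverse_complement(small_flanks.right_flank),
        ):
            e = encode(seq)
            for x in range(k_low, len(seq)):
                p = tiny_model.next_base_distribution(e[:x])
                total += -math.log(p[e[x]])
            denom += len(seq)
        assert validation_loss(tiny_model, small_flanks, k_low) == pytest.approx(
            total / denom, abs=1e-9
        )

    def test_flank_not_longer_than_k_low_rejected(self, tiny_model):
        flanks = FlankPair(
            "g",
            NucleotideSequence("l", "ACGT" * 10),
            NucleotideSequence("r", "ACGT" * 10),
        )
        with pytest.raises(ValueError):
            validation_loss(tiny_model, flanks, k_low=40)

    def test_positions_scored_denominator_option(self, uniform_model, small_flanks):
        loss = validation_loss(
            uniform_model, small_flanks, k_low=52, denominator="positions_scored"
        )
        assert loss == pytest.approx(math.log(4), abs=1e-9)


class TestTrainLoop:
    def _data(self, seed=0, n=30, length=80):
        rng = np.random.default_rng(seed)
        reads = _readset(rng, n, length)
        flanks = FlankPair(
            "g",
            NucleotideSequence("l", "".join(rng.choice(list("ACGT"), size=70))),
            NucleotideSequence("r", "".join(rng.choice(list("ACGT"), size=70))),
        )
        return reads, flanks

    def test_epoch_bound_respected(self):
        reads, flanks = self._data()
        m = build_model(ModelConfig(embedding_dim=8, recurrent_units=12), 0)
        cfg = TrainingConfig(
            batch_size=8, k_low=40, max_epochs=5, patience=2, steps_per_epoch=2, seed=0
        )
        h = train(m, reads, flanks, cfg)
        assert h.stopped_epoch <= 5
        assert h.stopped_epoch - h.best_epoch <= 2

    def test_constant_validation_loss_stops_after_patience(self, uniform_model):
        reads, flanks = self._data()
        # zeroed output layer + zero learning rate: validation loss frozen
        frozen_cfg = ModelConfig(
            embedding_dim=8, recurrent_units=12, learning_rate=0.0
        )
        m = build_model(frozen_cfg, 0)
        m.params["Wy"][:] = 0.0
        m.params["by"][:] = 0.0
        cfg = TrainingConfig(
            batch_size=4, k_low=40, max_epochs=50, patience=1, steps_per_epoch=1, seed=0
        )
        h = train(m, reads, flanks, cfg)
        assert h.stopped_epoch == 2
        assert h.best_epoch == 1

    def test_restored_parameters_reproduce_best_validation_loss(self):
        reads, flanks = self._data(seed=3)
        m = build_model(ModelConfig(embedding_dim=8, recurrent_units=12), 3)
        cfg = TrainingConfig(
            batch_size=8, k_low=40, max_epochs=8, patience=8, steps_per_epoch=2, seed=3
        )
        h = train(m, reads, flanks, cfg)
        re_evaluated = validation_loss(m, flanks, cfg.k_low)
        assert re_evaluated == pytest.approx(h.best_validation_loss, abs=1e-9)

    def test_learning_progress_on_easy_simulated_data(self, easy_case):
        m = build_model(ModelConfig(embedding_dim=16, recurrent_units=32), 7)
        cfg = TrainingConfig(
            batch_size=32, k_low=52, max_epochs=8, patience=8, seed=7
        )
        h = train(m, easy_case.reads, easy_case.flanks, cfg)
        assert h.best_validation_loss < h.validation_loss[0]

    def test_empty_readset_rejected(self):
        _, flanks = self._data()
        m = build_model(ModelConfig(embedding_dim=8, recurrent_units=12), 0)
        with pytest.raises(ValueError):
            train(m, ReadSet([]), flanks, TrainingConfig(batch_size=4, k_low=40))

    def test_default_steps_per_epoch_is_one_augmented_pass(self):
        rng = np.random.default_rng(0)
        reads = _readset(rng, 64, 100)
        # 2 * 6400 bases / (16 * 100) = 8
        assert default_steps_per_epoch(reads, batch_size=16) == 8


def test_patience_cannot_exceed_max_epochs():
    with pytest.raises(ValueError):
        TrainingConfig(max_epochs=10, patience=20)
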