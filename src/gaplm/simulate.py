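"""Synthetic gap fixtures: a genomic region with a known gap and
error-bearing paired-end reads spanning its flanks.

The generator emulates the situation the gap filler faces in a draft
assembly: a region of i.i.d. background sequence at a chosen GC content,
a central interval declared "unknown" (the gap) bordered by two known
flanks, and paired-end reads sampled from sequencing fragments placed
uniformly over the region. Fragments longer than the gap let read pairs
bridge it, which is exactly the regime in which flank-trained language
models can recover gap sequence. An optional tandem repeat can be written
into the gap to create repeat-laden, harder cases, and coverage and
substitution error rate are configurable so both easy and hard corpora can
be produced. Read recruitment is emulated by keeping only pairs that
overlap the flank+gap interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequences import (
    ALPHABET,
    FlankPair,
    NucleotideSequence,
    ReadSet,
    reverse_complement,
    write_fasta,
    write_fastq,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated gap case (lengths in bases).

    Defaults are a small-scale case: a 2 kb region with a 50 bp gap and
    250 bp flanks, 100 bp paired reads from 300±30 bp fragments at 50×
    coverage, error-free. Real gap sets would use longer (500 bp) flanks;
    the geometry here is identical, just shorter.
    """

    region_length: int = 2000
    gap_length: int = 50
    flank_length: int = 250
    read_length: int = 100
    fragment_mean: int = 300
    fragment_sd: float = 30.0
    coverage_depth: float = 50.0
    substitution_error_rate: float = 0.0
    gc_content: float = 0.5
    repeat_unit_length: int | None = None
    repeat_copies: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_length + 2 * self.flank_length > self.region_length:
            raise ValueError("gap + both flanks must fit inside the region")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed the mean fragment length")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if (self.repeat_unit_length is None) != (self.repeat_copies is None):
            raise ValueError("repeat_unit_length and repeat_copies go together")


@dataclass
class SimulatedGapCase:
    """One generated fixture: the ground truth plus the gap filler's inputs."""

    truth_region: NucleotideSequence
    truth_gap: NucleotideSequence
    flanks: FlankPair
    reads: ReadSet
    manifest: dict


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(rng.choice(list(ALPHABET), size=n, p=probs))


def simulate_region(cfg: SimulationConfig, rng: np.random.Generator) -> NucleotideSequence:
    """I.i.d. background at the stated GC content, with an optional tandem
    repeat written into the gap interval."""
    bases = list(_random_bases(cfg.region_length, cfg.gc_content, rng))
    if cfg.repeat_unit_length is not None:
        unit = _random_bases(cfg.repeat_unit_length, cfg.gc_content, rng)
        tandem = unit * cfg.repeat_copies
        gap_start = (cfg.region_length - cfg.gap_length) // 2
        if len(tandem) > cfg.gap_length:
            raise ValueError("tandem repeat does not fit inside the gap")
        offset = gap_start + (cfg.gap_length - len(tandem)) // 2
        bases[offset : offset + len(tandem)] = tandem
    return NucleotideSequence("region", "".join(bases))


def _inject_errors(read: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return read
    flip = rng.random(read.size) < rate
    if flip.any():
        read = read.copy()
        # substitute with one of the three other bases, uniformly
        read[flip] = (read[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
    return read


def simulate_reads(
    region: NucleotideSequence, cfg: SimulationConfig, rng: np.random.Generator
) -> ReadSet:
    """Paired-end reads from fragments placed uniformly over the region.

    Each fragment yields a forward read from its 5' end and a
    reverse-complemented read from its 3' end; substitutions are injected
    per base at the configured rate.
    """
    from .sequences import encode, decode

    n_fragments = int(round(cfg.coverage_depth * cfg.region_length / (2 * cfg.read_length)))
    if n_fragments < 1:
        raise ValueError("coverage too low: zero fragments")
    encoded = encode(region)
    reads: list[NucleotideSequence] = []
    for i in range(n_fragments):
        frag_len = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
        frag_len = max(cfg.read_length, min(frag_len, cfg.region_length))
        start = int(rng.integers(0, cfg.region_length - frag_len + 1))
        frag = encoded[start : start + frag_len]
        r1 = _inject_errors(frag[: cfg.read_length], cfg.substitution_error_rate, rng)
        r2_fwd = frag[-cfg.read_length :]
        r2 = _inject_errors(r2_fwd, cfg.substitution_error_rate, rng)
        reads.append(decode(r1, id=f"frag{i}/1"))
        reads.append(reverse_complement(decode(r2, id=f"frag{i}/2")))
    pairing = {f"frag{i}/1": f"frag{i}/2" for i in range(n_fragments)}
    return ReadSet(reads, pairing)


def _fragment_span(read_id: str) -> str:
    return read_id.split("/")[0]


def make_gap_case(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedGapCase:
    """Generate one gap case: region, truth gap, flanks, recruited reads.

    Reads are kept only if their pair's fragment overlaps the
    flank+gap interval, emulating recruitment of reads mapping to the
    flanks. Deterministic given ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    region = simulate_region(cfg, rng)
    gap_start = (cfg.region_length - cfg.gap_length) // 2
    gap_end = gap_start + cfg.gap_length
    left = region.slice(gap_start - cfg.flank_length, gap_start)
    right = region.slice(gap_end, gap_end + cfg.flank_length)
    truth_gap = region.slice(gap_start, gap_end)

    all_reads = simulate_reads(region, cfg, rng)
    window = (gap_start - cfg.flank_length, gap_end + cfg.flank_length)
    kept: list[NucleotideSequence] = []
    # a read pair is recruited when its fragment intersects the window;
    # fragment extent is recovered from the simulated positions
    positions = _read_positions(region, all_reads, cfg)
    for i in range(0, len(all_reads.reads), 2):
        r1, r2 = all_reads.reads[i], all_reads.reads[i + 1]
        span = positions[i // 2]
        if span[0] < window[1] and span[1] > window[0]:
            kept.extend([r1, r2])
    flanks = FlankPair(
        f"gap_seed{cfg.seed}",
        NucleotideSequence(f"gap_seed{cfg.seed}_left", left.bases),
        NucleotideSequence(f"gap_seed{cfg.seed}_right", right.bases),
    )
    manifest = dataclasses.asdict(cfg)
    manifest.update(
        gap_start=gap_start,
        gap_end=gap_end,
        n_reads_total=len(all_reads),
        n_reads_recruited=len(kept),
    )
    return SimulatedGapCase(
        truth_region=region,
        truth_gap=NucleotideSequence(f"gap_seed{cfg.seed}_truth", truth_gap.bases),
        flanks=flanks,
        reads=ReadSet(kept),
        manifest=manifest,
    )


def _read_positions(
    region: NucleotideSequence, reads: ReadSet, cfg: SimulationConfig
) -> list[tuple[int, int]]:
    """Fragment spans, reconstructed from paired read placement.

    Simulation retains no side channel: spans are recomputed by locating
    each fragment's 5' read in the region. With substitution errors the
    exact locate can fail; those pairs fall back to a window around the
    best guess being 'unknown' and are kept (recruitment errs inclusive).
    """
    spans: list[tuple[int, int]] = []
    n_pairs = len(reads.reads) // 2
    for i in range(n_pairs):
        r1 = reads.reads[2 * i]
        r2 = reads.reads[2 * i + 1]
        pos1 = region.bases.find(r1.bases)
        rc2 = reverse_complement(r2).bases
        pos2 = region.bases.find(rc2)
        if pos1 >= 0 and pos2 >= 0:
            spans.append((pos1, pos2 + len(rc2)))
        elif pos1 >= 0:
            spans.append((pos1, pos1 + cfg.fragment_mean))
        elif pos2 >= 0:
            spans.append((pos2 + len(rc2) - cfg.fragment_mean, pos2 + len(rc2)))
        else:
            spans.append((0, len(region)))  # unplaceable: recruit it
    return spans


def write_gap_case(case: SimulatedGapCase, outdir: str | Path) -> dict[str, Path]:
    """Write flanks.fa, reads.fq, truth_gap.fa, truth_region.fa, manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "flanks": outdir / "flanks.fa",
        "reads": outdir / "reads.fq",
        "truth_gap": outdir / "truth_gap.fa",
        "truth_region": outdir / "truth_region.fa",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(paths["flanks"], [case.flanks.left_flank, case.flanks.right_flank])
    write_fastq(paths["reads"], case.reads)
    write_fasta(paths["truth_gap"], [case.truth_gap])
    write_fasta(paths["truth_region"], [case.truth_region])
    paths["manifest"].write_text(json.dumps(case.manifest, indent=2) + "\n")
    return paths
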