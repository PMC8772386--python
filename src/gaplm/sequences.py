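"""Nucleotide sequences, strand operations, base encoding, and FASTA/FASTQ I/O.

Sequences are kept as plain uppercase strings over ``{A, C, G, T, N}``.
The model itself works on the four-letter alphabet; ``N`` is tolerated in
input sequences but must be resolved (reads dropped, flanks rejected)
before anything reaches the encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
ALPHABET_WITH_N = "ACGTN"

#: Canonical base encoding: A→0, C→1, G→2, T→3.
BASE_INDEX = {base: i for i, base in enumerate(ALPHABET)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA sequence in canonical uppercase form.

    Parameters
    ----------
    id
        Free-text label (FASTA/FASTQ record id).
    bases
        Sequence over ``{A, C, G, T, N}``. Lowercase input is uppercased;
        any other character raises :class:`SequenceAlphabetError` with the
        offending position.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        upper = self.bases.upper()
        for pos, ch in enumerate(upper):
            if ch not in ALPHABET_WITH_N:
                raise SequenceAlphabetError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {pos}"
                )
        object.__setattr__(self, "bases", upper)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def has_n(self) -> bool:
        return "N" in self.bases

    def slice(self, start: int, stop: int, id_suffix: str = "") -> "NucleotideSequence":
        return NucleotideSequence(self.id + id_suffix, self.bases[start:stop])


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Return the opposite-strand sequence, 5'→3' (reverse order, complemented).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    ``N`` complements to ``N``.
    """
    return NucleotideSequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1])


def encode(seq: NucleotideSequence) -> np.ndarray:
    """Encode bases as integer indices A→0, C→1, G→2, T→3.

    The sequence must be N-free: callers resolve N (drop the read or reject
    the flank) before encoding.
    """
    if seq.has_n:
        raise SequenceAlphabetError(
            f"sequence {seq.id!r} contains N; resolve ambiguous bases before "
            "encoding (reads with N are dropped, flanks with N are rejected)"
        )
    arr = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.int64)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def decode(indices: Iterable[int], id: str = "") -> NucleotideSequence:
    """Inverse of :func:`encode`."""
    return NucleotideSequence(id, "".join(ALPHABET[i] for i in indices))


@dataclass(frozen=True)
class FlankPair:
    """The two known sequences bordering one scaffold gap, forward strand.

    ``left_flank`` ends where the gap begins; ``right_flank`` begins where
    the gap ends.
    """

    gap_id: str
    left_flank: NucleotideSequence
    right_flank: NucleotideSequence

    def __post_init__(self) -> None:
        for name, flank in (("left", self.left_flank), ("right", self.right_flank)):
            if len(flank) == 0:
                raise ValueError(f"{name} flank of gap {self.gap_id!r} is empty")
            if flank.has_n:
                raise SequenceAlphabetError(
                    f"{name} flank of gap {self.gap_id!r} contains N; "
                    "flanks must be unambiguous"
                )


@dataclass
class ReadSet:
    """Recruited reads used as the training corpus for one gap.

    Mate pairing is retained only as an optional association; the language
    model treats every read (and its reverse complement) independently.
    """

    reads: list[NucleotideSequence] = field(default_factory=list)
    pairing: dict[str, str] | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.reads)

    def drop_ambiguous(self) -> "ReadSet":
        """Return a copy without N-containing reads (logged)."""
        kept = [r for r in self.reads if not r.has_n]
        dropped = len(self.reads) - len(kept)
        if dropped:
            logger.info("dropped %d/%d reads containing N", dropped, len(self.reads))
        return ReadSet(kept, self.pairing)

    def length_range(self) -> tuple[int, int]:
        lengths = [len(r) for r in self.reads]
        return (min(lengths), max(lengths)) if lengths else (0, 0)


def read_flanks(path: str | Path, gap_id: str | None = None) -> FlankPair:
    """Load a two-record FASTA file of gap flanks.

    Record order defines orientation: the first record is the left flank,
    the second the right flank. Record ids are free text; lowercase bases
    are uppercased.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"{path}: expected 2 flanks (left then right), found {len(records)} records"
        )
    left, right = (NucleotideSequence(r.id, str(r.seq)) for r in records)
    if gap_id is None:
        gap_id = left.id.rsplit("_", 1)[0] if "_" in left.id else left.id
    return FlankPair(gap_id, left, right)


def read_reads(path: str | Path) -> ReadSet:
    """Load a FASTQ file of recruited paired-end reads.

    Quality scores are parsed (the format requires them) and ignored — the
    model never uses them. Malformed records raise ``ValueError``.
    """
    reads = [NucleotideSequence(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]
    rs = ReadSet(reads)
    if reads:
        lo, hi = rs.length_range()
        logger.info("loaded %d reads from %s (length %d-%d)", len(reads), path, lo, hi)
    else:
        logger.warning("loaded 0 reads from %s", path)
    return rs


def write_fasta(path: str | Path, seqs: Iterable[NucleotideSequence]) -> None:
    """Write sequences as FASTA, wrapped at 80 columns."""
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def write_fastq(path: str | Path, seqs: Iterable[NucleotideSequence], quality_char: str = "I") -> None:
    """Write reads as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f"@{s.id}\n{s.bases}\n+\n{quality_char * len(s)}\n")
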