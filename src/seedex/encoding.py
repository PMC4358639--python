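"""Packed 3-bit DNA sequence encoding and FASTA/FASTQ ingestion.

Sequences are stored as 21 three-bit symbols per 64-bit word (bit 63 unused),
packed from low-order to high-order bits.  The symbol codes are::

    A = 0b100   C = 0b101   G = 0b110   T = 0b111   N = 0b000

For the four bases the high bit is set and the low two bits are the
conventional 2-bit code (A=00, C=01, G=10, T=11).  N is all-zero so that an
N never matches any base (nor another N) under bitwise comparison.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

SYMBOLS_PER_WORD = 21

CODE_A = 0b100
CODE_C = 0b101
CODE_G = 0b110
CODE_T = 0b111
CODE_N = 0b000

_CODE_OF = np.zeros(256, dtype=np.uint8)
for _c, _v in (("A", CODE_A), ("C", CODE_C), ("G", CODE_G), ("T", CODE_T), ("N", CODE_N)):
    _CODE_OF[ord(_c)] = _v
    _CODE_OF[ord(_c.lower())] = _v
_VALID = np.zeros(256, dtype=bool)
for _c in "ACGTNacgtn":
    _VALID[ord(_c)] = True

# codes 0b001..0b011 are unassigned; they decode as N
_SYM_OF = np.array([ord(c) for c in "NNNNACGT"], dtype=np.uint8)

_SHIFTS = (np.arange(SYMBOLS_PER_WORD, dtype=np.uint64) * np.uint64(3))


class EncodingError(ValueError):
    """Input contains a symbol outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class PackedSequence:
    """A DNA sequence packed 21 symbols per 64-bit word.

    ``words`` is the canonical packed representation; ``codes`` is the
    per-symbol 3-bit code array kept alongside for fast symbol access.
    Unused high bits of the final word are always zero, so word-level
    equality coincides with sequence equality.
    """

    words: tuple[int, ...]
    length: int
    codes: np.ndarray = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        expect = -(-self.length // SYMBOLS_PER_WORD)
        if len(self.words) != expect:
            raise ValueError(f"{len(self.words)} words for length {self.length}; expected {expect}")

    def __len__(self) -> int:
        return self.length

    def __str__(self) -> str:
        return decode(self)


def _pack(codes: np.ndarray) -> tuple[int, ...]:
    n = codes.size
    nwords = -(-n // SYMBOLS_PER_WORD)
    padded = np.zeros(nwords * SYMBOLS_PER_WORD, dtype=np.uint64)
    padded[:n] = codes
    grid = padded.reshape(nwords, SYMBOLS_PER_WORD) << _SHIFTS
    return tuple(int(w) for w in grid.sum(axis=1, dtype=np.uint64))


def from_codes(codes: np.ndarray) -> PackedSequence:
    """Build a PackedSequence from an array of 3-bit symbol codes."""
    codes = np.ascontiguousarray(codes, dtype=np.uint8)
    return PackedSequence(words=_pack(codes), length=int(codes.size), codes=codes)


def encode(sequence: str) -> PackedSequence:
    """Encode a DNA string over {A,C,G,T,N} (case-insensitive).

    Symbol ``i`` occupies bits ``[3*(i%21), 3*(i%21)+2]`` of word ``i//21``.

    Raises
    ------
    EncodingError
        If a symbol outside the alphabet occurs; the message names the
        0-based position of the first offender.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = np.nonzero(~_VALID[raw])[0]
    if bad.size:
        pos = int(bad[0])
        raise EncodingError(f"invalid symbol {sequence[pos]!r} at position {pos}")
    return from_codes(_CODE_OF[raw])


def decode(seq: PackedSequence) -> str:
    """Decode back to an uppercase DNA string (unassigned codes decode as N)."""
    return _SYM_OF[seq.codes].tobytes().decode("ascii")


_COMPLEMENT = np.array([0, 0, 0, 0, CODE_T, CODE_G, CODE_C, CODE_A], dtype=np.uint8)


def reverse_complement(seq: PackedSequence) -> PackedSequence:
    """Reverse complement (N stays N); an involution that preserves length."""
    return from_codes(_COMPLEMENT[seq.codes[::-1]])


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[tuple[str, PackedSequence]]:
    """Read a (possibly gzipped, multi-record) FASTA file.

    Records are returned in file order; their list index is the subId used
    throughout the index and aligner.
    """
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                out.append((rec.id, encode(str(rec.seq))))
            except EncodingError as exc:
                raise EncodingError(f"{path}: record {rec.id}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def read_fastq(path) -> Iterator[tuple[str, PackedSequence, str]]:
    """Stream (name, PackedSequence, Phred+33 quality string) from FASTQ."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            try:
                yield rec.id, encode(str(rec.seq)), qual
            except EncodingError as exc:
                raise EncodingError(f"{path}: record {rec.id}: {exc}") from exc


def write_fasta(records: list[tuple[str, PackedSequence]], path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            s = decode(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(records: list[tuple[str, PackedSequence, str]], path) -> None:
    with open(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{decode(seq)}\n+\n{qual}\n")
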