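"""Seed definitions and lookup-key computation.

Two seed families are used:

* :class:`SpacedSeed` — a periodic spaced seed (gapped q-gram).  The default
  repeats the 7-bit pattern ``0010111`` across a span of 84 positions; a
  candidate locus must match the read at every "care" position (pattern
  bit 1) but may mismatch freely elsewhere.  Probed at 7 adjacent read
  offsets this seed detects every nongapped mapping with up to two
  mismatches (verified exhaustively by :func:`sensitivity`).
* :class:`ContigSeed` — a contiguous k-mer (default 20-mer) used by the
  gapped aligner.

Both produce 30-bit lookup keys via MurmurHash3 with a fixed hash seed that
is recorded in the index header so index and aligner always agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .encoding import SYMBOLS_PER_WORD, PackedSequence
from .hashing import murmur3_32, murmur3_32_batch

DEFAULT_PATTERN = "0010111"
DEFAULT_SPAN = 84
DEFAULT_KEY_WIDTH = 30
DEFAULT_HASH_SEED = 0x5EED1E57  # arbitrary fixed constant, stored in the index header
DEFAULT_CONTIG_LENGTH = 20


def care_positions(pattern: str, span: int) -> list[int]:
    """0-based offsets within ``span`` where the periodically repeated
    ``pattern`` has bit 1."""
    if not pattern or any(c not in "01" for c in pattern):
        raise ValueError(f"pattern must be a nonempty bit string, got {pattern!r}")
    period = len(pattern)
    return [p for p in range(span) if pattern[p % period] == "1"]


@dataclass(frozen=True)
class SpacedSeed:
    pattern: str = DEFAULT_PATTERN
    span: int = DEFAULT_SPAN
    key_width: int = DEFAULT_KEY_WIDTH
    hash_seed: int = DEFAULT_HASH_SEED
    care: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        if self.span < len(self.pattern):
            raise ValueError("span must be at least one pattern period")
        if not 0 < self.key_width <= 32:
            raise ValueError("key_width must be in (0, 32]")
        object.__setattr__(self, "care", tuple(care_positions(self.pattern, self.span)))

    @property
    def key_mask(self) -> int:
        return (1 << self.key_width) - 1


@dataclass(frozen=True)
class ContigSeed:
    length: int = DEFAULT_CONTIG_LENGTH
    key_width: int = DEFAULT_KEY_WIDTH
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self):
        if not 0 < self.length <= 31:
            raise ValueError("contiguous seed length must be in (0, 31]")

    @property
    def span(self) -> int:
        return self.length

    @property
    def key_mask(self) -> int:
        return (1 << self.key_width) - 1


def spaced_keys(codes: np.ndarray, offsets: np.ndarray, seed: SpacedSeed) -> tuple[np.ndarray, np.ndarray]:
    """Lookup keys for a spaced seed at each of ``offsets`` into a code array.

    Returns ``(keys, valid)``; ``valid[i]`` is False when an N occurs at any
    care position (no key is emitted for that offset).  The key is a
    function of exactly the care-position symbols: the 3-bit codes at the
    care offsets are hashed (one byte per symbol) and truncated to
    ``key_width`` bits.
    """
    offsets = np.asarray(offsets, dtype=np.int64)
    if offsets.size == 0:
        return np.empty(0, dtype=np.uint32), np.empty(0, dtype=bool)
    if offsets.min() < 0 or offsets.max() + seed.span > codes.size:
        raise ValueError("seed offset out of range")
    care = np.asarray(seed.care, dtype=np.int64)
    rows = codes[offsets[:, None] + care[None, :]]
    valid = ~(rows == 0).any(axis=1)
    keys = murmur3_32_batch(rows, seed.hash_seed) & np.uint32(seed.key_mask)
    return keys, valid


def spaced_key(seq: PackedSequence, offset: int, seed: SpacedSeed) -> int | None:
    """Key at a single offset, or None when an N masks a care position."""
    keys, valid = spaced_keys(seq.codes, np.array([offset]), seed)
    return int(keys[0]) if valid[0] else None


def _pack_rows(rows: np.ndarray) -> np.ndarray:
    """Pack (n, L) 3-bit code rows into little-endian packed-word bytes."""
    n, L = rows.shape
    nwords = -(-L // SYMBOLS_PER_WORD)
    padded = np.zeros((n, nwords * SYMBOLS_PER_WORD), dtype=np.uint64)
    padded[:, :L] = rows
    shifts = (np.arange(SYMBOLS_PER_WORD, dtype=np.uint64) * np.uint64(3))
    words = (padded.reshape(n, nwords, SYMBOLS_PER_WORD) << shifts).sum(axis=2, dtype=np.uint64)
    return np.ascontiguousarray(words.astype("<u8")).view(np.uint8).reshape(n, nwords * 8)


def contig_keys(codes: np.ndarray, offsets: np.ndarray, seed: ContigSeed) -> tuple[np.ndarray, np.ndarray]:
    """Lookup keys for a contiguous seed at each of ``offsets``.

    The seed symbols are packed into 64-bit words (21 symbols/word) and the
    little-endian bytes are hashed with MurmurHash3, truncated to
    ``key_width`` bits.  Offsets whose seed contains an N are invalid.
    """
    offsets = np.asarray(offsets, dtype=np.int64)
    if offsets.size == 0:
        return np.empty(0, dtype=np.uint32), np.empty(0, dtype=bool)
    if offsets.min() < 0 or offsets.max() + seed.length > codes.size:
        raise ValueError("seed offset out of range")
    rows = codes[offsets[:, None] + np.arange(seed.length)[None, :]]
    valid = ~(rows == 0).any(axis=1)
    packed = _pack_rows(rows)
    keys = murmur3_32_batch(packed, seed.hash_seed) & np.uint32(seed.key_mask)
    return keys, valid


def contig_key(seq: PackedSequence, offset: int, seed: ContigSeed) -> int | None:
    keys, valid = contig_keys(seq.codes, np.array([offset]), seed)
    return int(keys[0]) if valid[0] else None


def contig_key_bytes(data: bytes, seed: ContigSeed) -> int:
    """Key from already-packed seed bytes (header/test plumbing)."""
    return murmur3_32(data, seed.hash_seed) & seed.key_mask


def _offset_masks(seed: SpacedSeed, n_offsets: int) -> list[int]:
    """Per probe offset, a bitmask over read positions of its care set."""
    masks = []
    for off in range(n_offsets):
        m = 0
        for p in seed.care:
            m |= 1 << (off + p)
        masks.append(m)
    return masks


def sensitivity(seed: SpacedSeed, read_len: int, k: int, n_offsets: int) -> float:
    """Fraction of k-mismatch placements detected by ``n_offsets`` adjacent probes.

    Exhaustive: every placement of k mismatch positions within the read is
    enumerated; a placement is detected iff some probe offset has no
    mismatch at any of its care positions.
    """
    if n_offsets < 1:
        raise ValueError("n_offsets must be >= 1")
    if seed.span + n_offsets - 1 > read_len:
        raise ValueError("probe offsets exceed read length")
    if k == 0:
        return 1.0
    masks = _offset_masks(seed, n_offsets)
    total = 0
    detected = 0
    for placement in combinations(range(read_len), k):
        m = 0
        for p in placement:
            m |= 1 << p
        total += 1
        if any((om & m) == 0 for om in masks):
            detected += 1
    return detected / total


def max_fully_sensitive_mismatches(
    seed: SpacedSeed, read_len: int, n_offsets: int, k_max: int = 4
) -> int:
    """Largest k for which ``sensitivity(..., k, n_offsets) == 1.0``."""
    best = 0
    for k in range(1, k_max + 1):
        if sensitivity(seed, read_len, k, n_offsets) == 1.0:
            best = k
        else:
            break
    return best
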