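"""MurmurHash3 (x86, 32-bit) — scalar and numpy-vectorised over fixed-width rows.

The 32-bit variant with a fixed hash seed is used for all lookup keys;
keys are truncated to the configured key width (30 bits by default).
"""

from __future__ import annotations

import numpy as np

_MASK32 = 0xFFFFFFFF
_C1 = 0xCC9E2D51
_C2 = 0x1B873593


def _rotl32(x: int, r: int) -> int:
    return ((x << r) | (x >> (32 - r))) & _MASK32


def murmur3_32(data: bytes, seed: int = 0) -> int:
    """MurmurHash3 x86_32 of ``data`` with the given hash seed."""
    h = seed & _MASK32
    n = len(data)
    nblocks = n // 4
    for i in range(nblocks):
        k = int.from_bytes(data[4 * i : 4 * i + 4], "little")
        k = (k * _C1) & _MASK32
        k = _rotl32(k, 15)
        k = (k * _C2) & _MASK32
        h ^= k
        h = _rotl32(h, 13)
        h = (h * 5 + 0xE6546B64) & _MASK32
    k = 0
    tail = data[nblocks * 4 :]
    for i in range(len(tail) - 1, -1, -1):
        k = (k << 8) | tail[i]
    if tail:
        k = (k * _C1) & _MASK32
        k = _rotl32(k, 15)
        k = (k * _C2) & _MASK32
        h ^= k
    h ^= n
    h ^= h >> 16
    h = (h * 0x85EBCA6B) & _MASK32
    h ^= h >> 13
    h = (h * 0xC2B2AE35) & _MASK32
    h ^= h >> 16
    return h


def _vrotl32(x: np.ndarray, r: int) -> np.ndarray:
    return (x << np.uint32(r)) | (x >> np.uint32(32 - r))


def murmur3_32_batch(rows: np.ndarray, seed: int = 0) -> np.ndarray:
    """MurmurHash3 x86_32 of every row of a (n, L) uint8 array.

    Equivalent to ``murmur3_32(row.tobytes(), seed)`` per row.
    """
    rows = np.ascontiguousarray(rows, dtype=np.uint8)
    n, L = rows.shape
    with np.errstate(over="ignore"):
        h = np.full(n, seed & _MASK32, dtype=np.uint32)
        c1 = np.uint32(_C1)
        c2 = np.uint32(_C2)
        nblocks = L // 4
        if nblocks:
            blocks = rows[:, : nblocks * 4].view("<u4").reshape(n, nblocks)
            for i in range(nblocks):
                k = blocks[:, i] * c1
                k = _vrotl32(k, 15)
                k = k * c2
                h ^= k
                h = _vrotl32(h, 13)
                h = h * np.uint32(5) + np.uint32(0xE6546B64)
        tail = rows[:, nblocks * 4 :]
        if tail.shape[1]:
            k = np.zeros(n, dtype=np.uint32)
            for i in range(tail.shape[1] - 1, -1, -1):
                k = (k << np.uint32(8)) | tail[:, i].astype(np.uint32)
            k = k * c1
            k = _vrotl32(k, 15)
            k = k * c2
            h ^= k
        h ^= np.uint32(L)
        h ^= h >> np.uint32(16)
        h = h * np.uint32(0x85EBCA6B)
        h ^= h >> np.uint32(13)
        h = h * np.uint32(0xC2B2AE35)
        h ^= h >> np.uint32(16)
    return h
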