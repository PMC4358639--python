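"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package implementation: the
alignment oracle is a textbook full-matrix Gotoh recurrence, the list
oracles use plain set/sort/interval logic.
"""

from __future__ import annotations


def gotoh_local_score(a: str, b: str, match: int = 2, mismatch: int = -6,
                      gap_open: int = -5, gap_extend: int = -3) -> int:
    """Best local alignment score under affine gaps (full-matrix DP)."""
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def best_terminal_clip(per_position_scores) -> int:
    """Best score over all (left clip, right clip) choices, exhaustively."""
    n = len(per_position_scores)
    prefix = [0]
    for s in per_position_scores:
        prefix.append(prefix[-1] + s)
    best = 0
    for lo in range(n + 1):
        for hi in range(lo, n + 1):
            best = max(best, prefix[hi] - prefix[lo])
    return best


def merge_intervals(points, wobble):
    """Greedy interval merge over sorted points: groups whose consecutive
    gaps are <= wobble."""
    groups = []
    for p in sorted(points):
        if groups and p - groups[-1][-1] <= wobble:
            groups[-1].append(p)
        else:
            groups.append([p])
    return [(g[0], g[-1]) for g in groups]


def spaced_seed_detects(care_masks, mismatch_positions) -> bool:
    """A mismatch placement is detected iff some probe offset has no
    mismatch at any care position."""
    m = 0
    for p in mismatch_positions:
        m |= 1 << p
    return any((cm & m) == 0 for cm in care_masks)
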