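"""Search-space engine: deterministic list operations over packed candidates.

Candidate loci are 64-bit bitmapped values laid out so that ascending
integer order is lexicographic (strand, subId, dpos)::

    bit 63      : 0 (unused)
    bit 62      : strand (0 = forward, 1 = reverse-complement)
    bits 55..61 : subId (7 bits)
    bits 24..54 : dpos, diagonal-adjusted reference position (31 bits)
    bits 16..23 : seed-coverage count (8 bits, saturating at 255)
    bits  0..15 : flags (bit 0 = paired-candidate, bit 1 = clamped-at-origin)

``dpos`` is the reference position minus the seed's offset within the read,
so all seeds of one gapless alignment collapse onto a single diagonal.
Every operation here is a pure function of its inputs: a sequential,
order-deterministic equivalent of parallel sort/reduction primitives.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

log = logging.getLogger(__name__)

FLAG_PAIRED = 1 << 0
FLAG_CLAMPED = 1 << 1

_COV_SHIFT = 16
_DPOS_SHIFT = 24
_SUB_SHIFT = 55
_STRAND_SHIFT = 62

_COV_MAX = 0xFF
_SUB_MAX = 0x7F
_DPOS_MAX = (1 << 31) - 1

LOC_SHIFT = _DPOS_SHIFT  # >> LOC_SHIFT strips coverage+flags, leaving the locus


def make_candidate(strand: int, sub: int, dpos: int, coverage: int = 0, flags: int = 0) -> int:
    if not (0 <= sub <= _SUB_MAX and 0 <= dpos <= _DPOS_MAX and strand in (0, 1)):
        raise ValueError(f"candidate field out of range: strand={strand} sub={sub} dpos={dpos}")
    if coverage > _COV_MAX:
        log.debug("coverage %d saturates at %d", coverage, _COV_MAX)
        coverage = _COV_MAX
    return (strand << _STRAND_SHIFT) | (sub << _SUB_SHIFT) | (dpos << _DPOS_SHIFT) \
        | (coverage << _COV_SHIFT) | (flags & 0xFFFF)


def cand_strand(c: int) -> int:
    return (c >> _STRAND_SHIFT) & 1


def cand_sub(c: int) -> int:
    return (c >> _SUB_SHIFT) & _SUB_MAX


def cand_dpos(c: int) -> int:
    return (c >> _DPOS_SHIFT) & _DPOS_MAX


def cand_coverage(c: int) -> int:
    return (c >> _COV_SHIFT) & _COV_MAX


def cand_flags(c: int) -> int:
    return c & 0xFFFF


def cand_locus(c: int) -> int:
    """The (strand, subId, dpos) part alone; ordering key for set operations."""
    return c >> LOC_SHIFT


class Window(NamedTuple):
    sub: int
    strand: int
    start: int
    end: int  # exclusive


def adjust_to_diagonal(sub: int, pos: int, seed_offset_in_read: int, strand: int = 0) -> int:
    """Diagonal-adjust a seed hit: dpos = pos - seed offset within the read.

    A negative dpos (seed hanging off the reference origin) is clamped to 0
    and flagged.
    """
    dpos = pos - seed_offset_in_read
    flags = 0
    if dpos < 0:
        dpos = 0
        flags = FLAG_CLAMPED
    return make_candidate(strand, sub, dpos, 0, flags)


def sort_unduplicate(cands: list[int]) -> list[int]:
    """Ascending packed order with exact duplicates removed."""
    return sorted(set(cands))


def count_coverage(cands: list[int]) -> list[int]:
    """Collapse a sorted list (with duplicates) to one candidate per locus,
    with the coverage field set to the multiplicity (saturating at 255).
    Flags of collapsed entries are OR-combined."""
    out = []
    i, n = 0, len(cands)
    while i < n:
        loc = cand_locus(cands[i])
        j = i
        flags = 0
        while j < n and cand_locus(cands[j]) == loc:
            flags |= cand_flags(cands[j])
            j += 1
        out.append(make_candidate(cand_strand(cands[i]), cand_sub(cands[i]),
                                  cand_dpos(cands[i]), j - i, flags))
        i = j
    return out


def prioritize(cands: list[int], limit: int) -> list[int]:
    """Highest-priority prefix: coverage descending (paired-flagged candidates
    outrank unflagged at equal coverage), ties by (strand, subId, dpos)
    ascending; at most ``limit`` returned."""
    ranked = sorted(cands, key=lambda c: (-cand_coverage(c),
                                          -(cand_flags(c) & FLAG_PAIRED),
                                          cand_locus(c)))
    return ranked[:limit]


def pair_filter(c1: list[int], c2: list[int], tlen_min: int, tlen_max: int,
                orientation: str, read_len1: int, read_len2: int) -> tuple[list[int], list[int]]:
    """Flag candidates that have a compatible candidate in the other mate.

    Compatibility: same subId, strands as the orientation requires (FR/RF:
    opposite with the forward/reverse mate leftmost respectively; FF: same),
    and implied fragment length — rightmost window end minus leftmost window
    start — within [tlen_min, tlen_max].
    """
    if orientation not in ("FR", "FF", "RF"):
        raise ValueError(f"unknown orientation {orientation!r}")

    def compatible(a, la, b, lb):
        if cand_sub(a) != cand_sub(b):
            return False
        sa, sb = cand_strand(a), cand_strand(b)
        da, db = cand_dpos(a), cand_dpos(b)
        if orientation == "FF":
            if sa != sb:
                return False
        else:
            if sa == sb:
                return False
            fwd_d = da if sa == 0 else db
            rev_d = db if sa == 0 else da
            if orientation == "FR" and fwd_d > rev_d:
                return False
            if orientation == "RF" and rev_d > fwd_d:
                return False
        tlen = max(da + la, db + lb) - min(da, db)
        return tlen_min <= tlen <= tlen_max

    def flag(mine, lm, other, lo):
        out = []
        for a in mine:
            hit = any(compatible(a, lm, b, lo) for b in other)
            out.append(a | FLAG_PAIRED if hit else a)
        return out

    return flag(c1, read_len1, c2, read_len2), flag(c2, read_len2, c1, read_len1)


def exclude_previous(current: list[int], seen: list[int]) -> list[int]:
    """current \\ seen, comparing the (strand, subId, dpos) locus only."""
    seen_loci = {cand_locus(c) for c in seen}
    return [c for c in current if cand_locus(c) not in seen_loci]


def coalesce_windows(cands: list[int], read_len: int, wobble: int,
                     ref_lengths: list[int]) -> list[Window]:
    """Merge candidates on one (strand, subId) whose diagonals differ by at
    most ``wobble`` into a single alignment window
    [min dpos - wobble, max dpos + read_len + wobble), clipped to the
    reference.  The merge is greedy over sorted diagonals, which yields the
    minimal number of windows for this rule."""
    windows: list[Window] = []
    groups: dict[tuple[int, int], list[int]] = {}
    for c in sorted(cands):
        groups.setdefault((cand_strand(c), cand_sub(c)), []).append(cand_dpos(c))
    for (strand, sub), dposs in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        run = [dposs[0]]
        for d in dposs[1:]:
            if d - run[-1] <= wobble:
                run.append(d)
            else:
                windows.append(_window(sub, strand, run, read_len, wobble, ref_lengths))
                run = [d]
        windows.append(_window(sub, strand, run, read_len, wobble, ref_lengths))
    return windows


def _window(sub, strand, run, read_len, wobble, ref_lengths) -> Window:
    start = max(0, run[0] - wobble)
    end = min(ref_lengths[sub], run[-1] + read_len + wobble)
    return Window(sub=sub, strand=strand, start=start, end=end)
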