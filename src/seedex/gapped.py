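"""Gapped seed-and-extend aligner.

Seeds (20-mers by default) are drawn from the read in iterations: the first
iteration tiles the read with non-overlapping seeds; every later iteration
places seeds halfway between all previously examined offsets, so the
cumulative number of seeds roughly doubles per iteration until every
offset has been examined (six iterations for 20 nt seeds in a 100 nt
read).  Candidate loci from the lookup table are diagonal-adjusted,
deduplicated against earlier iterations, ranked by seed coverage,
coalesced into windows, and extended with Smith–Waterman–Gotoh local
alignment.  A read leaves the loop as soon as a configured number of
satisfactory mappings (score >= Vt) has been found.

Scoring: affine gaps — a gap of length L costs gap_open + L * gap_extend
(default 5 + 3L against match +2 / mismatch -6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .encoding import PackedSequence, reverse_complement
from .index import GenomeIndex, HashTables, _POS_BITS, _POS_MASK
from .listops import (adjust_to_diagonal, cand_locus, coalesce_windows,
                      count_coverage, exclude_previous, pair_filter, prioritize)
from .seeds import ContigSeed, contig_keys


@dataclass(frozen=True)
class SWGParams:
    """Affine-gap local alignment scoring.

    ``Vt`` is the minimum reportable alignment score (default 100, suiting
    100 nt reads; use 400 for 250 nt reads).
    """

    match: int = 2
    mismatch: int = -6
    gap_open: int = -5
    gap_extend: int = -3
    Vt: int = 100

    def __post_init__(self):
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("match must be positive; penalties must be <= 0")
        if self.Vt <= 0:
            raise ValueError("Vt must be positive")


@dataclass
class Mapping:
    """A scored alignment of one read against the forward reference."""

    sub: int
    pos: int            # 0-based leftmost aligned reference position
    strand: int         # 0 forward, 1 reverse-complement
    cigar: str
    AS: int
    NM: int
    MD: str
    mapq: int = 0
    flags: int = 0
    tlen: int = 0

    @property
    def key(self) -> tuple:
        return (self.strand, self.sub, self.pos, self.cigar)


def cigar_items(cigar: str) -> list[tuple[int, str]]:
    items, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            items.append((int(num), ch))
            num = ""
    return items


def cigar_read_len(cigar: str) -> int:
    return sum(n for n, op in cigar_items(cigar) if op in "MIS=X")


def cigar_ref_span(cigar: str) -> int:
    return sum(n for n, op in cigar_items(cigar) if op in "MD=X")


def seed_schedule(read_len: int, seed_len: int) -> list[list[int]]:
    """Seed offsets per iteration until every offset is scheduled.

    Iteration 1 tiles the read without overlap (last seed anchored at
    read_len - seed_len); iteration k > 1 takes the midpoints between all
    previously examined offsets.  No offset appears twice.
    """
    if seed_len > read_len:
        return []
    max_off = read_len - seed_len
    first = list(range(0, max_off + 1, seed_len))
    if first[-1] != max_off:
        first.append(max_off)
    iterations = [first]
    examined = set(first)
    while len(examined) <= max_off and len(examined) < max_off + 1:
        E = sorted(examined)
        new = set()
        for a, b in zip(E, E[1:]):
            m = (a + b) // 2
            if m not in examined:
                new.add(m)
        if not new:  # degenerate spacing; schedule the stragglers directly
            new = set(range(max_off + 1)) - examined
        iterations.append(sorted(new))
        examined |= new
    return iterations


class SwgResult(NamedTuple):
    score: int
    cigar: str
    ref_start: int  # 0-based within the window
    NM: int
    MD: str


def swg_align(read_codes: np.ndarray, window_codes: np.ndarray, params: SWGParams,
              min_score: int | None = None) -> Optional[SwgResult]:
    """Optimal Smith–Waterman–Gotoh local alignment of a read against a
    reference window.

    Returns None when the best local score is below ``min_score``
    (default ``params.Vt``).  Unaligned read ends become soft clips.
    Ties are broken toward fewer gaps (diagonal preferred during traceback)
    and toward the leftmost reference end.
    """
    if min_score is None:
        min_score = params.Vt
    n, m = len(read_codes), len(window_codes)
    if n == 0 or m == 0:
        return None
    ma, mi = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    goe = go + ge
    NEG = -(1 << 30)

    read = read_codes.tolist()
    win = window_codes.tolist()

    # tb bits per cell: 0..1 H-origin (0 stop, 1 diag, 2 up/F, 3 left/E);
    # bit 2: E extends E; bit 3: F extends F
    tb = [bytearray(m + 1) for _ in range(n + 1)]
    Hprev = [0] * (m + 1)
    Fcol = [NEG] * (m + 1)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        Hrow = [0] * (m + 1)
        tbi = tb[i]
        E = NEG
        Hdiag = 0  # Hprev[j-1]
        for j in range(1, m + 1):
            # E: gap in read consuming reference (left)
            eo = Hrow[j - 1] + goe
            ee = E + ge
            if ee > eo:
                E = ee
                tbi[j] |= 4
            else:
                E = eo
            # F: gap in reference consuming read (up)
            fo = Hprev[j] + goe
            fe = Fcol[j] + ge
            if fe > fo:
                F = fe
                tbi[j] |= 8
            else:
                F = fo
            Fcol[j] = F
            s = ma if (ri == win[j - 1] and ri >= 4) else mi
            d = Hdiag + s
            # prefer diag > up > left > stop on ties (fewer gaps first)
            h, o = 0, 0
            if d >= h:
                h, o = d, 1
            if F > h:
                h, o = F, 2
            if E > h:
                h, o = E, 3
            tbi[j] |= o << 4  # store origin in bits 4..5
            Hdiag = Hprev[j]
            Hrow[j] = h
            if h > best or (h == best and (j < bj or (j == bj and i < bi))):
                if h > 0:
                    best, bi, bj = h, i, j
        Hprev = Hrow
    if best < min_score:
        return None

    # traceback
    ops = []  # (op, read_idx or None) reversed
    i, j = bi, bj
    state = "H"
    while True:
        cell = tb[i][j]
        if state == "H":
            o = (cell >> 4) & 3
            if o == 0:
                break
            if o == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif o == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("I")
            ext = tb[i][j] & 8
            i -= 1
            if not ext:
                state = "H"
        else:  # E
            ops.append("D")
            ext = tb[i][j] & 4
            j -= 1
            if not ext:
                state = "H"
        if i == 0 and j == 0:
            break
        if state == "H" and (tb[i][j] >> 4) & 3 == 0:
            break
    ops.reverse()
    ref_start = j
    left_clip = i
    right_clip = n - bi

    cigar_parts = []
    if left_clip:
        cigar_parts.append((left_clip, "S"))
    for op in ops:
        if cigar_parts and cigar_parts[-1][1] == op:
            cigar_parts[-1] = (cigar_parts[-1][0] + 1, op)
        else:
            cigar_parts.append((1, op))
    if right_clip:
        cigar_parts.append((right_clip, "S"))
    cigar = "".join(f"{c}{o}" for c, o in cigar_parts)
    nm, md = cigar_md_nm(read_codes, window_codes, cigar, ref_start)
    return SwgResult(score=best, cigar=cigar, ref_start=ref_start, NM=nm, MD=md)


_SYM = "NNNNACGT"


def cigar_md_nm(read_codes: np.ndarray, window_codes: np.ndarray, cigar: str,
                ref_start: int) -> tuple[int, str]:
    """Edit distance and MD string for an alignment path within a window."""
    i = 0
    j = ref_start
    nm = 0
    md_parts: list[str] = []
    run = 0
    for count, op in cigar_items(cigar):
        if op == "S":
            i += count
        elif op == "M":
            for _ in range(count):
                a, b = int(read_codes[i]), int(window_codes[j])
                if a == b and a >= 4:
                    run += 1
                else:
                    md_parts.append(str(run))
                    md_parts.append(_SYM[b])
                    run = 0
                    nm += 1
                i += 1
                j += 1
        elif op == "I":
            i += count
            nm += count
        elif op == "D":
            md_parts.append(str(run))
            run = 0
            md_parts.append("^" + "".join(_SYM[int(window_codes[j + t])] for t in range(count)))
            j += count
            nm += count
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    md_parts.append(str(run))
    return nm, "".join(md_parts)


@dataclass
class GappedConfig:
    seed: ContigSeed = field(default_factory=ContigSeed)
    max_candidates: int = 32        # effort dial: loci extended per iteration
    max_satisfactory: int = 1       # mappings >= Vt that end the loop
    max_iterations: int | None = None
    wobble: int | None = None       # diagonal merge slack; None = derived from scoring


def default_wobble(params: SWGParams, read_len: int) -> int:
    """Largest gap length that can still yield a reportable score: the
    diagonal of a gapped alignment shifts by at most this much."""
    affordable = params.match * read_len + params.gap_open - params.Vt
    return max(1, affordable // (-params.gap_extend))


def _raw_candidates(codes_fwd, codes_rev, offsets, seed, tables: HashTables):
    raw = []
    for strand, codes in ((0, codes_fwd), (1, codes_rev)):
        offs = np.asarray([o for o in offsets if o + seed.length <= codes.size], dtype=np.int64)
        if offs.size == 0:
            continue
        keys, valid = contig_keys(codes, offs, seed)
        for off, key, ok in zip(offs.tolist(), keys.tolist(), valid.tolist()):
            if not ok:
                continue
            for packed in tables.lookup_arrays(key).tolist():
                sub = packed >> _POS_BITS
                pos = packed & _POS_MASK
                raw.append(adjust_to_diagonal(sub, pos, off, strand))
    return raw


class _ReadState:
    """Per-read bookkeeping across seed iterations."""

    def __init__(self, read: PackedSequence):
        self.read = read
        self.codes_fwd = read.codes
        self.codes_rev = reverse_complement(read).codes
        self.seen: list[int] = []
        self.mappings: dict[tuple, Mapping] = {}
        self.done = False

    def satisfied(self, max_satisfactory: int) -> bool:
        return len(self.mappings) >= max_satisfactory

    def result(self) -> list[Mapping]:
        return sorted(self.mappings.values(),
                      key=lambda m: (-m.AS, m.sub, m.pos, m.strand))


def _extend_state(state: _ReadState, cands: list[int], index: GenomeIndex,
                  reference, params: SWGParams, cfg: GappedConfig) -> None:
    read_len = state.read.length
    wobble = cfg.wobble if cfg.wobble is not None else default_wobble(params, read_len)
    top = prioritize(cands, cfg.max_candidates)
    state.seen = sorted(set(state.seen) | {c for c in top})
    windows = coalesce_windows(top, read_len, wobble, index.ref_lengths)
    for w in windows:
        codes = state.codes_fwd if w.strand == 0 else state.codes_rev
        ref_codes = reference[w.sub][1].codes[w.start:w.end]
        res = swg_align(codes, ref_codes, params)
        if res is None:
            continue
        mapping = Mapping(sub=w.sub, pos=w.start + res.ref_start, strand=w.strand,
                          cigar=res.cigar, AS=res.score, NM=res.NM, MD=res.MD)
        state.mappings.setdefault(mapping.key, mapping)


def _iteration_candidates(state: _ReadState, offsets, cfg: GappedConfig,
                          tables: HashTables) -> list[int]:
    raw = _raw_candidates(state.codes_fwd, state.codes_rev, offsets, cfg.seed, tables)
    cands = count_coverage(sorted(raw))
    return exclude_previous(cands, state.seen)


def align_read_gapped(read: PackedSequence, reference, index: GenomeIndex,
                      params: SWGParams, cfg: GappedConfig | None = None) -> list[Mapping]:
    """Full iterative gapped alignment of a single read."""
    cfg = cfg or GappedConfig()
    state = _ReadState(read)
    schedule = seed_schedule(read.length, cfg.seed.length)
    if cfg.max_iterations is not None:
        schedule = schedule[: cfg.max_iterations]
    for offsets in schedule:
        cands = _iteration_candidates(state, offsets, cfg, index.gapped)
        _extend_state(state, cands, index, reference, params, cfg)
        if state.satisfied(cfg.max_satisfactory):
            break
    return state.result()


def align_pair_gapped(read1: PackedSequence, read2: PackedSequence, reference,
                      index: GenomeIndex, params: SWGParams, cfg: GappedConfig,
                      tlen_min: int, tlen_max: int, orientation: str,
                      ) -> tuple[list[Mapping], list[Mapping]]:
    """Gapped alignment of both mates with paired-candidate prioritization.

    Candidates whose locus has a distance/orientation-compatible candidate
    in the other mate are flagged and outrank unflagged candidates of equal
    seed coverage.
    """
    s1, s2 = _ReadState(read1), _ReadState(read2)
    sched1 = seed_schedule(read1.length, cfg.seed.length)
    sched2 = seed_schedule(read2.length, cfg.seed.length)
    if cfg.max_iterations is not None:
        sched1 = sched1[: cfg.max_iterations]
        sched2 = sched2[: cfg.max_iterations]
    for it in range(max(len(sched1), len(sched2))):
        c1 = _iteration_candidates(s1, sched1[it], cfg, index.gapped) \
            if it < len(sched1) and not s1.done else []
        c2 = _iteration_candidates(s2, sched2[it], cfg, index.gapped) \
            if it < len(sched2) and not s2.done else []
        c1, c2 = pair_filter(sorted(c1), sorted(c2), tlen_min, tlen_max,
                             orientation, read1.length, read2.length)
        if not s1.done:
            _extend_state(s1, c1, index, reference, params, cfg)
            s1.done = s1.satisfied(cfg.max_satisfactory)
        if not s2.done:
            _extend_state(s2, c2, index, reference, params, cfg)
            s2.done = s2.satisfied(cfg.max_satisfactory)
        if s1.done and s2.done:
            break
    return s1.result(), s2.result()
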