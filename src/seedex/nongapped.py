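"""Spaced-seed nongapped aligner.

The read's spaced seed is probed at seven adjacent offsets (on both
orientations); because the don't-care residues of the 0010111 pattern form
a perfect difference set mod 7, those seven probes detect every gapless
mapping with up to two mismatches.  Each candidate locus is then verified
by direct symbol comparison of the entire read, terminal mismatches are
soft-clipped whenever clipping raises the score, and the mapping is scored
with the affine-gap parameter set (gapless, so only match/mismatch terms
apply).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import PackedSequence, reverse_complement
from .gapped import Mapping, SWGParams, cigar_md_nm
from .index import GenomeIndex, HashTables, _POS_BITS, _POS_MASK
from .listops import (adjust_to_diagonal, cand_dpos, cand_strand, cand_sub,
                      count_coverage)
from .seeds import SpacedSeed, spaced_keys

#: probe offsets per read orientation; with the default seed this gives
#: full sensitivity for two mismatches
DEFAULT_PROBE_OFFSETS = 7

_BOUNDARY = -(1 << 20)  # positions outside the reference must be clipped


@dataclass
class NongappedConfig:
    seed: SpacedSeed = field(default_factory=SpacedSeed)
    max_mismatches: int = 2
    n_probe_offsets: int = DEFAULT_PROBE_OFFSETS
    min_AS: int | None = None     # None = the scoring threshold Vt
    max_candidates: int = 64      # verification effort cap

    def __post_init__(self):
        if self.n_probe_offsets < 1 or self.max_mismatches < 0:
            raise ValueError("n_probe_offsets >= 1 and max_mismatches >= 0 required")


def probe_offsets(read: PackedSequence, tables: HashTables,
                  cfg: NongappedConfig) -> list[int]:
    """Candidate loci from probing the first ``n_probe_offsets`` read
    offsets on both orientations; sorted, deduplicated, coverage-counted.

    A read shorter than span + offsets - 1 yields no candidates (it falls
    through to the gapped aligner).
    """
    seed = cfg.seed
    if read.length < seed.span + cfg.n_probe_offsets - 1:
        return []
    rc = reverse_complement(read).codes
    raw = []
    offs = np.arange(cfg.n_probe_offsets, dtype=np.int64)
    for strand, codes in ((0, read.codes), (1, rc)):
        keys, valid = spaced_keys(codes, offs, seed)
        for off, key, ok in zip(offs.tolist(), keys.tolist(), valid.tolist()):
            if not ok:
                continue
            for packed in tables.lookup_arrays(key).tolist():
                sub = packed >> _POS_BITS
                pos = packed & _POS_MASK
                raw.append(adjust_to_diagonal(sub, pos, off, strand))
    return count_coverage(sorted(raw))


def _position_scores(read_codes, ref_codes, dpos, params):
    """Per-read-position contribution: +match on a symbol match, mismatch on
    a mismatch or N, and a forcing penalty outside the reference."""
    n = len(read_codes)
    scores = np.full(n, params.mismatch, dtype=np.int64)
    lo = max(0, -dpos)
    hi = min(n, len(ref_codes) - dpos)
    if hi > lo:
        r = read_codes[lo:hi]
        g = ref_codes[dpos + lo : dpos + hi]
        match = (r == g) & (r >= 4)
        scores[lo:hi] = np.where(match, params.match, params.mismatch)
    if lo > 0:
        scores[:lo] = _BOUNDARY
    if hi < n:
        scores[hi:] = _BOUNDARY
    return scores


def soft_clip(scores: np.ndarray) -> tuple[int, int, int]:
    """Optimal terminal clips for per-position scores.

    Returns (left_clip, right_clip, AS) where the retained segment
    [left_clip, n - right_clip) maximizes the summed score over all clip
    choices (ties: smallest left clip, then longest segment).  An empty
    segment (AS 0) is returned when every segment scores negative.
    """
    best_sum, best_s, best_e = 0, 0, 0
    n = len(scores)
    run_sum, run_start = 0, 0
    for e in range(n):
        if run_sum <= 0:
            # never resume across a forced-boundary position
            run_sum, run_start = 0, e
        run_sum += int(scores[e])
        if run_sum > best_sum or (run_sum == best_sum and
                                  (run_start < best_s or
                                   (run_start == best_s and e + 1 > best_e))):
            best_sum, best_s, best_e = run_sum, run_start, e + 1
    return best_s, n - best_e, best_sum


def verify(read: PackedSequence, reference, cand: int, params: SWGParams,
           cfg: NongappedConfig) -> Mapping | None:
    """Verify one candidate locus by whole-read symbol comparison.

    Returns a Mapping iff, after optimal soft clipping, the retained
    interior has at most ``max_mismatches`` mismatches and the score meets
    the reporting threshold.  Clipped-away terminal mismatches do not count
    toward the mismatch ceiling.
    """
    min_as = cfg.min_AS if cfg.min_AS is not None else params.Vt
    strand, sub, dpos = cand_strand(cand), cand_sub(cand), cand_dpos(cand)
    codes = read.codes if strand == 0 else reverse_complement(read).codes
    ref_codes = reference[sub][1].codes
    scores = _position_scores(codes, ref_codes, dpos, params)
    left, right, AS = soft_clip(scores)
    n = read.length
    if AS < min_as or left + right >= n:
        return None
    interior = scores[left : n - right]
    mismatches = int((interior == params.mismatch).sum())
    if mismatches > cfg.max_mismatches:
        return None
    parts = []
    if left:
        parts.append(f"{left}S")
    parts.append(f"{n - left - right}M")
    if right:
        parts.append(f"{right}S")
    cigar = "".join(parts)
    pos = dpos + left
    window = ref_codes[pos : pos + (n - left - right)]
    nm, md = cigar_md_nm(codes, window, cigar, 0)
    return Mapping(sub=sub, pos=pos, strand=strand, cigar=cigar, AS=int(AS),
                   NM=nm, MD=md)


def align_read_nongapped(read: PackedSequence, reference, index: GenomeIndex,
                         params: SWGParams, cfg: NongappedConfig | None = None
                         ) -> list[Mapping]:
    """Probe, verify, and score; mappings sorted by AS descending."""
    cfg = cfg or NongappedConfig()
    cands = probe_offsets(read, index.nongapped, cfg)
    # verify highest-coverage candidates first, bounded by the effort cap
    cands = sorted(cands, key=lambda c: (-((c >> 16) & 0xFF), c))[: cfg.max_candidates]
    out: dict[tuple, Mapping] = {}
    for cand in cands:
        m = verify(read, reference, cand, params, cfg)
        if m is not None:
            out.setdefault(m.key, m)
    return sorted(out.values(), key=lambda m: (-m.AS, m.sub, m.pos, m.strand))
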