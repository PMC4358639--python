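"""Batch orchestration and SAM emission.

Reads are processed in batches (a memory-bounding contract only: the output
is byte-identical for any batch size).  Each read first goes through the
nongapped spaced-seed aligner; only reads with fewer than the configured
number of satisfactory nongapped mappings enter the gapped stage.  Final
mappings are scored, assigned MAPQ, classified (pairing), and written as
SAM with AS/NM/MD tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .encoding import PackedSequence, decode, reverse_complement
from .gapped import (GappedConfig, Mapping, SWGParams, align_pair_gapped,
                     align_read_gapped, cigar_read_len, cigar_ref_span)
from .index import GenomeIndex
from .mapq import MapqInputs, compute_mapq
from .nongapped import NongappedConfig, align_read_nongapped

log = logging.getLogger(__name__)

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100


@dataclass
class PipelineConfig:
    batch_size: int = 5000
    sub_batch_size: int = 512            # alignments per DP pass (memory contract)
    nongapped: NongappedConfig = field(default_factory=NongappedConfig)
    gapped: GappedConfig = field(default_factory=GappedConfig)
    params: SWGParams = field(default_factory=SWGParams)
    min_nongapped_satisfactory: int = 1  # nongapped mappings that skip the gapped stage
    tlen_min: int = 100
    tlen_max: int = 500
    orientation: str = "FR"
    report_limit: int = 10
    mapq_model: str = "a"
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.tlen_min > self.tlen_max:
            raise ValueError("tlen_min must not exceed tlen_max")


@dataclass
class SamRecord:
    qname: str
    flag: int
    rname: str
    pos: int      # 1-based; 0 for unmapped
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    tlen: int
    seq: str
    qual: str
    tags: list[str]

    def line(self) -> str:
        cols = [self.qname, str(self.flag), self.rname, str(self.pos), str(self.mapq),
                self.cigar, self.rnext, str(self.pnext), str(self.tlen),
                self.seq, self.qual] + self.tags
        return "\t".join(cols)


def sam_header(index: GenomeIndex, cfg: PipelineConfig) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in zip(index.ref_names, index.ref_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    p = cfg.params
    cl = (f"match={p.match} mismatch={p.mismatch} gap_open={p.gap_open} "
          f"gap_extend={p.gap_extend} Vt={p.Vt} "
          f"gap_cost=open+L*extend "
          f"mapq_model={cfg.mapq_model} (a: 4+56*(best-second)/(perfect-Vt), ties<=3; "
          f"b: bucketed 0-44, ties<=1) "
          f"probe_offsets={cfg.nongapped.n_probe_offsets} "
          f"max_candidates={cfg.gapped.max_candidates} "
          f"orientation={cfg.orientation} tlen={cfg.tlen_min}:{cfg.tlen_max}")
    lines.append(f"@PG\tID:seedex\tPN:seedex\tVN:0.1.0\tCL:{cl}")
    return lines


def _mapq_for(mappings: list[Mapping], read_len: int, vt: int, model: str) -> None:
    if not mappings:
        return
    best = mappings[0].AS
    ties = sum(1 for m in mappings if m.AS == best)
    second = None
    for m in mappings[1:]:
        if m.AS < best:
            second = m.AS
            break
    aligned = cigar_read_len(mappings[0].cigar) - sum(
        n for n, op in _cigar_items(mappings[0].cigar) if op == "S")
    inputs = MapqInputs(best=best, second=second, tie_count=ties,
                        perfect=2 * aligned, read_len=read_len, vt=vt)
    q = compute_mapq(inputs, model)
    for i, m in enumerate(mappings):
        m.mapq = q if m.AS == best else max(0, q // 2)


def _cigar_items(cigar):
    from .gapped import cigar_items
    return cigar_items(cigar)


def align_single(read: PackedSequence, reference, index: GenomeIndex,
                 cfg: PipelineConfig, counters: dict | None = None) -> list[Mapping]:
    """Nongapped first; gapped only when too few satisfactory mappings."""
    mappings = align_read_nongapped(read, reference, index, cfg.params, cfg.nongapped)
    if counters is not None:
        counters["nongapped_attempted"] += 1
    if len(mappings) < cfg.min_nongapped_satisfactory:
        if counters is not None:
            counters["gapped_attempted"] += 1
        gapped = align_read_gapped(read, reference, index, cfg.params, cfg.gapped)
        seen = {m.key for m in mappings}
        mappings += [m for m in gapped if m.key not in seen]
        mappings.sort(key=lambda m: (-m.AS, m.sub, m.pos, m.strand))
    return mappings


def align_pair(read1: PackedSequence, read2: PackedSequence, reference,
               index: GenomeIndex, cfg: PipelineConfig,
               counters: dict | None = None) -> tuple[list[Mapping], list[Mapping]]:
    m1 = align_read_nongapped(read1, reference, index, cfg.params, cfg.nongapped)
    m2 = align_read_nongapped(read2, reference, index, cfg.params, cfg.nongapped)
    if counters is not None:
        counters["nongapped_attempted"] += 2
    need1 = len(m1) < cfg.min_nongapped_satisfactory
    need2 = len(m2) < cfg.min_nongapped_satisfactory
    if need1 or need2:
        if counters is not None:
            counters["gapped_attempted"] += int(need1) + int(need2)
        g1, g2 = align_pair_gapped(read1, read2, reference, index, cfg.params,
                                   cfg.gapped, cfg.tlen_min, cfg.tlen_max,
                                   cfg.orientation)
        if need1:
            seen = {m.key for m in m1}
            m1 += [m for m in g1 if m.key not in seen]
            m1.sort(key=lambda m: (-m.AS, m.sub, m.pos, m.strand))
        if need2:
            seen = {m.key for m in m2}
            m2 += [m for m in g2 if m.key not in seen]
            m2.sort(key=lambda m: (-m.AS, m.sub, m.pos, m.strand))
    return m1, m2


def _full_extent(m: Mapping) -> tuple[int, int]:
    """Leftmost/rightmost reference coordinates implied by the alignment
    including soft-clipped bases (for TLEN)."""
    items = _cigar_items(m.cigar)
    left = m.pos - (items[0][0] if items[0][1] == "S" else 0)
    right = m.pos + cigar_ref_span(m.cigar) + (items[-1][0] if items[-1][1] == "S" else 0)
    return left, right


def classify_pair(m1: list[Mapping], m2: list[Mapping], cfg: PipelineConfig
                  ) -> tuple[Mapping | None, Mapping | None, bool]:
    """Pick the primary mapping per mate, preferring concordant combinations.

    Concordant: same subId, orientation as configured, TLEN within range.
    Returns (primary1, primary2, proper) with TLEN set on both primaries.
    """
    best = None
    for a in m1[: cfg.report_limit]:
        for b in m2[: cfg.report_limit]:
            proper = _concordant(a, b, cfg)
            score = a.AS + b.AS
            key = (proper, score, -a.pos, -b.pos)
            if best is None or key > best[0]:
                best = (key, a, b, proper)
    if best is not None:
        _, a, b, proper = best
        if proper or (a.sub == b.sub):
            la, ra = _full_extent(a)
            lb, rb = _full_extent(b)
            left, right = min(la, lb), max(ra, rb)
            span = right - left
            a.tlen = span if la <= lb else -span
            b.tlen = -a.tlen if a.tlen != 0 else span
            if la == lb:  # degenerate overlap: leftmost-by-convention
                a.tlen, b.tlen = span, -span
        else:
            a.tlen = b.tlen = 0
        return a, b, proper
    return (m1[0] if m1 else None), (m2[0] if m2 else None), False


def _concordant(a: Mapping, b: Mapping, cfg: PipelineConfig) -> bool:
    if a.sub != b.sub:
        return False
    if cfg.orientation == "FF":
        if a.strand != b.strand:
            return False
    else:
        if a.strand == b.strand:
            return False
        fwd, rev = (a, b) if a.strand == 0 else (b, a)
        if cfg.orientation == "FR" and fwd.pos > rev.pos:
            return False
        if cfg.orientation == "RF" and rev.pos > fwd.pos:
            return False
    la, ra = _full_extent(a)
    lb, rb = _full_extent(b)
    tlen = max(ra, rb) - min(la, lb)
    return cfg.tlen_min <= tlen <= cfg.tlen_max


def _records_for_read(name, read, qual, mappings, primary, index, cfg,
                      pair_flags=0, mate=None, mate_mapped=False, proper=False):
    """SAM records for one read: primary first, then secondaries."""
    seq_fwd = decode(read)
    qual = qual or "*"
    records = []
    if not mappings:
        flag = FLAG_UNMAPPED | pair_flags
        if pair_flags and not mate_mapped:
            flag |= FLAG_MATE_UNMAPPED
        rnext, pnext = "*", 0
        if pair_flags and mate is not None:
            rnext, pnext = index.ref_names[mate.sub], mate.pos + 1
        records.append(SamRecord(name, flag, "*", 0, 0, "*", rnext, pnext, 0,
                                 seq_fwd, qual, ["AS:i:0"]))
        return records
    ordered = [primary] + [m for m in mappings if m is not primary]
    for rank, m in enumerate(ordered[: cfg.report_limit]):
        flag = pair_flags
        if m.strand:
            flag |= FLAG_REVERSE
        if rank > 0:
            flag |= FLAG_SECONDARY
        rnext, pnext, tlen = "*", 0, 0
        if pair_flags:
            if proper and rank == 0:
                flag |= FLAG_PROPER
            if mate is not None:
                rnext = "=" if mate.sub == m.sub else index.ref_names[mate.sub]
                pnext = mate.pos + 1
                if mate.strand:
                    flag |= FLAG_MATE_REVERSE
                if rank == 0:
                    tlen = m.tlen
            else:
                flag |= FLAG_MATE_UNMAPPED
                rnext, pnext = "=", m.pos + 1
        if m.strand:
            seq = decode(reverse_complement(read))
            q = qual[::-1] if qual != "*" else "*"
        else:
            seq, q = seq_fwd, qual
        tags = [f"AS:i:{m.AS}", f"NM:i:{m.NM}", f"MD:Z:{m.MD}"]
        records.append(SamRecord(name, flag, index.ref_names[m.sub], m.pos + 1,
                                 m.mapq, m.cigar, rnext, pnext, tlen, seq, q, tags))
    return records


def run(reference, index: GenomeIndex, reads, out_path, cfg: PipelineConfig | None = None,
        reads2=None) -> dict:
    """Align reads (single list or two mate lists of (name, seq, qual))
    against the reference and write SAM to ``out_path``.

    Returns the stage counters.  Output is deterministic and invariant to
    ``batch_size``.
    """
    cfg = cfg or PipelineConfig()
    index.check_reference(reference)
    counters = {"reads": 0, "mapped": 0, "nongapped_attempted": 0,
                "gapped_attempted": 0, "proper_pairs": 0}
    reads = list(reads)
    paired = reads2 is not None
    if paired:
        reads2 = list(reads2)
        if len(reads) != len(reads2):
            raise ValueError("mate files differ in read count")
    with open(out_path, "wt") as fh:
        for line in sam_header(index, cfg):
            fh.write(line + "\n")
        for start in range(0, len(reads), cfg.batch_size):
            batch = reads[start : start + cfg.batch_size]
            batch2 = reads2[start : start + cfg.batch_size] if paired else None
            for rec in _run_batch(batch, batch2, reference, index, cfg, counters):
                fh.write(rec.line() + "\n")
            log.info("batch %d: %s", start // cfg.batch_size, counters)
    return counters


def _run_batch(batch, batch2, reference, index, cfg, counters):
    vt = cfg.params.Vt
    records = []
    if batch2 is None:
        for name, read, qual in batch:
            counters["reads"] += 1
            ms = align_single(read, reference, index, cfg, counters)
            _mapq_for(ms, read.length, vt, cfg.mapq_model)
            if ms:
                counters["mapped"] += 1
            primary = ms[0] if ms else None
            records.extend(_records_for_read(name, read, qual, ms, primary, index, cfg))
    else:
        for (n1, r1, q1), (n2, r2, q2) in zip(batch, batch2):
            counters["reads"] += 2
            m1, m2 = align_pair(r1, r2, reference, index, cfg, counters)
            _mapq_for(m1, r1.length, vt, cfg.mapq_model)
            _mapq_for(m2, r2.length, vt, cfg.mapq_model)
            p1, p2, proper = classify_pair(m1, m2, cfg)
            counters["mapped"] += int(bool(m1)) + int(bool(m2))
            if proper:
                counters["proper_pairs"] += 1
            base1 = FLAG_PAIRED | FLAG_READ1
            base2 = FLAG_PAIRED | FLAG_READ2
            records.extend(_records_for_read(
                n1, r1, q1, m1, p1, index, cfg, base1, p2, bool(m2), proper))
            records.extend(_records_for_read(
                n2, r2, q2, m2, p2, index, cfg, base2, p1, bool(m1), proper))
    return records


def write_sam(records_per_read, index: GenomeIndex, cfg: PipelineConfig, path) -> None:
    """Write finalized SAM records (header + records) to ``path``."""
    with open(path, "wt") as fh:
        for line in sam_header(index, cfg):
            fh.write(line + "\n")
        for rec in records_per_read:
            fh.write(rec.line() + "\n")
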