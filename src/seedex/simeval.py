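"""Synthetic data generation and alignment evaluation.

The simulator produces ground-truthed reads the way a desk-scale read
simulator would: fragments drawn uniformly from an i.i.d.-background
reference (optionally carrying planted tandem repeats), per-base
substitutions and short (1-3 nt) indels at configurable rates, FR-oriented
mates, and a truth table recording each read's origin (subId, position,
strand) and its true CIGAR against the reference.  It is deliberately
simpler than a full error-model simulator (uniform errors, no
quality-dependence): only the statistical structure the evaluation needs.

Evaluation follows the position-tolerance rule: a read is assessed correct
when, after accounting for soft clipping, at least one of its aligned ends
lies within a tolerance (default 3 nt) of the corresponding true end on
the true reference sequence and strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .encoding import PackedSequence, decode, encode, reverse_complement
from .gapped import SWGParams, cigar_items


@dataclass(frozen=True)
class TruthRecord:
    name: str
    sub: int
    pos: int      # 0-based leftmost reference position of the true alignment
    strand: int   # 0 forward, 1 reverse
    cigar: str    # true alignment of the read against the reference

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in cigar_items(self.cigar) if op in "MD")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_reference(length: int, repeats: list[tuple[int, int]] | None = None,
                       seed: int = 0, name: str = "ref0") -> tuple[str, PackedSequence]:
    """Uniform-ACGT reference with optional planted tandem repeats.

    Each (unit_length, copy_number) repeat is written over the background at
    an rng-chosen position; deterministic for a fixed seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    arr = _BASES[rng.integers(0, 4, size=length)]
    for unit_len, copies in repeats or []:
        total = unit_len * copies
        if total > length:
            raise ValueError(f"repeat {unit_len}x{copies} exceeds reference length")
        start = int(rng.integers(0, length - total + 1))
        unit = _BASES[rng.integers(0, 4, size=unit_len)]
        arr[start : start + total] = np.tile(unit, copies)
    return name, encode(arr.tobytes().decode("ascii"))


def _mutate(ref_str: str, anchor: int, read_len: int, sub_rate: float,
            indel_rate: float, rng) -> tuple[str, str, int]:
    """Realize one read of ``read_len`` bases walking the reference forward
    from ``anchor``.  Returns (read, true CIGAR, ref span consumed)."""
    bases = "ACGT"
    out = []
    ops = []  # (op,) run-length-encoded at the end
    j = anchor
    while len(out) < read_len and j < len(ref_str):
        if rng.random() < indel_rate:
            L = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion into the read
                for _ in range(min(L, read_len - len(out))):
                    out.append(bases[rng.integers(0, 4)])
                    ops.append("I")
                continue
            else:                   # deletion from the read
                take = min(L, len(ref_str) - j)
                ops.extend("D" * take)
                j += take
                continue
        b = ref_str[j]
        if rng.random() < sub_rate:
            b = bases[(bases.index(b) + int(rng.integers(1, 4))) % 4]
        out.append(b)
        ops.append("M")
        j += 1
    # trailing deletions carry no information; trim them
    while ops and ops[-1] == "D":
        ops.pop()
        j -= 1
    if len(out) < read_len:
        raise ValueError("fragment ran off the reference; reduce read length")
    cigar_parts = []
    for op in ops:
        if cigar_parts and cigar_parts[-1][1] == op:
            cigar_parts[-1][0] += 1
        else:
            cigar_parts.append([1, op])
    cigar = "".join(f"{c}{o}" for c, o in cigar_parts)
    return "".join(out), cigar, j - anchor


def _reverse_cigar(cigar: str) -> str:
    return "".join(f"{c}{o}" for c, o in reversed(cigar_items(cigar)))


def _trim_flanking_deletions(pos: int, cigar: str) -> tuple[int, str]:
    """A deletion at either end of a true alignment carries no read bases;
    normalize it away (shifting pos for a leading one)."""
    items = cigar_items(cigar)
    while items and items[0][1] == "D":
        pos += items[0][0]
        items = items[1:]
    while items and items[-1][1] == "D":
        items = items[:-1]
    return pos, "".join(f"{c}{o}" for c, o in items)


def simulate_reads(reference: list[tuple[str, PackedSequence]], n_pairs: int,
                   read_len: int = 100, sub_rate: float = 0.01,
                   indel_rate: float = 0.001, tlen_mean: float = 350.0,
                   tlen_sd: float = 50.0, orientation: str = "FR",
                   seed: int = 0):
    """Ground-truthed FR paired-end reads.

    Returns (reads1, reads2, truth) where readsN are (name, PackedSequence,
    qual) lists and truth is a list of TruthRecord.  Mate 1 is the forward
    5' end of the fragment; mate 2 is the reverse complement of the 3' end.
    """
    if orientation != "FR":
        raise NotImplementedError("only FR simulation is provided")
    rng = np.random.default_rng(seed)
    lengths = [seq.length for _, seq in reference]
    if read_len > max(lengths):
        raise ValueError("read length exceeds reference length")
    ref_strs = [decode(seq) for _, seq in reference]
    weights = np.array(lengths, dtype=float) / sum(lengths)
    reads1, reads2, truth = [], [], []
    for i in range(n_pairs):
        while True:
            sub = int(rng.choice(len(reference), p=weights))
            tlen = int(round(rng.normal(tlen_mean, tlen_sd)))
            tlen = max(read_len, min(tlen, lengths[sub]))
            start = int(rng.integers(0, lengths[sub] - tlen + 1))
            end = start + tlen
            try:
                r1, c1, span1 = _mutate(ref_strs[sub], start, read_len,
                                        sub_rate, indel_rate, rng)
                # mate 2: walk the reverse-complement strand from the 3' end
                rc = str(decode(reverse_complement(reference[sub][1])))
                rc_anchor = lengths[sub] - end
                r2, c2rc, span2 = _mutate(rc, rc_anchor, read_len,
                                          sub_rate, indel_rate, rng)
            except ValueError:
                continue
            break
        name = f"sim{i}"
        qual = "I" * read_len
        reads1.append((f"{name}", encode(r1), qual))
        reads2.append((f"{name}", encode(r2), qual))
        p1, c1 = _trim_flanking_deletions(start, c1)
        p2, c2 = _trim_flanking_deletions(end - span2, _reverse_cigar(c2rc))
        truth.append(TruthRecord(name=f"{name}/1", sub=sub, pos=p1, strand=0, cigar=c1))
        truth.append(TruthRecord(name=f"{name}/2", sub=sub, pos=p2, strand=1, cigar=c2))
    return reads1, reads2, truth


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write("name\tsub\tpos\tstrand\tcigar\n")
        for t in truth:
            fh.write(f"{t.name}\t{t.sub}\t{t.pos}\t{t.strand}\t{t.cigar}\n")


def read_truth(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [TruthRecord(str(r["name"]), int(r["sub"]), int(r["pos"]),
                        int(r["strand"]), str(r["cigar"])) for _, r in df.iterrows()]


_MD_TOKEN = re.compile(r"(\d+)|\^([A-Z]+)|([A-Z])")


def score_from_cigar_md(cigar: str, md: str, params: SWGParams | None = None) -> int:
    """Alignment score implied by a record's CIGAR and MD fields.

    Matched bases score +match, MD mismatches score +mismatch, each gap
    costs gap_open + L*gap_extend; soft-clipped bases contribute nothing.
    """
    params = params or SWGParams()
    m_total = 0
    score = 0
    md_del = 0
    for count, op in cigar_items(cigar):
        if op == "M":
            m_total += count
        elif op in "ID":
            score += params.gap_open + count * params.gap_extend
        elif op not in "S":
            raise ValueError(f"unsupported CIGAR op {op!r}")
    mismatches = 0
    md_matches = 0
    for tok in _MD_TOKEN.finditer(md):
        num, dele, sub = tok.groups()
        if num is not None:
            md_matches += int(num)
        elif dele is not None:
            md_del += len(dele)
        else:
            mismatches += 1
    if md_matches + mismatches != m_total:
        raise ValueError(f"CIGAR {cigar} and MD {md} disagree: "
                         f"{md_matches}+{mismatches} aligned vs {m_total}M")
    score += params.match * md_matches + params.mismatch * mismatches
    return score


def _ends_from_sam(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """Leftmost/rightmost reference positions of the read's first and last
    base, projecting soft-clipped bases onto the reference."""
    left_clip = rec.cigartuples[0][1] if rec.cigartuples[0][0] == 4 else 0
    right_clip = rec.cigartuples[-1][1] if rec.cigartuples[-1][0] == 4 else 0
    start = rec.reference_start - left_clip
    end = rec.reference_end - 1 + right_clip
    return start, end


def _ends_from_truth(t: TruthRecord) -> tuple[int, int]:
    return t.pos, t.pos + t.ref_span - 1


def assess(sam_path, truth: list[TruthRecord], tolerance: int = 3,
           both_ends: bool = False) -> pd.DataFrame:
    """Per-read assessment of primary mappings against the truth table.

    Returns a DataFrame with columns name, status ('correct', 'incorrect',
    'unmapped'), mapq.
    """
    by_name = {t.name: t for t in truth}
    rows = []
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            if rec.is_paired:
                name = name + ("/1" if rec.is_read1 else "/2")
            t = by_name.get(name)
            if t is None:
                raise KeyError(f"read {name} not present in truth table")
            if rec.is_unmapped:
                rows.append((name, "unmapped", 0))
                continue
            ok = False
            if rec.reference_id == t.sub and int(rec.is_reverse) == t.strand:
                rs, re_ = _ends_from_sam(rec)
                ts, te = _ends_from_truth(t)
                hit_start = abs(rs - ts) <= tolerance
                hit_end = abs(re_ - te) <= tolerance
                ok = (hit_start and hit_end) if both_ends else (hit_start or hit_end)
            rows.append((name, "correct" if ok else "incorrect", rec.mapping_quality))
    return pd.DataFrame(rows, columns=["name", "status", "mapq"])


def mapq_curve(assessments: pd.DataFrame) -> pd.DataFrame:
    """Cumulative correct/incorrect counts for decreasing MAPQ."""
    mapped = assessments[assessments["status"] != "unmapped"]
    rows = []
    cum_c = cum_i = 0
    for q in sorted(mapped["mapq"].unique(), reverse=True):
        at = mapped[mapped["mapq"] == q]
        cum_c += int((at["status"] == "correct").sum())
        cum_i += int((at["status"] == "incorrect").sum())
        rows.append((q, cum_c, cum_i))
    return pd.DataFrame(rows, columns=["mapq", "cum_correct", "cum_incorrect"])
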