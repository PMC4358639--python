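"""Genome lookup tables: build, sample, query, persist.

Each aligner mode (nongapped / gapped) gets one H/J table pair over the
reference genome.  The J table is a flat array of reference locations
(subId, forward-strand position) sorted by (key, subId, pos); the H table
maps each seed key to its (offset, length) slice of J.  H is logically one
element per possible 30-bit key; it is represented sparsely since only
keys that occur in the reference carry entries — the contract is
behavioural, not a memory layout.

Repetitive regions produce "big buckets": keys whose location lists exceed
a configurable threshold.  :func:`big_bucket_sample` thins maximal runs of
consecutive reference positions whose keys are all big, retaining one
position in ``interval`` (anchored at the run start), so a read seeded at
up to ``interval`` adjacent offsets is guaranteed to hit a retained
location inside any sampled run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .encoding import PackedSequence, decode
from .seeds import ContigSeed, SpacedSeed, contig_keys, spaced_keys

log = logging.getLogger(__name__)

MAGIC = b"SEEDEXIDX1"
FORMAT_VERSION = 1

DEFAULT_BIG_BUCKET_THRESHOLD = 128
DEFAULT_SAMPLE_INTERVAL = 10

_POS_BITS = 32
_POS_MASK = (1 << _POS_BITS) - 1


class RefLocation(NamedTuple):
    subId: int
    pos: int


def pack_location(sub: int, pos: int) -> int:
    return (sub << _POS_BITS) | pos


def reference_digest(reference: list[tuple[str, PackedSequence]]) -> str:
    h = hashlib.sha256()
    for name, seq in reference:
        h.update(b">" + name.encode() + b"\n")
        h.update(decode(seq).encode())
        h.update(b"\n")
    return h.hexdigest()


@dataclass
class HashTables:
    """One H/J lookup-table pair for a given seed definition."""

    seed: SpacedSeed | ContigSeed
    hkeys: np.ndarray  # sorted uint64 keys present in the reference
    hoffs: np.ndarray  # J offset per key
    hcnts: np.ndarray  # J list length per key
    J: np.ndarray      # uint64 packed (subId << 32 | pos), sorted by (key, subId, pos)
    header: dict

    def __post_init__(self):
        self._hindex = {int(k): i for i, k in enumerate(self.hkeys)}

    @property
    def total_entries(self) -> int:
        return int(self.J.size)

    def lookup_arrays(self, key: int) -> np.ndarray:
        """J slice for a key as packed uint64 locations (empty when absent)."""
        i = self._hindex.get(int(key))
        if i is None:
            return np.empty(0, dtype=np.uint64)
        off = int(self.hoffs[i])
        return self.J[off : off + int(self.hcnts[i])]


def lookup(tables: HashTables, key: int) -> list[RefLocation]:
    """Sorted (subId, pos) list for a key; empty when the key is absent."""
    arr = tables.lookup_arrays(key)
    return [RefLocation(int(v) >> _POS_BITS, int(v) & _POS_MASK) for v in arr]


def _collect(reference, seed):
    """All (key, subId, pos) triples: one per valid seed position."""
    keys, subs, poss = [], [], []
    for sub, (name, seq) in enumerate(reference):
        n = seq.length - seed.span + 1
        if n <= 0:
            log.warning("reference %s (%d nt) shorter than seed span %d; no entries",
                        name, seq.length, seed.span)
            continue
        offs = np.arange(n, dtype=np.int64)
        if isinstance(seed, SpacedSeed):
            k, valid = spaced_keys(seq.codes, offs, seed)
        else:
            k, valid = contig_keys(seq.codes, offs, seed)
        keys.append(k[valid].astype(np.uint64))
        poss.append(offs[valid])
        subs.append(np.full(int(valid.sum()), sub, dtype=np.int64))
    if not keys:
        e = np.empty(0, dtype=np.int64)
        return e.astype(np.uint64), e, e
    return np.concatenate(keys), np.concatenate(subs), np.concatenate(poss)


def _assemble(seed, keys, subs, poss, header) -> HashTables:
    order = np.lexsort((poss, subs, keys))
    keys, subs, poss = keys[order], subs[order], poss[order]
    hkeys, hoffs, hcnts = np.unique(keys, return_index=True, return_counts=True)
    J = (subs.astype(np.uint64) << np.uint64(_POS_BITS)) | poss.astype(np.uint64)
    return HashTables(seed=seed, hkeys=hkeys, hoffs=hoffs.astype(np.int64),
                      hcnts=hcnts.astype(np.int64), J=J, header=header)


def _entry_triples(tables: HashTables):
    """Recover the (key, subId, pos) triples from built tables."""
    keys = np.repeat(tables.hkeys, tables.hcnts)
    subs = (tables.J >> np.uint64(_POS_BITS)).astype(np.int64)
    poss = (tables.J & np.uint64(_POS_MASK)).astype(np.int64)
    return keys, subs, poss


def big_bucket_sample(tables: HashTables, threshold: int,
                      interval: int = DEFAULT_SAMPLE_INTERVAL) -> HashTables:
    """Thin J lists inside runs of consecutive big-bucket positions.

    Within each maximal run of consecutive reference positions whose keys
    all have list length > ``threshold``, only positions congruent to the
    run start (mod ``interval``) keep their J entry; everything else is
    untouched, so the gap between retained positions inside a run never
    exceeds ``interval``.
    """
    if threshold < 1 or interval < 1:
        raise ValueError("threshold and interval must be >= 1")
    keys, subs, poss = _entry_triples(tables)
    cnt_of = np.repeat(tables.hcnts, tables.hcnts)
    big = cnt_of > threshold

    keep = np.ones(keys.size, dtype=bool)
    # walk each reference sequence in position order
    order = np.lexsort((poss, subs))
    for sub in np.unique(subs):
        sel = order[subs[order] == sub]
        p = poss[sel]
        b = big[sel]
        run_start = None
        for i in range(sel.size):
            if b[i] and (run_start is not None) and p[i] == prev_pos + 1:
                pass  # run continues
            elif b[i]:
                run_start = p[i]
            else:
                run_start = None
            if b[i] and (p[i] - run_start) % interval != 0:
                keep[sel[i]] = False
            prev_pos = p[i]
    header = dict(tables.header)
    header["big_bucket_threshold"] = int(threshold)
    header["sample_interval"] = int(interval)
    header["sampled"] = True
    return _assemble(tables.seed, keys[keep], subs[keep], poss[keep], header)


def build_tables(reference: list[tuple[str, PackedSequence]],
                 seed: SpacedSeed | ContigSeed,
                 big_bucket_threshold: int | None = DEFAULT_BIG_BUCKET_THRESHOLD,
                 sample_interval: int = DEFAULT_SAMPLE_INTERVAL) -> HashTables:
    """Build an H/J pair over the reference.

    Every valid seed position of every reference sequence contributes one
    J entry; big-bucket sampling is then applied unless
    ``big_bucket_threshold`` is None.
    """
    if not reference:
        raise ValueError("reference must be nonempty")
    header = {
        "seed": _seed_to_json(seed),
        "big_bucket_threshold": None,
        "sample_interval": int(sample_interval),
        "sampled": False,
        "ref_names": [name for name, _ in reference],
        "ref_lengths": [seq.length for _, seq in reference],
        "ref_digest": reference_digest(reference),
    }
    keys, subs, poss = _collect(reference, seed)
    tables = _assemble(seed, keys, subs, poss, header)
    if big_bucket_threshold is not None:
        tables = big_bucket_sample(tables, big_bucket_threshold, sample_interval)
    return tables


def seed_frequency_profile(tables: HashTables) -> list[tuple[int, int]]:
    """(key, list length) ranked by length descending, ties by key ascending."""
    order = np.lexsort((tables.hkeys, -tables.hcnts))
    return [(int(tables.hkeys[i]), int(tables.hcnts[i])) for i in order]


# ---------------------------------------------------------------- persistence

def _seed_to_json(seed) -> dict:
    if isinstance(seed, SpacedSeed):
        return {"kind": "spaced", "pattern": seed.pattern, "span": seed.span,
                "key_width": seed.key_width, "hash_seed": seed.hash_seed}
    return {"kind": "contig", "length": seed.length,
            "key_width": seed.key_width, "hash_seed": seed.hash_seed}


def _seed_from_json(d) -> SpacedSeed | ContigSeed:
    if d["kind"] == "spaced":
        return SpacedSeed(pattern=d["pattern"], span=d["span"],
                          key_width=d["key_width"], hash_seed=d["hash_seed"])
    return ContigSeed(length=d["length"], key_width=d["key_width"],
                      hash_seed=d["hash_seed"])


class IndexError_(RuntimeError):
    """Index file is corrupt, wrong version, or mismatches the reference."""


def _write_array(fh, arr: np.ndarray) -> None:
    data = np.ascontiguousarray(arr.astype("<u8")).tobytes()
    fh.write(struct.pack("<Q", arr.size))
    fh.write(data)


def _read_array(fh) -> np.ndarray:
    (n,) = struct.unpack("<Q", fh.read(8))
    return np.frombuffer(fh.read(8 * n), dtype="<u8").astype(np.uint64)


def save_tables(tables: HashTables, path) -> None:
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", FORMAT_VERSION))
        blob = json.dumps(tables.header, sort_keys=True).encode()
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        _write_array(fh, tables.hkeys)
        _write_array(fh, tables.hcnts)
        _write_array(fh, tables.J)


def load_tables(path) -> HashTables:
    with open(path, "rb") as fh:
        magic = fh.read(len(MAGIC))
        if magic != MAGIC:
            raise IndexError_(f"{path}: bad magic number (not an index file)")
        (version,) = struct.unpack("<I", fh.read(4))
        if version != FORMAT_VERSION:
            raise IndexError_(f"{path}: unsupported index format version {version}")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        hkeys = _read_array(fh)
        hcnts = _read_array(fh).astype(np.int64)
        J = _read_array(fh)
    hoffs = np.concatenate([[0], np.cumsum(hcnts)[:-1]]).astype(np.int64)
    return HashTables(seed=_seed_from_json(header["seed"]), hkeys=hkeys,
                      hoffs=hoffs, hcnts=hcnts, J=J, header=header)


@dataclass
class GenomeIndex:
    """Both table pairs (nongapped spaced-seed + gapped k-mer) for a genome."""

    nongapped: HashTables
    gapped: HashTables

    @property
    def ref_names(self) -> list[str]:
        return self.nongapped.header["ref_names"]

    @property
    def ref_lengths(self) -> list[int]:
        return self.nongapped.header["ref_lengths"]

    @property
    def ref_digest(self) -> str:
        return self.nongapped.header["ref_digest"]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_tables(self.nongapped, directory / "nongapped.sxi")
        save_tables(self.gapped, directory / "gapped.sxi")

    @classmethod
    def load(cls, directory) -> "GenomeIndex":
        directory = Path(directory)
        ng = load_tables(directory / "nongapped.sxi")
        gp = load_tables(directory / "gapped.sxi")
        if ng.header["ref_digest"] != gp.header["ref_digest"]:
            raise IndexError_(f"{directory}: table pairs built from different references")
        return cls(nongapped=ng, gapped=gp)

    def check_reference(self, reference: list[tuple[str, PackedSequence]]) -> None:
        """Refuse to align when the reference does not match the index."""
        digest = reference_digest(reference)
        if digest != self.ref_digest:
            raise IndexError_(
                "reference digest mismatch: index was built from a different reference")


def build_index(reference, spaced_seed: SpacedSeed | None = None,
                contig_seed: ContigSeed | None = None,
                big_bucket_threshold: int | None = DEFAULT_BIG_BUCKET_THRESHOLD,
                sample_interval: int = DEFAULT_SAMPLE_INTERVAL) -> GenomeIndex:
    """Build both table pairs over a reference."""
    spaced_seed = spaced_seed or SpacedSeed()
    contig_seed = contig_seed or ContigSeed()
    return GenomeIndex(
        nongapped=build_tables(reference, spaced_seed, big_bucket_threshold, sample_interval),
        gapped=build_tables(reference, contig_seed, big_bucket_threshold, sample_interval),
    )
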