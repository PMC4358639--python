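import random
from collections import Counter

import pytest

from oracles import merge_intervals
from seedex.listops import (FLAG_CLAMPED, FLAG_PAIRED, adjust_to_diagonal,
                            cand_coverage, cand_dpos, cand_flags, cand_locus,
                            cand_strand, cand_sub, coalesce_windows,
                            count_coverage, exclude_previous, make_candidate,
                            pair_filter, prioritize, sort_unduplicate)


def random_candidates(rng, n, subs=4, dpos_max=5000):
    return [make_candidate(rng.randrange(2), rng.randrange(subs),
                           rng.randrange(dpos_max)) for _ in range(n)]


def test_pack_unpack_round_trip():
    rng = random.Random(0)
    for _ in range(500):
        strand = rng.randrange(2)
        sub = rng.randrange(128)
        dpos = rng.randrange(2 ** 31)
        cov = rng.randrange(256)
        flags = rng.randrange(4)
        c = make_candidate(strand, sub, dpos, cov, flags)
        assert (cand_strand(c), cand_sub(c), cand_dpos(c),
                cand_coverage(c), cand_flags(c)) == (strand, sub, dpos, cov, flags)


def test_packed_order_is_lexicographic():
    rng = random.Random(1)
    cands = random_candidates(rng, 2000, subs=128)
    by_value = sorted(cands)
    by_fields = sorted(cands, key=lambda c: (cand_strand(c), cand_sub(c), cand_dpos(c)))
    assert by_value == by_fields


def test_coverage_saturates_at_255():
    c = make_candidate(0, 0, 10, coverage=300)
    assert cand_coverage(c) == 255


def test_field_out_of_range_rejected():
    with pytest.raises(ValueError):
        make_candidate(0, 200, 0)


def test_adjust_to_diagonal():
    assert cand_dpos(adjust_to_diagonal(0, 1000, 40)) == 960
    assert cand_dpos(adjust_to_diagonal(0, 555, 0)) == 555
    clamped = adjust_to_diagonal(0, 3, 40)
    assert cand_dpos(clamped) == 0 and cand_flags(clamped) & FLAG_CLAMPED


def test_seeds_of_one_gapless_alignment_share_a_diagonal():
    # two seeds at read offsets 0 and 20 matching one locus at pos P, P+20
    a = adjust_to_diagonal(2, 1000, 0)
    b = adjust_to_diagonal(2, 1020, 20)
    assert cand_locus(a) == cand_locus(b)


def test_sort_unduplicate_against_set_oracle():
    rng = random.Random(2)
    assert sort_unduplicate([]) == []
    x, y = make_candidate(0, 0, 5), make_candidate(0, 0, 9)
    assert sort_unduplicate([x, x, y]) == [x, y]
    cands = random_candidates(rng, 10_000, subs=2, dpos_max=300)  # many duplicates
    assert sort_unduplicate(cands) == sorted(set(cands))


def test_count_coverage_multiplicity_and_conservation():
    x, y = make_candidate(0, 1, 5), make_candidate(1, 1, 5)
    out = count_coverage(sorted([x, x, x, y]))
    assert [(cand_locus(c), cand_coverage(c)) for c in out] == \
        [(cand_locus(x), 3), (cand_locus(y), 1)]
    assert count_coverage([x]) == [make_candidate(0, 1, 5, coverage=1)]
    rng = random.Random(3)
    cands = sorted(random_candidates(rng, 5000, subs=2, dpos_max=200))
    out = count_coverage(cands)
    oracle = Counter(cand_locus(c) for c in cands)
    assert {cand_locus(c): cand_coverage(c) for c in out} == dict(oracle)
    assert sum(cand_coverage(c) for c in out) == len(cands)


def test_prioritize_orders_by_coverage_then_position():
    a = make_candidate(0, 0, 30, coverage=1)
    b = make_candidate(0, 0, 10, coverage=3)
    c = make_candidate(0, 0, 20, coverage=2)
    assert prioritize([a, b, c], 10) == [b, c, a]
    equal = [make_candidate(0, 0, d, coverage=2) for d in (50, 10, 30)]
    assert prioritize(equal, 10) == sorted(equal)
    assert len(prioritize([a, b, c], 2)) == 2


def test_prioritize_matches_stable_sort_oracle():
    rng = random.Random(4)
    cands = [make_candidate(rng.randrange(2), rng.randrange(3), rng.randrange(1000),
                            coverage=rng.randrange(5)) for _ in range(500)]
    got = prioritize(cands, len(cands))
    assert got == sorted(cands, key=lambda c: (-cand_coverage(c), cand_locus(c)))


def test_paired_flag_outranks_at_equal_coverage():
    plain = make_candidate(0, 0, 10, coverage=2)
    flagged = make_candidate(0, 0, 99, coverage=2, flags=FLAG_PAIRED)
    assert prioritize([plain, flagged], 2) == [flagged, plain]


class TestPairFilter:
    def test_fr_pair_within_range_both_flagged(self):
        m1 = [make_candidate(0, 0, 100)]
        m2 = [make_candidate(1, 0, 350)]
        f1, f2 = pair_filter(m1, m2, 100, 500, "FR", 100, 100)
        assert cand_flags(f1[0]) & FLAG_PAIRED
        assert cand_flags(f2[0]) & FLAG_PAIRED

    def test_empty_list_flags_nothing(self):
        m1 = [make_candidate(0, 0, 100)]
        f1, f2 = pair_filter(m1, [], 100, 500, "FR", 100, 100)
        assert not cand_flags(f1[0]) & FLAG_PAIRED and f2 == []

    def test_same_strand_not_flagged_under_fr(self):
        m1 = [make_candidate(0, 0, 100)]
        m2 = [make_candidate(0, 0, 350)]
        f1, f2 = pair_filter(m1, m2, 100, 500, "FR", 100, 100)
        assert not cand_flags(f1[0]) & FLAG_PAIRED
        assert not cand_flags(f2[0]) & FLAG_PAIRED

    def test_fragment_length_out_of_range_not_flagged(self):
        m1 = [make_candidate(0, 0, 100)]
        m2 = [make_candidate(1, 0, 2000)]
        f1, _ = pair_filter(m1, m2, 100, 500, "FR", 100, 100)
        assert not cand_flags(f1[0]) & FLAG_PAIRED

    def test_different_sub_not_flagged(self):
        m1 = [make_candidate(0, 0, 100)]
        m2 = [make_candidate(1, 1, 350)]
        f1, _ = pair_filter(m1, m2, 100, 500, "FR", 100, 100)
        assert not cand_flags(f1[0]) & FLAG_PAIRED

    def test_symmetric_up_to_mate_labels(self):
        rng = random.Random(5)
        c1 = sorted(random_candidates(rng, 40, subs=2, dpos_max=1000))
        c2 = sorted(random_candidates(rng, 40, subs=2, dpos_max=1000))
        f1, f2 = pair_filter(c1, c2, 100, 500, "FR", 100, 100)
        g2, g1 = pair_filter(c2, c1, 100, 500, "FR", 100, 100)
        assert f1 == g1 and f2 == g2

    def test_brute_force_flag_agreement(self):
        rng = random.Random(6)
        c1 = sorted(random_candidates(rng, 30, subs=2, dpos_max=800))
        c2 = sorted(random_candidates(rng, 30, subs=2, dpos_max=800))
        f1, _ = pair_filter(c1, c2, 100, 500, "FR", 100, 100)

        def ok(a, b):
            if cand_sub(a) != cand_sub(b) or cand_strand(a) == cand_strand(b):
                return False
            da, db = cand_dpos(a), cand_dpos(b)
            fwd = da if cand_strand(a) == 0 else db
            rev = db if cand_strand(a) == 0 else da
            if fwd > rev:
                return False
            tlen = max(da, db) + 100 - min(da, db)
            return 100 <= tlen <= 500

        for a, fa in zip(c1, f1):
            assert bool(cand_flags(fa) & FLAG_PAIRED) == any(ok(a, b) for b in c2)


def test_exclude_previous_set_difference():
    rng = random.Random(7)
    current = sorted(set(random_candidates(rng, 300, subs=2, dpos_max=500)))
    seen = sorted(set(random_candidates(rng, 300, subs=2, dpos_max=500)))
    got = exclude_previous(current, seen)
    seen_loci = {cand_locus(c) for c in seen}
    assert got == [c for c in current if cand_locus(c) not in seen_loci]
    assert exclude_previous(current, []) == current
    assert exclude_previous(current, current) == []
    # conservation: excluded + retained partitions the input
    retained_loci = {cand_locus(c) for c in got}
    for c in current:
        assert (cand_locus(c) in retained_loci) != (cand_locus(c) in seen_loci)


class TestCoalesceWindows:
    ref_lengths = [100_000]

    def test_single_candidate_single_window(self):
        w, = coalesce_windows([make_candidate(0, 0, 500)], 100, 8, self.ref_lengths)
        assert (w.sub, w.strand, w.start, w.end) == (0, 0, 492, 608)

    def test_nearby_diagonals_merge(self):
        cands = [make_candidate(0, 0, d) for d in (100, 101, 103)]
        windows = coalesce_windows(cands, 100, 8, self.ref_lengths)
        assert len(windows) == 1
        assert windows[0].start == 92 and windows[0].end == 103 + 100 + 8

    def test_distant_diagonals_stay_separate(self):
        cands = [make_candidate(0, 0, 100), make_candidate(0, 0, 10_000)]
        assert len(coalesce_windows(cands, 100, 8, self.ref_lengths)) == 2

    def test_window_clipped_to_reference(self):
        w, = coalesce_windows([make_candidate(0, 0, 2)], 100, 8, [50])
        assert w.start == 0 and w.end == 50

    def test_matches_interval_merge_oracle_and_covers_all(self):
        rng = random.Random(8)
        read_len, wobble = 100, 31
        cands = sorted({make_candidate(rng.randrange(2), 0, rng.randrange(3000))
                        for _ in range(200)})
        windows = coalesce_windows(cands, read_len, wobble, self.ref_lengths)
        for strand in (0, 1):
            pts = [cand_dpos(c) for c in cands if cand_strand(c) == strand]
            if not pts:
                continue
            oracle = merge_intervals(pts, wobble)
            ours = [w for w in windows if w.strand == strand]
            assert len(ours) == len(oracle)
            for w, (lo, hi) in zip(ours, oracle):
                assert w.start == max(0, lo - wobble)
                assert w.end == min(self.ref_lengths[0], hi + read_len + wobble)
        # every candidate's [dpos, dpos+read_len) extent is covered
        for c in cands:
            covering = [w for w in windows if w.strand == cand_strand(c)
                        and w.start <= cand_dpos(c)
                        and cand_dpos(c) + read_len <= w.end]
            assert len(covering) == 1
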