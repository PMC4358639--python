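import random

import pytest

import seedex as sx
from conftest import random_dna
from oracles import gotoh_local_score
from seedex.gapped import (GappedConfig, SWGParams, align_read_gapped,
                           cigar_md_nm, cigar_read_len, default_wobble,
                           seed_schedule, swg_align)
from seedex.simeval import score_from_cigar_md

PARAMS = SWGParams()


class TestSeedSchedule:
    def test_hundred_nt_read_needs_six_iterations(self):
        sched = seed_schedule(100, 20)
        assert len(sched) == 6
        assert sched[0] == [0, 20, 40, 60, 80]

    def test_all_offsets_scheduled_exactly_once(self):
        sched = seed_schedule(100, 20)
        flat = [o for it in sched for o in it]
        assert sorted(flat) == list(range(81))
        assert len(flat) == len(set(flat))

    def test_cumulative_offsets_roughly_double(self):
        sched = seed_schedule(100, 20)
        cum = 0
        counts = []
        for it in sched:
            cum += len(it)
            counts.append(cum)
        # 5, 9, 17, 33, 65, 81: doubling until the offset space is exhausted
        for a, b in zip(counts, counts[1:-1]):
            assert b >= 2 * a - 1

    def test_seed_equals_read_single_offset(self):
        assert seed_schedule(20, 20) == [[0]]

    def test_seed_longer_than_read_empty(self):
        assert seed_schedule(10, 20) == []

    def test_last_first_iteration_seed_anchored_at_read_end(self):
        sched = seed_schedule(95, 20)
        assert sched[0][-1] == 75
        flat = sorted(o for it in sched for o in it)
        assert flat == list(range(76))


class TestSwgAlign:
    def test_identical_sequences(self):
        s = sx.encode(random_dna(random.Random(0), 50)).codes
        r = swg_align(s, s, PARAMS, min_score=1)
        assert (r.score, r.cigar, r.ref_start) == (100, "50M", 0)

    def test_two_nt_deletion(self):
        rng = random.Random(1)
        ref = random_dna(rng, 100)
        read = ref[:49] + ref[51:]
        r = swg_align(sx.encode(read).codes, sx.encode(ref).codes, PARAMS, min_score=1)
        assert r.score == 98 * 2 - (5 + 2 * 3) == 185
        assert r.cigar == "49M2D49M"

    def test_insertion(self):
        rng = random.Random(2)
        ref = random_dna(rng, 100)
        read = (ref[:50] + "A" * 5 + ref[50:])[:100]
        r = swg_align(sx.encode(read).codes, sx.encode(ref).codes, PARAMS, min_score=1)
        assert "5I" in r.cigar
        assert r.score == 95 * 2 - (5 + 5 * 3)

    def test_no_positive_match_returns_none(self):
        a = sx.encode("A" * 30).codes
        b = sx.encode("C" * 60).codes
        assert swg_align(a, b, PARAMS) is None

    def test_score_below_vt_suppressed_by_default(self):
        s = sx.encode(random_dna(random.Random(3), 40)).codes  # perfect = 80 < Vt
        assert swg_align(s, s, PARAMS) is None
        assert swg_align(s, s, PARAMS, min_score=1).score == 80

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_oracle_on_larger_instances(self, trial):
        rng = random.Random(100 + trial)
        n, m = rng.randrange(80, 121), rng.randrange(150, 261)
        a, b = random_dna(rng, n), random_dna(rng, m)
        got = swg_align(sx.encode(a).codes, sx.encode(b).codes, PARAMS, min_score=1)
        want = gotoh_local_score(a, b)
        assert (got.score if got else 0) == want

    def test_random_instances_match_oracle_and_rescore(self):
        rng = random.Random(7)
        for _ in range(150):
            n, m = rng.randrange(5, 40), rng.randrange(10, 80)
            a, b = random_dna(rng, n), random_dna(rng, m)
            got = swg_align(sx.encode(a).codes, sx.encode(b).codes, PARAMS, min_score=1)
            want = gotoh_local_score(a, b)
            if got is None:
                assert want <= 0
                continue
            assert got.score == want
            assert cigar_read_len(got.cigar) == n
            assert score_from_cigar_md(got.cigar, got.MD, PARAMS) == got.score

    def test_n_matches_nothing(self):
        a = sx.encode("ACGTNACGT").codes
        r = swg_align(a, a, PARAMS, min_score=1)
        # the N-N column scores as a mismatch, so the best local alignment
        # either absorbs it (8*2-6=10) or clips to one flank (4*2=8)
        assert r.score == 10


def test_default_wobble_tracks_affordable_gap_length():
    assert default_wobble(SWGParams(), 100) == (200 - 5 - 100) // 3
    assert default_wobble(SWGParams(Vt=400), 250) > default_wobble(SWGParams(Vt=450), 250)


@pytest.fixture(scope="module")
def setup():
    rng = random.Random(51)
    ref_str = random_dna(rng, 10000)
    reference = [("g", sx.encode(ref_str))]
    return reference, ref_str, sx.build_index(reference)


class TestAlignReadGapped:
    def _cfg(self, index, **kw):
        return GappedConfig(seed=index.gapped.seed, **kw)

    def test_exact_read_found_in_first_iteration(self, setup):
        reference, ref_str, index = setup
        read = sx.encode(ref_str[4000:4100])
        cfg = self._cfg(index, max_iterations=1)
        ms = align_read_gapped(read, reference, index, PARAMS, cfg)
        assert ms and ms[0].AS == 200 and ms[0].pos == 4000 and ms[0].cigar == "100M"

    def test_foreign_read_unmapped(self, setup):
        reference, _, index = setup
        read = sx.encode(random_dna(random.Random(99), 100))
        assert align_read_gapped(read, reference, index, PARAMS, self._cfg(index)) == []

    def test_read_with_insertion_maps_with_i_cigar(self, setup):
        reference, ref_str, index = setup
        read = (ref_str[2000:2050] + "ACGTA" + ref_str[2050:2095])
        ms = align_read_gapped(sx.encode(read), reference, index, PARAMS, self._cfg(index))
        assert ms and "5I" in ms[0].cigar
        assert ms[0].AS == gotoh_local_score(read, ref_str[1900:2250])

    def test_read_with_deletion_maps_with_d_cigar(self, setup):
        reference, ref_str, index = setup
        read = ref_str[3000:3050] + ref_str[3053:3103]
        ms = align_read_gapped(sx.encode(read), reference, index, PARAMS, self._cfg(index))
        assert ms and "3D" in ms[0].cigar and ms[0].pos == 3000

    def test_reverse_strand_read(self, setup):
        reference, ref_str, index = setup
        read = sx.reverse_complement(sx.encode(ref_str[5000:5100]))
        ms = align_read_gapped(read, reference, index, PARAMS, self._cfg(index))
        assert ms and ms[0].strand == 1 and ms[0].pos == 5000

    def test_more_effort_never_loses_mappings(self, setup):
        """Raising the candidate limit keeps every mapping found at lower
        effort (the speed/sensitivity dial is monotone)."""
        reference, ref_str, index = setup
        rng = random.Random(52)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for _ in range(5):
            start = rng.randrange(0, 9800)
            s = list(ref_str[start:start + 100])
            for i in rng.sample(range(100), 4):
                s[i] = flip[s[i]]
            read = sx.encode("".join(s))
            low = align_read_gapped(read, reference, index, PARAMS,
                                    self._cfg(index, max_candidates=4, max_satisfactory=64))
            high = align_read_gapped(read, reference, index, PARAMS,
                                     self._cfg(index, max_candidates=64, max_satisfactory=64))
            assert {m.key for m in low} <= {m.key for m in high}

    def test_every_mapping_meets_vt_and_conserves_read_length(self, setup):
        reference, ref_str, index = setup
        rng = random.Random(53)
        for _ in range(10):
            start = rng.randrange(0, 9800)
            read = sx.encode(ref_str[start:start + 100])
            for m in align_read_gapped(read, reference, index, PARAMS, self._cfg(index)):
                assert m.AS >= PARAMS.Vt
                assert cigar_read_len(m.cigar) == 100

    def test_candidates_not_realigned_across_iterations(self, setup, monkeypatch):
        """Exclusion correctness: no locus reaches the DP stage twice."""
        reference, ref_str, index = setup
        seen_windows = []
        import seedex.gapped as gp
        real = gp.swg_align

        def spy(read_codes, window_codes, params, min_score=None):
            return real(read_codes, window_codes, params, min_score)
        monkeypatch.setattr(gp, "swg_align", spy)

        aligned_loci = []
        real_extend = gp._extend_state

        def spy_extend(state, cands, index_, reference_, params_, cfg_):
            from seedex.listops import cand_locus
            top = gp.prioritize(cands, cfg_.max_candidates)
            aligned_loci.extend(cand_locus(c) for c in top)
            return real_extend(state, cands, index_, reference_, params_, cfg_)
        monkeypatch.setattr(gp, "_extend_state", spy_extend)

        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        s = list(ref_str[6000:6100])
        for i in (10, 35, 60, 85):
            s[i] = flip[s[i]]
        align_read_gapped(sx.encode("".join(s)), reference, index, PARAMS,
                          self._cfg(index, max_satisfactory=4))
        assert len(aligned_loci) == len(set(aligned_loci))


def test_cigar_md_nm_roundtrip():
    read = sx.encode("ACGTACGTAC").codes
    window = sx.encode("ACGTTCGTAC").codes
    nm, md = cigar_md_nm(read, window, "10M", 0)
    assert nm == 1 and md == "4T5"
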