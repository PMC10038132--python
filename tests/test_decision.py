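"""Reconciliation, decision rules, tail filter and 1-bp re-positioning."""

import math

from nibbletrim import (
    DEFAULT_ADAPTER1,
    DEFAULT_ADAPTER2,
    ErrorProfile,
    FastqRead,
    PackedSeq,
    adjust_position,
    cut_pair,
    decide,
    four_way_match,
    reconcile,
    simulate_pair,
)
from nibbletrim.engine import MatchCandidate, PairMatchState
from nibbletrim.scoring import phred_array

from conftest import random_dna

ZERO = ErrorProfile(0, 0, 0)
ADAPTERS = (PackedSeq(DEFAULT_ADAPTER1), PackedSeq(DEFAULT_ADAPTER2))


class TestReconcile:
    def test_equal_positions_sum_scores(self):
        assert reconcile((30, 12.0), (30, 9.0)) == (30, 21.0)

    def test_unequal_positions_keep_max_score(self):
        assert reconcile((30, 12.0), (31, 9.0)) == (30, 12.0)
        assert reconcile((30, 9.0), (31, 12.0)) == (31, 12.0)

    def test_absent_is_identity(self):
        assert reconcile((None, 0.0), (42, 7.5)) == (42, 7.5)
        assert reconcile((42, 7.5), (None, 0.0)) == (42, 7.5)
        assert reconcile((None, 0.0), (None, 0.0)) == (None, 0.0)


def _state_for(r1, r2, **cands):
    """Build a PairMatchState with hand-set candidates."""
    absent = MatchCandidate(None, 0, 0.0, False)
    return PairMatchState(
        r1_adapter=cands.get("r1_adapter", absent),
        r2_adapter=cands.get("r2_adapter", absent),
        r1_pe=cands.get("r1_pe", absent),
        r2_pe=cands.get("r2_pe", absent),
        packed_r1=PackedSeq(r1.bases),
        packed_r2=PackedSeq(r2.bases),
        phred_r1=phred_array(r1.quals),
        phred_r2=phred_array(r2.quals),
        adapter1=ADAPTERS[0],
        adapter2=ADAPTERS[1],
    )


class TestDecide:
    def test_agreed_trim_on_error_free_pair(self, rng):
        r1, r2, _ = simulate_pair(50, 100, DEFAULT_ADAPTER1, DEFAULT_ADAPTER2, ZERO, rng)
        state = four_way_match(r1, r2, *ADAPTERS)
        v = decide(state, r1, r2)
        assert v.trim and v.insert_size_r1 == 50 and v.insert_size_r2 == 50
        assert v.reason == "agreed"
        t1, t2 = cut_pair(r1, r2, v)
        assert len(t1.bases) == len(t1.quals) == 50

    def test_adapter_free_pair_untrimmed(self, rng):
        r1, r2, _ = simulate_pair(120, 100, DEFAULT_ADAPTER1, DEFAULT_ADAPTER2, ZERO, rng)
        state = four_way_match(r1, r2, *ADAPTERS)
        v = decide(state, r1, r2)
        assert not v.trim and v.reason == "below-threshold"
        assert v.insert_size_r1 == 100 and v.insert_size_r2 == 100

    def test_low_quality_override_trims_both(self, rng):
        # read 1 finds the adapter at 8 with a strong score; read 2's 16-mer
        # at 8 is all Q2 (raw mean accuracy 0.369 < 0.6) -> both trimmed at 8.
        bases1 = random_dna(rng, 8) + DEFAULT_ADAPTER1 + random_dna(rng, 59)
        r1 = FastqRead("p/1", bases1, "I" * 100)
        # positions 7..12 of read 2 are C so the 1-bp re-positioning cannot
        # shift the cut (the adapter head AGAT contains no C)
        bases2 = random_dna(rng, 7) + "C" * 6 + random_dna(rng, 87)
        r2 = FastqRead("p/2", bases2, "I" * 8 + "#" * 92)
        state = _state_for(
            r1, r2, r1_adapter=MatchCandidate(8, 16, 15.0, True)
        )
        v = decide(state, r1, r2)
        assert v.trim and v.reason == "low-quality-override"
        assert v.insert_size_r1 == 8 and v.insert_size_r2 == 8

    def test_override_when_mate_too_short_to_check(self, rng):
        bases1 = random_dna(rng, 60) + DEFAULT_ADAPTER1 + random_dna(rng, 7)
        r1 = FastqRead("p/1", bases1, "I" * 100)
        r2 = FastqRead("p/2", random_dna(rng, 40), "I" * 40)  # len 40 <= pos 60
        state = _state_for(r1, r2, r1_adapter=MatchCandidate(60, 16, 15.0, True))
        v = decide(state, r1, r2)
        assert v.trim and v.reason == "low-quality-override"
        assert v.insert_size_r2 == 40  # clamped to the short mate

    def test_tail_false_positive_rejected(self, rng):
        r1 = FastqRead("p/1", random_dna(rng, 100), "I" * 100)
        r2 = FastqRead("p/2", random_dna(rng, 100), "I" * 100)
        # both hits of read 1 in the 12-bp tail but at different positions,
        # and no read has agreeing hits -> E & !R
        state = _state_for(
            r1,
            r2,
            r1_adapter=MatchCandidate(95, 16, 16.0, True),
            r1_pe=MatchCandidate(92, 16, 15.0, True),
        )
        v = decide(state, r1, r2)
        assert not v.trim and v.reason == "rejected-tail-FP"

    def test_tail_agreement_is_not_false_positive(self, rng):
        # C-run around position 95 keeps the 1-bp re-positioning at 95
        r1 = FastqRead("p/1", random_dna(rng, 94) + "C" * 6, "I" * 100)
        r2 = FastqRead("p/2", random_dna(rng, 100), "I" * 100)
        state = _state_for(
            r1,
            r2,
            r1_adapter=MatchCandidate(95, 16, 16.0, True),
            r1_pe=MatchCandidate(95, 16, 15.0, True),
        )
        v = decide(state, r1, r2)
        assert v.trim and v.insert_size_r1 == 95

    def test_adapter_only_tail_hit_passes_default_filter(self, rng):
        # with the pseudocode (both-hits-in-tail) definition, a lone adapter
        # hit in the tail is not suppressed; the prose variant suppresses it
        r1 = FastqRead("p/1", random_dna(rng, 100), "I" * 100)
        r2 = FastqRead("p/2", random_dna(rng, 100), "I" * 100)
        state = _state_for(r1, r2, r1_adapter=MatchCandidate(95, 16, 16.0, True))
        assert decide(state, r1, r2).trim
        v_prose = decide(state, r1, r2, tail_filter_prose=True)
        assert not v_prose.trim and v_prose.reason == "rejected-tail-FP"

    def test_infinite_threshold_never_trims(self, rng):
        for insert in (66, 80, 98):
            r1, r2, _ = simulate_pair(
                insert, 100, DEFAULT_ADAPTER1, DEFAULT_ADAPTER2, ZERO, rng
            )
            state = four_way_match(r1, r2, *ADAPTERS)
            assert not decide(state, r1, r2, trim_score=math.inf).trim

    def test_error_free_pairs_always_trimmed_exactly(self, rng):
        for _ in range(300):
            insert = int(rng.integers(33, 50)) * 2  # 66..98 even
            r1, r2, t = simulate_pair(
                insert, 100, DEFAULT_ADAPTER1, DEFAULT_ADAPTER2, ZERO, rng
            )
            state = four_way_match(r1, r2, *ADAPTERS)
            v = decide(state, r1, r2)
            assert v.trim
            assert v.insert_size_r1 == t.true_trim_pos_r1
            assert v.insert_size_r2 == t.true_trim_pos_r2

    def test_trimming_never_lengthens(self, rng):
        for insert in (66, 90, 100, 110):
            r1, r2, _ = simulate_pair(
                insert, 100, DEFAULT_ADAPTER1, DEFAULT_ADAPTER2,
                ErrorProfile.baseline(5), rng,
            )
            state = four_way_match(r1, r2, *ADAPTERS)
            t1, t2 = cut_pair(r1, r2, decide(state, r1, r2))
            assert len(t1.bases) <= 100 and len(t2.bases) <= 100
            assert len(t1.bases) == len(t1.quals)


class TestAdjustPosition:
    def test_exact_adapter_dominates(self, rng):
        read = PackedSeq(random_dna(rng, 40) + DEFAULT_ADAPTER1[:10] + random_dna(rng, 10))
        assert adjust_position(read, ADAPTERS[0], 40) == 40

    def test_deletion_before_adapter_shifts_left(self, rng):
        # a 1-bp deletion in the read just before the adapter: the adapter
        # really starts at s-1
        prefix = random_dna(rng, 39)
        read = PackedSeq(prefix + DEFAULT_ADAPTER1[:10] + random_dna(rng, 10))
        assert adjust_position(read, ADAPTERS[0], 40) == 39

    def test_all_candidates_tie_keeps_s(self):
        read = PackedSeq("A" * 50)
        adapter = PackedSeq("AAAA")
        assert adjust_position(read, adapter, 20) == 20

    def test_negative_candidate_skipped(self):
        read = PackedSeq(DEFAULT_ADAPTER1)
        assert adjust_position(read, ADAPTERS[0], 0) == 0
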