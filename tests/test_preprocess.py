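"""Trimming, DUST masking, repeat masking and cross-study merging."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radortho.preprocess import (MergePolicy, RadLocus, mask_low_complexity,
                                 mask_repeat_library, merge_studies, trim_loci)
from radortho.sequtil import revcomp

from _oracles import dust_mask_bruteforce
from conftest import DEBRUIJN_60, make_locus, random_seq


class TestTrim:
    def test_long_locus_is_cut_to_target(self, rng):
        loc = make_locus("sal|s1|L1", random_seq(rng, 95))
        res = trim_loci([loc], 60)
        assert len(res.loci) == 1 and len(res.loci[0].seq) == 60
        assert res.loci[0].seq == loc.seq[:60]
        assert res.n_dropped == 0

    def test_exact_length_locus_is_unchanged(self, rng):
        seq = random_seq(rng, 60)
        res = trim_loci([make_locus("a|s1|L1", seq)], 60)
        assert res.loci[0].seq == seq

    def test_short_locus_is_dropped_and_counted(self, rng):
        res = trim_loci([make_locus("a|s1|L1", random_seq(rng, 45)),
                         make_locus("a|s1|L2", random_seq(rng, 61))], 60)
        assert res.n_dropped == 1
        assert [l.id for l in res.loci] == ["a|s1|L2"]

    def test_trim_is_idempotent(self, rng):
        loci = [make_locus(f"a|s1|L{i}", random_seq(rng, 70)) for i in range(5)]
        once = trim_loci(loci, 60)
        twice = trim_loci(once.loci, 60)
        assert [l.seq for l in twice.loci] == [l.seq for l in once.loci]
        assert twice.n_dropped == 0


class TestDustMasking:
    def test_homopolymer_is_fully_masked(self):
        out = mask_low_complexity([make_locus("a|s1|L1", "A" * 60)])
        assert out[0].mask.all()
        assert out[0].seq == "A" * 60  # letters unchanged

    def test_all_distinct_triplets_unmasked(self):
        out = mask_low_complexity([make_locus("a|s1|L1", DEBRUIJN_60)])
        assert not out[0].mask.any()

    @pytest.mark.parametrize("seq", [
        "ACACACACACACGTGTGTGTGTGT",
        "A" * 10 + "CGTACGGTCA" * 3 + "TTTTTTTTTT",
        DEBRUIJN_60[:30] + "CACACACACACACA",
    ])
    def test_mask_matches_exhaustive_window_enumeration(self, seq):
        out = mask_low_complexity([make_locus("a|s1|L1", seq)],
                                  window=64, score_threshold=2.0)
        oracle = dust_mask_bruteforce(seq, 64, 2.0)
        assert np.array_equal(out[0].mask, oracle)

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 60)
            out = mask_low_complexity([make_locus("a|s1|L1", seq)])
            assert np.array_equal(out[0].mask,
                                  dust_mask_bruteforce(seq, 64, 2.0))

    def test_masking_is_idempotent(self, rng):
        loci = [make_locus("a|s1|L1", "ACACACACACACAC" + random_seq(rng, 46))]
        once = mask_low_complexity(loci)
        twice = mask_low_complexity(once)
        assert np.array_equal(once[0].mask, twice[0].mask)

    @given(st.floats(min_value=0.5, max_value=4.0),
           st.floats(min_value=0.5, max_value=4.0))
    @settings(max_examples=20, deadline=None)
    def test_masked_fraction_monotone_in_threshold(self, t1, t2):
        lo, hi = sorted((t1, t2))
        seq = "ACACACACACAC" + DEBRUIJN_60[:24] + "GGGGGGGG" + DEBRUIJN_60[24:40]
        m_strict = mask_low_complexity([make_locus("a|s1|L1", seq)],
                                       score_threshold=lo)[0].mask
        m_loose = mask_low_complexity([make_locus("a|s1|L1", seq)],
                                      score_threshold=hi)[0].mask
        assert (m_strict | m_loose).sum() == m_strict.sum()

    def test_non_acgtn_characters_rejected(self):
        with pytest.raises(ValueError):
            mask_low_complexity([make_locus("a|s1|L1", "ACGTX" * 6)])


class TestRepeatMasking:
    def test_exact_repeat_copy_is_masked(self, rng):
        repeat = random_seq(rng, 30)
        seq = DEBRUIJN_60[:20] + repeat + DEBRUIJN_60[20:30]
        out = mask_repeat_library([make_locus("a|s1|L1", seq)],
                                  [("rep1", repeat)])
        assert out[0].mask[20:50].all()
        assert not out[0].mask[:20].any() and not out[0].mask[50:].any()

    def test_unrelated_locus_is_unchanged(self, rng):
        out = mask_repeat_library([make_locus("a|s1|L1", DEBRUIJN_60)],
                                  [("rep1", random_seq(rng, 40))])
        assert not out[0].mask.any()

    def test_reverse_complement_repeat_is_masked(self, rng):
        repeat = random_seq(rng, 25)
        seq = DEBRUIJN_60[:15] + revcomp(repeat) + DEBRUIJN_60[15:35]
        out = mask_repeat_library([make_locus("a|s1|L1", seq)],
                                  [("rep1", repeat)])
        assert out[0].mask[15:40].all()

    def test_empty_library_is_noop(self, rng):
        loci = [make_locus("a|s1|L1", random_seq(rng))]
        assert mask_repeat_library(loci, []) is loci


class TestMergeStudies:
    def test_identical_locus_in_two_studies_merges_fully(self, rng):
        seq = random_seq(rng)
        loci = [make_locus("a|s1|L1", seq, species="a", study="s1"),
                make_locus("a|s2|L1", seq, species="a", study="s2")]
        res = merge_studies(loci, MergePolicy(min_studies=2))
        assert res.n_groups == 1
        assert res.sharing_pct == 100.0
        assert res.loci[0].id == "a|s1|L1"  # representative: first study

    def test_locus_below_study_threshold_is_excluded(self, rng):
        shared = random_seq(rng)
        loci = []
        for s in ("s1", "s2", "s3", "s4"):
            loci.append(make_locus(f"a|{s}|L1", shared, species="a", study=s))
        loci.append(make_locus("a|s1|L9", random_seq(rng), species="a",
                               study="s1"))  # in one study only
        res = merge_studies(loci, MergePolicy(min_studies=3))
        assert res.n_groups == 1
        assert all(l.id != "a|s1|L9" for l in res.loci)

    def test_sharing_is_relative_to_smallest_study(self, rng):
        # studies of 10 and 8 loci, 6 shared -> 75.0% of the smaller study
        shared = [random_seq(rng) for _ in range(6)]
        loci = []
        for i, seq in enumerate(shared):
            loci.append(make_locus(f"a|s1|L{i}", seq, species="a", study="s1"))
            loci.append(make_locus(f"a|s2|L{i}", seq, species="a", study="s2"))
        for i in range(4):
            loci.append(make_locus(f"a|s1|X{i}", random_seq(rng),
                                   species="a", study="s1"))
        for i in range(2):
            loci.append(make_locus(f"a|s2|Y{i}", random_seq(rng),
                                   species="a", study="s2"))
        res = merge_studies(loci, MergePolicy(min_studies=2))
        assert res.n_groups == 6
        assert res.sharing_pct == pytest.approx(75.0)

    def test_two_mismatches_still_merge_but_three_do_not(self, rng):
        seq = random_seq(rng)
        two = list(seq)
        two[5], two[20] = _other(two[5]), _other(two[20])
        three = list(two)
        three[40] = _other(three[40])
        pol = MergePolicy(identity_min=0.95, mismatch_max=2, min_studies=2)
        res2 = merge_studies([make_locus("a|s1|L1", seq, "a", "s1"),
                              make_locus("a|s2|L1", "".join(two), "a", "s2")],
                             pol)
        assert res2.n_groups == 1
        res3 = merge_studies([make_locus("a|s1|L1", seq, "a", "s1"),
                              make_locus("a|s2|L1", "".join(three), "a", "s2")],
                             pol)
        assert res3.n_groups == 0

    def test_reverse_complement_counts_as_same_locus(self, rng):
        seq = random_seq(rng)
        res = merge_studies([make_locus("a|s1|L1", seq, "a", "s1"),
                             make_locus("a|s2|L1", revcomp(seq), "a", "s2")],
                            MergePolicy(min_studies=2))
        assert res.n_groups == 1

    def test_same_study_duplicates_are_a_conflict(self, rng):
        seq = random_seq(rng)
        loci = [make_locus("a|s1|L1", seq, "a", "s1"),
                make_locus("a|s1|L2", seq, "a", "s1"),
                make_locus("a|s2|L1", seq, "a", "s2")]
        res = merge_studies(loci, MergePolicy(min_studies=2))
        assert res.n_conflicts == 1
        assert res.n_groups == 0

    def test_merge_invariant_to_input_order(self, rng):
        seqs = [random_seq(rng) for _ in range(8)]
        loci = []
        for i, seq in enumerate(seqs):
            loci.append(make_locus(f"a|s1|L{i}", seq, "a", "s1"))
            if i % 2 == 0:
                loci.append(make_locus(f"a|s2|M{i}", seq, "a", "s2"))
        fwd = merge_studies(loci, MergePolicy(min_studies=2))
        rev = merge_studies(loci[::-1], MergePolicy(min_studies=2))
        assert [l.id for l in fwd.loci] == [l.id for l in rev.loci]
        assert [l.seq for l in fwd.loci] == [l.seq for l in rev.loci]

    def test_multi_species_input_rejected(self, rng):
        with pytest.raises(ValueError):
            merge_studies([make_locus("a|s1|L1", random_seq(rng), "a", "s1"),
                           make_locus("b|s1|L1", random_seq(rng), "b", "s1")],
                          MergePolicy())


def _other(base: str) -> str:
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]


@pytest.mark.parametrize("kwargs", [
    {"identity_min": 0.0}, {"identity_min": 1.5},
    {"mismatch_max": -1}, {"min_studies": 0},
])
def test_invalid_merge_policies_rejected(kwargs):
    with pytest.raises(ValueError):
        MergePolicy(**kwargs)
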