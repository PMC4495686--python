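"""Seeded local alignment, best hits, threshold and uniqueness filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radortho.align import (AlignmentThresholds, PairwiseHit, ScoringScheme,
                            align_all_pairs, extract_best_hits, filter_hits,
                            filter_unique, read_hits, swap_hit, write_hits)
from radortho.sequtil import revcomp

from _oracles import sw_score
from conftest import make_locus, mutate, random_seq


def _hit(qid="A|s1|q", sid="B|s1|s", score=50.0, identity=0.95,
         length=60, mismatches=2, gaps=0, strand="+"):
    return PairwiseHit(qid, sid, qid.split("|")[0], sid.split("|")[0],
                       strand, length, identity, mismatches, gaps, score)


class TestAlignAllPairs:
    def test_identical_loci_align_perfectly(self, rng):
        seq = random_seq(rng)
        hits = align_all_pairs([make_locus("A|s1|q", seq)],
                               [make_locus("B|s1|s", seq)])
        assert len(hits) == 1
        h = hits[0]
        assert (h.aln_length, h.identity, h.mismatches, h.strand) == \
            (60, 1.0, 0, "+")
        assert h.score == 60.0

    def test_two_substitutions_verified_against_dp_oracle(self, rng):
        a = random_seq(rng)
        b = list(a)
        b[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[20]]
        b[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[40]]
        b = "".join(b)
        hits = align_all_pairs([make_locus("A|s1|q", a)],
                               [make_locus("B|s1|s", b)])
        assert len(hits) == 1
        h = hits[0]
        assert h.mismatches == 2
        assert h.identity == pytest.approx(58 / 60)
        assert h.score == sw_score(a, b)

    def test_reverse_complement_subject_found_on_minus_strand(self, rng):
        seq = random_seq(rng)
        hits = align_all_pairs([make_locus("A|s1|q", seq)],
                               [make_locus("B|s1|s", revcomp(seq))])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].identity == 1.0

    def test_fully_masked_locus_produces_no_hits(self, rng):
        seq = random_seq(rng)
        q = make_locus("A|s1|q", seq, mask=np.ones(60, dtype=bool))
        s = make_locus("B|s1|s", seq)
        assert align_all_pairs([q], [s]) == []
        assert align_all_pairs([make_locus("A|s1|q", seq)],
                               [make_locus("B|s1|s", seq,
                                           mask=np.ones(60, dtype=bool))]) == []

    def test_unrelated_loci_share_no_seed(self, rng):
        hits = align_all_pairs([make_locus("A|s1|q", random_seq(rng))],
                               [make_locus("B|s1|s", random_seq(rng))])
        assert hits == []

    def test_same_species_input_rejected(self, rng):
        loc = make_locus("A|s1|q", random_seq(rng))
        with pytest.raises(ValueError):
            align_all_pairs([loc], [loc])

    def test_seeded_aligner_equals_smith_waterman_oracle(
            self, related_locus_fixture):
        """On every cross-species pair: any reported hit carries the exact
        optimal local score, and every seed-sharing pair whose optimal score
        clears the floor is reported."""
        loci_a, loci_b = related_locus_fixture
        min_score = 20.0
        hits = {(h.query_id, h.subject_id): h
                for h in align_all_pairs(loci_a, loci_b, min_score=min_score)}
        k = 11
        for qa in loci_a:
            q_kmers = {qa.seq[i:i + k] for i in range(len(qa.seq) - k + 1)} | \
                {revcomp(qa.seq)[i:i + k]
                 for i in range(len(qa.seq) - k + 1)}
            for sb in loci_b:
                s_kmers = {sb.seq[i:i + k]
                           for i in range(len(sb.seq) - k + 1)}
                oracle = max(sw_score(qa.seq, sb.seq),
                             sw_score(revcomp(qa.seq), sb.seq))
                key = (qa.id, sb.id)
                if key in hits:
                    assert hits[key].score == oracle
                elif q_kmers & s_kmers:
                    assert oracle < min_score

    def test_score_symmetry_between_directions(self, related_locus_fixture):
        loci_a, loci_b = related_locus_fixture
        fwd = {(h.query_id, h.subject_id): h.score
               for h in align_all_pairs(loci_a, loci_b)}
        bwd = {(h.subject_id, h.query_id): h.score
               for h in align_all_pairs(loci_b, loci_a)}
        assert fwd == bwd


class TestBestHits:
    def test_highest_score_wins(self):
        hits = [_hit(sid="B|s1|s1", score=55), _hit(sid="B|s1|s2", score=40)]
        best = extract_best_hits(hits)
        assert len(best) == 1 and best[0].subject_id == "B|s1|s1"
        assert best[0].rank == 1

    def test_score_tie_broken_by_identity(self):
        hits = [_hit(sid="B|s1|s1", score=50, identity=0.95),
                _hit(sid="B|s1|s2", score=50, identity=0.97)]
        assert extract_best_hits(hits)[0].subject_id == "B|s1|s2"

    def test_full_tie_broken_by_subject_id(self):
        hits = [_hit(sid="B|s1|s2"), _hit(sid="B|s1|s1")]
        assert extract_best_hits(hits)[0].subject_id == "B|s1|s1"

    def test_query_without_hits_is_absent(self):
        assert extract_best_hits([]) == []

    def test_brute_force_agreement_on_random_hits(self, rng):
        hits = []
        for q in range(6):
            for s in range(4):
                hits.append(_hit(qid=f"A|s1|q{q}", sid=f"B|s1|s{s}",
                                 score=float(rng.integers(30, 36)),
                                 identity=float(rng.integers(90, 100)) / 100,
                                 length=int(rng.integers(50, 61))))
        best = {h.query_id: h for h in extract_best_hits(hits)}
        for qid in {h.query_id for h in hits}:
            mine = [h for h in hits if h.query_id == qid]
            expected = sorted(mine, key=lambda h: (-h.score, -h.identity,
                                                   -h.aln_length,
                                                   h.subject_id))[0]
            assert best[qid].subject_id == expected.subject_id


class TestFilterHits:
    def test_strict_bounds_reject_marginal_hit(self):
        h = _hit(identity=0.94, length=60, mismatches=3)
        assert filter_hits([h], AlignmentThresholds.strict()) == []

    def test_relaxed_keeps_what_strict_rejects(self):
        h = _hit(identity=0.90, length=48, mismatches=5)
        assert filter_hits([h], AlignmentThresholds.relaxed()) == [h]
        assert filter_hits([h], AlignmentThresholds.strict()) == []

    def test_perfect_hit_passes_both(self):
        h = _hit(identity=1.0, length=60, mismatches=0)
        assert filter_hits([h], AlignmentThresholds.strict()) == [h]
        assert filter_hits([h], AlignmentThresholds.relaxed()) == [h]

    @given(st.lists(st.tuples(
        st.floats(min_value=0.5, max_value=1.0),
        st.integers(min_value=20, max_value=60),
        st.integers(min_value=0, max_value=20)), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_strict_filtered_is_subset_of_relaxed(self, rows):
        hits = [_hit(qid=f"A|s1|q{i}", identity=ident, length=ln, mismatches=mm)
                for i, (ident, ln, mm) in enumerate(rows)]
        strict = filter_hits(hits, AlignmentThresholds.strict())
        relaxed = filter_hits(hits, AlignmentThresholds.relaxed())
        assert set(id(h) for h in strict) <= set(id(h) for h in relaxed)

    def test_preset_values(self):
        assert AlignmentThresholds.preset("strict") == \
            AlignmentThresholds(0.95, 50, 2)
        assert AlignmentThresholds.preset("relaxed") == \
            AlignmentThresholds(0.85, 45, 10)
        with pytest.raises(ValueError):
            AlignmentThresholds.preset("lenient")


class TestFilterUnique:
    def test_doubly_hit_subject_removed_with_both_hits(self):
        hits = [_hit(qid="A|s1|q1", sid="B|s1|s"),
                _hit(qid="A|s1|q2", sid="B|s1|s")]
        assert filter_unique(hits) == []

    def test_bijective_best_hits_unchanged(self):
        hits = [_hit(qid=f"A|s1|q{i}", sid=f"B|s1|s{i}") for i in range(3)]
        assert filter_unique(hits) == hits

    def test_incoming_degree_oracle(self):
        hits = [_hit(qid=f"A|s1|q{i}", sid="B|s1|shared") for i in range(5)]
        hits.append(_hit(qid="A|s1|q9", sid="B|s1|solo"))
        out = filter_unique(hits)
        degree: dict[str, int] = {}
        for h in hits:
            degree[h.subject_id] = degree.get(h.subject_id, 0) + 1
        assert out == [h for h in hits if degree[h.subject_id] == 1]
        assert len(out) == 1


class TestHitIO:
    def test_write_read_preserves_fields(self, tmp_path, rng):
        seq = random_seq(rng)
        hits = align_all_pairs(
            [make_locus("A|s1|q", seq)],
            [make_locus("B|s1|s", mutate(seq, 2, rng)),
             make_locus("B|s1|r", revcomp(seq))])
        path = tmp_path / "hits.tsv"
        write_hits(hits, path)
        back = read_hits(path)
        assert len(back) == len(hits)
        for h1, h2 in zip(hits, back):
            assert (h1.query_id, h1.subject_id, h1.strand) == \
                (h2.query_id, h2.subject_id, h2.strand)
            assert h1.aln_length == h2.aln_length
            assert h1.mismatches == h2.mismatches
            assert h1.score == h2.score
            assert (h1.qstart, h1.qend, h1.sstart, h1.send) == \
                (h2.qstart, h2.qend, h2.sstart, h2.send)

    def test_swap_hit_is_involutive(self):
        h = _hit(score=42.0)
        assert swap_hit(swap_hit(h)) == h
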