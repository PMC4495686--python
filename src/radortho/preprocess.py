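"""Locus normalisation: trimming, masking and within-species study merging.

Consensus RAD loci arriving from different laboratories differ in length
(60-96 bp in the cross-laboratory data regime this package targets), so all
loci are first trimmed to a common length (60 bp by default, the shortest
read length among studies).  Low-complexity runs are then annotated with a
DUST-style mask so they cannot seed misleading alignments, optionally
supplemented by matches to a user-supplied repeat library.  Finally, when a
species is represented by several studies, near-identical loci (>=95%
identity and <=2 mismatches over the full trimmed length, either strand, by
default) are merged into one file of common loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequtil import revcomp, encode, hamming

__all__ = [
    "RadLocus",
    "MergePolicy",
    "TrimResult",
    "MergeResult",
    "trim_loci",
    "mask_low_complexity",
    "mask_repeat_library",
    "merge_studies",
]


@dataclass
class RadLocus:
    """One consensus RAD locus with species/study provenance and a base mask.

    The mask is an annotation only: masked bases keep their letters but are
    excluded from alignment seeding downstream.
    """

    id: str
    species: str
    study: str
    seq: str
    mask: np.ndarray = None  # bool per base, True = masked

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.seq), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.seq):
            raise ValueError(f"mask length != seq length for {self.id}")


@dataclass
class MergePolicy:
    """When two loci from different studies count as the same locus."""

    identity_min: float = 0.95
    mismatch_max: int = 2
    min_studies: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_min <= 1.0:
            raise ValueError("identity_min must be in (0, 1]")
        if self.mismatch_max < 0:
            raise ValueError("mismatch_max must be >= 0")
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")


@dataclass
class TrimResult:
    loci: list
    n_dropped: int


@dataclass
class MergeResult:
    """Common loci for one species plus merge accounting.

    ``sharing_pct`` is the number of common loci relative to the size of the
    smallest contributing study, in percent (100.0 when every locus of the
    smallest study found a partner in enough other studies).
    """

    loci: list
    sharing_pct: float
    n_groups: int
    n_conflicts: int
    group_members: dict[str, list[str]] = field(default_factory=dict)


def trim_loci(loci: list[RadLocus], target_length: int) -> TrimResult:
    """Keep the first ``target_length`` bases; drop shorter loci."""
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    kept, dropped = [], 0
    for loc in loci:
        if len(loc.seq) < target_length:
            dropped += 1
            continue
        kept.append(RadLocus(loc.id, loc.species, loc.study,
                             loc.seq[:target_length], loc.mask[:target_length]))
    return TrimResult(kept, dropped)


def dust_score(triplets) -> float:
    """DUST score of one window: sum of c*(c-1)/2 over triplet counts,
    normalised by (number of triplets - 1)."""
    counts: dict[int, int] = {}
    for t in triplets:
        counts[t] = counts.get(t, 0) + 1
    k = len(triplets)
    if k <= 1:
        return 0.0
    return sum(c * (c - 1) / 2 for c in counts.values()) / (k - 1)


def mask_low_complexity(loci: list[RadLocus], window: int = 64,
                        score_threshold: float = 2.0) -> list[RadLocus]:
    """DUST-style low-complexity masking.

    Every window of 4..``window`` bases is scored by triplet-composition
    repetitiveness (sum of c*(c-1)/2 over triplet counts, normalised by the
    number of triplets minus one); all bases of any window whose score
    exceeds ``score_threshold`` are masked.  Defaults follow the classical
    DUST parameterisation (window 64, threshold 2.0 -- roughly "more than
    three copies of some triplet in a window").  Sequence letters are left
    unchanged; masking is an annotation.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    out = []
    for loc in loci:
        if set(loc.seq) - set("ACGTN"):
            raise ValueError(f"non-ACGTN characters in {loc.id}")
        n = len(loc.seq)
        mask = loc.mask.copy()
        if n >= 4:
            enc = encode(loc.seq.replace("N", "A"))
            trip = enc[:-2].astype(np.int32) * 16 + enc[1:-1] * 4 + enc[2:]
            # all sub-windows, scored incrementally: appending a triplet with
            # prior count c raises sum(c*(c-1)/2) by exactly c
            for start in range(n - 3):
                counts: dict[int, int] = {}
                pair_sum = 0
                max_t = min(start + window, n) - 2  # triplet starts covered
                for ti in range(start, max_t):
                    c = counts.get(trip[ti], 0)
                    pair_sum += c
                    counts[trip[ti]] = c + 1
                    k = ti - start + 1
                    if k >= 2 and pair_sum / (k - 1) > score_threshold:
                        mask[start:ti + 3] = True
        out.append(RadLocus(loc.id, loc.species, loc.study, loc.seq, mask))
    return out


def mask_repeat_library(loci: list[RadLocus], repeats: list[tuple[str, str]],
                        max_mismatch: int = 1, min_match: int = 18) -> list[RadLocus]:
    """Mask bases covered by a >=``min_match`` bp repeat match, either strand.

    ``repeats`` is a list of ``(id, sequence)`` records.  An empty library is
    a no-op.  Matching is a direct scan of every ``min_match``-length window
    against every repeat offset at <=``max_mismatch`` mismatches; suitable
    for the compact repeat libraries this tool accepts, not a full
    RepeatMasker replacement.
    """
    if not repeats:
        return loci
    rep_enc = []
    for _, rseq in repeats:
        for s in (rseq, revcomp(rseq)):
            if len(s) >= min_match:
                rep_enc.append(encode(s))
    out = []
    for loc in loci:
        mask = loc.mask.copy()
        q = encode(loc.seq)
        n = len(loc.seq)
        for renc in rep_enc:
            m = renc.size
            for i in range(n - min_match + 1):
                w = q[i:i + min_match]
                for j in range(m - min_match + 1):
                    if hamming(w, renc[j:j + min_match]) <= max_mismatch:
                        mask[i:i + min_match] = True
                        break
        out.append(RadLocus(loc.id, loc.species, loc.study, loc.seq, mask))
    return out


def _full_length_match(a: str, b: str, policy: MergePolicy) -> bool:
    if len(a) != len(b):
        return False
    n = len(a)
    for bb in (b, revcomp(b)):
        mm = hamming(encode(a), encode(bb))
        if mm <= policy.mismatch_max and (n - mm) / n >= policy.identity_min:
            return True
    return False


def merge_studies(loci: list[RadLocus], policy: MergePolicy) -> MergeResult:
    """Merge per-study loci of one species into common loci.

    Loci are grouped by single-linkage over the full-trimmed-length match
    criterion (identity >= ``identity_min`` AND mismatches <=
    ``mismatch_max``, either strand).  Groups seen in >= ``min_studies``
    distinct studies are emitted as one common locus, represented by the
    sequence from the lexicographically first (study, id) in the group.
    Groups in which one study contributes two or more loci are ambiguous --
    the merge cannot decide which copy is "the" locus -- and are excluded
    and counted as conflicts.
    """
    if not loci:
        return MergeResult([], 0.0, 0, 0)
    species = {l.species for l in loci}
    if len(species) != 1:
        raise ValueError("merge_studies expects loci from a single species")

    studies = sorted({l.study for l in loci})
    # single-linkage grouping; an exact-sequence prefilter keeps the common
    # case (identical loci across studies) linear
    parent = list(range(len(loci)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_seq: dict[str, list[int]] = {}
    for i, loc in enumerate(loci):
        key = min(loc.seq, revcomp(loc.seq))
        by_seq.setdefault(key, []).append(i)
    for members in by_seq.values():
        for i in members[1:]:
            union(members[0], i)
    if policy.mismatch_max > 0 or policy.identity_min < 1.0:
        reps = sorted({find(i) for i in range(len(loci))})
        for a in range(len(reps)):
            for b in range(a + 1, len(reps)):
                i, j = reps[a], reps[b]
                if find(i) != find(j) and _full_length_match(
                        loci[i].seq, loci[j].seq, policy):
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(loci)):
        groups.setdefault(find(i), []).append(i)

    common: list[RadLocus] = []
    group_members: dict[str, list[str]] = {}
    n_conflicts = 0
    for members in groups.values():
        studies_in = [loci[i].study for i in members]
        if len(set(studies_in)) < len(studies_in):
            n_conflicts += 1
            continue
        if len(set(studies_in)) < policy.min_studies:
            continue
        rep = min(members, key=lambda i: (loci[i].study, loci[i].id))
        rep_loc = loci[rep]
        common.append(RadLocus(rep_loc.id, rep_loc.species, rep_loc.study,
                               rep_loc.seq, rep_loc.mask))
        group_members[rep_loc.id] = sorted(loci[i].id for i in members)

    common.sort(key=lambda l: l.id)
    smallest = min(sum(1 for l in loci if l.study == s) for s in studies)
    sharing = 100.0 * len(common) / smallest if smallest else 0.0
    return MergeResult(common, sharing, len(common), n_conflicts, group_members)
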