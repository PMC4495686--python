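"""All-vs-all cross-species local alignment and best-hit filtering.

Cross-species ortholog candidates are found by locally aligning every locus
of one species against every locus of another.  Alignment uses a seed-and-
extend strategy: a pair is only aligned if the two loci share at least one
exact, unmasked k-mer (default k = 11) on either strand; the surviving
pairs are aligned optimally (Smith-Waterman scoring via Biopython's
PairwiseAligner) with affine gap penalties.  Significance is ranked by raw
alignment score, which is deterministic and monotone in the identity /
length / mismatch quantities the downstream filters act on.

Two filter presets mirror the two analyses this pipeline is built for:
``strict`` (>=95% identity, >=50 bp, <=2 mismatches -- used within closely
related species groups to separate orthologs from paralogs) and ``relaxed``
(>=85% identity, >=45 bp, <=10 mismatches -- used across distant species).
A uniqueness filter then removes any subject locus that is the best hit of
more than one query, guarding against residual paralogy and uncharacterised
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import Align

from .preprocess import RadLocus
from .sequtil import revcomp

__all__ = [
    "ScoringScheme",
    "AlignmentThresholds",
    "PairwiseHit",
    "align_all_pairs",
    "swap_hit",
    "extract_best_hits",
    "filter_hits",
    "filter_unique",
    "write_hits",
    "read_hits",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores (first gap base costs ``gap_open``,
    each further base ``gap_extend``)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class AlignmentThresholds:
    identity_min: float
    aln_length_min: int
    mismatch_max: int

    @classmethod
    def strict(cls) -> "AlignmentThresholds":
        return cls(0.95, 50, 2)

    @classmethod
    def relaxed(cls) -> "AlignmentThresholds":
        return cls(0.85, 45, 10)

    @classmethod
    def preset(cls, name: str) -> "AlignmentThresholds":
        try:
            return {"strict": cls.strict, "relaxed": cls.relaxed}[name]()
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None


@dataclass
class PairwiseHit:
    """One scored local alignment between loci of two different species.

    ``identity`` counts gap columns against identity but not against
    ``mismatches`` (mismatches are substitution columns only).  For minus-
    strand hits the query coordinates refer to the reverse-complemented
    query.  ``rank`` is 1 for the best hit of a query against a species.
    """

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    strand: str
    aln_length: int
    identity: float
    mismatches: int
    gaps: int
    score: float
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    rank: int = 0


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


def _unmasked_kmers(seq: str, mask, k: int):
    """Yield (kmer, start) for windows containing no masked base."""
    run = 0
    for i in range(len(seq)):
        run = run + 1 if not mask[i] else 0
        if run >= k:
            yield seq[i - k + 1:i + 1], i - k + 1


def _hit_from_alignment(aln, qid, sid, qsp, ssp, strand) -> PairwiseHit:
    c = aln.counts()
    gaps = c.internal_gaps  # local mode: flanks are outside the alignment
    length = c.identities + c.mismatches + gaps
    qsegs, ssegs = aln.aligned
    return PairwiseHit(
        query_id=qid, subject_id=sid, query_species=qsp, subject_species=ssp,
        strand=strand, aln_length=int(length),
        identity=c.identities / length if length else 0.0,
        mismatches=int(c.mismatches), gaps=int(gaps), score=float(aln.score),
        qstart=int(qsegs[0][0]), qend=int(qsegs[-1][1]),
        sstart=int(ssegs[0][0]), send=int(ssegs[-1][1]),
    )


def align_all_pairs(loci_a: list[RadLocus], loci_b: list[RadLocus],
                    scoring: ScoringScheme = ScoringScheme(),
                    seed_k: int = 11, min_score: float = 20.0) -> list[PairwiseHit]:
    """Local alignments between two species' locus sets.

    A query/subject pair is aligned only if it shares an exact k-mer that is
    unmasked in both loci, on either strand; hits scoring below
    ``min_score`` are suppressed.  One hit (the better strand; ties go to
    '+') is reported per aligned pair.
    """
    if not loci_a or not loci_b:
        return []
    if loci_a[0].species == loci_b[0].species:
        raise ValueError("align_all_pairs expects loci from different species")
    aligner = _aligner(scoring)

    index: dict[str, set[int]] = {}
    for j, sub in enumerate(loci_b):
        for kmer, _ in _unmasked_kmers(sub.seq, sub.mask, seed_k):
            index.setdefault(kmer, set()).add(j)

    hits: list[PairwiseHit] = []
    for q in loci_a:
        candidates: dict[int, set[str]] = {}
        for strand, (seq, mask) in (("+", (q.seq, q.mask)),
                                    ("-", (revcomp(q.seq), q.mask[::-1]))):
            for kmer, _ in _unmasked_kmers(seq, mask, seed_k):
                for j in index.get(kmer, ()):
                    candidates.setdefault(j, set()).add(strand)
        for j in sorted(candidates):
            sub = loci_b[j]
            best = None
            for strand in sorted(candidates[j]):  # '+' before '-'
                qseq = q.seq if strand == "+" else revcomp(q.seq)
                alns = aligner.align(qseq, sub.seq)
                if alns.score < min_score:
                    continue
                hit = _hit_from_alignment(alns[0], q.id, sub.id,
                                          q.species, sub.species, strand)
                if best is None or hit.score > best.score:
                    best = hit
            if best is not None:
                hits.append(best)
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


def swap_hit(hit: PairwiseHit) -> PairwiseHit:
    """The same alignment viewed from the subject side (score symmetric)."""
    return replace(
        hit, query_id=hit.subject_id, subject_id=hit.query_id,
        query_species=hit.subject_species, subject_species=hit.query_species,
        qstart=hit.sstart, qend=hit.send, sstart=hit.qstart, send=hit.qend,
        rank=0,
    )


def extract_best_hits(hits: list[PairwiseHit]) -> list[PairwiseHit]:
    """Keep, per query, its most significant hit against the subject species.

    Significance order: score, then identity, then alignment length, then
    lexicographically smallest subject id.
    """
    by_query: dict[str, list[PairwiseHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    best: list[PairwiseHit] = []
    for qid in sorted(by_query):
        winner = min(by_query[qid],
                     key=lambda h: (-h.score, -h.identity, -h.aln_length,
                                    h.subject_id))
        best.append(replace(winner, rank=1))
    return best


def filter_hits(hits: list[PairwiseHit],
                thresholds: AlignmentThresholds) -> list[PairwiseHit]:
    """Quality filter: identity AND length AND mismatch bounds."""
    return [h for h in hits
            if h.identity >= thresholds.identity_min
            and h.aln_length >= thresholds.aln_length_min
            and h.mismatches <= thresholds.mismatch_max]


def filter_unique(hits: list[PairwiseHit]) -> list[PairwiseHit]:
    """Drop subjects that are the best hit of more than one query.

    Input must be best hits for one directed species pair; in the output
    every subject has exactly one incoming best hit.
    """
    incoming: dict[str, int] = {}
    for h in hits:
        incoming[h.subject_id] = incoming.get(h.subject_id, 0) + 1
    return [h for h in hits if incoming[h.subject_id] == 1]


_COLUMNS = ("query", "subject", "pident", "length", "mismatches", "gaps",
            "qstart", "qend", "sstart", "send", "score", "rank")


def write_hits(hits: list[PairwiseHit], path) -> None:
    """12-column tab-separated hit table (minus strand: sstart > send)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for h in hits:
            sstart, send = (h.sstart + 1, h.send) if h.strand == "+" \
                else (h.send, h.sstart + 1)
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, f"{100 * h.identity:.2f}",
                h.aln_length, h.mismatches, h.gaps,
                h.qstart + 1, h.qend, sstart, send,
                f"{h.score:g}", h.rank))) + "\n")


def read_hits(path, species_of=lambda lid: lid.split("|")[0]) -> list[PairwiseHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (qid, sid, pid, length, mm, gaps, qs, qe, ss, se,
             score, rank) = line.rstrip("\n").split("\t")
            minus = int(ss) > int(se)
            sstart, send = (int(se) - 1, int(ss)) if minus \
                else (int(ss) - 1, int(se))
            hits.append(PairwiseHit(
                query_id=qid, subject_id=sid,
                query_species=species_of(qid), subject_species=species_of(sid),
                strand="-" if minus else "+", aln_length=int(length),
                identity=float(pid) / 100.0, mismatches=int(mm),
                gaps=int(gaps), score=float(score),
                qstart=int(qs) - 1, qend=int(qe), sstart=sstart, send=send,
                rank=int(rank)))
    return hits
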