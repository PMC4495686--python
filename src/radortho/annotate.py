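"""Genic annotation of RAD loci by similarity search against a gene database.

SbfI RAD loci are biased toward gene-rich genomic regions, and the fraction
of ortholog clusters falling in genes is one of the pipeline's headline
summaries.  A locus is flagged genic when its best local alignment against
a user-supplied nucleotide gene database is significant at an E-value-like
threshold (default 1e-5).

Significance follows a Karlin-Altschul-style formula,
``E = K * m * n * exp(-lambda * S)``, with fixed constants per search mode
(nucleotide: lambda = 1.33, K = 0.621, appropriate for +1/-2 ungapped
scoring; translated: lambda = 0.267, K = 0.041, appropriate for BLOSUM62),
where m is the query length, n the summed database length and S the best
raw alignment score.  The constants are part of this tool's definition of
significance -- they make the configured threshold reproducible -- rather
than an attempt to replicate any specific search engine's statistics.

Translated mode compares all six reading frames of the locus against all
six frames of each gene, catching protein-level conservation that
synonymous saturation hides from the nucleotide search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .preprocess import RadLocus
from .sequtil import revcomp

__all__ = ["AnnotationConfig", "AnnotationResult", "annotate_loci",
           "annotate_clusters", "significance"]

_NT_LAMBDA, _NT_K = 1.33, 0.621
_AA_LAMBDA, _AA_K = 0.267, 0.041


@dataclass
class AnnotationConfig:
    evalue_threshold: float = 1e-5
    search_mode: str = "nucleotide"  # or "translated"
    min_seed: int = 11

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.search_mode not in ("nucleotide", "translated"):
            raise ValueError("search_mode must be 'nucleotide' or 'translated'")
        if self.min_seed < 4:
            raise ValueError("min_seed must be >= 4")


@dataclass
class AnnotationResult:
    locus_id: str
    genic: bool
    best_gene: str | None
    evalue: float  # inf when no hit


def significance(score: float, query_len: int, db_len: int,
                 mode: str = "nucleotide") -> float:
    """E = K * m * n * exp(-lambda * S) with the module's fixed constants."""
    lam, k = (_NT_LAMBDA, _NT_K) if mode == "nucleotide" else (_AA_LAMBDA, _AA_K)
    return k * query_len * db_len * math.exp(-lam * score)


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _six_frames(seq: str) -> list[str]:
    frames = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            if sub:
                frames.append(str(Seq(sub).translate()))
    return frames


def _kmers(seq: str, mask, k: int) -> set[str]:
    out = set()
    run = 0
    for i in range(len(seq)):
        run = run + 1 if (mask is None or not mask[i]) else 0
        if run >= k:
            out.add(seq[i - k + 1:i + 1])
    return out


def annotate_loci(loci: list[RadLocus], gene_db: list[tuple[str, str]],
                  config: AnnotationConfig = AnnotationConfig()
                  ) -> dict[str, AnnotationResult]:
    """Flag each locus genic iff its best database hit is significant.

    ``gene_db`` is a list of (gene_id, sequence).  An empty database yields
    all-non-genic results.  In nucleotide mode, repeat/low-complexity-masked
    bases of the locus are excluded from seeding, mirroring the cross-species
    alignment stage.
    """
    results: dict[str, AnnotationResult] = {}
    if not gene_db:
        for loc in loci:
            results[loc.id] = AnnotationResult(loc.id, False, None, math.inf)
        return results

    db_len = sum(len(s) for _, s in gene_db)
    if config.search_mode == "nucleotide":
        aligner = _nt_aligner()
        gene_kmer_index: list[tuple[str, str, set[str]]] = []
        for gid, gseq in gene_db:
            kmers = _kmers(gseq, None, config.min_seed)
            gene_kmer_index.append((gid, gseq, kmers))
        for loc in loci:
            q_kmers = _kmers(loc.seq, loc.mask, config.min_seed) | \
                _kmers(revcomp(loc.seq), loc.mask[::-1], config.min_seed)
            best_score, best_gene = 0.0, None
            for gid, gseq, gk in gene_kmer_index:
                if not (q_kmers & gk):
                    continue
                for qseq in (loc.seq, revcomp(loc.seq)):
                    s = aligner.score(qseq, gseq)
                    if s > best_score or (s == best_score and best_gene is None):
                        best_score, best_gene = float(s), gid
            ev = significance(best_score, len(loc.seq), db_len, "nucleotide") \
                if best_gene else math.inf
            results[loc.id] = AnnotationResult(
                loc.id, ev < config.evalue_threshold, best_gene, ev)
    else:
        aa_db_len = db_len // 3
        aligner = _aa_aligner()
        gene_frames = [(gid, _six_frames(gseq)) for gid, gseq in gene_db]
        for loc in loci:
            q_frames = _six_frames(loc.seq)
            best_score, best_gene = 0.0, None
            for gid, frames in gene_frames:
                for qf in q_frames:
                    for gf in frames:
                        s = aligner.score(qf, gf)
                        if s > best_score:
                            best_score, best_gene = float(s), gid
            ev = significance(best_score, len(loc.seq) // 3, aa_db_len,
                              "translated") if best_gene else math.inf
            results[loc.id] = AnnotationResult(
                loc.id, ev < config.evalue_threshold, best_gene, ev)
    return results


def annotate_clusters(clusters, locus_flags: dict[str, bool],
                      rule: str = "any") -> tuple[dict[str, bool], float]:
    """Per-cluster genic flag plus the genic percentage over clusters.

    ``rule`` 'any': a cluster is genic iff >=1 member is genic; 'all':
    every member must be genic.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    agg = any if rule == "any" else all
    flags = {c.cluster_id: agg(locus_flags.get(m, False) for m in c.members)
             for c in clusters}
    n = len(flags)
    pct = 100.0 * sum(flags.values()) / n if n else 0.0
    return flags, pct
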