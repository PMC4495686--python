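"""Per-cluster alignment, interspecific variant extraction, concatenation.

Each ortholog cluster is multiple-aligned (center-star: the member
minimising summed pairwise distance is the center, every other member is
pairwise-aligned to it and the alignments are merged; for the typical
indel-free, equal-length RAD loci this reduces to columnwise stacking).
Species without sequence at a cluster are filled with 'N' across the whole
alignment, so missing data is coded explicitly rather than by omission.

A column is an interspecific variant iff at least two species have a
non-missing character there ('-' and 'N' count as missing) and at least two
distinct bases occur among them.  Variant columns from all clusters,
ordered by (cluster id, column), are concatenated into one species x sites
character matrix which can be written as sequential relaxed PHYLIP
(whitespace-delimited names, no 10-character truncation) for external
maximum-likelihood programs.  Note that such variant-only matrices carry
ascertainment bias; ML programs should be run with an appropriate
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "ClusterAlignment",
    "VariantSupermatrix",
    "MatrixStats",
    "align_cluster",
    "extract_variants",
    "concatenate",
    "write_phylip",
    "read_phylip",
    "matrix_stats",
    "write_provenance",
]

_MISSING = frozenset("N-")


@dataclass
class ClusterAlignment:
    """One cluster's species x columns alignment over {A,C,G,T,N,-}."""

    cluster_id: str
    rows: dict[str, str]  # species -> gapped/filled sequence
    n_columns: int

    def __post_init__(self) -> None:
        for sp, row in self.rows.items():
            if len(row) != self.n_columns:
                raise ValueError(f"row length mismatch for {sp} in "
                                 f"{self.cluster_id}")


@dataclass
class VariantSupermatrix:
    """Concatenated interspecific variant sites, one row per species.

    ``provenance`` maps each column (by position) to its source
    ``(cluster_id, cluster_column)``.
    """

    species: list[str]
    data: np.ndarray  # (n_species, n_columns) of single characters
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, sp: str) -> str:
        return "".join(self.data[self.species.index(sp)])

    def per_species_missing(self) -> dict[str, int]:
        return {sp: int(np.sum(self.data[i] == "N"))
                for i, sp in enumerate(self.species)}

    def pct_missing(self) -> float:
        if self.data.size == 0:
            return 0.0
        return 100.0 * float(np.sum(self.data == "N")) / self.data.size


@dataclass
class MatrixStats:
    n_loci: int
    n_variants: int
    pct_missing: float
    per_species_missing: dict[str, int]
    missing_range: tuple[int, int]


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _pair_rows(aln) -> tuple[str, str]:
    return str(aln[0]), str(aln[1])


def align_cluster(cluster_id: str, members: list[tuple[str, str, str]],
                  species_list: list[str] | None = None) -> ClusterAlignment:
    """Center-star alignment of one cluster.

    ``members`` are ``(locus_id, species, sequence)`` with sequences already
    re-oriented to the cluster reference strand.  The center is the member
    with minimal summed pairwise distance (ties by lexicographic locus id);
    when all members have equal length the distance is the Hamming distance
    and the merged alignment is the trivial columnwise stacking.  Species in
    ``species_list`` without a member get an all-'N' row.
    """
    if not members:
        raise ValueError("empty cluster")
    for lid, _, seq in members:
        if len(seq) == 0:
            raise ValueError(f"zero-length member {lid}")

    lengths = {len(seq) for _, _, seq in members}
    ids = [m[0] for m in members]
    seqs = [m[2] for m in members]
    n = len(members)

    if len(lengths) == 1:
        # equal-length members align gaplessly: columnwise stacking, and the
        # center choice cannot alter the rows
        rows = {members[i][1]: seqs[i] for i in range(n)}
        ncol = len(seqs[0])
    else:
        aligner = _global_aligner()
        # distances = mismatches + gap columns of the pairwise alignment
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aln = aligner.align(seqs[i], seqs[j])[0]
                c = aln.counts()
                d[i, j] = d[j, i] = c.mismatches + c.gaps
        center = min(range(n), key=lambda i: (d[i].sum(), ids[i]))
        rows_list = _center_star(seqs, center, aligner)
        rows = {members[i][1]: rows_list[i] for i in range(n)}
        ncol = len(rows_list[0])

    if species_list is not None:
        for sp in species_list:
            rows.setdefault(sp, "N" * ncol)
    return ClusterAlignment(cluster_id, rows, ncol)


def _center_star(seqs: list[str], center: int, aligner) -> list[str]:
    """Merge pairwise alignments against the center into one MSA."""
    c = seqs[center]
    # master gap pattern: number of inserted columns after each center pos
    ins_after = [0] * (len(c) + 1)
    pairs = []
    for i, s in enumerate(seqs):
        if i == center:
            pairs.append(None)
            continue
        a_c, a_s = _pair_rows(aligner.align(c, s)[0])
        pairs.append((a_c, a_s))
        pos = 0  # center residues consumed
        run = 0
        for ch in a_c:
            if ch == "-":
                run += 1
            else:
                ins_after[pos] = max(ins_after[pos], run)
                run = 0
                pos += 1
        ins_after[pos] = max(ins_after[pos], run)

    out = []
    for i, s in enumerate(seqs):
        if i == center:
            row = []
            for p, base in enumerate(c):
                row.append("-" * ins_after[p])
                row.append(base)
            row.append("-" * ins_after[len(c)])
            out.append("".join(row))
            continue
        a_c, a_s = pairs[i]
        row = []
        pos = 0
        pending = []  # member chars aligned to a center gap run
        for cc, sc in zip(a_c, a_s):
            if cc == "-":
                pending.append(sc)
            else:
                row.append(_pad_insertion(pending, ins_after[pos]))
                pending = []
                row.append(sc)
                pos += 1
        row.append(_pad_insertion(pending, ins_after[pos]))
        out.append("".join(row))
    return out


def _pad_insertion(pending: list[str], width: int) -> str:
    """Left-align a center-gap insertion run into its master-width slot."""
    return "".join(pending) + "-" * (width - len(pending))


def extract_variants(alignment: ClusterAlignment) -> list[tuple[int, dict[str, str]]]:
    """Columns that are interspecific single-nucleotide variants.

    A column qualifies iff >=2 species are non-missing ('-' and 'N' are
    missing) and >=2 distinct bases occur among them.  Each returned entry
    is ``(column_index, {species: base or 'N'})``.
    """
    species = sorted(alignment.rows)
    variants = []
    for col in range(alignment.n_columns):
        chars = {sp: alignment.rows[sp][col] for sp in species}
        observed = [c for c in chars.values() if c not in _MISSING]
        if len(observed) >= 2 and len(set(observed)) >= 2:
            variants.append((col, {sp: (c if c not in _MISSING else "N")
                                   for sp, c in chars.items()}))
    return variants


def concatenate(cluster_variants: dict[str, list[tuple[int, dict[str, str]]]],
                species: list[str]) -> VariantSupermatrix:
    """Concatenate variant columns over clusters, ordered by (cluster, column)."""
    if len(set(cluster_variants)) != len(cluster_variants):
        raise ValueError("duplicate cluster ids")
    species = list(species)
    columns = []
    provenance = []
    for cid in sorted(cluster_variants):
        for col, chars in cluster_variants[cid]:
            columns.append([chars.get(sp, "N") for sp in species])
            provenance.append((cid, col))
    if columns:
        data = np.array(columns, dtype="U1").T
    else:
        data = np.empty((len(species), 0), dtype="U1")
    return VariantSupermatrix(species, data, provenance)


def write_phylip(matrix: VariantSupermatrix, path) -> None:
    """Sequential relaxed PHYLIP: '<n_taxa> <n_sites>' header, then one
    whitespace-separated name + sequence row per species."""
    if len(matrix.species) < 2:
        raise ValueError("need >=2 species to write PHYLIP")
    if matrix.n_columns < 1:
        raise ValueError("empty matrix")
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.species)} {matrix.n_columns}\n")
        for sp in matrix.species:
            fh.write(f"{sp} {matrix.row(sp)}\n")


def read_phylip(path) -> VariantSupermatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_sites = int(header[0]), int(header[1])
        species, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split()
            species.append(name)
            rows.append(list(seq))
    if len(species) != n_taxa or any(len(r) != n_sites for r in rows):
        raise ValueError("PHYLIP header disagrees with records")
    return VariantSupermatrix(species, np.array(rows, dtype="U1"))


def matrix_stats(matrix: VariantSupermatrix) -> MatrixStats:
    per_sp = matrix.per_species_missing()
    vals = list(per_sp.values()) or [0]
    return MatrixStats(
        n_loci=len({cid for cid, _ in matrix.provenance}),
        n_variants=matrix.n_columns,
        pct_missing=matrix.pct_missing(),
        per_species_missing=per_sp,
        missing_range=(min(vals), max(vals)),
    )


def write_provenance(matrix: VariantSupermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#column_index\tcluster_id\tcluster_column\n")
        for i, (cid, col) in enumerate(matrix.provenance):
            fh.write(f"{i}\t{cid}\t{col}\n")
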