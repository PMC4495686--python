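"""Ortholog cluster inference from reciprocal unique best hits.

Loci from different species are declared orthologous when they are each
other's unique best alignment (reciprocal best hit, RBH).  The RBH relation
over all species pairs forms an undirected graph; clusters are, by default,
its maximal cliques -- every member pair must be a reciprocal unique best
hit -- with connected components available as a more permissive alternative
for sensitivity analysis.

Cluster-level filters then remove likely paralogy and enforce taxon
coverage, in this order: (1) any cluster containing a locus assigned to
multiple clusters is removed outright (overlapping cliques are never
arbitrated by score); (2) clusters with two members from one species are
removed; (3) clusters seen in fewer than ``min_species`` species, or
failing a species-group constraint such as "at least one non-salmonid",
are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .align import PairwiseHit

__all__ = [
    "OrthologCluster",
    "CoverageFilter",
    "build_rbh_graph",
    "infer_clusters",
    "remove_multi_cluster_sequences",
    "remove_multi_species_duplicates",
    "filter_coverage",
    "report_cluster_stats",
    "write_clusters",
]


@dataclass
class OrthologCluster:
    """A set of loci, at most one per species after filtering.

    ``orientation`` gives each member's strand relative to the reference
    member (the lexicographically smallest locus id, always '+').
    """

    cluster_id: str
    members: dict[str, str]  # locus_id -> species
    orientation: dict[str, str] = field(default_factory=dict)

    @property
    def species(self) -> set[str]:
        return set(self.members.values())

    @property
    def reference(self) -> str:
        return min(self.members)


@dataclass
class CoverageFilter:
    """Minimum species count plus optional group constraints.

    Each constraint is ``(species_group, min_count)``: the cluster must
    contain at least ``min_count`` members from ``species_group`` (e.g. one
    non-salmonid, to drop salmonid-specific clusters from an all-species
    analysis).
    """

    min_species: int
    required_groups: list[tuple[frozenset, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_species < 2:
            raise ValueError("min_species must be >= 2")


def build_rbh_graph(unique_hits: list[PairwiseHit]) -> nx.Graph:
    """Undirected RBH graph from uniqueness-filtered directed best hits.

    Edge (a, b) exists iff a's unique best hit in b's species is b and
    b's unique best hit in a's species is a.  Edges carry the relative
    alignment strand; nodes carry their species.
    """
    best: dict[tuple[str, str], tuple[str, str]] = {}
    species: dict[str, str] = {}
    for h in unique_hits:
        best[(h.query_id, h.subject_species)] = (h.subject_id, h.strand)
        species[h.query_id] = h.query_species
        species[h.subject_id] = h.subject_species
    g = nx.Graph()
    for (qid, ssp), (sid, strand) in best.items():
        back = best.get((sid, species[qid]))
        if back is not None and back[0] == qid:
            g.add_node(qid, species=species[qid])
            g.add_node(sid, species=ssp)
            g.add_edge(qid, sid, strand=strand)
    return g


def _orient(graph: nx.Graph, members: list[str]) -> dict[str, str]:
    """Strand of each member relative to the smallest member id.

    Strands compose along paths; within a clique the direct edge to the
    reference is used.  In component mode a BFS assignment is used (strand
    parity conflicts on odd cycles are resolved in BFS order).
    """
    ref = min(members)
    strands = {ref: "+"}
    queue = [ref]
    mset = set(members)
    while queue:
        u = queue.pop(0)
        for v in sorted(graph.neighbors(u)):
            if v in mset and v not in strands:
                rel = graph.edges[u, v]["strand"]
                strands[v] = strands[u] if rel == "+" else \
                    ("-" if strands[u] == "+" else "+")
                queue.append(v)
    return strands


def infer_clusters(graph: nx.Graph, mode: str = "clique") -> list[OrthologCluster]:
    """Enumerate clusters: maximal cliques (default) or connected components.

    Only groups of >=2 loci are emitted; ordering is deterministic (sorted
    member ids).  Because RBH edges only join different species, cliques
    can never contain two loci of one species; components can.
    """
    if mode == "clique":
        raw = [sorted(c) for c in nx.find_cliques(graph) if len(c) >= 2]
    elif mode == "component":
        raw = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    else:
        raise ValueError(f"unknown cluster mode {mode!r}")
    raw.sort()
    clusters = []
    for i, members in enumerate(raw):
        clusters.append(OrthologCluster(
            cluster_id=f"C{i:06d}",
            members={m: graph.nodes[m]["species"] for m in members},
            orientation=_orient(graph, members)))
    return clusters


def remove_multi_cluster_sequences(
        clusters: list[OrthologCluster]) -> tuple[list[OrthologCluster], int]:
    """Remove every cluster containing a locus assigned to >=2 clusters
    (potential paralogous regions).  Returns (clusters, n_removed)."""
    seen: dict[str, int] = {}
    for c in clusters:
        for m in c.members:
            seen[m] = seen.get(m, 0) + 1
    kept = [c for c in clusters if all(seen[m] == 1 for m in c.members)]
    return kept, len(clusters) - len(kept)


def remove_multi_species_duplicates(
        clusters: list[OrthologCluster]) -> tuple[list[OrthologCluster], int]:
    """Remove clusters with two or more members from a single species."""
    kept = [c for c in clusters if len(c.species) == len(c.members)]
    return kept, len(clusters) - len(kept)


def filter_coverage(clusters: list[OrthologCluster], cov: CoverageFilter,
                    known_species: set[str] | None = None) -> list[OrthologCluster]:
    """Keep clusters with >= min_species species meeting all group constraints."""
    if known_species is not None:
        for group, _ in cov.required_groups:
            unknown = group - known_species
            if unknown:
                raise ValueError(f"unknown species in coverage constraint: "
                                 f"{sorted(unknown)}")
    out = []
    for c in clusters:
        if len(c.species) < cov.min_species:
            continue
        if all(len(c.species & group) >= n for group, n in cov.required_groups):
            out.append(c)
    return out


def report_cluster_stats(clusters: list[OrthologCluster],
                         genic_flags: dict[str, bool] | None = None) -> dict:
    """Summary: cluster count, per-species presence, genic count/fraction."""
    per_species: dict[str, int] = {}
    for c in clusters:
        for sp in c.species:
            per_species[sp] = per_species.get(sp, 0) + 1
    stats = {
        "n_clusters": len(clusters),
        "per_species": dict(sorted(per_species.items())),
    }
    if genic_flags is not None:
        n_genic = sum(bool(genic_flags.get(c.cluster_id)) for c in clusters)
        stats["n_genic"] = n_genic
        stats["pct_genic"] = 100.0 * n_genic / len(clusters) if clusters else 0.0
    return stats


def write_clusters(clusters: list[OrthologCluster], path) -> None:
    """Tab-separated membership: cluster_id, species, locus_id, strand."""
    with open(path, "w") as fh:
        fh.write("#cluster_id\tspecies\tlocus_id\tstrand\n")
        for c in clusters:
            for m in sorted(c.members):
                fh.write(f"{c.cluster_id}\t{c.members[m]}\t{m}\t"
                         f"{c.orientation.get(m, '+')}\n")
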