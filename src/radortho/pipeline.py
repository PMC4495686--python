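"""End-to-end orchestration: preprocess -> align -> cluster -> matrix -> tree.

One configuration object drives the whole run; every intermediate artifact
(merged loci, hit tables, cluster membership, PHYLIP matrix, newick tree,
run summary) is written to the output directory, and the run log records
every count the stages report (loci dropped at trimming, hits removed per
filter, clusters removed per rule) so a run can be audited line by line.
Identical configuration + seed produces a byte-identical bundle.

Two presets bind the alignment thresholds of the two standard analyses:
``salmonid-strict`` (95% identity / 50 bp / <=2 mismatches) and
``all-species-relaxed`` (85% identity / 45 bp / <=10 mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import align as al
from . import annotate as an
from . import cluster as cl
from . import preprocess as pp
from . import supermatrix as sm
from . import tree as tr

__all__ = ["PipelineConfig", "PipelineResult", "validate_config",
           "run_pipeline", "load_manifest_fasta"]

PRESETS = {
    "salmonid-strict": al.AlignmentThresholds.strict(),
    "all-species-relaxed": al.AlignmentThresholds.relaxed(),
}


@dataclass
class PipelineConfig:
    """All stage parameters plus the input manifest.

    ``manifest`` maps species -> study -> FASTA path.  ``min_studies`` None
    means "majority of that species' studies".  ``thresholds`` override the
    preset when given.  ``bootstrap_replicates`` 0 skips bootstrapping
    (point-estimate tree only).
    """

    manifest: dict[str, dict[str, str]]
    outdir: str
    seed: int = 0
    preset: str = "salmonid-strict"
    thresholds: al.AlignmentThresholds | None = None
    trim_length: int = 60
    dust_window: int = 64
    dust_threshold: float = 2.0
    repeat_library: str | None = None
    merge_identity_min: float = 0.95
    merge_mismatch_max: int = 2
    min_studies: int | None = None
    scoring: al.ScoringScheme = field(default_factory=al.ScoringScheme)
    seed_k: int = 11
    min_score: float = 20.0
    cluster_mode: str = "clique"
    min_species: int = 2
    required_groups: list[tuple[frozenset, int]] = field(default_factory=list)
    gene_db: str | None = None
    annotation: an.AnnotationConfig = field(default_factory=an.AnnotationConfig)
    distance_model: str = "p-distance"
    bootstrap_replicates: int = 1000
    run_tree: bool = True


@dataclass
class PipelineResult:
    clusters: list
    matrix: sm.VariantSupermatrix | None
    stats: sm.MatrixStats | None
    tree: tr.SpeciesTree | None
    summary: dict
    log: list[str]
    degenerate_reason: str | None = None


def validate_config(config: PipelineConfig) -> list[str]:
    """All violations/warnings; an empty list means the config is runnable."""
    issues = []
    if config.preset not in PRESETS:
        issues.append(f"unknown preset {config.preset!r}")
    elif config.thresholds is not None and \
            config.thresholds != PRESETS[config.preset]:
        issues.append(f"warning: preset {config.preset!r} thresholds "
                      f"overridden by explicit thresholds")
    if not config.manifest:
        issues.append("empty manifest")
    for sp, studies in config.manifest.items():
        for study, path in studies.items():
            if not Path(path).exists():
                issues.append(f"missing FASTA for {sp}/{study}: {path}")
    for path in (config.repeat_library, config.gene_db):
        if path is not None and not Path(path).exists():
            issues.append(f"missing file: {path}")
    if config.min_species < 2:
        issues.append("min_species must be >= 2")
    if config.cluster_mode not in ("clique", "component"):
        issues.append(f"unknown cluster mode {config.cluster_mode!r}")
    return issues


def load_manifest_fasta(manifest: dict[str, dict[str, str]]
                        ) -> dict[str, dict[str, list[pp.RadLocus]]]:
    out: dict[str, dict[str, list[pp.RadLocus]]] = {}
    for sp in sorted(manifest):
        out[sp] = {}
        for study in sorted(manifest[sp]):
            records = []
            for rec in SeqIO.parse(manifest[sp][study], "fasta"):
                records.append(pp.RadLocus(rec.id, sp, study,
                                           str(rec.seq).upper()))
            out[sp][study] = records
    return out


def _read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages in fixed order, writing every intermediate.

    Stage order: preprocess (trim, mask, merge studies) -> all-vs-all
    alignment -> best-hit / threshold / uniqueness filtering -> RBH graph ->
    cluster enumeration -> paralogy and coverage filters -> per-cluster
    alignment and variant extraction -> supermatrix -> [annotation] -> tree.
    A degenerate matrix (no variant columns, as on zero-divergence data) is
    surfaced as a result with ``degenerate_reason`` set instead of an error.
    """
    issues = [m for m in validate_config(config) if not m.startswith("warning")]
    if issues:
        raise ValueError("invalid pipeline configuration: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    thresholds = config.thresholds or PRESETS[config.preset]

    # ---- preprocess ------------------------------------------------------
    raw = load_manifest_fasta(config.manifest)
    repeats = _read_fasta(config.repeat_library) if config.repeat_library else []
    per_species: dict[str, list[pp.RadLocus]] = {}
    for sp in sorted(raw):
        merged_studies: list[pp.RadLocus] = []
        n_studies = len(raw[sp])
        for study in sorted(raw[sp]):
            trimmed = pp.trim_loci(raw[sp][study], config.trim_length)
            log.append(f"preprocess\t{sp}/{study}\ttrimmed_to={config.trim_length}"
                       f"\tkept={len(trimmed.loci)}\tdropped={trimmed.n_dropped}")
            loci = pp.mask_low_complexity(trimmed.loci, config.dust_window,
                                          config.dust_threshold)
            if repeats:
                loci = pp.mask_repeat_library(loci, repeats)
            merged_studies.extend(loci)
        if n_studies > 1:
            min_studies = config.min_studies or (n_studies // 2 + 1)
            policy = pp.MergePolicy(config.merge_identity_min,
                                    config.merge_mismatch_max, min_studies)
            merge = pp.merge_studies(merged_studies, policy)
            log.append(f"merge\t{sp}\tstudies={n_studies}\t"
                       f"common={merge.n_groups}\tconflicts={merge.n_conflicts}"
                       f"\tsharing_pct={merge.sharing_pct:.1f}")
            per_species[sp] = merge.loci
        else:
            per_species[sp] = merged_studies
        with open(outdir / f"{sp}.processed.fasta", "w") as fh:
            for loc in per_species[sp]:
                fh.write(f">{loc.id}\n{loc.seq}\n")

    species_list = sorted(per_species)
    loci_by_id = {loc.id: loc for sp in species_list for loc in per_species[sp]}

    # ---- all-vs-all alignment and filtering ------------------------------
    unique_hits: list[al.PairwiseHit] = []
    for i, sp_a in enumerate(species_list):
        for sp_b in species_list[i + 1:]:
            hits = al.align_all_pairs(per_species[sp_a], per_species[sp_b],
                                      config.scoring, config.seed_k,
                                      config.min_score)
            for direction, dir_hits in (
                    (f"{sp_a}->{sp_b}", hits),
                    (f"{sp_b}->{sp_a}", [al.swap_hit(h) for h in hits])):
                best = al.extract_best_hits(dir_hits)
                kept = al.filter_hits(best, thresholds)
                uniq = al.filter_unique(kept)
                log.append(f"align\t{direction}\thits={len(dir_hits)}\t"
                           f"best={len(best)}\tfiltered={len(kept)}\t"
                           f"unique={len(uniq)}")
                unique_hits.extend(uniq)
            al.write_hits(hits, outdir / f"hits.{sp_a}.{sp_b}.tsv")

    # ---- clustering ------------------------------------------------------
    graph = cl.build_rbh_graph(unique_hits)
    clusters = cl.infer_clusters(graph, config.cluster_mode)
    log.append(f"cluster\tenumerated={len(clusters)}")
    clusters, n_multi = cl.remove_multi_cluster_sequences(clusters)
    log.append(f"cluster\tremoved_multi_cluster={n_multi}")
    clusters, n_dup = cl.remove_multi_species_duplicates(clusters)
    log.append(f"cluster\tremoved_multi_species={n_dup}")
    cov = cl.CoverageFilter(config.min_species, config.required_groups)
    clusters = cl.filter_coverage(clusters, cov, set(species_list))
    log.append(f"cluster\tafter_coverage_filter={len(clusters)}")
    cl.write_clusters(clusters, outdir / "clusters.tsv")

    # ---- per-cluster alignment and variants ------------------------------
    from .sequtil import revcomp
    cluster_variants: dict[str, list] = {}
    n_loci_aligned = 0
    for c in clusters:
        members = []
        for m in sorted(c.members):
            seq = loci_by_id[m].seq
            if c.orientation.get(m, "+") == "-":
                seq = revcomp(seq)
            members.append((m, c.members[m], seq))
        ca = sm.align_cluster(c.cluster_id, members, species_list)
        cluster_variants[c.cluster_id] = sm.extract_variants(ca)
        n_loci_aligned += 1
    matrix = sm.concatenate(cluster_variants, species_list)
    summary: dict = {"n_species": len(species_list),
                     "n_clusters": len(clusters)}

    # ---- annotation (optional) -------------------------------------------
    genic_flags = None
    if config.gene_db:
        gene_db = _read_fasta(config.gene_db)
        per_locus = an.annotate_loci(
            [loci_by_id[m] for c in clusters for m in sorted(c.members)],
            gene_db, config.annotation)
        flags = {lid: r.genic for lid, r in per_locus.items()}
        genic_flags, pct_genic = an.annotate_clusters(clusters, flags)
        summary["n_genic"] = sum(genic_flags.values())
        summary["pct_genic"] = round(pct_genic, 1)
        with open(outdir / "annotation.tsv", "w") as fh:
            fh.write("#locus_id\tgenic\tbest_gene\tsignificance\n")
            for lid in sorted(per_locus):
                r = per_locus[lid]
                fh.write(f"{lid}\t{int(r.genic)}\t{r.best_gene or '.'}\t"
                         f"{r.evalue:.3g}\n")

    cstats = cl.report_cluster_stats(clusters, genic_flags)
    summary["per_species_clusters"] = cstats["per_species"]

    # ---- supermatrix outputs ---------------------------------------------
    stats = None
    tree = None
    degenerate = None
    if matrix.n_columns == 0:
        degenerate = "no interspecific variant columns (degenerate matrix); " \
                     "no tree estimated"
        log.append(f"matrix\tdegenerate\t{degenerate}")
        summary.update({"n_variants": 0, "pct_missing": 0.0})
    else:
        stats = sm.matrix_stats(matrix)
        summary.update({"n_variants": stats.n_variants,
                        "pct_missing": round(stats.pct_missing, 2),
                        "missing_range": stats.missing_range})
        sm.write_phylip(matrix, outdir / "supermatrix.phy")
        sm.write_provenance(matrix, outdir / "supermatrix.provenance.tsv")
        log.append(f"matrix\tn_variants={stats.n_variants}\t"
                   f"pct_missing={stats.pct_missing:.2f}")
        # ---- tree --------------------------------------------------------
        if config.run_tree and len(species_list) >= 3:
            try:
                if config.bootstrap_replicates > 0:
                    tree = tr.bootstrap_support(
                        matrix, config.bootstrap_replicates,
                        seed=config.seed, model=config.distance_model)
                else:
                    names, d = tr.distance_matrix(matrix, config.distance_model)
                    tree = tr.neighbor_joining(names, d)
                with open(outdir / "tree.nwk", "w") as fh:
                    fh.write(tree.newick + "\n")
                log.append("tree\twritten")
            except ValueError as exc:
                degenerate = f"tree inference failed: {exc}"
                log.append(f"tree\terror\t{exc}")

    with open(outdir / "summary.tsv", "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")

    return PipelineResult(clusters, matrix, stats, tree, summary, log,
                          degenerate)
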