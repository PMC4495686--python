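"""Synthetic RAD-locus datasets with known orthology and phylogeny.

Real RAD-seq consensus loci are short (~60-95 bp) sequences flanking a rare
restriction-enzyme recognition site (SbfI, CCTGCAGG, in the datasets this
package targets).  As species diverge, mutations destroy recognition sites,
so the set of loci shared between two species shrinks with their evolutionary
distance; whole-genome duplication and repeats add paralogous copies; and
different laboratories sequencing the same species recover overlapping but
not identical locus sets.

This module emulates exactly that generative process on a user-supplied
species tree so that every downstream stage (merging, alignment, ortholog
clustering, supermatrix construction, tree inference) can be tested against
a known ground truth:

* ancestral loci evolve down the tree under JC69 or K2P;
* a locus is lost below any branch on which its restriction site is
  destroyed (per-branch probability ``1 - exp(-site_loss_rate * t)``; loss
  is absorbing -- regain is not modelled);
* a configurable fraction of loci carries a paralogous duplicate, created at
  the root with extra divergence and inherited independently;
* each species' locus set is replicated into several "studies", each of
  which independently drops loci at a technical dropout rate.

Three independent RNG streams (sequence evolution, site loss, study
replication), all spawned from the master seed, keep the stages
individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "write_dataset",
    "write_truth",
    "read_truth",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``tree`` is a newick string with branch lengths in expected
    substitutions per site.  ``site_loss_rate`` is the per-unit-branch-length
    hazard of restriction-site loss; it is a free parameter of the simulator
    (restriction-site turnover rates are not pinned down by the data regime
    we emulate) and defaults to 0.5 so that dropout is visible but not
    dominant at the branch lengths used throughout the test-suite.
    """

    tree: str
    n_loci: int
    locus_length: int = 60
    recognition_site: str = "CCTGCAGG"  # SbfI
    site_loss_rate: float = 0.5
    paralog_fraction: float = 0.0
    paralog_extra_divergence: float = 0.3
    n_studies_per_species: int = 1
    study_dropout_rate: float = 0.0
    substitution_model: str = "JC69"
    kappa: float = 2.0
    indel_rate: float = 0.0  # per emitted locus; aligner stress-test only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.locus_length <= 0:
            raise ValueError("locus_length must be positive")
        if len(self.recognition_site) < 4 or set(self.recognition_site) - set("ACGT"):
            raise ValueError("recognition_site must be >=4 bp of ACGT")
        if self.site_loss_rate < 0:
            raise ValueError("site_loss_rate must be >= 0")
        if not 0.0 <= self.paralog_fraction <= 1.0:
            raise ValueError("paralog_fraction must be in [0, 1]")
        if self.paralog_extra_divergence < 0:
            raise ValueError("paralog_extra_divergence must be >= 0")
        if self.n_studies_per_species <= 0:
            raise ValueError("n_studies_per_species must be positive")
        if not 0.0 <= self.study_dropout_rate <= 1.0:
            raise ValueError("study_dropout_rate must be in [0, 1]")
        if self.substitution_model not in ("JC69", "K2P"):
            raise ValueError("substitution_model must be 'JC69' or 'K2P'")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        # parse eagerly so invalid newick fails at construction time
        t = _parse_tree(self.tree)
        if len(t.leaf_nodes()) < 2:
            raise ValueError("tree must have at least 2 leaves")


@dataclass
class GroundTruth:
    """Known orthology of a simulated dataset.

    ``ortholog_map`` sends every emitted locus id to the id of the ancestral
    unit it descends from; copies of one unit in different species are true
    orthologs.  Paralogous duplicates are separate ancestral units (ids
    prefixed ``P``) whose emitted copies are flagged in ``is_paralog``.
    ``present_in`` records, per ancestral unit, the species that retained the
    locus (before per-study technical dropout).
    """

    ortholog_map: dict[str, str]
    present_in: dict[str, set[str]]
    true_tree: str
    is_paralog: dict[str, bool]


def _parse_tree(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"invalid newick tree: {exc}") from exc


def _substitution_probs(t: float, model: str, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each single transversion)) after branch length t.

    JC69 is the kappa=1 special case of K2P, so both models share the K2P
    closed form with branch length measured in expected substitutions/site.
    """
    if model == "JC69":
        kappa = 1.0
    # K2P with rates normalised to one expected substitution per unit length
    e1 = np.exp(-4.0 * t / (kappa + 2.0))
    e2 = np.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_tv = 0.25 - 0.25 * e1  # each of the two transversions
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return float(p_ts), float(p_tv)


def _evolve(seqs: np.ndarray, t: float, model: str, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a (n, L) uint8 base matrix (A,C,G,T = 0..3) along one branch."""
    if t == 0.0:
        return seqs.copy()
    p_ts, p_tv = _substitution_probs(t, model, kappa)
    u = rng.random(seqs.shape)
    out = seqs.copy()
    # transition partner: A<->G, C<->T, i.e. XOR with 2 in this encoding
    ts = u < p_ts
    out[ts] ^= 2
    # the two transversion partners of base b are b^1 and b^3
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[tv1] = seqs[tv1] ^ 1
    out[tv2] = seqs[tv2] ^ 3
    return out


def _decode(row: np.ndarray) -> str:
    return _BASES[row].tobytes().decode("ascii")


def simulate_dataset(config: SimulationConfig):
    """Simulate per-species, per-study FASTA records plus ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` maps
    species -> study -> list of ``(record_id, sequence)`` and record ids
    follow ``<species>|<study>|<locus_serial>``.  Deterministic given
    ``config.seed``.
    """
    tree = _parse_tree(config.tree)
    ss = np.random.SeedSequence(config.seed)
    rng_evo, rng_loss, rng_study = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_loci
    L = config.locus_length
    n_par = int(round(config.paralog_fraction * n))

    unit_ids = [f"L{i:05d}" for i in range(n)]
    root_seqs = rng_evo.integers(0, 4, size=(n, L), dtype=np.uint8)
    if n_par:
        # duplicates of the first n_par ancestral loci, diverged at the root
        par_ids = [f"P{i:05d}" for i in range(n_par)]
        par_seqs = _evolve(root_seqs[:n_par], config.paralog_extra_divergence,
                           config.substitution_model, config.kappa, rng_evo)
        unit_ids = unit_ids + par_ids
        root_seqs = np.vstack([root_seqs, par_seqs])
    n_units = len(unit_ids)

    leaf_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def descend(node, seqs: np.ndarray, present: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seqs = _evolve(seqs, t, config.substitution_model,
                                 config.kappa, rng_evo)
            p_loss = 1.0 - np.exp(-config.site_loss_rate * t)
            lost = rng_loss.random(n_units) < p_loss
            child_present = present & ~lost
            if child.is_leaf():
                leaf_state[child.taxon.label] = (child_seqs, child_present)
            else:
                descend(child, child_seqs, child_present)

    descend(tree.seed_node, root_seqs, np.ones(n_units, dtype=bool))

    species_names = sorted(leaf_state)
    studies = [f"s{j + 1}" for j in range(config.n_studies_per_species)]

    dataset: dict[str, dict[str, list[tuple[str, str]]]] = {}
    ortholog_map: dict[str, str] = {}
    is_paralog: dict[str, bool] = {}
    present_in: dict[str, set[str]] = {u: set() for u in unit_ids}

    for sp in species_names:
        seqs, present = leaf_state[sp]
        idx = np.flatnonzero(present)
        for i in idx:
            present_in[unit_ids[i]].add(sp)
        dataset[sp] = {}
        for study in studies:
            keep = rng_study.random(idx.size) >= config.study_dropout_rate
            records: list[tuple[str, str]] = []
            for i in idx[keep]:
                uid = unit_ids[i]
                rid = f"{sp}|{study}|{uid}"
                seq = _decode(seqs[i])
                if config.indel_rate and rng_study.random() < config.indel_rate:
                    dlen = int(rng_study.integers(1, 4))
                    pos = int(rng_study.integers(1, max(2, L - dlen)))
                    seq = seq[:pos] + seq[pos + dlen:]
                records.append((rid, seq))
                ortholog_map[rid] = uid
                is_paralog[rid] = uid.startswith("P")
            dataset[sp][study] = records

    truth = GroundTruth(
        ortholog_map=ortholog_map,
        present_in={u: s for u, s in present_in.items() if s},
        true_tree=config.tree,
        is_paralog=is_paralog,
    )
    return dataset, truth


def write_dataset(dataset, outdir) -> dict[str, dict[str, str]]:
    """Write one FASTA per species per study; return the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    for sp in sorted(dataset):
        manifest[sp] = {}
        for study in sorted(dataset[sp]):
            path = outdir / f"{sp}_{study}.fasta"
            with open(path, "w") as fh:
                for rid, seq in dataset[sp][study]:
                    fh.write(f">{rid}\n{seq}\n")
            manifest[sp][study] = str(path)
    return manifest


def write_truth(truth: GroundTruth, path) -> None:
    """Serialise ground truth as JSON (lossless round trip via read_truth)."""
    payload = {
        "ortholog_map": dict(sorted(truth.ortholog_map.items())),
        "present_in": {k: sorted(v) for k, v in sorted(truth.present_in.items())},
        "true_tree": truth.true_tree,
        "is_paralog": dict(sorted(truth.is_paralog.items())),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        ortholog_map=payload["ortholog_map"],
        present_in={k: set(v) for k, v in payload["present_in"].items()},
        true_tree=payload["true_tree"],
        is_paralog=payload["is_paralog"],
    )
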