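# Methods

## Problem setting

Consensus RAD loci are short population-level sequences flanking a rare
restriction site (SbfI here). Given per-species — optionally per-study —
FASTA files of such loci, the package infers cross-species ortholog
clusters, extracts the interspecific single-nucleotide variants they
contain, concatenates them into a species × sites supermatrix, and
estimates a bootstrapped phylogeny. Inputs are consensus sequences, not
reads: within-species polymorphism is assumed already collapsed to the
majority allele upstream.

## Synthetic data model

The generator (`radortho.simulate`) emulates the process that shapes real
cross-laboratory RAD data:

- **Sequence evolution.** Ancestral loci (default 60 bp, i.i.d. uniform
  bases) evolve down a user-supplied newick tree with branch lengths in
  expected substitutions/site, under JC69 or K2P. Both models use the K2P
  closed-form transition/transversion probabilities (JC69 is the κ = 1
  case), applied independently per site per branch.
- **Locus dropout.** A locus is lost below a branch of length *t* with
  probability 1 − exp(−λ·t), λ = `site_loss_rate`. Loss is absorbing: site
  regain is not modelled, since at the rates of interest regain is
  negligible and dropout is the phenomenon the downstream filters must
  face. Restriction-site turnover rates are not well pinned down
  empirically, so λ is documented as a free parameter; the default 0.5
  makes dropout visible but not dominant at the branch lengths used in the
  tests (~10–20% loss on a 0.1-substitutions/site path).
- **Paralogy.** A fraction of ancestral loci receives a duplicate, created
  at the root with `paralog_extra_divergence` substitutions/site of extra
  divergence and inherited independently thereafter. Duplicates are
  separate ancestral units (ids `P…`); their emitted copies are flagged in
  the ground truth so paralog-handling filters can be scored.
- **Study structure.** Each species' surviving loci are replicated into
  `n_studies_per_species` study files; each study drops loci independently
  at `study_dropout_rate`, emulating technical (library/pipeline)
  variation between laboratories.
- **Indels** are off by default — cross-laboratory RAD loci are observed
  to be essentially indel-free — but an `indel_rate` exists to stress-test
  the aligner with 1–3 bp deletions.

Three RNG streams (evolution, site loss, study replication) are spawned
from the master seed, so each stage is independently reproducible and the
whole dataset is byte-deterministic given the configuration.

What the generator does *not* emulate: coalescent gene-tree/species-tree
discordance, base-composition and rate heterogeneity, sequencing error in
consensus calls, and length variation between studies (loci are emitted at
a single length; the trimming path is exercised by explicit fixtures
instead). Passing tests on synthetic data therefore demonstrate
correctness of the pipeline's logic under a clean substitution+dropout
model, not robustness to every artefact of real libraries.

## Preprocessing

- **Trimming** keeps the first `trim_length` bases (default 60); shorter
  loci are dropped and counted. Real datasets are all ≥ the trim length,
  but the edge needs a defined behaviour and dropping is the conservative
  one.
- **Low-complexity masking** is a DUST-style score: within every window of
  4..64 bases, the triplet counts c contribute Σc(c−1)/2, normalised by
  (number of triplets − 1); windows scoring > 2.0 are masked. All
  sub-windows are scored (incrementally, so the scan is O(n·window)),
  because a short repeat diluted inside a longer window would otherwise
  escape. Masking is an annotation: letters are unchanged, masked bases
  are simply excluded from alignment seeding.
- **Repeat-library masking** (optional) masks bases covered by any ≥18 bp
  window matching a library sequence, either strand, at ≤1 mismatch by
  default. It is a direct scan suitable for compact libraries, not a
  RepeatMasker replacement.
- **Cross-study merging** groups loci of one species by single linkage
  over a full-trimmed-length match criterion (identity ≥ 0.95 AND
  mismatches ≤ 2, either strand). Full-length comparison rather than local
  alignment is used because loci are pre-trimmed to equal length — at
  60 bp the identity and mismatch constraints nearly coincide, and both
  are enforced as stated. Groups seen in fewer than `min_studies` studies
  (default: a majority of that species' studies) are discarded; groups in
  which one study contributes two or more loci are ambiguous and excluded
  as conflicts, since the merge cannot decide which copy represents the
  locus. The representative sequence comes from the lexicographically
  first (study, id) pair — an arbitrary but deterministic tie-break. The
  sharing percentage is reported relative to the smallest contributing
  study.

## Alignment and best hits

Every cross-species locus pair sharing at least one exact 11-mer that is
unmasked in both loci (either strand) is aligned with an optimal local
alignment (match +1, mismatch −2, gap open −5, gap extend −2; Biopython's
PairwiseAligner, which implements Smith–Waterman with affine gaps). Hits
scoring below 20 are suppressed; at that floor, chance alignments between
unrelated 60-mers are vanishingly rare while any biologically meaningful
hit passes easily. Significance is ranked by raw score — deterministic,
and monotone in the identity/length/mismatch quantities the filters act
on — rather than by database-size E-value statistics. Identity counts gap
columns against the denominator but mismatches are substitution columns
only; the mismatch accounting for gapped hits is a convention this package
fixes explicitly. The seed length (11) and scoring scheme are classical
nucleotide-search defaults, stated here as assumptions.

Per query and subject species, the best hit is kept (score, then identity,
then alignment length, then lexicographic subject id). The uniqueness
filter then removes every subject that is the best hit of two or more
queries, together with all hits pointing at it — within-genome duplication
(salmonids) and uncharacterised repeats otherwise masquerade as orthologs.
Uniqueness is enforced per directed species pair. Because the alignment
score is symmetric, the reverse direction of each species pair is derived
by swapping hit endpoints rather than re-aligning.

## Clustering

The reciprocal unique best-hit (RBH) relation defines an undirected graph;
an edge exists iff each locus is the other's unique best hit in the
respective species. Clusters are maximal cliques by default — every member
pair must be an RBH — with connected components available as a more
permissive mode for sensitivity analysis; the clique reading is the
stricter interpretation of "all members align to each other", and the two
modes are deliberately both exposed rather than blessing one.

Filters run in a fixed order: (1) any cluster containing a locus that
appears in two or more clusters is removed outright (overlapping cliques
are never arbitrated by score — both are treated as potential paralogy);
(2) clusters with two members from one species are removed; (3) clusters
with fewer than `min_species` species, or failing a species-group
constraint (e.g. "≥1 non-salmonid", to drop lineage-specific clusters),
are removed. Member orientation is recorded relative to the
lexicographically smallest member id, composing hit strands along edges.

## Supermatrix

Cluster members (re-oriented to the reference strand) are multiple-aligned
by center-star: the member minimising summed pairwise distance is the
center (ties by id), every member is pairwise-aligned to it, and the
alignments are merged. For the typical indel-free, equal-length case this
is exactly columnwise stacking; with indels the center-star sum-of-pairs
distance is within the classical factor-2 bound of the exact optimum,
which the tests verify against an exhaustive three-sequence DP. Species
absent from a cluster get an all-`N` row, so missingness is explicit.

A column is an interspecific variant iff ≥2 species are non-missing and
≥2 distinct bases occur among them; gaps are treated as missing for
variant calling (configurable in principle, but with near-indel-free loci
the choice is inconsequential, and a column with one observed base and all
else missing carries no information). Sites with more than two alleles are
retained. Variant columns are concatenated ordered by (cluster id,
column), with a provenance map from matrix column to source cluster.

PHYLIP export is sequential relaxed (whitespace-delimited names): strict
10-character names would collide for realistic species labels. The file
re-parses to the identical matrix.

## Tree inference

Distances are p-distances over pairwise-shared non-missing columns
(pairwise deletion — the pipeline deliberately retains missing-rich
matrices, so complete-case deletion would be self-defeating), optionally
JC69-transformed (undefined at p ≥ 0.75, reported as an error naming the
pair). The default for pipeline runs is the p-distance: variant-only
matrices push p high enough that the JC69 transform can hit its pole for
distant pairs, and for topology recovery the monotone p-distance is
sufficient. Neighbor joining uses the Saitou–Nei Q-criterion with
deterministic lexicographic tie-breaking; negative branch-length estimates
are clamped to zero. Bootstrap support resamples matrix columns with
replacement (default 1,000 replicates), re-estimates the tree, and labels
each internal bipartition of the point estimate with the percentage of
replicates containing it; replicates in which some species pair loses all
shared columns are skipped and support is taken over completed replicates.
Robinson–Foulds distances compare unrooted bipartition sets.

The internal tree builder is distance-based by design: the package's claim
is pipeline-level topology recovery, and maximum-likelihood inference on
variant-only data needs ascertainment-bias correction that belongs in
dedicated ML software — hence the PHYLIP export path. Branch lengths are
in (transformed) proportion-of-variant-sites units, not substitutions per
genomic site; they should not be compared across matrices with different
variant densities.

## Genic annotation

A locus is genic iff its best local alignment against a user-supplied gene
database is significant at `evalue_threshold` (default 1e−5). Significance
is a Karlin–Altschul-style quantity E = K·m·n·exp(−λS) with fixed,
documented constants (nucleotide: λ = 1.33, K = 0.621; translated/BLOSUM62:
λ = 0.267, K = 0.041) and database-length scaling — the threshold is a
reproducible significance cut-off within this tool, not an emulation of
any specific search engine's statistics. Translated mode compares all six
reading frames of locus and gene, recovering protein-level conservation
hidden by synonymous saturation. A cluster is genic iff any member is
(configurable to all-members); the any-member default matches how
cluster-level genic counts are conventionally reported.

## Problem sizes and determinism

The test-suite and acceptance script run entirely on simulated data at
desk scale: 5–10 taxa, 120–500 loci, 60 bp, 10 seeds for the stochastic
properties — sizes chosen so the full suite completes in a couple of
minutes while leaving the statistical assertions (closed-form JC69
identity within 3 standard errors, monotone dropout averaged over 10
seeds, topology recovery in ≥9/10 seeds) well-powered. All randomness
flows from explicit seeds; identical configuration + seed reproduces every
output byte-identically.

## Known limitations

- Orthology is sequence-similarity-based (RBH cliques); tree-aware or
  synteny-based validation is out of scope.
- The repeat masker and the genic-annotation search are deliberately
  simple seeded scanners with fixed statistics; for real analyses with
  large repeat libraries or gene sets, dedicated tools remain preferable
  and their output can be supplied via the masking annotation.
- Headline counts from any particular real cross-laboratory compilation
  depend on upstream per-study processing that this package does not
  reproduce; its guarantees are the pipeline properties validated on
  synthetic data plus deterministic re-parses of its own outputs.
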