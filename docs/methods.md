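# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic cohorts do and do not emulate, and the known
limitations.

## Single-cell DNA clone reconstruction

**Filter cascade.** The per-call and per-axis thresholds (GQ < 30, depth
< 10 reads, mutant VAF < 25%, variant genotyped in < 50% of cells, cell with
< 50% of genotypes, variant mutated in < 0.5% of cells, pathogenic
annotation required, germline-like variants discarded) are applied in a
fixed order: per-call masking first, then variant coverage, then cell
coverage, then prevalence, pathogenicity and the germline heuristic. Masking
first is the most conservative ordering — a low-quality call can then never
rescue a variant's coverage fraction. Two choices the thresholds alone do
not pin down:

* VAF masking applies only to mutant calls (gt ∈ {het, hom}); a WT call with
  a low VAF is expected, not suspect.
* The prevalence filter (0.5% mutated) is computed after cell removal; the
  order is configurable.
* "Germline-like" means mutant in ≥ 95% of genotyped cells (configurable);
  pathogenicity itself is an input annotation — database lookups are out of
  scope.

The cascade is idempotent, and the filter report records the count removed
at every step.

**Clone calling.** Only cells with complete genotypes over the retained
variants enter clone calling; clones are exact genotype groups, so zygosity
differences separate clones. Allele dropout (ADO) converts true het calls to
apparent WT and thereby seeds small spurious groups one zygosity flip away
from a real clone. Groups with frequency below the ADO threshold (default
1%) that differ from a larger group at exactly one site by a het↔WT or
het↔hom flip are merged into that group *before* the minimum-size rule
(10 cells) discards what remains. Merging first conserves cells into their
parent clone; the merge never shrinks a clone and multi-site differences are
never merged (a conservative single-flip rule). When several candidate
parents exist the largest wins, with lexicographic clone id as the
deterministic tie-break.

Frequency recovery under ADO works because dropout correlates with poor
amplification: the generator (and, mechanistically, droplet genotyping)
gives ADO'd calls decreased GQ/depth, the cascade masks most of them to
missing, and the affected cells drop out of the complete-genotype
denominator instead of biasing it.

**Lineage.** Clone A is the parent of B iff A's mutated-variant set is a
strict subset of B's with no intermediate clone; disjoint clones attach in
parallel to the WT root. Founding variants are those of the
highest-frequency non-WT clone; variants confined to other clones are
subclonal. Zygosity is ignored for nesting (a het→hom transition is not
treated as an ancestry step).

**Compartments.** Antibody counts are CLR-transformed per cell
(log(x+1) centred across the panel — the standard treatment for
compositional antibody captures) and averaged per clone. The across-clone
midpoint ((max+min)/2) of each marker splits high from low: CD19 above
midpoint → `malignant_B`; CD19 below midpoint with any T-lineage marker
(CD5/CD2/CD3/CD7) above its own midpoint → `clonal_hematopoiesis`;
otherwise `ambiguous`. A variant inherits the label of the largest clone
carrying it. The midpoint rule assumes at least one clone on each side of
the contrast, which holds whenever a WT (mixed-lineage) background clone is
present.

## scRNA-seq core

**QC and doublets.** Cells pass QC with 200–6000 detected genes (inclusive)
and a mitochondrial fraction strictly below 0.15 (MT- gene prefix; if the
panel has no MT- genes the fraction is 0 with a warning). Doublet detection
is a deliberately simple artificial-doublet score: synthetic doublets
(25% of the number of qc-pass cells) are averages of random cell pairs; each
cell's score is the fraction of artificial doublets among its 20 nearest
neighbors in a 30-component PCA of the joint log-normalized matrix, and the
top 10% (the assumed formation rate) are flagged. This captures the
between-program doublets that matter for clustering; it does not model
homotypic doublets, which published heuristics also struggle with.

**Normalization and scaling.** Counts are scaled to 10,000 per cell and
log1p-transformed. S and G2/M cell-cycle scores (module scores of canonical
gene sets) are regressed out of every gene by OLS; residuals are
standardized to unit variance and clipped at ±10 (the clip bounds the
leverage of rare extreme cells, as is conventional before PCA).

**Clustering.** PCA (30 components, deterministic full SVD) feeds a
shared-nearest-neighbor graph: k = 20 neighbors (self included), edge
weight = Jaccard overlap of neighbor sets, edges below 1/15 pruned — then
Louvain community detection at resolution 0.3. The Louvain RNG is seeded,
so labels are reproducible. An integration hook (a callable applied to the
embedding) is exposed for batch correction; the default is the identity
since the synthetic cohorts carry no batch structure. A matrix of identical
cells short-circuits to a single cluster.

**Cluster origin and malignancy.** With tonsil controls present, a cluster
is a `tonsil_cluster` when ≥ 95% of its cells come from controls, a
`common_cluster` when every sample contributes ≥ 1% of it, and a
`lymphoma_cluster` when ≥ 90% comes from a single lymphoma sample
(thresholds configurable; clusters matching none fall back to dominant
composition with a flag). Light chains are called per cell from raw counts
(κ if IGKC > IGLC2+IGLC3, λ if lower, unassigned on ties/zeros — the ratio
is undefined there, so such cells leave the denominator). A cluster is
light-chain exclusive iff its κ fraction is strictly below 1% or strictly
above 91%; the boundary values themselves are not exclusive. Clusters with
fewer than 10 κ/λ-assigned cells abstain (not-evaluable) — a handful of
cells cannot support a restriction call, mirroring the 10-cell minimum
clone size. Note the rule is asymmetric: a κ-restricted clone passes with
up to 9% contamination, a λ-restricted clone with under 1%. Cells are
malignant iff their cluster is a lymphoma cluster *and* exclusive;
lymphoma clusters without restriction are reported as discordant, never
malignant.

**Cell types.** Cluster resolution 0.3 is tuned for the major compartments,
so per-cell types are assigned directly: the argmax over module scores of
canonical marker sets (B, CD4 Tfh, CD4 Treg, CD8 Teff, CD8 TCM, naive T,
NK, myeloid, plasma). This keeps signature targeting correct even when two
T subsets share a cluster.

**Markers and composition.** Cluster markers: Wilcoxon rank-sum vs rest,
reported when detection > 20% in either group, ln fold change
(ln(mean(expm1)+1) difference) > 0.2, and Bonferroni-adjusted p < 0.05. The
Bonferroni denominator is the number of genes passing the detection filter
for that cluster (configurable). Composition contrasts use the two-sided
Fisher exact test; a zero margin returns p = 1.

## Signature scoring

The module score contrasts a gene set against expression-matched controls:
genes are ranked by mean expression over the scored cells (stable sort) and
cut into 24 equal bins; each signature gene contributes 100 control genes
drawn uniformly from its bin — without replacement when the bin is large
enough, with replacement otherwise. Control pools exclude the signature
genes themselves, making the score a clean signature-vs-background
contrast (and exactly linear: adding c to the signature genes' values adds
exactly c to the score as long as bin memberships are unchanged). Each
signature draws from its own named RNG stream, so scoring one signature
never perturbs another. Defaults (24 bins, 100 controls) are the canonical
choices for this scoring family and are exposed in the signature
definition.

Group comparisons use the two-sided Wilcoxon rank-sum test — exact when the
combined sample is ≤ 50 without ties, normal approximation otherwise — with
Bonferroni correction over the comparisons performed in a run (the
denominator is overridable; correction across marker genes is handled
separately in the marker test). Patient aggregation takes the per-patient
median score; transformed patients stratify as stFL (time to transformation
≤ 12 months) or ltFL (> 12 months), never-transformed patients as ntFL, and
a transformed patient with unknown time is reported NA.

## Spatial niches

Bins are typed by the argmax of nine cell-type signature scores (bins as
observations, same bin-matched scoring); exact ties produce a sorted
"+"-joined combined label, and bins negative for every signature are
excluded. Combined-label bins (rare by construction) are also excluded from
enrichment and ligand–receptor analyses, configurably. Adjacency on the
gap-free grid defaults to queen (8-neighbor) contact — with no gap between
bins, diagonal contact is physical — with rook (4-neighbor) selectable;
every result records its mode.

Neighborhood enrichment counts edges joining each unordered type pair and
compares them to a null built by permuting labels over the included bins
(default 1000 permutations, seeded); z = (obs − null mean)/null sd, with
z = 0 wherever the null sd is 0 (degenerate pairs, single-class labelings).
The z matrices of all samples are jointly min-max scaled to [0, 1] (global
pooled range; a degenerate range scales to 0), which preserves
within-sample ordering and makes cross-sample comparison possible.

Ligand–receptor co-localization over directed adjacent pairs (i ∈ source
bins, j ∈ target bins): strength = mean of ℓ(i)·r(j) where ℓ and r are the
ligand/receptor expressions min-max scaled across the sample's bins;
frequency = fraction of source bins with at least one receptor-positive
target neighbor. The product form is one reasonable choice among several;
it is isolated behind a single function so alternatives can be swapped.
Default pairs: CD40LG→CD40, CXCL13→CXCR5, CD2→CD58, evaluated Tfh→B.
A 2×2 sum-pooling step supports 16 µm analysis; 8 µm is the default.

## Synthetic cohorts

The generators are pure functions of a configuration carrying the seed;
reruns are bit-identical, and planted truth lives in evaluation-only slots
(`uns["truth"]`, `GenotypeDataset.truth`) that no analysis stage reads.

* **Genotypes** — cells drawn from configured clones (remainder WT), ADO as
  het→WT flips at rate 0.05, missing calls at 0.02, a configurable fraction
  of calls failing the GQ/DP gates (0.05), ADO'd calls low-quality with
  probability 0.9, plus non-pathogenic scatter variants and one
  germline-like variant to exercise the cascade. Antibody counts are
  negative binomial with CD19-high B profiles and CD2/CD3/CD7/CD5-high T
  profiles; WT background cells are a 50/50 B/T mixture.
* **Expression** — negative binomial (shared dispersion θ = 10) over a
  ~1000-gene panel: canonical markers per cell type, pan-T genes, light
  chains, MT genes, cycle genes and synthetic filler. Malignant B cells of
  each lymphoma sample add a patient-specific program (30 filler genes,
  +3 mean counts); normal B cells share one program across samples, and
  tonsil controls add a tonsil-restricted GC program to half their B cells
  so the tonsil/common/lymphoma tri-partition is realizable. Malignant
  cells draw their light chain from the clonal class with probability 0.97
  (κ by default — at that purity only κ-restricted clones clear the
  asymmetric <1%/>91% rule; λ-restricted tumors would need > 99% purity);
  normal B cells are κ with probability 0.55. tFL/DLBCL-like conditions add
  `condition_effect` (default 1.0 mean counts) to the exhaustion genes in
  CD8 Teff/CD4 Treg and the adhesion genes in CD4 Tfh. Doublets replace a
  5% fraction with sums of random cell pairs; 2% of cells are planted QC
  failures (half low-complexity, half high-mito).
* **Spatial** — follicular layouts place disc-shaped B-cell patches
  (~1 follicle per 450 bins, radius 10–16% of the grid side) with
  Tfh-enriched rims on a background immune mixture; diffuse layouts draw
  types independently with spatial mixing. A positive `lr_effect` (5 mean
  counts in the tFL-like default) elevates ligands in Tfh bins and
  receptors in B bins; the elevation must be substantial because sample-wise
  min-max scaling cancels most of a uniform shift of the very bins that set
  the scale.

What the cohorts do **not** emulate: transcriptome-wide gene-gene
correlation structure, batch effects, ambient RNA, empty droplets, copy
number, segmentation error or bin mixtures at follicle boundaries. Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under the stated generative assumptions, not performance on real
tissue.

## Orchestration

Stages share one global seed expanded into per-stage streams (stage-name
CRC mixed into the seed), so inserting or removing a stage leaves the
others' draws untouched. The runner executes stages in dependency order,
records per-stage counts, warnings, wall time and output SHA-256 digests in
a pydantic-validated report (schema published in
`schemas/run_report.schema.json`), marks a failing stage and skips its
dependents. All text outputs are UTF-8 CSV/TSV with "." decimals; genotype
CSVs write floats at 17 significant digits and read them back with
round-trip parsing so file round trips are exact.

## Problem sizes used in validation

The test suite and acceptance script run deliberately compact versions of
each experiment — 2000-cell genotype cohorts (10–20 seeds), 4-sample
expression cohorts of 500 cells × 600 genes, calibration batches of
2 × 250 cells × 400 genes, and 30×30–50×50 grids with 300–1000
permutations. These sizes were chosen so the full validation executes in
minutes while keeping every estimate's Monte-Carlo error well inside the
asserted bounds.

## Known limitations

* The ADO merge is single-flip and frequency-gated; a real per-run ADO-rate
  estimate could replace the fixed 1% default (it is a parameter).
* Compartment classification needs both lineages represented among clones;
  a dataset whose clones are all B-lineage labels everything relative to the
  WT background.
* The doublet score is a simplified stand-in for published
  artificial-nearest-neighbor methods and shares their blindness to
  homotypic doublets.
* The light-chain rule inherits its asymmetry (<1% vs >91%) from clinical
  practice; λ-restricted populations need higher purity to register.
* Origin-category thresholds (95%/1%/90%) are pragmatic surrogates for what
  is, in practice, expert inspection; they are all configurable.
* The LR strength definition (scaled product over adjacent pairs) is a
  declared convention, not a fitted interaction model.
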