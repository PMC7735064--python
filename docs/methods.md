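# Methods

This note documents the models behind `cernet`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions a user should know before trusting a result.

## Scope and design

The pipeline assembles a core ceRNA (competing endogenous RNA) network in
five stages: bulk differential expression, weighted co-expression module
analysis, single-cell cell-type analysis, seed-match target prediction, and
tripartite network assembly, with CFG evidence scoring and hypergeometric
enrichment as companion analyses. Each stage is a pure function over
explicit in-memory containers (pandas DataFrames, AnnData, networkx
graphs), so stages can be re-run, swapped or tested in isolation. The
package is library-first: the importable API plus the narrative scripts in
`examples/` are the interface, and file I/O helpers (`cernet.io`) cover the
plain-text interchange formats (TSV, MTX triplet, FASTA, GraphML, JSON).

## Differential expression (`cernet.diffexpr`)

Expression is modelled on the log2 scale (microarray-style intensities or
log-normalised counts). The two-group contrast is a per-feature Welch
*t*-test — the original analysis names only a software product, not a
statistic, so the unequal-variance *t* is used and recorded here as this
package's choice. `log2fc` is the case-minus-control mean difference on the
log2 scale. Multiplicity is handled by Benjamini–Hochberg over all tested
features; the significance gates are deliberately strict inequalities,
|log2FC| > 1.0 and adjusted *p* < 0.05, matching the published "> 1.0" and
"< 0.05". A feature constant in both groups gets *p* = 1 by convention and
a `constant` flag rather than an error.

The qPCR companion statistic is 2^-ΔΔCt: ΔCt = Ct_target − Ct_reference
per sample, ΔΔCt subtracts the arithmetic mean control ΔCt (the baseline
convention is unstated in the source; the arithmetic mean is this package's
choice), and the group comparison is a Student *t* on ΔCt. Degenerate
designs (one sample per group) report the fold change with a missing
*p*-value instead of failing.

Top-*n* tables rank by |log2FC| descending with ties broken by smaller
adjusted *p*, then lexicographic feature id, so outputs are reproducible to
the byte.

## Co-expression analysis (`cernet.coexpression`)

The network is **unsigned**: adjacency `a_ij = |cor(x_i, x_j)|^β` with
Pearson correlation throughout (the source states neither signedness nor
the correlation type; unsigned Pearson is the historical default). β is
chosen by the scale-free topology criterion: connectivities are binned
(10 bins), log10 frequency is regressed on log10 mean connectivity, and the
smallest β whose signed fit `−sign(slope)·R²` reaches 0.8 wins, falling
back to the argmax with a warning when no candidate reaches it — the
fallback is normal for small designs, where high powers shrink most
adjacencies toward zero.

Topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with `k_i = Σ_{u≠i} a_iu` and a unit diagonal; the implementation is
vectorised and is checked against a literal double-loop evaluation to
1e-12 in the tests.

Module detection clusters `1 − TOM` by average linkage and cuts the tree at
a deepSplit-dependent fraction of the top merge height (0.99 for
deepSplit = 0 down to 0.91 for deepSplit = 4); branches smaller than
`min_module_size` (default 30) stay unassigned ("grey"). This is a
height-cut approximation of the dynamic tree cut — deepSplit = 0 keeps its
"least splitting" semantics — and label-for-label equality with other
implementations is explicitly not a goal; recovery of planted modules is
what the tests assert. When the expression matrix is supplied, candidate
modules are cleaned by eigengene membership: members with |kME| below
`kme_min` (default 0.6) are released to grey over two passes. In
small-sample designs (the default is 14 arrays) background features attach
to branches through chance correlations of |r| ≈ 0.3–0.5, and kME cleanup
is what keeps planted-module recovery above ARI 0.8; the default was fixed
against planted truth before the acceptance thresholds were evaluated.
Module labels are color names assigned by decreasing final size from a
fixed palette, ties broken by first member position.

The module eigengene is the first principal component of the standardized
module submatrix (unit norm, sign-fixed positive against the module's mean
profile; a singleton module yields that feature standardized). Gene
significance GS_i = cor(x_i, trait) (point-biserial for a 0/1 trait) and
module membership MM_iM = cor(x_i, ME_M). A module qualifies when
cor(|GS|, |MM|) over its members exceeds 0.4 with *p* < 0.05 (Pearson
correlation test); modules under 3 members cannot be tested and are
excluded with a warning. Hubs are the top-5 members by |kME|, ties
lexicographic. Edge export sorts intra-module pairs by TOM weight
descending (ties by id pair) and slices the top 1000 by default, returning
all pairs when fewer exist.

## Single-cell analysis (`cernet.single_cell`)

The canonical container is `AnnData` (cells × genes); `from_counts` adapts
a genes × cells table and flags mitochondrial genes by the `MT-` prefix
when no explicit list is given. QC applies the published strict bounds —
cells kept iff 800 < detected genes < 7,000 and mitochondrial fraction
< 0.15, then genes kept iff detected in ≥ 30 retained cells — and reports
per-rule removal counts independently, so overlapping violations remain
visible. Normalisation is depth scaling to 10,000 counts per cell plus
log1p; HVGs are the top 3,000 genes by Seurat-style normalised dispersion
(both the scale factor and the flavor are the package defaults the source
invokes as "default"). Clustering scales the HVGs (clipped at 10), runs
PCA (30 components by default), builds a shared-nearest-neighbour graph
(k = 15) and applies Leiden community detection with a fixed seed — a
modularity-based community method in the same family as the source's
package defaults; exact cluster reproduction is out of reach and replaced
by planted-truth recovery. Downsampling keeps the first 40 barcodes in
lexicographic order within each (sample, cluster) — "ordered by barcode"
read literally — which makes the subset order-independent and idempotent.
Cluster annotation scores each cell type as the mean z-scored expression of
its markers over the cluster's cells; the margin between the best and
second-best type must reach 0.1, otherwise the cluster is "unknown" (ties
never guess silently). Module–trait correlation uses one-hot indicators
per cell-type and gestational-week level; a module is cell-type specific
iff its max |r| over types exceeds 0.6 and developmentally stable iff all
gestational-week |r| stay below 0.3; levels with fewer than 3 cells report
missing correlations.

## Target prediction (`cernet.targets`)

The predictor is a pure seed-complementarity model: an exact Watson–Crick
match to the reverse complement of miRNA positions 2–7 (no G:U wobble, no
thermodynamics, no alignment extension — the exactness is what makes the
brute-force oracle in the tests a true oracle). Site classes follow the
canonical hierarchy: 8mer (core + m8 match + target A opposite position 1),
7mer-m8, 7mer-A1, 6mer; each core hit is reported once under its most
specific class, so classes partition the hits. U and T are interchangeable
on both sides; any other character is an error naming its position.
circRNAs are scanned as circular sequences by appending a 7-nt wrap-around
pad; coordinates are 0-based half-open and reported modulo the transcript
length, so a junction-spanning site may have start > end (its `length`
field is authoritative). Edge scores are the weighted site tally
5·8mer + 3·7mer-m8 + 2·7mer-A1 + 1·6mer; ranking is score-descending with
id tie-breaks. Externally computed edge tables can replace the scanner in
every network function, which accepts plain edge lists.

## Network assembly (`cernet.network`)

The graph is strictly layered — circRNA → miRNA → mRNA, never a direct
circRNA–mRNA edge, enforced at insertion. The multidimensional cascade is
top-20 miRNAs per circRNA → miRNAs shared by ≥ 2 circRNAs → top-5 mRNAs per
retained miRNA. The core network restricts edges to (hub circRNA → DE
miRNA) and (DE miRNA → module-annotated DE mRNA), then iteratively deletes
miRNAs with no surviving mRNA target and circRNAs with no surviving miRNA,
to a fixed point; assembly is independent of input edge order and the
pruning never removes a node on a surviving complete path. Sponge-direction
consistency — sign(circRNA) = sign(mRNA) ≠ sign(miRNA) — is an annotation
only, with "indeterminate" for any non-significant member; biologically it
encodes that a sponged miRNA should move opposite to both the sponge and
the de-repressed target.

## CFG scoring (`cernet.cfg`)

The CFG score sums five binary indicators: nonzero eQTL count, nonzero
GWAS count, nonempty PPI with {APP, PSEN1, PSEN2, APOE, MAPT}, early
differential expression in AD mouse models, and ≥ one asterisk on the
pathology correlation in either mouse line ("ns" and missing both score
zero). The additive rule is not spelled out where the score originates; it
was validated by recomputing every row of the published 47-gene table
before being frozen, and the packaged transcription of that table (with its
printed score column retained for verification only) is a permanent
regression fixture — any future change to the rule must re-pass all 47
rows. The parser accepts the table's printed typography: "–"/"-"/"NA" as
missing, "value, mark" pathology cells, and both U+2212 and ASCII minus.

## Enrichment (`cernet.enrichment`)

Over-representation is the one-sided hypergeometric (Fisher) upper tail,
P(X ≥ k), with fold enrichment (k/n)/(K/N) and BH adjustment across the
collection. The background universe is a required argument: whether it
should be the array's parent genes or the whole genome is a study-level
decision the package deliberately does not make. Gene sets travel as GMT.

## Synthetic data (`cernet.synthetic`)

The generators' defaults are the study conditions the pipeline assumes.

**Bulk** (default 300 features × 8 cases + 6 controls): Gaussian noise on
the log2 scale (the source data are microarray intensities, not counts —
the Gaussian-on-log choice is an assumption recorded here, not inferred
intent), baseline ~ N(8, 2), noise SD 1. Three planted classes are
disjoint so every effect is attributable: (i) three modules of 60 features
from a one-factor model x = ℓ·f + √(1−ℓ²)·ε with loadings ℓ drawn around
√(intra_module_cor) (default 0.8) with spread 0.15, so the mean pairwise
intra-module correlation is the configured value while memberships vary
realistically; module factors carry a controlled correlation (default 0.5)
with disease status, and their residuals are Gram–Schmidt orthogonalised
against the trait and each other so the realised inter-module correlation
is the trait correlation squared, keeping modules separable in a 14-sample
design; (ii) 10% chromosome-21 features dosage-shifted in cases by
log2(1.5) — the trisomic expectation, below the DE fold gate by design;
(iii) 10% DE features with signed log2 effects ~ N(1.5, 0.5). chr21 and DE
features are drawn outside the modules so group-mean shifts cannot inflate
the planted correlations.

**Single cell** (default 2,000 genes × 500 cells): negative-binomial
counts (dispersion θ = 2) over gene weights ~ Gamma(2) normalised to a
5% mitochondrial share, per-cell log-normal depth around 6,000 counts, four
cell types with 20 markers each boosted 8-fold, gestational-week labels
(17/20/23, doubling as sample labels) independent of type. 10% of cells
violate exactly one QC rule: low-depth cells (20-fold collapse, ≈ 270
detected genes) fail the >800-genes gate, and high-mito cells (share pinned
at 40%) fail the <15% gate with ≥ 4 SD of margin under NB noise. The
>7,000-genes rule is only constructible when the simulated gene universe
exceeds that threshold, which the default size deliberately does not; the
generator therefore never plants that violation at defaults.

**Sequences**: transcripts are random DNA (300 nt), miRNAs random RNA
(22 nt). For every planted triplet an exact 8mer site for the partner
miRNA is embedded in the circRNA body and the mRNA 3′UTR at a recorded
0-based position. miRNAs are drawn so that no miRNA's 8-nt site contains
another's 6-nt core complement (otherwise embeddings would collide
systematically), and every transcript — including 10 circRNA and 10 UTR
decoys — is re-scanned before delivery: partner sites must be found at the
recorded positions and non-partner scans must be empty, with bounded
regeneration on chance hits. Planted triplet directions default to
(up, down, up), the sponge-consistent configuration.

**Not emulated**: batch effects, probe-level microarray artefacts,
back-splice junction reads, doublets, ambient RNA, cell-type-dependent
depth, correlated gestational-week composition, G:U wobble in seeds, and
partial/imperfect miRNA sites. Passing recovery tests therefore shows the
pipeline's logic is correct under its own modelling assumptions, not that
it is robust to every artefact of real data.

## Problem sizes and determinism

Recovery suites run 20 generator seeds at the default sizes above; the
worked hub-count analysis uses a larger engineered design (280 features,
30 + 30 samples, three modules of 70, trait correlation 0.55, loading
spread 0.25) chosen so that exactly three strong modules pass the GS–MM
filter and the top-5 rule yields 15 hubs. All generators are deterministic
given `GeneratorConfig.seed` (independent numpy Generator streams per
generator), clustering takes an explicit seed, and every ranking in the
package carries a documented tie-break, so repeated runs are byte-identical.

## Known limitations

* The tree cut is a height-cut approximation; highly nested module
  structure that the dynamic-hybrid cut would resolve may be merged.
* The GS–MM qualification has low power in very small designs (e.g. 14
  samples with homogeneous memberships); this mirrors the statistic itself,
  not an implementation limit.
* The seed matcher ignores binding energetics and 3′-compensatory pairing;
  it is a stand-in designed for exactness, with external edge tables as the
  escape hatch.
* CFG scoring is frozen to the five-indicator additive rule; evidence
  categories with graded strength (e.g. large eQTL counts) still contribute
  a single point.
* No module merging by eigengene similarity, no blockwise decomposition for
  very large feature sets, no consensus networks, no batch integration, no
  trajectory inference.
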