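# cernet

Extraction of a core **circRNA–miRNA–mRNA (ceRNA) network** from bulk and
single-cell transcriptomics, with planted-truth synthetic data for every
stage.

Covalently closed circular RNAs can sequester miRNAs through miRNA response
elements, de-repressing the miRNAs' mRNA targets ("sponging"). This package
re-implements, as a tested and reusable library, the integrative procedure
used to chart that regulatory layer in the trisomy-21 (Down syndrome) fetal
hippocampus: differential circRNA expression from a case/control microarray
design, weighted co-expression modules and hub selection, single-cell
cell-type modules, seed-complementarity target prediction, tripartite
network assembly with pruning, and a convergent functional genomics (CFG)
evidence score for the network's target genes. It is aimed at computational
biologists who want each stage as an importable, recovery-testable function
rather than a chain of web services.

## Methods at the core

* **Differential expression** — per-feature Welch *t* on log2 intensities,
  Benjamini–Hochberg adjustment, strict gates |log2FC| > 1.0 and adjusted
  *p* < 0.05.
* **Co-expression** — unsigned adjacency $a_{ij} = |\mathrm{cor}(x_i,x_j)|^\beta$
  with β from the scale-free topology criterion; topological overlap
  $\mathrm{TOM}_{ij} = \frac{\sum_{u \ne i,j} a_{iu}a_{uj} + a_{ij}}{\min(k_i,k_j) + 1 - a_{ij}}$;
  average-linkage clustering of $1-\mathrm{TOM}$ with a conservative height
  cut (deepSplit = 0, minimum module size 30) plus kME cleanup; module
  eigengenes (first PC); modules kept when cor(|GS|, |MM|) > 0.4 at
  *p* < 0.05; hubs = top-5 |kME| per passing module; top-1000 TOM edges
  exported per module.
* **Single cell** — strict QC (cells with >800 and <7,000 detected genes,
  <15% mitochondrial fraction; genes in ≥30 cells), depth normalisation to
  10,000 + log1p, top-3,000 dispersion-ranked HVGs, PCA → SNN graph →
  Leiden communities with a fixed seed, first-40-barcodes-per-cluster
  downsampling, marker-score cluster annotation, and module eigengene
  correlation with one-hot cell types (specific iff max |r| > 0.6) and
  gestational weeks (stable iff all |r| < 0.3).
* **Target prediction** — exact Watson–Crick complement of miRNA seed
  positions 2–7, classified 8mer / 7mer-m8 / 7mer-A1 / 6mer; circRNAs are
  scanned as circular sequences (sites may wrap the back-splice junction);
  edge score 5·8mer + 3·7mer-m8 + 2·7mer-A1 + 1·6mer; top-20 miRNAs per
  circRNA, miRNAs kept when ≥2 circRNAs share them, top-5 mRNAs per miRNA.
* **Network assembly** — tripartite circRNA → miRNA → mRNA graph (no direct
  circRNA–mRNA edges); the core network keeps hub circRNAs, DE miRNAs and
  module-annotated DE mRNAs and iteratively deletes molecules that reach no
  DE mRNA; sponge-direction consistency (circRNA and mRNA moving together,
  opposite the miRNA) is annotated, never filtered on.
* **CFG score** — per gene, one point for each of: nonzero eQTL count,
  nonzero GWAS count, physical interaction with APP/PSEN1/PSEN2/APOE/MAPT,
  early differential expression in AD mouse models, and a significant
  pathology correlation in either the amyloid-β or tau line (0–5 total).
* **Enrichment** — one-sided hypergeometric over-representation against an
  explicit universe, BH across the collection.

The synthetic generators (`cernet.synthetic`) emulate the study design —
8 cases vs 6 controls, chromosome-21 dosage at 1.5×, latent-factor
co-expression modules, negative-binomial single-cell counts with planted
cell types and QC violators, and sequence pools with embedded miRNA
response elements — and return machine-readable ground truth so every
stage's recovery is testable offline.

## Worked example

```bash
python examples/02_coexpression_modules.py
```

```
soft threshold: power=10, scale-free R^2=0.410
modules found: ['turquoise', 'blue', 'brown'] (ARI vs planted truth: 0.962)

GS-MM filter (cor > 0.4, p < 0.05): ['turquoise', 'blue', 'brown'] pass
             cor    p   n  passed
module
turquoise  0.830  0.0  70    True
blue       0.803  0.0  68    True
brown      0.832  0.0  68    True

hub circRNAs (15 total = top 5 MM per passing module):
  turquoise: ['circ_00133', 'circ_00107', 'circ_00105', 'circ_00124', 'circ_00138']
  ...
```

Three planted trait-linked modules are recovered almost exactly (adjusted
Rand index 0.96 against the planted partition), all three pass the GS–MM
qualification, and the top-5 module-membership rule yields 15 hub circRNAs
— the hub count the full pipeline is designed to produce when exactly three
modules qualify. The other scripts in `examples/` walk the remaining
stages (differential expression, single-cell pipeline, target scanning,
core-network assembly and pruning, CFG scoring, enrichment), each printing
the quantities it computes and what they mean.

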