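"""Synthetic data with planted, machine-readable ground truth.

Every stage of the ceRNA pipeline gets a recovery-testable input:

* **Bulk circRNA microarray**: Gaussian log2-intensity matrix for a
  case/control design (default eight trisomy-21 cases vs six diploid
  controls), with (i) chromosome-21 features dosage-shifted in cases by a
  configurable fold (default 1.5x, the trisomic expectation), (ii) planted
  co-expression modules built from a latent one-factor model so the
  intra-module correlation is controlled analytically, with the module
  factor linked to disease status so GS/MM filtering has signal, and
  (iii) a planted differentially-expressed feature set with configurable
  log2 effect sizes.  An annotation table assigns chromosome, parent gene
  and category (exon/intron/intergenic/other) per feature.
* **Single-cell counts**: negative-binomial UMI counts with discrete
  cell-type programs (upregulated marker blocks), designated mitochondrial
  genes, per-cell depth variation, gestational-week/sample labels, and an
  engineered fraction of cells that each violate exactly one QC rule.
* **Sequence pools**: DNA transcripts (circRNA bodies, mRNA 3'UTRs) with an
  embedded exact seed site for the partner miRNA of every planted sponge
  triplet, verified by scanning before delivery so decoys carry no site for
  any generated miRNA.

All generators are deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import targets as _targets

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "BulkDataset",
    "ScDataset",
    "SequencePools",
    "generate_bulk_circrna",
    "generate_scrna",
    "generate_sequences",
]

_CATEGORIES = ("exon", "intron", "intergenic", "other")
_CATEGORY_PROBS = (0.75, 0.12, 0.08, 0.05)  # exonic majority, as in arrays


@dataclass
class GeneratorConfig:
    """All knobs for the three generators; defaults mirror the study design."""

    # bulk microarray
    n_features: int = 300
    n_case: int = 8
    n_control: int = 6
    n_modules: int = 3
    module_size: int = 60
    intra_module_cor: float = 0.8
    loading_spread: float = 0.15
    module_trait_cor: float = 0.5
    chr21_fraction: float = 0.1
    dosage_effect: float = 1.5
    de_fraction: float = 0.1
    lfc_mean: float = 1.5
    lfc_sd: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    # single cell
    n_cells: int = 500
    n_genes: int = 2000
    n_cell_types: int = 4
    marker_genes_per_type: int = 20
    marker_fold: float = 8.0
    mito_gene_count: int = 10
    mito_fraction: float = 0.05
    qc_violator_fraction: float = 0.1
    nb_dispersion: float = 2.0
    counts_per_cell: int = 6000
    gestational_weeks: tuple[int, ...] = (17, 20, 23)
    # sequences
    n_triplets: int = 5
    n_decoys: int = 10
    transcript_length: int = 300
    mirna_length: int = 22
    # rng
    seed: int = 0

    def validate(self) -> None:
        for name in ("intra_module_cor", "chr21_fraction", "de_fraction",
                     "qc_violator_fraction", "mito_fraction", "module_trait_cor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_features", "n_case", "n_control", "n_cells", "n_genes",
                     "n_cell_types", "n_triplets", "transcript_length",
                     "mirna_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_modules * self.module_size > self.n_features:
            raise ValueError(
                f"module_size * n_modules = {self.n_modules * self.module_size} "
                f"exceeds n_features = {self.n_features}"
            )
        if self.n_cell_types > self.n_cells:
            raise ValueError("n_cell_types exceeds n_cells")
        if self.mirna_length < 8:
            raise ValueError("mirna_length must be at least 8")


@dataclass
class SyntheticTruth:
    """Ground truth shared across the generated artifacts."""

    de_features: dict[str, float] = field(default_factory=dict)  # id -> signed log2 effect
    chr21_features: list[str] = field(default_factory=list)
    module_map: dict[str, int] = field(default_factory=dict)  # feature -> planted module
    module_factors: pd.DataFrame | None = None  # samples x planted modules
    cell_labels: dict[str, int] = field(default_factory=dict)  # barcode -> planted type
    qc_violations: dict[str, str] = field(default_factory=dict)  # barcode -> rule
    triplets: list[tuple[str, str, str]] = field(default_factory=list)
    triplet_directions: tuple[str, str, str] = ("up", "down", "up")
    mre_positions: dict[str, list[dict]] = field(default_factory=dict)


@dataclass
class BulkDataset:
    matrix: pd.DataFrame  # features x samples, log2 scale
    groups: pd.Series  # sample -> "case"/"control"
    annotation: pd.DataFrame  # feature -> chromosome, parent_gene, category
    truth: SyntheticTruth


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_bulk_circrna(config: GeneratorConfig) -> BulkDataset:
    """Two-group log2-intensity circRNA matrix with planted structure.

    Module features come first (contiguous blocks), followed by chr21
    dosage features, planted DE features and pure-noise background; the
    three planted classes are disjoint so each effect is attributable.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_features
    features = [f"circ_{i:05d}" for i in range(n)]
    samples = [f"case_{i + 1}" for i in range(config.n_case)] + [
        f"control_{i + 1}" for i in range(config.n_control)
    ]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control,
        index=samples,
        name="group",
    )
    g = np.where(groups.to_numpy() == "case", 0.5, -0.5)
    n_samples = len(samples)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    x = np.tile(baseline[:, None], (1, n_samples)).astype(float)

    truth = SyntheticTruth()

    # Planted co-expression modules: one latent factor per module with a
    # controlled correlation to disease status.  Residuals are Gram-Schmidt
    # orthogonalised against the trait and against each other, so the
    # realised inter-module factor correlation is module_trait_cor**2 and
    # modules stay separable even in small designs.
    g_std = (g - g.mean()) / g.std()
    a = config.module_trait_cor
    factors = np.zeros((n_samples, config.n_modules))
    residuals: list[np.ndarray] = []
    pos = 0
    for m in range(config.n_modules):
        z = rng.normal(size=n_samples)
        for b in [g_std, *residuals]:
            z = z - (z @ b) / (b @ b) * b
        if z.std() == 0:
            raise ValueError("too many modules for the number of samples")
        z = z / z.std()
        residuals.append(z)
        f = a * g_std + np.sqrt(1.0 - a**2) * z
        factors[:, m] = f
        for _ in range(config.module_size):
            fid = features[pos]
            loading = np.sqrt(config.intra_module_cor) + rng.uniform(
                -config.loading_spread, config.loading_spread
            )
            loading = float(np.clip(loading, 0.05, 0.995))
            eps = rng.normal(size=n_samples)
            x[pos] += config.noise_sd * (
                loading * f + np.sqrt(1.0 - loading**2) * eps
            )
            truth.module_map[fid] = m
            pos += 1
    truth.module_factors = pd.DataFrame(
        factors, index=samples, columns=[f"planted_{m}" for m in range(config.n_modules)]
    )

    # independent noise for everything outside the planted modules
    x[pos:] += config.noise_sd * rng.normal(size=(n - pos, n_samples))

    # chromosome-21 dosage features, drawn outside the modules so the
    # group-mean shift does not distort the planted correlations
    free = np.arange(pos, n)
    n_chr21 = int(round(config.chr21_fraction * n))
    chr21_idx = rng.choice(free, size=min(n_chr21, len(free)), replace=False)
    dosage_lfc = float(np.log2(config.dosage_effect))
    case_mask = (groups == "case").to_numpy()
    for i in chr21_idx:
        x[i, case_mask] += dosage_lfc
        truth.chr21_features.append(features[i])

    # planted DE features (disjoint from modules and chr21)
    remaining = np.setdiff1d(free, chr21_idx)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(remaining, size=min(n_de, len(remaining)), replace=False)
    for i in de_idx:
        effect = rng.choice([-1.0, 1.0]) * rng.normal(config.lfc_mean, config.lfc_sd)
        x[i, case_mask] += effect
        truth.de_features[features[i]] = float(effect)

    chroms = np.array(
        [f"chr{c}" for c in list(range(1, 21)) + [22, "X"]], dtype=object
    )
    chromosome = rng.choice(chroms, size=n)
    chromosome[chr21_idx] = "chr21"
    annotation = pd.DataFrame(
        {
            "chromosome": chromosome,
            "parent_gene": [f"GENE{i // 3:04d}" for i in range(n)],
            "category": rng.choice(_CATEGORIES, size=n, p=_CATEGORY_PROBS),
        },
        index=pd.Index(features, name="feature"),
    )
    matrix = pd.DataFrame(x, index=annotation.index, columns=samples)
    return BulkDataset(matrix=matrix, groups=groups, annotation=annotation, truth=truth)


@dataclass
class ScDataset:
    counts: pd.DataFrame  # genes x cells (UMI counts)
    obs: pd.DataFrame  # per-cell: cell_type, gestational_week, sample, qc_violation
    var: pd.DataFrame  # per-gene: mito flag, marker_type
    truth: SyntheticTruth


def generate_scrna(config: GeneratorConfig) -> ScDataset:
    """Negative-binomial UMI counts with planted cell types and QC violators.

    Gene layout: ``MT-*`` mitochondrial genes first, then one marker block
    per cell type (upregulated ``marker_fold``-fold in that type), then
    background genes.  A ``qc_violator_fraction`` of cells is engineered to
    fail exactly one QC rule — either the minimum-genes-detected rule
    (depth collapsed ~20-fold) or the mitochondrial-fraction rule (mito
    share raised to ~30%); the maximum-genes rule is only constructible
    when the simulated gene universe exceeds that threshold, which the
    default size deliberately does not.
    """
    config.validate()
    rng = _rng(config, 2)
    n_genes, n_cells = config.n_genes, config.n_cells
    n_mito = config.mito_gene_count
    n_marker = config.n_cell_types * config.marker_genes_per_type
    if n_mito + n_marker > n_genes:
        raise ValueError("mito + marker genes exceed n_genes")

    genes = (
        [f"MT-{i + 1}" for i in range(n_mito)]
        + [
            f"MARK{t}_{j + 1}"
            for t in range(config.n_cell_types)
            for j in range(config.marker_genes_per_type)
        ]
        + [f"BG_{i + 1:05d}" for i in range(n_genes - n_mito - n_marker)]
    )
    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]

    # relative expression weights; mito genes rescaled to the target share
    w = rng.gamma(2.0, 1.0, size=n_genes)
    w /= w.sum()
    mito = np.zeros(n_genes, dtype=bool)
    mito[:n_mito] = True
    w[mito] *= config.mito_fraction / w[mito].sum()
    w[~mito] *= (1.0 - config.mito_fraction) / w[~mito].sum()

    cell_type = rng.integers(config.n_cell_types, size=n_cells)
    gw = rng.choice(np.array(config.gestational_weeks), size=n_cells)

    n_viol = int(round(config.qc_violator_fraction * n_cells))
    viol_idx = rng.choice(n_cells, size=n_viol, replace=False)
    viol_rule = {
        int(c): ("low_genes" if j % 2 == 0 else "high_mito")
        for j, c in enumerate(viol_idx)
    }

    depth = np.exp(rng.normal(0.0, 0.25, size=n_cells)) * config.counts_per_cell
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    theta = config.nb_dispersion
    marker_slice = {
        t: slice(
            n_mito + t * config.marker_genes_per_type,
            n_mito + (t + 1) * config.marker_genes_per_type,
        )
        for t in range(config.n_cell_types)
    }
    for c in range(n_cells):
        wc = w.copy()
        wc[marker_slice[int(cell_type[c])]] *= config.marker_fold
        rule = viol_rule.get(c)
        if rule == "high_mito":
            # pin the expected mito share at 40%, comfortably past the 15%
            # gate even under negative-binomial noise
            target = 0.40
            wc[mito] *= (target / (1 - target)) * wc[~mito].sum() / wc[mito].sum()
        wc /= wc.sum()
        d = depth[c] * (0.05 if rule == "low_genes" else 1.0)
        mu = d * wc
        counts[:, c] = rng.negative_binomial(theta, theta / (theta + mu))

    truth = SyntheticTruth(
        cell_labels={barcodes[c]: int(cell_type[c]) for c in range(n_cells)},
        qc_violations={barcodes[c]: r for c, r in viol_rule.items()},
    )
    obs = pd.DataFrame(
        {
            "cell_type": cell_type,
            "gestational_week": gw,
            "sample": [f"GW{int(v)}" for v in gw],
            "qc_violation": [viol_rule.get(c, "") for c in range(n_cells)],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(
        {
            "mito": mito,
            "marker_type": [
                next(
                    (t for t in range(config.n_cell_types)
                     if marker_slice[t].start <= i < marker_slice[t].stop),
                    -1,
                )
                for i in range(n_genes)
            ],
        },
        index=pd.Index(genes, name="gene"),
    )
    return ScDataset(
        counts=pd.DataFrame(counts, index=var.index, columns=obs.index),
        obs=obs,
        var=var,
        truth=truth,
    )


@dataclass
class SequencePools:
    circ_seqs: dict[str, str]  # DNA alphabet; scanned as circular
    utr_seqs: dict[str, str]  # mRNA 3'UTRs, DNA alphabet
    mirna_seqs: dict[str, str]  # RNA alphabet, 5'->3'
    truth: SyntheticTruth


_DNA = np.array(list("ACGT"))
_D2R = str.maketrans("T", "U")
_COMP = str.maketrans("ACGT", "TGCA")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def _embed_site(rng, seq: str, mirna_rna: str, avoid: int | None = None) -> tuple[str, int]:
    """Insert an 8mer site for the miRNA at a random interior position."""
    m = mirna_rna.translate(_D2R).replace("U", "T")
    core = m[1:7]
    site = m[7].translate(_COMP) + core.translate(_COMP)[::-1] + "A"  # 8 nt
    start = int(rng.integers(1, len(seq) - len(site) - 1))
    if avoid is not None and abs(start - avoid) < 10:
        start = (start + 20) % (len(seq) - len(site) - 2) + 1
    return seq[:start] + site + seq[start + len(site):], start


def generate_sequences(
    config: GeneratorConfig,
    truth: SyntheticTruth | None = None,
    max_retries: int = 50,
) -> SequencePools:
    """Sequence pools realising the planted sponge triplets.

    For every planted triplet (circRNA, miRNA, mRNA), both the circRNA body
    and the mRNA 3'UTR contain at least one exact 8mer site for the miRNA;
    decoy transcripts contain no seed site for *any* generated miRNA.  Each
    transcript is re-scanned before delivery and regenerated (up to
    ``max_retries`` times) if a chance site for a non-partner miRNA
    appeared; exhaustion raises ``RuntimeError``.
    """
    config.validate()
    rng = _rng(config, 3)
    if truth is None:
        truth = SyntheticTruth()
    if not truth.triplets:
        truth.triplets = [
            (f"circ_T{i}", f"miR-T{i}", f"gene_T{i}") for i in range(config.n_triplets)
        ]
    mirna_ids = list(dict.fromkeys(m for _, m, _ in truth.triplets))

    # Distinct seed cores, and no miRNA's 8-nt target site may contain
    # another's 6-nt core complement — otherwise every embedding of one site
    # would systematically create a site for the other miRNA.
    def _site8(rna: str) -> str:
        m = rna.replace("U", "T")
        return m[7].translate(_COMP) + m[1:7].translate(_COMP)[::-1] + "A"

    mirna_seqs: dict[str, str] = {}
    sites8: list[str] = []
    for mid in mirna_ids:
        for _ in range(max_retries):
            seq = _random_dna(rng, config.mirna_length).translate(_D2R)
            s8 = _site8(seq)
            core6 = s8[1:7]
            clash = any(
                core6 in other or other[1:7] in s8 for other in sites8
            )
            if not clash:
                sites8.append(s8)
                mirna_seqs[mid] = seq
                break
        else:
            raise RuntimeError("could not draw miRNAs with non-colliding seeds")

    def build(tid: str, partners: list[str], circular: bool) -> str:
        for _ in range(max_retries):
            seq = _random_dna(rng, config.transcript_length)
            starts = {}
            ok = True
            for mid in partners:
                seq, start = _embed_site(rng, seq, mirna_seqs[mid])
                starts[mid] = start
            for mid, mseq in mirna_seqs.items():
                sites = _targets.find_seed_sites(
                    seq, mseq, transcript_id=tid, circular=circular
                )
                if mid in partners:
                    planted = [s for s in sites if s.site_class == "8mer"
                               and s.start == starts[mid]]
                    if not planted:
                        ok = False
                        break
                elif sites:
                    ok = False
                    break
            if ok:
                truth.mre_positions[tid] = [
                    s.__dict__
                    | {"mirna": mid}
                    for mid in partners
                    for s in _targets.find_seed_sites(
                        seq, mirna_seqs[mid], transcript_id=tid, circular=circular
                    )
                ]
                return seq
        raise RuntimeError(f"site embedding kept colliding for {tid}")

    by_circ: dict[str, list[str]] = {}
    by_gene: dict[str, list[str]] = {}
    for c, m, g in truth.triplets:
        by_circ.setdefault(c, []).append(m)
        by_gene.setdefault(g, []).append(m)

    circ_seqs = {c: build(c, ms, circular=True) for c, ms in by_circ.items()}
    utr_seqs = {g: build(g, ms, circular=False) for g, ms in by_gene.items()}
    for i in range(config.n_decoys):
        circ_seqs[f"circ_D{i}"] = build(f"circ_D{i}", [], circular=True)
        utr_seqs[f"gene_D{i}"] = build(f"gene_D{i}", [], circular=False)

    return SequencePools(
        circ_seqs=circ_seqs, utr_seqs=utr_seqs, mirna_seqs=mirna_seqs, truth=truth
    )
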