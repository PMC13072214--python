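"""Synthetic germinal-center lymphoma cohorts.

Generates the three data modalities the analysis stages consume, with the
statistical structure those stages assume, so the whole pipeline is testable
without access to patient data:

* :func:`generate_scdna` — multi-clone single-cell genotype tables with
  allele dropout (ADO), missing calls, quality/depth layers and an
  antibody-count layer (Tapestri-like).
* :func:`generate_scrna` — cell × gene negative-binomial count matrices for
  a cohort of lymphoma and tonsil-control samples. Malignant B cells of each
  simulated patient carry a patient-specific transcriptional program on top
  of a shared B program, with clonal light-chain (κ/λ) restriction; normal
  infiltrating B cells share one program across all samples; tFL/DLBCL-like
  conditions shift exhaustion and adhesion genes in the designated T subsets.
* :func:`generate_spatial` — gap-free grid bins (Visium-HD-like, 8 µm) with
  follicular (B-cell discs with Tfh-enriched rims) or diffuse layouts.

All generators are pure functions of the configuration (which carries the
seed): reruns are bit-identical. Planted truth labels are stored in
evaluation-only slots (``uns["truth"]`` / ``GenotypeDataset.truth``) that no
analysis stage reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .scdna_clones import GenotypeDataset

# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

TYPE_MARKERS: dict[str, list[str]] = {
    "B": ["MS4A1", "CD79A", "CD79B", "CD19", "BANK1", "CD74"],
    "CD4_Tfh": ["CXCL13", "TOX2", "CXCR5", "CD40LG", "ICOS", "MAF", "CD4"],
    "CD4_Treg": ["FOXP3", "IL2RA", "CTLA4", "TNFRSF1B", "IKZF2", "CD4"],
    "CD8_Teff": ["GZMK", "NKG7", "PRF1", "GZMB", "CD8A", "CD8B"],
    "CD8_TCM": ["IL7R", "CD44", "ITGA1", "CD8A", "CD8B"],
    "naive_T": ["SELL", "CCR7", "TCF7", "LEF1"],
    "NK": ["AOAH", "SLAMF7", "CD96", "SAMD3", "KLRD1", "GNLY"],
    "myeloid": ["LYZ", "CD68", "CD14", "CD163", "AIF1"],
    "plasma": ["MZB1", "JCHAIN", "XBP1", "TNFRSF17", "PRDM1"],
}

PAN_T_GENES = ["CD3D", "CD3E", "CD3G", "TRAC", "CD2", "CD7"]
T_TYPES = ("CD4_Tfh", "CD4_Treg", "CD8_Teff", "CD8_TCM", "naive_T")

EXHAUSTION_GENES = ["PDCD1", "LAG3", "HAVCR2"]
ADHESION_GENES = ["CD2", "CTLA4", "MAF", "PDCD1", "CD40LG", "ICOS"]
#: T subsets in which the condition effect is planted
EXHAUSTION_TYPES = ("CD8_Teff", "CD4_Treg")
ADHESION_TYPES = ("CD4_Tfh",)

KAPPA_GENE = "IGKC"
LAMBDA_GENES = ["IGLC2", "IGLC3"]
MT_GENES = ["MT-CO1", "MT-CO2", "MT-CO3", "MT-ND1", "MT-ND2", "MT-ATP6", "MT-CYB"]
S_GENES = ["MCM6", "PCNA", "RRM2", "TYMS", "FEN1"]
G2M_GENES = ["MKI67", "TOP2A", "CCNB1", "BIRC5", "CDK1", "UBE2C"]
TONSIL_GC_GENES = ["BCL6", "AICDA", "RGS13", "LRMP", "SUGCT"]
#: spatial ligand→receptor axes planted on the follicle rim/core
LR_PAIRS = [("CD40LG", "CD40"), ("CXCL13", "CXCR5"), ("CD2", "CD58")]
RECEPTOR_GENES = ["CD40", "CD58"]  # CXCR5 already in the Tfh marker list

PROTEIN_PANEL = ["CD19", "CD5", "CD10", "CD30", "CD2", "CD3", "CD7"]

_CORE_GENES: list[str] = []
for _lst in list(TYPE_MARKERS.values()) + [PAN_T_GENES, EXHAUSTION_GENES, ADHESION_GENES,
                                           [KAPPA_GENE], LAMBDA_GENES, MT_GENES,
                                           S_GENES, G2M_GENES, TONSIL_GC_GENES, RECEPTOR_GENES]:
    for _g in _lst:
        if _g not in _CORE_GENES:
            _CORE_GENES.append(_g)


def build_gene_panel(n_genes: int) -> list[str]:
    """Core marker/signature genes followed by synthetic filler genes."""
    if n_genes < len(_CORE_GENES):
        raise ValueError(f"n_genes must be ≥ {len(_CORE_GENES)} to hold the required panel")
    filler = [f"SYN{i:04d}" for i in range(n_genes - len(_CORE_GENES))]
    return _CORE_GENES + filler


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CloneSpec:
    """One planted genotype clone: label, cohort fraction, variant→zygosity
    map (1 het / 2 hom) and the lineage its cells belong to ('B' malignant
    B-cell clone, 'T' T-compartment clonal-hematopoiesis clone)."""

    label: str
    fraction: float
    genotype: dict[str, int]
    lineage: str = "B"


@dataclass
class SampleSpec:
    """One simulated specimen."""

    sample_id: str
    condition: str = "ntFL"            # ntFL | tFL | DLBCL | tonsil
    malignant_fraction: float = 0.8    # of B cells; 0 for tonsil controls
    light_chain: str = "kappa"         # clonal light-chain class of the tumor

    @property
    def is_control(self) -> bool:
        return self.condition == "tonsil"


def _default_samples() -> list[SampleSpec]:
    return [
        SampleSpec("ntFL1", "ntFL", 0.8, "kappa"),
        SampleSpec("tFL1", "tFL", 0.8, "kappa"),
        SampleSpec("tonsil1", "tonsil", 0.0),
        SampleSpec("tonsil2", "tonsil", 0.0),
    ]


def _default_clones() -> list[CloneSpec]:
    return [
        CloneSpec("founder", 0.60, {"KMT2D_c.3428C>T": 1}, "B"),
        CloneSpec("subclone", 0.30, {"KMT2D_c.3428C>T": 1, "EZH2_p.Y646N": 1}, "B"),
    ]


def _default_fractions() -> dict[str, float]:
    return {"B": 0.40, "CD4_Tfh": 0.12, "CD4_Treg": 0.08, "CD8_Teff": 0.10,
            "CD8_TCM": 0.08, "naive_T": 0.10, "NK": 0.05, "myeloid": 0.07}


@dataclass
class SimConfig:
    """Study-condition parameters for all three generators."""

    seed: int = 0
    n_cells: int = 1000                # per sample
    samples: list[SampleSpec] = field(default_factory=_default_samples)
    clone_spec: list[CloneSpec] = field(default_factory=_default_clones)
    ado_rate: float = 0.05
    missing_rate: float = 0.02
    lowqual_frac: float = 0.05         # calls failing the GQ/DP gates
    ado_lowqual_frac: float = 0.90     # ADO'd calls with decreased GQ/DP
    low_vaf_frac: float = 0.02         # mutant calls below the VAF gate
    n_nonpathogenic_variants: int = 2
    include_germline: bool = True
    n_genes: int = 1000
    cell_type_fractions: dict[str, float] = field(default_factory=_default_fractions)
    malignant_program_strength: float = 3.0   # added mean counts on program genes
    n_program_genes: int = 30
    kappa_purity: float = 0.97         # clonal light-chain restriction
    normal_kappa_rate: float = 0.55    # polyclonal κ fraction in normal B cells
    condition_effect: float = 1.0      # added mean counts on signature genes (tFL/DLBCL)
    effect_conditions: tuple = ("tFL", "DLBCL")
    doublet_rate: float = 0.05
    qc_fail_frac: float = 0.02
    cycling_fraction: float = 0.0
    nb_dispersion: float = 10.0
    grid_rows: int = 50
    grid_cols: int = 50
    layout: str = "follicular"         # follicular | diffuse
    lr_effect: float = 0.0             # ligand/receptor elevation (tFL-like niches)

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.clone_spec)
        if total > 1.0 + 1e-9:
            raise ValueError(f"clone fractions sum to {total:.3f} > 1")
        fsum = sum(self.cell_type_fractions.values())
        if abs(fsum - 1.0) > 1e-6:
            raise ValueError(f"cell_type_fractions sum to {fsum:.4f}, expected 1")
        for name in ("ado_rate", "missing_rate", "lowqual_frac", "ado_lowqual_frac",
                     "low_vaf_frac", "kappa_purity", "normal_kappa_rate",
                     "doublet_rate", "qc_fail_frac", "cycling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.condition_effect < 0 or self.malignant_program_strength <= 0:
            raise ValueError("effect strengths must be non-negative / positive")
        if self.layout not in ("follicular", "diffuse"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if min(self.grid_rows, self.grid_cols) < 5:
            raise ValueError("grid must be at least 5×5")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), *stream]))


# ---------------------------------------------------------------------------
# negative-binomial sampling
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(μ, θ) with var = μ + μ²/θ; μ may be 0."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(dispersion, p)
    out[mean <= 0] = 0
    return out.astype(np.int32)


# ---------------------------------------------------------------------------
# scDNA generator
# ---------------------------------------------------------------------------

def generate_scdna(config: SimConfig) -> GenotypeDataset:
    """Multi-clone genotype table with ADO, missing calls and protein counts.

    Cells are drawn from the planted clones per their fractions (remainder
    WT). Heterozygous calls flip to WT with probability ``ado_rate``; ADO'd
    calls carry decreased genotype quality and depth with probability
    ``ado_lowqual_frac`` (so the quality cascade can mask them). Antibody
    counts follow the clone lineage: CD19-high for B clones, CD2/CD3/CD7/CD5
    high for T-compartment CH clones; WT background cells are a 50/50 B/T
    polyclonal mixture. Planted truth is stored in ``dataset.truth``.
    """
    rng = config.rng(1)
    n = config.n_cells
    variants = sorted({v for c in config.clone_spec for v in c.genotype})
    extra = [f"NPV{i + 1}" for i in range(config.n_nonpathogenic_variants)]
    germ = ["GERMLINE1"] if config.include_germline else []
    all_variants = variants + extra + germ
    pathogenic = pd.Series([True] * len(variants) + [False] * len(extra) + [True] * len(germ),
                           index=all_variants, dtype=object)

    fractions = np.array([c.fraction for c in config.clone_spec])
    wt_frac = 1.0 - fractions.sum()
    probs = np.append(fractions, wt_frac)
    assignment = rng.choice(len(probs), size=n, p=probs)  # last index = WT

    nv = len(all_variants)
    gt = np.zeros((n, nv))
    vi = {v: i for i, v in enumerate(all_variants)}
    for ci, spec in enumerate(config.clone_spec):
        rows = assignment == ci
        for v, z in spec.genotype.items():
            gt[rows, vi[v]] = z
    for v in extra:  # scattered non-pathogenic het noise
        hits = rng.random(n) < 0.05
        gt[hits, vi[v]] = np.maximum(gt[hits, vi[v]], 1)
    for v in germ:   # germline-like: het in ~99% of cells
        hits = rng.random(n) < 0.99
        gt[hits, vi[v]] = np.maximum(gt[hits, vi[v]], 1)

    # allele dropout: het → WT
    ado = (gt == 1) & (rng.random((n, nv)) < config.ado_rate)
    gt[ado] = 0

    # quality layers
    gq = rng.integers(40, 100, size=(n, nv))
    dp = np.maximum(rng.poisson(85, size=(n, nv)), 10)
    lowq = rng.random((n, nv)) < config.lowqual_frac
    which = rng.random((n, nv)) < 0.5
    low_gq = lowq & which
    low_dp = lowq & ~which
    ado_low = ado & (rng.random((n, nv)) < config.ado_lowqual_frac)
    low_gq |= ado_low
    low_dp |= ado_low
    gq = np.where(low_gq, rng.integers(0, 30, size=(n, nv)), gq)
    dp = np.where(low_dp, rng.integers(1, 10, size=(n, nv)), dp)

    vaf = np.clip(np.abs(rng.normal(0.01, 0.01, size=(n, nv))), 0, 1)
    het = gt == 1
    hom = gt == 2
    vaf[het] = np.clip(rng.normal(0.5, 0.07, size=int(het.sum())), 0.05, 0.95)
    vaf[hom] = np.clip(rng.normal(0.95, 0.03, size=int(hom.sum())), 0.5, 1.0)
    low_vaf = (gt > 0) & (rng.random((n, nv)) < config.low_vaf_frac)
    vaf[low_vaf] = rng.uniform(0.05, 0.20, size=int(low_vaf.sum()))

    # missing calls
    gt[rng.random((n, nv)) < config.missing_rate] = np.nan

    # protein counts per clone lineage
    lineages = np.array([c.lineage for c in config.clone_spec] + ["WT"])
    cell_lineage = lineages[assignment]
    wt_rows = cell_lineage == "WT"
    cell_lineage = cell_lineage.copy()
    cell_lineage[wt_rows] = np.where(rng.random(int(wt_rows.sum())) < 0.5, "B", "T")
    b_means = {"CD19": 100, "CD5": 3, "CD10": 30, "CD30": 10, "CD2": 3, "CD3": 3, "CD7": 3}
    t_means = {"CD19": 2, "CD5": 60, "CD10": 2, "CD30": 5, "CD2": 80, "CD3": 90, "CD7": 70}
    mean = np.array([[ (b_means if lin == "B" else t_means)[ab] for ab in PROTEIN_PANEL]
                     for lin in cell_lineage], dtype=float)
    protein = _nb_sample(rng, mean, config.nb_dispersion)

    cells = pd.Index([f"cell{i:05d}" for i in range(n)])
    clone_labels = np.array([c.label for c in config.clone_spec] + ["WT"])[assignment]
    ds = GenotypeDataset(
        cells=cells, variants=pd.Index(all_variants), gt=gt, gq=gq, dp=dp, vaf=vaf,
        pathogenic=pathogenic,
        protein=pd.DataFrame(protein, index=cells, columns=PROTEIN_PANEL),
        sample_id="scdna_sim",
    )
    ds.truth = pd.DataFrame({"clone": clone_labels, "lineage": cell_lineage}, index=cells)
    return ds


# ---------------------------------------------------------------------------
# expression programs shared by scRNA and spatial generators
# ---------------------------------------------------------------------------

#: baseline mean counts for genes outside a cell's programs
_BASE_MEAN = 0.5
_OFF_MARKER_MEAN = 0.05
_MARKER_MEAN = 8.0
_PAN_T_MEAN = 5.0
_MT_MEAN = 2.0


def _type_means(genes: list[str]) -> pd.DataFrame:
    """Cell-type × gene matrix of NB mean counts for the canonical programs."""
    gi = {g: i for i, g in enumerate(genes)}
    types = list(TYPE_MARKERS)
    mat = np.full((len(types), len(genes)), _BASE_MEAN)
    marker_cols = [gi[g] for ms in TYPE_MARKERS.values() for g in ms if g in gi]
    mat[:, sorted(set(marker_cols))] = _OFF_MARKER_MEAN
    for g in PAN_T_GENES + [KAPPA_GENE] + LAMBDA_GENES + RECEPTOR_GENES + \
            EXHAUSTION_GENES + TONSIL_GC_GENES:
        if g in gi:
            mat[:, gi[g]] = _OFF_MARKER_MEAN
    for ti, t in enumerate(types):
        for g in TYPE_MARKERS[t]:
            mat[ti, gi[g]] = _MARKER_MEAN
    for t in T_TYPES:
        ti = types.index(t)
        for g in PAN_T_GENES:
            mat[ti, gi[g]] = _PAN_T_MEAN
    for t in EXHAUSTION_TYPES:  # baseline checkpoint expression in these subsets
        ti = types.index(t)
        for g in EXHAUSTION_GENES:
            mat[ti, gi[g]] = 1.0
    bi = types.index("B")
    mat[bi, gi["CD40"]] = 3.0
    mat[bi, gi["CXCR5"]] = 3.0
    mat[:, gi["CD58"]] = 1.0
    for g in MT_GENES:
        mat[:, gi[g]] = _MT_MEAN
    return pd.DataFrame(mat, index=types, columns=genes)


def _apply_light_chain(mean_row: np.ndarray, gi: dict, chain: str) -> None:
    if chain == "kappa":
        mean_row[gi[KAPPA_GENE]] = 20.0
        for g in LAMBDA_GENES:
            mean_row[gi[g]] = 0.02
    else:
        mean_row[gi[KAPPA_GENE]] = 0.02
        for g in LAMBDA_GENES:
            mean_row[gi[g]] = 10.0


# ---------------------------------------------------------------------------
# scRNA generator
# ---------------------------------------------------------------------------

def generate_scrna(config: SimConfig) -> ad.AnnData:
    """Cohort count matrix with planted malignant, immune and condition structure.

    Returns an AnnData with raw counts in ``X``, per-cell ``sample_id`` and
    ``condition`` in ``obs``, and the evaluation-only truth table (cell type,
    malignancy, doublet flag, light chain, cycle phase) in ``uns['truth']``.
    """
    genes = build_gene_panel(config.n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    programs = _type_means(genes)
    types = list(config.cell_type_fractions)
    missing = [t for t in types if t not in programs.index]
    if missing:
        raise ValueError(f"unknown cell types in fractions: {missing}")
    type_probs = np.array([config.cell_type_fractions[t] for t in types])

    filler = [g for g in genes if g.startswith("SYN")]
    if len(filler) < config.n_program_genes:
        raise ValueError("n_genes too small for the patient-specific programs")

    blocks = []   # (obs rows, truth rows, count matrix)
    for si, samp in enumerate(config.samples):
        rng = config.rng(2, si)
        n = config.n_cells
        ct = np.array(types)[rng.choice(len(types), size=n, p=type_probs)]
        mean = programs.loc[ct].to_numpy().copy()

        is_b = ct == "B"
        malignant = is_b & (rng.random(n) < samp.malignant_fraction)
        if samp.is_control:
            malignant[:] = False
        # patient-specific malignant program on filler genes
        prog_rng = config.rng(3, si)
        prog_genes = prog_rng.choice(filler, size=config.n_program_genes, replace=False)
        prog_cols = [gi[g] for g in prog_genes]
        mean[np.ix_(malignant, prog_cols)] += config.malignant_program_strength

        # light chains: clonal restriction in malignant cells, polyclonal in normal B
        chain = np.array([""] * n, dtype=object)
        mal_idx = np.flatnonzero(malignant)
        clonal = samp.light_chain
        other = "lambda" if clonal == "kappa" else "kappa"
        draws = rng.random(len(mal_idx))
        chain[mal_idx] = np.where(draws < config.kappa_purity, clonal, other)
        norm_idx = np.flatnonzero(is_b & ~malignant)
        chain[norm_idx] = np.where(rng.random(len(norm_idx)) < config.normal_kappa_rate,
                                   "kappa", "lambda")
        for i in np.flatnonzero(chain != ""):
            _apply_light_chain(mean[i], gi, chain[i])

        # tonsil controls: half of B cells carry a tonsil-specific GC program
        tonsil_gc = np.zeros(n, dtype=bool)
        if samp.is_control:
            tonsil_gc = is_b & (rng.random(n) < 0.5)
            for g in TONSIL_GC_GENES:
                mean[tonsil_gc, gi[g]] += 5.0

        # condition-dependent exhaustion / adhesion shifts
        if samp.condition in config.effect_conditions and config.condition_effect > 0:
            exh_rows = np.isin(ct, EXHAUSTION_TYPES)
            for g in EXHAUSTION_GENES:
                mean[exh_rows, gi[g]] += config.condition_effect
            adh_rows = np.isin(ct, ADHESION_TYPES)
            for g in ADHESION_GENES:
                mean[adh_rows, gi[g]] += config.condition_effect

        # cycling cells (S-phase program)
        phase = np.array(["none"] * n, dtype=object)
        if config.cycling_fraction > 0:
            cyc = rng.random(n) < config.cycling_fraction
            phase[cyc] = "S"
            for g in S_GENES:
                mean[cyc, gi[g]] += 4.0

        # QC failures: low-complexity or high-mito cells
        qc_bad = rng.random(n) < config.qc_fail_frac
        bad_idx = np.flatnonzero(qc_bad)
        half = len(bad_idx) // 2
        mean[bad_idx[:half]] *= 0.05                         # few detected genes
        mt_cols = [gi[g] for g in MT_GENES]
        mean[np.ix_(bad_idx[half:], mt_cols)] *= 25.0        # mito fraction > 15%

        counts = _nb_sample(rng, mean, config.nb_dispersion)

        # doublets: replace a fraction of cells with sums of random pairs
        doublet = np.zeros(n, dtype=bool)
        n_dbl = int(round(config.doublet_rate * n))
        if n_dbl:
            targets = rng.choice(n, size=n_dbl, replace=False)
            pairs = rng.integers(0, n, size=(n_dbl, 2))
            counts[targets] = counts[pairs[:, 0]] + counts[pairs[:, 1]]
            doublet[targets] = True
            ct = ct.copy()

        cell_ids = [f"{samp.sample_id}_c{i:05d}" for i in range(n)]
        obs = pd.DataFrame({"sample_id": samp.sample_id, "condition": samp.condition},
                           index=cell_ids)
        truth = pd.DataFrame({
            "cell_type": ct, "malignant": malignant, "doublet": doublet,
            "light_chain": chain, "phase": phase, "tonsil_gc": tonsil_gc,
            "qc_bad": qc_bad,
        }, index=cell_ids)
        blocks.append((obs, truth, counts))

    obs = pd.concat([b[0] for b in blocks])
    truth = pd.concat([b[1] for b in blocks])
    X = np.vstack([b[2] for b in blocks])
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["truth"] = truth
    return adata


# ---------------------------------------------------------------------------
# spatial generator
# ---------------------------------------------------------------------------

#: background bin-type mixture outside follicles (follicular layout)
_FOLLICULAR_BACKGROUND = {
    "CD4_Treg": 0.12, "CD8_Teff": 0.12, "CD8_TCM": 0.10, "naive_T": 0.14,
    "NK": 0.08, "myeloid": 0.24, "plasma": 0.08, "CD4_Tfh": 0.07, "B": 0.05,
}
#: well-mixed bin-type distribution (diffuse layout)
_DIFFUSE_FRACTIONS = {
    "B": 0.45, "CD4_Tfh": 0.10, "CD4_Treg": 0.08, "CD8_Teff": 0.09,
    "CD8_TCM": 0.07, "naive_T": 0.07, "NK": 0.04, "myeloid": 0.07, "plasma": 0.03,
}


def generate_spatial(config: SimConfig, sample_id: str = "spatial_sim") -> ad.AnnData:
    """Gridded spatial bins with a follicular or diffuse latent layout.

    Follicular layouts place disc-shaped B-cell patches with Tfh-enriched
    rims on the grid; diffuse layouts scatter types independently. Per-bin
    expression is drawn from the latent type's program; a positive
    ``lr_effect`` elevates ligand genes (CD40LG, CXCL13, CD2) in Tfh bins and
    their receptors (CD40, CXCR5, CD58) in B bins, emulating enhanced Tfh–B
    contact in tFL-like tissue. Truth types live in ``uns['truth']``.
    """
    rng = config.rng(4)
    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    n = rows * cols

    if config.layout == "diffuse":
        names = list(_DIFFUSE_FRACTIONS)
        probs = np.array(list(_DIFFUSE_FRACTIONS.values()))
        types = np.array(names)[rng.choice(len(names), size=n, p=probs / probs.sum())]
    else:
        names = list(_FOLLICULAR_BACKGROUND)
        probs = np.array(list(_FOLLICULAR_BACKGROUND.values()))
        types = np.array(names)[rng.choice(len(names), size=n, p=probs / probs.sum())]
        n_follicles = max(1, (rows * cols) // 450)
        for _ in range(n_follicles):
            cy = rng.uniform(0.2 * rows, 0.8 * rows)
            cx = rng.uniform(0.2 * cols, 0.8 * cols)
            radius = rng.uniform(min(rows, cols) * 0.10, min(rows, cols) * 0.16)
            dist = np.hypot(rr - cy, cc - cx)
            core = dist <= radius
            rim = (dist > radius) & (dist <= radius + 1.8)
            types[core] = np.where(rng.random(int(core.sum())) < 0.92, "B", types[core])
            types[rim] = np.where(rng.random(int(rim.sum())) < 0.70, "CD4_Tfh", types[rim])

    genes = build_gene_panel(config.n_genes)
    gi = {g: i for i, g in enumerate(genes)}
    programs = _type_means(genes)
    mean = programs.loc[types].to_numpy().copy()
    # spatial B bins are tumor follicles: give them the clonal light chain
    b_rows = np.flatnonzero(types == "B")
    for i in b_rows:
        _apply_light_chain(mean[i], gi, "kappa")
    if config.lr_effect > 0:
        tfh_rows = types == "CD4_Tfh"
        for lig, rec in LR_PAIRS:
            mean[tfh_rows, gi[lig]] += config.lr_effect
            mean[types == "B", gi[rec]] += config.lr_effect
    counts = _nb_sample(rng, mean, config.nb_dispersion)

    bin_ids = [f"{sample_id}_bin{i:05d}" for i in range(n)]
    obs = pd.DataFrame({"row": rr, "col": cc, "sample_id": sample_id}, index=bin_ids)
    adata = ad.AnnData(X=counts, obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["truth"] = pd.DataFrame({"bin_type": types}, index=bin_ids)
    adata.uns["layout"] = config.layout
    return adata
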