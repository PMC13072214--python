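"""QC, clustering and malignant B-cell discrimination for scRNA-seq.

Malignant B cells in germinal-center lymphomas carry patient-specific
transcriptional programs, whereas normal infiltrating B cells share a common
program across samples (including tonsil controls). After QC, doublet
flagging, normalization, cell-cycle regression and Louvain clustering on an
SNN graph, B-cell clusters are classified by sample composition into
tonsil / common / lymphoma clusters, and lymphoma clusters are called
malignant only when they additionally show clonal light-chain (κ/λ)
restriction — an exclusive light-chain fraction below 1% or above 91%.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import synthetic_data as _syn
from .signatures import SignatureDef, module_score

KAPPA_GENE = "IGKC"
LAMBDA_GENES = ("IGLC2", "IGLC3")


@dataclass
class ClusteringParams:
    """Embedding and community-detection parameters (SNN k=20, Louvain 0.3)."""

    n_pcs: int = 30
    snn_k: int = 20
    resolution: float = 0.3
    prune: float = 1 / 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be ≥ 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


# ---------------------------------------------------------------------------
# QC and doublets
# ---------------------------------------------------------------------------

def qc_filter(adata, min_genes: int = 200, max_genes: int = 6000,
              max_mito: float = 0.15) -> pd.DataFrame:
    """Flag cells passing gene-count and mitochondrial-fraction gates.

    Pass iff detected genes ∈ [min_genes, max_genes] (inclusive) and the
    MT-prefixed transcript fraction is strictly below ``max_mito``.
    Annotates obs with ``n_genes_detected``, ``mito_frac``, ``qc_pass``.
    """
    X = np.asarray(adata.X)
    n_detected = (X > 0).sum(axis=1)
    mt = np.array([g.startswith("MT-") for g in adata.var_names])
    if not mt.any():
        warnings.warn("no MT- genes in panel; mitochondrial fraction set to 0")
        mito = np.zeros(adata.n_obs)
    else:
        total = X.sum(axis=1)
        mito = np.divide(X[:, mt].sum(axis=1), total,
                         out=np.zeros(adata.n_obs), where=total > 0)
    qc_pass = (n_detected >= min_genes) & (n_detected <= max_genes) & (mito < max_mito)
    adata.obs["n_genes_detected"] = n_detected
    adata.obs["mito_frac"] = mito
    adata.obs["qc_pass"] = qc_pass
    return adata.obs


def doublet_score(adata, expected_rate: float = 0.10, seed: int = 0,
                  n_pcs: int = 30, k: int = 20) -> pd.DataFrame:
    """Artificial-doublet nearest-neighbor score; flag the top fraction.

    Artificial doublets (25% of the number of qc-pass cells) are averages of
    random qc-pass cell pairs. Each real cell's score is the fraction of
    artificial doublets among its ``k`` nearest neighbors in a
    ``n_pcs``-component PCA of the joint log-normalized matrix; the
    ``expected_rate`` fraction of cells with the highest scores are flagged.
    """
    if "qc_pass" not in adata.obs:
        raise ValueError("run qc_filter first")
    mask = adata.obs["qc_pass"].to_numpy()
    n = int(mask.sum())
    adata.obs["doublet_score"] = 0.0
    adata.obs["doublet"] = False
    if n < 50:
        warnings.warn(f"only {n} qc-pass cells; doublet detection skipped")
        return adata.obs
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    X = np.asarray(adata.X)[mask].astype(float)
    n_art = max(int(round(0.25 * n)), 1)
    pairs = rng.integers(0, n, size=(n_art, 2))
    art = (X[pairs[:, 0]] + X[pairs[:, 1]]) / 2.0
    joint = np.vstack([X, art])
    joint = _lognorm(joint)
    comps = min(n_pcs, joint.shape[0] - 1, joint.shape[1])
    emb = PCA(n_components=comps, svd_solver="full").fit_transform(joint)
    k_eff = min(k, joint.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    neigh = idx[:, 1:]          # drop self
    scores = (neigh >= n).mean(axis=1)
    n_flag = int(np.floor(expected_rate * n))
    flags = np.zeros(n, dtype=bool)
    if n_flag > 0:
        order = np.lexsort((np.arange(n), -scores))   # ties: earlier cell first
        flags[order[:n_flag]] = True
    adata.obs.loc[mask, "doublet_score"] = scores
    adata.obs.loc[mask, "doublet"] = flags
    return adata.obs


# ---------------------------------------------------------------------------
# normalization, cell-cycle regression, scaling
# ---------------------------------------------------------------------------

def _lognorm(X: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    total = X.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return np.log1p(X / total * target_sum)


def normalize(adata, target_sum: float = 1e4) -> None:
    """Per-cell scaling to ``target_sum`` total counts followed by log1p,
    stored in ``layers['lognorm']``."""
    adata.layers["lognorm"] = _lognorm(np.asarray(adata.X).astype(float), target_sum)


def cell_cycle_scores(adata, s_genes=None, g2m_genes=None, seed: int = 0) -> pd.DataFrame:
    """S and G2/M module scores (bin-matched controls) stored in obs."""
    s_genes = tuple(s_genes if s_genes is not None else _syn.S_GENES)
    g2m_genes = tuple(g2m_genes if g2m_genes is not None else _syn.G2M_GENES)
    if not s_genes or not g2m_genes:
        raise ValueError("cell-cycle gene lists must be non-empty")
    values = adata.layers["lognorm"]
    genes = list(adata.var_names)
    adata.obs["s_score"] = module_score(values, genes, SignatureDef("s_phase", s_genes, seed=seed))
    adata.obs["g2m_score"] = module_score(values, genes,
                                          SignatureDef("g2m_phase", g2m_genes, seed=seed))
    return adata.obs


def scale_regress(adata, covariates=("s_score", "g2m_score"), clip: float = 10.0) -> None:
    """Regress covariates out of each gene, standardize residuals, clip ±clip.

    Stored in ``layers['scaled']``; per-gene mean 0 and (for non-constant
    residuals) unit variance.
    """
    Y = np.asarray(adata.layers["lognorm"], dtype=float)
    C = np.column_stack([np.ones(adata.n_obs)] +
                        [adata.obs[c].to_numpy(dtype=float) for c in covariates])
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ beta
    sd = resid.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    adata.layers["scaled"] = np.clip(resid / sd, -clip, clip)


# ---------------------------------------------------------------------------
# embedding + SNN Louvain clustering
# ---------------------------------------------------------------------------

def snn_graph(emb: np.ndarray, k: int = 20, prune: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbor graph: Jaccard overlap of k-NN sets (self
    included), edges below ``prune`` discarded."""
    n = emb.shape[0]
    k_eff = min(k, n)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(emb)
    _, idx = nn.kneighbors(emb)
    neigh_sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neigh_sets[i] & neigh_sets[j])
            jac = shared / (2 * k_eff - shared)
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def embed_and_cluster(adata, params: ClusteringParams | None = None,
                      layer: str = "scaled", integrate=None) -> pd.DataFrame:
    """PCA embedding, optional integration hook, SNN graph, Louvain clusters.

    ``integrate`` is an optional callable applied to the PCA embedding (a
    batch-integration hook; the default identity applies no correction).
    Cluster labels are stored in ``obs['cluster']`` as strings.
    """
    params = params or ClusteringParams()
    X = np.asarray(adata.layers[layer] if layer in adata.layers else adata.X, dtype=float)
    if np.all(X == X[0]):   # degenerate: identical cells form one community
        adata.obs["cluster"] = pd.Categorical(["0"] * X.shape[0])
        adata.obsm["X_pca"] = np.zeros((X.shape[0], 1))
        return adata.obs
    comps = min(params.n_pcs, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=comps, svd_solver="full",
              random_state=params.seed).fit_transform(X)
    if integrate is not None:
        emb = integrate(emb)
    adata.obsm["X_pca"] = emb
    k = params.snn_k
    if X.shape[0] <= k:
        warnings.warn(f"fewer cells than snn_k={k}; reducing k")
        k = max(X.shape[0] - 1, 1)
    g = snn_graph(emb, k=k, prune=params.prune)
    _pyrandom.seed(params.seed)    # igraph draws from Python's random module
    part = g.community_multilevel(weights="weight", resolution=params.resolution)
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size for stable, readable ids
    sizes = pd.Series(labels).value_counts()
    remap = {old: str(new) for new, old in enumerate(sizes.index)}
    adata.obs["cluster"] = pd.Categorical([remap[l] for l in labels])
    return adata.obs


# ---------------------------------------------------------------------------
# cluster origin, light chains, malignancy
# ---------------------------------------------------------------------------

def classify_cluster_origin(cluster_id: pd.Series, sample_id: pd.Series,
                            control_samples, tonsil_min_frac: float = 0.95,
                            common_min_frac: float = 0.01,
                            lymphoma_min_frac: float = 0.90) -> pd.DataFrame:
    """Tri-partition clusters by sample composition.

    tonsil_cluster: ≥ ``tonsil_min_frac`` of cells from control samples;
    common_cluster: every sample (lymphoma and control) contributes
    ≥ ``common_min_frac`` of the cluster; lymphoma_cluster:
    ≥ ``lymphoma_min_frac`` from a single lymphoma sample. Clusters matching
    none fall back to the dominant composition with a warning flag.
    """
    cluster_id = pd.Series(np.asarray(cluster_id), name="cluster")
    sample_id = pd.Series(np.asarray(sample_id), name="sample")
    control_samples = set(control_samples)
    all_samples = set(sample_id.unique())
    if not control_samples & all_samples:
        warnings.warn("no control samples present; tonsil/common logic disabled, "
                      "clusters assigned by dominance only")
    rows = []
    for cl, samples in sample_id.groupby(cluster_id, observed=True):
        comp = samples.value_counts(normalize=True)
        ctrl_frac = comp[comp.index.isin(control_samples)].sum()
        top_lymph = comp[~comp.index.isin(control_samples)]
        category, flagged = None, False
        if control_samples & all_samples and ctrl_frac >= tonsil_min_frac:
            category = "tonsil_cluster"
        elif (control_samples & all_samples
              and all(comp.get(s, 0.0) >= common_min_frac for s in all_samples)):
            category = "common_cluster"
        elif len(top_lymph) and top_lymph.iloc[0] >= lymphoma_min_frac:
            category = "lymphoma_cluster"
        else:
            flagged = True
            if len(top_lymph) and top_lymph.iloc[0] >= ctrl_frac:
                category = "lymphoma_cluster"
            elif ctrl_frac >= 0.5:
                category = "tonsil_cluster"
            else:
                category = "common_cluster"
        rows.append({"cluster": cl, "origin_category": category,
                     "dominant_sample": comp.index[0], "dominant_frac": float(comp.iloc[0]),
                     "control_frac": float(ctrl_frac), "flagged": flagged})
    return pd.DataFrame(rows).set_index("cluster")


def light_chain_call(adata, cluster_col: str = "cluster",
                     exclusive_low: float = 0.01, exclusive_high: float = 0.91,
                     min_assigned: int = 10) -> tuple[pd.Series, pd.DataFrame]:
    """Per-cell κ/λ call from raw counts and per-cluster restriction.

    A cell is κ when IGKC counts exceed IGLC2+IGLC3, λ when lower, unassigned
    when both are zero or tied. Per cluster, kappa_fraction = κ/(κ+λ); the
    cluster is light-chain exclusive iff the fraction is strictly below
    ``exclusive_low`` or strictly above ``exclusive_high``. Clusters with
    fewer than ``min_assigned`` κ/λ cells cannot support a restriction call
    and are not evaluable (exclusive = NA).
    """
    for g in (KAPPA_GENE, *LAMBDA_GENES):
        if g not in adata.var_names:
            raise ValueError(f"light-chain gene {g} absent from panel")
    X = np.asarray(adata.X)
    kappa = X[:, adata.var_names.get_loc(KAPPA_GENE)]
    lam = sum(X[:, adata.var_names.get_loc(g)] for g in LAMBDA_GENES)
    call = np.where(kappa > lam, "kappa", np.where(kappa < lam, "lambda", "unassigned"))
    call[(kappa == 0) & (lam == 0)] = "unassigned"
    light_chain = pd.Series(call, index=adata.obs_names, name="light_chain")

    rows = []
    for cl, sub in light_chain.groupby(adata.obs[cluster_col], observed=True):
        nk = int((sub == "kappa").sum())
        nl = int((sub == "lambda").sum())
        if nk + nl < min_assigned:
            frac = nk / (nk + nl) if nk + nl else np.nan
            rows.append({"cluster": cl, "kappa_fraction": frac,
                         "exclusive": pd.NA, "n_assigned": nk + nl})
            continue
        frac = nk / (nk + nl)
        rows.append({"cluster": cl, "kappa_fraction": frac,
                     "exclusive": bool(frac < exclusive_low or frac > exclusive_high),
                     "n_assigned": nk + nl})
    return light_chain, pd.DataFrame(rows).set_index("cluster")


def call_malignant(origin: pd.DataFrame, chains: pd.DataFrame,
                   cluster_id: pd.Series) -> tuple[pd.Series, pd.DataFrame]:
    """Cells are malignant iff their cluster is a lymphoma_cluster AND
    light-chain exclusive; lymphoma clusters without restriction are
    reported as discordant, never malignant."""
    table = origin.join(chains, how="left")
    is_lymph = table["origin_category"] == "lymphoma_cluster"
    excl = table["exclusive"].map(lambda v: bool(v) if pd.notna(v) else False)
    table["malignant"] = is_lymph & excl
    table["discordant"] = is_lymph & ~excl
    per_cell = pd.Series(np.asarray(cluster_id), index=cluster_id.index).map(
        table["malignant"]).astype("boolean").fillna(False).astype(bool)
    per_cell.name = "malignant"
    return per_cell, table


# ---------------------------------------------------------------------------
# cell-type annotation
# ---------------------------------------------------------------------------

def annotate_cell_types(adata, marker_sets: dict[str, list] | None = None,
                        layer: str = "lognorm", seed: int = 0) -> pd.Series:
    """Per-cell argmax over marker-set module scores.

    Uses the same bin-matched scoring as the signatures; a deterministic
    label per cell even when subsets co-cluster at the chosen resolution.
    """
    marker_sets = marker_sets or _syn.TYPE_MARKERS
    values = np.asarray(adata.layers[layer] if layer in adata.layers else adata.X)
    genes = list(adata.var_names)
    names = sorted(marker_sets)
    scores = np.column_stack([
        module_score(values, genes, SignatureDef(f"type:{t}", tuple(marker_sets[t]), seed=seed))
        for t in names])
    labels = np.array(names)[scores.argmax(axis=1)]
    out = pd.Series(labels, index=adata.obs_names, name="cell_type")
    adata.obs["cell_type"] = out
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def composition_fisher(table: np.ndarray) -> float:
    """Two-sided Fisher exact p on a 2×2 count table (p = 1 on zero margins)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2×2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def rank_markers(adata, cluster_col: str = "cluster", layer: str = "lognorm",
                 min_pct: float = 0.20, min_lfc: float = 0.2,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-cluster positive markers vs the rest (Wilcoxon rank-sum).

    A gene is reported for a cluster when its detection fraction exceeds
    ``min_pct`` in either group, the natural-log fold change of mean
    expression exceeds ``min_lfc`` and the Bonferroni-adjusted p (denominator
    = genes passing the detection filter for that cluster) is below
    ``alpha``. log fold change = ln(mean(expm1(x_in)) + 1) − ln(mean(expm1(x_out)) + 1).
    """
    values = np.asarray(adata.layers[layer])
    clusters = pd.Series(np.asarray(adata.obs[cluster_col]), index=adata.obs_names)
    detected = values > 0
    rows = []
    for cl in sorted(clusters.unique(), key=str):
        in_mask = (clusters == cl).to_numpy()
        n_in = int(in_mask.sum())
        if n_in < 2:
            warnings.warn(f"cluster {cl} has {n_in} cell(s); skipped")
            continue
        out_mask = ~in_mask
        pct_in = detected[in_mask].mean(axis=0)
        pct_out = detected[out_mask].mean(axis=0)
        testable = np.flatnonzero((pct_in > min_pct) | (pct_out > min_pct))
        if len(testable) == 0:
            continue
        mean_in = np.expm1(values[in_mask][:, testable]).mean(axis=0)
        mean_out = np.expm1(values[out_mask][:, testable]).mean(axis=0)
        lfc = np.log(mean_in + 1) - np.log(mean_out + 1)
        m = len(testable)
        for gidx, l, pi, po in zip(testable, lfc, pct_in[testable], pct_out[testable]):
            if l <= min_lfc:
                continue
            p = stats.mannwhitneyu(values[in_mask, gidx], values[out_mask, gidx],
                                   alternative="two-sided", method="asymptotic").pvalue
            p_adj = min(p * m, 1.0)
            if p_adj < alpha:
                rows.append({"cluster": cl, "gene": adata.var_names[gidx],
                             "log_fc": float(l), "pct_in": float(pi),
                             "pct_out": float(po), "p": float(p), "p_adj": float(p_adj)})
    return pd.DataFrame(rows, columns=["cluster", "gene", "log_fc", "pct_in",
                                       "pct_out", "p", "p_adj"])
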