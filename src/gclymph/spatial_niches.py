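"""Spatial bin typing, neighborhood enrichment and ligand–receptor scores.

High-definition spatial data arrive as gap-free 8 µm grid bins with per-bin
expression. Each bin is assigned the cell type whose bin-matched signature
score is highest; bins negative for every signature are excluded. Adjacency
on the gap-free grid defaults to queen (8-neighbor) contact — diagonal
contact is physical when bins touch corner to corner. Neighborhood
enrichment compares observed adjacent type-pair counts to a label
permutation null (z-scores), and z matrices are min-max scaled to [0, 1]
jointly across samples for comparison. Ligand–receptor co-localization is
scored over directed adjacent source→target bin pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import SignatureDef, module_score
from .synthetic_data import LR_PAIRS, TYPE_MARKERS

ADJACENCY_MODES = ("queen8", "rook4")


@dataclass
class EnrichmentResult:
    """Permutation z-scores of adjacent type-pair counts for one sample."""

    z: pd.DataFrame             # type × type, symmetric
    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    n_perms: int
    seed: int
    mode: str
    sample_id: str = ""
    scaled: pd.DataFrame | None = None
    status: str = "ok"


@dataclass
class LRScore:
    """Directed source→target ligand–receptor co-localization score."""

    ligand: str
    receptor: str
    source: str
    target: str
    frequency: float            # fraction of source bins with a receptor+ target neighbor
    strength: float             # mean scaled ligand·receptor product over adjacent pairs
    n_pairs: int = 0
    status: str = "ok"


# ---------------------------------------------------------------------------
# bin typing
# ---------------------------------------------------------------------------

def default_spatial_signatures() -> dict[str, tuple]:
    """The 9 cell-type signatures used for bin assignment."""
    return {t: tuple(genes) for t, genes in TYPE_MARKERS.items()}


def assign_bins(adata, signatures: dict[str, tuple] | None = None,
                layer: str = "lognorm", n_bins: int = 24, n_ctrl: int = 100,
                seed: int = 0) -> pd.DataFrame:
    """Label each bin with the argmax cell-type signature score.

    Exact top-score ties produce a combined label joining the tied types
    (sorted, '+'-separated); bins with all scores negative are excluded.
    Results land in ``obs['assigned_type']`` / ``obs['excluded']`` and the
    per-bin score matrix is returned.
    """
    signatures = signatures if signatures is not None else default_spatial_signatures()
    if not signatures or any(len(g) == 0 for g in signatures.values()):
        raise ValueError("empty signature set")
    if layer not in adata.layers:
        from .scrna_core import normalize
        normalize(adata)
    values = np.asarray(adata.layers[layer])
    genes = list(adata.var_names)
    names = sorted(signatures)
    scores = np.column_stack([
        module_score(values, genes,
                     SignatureDef(f"bin:{t}", tuple(signatures[t]),
                                  n_bins=n_bins, n_ctrl=n_ctrl, seed=seed))
        for t in names])
    top = scores.max(axis=1)
    labels = []
    for i in range(scores.shape[0]):
        tied = [names[j] for j in range(len(names)) if scores[i, j] == top[i]]
        labels.append("+".join(sorted(tied)))
    excluded = top < 0
    adata.obs["assigned_type"] = np.where(excluded, "", labels)
    adata.obs["excluded"] = excluded
    adata.obs["combined_label"] = np.array(["+" in l for l in labels]) & ~excluded
    return pd.DataFrame(scores, index=adata.obs_names, columns=names)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def grid_adjacency(rows: np.ndarray, cols: np.ndarray,
                   mode: str = "queen8") -> np.ndarray:
    """Undirected edges (index pairs, i<j) between adjacent grid bins.

    queen8: |Δrow| ≤ 1 and |Δcol| ≤ 1 (not identical); rook4:
    |Δrow| + |Δcol| = 1. Positions must be unique.
    """
    if mode not in ADJACENCY_MODES:
        raise ValueError(f"mode must be one of {ADJACENCY_MODES}")
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    pos = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    if len(pos) != len(rows):
        raise ValueError("duplicate (row, col) positions")
    if mode == "rook4":
        offsets = [(0, 1), (1, 0)]
    else:
        offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    edges = []
    for (r, c), i in pos.items():
        for dr, dc in offsets:
            j = pos.get((r + dr, c + dc))
            if j is not None:
                edges.append((min(i, j), max(i, j)))
    return np.array(sorted(set(edges)), dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# neighborhood enrichment
# ---------------------------------------------------------------------------

def _pair_counts(codes: np.ndarray, e0: np.ndarray, e1: np.ndarray,
                 k: int) -> np.ndarray:
    """Symmetric k×k matrix: number of edges joining each unordered type pair."""
    a, b = codes[e0], codes[e1]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    cnt = np.bincount(lo * k + hi, minlength=k * k).reshape(k, k)
    return cnt + np.triu(cnt, 1).T


def neighborhood_enrichment(labels, edges: np.ndarray, n_perms: int = 1000,
                            seed: int = 0, mode: str = "queen8",
                            sample_id: str = "") -> EnrichmentResult:
    """Permutation z-scores for adjacent type-pair counts.

    The null permutes labels over bins ``n_perms`` times;
    z = (observed − null mean) / null sd, with z = 0 where the null sd is 0
    (degenerate pairs, e.g. a single label class).
    """
    labels = pd.Series(np.asarray(labels, dtype=object))
    cats = sorted(labels.unique())
    k = len(cats)
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy(dtype=int)
    e0, e1 = (edges[:, 0], edges[:, 1]) if len(edges) else (np.array([], int),) * 2
    obs = _pair_counts(codes, e0, e1, k)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    null = np.empty((n_perms, k, k))
    for p in range(n_perms):
        null[p] = _pair_counts(rng.permutation(codes), e0, e1, k)
    mean = null.mean(axis=0)
    sd = null.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, 0.0)
    status = "ok" if k > 1 else "degenerate: single label class"
    wrap = lambda m: pd.DataFrame(m, index=cats, columns=cats)
    return EnrichmentResult(z=wrap(z), observed=wrap(obs.astype(float)),
                            null_mean=wrap(mean), null_sd=wrap(sd),
                            n_perms=n_perms, seed=seed, mode=mode,
                            sample_id=sample_id, status=status)


def normalize_enrichment(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Min-max scale all z matrices to [0, 1] using the pooled global range.

    Degenerate range (max = min) scales to all zeros. Scaling is monotone,
    so within-sample ordering of pairs is preserved.
    """
    if not results:
        raise ValueError("no enrichment results")
    pooled = np.concatenate([r.z.to_numpy().ravel() for r in results])
    lo, hi = float(pooled.min()), float(pooled.max())
    for r in results:
        if hi == lo:
            r.scaled = r.z * 0.0
        else:
            r.scaled = (r.z - lo) / (hi - lo)
    return results


# ---------------------------------------------------------------------------
# ligand–receptor co-localization
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def lr_interaction(adata, edges: np.ndarray, labels,
                   pairs: list[tuple] | None = None,
                   source: str = "CD4_Tfh", target: str = "B",
                   layer: str = "lognorm") -> list[LRScore]:
    """Score ligand–receptor co-localization over adjacent bin pairs.

    For directed adjacent pairs (i ∈ source bins, j ∈ target bins):
    strength = mean of ℓ(i)·r(j) with ℓ, r the per-gene expressions min-max
    scaled to [0, 1] across the sample's bins; frequency = fraction of
    source bins with at least one target neighbor expressing the receptor.
    """
    pairs = pairs if pairs is not None else list(LR_PAIRS)
    labels = np.asarray(labels, dtype=object)
    values = np.asarray(adata.layers[layer] if layer in adata.layers else adata.X)
    genes = list(adata.var_names)
    gi = {g: i for i, g in enumerate(genes)}
    for lig, rec in pairs:
        if lig not in gi or rec not in gi:
            raise ValueError(f"ligand/receptor gene missing from panel: {lig}->{rec}")

    src_mask = labels == source
    tgt_mask = labels == target
    di, dj = [], []
    for a, b in edges:
        if src_mask[a] and tgt_mask[b]:
            di.append(a)
            dj.append(b)
        if src_mask[b] and tgt_mask[a]:
            di.append(b)
            dj.append(a)
    di = np.array(di, dtype=int)
    dj = np.array(dj, dtype=int)

    out = []
    for lig, rec in pairs:
        l = _minmax(values[:, gi[lig]].astype(float))
        r = _minmax(values[:, gi[rec]].astype(float))
        if len(di) == 0:
            out.append(LRScore(lig, rec, source, target, 0.0, 0.0, 0,
                               status="no source-target adjacencies"))
            continue
        strength = float((l[di] * r[dj]).mean())
        has_pos = pd.Series(r[dj] > 0).groupby(pd.Series(di)).any()
        n_source = int(src_mask.sum())
        freq = float(has_pos.sum() / n_source) if n_source else 0.0
        out.append(LRScore(lig, rec, source, target, freq, strength, len(di)))
    return out


def pool_16um(adata) -> "object":
    """Sum-pool 8 µm bins into 16 µm bins (2×2 aggregation).

    Returns a new AnnData with halved grid coordinates; counts of the up to
    four constituent bins are summed.
    """
    import anndata as ad
    rows = adata.obs["row"].to_numpy() // 2
    cols = adata.obs["col"].to_numpy() // 2
    key = pd.Series(list(zip(rows, cols)))
    groups = key.groupby(key).indices
    ordered = sorted(groups)
    X = np.asarray(adata.X)
    pooled = np.vstack([X[groups[g]].sum(axis=0) for g in ordered])
    obs = pd.DataFrame({"row": [g[0] for g in ordered], "col": [g[1] for g in ordered]},
                       index=[f"bin16_{g[0]}_{g[1]}" for g in ordered])
    if "sample_id" in adata.obs:
        obs["sample_id"] = adata.obs["sample_id"].iloc[0]
    return ad.AnnData(X=pooled, obs=obs, var=adata.var.copy())
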