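"""Bin typing, grid adjacency, permutation enrichment and LR scores."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from gclymph import SimConfig, generate_spatial
from gclymph import scrna_core as core
from gclymph.spatial_niches import (EnrichmentResult, assign_bins,
                                    grid_adjacency, lr_interaction,
                                    neighborhood_enrichment,
                                    normalize_enrichment, pool_16um,
                                    _pair_counts)


def _grid_adata(rows, cols, n_genes=20, seed=0):
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    n = rows * cols
    a = ad.AnnData(X=rng.poisson(3.0, size=(n, n_genes)).astype(np.int32),
                   obs=pd.DataFrame({"row": rr.ravel(), "col": cc.ravel()},
                                    index=[f"b{i}" for i in range(n)]))
    a.var_names = [f"G{i}" for i in range(n_genes)]
    return a


# ---------------------------------------------------------------------------
# bin assignment
# ---------------------------------------------------------------------------

def test_assign_bins_argmax_tie_and_negative():
    # hand-made score situation via a tiny panel: one bin dominated by sigA
    # genes, one tied, one negative everywhere
    rng = np.random.default_rng(0)
    n_genes = 60
    genes = [f"G{i}" for i in range(n_genes)]
    X = np.abs(rng.normal(1.0, 0.1, size=(300, n_genes)))
    sig_a = tuple(genes[0:5])
    sig_b = tuple(genes[5:10])
    X[0, 0:5] += 5.0                      # bin 0 -> A
    X[1, 0:5] += 4.0                      # bin 1 -> tie by symmetric construction
    X[1, 5:10] = X[1, 0:5]
    a = ad.AnnData(X=X, obs=pd.DataFrame({"row": np.arange(300), "col": 0},
                                         index=[f"b{i}" for i in range(300)]))
    a.var_names = genes
    a.layers["lognorm"] = X
    scores = assign_bins(a, {"A": sig_a, "B": sig_b}, seed=0)
    assert a.obs["assigned_type"].iloc[0] == "A"
    if scores.iloc[1]["A"] == scores.iloc[1]["B"]:
        assert a.obs["assigned_type"].iloc[1] == "A+B"


def test_assign_bins_all_negative_excluded():
    a = _grid_adata(5, 5, n_genes=40)
    X = np.ones((25, 40))
    X[0, :] = 0.0                         # bin 0 zero everywhere
    X[0, 20:] = 2.0                       # but high in non-signature genes
    a.layers["lognorm"] = X
    assign_bins(a, {"A": ("G0", "G1"), "B": ("G2", "G3")}, seed=0)
    assert bool(a.obs["excluded"].iloc[0])
    assert a.obs["assigned_type"].iloc[0] == ""


def test_assign_bins_empty_signature_error():
    a = _grid_adata(5, 5)
    with pytest.raises(ValueError, match="empty signature"):
        assign_bins(a, {"A": ()})


def test_generator_layout_recovered(small_cohort=None):
    sp = generate_spatial(SimConfig(seed=3, n_genes=500, grid_rows=20, grid_cols=20))
    core.normalize(sp)
    assign_bins(sp, seed=0)
    truth = sp.uns["truth"]["bin_type"].to_numpy()
    ok = ~sp.obs["excluded"].to_numpy()
    acc = (sp.obs["assigned_type"].to_numpy()[ok] == truth[ok]).mean()
    assert acc >= 0.95


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

def _degrees(edges, n):
    deg = np.zeros(n, dtype=int)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def test_grid_adjacency_queen8_degrees():
    a = _grid_adata(3, 3)
    edges = grid_adjacency(a.obs["row"], a.obs["col"], "queen8")
    deg = _degrees(edges, 9)
    center = 4                            # (1,1) in row-major order
    assert deg[center] == 8
    assert deg[0] == 3                    # corner


def test_grid_adjacency_rook4_degrees():
    a = _grid_adata(3, 3)
    edges = grid_adjacency(a.obs["row"], a.obs["col"], "rook4")
    deg = _degrees(edges, 9)
    assert deg[4] == 4
    assert deg[0] == 2


@pytest.mark.parametrize("r,c", [(3, 3), (4, 7), (6, 2)])
def test_rook_edge_count_closed_form(r, c):
    a = _grid_adata(r, c)
    edges = grid_adjacency(a.obs["row"], a.obs["col"], "rook4")
    assert len(edges) == r * (c - 1) + c * (r - 1)


def test_adjacency_rejects_duplicates_and_bad_mode():
    with pytest.raises(ValueError, match="mode"):
        grid_adjacency([0], [0], "hex")
    with pytest.raises(ValueError, match="duplicate"):
        grid_adjacency([0, 0], [1, 1])


# ---------------------------------------------------------------------------
# neighborhood enrichment
# ---------------------------------------------------------------------------

def test_single_label_class_z_zero():
    a = _grid_adata(5, 5)
    edges = grid_adjacency(a.obs["row"], a.obs["col"])
    res = neighborhood_enrichment(["X"] * 25, edges, n_perms=50, seed=0)
    assert (res.z.to_numpy() == 0).all()
    assert "degenerate" in res.status


def test_two_block_layout_signs():
    a = _grid_adata(10, 10)
    labels = np.where(a.obs["col"].to_numpy() < 5, "A", "B")
    edges = grid_adjacency(a.obs["row"], a.obs["col"])
    res = neighborhood_enrichment(labels, edges, n_perms=500, seed=0)
    assert res.z.loc["A", "A"] > 0
    assert res.z.loc["A", "B"] < 0
    assert res.z.loc["A", "B"] == res.z.loc["B", "A"]   # symmetric


def test_enrichment_invariant_to_graph_relabeling():
    a = _grid_adata(8, 8)
    rng = np.random.default_rng(4)
    labels = rng.choice(["A", "B", "C"], size=64)
    edges = grid_adjacency(a.obs["row"], a.obs["col"])
    res1 = neighborhood_enrichment(labels, edges, n_perms=1500, seed=9)
    perm = rng.permutation(64)            # isomorphic re-indexing
    inv = np.empty(64, dtype=int)
    inv[perm] = np.arange(64)
    edges2 = inv[edges]
    res2 = neighborhood_enrichment(labels[perm], edges2, n_perms=1500, seed=9)
    # observed counts are exactly invariant; the sampled null (hence z) agrees
    # within Monte-Carlo error of two independent estimates
    pd.testing.assert_frame_equal(res1.observed, res2.observed)
    z1, z2 = res1.z.to_numpy(), res2.z.to_numpy()
    se = np.sqrt(2 * (1 + 0.5 * z1 ** 2) / 1500)
    assert np.all(np.abs(z1 - z2) <= 4 * se)


def test_null_mean_matches_analytic_expectation():
    # E[pair count] = 2 E p_a p_b for a != b under label permutation
    a = _grid_adata(20, 20)
    rng = np.random.default_rng(5)
    labels = rng.choice(["A", "B", "C"], size=400, p=[0.5, 0.3, 0.2])
    edges = grid_adjacency(a.obs["row"], a.obs["col"])
    res = neighborhood_enrichment(labels, edges, n_perms=2000, seed=1)
    E = len(edges)
    n = 400
    counts = pd.Series(labels).value_counts()
    for x, y in itertools.combinations(counts.index, 2):
        exp = 2 * E * (counts[x] / n) * (counts[y] / n)
        got = res.null_mean.loc[x, y]
        mc_sd = res.null_sd.loc[x, y] / np.sqrt(res.n_perms)
        # analytic expectation uses iid fractions; permutation fixes counts —
        # agreement within a few MC errors plus the O(1/n) correction
        assert abs(got - exp) < 4 * mc_sd + 0.02 * exp


def exhaustive_enrichment(labels, edges):
    """Full enumeration over all node-label permutations (n! assignments)."""
    labels = np.asarray(labels, dtype=object)
    cats = sorted(set(labels))
    k = len(cats)
    codes = np.array([cats.index(l) for l in labels])
    e0, e1 = edges[:, 0], edges[:, 1]
    all_counts = [_pair_counts(codes[list(p)], e0, e1, k)
                  for p in itertools.permutations(range(len(labels)))]
    all_counts = np.array(all_counts, dtype=float)
    return cats, all_counts.mean(axis=0), all_counts.std(axis=0)


def test_sampled_permutations_match_exhaustive_enumeration():
    # 7-node path graph, labels AAABBCC
    n = 7
    edges = np.array([[i, i + 1] for i in range(n - 1)])
    labels = list("AAABBCC")
    cats, mean_ex, sd_ex = exhaustive_enrichment(labels, edges)
    res = neighborhood_enrichment(labels, edges, n_perms=4000, seed=2)
    obs = res.observed.loc[cats, cats].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z_ex = np.where(sd_ex > 0, (obs - mean_ex) / sd_ex, 0.0)
    z_s = res.z.loc[cats, cats].to_numpy()
    # Monte-Carlo standard error of a z estimate from n sampled permutations
    se = np.sqrt((1 + 0.5 * z_ex ** 2) / res.n_perms)
    ok = sd_ex > 0
    assert np.all(np.abs(z_s[ok] - z_ex[ok]) <= 3 * se[ok])


def test_enrichment_deterministic():
    a = _grid_adata(6, 6)
    labels = np.random.default_rng(0).choice(["A", "B"], size=36)
    edges = grid_adjacency(a.obs["row"], a.obs["col"])
    r1 = neighborhood_enrichment(labels, edges, n_perms=200, seed=5)
    r2 = neighborhood_enrichment(labels, edges, n_perms=200, seed=5)
    pd.testing.assert_frame_equal(r1.z, r2.z)


# ---------------------------------------------------------------------------
# 0–1 scaling
# ---------------------------------------------------------------------------

def _fake_result(z, sample_id="s"):
    idx = [f"t{i}" for i in range(z.shape[0])]
    df = pd.DataFrame(z, index=idx, columns=idx)
    return EnrichmentResult(z=df, observed=df, null_mean=df, null_sd=df,
                            n_perms=1, seed=0, mode="queen8", sample_id=sample_id)


def test_minmax_endpoints_and_monotonicity():
    r1 = _fake_result(np.array([[2.0, -1.0], [-1.0, 0.5]]), "a")
    r2 = _fake_result(np.array([[1.0, 0.0], [0.0, -3.0]]), "b")
    normalize_enrichment([r1, r2])
    pooled = np.concatenate([r1.scaled.to_numpy().ravel(),
                             r2.scaled.to_numpy().ravel()])
    assert pooled.min() == 0.0 and pooled.max() == 1.0
    assert r1.scaled.loc["t0", "t0"] == 1.0      # global max
    assert r2.scaled.loc["t1", "t1"] == 0.0      # global min
    order_z = np.argsort(r1.z.to_numpy().ravel())
    order_s = np.argsort(r1.scaled.to_numpy().ravel())
    np.testing.assert_array_equal(order_z, order_s)


def test_minmax_degenerate_all_zero():
    r = _fake_result(np.full((2, 2), 1.5))
    normalize_enrichment([r])
    assert (r.scaled.to_numpy() == 0).all()


# ---------------------------------------------------------------------------
# ligand–receptor
# ---------------------------------------------------------------------------

def _lr_adata(lig_vals, rec_vals, labels):
    n = len(labels)
    X = np.zeros((n, 3))
    X[:, 0] = lig_vals
    X[:, 1] = rec_vals
    X[:, 2] = 1.0
    a = ad.AnnData(X=X, obs=pd.DataFrame({"row": np.arange(n), "col": 0},
                                         index=[f"b{i}" for i in range(n)]))
    a.var_names = ["LIG", "REC", "OTHER"]
    a.layers["lognorm"] = X
    return a


def test_lr_zero_ligand_gives_zero_strength():
    labels = ["S", "T", "S", "T"]
    a = _lr_adata([0, 0, 0, 0], [1, 5, 2, 3], labels)
    edges = np.array([[0, 1], [1, 2], [2, 3]])
    (lr,) = lr_interaction(a, edges, labels, pairs=[("LIG", "REC")],
                           source="S", target="T")
    assert lr.strength == 0.0


def test_lr_saturated_upper_bound():
    labels = ["S", "T"] * 4
    lig = [9.0 if l == "S" else 0.0 for l in labels]
    rec = [7.0 if l == "T" else 0.0 for l in labels]
    a = _lr_adata(lig, rec, labels)
    edges = np.array([[i, i + 1] for i in range(7)])
    (lr,) = lr_interaction(a, edges, labels, pairs=[("LIG", "REC")],
                           source="S", target="T")
    assert lr.strength == pytest.approx(1.0)
    assert lr.frequency == pytest.approx(1.0)


def test_lr_no_adjacency_status():
    labels = ["S", "S", "T"]
    a = _lr_adata([1, 1, 1], [1, 1, 1], labels)
    edges = np.array([[0, 1]])            # no S-T edge
    (lr,) = lr_interaction(a, edges, labels, pairs=[("LIG", "REC")],
                           source="S", target="T")
    assert lr.strength == 0.0 and lr.frequency == 0.0
    assert "no source-target" in lr.status


def test_lr_elevated_rim_core_layout_scores_higher():
    flat = generate_spatial(SimConfig(seed=41, n_genes=500, grid_rows=25,
                                      grid_cols=25, lr_effect=0.0))
    hot = generate_spatial(SimConfig(seed=42, n_genes=500, grid_rows=25,
                                     grid_cols=25, lr_effect=5.0))
    out = {}
    for name, sp in (("flat", flat), ("hot", hot)):
        core.normalize(sp)
        assign_bins(sp, seed=0)
        inc = sp[(~sp.obs["excluded"] & ~sp.obs["combined_label"]).to_numpy()].copy()
        edges = grid_adjacency(inc.obs["row"], inc.obs["col"])
        lrs = lr_interaction(inc, edges, inc.obs["assigned_type"].to_numpy())
        out[name] = {l.ligand: l.strength for l in lrs}
    for lig in ("CD40LG", "CXCL13", "CD2"):
        assert out["hot"][lig] > out["flat"][lig]


# ---------------------------------------------------------------------------
# 16 µm pooling
# ---------------------------------------------------------------------------

def test_pool_16um_sums_quads():
    a = _grid_adata(4, 4, n_genes=5, seed=7)
    pooled = pool_16um(a)
    assert pooled.n_obs == 4
    assert pooled.X.sum() == np.asarray(a.X).sum()
    first = [i for i, (r, c) in enumerate(zip(a.obs["row"], a.obs["col"]))
             if r < 2 and c < 2]
    np.testing.assert_array_equal(np.asarray(pooled.X)[0],
                                  np.asarray(a.X)[first].sum(axis=0))
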