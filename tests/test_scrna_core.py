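"""QC gates, doublets, normalization, clustering and malignancy calling."""

import itertools
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from gclymph import SimConfig, generate_scrna
from gclymph import scrna_core as core
from gclymph.synthetic_data import SampleSpec


def _adata(X, genes=None, obs=None):
    X = np.asarray(X)
    genes = genes or [f"G{i}" for i in range(X.shape[1])]
    a = ad.AnnData(X=X.astype(np.int32),
                   obs=obs if obs is not None else pd.DataFrame(
                       index=[f"c{i}" for i in range(X.shape[0])]),
                   var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return a


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_boundaries():
    genes = [f"G{i}" for i in range(7000)] + ["MT-X"]
    X = np.zeros((4, 7001), dtype=int)
    X[0, :150] = 1                      # 150 genes -> fail
    X[1, :5000] = 1                     # 5000 genes, mito 0 -> pass
    X[2, :200] = 1                      # exactly 200 -> pass (inclusive)
    X[3, :1700] = 1                     # mito exactly 0.15 -> fail (strict)
    X[3, 7000] = 300                    # 300 / 2000 = 0.15
    a = _adata(X, genes)
    core.qc_filter(a)
    assert list(a.obs["qc_pass"]) == [False, True, True, False]
    assert a.obs.loc[a.obs_names[3], "mito_frac"] == pytest.approx(0.15)


def test_qc_no_mt_genes_warns_and_passes_zero_mito():
    X = np.ones((3, 300), dtype=int)
    a = _adata(X)
    with pytest.warns(UserWarning, match="MT-"):
        core.qc_filter(a)
    assert (a.obs["mito_frac"] == 0).all()


# ---------------------------------------------------------------------------
# doublets
# ---------------------------------------------------------------------------

def test_doublet_rate_zero_flags_nothing(small_cohort):
    _, adata = small_cohort
    a = adata.copy()
    core.qc_filter(a)
    core.doublet_score(a, expected_rate=0.0, seed=0)
    assert not a.obs["doublet"].any()


def test_doublet_flag_fraction_matches_quantile():
    rng = np.random.default_rng(0)
    a = _adata(rng.poisson(5, size=(400, 300)))
    core.qc_filter(a, min_genes=1)
    core.doublet_score(a, expected_rate=0.10, seed=0)
    assert int(a.obs["doublet"].sum()) == int(np.floor(0.10 * a.obs["qc_pass"].sum()))


def test_doublet_recall_on_two_program_mixture(small_cohort):
    _, adata = small_cohort
    a = adata.copy()
    core.qc_filter(a)
    core.doublet_score(a, expected_rate=0.10, seed=0)
    truth = a.uns["truth"]
    qc = a.obs["qc_pass"].to_numpy()
    td = truth["doublet"].to_numpy() & qc
    flagged = a.obs["doublet"].to_numpy()
    recall = (flagged & td).sum() / td.sum()
    assert recall >= 0.7


def test_doublet_skip_below_50_cells():
    a = _adata(np.ones((20, 300)))
    core.qc_filter(a, min_genes=1)
    with pytest.warns(UserWarning, match="skip"):
        core.doublet_score(a, seed=0)
    assert not a.obs["doublet"].any()


# ---------------------------------------------------------------------------
# normalization / scaling
# ---------------------------------------------------------------------------

def test_lognorm_closed_form():
    X = np.zeros((1, 3), dtype=int)
    X[0] = [1, 9999, 0]                 # total 10,000, count 1 -> log(2)
    a = _adata(X)
    core.normalize(a)
    assert a.layers["lognorm"][0, 0] == pytest.approx(np.log(2.0))


def test_scaled_layer_mean_zero_unit_sd():
    cfg = SimConfig(seed=19, n_cells=300, n_genes=400, doublet_rate=0.0,
                    qc_fail_frac=0.0, samples=[SampleSpec("s", "ntFL")])
    a = generate_scrna(cfg)
    core.normalize(a)
    core.cell_cycle_scores(a, seed=0)
    core.scale_regress(a)
    S = a.layers["scaled"]
    np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-8)
    sds = S.std(axis=0)
    varying = np.asarray(a.layers["lognorm"]).std(axis=0) > 0
    np.testing.assert_allclose(sds[varying], 1.0, atol=1e-6)


def test_regression_removes_collinear_gene():
    rng = np.random.default_rng(1)
    n = 200
    s = rng.normal(size=n)
    a = _adata(np.ones((n, 30), dtype=int))
    a.layers["lognorm"] = rng.normal(size=(n, 30))
    a.layers["lognorm"][:, 0] = 3.0 * s + 1.0   # perfectly collinear with s_score
    a.obs["s_score"] = s
    a.obs["g2m_score"] = rng.normal(size=n)
    core.scale_regress(a)
    Y = a.layers["lognorm"]
    C = np.column_stack([np.ones(n), s, a.obs["g2m_score"]])
    resid = Y[:, 0] - C @ np.linalg.lstsq(C, Y[:, 0], rcond=None)[0]
    assert resid.std() < 1e-8


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_two_programs_give_two_clusters():
    cfg = SimConfig(seed=23, n_cells=400, n_genes=400, doublet_rate=0.0,
                    qc_fail_frac=0.0, samples=[SampleSpec("s", "ntFL", 0.0)],
                    cell_type_fractions={"B": 0.5, "myeloid": 0.5})
    a = generate_scrna(cfg)
    core.normalize(a)
    core.cell_cycle_scores(a, seed=0)
    core.scale_regress(a)
    core.embed_and_cluster(a, core.ClusteringParams(seed=0))
    truth = a.uns["truth"]["cell_type"]
    assert a.obs["cluster"].nunique() == 2
    assert adjusted_rand_score(truth, a.obs["cluster"]) >= 0.95


def test_identical_cells_one_cluster():
    a = _adata(np.full((100, 50), 3))
    a.layers["scaled"] = np.zeros((100, 50))
    core.embed_and_cluster(a)
    assert a.obs["cluster"].nunique() == 1


def test_clustering_deterministic_rerun():
    cfg = SimConfig(seed=29, n_cells=300, n_genes=400, doublet_rate=0.0)
    a = generate_scrna(cfg)
    core.normalize(a)
    core.cell_cycle_scores(a, seed=0)
    core.scale_regress(a)
    core.embed_and_cluster(a, core.ClusteringParams(seed=3))
    first = a.obs["cluster"].copy()
    core.embed_and_cluster(a, core.ClusteringParams(seed=3))
    assert (first == a.obs["cluster"]).all()


# ---------------------------------------------------------------------------
# cluster origin / light chain / malignancy
# ---------------------------------------------------------------------------

def test_cluster_origin_rules():
    # cluster 0: 98% one lymphoma sample; 1: all samples >= 1%; 2: pure tonsil
    cluster = ["0"] * 100 + ["1"] * 100 + ["2"] * 50
    sample = (["L1"] * 98 + ["T1"] * 2
              + ["L1"] * 40 + ["L2"] * 30 + ["T1"] * 15 + ["T2"] * 15
              + ["T1"] * 50)
    out = core.classify_cluster_origin(pd.Series(cluster), pd.Series(sample),
                                       control_samples=["T1", "T2"])
    assert out.loc["0", "origin_category"] == "lymphoma_cluster"
    assert out.loc["1", "origin_category"] == "common_cluster"
    assert out.loc["2", "origin_category"] == "tonsil_cluster"
    assert not out["flagged"].any()


def test_cluster_origin_no_controls_warns():
    with pytest.warns(UserWarning, match="control"):
        out = core.classify_cluster_origin(
            pd.Series(["0"] * 10), pd.Series(["L1"] * 10), control_samples=[])
    assert out.loc["0", "origin_category"] == "lymphoma_cluster"


def _light_chain_adata(n_kappa, n_lambda, n_silent=0):
    n = n_kappa + n_lambda + n_silent
    genes = ["IGKC", "IGLC2", "IGLC3", "OTHER"]
    X = np.zeros((n, 4), dtype=int)
    X[:n_kappa, 0] = 5
    X[n_kappa:n_kappa + n_lambda, 1] = 3
    X[n_kappa:n_kappa + n_lambda, 2] = 2
    X[:, 3] = 1
    a = _adata(X, genes)
    a.obs["cluster"] = "0"
    return a


def test_light_chain_cell_calls():
    a = _light_chain_adata(2, 1, 1)
    calls, chains = core.light_chain_call(a)
    assert list(calls) == ["kappa", "kappa", "lambda", "unassigned"]
    assert chains.loc["0", "n_assigned"] == 3


@pytest.mark.parametrize("nk,nl,expected", [
    (95, 5, True),        # 0.95 > 0.91 -> exclusive
    (91, 9, False),       # exactly 0.91 -> NOT exclusive (strict)
    (911, 89, True),      # 0.911 -> exclusive
    (910, 90, False),     # 0.910 -> not
    (60, 40, False),      # interior
    (0, 100, True),       # 0.0 < 0.01 -> exclusive
    (1, 99, False),       # exactly 0.01 -> NOT exclusive
])
def test_light_chain_exclusivity_boundaries(nk, nl, expected):
    a = _light_chain_adata(nk, nl)
    _, chains = core.light_chain_call(a)
    assert chains.loc["0", "exclusive"] == expected


def test_light_chain_empty_cluster_not_evaluable():
    a = _light_chain_adata(0, 0, 5)
    _, chains = core.light_chain_call(a)
    assert pd.isna(chains.loc["0", "exclusive"])


def test_call_malignant_requires_lymphoma_and_exclusive():
    origin = pd.DataFrame({"origin_category": ["lymphoma_cluster", "common_cluster",
                                               "lymphoma_cluster"]},
                          index=pd.Index(["0", "1", "2"], name="cluster"))
    chains = pd.DataFrame({"exclusive": [True, True, False],
                           "kappa_fraction": [0.95, 0.95, 0.5]},
                          index=pd.Index(["0", "1", "2"], name="cluster"))
    cells = pd.Series(["0", "1", "2", "0"], index=[f"c{i}" for i in range(4)])
    per_cell, table = core.call_malignant(origin, chains, cells)
    assert table.loc["0", "malignant"] and not table.loc["1", "malignant"]
    assert table.loc["2", "discordant"] and not table.loc["2", "malignant"]
    assert list(per_cell) == [True, False, False, True]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def test_fisher_no_association():
    assert core.composition_fisher([[1, 1], [1, 1]]) == 1.0


def test_fisher_extreme_table_exact_value():
    assert core.composition_fisher([[10, 0], [0, 10]]) == pytest.approx(
        2 / comb(20, 10), rel=1e-12)


def test_fisher_row_swap_symmetry():
    t = [[7, 2], [3, 9]]
    assert core.composition_fisher(t) == pytest.approx(
        core.composition_fisher(t[::-1]), rel=1e-12)


def test_fisher_zero_margin():
    assert core.composition_fisher([[0, 0], [5, 3]]) == 1.0


def fisher_enumeration(table):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    probs = {}
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs[x] = (comb(c1, x) * comb(n - c1, r1 - x)) / comb(n, r1)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize("table", [[[3, 5], [6, 2]], [[1, 9], [8, 2]],
                                   [[4, 4], [4, 4]], [[0, 7], [6, 1]]])
def test_fisher_matches_enumeration(table):
    assert core.composition_fisher(table) == pytest.approx(
        fisher_enumeration(table), rel=1e-9)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def _marker_adata(seed=0):
    rng = np.random.default_rng(seed)
    n = 200
    X = rng.poisson(2.0, size=(n, 50))
    X[:100, 0] = rng.poisson(25.0, size=100)   # gene 0 high in cluster A
    a = _adata(X)
    a.obs["cluster"] = ["A"] * 100 + ["B"] * 100
    core.normalize(a)
    return a


def test_marker_detected_for_separating_gene():
    a = _marker_adata()
    out = core.rank_markers(a)
    hits = out[(out["cluster"] == "A") & (out["gene"] == "G0")]
    assert len(hits) == 1


def test_marker_low_lfc_excluded():
    rng = np.random.default_rng(3)
    X = rng.poisson(10.0, size=(200, 30))
    X[:100, 0] = rng.poisson(11.0, size=100)   # logFC ~ ln(11/10) ≈ 0.095 < 0.2
    a = _adata(X)
    a.obs["cluster"] = ["A"] * 100 + ["B"] * 100
    core.normalize(a)
    out = core.rank_markers(a)
    assert out[(out["cluster"] == "A") & (out["gene"] == "G0")].empty


def test_marker_permuted_labels_near_zero_hits():
    total = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        X = rng.poisson(3.0, size=(120, 40))
        a = _adata(X)
        a.obs["cluster"] = rng.permutation(["A"] * 60 + ["B"] * 60)
        core.normalize(a)
        total += len(core.rank_markers(a))
    # Bonferroni caps the FWER at 0.05 per (seed, cluster) family: 40 families
    # -> ~2 expected false hits; 5 is the ~96% binomial envelope
    assert total <= 5


# ---------------------------------------------------------------------------
# permutation equivariance
# ---------------------------------------------------------------------------

def test_qc_and_normalize_equivariant_under_cell_permutation(small_cohort):
    _, adata = small_cohort
    a = adata[:, :].copy()
    rng = np.random.default_rng(0)
    perm = rng.permutation(a.n_obs)
    b = a[perm].copy()
    core.qc_filter(a)
    core.qc_filter(b)
    assert (a.obs["qc_pass"].to_numpy()[perm] == b.obs["qc_pass"].to_numpy()).all()
    core.normalize(a)
    core.normalize(b)
    np.testing.assert_allclose(np.asarray(a.layers["lognorm"])[perm],
                               np.asarray(b.layers["lognorm"]))
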