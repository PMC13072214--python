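"""Expression-bin-matched gene module scoring and signature group analysis.

The module score of a gene set in a cell is the mean normalized expression
of the set minus the mean of control genes matched on average expression:
all genes are ranked by their mean expression across cells and cut into
``n_bins`` equal-size bins, and each signature gene contributes ``n_ctrl``
control genes drawn uniformly from its own bin. This removes the depth /
baseline-expression component that a naive mean over the set would carry.

Two built-in immune signatures follow the germinal-center lymphoma setting:
an exhaustion/immunosuppressive signature (PDCD1, LAG3, HAVCR2; evaluated in
CD8 effector and CD4 regulatory T cells) and a Tfh adhesion signature (CD2,
CTLA4, MAF, PDCD1, CD40LG, ICOS; evaluated in CD4 follicular helper cells).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXHAUSTION_GENES = ("PDCD1", "LAG3", "HAVCR2")
ADHESION_GENES = ("CD2", "CTLA4", "MAF", "PDCD1", "CD40LG", "ICOS")


@dataclass
class SignatureDef:
    """A named gene set with control-matching parameters and target cell types."""

    name: str
    genes: tuple
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0
    target_types: tuple = ()

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        self.genes = tuple(self.genes)
        self.target_types = tuple(self.target_types)

    def rng(self) -> np.random.Generator:
        # dedicated stream per signature: adding another signature to a run
        # does not perturb this one's control draws
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), zlib.crc32(self.name.encode())]))


def exhaustion_signature(seed: int = 0) -> SignatureDef:
    return SignatureDef("exhaustion", EXHAUSTION_GENES, seed=seed,
                        target_types=("CD8_Teff", "CD4_Treg"))


def adhesion_signature(seed: int = 0) -> SignatureDef:
    return SignatureDef("adhesion", ADHESION_GENES, seed=seed,
                        target_types=("CD4_Tfh",))


# ---------------------------------------------------------------------------
# core score
# ---------------------------------------------------------------------------

def expression_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size expression bins from the mean profile.

    Genes are ranked by mean expression across cells (stable sort, so ties
    resolve by input order) and cut into ``n_bins`` near-equal bins; returns
    the bin index per gene.
    """
    avg = np.asarray(values).mean(axis=0)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(avg))
    return (ranks * n_bins // len(avg)).astype(int)


def module_score(values: np.ndarray, genes, sig: SignatureDef) -> np.ndarray:
    """Per-cell module score of ``sig`` on a cells × genes matrix.

    Control genes are drawn uniformly from each signature gene's expression
    bin — without replacement when the bin holds at least ``n_ctrl`` genes,
    with replacement otherwise. Deterministic given the signature's seed.
    """
    values = np.asarray(values)
    genes = list(genes)
    if values.ndim != 2 or values.shape[1] != len(genes):
        raise ValueError("values must be cells × genes matching the gene list")
    gi = {g: i for i, g in enumerate(genes)}
    present = [g for g in sig.genes if g in gi]
    absent = [g for g in sig.genes if g not in gi]
    if absent:
        warnings.warn(f"signature {sig.name!r}: {len(absent)} gene(s) absent "
                      f"from panel dropped: {absent}")
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the panel")
    if len(genes) < sig.n_bins:
        raise ValueError(f"panel has {len(genes)} genes < n_bins={sig.n_bins}")

    bins = expression_bins(values, sig.n_bins)
    rng = sig.rng()
    sig_set = {gi[g] for g in present}
    ctrl_cols: list[np.ndarray] = []
    for g in present:
        members = np.flatnonzero(bins == bins[gi[g]])
        # control pool excludes the signature itself so the score is a clean
        # signature-vs-background contrast
        members = members[~np.isin(members, list(sig_set))]
        if len(members) == 0:
            members = np.setdiff1d(np.arange(len(genes)), list(sig_set))
        replace = len(members) < sig.n_ctrl
        ctrl_cols.append(rng.choice(members, size=sig.n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_cols)
    sig_cols = np.array([gi[g] for g in present])
    return values[:, sig_cols].mean(axis=1) - values[:, ctrl].mean(axis=1)


# ---------------------------------------------------------------------------
# scoring over an annotated dataset
# ---------------------------------------------------------------------------

def score_signature(adata, annotation: pd.DataFrame, sig: SignatureDef,
                    layer: str = "lognorm") -> pd.DataFrame:
    """Score the whole matrix, restrict to the signature's target cell types.

    ``annotation`` must carry ``cell_type`` (and optionally ``sample_id`` /
    ``condition``) indexed like ``adata.obs``. Returns the long-format score
    table (cell_id, signature, score, cell_type, sample_id, group).
    """
    values = adata.layers[layer] if layer in adata.layers else adata.X
    scores = module_score(np.asarray(values), list(adata.var_names), sig)
    table = pd.DataFrame({
        "cell_id": adata.obs_names,
        "signature": sig.name,
        "score": scores,
    }).set_index("cell_id")
    ann = annotation.reindex(adata.obs_names)
    table["cell_type"] = ann["cell_type"]
    for col in ("sample_id", "condition"):
        src = ann[col] if col in ann else adata.obs.get(col)
        if src is not None:
            table[col] = np.asarray(src)
    if sig.target_types:
        table = table[table["cell_type"].isin(sig.target_types)]
    if table.empty:
        warnings.warn(f"signature {sig.name!r}: no cells of target types "
                      f"{sig.target_types} — empty score table")
    if "condition" in table:
        table = table.rename(columns={"condition": "group"})
    return table.reset_index()


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def rank_sum(x, y, exact_max_n: int = 50) -> float:
    """Two-sided Wilcoxon rank-sum p; exact null when combined n ≤ 50 (and
    no ties), normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    use_exact = (len(x) + len(y) <= exact_max_n
                 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    method = "exact" if use_exact else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_groups(table: pd.DataFrame, group_col: str = "group",
                   value_col: str = "score", n_comparisons: int | None = None
                   ) -> pd.DataFrame:
    """Group medians and pairwise two-sided rank-sum tests with Bonferroni.

    One row per group pair per signature present in the table; empty groups
    are skipped (status column). ``n_comparisons`` overrides the Bonferroni
    denominator (default: number of comparisons performed in this call).
    """
    rows = []
    for signame, sub in table.groupby("signature", sort=True, observed=True):
        # observed=False so declared-but-empty categorical groups are
        # reported as skipped rather than silently dropped
        groups = {g: s[value_col].to_numpy() for g, s in
                  sub.groupby(group_col, sort=True, observed=False)}
        names = sorted(groups)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                a, b = groups[ga], groups[gb]
                if len(a) == 0 or len(b) == 0:
                    rows.append({"signature": signame, "group_a": ga, "group_b": gb,
                                 "median_a": np.nan, "median_b": np.nan,
                                 "p": np.nan, "status": "skipped: empty group"})
                    continue
                rows.append({"signature": signame, "group_a": ga, "group_b": gb,
                             "median_a": float(np.median(a)),
                             "median_b": float(np.median(b)),
                             "p": rank_sum(a, b), "status": "ok"})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    m = n_comparisons if n_comparisons is not None else int((out["status"] == "ok").sum())
    out["p_adj"] = np.minimum(out["p"] * max(m, 1), 1.0)
    return out


def aggregate_patient(table: pd.DataFrame,
                      time_to_transform: dict[str, float] | None = None,
                      value_col: str = "score") -> pd.DataFrame:
    """Per-patient median scores with stFL / ltFL / ntFL strata.

    ``time_to_transform`` maps transformed patients to months from diagnosis
    to transformation: ≤ 12 months → stFL, > 12 months → ltFL; patients not
    in the map never transformed (ntFL); a transformed patient with missing
    time gets stratum 'NA'.
    """
    time_to_transform = time_to_transform or {}
    rows = []
    for (signame, patient), sub in table.groupby(["signature", "sample_id"],
                                                 sort=True, observed=True):
        if patient in time_to_transform:
            t = time_to_transform[patient]
            if t is None or (isinstance(t, float) and np.isnan(t)):
                stratum = "NA"
            else:
                stratum = "stFL" if t <= 12 else "ltFL"
        else:
            stratum = "ntFL"
        rows.append({"signature": signame, "sample_id": patient,
                     "median_score": float(sub[value_col].median()),
                     "n_cells": len(sub), "stratum": stratum})
    return pd.DataFrame(rows)
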