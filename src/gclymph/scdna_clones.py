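"""Clonal architecture from single-cell DNA genotypes.

Reconstructs genotype-defined clones from per-cell variant calls produced by
targeted single-cell DNA platforms (Tapestri-like), and classifies each clone
into the malignant B-cell compartment or a clonal-hematopoiesis (CH)
compartment using the antibody-derived protein layer.

The stages run in a fixed order:

1. :func:`filter_variants` — quality cascade over calls, variants and cells.
2. :func:`call_clones` — exact-genotype grouping (zygosity-aware) with a
   minimum clone size and an allele-dropout (ADO) false-positive merge.
3. :func:`order_clones` — subset-inclusion lineage (founding vs subclonal).
4. :func:`protein_profile` / :func:`classify_compartment` — CLR-normalized
   antibody profiles per clone and malignant-B vs CH labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = np.nan

#: canonical B-lineage antibody used for compartment classification
B_MARKER = "CD19"
#: T/myeloid-lineage antibodies; any one suffices for a CH call
T_MARKERS = ("CD5", "CD2", "CD3", "CD7")


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Per-cell variant calls with quality layers and optional protein counts.

    Genotypes are coded 0 (WT), 1 (het), 2 (hom); missing calls are NaN.
    ``vaf`` is only meaningful where ``dp > 0``.
    """

    cells: pd.Index
    variants: pd.Index
    gt: np.ndarray          # float (n_cells, n_variants), values {0,1,2,NaN}
    gq: np.ndarray          # int (n_cells, n_variants)
    dp: np.ndarray          # int (n_cells, n_variants)
    vaf: np.ndarray         # float (n_cells, n_variants) in [0,1]
    pathogenic: pd.Series   # per variant: True / False / None (unknown)
    protein: pd.DataFrame | None = None   # cells × antibodies, counts
    sample_id: str = "sample"
    truth: pd.DataFrame | None = None     # evaluation-only planted labels; never read by analysis

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells)
        self.variants = pd.Index(self.variants)
        shape = (len(self.cells), len(self.variants))
        for name in ("gt", "gq", "dp", "vaf"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} has shape {arr.shape}, expected {shape}")
        self.gt = np.asarray(self.gt, dtype=float)
        valid = ~np.isnan(self.gt)
        if not np.isin(self.gt[valid], [0.0, 1.0, 2.0]).all():
            raise ValueError("genotypes must be 0, 1, 2 or missing")
        vaf = np.asarray(self.vaf, dtype=float)
        observed = np.asarray(self.dp) > 0
        if np.any((vaf[observed] < 0) | (vaf[observed] > 1)):
            raise ValueError("vaf outside [0, 1] where dp > 0")
        self.pathogenic = pd.Series(self.pathogenic, index=self.variants)
        if self.protein is not None and not self.protein.index.equals(self.cells):
            self.protein = self.protein.reindex(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, cell_mask: np.ndarray, variant_mask: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            cells=self.cells[cell_mask],
            variants=self.variants[variant_mask],
            gt=self.gt[np.ix_(cell_mask, variant_mask)],
            gq=self.gq[np.ix_(cell_mask, variant_mask)],
            dp=self.dp[np.ix_(cell_mask, variant_mask)],
            vaf=self.vaf[np.ix_(cell_mask, variant_mask)],
            pathogenic=self.pathogenic[variant_mask],
            protein=None if self.protein is None else self.protein.loc[cell_mask],
            sample_id=self.sample_id,
        )


@dataclass
class FilterThresholds:
    """Quality cascade thresholds.

    Defaults: genotype quality < 30 or depth < 10 reads masks a call, a
    mutant call with single-cell VAF < 25% is masked, variants genotyped in
    < 50% of cells are dropped, cells with < 50% of the remaining genotypes
    present are dropped, variants mutated in < 0.5% of remaining cells are
    dropped; only variants annotated pathogenic are retained and
    germline-like variants (mutant in ≥ 95% of genotyped cells) discarded.
    """

    gq_min: int = 30
    dp_min: int = 10
    vaf_min: float = 0.25
    variant_genotyped_min_frac: float = 0.50
    cell_genotyped_min_frac: float = 0.50
    variant_mutated_min_frac: float = 0.005
    require_pathogenic: bool = True
    germline_mutated_frac: float = 0.95

    def __post_init__(self) -> None:
        for name in ("vaf_min", "variant_genotyped_min_frac",
                     "cell_genotyped_min_frac", "variant_mutated_min_frac",
                     "germline_mutated_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-step accounting of the filter cascade."""

    calls_masked: int = 0
    variants_low_genotyped: int = 0
    cells_low_genotyped: int = 0
    variants_low_mutated: int = 0
    variants_not_pathogenic: int = 0
    variants_germline: int = 0
    n_cells_in: int = 0
    n_variants_in: int = 0
    n_cells_out: int = 0
    n_variants_out: int = 0
    status: str = "ok"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Clone:
    clone_id: str
    genotype: dict          # variant id -> zygosity (0/1/2) over retained variants
    cells: list
    size: int
    frequency: float
    parent: str | None = None

    @property
    def mutated(self) -> frozenset:
        return frozenset(v for v, z in self.genotype.items() if z > 0)


@dataclass
class CloneModel:
    """Genotype-defined clones with sizes, frequencies and lineage nesting."""

    clones: list            # list[Clone], sorted by size descending, WT included
    n_cells_genotyped: int
    min_clone_size: int = 10
    ado_threshold: float = 0.01
    n_cells_dropped: int = 0
    n_groups_merged: int = 0
    founding_variants: frozenset = frozenset()
    subclonal_variants: frozenset = frozenset()
    status: str = "ok"

    def clone(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    @property
    def non_wt(self) -> list:
        return [c for c in self.clones if c.mutated]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clones:
            gstr = ";".join(f"{v}:{int(z)}" for v, z in sorted(c.genotype.items()) if z > 0)
            rows.append({"clone_id": c.clone_id, "genotype": gstr or "WT",
                         "size": c.size, "frequency": c.frequency,
                         "parent": c.parent if c.parent is not None else ""})
        return pd.DataFrame(rows)


@dataclass
class CompartmentCall:
    """Per-clone and per-variant compartment labels with supporting profiles."""

    clone_labels: dict      # clone id -> {malignant_B, clonal_hematopoiesis, ambiguous}
    variant_labels: dict    # variant id -> same label set
    profile: pd.DataFrame   # clone × antibody CLR values


# ---------------------------------------------------------------------------
# 1. variant / cell filter cascade
# ---------------------------------------------------------------------------

def filter_variants(ds: GenotypeDataset,
                    th: FilterThresholds | None = None) -> tuple[GenotypeDataset, FilterReport]:
    """Apply the quality cascade in fixed order and report removals.

    Order: (1) per-call masking on GQ/DP (all calls) and VAF (mutant calls
    only), (2) drop low-genotyped variants, (3) drop low-genotyped cells,
    (4) drop low-prevalence variants, (5) keep pathogenic-annotated variants,
    (6) drop germline-like variants. The cascade is idempotent.
    """
    th = th or FilterThresholds()
    if ds.n_cells == 0 or ds.n_variants == 0:
        raise ValueError("empty dataset")
    rep = FilterReport(n_cells_in=ds.n_cells, n_variants_in=ds.n_variants)

    gt = ds.gt.copy()
    called = ~np.isnan(gt)
    bad_quality = (ds.gq < th.gq_min) | (ds.dp < th.dp_min)
    mutant = called & (gt > 0)
    low_vaf = mutant & (ds.vaf < th.vaf_min)
    mask = called & (bad_quality | low_vaf)
    rep.calls_masked = int(mask.sum())
    gt[mask] = MISSING
    called = ~np.isnan(gt)

    # step 2: variants genotyped in < variant_genotyped_min_frac of cells
    vfrac = called.mean(axis=0)
    vkeep = vfrac >= th.variant_genotyped_min_frac
    rep.variants_low_genotyped = int((~vkeep).sum())

    # step 3: cells with < cell_genotyped_min_frac of remaining variants present
    if vkeep.any():
        cfrac = called[:, vkeep].mean(axis=1)
    else:
        cfrac = np.zeros(ds.n_cells)
    ckeep = cfrac >= th.cell_genotyped_min_frac
    rep.cells_low_genotyped = int((~ckeep).sum())

    # step 4: variants mutated in < variant_mutated_min_frac of remaining cells
    sub_gt = gt[np.ix_(ckeep, vkeep)]
    n_cells = max(int(ckeep.sum()), 1)
    mut_frac = np.nansum(sub_gt > 0, axis=0) / n_cells
    prev_keep = mut_frac >= th.variant_mutated_min_frac
    rep.variants_low_mutated = int((~prev_keep).sum())

    # step 5: pathogenicity annotation (lookup itself is an input flag)
    sub_path = ds.pathogenic[vkeep].to_numpy(dtype=object)
    if th.require_pathogenic:
        path_keep = np.array([bool(p is True or p == True) for p in sub_path],
                             dtype=bool)  # noqa: E712
    else:
        path_keep = np.ones(len(sub_path), dtype=bool)
    rep.variants_not_pathogenic = int((prev_keep & ~path_keep).sum())

    # step 6: germline-like — mutant (het/hom) in ≥ germline_mutated_frac of genotyped cells
    genotyped = ~np.isnan(sub_gt)
    n_geno = genotyped.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        germ_frac = np.where(n_geno > 0, np.nansum(sub_gt > 0, axis=0) / np.maximum(n_geno, 1), 0.0)
    germline = germ_frac >= th.germline_mutated_frac
    rep.variants_germline = int((prev_keep & path_keep & germline).sum())

    final_vkeep = prev_keep & path_keep & ~germline
    vmask = np.zeros(ds.n_variants, dtype=bool)
    vmask[np.flatnonzero(vkeep)[final_vkeep]] = True

    masked_ds = GenotypeDataset(ds.cells, ds.variants, gt, ds.gq, ds.dp, ds.vaf,
                                ds.pathogenic, ds.protein, ds.sample_id)
    out = masked_ds.subset(ckeep, vmask)
    rep.n_cells_out = out.n_cells
    rep.n_variants_out = out.n_variants
    if out.n_cells == 0 or out.n_variants == 0:
        rep.status = "empty"
    return out, rep


# ---------------------------------------------------------------------------
# 2. clone calling
# ---------------------------------------------------------------------------

def _is_single_zygosity_flip(g1: np.ndarray, g2: np.ndarray) -> bool:
    """True iff the genotype vectors differ at exactly one site and that
    difference is a het↔WT or het↔hom flip (the droplet ADO mechanism)."""
    diff = np.flatnonzero(g1 != g2)
    if len(diff) != 1:
        return False
    pair = {int(g1[diff[0]]), int(g2[diff[0]])}
    return pair in ({0, 1}, {1, 2})


def call_clones(ds: GenotypeDataset,
                min_clone_size: int = 10,
                ado_threshold: float = 0.01) -> CloneModel:
    """Group complete-genotype cells into zygosity-distinct clones.

    Cells with any missing genotype are excluded. Groups below the ADO rate
    (frequency < ``ado_threshold``) that differ from a larger group by a
    single het↔WT or het↔hom flip are merged into that group as allele-dropout
    false positives; remaining groups smaller than ``min_clone_size`` cells
    are discarded. Output is sorted by size descending and deterministic.
    """
    complete = ~np.isnan(ds.gt).any(axis=1)
    n_complete = int(complete.sum())
    if n_complete == 0:
        return CloneModel(clones=[], n_cells_genotyped=0,
                          min_clone_size=min_clone_size, ado_threshold=ado_threshold,
                          status="warning: no cells with complete genotypes")

    gt = ds.gt[complete].astype(int)
    cell_ids = ds.cells[complete]
    keys = [tuple(row) for row in gt]
    groups: dict[tuple, list] = {}
    for key, cid in zip(keys, cell_ids):
        groups.setdefault(key, []).append(cid)

    # deterministic ordering: size desc, then genotype tuple
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    sizes = {k: len(v) for k, v in ordered}

    # ADO merge: smallest-first, into the largest single-flip neighbour
    n_merged = 0
    merged_into: dict[tuple, tuple] = {}
    for key, members in sorted(ordered, key=lambda kv: (len(kv[1]), kv[0])):
        if sizes[key] / n_complete >= ado_threshold:
            continue
        g = np.array(key)
        candidates = [k for k in groups
                      if k != key and k not in merged_into
                      and sizes[k] > sizes[key]
                      and _is_single_zygosity_flip(g, np.array(k))]
        if not candidates:
            continue
        target = max(candidates, key=lambda k: (sizes[k], [-x for x in k]))
        groups[target].extend(groups[key])
        sizes[target] += sizes[key]
        sizes[key] = 0
        merged_into[key] = target
        n_merged += 1
    groups = {k: v for k, v in groups.items() if k not in merged_into}

    kept = [(k, v) for k, v in groups.items() if len(v) >= min_clone_size]
    n_dropped = n_complete - sum(len(v) for _, v in kept)
    kept.sort(key=lambda kv: (-len(kv[1]), kv[0]))

    clones = []
    idx = 1
    for key, members in kept:
        genotype = {v: int(z) for v, z in zip(ds.variants, key)}
        if all(z == 0 for z in key):
            cid = "WT"
        else:
            cid = f"C{idx}"
            idx += 1
        clones.append(Clone(clone_id=cid, genotype=genotype, cells=sorted(members),
                            size=len(members), frequency=len(members) / n_complete))
    return CloneModel(clones=clones, n_cells_genotyped=n_complete,
                      min_clone_size=min_clone_size, ado_threshold=ado_threshold,
                      n_cells_dropped=n_dropped, n_groups_merged=n_merged)


# ---------------------------------------------------------------------------
# 3. lineage ordering
# ---------------------------------------------------------------------------

def order_clones(model: CloneModel) -> CloneModel:
    """Nest clones by subset inclusion of their mutated-variant sets.

    Clone A is the parent of B iff A's mutated set is a strict subset of B's
    and no other clone lies strictly between them. Clones whose set has no
    strict subset among the others attach to the WT root. Founding variants
    are those of the highest-frequency non-WT clone; variants appearing only
    in other clones are subclonal.
    """
    non_wt = model.non_wt
    if not non_wt:
        return model
    sets = {c.clone_id: c.mutated for c in non_wt}
    for c in non_wt:
        strict_subsets = [o for o in non_wt
                          if o.clone_id != c.clone_id and sets[o.clone_id] < sets[c.clone_id]]
        if strict_subsets:
            # maximal subset = immediate parent; ties by frequency then id
            best = max(strict_subsets,
                       key=lambda o: (len(sets[o.clone_id]), o.frequency, o.clone_id))
            c.parent = best.clone_id
        else:
            c.parent = "WT"
    for c in model.clones:
        if not c.mutated:
            c.parent = None
    founder = max(non_wt, key=lambda c: c.frequency)
    model.founding_variants = founder.mutated
    all_mut = frozenset().union(*(c.mutated for c in non_wt))
    model.subclonal_variants = all_mut - model.founding_variants
    return model


# ---------------------------------------------------------------------------
# 4. protein integration & compartment classification
# ---------------------------------------------------------------------------

def clr(counts: np.ndarray) -> np.ndarray:
    """Centered log-ratio of (count + 1) across antibodies, per cell."""
    lg = np.log(np.asarray(counts, dtype=float) + 1.0)
    return lg - lg.mean(axis=1, keepdims=True)


def protein_profile(model: CloneModel, ds: GenotypeDataset) -> pd.DataFrame:
    """Per-clone mean CLR antibody profile (clone × antibody)."""
    if ds.protein is None:
        raise ValueError("dataset has no protein layer")
    values = clr(ds.protein.to_numpy())
    clr_df = pd.DataFrame(values, index=ds.protein.index, columns=ds.protein.columns)
    rows = {}
    for c in model.clones:
        members = clr_df.index.intersection(c.cells)
        rows[c.clone_id] = clr_df.loc[members].mean(axis=0) if len(members) else \
            pd.Series(np.nan, index=clr_df.columns)
    return pd.DataFrame(rows).T.reindex([c.clone_id for c in model.clones])


def classify_compartment(model: CloneModel, profile: pd.DataFrame,
                         b_marker: str = B_MARKER,
                         t_markers: tuple = T_MARKERS) -> CompartmentCall:
    """Label each non-WT clone malignant_B, clonal_hematopoiesis or ambiguous.

    A clone is malignant_B when its CD19 CLR exceeds the across-clone CD19
    midpoint ((max+min)/2); clonal_hematopoiesis when CD19 is below midpoint
    while any T-lineage marker is above its own midpoint; ambiguous otherwise.
    Each variant inherits the label of the largest clone carrying it (ties
    broken by lexicographic clone id).
    """
    if b_marker not in profile.columns:
        raise ValueError(f"required B-lineage marker {b_marker!r} absent from protein panel")
    present_t = [m for m in t_markers if m in profile.columns]
    if not present_t:
        raise ValueError(f"no T/myeloid-lineage marker among {t_markers} in protein panel")

    def midpoint(col: pd.Series) -> float:
        vals = col.dropna()
        return float((vals.max() + vals.min()) / 2) if len(vals) else np.nan

    b_mid = midpoint(profile[b_marker])
    t_mid = {m: midpoint(profile[m]) for m in present_t}

    clone_labels = {}
    for c in model.non_wt:
        row = profile.loc[c.clone_id]
        if not np.isfinite(row.get(b_marker, np.nan)):
            clone_labels[c.clone_id] = "ambiguous"
            continue
        if row[b_marker] > b_mid:
            clone_labels[c.clone_id] = "malignant_B"
        elif any(np.isfinite(row[m]) and row[m] > t_mid[m] for m in present_t):
            clone_labels[c.clone_id] = "clonal_hematopoiesis"
        else:
            clone_labels[c.clone_id] = "ambiguous"

    variant_labels = {}
    all_variants = frozenset().union(*(c.mutated for c in model.non_wt)) if model.non_wt else frozenset()
    for v in sorted(all_variants):
        carriers = [c for c in model.non_wt if v in c.mutated]
        largest = max(carriers, key=lambda c: (c.size, _neg_lex(c.clone_id)))
        variant_labels[v] = clone_labels[largest.clone_id]
    return CompartmentCall(clone_labels=clone_labels, variant_labels=variant_labels,
                           profile=profile)


def _neg_lex(s: str) -> tuple:
    """Sort key that prefers lexicographically SMALLER ids under max()."""
    return tuple(-ord(ch) for ch in s)


def variants_frame(model: CloneModel, call: CompartmentCall | None = None) -> pd.DataFrame:
    """Per-variant table: compartment label and founding/subclonal status."""
    rows = []
    all_mut = sorted(model.founding_variants | model.subclonal_variants)
    for v in all_mut:
        rows.append({
            "variant_id": v,
            "label": call.variant_labels.get(v, "") if call else "",
            "status": "founding" if v in model.founding_variants else "subclonal",
        })
    return pd.DataFrame(rows)
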