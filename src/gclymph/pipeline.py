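"""Pipeline orchestration: simulate → scdna → scrna → signatures → spatial.

Each stage is a function over files so the CLI subcommands and the
end-to-end runner share one implementation. A single global seed expands
into per-stage streams (stage-name hashed), so inserting or skipping a
stage does not perturb the others. The run report is a pydantic model whose
JSON schema is published in ``schemas/run_report.schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as gio
from . import scdna_clones as scdna
from . import scrna_core as core
from . import signatures as sigs
from . import spatial_niches as spatial
from .synthetic_data import (CloneSpec, SampleSpec, SimConfig, generate_scdna,
                             generate_scrna, generate_spatial)

log = logging.getLogger("gclymph")

STAGE_ORDER = ("simulate", "scdna", "scrna", "signatures", "spatial")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage derived stream, stable under stage insertion/removal."""
    return (int(global_seed) * 100003 + zlib.crc32(stage.encode())) % (2 ** 31)


# ---------------------------------------------------------------------------
# configuration & report models
# ---------------------------------------------------------------------------

class SpatialSampleCfg(BaseModel):
    sample_id: str
    layout: str = "follicular"
    lr_effect: float = 0.0
    condition: str = "ntFL"


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    model_config = {"extra": "forbid"}

    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))
    simulate: dict = Field(default_factory=dict)        # SimConfig overrides
    spatial_samples: list[SpatialSampleCfg] = Field(default_factory=lambda: [
        SpatialSampleCfg(sample_id="ntFL1_sp", layout="follicular",
                         lr_effect=0.0, condition="ntFL"),
        SpatialSampleCfg(sample_id="tFL1_sp", layout="follicular",
                         lr_effect=5.0, condition="tFL"),
    ])
    scdna: dict = Field(default_factory=dict)           # FilterThresholds / clone params
    scrna: dict = Field(default_factory=dict)           # QC / clustering params
    signatures: dict = Field(default_factory=dict)
    spatial: dict = Field(default_factory=dict)         # n_perms, adjacency mode
    time_to_transform: dict[str, float] = Field(
        default_factory=lambda: {"tFL1": 16.0})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


class StageRecord(BaseModel):
    name: str
    status: str = "ok"                                  # ok | failed | skipped
    n_records: dict[str, int] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)
    outputs: dict[str, str] = Field(default_factory=dict)   # file → sha256
    wall_time_s: float = 0.0
    error: str | None = None


class RunReport(BaseModel):
    seed: int
    stages: list[StageRecord] = Field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register_outputs(rec: StageRecord, outdir: Path, names: list[str]) -> None:
    for name in names:
        p = outdir / name
        if p.is_dir():
            for child in sorted(p.iterdir()):
                rec.outputs[f"{name}/{child.name}"] = _digest(child)
        elif p.exists():
            rec.outputs[name] = _digest(p)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _build_sim_config(overrides: dict, seed: int) -> SimConfig:
    kw = dict(overrides)
    if "samples" in kw:
        kw["samples"] = [SampleSpec(**s) if isinstance(s, dict) else s
                         for s in kw["samples"]]
    if "clone_spec" in kw:
        kw["clone_spec"] = [CloneSpec(**c) if isinstance(c, dict) else c
                            for c in kw["clone_spec"]]
    kw["seed"] = seed
    return SimConfig(**kw)


def stage_simulate(cfg: PipelineConfig, outdir: Path, rec: StageRecord) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    sim = _build_sim_config(cfg.simulate, seed)

    ds = generate_scdna(sim)
    gio.write_genotypes(ds, outdir / "genotypes.csv")
    gio.write_protein(ds.protein, outdir / "protein.csv")
    ds.truth.rename_axis("cell_id").to_csv(outdir / "scdna_truth.csv")
    rec.n_records["scdna_cells"] = ds.n_cells

    adata = generate_scrna(sim)
    gio.write_counts(adata, outdir / "counts")
    adata.obs.rename_axis("cell_id").to_csv(outdir / "metadata.csv")
    adata.uns["truth"].rename_axis("cell_id").to_csv(outdir / "scrna_truth.csv")
    rec.n_records["scrna_cells"] = adata.n_obs
    rec.n_records["genes"] = adata.n_vars

    for sp in cfg.spatial_samples:
        sp_sim = _build_sim_config({**cfg.simulate, "layout": sp.layout,
                                    "lr_effect": sp.lr_effect}, seed + zlib.crc32(
                                        sp.sample_id.encode()) % 9973)
        spdata = generate_spatial(sp_sim, sample_id=sp.sample_id)
        gio.write_positions(spdata, outdir / f"positions_{sp.sample_id}.csv")
        gio.write_counts(spdata, outdir / f"counts_{sp.sample_id}")
        spdata.uns["truth"].rename_axis("bin_id").to_csv(
            outdir / f"spatial_truth_{sp.sample_id}.csv")
        rec.n_records[f"bins_{sp.sample_id}"] = spdata.n_obs
    _register_outputs(rec, outdir,
                      ["genotypes.csv", "protein.csv", "counts", "metadata.csv"] +
                      [f"positions_{s.sample_id}.csv" for s in cfg.spatial_samples] +
                      [f"counts_{s.sample_id}" for s in cfg.spatial_samples])


def stage_scdna(genotypes: Path, protein: Path | None, outdir: Path,
                params: dict | None = None, rec: StageRecord | None = None) -> dict:
    params = dict(params or {})
    rec = rec or StageRecord(name="scdna")
    ds = gio.read_genotypes(genotypes)
    if protein is not None and Path(protein).exists():
        ds.protein = gio.read_protein(protein).reindex(ds.cells)
    th_kw = {k: v for k, v in params.items()
             if k in scdna.FilterThresholds.__dataclass_fields__}
    filtered, report = scdna.filter_variants(ds, scdna.FilterThresholds(**th_kw))
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    rec.n_records.update(cells_in=report.n_cells_in, variants_in=report.n_variants_in,
                         cells_out=report.n_cells_out, variants_out=report.n_variants_out)
    if report.status == "empty":
        rec.warnings.append("filter cascade removed all cells or variants")
        pd.DataFrame().to_csv(outdir / "clones.csv")
        return {"model": None}
    model = scdna.call_clones(
        filtered,
        min_clone_size=int(params.get("min_clone_size", 10)),
        ado_threshold=float(params.get("ado_threshold", 0.01)))
    model = scdna.order_clones(model)
    call = None
    if filtered.protein is not None:
        profile = scdna.protein_profile(model, filtered)
        if model.non_wt:
            call = scdna.classify_compartment(model, profile)
            profile.rename_axis("clone_id").to_csv(outdir / "clone_protein_profile.csv")
    frame = model.to_frame()
    if call is not None:
        frame["compartment"] = frame["clone_id"].map(call.clone_labels).fillna("")
    frame.to_csv(outdir / "clones.csv", index=False)
    scdna.variants_frame(model, call).to_csv(outdir / "variants.csv", index=False)
    rec.n_records["clones"] = len(model.clones)
    _register_outputs(rec, outdir, ["clones.csv", "variants.csv", "filter_report.json"])
    return {"model": model, "compartments": call}


def stage_scrna(counts_dir: Path, meta: Path, outdir: Path,
                params: dict | None = None, seed: int = 0,
                rec: StageRecord | None = None) -> dict:
    params = dict(params or {})
    rec = rec or StageRecord(name="scrna")
    adata = gio.read_counts(counts_dir)
    metadata = pd.read_csv(meta, index_col="cell_id")
    adata.obs = adata.obs.join(metadata)

    core.qc_filter(adata, min_genes=int(params.get("min_genes", 200)),
                   max_genes=int(params.get("max_genes", 6000)),
                   max_mito=float(params.get("max_mito", 0.15)))
    core.doublet_score(adata, expected_rate=float(params.get("doublet_rate", 0.10)),
                       seed=seed)
    keep = (adata.obs["qc_pass"] & ~adata.obs["doublet"]).to_numpy()
    sub = adata[keep].copy()
    core.normalize(sub)
    core.cell_cycle_scores(sub, seed=seed)
    core.scale_regress(sub)
    cp = core.ClusteringParams(
        n_pcs=int(params.get("n_pcs", 30)), snn_k=int(params.get("snn_k", 20)),
        resolution=float(params.get("resolution", 0.3)), seed=seed)
    core.embed_and_cluster(sub, cp)

    controls = sorted(sub.obs.loc[sub.obs["condition"] == "tonsil", "sample_id"].unique())
    origin = core.classify_cluster_origin(sub.obs["cluster"], sub.obs["sample_id"],
                                          control_samples=controls)
    light_chain, chains = core.light_chain_call(sub)
    malignant, cluster_table = core.call_malignant(origin, chains, sub.obs["cluster"])
    sub.obs["light_chain"] = light_chain
    sub.obs["malignant"] = malignant
    sub.obs["origin_category"] = sub.obs["cluster"].map(
        origin["origin_category"]).astype(str)
    core.annotate_cell_types(sub, seed=seed)

    ann = adata.obs.copy()
    for col in ("cluster", "origin_category", "light_chain", "cell_type",
                "s_score", "g2m_score"):
        ann[col] = sub.obs[col].reindex(ann.index)
    ann["malignant"] = sub.obs["malignant"].reindex(ann.index).fillna(False).astype(bool)
    ann.rename_axis("cell_id").to_csv(outdir / "annotation.csv")
    cluster_table.rename_axis("cluster").to_csv(outdir / "clusters.csv")

    if params.get("run_markers", True):
        markers = core.rank_markers(sub)
        markers.to_csv(outdir / "markers.csv", index=False)
        rec.n_records["marker_genes"] = len(markers)

    # composition tests: per cell type, each lymphoma sample vs pooled others
    comp_rows = []
    ct = sub.obs["cell_type"]
    for t in sorted(ct.unique()):
        for s in sorted(sub.obs["sample_id"].unique()):
            in_s = (sub.obs["sample_id"] == s).to_numpy()
            is_t = (ct == t).to_numpy()
            table = np.array([[int((in_s & is_t).sum()), int((in_s & ~is_t).sum())],
                              [int((~in_s & is_t).sum()), int((~in_s & ~is_t).sum())]])
            comp_rows.append({"cell_type": t, "sample_id": s,
                              "frac_in_sample": table[0, 0] / max(table[0].sum(), 1),
                              "p": core.composition_fisher(table)})
    pd.DataFrame(comp_rows).to_csv(outdir / "composition.csv", index=False)

    rec.n_records.update(cells=adata.n_obs, qc_pass=int(adata.obs["qc_pass"].sum()),
                         doublets=int(adata.obs["doublet"].sum()),
                         clusters=int(sub.obs["cluster"].nunique()),
                         malignant_cells=int(ann["malignant"].sum()))
    _register_outputs(rec, outdir, ["annotation.csv", "clusters.csv",
                                    "markers.csv", "composition.csv"])
    return {"adata": sub, "annotation": ann, "clusters": cluster_table}


def stage_signatures(counts_dir: Path, annotation: Path, outdir: Path,
                     params: dict | None = None, seed: int = 0,
                     time_to_transform: dict | None = None,
                     rec: StageRecord | None = None) -> dict:
    params = dict(params or {})
    rec = rec or StageRecord(name="signatures")
    adata = gio.read_counts(counts_dir)
    ann = pd.read_csv(annotation, index_col="cell_id")
    keep = ann.reindex(adata.obs_names)
    mask = (keep["qc_pass"].fillna(False).astype(bool)
            & ~keep["doublet"].fillna(False).astype(bool)).to_numpy()
    sub = adata[mask].copy()
    sub.obs = sub.obs.join(ann)
    core.normalize(sub)

    defs = [sigs.exhaustion_signature(seed), sigs.adhesion_signature(seed)]
    tables = [sigs.score_signature(sub, sub.obs, d) for d in defs]
    scores = pd.concat(tables, ignore_index=True)
    scores.to_csv(outdir / "scores.csv", index=False)
    comparisons = sigs.compare_groups(scores)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)
    patient = sigs.aggregate_patient(scores, time_to_transform or {})
    patient.to_csv(outdir / "patient.csv", index=False)
    rec.n_records.update(scored_cells=len(scores), comparisons=len(comparisons))
    _register_outputs(rec, outdir, ["scores.csv", "comparisons.csv", "patient.csv"])
    return {"scores": scores, "comparisons": comparisons, "patient": patient}


def stage_spatial(samples: list[tuple[str, Path, Path]], outdir: Path,
                  params: dict | None = None, seed: int = 0,
                  rec: StageRecord | None = None) -> dict:
    """``samples``: (sample_id, positions CSV, counts dir) triples."""
    params = dict(params or {})
    rec = rec or StageRecord(name="spatial")
    mode = params.get("adjacency", "queen8")
    n_perms = int(params.get("n_perms", 1000))
    results, bin_rows, lr_rows = [], [], []
    for sample_id, pos_path, counts_dir in samples:
        adata = gio.read_counts(counts_dir)
        pos = gio.read_positions(pos_path).reindex(adata.obs_names)
        adata.obs["row"] = pos["row"].to_numpy()
        adata.obs["col"] = pos["col"].to_numpy()
        adata.obs["sample_id"] = sample_id
        core.normalize(adata)
        spatial.assign_bins(adata, seed=seed)
        include = (~adata.obs["excluded"]
                   & ~adata.obs["combined_label"]).to_numpy()
        inc = adata[include].copy()
        edges = spatial.grid_adjacency(inc.obs["row"], inc.obs["col"], mode=mode)
        labels = inc.obs["assigned_type"].to_numpy()
        res = spatial.neighborhood_enrichment(labels, edges, n_perms=n_perms,
                                              seed=seed, mode=mode, sample_id=sample_id)
        results.append(res)
        for lr in spatial.lr_interaction(inc, edges, labels):
            lr_rows.append({"sample_id": sample_id, "ligand": lr.ligand,
                            "receptor": lr.receptor, "source": lr.source,
                            "target": lr.target, "frequency": lr.frequency,
                            "strength": lr.strength, "status": lr.status})
        df = adata.obs[["row", "col", "assigned_type", "excluded"]].copy()
        df.insert(0, "sample_id", sample_id)
        bin_rows.append(df.rename_axis("bin_id").reset_index())
        rec.n_records[f"bins_{sample_id}"] = adata.n_obs
        rec.n_records[f"excluded_{sample_id}"] = int(adata.obs["excluded"].sum())
    spatial.normalize_enrichment(results)
    enr_rows = []
    for res in results:
        for a in res.z.index:
            for b in res.z.columns:
                enr_rows.append({"sample_id": res.sample_id, "type_a": a, "type_b": b,
                                 "z": res.z.loc[a, b], "scaled": res.scaled.loc[a, b],
                                 "mode": res.mode, "n_perms": res.n_perms})
    pd.concat(bin_rows, ignore_index=True).to_csv(outdir / "bin_annotation.csv", index=False)
    pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.csv", index=False)
    pd.DataFrame(lr_rows).to_csv(outdir / "lr.csv", index=False)
    _register_outputs(rec, outdir, ["bin_annotation.csv", "enrichment.csv", "lr.csv"])
    return {"enrichment": results, "lr": lr_rows}


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> RunReport:
    """Execute the configured stages in dependency order.

    A failed stage is recorded and every downstream stage is skipped.
    Identical config + seed yields identical output digests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    failed = False
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        rec = StageRecord(name=stage)
        if failed:
            rec.status = "skipped"
            report.stages.append(rec)
            continue
        t0 = time.perf_counter()
        log.info("running stage %s", stage)
        try:
            import warnings as _w
            with _w.catch_warnings(record=True) as caught:
                _w.simplefilter("always")
                seed = stage_seed(cfg.seed, stage)
                if stage == "simulate":
                    stage_simulate(cfg, outdir, rec)
                elif stage == "scdna":
                    stage_scdna(outdir / "genotypes.csv", outdir / "protein.csv",
                                outdir, cfg.scdna, rec)
                elif stage == "scrna":
                    stage_scrna(outdir / "counts", outdir / "metadata.csv",
                                outdir, cfg.scrna, seed, rec)
                elif stage == "signatures":
                    stage_signatures(outdir / "counts", outdir / "annotation.csv",
                                     outdir, cfg.signatures, seed,
                                     cfg.time_to_transform, rec)
                elif stage == "spatial":
                    triples = [(s.sample_id, outdir / f"positions_{s.sample_id}.csv",
                                outdir / f"counts_{s.sample_id}")
                               for s in cfg.spatial_samples]
                    stage_spatial(triples, outdir, cfg.spatial, seed, rec)
            rec.warnings.extend(str(w.message) for w in caught)
        except Exception as exc:  # noqa: BLE001 — report and halt downstream
            log.exception("stage %s failed", stage)
            rec.status = "failed"
            rec.error = f"{type(exc).__name__}: {exc}"
            failed = True
        rec.wall_time_s = round(time.perf_counter() - t0, 3)
        report.stages.append(rec)
    report.to_json(outdir / "report.json")
    return report
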