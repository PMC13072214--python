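"""File formats: Matrix Market count triplets, genotype/protein CSV, positions.

Counts travel as a CellRanger-style directory (``matrix.mtx`` in coordinate
form with genes as rows and cells as columns, plus ``features.tsv`` and
``barcodes.tsv``); genotypes as a long CSV
(``cell_id,variant_id,gt,gq,dp,vaf[,pathogenic]``) with missing genotypes
encoded ``NA``. All readers are gzip-transparent (a ``.gz`` sibling of the
expected file is picked up automatically); round trips preserve values
exactly.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .scdna_clones import GenotypeDataset


def _find(path: Path) -> Path:
    if path.exists():
        return path
    gz = path.with_name(path.name + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(path)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# counts (MTX triplet directories)
# ---------------------------------------------------------------------------

def write_counts(adata, outdir: str | Path) -> None:
    """Write cells × genes counts as genes × cells MTX with feature/barcode TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.coo_matrix(np.asarray(adata.X).T)
    spio.mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)


def read_counts(indir: str | Path) -> ad.AnnData:
    """Read a counts directory back into a cells × genes AnnData."""
    indir = Path(indir)
    mtx = _find(indir / "matrix.mtx")
    with (gzip.open(mtx, "rb") if mtx.suffix == ".gz" else open(mtx, "rb")) as fh:
        M = spio.mmread(fh)
    with _open_text(_find(indir / "features.tsv")) as fh:
        genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with _open_text(_find(indir / "barcodes.tsv")) as fh:
        cells = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    M = sparse.coo_matrix(M)
    if M.shape != (len(genes), len(cells)):
        raise ValueError(f"matrix.mtx is {M.shape} but features.tsv has {len(genes)} "
                         f"rows and barcodes.tsv {len(cells)}")
    X = np.asarray(M.todense()).T.astype(np.int64)
    return ad.AnnData(X=X,
                      obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
                      var=pd.DataFrame(index=pd.Index(genes, name="gene")))


# ---------------------------------------------------------------------------
# genotype long CSV + protein CSV
# ---------------------------------------------------------------------------

def write_genotypes(ds: GenotypeDataset, path: str | Path) -> None:
    """Long CSV, one row per (cell, variant); missing genotype encoded NA."""
    n_c, n_v = ds.n_cells, ds.n_variants
    cell_rep = np.repeat(ds.cells.to_numpy(), n_v)
    var_rep = np.tile(ds.variants.to_numpy(), n_c)
    gt = ds.gt.ravel()
    gt_str = np.where(np.isnan(gt), "NA", np.char.mod("%d", np.nan_to_num(gt).astype(int)))
    path_flag = ds.pathogenic.map(
        lambda v: "" if v is None else ("true" if v else "false")).to_numpy()
    df = pd.DataFrame({
        "cell_id": cell_rep, "variant_id": var_rep, "gt": gt_str,
        "gq": ds.gq.ravel(), "dp": ds.dp.ravel(), "vaf": ds.vaf.ravel(),
        "pathogenic": np.tile(path_flag, n_c),
    })
    # %.17g guarantees exact float round trips for the vaf column
    df.to_csv(path, index=False, float_format="%.17g")


_GT_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


def read_genotypes(path: str | Path, sample_id: str = "sample") -> GenotypeDataset:
    df = pd.read_csv(path, dtype={"gt": str}, keep_default_na=False,
                     na_values=[], low_memory=False, float_precision="round_trip")
    required = ["cell_id", "variant_id", "gt", "gq", "dp", "vaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"genotype CSV missing columns: {missing}")
    bad = ~df["gt"].isin(_GT_TOKENS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unknown gt token {df['gt'].iloc[row]!r} at data row {row + 1}")
    vaf = pd.to_numeric(df["vaf"])
    if ((vaf < 0) | (vaf > 1)).any():
        row = int(np.flatnonzero(((vaf < 0) | (vaf > 1)).to_numpy())[0])
        raise ValueError(f"vaf outside [0, 1] at data row {row + 1}")
    cells = pd.Index(pd.unique(df["cell_id"]))
    variants = pd.Index(pd.unique(df["variant_id"]))
    ci = pd.Series(np.arange(len(cells)), index=cells)[df["cell_id"]].to_numpy()
    vi = pd.Series(np.arange(len(variants)), index=variants)[df["variant_id"]].to_numpy()
    shape = (len(cells), len(variants))
    gt = np.full(shape, np.nan)
    gq = np.zeros(shape, dtype=int)
    dp = np.zeros(shape, dtype=int)
    vaf_m = np.zeros(shape)
    gt[ci, vi] = df["gt"].map(_GT_TOKENS).to_numpy()
    gq[ci, vi] = pd.to_numeric(df["gq"]).to_numpy()
    dp[ci, vi] = pd.to_numeric(df["dp"]).to_numpy()
    vaf_m[ci, vi] = vaf.to_numpy()
    if "pathogenic" in df.columns:
        first = df.drop_duplicates("variant_id").set_index("variant_id")["pathogenic"]
        pathogenic = pd.Series(
            [ {"true": True, "false": False}.get(str(first[v]).strip().lower(), None)
              for v in variants], index=variants, dtype=object)
    else:
        pathogenic = pd.Series([None] * len(variants), index=variants, dtype=object)
    return GenotypeDataset(cells=cells, variants=variants, gt=gt, gq=gq, dp=dp,
                           vaf=vaf_m, pathogenic=pathogenic, sample_id=sample_id)


def write_protein(protein: pd.DataFrame, path: str | Path) -> None:
    protein.rename_axis("cell_id").to_csv(path)


def read_protein(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="cell_id")


# ---------------------------------------------------------------------------
# spatial positions
# ---------------------------------------------------------------------------

def write_positions(adata, path: str | Path) -> None:
    pd.DataFrame({"bin_id": adata.obs_names,
                  "row": adata.obs["row"].to_numpy(),
                  "col": adata.obs["col"].to_numpy()}).to_csv(path, index=False)


def read_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("bin_id", "row", "col") if c not in df.columns]
    if missing:
        raise ValueError(f"positions CSV missing columns: {missing}")
    return df.set_index("bin_id")
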