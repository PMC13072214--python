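"""Shared fixtures: tiny hand-built genotype tables and cached synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from gclymph import SimConfig, generate_scrna
from gclymph.scdna_clones import GenotypeDataset


def make_genotype_dataset(gt, gq=None, dp=None, vaf=None, pathogenic=None,
                          protein=None):
    """Build a GenotypeDataset from a genotype matrix with benign defaults
    (everything passes the quality gates unless overridden)."""
    gt = np.asarray(gt, dtype=float)
    n_c, n_v = gt.shape
    cells = pd.Index([f"c{i}" for i in range(n_c)])
    variants = pd.Index([f"V{j}" for j in range(n_v)])
    gq = np.full((n_c, n_v), 90) if gq is None else np.asarray(gq)
    dp = np.full((n_c, n_v), 80) if dp is None else np.asarray(dp)
    if vaf is None:
        vaf = np.where(gt == 1, 0.5, np.where(gt == 2, 0.95, 0.01))
        vaf = np.nan_to_num(vaf, nan=0.0)
    if pathogenic is None:
        pathogenic = pd.Series([True] * n_v, index=variants, dtype=object)
    else:
        pathogenic = pd.Series(pathogenic, index=variants, dtype=object)
    if protein is not None:
        protein = pd.DataFrame(protein[1], index=cells, columns=protein[0])
    return GenotypeDataset(cells=cells, variants=variants, gt=gt, gq=gq, dp=dp,
                           vaf=np.asarray(vaf, dtype=float), pathogenic=pathogenic,
                           protein=protein)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only scRNA tests."""
    cfg = SimConfig(seed=11, n_cells=500, n_genes=600)
    return cfg, generate_scrna(cfg)
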