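"""Cell/gene quality control and library-size normalization.

Filters applied in order: (1) cells expressing <200 genes; (2) genes
detected in fewer than 6 cells; (3) cells kept with 2000-7000 total UMIs
(inclusive); (4) cells kept with <25% mitochondrial counts. Guide features
are exempt from the gene filters and excluded from cell totals, so guide
abundance does not perturb normalization. Expression is then scaled to
10,000 counts per cell and log2(1 + x) transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .screen_sim import GENE_TYPE


@dataclass(frozen=True)
class QcParams:
    min_genes_per_cell: int = 200  # strict: cells with < this many expressed genes drop
    min_cells_per_gene: int = 6  # strict: genes seen in fewer cells drop
    umi_min: int = 2000  # inclusive bounds on per-cell gene UMI totals
    umi_max: int = 7000
    max_mito_fraction: float = 0.25  # strict: cells at/above this fraction drop
    scale_factor: float = 10_000.0
    mito_prefix: str = "MT-"

    def __post_init__(self):
        if self.umi_min >= self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if min(self.min_genes_per_cell, self.min_cells_per_gene, self.umi_min) <= 0:
            raise ValueError("thresholds must be positive")


def _gene_mask(adata: ad.AnnData) -> np.ndarray:
    return (adata.var["feature_type"] == GENE_TYPE).to_numpy()


def mito_fraction(adata: ad.AnnData, mito_prefix: str = "MT-") -> np.ndarray:
    """Per-cell fraction of gene counts from mito-prefixed genes.

    Returns zeros (with a warning) when no gene name carries the prefix.
    Guide features never enter the numerator or denominator.
    """
    gmask = _gene_mask(adata)
    x = sp.csr_matrix(adata.X)[:, gmask]
    names = adata.var["name"].astype(str).to_numpy()[gmask]
    mito = np.char.startswith(names.astype(str), mito_prefix)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if not mito.any():
        warnings.warn(f"no genes with prefix {mito_prefix!r}; mito fraction is 0")
        return np.zeros(adata.n_obs)
    mt = np.asarray(x[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mt / np.maximum(totals, 1), 0.0)
    return frac


def qc_filter(adata: ad.AnnData, params: QcParams | None = None) -> tuple[ad.AnnData, dict]:
    """Apply the four QC filters in order; return the matrix and a report.

    The report counts cells/genes removed at each step. Guide features are
    retained untouched. Emits a warning (not an error) when all cells are
    removed.
    """
    params = params or QcParams()
    report = {"cells_initial": adata.n_obs}
    gmask = _gene_mask(adata)
    report["genes_initial"] = int(gmask.sum())

    x = sp.csr_matrix(adata.X)
    pos = x.copy()
    pos.data = np.ones_like(pos.data)  # indicator of expression

    # step 1: cells expressing too few genes
    genes_expressed = np.asarray(pos[:, gmask].sum(axis=1)).ravel()
    cell_keep = genes_expressed >= params.min_genes_per_cell
    report["cells_removed_min_genes"] = int((~cell_keep).sum())

    # step 2: genes detected in too few remaining cells (guides exempt)
    cells_per_gene = np.asarray(pos[cell_keep].sum(axis=0)).ravel()
    feat_keep = ~(gmask & (cells_per_gene < params.min_cells_per_gene))
    report["genes_removed_min_cells"] = int((~feat_keep).sum())

    # step 3: per-cell totals over remaining genes inside [umi_min, umi_max]
    totals = np.asarray(x[:, feat_keep & gmask].sum(axis=1)).ravel()
    in_range = (totals >= params.umi_min) & (totals <= params.umi_max)
    step3_keep = cell_keep & in_range
    report["cells_removed_umi"] = int((cell_keep & ~in_range).sum())

    # step 4: mitochondrial fraction (over remaining genes) strictly below cap
    sub = adata[:, feat_keep]
    frac = mito_fraction(sub, params.mito_prefix)
    mito_ok = frac < params.max_mito_fraction
    report["cells_removed_mito"] = int((step3_keep & ~mito_ok).sum())
    final_cells = step3_keep & mito_ok

    out = adata[final_cells, feat_keep].copy()
    report["cells_kept"] = out.n_obs
    report["genes_kept"] = int(_gene_mask(out).sum())
    if out.n_obs == 0:
        warnings.warn("QC removed every cell")
    return out, report


def normalize_log2(adata: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Scale each cell's gene counts to ``scale_factor`` and log2(1+x) transform.

    Returns a genes-only AnnData with float values
    log2(1 + scale_factor * x / cell_total); zeros map to zero, so per cell
    the inverse transform sums back to ``scale_factor``. Cells with zero
    gene counts must have been removed by QC beforehand.
    """
    gmask = _gene_mask(adata)
    genes = adata[:, gmask].copy()
    x = sp.csr_matrix(genes.X, dtype=float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            f"{int((totals == 0).sum())} cells have zero gene counts; run QC first"
        )
    inv = sp.diags(scale_factor / totals)
    xn = inv @ x
    xn = xn.tocsr()
    xn.data = np.log2(1.0 + xn.data)
    out = ad.AnnData(
        X=xn, obs=genes.obs.copy(), var=genes.var.copy()
    )
    out.obs["gene_umi_total"] = totals
    out.uns["scale_factor"] = scale_factor
    out.uns["log_base"] = 2
    return out
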