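"""Guide-to-cell assignment from the guide x cell UMI submatrix.

A guide is called present in a cell when its UMI count exceeds zero; cells
with exactly one detected guide are kept for association analysis. MOI is
estimated from the Poisson zero fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._util import write_tsv
from .screen_sim import GUIDE_TYPE


def extract_guide_matrix(adata: ad.AnnData) -> ad.AnnData:
    """Restrict features to guide features (column order preserved)."""
    mask = (adata.var["feature_type"] == GUIDE_TYPE).to_numpy()
    if not mask.any():
        raise ValueError("matrix contains no guide features")
    return adata[:, mask].copy()


@dataclass
class GuideAssignment:
    """Binarized guide presence per cell and the single-guide cell set."""

    indicator: sp.csr_matrix  # cells x guides, 0/1
    guide_ids: list[str]
    barcodes: list[str]
    n_guides_per_cell: np.ndarray
    min_umi: int = 1

    @property
    def kept_mask(self) -> np.ndarray:
        return self.n_guides_per_cell == 1

    @property
    def kept_cells(self) -> list[str]:
        return [b for b, k in zip(self.barcodes, self.kept_mask) if k]

    def assigned_guide(self) -> pd.Series:
        """barcode -> guide_id over kept (single-guide) cells."""
        kept = np.flatnonzero(self.kept_mask)
        sub = self.indicator[kept]
        idx = sub.argmax(axis=1)
        idx = np.asarray(idx).ravel()
        return pd.Series(
            [self.guide_ids[j] for j in idx],
            index=[self.barcodes[i] for i in kept],
            name="guide_id",
        )

    def multiplicity_histogram(self) -> pd.Series:
        vals, counts = np.unique(self.n_guides_per_cell, return_counts=True)
        return pd.Series(counts, index=vals, name="n_cells")


def assign_guides(adata: ad.AnnData, min_umi: int = 1) -> GuideAssignment:
    """Binarize guide UMIs at ``count >= min_umi`` (default: any UMI > 0).

    The default reproduces the literal coding rule — UMI count > 0 is coded
    1, otherwise 0 — with ``min_umi`` exposed for noisier data.
    """
    guides = extract_guide_matrix(adata)
    x = sp.csr_matrix(guides.X)
    indicator = (x >= min_umi).astype(np.int8).tocsr()
    n_per_cell = np.asarray(indicator.sum(axis=1)).ravel().astype(np.int64)
    return GuideAssignment(
        indicator=indicator,
        guide_ids=list(guides.var_names),
        barcodes=list(adata.obs_names),
        n_guides_per_cell=n_per_cell,
        min_umi=min_umi,
    )


def estimate_moi(fraction_zero: float) -> float:
    """MOI from the zero fraction under Poisson uptake: lambda = -ln f0.

    ``fraction_zero`` should be measured before selection removes unguided
    cells; when computed from the detected-guide histogram instead,
    detection dropout biases the estimate downward.
    """
    if not 0.0 < fraction_zero <= 1.0:
        raise ValueError(f"fraction_zero must be in (0, 1], got {fraction_zero}")
    return -math.log(fraction_zero)


def cells_per_guide(a: GuideAssignment) -> tuple[pd.Series, dict]:
    """Kept (single-guide) cells per guide, with mean/sd/min/max summary.

    Guides with zero kept cells are reported as 0, not dropped; the sum of
    counts equals the number of kept cells. SD is the sample SD.
    """
    assigned = a.assigned_guide()
    counts = assigned.value_counts().reindex(a.guide_ids, fill_value=0)
    counts.name = "n_cells"
    arr = counts.to_numpy(dtype=float)
    summary = {
        "n_kept_cells": int(arr.sum()),
        "mean": float(arr.mean()) if arr.size else float("nan"),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        "min": int(arr.min()) if arr.size else 0,
        "max": int(arr.max()) if arr.size else 0,
    }
    return counts, summary


def write_assignment(a: GuideAssignment, path: str | Path, seed=None) -> None:
    """Assignment TSV: barcode, guide_id (kept cells only), multiplicity."""
    assigned = a.assigned_guide()
    df = pd.DataFrame(
        {
            "barcode": a.barcodes,
            "guide_id": [assigned.get(b, "") for b in a.barcodes],
            "multiplicity": a.n_guides_per_cell,
        }
    )
    write_tsv(df, path, seed=seed)


def read_assignment(path: str | Path) -> pd.Series:
    """barcode -> guide_id for kept cells from an assignment TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    kept = df[(df["multiplicity"] == 1) & (df["guide_id"] != "")]
    return pd.Series(kept["guide_id"].values, index=kept["barcode"].values, name="guide_id")
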