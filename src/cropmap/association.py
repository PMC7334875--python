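"""Per-eSNP association testing with locus-wise multiple-testing control.

For each candidate guide, normalized expression of its locus's target gene
is regressed on the binary guide indicator over single-guide cells (cells
carrying the guide vs cells carrying any other single guide). The OLS slope
equals the group-mean difference and its Student's t-test equals the pooled
two-sample t-test. Tests within a locus share a Bonferroni-adjusted
critical value alpha / tests_per_locus (0.05 / 20 = 0.0025 by default).
Adjacent genes at each locus are tested the same way as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from ._util import InsufficientCellsError
from .assign import GuideAssignment
from .screen_sim import ScreenDesign

RESULT_COLUMNS = [
    "guide_id", "snp_id", "gene", "locus", "role", "n1", "n0",
    "beta", "se", "t", "df", "p", "alpha_adj", "significant", "testable",
]


@dataclass(frozen=True)
class MtcParams:
    """Locus-wise Bonferroni control: alpha divided by tests per locus."""

    alpha: float = 0.05
    tests_per_locus: int = 20

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tests_per_locus < 1:
            raise ValueError("tests_per_locus must be >= 1")


def bonferroni_threshold(mtc: MtcParams) -> float:
    """Adjusted critical value alpha / tests_per_locus."""
    return mtc.alpha / mtc.tests_per_locus


def test_guide_gene(y: np.ndarray, g: np.ndarray) -> dict:
    """OLS of expression on a binary guide indicator; slope t-test.

    Fits y = a + beta * g by ordinary least squares; beta equals
    mean(y | g=1) - mean(y | g=0) exactly, and t = beta / se with n-2
    degrees of freedom gives a two-sided p. A zero-variance y yields
    beta = 0, p = 1. Raises ``InsufficientCellsError`` when either group
    has fewer than 2 cells.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(g).ravel().astype(float)
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    n = y.size
    n1 = int(g.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise InsufficientCellsError(
            f"need >= 2 cells per group, got n1={n1}, n0={n0}"
        )
    df = n - 2
    if np.ptp(y) == 0.0:
        return {"beta": 0.0, "se": 0.0, "t": 0.0, "df": df, "p": 1.0, "n1": n1, "n0": n0}
    # explicit OLS with design matrix [1, g]
    x = np.column_stack([np.ones(n), g])
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ (x.T @ y)
    resid = y - x @ coef
    rss = float(resid @ resid)
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        t = float("inf") if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / se
        p = 2.0 * float(scipy.stats.t.sf(abs(t), df))
    return {"beta": beta, "se": se, "t": t, "df": df, "p": p, "n1": n1, "n0": n0}


test_guide_gene.__test__ = False  # keep pytest from collecting the API name


def run_screen(
    norm: ad.AnnData,
    assignment: GuideAssignment | pd.Series,
    design: ScreenDesign,
    mtc: MtcParams | None = None,
    include_adjacent: bool = True,
    control_group: str = "others",
) -> pd.DataFrame:
    """Association table over all candidate guides of a screen.

    ``norm`` is the normalized genes-only matrix; ``assignment`` maps kept
    (single-guide) barcodes to their guide. For each candidate guide the
    target gene is tested (role='target'); with ``include_adjacent``, each
    locus's adjacent genes are tested per guide too (role='adjacent').
    ``control_group='others'`` compares against all other single-guide
    cells; ``'negative'`` restricts the comparison group to
    negative-control cells (sensitivity analysis). Results are sorted by
    locus then p; guides absent from the assignment are skipped with a
    warning, and tests with <2 cells in a group are flagged untestable.
    """
    mtc = mtc or MtcParams()
    alpha_adj = bonferroni_threshold(mtc)
    assigned = (
        assignment.assigned_guide()
        if isinstance(assignment, GuideAssignment)
        else assignment
    )
    # align to cells that survived QC
    assigned = assigned[assigned.index.isin(norm.obs_names)]
    cells = assigned.index.to_numpy()
    guide_of_cell = assigned.to_numpy()
    norm_cells = norm[cells]
    x = sp.csr_matrix(norm_cells.X)
    gene_index = {g: j for j, g in enumerate(norm.var_names)}
    ctrl_class = design.control_class_of()
    snp_of = {g.guide_id: g.snp_id for g in design.guides}

    if control_group == "negative":
        neg_guides = {g for g, c in ctrl_class.items() if c == "negative"}
        base_mask = np.isin(guide_of_cell, list(neg_guides))
    elif control_group == "others":
        base_mask = None
    else:
        raise ValueError("control_group must be 'others' or 'negative'")

    rows = []
    import warnings as _warnings

    # densify each tested gene's column once (few genes, many guides)
    tested_genes = set()
    for ls in design.loci.values():
        tested_genes.add(ls.target_gene)
        if include_adjacent:
            tested_genes.update(ls.adjacent_genes)
    y_cache = {
        gene: np.asarray(x[:, gene_index[gene]].todense()).ravel()
        for gene in tested_genes
        if gene in gene_index
    }

    for locus, ls in design.loci.items():
        genes = [("target", ls.target_gene)]
        if include_adjacent:
            genes += [("adjacent", a) for a in ls.adjacent_genes]
        for gid in ls.candidate_guide_ids:
            in_group = guide_of_cell == gid
            if not in_group.any():
                _warnings.warn(f"guide {gid} absent from assignment; skipped")
                continue
            if base_mask is None:
                mask = np.ones(len(cells), dtype=bool)
            else:
                mask = in_group | base_mask
            for role, gene in genes:
                row = {
                    "guide_id": gid, "snp_id": snp_of.get(gid), "gene": gene,
                    "locus": locus, "role": role, "alpha_adj": alpha_adj,
                }
                if gene not in gene_index:
                    row.update(
                        n1=int(in_group.sum()), n0=int(mask.sum() - in_group.sum()),
                        beta=np.nan, se=np.nan, t=np.nan, df=np.nan, p=np.nan,
                        significant=False, testable=False,
                    )
                    rows.append(row)
                    continue
                y = y_cache[gene][mask]
                gvec = in_group[mask].astype(float)
                try:
                    res = test_guide_gene(y, gvec)
                except InsufficientCellsError:
                    row.update(
                        n1=int(gvec.sum()), n0=int(len(gvec) - gvec.sum()),
                        beta=np.nan, se=np.nan, t=np.nan, df=np.nan, p=np.nan,
                        significant=False, testable=False,
                    )
                    rows.append(row)
                    continue
                row.update(res)
                row["significant"] = bool(res["p"] < alpha_adj)
                row["testable"] = True
                rows.append(row)

    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return out.sort_values(["locus", "p"], kind="mergesort").reset_index(drop=True)


def replicate_concordance(res_a: pd.DataFrame, res_b: pd.DataFrame) -> dict:
    """Hits significant in both replicates, plus single-replicate nominals.

    Tables must come from the same design (same guide/gene/role test set).
    Returns ``{"hits": ..., "single_replicate": ...}`` DataFrames keyed by
    (guide_id, gene, role) with per-replicate p-values.
    """
    key = ["guide_id", "gene", "role"]
    a = res_a.set_index(key)
    b = res_b.set_index(key)
    if set(a.index) != set(b.index):
        raise ValueError("result tables test different (guide, gene, role) sets")
    merged = a[["p", "significant", "alpha_adj"]].join(
        b[["p", "significant"]], lsuffix="_rep1", rsuffix="_rep2"
    )
    both = merged["significant_rep1"] & merged["significant_rep2"]
    one = merged["significant_rep1"] ^ merged["significant_rep2"]
    return {
        "hits": merged[both].reset_index(),
        "single_replicate": merged[one].reset_index(),
    }
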