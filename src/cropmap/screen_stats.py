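"""Screen-level statistics: guide representation, power, effect-size algebra.

Covers RNA-vs-DNA guide representation with an exact binomial depletion
test, conversion between an editing-induced expression shift (in SD units)
and the variance explained by an equivalent eQTL, two-sample t-test power
from the noncentral t distribution, relative qPCR quantification
(2^-ddCt), and annotation of SNPs against chromatin-accessibility peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree

from ._util import ParseError
from .guide_design import SnpTarget


# ---------------------------------------------------------------------------
# guide representation (RNA cells vs DNA plasmid reads)

def representation_table(dna_counts: pd.Series, rna_cells: pd.Series) -> pd.DataFrame:
    """Per-guide DNA/RNA fractions and their log2 ratio.

    ``log2_ratio`` is NaN (flagged in ``ratio_defined``) when either count
    is zero, never +/-inf. Guide sets must match.
    """
    if set(dna_counts.index) != set(rna_cells.index):
        raise ValueError("DNA and RNA tables cover different guide sets")
    rna_cells = rna_cells.reindex(dna_counts.index)
    if dna_counts.sum() <= 0 or rna_cells.sum() <= 0:
        raise ValueError("totals must be positive")
    df = pd.DataFrame(
        {
            "dna_count": dna_counts.astype(float),
            "rna_cells": rna_cells.astype(float),
        }
    )
    df["dna_frac"] = df["dna_count"] / df["dna_count"].sum()
    df["rna_frac"] = df["rna_cells"] / df["rna_cells"].sum()
    defined = (df["dna_frac"] > 0) & (df["rna_frac"] > 0)
    df["ratio_defined"] = defined
    df["log2_ratio"] = np.where(
        defined, np.log2(df["rna_frac"].where(defined) / df["dna_frac"].where(defined)), np.nan
    )
    df.index.name = "guide_id"
    return df


def depletion_test(
    table: pd.DataFrame, alpha: float = 0.05, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Exact two-sided binomial test of RNA representation against DNA share.

    Each guide's assigned-cell count is tested against
    Binomial(total cells, dna_frac); guides under-represented in RNA
    relative to the plasmid pool (essential-gene positive controls) are
    the expected signal. Bonferroni over guides by default.
    """
    total = int(table["rna_cells"].sum())
    n_tests = len(table)
    thr = alpha / n_tests if correction == "bonferroni" else alpha
    out = table.copy()
    pvals, anomaly = [], []
    for gid, row in table.iterrows():
        if row["dna_frac"] == 0:
            pvals.append(np.nan)
            anomaly.append(row["rna_cells"] > 0)
            continue
        anomaly.append(False)
        res = scipy.stats.binomtest(
            int(row["rna_cells"]), total, row["dna_frac"], alternative="two-sided"
        )
        pvals.append(res.pvalue)
    out["p"] = pvals
    out["anomaly"] = anomaly
    out["depleted"] = (out["p"] < thr) & (out["rna_frac"] < out["dna_frac"])
    out["called"] = out["p"] < thr
    out.attrs["alpha_adj"] = thr
    return out


# ---------------------------------------------------------------------------
# effect size and power

def pve_from_shift(delta_sd: float, allele_freq: float, mode: str = "biallelic") -> float:
    """Variance explained by an eQTL equivalent to an editing-induced shift.

    Under the standard additive model with unit phenotype variance, a
    variant with per-allele effect beta at frequency p explains
    2p(1-p) beta^2 of the variance. Biallelic disruption of both alleles
    shifts expression by 2*beta, so beta = delta/2; monoallelic disruption
    maps the full shift onto one allele, beta = delta.
    """
    if delta_sd < 0:
        raise ValueError("delta_sd must be >= 0")
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must be in (0, 1)")
    if mode == "monoallelic":
        beta = delta_sd
    elif mode == "biallelic":
        beta = delta_sd / 2.0
    else:
        raise ValueError("mode must be 'monoallelic' or 'biallelic'")
    return 2.0 * allele_freq * (1.0 - allele_freq) * beta**2


def power_two_group(n1: int, n0: int, delta_sd: float, alpha: float = 0.05) -> float:
    """Power of the two-sided pooled two-sample t-test.

    ``delta_sd`` is the true group-mean difference in SD units; the
    noncentrality parameter is delta * sqrt(n1*n0/(n1+n0)) with
    n1+n0-2 degrees of freedom.
    """
    if n1 < 2 or n0 < 2:
        raise ValueError("need n1, n0 >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n0 - 2
    ncp = delta_sd * np.sqrt(n1 * n0 / (n1 + n0))
    tcrit = scipy.stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        scipy.stats.nct.sf(tcrit, df, ncp) + scipy.stats.nct.cdf(-tcrit, df, ncp)
    )


# ---------------------------------------------------------------------------
# qPCR relative quantification

@dataclass(frozen=True)
class DdctInput:
    """Cycle thresholds for one sample: target gene, reference genes, and
    the dCt values of the negative-control samples."""

    ct_target: float
    ct_refs: Sequence[float]
    control_dcts: Sequence[float]

    def __post_init__(self):
        if len(self.ct_refs) == 0:
            raise ValueError("need at least one reference gene Ct")
        if len(self.control_dcts) == 0:
            raise ValueError("need at least one control dCt")


def fold_change_ddct(x: DdctInput) -> float:
    """Relative expression by 2^-ddCt.

    dCt = Ct_target - mean(Ct_refs); ddCt = dCt - mean(control dCts);
    fold change = 2^-ddCt. Reference genes are averaged arithmetically.
    """
    dct = x.ct_target - float(np.mean(x.ct_refs))
    ddct = dct - float(np.mean(x.control_dcts))
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# chromatin-accessibility peak overlap

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file (0-based half-open intervals)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer interval") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start")
            rows.append({"chrom": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def annotate_peak_overlap(
    snps: Iterable[SnpTarget] | pd.DataFrame, peaks: pd.DataFrame | str | Path
) -> pd.DataFrame:
    """Flag each SNP whose 1-based position falls inside any peak.

    Peaks are 0-based half-open, so a SNP at 1-based pos overlaps interval
    [start, end) iff start <= pos-1 < end. Accepts SnpTargets or a frame
    with snp_id/chrom/pos; peaks as a frame or BED path.
    """
    if not isinstance(peaks, pd.DataFrame):
        peaks = read_bed(peaks)
    trees: dict[str, IntervalTree] = {}
    for row in peaks.itertuples(index=False):
        if row.end > row.start:  # zero-length intervals cover nothing
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    if isinstance(snps, pd.DataFrame):
        records = [(r.snp_id, r.chrom, int(r.pos)) for r in snps.itertuples(index=False)]
    else:
        records = [(s.snp_id, s.chrom, s.pos) for s in snps]
    rows = []
    for snp_id, chrom, pos in records:
        tree = trees.get(chrom)
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": pos,
                "in_peak": bool(tree is not None and tree.overlaps_point(pos - 1)),
            }
        )
    return pd.DataFrame(rows)
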