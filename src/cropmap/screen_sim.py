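"""Synthetic expression CROP-seq screens.

Generates pooled single-cell CRISPR screens end to end: zero-truncated
Poisson guide uptake (puromycin selection removes unguided cells), per-guide
detection dropout, per-cell editing outcomes (edited / single- vs bi-allelic
/ SNP-disrupting), negative-binomial gene UMI counts with injected
cis-regulatory effects on designated causal guides, mitochondrial
pseudo-genes, guide-feature UMIs, and a plasmid-pool DNA read table. Output
is a 10x-style MatrixMarket trio plus ground-truth tables, so every
downstream module is testable without external data.

The default library mirrors a 67-guide screen: 57 candidate eSNPs across
three loci (CISD1 20, PARK7 19, DAP 18) plus 10 controls (5 positive
essential-gene, 3 negative non-targeting, 2 other non-SNP controls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.optimize
import scipy.sparse as sp
import scipy.stats

from ._util import write_tsv
from .guide_design import GuideRecord

GENE_TYPE = "Gene Expression"
GUIDE_TYPE = "Guide"

#: locus -> (n candidate guides, target chromosome, adjacent genes tested)
DEFAULT_LOCI: dict[str, tuple[int, str, tuple[str, ...]]] = {
    "CISD1": (20, "chr10", ("IPMK", "UBE2D1")),
    "PARK7": (19, "chr1", ("ERRFI1",)),
    "DAP": (18, "chr5", ("ANKRD33B",)),
}

#: default causal guides: guide_id -> multiplier on SimParams.effect_sd.
#: One CISD1 eSNP at the nominal effect and one PARK7 eSNP at three times
#: the effect, mirroring a screen where one locus shows a far larger shift.
DEFAULT_CAUSAL = {"CISD1_snp07": 1.0, "PARK7_snp03": 3.0}

_MT_GENES = [f"MT-{n}" for n in (
    "ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND4L", "ND4",
    "ND5", "ND6", "CYB",
)]


@dataclass
class LocusSpec:
    target_gene: str
    adjacent_genes: tuple[str, ...]
    candidate_guide_ids: tuple[str, ...]


@dataclass
class ScreenDesign:
    """Guide library with per-guide target gene, locus, and control class."""

    guides: list[GuideRecord]
    loci: dict[str, LocusSpec]
    causal_effects: dict[str, float] = field(default_factory=dict)

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def n_candidates(self) -> int:
        return sum(1 for g in self.guides if g.control_class == "candidate")

    @property
    def n_controls(self) -> int:
        return sum(1 for g in self.guides if g.control_class != "candidate")

    def control_class_of(self) -> dict[str, str]:
        return {g.guide_id: g.control_class for g in self.guides}

    def target_gene_of(self) -> dict[str, str]:
        """Candidate guide -> its locus target gene."""
        out = {}
        for locus, ls in self.loci.items():
            for gid in ls.candidate_guide_ids:
                out[gid] = ls.target_gene
        return out

    def locus_of(self) -> dict[str, str]:
        out = {}
        for locus, ls in self.loci.items():
            for gid in ls.candidate_guide_ids:
                out[gid] = locus
        return out


def _random_protospacer(rng: np.random.Generator, length: int = 19) -> str:
    while True:
        proto = "".join(rng.choice(list("ACGT"), size=length))
        gc = (proto.count("G") + proto.count("C")) / length
        if 0.40 <= gc <= 0.80:
            return proto


def default_screen_design(seed: int = 0) -> ScreenDesign:
    """The 67-guide fixture: 57 candidates over three loci plus 10 controls.

    Candidate SNP coordinates are synthetic (evenly spread in a credible
    interval per locus); protospacers are random GC-compliant 19-mers,
    deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    guides: list[GuideRecord] = []
    loci: dict[str, LocusSpec] = {}
    for locus, (n_cand, chrom, adjacent) in DEFAULT_LOCI.items():
        ids = []
        base = int(rng.integers(1_000_000, 50_000_000))
        for i in range(n_cand):
            gid = f"{locus}_snp{i + 1:02d}"
            pos = base + 800 * i + int(rng.integers(0, 400))
            offset = int(rng.integers(-8, 9))  # cut lands within ~8 bp of SNP
            guides.append(
                GuideRecord(
                    guide_id=gid,
                    protospacer=_random_protospacer(rng),
                    pam="".join(rng.choice(list("ACGT"))) + "GG",
                    strand="+" if rng.random() < 0.5 else "-",
                    cut_pos=pos + offset,
                    snp_distance=abs(offset),
                    genome_matches=1,
                    control_class="candidate",
                    snp_id=f"rs{locus.lower()}{i + 1:04d}",
                    locus=locus,
                    chrom=chrom,
                )
            )
            ids.append(gid)
        loci[locus] = LocusSpec(
            target_gene=locus, adjacent_genes=adjacent, candidate_guide_ids=tuple(ids)
        )

    def _control(gid, cls, gene=None):
        guides.append(
            GuideRecord(
                guide_id=gid,
                protospacer=_random_protospacer(rng),
                pam="".join(rng.choice(list("ACGT"))) + "GG",
                strand="+",
                cut_pos=int(rng.integers(1_000_000, 50_000_000)),
                genome_matches=1 if cls != "negative" else 0,
                control_class=cls,
                locus=gene,
            )
        )

    for i in range(3):
        _control(f"pos_TUBB_{i + 1}", "positive", "TUBB")
    for i in range(2):
        _control(f"pos_RUNX1_{i + 1}", "positive", "RUNX1")
    for i in range(3):
        _control(f"neg_ctrl_{i + 1}", "negative")
    for i in range(2):
        _control(f"nonsnp_ctrl_{i + 1}", "non_snp")

    return ScreenDesign(guides=guides, loci=loci, causal_effects=dict(DEFAULT_CAUSAL))


@dataclass
class SimParams:
    """Study conditions for a simulated screen.

    Editing-outcome defaults mirror deep characterization of edited clones:
    92% of guided cells carry at least one edited allele, 29% of edited
    cells have exactly one edited allele, and 67% of edits disrupt the
    target SNP (mutation within 3 bp). ``effect_sd`` is the cis shift, in
    SD units of normalized log2 expression, induced in SNP-disrupted cells
    of a causal guide (scaled per guide by ``ScreenDesign.causal_effects``).
    """

    n_cells: int = 8000
    moi: float = 0.5
    guide_probs: np.ndarray | None = None  # default uniform over guides
    p_edit: float = 0.92
    p_single_allele: float = 0.29
    p_disrupt: float = 0.67
    effect_sd: float = 0.5
    baseline_means: pd.Series | None = None  # mean UMI per gene at reference depth
    dispersion: float = 10.0  # NB inverse-dispersion r; var = mu + mu^2/r
    libsize_range: tuple[float, float] = (2000.0, 7000.0)
    mito_fraction_mean: float = 0.08
    guide_umi_mean: float = 4.0
    detect_dropout: float = 0.05
    essential_survival: float = 1.0  # survival prob. of positive-control cells
    plasmid_reads: int = 500_000
    n_background_genes: int = 250
    seed: int = 0

    def __post_init__(self):
        for name in ("p_edit", "p_single_allele", "p_disrupt", "detect_dropout",
                     "essential_survival", "mito_fraction_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.moi <= 0:
            raise ValueError("moi must be positive")
        if self.guide_umi_mean < 1:
            raise ValueError("guide_umi_mean must be >= 1")
        if self.guide_probs is not None:
            p = np.asarray(self.guide_probs, dtype=float)
            if not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("guide_probs must sum to 1")


@dataclass
class SimulatedScreen:
    """A simulated screen plus its ground truth.

    ``adata`` is cells x features (genes then guides; ``var['feature_type']``
    distinguishes them). ``cell_truth`` holds per-cell integration and
    editing truth; ``plasmid_counts`` the per-guide DNA pool reads;
    ``n_zero_preselection`` the number of zero-integration cells removed by
    selection (for MOI recovery).
    """

    adata: ad.AnnData
    cell_truth: pd.DataFrame
    plasmid_counts: pd.Series
    n_zero_preselection: int
    design: ScreenDesign
    params: SimParams


def default_gene_panel(
    design: ScreenDesign, params: SimParams, seed: int = 0
) -> pd.Series:
    """Per-gene mean UMI at the reference library size.

    Target and adjacent genes get fixed moderate means, essential genes high
    means, 13 mitochondrial pseudo-genes share ``mito_fraction_mean`` of the
    total, and background genes draw log-normal means. The series is scaled
    so means sum to the geometric mean of ``libsize_range``.
    """
    rng = np.random.default_rng(seed)
    t0 = math.sqrt(params.libsize_range[0] * params.libsize_range[1])
    fixed = {
        "CISD1": 12.0, "PARK7": 15.0, "DAP": 8.0,
        "IPMK": 5.0, "UBE2D1": 6.0, "ERRFI1": 4.0, "ANKRD33B": 3.0,
        "TUBB": 40.0, "RUNX1": 20.0,
    }
    # make sure every design target/adjacent gene is present
    for ls in design.loci.values():
        fixed.setdefault(ls.target_gene, 10.0)
        for g in ls.adjacent_genes:
            fixed.setdefault(g, 5.0)
    n_bg = params.n_background_genes
    bg_names = [f"GENE{i + 1:04d}" for i in range(n_bg)]
    bg_means = np.exp(rng.normal(math.log(8.0), 1.0, size=n_bg))
    means = pd.Series(fixed, dtype=float)
    means = pd.concat([means, pd.Series(bg_means, index=bg_names)])
    # mito block takes mito_fraction_mean of the total; rest rescaled
    mito_total = params.mito_fraction_mean * t0
    non_mito_total = t0 - mito_total
    means *= non_mito_total / means.sum()
    mt_weights = rng.dirichlet(np.full(len(_MT_GENES), 20.0)) * mito_total
    means = pd.concat([means, pd.Series(mt_weights, index=_MT_GENES)])
    return means


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws via inverse CDF."""
    p0 = math.exp(-lam)
    u = p0 + rng.random(size) * (1.0 - p0)
    return scipy.stats.poisson.ppf(u, lam).astype(np.int64)


def calibrate_effect_factor(
    mean_umi: float,
    dispersion: float,
    libsize: float,
    scale_factor: float,
    effect_sd: float,
    gene_total: float | None = None,
) -> float:
    """Multiplicative NB-mean factor producing a given shift in normalized log2 units.

    Finds f in (0, 1] such that the expected normalized log2 expression of a
    gene with mean ``f * mean_umi`` sits ``effect_sd`` baseline standard
    deviations below the baseline expectation, where values are
    log2(1 + scale_factor * x / libsize) under NB(mean, r). Raises
    ``ValueError`` when the requested shift exceeds what a factor in (0, 1]
    can produce (infeasible calibration).
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if effect_sd == 0:
        return 1.0
    r = dispersion
    sf = scale_factor

    def moments(mu):
        sd = math.sqrt(mu + mu * mu / r)
        kmax = int(mu + 12 * sd) + 5
        k = np.arange(kmax + 1)
        pmf = scipy.stats.nbinom.pmf(k, r, r / (r + mu))
        v = np.log2(1.0 + sf * k / libsize)
        m = float(np.sum(pmf * v))
        s = math.sqrt(max(float(np.sum(pmf * (v - m) ** 2)), 1e-30))
        return m, s

    m0, s0 = moments(mean_umi)
    target = m0 - effect_sd * s0
    if target <= 0:
        raise ValueError(
            f"infeasible calibration: shift of {effect_sd} SD drives expected "
            "normalized expression below zero"
        )

    def gap(f):
        return moments(f * mean_umi)[0] - target

    return float(scipy.optimize.brentq(gap, 1e-6, 1.0, xtol=1e-6))


def _sample_guides(
    rng: np.random.Generator, k_per_cell: np.ndarray, probs: np.ndarray
) -> list[np.ndarray]:
    """Weighted sampling without replacement per cell (Gumbel-top-k)."""
    n, g = len(k_per_cell), len(probs)
    keys = np.log(probs)[None, :] + rng.gumbel(size=(n, g))
    kmax = int(k_per_cell.max())
    order = np.argsort(-keys, axis=1)[:, :kmax]
    return [order[i, : k_per_cell[i]] for i in range(n)]


def _barcode(i: int) -> str:
    """Deterministic 16-mer cell barcode from the cell index."""
    bases = "ACGT"
    s = []
    for _ in range(16):
        s.append(bases[i % 4])
        i //= 4
    return "".join(reversed(s)) + "-1"


def simulate_screen(design: ScreenDesign, params: SimParams | None = None) -> SimulatedScreen:
    """Simulate one screen under the given design and study conditions.

    Identical ``params.seed`` yields byte-identical output. See the module
    docstring for the generative model.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    n_guides = len(design.guides)
    guide_ids = design.guide_ids
    probs = (
        np.full(n_guides, 1.0 / n_guides)
        if params.guide_probs is None
        else np.asarray(params.guide_probs, dtype=float)
    )
    if len(probs) != n_guides:
        raise ValueError("guide_probs length does not match design")

    # --- uptake: zero-truncated Poisson integrations; record pre-selection zeros
    n_cells = params.n_cells
    p_nonzero = 1.0 - math.exp(-params.moi)
    n_zero_pre = int(rng.negative_binomial(n_cells, p_nonzero))
    k_int = _zt_poisson(rng, params.moi, n_cells)
    cell_guides = _sample_guides(rng, k_int, probs)

    ctrl_class = design.control_class_of()
    targeting = np.array([ctrl_class[g] != "negative" for g in guide_ids])
    positive = np.array([ctrl_class[g] == "positive" for g in guide_ids])

    # --- essential-gene selection: cells carrying positive controls may die
    if params.essential_survival < 1.0:
        carries_pos = np.array([positive[idx].any() for idx in cell_guides])
        survive = ~carries_pos | (rng.random(n_cells) < params.essential_survival)
        k_int = k_int[survive]
        cell_guides = [cg for cg, s in zip(cell_guides, survive) if s]
        n_cells = len(cell_guides)

    # flatten (cell, guide) integration pairs, ordered by cell then draw order
    k_int = np.asarray(k_int)
    flat_cells = np.repeat(np.arange(n_cells), k_int)
    flat_guides = (
        np.concatenate(cell_guides) if n_cells else np.array([], dtype=np.int64)
    )

    # --- editing truth for the primary (first-drawn) targeting guide
    target_gene = design.target_gene_of()
    primary = np.full(n_cells, -1, dtype=np.int64)
    t_mask = targeting[flat_guides]
    t_pos = np.flatnonzero(t_mask)
    t_cells, first_idx = np.unique(flat_cells[t_pos], return_index=True)
    primary[t_cells] = flat_guides[t_pos[first_idx]]
    has_target = primary >= 0
    edited = has_target & (rng.random(n_cells) < params.p_edit)
    single = rng.random(n_cells) < params.p_single_allele
    n_alleles = np.where(edited, np.where(single, 1, 2), 0)
    disrupted = edited & (rng.random(n_cells) < params.p_disrupt)

    # --- gene expression
    means = (
        params.baseline_means
        if params.baseline_means is not None
        else default_gene_panel(design, params, seed=params.seed)
    )
    gene_names = list(means.index)
    w = means.to_numpy(dtype=float)
    t0 = w.sum()
    lo, hi = params.libsize_range
    center = math.sqrt(lo * hi)
    # per-cell target depth: log-normal concentrated inside libsize_range
    depth = np.exp(rng.normal(math.log(center), 0.17, size=n_cells))
    mu = np.outer(depth / t0, w)

    # causal effects: scale the target gene's mean in disrupted causal cells
    scale_factor = 10_000.0
    gene_index = {g: j for j, g in enumerate(gene_names)}
    for gid, mult in design.causal_effects.items():
        if gid not in target_gene:
            continue
        gene = target_gene[gid]
        gidx = guide_ids.index(gid)
        factor = calibrate_effect_factor(
            float(means[gene]), params.dispersion, center, scale_factor,
            params.effect_sd * mult,
        )
        affected = disrupted & (primary == gidx)
        mu[affected, gene_index[gene]] *= factor

    r = params.dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    gene_counts = rng.poisson(lam).astype(np.int64)

    # --- guide UMIs: detection dropout per integrated guide, then >=1 UMIs
    det_mask = rng.random(flat_guides.size) >= params.detect_dropout
    det_cells = flat_cells[det_mask]
    det_guides = flat_guides[det_mask]
    umis = 1 + rng.poisson(params.guide_umi_mean - 1.0, size=det_guides.size)
    guide_mat = sp.coo_matrix(
        (umis, (det_cells, det_guides)), shape=(n_cells, n_guides), dtype=np.int64
    ).tocsr()
    n_detected = np.bincount(det_cells, minlength=n_cells)
    detected_sets = np.split(det_guides, np.cumsum(n_detected)[:-1])

    # --- assemble AnnData (genes then guides)
    x = sp.hstack([sp.csr_matrix(gene_counts), guide_mat], format="csr")
    var = pd.DataFrame(
        {
            "name": gene_names + guide_ids,
            "feature_type": [GENE_TYPE] * len(gene_names) + [GUIDE_TYPE] * n_guides,
        },
        index=gene_names + guide_ids,
    )
    barcodes = [_barcode(i) for i in range(n_cells)]
    adata = ad.AnnData(X=x, obs=pd.DataFrame(index=barcodes), var=var)

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "n_integrations": k_int,
            "guides": [";".join(guide_ids[j] for j in idx) for idx in cell_guides],
            "detected_guides": [
                ";".join(guide_ids[j] for j in det) for det in detected_sets
            ],
            "n_detected": n_detected,
            "primary_guide": [guide_ids[p] if p >= 0 else "" for p in primary],
            "targeting": has_target,
            "edited": edited,
            "n_alleles_edited": n_alleles,
            "disrupted": disrupted,
        }
    )

    plasmid = pd.Series(
        rng.multinomial(params.plasmid_reads, probs), index=guide_ids, name="dna_reads"
    )
    return SimulatedScreen(
        adata=adata,
        cell_truth=truth,
        plasmid_counts=plasmid,
        n_zero_preselection=n_zero_pre,
        design=design,
        params=params,
    )


# ---------------------------------------------------------------------------
# 10x-style MatrixMarket I/O

def write_10x_like(sim: SimulatedScreen | ad.AnnData, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx / features.tsv / barcodes.tsv (plus truth tables).

    The matrix is written features x cells in integer coordinate format, the
    dialect emitted by 10x-style counters. For a ``SimulatedScreen``, the
    truth table, plasmid counts, and design are written alongside.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata = sim.adata if isinstance(sim, SimulatedScreen) else sim
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    mat = sp.coo_matrix(adata.X.T.astype(np.int64))
    scipy.io.mmwrite(str(paths["matrix"]), mat, field="integer")
    feats = pd.DataFrame(
        {
            "id": adata.var_names,
            "name": adata.var["name"] if "name" in adata.var else adata.var_names,
            "type": adata.var["feature_type"],
        }
    )
    feats.to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    if isinstance(sim, SimulatedScreen):
        paths["cell_truth"] = out / "cell_truth.tsv"
        write_tsv(sim.cell_truth, paths["cell_truth"], seed=sim.params.seed)
        paths["plasmid_counts"] = out / "plasmid_counts.tsv"
        write_tsv(
            sim.plasmid_counts.rename_axis("guide_id").reset_index(),
            paths["plasmid_counts"],
            seed=sim.params.seed,
        )
        paths["design"] = out / "design.tsv"
        write_design(sim.design, paths["design"])
        (out / "moi_preselection.txt").write_text(
            f"{sim.n_zero_preselection}\t{len(sim.adata)}\n"
        )
    return paths


def read_10x_like(in_dir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx / features.tsv / barcodes.tsv trio into AnnData."""
    d = Path(in_dir)
    mat = scipy.io.mmread(str(d / "matrix.mtx")).T.tocsr()
    feats = pd.read_csv(
        d / "features.tsv", sep="\t", header=None, names=["id", "name", "type"]
    )
    try:
        barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        barcodes = pd.Series([], dtype=str)
    var = pd.DataFrame(
        {"name": feats["name"].values, "feature_type": feats["type"].values},
        index=feats["id"].astype(str).values,
    )
    return ad.AnnData(X=mat, obs=pd.DataFrame(index=barcodes.values), var=var)


# ---------------------------------------------------------------------------
# design table I/O (round-trips ScreenDesign through TSV)

def write_design(design: ScreenDesign, path: str | Path) -> None:
    locus_of = design.locus_of()
    target = design.target_gene_of()
    rows = []
    for g in design.guides:
        locus = locus_of.get(g.guide_id, g.locus)
        adjacent = ""
        if locus in design.loci:
            adjacent = ";".join(design.loci[locus].adjacent_genes)
        rows.append(
            {
                "guide_id": g.guide_id,
                "snp_id": g.snp_id or "",
                "locus": locus or "",
                "chrom": g.chrom or "",
                "protospacer": g.protospacer,
                "pam": g.pam,
                "strand": g.strand,
                "cut_pos": g.cut_pos,
                "control_class": g.control_class,
                "target_gene": target.get(g.guide_id, ""),
                "adjacent_genes": adjacent if g.control_class == "candidate" else "",
                "causal_multiplier": design.causal_effects.get(g.guide_id, 0.0),
            }
        )
    write_tsv(pd.DataFrame(rows), path)


def read_design(path: str | Path) -> ScreenDesign:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    guides, loci_acc, causal = [], {}, {}
    for row in df.itertuples(index=False):
        guides.append(
            GuideRecord(
                guide_id=row.guide_id,
                protospacer=row.protospacer,
                pam=row.pam,
                strand=row.strand,
                cut_pos=int(row.cut_pos),
                control_class=row.control_class,
                snp_id=row.snp_id or None,
                locus=row.locus or None,
                chrom=row.chrom or None,
            )
        )
        if row.control_class == "candidate":
            entry = loci_acc.setdefault(
                row.locus,
                {"target_gene": row.target_gene, "adjacent": row.adjacent_genes, "ids": []},
            )
            entry["ids"].append(row.guide_id)
        if float(row.causal_multiplier) > 0:
            causal[row.guide_id] = float(row.causal_multiplier)
    loci = {
        name: LocusSpec(
            target_gene=e["target_gene"],
            adjacent_genes=tuple(a for a in e["adjacent"].split(";") if a),
            candidate_guide_ids=tuple(e["ids"]),
        )
        for name, e in loci_acc.items()
    }
    return ScreenDesign(guides=guides, loci=loci, causal_effects=causal)
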