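"""SNP-targeted SpCas9 guide design.

Enumerates every protospacer adjacent to an NGG PAM inside the flanking
window of a candidate eSNP (both strands), annotates GC content, blunt-cut
coordinate and cut-to-SNP distance, counts perfect genomic matches, and
selects one guide per SNP: GC within bounds, unique in the reference, and
minimal cut-to-SNP distance.

Coordinates are 1-based inclusive externally (dbSNP convention); the scan
uses 0-based offsets internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from ._util import ParseError, gc_fraction, revcomp, validate_dna, write_tsv

log = logging.getLogger(__name__)

CONTROL_CLASSES = ("candidate", "positive", "negative", "non_snp")


class EmptyWindowError(ValueError):
    """Flanking window too short to hold a protospacer plus PAM."""


@dataclass(frozen=True)
class SnpTarget:
    """A candidate eSNP with its genomic coordinate and flanking sequence.

    ``pos`` is the 1-based coordinate of the variant; ``flank_start`` is the
    1-based coordinate of ``flank[0]``. ``locus`` is the target eGene symbol.
    """

    snp_id: str
    chrom: str
    pos: int
    flank: str
    flank_start: int
    locus: str

    def __post_init__(self):
        validate_dna(self.flank)
        if not (self.flank_start <= self.pos <= self.flank_start + len(self.flank) - 1):
            raise ValueError(
                f"{self.snp_id}: pos {self.pos} outside flank "
                f"[{self.flank_start}, {self.flank_start + len(self.flank) - 1}]"
            )


@dataclass
class GuideRecord:
    """A protospacer+PAM with strand, cut site, filter annotations.

    ``cut_pos`` is the 1-based genomic coordinate of the protospacer base
    immediately 3' of the blunt Cas9 cut (3 bp 5' of the PAM on the
    protospacer strand). ``control_class`` distinguishes candidate-eSNP
    guides from positive (essential gene), negative (non-targeting), and
    non-SNP-targeting controls.
    """

    guide_id: str
    protospacer: str
    pam: str
    strand: str
    cut_pos: int
    snp_distance: int | None = None
    gc: float | None = None
    genome_matches: int | None = None
    control_class: str = "candidate"
    snp_id: str | None = None
    locus: str | None = None
    chrom: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.control_class not in CONTROL_CLASSES:
            raise ValueError(f"unknown control_class {self.control_class!r}")
        if self.gc is None:
            self.gc = gc_fraction(self.protospacer)


@dataclass(frozen=True)
class DesignParams:
    """Guide-design rules.

    Defaults follow standard SpCas9 screen practice: 19-nt protospacers,
    GC kept within [0.40, 0.80], cut-to-SNP distance typically <10 bases,
    and a single perfect genomic match required.
    """

    protospacer_len: int = 19
    gc_min: float = 0.40
    gc_max: float = 0.80
    max_snp_distance: int = 10  # descriptive guideline, not a hard filter
    require_unique: bool = True

    def __post_init__(self):
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.protospacer_len < 17:
            raise ValueError("protospacer_len must be >= 17")


def cut_position(pam_start: int, strand: str) -> int:
    """1-based genomic coordinate of the base 3' of the blunt cut.

    SpCas9 cuts bluntly 3 bp 5' of the PAM. ``pam_start`` is the genomic
    coordinate of the PAM base closest to the protospacer (the N of NGG) on
    the plus strand for ``strand == '+'``; for minus-strand guides it is the
    plus-strand coordinate of the PAM's N (the rightmost base of the CCN
    motif as read on the plus strand).
    """
    if strand == "+":
        return pam_start - 3
    return pam_start + 3


def scan_protospacers(target: SnpTarget, params: DesignParams | None = None) -> list[GuideRecord]:
    """Enumerate every NGG-adjacent protospacer in the SNP's flank, both strands.

    No GC or distance filtering is applied here; windows containing N are
    skipped. Minus-strand hits carry the reverse-complemented protospacer
    and plus-strand genomic coordinates.
    """
    params = params or DesignParams()
    L = params.protospacer_len
    flank = target.flank.upper()
    validate_dna(flank)
    if len(flank) < L + 3:
        raise EmptyWindowError(
            f"{target.snp_id}: flank of {len(flank)} nt cannot hold a "
            f"{L}-nt protospacer plus 3-nt PAM"
        )

    guides: list[GuideRecord] = []
    n_skipped_n = 0
    # forward strand: protospacer at i..i+L-1, PAM at i+L..i+L+2
    for i in range(len(flank) - (L + 3) + 1):
        window = flank[i : i + L + 3]
        if window[L + 1 : L + 3] != "GG":
            continue
        if "N" in window:
            n_skipped_n += 1
            continue
        pam_start = target.flank_start + i + L
        cut = cut_position(pam_start, "+")
        guides.append(
            GuideRecord(
                guide_id=f"{target.snp_id}_fwd_{i}",
                protospacer=window[:L],
                pam=window[L:],
                strand="+",
                cut_pos=cut,
                snp_distance=abs(cut - target.pos),
                snp_id=target.snp_id,
                locus=target.locus,
                chrom=target.chrom,
            )
        )
    # minus strand: plus-strand motif CCN + protospacer(rc); PAM N at j+2
    for j in range(len(flank) - (L + 3) + 1):
        window = flank[j : j + L + 3]
        if window[0:2] != "CC":
            continue
        if "N" in window:
            n_skipped_n += 1
            continue
        pam_start = target.flank_start + j + 2
        cut = cut_position(pam_start, "-")
        guides.append(
            GuideRecord(
                guide_id=f"{target.snp_id}_rev_{j}",
                protospacer=revcomp(window[3:]),
                pam=revcomp(window[:3]),
                strand="-",
                cut_pos=cut,
                snp_distance=abs(cut - target.pos),
                snp_id=target.snp_id,
                locus=target.locus,
                chrom=target.chrom,
            )
        )
    if n_skipped_n:
        log.info("%s: skipped %d window(s) containing N", target.snp_id, n_skipped_n)
    return guides


def count_genome_matches(
    protospacer: str, reference: Mapping[str, str] | str | Path, strand_aware: bool = True
) -> int:
    """Number of exact protospacer+NGG occurrences on either reference strand.

    The PAM's first base is a wildcard. ``reference`` is a mapping of
    sequence name to sequence, or a FASTA path. Overlapping occurrences are
    counted.
    """
    seqs = load_fasta(reference) if not isinstance(reference, Mapping) else reference
    pat = re.compile("(?=" + re.escape(protospacer.upper()) + ".GG)")
    n = 0
    for seq in seqs.values():
        s = str(seq).upper()
        n += sum(1 for _ in pat.finditer(s))
        n += sum(1 for _ in pat.finditer(revcomp(s)))
    return n


def select_guide(
    candidates: Iterable[GuideRecord],
    target: SnpTarget,
    params: DesignParams | None = None,
) -> GuideRecord | None:
    """Pick the guide with the smallest cut-to-SNP distance among survivors.

    Survivors have GC within [gc_min, gc_max] and (when ``require_unique``)
    exactly one perfect genomic match. Ties on distance break to the
    lexicographically smallest protospacer. Returns ``None`` when no
    candidate survives.
    """
    params = params or DesignParams()
    survivors = []
    for g in candidates:
        if g.gc is None:
            g.gc = gc_fraction(g.protospacer)
        if not (params.gc_min <= g.gc <= params.gc_max):
            continue
        if params.require_unique and g.genome_matches != 1:
            continue
        dist = g.snp_distance
        if dist is None:
            dist = abs(g.cut_pos - target.pos)
            g.snp_distance = dist
        survivors.append(g)
    if not survivors:
        return None
    return min(survivors, key=lambda g: (g.snp_distance, g.protospacer))


def design_guides(
    targets: Iterable[SnpTarget],
    reference: Mapping[str, str] | str | Path | None = None,
    params: DesignParams | None = None,
) -> list[GuideRecord]:
    """One selected guide per SNP target (SNPs with no survivor are skipped)."""
    params = params or DesignParams()
    ref = None
    if reference is not None:
        ref = load_fasta(reference) if not isinstance(reference, Mapping) else reference
    chosen = []
    for t in targets:
        cands = scan_protospacers(t, params)
        if ref is not None:
            for g in cands:
                g.genome_matches = count_genome_matches(g.protospacer, ref)
        elif params.require_unique:
            raise ValueError("require_unique needs a reference genome")
        g = select_guide(cands, t, params)
        if g is not None:
            g.guide_id = t.snp_id
            chosen.append(g)
    return chosen


# ---------------------------------------------------------------------------
# I/O

GUIDE_TABLE_COLUMNS = [
    "guide_id",
    "snp_id",
    "locus",
    "chrom",
    "protospacer",
    "pam",
    "strand",
    "cut_pos",
    "snp_distance",
    "gc",
    "genome_matches",
    "control_class",
]


def load_fasta(path: str | Path) -> dict[str, str]:
    try:
        with open(path) as fh:
            return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    except OSError as exc:
        raise IOError(f"cannot read FASTA {path}: {exc}") from exc


def read_snp_table(
    path: str | Path,
    reference: Mapping[str, str] | str | Path | None = None,
    flank_size: int = 30,
) -> list[SnpTarget]:
    """Read a SNP table (TSV: snp_id, chrom, pos, locus [, flank, flank_start]).

    When ``flank`` is absent, windows of ``±flank_size`` bases are extracted
    from ``reference``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "chrom", "pos", "locus"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    targets = []
    ref = None
    if "flank" not in df.columns:
        if reference is None:
            raise ValueError("SNP table has no flank column and no reference given")
        ref = load_fasta(reference) if not isinstance(reference, Mapping) else reference
    for row in df.itertuples(index=False):
        if ref is not None:
            seq = ref[str(row.chrom)]
            start0 = max(0, int(row.pos) - 1 - flank_size)
            end0 = min(len(seq), int(row.pos) + flank_size)
            flank, flank_start = seq[start0:end0], start0 + 1
        else:
            flank = row.flank
            flank_start = int(getattr(row, "flank_start", int(row.pos) - (len(row.flank) // 2)))
        targets.append(
            SnpTarget(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                flank=str(flank).upper(),
                flank_start=flank_start,
                locus=str(row.locus),
            )
        )
    return targets


def guides_to_frame(guides: Iterable[GuideRecord]) -> pd.DataFrame:
    rows = [
        {
            "guide_id": g.guide_id,
            "snp_id": g.snp_id,
            "locus": g.locus,
            "chrom": g.chrom,
            "protospacer": g.protospacer,
            "pam": g.pam,
            "strand": g.strand,
            "cut_pos": g.cut_pos,
            "snp_distance": g.snp_distance,
            "gc": g.gc,
            "genome_matches": g.genome_matches,
            "control_class": g.control_class,
        }
        for g in guides
    ]
    return pd.DataFrame(rows, columns=GUIDE_TABLE_COLUMNS)


def write_guide_table(guides: Iterable[GuideRecord], path, seed=None) -> None:
    write_tsv(guides_to_frame(guides), path, seed=seed)


def read_guide_table(path) -> list[GuideRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    guides = []
    for row in df.itertuples(index=False):
        guides.append(
            GuideRecord(
                guide_id=str(row.guide_id),
                protospacer=str(row.protospacer),
                pam=str(row.pam),
                strand=str(row.strand),
                cut_pos=int(row.cut_pos),
                snp_distance=None if pd.isna(row.snp_distance) else int(row.snp_distance),
                gc=float(row.gc),
                genome_matches=None if pd.isna(row.genome_matches) else int(row.genome_matches),
                control_class=str(row.control_class),
                snp_id=None if pd.isna(row.snp_id) else str(row.snp_id),
                locus=None if pd.isna(row.locus) else str(row.locus),
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
            )
        )
    return guides
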