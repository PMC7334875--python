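"""Extended-reference construction for guide detection in scRNA-seq.

Each guide in the library becomes one artificial chromosome appended to the
genome FASTA: 241 bp U6 promoter + 8 bp gap + 20 bp guide + 261 bp backbone
(530 bp total), annotated in the companion GTF as a single-exon gene so a
downstream counter attributes guide UMIs to a gene-like feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .guide_design import GuideRecord

U6_LEN, GAP_LEN, GUIDE_LEN, BACKBONE_LEN = 241, 8, 20, 261
CHROM_LEN = U6_LEN + GAP_LEN + GUIDE_LEN + BACKBONE_LEN  # 530


def _synthetic_segment(length: int, seed: int) -> str:
    """Deterministic synthetic DNA segment of the requested length.

    The true U6-promoter and vector-backbone sequences of the guide
    expression construct are not redistributable here, and only the segment
    lengths drive detection geometry, so synthetic stand-ins are used.
    """
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


DEFAULT_U6 = _synthetic_segment(U6_LEN, 2020_03)
DEFAULT_GAP = _synthetic_segment(GAP_LEN, 2020_04)
DEFAULT_BACKBONE = _synthetic_segment(BACKBONE_LEN, 2020_05)


@dataclass(frozen=True)
class ConstructSpec:
    """Segment layout of one artificial guide chromosome (241/8/20/261 bp).

    Default segment contents are synthetic stand-ins for the U6 promoter and
    vector backbone; swap in the real sequences via the fields if available.
    """

    u6_seq: str = DEFAULT_U6
    gap_seq: str = DEFAULT_GAP
    backbone_seq: str = DEFAULT_BACKBONE
    guide_len: int = GUIDE_LEN

    def __post_init__(self):
        for name, seq, want in (
            ("u6_seq", self.u6_seq, U6_LEN),
            ("gap_seq", self.gap_seq, GAP_LEN),
            ("backbone_seq", self.backbone_seq, BACKBONE_LEN),
        ):
            if len(seq) != want:
                raise ValueError(f"{name} must be {want} bp, got {len(seq)}")
        if self.guide_len != GUIDE_LEN:
            raise ValueError(f"guide_len must be {GUIDE_LEN}")


def pad_guide(protospacer: str, guide_len: int = GUIDE_LEN) -> str:
    """Left-pad a protospacer with G to the construct's guide length.

    A 19-nt design protospacer becomes a 20-nt guide by prepending one G
    (the conventional U6 transcription-start G); inputs already at
    ``guide_len`` pass through unchanged.
    """
    if len(protospacer) > guide_len:
        raise ValueError(
            f"protospacer of {len(protospacer)} nt exceeds guide_len {guide_len}"
        )
    return "G" * (guide_len - len(protospacer)) + protospacer


def build_artificial_chromosome(
    guide: GuideRecord, spec: ConstructSpec | None = None
) -> tuple[str, str]:
    """(name, sequence) of the guide's artificial chromosome (530 bp)."""
    spec = spec or ConstructSpec()
    seq = spec.u6_seq + spec.gap_seq + pad_guide(guide.protospacer, spec.guide_len) + spec.backbone_seq
    assert len(seq) == CHROM_LEN
    return guide.guide_id, seq


def _gtf_lines(guide_id: str) -> list[str]:
    attrs = f'gene_id "{guide_id}"; transcript_id "{guide_id}.1"; gene_name "{guide_id}"; gene_biotype "protein_coding";'
    lines = []
    for feature in ("gene", "transcript", "exon"):
        lines.append(
            "\t".join(
                [guide_id, "cropmap", feature, "1", str(CHROM_LEN), ".", "+", ".", attrs]
            )
        )
    return lines


def write_extended_reference(
    genome: Mapping[str, str] | str | Path,
    guides: Iterable[GuideRecord],
    spec: ConstructSpec | None = None,
    out_fasta: str | Path = "extended.fa",
    out_gtf: str | Path = "extended.gtf",
) -> tuple[Path, Path]:
    """Append one artificial chromosome per guide to the genome FASTA.

    Emits a 60-column-wrapped FASTA (genome records first, then guide
    chromosomes) and a GTF with gene/transcript/exon lines spanning
    1..530 on the plus strand for every guide. Guide ids must be unique.
    """
    spec = spec or ConstructSpec()
    guides = list(guides)
    ids = [g.guide_id for g in guides]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate guide_id(s): {dup}")

    if isinstance(genome, Mapping):
        genome_records = [
            SeqRecord(Seq(s), id=name, description="") for name, s in genome.items()
        ]
    else:
        with open(genome) as fh:
            genome_records = [
                SeqRecord(rec.seq, id=rec.id, description="")
                for rec in SeqIO.parse(fh, "fasta")
            ]

    records = list(genome_records)
    gtf_lines: list[str] = []
    for g in guides:
        name, seq = build_artificial_chromosome(g, spec)
        records.append(SeqRecord(Seq(seq), id=name, description=""))
        gtf_lines.extend(_gtf_lines(name))

    out_fasta, out_gtf = Path(out_fasta), Path(out_gtf)
    with open(out_fasta, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # biopython wraps at 60 columns
    with open(out_gtf, "w") as fh:
        for line in gtf_lines:
            fh.write(line + "\n")
    return out_fasta, out_gtf
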