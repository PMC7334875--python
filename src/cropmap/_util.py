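"""Shared helpers: errors, sequence utilities, seeded TSV output."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


class CropmapError(Exception):
    """Base class for package errors."""


class ConfigError(CropmapError):
    """Invalid or incomplete run configuration."""


class ParseError(CropmapError):
    """Malformed input file."""


class InsufficientCellsError(CropmapError):
    """Too few cells in one of the comparison groups to fit the model."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, allow_n: bool = True) -> None:
    allowed = VALID_BASES if allow_n else VALID_BASES - {"N"}
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``.

    Raises ``ValueError`` on an empty string.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence is undefined")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def write_tsv(df: pd.DataFrame, path, seed=None, version: str | None = None) -> None:
    """Write a TSV with a provenance header comment (version, seed)."""
    from . import __version__

    buf = io.StringIO()
    ver = version or __version__
    tag = f"# cropmap {ver}"
    if seed is not None:
        tag += f" seed={seed}"
    buf.write(tag + "\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def child_seed(rng: np.random.Generator) -> int:
    """Derive an independent 31-bit child seed from a generator."""
    return int(rng.integers(0, 2**31 - 1))
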