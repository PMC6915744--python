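"""Sequence windows around CpG sites and compositional statistics.

A window is the fixed-offset genomic sequence centered at a DMS cytosine:
``[start - offset, start + offset)``, clipped at chromosome bounds.  The
default offset of 50 yields 100 nt.  Composition statistics (G+C content and
the observed/expected CpG ratio in the Gardiner-Garden & Frommer form) are
computed per window with N bases excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from pyfaidx import Fasta

from .preprocess import DMSRecord

__all__ = [
    "SequenceWindow",
    "open_genome",
    "fetch_window",
    "fetch_windows",
    "gc_content",
    "cpg_count",
    "cpg_oe_ratio",
    "reverse_complement",
    "windows_to_fasta",
    "windows_to_bed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceWindow:
    """A genome window centered at one DMS, uppercase over {A,C,G,T,N}."""

    site: DMSRecord
    offset: int
    sequence: str
    window_start: int
    window_end: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != len(self.sequence):
            raise ValueError("window coordinates inconsistent with sequence length")
        if not (self.window_start <= self.site.start < self.window_end):
            raise ValueError("site position outside window")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"invalid bases in window sequence: {sorted(bad)}")

    @property
    def center(self) -> int:
        """Window-relative position of the CpG cytosine."""
        return self.site.start - self.window_start

    def __len__(self) -> int:
        return len(self.sequence)


def open_genome(path: str | Path) -> Fasta:
    """Open an indexed FASTA (the .fai sidecar is created if missing)."""
    return Fasta(str(path), sequence_always_upper=False, rebuild=False)


def _clean(seq: str, mask_lowercase: bool) -> str:
    if mask_lowercase:
        seq = "".join("N" if c.islower() else c for c in seq)
    seq = seq.upper()
    return "".join(c if c in _VALID else "N" for c in seq)


def fetch_window(
    genome: Fasta | Mapping[str, str],
    site: DMSRecord,
    offset: int = 50,
    mask_lowercase: bool = False,
) -> SequenceWindow:
    """Fetch the ``[start - offset, start + offset)`` window around a site.

    ``genome`` is an indexed FASTA or a plain chrom -> sequence mapping.
    Windows running off a chromosome end are clipped (flagged); soft-masked
    lowercase bases are uppercased by default, or turned into N when
    ``mask_lowercase`` is set.
    """
    if offset < 1:
        raise ValueError("offset must be a positive integer")
    if isinstance(genome, Fasta):
        names = list(genome.keys())
        if site.chrom not in genome:
            raise KeyError(
                f"chromosome {site.chrom!r} not in genome (available: {names})"
            )
        chrom_len = len(genome[site.chrom])
        lo = max(0, site.start - offset)
        hi = min(chrom_len, site.start + offset)
        raw = str(genome[site.chrom][lo:hi])
    else:
        if site.chrom not in genome:
            raise KeyError(
                f"chromosome {site.chrom!r} not in genome "
                f"(available: {sorted(genome)})"
            )
        chrom_len = len(genome[site.chrom])
        lo = max(0, site.start - offset)
        hi = min(chrom_len, site.start + offset)
        raw = genome[site.chrom][lo:hi]
    if not (0 <= site.start < chrom_len):
        raise ValueError(
            f"site {site.chrom}:{site.start} outside chromosome of length {chrom_len}"
        )
    clipped = (lo != site.start - offset) or (hi != site.start + offset)
    return SequenceWindow(
        site=site,
        offset=offset,
        sequence=_clean(raw, mask_lowercase),
        window_start=lo,
        window_end=hi,
        clipped=clipped,
    )


def fetch_windows(
    genome: Fasta | Mapping[str, str],
    sites: Iterable[DMSRecord],
    offset: int = 50,
    mask_lowercase: bool = False,
) -> list[SequenceWindow]:
    return [fetch_window(genome, s, offset, mask_lowercase) for s in sites]


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); NaN for an empty or all-N sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    if total == 0:
        return float("nan")
    return gc / total


def cpg_count(sequence: str) -> int:
    """Number of CpG dinucleotides (overlap-free by construction)."""
    return sequence.upper().count("CG")


def cpg_oe_ratio(sequence: str) -> float:
    """Observed/expected CpG ratio: (#CpG x L) / (#C x #G), L excluding N.

    Returns NaN when the sequence contains no C or no G.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    c, g = seq.count("C"), seq.count("G")
    if c == 0 or g == 0:
        return float("nan")
    length = len(seq) - seq.count("N")
    return seq.count("CG") * length / (c * g)


def windows_to_fasta(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            name = w.site.site_id or f"{w.site.chrom}:{w.site.start}"
            fh.write(f">{name} {w.site.chrom}:{w.window_start}-{w.window_end}\n")
            fh.write(w.sequence + "\n")


def windows_to_bed(windows: Iterable[SequenceWindow], path: str | Path) -> None:
    """Export windows as BED6 (score = delta-beta when present, else 0)."""
    with open(path, "w") as fh:
        for w in windows:
            name = w.site.site_id or f"{w.site.chrom}:{w.site.start}"
            score = w.site.delta_beta if w.site.delta_beta is not None else 0.0
            fh.write(
                f"{w.site.chrom}\t{w.window_start}\t{w.window_end}\t{name}\t"
                f"{score:.4g}\t+\n"
            )
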