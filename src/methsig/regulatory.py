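"""Cis-regulatory features: PWM motif scans, track overlaps, splice sites.

Transcription-factor binding sites are detected by scanning log-odds
position weight matrices (built from JASPAR-style position frequency
matrices) over each window and keeping placements whose relative score
``(score - min) / (max - min)`` reaches a threshold.  Conserved-TFBS and
alternative-splicing annotations are consumed as BED interval tracks and
counted per overlapping interval.  Tentative donor/acceptor splice sites are
scored with the Shapiro-Senapathy percentile scheme over per-position base
frequency tables (shipped as editable TSV data; donor = 9 positions -3..+6,
acceptor = 15 positions ending in the invariant AG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from intervaltree import IntervalTree

from .preprocess import DMSRecord
from .seqcontext import SequenceWindow, reverse_complement

__all__ = [
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "PwmHit",
    "SpliceSiteModel",
    "SpliceHit",
    "AnnotationTrack",
    "load_jaspar_pfms",
    "pfm_to_pwm",
    "scan_pwm",
    "tfbs_count",
    "restrict_to_regions",
    "count_track_overlaps",
    "ss_score",
    "find_splice_sites",
    "donor_model",
    "acceptor_model",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif position; rows in A, C, G, T order."""

    motif_id: str
    motif_name: str
    counts: np.ndarray  # (4, L)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x L")
        if c.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if (c < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if (c.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.motif_id}: column with no positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds matrix with its achievable score range."""

    motif_id: str
    matrix: np.ndarray  # (4, L)
    max_score: float
    min_score: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PwmHit:
    motif_id: str
    start: int  # window-relative, forward coordinates
    strand: str
    score: float
    rel_score: float


@dataclass(frozen=True)
class SpliceHit:
    site_type: str
    start: int
    strand: str
    score: float


def load_jaspar_pfms(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Parse a JASPAR-format PFM text file (header line, bracketed A/C/G/T rows).

    Row labels in the file determine base assignment, so files listing rows in
    a different order are normalized to A, C, G, T.  A malformed matrix raises
    with the motif id when it can be recovered.
    """
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        try:
            out.append(
                PositionFrequencyMatrix(
                    motif_id=m.matrix_id or m.name,
                    motif_name=m.name or m.matrix_id,
                    counts=counts,
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed matrix {m.matrix_id or m.name!r}: {exc}")
    return out


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.8,
    background: Sequence[float] | None = None,
) -> PositionWeightMatrix:
    """Log2-odds PWM with background-proportional pseudocount allocation.

    Per cell: ``log2(((count_b + pseudocount * bg_b) / (column_total +
    pseudocount)) / bg_b)``.  With a uniform background and all-equal counts
    every cell is 0 (the log-odds of background itself).
    """
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,):
            raise ValueError("background must have 4 entries (A, C, G, T)")
        if (bg <= 0).any():
            raise ValueError("background entries must be positive")
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = pfm.counts
    totals = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    mat = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(
        motif_id=pfm.motif_id,
        matrix=mat,
        max_score=float(mat.max(axis=0).sum()),
        min_score=float(mat.min(axis=0).sum()),
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, -1) for c in seq], dtype=np.int64)


def _sliding_scores(idx: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every placement of a (4, L) score matrix; invalid = has N."""
    L = mat.shape[1]
    n = idx.size
    if n < L:
        return np.empty(0), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = mat[safe, np.arange(L)].sum(axis=1)
    return scores, valid


def scan_pwm(
    window: SequenceWindow | str,
    pwm: PositionWeightMatrix,
    min_rel_score: float = 0.8,
    both_strands: bool = True,
) -> list[PwmHit]:
    """All placements with relative score >= ``min_rel_score``.

    Placements containing N are skipped.  Minus-strand hits are reported at
    their forward-strand start coordinate.
    """
    if not 0 <= min_rel_score <= 1:
        raise ValueError("min_rel_score must lie in [0, 1]")
    seq = window.sequence if isinstance(window, SequenceWindow) else window
    seq = seq.upper()
    n = len(seq)
    L = pwm.length
    span = pwm.max_score - pwm.min_score
    hits: list[PwmHit] = []

    def _collect(s: str, strand: str) -> None:
        scores, valid = _sliding_scores(_encode(s), pwm.matrix)
        for o in np.flatnonzero(valid):
            rel = 1.0 if span == 0 else (scores[o] - pwm.min_score) / span
            if rel >= min_rel_score:
                start = int(o) if strand == "+" else n - int(o) - L
                hits.append(PwmHit(pwm.motif_id, start, strand,
                                   float(scores[o]), float(rel)))

    _collect(seq, "+")
    if both_strands:
        _collect(reverse_complement(seq), "-")
    return sorted(hits, key=lambda h: (h.start, h.strand))


def tfbs_count(
    window: SequenceWindow | str,
    pwms: Iterable[PositionWeightMatrix],
    min_rel_score: float = 0.8,
    both_strands: bool = True,
) -> int:
    """Total PWM hits over a motif set (the signature's TFBS feature)."""
    return sum(
        len(scan_pwm(window, p, min_rel_score, both_strands)) for p in pwms
    )


# ---------------------------------------------------------------------------
# annotation tracks

_TRACK_KINDS = ("conserved_tfbs", "alt_splicing", "promoter", "cpg_island")


@dataclass
class AnnotationTrack:
    """A BED-like interval track (0-based half-open), sorted per chromosome."""

    intervals: pd.DataFrame  # columns chrom, start, end, label
    kind: str
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in _TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}; one of {_TRACK_KINDS}")
        df = self.intervals.copy()
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"track needs column {col!r}")
        if "label" not in df.columns:
            df["label"] = "."
        if (df["start"] >= df["end"]).any():
            raise ValueError("track contains empty or inverted intervals")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        self._trees = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), lab)
                for s, e, lab in zip(sub["start"], sub["end"], sub["label"])
            )

    @classmethod
    def from_bed(cls, path: str | Path, kind: str) -> "AnnotationTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                label = parts[3] if len(parts) > 3 else "."
                rows.append((parts[0], int(parts[1]), int(parts[2]), label))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
        return cls(intervals=df, kind=kind)

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(start, end))

    def __len__(self) -> int:
        return len(self.intervals)


def restrict_to_regions(
    sites: Sequence[DMSRecord], track: AnnotationTrack
) -> list[DMSRecord]:
    """Sites whose cytosine position falls inside any track interval.

    Intended for narrowing analyses to promoters or CpG islands.
    """
    if track.kind not in ("promoter", "cpg_island"):
        raise ValueError(
            f"restrict_to_regions expects a promoter or cpg_island track, "
            f"got {track.kind!r}"
        )
    return [s for s in sites if track.overlapping(s.chrom, s.start, s.start + 1)]


def count_track_overlaps(window: SequenceWindow, track: AnnotationTrack) -> int:
    """Number of track intervals intersecting the window (per interval)."""
    return len(track.overlapping(window.site.chrom, window.window_start,
                                 window.window_end))


# ---------------------------------------------------------------------------
# splice sites


@dataclass(frozen=True)
class SpliceSiteModel:
    """Per-position base frequencies for a donor (L=9) or acceptor (L=15) site."""

    site_type: Literal["donor", "acceptor"]
    freq: np.ndarray  # (4, L), columns sum to 1

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "freq", f)
        expected = {"donor": 9, "acceptor": 15}
        if self.site_type not in expected:
            raise ValueError("site_type must be 'donor' or 'acceptor'")
        if f.shape != (4, expected[self.site_type]):
            raise ValueError(
                f"{self.site_type} model must be 4 x {expected[self.site_type]}, "
                f"got {f.shape}"
            )
        colsums = f.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError("frequency columns must sum to 1 within 1e-6")

    @property
    def length(self) -> int:
        return self.freq.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freq.argmax(axis=0))

    @classmethod
    def from_tsv(cls, path: str | Path,
                 site_type: Literal["donor", "acceptor"]) -> "SpliceSiteModel":
        """Load from TSV: a ``base`` column (A/C/G/T rows) and one column per
        position; values may be percentages or fractions (normalized here)."""
        df = pd.read_csv(path, sep="\t")
        if "base" not in df.columns:
            raise ValueError("splice model TSV needs a 'base' column")
        df = df.set_index("base").loc[list(_BASES)]
        f = df.to_numpy(dtype=float)
        f = f / f.sum(axis=0, keepdims=True)
        return cls(site_type=site_type, freq=f)


def donor_model() -> SpliceSiteModel:
    """The bundled 9-position donor frequency table (-3..+6, invariant GT)."""
    with resources.as_file(
        resources.files("methsig.data") / "donor_ss.tsv"
    ) as p:
        return SpliceSiteModel.from_tsv(p, "donor")


def acceptor_model() -> SpliceSiteModel:
    """The bundled 15-position acceptor frequency table (invariant AG at -2/-1)."""
    with resources.as_file(
        resources.files("methsig.data") / "acceptor_ss.tsv"
    ) as p:
        return SpliceSiteModel.from_tsv(p, "acceptor")


def ss_score(sequence_kmer: str, model: SpliceSiteModel) -> float:
    """Shapiro-Senapathy percentile score in [0, 100].

    ``100 * (t - t_min) / (t_max - t_min)`` where t is the sum of the
    per-position frequencies of the observed bases and t_min/t_max are the
    sums of the column minima/maxima.
    """
    kmer = sequence_kmer.upper()
    if len(kmer) != model.length:
        raise ValueError(
            f"k-mer length {len(kmer)} does not match model length {model.length}"
        )
    if any(c not in _BASE_IDX for c in kmer):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    idx = _encode(kmer)
    t = float(model.freq[idx, np.arange(model.length)].sum())
    t_min = float(model.freq.min(axis=0).sum())
    t_max = float(model.freq.max(axis=0).sum())
    return 100.0 * (t - t_min) / (t_max - t_min)


def find_splice_sites(
    window: SequenceWindow | str,
    donor: SpliceSiteModel | None = None,
    acceptor: SpliceSiteModel | None = None,
    min_score: float = 80.0,
    both_strands: bool = True,
) -> tuple[bool, list[SpliceHit]]:
    """Scan a window for tentative donor/acceptor sites on both strands.

    Returns ``(any_hit, hits)`` with every placement whose percentile score
    reaches ``min_score``; placements containing N are skipped.  The logical
    is later joined with alternative-splicing overlap into the signature's
    splicing attribute.
    """
    donor = donor if donor is not None else donor_model()
    acceptor = acceptor if acceptor is not None else acceptor_model()
    seq = window.sequence if isinstance(window, SequenceWindow) else window
    seq = seq.upper()
    n = len(seq)
    hits: list[SpliceHit] = []
    for model in (donor, acceptor):
        L = model.length
        t_min = model.freq.min(axis=0).sum()
        t_max = model.freq.max(axis=0).sum()
        span = t_max - t_min

        def _collect(s: str, strand: str) -> None:
            scores, valid = _sliding_scores(_encode(s), model.freq)
            pct = 100.0 * (scores - t_min) / span
            for o in np.flatnonzero(valid & (pct >= min_score)):
                start = int(o) if strand == "+" else n - int(o) - L
                hits.append(SpliceHit(model.site_type, start, strand,
                                      float(pct[o])))

        _collect(seq, "+")
        if both_strands:
            _collect(reverse_complement(seq), "-")
    hits.sort(key=lambda h: (h.start, h.site_type, h.strand))
    return bool(hits), hits
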