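"""Structure-related sequence features: G-quadruplexes, palindromes, DNA shape.

G-quadruplex detection is a canonical-motif detector: four runs of at least
``min_run`` guanines separated by three loops whose lengths lie within
``[loop_min, loop_max]``.  Minus-strand quadruplexes are found as the
equivalent C-run pattern on the input strand.  Overlapping candidates are
resolved greedily left-to-right, taking the longest match at each start, so
counts are stable and order-independent.

Palindromes are segments whose left arm equals the exact reverse complement
of the right arm, separated by a loop of bounded length; only maximal arms
are reported (an arm that could be extended outward by one complementary
base pair is not a separate match).

Methylation-induced DNA-shape changes are computed from pentamer lookup
tables over the extended alphabet {A,C,G,T,M,W} where M is 5-methylcytosine
and W is the guanine paired with a methylated cytosine on the opposite
strand.  The central CpG dyad is modified symmetrically (C->M, G->W), both
profiles are decoded, and the per-position differences at pentamers covering
the dyad are tested with a two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqcontext import SequenceWindow, reverse_complement

__all__ = [
    "G4Match",
    "PalindromeMatch",
    "ShapeDelta",
    "PentamerShapeTable",
    "SHAPE_NAMES",
    "find_g4",
    "g4_count",
    "find_palindromes",
    "palindrome_count",
    "shape_delta",
    "shape_significant",
]

SHAPE_NAMES = ("MGW", "Roll", "ProT", "HelT")


@dataclass(frozen=True)
class G4Match:
    """A canonical quadruplex match, window-relative 0-based half-open."""

    start: int
    end: int
    strand: str
    n_runs: int
    loop_lengths: tuple[int, ...]


@dataclass(frozen=True)
class PalindromeMatch:
    """A maximal-arm palindrome: arms of ``arm_length`` around a loop."""

    arm_start: int
    arm_length: int
    loop_length: int

    @property
    def end(self) -> int:
        return self.arm_start + 2 * self.arm_length + self.loop_length


@dataclass(frozen=True)
class ShapeDelta:
    """Per-position shape difference (methylated minus unmethylated state)."""

    shape_name: str
    deltas: tuple[float, ...]
    p_value: float
    informative_positions: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# G-quadruplexes


def _g4_pattern(run_char: str, min_run: int, loop_min: int, loop_max: int) -> re.Pattern:
    run = f"{run_char}{{{min_run},}}"
    loop = f"[ACGT]{{{loop_min},{loop_max}}}"
    return re.compile(f"({run})({loop})({run})({loop})({run})({loop})({run})")


def _scan_strand(
    seq: str, run_char: str, min_run: int, loop_min: int, loop_max: int
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Greedy left-to-right, longest-first-at-equal-start non-overlapping scan."""
    pat = _g4_pattern(run_char, min_run, loop_min, loop_max)
    run_re = re.compile(f"{run_char}{{{min_run},}}")
    n = len(seq)
    min_len = 4 * min_run + 3 * loop_min
    out: list[tuple[int, int, tuple[int, ...]]] = []
    cursor = 0
    for run_m in run_re.finditer(seq):
        s = run_m.start()
        if s < cursor:
            continue
        # longest full match starting at s: try candidate ends from the right
        best = None
        for j in range(n, s + min_len - 1, -1):
            if seq[j - 1] != run_char:
                continue
            m = pat.fullmatch(seq, s, j)
            if m:
                best = m
                break
        if best is None:
            continue
        loops = tuple(len(best.group(k)) for k in (2, 4, 6))
        out.append((s, best.end(), loops))
        cursor = best.end()
    return out


def find_g4(
    sequence: str,
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    both_strands: bool = True,
) -> list[G4Match]:
    """Find maximal non-overlapping canonical quadruplex matches.

    Plus-strand matches are G-run patterns on the input; minus-strand matches
    are the C-run pattern on the input (equivalently the G-pattern on the
    reverse complement).  Each strand is resolved independently.
    """
    if loop_min > loop_max:
        raise ValueError("loop_min must not exceed loop_max")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = sequence.upper()
    matches = [
        G4Match(s, e, "+", 4, loops)
        for s, e, loops in _scan_strand(seq, "G", min_run, loop_min, loop_max)
    ]
    if both_strands:
        matches += [
            G4Match(s, e, "-", 4, loops)
            for s, e, loops in _scan_strand(seq, "C", min_run, loop_min, loop_max)
        ]
    return sorted(matches, key=lambda m: (m.start, m.strand))


def g4_count(window: SequenceWindow | str, **params) -> int:
    """Number of quadruplex matches in a window (the signature's G4 feature)."""
    seq = window.sequence if isinstance(window, SequenceWindow) else window
    return len(find_g4(seq, **params))


# ---------------------------------------------------------------------------
# palindromes

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def find_palindromes(
    sequence: str, min_arm: int = 6, max_loop: int = 10
) -> list[PalindromeMatch]:
    """All maximal-arm palindromes with arm >= ``min_arm`` and loop <= ``max_loop``.

    For every (arm boundary, loop length) pair the arms are expanded outward
    while the bases are exact Watson-Crick complements; an expansion of length
    at least ``min_arm`` is one match.  Expansion-to-mismatch guarantees arms
    are maximal.
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if max_loop < 0:
        raise ValueError("max_loop must be >= 0")
    seq = sequence.upper()
    n = len(seq)
    out: list[PalindromeMatch] = []
    for i in range(1, n):  # i = end of the left arm (exclusive)
        for loop in range(0, max_loop + 1):
            j = i + loop  # start of the right arm
            if j >= n:
                break
            k = 0
            while (
                i - 1 - k >= 0
                and j + k < n
                and _PAIR.get(seq[i - 1 - k]) == seq[j + k]
            ):
                k += 1
            if k >= min_arm:
                out.append(PalindromeMatch(arm_start=i - k, arm_length=k,
                                           loop_length=loop))
    return sorted(out, key=lambda m: (m.arm_start, m.loop_length))


def palindrome_count(window: SequenceWindow | str, **params) -> int:
    """Number of palindrome matches in a window (the signature's Pals feature)."""
    seq = window.sequence if isinstance(window, SequenceWindow) else window
    return len(find_palindromes(seq, **params))


# ---------------------------------------------------------------------------
# DNA shape

_SHAPE_ALPHABET = "ACGTMW"


@dataclass
class PentamerShapeTable:
    """Pentamer -> shape-value lookup over the alphabet {A,C,G,T,M,W}.

    ``values`` maps shape name -> {pentamer: value}.  ``default`` (per shape)
    is used for pentamers absent from the table; without a default, a missing
    pentamer raises.
    """

    values: dict[str, dict[str, float]]
    default: dict[str, float] = field(default_factory=dict)

    def lookup(self, pentamer: str, shape_name: str) -> float:
        if shape_name not in self.values:
            raise KeyError(f"unknown shape {shape_name!r}")
        table = self.values[shape_name]
        if pentamer in table:
            return table[pentamer]
        if shape_name in self.default:
            return self.default[shape_name]
        raise KeyError(
            f"pentamer {pentamer!r} absent from {shape_name} table and no default set"
        )

    @classmethod
    def from_tsv(cls, path: str | Path,
                 default: dict[str, float] | None = None) -> "PentamerShapeTable":
        """Load from TSV with header ``pentamer<TAB>MGW<TAB>Roll<TAB>ProT<TAB>HelT``."""
        df = pd.read_csv(path, sep="\t")
        if "pentamer" not in df.columns:
            raise ValueError("shape table needs a 'pentamer' column")
        shapes = [c for c in df.columns if c != "pentamer"]
        values = {
            s: dict(zip(df["pentamer"].astype(str), df[s].astype(float)))
            for s in shapes
        }
        return cls(values=values, default=default or {})

    @classmethod
    def synthetic(
        cls,
        seed: int = 0,
        methyl_shift_sd: float = 0.3,
        shapes: Sequence[str] = SHAPE_NAMES,
    ) -> "PentamerShapeTable":
        """A complete synthetic table for testing and simulation.

        Every ACGT pentamer gets a seed-deterministic base value; pentamers
        containing the modified symbols M/W get the value of their unmodified
        counterpart plus a pentamer-specific perturbation with standard
        deviation ``methyl_shift_sd``.  The values are synthetic stand-ins
        with the same interface as published methyl-aware pentamer tables,
        not physical predictions.
        """
        rng = np.random.default_rng(seed)
        base_levels = {"MGW": 5.0, "Roll": 0.0, "ProT": -7.0, "HelT": 34.0}
        acgt = ["".join(p) for p in itertools.product("ACGT", repeat=5)]
        values: dict[str, dict[str, float]] = {}
        for shape in shapes:
            level = base_levels.get(shape, 0.0)
            tab = {p: level + rng.normal(0, 1) for p in acgt}
            full = dict(tab)
            for p in itertools.product(_SHAPE_ALPHABET, repeat=5):
                pent = "".join(p)
                if pent in full:
                    continue
                unmod = pent.replace("M", "C").replace("W", "G")
                full[pent] = tab[unmod] + rng.normal(0, methyl_shift_sd)
            values[shape] = full
        return cls(values=values)

    def to_tsv(self, path: str | Path) -> None:
        shapes = list(self.values)
        pents = sorted(set().union(*(self.values[s] for s in shapes)))
        with open(path, "w") as fh:
            fh.write("pentamer\t" + "\t".join(shapes) + "\n")
            for p in pents:
                row = "\t".join(f"{self.values[s].get(p, float('nan')):.6g}"
                                for s in shapes)
                fh.write(f"{p}\t{row}\n")


def _decode_profile(seq: str, table: PentamerShapeTable, shape: str) -> np.ndarray:
    vals = [table.lookup(seq[j - 2 : j + 3], shape) for j in range(2, len(seq) - 2)]
    return np.asarray(vals, dtype=float)


def shape_delta(
    window: SequenceWindow, table: PentamerShapeTable, shape_name: str
) -> ShapeDelta:
    """Shape change induced by methylating the window's central CpG.

    Decodes two pentamer profiles — the native sequence and the sequence with
    the central CpG dyad methylated (C->M, complementary-strand G encoded as
    W) — and returns their per-position difference.  The p-value is from a
    two-sided Wilcoxon signed-rank test over positions whose pentamer covers
    the modified bases; with fewer than 4 informative positions, or all-zero
    differences, the test is degenerate and p is defined as 1.
    """
    seq = window.sequence
    if len(seq) < 5:
        raise ValueError("window shorter than one pentamer")
    p = window.center
    if seq[p : p + 2] != "CG":
        raise ValueError(
            f"no CpG at the site position (found {seq[p:p+2]!r} at offset {p})"
        )
    meth = seq[:p] + "MW" + seq[p + 2 :]
    native_prof = _decode_profile(seq, table, shape_name)
    meth_prof = _decode_profile(meth, table, shape_name)
    deltas = meth_prof - native_prof
    # profile position j corresponds to sequence index j+2; pentamer covers
    # sequence indices [j, j+4], so it touches the dyad (p, p+1) iff
    # p - 2 <= j + 2 <= p + 3
    lo = max(0, p - 4)
    hi = min(len(deltas) - 1, p + 1)
    informative = tuple(range(lo, hi + 1)) if hi >= lo else ()
    diffs = deltas[list(informative)] if informative else np.array([])
    nonzero = diffs[diffs != 0]
    if len(informative) < 4 or nonzero.size == 0:
        pval = 1.0
    else:
        pval = float(stats.wilcoxon(nonzero, alternative="two-sided").pvalue)
    return ShapeDelta(
        shape_name=shape_name,
        deltas=tuple(float(d) for d in deltas),
        p_value=pval,
        informative_positions=informative,
    )


def shape_significant(deltas: Iterable[ShapeDelta], alpha: float = 0.05) -> bool:
    """True iff at least one shape change is significant (min p < alpha)."""
    deltas = list(deltas)
    if not deltas:
        warnings.warn("no shape deltas supplied; reporting not significant",
                      stacklevel=2)
        return False
    return min(d.p_value for d in deltas) < alpha
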