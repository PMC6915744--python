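"""Loading, validation, conversion and differential filtering of methylation data.

This module turns raw methylation measurements — BED-like interval files,
sample x probe beta-value matrices with a two-group annotation, or per-site
bisulfite read counts — into a canonical list of differentially methylated
sites (:class:`DMSRecord`).

Conventions
-----------
* Coordinates are BED-style 0-based half-open everywhere; a CpG site is the
  single base of the cytosine (``end = start + 1``).
* A beta value is the methylation fraction in [0, 1]; the M value is its
  logit on base 2, ``M = log2(beta / (1 - beta))``.
* Delta-beta is ``mean(case group) - mean(control group)``; the case group
  is the first label encountered in the sample annotation unless stated
  explicitly.  A site with positive delta-beta is hypermethylated (DMS+),
  negative is hypomethylated (DMS-).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DMSRecord",
    "BetaMatrix",
    "BisulfiteCounts",
    "load_dms_bed",
    "write_dms_bed",
    "beta_from_intensities",
    "m_to_beta",
    "beta_to_m",
    "beta_from_counts",
    "bh_fdr",
    "differential_filter",
    "subsample_dms",
    "load_beta_matrix",
]


@dataclass(frozen=True)
class DMSRecord:
    """One differentially methylated site (a single CpG cytosine).

    ``delta_beta`` is the signed group-mean beta difference in [-1, 1].
    ``score`` optionally keeps a raw score read from file when its units are
    not beta-scale (e.g. an M-value difference); in that case ``delta_beta``
    may be None.
    """

    chrom: str
    start: int
    end: int
    delta_beta: float | None = None
    p_value: float | None = None
    fdr: float | None = None
    site_id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.delta_beta is not None and abs(self.delta_beta) > 1:
            raise ValueError(f"|delta_beta| > 1: {self.delta_beta}")
        for name in ("p_value", "fdr"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"{name} outside [0, 1]: {v}")

    @property
    def is_hyper(self) -> bool:
        """True for DMS+ (hypermethylated in the case group)."""
        return self.delta_beta is not None and self.delta_beta > 0

    @property
    def abs_delta(self) -> float:
        return abs(self.delta_beta) if self.delta_beta is not None else 0.0


@dataclass
class BetaMatrix:
    """Sites x samples beta values with a two-group sample annotation.

    ``values``: DataFrame indexed by site id, columns = sample ids, entries in
    [0, 1] or NaN.  ``groups``: Series mapping sample id -> group label with
    exactly two distinct labels.  ``sites``: optional DataFrame indexed by
    site id with columns chrom/start/end giving each CpG's coordinate.
    ``case_group`` names the group whose mean comes first in delta-beta.
    """

    values: pd.DataFrame
    groups: pd.Series
    sites: pd.DataFrame | None = None
    case_group: str | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        labels = list(pd.unique(self.groups.loc[self.values.columns]))
        if len(labels) != 2:
            raise ValueError(f"exactly two group labels required, got {labels}")
        if self.case_group is None:
            self.case_group = labels[0]
        elif self.case_group not in labels:
            raise ValueError(f"case_group {self.case_group!r} not among {labels}")
        if self.sites is not None:
            extra = set(self.values.index) - set(self.sites.index)
            if extra:
                raise ValueError(f"sites without coordinates: {sorted(extra)[:5]} ...")

    @property
    def control_group(self) -> str:
        labels = list(pd.unique(self.groups.loc[self.values.columns]))
        return labels[1] if labels[0] == self.case_group else labels[0]

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == label]


@dataclass
class BisulfiteCounts:
    """Per-site methylated / total read counts from bisulfite sequencing."""

    sites: pd.DataFrame  # index site_id, columns chrom/start/end
    meth_reads: np.ndarray
    total_reads: np.ndarray

    def __post_init__(self) -> None:
        self.meth_reads = np.asarray(self.meth_reads)
        self.total_reads = np.asarray(self.total_reads)
        if self.meth_reads.shape != self.total_reads.shape:
            raise ValueError("meth_reads and total_reads shapes differ")
        if (self.meth_reads < 0).any() or (self.total_reads < 0).any():
            raise ValueError("read counts must be non-negative")
        if (self.meth_reads > self.total_reads).any():
            raise ValueError("meth_reads exceeds total_reads")


# ---------------------------------------------------------------------------
# loading


def load_dms_bed(
    path: str | Path,
    score_scale: Literal["delta_beta", "m_diff"] = "delta_beta",
) -> list[DMSRecord]:
    """Read DMS records from a BED3/BED4 file (tab-separated, 0-based half-open).

    The optional 4th column is a score: with ``score_scale="delta_beta"`` it is
    validated to [-1, 1] and stored as ``delta_beta``; with ``"m_diff"`` it is
    kept verbatim in ``score`` (no unit guessing).  Malformed lines are skipped
    with a per-line message collected into one summary warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BED file not found: {path}")
    records: list[DMSRecord] = []
    problems: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                problems.append(f"line {lineno}: fewer than 3 tab-separated columns")
                continue
            chrom = parts[0].strip()
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                problems.append(f"line {lineno}: non-integer coordinates")
                continue
            delta_beta = score = None
            if len(parts) >= 4 and parts[3].strip() not in ("", "."):
                try:
                    raw = float(parts[3])
                except ValueError:
                    problems.append(f"line {lineno}: non-numeric score {parts[3]!r}")
                    continue
                if score_scale == "delta_beta":
                    if abs(raw) > 1:
                        problems.append(
                            f"line {lineno}: delta_beta outside [-1, 1]: {raw}"
                        )
                        continue
                    delta_beta = raw
                else:
                    score = raw
            site_id = parts[4].strip() if len(parts) >= 5 and parts[4].strip() else None
            try:
                records.append(
                    DMSRecord(chrom, start, end, delta_beta=delta_beta,
                              score=score, site_id=site_id)
                )
            except ValueError as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        warnings.warn(
            f"{path.name}: skipped {len(problems)} malformed line(s): "
            + "; ".join(problems[:10]),
            stacklevel=2,
        )
    if not records:
        warnings.warn(f"{path.name}: no DMS records loaded", stacklevel=2)
    return records


def write_dms_bed(records: Iterable[DMSRecord], path: str | Path) -> None:
    """Write records as BED4(+name): chrom, start, end, delta_beta, site_id."""
    with open(path, "w") as fh:
        for r in records:
            score = "." if r.delta_beta is None else f"{r.delta_beta:.6g}"
            name = r.site_id or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{score}\t{name}\n")


def load_beta_matrix(
    values_path: str | Path,
    groups_path: str | Path,
    sites_path: str | Path | None = None,
    case_group: str | None = None,
) -> BetaMatrix:
    """Load a beta matrix from TSV files.

    ``values_path``: first column site id, header row of sample ids.
    ``groups_path``: two columns (sample id, group label), no header required;
    the case group defaults to the first label in file order.
    ``sites_path``: optional site coordinates (site_id, chrom, start, end).
    When absent, site ids of the form ``chrom:pos`` are parsed as coordinates.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t", header=None, comment="#")
    if ann.shape[1] < 2:
        raise ValueError("group annotation needs two columns: sample, group")
    # tolerate a header row
    if str(ann.iloc[0, 0]) not in values.columns and ann.shape[0] > 1:
        if str(ann.iloc[1, 0]) in values.columns:
            ann = ann.iloc[1:]
    groups = pd.Series(ann.iloc[:, 1].astype(str).values,
                       index=ann.iloc[:, 0].astype(str).values)
    if case_group is None:
        case_group = str(ann.iloc[0, 1])
    sites = None
    if sites_path is not None:
        sites = pd.read_csv(sites_path, sep="\t", index_col=0)
    else:
        parsed = {}
        for sid in values.index:
            s = str(sid)
            if ":" in s:
                chrom, _, pos = s.partition(":")
                try:
                    start = int(pos)
                except ValueError:
                    parsed = None
                    break
                parsed[s] = (chrom, start, start + 1)
            else:
                parsed = None
                break
        if parsed:
            sites = pd.DataFrame.from_dict(
                parsed, orient="index", columns=["chrom", "start", "end"]
            )
    return BetaMatrix(values=values, groups=groups, sites=sites, case_group=case_group)


# ---------------------------------------------------------------------------
# value conversions


def beta_from_intensities(
    meth_intensity: float | np.ndarray,
    unmeth_intensity: float | np.ndarray,
    alpha: float = 100.0,
) -> float | np.ndarray:
    """Beta value from array probe intensities: meth / (meth + unmeth + alpha).

    The offset ``alpha`` (default 100) regularises low-intensity probes.
    """
    m = np.asarray(meth_intensity, dtype=float)
    u = np.asarray(unmeth_intensity, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    out = m / (m + u + alpha)
    return float(out) if out.ndim == 0 else out


def m_to_beta(m: float | np.ndarray) -> float | np.ndarray:
    """Convert an M value to a beta value: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("M values must be finite")
    # expit on the log2 scale, computed stably for large |M|
    out = np.where(m >= 0, 1.0 / (1.0 + np.exp2(-m)),
                   np.exp2(np.minimum(m, 0)) / (np.exp2(np.minimum(m, 0)) + 1.0))
    return float(out) if out.ndim == 0 else out


def beta_to_m(beta: float | np.ndarray) -> float | np.ndarray:
    """Convert a beta value to the M (logit2) scale; undefined at 0 and 1."""
    b = np.asarray(beta, dtype=float)
    if ((b <= 0) | (b >= 1)).any():
        raise ValueError("beta_to_m requires beta strictly inside (0, 1)")
    out = np.log2(b / (1.0 - b))
    return float(out) if out.ndim == 0 else out


def beta_from_counts(
    counts: BisulfiteCounts, min_depth: int = 10
) -> np.ndarray:
    """Per-site beta = meth/total, with sites under ``min_depth`` masked as NaN.

    Zero-depth sites are masked, never a division error.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be a positive integer")
    total = counts.total_reads.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(total > 0, counts.meth_reads / np.maximum(total, 1), np.nan)
    beta = np.where(total < min_depth, np.nan, beta)
    return beta


# ---------------------------------------------------------------------------
# differential analysis


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def differential_filter(
    matrix: BetaMatrix,
    min_abs_delta: float = 0.3,
    max_p: float = 0.01,
    max_fdr: float = 0.01,
    test: Literal["t", "mannwhitney"] = "t",
) -> list[DMSRecord]:
    """Identify differentially methylated sites between the two sample groups.

    Per site: delta-beta = mean(case) - mean(control) over non-missing values;
    a two-sided two-sample test (Welch's t by default, Mann-Whitney optional)
    gives p; Benjamini-Hochberg across all tested sites gives the FDR.  A site
    passes when ``|delta| >= min_abs_delta`` and ``p < max_p`` and
    ``fdr < max_fdr``.  Sites with fewer than 2 usable samples in either group
    are excluded from testing with a warning.
    """
    case = matrix.values[matrix.group_samples(matrix.case_group)].to_numpy(float)
    ctrl = matrix.values[matrix.group_samples(matrix.control_group)].to_numpy(float)
    n_case = (~np.isnan(case)).sum(axis=1)
    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    testable = (n_case >= 2) & (n_ctrl >= 2)
    n_dropped = int((~testable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} site(s) excluded: fewer than 2 usable samples in a group",
            stacklevel=2,
        )
    if not testable.any():
        return []

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(case[testable], axis=1) - np.nanmean(ctrl[testable], axis=1)
        if test == "t":
            pvals = stats.ttest_ind(
                case[testable], ctrl[testable], axis=1,
                equal_var=False, nan_policy="omit",
            ).pvalue
        elif test == "mannwhitney":
            pvals = np.empty(int(testable.sum()))
            for i, idx in enumerate(np.flatnonzero(testable)):
                a = case[idx][~np.isnan(case[idx])]
                b = ctrl[idx][~np.isnan(ctrl[idx])]
                pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
    pvals = np.asarray(pvals, dtype=float)
    # identical constant groups give nan from a 0/0 t statistic: no evidence
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_fdr(pvals)

    keep = (np.abs(delta) >= min_abs_delta) & (pvals < max_p) & (qvals < max_fdr)
    site_ids = np.asarray(matrix.values.index)[testable]
    out: list[DMSRecord] = []
    for sid, d, p, q, k in zip(site_ids, delta, pvals, qvals, keep):
        if not k:
            continue
        if matrix.sites is not None:
            row = matrix.sites.loc[sid]
            chrom, start, end = str(row["chrom"]), int(row["start"]), int(row["end"])
        else:
            chrom, start, end = "unknown", 0, 1
        out.append(
            DMSRecord(chrom, start, end, delta_beta=float(np.clip(d, -1, 1)),
                      p_value=float(p), fdr=float(min(q, 1.0)), site_id=str(sid))
        )
    return out


def subsample_dms(
    records: Sequence[DMSRecord], n_max: int = 1000, seed: int = 0
) -> list[DMSRecord]:
    """Uniformly subsample at most ``n_max`` records without replacement.

    Returns all records when there are no more than ``n_max``; otherwise a
    seed-reproducible uniform sample, preserving the input order.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    records = list(records)
    if len(records) <= n_max:
        return records
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=n_max, replace=False))
    return [records[i] for i in idx]
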