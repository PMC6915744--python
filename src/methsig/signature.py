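"""Genomic signatures and the weighted-sum genomic index.

Raw per-site feature readouts are mapped onto the unit interval: the count
features (G4, Pals, TFBS, cTFBS) are min-max normalized across the analyzed
dataset; splicing-related observations (tentative donor/acceptor hits and
alternative-splicing overlap) are joined into one logical; the four DNA
shape changes are joined into one logical that is positive when at least one
shape alteration is significant (p < 0.05).  The genomic index of a site is
the weighted sum of its mapped attributes — with unit weights over the six
default attributes it lies in [0, 6] — and sites are ranked by descending
index with deterministic tie-breaking (|delta-beta| descending, then
coordinates ascending).

Min-max normalization is dataset-relative: the mapping metadata records the
min/max actually used so a signature can be reproduced or re-based, and
fixed global bounds may be supplied instead.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureVector",
    "SignatureMatrix",
    "WeightScheme",
    "RankedResult",
    "DEFAULT_ATTRIBUTES",
    "COUNT_ATTRIBUTES",
    "features_to_frame",
    "map_attributes",
    "genomic_index",
    "rank_sites",
    "export_signatures",
    "read_signatures",
]

COUNT_ATTRIBUTES = ("G4", "Pals", "TFBS", "cTFBS")
DEFAULT_ATTRIBUTES = COUNT_ATTRIBUTES + ("splicing", "shape")

_RAW_COUNT_COLS = {"G4": "g4", "Pals": "pals", "TFBS": "tfbs", "cTFBS": "ctfbs"}
_SPLICE_COLS = ("donor_hits", "acceptor_hits", "altspl_count")
_SHAPE_P_COLS = ("shape_MGW_p", "shape_Roll_p", "shape_ProT_p", "shape_HelT_p")


@dataclass(frozen=True)
class FeatureVector:
    """Raw per-site feature readouts before mapping."""

    site_id: str
    g4: int = 0
    pals: int = 0
    tfbs: int = 0
    ctfbs: int = 0
    donor_hits: int = 0
    acceptor_hits: int = 0
    altspl_count: int = 0
    shape_p_values: tuple[float, ...] = ()
    delta_beta: float = 0.0
    chrom: str = "unknown"
    start: int = 0

    def __post_init__(self) -> None:
        for name in ("g4", "pals", "tfbs", "ctfbs",
                     "donor_hits", "acceptor_hits", "altspl_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for p in self.shape_p_values:
            if not 0 <= p <= 1:
                raise ValueError(f"shape p-value outside [0, 1]: {p}")


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabulate FeatureVectors; shape p-values expand to per-shape columns."""
    rows = []
    for f in features:
        row = {
            "site_id": f.site_id, "chrom": f.chrom, "start": f.start,
            "delta_beta": f.delta_beta,
            "g4": f.g4, "pals": f.pals, "tfbs": f.tfbs, "ctfbs": f.ctfbs,
            "donor_hits": f.donor_hits, "acceptor_hits": f.acceptor_hits,
            "altspl_count": f.altspl_count,
        }
        for col, p in zip(_SHAPE_P_COLS, f.shape_p_values):
            row[col] = p
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SignatureMatrix:
    """Mapped attribute values per site, with the mapping metadata.

    ``values``: DataFrame indexed by site id with one column per attribute,
    every entry in [0, 1].  ``mapping``: per-attribute metadata (min/max used
    for counts; join rule for logicals) sufficient to reproduce the mapping.
    ``sites``: per-site chrom/start/delta_beta used for tie-breaking.
    """

    values: pd.DataFrame
    mapping: dict
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and ((v < 0) | (v > 1)).any():
            raise ValueError("mapped attribute values must lie in [0, 1]")

    @property
    def attributes(self) -> list[str]:
        return list(self.values.columns)


def map_attributes(
    features: Sequence[FeatureVector] | pd.DataFrame,
    shape_alpha: float = 0.05,
    fixed_bounds: Mapping[str, tuple[float, float]] | None = None,
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
) -> SignatureMatrix:
    """Build the signature matrix from raw features.

    Count attributes are min-max normalized across the dataset (or against
    ``fixed_bounds`` when supplied); a constant count column maps to 0 with a
    warning.  The splicing attribute is 1 when any of donor hit / acceptor
    hit / alt-splicing overlap is present; the shape attribute is 1 when any
    shape p-value is below ``shape_alpha``.
    """
    df = features if isinstance(features, pd.DataFrame) else features_to_frame(features)
    if df.empty:
        raise ValueError("empty feature table")
    df = df.reset_index(drop=True)
    mapping: dict = {}
    cols: dict[str, np.ndarray] = {}

    for attr in attributes:
        if attr in COUNT_ATTRIBUTES:
            raw_col = _RAW_COUNT_COLS[attr]
            if raw_col not in df.columns:
                raise ValueError(f"feature table lacks column {raw_col!r} for {attr}")
            raw = df[raw_col].to_numpy(dtype=float)
            if np.isnan(raw).any():
                raise ValueError(f"attribute {attr} missing for some sites")
            if fixed_bounds and attr in fixed_bounds:
                lo, hi = fixed_bounds[attr]
            else:
                lo, hi = float(raw.min()), float(raw.max())
            if hi <= lo:
                warnings.warn(
                    f"attribute {attr} is constant ({lo}); mapped to 0",
                    stacklevel=2,
                )
                cols[attr] = np.zeros(len(df))
            else:
                cols[attr] = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
            mapping[attr] = {"kind": "minmax", "min": lo, "max": hi}
        elif attr == "splicing":
            present = [c for c in _SPLICE_COLS if c in df.columns]
            if not present:
                raise ValueError("feature table lacks splicing columns")
            if df[present].isna().any().any():
                raise ValueError("splicing attribute missing for some sites")
            joined = (df[present].to_numpy(dtype=float) > 0).any(axis=1)
            cols[attr] = joined.astype(float)
            mapping[attr] = {"kind": "logical_any", "components": present}
        elif attr == "shape":
            present = [c for c in _SHAPE_P_COLS if c in df.columns]
            if not present:
                raise ValueError("feature table lacks shape p-value columns")
            if df[present].isna().any().any():
                raise ValueError("shape attribute missing for some sites")
            sig = (df[present].to_numpy(dtype=float) < shape_alpha).any(axis=1)
            cols[attr] = sig.astype(float)
            mapping[attr] = {"kind": "logical_min_p", "alpha": shape_alpha,
                             "components": present}
        else:
            raise ValueError(f"unknown attribute {attr!r}")

    site_ids = df["site_id"].astype(str) if "site_id" in df.columns else \
        pd.Series([str(i) for i in range(len(df))])
    values = pd.DataFrame(cols, index=site_ids.values)[list(attributes)]
    site_cols = {}
    for c in ("chrom", "start", "delta_beta"):
        site_cols[c] = df[c].values if c in df.columns else (
            np.zeros(len(df)) if c != "chrom" else np.repeat("unknown", len(df)))
    sites = pd.DataFrame(site_cols, index=site_ids.values)
    return SignatureMatrix(values=values, mapping=mapping, sites=sites)


@dataclass(frozen=True)
class WeightScheme:
    """Non-negative per-attribute weights; default all 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")

    @classmethod
    def uniform(cls, attributes: Sequence[str] = DEFAULT_ATTRIBUTES) -> "WeightScheme":
        return cls({a: 1.0 for a in attributes})

    def vector(self, attributes: Sequence[str]) -> np.ndarray:
        missing = [a for a in attributes if a not in self.weights]
        if missing:
            raise ValueError(f"weights missing for attributes {missing}")
        return np.array([self.weights[a] for a in attributes], dtype=float)


@dataclass(frozen=True)
class RankedResult:
    site_id: str
    genomic_index: float
    rank: int
    abs_delta_beta: float = 0.0
    chrom: str = "unknown"
    start: int = 0


def genomic_index(
    signature_row: Mapping[str, float] | pd.Series | np.ndarray,
    weights: WeightScheme | None = None,
    attributes: Sequence[str] = DEFAULT_ATTRIBUTES,
) -> float:
    """Weighted sum of one site's mapped attributes: idx = sum_j w_j a'_ij."""
    if weights is None:
        weights = WeightScheme.uniform(attributes)
    if isinstance(signature_row, np.ndarray):
        vals = np.asarray(signature_row, dtype=float)
        if vals.shape != (len(attributes),):
            raise ValueError("row length does not match attribute list")
    else:
        vals = np.array([signature_row[a] for a in attributes], dtype=float)
    w = weights.vector(attributes)
    return float(vals @ w)


def rank_sites(
    matrix: SignatureMatrix, weights: WeightScheme | None = None
) -> list[RankedResult]:
    """Rank sites by descending genomic index.

    Ties are broken by |delta-beta| descending, then (chrom, start)
    ascending, so the output is deterministic and independent of input order.
    """
    attrs = matrix.attributes
    if weights is None:
        weights = WeightScheme.uniform(attrs)
    w = weights.vector(attrs)
    idx = matrix.values.to_numpy(dtype=float) @ w
    abs_db = np.abs(matrix.sites["delta_beta"].to_numpy(dtype=float))
    order = sorted(
        range(len(idx)),
        key=lambda i: (
            -idx[i],
            -abs_db[i],
            str(matrix.sites["chrom"].iloc[i]),
            int(matrix.sites["start"].iloc[i]),
            str(matrix.values.index[i]),
        ),
    )
    return [
        RankedResult(
            site_id=str(matrix.values.index[i]),
            genomic_index=float(idx[i]),
            rank=r + 1,
            abs_delta_beta=float(abs_db[i]),
            chrom=str(matrix.sites["chrom"].iloc[i]),
            start=int(matrix.sites["start"].iloc[i]),
        )
        for r, i in enumerate(order)
    ]


def export_signatures(
    results: Sequence[RankedResult],
    matrix: SignatureMatrix,
    path: str | Path,
    raw_features: pd.DataFrame | None = None,
    weights: WeightScheme | None = None,
) -> None:
    """Write the ranked signature table as TSV with a reproducibility header.

    Header comment lines record the weight vector and the per-attribute
    mapping metadata (min/max, join rules), so indices can be reproduced from
    the raw feature values.
    """
    attrs = matrix.attributes
    if weights is None:
        weights = WeightScheme.uniform(attrs)
    by_id = {r.site_id: r for r in results}
    if set(by_id) != set(map(str, matrix.values.index)):
        raise ValueError("results and matrix cover different site sets")
    rows = []
    for r in sorted(results, key=lambda r: r.rank):
        row = {
            "site_id": r.site_id, "chrom": r.chrom, "start": r.start,
            "delta_beta": float(matrix.sites.loc[r.site_id, "delta_beta"]),
        }
        if raw_features is not None:
            raw = raw_features.set_index(raw_features["site_id"].astype(str))
            for c in raw.columns:
                if c not in row and c != "site_id":
                    row[f"raw_{c}"] = raw.loc[r.site_id, c]
        for a in attrs:
            row[f"mapped_{a}"] = float(matrix.values.loc[r.site_id, a])
        row["genomic_index"] = r.genomic_index
        row["rank"] = r.rank
        rows.append(row)
    out = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# methsig signature export\n")
        fh.write("# weights\t" + "\t".join(
            f"{a}={weights.weights[a]:g}" for a in attrs) + "\n")
        for a in attrs:
            fh.write(f"# mapping\t{a}\t{matrix.mapping[a]}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_signatures(path: str | Path) -> pd.DataFrame:
    """Read a signature TSV written by :func:`export_signatures`."""
    return pd.read_csv(path, sep="\t", comment="#")
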