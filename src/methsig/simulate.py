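"""Seeded synthetic genomes, methylation matrices and feature-planted windows.

The generators emulate the statistical structure the framework assumes in
real data: a random genome at a chosen G+C fraction with CpG sites at known
coordinates; per-group beta values drawn from a bimodal Beta mixture (array
data concentrate near 0 and 1) with designated differential sites shifted by
a configured effect; windows around "enriched" sites carrying planted
canonical motifs (a G-quadruplex, a palindrome, a TF consensus, a donor
consensus) at high probability versus "desert" sites at low probability; and
a gene-expression table whose |log2 fold change| is coupled to the number of
planted elements with the sign opposed to the methylation change
(hypermethylation <-> down-regulation).

Every generator is a pure function of its config and seed: identical seeds
give identical bytes.  Planted motifs are fixed documented strings so that
detector recall is exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import BetaMatrix, DMSRecord
from .regulatory import AnnotationTrack, PositionFrequencyMatrix

__all__ = [
    "SimulationConfig",
    "G4_MOTIF",
    "PALINDROME_MOTIF",
    "TF_CONSENSUS",
    "DONOR_CONSENSUS",
    "fixture_pfm",
    "make_genome",
    "plant_features",
    "make_tracks",
    "make_beta_matrix",
    "make_expression_table",
    "make_g4_contrast_windows",
    "write_fixtures",
]

# fixed planting motifs (documented strings; see module docstring)
G4_MOTIF = "GGGTTAGGGTTAGGGTTAGGG"  # four G3 runs, TTA loops (len 3)
_PAL_ARM = "ATCGGCTA"
PALINDROME_MOTIF = _PAL_ARM + "CACA" + "TAGCCGAT"  # arm 8, loop 4
TF_CONSENSUS = "TTGCACAA"
DONOR_CONSENSUS = "CAGGTAAGT"  # consensus of the bundled donor table

# plant offsets relative to the CpG cytosine position; all fit inside a
# +/-50 window and never touch the central CpG dyad
_PLANT_OFFSETS = {
    "g4": -45,        # occupies [-45, -24)
    "palindrome": -22,  # occupies [-22, -2)
    "tf": 3,          # occupies [+3, +11)
    "donor": 15,      # occupies [+15, +24)
}
_PLANT_MOTIFS = {
    "g4": G4_MOTIF,
    "palindrome": PALINDROME_MOTIF,
    "tf": TF_CONSENSUS,
    "donor": DONOR_CONSENSUS,
}
PLANT_KINDS = tuple(_PLANT_MOTIFS)


def fixture_pfm(weight: int = 97) -> PositionFrequencyMatrix:
    """A synthetic PFM whose consensus is :data:`TF_CONSENSUS`.

    Each column gives ``weight`` counts to the consensus base and 1 to every
    other base, so the consensus placement scores rel_score = 1.0.
    """
    counts = np.ones((4, len(TF_CONSENSUS)))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for j, b in enumerate(TF_CONSENSUS):
        counts[base_idx[b], j] = weight
    return PositionFrequencyMatrix(
        motif_id="SYN0001", motif_name="synthetic_fixture", counts=counts
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    ``beta_modes`` are the (a, b) parameters of the two Beta mixture
    components for null sites (unmethylated and methylated modes).  ``effect``
    is the planted group-mean beta difference at differential sites;
    per-sample values at those sites come from Beta distributions with the
    target means and concentration ``beta_concentration`` (mean * kappa,
    (1 - mean) * kappa), keeping every value inside (0, 1).  ``plant_probs``
    gives the per-feature planting probability for the enriched and desert
    site classes.
    """

    seed: int
    genome_length: int = 80_000
    gc_fraction: float = 0.41
    n_sites: int = 400
    n_samples_per_group: int = 10
    site_spacing: int = 150
    offset: int = 50
    beta_modes: tuple[tuple[float, float], tuple[float, float]] = (
        (0.5, 5.0), (5.0, 0.5))
    beta_concentration: float = 100.0
    effect: float = 0.4
    plant_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {k: (0.9, 0.05) for k in PLANT_KINDS})
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.n_samples_per_group < 3:
            raise ValueError("n_samples_per_group must be >= 3")
        for k, (pe, pd_) in self.plant_probs.items():
            if not (0 <= pe <= 1 and 0 <= pd_ <= 1):
                raise ValueError(f"planting probabilities for {k} outside [0, 1]")
        needed = self.site_spacing * self.n_sites + 2 * self.offset
        if self.genome_length < needed:
            raise ValueError(
                f"genome_length {self.genome_length} too short for "
                f"{self.n_sites} sites at spacing {self.site_spacing}"
            )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def make_genome(config: SimulationConfig) -> tuple[dict[str, str], list[DMSRecord]]:
    """Random genome at the configured G+C fraction, with CpG sites placed.

    Sites are evenly spaced (first at ``offset + spacing/2``) and a CG
    dinucleotide is written at each site so every window carries a central
    CpG.  Returns the genome mapping and the site records (delta_beta unset).
    """
    rng = np.random.default_rng(config.seed)
    arr = _random_sequence(rng, config.genome_length, config.gc_fraction)
    first = config.offset + config.site_spacing // 2
    positions = [first + i * config.site_spacing for i in range(config.n_sites)]
    for pos in positions:
        arr[pos] = b"C"
        arr[pos + 1] = b"G"
    seq = arr.tobytes().decode("ascii")
    sites = [
        DMSRecord(config.chrom, pos, pos + 1, site_id=f"site{i:05d}")
        for i, pos in enumerate(positions)
    ]
    return {config.chrom: seq}, sites


def plant_features(
    genome: Mapping[str, str],
    sites: Sequence[DMSRecord],
    classes: Mapping[str, str],
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant canonical motifs inside enriched/desert windows.

    ``classes`` maps site id -> "enriched" or "desert"; each feature kind is
    planted independently with the class probability from
    ``config.plant_probs``.  Motifs are written at fixed per-kind offsets
    inside the +/-offset window, never overlapping each other or the central
    CpG.  Returns the modified genome and a truth table with one row per
    planted element (site_id, kind, start, end, motif).
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = {c: bytearray(s, "ascii") for c, s in genome.items()}
    truth_rows = []
    for site in sites:
        cls = classes[site.site_id]
        if cls not in ("enriched", "desert"):
            raise ValueError(f"unknown site class {cls!r}")
        col = 0 if cls == "enriched" else 1
        for kind in PLANT_KINDS:
            p = config.plant_probs[kind][col]
            if rng.random() >= p:
                continue
            motif = _PLANT_MOTIFS[kind]
            start = site.start + _PLANT_OFFSETS[kind]
            end = start + len(motif)
            if start < site.start - config.offset or end > site.start + config.offset:
                raise ValueError(f"planted {kind} does not fit inside the window")
            buf = chroms[site.chrom]
            if start < 0 or end > len(buf):
                raise ValueError("planted element outside chromosome")
            buf[start:end] = motif.encode("ascii")
            truth_rows.append({
                "site_id": site.site_id, "kind": kind,
                "chrom": site.chrom, "start": start, "end": end, "motif": motif,
            })
    out_genome = {c: bytes(b).decode("ascii") for c, b in chroms.items()}
    truth = pd.DataFrame(
        truth_rows, columns=["site_id", "kind", "chrom", "start", "end", "motif"]
    )
    return out_genome, truth


def make_tracks(
    sites: Sequence[DMSRecord],
    classes: Mapping[str, str],
    config: SimulationConfig,
    probs: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[AnnotationTrack, AnnotationTrack]:
    """Synthetic conserved-TFBS and alternative-splicing interval tracks.

    An interval overlapping the site's window is emitted per track with the
    class probability (defaults to the config's planting probabilities).
    """
    if probs is None:
        probs = {"ctfbs": config.plant_probs.get("tf", (0.9, 0.05)),
                 "altspl": config.plant_probs.get("donor", (0.9, 0.05))}
    rng = np.random.default_rng(config.seed + 2)
    rows = {"ctfbs": [], "altspl": []}
    for site in sites:
        col = 0 if classes[site.site_id] == "enriched" else 1
        for name in ("ctfbs", "altspl"):
            if rng.random() < probs[name][col]:
                jitter = int(rng.integers(-20, 21))
                start = max(0, site.start + jitter - 10)
                rows[name].append((site.chrom, start, start + 20,
                                   f"{name}_{site.site_id}"))
    cols = ["chrom", "start", "end", "label"]
    ctfbs = AnnotationTrack(pd.DataFrame(rows["ctfbs"], columns=cols),
                            kind="conserved_tfbs")
    altspl = AnnotationTrack(pd.DataFrame(rows["altspl"], columns=cols),
                             kind="alt_splicing")
    return ctfbs, altspl


def make_beta_matrix(
    config: SimulationConfig,
    sites: Sequence[DMSRecord],
    differential_ids: Sequence[str] = (),
    differential_signs: Mapping[str, int] | None = None,
) -> BetaMatrix:
    """Two-group beta matrix with designated differential sites.

    Null sites draw both groups from one (seeded per site) Beta mixture
    component.  Differential sites draw the control group around a base mean
    of 0.2 (hyper) or 0.2 + effect (hypo) and the case group shifted by
    +/- ``config.effect``, each per-sample value from a Beta with the target
    mean at concentration ``beta_concentration``.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_samples_per_group
    diff = set(differential_ids)
    signs = dict(differential_signs or {})
    case_cols = [f"case{j:02d}" for j in range(n)]
    ctrl_cols = [f"ctrl{j:02d}" for j in range(n)]
    values = {}
    kappa = config.beta_concentration
    for site in sites:
        sid = site.site_id
        if sid in diff:
            sign = signs.get(sid, 1 if rng.random() < 0.5 else -1)
            lo_mean = 0.2
            hi_mean = min(lo_mean + config.effect, 0.98)
            case_mean, ctrl_mean = (hi_mean, lo_mean) if sign > 0 else (lo_mean, hi_mean)
            case = rng.beta(case_mean * kappa, (1 - case_mean) * kappa, size=n)
            ctrl = rng.beta(ctrl_mean * kappa, (1 - ctrl_mean) * kappa, size=n)
        else:
            a, b = config.beta_modes[int(rng.random() < 0.5)]
            case = rng.beta(a, b, size=n)
            ctrl = rng.beta(a, b, size=n)
        values[sid] = np.concatenate([case, ctrl])
    df = pd.DataFrame.from_dict(values, orient="index",
                                columns=case_cols + ctrl_cols)
    groups = pd.Series(
        ["case"] * n + ["ctrl"] * n, index=case_cols + ctrl_cols
    )
    site_df = pd.DataFrame(
        {"chrom": [s.chrom for s in sites],
         "start": [s.start for s in sites],
         "end": [s.end for s in sites]},
        index=[s.site_id for s in sites],
    )
    return BetaMatrix(values=df, groups=groups, sites=site_df, case_group="case")


def make_expression_table(
    truth: pd.DataFrame,
    sites: Sequence[DMSRecord],
    coupling: float,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-expression links: |log2FC| = coupling x (#planted elements) + noise.

    The sign of the fold change opposes the site's methylation change
    (hypermethylation maps to down-regulation); sites without a known
    delta-beta get a random sign.  Returns columns site_id, gene, log2fc.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    rng = np.random.default_rng(seed)
    counts = truth.groupby("site_id").size() if len(truth) else pd.Series(dtype=int)
    rows = []
    for i, site in enumerate(sites):
        k = int(counts.get(site.site_id, 0))
        mag = abs(coupling * k + rng.normal(0, noise_sd))
        if site.delta_beta is not None and site.delta_beta != 0:
            sign = -1 if site.delta_beta > 0 else 1
        else:
            sign = 1 if rng.random() < 0.5 else -1
        rows.append({"site_id": site.site_id, "gene": f"GENE{i:05d}",
                     "log2fc": sign * mag})
    return pd.DataFrame(rows)


def make_g4_contrast_windows(
    n_per_group: int = 500,
    p_high: float = 0.60,
    p_low: float = 0.15,
    length: int = 100,
    gc_fraction: float = 0.41,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Windows for the methylation-stratum G-quadruplex contrast.

    Random windows for a high-beta and a low-beta stratum with the G4 motif
    planted at a fixed offset with probability ``p_high`` / ``p_low``
    respectively.  Returns ``(high_windows, low_windows)``.
    """
    rng = np.random.default_rng(seed)

    def _group(n: int, p: float) -> list[str]:
        out = []
        for _ in range(n):
            arr = _random_sequence(rng, length, gc_fraction)
            if rng.random() < p:
                start = 10
                arr[start : start + len(G4_MOTIF)] = np.frombuffer(
                    G4_MOTIF.encode(), dtype="S1")
            out.append(arr.tobytes().decode("ascii"))
        return out

    return _group(n_per_group, p_high), _group(n_per_group, p_low)


def write_fixtures(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture set (FASTA, BED, beta TSV, annotation, truth,
    expression) for CLI use; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, sites = make_genome(config)
    rng = np.random.default_rng(config.seed + 4)
    n_enr = config.n_sites // 2
    classes = {
        s.site_id: ("enriched" if i < n_enr else "desert")
        for i, s in enumerate(sites)
    }
    genome, truth = plant_features(genome, sites, classes, config)
    diff_ids = [s.site_id for s in sites]
    matrix = make_beta_matrix(config, sites, differential_ids=diff_ids[: n_enr])
    expr = make_expression_table(truth, sites, coupling=0.5, noise_sd=0.1,
                                 seed=config.seed + 5)

    paths = {}
    paths["genome"] = outdir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["sites"] = outdir / "sites.bed"
    with open(paths["sites"], "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t0\t{s.site_id}\n")
    paths["beta"] = outdir / "beta_matrix.tsv"
    matrix.values.to_csv(paths["beta"], sep="\t")
    paths["groups"] = outdir / "groups.tsv"
    matrix.groups.to_csv(paths["groups"], sep="\t", header=False)
    paths["coords"] = outdir / "site_coords.tsv"
    matrix.sites.to_csv(paths["coords"], sep="\t")
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", index=False)
    return paths
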