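"""End-to-end orchestration: windows -> raw features -> signatures -> ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .conformational import (
    SHAPE_NAMES,
    PentamerShapeTable,
    find_palindromes,
    g4_count,
    shape_delta,
)
from .regulatory import (
    AnnotationTrack,
    PositionWeightMatrix,
    SpliceSiteModel,
    acceptor_model,
    count_track_overlaps,
    donor_model,
    find_splice_sites,
    scan_pwm,
)
from .seqcontext import SequenceWindow, cpg_oe_ratio, gc_content
from .signature import (
    SignatureMatrix,
    WeightScheme,
    map_attributes,
    rank_sites,
)

__all__ = ["FeatureConfig", "extract_features", "build_ranking"]


@dataclass
class FeatureConfig:
    """Detector parameters for one feature-extraction run."""

    g4_min_run: int = 3
    g4_loop_min: int = 1
    g4_loop_max: int = 7
    pal_min_arm: int = 6
    pal_max_loop: int = 10
    pwm_min_rel_score: float = 0.8
    ss_min_score: float = 80.0
    shape_alpha: float = 0.05


def extract_features(
    windows: Sequence[SequenceWindow],
    pwms: Sequence[PositionWeightMatrix] = (),
    ctfbs_track: AnnotationTrack | None = None,
    altspl_track: AnnotationTrack | None = None,
    donor: SpliceSiteModel | None = None,
    acceptor: SpliceSiteModel | None = None,
    shape_table: PentamerShapeTable | None = None,
    config: FeatureConfig | None = None,
    composition: bool = True,
) -> pd.DataFrame:
    """Raw per-window feature table (one row per site).

    Columns: site_id, chrom, start, delta_beta, g4, pals, tfbs, ctfbs,
    donor_hits, acceptor_hits, altspl_count, shape_<name>_p per shape (when a
    shape table is given), and gc / cpg_oe composition statistics.
    """
    cfg = config or FeatureConfig()
    donor = donor if donor is not None else donor_model()
    acceptor = acceptor if acceptor is not None else acceptor_model()
    rows = []
    for w in windows:
        site = w.site
        row: dict = {
            "site_id": site.site_id or f"{site.chrom}:{site.start}",
            "chrom": site.chrom,
            "start": site.start,
            "delta_beta": site.delta_beta if site.delta_beta is not None else 0.0,
        }
        row["g4"] = g4_count(
            w, min_run=cfg.g4_min_run, loop_min=cfg.g4_loop_min,
            loop_max=cfg.g4_loop_max,
        )
        row["pals"] = len(
            find_palindromes(w.sequence, cfg.pal_min_arm, cfg.pal_max_loop)
        )
        row["tfbs"] = sum(
            len(scan_pwm(w, p, cfg.pwm_min_rel_score)) for p in pwms
        )
        row["ctfbs"] = (
            count_track_overlaps(w, ctfbs_track) if ctfbs_track is not None else 0
        )
        _, hits = find_splice_sites(w, donor, acceptor, cfg.ss_min_score)
        row["donor_hits"] = sum(1 for h in hits if h.site_type == "donor")
        row["acceptor_hits"] = sum(1 for h in hits if h.site_type == "acceptor")
        row["altspl_count"] = (
            count_track_overlaps(w, altspl_track) if altspl_track is not None else 0
        )
        if shape_table is not None:
            for shape in SHAPE_NAMES:
                row[f"shape_{shape}_p"] = shape_delta(w, shape_table, shape).p_value
        if composition:
            row["gc"] = gc_content(w.sequence)
            row["cpg_oe"] = cpg_oe_ratio(w.sequence)
        rows.append(row)
    return pd.DataFrame(rows)


def build_ranking(
    features: pd.DataFrame,
    weights: WeightScheme | None = None,
    attributes: Sequence[str] | None = None,
    shape_alpha: float = 0.05,
):
    """Map raw features and rank sites; returns (matrix, ranked results).

    Attributes default to the six standard ones, dropping shape/splicing when
    their raw columns are absent from the feature table.
    """
    if attributes is None:
        attributes = ["G4", "Pals", "TFBS", "cTFBS"]
        if any(c in features.columns
               for c in ("donor_hits", "acceptor_hits", "altspl_count")):
            attributes.append("splicing")
        if any(c.startswith("shape_") for c in features.columns):
            attributes.append("shape")
    matrix = map_attributes(features, shape_alpha=shape_alpha,
                            attributes=tuple(attributes))
    if weights is None:
        weights = WeightScheme.uniform(tuple(attributes))
    return matrix, rank_sites(matrix, weights)
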