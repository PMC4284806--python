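"""Overlap accounting of DMRs with genomic features and fold enrichment.

Fold enrichment follows the density-ratio statistic
(observed features in the examined regions / examined bp) /
(features in the reference / reference bp); a feature counts as "in" a
region set when it overlaps it by >= 1 bp, at most once per region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import intervals as _iv
from .core import FeatureSet, GenomicInterval

__all__ = [
    "EnrichmentResult",
    "fold_enrichment",
    "containment_table",
    "methylation_stratified_marks",
    "predict_important_tfs",
]


@dataclass
class EnrichmentResult:
    feature_name: str
    observed_count: int
    region_bp: int
    reference_count: int
    reference_bp: int
    fold: Optional[float]  # None when the reference is empty
    containment_frac: float


def _merged_by_chrom(regions: Sequence[GenomicInterval]):
    tmp = FeatureSet("regions", list(regions)).by_chrom()
    return {c: _iv.merge(s, e) for c, (s, e) in tmp.items()}


def _regions_overlapping_features(
    regions: Sequence[GenomicInterval], features: FeatureSet
) -> np.ndarray:
    merged = {c: _iv.merge(s, e) for c, (s, e) in features.by_chrom().items()}
    out = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        if r.chrom in merged:
            ms, me = merged[r.chrom]
            out[i] = bool(_iv.overlaps_any(r.start, r.end, ms, me))
    return out


def fold_enrichment(
    features: FeatureSet,
    regions: Sequence[GenomicInterval],
    reference_bp: int,
    reference_count: int,
) -> EnrichmentResult:
    """Density of features in the examined regions over their density in a
    reference region set (whole genome or total DMRs).

    ``region_bp`` is the merged (union) length of the examined regions.
    A zero-feature reference leaves ``fold`` undefined (None); containment
    is always computed.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if reference_bp <= 0:
        raise ValueError("reference_bp must be positive")
    merged = _merged_by_chrom(regions)
    region_bp = sum(int(np.sum(me - ms)) for ms, me in merged.values())
    observed = 0
    for chrom, (fs, fe) in features.by_chrom().items():
        if chrom in merged:
            ms, me = merged[chrom]
            observed += _iv.count_features_overlapping(fs, fe, ms, me)
    fold: Optional[float] = None
    if reference_count > 0:
        fold = (observed / region_bp) / (reference_count / reference_bp)
    containment = float(np.mean(_regions_overlapping_features(regions, features)))
    return EnrichmentResult(
        feature_name=features.feature_name,
        observed_count=observed,
        region_bp=region_bp,
        reference_count=reference_count,
        reference_bp=reference_bp,
        fold=fold,
        containment_frac=containment,
    )


def containment_table(
    regions: Sequence[GenomicInterval], feature_sets: Sequence[FeatureSet]
) -> pd.Series:
    """Per feature set, the fraction of regions containing >= 1 feature."""
    return pd.Series(
        {
            fs.feature_name: float(np.mean(_regions_overlapping_features(regions, fs)))
            if regions
            else float("nan")
            for fs in feature_sets
        }
    )


def methylation_stratified_marks(
    dmrs: Sequence,
    dmr_levels: np.ndarray,
    k4_clusters: FeatureSet,
    k27_clusters: FeatureSet,
    low: float = 0.30,
    high: float = 0.70,
) -> pd.DataFrame:
    """Association of active/polycomb marks with DMR methylation strata.

    ``dmr_levels`` holds one methylation value per DMR-sample pair examined
    (rows align with ``dmrs`` repeated per sample, or one value per DMR).
    Pairs with level < ``low`` form the low stratum, >= ``high`` the high
    stratum; intermediate pairs are not tabulated. Reports, per stratum,
    the fraction of pairs whose DMR overlaps both marks, either, or none.
    """
    dmr_list = list(dmrs)
    lv = np.asarray(dmr_levels, dtype=float).reshape(len(dmr_list), -1)
    iv = [d.interval if hasattr(d, "interval") else d for d in dmr_list]
    has_k4 = _regions_overlapping_features(iv, k4_clusters)
    has_k27 = _regions_overlapping_features(iv, k27_clusters)

    rows = {}
    for name, mask in (("low", lv < low), ("high", lv >= high)):
        pair_idx, _ = np.nonzero(mask)
        n = len(pair_idx)
        if n == 0:
            rows[name] = dict(n_pairs=0, both=np.nan, either=np.nan, none=np.nan)
            continue
        b = has_k4[pair_idx] & has_k27[pair_idx]
        e = has_k4[pair_idx] | has_k27[pair_idx]
        rows[name] = dict(
            n_pairs=n,
            both=float(np.mean(b)),
            either=float(np.mean(e)),
            none=float(np.mean(~e)),
        )
    return pd.DataFrame(rows).T


def predict_important_tfs(
    tf_site_sets: Sequence[FeatureSet],
    dmr3_regions: Sequence[GenomicInterval],
    all_dmr_regions: Sequence[GenomicInterval],
    min_fold: float = 1.2,
    min_overlap: float = 0.10,
    overlap_basis: str = "regions",
) -> pd.DataFrame:
    """Select factors over-represented in ESC-only-demethylated DMRs.

    A factor passes when (a) more than ``min_overlap`` of the DMR-3 regions
    contain >= 1 of its sites (``overlap_basis="regions"``; ``"bp"`` uses the
    base-pair fraction of DMR-3 covered by sites instead) and (b) the fold
    enrichment of its sites in DMR-3 relative to the total-DMR reference
    exceeds ``min_fold``. Factors with empty site sets are skipped.
    """
    all_merged = _merged_by_chrom(all_dmr_regions)
    ref_bp = sum(int(np.sum(me - ms)) for ms, me in all_merged.values())
    dmr3_merged = _merged_by_chrom(dmr3_regions)
    rows = []
    for fs in tf_site_sets:
        if len(fs) == 0:
            continue
        ref_count = 0
        for chrom, (s, e) in fs.by_chrom().items():
            if chrom in all_merged:
                ms, me = all_merged[chrom]
                ref_count += _iv.count_features_overlapping(s, e, ms, me)
        res = fold_enrichment(fs, list(dmr3_regions), ref_bp, ref_count)
        if overlap_basis == "regions":
            overlap = res.containment_frac
        else:
            cov = 0
            tot = 0
            site_merged = {c: _iv.merge(s, e) for c, (s, e) in fs.by_chrom().items()}
            for chrom, (ms, me) in dmr3_merged.items():
                tot += int(np.sum(me - ms))
                if chrom in site_merged:
                    ss, se = site_merged[chrom]
                    cov += int(np.sum(_iv.covered_bp(ms, me, ss, se)))
            overlap = cov / tot if tot else 0.0
        selected = (
            res.fold is not None and res.fold > min_fold and overlap > min_overlap
        )
        rows.append(
            dict(
                factor=fs.feature_name,
                fold=res.fold,
                overlap=overlap,
                selected=bool(selected),
            )
        )
    return pd.DataFrame(rows, columns=["factor", "fold", "overlap", "selected"])
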