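"""Methylation and histone-mark change at and around TF binding sites.

Focal statistics average within the binding-site interval; neighborhood
profiles lay symmetric fixed-width bins around the (unoriented) site
midpoint — by default 400 bins of 200 bp, i.e. +/- 40 kb — and average the
per-CpG change relative to the somatic baseline across all sites of a
factor. Histone change uses a peak-coverage enrichment score computed on
30-bp windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import intervals as _iv
from .core import FeatureSet, GenomicInterval, Methylome, SampleSeries, SiteMatrix

__all__ = [
    "FocalDelta",
    "NeighborhoodProfile",
    "site_methylation",
    "focal_delta",
    "neighborhood_profile",
    "histone_delta_profile",
    "half_width_at_half_depth",
]


@dataclass
class FocalDelta:
    feature_name: str
    samples: list[str]
    per_sample_delta: np.ndarray  # mean within-site change vs baseline
    n_sites_used: np.ndarray  # per sample


@dataclass
class NeighborhoodProfile:
    feature_name: str
    bin_width: int
    n_bins: int
    samples: list[str]
    delta_matrix: np.ndarray  # (n_bins, n_samples)
    n_sites_contributing: np.ndarray  # per bin


def site_methylation(site: GenomicInterval, methylome: Methylome) -> float:
    """Unweighted mean adjusted level of covered CpGs inside the site; NaN
    when the site holds no covered CpG."""
    df = methylome.sites
    if "level" not in df.columns:
        raise ValueError("methylome has no levels; run calling.add_levels first")
    sel = df["chrom"].to_numpy() == site.chrom
    pos = df["pos"].to_numpy()[sel]
    lv = df["level"].to_numpy()[sel]
    lo, hi = np.searchsorted(pos, [site.start, site.end])
    vals = lv[lo:hi]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def _site_level_matrix(feature_set: FeatureSet, sm: SiteMatrix) -> np.ndarray:
    """(n_sites_in_set, n_samples) mean covered-CpG level per site; NaN when
    a site has no covered CpG for that sample."""
    chrom_index = {c: sl for c, sl in sm.chrom_slices()}
    out = np.full((len(feature_set.intervals), len(sm.samples)), np.nan)
    for i, ivl in enumerate(feature_set.intervals):
        sl = chrom_index.get(ivl.chrom)
        if sl is None:
            continue
        pos = sm.pos[sl]
        lo, hi = np.searchsorted(pos, [ivl.start, ivl.end])
        if lo == hi:
            continue
        lv = sm.levels[sl][lo:hi]
        with np.errstate(invalid="ignore"):
            cnt = np.sum(~np.isnan(lv), axis=0)
            s = np.nansum(lv, axis=0)
        out[i] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return out


def focal_delta(
    feature_set: FeatureSet, sm: SiteMatrix, series: SampleSeries
) -> FocalDelta:
    """Mean within-site methylation change vs the baseline, per sample.

    Sites missing in either the sample or the baseline are excluded
    pairwise; an all-missing factor is an error.
    """
    site_lv = _site_level_matrix(feature_set, sm)
    b = sm.sample_index(series.baseline_label)
    base = site_lv[:, b]
    deltas = np.full(len(sm.samples), np.nan)
    n_used = np.zeros(len(sm.samples), dtype=int)
    for j in range(len(sm.samples)):
        ok = ~np.isnan(site_lv[:, j]) & ~np.isnan(base)
        n_used[j] = int(ok.sum())
        if n_used[j]:
            deltas[j] = float(np.mean(site_lv[ok, j] - base[ok]))
    if n_used.max() == 0:
        raise ValueError(f"no site of {feature_set.feature_name} has covered CpGs")
    return FocalDelta(feature_set.feature_name, list(sm.samples), deltas, n_used)


def neighborhood_profile(
    feature_set: FeatureSet,
    sm: SiteMatrix,
    series: SampleSeries,
    bin_width: int = 200,
    n_bins: int = 400,
) -> NeighborhoodProfile:
    """Binned mean per-CpG methylation change vs baseline around site
    midpoints. Bins beyond chromosome ends simply receive no CpGs; the
    number of sites contributing >= 1 CpG is tracked per bin."""
    if n_bins % 2:
        raise ValueError("n_bins must be even")
    half = (n_bins // 2) * bin_width
    b = sm.sample_index(series.baseline_label)
    chrom_index = {c: sl for c, sl in sm.chrom_slices()}

    S = len(sm.samples)
    sums = np.zeros((n_bins, S))
    cnts = np.zeros((n_bins, S))
    site_hits = np.zeros(n_bins, dtype=int)
    for ivl in feature_set.intervals:
        sl = chrom_index.get(ivl.chrom)
        if sl is None:
            continue
        pos = sm.pos[sl]
        mid = ivl.midpoint
        lo, hi = np.searchsorted(pos, [mid - half, mid + half])
        if lo == hi:
            continue
        bins = (pos[lo:hi] - (mid - half)) // bin_width
        bins = bins.astype(int)
        lv = sm.levels[sl][lo:hi]
        delta = lv - lv[:, b][:, None]
        ok = ~np.isnan(delta)
        np.add.at(sums, bins, np.where(ok, delta, 0.0))
        np.add.at(cnts, bins, ok.astype(float))
        site_hits[np.unique(bins)] += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return NeighborhoodProfile(
        feature_set.feature_name, bin_width, n_bins, list(sm.samples), mat, site_hits
    )


def _merged_peaks(peaks: FeatureSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {c: _iv.merge(s, e) for c, (s, e) in peaks.by_chrom().items()}


def _window_scores(
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    if chrom not in merged:
        return np.zeros(len(starts))
    ms, me = merged[chrom]
    return _iv.coverage_fraction(starts, ends, ms, me)


def histone_delta_profile(
    peak_sets_by_sample: dict[str, FeatureSet],
    feature_set: FeatureSet,
    series: SampleSeries,
    window: int = 30,
    mode: str = "focal",
    bin_width: int = 200,
    n_bins: int = 400,
) -> FocalDelta | NeighborhoodProfile:
    """Histone enrichment change vs baseline at ("focal") or around
    ("neighborhood") binding sites.

    The enrichment score of a ``window``-bp window is the fraction of it
    covered by a peak; site scores average over the windows tiling the site
    (focal) or the neighborhood grid, which is then aggregated into
    ``bin_width`` bins like the methylation profile.
    """
    merged = {lab: _merged_peaks(ps) for lab, ps in peak_sets_by_sample.items()}
    labels = list(series.labels)
    missing = [l for l in labels if l not in merged]
    if missing:
        raise ValueError(f"missing peak sets for samples {missing}")

    if mode == "focal":
        deltas = np.zeros(len(labels))
        per_site = np.full((len(feature_set.intervals), len(labels)), np.nan)
        for i, ivl in enumerate(feature_set.intervals):
            w_start = np.arange(ivl.start, ivl.end, window, dtype=np.int64)
            w_end = np.minimum(w_start + window, ivl.end)
            for j, lab in enumerate(labels):
                sc = _window_scores(ivl.chrom, w_start, w_end, merged[lab])
                per_site[i, j] = float(np.mean(sc))
        b = labels.index(series.baseline_label)
        delta = per_site - per_site[:, b][:, None]
        deltas = np.nanmean(delta, axis=0)
        n_used = np.sum(~np.isnan(delta), axis=0)
        return FocalDelta(feature_set.feature_name, labels, deltas, n_used)

    if mode != "neighborhood":
        raise ValueError("mode must be 'focal' or 'neighborhood'")
    if n_bins % 2:
        raise ValueError("n_bins must be even")
    half = (n_bins // 2) * bin_width
    sums = np.zeros((n_bins, len(labels)))
    cnts = np.zeros((n_bins, len(labels)))
    site_hits = np.zeros(n_bins, dtype=int)
    for ivl in feature_set.intervals:
        mid = ivl.midpoint
        w_start = np.arange(mid - half, mid + half, window, dtype=np.int64)
        w_start = w_start[w_start >= 0]
        w_end = w_start + window
        w_mid = w_start + window // 2
        bins = np.clip((w_mid - (mid - half)) // bin_width, 0, n_bins - 1).astype(int)
        scores = np.stack(
            [_window_scores(ivl.chrom, w_start, w_end, merged[lab]) for lab in labels],
            axis=1,
        )
        b = labels.index(series.baseline_label)
        delta = scores - scores[:, b][:, None]
        np.add.at(sums, bins, delta)
        np.add.at(cnts, bins, 1.0)
        site_hits[np.unique(bins)] += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return NeighborhoodProfile(
        feature_set.feature_name, bin_width, n_bins, labels, mat, site_hits
    )


def half_width_at_half_depth(
    delta: np.ndarray, bin_width: int, sign: int = -1
) -> Optional[float]:
    """Half-width (bp) of a dip/bump in a binned profile at half its depth.

    With ``sign=-1`` the profile's minimum is the dip apex; the width is the
    contiguous run of bins around the apex at least half as deep, converted
    to bp and halved. Returns None for a flat profile.
    """
    d = np.asarray(delta, dtype=float) * sign  # make the feature a maximum
    d = np.where(np.isnan(d), 0.0, d)
    apex = int(np.argmax(d))
    depth = d[apex]
    if depth <= 0:
        return None
    thr = depth / 2.0
    lo = apex
    while lo > 0 and d[lo - 1] >= thr:
        lo -= 1
    hi = apex
    while hi < len(d) - 1 and d[hi + 1] >= thr:
        hi += 1
    return (hi - lo + 1) * bin_width / 2.0
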