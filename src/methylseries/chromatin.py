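"""Cross-sample joining of histone-mark peaks into clusters.

Peaks from all samples of one mark are unioned; connected components under
>= 1 bp overlap form clusters (abutting peaks stay separate under the
half-open convention). Each sample's histone mark score within a cluster is
the total base pairs of its peaks there; scores are normalized per cluster
or per gene so the widest sample maps to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as _iv
from .core import FeatureSet, GenomicInterval

__all__ = ["PeakCluster", "join_peaks", "normalize_scores", "assign_to_genes"]


@dataclass
class PeakCluster:
    mark: str
    interval: GenomicInterval
    width_by_sample: dict[str, int]


def join_peaks(peak_sets_by_sample: dict[str, FeatureSet], mark: str) -> list[PeakCluster]:
    """Connected-component clusters of all samples' peaks for one mark."""
    labels = list(peak_sets_by_sample)
    all_iv: list[tuple[str, int, int]] = []
    for lab in labels:
        for p in peak_sets_by_sample[lab].intervals:
            all_iv.append((p.chrom, p.start, p.end))
    if not all_iv:
        return []
    per_sample_merged = {
        lab: {c: _iv.merge(s, e) for c, (s, e) in peak_sets_by_sample[lab].by_chrom().items()}
        for lab in labels
    }
    # cluster spans: merge the union of all peaks
    chroms = sorted({c for c, _, _ in all_iv})
    clusters: list[PeakCluster] = []
    for chrom in chroms:
        starts = np.array([s for c, s, e in all_iv if c == chrom], dtype=np.int64)
        ends = np.array([e for c, s, e in all_iv if c == chrom], dtype=np.int64)
        ms, me = _iv.merge(starts, ends)
        for s, e in zip(ms, me):
            widths = {}
            for lab in labels:
                if chrom in per_sample_merged[lab]:
                    ps, pe = per_sample_merged[lab][chrom]
                    widths[lab] = int(_iv.covered_bp(s, e, ps, pe)[0])
                else:
                    widths[lab] = 0
            clusters.append(
                PeakCluster(mark, GenomicInterval(chrom, int(s), int(e)), widths)
            )
    return clusters


def normalize_scores(scores: dict[str, float] | pd.Series) -> dict[str, float]:
    """Scale a per-sample score vector so the maximum is 1; an all-zero
    vector stays all zero."""
    items = dict(scores)
    mx = max(items.values()) if items else 0.0
    if mx <= 0:
        return {k: 0.0 for k in items}
    return {k: v / mx for k, v in items.items()}


def assign_to_genes(
    clusters_by_mark: dict[str, list[PeakCluster]],
    genes: pd.DataFrame,
    promoters: dict[str, GenomicInterval],
    bodies: dict[str, GenomicInterval],
) -> pd.DataFrame:
    """Per-gene per-mark per-sample peak-width scores.

    Promoter marks (H3K4me3, H3K27me3) are assigned when a cluster overlaps
    the gene's promoter; H3K36me3 when it overlaps the gene body. Scores are
    summed cluster widths per sample. Returns a long-format DataFrame with
    gene_id, mark, sample, width.
    """
    promoter_marks = {"H3K4me3", "H3K27me3"}
    rows = []
    for mark, clusters in clusters_by_mark.items():
        target = promoters if mark in promoter_marks else bodies
        # index clusters per chrom for sweep
        by_chrom: dict[str, list[PeakCluster]] = {}
        for cl in clusters:
            by_chrom.setdefault(cl.interval.chrom, []).append(cl)
        for gene_id in genes["gene_id"]:
            reg = target[gene_id]
            for cl in by_chrom.get(reg.chrom, []):
                if cl.interval.overlaps(reg):
                    for lab, w in cl.width_by_sample.items():
                        rows.append((gene_id, mark, lab, w))
    df = pd.DataFrame(rows, columns=["gene_id", "mark", "sample", "width"])
    if len(df):
        df = df.groupby(["gene_id", "mark", "sample"], as_index=False)["width"].sum()
    return df
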