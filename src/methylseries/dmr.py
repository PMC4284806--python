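"""Sliding-window differential-methylation-region (DMR) detection.

The genome is scanned with windows of ``window_size`` consecutive CpGs
(default 30), advancing one CpG per step, restricted to windows spanning
less than ``max_span`` bp whose CpGs are well covered in every sample.
Each window is tested with a one-way ANOVA (samples as groups, per-CpG
adjusted levels as observations) and screened on effect size (maximum
between-sample difference of window means and max/min fold change).
Benjamini-Hochberg correction is applied genome-wide over all tested
windows; differential windows are joined into DMRs, annotated hyper/hypo
per sample against the somatic baseline, and clustered into trajectory
groups on correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, SampleSeries, SiteMatrix

__all__ = [
    "WindowScan",
    "DMR",
    "build_windows",
    "test_window",
    "scan_windows",
    "bh_adjust",
    "join_windows",
    "classify_status",
    "cluster_dmrs",
    "dmr_accumulation",
    "find_dmrs",
    "archetype_templates",
    "ARCHETYPE_LABELS",
]

# CpG dyads occupy two bases; a window's genomic span runs from its first
# C to the end of its last dyad.
_DYAD = 2

ARCHETYPE_LABELS = ("DMR-1a", "DMR-1b", "DMR-2a", "DMR-2b", "DMR-3")


@dataclass
class WindowScan:
    """All tested windows of one scan, row-aligned across attributes."""

    table: pd.DataFrame  # chrom, start, end, start_idx, max_diff, fold, anova_p, candidate[, q, differential]
    levels: np.ndarray  # (n_windows, n_samples) per-sample window means
    samples: list[str]
    window_size: int

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DMR:
    interval: GenomicInterval
    member_windows: list[int]
    per_sample_levels: dict[str, float]
    status_by_sample: dict[str, str] = field(default_factory=dict)
    group_label: Optional[str] = None
    cluster_id: Optional[int] = None
    site_index_range: Optional[tuple[int, int]] = None  # [lo, hi) into the SiteMatrix


def _sliding_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Sum over length-w windows along axis 0."""
    c = np.cumsum(a, axis=0, dtype=np.float64)
    out = c[w - 1 :].copy()
    out[1:] -= c[:-w]
    return out


def build_windows(
    sm: SiteMatrix,
    window_size: int = 30,
    max_span: int = 6000,
    min_depth: int = 5,
    min_covered: int = 15,
) -> pd.DataFrame:
    """Enumerate eligible windows: every run of ``window_size`` consecutive
    CpGs spanning < ``max_span`` bp where every sample has depth >
    ``min_depth`` at >= ``min_covered`` of the CpGs.

    Returns a DataFrame with chrom, start, end, start_idx (global site index).
    """
    rows = []
    for chrom, sl in sm.chrom_slices():
        pos = sm.pos[sl]
        total = sm.total[sl]
        n = len(pos)
        if n < window_size:
            continue
        nw = n - window_size + 1
        span_ok = (pos[window_size - 1 :] + _DYAD - pos[:nw]) < max_span
        deep = (total > min_depth).astype(np.int64)
        cov_counts = _sliding_sum(deep, window_size)
        cov_ok = (cov_counts >= min_covered).all(axis=1)
        elig = np.flatnonzero(span_ok & cov_ok)
        if elig.size:
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": pos[elig],
                        "end": pos[elig + window_size - 1] + _DYAD,
                        "start_idx": elig + sl.start,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "start_idx"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class WindowTest:
    per_sample_levels: np.ndarray
    max_diff: float
    fold: float
    anova_p: float
    candidate: bool


def test_window(
    levels_by_sample: Sequence[np.ndarray],
    diff_min: float = 0.30,
    fold_min: float = 4.0,
    fold_floor: float = 0.01,
) -> WindowTest:
    """Test a single window from per-sample vectors of covered-CpG levels.

    Reference implementation used for small instances and as the oracle for
    the vectorized scan; groups are samples, observations per-CpG levels.
    """
    groups = [np.asarray(g, dtype=float) for g in levels_by_sample]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every sample needs >= 1 covered CpG in the window")
    means = np.array([g.mean() for g in groups])
    max_diff = float(means.max() - means.min())
    fold = float(means.max() / max(means.min(), fold_floor))
    if all(np.allclose(g, g[0]) for g in groups) and np.allclose(means, means[0]):
        p = 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*groups)
        if np.isnan(p):  # zero within-group variance, unequal means
            p = 0.0
    candidate = (max_diff >= diff_min) and (fold >= fold_min)
    return WindowTest(means, max_diff, fold, float(p), candidate)


def scan_windows(
    sm: SiteMatrix,
    window_size: int = 30,
    max_span: int = 6000,
    min_depth: int = 5,
    min_covered: int = 15,
    diff_min: float = 0.30,
    fold_min: float = 4.0,
    fold_floor: float = 0.01,
) -> WindowScan:
    """Vectorized genome-wide window scan (means, effect screen, ANOVA p)."""
    win = build_windows(sm, window_size, max_span, min_depth, min_covered)
    n_samples = len(sm.samples)
    if len(win) == 0:
        table = win.assign(max_diff=[], fold=[], anova_p=[], candidate=[])
        return WindowScan(table, np.zeros((0, n_samples)), list(sm.samples), window_size)

    # per-site observation arrays: covered = depth > 0, level defined there
    covered = sm.total > 0
    x = np.where(covered, np.nan_to_num(sm.levels), 0.0)

    means_all, f_p, mdiff, fold = [], [], [], []
    lev_rows = []
    for chrom, sl in sm.chrom_slices():
        idx = win.index[win["chrom"] == chrom]
        if len(idx) == 0:
            continue
        local = win.loc[idx, "start_idx"].to_numpy() - sl.start
        xs = x[sl]
        cv = covered[sl].astype(np.float64)
        s1 = _sliding_sum(xs, window_size)[local]  # (nw, S) sums
        s2 = _sliding_sum(xs * xs, window_size)[local]
        nv = _sliding_sum(cv, window_size)[local]
        if np.any(nv == 0):
            raise AssertionError("window with an uncovered sample slipped the gate")
        mean = s1 / nv
        ntot = nv.sum(axis=1)
        grand = s1.sum(axis=1) / ntot
        ssb = (nv * (mean - grand[:, None]) ** 2).sum(axis=1)
        ssw = np.maximum((s2 - nv * mean**2).sum(axis=1), 0.0)
        k = nv.shape[1]
        df1, df2 = k - 1, ntot - k
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat = (ssb / df1) / (ssw / df2)
        p = stats.f.sf(f_stat, df1, df2)
        # degenerate windows: no within variance
        tiny = ssw <= 1e-12 * np.maximum(ssb, 1.0)
        p = np.where(tiny & (ssb > 1e-12), 0.0, p)
        p = np.where(tiny & (ssb <= 1e-12), 1.0, p)
        lev_rows.append(mean)
        means_all.append(mean)
        f_p.append(p)
        mdiff.append(mean.max(axis=1) - mean.min(axis=1))
        fold.append(mean.max(axis=1) / np.maximum(mean.min(axis=1), fold_floor))

    levels = np.concatenate(lev_rows, axis=0)
    table = win.copy()
    table["max_diff"] = np.concatenate(mdiff)
    table["fold"] = np.concatenate(fold)
    table["anova_p"] = np.concatenate(f_p)
    table["candidate"] = (table["max_diff"] >= diff_min) & (table["fold"] >= fold_min)
    return WindowScan(table, levels, list(sm.samples), window_size)


def bh_adjust(p_values, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one family; returns (q_values, reject)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def mark_differential(scan: WindowScan, alpha: float = 0.01) -> WindowScan:
    """BH over all tested windows; differential = candidate AND q < alpha."""
    q, _ = bh_adjust(scan.table["anova_p"].to_numpy(), alpha)
    scan.table["q"] = q
    scan.table["differential"] = scan.table["candidate"] & (q < alpha)
    return scan


def join_windows(
    windows: pd.DataFrame | Sequence[tuple[str, int, int]],
    reciprocal_frac: float = 0.60,
    rule: str = "extension",
) -> list[dict]:
    """Join differential windows into DMR intervals.

    Pass 1 merges windows overlapping by >= 1 bp (single linkage). Pass 2,
    iterated to a fixpoint, additionally merges consecutive regions when the
    smaller of the two, extended across the gap, would still cover more than
    ``reciprocal_frac`` of itself inside the union — i.e. when the gap is
    below ``(1 - reciprocal_frac) * min(len_a, len_b)`` (rule="extension",
    default) or ``(1 - reciprocal_frac) * len_a`` with the progressing
    (left) region as the yardstick (rule="progressing").

    Returns dicts with chrom, start, end, members (input row indices).
    """
    if rule not in ("extension", "progressing"):
        raise ValueError("rule must be 'extension' or 'progressing'")
    if isinstance(windows, pd.DataFrame):
        recs = list(
            zip(windows["chrom"].tolist(), windows["start"].tolist(), windows["end"].tolist())
        )
    else:
        recs = [(c, int(s), int(e)) for c, s, e in windows]
    order = sorted(range(len(recs)), key=lambda i: (recs[i][0], recs[i][1], recs[i][2]))

    regions: list[dict] = []
    for i in order:
        c, s, e = recs[i]
        if regions and regions[-1]["chrom"] == c and s < regions[-1]["end"]:
            regions[-1]["end"] = max(regions[-1]["end"], e)
            regions[-1]["members"].append(i)
        else:
            regions.append({"chrom": c, "start": s, "end": e, "members": [i]})

    changed = True
    while changed:
        changed = False
        out: list[dict] = []
        for r in regions:
            if out and out[-1]["chrom"] == r["chrom"]:
                a, b = out[-1], r
                gap = b["start"] - a["end"]
                len_a = a["end"] - a["start"]
                len_b = b["end"] - b["start"]
                yardstick = len_a if rule == "progressing" else min(len_a, len_b)
                if gap < (1.0 - reciprocal_frac) * yardstick:
                    a["end"] = max(a["end"], b["end"])
                    a["members"].extend(b["members"])
                    changed = True
                    continue
            out.append(r)
        regions = out
    return regions


def classify_status(
    per_sample_levels: dict[str, float], series: SampleSeries, delta: float = 0.20
) -> dict[str, str]:
    """Hyper/hypo/none per non-baseline sample vs the baseline level.

    Strictly more than ``delta`` (absolute level units) above the baseline is
    hyper, below is hypo.
    """
    if series.baseline_label not in per_sample_levels:
        raise ValueError("baseline level missing")
    base = per_sample_levels[series.baseline_label]
    out = {}
    for lab in series.labels:
        if lab == series.baseline_label:
            continue
        lv = per_sample_levels[lab]
        if lv - base > delta:
            out[lab] = "hyper"
        elif base - lv > delta:
            out[lab] = "hypo"
        else:
            out[lab] = "none"
    return out


def archetype_templates(series: SampleSeries) -> dict[str, np.ndarray]:
    """Idealized trajectory per DMR group over the sample order.

    1a gains early in the time-course, 1b gains late; 2a loses methylation
    toward the F-class state but is methylated in ESC-like samples, 2b the
    mirror image; 3 is demethylated only in the ESC-like state.
    """
    course = [
        l
        for l in series.labels
        if l != series.baseline_label and l not in series.esc_like_labels
    ]
    n_course = max(len(course), 1)
    ramp = {l: (i + 1) / n_course for i, l in enumerate(course)}

    def build(base: float, course_val, esc: float) -> np.ndarray:
        vals = []
        for l in series.labels:
            if l == series.baseline_label:
                vals.append(base)
            elif l in series.esc_like_labels:
                vals.append(esc)
            else:
                vals.append(course_val(l))
        return np.asarray(vals, dtype=float)

    half = 0.35  # fraction of the course considered "early"
    return {
        "DMR-1a": build(0.0, lambda l: 1.0 if ramp[l] > half else ramp[l] / half, 1.0),
        "DMR-1b": build(0.0, lambda l: max(0.0, (ramp[l] - half) / (1 - half)), 1.0),
        "DMR-2a": build(1.0, lambda l: 1.0 - ramp[l], 1.0),
        "DMR-2b": build(0.0, lambda l: ramp[l], 0.0),
        "DMR-3": build(1.0, lambda l: 1.0, 0.0),
    }


def cluster_dmrs(
    levels: np.ndarray,
    series: SampleSeries,
    n_groups: int = 6,
) -> pd.DataFrame:
    """Cluster DMR trajectories and map clusters to archetype labels.

    Rows are mean-centred and variance-scaled; agglomerative clustering with
    distance 1 - Pearson correlation and average linkage, cut into
    ``n_groups``. Each cluster's mean trajectory is then assigned the
    best-correlated archetype label; the raw cluster id is retained.
    Zero-variance rows are excluded from clustering (cluster_id -1) and
    labelled by nearest archetype in level space.
    """
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    sd = levels.std(axis=1)
    variable = sd > 1e-12
    cluster_id = np.full(n, -1, dtype=int)
    if variable.sum() >= 1:
        z = levels[variable]
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        k = min(n_groups, variable.sum())
        if variable.sum() == 1:
            cluster_id[variable] = 1
        else:
            d = pdist(z, metric="correlation")
            lk = linkage(d, method="average")
            cluster_id[variable] = fcluster(lk, t=k, criterion="maxclust")

    templates = archetype_templates(series)
    t_names = list(templates)
    t_mat = np.stack([templates[name] for name in t_names])
    t_z = (t_mat - t_mat.mean(axis=1, keepdims=True)) / np.maximum(
        t_mat.std(axis=1, keepdims=True), 1e-12
    )

    labels = np.empty(n, dtype=object)
    for cid in np.unique(cluster_id):
        sel = cluster_id == cid
        if cid == -1:
            # flat trajectories: nearest archetype by Euclidean distance
            for i in np.flatnonzero(sel):
                dist = np.linalg.norm(t_mat - levels[i], axis=1)
                labels[i] = t_names[int(np.argmin(dist))]
            continue
        mean_traj = levels[sel].mean(axis=0)
        mz = mean_traj - mean_traj.mean()
        msd = mz.std()
        if msd <= 1e-12:
            dist = np.linalg.norm(t_mat - mean_traj, axis=1)
            labels[sel] = t_names[int(np.argmin(dist))]
            continue
        mz = mz / msd
        corr = (t_z * mz).mean(axis=1)
        labels[sel] = t_names[int(np.argmax(corr))]
    return pd.DataFrame({"cluster_id": cluster_id, "group_label": labels})


def dmr_accumulation(
    dmrs: Sequence[DMR],
    series: SampleSeries,
    sharing_pairs: Sequence[tuple[str, str]] = (),
) -> tuple[pd.DataFrame, dict]:
    """Per-sample hyper/hypo DMR counts plus status-sharing fractions.

    ``sharing_pairs`` are (sample_a, sample_b) pairs; the sharing fraction
    for a status is the fraction of DMRs with that status in sample_a that
    also carry it in sample_b.
    """
    samples = [l for l in series.labels if l != series.baseline_label]
    counts = pd.DataFrame(
        0, index=samples, columns=["hyper", "hypo"], dtype=int
    )
    for d in dmrs:
        for lab, st in d.status_by_sample.items():
            if st in ("hyper", "hypo"):
                counts.loc[lab, st] += 1
    sharing = {}
    for a, b in sharing_pairs:
        for st in ("hyper", "hypo"):
            in_a = [d for d in dmrs if d.status_by_sample.get(a) == st]
            if not in_a:
                sharing[(a, b, st)] = float("nan")
            else:
                both = sum(1 for d in in_a if d.status_by_sample.get(b) == st)
                sharing[(a, b, st)] = both / len(in_a)
    return counts, sharing


def find_dmrs(
    sm: SiteMatrix,
    series: SampleSeries,
    window_size: int = 30,
    max_span: int = 6000,
    min_depth: int = 5,
    min_covered: int = 15,
    diff_min: float = 0.30,
    fold_min: float = 4.0,
    fdr_alpha: float = 0.01,
    status_delta: float = 0.20,
    join_frac: float = 0.60,
    n_groups: int = 6,
    join_rule: str = "extension",
) -> tuple[WindowScan, list[DMR]]:
    """End-to-end DMR detection on a common-site matrix.

    Returns the full window scan and the joined, annotated, clustered DMRs.
    """
    if list(sm.samples) != list(series.labels):
        raise ValueError("site matrix sample order must match the series")
    scan = scan_windows(
        sm, window_size, max_span, min_depth, min_covered, diff_min, fold_min
    )
    scan = mark_differential(scan, fdr_alpha)
    diff = scan.table[scan.table["differential"]]
    regions = join_windows(diff, join_frac, join_rule)

    covered = sm.total > 0
    lv = np.nan_to_num(sm.levels) * covered
    dmrs: list[DMR] = []
    for r in regions:
        member_rows = [int(diff.index[m]) for m in r["members"]]
        member_starts = [int(diff.iloc[m]["start_idx"]) for m in r["members"]]
        idx_lo = min(member_starts)
        idx_hi = max(member_starts) + window_size
        # all CpGs inside the DMR interval (pass-2 joins may bridge a gap)
        per_sample = {}
        sub_lv = lv[idx_lo:idx_hi]
        sub_cov = covered[idx_lo:idx_hi]
        with np.errstate(invalid="ignore"):
            means = sub_lv.sum(axis=0) / np.maximum(sub_cov.sum(axis=0), 1)
        for j, lab in enumerate(sm.samples):
            per_sample[lab] = float(means[j])
        d = DMR(
            interval=GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
            member_windows=member_rows,
            per_sample_levels=per_sample,
            site_index_range=(idx_lo, idx_hi),
        )
        d.status_by_sample = classify_status(per_sample, series, status_delta)
        dmrs.append(d)

    if len(dmrs) >= 2:
        lvmat = np.array([[d.per_sample_levels[s] for s in sm.samples] for d in dmrs])
        cl = cluster_dmrs(lvmat, series, n_groups=min(n_groups, len(dmrs)))
        for d, cid, lab in zip(dmrs, cl["cluster_id"], cl["group_label"]):
            d.cluster_id = int(cid)
            d.group_label = str(lab)
    elif len(dmrs) == 1:
        dmrs[0].cluster_id = 1
        templates = archetype_templates(series)
        row = np.array([dmrs[0].per_sample_levels[s] for s in sm.samples])
        best = min(templates, key=lambda k: np.linalg.norm(templates[k] - row))
        dmrs[0].group_label = best
    return scan, dmrs
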