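"""Seeded generator of complete pipeline inputs with ground truth.

The generator lays planted elements (CpG islands, DMR archetype regions,
gene promoters, TF binding sites) along one synthetic chromosome, fills the
gaps with background CpGs, assigns every CpG a true methylation trajectory
across the sample series, and samples read counts binomially with the
bisulfite nonconversion error folded into the success probability (optional
beta-binomial overdispersion). It also emits spike-in controls, per-sample
histone peak tracks anti-correlated with methylation, TFBS sets with focal
demethylation kernels that widen in the ESC-like samples, gene models and
FPKM trajectories for the seven expression classes — together with a
manifest of where everything was planted.

One seed fixes the whole bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import FeatureSet, GenomicInterval, Methylome, SampleSeries
from .calling import SpikeInControl
from .dmr import ARCHETYPE_LABELS, archetype_templates

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimBundle",
    "default_series",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_tfbs_and_peaks",
    "simulate_expression",
    "simulate_bundle",
    "simulate_promoter_mark_transitions",
    "class_on_pattern",
    "class_promoter_trajectory",
    "write_bundle",
]

# provenance codes for CpG sites
BG, ISLAND, DMRSITE, PROMOTER, TFSITE = 0, 1, 2, 3, 4

_DYAD = 2


def default_series() -> SampleSeries:
    """Twelve samples: somatic baseline, dox time-course intermediates, the
    two F-class samples, and four ESC-like pluripotent samples."""
    return SampleSeries(
        labels=(
            "MEF",
            "D2H",
            "D5H",
            "D8H",
            "D11H",
            "D16H",
            "D18H",
            "D21L",
            "D21N",
            "iPSC1",
            "iPSC2",
            "ESC",
        ),
        baseline_label="MEF",
        esc_like_labels=("D21N", "iPSC1", "iPSC2", "ESC"),
        fclass_labels=("D16H", "D18H"),
    )


@dataclass
class SimConfig:
    """All generator knobs. Defaults define the standard study conditions:
    one 10-Mb chromosome, ~50,000 CpGs, 12 samples at 30x mean depth,
    nonconversion 0.005, 60 planted regions per DMR archetype with a
    0.1-0.8 level swing, focal kernels of sd 1 kb widening to 10 kb in the
    ESC-like state, and 40 genes per expression class."""

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    n_cpgs: int = 50_000
    # islands
    n_islands: int = 40
    island_n_cpgs: int = 60
    island_spacing: float = 12.0
    # methylation levels
    background_high: float = 0.80
    low_level: float = 0.10
    level_jitter_sd: float = 0.03
    # counts
    depth_mean: float = 30.0
    nonconversion: float = 0.005
    spike_total: int = 100_000
    overdispersion: float = 0.0  # beta-binomial intra-class correlation
    # planted DMR archetypes
    dmr_counts: dict = field(
        default_factory=lambda: {lab: 60 for lab in ARCHETYPE_LABELS}
    )
    dmr_n_cpgs: int = 35
    dmr_spacing: float = 35.0
    # genes / expression
    genes_per_class: int = 40
    n_unclassified_genes: int = 70
    promoter_n_cpgs: int = 20
    promoter_spacing: float = 18.0
    gene_length_range: tuple = (2000, 8000)
    on_fpkm_level: float = 10.0
    off_fpkm_max: float = 0.3
    expr_noise_sigma: float = 0.10
    on_fpkm_threshold: float = 1.0
    # TF binding sites and demethylation kernels
    tf_factors: tuple = (
        ("OCT4", "active_early"),
        ("SOX2", "active_early"),
        ("ESRRB", "esc_only"),
    )
    tf_sites_per_factor: int = 12
    tf_site_width: int = 200
    tf_site_n_cpgs: int = 8
    kernel_depth: float = 0.70
    kernel_sd_intermediate: float = 1000.0
    kernel_sd_esc: float = 10_000.0
    # histone peaks
    mark_low_meth_coupling: float = 0.95
    peak_pad: int = 200
    meth_low_for_peak: float = 0.30

    @classmethod
    def null(cls, seed: int = 0, n_cpgs: int = 50_000) -> "SimConfig":
        """Study conditions with nothing planted: every CpG follows a stable
        trajectory, for null-calibration experiments."""
        return cls(
            seed=seed,
            n_cpgs=n_cpgs,
            n_islands=250,
            island_n_cpgs=100,
            dmr_counts={lab: 0 for lab in ARCHETYPE_LABELS},
            genes_per_class=0,
            n_unclassified_genes=50,
            tf_factors=(),
        )


@dataclass
class GroundTruth:
    dmr_regions: pd.DataFrame  # chrom,start,end,label,idx_lo,idx_hi + per-sample true levels
    differential_regions: pd.DataFrame  # chrom,start,end,source — every truly changing locus
    tf_truth: pd.DataFrame  # factor, mode, kernel depth/sds
    gene_class_truth: pd.DataFrame  # gene_id, class_label


@dataclass
class GenomeLayout:
    config: SimConfig
    series: SampleSeries
    pos: np.ndarray
    provenance: np.ndarray
    elem_id: np.ndarray  # index into the element table for non-background sites
    islands: list
    dmr_regions: pd.DataFrame
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end, class_label, cpg_rich, prom_idx_lo, prom_idx_hi
    tf_sites: dict  # factor -> FeatureSet
    tf_truth: pd.DataFrame


@dataclass
class SimBundle:
    config: SimConfig
    series: SampleSeries
    layout: GenomeLayout
    true_levels: np.ndarray  # (n_sites, n_samples)
    methylomes: list
    spikeins: dict
    tf_sites: dict
    peaks: dict  # mark -> {sample -> FeatureSet}
    expression: pd.DataFrame
    truth: GroundTruth


def _positions_from_spacings(start: float, spacings: np.ndarray) -> np.ndarray:
    return (start + np.cumsum(spacings)).astype(np.int64)


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenomeLayout:
    """Place islands, DMR regions, gene promoters and TF sites along the
    chromosome and fill gaps with background CpGs."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    series = default_series()
    cfg = config

    # element roster
    elements: list[tuple[str, object]] = []
    elements += [("island", None)] * cfg.n_islands
    for lab, cnt in cfg.dmr_counts.items():
        elements += [("dmr", lab)] * int(cnt)
    gene_classes = [c for c in _expr_class_order() for _ in range(cfg.genes_per_class)]
    gene_classes += ["unclassified"] * cfg.n_unclassified_genes
    elements += [("gene", c) for c in gene_classes]
    for name, mode in cfg.tf_factors:
        elements += [("tf", name)] * cfg.tf_sites_per_factor
    rng.shuffle(elements)

    elem_cpgs = (
        cfg.n_islands * cfg.island_n_cpgs
        + sum(cfg.dmr_counts.values()) * cfg.dmr_n_cpgs
        + len(gene_classes) * cfg.promoter_n_cpgs
        + len(cfg.tf_factors) * cfg.tf_sites_per_factor * cfg.tf_site_n_cpgs
    )
    bg_total = max(cfg.n_cpgs - elem_cpgs, 1000)
    elem_bp = (
        cfg.n_islands * cfg.island_n_cpgs * cfg.island_spacing
        + sum(cfg.dmr_counts.values()) * cfg.dmr_n_cpgs * cfg.dmr_spacing
        + len(gene_classes) * cfg.promoter_n_cpgs * cfg.promoter_spacing
        + len(cfg.tf_factors) * cfg.tf_sites_per_factor * cfg.tf_site_width
    )
    gap_bp_total = max(cfg.chrom_length - elem_bp, cfg.chrom_length * 0.2)
    mean_gap = gap_bp_total / (len(elements) + 1)
    bg_spacing = gap_bp_total / bg_total
    if bg_spacing < 3:
        raise ValueError("configured CpG density exceeds ~1 CpG per 3 bp")

    pos: list[int] = []
    prov: list[int] = []
    elem_id: list[int] = []
    islands = []
    dmr_rows = []
    gene_rows = []
    tf_site_rows: dict[str, list[GenomicInterval]] = {n: [] for n, _ in cfg.tf_factors}
    cursor = 100.0
    n_genes_done = 0

    def emit_background(gap_len: float) -> None:
        nonlocal cursor
        end = cursor + gap_len
        p = cursor + rng.exponential(bg_spacing)
        while p < end - 2:
            pos.append(int(p))
            prov.append(BG)
            elem_id.append(-1)
            p += max(rng.exponential(bg_spacing), 2.0)
        cursor = end

    for kind, info in elements:
        emit_background(rng.uniform(0.7, 1.3) * mean_gap)
        start = cursor
        if kind == "island":
            spac = rng.exponential(cfg.island_spacing, cfg.island_n_cpgs) + 2
            ps = _positions_from_spacings(start, spac)
            pos.extend(ps.tolist())
            prov.extend([ISLAND] * len(ps))
            elem_id.extend([len(islands)] * len(ps))
            islands.append((int(ps[0]), int(ps[-1] + _DYAD)))
            cursor = float(ps[-1] + 10)
        elif kind == "dmr":
            spac = rng.exponential(cfg.dmr_spacing, cfg.dmr_n_cpgs) + 10
            ps = _positions_from_spacings(start, spac)
            idx_lo = len(pos)
            pos.extend(ps.tolist())
            prov.extend([DMRSITE] * len(ps))
            elem_id.extend([len(dmr_rows)] * len(ps))
            dmr_rows.append(
                dict(
                    chrom=cfg.chrom,
                    start=int(ps[0]),
                    end=int(ps[-1] + _DYAD),
                    label=info,
                    idx_lo=idx_lo,
                    idx_hi=idx_lo + len(ps),
                )
            )
            cursor = float(ps[-1] + 10)
        elif kind == "gene":
            spac = rng.exponential(cfg.promoter_spacing, cfg.promoter_n_cpgs) + 4
            ps = _positions_from_spacings(start, spac)
            idx_lo = len(pos)
            pos.extend(ps.tolist())
            prov.extend([PROMOTER] * len(ps))
            elem_id.extend([len(gene_rows)] * len(ps))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = int(ps[len(ps) // 2])
            glen = int(rng.integers(*cfg.gene_length_range))
            if strand == "+":
                g_start, g_end = tss, tss + glen
            else:
                g_start, g_end = max(0, tss - glen), tss
            n_genes_done += 1
            gene_rows.append(
                dict(
                    gene_id=f"gene{n_genes_done:04d}",
                    chrom=cfg.chrom,
                    strand=strand,
                    start=g_start,
                    end=g_end,
                    class_label=info,
                    cpg_rich=bool(rng.random() < 0.5) if info == "unclassified" else True,
                    tss=tss,
                    prom_idx_lo=idx_lo,
                    prom_idx_hi=idx_lo + len(ps),
                )
            )
            cursor = float(ps[-1] + 10)
        else:  # tf site
            width = cfg.tf_site_width
            ps = np.linspace(start + 5, start + width - 5, cfg.tf_site_n_cpgs).astype(
                np.int64
            )
            ps = np.unique(ps)
            pos.extend(ps.tolist())
            prov.extend([TFSITE] * len(ps))
            elem_id.extend([len(tf_site_rows[info])] * len(ps))
            tf_site_rows[info].append(
                GenomicInterval(cfg.chrom, int(start), int(start + width))
            )
            cursor = start + width + 10
    emit_background(rng.uniform(0.7, 1.3) * mean_gap)

    pos_arr = np.asarray(pos, dtype=np.int64)
    # enforce strictly increasing (collisions from int truncation)
    keep = np.ones(len(pos_arr), dtype=bool)
    keep[1:] = np.diff(pos_arr) >= 2
    pos_arr = pos_arr[keep]
    prov_arr = np.asarray(prov)[keep]
    eid_arr = np.asarray(elem_id)[keep]
    # re-index dmr/promoter site ranges after the dedupe
    old_to_new = np.cumsum(keep) - 1
    for row in dmr_rows:
        row["idx_lo"] = int(old_to_new[row["idx_lo"]])
        row["idx_hi"] = int(old_to_new[row["idx_hi"] - 1]) + 1
    for row in gene_rows:
        row["prom_idx_lo"] = int(old_to_new[row["prom_idx_lo"]])
        row["prom_idx_hi"] = int(old_to_new[row["prom_idx_hi"] - 1]) + 1

    tf_truth_rows = []
    for name, mode in cfg.tf_factors:
        tf_truth_rows.append(
            dict(
                factor=name,
                mode=mode,
                depth=cfg.kernel_depth,
                sd_intermediate=cfg.kernel_sd_intermediate,
                sd_esc=cfg.kernel_sd_esc,
            )
        )
    return GenomeLayout(
        config=cfg,
        series=series,
        pos=pos_arr,
        provenance=prov_arr,
        elem_id=eid_arr,
        islands=islands,
        dmr_regions=pd.DataFrame(
            dmr_rows,
            columns=["chrom", "start", "end", "label", "idx_lo", "idx_hi"],
        ),
        genes=pd.DataFrame(gene_rows),
        tf_sites={
            name: FeatureSet(name, ivs) for name, ivs in tf_site_rows.items()
        },
        tf_truth=pd.DataFrame(
            tf_truth_rows, columns=["factor", "mode", "depth", "sd_intermediate", "sd_esc"]
        ),
    )


def _expr_class_order() -> tuple[str, ...]:
    from .genes import EXPR_CLASSES

    return EXPR_CLASSES


def class_on_pattern(cls: str, series: SampleSeries) -> dict[str, bool]:
    """Idealized on/off expression template per class over the series."""
    base = series.baseline_label
    inter = series.intermediate_labels
    fclass = series.fclass_labels
    esc = series.esc_like_labels
    on = {l: False for l in series.labels}
    if cls == "Expr-1a":
        for l in series.labels:
            on[l] = l != base
    elif cls in ("Expr-1b", "Expr-1c"):
        for l in esc:
            on[l] = True
    elif cls in ("Expr-2a", "Expr-2b"):
        on[base] = True
        if inter:
            on[inter[0]] = True  # decays off early in the course
    elif cls == "Expr-3a":
        for l in fclass:
            on[l] = True
    elif cls == "Expr-3b":
        for l in series.labels:
            on[l] = l not in fclass
    return on


def class_promoter_trajectory(
    cls: str, series: SampleSeries, low: float = 0.10, high: float = 0.90
) -> np.ndarray:
    """True promoter methylation per sample for each expression class.

    Expr-1c promoters are fully methylated until the ESC-like state
    (late demethylation); Expr-2b promoters gain methylation early in the
    course; all other classes keep stable low methylation.
    """
    vals = []
    inter = series.intermediate_labels
    gain_from = set(inter[1:]) | set(series.fclass_labels) | set(series.esc_like_labels)
    for l in series.labels:
        if cls == "Expr-1c":
            vals.append(low if l in series.esc_like_labels else high)
        elif cls == "Expr-2b":
            vals.append(high if l in gain_from else low)
        else:
            vals.append(low)
    return np.asarray(vals)


def _true_level_matrix(layout: GenomeLayout) -> np.ndarray:
    """Noise-free per-CpG, per-sample methylation level from the layout."""
    cfg = layout.config
    series = layout.series
    S = len(series.labels)
    n = len(layout.pos)
    lvl = np.full((n, S), cfg.background_high)
    lvl[layout.provenance == ISLAND] = cfg.low_level

    templates = archetype_templates(series)
    for row in layout.dmr_regions.itertuples(index=False):
        t = templates[row.label]
        lvl[row.idx_lo : row.idx_hi] = cfg.low_level + (
            cfg.background_high - cfg.low_level
        ) * t

    from .genes import promoter_interval

    bg_mask = layout.provenance == BG
    for g in layout.genes.itertuples(index=False):
        if g.class_label == "unclassified":
            traj = np.full(S, 0.10 if g.cpg_rich else 0.90)
        else:
            traj = class_promoter_trajectory(g.class_label, series)
        lvl[g.prom_idx_lo : g.prom_idx_hi] = traj
        # the whole promoter region shares the gene's methylation state:
        # extend the trajectory to background CpGs inside the promoter
        prom = promoter_interval(g.chrom, g.tss, g.strand)
        lo, hi = np.searchsorted(layout.pos, [prom.start, prom.end])
        idx = np.arange(lo, hi)[bg_mask[lo:hi]]
        lvl[idx] = traj

    # focal/broad demethylation kernels around TF sites (background and
    # site CpGs only: planted elements keep their own trajectories)
    kernel_ok = (layout.provenance == BG) | (layout.provenance == TFSITE)
    esc = set(series.esc_like_labels)
    for t in layout.tf_truth.itertuples(index=False):
        sites = layout.tf_sites[t.factor].intervals
        for site in sites:
            mid = site.midpoint
            for j, lab in enumerate(series.labels):
                if lab in esc:
                    sd = t.sd_esc
                elif t.mode == "active_early" and lab != series.baseline_label:
                    sd = t.sd_intermediate
                else:
                    continue
                lo, hi = np.searchsorted(layout.pos, [mid - 4 * sd, mid + 4 * sd])
                sel = slice(lo, hi)
                ok = kernel_ok[sel]
                d = layout.pos[sel][ok] - mid
                cand = lvl[sel, j][ok] - t.depth * np.exp(-(d**2) / (2 * sd**2))
                idx = np.flatnonzero(ok) + lo
                lvl[idx, j] = np.maximum(np.minimum(lvl[idx, j], cand), 0.0)
    return lvl


def simulate_methylomes(
    config: SimConfig,
    layout: GenomeLayout,
    true_levels: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Methylome], dict[str, SpikeInControl], np.ndarray]:
    """Sample per-CpG counts and spike-in controls from the true levels.

    Depth ~ Poisson(depth_mean); methylated reads ~ Binomial(depth, q) with
    q = level + (1 - level) * nonconversion (a truly unmethylated cytosine
    still reads methylated at the nonconversion rate). Per-site Gaussian
    jitter (sd ``level_jitter_sd``) models biological variability; optional
    beta-binomial overdispersion via ``overdispersion``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if true_levels is None:
        true_levels = _true_level_matrix(layout)
    series = layout.series
    n, S = true_levels.shape
    lvl = np.clip(true_levels + rng.normal(0, config.level_jitter_sd, (n, S)), 0, 1)
    q = lvl + (1.0 - lvl) * config.nonconversion
    depth = rng.poisson(config.depth_mean, (n, S))
    if config.overdispersion > 0:
        rho = config.overdispersion
        nu = 1.0 / rho - 1.0
        a = np.clip(q * nu, 1e-6, None)
        b = np.clip((1 - q) * nu, 1e-6, None)
        q = rng.beta(a, b)
    meth = rng.binomial(depth, q)

    methylomes = []
    spikeins = {}
    for j, lab in enumerate(series.labels):
        df = pd.DataFrame(
            {
                "chrom": config.chrom,
                "pos": layout.pos,
                "meth_count": meth[:, j],
                "total_count": depth[:, j],
            }
        )
        methylomes.append(Methylome(sample_label=lab, sites=df))
        spikeins[lab] = SpikeInControl(
            total_c_calls=config.spike_total,
            unconverted_calls=int(rng.binomial(config.spike_total, config.nonconversion)),
        )
    return methylomes, spikeins, true_levels


def simulate_expression(
    config: SimConfig,
    genes: pd.DataFrame,
    series: SampleSeries,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """FPKM table (genes x samples): class template x lognormal noise when
    on, small uniform values below the on-threshold when off."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rows = {}
    for g in genes.itertuples(index=False):
        if g.class_label == "unclassified":
            always_on = rng.random() < 0.5
            pattern = {l: always_on for l in series.labels}
        else:
            pattern = class_on_pattern(g.class_label, series)
        vals = []
        for l in series.labels:
            if pattern[l]:
                vals.append(
                    config.on_fpkm_level
                    * float(rng.lognormal(0.0, config.expr_noise_sigma))
                )
            else:
                vals.append(float(rng.uniform(0, config.off_fpkm_max)))
        rows[g.gene_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(series.labels)).rename_axis(
        "gene_id"
    )


def simulate_tfbs_and_peaks(
    config: SimConfig,
    layout: GenomeLayout,
    true_levels: np.ndarray,
    expression: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, dict]:
    """Per-sample histone peak tracks anti-correlated with methylation.

    H3K4me3 appears over islands, low-methylation promoters and demethylated
    TF sites; H3K27me3 over low-methylation promoters of silent genes and
    (with probability ``mark_low_meth_coupling``, jointly with H3K4me3) over
    low-methylation DMR regions; H3K36me3 covers the bodies of expressed
    genes. Returns (tf_sites, peaks[mark][sample]).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    series = layout.series
    cfg = config
    pad = cfg.peak_pad
    low = cfg.meth_low_for_peak

    def region_level(idx_lo, idx_hi, j):
        return float(true_levels[idx_lo:idx_hi, j].mean())

    marked_dmr = rng.random(len(layout.dmr_regions)) < cfg.mark_low_meth_coupling
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        m: {l: [] for l in series.labels} for m in ("H3K4me3", "H3K27me3", "H3K36me3")
    }
    for j, lab in enumerate(series.labels):
        k4 = peaks["H3K4me3"][lab]
        k27 = peaks["H3K27me3"][lab]
        k36 = peaks["H3K36me3"][lab]
        for s, e in layout.islands:
            k4.append(GenomicInterval(cfg.chrom, max(0, s - pad), e + pad))
        for g in layout.genes.itertuples(index=False):
            pl = region_level(g.prom_idx_lo, g.prom_idx_hi, j)
            span = (
                max(0, int(layout.pos[g.prom_idx_lo]) - pad),
                int(layout.pos[g.prom_idx_hi - 1]) + _DYAD + pad,
            )
            expressed = expression.loc[g.gene_id, lab] >= cfg.on_fpkm_threshold
            if pl < low:
                if expressed:
                    k4.append(GenomicInterval(cfg.chrom, *span))
                else:
                    k27.append(GenomicInterval(cfg.chrom, *span))
            if expressed and g.end > g.start:
                k36.append(GenomicInterval(cfg.chrom, int(g.start), int(g.end)))
        for fs in layout.tf_sites.values():
            for site in fs.intervals:
                lo, hi = np.searchsorted(layout.pos, [site.start, site.end])
                if hi > lo and float(true_levels[lo:hi, j].mean()) < low:
                    k4.append(
                        GenomicInterval(cfg.chrom, max(0, site.start - pad), site.end + pad)
                    )
        for i, row in enumerate(layout.dmr_regions.itertuples(index=False)):
            if not marked_dmr[i]:
                continue
            if region_level(row.idx_lo, row.idx_hi, j) < low:
                iv = GenomicInterval(cfg.chrom, max(0, row.start - pad), row.end + pad)
                k4.append(iv)
                k27.append(iv)
    peak_sets = {
        mark: {lab: FeatureSet(f"{mark}:{lab}", ivs) for lab, ivs in by_lab.items()}
        for mark, by_lab in peaks.items()
    }
    return layout.tf_sites, peak_sets


def _kernel_footprints(layout: GenomeLayout, min_change: float = 0.10) -> list[dict]:
    """Intervals around TF sites where a kernel moves the level by at least
    ``min_change`` in some sample."""
    out = []
    for t in layout.tf_truth.itertuples(index=False):
        sd_max = max(t.sd_esc, t.sd_intermediate if t.mode == "active_early" else 0.0)
        if t.depth < min_change:
            continue
        r = sd_max * np.sqrt(2.0 * np.log(t.depth / min_change))
        for site in layout.tf_sites[t.factor].intervals:
            mid = site.midpoint
            out.append(
                dict(
                    chrom=site.chrom,
                    start=max(0, int(mid - r)),
                    end=int(mid + r),
                    source=f"kernel:{t.factor}",
                )
            )
    return out


def _assemble_truth(layout: GenomeLayout, true_levels: np.ndarray) -> GroundTruth:
    series = layout.series
    dmr = layout.dmr_regions.copy()
    for j, lab in enumerate(series.labels):
        dmr[lab] = [
            float(true_levels[r.idx_lo : r.idx_hi, j].mean())
            for r in layout.dmr_regions.itertuples(index=False)
        ]
    diff_rows = [
        dict(chrom=r.chrom, start=r.start, end=r.end, source=f"dmr:{r.label}")
        for r in layout.dmr_regions.itertuples(index=False)
    ]
    from .genes import promoter_interval

    for g in layout.genes.itertuples(index=False):
        if g.class_label in ("Expr-1c", "Expr-2b"):
            prom = promoter_interval(g.chrom, g.tss, g.strand)
            diff_rows.append(
                dict(
                    chrom=g.chrom,
                    start=prom.start,
                    end=prom.end,
                    source=f"promoter:{g.class_label}",
                )
            )
    diff_rows.extend(_kernel_footprints(layout))
    return GroundTruth(
        dmr_regions=dmr,
        differential_regions=pd.DataFrame(
            diff_rows, columns=["chrom", "start", "end", "source"]
        ),
        tf_truth=layout.tf_truth,
        gene_class_truth=layout.genes[["gene_id", "class_label"]].copy(),
    )


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Generate the complete input bundle plus ground truth from one seed."""
    rng = np.random.default_rng(config.seed)
    layout = simulate_genome(config, rng)
    true_levels = _true_level_matrix(layout)
    methylomes, spikeins, _ = simulate_methylomes(config, layout, true_levels, rng)
    expression = simulate_expression(config, layout.genes, layout.series, rng)
    tf_sites, peak_sets = simulate_tfbs_and_peaks(
        config, layout, true_levels, expression, rng
    )
    return SimBundle(
        config=config,
        series=layout.series,
        layout=layout,
        true_levels=true_levels,
        methylomes=methylomes,
        spikeins=spikeins,
        tf_sites=tf_sites,
        peaks=peak_sets,
        expression=expression,
        truth=_assemble_truth(layout, true_levels),
    )


def simulate_promoter_mark_transitions(
    n_per_stratum: int,
    p_low: float = 0.8,
    p_high: float = 0.2,
    seed: int = 0,
    low: float = 0.10,
    high: float = 0.90,
) -> pd.DataFrame:
    """Toy cohort for the mark-transition analysis: genes lacking a mark at
    baseline acquire it in the ESC-like state with probability ``p_low``
    (hypomethylated baseline promoter) or ``p_high`` (hypermethylated)."""
    rng = np.random.default_rng(seed)
    rows = []
    for stratum, meth, p in (("low", low, p_low), ("high", high, p_high)):
        acq = rng.random(n_per_stratum) < p
        for i in range(n_per_stratum):
            rows.append(
                dict(
                    gene_id=f"{stratum}{i:04d}",
                    baseline_meth=meth,
                    mark_at_baseline=False,
                    mark_at_esc=bool(acq[i]),
                )
            )
    return pd.DataFrame(rows)


def write_bundle(bundle: SimBundle, workdir) -> None:
    """Write the bundle as the on-disk formats the pipeline reads, plus the
    ground-truth manifest TSVs."""
    from . import io as mio

    wd = Path(workdir)
    (wd / "methylomes").mkdir(parents=True, exist_ok=True)
    for m in bundle.methylomes:
        mio.write_cpg_table(m, wd / "methylomes" / f"{m.sample_label}.cpg.tsv")
    spike = pd.DataFrame(
        [
            dict(
                sample=lab,
                total_c_calls=c.total_c_calls,
                unconverted_calls=c.unconverted_calls,
            )
            for lab, c in bundle.spikeins.items()
        ]
    )
    spike.to_csv(wd / "spikein.tsv", sep="\t", index=False)
    mio.write_bed(
        [GenomicInterval(bundle.config.chrom, s, e) for s, e in bundle.layout.islands],
        wd / "cgi.bed",
    )
    (wd / "tfbs").mkdir(exist_ok=True)
    for name, fs in bundle.tf_sites.items():
        mio.write_bed(fs.intervals, wd / "tfbs" / f"{name}.bed")
    for mark, by_lab in bundle.peaks.items():
        d = wd / "peaks" / mark
        d.mkdir(parents=True, exist_ok=True)
        for lab, fs in by_lab.items():
            mio.write_bed(fs.intervals, d / f"{lab}.bed")
    genes = bundle.layout.genes[["gene_id", "chrom", "strand", "start", "end"]]
    genes.to_csv(wd / "genes.tsv", sep="\t", index=False)
    bundle.expression.to_csv(wd / "expression.tsv", sep="\t")
    tdir = wd / "truth"
    tdir.mkdir(exist_ok=True)
    bundle.truth.dmr_regions.to_csv(tdir / "dmr_regions.tsv", sep="\t", index=False)
    bundle.truth.differential_regions.to_csv(
        tdir / "differential_regions.tsv", sep="\t", index=False
    )
    bundle.truth.tf_truth.to_csv(tdir / "tf_kernels.tsv", sep="\t", index=False)
    bundle.truth.gene_class_truth.to_csv(tdir / "gene_classes.tsv", sep="\t", index=False)
    series = bundle.series
    import yaml

    with open(wd / "series.yaml", "w") as fh:
        yaml.safe_dump(
            dict(
                labels=list(series.labels),
                baseline_label=series.baseline_label,
                esc_like_labels=list(series.esc_like_labels),
                fclass_labels=list(series.fclass_labels),
                seed=bundle.config.seed,
            ),
            fh,
        )
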