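"""Promoter annotation, expression integration and gene-class assignment.

Promoters are 5 kb upstream to 1 kb downstream of the TSS, strand-aware.
Genes are assigned to expression trajectory classes by a parameterized rule
cascade over on/off expression calls (FPKM threshold) and promoter
methylation in the baseline and ESC-like samples:

Expr-1a  activated early in the time-course and on in the ESC-like state;
Expr-1b  activated only at the ESC-like state, low baseline methylation;
Expr-1c  as 1b but fully methylated baseline promoter;
Expr-2a  on at baseline, silenced in ESC-like, low ESC promoter methylation;
Expr-2b  as 2a but fully methylated ESC promoter;
Expr-3a  on only in the F-class samples;
Expr-3b  on at baseline/intermediates and in ESC-like, off in F-class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core import GenomicInterval, Methylome, SampleSeries

__all__ = [
    "GeneRecord",
    "GeneEpigenomeState",
    "ExprClassAssignment",
    "EXPR_CLASSES",
    "promoter_interval",
    "gene_records",
    "promoter_methylation",
    "assign_expr_class",
    "mark_transition_rates",
]

EXPR_CLASSES = (
    "Expr-1a",
    "Expr-1b",
    "Expr-1c",
    "Expr-2a",
    "Expr-2b",
    "Expr-3a",
    "Expr-3b",
)

PROMOTER_UP = 5000
PROMOTER_DOWN = 1000


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    promoter: GenomicInterval
    body: GenomicInterval


def promoter_interval(
    chrom: str,
    tss: int,
    strand: str,
    chrom_length: Optional[int] = None,
    upstream: int = PROMOTER_UP,
    downstream: int = PROMOTER_DOWN,
) -> GenomicInterval:
    """[tss-5000, tss+1000) on +, mirrored on -, clipped at chromosome bounds."""
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, end)


def gene_records(
    genes: pd.DataFrame, chrom_lengths: Optional[Mapping[str, int]] = None
) -> list[GeneRecord]:
    """Build strand-aware promoter/body records from a gene model table
    (gene_id, chrom, strand, start, end; transcript span, 0-based)."""
    out = []
    for row in genes.itertuples(index=False):
        clen = chrom_lengths.get(row.chrom) if chrom_lengths else None
        if row.strand == "+":
            tss, tes = int(row.start), int(row.end)
        else:
            tss, tes = int(row.end), int(row.start)
        out.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chrom=row.chrom,
                strand=row.strand,
                tss=tss,
                tes=tes,
                promoter=promoter_interval(row.chrom, tss, row.strand, clen),
                body=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            )
        )
    return out


def promoter_methylation(gene: GeneRecord, methylome: Methylome) -> float:
    """Unweighted mean CpG level in the promoter; NaN when CpG-free."""
    from .tfbs import site_methylation

    return site_methylation(gene.promoter, methylome)


@dataclass
class GeneEpigenomeState:
    gene_id: str
    promoter_meth_by_sample: dict[str, float]
    fpkm_by_sample: dict[str, float]
    k4_score_by_sample: dict[str, float] = field(default_factory=dict)
    k27_score_by_sample: dict[str, float] = field(default_factory=dict)
    k36_score_by_sample: dict[str, float] = field(default_factory=dict)


@dataclass
class ExprClassAssignment:
    gene_id: str
    class_label: str
    rule_trace: list[str] = field(default_factory=list)


def _mean_or_nan(values: Sequence[float]) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def assign_expr_class(
    state: GeneEpigenomeState,
    series: SampleSeries,
    on_fpkm: float = 1.0,
    low_meth: float = 0.30,
    high_meth: float = 0.70,
    early_boundary_index: int = 1,
) -> ExprClassAssignment:
    """Assign a gene to one expression trajectory class (or 'unclassified').

    A gene is "on" in a sample when FPKM >= ``on_fpkm``. "Early" activation
    means on in intermediate sample ``early_boundary_index`` (0-based) or
    sooner. Baseline/ESC promoter methylation is compared against
    ``low_meth``/``high_meth``; a rule needing a missing methylation value
    leaves the gene unclassified with the failure recorded in the trace.
    """
    trace: list[str] = []
    on = {lab: state.fpkm_by_sample[lab] >= on_fpkm for lab in series.labels}
    base = series.baseline_label
    inter = series.intermediate_labels
    fclass = series.fclass_labels
    esc = series.esc_like_labels
    if not esc:
        raise ValueError("series defines no ESC-like samples")

    on_esc_all = all(on[l] for l in esc)
    off_esc_all = all(not on[l] for l in esc)
    on_f_all = all(on[l] for l in fclass) if fclass else False
    off_f_all = all(not on[l] for l in fclass) if fclass else True
    early = inter[: early_boundary_index + 1]
    meth_base = state.promoter_meth_by_sample.get(base, float("nan"))
    meth_esc = _mean_or_nan(
        [state.promoter_meth_by_sample.get(l, float("nan")) for l in esc]
    )

    def result(label: str) -> ExprClassAssignment:
        trace.append(f"assigned:{label}")
        return ExprClassAssignment(state.gene_id, label, trace)

    # 1a: off at baseline, on early, on in ESC-like
    if not on[base] and any(on[l] for l in early) and on_esc_all:
        return result("Expr-1a")
    # 1b/1c: off everywhere before the ESC-like state, on there
    if (
        not on[base]
        and not any(on[l] for l in inter)
        and off_f_all
        and on_esc_all
    ):
        if np.isnan(meth_base):
            trace.append("missing:baseline promoter methylation")
            return result("unclassified")
        if meth_base < low_meth:
            return result("Expr-1b")
        if meth_base >= high_meth:
            return result("Expr-1c")
        trace.append("baseline methylation intermediate")
    # 2a/2b: on at baseline, silenced in ESC-like
    if on[base] and off_esc_all:
        if np.isnan(meth_esc):
            trace.append("missing:ESC promoter methylation")
            return result("unclassified")
        if meth_esc < low_meth:
            return result("Expr-2a")
        if meth_esc >= high_meth:
            return result("Expr-2b")
        trace.append("ESC methylation intermediate")
    # 3a: off at baseline, on in F-class, off in ESC-like
    if fclass and not on[base] and on_f_all and off_esc_all:
        return result("Expr-3a")
    # 3b: on at baseline and/or intermediates, off in F-class, on in ESC-like
    if (
        fclass
        and (on[base] or any(on[l] for l in inter))
        and all(not on[l] for l in fclass)
        and on_esc_all
    ):
        return result("Expr-3b")
    return result("unclassified")


def mark_transition_rates(
    baseline_meth: np.ndarray,
    mark_at_baseline: np.ndarray,
    mark_at_esc: np.ndarray,
    low_meth: float = 0.30,
    high_meth: float = 0.70,
) -> dict:
    """ESC-specific mark acquisition rate, stratified by initial methylation.

    Among genes lacking the mark at baseline, the fraction acquiring it in
    the ESC-like state is computed separately for promoters with low
    (< ``low_meth``) and high (>= ``high_meth``) baseline methylation, with a
    two-sided Fisher exact test on the 2x2 acquisition table. Empty strata
    yield NaN rates and are flagged.
    """
    meth = np.asarray(baseline_meth, dtype=float)
    at_base = np.asarray(mark_at_baseline, dtype=bool)
    at_esc = np.asarray(mark_at_esc, dtype=bool)
    eligible = ~at_base & ~np.isnan(meth)
    low = eligible & (meth < low_meth)
    high = eligible & (meth >= high_meth)
    acquired = at_esc

    def rate(mask):
        n = int(mask.sum())
        return (float(acquired[mask].mean()) if n else float("nan")), n

    rate_low, n_low = rate(low)
    rate_high, n_high = rate(high)
    table = np.array(
        [
            [int((acquired & low).sum()), int((~acquired & low).sum())],
            [int((acquired & high).sum()), int((~acquired & high).sum())],
        ]
    )
    if n_low and n_high:
        odds, p = fisher_exact(table, alternative="two-sided")
    else:
        odds, p = float("nan"), float("nan")
    return {
        "rate_low": rate_low,
        "rate_high": rate_high,
        "n_low": n_low,
        "n_high": n_high,
        "table": table,
        "odds_ratio": float(odds),
        "p_value": float(p),
        "empty_stratum": not (n_low and n_high),
    }
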