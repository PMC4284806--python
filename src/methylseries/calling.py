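"""Spike-in calibrated binomial methylcytosine calling.

The error rate p (bisulfite nonconversion plus sequencing error) is
estimated from an unmethylated spike-in genome. At a CpG with read depth n
and k methylated (unconverted) reads, the upper binomial tail
P(X >= k), X ~ B(n, p), measures how surprising k is under the
no-methylation null. A per-site tail cutoff M is chosen by an empirical
scan so that the expected number of error-driven calls stays below a
configurable fraction (default 1%) of the calls made:

    M * N_not_called(M) < fdr * N_called(M)

where N_called(M) is the number of tested sites with tail < M. The cutoff
is then folded into a minimum methylated-read count per depth. When the
error rate itself is at or above the fdr, no site is callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import binom

from .core import Methylome

__all__ = [
    "SpikeInControl",
    "CallThresholdTable",
    "MethylationCallSet",
    "estimate_error_rate",
    "binomial_upper_tail",
    "calibrate_call_threshold",
    "call_methylcytosines",
    "adjusted_level",
    "add_levels",
]


@dataclass(frozen=True)
class SpikeInControl:
    """Counts from the unmethylated spike-in (e.g. lambda phage).

    ``total_c_calls``: base calls observed at reference cytosine positions;
    ``unconverted_calls``: of those, read as cytosine (apparent methylation,
    all attributable to nonconversion/sequencing error).
    """

    total_c_calls: int
    unconverted_calls: int

    def __post_init__(self) -> None:
        if not (0 <= self.unconverted_calls <= self.total_c_calls):
            raise ValueError("need 0 <= unconverted_calls <= total_c_calls")


class CalibrationError(ValueError):
    pass


def estimate_error_rate(control: SpikeInControl) -> float:
    """Error rate p = unconverted / total cytosine calls in the spike-in."""
    if control.total_c_calls == 0:
        raise CalibrationError("spike-in control has zero cytosine calls")
    return control.unconverted_calls / control.total_c_calls


def binomial_upper_tail(k, n, p) -> np.ndarray | float:
    """P(X >= k) for X ~ Binomial(n, p); vectorized and stable for n <= 1e4."""
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    if np.any(k_arr < 0) or np.any(k_arr > n_arr):
        raise ValueError("need 0 <= k <= n")
    if not (0 <= np.min(p) and np.max(p) < 1):
        raise ValueError("need 0 <= p < 1")
    out = binom.sf(k_arr - 1, n_arr, p)
    if np.isscalar(k) and np.isscalar(n):
        return float(out)
    return out


@dataclass
class CallThresholdTable:
    """Calibrated per-depth minimum methylated-read counts.

    ``p_cutoff`` is the tail cutoff M; ``k_min_by_depth[n]`` the smallest
    methylated-read count at which a depth-n site is callable (n + 1 when no
    count suffices). ``all_uncallable`` is set when the sample-wide error
    rate is at or above the fdr and no site may be called.
    """

    p_cutoff: float
    error_rate: float
    fdr: float
    k_min_by_depth: dict[int, int] = field(default_factory=dict)
    all_uncallable: bool = False

    def k_min(self, depth: int) -> int:
        if self.all_uncallable or depth <= 0:
            return depth + 1
        if depth not in self.k_min_by_depth:
            self.k_min_by_depth[depth] = _k_min_for_depth(
                depth, self.error_rate, self.p_cutoff
            )
        return self.k_min_by_depth[depth]


def _k_min_for_depth(n: int, p: float, m_cutoff: float) -> int:
    """Smallest k in [1, n] with P(X >= k) < M, else n + 1."""
    if m_cutoff <= 0.0:
        return n + 1
    ks = np.arange(1, n + 1)
    tails = binom.sf(ks - 1, n, p)
    ok = np.flatnonzero(tails < m_cutoff)
    return int(ks[ok[0]]) if ok.size else n + 1


def calibrate_call_threshold(
    methylome: Methylome,
    error_rate: float,
    fdr: float = 0.01,
    uncalled_base: str = "uncalled",
) -> CallThresholdTable:
    """Scan observed per-site tail probabilities for the largest cutoff M
    with M * N_uncalled(M) < fdr * N_called(M).

    Depth-0 sites are excluded from the scan (missing, not unmethylated).
    ``uncalled_base`` selects the count multiplying M: uncalled tested sites
    ("uncalled", default) or all tested sites ("tested").
    """
    if uncalled_base not in ("uncalled", "tested"):
        raise ValueError("uncalled_base must be 'uncalled' or 'tested'")
    if error_rate >= fdr:
        # sample-wide guard: error rate too high for any confident call
        return CallThresholdTable(
            p_cutoff=0.0, error_rate=error_rate, fdr=fdr, all_uncallable=True
        )
    depth = methylome.depth()
    meth = methylome.meth()
    tested = depth > 0
    n_tested = int(np.count_nonzero(tested))
    table = CallThresholdTable(p_cutoff=0.0, error_rate=error_rate, fdr=fdr)
    if n_tested == 0:
        table.all_uncallable = True
        return table

    tails = binom.sf(meth[tested] - 1, depth[tested], error_rate)
    tails_ordered = np.sort(tails)
    u = np.unique(tails_ordered)
    # each distinct observed tail u is the infimum cutoff whose call set is
    # {tail <= u}; the condition is evaluated there and the operational
    # threshold nudged just above u so the strict "tail < M" rule keeps ties.
    n_called_at = np.searchsorted(tails_ordered, u, side="right")
    best = 0.0
    for uu, nc in zip(u, n_called_at):
        if uu >= 1.0:
            # the tail of k = 0 sites; zero methylated reads is never callable
            continue
        base = n_tested - int(nc) if uncalled_base == "uncalled" else n_tested
        if nc > 0 and uu * base < fdr * nc:
            best = max(best, float(uu))
    table.p_cutoff = float(np.nextafter(best, 1.0)) if best > 0.0 else 0.0
    if best > 0.0:
        for n in np.unique(depth[tested]):
            table.k_min_by_depth[int(n)] = _k_min_for_depth(
                int(n), error_rate, table.p_cutoff
            )
    else:
        table.all_uncallable = True
    return table


@dataclass
class MethylationCallSet:
    """Boolean methylation calls plus adjusted levels, row-aligned with the
    methylome's site table. ``levels`` is NaN where depth is zero."""

    sample_label: str
    called: np.ndarray
    levels: np.ndarray

    @property
    def n_called(self) -> int:
        return int(np.count_nonzero(self.called))


def call_methylcytosines(
    methylome: Methylome, table: CallThresholdTable
) -> MethylationCallSet:
    """Call a site methylated iff depth >= 1 and meth_count >= k_min(depth)."""
    depth = methylome.depth()
    meth = methylome.meth()
    called = np.zeros(len(depth), dtype=bool)
    if not table.all_uncallable:
        for n in np.unique(depth):
            if n <= 0:
                continue
            kmin = table.k_min(int(n))
            sel = depth == n
            called[sel] = meth[sel] >= kmin
    cr = methylome.conversion_rate
    if cr is None:
        cr = 1.0 - table.error_rate
    levels = adjusted_level(meth, depth, cr)
    return MethylationCallSet(
        sample_label=methylome.sample_label, called=called, levels=levels
    )


def adjusted_level(meth_count, total_count, conversion_rate: float):
    """Conversion-adjusted methylation level, clamped to [0, 1].

    raw = meth/total; adjusted = (raw - (1 - cr)) / cr. Reduces to the raw
    fraction at cr = 1. Zero-depth sites are NaN (missing), never 0.
    """
    if not (0.0 < conversion_rate <= 1.0):
        raise ValueError("conversion_rate must be in (0, 1]")
    meth = np.asarray(meth_count, dtype=float)
    total = np.asarray(total_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
        adj = (raw - (1.0 - conversion_rate)) / conversion_rate
    adj = np.clip(adj, 0.0, 1.0)
    if np.isscalar(meth_count) and np.isscalar(total_count):
        return float(adj) if total_count > 0 else float("nan")
    return adj


def add_levels(
    methylome: Methylome,
    error_rate: float,
    table: Optional[CallThresholdTable] = None,
) -> Methylome:
    """Attach error rate, adjusted levels and (optionally) calls to a methylome."""
    m = methylome.with_rates(error_rate)
    df = m.sites.copy()
    df["level"] = adjusted_level(
        df["meth_count"].to_numpy(), df["total_count"].to_numpy(), m.conversion_rate
    )
    if table is not None:
        calls = call_methylcytosines(m, table)
        df["called"] = calls.called.astype(np.int8)
    m.sites = df
    return m
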