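"""Core domain types shared by every pipeline stage.

Coordinates are 0-based, half-open (BED convention) throughout. A CpG is
represented once per dyad, by the position of the C on the plus strand,
with read counts from both strands combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSeries",
    "GenomicInterval",
    "FeatureSet",
    "Methylome",
    "SiteMatrix",
    "stack_methylomes",
]


@dataclass(frozen=True)
class SampleSeries:
    """Ordered registry of the samples in a reprogramming time-course.

    Parameters
    ----------
    labels
        All sample identifiers, in biological order (somatic baseline first,
        then intermediates, ending in the pluripotent samples).
    baseline_label
        The somatic baseline against which hyper/hypo status and all deltas
        are computed (the role of a secondary-MEF sample).
    esc_like_labels
        Samples in the ESC-like pluripotent state.
    fclass_labels
        Samples in the alternative stable pluripotent state ("F-class").
    """

    labels: tuple[str, ...]
    baseline_label: str
    esc_like_labels: tuple[str, ...] = ()
    fclass_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "esc_like_labels", tuple(self.esc_like_labels))
        object.__setattr__(self, "fclass_labels", tuple(self.fclass_labels))
        if len(set(labels)) != len(labels):
            raise ValueError("sample labels must be unique")
        if self.baseline_label not in labels:
            raise ValueError(f"baseline {self.baseline_label!r} not in labels")
        for lab in self.esc_like_labels + self.fclass_labels:
            if lab not in labels:
                raise ValueError(f"unknown sample label {lab!r}")
        if set(self.esc_like_labels) & set(self.fclass_labels):
            raise ValueError("esc_like_labels and fclass_labels must be disjoint")

    @property
    def intermediate_labels(self) -> tuple[str, ...]:
        """Samples that are neither baseline, F-class nor ESC-like."""
        special = {self.baseline_label, *self.esc_like_labels, *self.fclass_labels}
        return tuple(l for l in self.labels if l not in special)

    @property
    def baseline_index(self) -> int:
        return self.labels.index(self.baseline_label)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def indices(self, labels: Iterable[str]) -> list[int]:
        return [self.labels.index(l) for l in labels]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class FeatureSet:
    """A named collection of genomic intervals (one factor's binding sites,
    one histone mark's peaks, CpG islands, ...). Intervals may overlap."""

    feature_name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays sorted by start."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, ([], []))
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        result = {}
        for chrom, (starts, ends) in out.items():
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            order = np.argsort(s, kind="stable")
            result[chrom] = (s[order], e[order])
        return result

    def total_bp(self) -> int:
        """Total merged base pairs covered by the set."""
        from . import intervals as _iv

        return sum(
            int(np.sum(me - ms))
            for ms, me in (_iv.merge(s, e) for s, e in self.by_chrom().values())
        )


_CPG_COLUMNS = ["chrom", "pos", "meth_count", "total_count"]


@dataclass
class Methylome:
    """Per-CpG bisulfite counts for one sample.

    ``sites`` is a DataFrame with columns chrom, pos, meth_count, total_count
    (plus, after level computation, ``level`` and ``called``), sorted by
    (chrom, pos) with strictly increasing positions within each chromosome.
    ``conversion_rate``/``error_rate`` stay unset (None) until spike-in
    calibration; by construction error_rate = 1 - conversion_rate.
    """

    sample_label: str
    sites: pd.DataFrame
    conversion_rate: Optional[float] = None
    error_rate: Optional[float] = None

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in _CPG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"methylome table missing columns {missing}")
        if len(df):
            bad = (df["meth_count"] < 0) | (df["meth_count"] > df["total_count"])
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                row = df.iloc[i]
                raise ValueError(
                    f"meth_count > total_count at {row['chrom']}:{row['pos']}"
                )
            df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
            dup = df.duplicated(subset=["chrom", "pos"])
            if dup.any():
                row = df[dup].iloc[0]
                raise ValueError(f"duplicate CpG record at {row['chrom']}:{row['pos']}")
            self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    def with_rates(self, error_rate: float) -> "Methylome":
        return replace(
            self, error_rate=float(error_rate), conversion_rate=1.0 - float(error_rate)
        )

    def depth(self) -> np.ndarray:
        return self.sites["total_count"].to_numpy()

    def meth(self) -> np.ndarray:
        return self.sites["meth_count"].to_numpy()


@dataclass
class SiteMatrix:
    """CpG sites common to every sample of a series, as dense matrices.

    Rows are sites (sorted by chrom then pos), columns follow ``samples``.
    ``levels`` holds adjusted methylation levels with NaN where a site has
    zero depth in that sample (missing, not zero).
    """

    chrom: np.ndarray  # object/str array, per site
    pos: np.ndarray  # int64, per site
    meth: np.ndarray  # (n_sites, n_samples) int
    total: np.ndarray  # (n_sites, n_samples) int
    levels: np.ndarray  # (n_sites, n_samples) float, NaN where total == 0
    samples: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous per-chromosome slices (sites are chrom-sorted)."""
        out = []
        chroms = self.chrom
        n = len(chroms)
        i = 0
        while i < n:
            j = i
            while j < n and chroms[j] == chroms[i]:
                j += 1
            out.append((str(chroms[i]), slice(i, j)))
            i = j
        return out

    def sample_index(self, label: str) -> int:
        return self.samples.index(label)


def stack_methylomes(
    methylomes: Sequence[Methylome], series: Optional[SampleSeries] = None
) -> SiteMatrix:
    """Intersect the CpG universes of several methylomes into a SiteMatrix.

    Only positions present in every sample's table are retained (the common
    site universe used by the window scan). Levels must have been computed
    (see :func:`methylseries.calling.add_levels`) or are derived as raw
    fractions when a methylome has no conversion rate set.
    """
    if not methylomes:
        raise ValueError("need at least one methylome")
    order = (
        list(series.labels)
        if series is not None
        else [m.sample_label for m in methylomes]
    )
    by_label = {m.sample_label: m for m in methylomes}
    missing = [l for l in order if l not in by_label]
    if missing:
        raise ValueError(f"missing methylomes for samples {missing}")

    key = None
    for label in order:
        df = by_label[label].sites
        k = pd.MultiIndex.from_arrays([df["chrom"], df["pos"]])
        key = k if key is None else key.intersection(k)
    key = key.sortlevel([0, 1])[0]

    n, s = len(key), len(order)
    meth = np.zeros((n, s), dtype=np.int64)
    total = np.zeros((n, s), dtype=np.int64)
    levels = np.full((n, s), np.nan)
    for j, label in enumerate(order):
        m = by_label[label]
        df = m.sites.set_index(["chrom", "pos"]).loc[key]
        meth[:, j] = df["meth_count"].to_numpy()
        total[:, j] = df["total_count"].to_numpy()
        if "level" in df.columns:
            levels[:, j] = df["level"].to_numpy()
        else:
            from .calling import adjusted_level

            cr = m.conversion_rate if m.conversion_rate is not None else 1.0
            levels[:, j] = adjusted_level(meth[:, j], total[:, j], cr)
    chrom = np.asarray(key.get_level_values(0), dtype=object)
    pos = np.asarray(key.get_level_values(1), dtype=np.int64)
    return SiteMatrix(chrom=chrom, pos=pos, meth=meth, total=total, levels=levels, samples=list(order))
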