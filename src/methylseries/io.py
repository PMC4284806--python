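"""Readers and writers for the external text formats.

All tabular formats are plain TSV (gzip-transparent: a ``.gz`` suffix is
honoured on read and write). Interval files are BED3/BED6, 0-based
half-open; extra columns beyond the sixth (e.g. MACS narrowPeak scores)
are ignored on read.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import FeatureSet, GenomicInterval, Methylome

__all__ = [
    "read_cpg_table",
    "write_cpg_table",
    "read_bed",
    "write_bed",
    "write_dmr_bed",
    "read_gene_table",
    "read_expression_table",
]

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode.replace("t", "") or "r")


class ParseError(ValueError):
    """A malformed input row, reported with its 1-based line number."""


def read_cpg_table(path: PathLike, sample_label: str) -> Methylome:
    """Read a per-CpG count table: chrom, pos, meth_count, total_count.

    Lines starting with ``#`` are comments/headers. Raises :class:`ParseError`
    naming the offending line for malformed rows and a validation error when
    meth_count exceeds total_count.
    """
    chroms: list[str] = []
    pos: list[int] = []
    meth: list[int] = []
    total: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                p, m, t = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer field ({exc})") from None
            if m < 0 or t < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if m > t:
                raise ParseError(
                    f"{path}: line {lineno}: meth_count {m} > total_count {t}"
                )
            chroms.append(parts[0])
            pos.append(p)
            meth.append(m)
            total.append(t)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=object),
            "pos": pd.Series(pos, dtype=np.int64),
            "meth_count": pd.Series(meth, dtype=np.int64),
            "total_count": pd.Series(total, dtype=np.int64),
        }
    )
    return Methylome(sample_label=sample_label, sites=df)


def write_cpg_table(methylome: Methylome, path: PathLike) -> None:
    """Write a methylome back to the 4-column TSV (plus level/called when present)."""
    cols = ["chrom", "pos", "meth_count", "total_count"]
    extra = [c for c in ("level", "called") if c in methylome.sites.columns]
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(cols + extra) + "\n")
        methylome.sites[cols + extra].to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path: PathLike, feature_name: str) -> FeatureSet:
    """Read BED3+ intervals; name (col 4) and strand (col 6) kept if present."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            intervals.append(GenomicInterval(parts[0], start, end, name=name, strand=strand))
    return FeatureSet(feature_name=feature_name, intervals=intervals)


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.strand is not None:
                fields += ["0", iv.strand]
            fh.write("\t".join(fields) + "\n")


def write_dmr_bed(dmrs: Sequence, path: PathLike, tsv_path: Optional[PathLike] = None) -> None:
    """Write DMRs as BED (name = trajectory group) plus a per-sample-level TSV.

    ``dmrs`` are :class:`methylseries.dmr.DMR` records. The companion TSV
    defaults to ``<path>.levels.tsv``.
    """
    path = Path(path)
    if tsv_path is None:
        tsv_path = path.with_suffix(path.suffix + ".levels.tsv")
    with _open_text(path, "wt") as fh:
        for d in dmrs:
            label = d.group_label if d.group_label is not None else "."
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{label}\n")
    samples: list[str] = list(dmrs[0].per_sample_levels.keys()) if len(dmrs) else []
    with _open_text(tsv_path, "wt") as fh:
        fh.write("\t".join(["chrom", "start", "end", "group"] + samples) + "\n")
        for d in dmrs:
            label = d.group_label if d.group_label is not None else "."
            lv = "\t".join(f"{d.per_sample_levels[s]:.6g}" for s in samples)
            fh.write(f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{label}" + ("\t" + lv if samples else "") + "\n")


def read_gene_table(path: PathLike) -> pd.DataFrame:
    """Gene models: TSV with columns gene_id, chrom, strand, start, end.

    ``start``/``end`` are the transcript span (0-based half-open); the TSS is
    ``start`` on + and ``end`` on - strand.
    """
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"gene_id", "chrom", "strand", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene table missing columns {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: gene with start >= end")
    return df


def read_expression_table(path: PathLike) -> pd.DataFrame:
    """Expression matrix: rows = genes (index gene_id), columns = samples, FPKM."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: expression table missing gene_id column")
    return df.set_index("gene_id")
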