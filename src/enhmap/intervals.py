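"""Genomic interval data model, interval algebra and BED/narrowPeak I/O.

Coordinates are 0-based half-open throughout (BED-native). Region boundaries
quoted from genome-browser positions (1-based inclusive) are converted on
construction by :func:`region_from_browser`.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakCall",
    "RegionMask",
    "BUILTIN_MASKS",
    "region_from_browser",
    "read_narrowpeak",
    "merge_intervals",
    "intersect",
    "overlap_length",
    "read_bed",
    "write_bed",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names the offending line."""


@dataclasses.dataclass(frozen=True, order=False)
class GenomicInterval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __lt__(self, other: "GenomicInterval") -> bool:
        return self.sort_key < other.sort_key

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return overlap_length(self, other) >= min_overlap

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclasses.dataclass(frozen=True)
class PeakCall:
    """A single ChIP-seq peak call (narrowPeak semantics).

    ``summit_offset`` is the summit position relative to ``interval.start``;
    ``qvalue`` is the -log10 FDR from the peak caller.
    """

    interval: GenomicInterval
    summit_offset: int
    score: float = 0.0
    signal: float = 0.0
    pvalue: float = 0.0
    qvalue: float = 0.0
    name: str = "."
    sample_id: tuple | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval}"
            )
        if self.qvalue < 0:
            raise ValueError("qvalue (-log10 FDR) must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def summit(self) -> int:
        """Absolute summit coordinate."""
        return self.interval.start + self.summit_offset


@dataclasses.dataclass(frozen=True)
class RegionMask:
    name: str
    interval: GenomicInterval


def region_from_browser(name: str, chrom: str, start_1based: int, end: int) -> RegionMask:
    """Build a mask from 1-based inclusive browser coordinates."""
    return RegionMask(name, GenomicInterval(chrom, start_1based - 1, end))


#: Region masks for the MHC and its class I/II sub-regions, as quoted from
#: browser coordinates (1-based inclusive, converted to half-open here).
BUILTIN_MASKS: dict[str, RegionMask] = {
    m.name: m
    for m in (
        region_from_browser("MHC", "chr6", 29_580_000, 33_100_000),
        region_from_browser("MHC_class_II", "chr6", 32_400_000, 33_100_000),
        region_from_browser("MHC_class_I", "chr6", 29_640_000, 31_325_000),
    )
}


# ---------------------------------------------------------------------------
# narrowPeak / BED I/O


def read_narrowpeak(path: str | Path, sample_id: tuple | None = None) -> list[PeakCall]:
    """Read an ENCODE narrowPeak (BED6+4) file into PeakCall records.

    The summit column (10th, 0-based offset from start) may carry the -1
    sentinel, which is mapped to the interval midpoint.
    """
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: expected 10 tab-delimited narrowPeak "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4])
                strand = fields[5] if fields[5] in {"+", "-"} else "."
                signal = float(fields[6])
                pvalue = float(fields[7])
                qvalue = float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if summit == -1:
                summit = (end - start) // 2
            try:
                peaks.append(
                    PeakCall(
                        GenomicInterval(chrom, start, end, strand),
                        summit_offset=summit,
                        score=score,
                        signal=signal,
                        pvalue=pvalue,
                        qvalue=qvalue,
                        name=name,
                        sample_id=sample_id,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals on the same chromosome separated by <= ``gap`` bp.

    Output is sorted and pairwise non-overlapping; with ``gap == 0`` the
    union of covered bases is preserved exactly. Strand is dropped.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    ivs = sorted(intervals, key=lambda iv: iv.sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> dict[GenomicInterval, list[GenomicInterval]]:
    """Map each interval of ``a`` to the intervals of ``b`` it overlaps.

    A pair is reported iff the shared length is >= ``min_overlap`` bp; the
    relation is symmetric under swapping ``a`` and ``b``. Every member of
    ``a`` appears as a key (possibly with an empty hit list).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for iv in b:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    out: dict[GenomicInterval, list[GenomicInterval]] = {}
    for iv in a:
        hits = []
        tree = trees.get(iv.chrom)
        if tree is not None:
            for node in tree.overlap(iv.start, iv.end):
                if overlap_length(iv, node.data) >= min_overlap:
                    hits.append(node.data)
        hits.sort(key=lambda x: x.sort_key)
        out[iv] = hits
    return out


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, list[str]]]:
    """Read BED3+ records as (interval, extra-columns) pairs.

    Columns 4-6 (name, score, strand) and beyond are preserved as strings;
    a valid strand column populates the interval's strand field.
    """
    records: list[tuple[GenomicInterval, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((iv, fields[3:]))
    return records


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    return [iv for iv, _ in read_bed(path)]


def write_bed(
    records: Iterable[GenomicInterval | tuple[GenomicInterval, Sequence]],
    path: str | Path,
) -> None:
    """Write BED3+ records; extra columns are stringified and preserved."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, extra = rec, ()
            else:
                iv, extra = rec[0], tuple(rec[1])
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            cols.extend(str(x) for x in extra)
            fh.write("\t".join(cols) + "\n")
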