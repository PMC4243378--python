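"""Gene association of binding intervals by TSS distance.

A BI is associated with a gene when the distance from the gene's TSS to the
nearest base of the BI is strictly below ``max_dist`` (default 10 kb, either
side). Associations within 2 kb are 'proximal', the rest 'distal'; genes are
then classified by their pattern of proximal/distal BIs.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingInterval
from .intervals import ParseError

__all__ = [
    "GeneModel",
    "GeneAssociation",
    "read_tss_table",
    "read_genes_bed",
    "associate_genes",
    "classify_gene_pattern",
    "distance_histogram",
    "PROXIMAL_DIST",
    "MAX_DIST",
]

#: association window: TSS-to-BI distance strictly below this (bp, each side)
MAX_DIST = 10_000
#: proximal/distal split: |distance| <= this is proximal (bp)
PROXIMAL_DIST = 2_000


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: TSS must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclasses.dataclass(frozen=True)
class GeneAssociation:
    """One (gene, BI) link with signed TSS distance.

    ``distance`` is 0 when the TSS lies inside the BI; otherwise the gap to
    the nearest covered base, negative when the BI lies upstream of the TSS
    in gene orientation.
    """

    gene_id: str
    bi: BindingInterval
    distance: int

    @property
    def klass(self) -> str:
        return "proximal" if abs(self.distance) <= PROXIMAL_DIST else "distal"


def read_tss_table(path: str | Path) -> list[GeneModel]:
    """Read a 4-column TSS table (gene_id, chrom, tss, strand)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                genes.append(GeneModel(fields[0], fields[1], int(fields[2]), fields[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6; TSS = start for '+', end-1 for '-'."""
    from .intervals import read_bed

    genes = []
    for iv, extra in read_bed(path):
        gene_id = extra[0] if extra else str(iv)
        if iv.strand not in {"+", "-"}:
            raise ParseError(f"{path}: gene {gene_id} lacks a strand")
        tss = iv.start if iv.strand == "+" else iv.end - 1
        genes.append(GeneModel(gene_id, iv.chrom, tss, iv.strand))
    return genes


def tss_distance(bi: BindingInterval, gene: GeneModel) -> int | None:
    """Signed TSS->BI distance, or None on a different chromosome."""
    if bi.interval.chrom != gene.chrom:
        return None
    start, end = bi.interval.start, bi.interval.end
    if start <= gene.tss < end:
        return 0
    if gene.tss < start:
        genomic = start - gene.tss  # BI right of (3' of, on +) the TSS
    else:
        genomic = -(gene.tss - (end - 1))  # BI left of the TSS
    return genomic if gene.strand == "+" else -genomic


def associate_genes(
    bis: Sequence[BindingInterval],
    genes: Sequence[GeneModel],
    max_dist: int = MAX_DIST,
) -> list[GeneAssociation]:
    """All (BI, gene) pairs with |TSS distance| strictly < ``max_dist``.

    Many-to-many: a gene may associate with several BIs and vice versa.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.tss)
    out: list[GeneAssociation] = []
    for bi in bis:
        glist = by_chrom.get(bi.interval.chrom, ())
        if not glist:
            continue
        tss = np.array([g.tss for g in glist])
        lo = np.searchsorted(tss, bi.interval.start - max_dist)
        hi = np.searchsorted(tss, bi.interval.end - 1 + max_dist, side="right")
        for g in glist[lo:hi]:
            d = tss_distance(bi, g)
            if d is not None and abs(d) < max_dist:
                out.append(GeneAssociation(g.gene_id, bi, d))
    return out


def classify_gene_pattern(
    associations: Iterable[GeneAssociation],
) -> dict[str, str]:
    """Classify each associated gene as single-proximal / single-distal / both."""
    classes: dict[str, set[str]] = defaultdict(set)
    for a in associations:
        classes[a.gene_id].add(a.klass)
    out = {}
    for gene, ks in classes.items():
        if ks == {"proximal"}:
            out[gene] = "single-proximal"
        elif ks == {"distal"}:
            out[gene] = "single-distal"
        else:
            out[gene] = "both"
    return out


def pattern_fractions(
    associations: Iterable[GeneAssociation],
) -> pd.DataFrame:
    """Per-condition fractions of genes in each proximal/distal pattern class."""
    by_cond: dict[str, list[GeneAssociation]] = defaultdict(list)
    for a in associations:
        by_cond[a.bi.condition].append(a)
    rows = {}
    for cond, assocs in sorted(by_cond.items()):
        patt = classify_gene_pattern(assocs)
        n = len(patt)
        counts = pd.Series(list(patt.values())).value_counts()
        rows[cond] = {
            k: counts.get(k, 0) / n
            for k in ("single-proximal", "single-distal", "both")
        }
    return pd.DataFrame(rows).T.fillna(0.0)


def distance_histogram(
    associations: Iterable[GeneAssociation],
    bin_edges: Sequence[int],
) -> np.ndarray:
    """Counts of signed TSS distances per bin (edges must be increasing)."""
    edges = np.asarray(bin_edges)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    dists = [a.distance for a in associations]
    counts, _ = np.histogram(dists, bins=edges)
    return counts
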