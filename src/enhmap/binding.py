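"""Replicate-consensus Binding Intervals (BIs) and their classification.

A BI is a genomic region supported by enriched peaks for one factor (CIITA
or RFX5) in *both* individuals of a cell type/condition: the base-pair
intersection of the two individuals' peak sets, with touching/overlapping
shared pieces merged. CE-marks are CIITA BIs co-incident with RFX5 BIs, and
the data-coincidence score (DCS) counts how many configured feature tracks
(DNase hypersensitivity plus enhanceosome factors) overlap a BI.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    PeakCall,
    RegionMask,
    intersect,
    merge_intervals,
    overlap_length,
)

__all__ = [
    "BindingInterval",
    "BISummary",
    "derive_binding_intervals",
    "classify_ce_marks",
    "compute_dcs",
    "annotate_dcs",
    "classify_condition_specific",
    "summarize",
    "fold_change",
]


@dataclasses.dataclass(eq=False)
class BindingInterval:
    """A consensus binding region for one factor in one condition."""

    interval: GenomicInterval
    condition: str
    factors: frozenset[str]
    member_peaks: tuple[PeakCall, ...]
    summit: int
    is_ce_mark: bool = False
    dcs: int | None = None

    def __post_init__(self) -> None:
        individuals_by_factor: dict[str, set] = defaultdict(set)
        for p in self.member_peaks:
            if p.sample_id is not None:
                ind, _cond, factor = p.sample_id
                individuals_by_factor[factor].add(ind)
        for factor in self.factors:
            if individuals_by_factor and len(individuals_by_factor.get(factor, ())) < 2:
                raise ValueError(
                    f"BI {self.interval} claims support for {factor} but lacks "
                    "member peaks from both individuals"
                )

    @property
    def name(self) -> str:
        return f"{'+'.join(sorted(self.factors))}|{self.condition}|{self.interval}"


def derive_binding_intervals(
    peaks_by_group: Mapping[tuple[str, str, str], Sequence[PeakCall]],
) -> list[BindingInterval]:
    """Derive BIs from peaks grouped by (condition, factor, individual).

    For each (condition, factor) the two individuals' peak sets are
    intersected base-wise (>=1 bp), and contiguous/overlapping shared pieces
    merged (gap 0) into BIs. The representative summit is the summit of the
    highest-scoring member peak (ties: leftmost summit).
    """
    by_cf: dict[tuple[str, str], dict[str, list[PeakCall]]] = defaultdict(dict)
    for (condition, factor, individual), peaks in peaks_by_group.items():
        tagged = [
            dataclasses.replace(p, sample_id=(individual, condition, factor))
            for p in peaks
        ]
        by_cf[(condition, factor)][individual] = tagged

    bis: list[BindingInterval] = []
    for (condition, factor), by_ind in sorted(by_cf.items()):
        if len(by_ind) != 2:
            raise ValueError(
                f"({condition}, {factor}): expected exactly 2 individuals, "
                f"got {sorted(by_ind)}"
            )
        (ind1, peaks1), (ind2, peaks2) = sorted(by_ind.items())
        ivs1 = merge_intervals([p.interval for p in peaks1])
        ivs2 = merge_intervals([p.interval for p in peaks2])
        shared: list[GenomicInterval] = []
        for a, hits in intersect(ivs1, ivs2).items():
            for b in hits:
                shared.append(
                    GenomicInterval(a.chrom, max(a.start, b.start), min(a.end, b.end))
                )
        for region in merge_intervals(shared):
            members = tuple(
                p
                for p in (*peaks1, *peaks2)
                if overlap_length(p.interval, region) >= 1
            )
            best = min(members, key=lambda p: (-p.score, p.summit))
            bis.append(
                BindingInterval(
                    interval=region,
                    condition=condition,
                    factors=frozenset({factor}),
                    member_peaks=members,
                    summit=best.summit,
                )
            )
    bis.sort(key=lambda bi: (bi.condition, sorted(bi.factors), bi.interval.sort_key))
    return bis


def classify_ce_marks(
    ciita_bis: Sequence[BindingInterval],
    rfx5_bis: Sequence[BindingInterval],
    min_overlap: int = 1,
) -> dict[str, int]:
    """Flag CIITA BIs co-incident with RFX5 binding as CE-marks.

    Mutates ``is_ce_mark`` on the CIITA BIs and returns the count breakdown
    {ce, ciita_only, rfx5_only}.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rfx_ivs = [bi.interval for bi in rfx5_bis]
    hit_rfx: set[int] = set()
    n_ce = 0
    for bi in ciita_bis:
        bi.is_ce_mark = False
        for j, riv in enumerate(rfx_ivs):
            if overlap_length(bi.interval, riv) >= min_overlap:
                bi.is_ce_mark = True
                hit_rfx.add(j)
        n_ce += bi.is_ce_mark
    return {
        "ce": n_ce,
        "ciita_only": len(ciita_bis) - n_ce,
        "rfx5_only": len(rfx5_bis) - len(hit_rfx),
    }


def compute_dcs(
    bi: BindingInterval,
    tracks: Mapping[str, Sequence[GenomicInterval]],
    min_overlap: int = 1,
) -> int:
    """Count distinct feature tracks overlapping the BI; stored on the BI."""
    if not tracks:
        raise ValueError("at least one co-incidence track is required")
    score = 0
    for _name, ivs in tracks.items():
        if any(overlap_length(bi.interval, iv) >= min_overlap for iv in ivs):
            score += 1
    bi.dcs = score
    return score


def annotate_dcs(
    bis: Iterable[BindingInterval],
    tracks: Mapping[str, Sequence[GenomicInterval]],
    min_overlap: int = 1,
) -> None:
    for bi in bis:
        compute_dcs(bi, tracks, min_overlap=min_overlap)


def classify_condition_specific(
    bis_by_condition: Mapping[str, Sequence[BindingInterval]],
    min_overlap: int = 1,
) -> dict[BindingInterval, str]:
    """Label each BI 'shared' or 'condition-specific' across >=2 conditions.

    A BI is condition-specific iff no BI from any *other* condition overlaps
    it by >= ``min_overlap`` bp.
    """
    if len(bis_by_condition) < 2:
        raise ValueError("need >= 2 conditions to classify condition specificity")
    labels: dict[BindingInterval, str] = {}
    for cond, bis in bis_by_condition.items():
        others = [
            bi.interval
            for other, obis in bis_by_condition.items()
            if other != cond
            for bi in obis
        ]
        for bi in bis:
            shared = any(
                overlap_length(bi.interval, iv) >= min_overlap for iv in others
            )
            labels[bi] = "shared" if shared else "condition-specific"
    return labels


@dataclasses.dataclass
class BISummary:
    """Per-stratum BI counts and CE fractions.

    ``counts`` is indexed by (condition, factor) with one column per stratum
    (genome_wide, each region mask, outside_MHC); ``ce_fraction`` holds the
    CE-mark fraction among CIITA BIs per condition.
    """

    counts: pd.DataFrame
    ce_fraction: pd.Series

    def check(self) -> None:
        inside = self.counts.get("MHC", 0)
        outside = self.counts["outside_MHC"]
        if not ((inside + outside) == self.counts["genome_wide"]).all():
            raise AssertionError("MHC/outside-MHC strata do not sum to genome-wide")


def summarize(
    bis: Sequence[BindingInterval],
    masks: Mapping[str, RegionMask],
) -> BISummary:
    """Count BIs per condition x factor x region stratum and CE fractions.

    A BI falls 'within' a mask iff it overlaps it by >=1 bp; 'outside_MHC'
    means no overlap with the mask named 'MHC' (everything counts as outside
    when no MHC mask is configured).
    """
    strata = ["genome_wide", *masks.keys(), "outside_MHC"]
    rows: dict[tuple[str, str], dict[str, int]] = defaultdict(
        lambda: dict.fromkeys(strata, 0)
    )
    ce_num: dict[str, int] = defaultdict(int)
    ce_den: dict[str, int] = defaultdict(int)
    for bi in bis:
        factor = "+".join(sorted(bi.factors))
        row = rows[(bi.condition, factor)]
        row["genome_wide"] += 1
        in_mhc = False
        for name, mask in masks.items():
            if overlap_length(bi.interval, mask.interval) >= 1:
                row[name] += 1
                if name == "MHC":
                    in_mhc = True
        if not in_mhc:
            row["outside_MHC"] += 1
        if "CIITA" in bi.factors:
            ce_den[bi.condition] += 1
            ce_num[bi.condition] += bi.is_ce_mark
    if rows:
        index = pd.MultiIndex.from_tuples(sorted(rows), names=["condition", "factor"])
        counts = pd.DataFrame(
            [rows[key] for key in sorted(rows)], index=index, columns=strata, dtype=int
        )
    else:
        index = pd.MultiIndex.from_arrays([[], []], names=["condition", "factor"])
        counts = pd.DataFrame([], index=index, columns=strata, dtype=int)
    ce_fraction = pd.Series(
        {c: ce_num[c] / ce_den[c] for c in ce_den if ce_den[c]}, dtype=float
    )
    summary = BISummary(counts=counts, ce_fraction=ce_fraction)
    if "MHC" in masks and len(counts):
        summary.check()
    return summary


def fold_change(count_a: int, count_b: int) -> float:
    """Ratio of two BI counts, e.g. treated vs naive monocyte CIITA BIs."""
    if count_b <= 0:
        raise ValueError("denominator count must be positive")
    return count_a / count_b
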