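"""Rank-based eCDF enrichment of gene sets in differential-expression results.

Genes are ranked by DE p-value (smallest p = rank 1, average ranks on ties)
and mapped to rank-quantiles u = rank/N. For a target gene set, the
empirical CDF of its members' rank-quantiles is compared with the diagonal
F(u) = u expected in the absence of enrichment: a curve above the diagonal
means the set is enriched for differentially expressed genes. A pointwise
bootstrap percentile band quantifies uncertainty, and the one-sided sup
deviation D = sup_u (F-hat(u) - u) gets a Monte-Carlo p-value from
same-sized uniform draws.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionRanking",
    "ECDFResult",
    "ecdf_enrichment",
    "deviation_statistic",
    "split_target_sets",
]


class ExpressionRanking:
    """Genes ranked by differential-expression p-value.

    Rank-quantiles u = rank/N lie in (0, 1]; ties get average ranks.
    """

    def __init__(self, pvalues: Mapping[str, float] | pd.Series):
        s = pd.Series(pvalues, dtype=float)
        if s.empty:
            raise ValueError("ranking requires at least one gene")
        if ((s < 0) | (s > 1)).any() or s.isna().any():
            raise ValueError("p-values must lie in [0, 1]")
        self.pvalues = s
        ranks = stats.rankdata(s.to_numpy(), method="average")
        self.quantiles = pd.Series(ranks / len(s), index=s.index)

    def __len__(self) -> int:
        return len(self.pvalues)

    @classmethod
    def from_table(cls, path: str | Path) -> "ExpressionRanking":
        """Read a two-column tab-delimited (gene_id, p_value) table."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected (gene_id, p_value) columns")
        return cls(pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0]))

    def target_quantiles(self, target_set: Iterable[str]) -> np.ndarray:
        ids = list(target_set)
        missing = [g for g in ids if g not in self.quantiles.index]
        if missing:
            raise KeyError(
                f"{len(missing)} target genes absent from the ranking: "
                f"{sorted(missing)[:10]}"
            )
        return np.sort(self.quantiles.loc[ids].to_numpy())


def deviation_statistic(sorted_u: np.ndarray) -> float:
    """Exact one-sided sup deviation D = sup_u (F-hat(u) - u).

    For sorted quantiles u_(1) <= ... <= u_(m) the sup over u is attained at
    the jump points: D = max_i (i/m - u_(i)).
    """
    m = len(sorted_u)
    return float(np.max(np.arange(1, m + 1) / m - sorted_u))


@dataclasses.dataclass
class ECDFResult:
    """eCDF curve of a target set with confidence band and sup deviation."""

    grid: np.ndarray
    ecdf: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float
    n_boot: int
    n_target: int
    deviation: float
    pvalue: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"u": self.grid, "ecdf": self.ecdf, "lower": self.lower, "upper": self.upper}
        )

    def summary(self) -> dict:
        return {
            "D": self.deviation,
            "p": self.pvalue,
            "n_target": self.n_target,
            "alpha": self.alpha,
            "n_boot": self.n_boot,
        }


def _ecdf_at(sorted_u: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_u, grid, side="right") / len(sorted_u)


def ecdf_enrichment(
    ranking: ExpressionRanking,
    target_set: Iterable[str],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    grid: np.ndarray | None = None,
    n_mc: int = 10_000,
) -> ECDFResult:
    """eCDF of a target set's DE rank-quantiles with band and deviation test.

    The 1-alpha band is a pointwise bootstrap percentile interval from
    ``n_boot`` resamples of the target set with replacement (clamped to
    contain the observed curve). The sup deviation D above the diagonal is
    assigned a one-sided Monte-Carlo p-value from ``n_mc`` draws of
    |target|-sized uniform samples (skipped when ``n_mc`` is 0).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = ranking.target_quantiles(target_set)
    m = len(u)
    if m < 5:
        raise ValueError("target set must contain at least 5 ranked genes")
    if grid is None:
        grid = np.linspace(0.01, 0.99, 99)
    grid = np.asarray(grid, dtype=float)

    F = _ecdf_at(u, grid)
    boot = rng.choice(u, size=(n_boot, m), replace=True)
    boot.sort(axis=1)
    # bootstrap eCDF at every grid point: counts <= g via broadcasting
    F_boot = (boot[:, :, None] <= grid[None, None, :]).mean(axis=1)
    lower = np.quantile(F_boot, alpha / 2, axis=0)
    upper = np.quantile(F_boot, 1 - alpha / 2, axis=0)
    lower = np.minimum(lower, F)
    upper = np.maximum(upper, F)

    D = deviation_statistic(u)
    pvalue: float | None = None
    if n_mc > 0:
        null = rng.random(size=(n_mc, m))
        null.sort(axis=1)
        ranks = np.arange(1, m + 1) / m
        D_null = np.max(ranks[None, :] - null, axis=1)
        pvalue = float((1 + np.sum(D_null >= D)) / (1 + n_mc))
    return ECDFResult(
        grid=grid,
        ecdf=F,
        lower=lower,
        upper=upper,
        alpha=alpha,
        n_boot=n_boot,
        n_target=m,
        deviation=D,
        pvalue=pvalue,
    )


def split_target_sets(
    associations: Sequence,
    known_targets: Iterable[str],
) -> dict[str, set[str]]:
    """Partition BI-associated genes into the four enrichment gene sets.

    Returns {ce, ciita_no_rfx5, known, novel}: a gene joins ``ce`` if any of
    its associated CIITA BIs is a CE-mark, else ``ciita_no_rfx5`` (the two
    are disjoint); ``known``/``novel`` partition the same universe by
    membership in the supplied known-target list.
    """
    known = set(known_targets)
    ce: set[str] = set()
    universe: set[str] = set()
    for a in associations:
        if "CIITA" not in a.bi.factors:
            continue
        universe.add(a.gene_id)
        if a.bi.is_ce_mark:
            ce.add(a.gene_id)
    return {
        "ce": ce,
        "ciita_no_rfx5": universe - ce,
        "known": universe & known,
        "novel": universe - known,
    }
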