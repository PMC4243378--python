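"""Allele-specific binding at heterozygous SNPs and simplified eQTL mapping.

Reads spanning a heterozygous site are tallied by allele per individual;
the allelic fraction is tested against 0.5 per individual (exact binomial)
and across individuals (one-sample t-test of the fractions, the headline
p-value). A single-marker OLS with optional covariates (e.g. expression
principal components) provides the cis/trans eQTL association used to
integrate a trans-regulated gene network with the ChIP-seq BI gene set.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import PWM, match_score

__all__ = [
    "AlleleCounts",
    "ASBResult",
    "EqtlResult",
    "count_alleles",
    "read_allele_counts",
    "asb_test",
    "allele_pwm_delta",
    "eqtl_association",
    "integrate_trans_network",
    "CIS_WINDOW",
]

#: a SNP-gene pair is cis iff the gene TSS lies within this many bp of the SNP
CIS_WINDOW = 1_000_000


@dataclasses.dataclass(frozen=True)
class AlleleCounts:
    """Allelic read counts at one heterozygous SNP for one individual."""

    snp_id: str
    chrom: str
    pos: int  # 0-based
    allele_a: str
    allele_b: str
    count_a: int
    count_b: int
    individual: str = ""
    count_other: int = 0

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b or not (
            len(self.allele_a) == len(self.allele_b) == 1
        ):
            raise ValueError("alleles must be two distinct single nucleotides")
        if min(self.count_a, self.count_b, self.count_other) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def depth(self) -> int:
        return self.count_a + self.count_b

    @property
    def fraction_a(self) -> float:
        if self.depth == 0:
            raise ZeroDivisionError("no allelic reads at site")
        return self.count_a / self.depth


def count_alleles(
    alignments,
    snp: tuple[str, str, int, str, str],
    individual: str = "",
    min_base_quality: int = 20,
    min_map_quality: int = 20,
) -> AlleleCounts:
    """Tally allelic read bases at a biallelic SNV from a SAM/BAM file.

    ``alignments`` is a pysam.AlignmentFile (or a path); ``snp`` is
    (snp_id, chrom, 0-based pos, allele_a, allele_b). Duplicate, unmapped,
    secondary/supplementary and low-quality reads are excluded; covering
    bases matching neither allele are reported in ``count_other``.
    """
    import pysam

    snp_id, chrom, pos, allele_a, allele_b = snp
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments))
    if chrom not in alignments.references:
        raise ValueError(f"SNP contig {chrom!r} absent from alignment header")
    if pos >= alignments.get_reference_length(chrom):
        raise ValueError(f"SNP position {pos} beyond end of {chrom}")
    counts = {allele_a.upper(): 0, allele_b.upper(): 0}
    other = 0
    for read in alignments.fetch(until_eof=True):
        if (
            read.is_unmapped
            or read.is_duplicate
            or read.is_secondary
            or read.is_supplementary
            or read.reference_name != chrom
            or read.mapping_quality < min_map_quality
        ):
            continue
        if not (read.reference_start <= pos < (read.reference_end or -1)):
            continue
        qpos = None
        for q, r in read.get_aligned_pairs(matches_only=True):
            if r == pos:
                qpos = q
                break
        if qpos is None:
            continue
        quals = read.query_qualities
        if quals is not None and quals[qpos] < min_base_quality:
            continue
        base = read.query_sequence[qpos].upper()
        if base in counts:
            counts[base] += 1
        else:
            other += 1
    return AlleleCounts(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        allele_a=allele_a.upper(),
        allele_b=allele_b.upper(),
        count_a=counts[allele_a.upper()],
        count_b=counts[allele_b.upper()],
        individual=individual,
        count_other=other,
    )


def read_allele_counts(path: str | Path) -> list[AlleleCounts]:
    """Read a tab-delimited counts table:
    individual, snp_id, chrom, pos, allele_a, allele_b, count_a, count_b."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AlleleCounts(
            snp_id=str(r.snp_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            allele_a=str(r.allele_a),
            allele_b=str(r.allele_b),
            count_a=int(r.count_a),
            count_b=int(r.count_b),
            individual=str(r.individual),
        )
        for r in df.itertuples()
    ]


@dataclasses.dataclass
class ASBResult:
    """Pooled allele-specific binding result across individuals.

    ``mean_pct``/``sd_pct`` are the mean and (n-1) SD of the per-individual
    allele-A fractions, as percentages; ``pvalue`` is the two-sided
    cross-individual one-sample t-test of the fractions against 0.5.
    """

    snp_id: str
    fractions: np.ndarray
    mean_pct: float
    sd_pct: float
    binomial_p: np.ndarray
    pvalue: float


def asb_test(counts: Sequence[AlleleCounts]) -> ASBResult:
    """Cross-individual allele-specific binding test at one SNP."""
    usable = [c for c in counts if c.depth >= 1]
    if len(usable) < 2:
        raise ValueError("need >= 2 individuals with allelic reads")
    snp_ids = {c.snp_id for c in usable}
    if len(snp_ids) != 1:
        raise ValueError(f"counts mix multiple SNPs: {sorted(snp_ids)}")
    f = np.array([c.fraction_a for c in usable])
    binom_p = np.array(
        [
            stats.binomtest(c.count_a, c.depth, 0.5, alternative="two-sided").pvalue
            for c in usable
        ]
    )
    sd = float(np.std(f, ddof=1))
    if sd == 0.0:
        if np.allclose(f, 0.5):
            p = 1.0
        else:
            warnings.warn(
                "all allelic fractions identical and != 0.5; cross-individual "
                "t-test degenerate, reporting p below machine precision",
                stacklevel=2,
            )
            p = float(np.nextafter(0.0, 1.0))
    else:
        p = float(stats.ttest_1samp(f, 0.5).pvalue)
    return ASBResult(
        snp_id=usable[0].snp_id,
        fractions=f,
        mean_pct=float(100.0 * f.mean()),
        sd_pct=100.0 * sd,
        binomial_p=binom_p,
        pvalue=p,
    )


def allele_pwm_delta(
    pwm: PWM, ref_window: str, alt_window: str
) -> tuple[float, float, float]:
    """Matrix-similarity scores of two allelic windows and their difference.

    Windows must be equal-length and differ at exactly one position; a
    positive delta favours the reference allele.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("allelic windows must have equal length")
    diffs = sum(a != b for a, b in zip(ref_window.upper(), alt_window.upper()))
    if diffs != 1:
        raise ValueError(f"windows differ at {diffs} positions, expected exactly 1")
    if len(ref_window) != pwm.length:
        # score the best window within the probe on either strand
        from .motifs import revcomp, scan_scores

        def best(seq: str) -> float:
            fwd = scan_scores(pwm, seq)
            rev = scan_scores(pwm, revcomp(seq))
            return float(max(fwd.max(), rev.max()))

        score_ref, score_alt = best(ref_window), best(alt_window)
    else:
        score_ref = match_score(pwm, ref_window)
        score_alt = match_score(pwm, alt_window)
    return score_ref, score_alt, score_ref - score_alt


@dataclasses.dataclass(frozen=True)
class EqtlResult:
    snp_id: str
    gene_id: str
    beta: float
    se: float
    pvalue: float
    label: str  # 'cis' or 'trans'
    n: int


def eqtl_association(
    dosage: Sequence[float],
    expression: Sequence[float],
    covariates: np.ndarray | None = None,
    snp_id: str = "snp",
    gene_id: str = "gene",
    snp_pos: tuple[str, int] | None = None,
    gene_tss: tuple[str, int] | None = None,
    cis_window: int = CIS_WINDOW,
) -> EqtlResult:
    """Single-marker OLS of expression on genotype dosage plus covariates.

    The slope's two-sided t-test p-value is reported; the pair is labelled
    cis iff the gene TSS lies within ``cis_window`` of the SNP (label
    'unknown' when positions are not supplied).
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("dosage and expression must be equal-length vectors")
    n = len(g)
    if np.ptp(g) == 0:
        raise ValueError("dosage is constant; slope undefined")
    X = [np.ones(n), g]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate matrix does not match sample size")
        X.extend(C[:, j] for j in range(C.shape[1]))
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough samples for the design")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), dof))
    label = "unknown"
    if snp_pos is not None and gene_tss is not None:
        same_chrom = snp_pos[0] == gene_tss[0]
        label = (
            "cis"
            if same_chrom and abs(snp_pos[1] - gene_tss[1]) <= cis_window
            else "trans"
        )
    return EqtlResult(
        snp_id=snp_id, gene_id=gene_id, beta=beta, se=se, pvalue=p, label=label, n=n
    )


def integrate_trans_network(
    eqtl_results: Iterable[EqtlResult],
    p_threshold: float,
    bi_gene_set: Iterable[str],
) -> pd.DataFrame:
    """Trans genes passing the eQTL p threshold, flagged by BI support.

    Returns a table (gene_id, beta, pvalue, bi_supported) sorted by p-value;
    the ``attrs`` carry supported/unsupported counts.
    """
    bi_genes = set(bi_gene_set)
    rows = [
        {
            "gene_id": r.gene_id,
            "beta": r.beta,
            "pvalue": r.pvalue,
            "bi_supported": r.gene_id in bi_genes,
        }
        for r in eqtl_results
        if r.label == "trans" and r.pvalue < p_threshold
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "beta", "pvalue", "bi_supported"])
    df = df.sort_values("pvalue", ignore_index=True) if len(df) else df
    df.attrs["n_supported"] = int(df["bi_supported"].sum()) if len(df) else 0
    df.attrs["n_unsupported"] = len(df) - df.attrs["n_supported"]
    return df
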