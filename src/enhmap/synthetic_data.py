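"""Synthetic toy datasets with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the study inputs: two
individuals x three cell conditions of CIITA/RFX5 peak calls with shared
and individual-specific peaks, ordered RFX5-CREB-NF-Y modules planted in a
subset of promoters, DE p-values enriched in BI-associated genes, an eSNP
with a cis effect on a regulator and a mediated trans gene set, and
heterozygous-site read counts at a planted allelic ratio. Every output is a
pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .intervals import GenomicInterval, PeakCall
from .motifs import revcomp

__all__ = [
    "TruthBI",
    "TruthSet",
    "generate_genome",
    "plant_binding_sites",
    "plant_modules",
    "generate_peaks",
    "generate_expression",
    "generate_allelic_reads",
    "write_sam",
    "generate_genotypes_expression",
    "DEFAULT_CONDITIONS",
    "MODULE_CONSENSUS",
]

#: (cell type, treatment) condition labels of the study design
DEFAULT_CONDITIONS = ("Bcell_naive", "mono_naive", "mono_IFNg")

#: synthetic consensus strings for the ordered tri-motif module
#: (X-box-like, CRE-like, CCAAT-box-like; toy motifs, not database matrices)
MODULE_CONSENSUS = {
    "RFX5": "GTTGCCATGGCAAC",
    "CREB": "TGACGTCA",
    "NFY": "AGCCAATCA",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class TruthBI:
    """A planted consensus binding region for one factor in one condition."""

    chrom: str
    start: int
    end: int
    condition: str
    factor: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclasses.dataclass
class TruthSet:
    """Ground truth serialized alongside generator outputs."""

    seed: int
    bis: list[TruthBI] = dataclasses.field(default_factory=list)
    module_genes: dict = dataclasses.field(default_factory=dict)
    de_target_genes: list[str] = dataclasses.field(default_factory=list)
    esnp: dict = dataclasses.field(default_factory=dict)
    allelic: dict = dataclasses.field(default_factory=dict)
    gene_associations: dict = dataclasses.field(default_factory=dict)
    config: dict = dataclasses.field(default_factory=dict)

    def ce_flags(self) -> dict[tuple[str, int, int, str], bool]:
        """True CE status per CIITA truth BI: an RFX5 truth BI of the same
        condition overlaps it by >= 1 bp."""
        rfx = [b for b in self.bis if b.factor == "RFX5"]
        flags = {}
        for b in self.bis:
            if b.factor != "CIITA":
                continue
            hit = any(
                r.condition == b.condition
                and r.chrom == b.chrom
                and min(r.end, b.end) - max(r.start, b.start) >= 1
                for r in rfx
            )
            flags[(b.chrom, b.start, b.end, b.condition)] = hit
        return flags

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "bis": [dataclasses.asdict(b) for b in self.bis],
            "module_genes": self.module_genes,
            "de_target_genes": self.de_target_genes,
            "esnp": self.esnp,
            "allelic": self.allelic,
            "gene_associations": self.gene_associations,
            "config": self.config,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["bis"] = [TruthBI(**b) for b in d["bis"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# genome and genes


def generate_genome(
    n_contigs: int = 2,
    contig_len: int = 600_000,
    n_genes: int = 200,
    seed: int | np.random.Generator = 0,
    min_spacing: int = 5_000,
    edge_margin: int = 10_500,
    desert_len: int = 40_000,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-composition contigs with spaced genes of random strand.

    Genes keep >= ``min_spacing`` bp between TSSs and an ``edge_margin``
    from contig ends so that promoter and control windows always fit; the
    last ``desert_len`` bp of each contig stay gene-free (a gene desert
    where intergenic binding sites can be planted far from every TSS).
    """
    if contig_len < 50_000:
        raise ValueError("contig_len must be >= 50 kb")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1
    for ci in range(n_contigs):
        chrom = f"chr_sim{ci + 1}"
        codes = rng.integers(0, 4, size=contig_len, dtype=np.uint8)
        genome[chrom] = bytes(_BASES[codes]).decode()
        k = per_contig[ci]
        if k == 0:
            continue
        usable = contig_len - 2 * edge_margin - desert_len - (k - 1) * min_spacing
        if usable <= k:
            raise ValueError(
                f"{k} genes with {min_spacing} bp spacing do not fit in a "
                f"{contig_len} bp contig"
            )
        draws = np.sort(rng.choice(usable, size=k, replace=False))
        tss = edge_margin + draws + np.arange(k) * min_spacing
        strands = rng.choice(["+", "-"], size=k)
        for gi in range(k):
            genes.append(
                GeneModel(f"gene_{ci + 1}_{gi:04d}", chrom, int(tss[gi]), strands[gi])
            )
    return genome, genes


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tss_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# promoter modules


def plant_modules(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    promoter_genes: Sequence[str],
    consensus: Mapping[str, str] = MODULE_CONSENSUS,
    spacing: int = 10,
    seed: int | np.random.Generator = 0,
    window: int = 300,
) -> tuple[dict[str, str], dict]:
    """Write the ordered motif consensus strings into selected promoters.

    The module (motifs in order, ``spacing`` bp apart) is placed at a random
    offset of the [TSS - window, TSS) window of each selected gene, oriented
    along the gene strand. Returns the modified genome and a truth mapping
    gene_id -> {start, strand, offsets}.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in genes}
    motifs = list(consensus.items())
    span = sum(len(s) for _, s in motifs) + spacing * (len(motifs) - 1)
    if span > window:
        raise ValueError(f"module span {span} exceeds promoter window {window}")
    seqs = {c: bytearray(s.encode()) for c, s in genome.items()}
    truth: dict[str, dict] = {}
    occupied: list[tuple[str, int, int]] = []
    for gene_id in promoter_genes:
        g = by_id[gene_id]
        w_lo = g.tss - window
        if w_lo < 0:
            raise ValueError(f"promoter window of {gene_id} exceeds contig start")
        for chrom, lo, hi in occupied:
            if chrom == g.chrom and min(hi, g.tss) - max(lo, w_lo) > 0:
                raise ValueError(f"promoter window of {gene_id} collides with another module")
        occupied.append((g.chrom, w_lo, g.tss))
        start = w_lo + int(rng.integers(0, window - span + 1))
        # build module in gene orientation, then place on the forward strand
        offsets: dict[str, int] = {}
        pos = 0
        parts: list[tuple[str, str]] = []
        for name, cons in motifs:
            offsets[name] = pos
            parts.append((name, cons))
            pos += len(cons) + spacing
        module = bytearray(seqs[g.chrom][start : start + span])
        for name, cons in parts:
            o = offsets[name]
            module[o : o + len(cons)] = cons.encode()
        if g.strand == "-":
            module = bytearray(revcomp(module.decode()).encode())
        seqs[g.chrom][start : start + span] = module
        truth[gene_id] = {
            "chrom": g.chrom,
            "start": start,
            "span": span,
            "strand": g.strand,
            "offsets": offsets,
        }
    return {c: s.decode() for c, s in seqs.items()}, truth


# ---------------------------------------------------------------------------
# binding sites and peaks


def plant_binding_sites(
    genes: Sequence[GeneModel],
    contig_lengths: Mapping[str, int],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    n_promoter_sites: int = 40,
    n_intergenic_sites: int = 10,
    site_len: int = 400,
    seed: int | np.random.Generator = 0,
    p_both: float = 0.4,
    p_ciita_only: float = 0.25,
    p_rfx5_only: float = 0.15,
    anchors: Sequence[tuple[str, int]] = (),
) -> list[TruthBI]:
    """Plant consensus binding sites at promoters and intergenic positions.

    Per site and condition the factor pattern is drawn from {both, CIITA
    only, RFX5 only, absent}; 'both' sites are true CE-marks in that
    condition. Promoter sites sit at a random offset within 8 kb of a gene
    TSS, intergenic sites away from all gene territories. ``anchors`` are
    fixed (chrom, centre) positions — e.g. planted promoter modules — that
    always receive a site with CIITA support in every condition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_promoter_sites > len(genes):
        raise ValueError("more promoter sites requested than genes available")
    chosen = rng.choice(len(genes), size=n_promoter_sites, replace=False)
    locations: list[tuple[str, int]] = []

    def conflicts(chrom: str, start: int) -> bool:
        # sites kept 2 site lengths apart so jittered peaks can never merge
        return any(
            c == chrom and abs(s - start) < 2 * site_len for c, s in locations
        )

    anchored: list[tuple[str, int]] = []
    for chrom, centre in anchors:
        start = centre - site_len // 2
        if start < 0 or conflicts(chrom, start):
            raise ValueError(f"anchored site at {chrom}:{centre} collides")
        locations.append((chrom, start))
        anchored.append((chrom, start))
    for gi in sorted(chosen):
        g = genes[gi]
        for _try in range(200):
            offset = int(rng.integers(-8000, 8001))
            start = g.tss + offset - site_len // 2
            if start >= 1000 and not conflicts(g.chrom, start):
                locations.append((g.chrom, start))
                break
        else:
            raise ValueError(f"could not place a promoter site near {g.gene_id}")
    chroms = sorted(contig_lengths)
    gene_pos = {
        c: np.array(sorted(g.tss for g in genes if g.chrom == c)) for c in chroms
    }
    n_wanted = len(anchored) + n_promoter_sites + n_intergenic_sites
    attempts = 0
    while len(locations) < n_wanted:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place intergenic sites away from genes")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(12_000, contig_lengths[chrom] - 12_000))
        near = gene_pos[chrom]
        if near.size and np.min(np.abs(near - pos)) <= 10_000 + site_len:
            continue
        if conflicts(chrom, pos):
            continue
        locations.append((chrom, pos))
    probs = np.array(
        [p_both, p_ciita_only, p_rfx5_only, 1 - p_both - p_ciita_only - p_rfx5_only]
    )
    if np.any(probs < 0):
        raise ValueError("factor-pattern probabilities must sum to <= 1")
    anchored_set = set(anchored)
    p_rfx_given_ciita = p_both / (p_both + p_ciita_only)
    bis: list[TruthBI] = []
    for chrom, start in locations:
        for cond in conditions:
            if (chrom, start) in anchored_set:
                # anchored (module) sites always carry CIITA
                factors = (
                    ("CIITA", "RFX5")
                    if rng.random() < p_rfx_given_ciita
                    else ("CIITA",)
                )
            else:
                pattern = rng.choice(4, p=probs)
                factors = (("CIITA", "RFX5"), ("CIITA",), ("RFX5",), ())[pattern]
            for f in factors:
                bis.append(TruthBI(chrom, start, start + site_len, cond, f))
    return bis


def generate_peaks(
    truth_bis: Sequence[TruthBI],
    contig_lengths: Mapping[str, int],
    n_individuals: int = 2,
    jitter_sd: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    fp_len: int = 300,
) -> dict[tuple[str, str, str], list[PeakCall]]:
    """Per-(condition, factor, individual) narrowPeak-style peak calls.

    Each truth BI emits one peak per individual with Normal(0, jitter_sd)
    endpoint jitter (clamped to keep >= 50% reciprocal overlap with the
    truth extent) and is dropped independently with probability ``fn_rate``.
    Spurious individual-specific peaks are added at ``fp_rate`` per 100 kb;
    by construction they overlap neither truth sites nor the other
    individual's spurious peaks, so they can never form a BI.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    groups: dict[tuple[str, str, str], list[PeakCall]] = {
        (b.condition, b.factor, ind): []
        for b in truth_bis
        for ind in individuals
    }
    for b in truth_bis:
        length = b.end - b.start
        # each endpoint moves at most a quarter length: >=50% reciprocal overlap
        max_shift = length // 4
        for ind in individuals:
            if rng.random() < fn_rate:
                continue
            if jitter_sd > 0:
                d1 = int(np.clip(rng.normal(0, jitter_sd), -max_shift, max_shift))
                d2 = int(np.clip(rng.normal(0, jitter_sd), -max_shift, max_shift))
            else:
                d1 = d2 = 0
            start, end = b.start + d1, b.end + d2
            start = max(0, start)
            end = min(contig_lengths[b.chrom], max(end, start + 1))
            iv = GenomicInterval(b.chrom, start, end)
            groups[(b.condition, b.factor, ind)].append(
                PeakCall(
                    iv,
                    summit_offset=(end - start) // 2,
                    score=float(rng.integers(20, 100)),
                    signal=float(rng.uniform(5, 15)),
                    pvalue=float(rng.uniform(5, 30)),
                    qvalue=float(rng.uniform(2, 20)),
                    name=f"{b.factor}_{b.chrom}_{b.start}",
                )
            )
    if fp_rate > 0:
        truth_by_cf: dict[tuple[str, str], list[TruthBI]] = {}
        for b in truth_bis:
            truth_by_cf.setdefault((b.condition, b.factor), []).append(b)
        total_len = sum(contig_lengths.values())
        chroms = sorted(contig_lengths)
        for (cond, factor), sites in sorted(truth_by_cf.items()):
            occupied: list[tuple[str, int, int]] = [
                (b.chrom, b.start - 1, b.end + 1) for b in sites
            ]
            for ind in individuals:
                n_fp = rng.poisson(fp_rate * total_len / 100_000)
                placed = 0
                tries = 0
                while placed < n_fp and tries < 100 * max(n_fp, 1):
                    tries += 1
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    start = int(rng.integers(0, contig_lengths[chrom] - fp_len))
                    if any(
                        c == chrom and min(e, start + fp_len) - max(s, start) > 0
                        for c, s, e in occupied
                    ):
                        continue
                    occupied.append((chrom, start, start + fp_len))
                    groups[(cond, factor, ind)].append(
                        PeakCall(
                            GenomicInterval(chrom, start, start + fp_len),
                            summit_offset=fp_len // 2,
                            score=float(rng.integers(20, 100)),
                            signal=float(rng.uniform(5, 15)),
                            pvalue=float(rng.uniform(5, 30)),
                            qvalue=float(rng.uniform(2, 20)),
                            name=f"fp_{factor}_{chrom}_{start}",
                        )
                    )
                    placed += 1
    for peaks in groups.values():
        peaks.sort(key=lambda p: p.interval.sort_key)
    return groups


def write_narrowpeak_files(
    groups: Mapping[tuple[str, str, str], Sequence[PeakCall]], out_dir: str | Path
) -> dict[tuple[str, str, str], Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for (cond, factor, ind), peaks in sorted(groups.items()):
        path = out_dir / f"{cond}.{factor}.{ind}.narrowPeak"
        with open(path, "w") as fh:
            for p in peaks:
                fh.write(
                    "\t".join(
                        [
                            p.interval.chrom,
                            str(p.interval.start),
                            str(p.interval.end),
                            p.name,
                            f"{p.score:g}",
                            ".",
                            f"{p.signal:g}",
                            f"{p.pvalue:g}",
                            f"{p.qvalue:g}",
                            str(p.summit_offset),
                        ]
                    )
                    + "\n"
                )
        paths[(cond, factor, ind)] = path
    return paths


# ---------------------------------------------------------------------------
# expression, allelic reads, genotypes


def generate_expression(
    genes: Sequence[str],
    target_set: Sequence[str],
    a: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """DE p-values: Uniform(0,1) background, Beta(a, 1) targets (a < 1 =>
    enrichment of small p-values in the target set)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = set(target_set)
    if not targets <= set(genes):
        raise ValueError("target_set must be a subset of genes")
    p = pd.Series(rng.random(len(genes)), index=list(genes))
    if targets:
        idx = [g for g in genes if g in targets]
        p.loc[idx] = rng.beta(a, 1.0, size=len(idx))
    return p


def generate_allelic_reads(
    ratio: float = 0.661,
    depth: int = 100,
    n_individuals: int = 5,
    seed: int | np.random.Generator = 0,
    snp: tuple[str, str, int, str, str] = ("rs_sim1", "chr_sim1", 50_000, "A", "G"),
) -> list:
    """Binomial(depth, ratio) allele-A counts for each heterozygous
    individual at the planted SNP (default ratio 0.661 emulates the observed
    allelic skew)."""
    from .allelic import AlleleCounts

    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snp_id, chrom, pos, a, b = snp
    out = []
    for i in range(n_individuals):
        ca = int(rng.binomial(depth, ratio))
        out.append(
            AlleleCounts(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                allele_a=a,
                allele_b=b,
                count_a=ca,
                count_b=depth - ca,
                individual=f"het{i + 1}",
            )
        )
    return out


def write_allele_counts(counts: Sequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tsnp_id\tchrom\tpos\tallele_a\tallele_b\tcount_a\tcount_b\n")
        for c in counts:
            fh.write(
                f"{c.individual}\t{c.snp_id}\t{c.chrom}\t{c.pos}\t"
                f"{c.allele_a}\t{c.allele_b}\t{c.count_a}\t{c.count_b}\n"
            )


def write_sam(
    counts,
    path: str | Path,
    contig_len: int = 100_000,
    read_len: int = 51,
    seed: int | np.random.Generator = 0,
) -> Path:
    """Emit a plain-text SAM with reads spanning the SNP carrying the drawn
    allele bases, for end-to-end testing of allele counting."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path = Path(path)
    chrom, pos = counts.chrom, counts.pos
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{contig_len}\n")
        rid = 0
        for base, n in ((counts.allele_a, counts.count_a), (counts.allele_b, counts.count_b)):
            for _ in range(n):
                offset = int(rng.integers(1, read_len - 1))
                start = pos - offset  # 0-based leftmost
                if start < 0:
                    start, offset = 0, pos
                codes = rng.integers(0, 4, size=read_len)
                seq = list("ACGT"[c] for c in codes)
                seq[offset] = base
                fh.write(
                    "\t".join(
                        [
                            f"read{rid}",
                            "0",
                            chrom,
                            str(start + 1),
                            "60",
                            f"{read_len}M",
                            "*",
                            "0",
                            "0",
                            "".join(seq),
                            "I" * read_len,
                        ]
                    )
                    + "\n"
                )
                rid += 1
    return path


def generate_genotypes_expression(
    n: int = 281,
    maf: float = 0.3,
    beta_cis: float = 0.5,
    trans_genes: Sequence[str] = (),
    beta_trans: float = 0.5,
    noise_sd: float = 1.0,
    background_genes: Sequence[str] = (),
    cis_gene: str = "CIITA",
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Hardy-Weinberg genotypes and a mediated expression matrix.

    The cis gene's expression is beta_cis * dosage + noise; each trans gene
    is beta_trans * (cis expression) + noise (mediation through the
    regulator); background genes are pure noise. Returns (dosage,
    genes x individuals DataFrame).
    """
    if not 0 < maf < 0.5:
        raise ValueError("maf must lie in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosage = rng.binomial(2, maf, size=n).astype(float)
    while np.ptp(dosage) == 0:  # astronomically rare at n >= 20
        dosage = rng.binomial(2, maf, size=n).astype(float)
    expr: dict[str, np.ndarray] = {}
    cis_expr = beta_cis * dosage + rng.normal(0, noise_sd, n)
    expr[cis_gene] = cis_expr
    for g in trans_genes:
        expr[g] = beta_trans * cis_expr + rng.normal(0, noise_sd, n)
    for g in background_genes:
        expr[g] = rng.normal(0, noise_sd, n)
    cols = [f"s{i + 1:03d}" for i in range(n)]
    return dosage, pd.DataFrame(expr, index=cols).T
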