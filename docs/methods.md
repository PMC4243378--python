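# Methods

This note documents the models and procedures implemented in `enhmap`, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical/design choices that were genuinely open.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED-native). Region boundaries
quoted in browser style (1-based inclusive, e.g. the MHC at
chr6:29,580,000–33,100,000) are converted on construction by subtracting 1
from the start; the built-in masks (MHC, MHC class II, MHC class I) follow
this convention. Overlap anywhere in the pipeline means a shared length of
at least `min_overlap` bp, default 1 — no minimum overlap is inherent to
the definitions, so the threshold is a configuration knob everywhere it
appears (CE-marks, DCS, condition specificity, interval intersection).

`merge_intervals` merges same-chromosome intervals separated by ≤ `gap` bp
(default 0, which preserves the covered-base union exactly and merges
book-ended intervals); it is idempotent. `intersect` reports pairs with
overlap ≥ `min_overlap` and is symmetric in its two arguments.

## Binding intervals

Within one (cell type/condition, factor) a **binding interval** is derived
from exactly two individuals' FDR-filtered peak calls as:

1. per individual, merge the peak footprints (gap 0);
2. intersect the two individuals' merged sets base-wise (≥1 bp);
3. merge contiguous/overlapping shared pieces into BIs.

The consensus footprint is the base-pair **intersection**, not the union:
presence in both individuals is the defining requirement, and the
intersection is the conservative region both replicates support (this is
also what the per-base boolean oracle in the tests checks). Member peaks
from both individuals are retained as metadata; the representative summit
is the summit of the highest-scoring member peak, ties broken by the
leftmost summit coordinate so derivation is deterministic and invariant to
input order.

A CIITA BI overlapping an RFX5 BI from the same condition (≥ `min_overlap`
bp) is a **CE-mark**. The **DCS** of a BI is defined here as the count of
distinct configured feature tracks (default set: DHS plus RFX5, CREB1,
ATF1, NFYA, NFYB) overlapping it by ≥1 bp — a count out of 6, so "DCS > 4"
means at least five co-incident features. A weighted score would be an
alternative reading; the count is the simplest score consistent with a
bounded 0–6 scale and is stated as a package definition. A BI is
condition-specific when no BI of any other condition of the same cell type
overlaps it.

## Gene association

Distance is measured from the gene TSS to the nearest covered base of the
BI: 0 if the TSS lies inside the BI, otherwise `start − tss` (BI to the
right) or `tss − (end − 1)` (BI to the left). Edges rather than summits
define the distance because the BI, not the summit, is the unit of
association. The association window is strict (`|d| < 10,000` bp by
default, either side) while the proximal class is inclusive
(`|d| ≤ 2,000`); the sign is oriented by gene strand (negative = BI
upstream). The relation is many-to-many, and genes are classified
single-proximal / single-distal / both from their association pattern.

## Motif module scoring

PWMs are read from JASPAR-format count matrices (via Biopython). Counts
become column frequencies, every frequency cell gets a +0.01 pseudocount
and columns are renormalized — this avoids ln 0 at a distortion below 4%
per cell. The information vector is `I(i) = Σ_b f(i,b) ln(4 f(i,b))`
(0 for a uniform column, ln 4 in the degenerate limit).

A window of PWM length scores
`(Current − Min)/(Max − Min)` with `Current = Σᵢ I(i)·f(i,bᵢ)` and
Min/Max the per-position worst/best sums, so the consensus scores exactly
1 and the per-position-worst sequence exactly 0. `N` contributes the
per-position minimum; scoring is case-insensitive. If the matrix carries no
information at all (Max = Min) the score is defined as 0.

The ordered module search evaluates, for both orientations of a 150 bp
summit-centred segment, all placements of the motif series (RFX5, CREB,
NF-Y) with strictly increasing, non-overlapping starts on that orientation,
and returns the placement maximizing the average component score
(implemented exactly by a suffix-max dynamic program; the tests compare it
against cubic enumeration). Ties resolve to the leftmost first-motif start,
then second, then third, then to the forward orientation. Requiring a
single shared orientation reflects the cis arrangement of the S–X–X2–Y
module; whether opposite-strand or overlapping placements should be
admitted is genuinely open, and the single-strand non-overlapping reading
was chosen as the stricter one. No core-similarity prefilter or score
cutoff is applied — the normalized score in [0,1] is used directly so that
averages of component scores are well defined.

Control segments are drawn per gene from the strand-oriented
[TSS − 10 kb, TSS + 150 bp) window, one uniformly random 150 bp slice per
sampled gene; genes whose window leaves the contig are resampled with a
logged warning. Group score distributions are compared by the two-sided
Mann–Whitney U test with tie correction (scipy).

## eCDF enrichment

Genes are ranked by DE p-value (average ranks on ties) and mapped to
rank-quantiles u = rank/N ∈ (0,1]. For a target set of m ≥ 5 genes the
empirical CDF F̂ of the members' quantiles is evaluated on a fixed grid
(99 points, 0.01…0.99). The confidence band is a **pointwise bootstrap
percentile interval**: `n_boot` (default 1,000) resamples of the target set
with replacement, per-grid-point α/2 and 1−α/2 quantiles, clamped to
contain the observed curve. A simultaneous band would be wider; pointwise
was chosen because the band is a per-point visual uncertainty, and the
calibration suite verifies its per-point coverage directly.

The deviation statistic is the one-sided sup deviation above the diagonal,
computed exactly at the eCDF jump points: `D = maxᵢ (i/m − u₍ᵢ₎)`. Its
null distribution is simulated by Monte-Carlo from m-sized iid Uniform(0,1)
draws (default 10,000 replicates), and the p-value uses the standard
(1 + #{D_null ≥ D})/(1 + n_mc) estimator. Sampling target quantiles as iid
uniforms ignores the without-replacement structure of ranks; at
m/N ≤ a few percent the finite-population correction is negligible, and
the calibration checks confirm near-uniform null p-values.

## Allele-specific binding

Reads spanning a biallelic SNV are tallied per allele from SAM/BAM
(streaming, no index required): unmapped, duplicate, secondary and
supplementary reads are excluded, and both mapping quality and base
quality must be ≥ 20 (matching the read-filtering spirit of ChIP-seq
pipelines). Bases matching neither allele are counted separately and never
enter the test.

Per individual, an exact two-sided binomial test of count_a against 0.5 is
reported. The headline cross-individual p-value is a two-sided one-sample
t-test of the per-individual allele-A fractions against 0.5; the mean and
the n−1 SD of the fractions are reported as percentages. The choice of the
pooled test was open (the source analysis reports a single p-value for
five individuals without naming the test); the t-test on fractions treats
individuals, not reads, as the unit of replication, and the per-individual
binomials are reported alongside so neither reading is lost. If all
fractions coincide away from 0.5 the t statistic degenerates; the result
is reported as a p-value below machine precision with a warning.

## eQTL association and trans integration

Expression is regressed on genotype dosage (0/1/2) with an intercept and
optional covariates by OLS; the slope's two-sided t-test provides the
p-value. Constant dosage and rank-deficient designs are rejected. A
SNP–gene pair is cis iff the gene TSS lies within 1 Mb of the SNP.
Trans integration filters trans-labelled results at a p threshold
(default 3×10⁻⁴, the threshold used for the published trans network at
n = 281) and flags each passing gene by membership in the BI-associated
gene set.

## Synthetic-data generator

The generator is a pure function of (config, seed) — every output is
byte-identical across runs — and serializes a truth JSON next to its
outputs. Defaults mirror the study design where one exists:

| parameter | default | rationale |
|---|---|---|
| individuals per condition | 2 | replicate-consensus design |
| conditions | B cells, naive monocytes, IFNγ-treated monocytes | study design |
| allelic ratio / depth / individuals | 0.661 / 100 / 5 | observed allelic skew, typical site depth, five heterozygotes |
| eQTL cohort size | 281 | expression cohort size |
| DE target p-values | Beta(0.2, 1) | strong but not degenerate enrichment |
| genome | 2 contigs × 600 kb, 200 genes, ≥5 kb TSS spacing | every stage runs in seconds |
| peak jitter / FP / FN | 0 / 0 / 0 | noiseless by default; knobs for robustness runs |

Two scale choices deviate from round numbers for geometric reasons: 200
genes at ≥5 kb spacing plus 10.5 kb edge margins cannot fit in 2×500 kb,
so contigs default to 600 kb; and the last 40 kb of each contig is kept
gene-free (a "gene desert") so that intergenic binding sites farther than
10 kb from every TSS exist at this gene density. Planted binding sites are
kept ≥2 site-lengths apart so that jittered peaks can never merge two
truth sites into one BI, which keeps site-count recovery exact. Spurious
peaks are individual-specific by construction (they overlap neither truth
sites nor the other individual's spurious peaks), so they can never create
a consensus BI — a property, not an accident, of the consensus rule.

Peak endpoint jitter is Normal(0, jitter_sd) clamped to a quarter of the
site length per endpoint, which guarantees ≥50% reciprocal overlap with
the truth extent. Module planting writes the three consensus strings in
order, 10 bp apart, at a random offset of the [TSS−300, TSS) window
(the S–X–X2–Y module sits within ~300 bp of transcription initiation),
oriented along the gene strand. The module PWMs are synthetic toy
matrices built from X-box-like, CRE-like and CCAAT-box-like consensus
strings — they are deliberately not database matrices, so tests exercise
the scoring machinery without shipping third-party data.

The mediated trans-network simulation (trans gene = β_trans × regulator
expression + noise) uses β_cis = β_trans = 1 and noise SD 0.5 in the
pipeline defaults: a mediated slope of β_cis·β_trans must clear the
3×10⁻⁴ threshold at n = 281, and power arithmetic shows the weaker
(0.5, 1.0) setting used for the slope-recovery simulations would leave
individual trans genes near t ≈ 2.4, i.e. undetectable at that threshold.
The slope-recovery checks themselves keep β_cis = 0.5, noise SD 1.

What the generator does **not** emulate: read-level coverage and fragment
models (peaks are simulated directly, since peak calling is out of scope),
mappability and reference bias at heterozygous sites, linkage
disequilibrium between markers, correlated noise across genes, and
realistic promoter base composition (contigs are iid uniform). Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under the stated model, not robustness to artefacts of
real sequencing data.

## Problem sizes used by the validation suites

The test and calibration suites use deliberately small instances chosen so
that exact brute-force oracles remain feasible: interval oracles run on
10–200 kb toy chromosomes with tens of features; the module-search oracle
enumerates all ordered placements of three 4-mers in 60 bp segments; band
calibration uses 1,000 uniform-null replicates of 10,000 genes with
200-gene targets and 1,000 bootstrap resamples; power checks use 100
simulated genomes (50 planted vs 50 control segments), 100 DE data sets,
500 allelic simulations and 100 eQTL cohorts of n = 281.

## Known limitations

- The BI consensus uses the two-individual intersection; designs with >2
  replicates per condition are rejected rather than generalized.
- The DCS is an unweighted track count; no signal-strength weighting.
- Control-segment sampling is per-gene uniform; no GC or repeat matching.
- The eQTL module is a single-marker OLS utility — no genome-wide scan,
  FDR machinery, PEER/latent-factor estimation, or LD awareness.
- One TSS per gene record; transcript isoforms are not modelled.
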