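# enhmap

Consensus ChIP-seq binding-interval mapping and enhanceosome module
analysis for the MHC class II transactivator system (CIITA/RFX5), with
rank-based differential-expression enrichment, allele-specific binding
quantification and a simplified eQTL integration.

CIITA is a non-DNA-binding coactivator recruited to MHC class II promoters
through the enhanceosome — RFX (via the X box), CREB1/ATF1 and NF-Y bound
at the constrained S–X–X2–Y promoter module. `enhmap` implements, as a
tested and reusable pipeline, the analyses needed to map such a factor
genome-wide from replicated ChIP-seq and to connect binding to expression
genetics:

- **Binding intervals (BIs).** Within a cell type/condition, a BI is the
  merged base-pair intersection of a factor's enriched peaks called in
  *both* individuals — a replicate-consensus footprint. CIITA BIs
  co-incident (≥1 bp) with RFX5 BIs are classified as **CE-marks**
  (CIITA enhanceosome marks); a **data-coincidence score (DCS)** counts how
  many accessory feature tracks (DNase hypersensitivity, RFX5, CREB1, ATF1,
  NFYA, NFYB) overlap each BI.
- **Gene association.** A BI is linked to a gene when its nearest edge lies
  strictly within 10 kb of the TSS (either side); links within 2 kb are
  proximal, and genes are classified single-proximal / single-distal /
  both.
- **Ordered tri-motif module scoring.** 150 bp segments centred on BI
  summits are scanned for the RFX5→CREB→NF-Y module: each motif gets a
  MATCH-style matrix-similarity score
  `(Current − Min)/(Max − Min)` with `Current = Σᵢ I(i)·f(i, bᵢ)` and
  `I(i) = Σ_b f(i,b)·ln 4f(i,b)`, and the best same-strand, ordered,
  non-overlapping placement maximizing the average component score is
  reported. Score groups (module-bearing vs control promoters) are compared
  with a two-sided Mann–Whitney test.
- **eCDF enrichment.** Genes ranked by DE p-value map to rank-quantiles
  u = rank/N; the empirical CDF of a target gene set is compared with the
  diagonal F(u) = u, with a pointwise 95% bootstrap band and the one-sided
  sup deviation D = sup_u (F̂(u) − u) tested by Monte-Carlo.
- **Allele-specific binding.** Reads spanning a heterozygous SNP are
  tallied per allele (base/mapping quality ≥ 20, duplicates excluded); each
  individual gets an exact binomial test against 0.5 and the headline
  p-value is a cross-individual one-sample t-test of the allelic fractions.
- **eQTL integration.** Single-marker OLS of expression on genotype dosage
  (plus optional covariates such as expression principal components),
  cis/trans labelled by a 1 Mb window, and trans genes passing a p
  threshold flagged by membership in the BI-associated gene set.

A first-class synthetic-data generator (`enhmap.synthetic_data`) emulates
every input — two individuals × three conditions of peak calls with shared
and individual-specific peaks, promoter-planted motif modules, enriched DE
p-values, a cis-eSNP with a mediated trans network, and allelic read
counts at a planted 66.1% ratio — and serializes the ground truth so every
stage can be validated exactly.

## Worked example

```bash
enhmap run-all --seed 1 --out demo_run
```

runs the whole synthetic workflow (simulate → derive BIs → CE-marks/DCS →
gene association → module scan → enrichment → ASB → eQTL integration) and
prints, among other things:

```json
{
 "binding": {"n_bis": 288, "n_ciita_bis": 167, "n_rfx5_bis": 121, ...},
 "annotate": {"n_associations": 508, "n_genes": 144,
              "fraction_ciita_bis_with_gene": 0.922, ...},
 "truth_match": {"bi_counts": true, "ce_flags": true,
                 "gene_associations": true, "trans_support": true}
}
```

Here 288 consensus BIs were derived from the simulated peak calls (167
CIITA, 121 RFX5 across three conditions), 92% of CIITA BIs fell within
10 kb of a TSS covering 144 genes, and — because the default configuration
adds no peak noise — every derived quantity matches the serialized
generator truth exactly (`truth_match` all true). The full summary in
`demo_run/summary.json` also reports the module-score contrast
(median planted score 1.0 vs 0.64 control, Mann–Whitney p ≈ 2×10⁻¹⁴), the
DE enrichment deviation (D ≈ 0.15, Monte-Carlo p < 0.001), the pooled
allelic fraction (69.0% mean, t-test p ≈ 3×10⁻⁴ against 50%) and the
cis-eQTL slope with the 12-gene trans network of which 8 are supported by
a BI.

The same stages are available as file-based subcommands (`derive-bi`,
`ce-marks`, `dcs`, `annotate`, `module-scan`, `enrich`, `asb`, `eqtl`,
`integrate`) over narrowPeak/BED/FASTA/JASPAR/TSV inputs, and as plain
library functions.

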