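# Methods

`varburden` asks one question about one gene: do its rare missense
variants show a population-specific overload consistent with a founder
effect?  The motivating case is *OTOG* (otogelin) in familial Meniere
disease, where a small cohort of probands carries a set of rare missense
variants whose frequencies can be contrasted with gnomAD v2.1 exome
populations.  The package decomposes the question into four estimators,
each fed by the same variant-table data model, plus a synthetic generator
that plants known truth for every estimator.

## Per-variant enrichment

For a variant and an ordered population pair, the allele-count table

|        | alt | ref |
|--------|-----|-----|
| pop 1  | a   | b   |
| pop 2  | c   | d   |

is summarized by the sample odds ratio OR = ad/bc.  A variant is
*enriched* in pop 1 when OR ≥ 1 and p < α (default 0.05), *depleted*
symmetrically.  Margins default to AN = 2N with the gnomAD v2.1 exome
sample sizes (NFE 56,885; AFR 8,128; EAS 9,197; SAS 15,308; AMR 17,296;
global 125,748 individuals); per-site AN overrides are honored when a
table provides them.  A population in which the variant is unobserved
contributes AC = 0 at its panel AN — absence from a surveyed population
is evidence of frequency ≈ 0, not missing data.

**Real-valued cells.**  Public databases print rounded AFs.  For a rare
variant the implied count AF·AN is small, and rounding it to an integer
(2.41 → 2) moves the odds ratio by double-digit percentages.  Cells
reconstructed from AF are therefore kept real-valued by default; integer
rounding (`rounding="nearest"`) is applied only inside the exact test,
which needs counts.  This is what makes odds ratios recomputed from a
published frequency table agree with the published ORs to within the
print precision.

**Inference.**  The p-value is the two-sided Fisher exact test under the
minimum-likelihood rule (sum of hypergeometric probabilities no larger
than the observed table's), computed on scipy's hypergeometric pmf and
verified against full enumeration.  The default CI is Woolf's:
exp(log OR ± z·√(1/a+1/b+1/c+1/d)), on the Haldane-corrected (+0.5)
table when a cell is zero; the conditional exact interval (inverting the
noncentral hypergeometric test, via scipy) is available as
`method="exact"` because published intervals for sparse tables are often
exact-test based and much wider than Woolf's.  Zero alt counts yield
OR = 0 or ∞ under the default `zero_policy="none"`; Haldane correction is
a flag.  Raw p-values are reported per comparison (matching how such
tables are usually published); Benjamini–Hochberg adjustment across all
comparisons is an option.

## Gene-level burden

Allele-level collapsing: per-variant alt counts are summed over the
gene's rare (reference AF < 0.01, strict) missense variants and divided
by a single allele number, for the cohort (2 × probands alleles) and for
each reference population; the two aggregated frequencies enter the same
2×2 machinery.  With one variant the burden OR reduces exactly to that
variant's OR.  Carrier-level collapsing is deliberately not the default:
the aggregated-AF formulation is the one that can be computed from a
sites-only frequency table without genotypes.

Control genes are selected by |CDS length − focal length| ≤ tolerance
(default ±439 bp around 8,778 bp, i.e. a ~5% band).  The focal gene's
variant count is ranked in the panel by midrank percentile,
100·(below + 0.5·ties)/(n+1); the +1 keeps the focal gene inside its own
ranking.  BH q-values are computed (statsmodels) over whatever family of
p-values the caller assembles.  In the pipeline the family is the focal
gene's set of population comparisons: control genes in a frequency-table
workflow carry no cohort counts, so they contribute length matching and
percentile context, not burden p-values.

## Variant density and constrained regions

At each CDS position i (step 1) the density is the number of distinct
variant sites carried (AC > 0) in the population within
[i−100, i+100] — a 201-bp window — divided by the window length, with
terminal windows clipped and rescaled so CDS ends are not artifactually
"low density".  A site counts once regardless of frequency.  The
threshold is an expected density: a user-supplied expected missense count
for the whole release (gnomAD-constraint style), scaled per population as
a direct proportion and divided by CDS length.  Two proportionality
readings are implemented — allele-number share (default) and
observed-variant share — because the choice is genuinely open; neither
changes the machinery.  Positions strictly below threshold are LDR
("constrained"), others HDR; maximal runs partition the CDS, variants are
annotated by containing region, and two populations' labelings are
compared as the percentage of agreeing CDS positions.

Density operates in concatenated-CDS coordinates: windows never span
introns, matching how such profiles are drawn against protein position.
The published similarity percentages for *OTOG* (73.78 / 66.37 / 65.35 /
60.18 vs SAS/AMR/EAS/AFR) require the full gnomAD v2.1 per-population
variant lists; reproducing them is a replication recipe (download the
gene's missense variants per population, build one profile per population
with the release's expected counts, call regions, compare), not a test —
the packaged data ship only the cohort's 13 variants.

## Linkage disequilibrium

r² = D²/(p_A q_A p_B q_B) with D = p_AB − p_A p_B.  From phased
haplotypes the computation is exact integer arithmetic, so a sample with
only two segregating haplotypes returns exactly 1.  From unphased
dosages, the two-locus EM resolves double heterozygotes: starting at
linkage equilibrium, E-steps split the ambiguous class between coupling
and repulsion in proportion to the current likelihood, to tolerance
1e-10 within 1000 iterations (the two-locus likelihood is unimodal in
practice; non-convergence raises).  When no unambiguous repulsion
haplotype exists and EM drives the ambiguous mass to one side, the
boundary MLE is recognized and r² = 1 is returned exactly.  EM equals the
phased closed form whenever the sample contains no double heterozygote.
Monomorphic sites yield a flagged NaN, never 0 — "no information" and "no
association" are different findings.  Missing dosages are rejected rather
than imputed.

## Synthetic data

The generator emulates the statistical skeleton of the study inputs, not
their biology:

* **Frequencies** — one true AF per variant drawn log-uniformly from
  (1e-5, 5e-3) (the rare regime below the 0.01 filter; the upper bound
  leaves headroom for planted enrichment), shared across populations
  under the null; counts are binomial at each population's AN; the
  global column is the sum over populations.
* **Enrichment** — planted on the odds scale, odds(p_target) =
  OR·odds(p_base), so the sample OR is the estimand.
* **Positions** — distinct CDS positions drawn uniformly, then thinned
  inside planted segments by an intensity multiplier < 1; a multiplier of
  0.1 over 1,500 bp of an 8,778-bp CDS is the canonical recovery setting.
* **Cohort** — 100 probands (200 alleles) by default; counts binomial at
  the reference AF, optionally with a planted odds multiplier or fixed
  counts.  Because odds are convex, a per-variant odds multiplier k
  implies a slightly larger aggregated odds ratio; `cohort_truth_or`
  returns the exact aggregated estimand.
* **Controls** — 64 genes, lengths uniform within ±439 bp; counts
  Poisson at per-population per-bp rates matched (by default) to the
  expected carried-site count of a null focal gene.
* **Genotypes** — each planted pair gets the four-haplotype table
  achieving its target r² for its MAFs (feasibility
  r² ≤ min(p₁q₂/q₁p₂, q₁p₂/p₁q₂) is enforced with the bound reported);
  two haplotypes per individual are drawn independently — no
  recombination, no structure, no missingness, because only pairwise r²
  is consumed downstream.

One seed drives everything; per-stage generators are derived with fixed
spawn keys so stages are independently reproducible.  What passing
recovery tests show is that the estimators invert this generator — they
do not show robustness to sequencing artifacts, population substructure,
per-site AN variation or annotation error, none of which the generator
emulates.

### Recovery experiment conditions

Chosen once to mirror the study scale and kept fixed:

* Enrichment: 500 replicate variants, baseline AF 1.5e-4, OR 9 planted on
  the smaller (AFR-sized) population against the NFE-sized one, so both
  alt-count cells stay informative (expected counts ≥ 17; mean-of-ratios
  bias stays within a few percent).  Measured with Haldane policy.
* Burden: 300 replicates of a 60-variant gene, per-variant cohort odds
  ×3; mean estimate compared with the exact aggregated estimand.
* Density: 50 seeds, 2,000 drawn variants, one 1,500-bp segment at
  multiplier 0.1; threshold at half the background density — any
  threshold strictly between the thinned and background densities
  identifies the segment, and the midpoint maximizes the margin on both
  sides.  Recovery scored as Jaccard overlap of called vs planted LDR.
* LD: 200 replicates at n = 5,000 individuals for planted r² of 0.332
  (MAF 0.05) and 0.832 (MAF 0.10) — the moderate- and high-linkage
  magnitudes reported for the motivating gene's variant pairs.
* CI calibration: 2,000 variants at true OR 2, baselines log-uniform in
  (1e-3, 8e-3), Woolf 95% coverage checked against a 93–97% band.

## Numerical choices and degenerate inputs

* Positions are 1-based (HGVS g.-style) in variant tables; BED exports
  are 0-based half-open in CDS coordinates.
* AC reconstruction from a printed AF uses round(AF·AN) where an integer
  is required; the validator accepts |AF − AC/AN| ≤ 0.5/AN.
* Fisher ties are compared with a 1+1e-9 relative tolerance so equal
  hypergeometric probabilities degraded by floating point still count as
  ties.
* Degenerate 2×2 tables (an empty alt or ref column) return NaN
  intervals and are flagged, not raised: an all-zero variant is a valid
  row of a frequency table.
* A cohort table validates cohort_an = 2×probands and the strict rarity
  filter on construction, so downstream code never re-checks.
* Pipeline outputs contain no timestamps; a rerun with the same
  configuration is byte-identical, and the manifest stores SHA-256
  checksums of all outputs.

## Known limitations

* The gene-level burden here is the aggregated-frequency cross-product
  OR.  Published gene-burden analyses that use carrier-based or
  regression-based association can give systematically different point
  estimates from the same table (for the motivating cohort: ≈3.98 here
  vs a published 3.40 [2.10–5.49]); the implementation documents, and
  tests against, interval-level agreement only.
* Exact-test-style confidence intervals for sparse tables are not
  uniquely defined across software; only point estimates are treated as
  reproducible surfaces.
* No liftover or genome-build reconciliation: positions are stored as
  given.
* LDR calling assigns no statistical significance to regions; it is a
  thresholded descriptive profile.
* VCF `Float` INFO fields are single precision by specification, so AFs
  round-trip through VCF at ~7 significant digits; the TSV path is
  lossless.
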