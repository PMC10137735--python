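# Methods

## Setting

A complete diallel cross over P inbred parents produces up to P(P−1)
hybrids (reciprocals distinct, female parent recorded).  The reference
layout shipped with the package has P = 8 with three unobtained cells, hence
53 hybrids, ten yield-related traits, and leaf transcriptomes (three
biological replicates per parent) summarised as FPKM.  The pipeline relates
three summaries of the *parental* transcriptomes — differential-expression
counts, profile distances, and per-gene parental expression values — to the
*hybrids'* trait values and heterosis.

## Heterosis statistics

For hybrid value F1 with parental values P_f, P_m (both required positive):
MP = (P_f + P_m)/2, HP = max(P_f, P_m) by default (direction configurable
per trait, since "better" is trait-dependent).  Two conventions:

* difference: MPH = 100·(F1 − MP)/MP, HPH = 100·(F1 − HP)/HP;
* ratio: MPH = 100·F1/MP, HPH = 100·F1/HP.

Each ratio statistic equals its difference counterpart plus exactly 100, so
Pearson correlations against either are identical; the convention is stamped
into every output.  The difference convention implies HPH ≤ MPH for every
record; published per-trait summaries in this literature sometimes violate
that inequality, which identifies them as ratio-convention numbers — one
reason both are implemented.  Non-positive parental references make the
percent statistics undefined; such records are skipped with a warning rather
than imputed.

## DEG calling

Between the two parents of a pair, genes with zero FPKM in every replicate
of both parents are removed from the universe; for the rest, p-values come
from a two-sided Welch (unequal-variance) t-test on log2(FPKM + 1) across
replicates, adjusted by Benjamini–Hochberg over the tested genes.  A gene is
called up (higher in the female parent) when q < 0.05 and
log2((μ_f + 0.1)/(μ_m + 0.1)) > 1 on replicate-mean FPKM, down for the
mirrored condition.  The 0.1-FPKM pseudo-count bounds fold changes at zero
expression; with it, a true 2-fold change at low expression (4 vs 2 FPKM)
falls just below the threshold — a deliberate conservative property covered
by a test.  The test is a pragmatic choice for mean-difference detection on
normalised values at n = 3; the downstream analyses consume only the
counts and directions, and swapping the parents exactly negates log2FC and
swaps UP/DOWN (an invariant the pipeline exploits to compute each unordered
pair once).

## Distances

Euclidean distance is computed on replicate-mean FPKM profiles, by default
untransformed (literal profile distance; dominated by highly expressed
genes) with log2(x+1) available by configuration.  The binary distance uses
presence = FPKM > τ (τ = 0 by default): with a/b/c the counts of genes
present in both / only the first / only the second parent, it is
(b + c)/(a + b + c), i.e. the Jaccard dissimilarity of presence patterns
(R's "binary" distance), 0 when no gene is present in either profile.  The
gene universe used is recorded in the output.

## Correlation analyses

All associations are sample Pearson correlations with two-sided p from the
exact t reference (t = r·√((n−2)/(1−r²)), n−2 df).  Stars mark p < 0.05 and
p < 0.01.  DEG-count predictors attach to hybrids through their ordered
parent pair; distances through the unordered pair, so reciprocal hybrids
share a predictor value but remain distinct observations.  The gene screen
tests HPV/MPV/LPV (max/mean/min of the two parental means) against the
observed value and the MPH of a target trait; BH adjustment runs within
each basis × response family (matching the practice of reporting separate
per-basis counts), with a pooled mode off by default.  Genes with constant
basis values are flagged and excluded from the BH universe.  Reported table
extrema are rounded half away from zero to two decimals, the convention of
printed tables.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) for k of n query genes annotated to a
term covering K of the N background genes, computed with scipy's stable
survival function and BH-adjusted across terms with k ≥ 1.  The background
is the expression matrix's gene universe after the zero-expression filter —
a snapshot-independent choice, since a "genome background" depends on the
annotation release.

## Synthetic-data generator

The generator emulates the reference study's conditions and provides ground
truth for recovery tests.

* **Expression.**  Baseline log2 FPKM ~ N(3, 2²) (planted pathway-like
  genes N(4, 1), matching the high expression of e.g. ribosomal genes);
  null genes get independent parent-specific deviations (SD 0.35 log2);
  20% of null genes are "variably present" and silent in each parent with
  probability 0.3, producing realistic presence/absence variation for the
  binary distance; per-parent planted DEG shifts of ±2 log2 affect 2% of
  genes per parent.  Counts are negative-binomial (dispersion 0.05, typical
  of controlled biological replicates of inbred lines) with lognormal gene
  lengths (median 1.5 kb) and library sizes of 15–25 M fragments, converted
  to FPKM with the package's own normaliser using realised column totals.
* **Traits.**  Parent values are truncated normal with the reference
  study's per-trait means and SDs.  Hybrid values are built on the ratio
  scale: MPH_ratio ~ mean + sd·S (per-trait moments from the study's
  reported heterosis summaries; SD = quarter-range where a range is
  reported, mean/4 otherwise; floored at 10% to keep every value positive),
  and F1 = MP·MPH_ratio/100.
* **Planted gene–heterosis correlation.**  Each parent has a latent score
  u_p; planted genes load linearly on it (mean FPKM ∝ clip(1 + 0.4·s·u_p)),
  making their mid-parent expression collinear with
  z = standardised(u_f + u_m) across hybrids.  The target trait's signal is
  S = c·z + √(1−c²)·ε with c = ρ/att, where the attenuation
  att = mean |corr(z, realised MPV)| over planted genes is measured from the
  generated matrix; the *measured* planted MPV–MPH correlation is therefore
  ρ in expectation.  ρ > att is rejected as infeasible at the configured
  noise level.  Non-target traits instead take S = γ·z_d + √(1−γ²)·ε with
  z_d the standardised realised Euclidean distance (γ = 0.4).
* **Annotation.**  ~1.2 random terms per gene over 200 terms, plus one term
  covering 70% of the positively planted genes (at ~0.5% background rate)
  for enrichment-recovery tests.

Identical configs and seeds give byte-identical files (hash-checked).  The
default scale is 20,000 genes; a 500-gene `tiny` profile drives the test
suite.  What the generator does **not** emulate: read-level sequencing
noise, isoform structure, batch effects, genetic linkage between planted
genes, and trait–trait correlations; passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not performance on any particular real dataset.

## What the diallel's structure does to the gene screen

The 53 hybrids are not independent: each parent appears in ~13 of them, and
every gene-level predictor (HPV/MPV/LPV) is a symmetric function of the two
parents — after centring it lives in a ≤ 7-dimensional subspace of the
53-dimensional observation space.  Consequently:

* If the response carries parent-structured signal (as any true heterosis
  signal must), null genes — random vectors in the same subspace — acquire
  spurious correlations of typical size |signal share|/√7.  At a planted
  correlation of 0.6 this is ≈ 0.23, far above the 1/√53 ≈ 0.14 the t
  reference assumes.  Strict FDR control of the naive screen at the diallel
  level is therefore impossible in principle — a property of the design
  (and of any real dataset with this layout), not of the implementation.
* The observed-value response inherits mid-parent structure through
  F1 = MP·(MPH/100) even under a global null, mildly inflating
  observed-family discovery fractions; the MPH response under the null
  architecture is exchangeable and calibrates exactly.

The package therefore calibrates the screen's operating characteristics
(null discovery fraction, sensitivity ≈ 0.8 and empirical FDR ≈ 0.01 at
q < 0.01 for 100 planted series at ρ = 0.6 among 20,000 at n = 53) on
exchangeable series, while diallel-level tests assert what the structure
allows: the planted-correlation magnitude band, sign-consistent
classification, and planted genes dominating the top of the ranking.  This
also cautions that large gene lists from such screens on real diallel data
likely include parent-structure artefacts.

## Numerical and scale choices

* Sample SD uses the n−1 denominator throughout; CV% = 100·SD/mean is
  recomputed, never read back from rounded inputs, and flagged undefined
  for non-positive means.
* Degenerate Welch statistics (zero variance in both groups) are treated
  conservatively (p = 1).
* BH families are adjusted independently; q-values are clipped at 1 and
  order-preserving.
* Test-suite and acceptance scales — null screen calibration 100 seeds ×
  5,000 genes, DEG null 200 repetitions × 2,000 genes, recovery 3 seeds ×
  20,000 series, pipeline runs on the 500-gene tiny profile — were chosen
  as the smallest sizes at which the asserted averages are stable.
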