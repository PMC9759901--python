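# Methods

This note documents the statistical procedures, the synthetic data
model, the default parameters and the design decisions behind
`methmirnet`, in the spirit of a model-description appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Methylation site calling

At each cytosine the data are a methylated read count *m* and an
unmethylated count *u*. The site test asks whether the methylated
fraction exceeds what bisulfite non-conversion and sequencing error
alone would produce: the p-value is the exact binomial upper tail
P(X ≥ m | n = m + u, p₀). A site is *called* iff depth ≥ `depth_min`
(default 5) **and** p ≤ `p_max` (default 0.05); under-covered sites are
never called regardless of p.

* `p0` — null methylated fraction; default **0.005**, a typical
  non-conversion rate. The upstream protocol this reimplements does not
  state its null, so the parameter is exposed everywhere.
* The test is one exact binomial test. An alternative reading of the
  source protocol ("two distribution tests") as two separate tests has
  no defined second test, so the single exact test was fixed here.
* Exact tests are discrete: at realistic depth (~30×) the achieved
  level is below the nominal 5% (conservative, never liberal). The
  calibration test therefore checks the nominal rate in the
  near-continuous regime (simulated depth 5000×, p₀ = 0.5), and checks
  only conservativeness at realistic depth. This is a property of every
  exact test, not an implementation artifact.

## 2. DMR detection

A sliding window of `window_bp` = 1000 advanced by `step_bp` = 100
scans each chromosome. A site enters the scan when its coverage reaches
`depth_min` in both groups — pooled across replicates by default, or in
every sample with `coverage_mode='per_sample'`. A window is testable
iff it holds ≥ `min_cpgs` = 3 such sites. The window statistic is
Fisher's exact test on the pooled 2×2 table (m, u) × (case, control);
BH correction runs across all testable windows; windows passing
p ≤ 0.05, q ≤ 0.05 and |Δ| ≥ `min_mean_diff` = 0.1 are merged where
they overlap (half-open intervals; touching windows stay separate).
A merged region keeps the minimum window p (and its q) while its
methylation difference and CpG count are recomputed over the merged
span. Direction: *hyper* iff the pooled case level exceeds control;
zero differences are unclassifiable and dropped with a warning.

Design decisions:

* The upstream DMR tool's internals are not published; this window
  procedure is a fully specified, parameterized stand-in and is tested
  as such (Fisher p against hypergeometric enumeration; label-swap
  antisymmetry; null calibration of the window test at ~5%).
* Pooling counts within groups is the default because n = 5 with ~30×
  coverage leaves per-sample tests underpowered; a Welch t-test on
  per-sample window mean levels is available as `test='ttest'`.
* Pooled Fisher assumes binomial counts; the generator's beta-binomial
  overdispersion (below) deliberately violates this, so a small number
  of decoy windows reach significance. Downstream differential and
  correlation gates absorb them; this mirrors the real behaviour of
  pooled tests on overdispersed bisulfite data.
* All coordinates are 0-based half-open; 1-based inputs must be
  converted at the reader boundary.

## 3. Expression normalization and differential screen

miRNA counts are scaled to reads per million (RPM); mRNA counts to
reads per kilobase of exon per million (RPKM), requiring a positive
exon length per gene. The differential test is a two-sided Welch t on
log₂(normalized value + pseudocount), pseudocount default **1.0**; BH
adjusted Q values across all tested features; features with all-zero
counts in both groups are excluded before testing (count logged).
Presets: miRNA |log₂FC| ≥ 1, P < 0.05, Q ≤ 0.05; mRNA P < 0.05,
Q ≤ 0.05 (no fold-change floor). The looser miRNA screen without the
Q gate is a parameter away (`q_max=1`).

* The source protocol never names its DE test; Welch on log counts was
  chosen for determinism and small-n robustness over a count GLM.
* Welch's test is itself mildly conservative at n = 5 per group
  (Satterthwaite df estimation); its null calibration is checked at
  n = 20 per group, where it attains the nominal level, pooled over
  independent cohorts because features within one cohort share samples
  and are not independent units.

## 4. Promoters, overlap, targets

The promoter of a miRNA is the `upstream_bp` = 2000 window upstream of
its TSS, strand-aware, clipped to the chromosome (the upstream study
cites a genome browser but states no window; 2 kb is the conventional
choice and is configurable). DMR–promoter pairs require ≥ 1 bp
intersection under half-open semantics. Target candidates use the
7mer-m8 seed rule by default — an exact occurrence of the reverse
complement of miRNA positions 2–8 in the 3'UTR, overlapping occurrences
counted — with 7mer-A1 and 8mer behind a flag; U/T are normalized to
one alphabet at the boundary. Full hybridization/energy alignment is
deliberately not reproduced; externally computed pair tables can be
loaded instead (`load_target_map`).

## 5. Network assembly

Candidate meth→miRNA edges are promoter-overlap pairs whose DMR passed
screening and whose miRNA is differentially expressed; miRNA→mRNA
candidates are target pairs with both features differential. Each
candidate is scored by Pearson correlation (Spearman selectable) of
per-sample values: the DMR's coverage-weighted mean methylation level
vs miRNA RPM, and miRNA RPM vs mRNA RPKM. Retention requires p ≤ 0.05
and |r| ≥ `r_min` = 0.7; **strict mode** (default) additionally
requires r < 0 on both edge kinds and the sign-consistent pattern
(hypo, up, down) or (hyper, down, up). Permissive mode drops the sign
constraints and reproduces mixed-direction networks. Zero-variance
vectors make a correlation undefined; such edges are skipped and
logged. One miRNA overlapping several DMRs keeps all pairs (no
best-edge selection). r_min and the edge p ceiling are package
defaults — the upstream study names Pearson retention but no cutoffs.

Triplet recovery against generator truth scores unique (miRNA, mRNA)
pairs; a pair counts as true when it was planted and at least one of
its DMRs overlaps the planted promoter interval.

## 6. Clinical statistics

`ttest_from_summary` computes the two-sample t directly from printed
mean ± SD ± n, pooled (df = n₁+n₂−2) or Welch (Satterthwaite df);
two zero-SD groups with equal means return t = 0, p = 1 by convention.
Comparisons against printed tables round half away from zero to the
printed decimals. Trait correlation tables use pairwise-complete
observations, require ≥ 3 pairs per cell and skip constant columns with
a warning. `ddct` is the plain 2^−ΔΔCT transform.

The qRT-PCR validation cohort's printed p-values are not reproducible
from its printed summaries under any t-test (the upstream analysis used
rank-sum tests on raw values that are not deposited); only the
sequencing cohort's summary table is used quantitatively.

## 7. Synthetic cohort generator

The generator emulates a 2-group sequencing study at configurable
scale; defaults: 5 case + 5 control samples, 4 chromosomes of 1 Mb,
50 miRNAs and 200 mRNAs, 8 CpGs per promoter, 5 planted triplets.

* **Methylation**: CpGs live inside miRNA promoter windows; coverage is
  Poisson(`coverage_mean` = 30); methylated counts are beta-binomial
  with intra-class correlation `bb_overdispersion` = 0.02 (binomial at
  0) around the group's level. Background level `meth_base` = 0.5 in
  both groups; planted promoters shift the case level by ±`meth_delta`
  = 0.4 (hypo by default; hyper and alternating available).
* **Expression**: negative-binomial (gamma-Poisson) counts with
  dispersion `nb_dispersion` = 0.05 and log-normal library sizes
  (mean 10⁶, CV 0.1). Baseline relative abundances are log-normal
  (σ = 1); planted features draw from the upper half of that
  distribution (folded normal) because a feature whose regulation is
  detectable must be expressed — without this, planted targets falling
  in the low-expression tail are undetectable at n = 5 for reasons
  unrelated to the method under test. Planted miRNAs shift by
  2^±`expr_log2fc` (default 4-fold) in cases with sign opposite to
  their promoter shift; their targets shift the opposite way.
* **Sequences**: miRNAs are random 22-nt RNA; 3'UTRs are random DNA of
  `utr_length_bp` = 500. Chance occurrences of a *planted* miRNA's
  seed site anywhere are mutated away before its `sites_per_target` = 2
  intended sites are planted, so the planted truth is unambiguous.
  Decoy miRNAs keep their chance matches — realistic noise that the
  differential gates must absorb.
* **Clinical traits**: normal per group with parameters resembling a
  small angiography cohort; the Gensini severity score is an affine
  function of the first planted promoter's realized methylation with
  target correlation `gensini_meth_r` = −0.77 plus noise, scaled to
  mean 30 / SD 25 and clipped at 0.

What the generator does **not** emulate: read-level artifacts (mapping,
duplicates, conversion efficiency), genomic CpG density outside
promoters, correlated co-regulation among decoys, isoform structure,
batch effects, or any real linkage between clinical traits and
expression beyond the single planted Gensini link. Passing recovery
tests therefore demonstrates the pipeline's logic and calibration, not
performance on real cohorts.

## 8. Problem sizes and numerical choices

The recovery experiment plants 10 triplets among 200 decoy miRNAs and
1,000 decoy mRNAs (n = 5 per group, 50× coverage, Δ = 0.4, 4-fold
expression shifts, strict mode, r_min = 0.7); the test suite reports
the median precision/recall over 25 seeds and the acceptance script
over 5 seeds — both at the same conditions; the 5-seed protocol is the
script's reporting choice. Calibration experiments use ≥ 2,000 units
(5,600 CpGs; 2,400 features across 3 independent cohorts; ≥ 2,000
windows) with two-standard-error bands around the nominal 5%.
Monte-Carlo generator checks average 100–500 seeds. Ties in BH are
handled by the step-up minimum; Fisher's two-sided p uses the
conventional "sum of no-more-probable tables" rule; merged-region
p-values are not re-combined across windows (the minimum window p is
reported, a deliberate anti-conservative convention shared by common
window scanners and immaterial after BH at the window level).

## 9. Known limitations

* The pooled Fisher window test inherits binomial assumptions;
  overdispersed data inflate its false-positive rate (absorbed
  downstream, see §2). The per-sample t mode trades power for
  robustness.
* n = 5 per group caps power: planted features near the screening
  thresholds are missed at rates the recovery tests make visible.
* Seed matching is a proxy for target prediction; it neither scores
  binding energy nor conservation.
* Strict-mode sign logic encodes the canonical promoter-methylation
  chain; regulatory relationships outside it (e.g. methylation that
  silences in cases) appear only in permissive mode.
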