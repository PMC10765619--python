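# Methods

This note documents the models and estimators implemented in `sweepibd`,
the defaults chosen where several conventions exist, what the synthetic
data does and does not emulate, and the known limitations.

## Variant processing

**Hard filters.** Six rules, applied per record: QD > 2, FS < 60,
MQ > 40, MQRankSum > −12.5, ReadPosRankSum > −8, and missing-call
fraction ≤ 0.2 (equivalent to a vcftools `--max-missing 0.8` requirement
of ≥ 80 % called genotypes, implemented as *fail if missing fraction
strictly exceeds 0.2*). An INFO metric absent from a record does not fail
its rule: GATK leaves the rank-sum annotations undefined at sites without
both homozygous and heterozygous carriers, and failing such sites would
discard records a standard pipeline keeps. The filter is monotone in all
thresholds (property-tested).

**Region classification.** Only biallelic SNPs are analyzed. Each SNP
receives exactly one of eight region categories with priority
exonic > splicing > 5′UTR > 3′UTR > intronic > upstream > downstream >
intergenic. Flanking windows are 5 kb and the splice window is 2 bp into
the intron (common annotator defaults). One representative transcript per
gene is used — the longest spliced transcript, a deterministic and common
reduction. Coding effects (synonymous, nonsynonymous, stop-gain,
stop-loss) come from the standard genetic code; minus-strand genes are
handled by complementing the alleles into coding orientation. The
classifier is verified against an exhaustive mutate-translate-compare
oracle over every possible SNP of a random CDS.

**Coordinates.** Internally everything is 0-based half-open (BED
convention); VCF (1-based) and GFF3 (1-based closed) are converted at the
I/O boundary. Conversion preserves interval length exactly.

## Window statistics

Windows are 200 kb sliding with 100-kb steps, tiling each chromosome from
position 0; windows with fewer than 10 usable variants or a zero
F<sub>ST</sub> denominator are dropped from the table (and therefore from
every quantile denominator). Defaults follow the windowing a
vcftools-based scan would use.

* **Diversity.** Per site, the unbiased heterozygosity
  `π_i = 2 p (1−p) · n/(n−1)` with `n` the called allele count at the
  site in that population; sites with fewer than two called alleles are
  excluded, never imputed. Windowed π is `Σ π_i / window_bp` — note the
  denominator is window length, not the variant count, so monomorphic
  stretches correctly dilute diversity.
* **F<sub>ST</sub>.** Weir & Cockerham (1984) two-population variance
  components `a` (between-population) and `a+b+c` (total), computed per
  site from sample sizes, allele frequencies and observed
  heterozygosities. The windowed estimate is the ratio of sums
  `Σa / Σ(a+b+c)` (the "weighted" estimator); a per-window mean of
  per-site ratios is *not* used because it is badly behaved at low-MAF
  sites. Sites monomorphic across both populations contribute nothing;
  negative windowed estimates are retained. The implementation is tested
  for exact (1e-10) agreement with an independent scalar transcription of
  the published equations, and for calibration: under Balding–Nichols
  divergence with parameter 0.2 the mean windowed estimate recovers 0.2
  within ±0.03 (20 + 20 diploids, 2000 sites).
* **Sweep statistic.** `log2(π_contrast / π_target)`. The orientation is
  chosen so that *high* values indicate diversity lost in the focal
  population; combined with the top-tail rule this selects sweeps in the
  focal population. (The equivalent ratio θπ_target/θπ_contrast < 1 under
  selection — e.g. ≈ 0.55 for a strong sweep — is the same quantity
  inverted; working with the log of the inverted ratio keeps "selected"
  in the upper tail for both statistics.) Windows where either π is zero
  have an undefined ratio and are excluded from quantile ranking and
  calling.

## Region calling

A window is selected when it lies in the top-q tails (default q = 0.05)
of *both* windowed F<sub>ST</sub> and the log₂ ratio, with cutoffs at the
empirical (1−q) quantile using linear interpolation between order
statistics and selection by ≥ cutoff (ties kept). The two tails are
computed on the same retained-window set. Selected windows that overlap
or are book-ended merge into maximal regions carrying the maximum of each
statistic — with 50 %-overlapping windows, separate book-ended regions
would be grid artifacts. With several contrasts, per-contrast regions are
called first and then intersected base-pair-wise (the top-5 % rule is
per-contrast, not pooled).

## IBD detection and transmission

BEAGLE-style haplotype-HMM refined IBD is out of scope; the package uses
a genotype-level IBS-exclusion scan with the same downstream logic:

1. For a sample pair, candidate segments are maximal runs of consecutive
   jointly-called markers containing no opposite-homozygote site — two
   individuals IBD1 at a locus can never be opposite homozygotes absent
   genotyping error.
2. Each run is scored with the classical one-shared-allele LOD,
   `Σ log10 [P(g_a, g_b | IBD1) / (P(g_a) P(g_b))]`, with Hardy–Weinberg
   marginals and the IBD1 joint table (`P(AA,AA)=p³`, `P(AA,Aa)=p²q`,
   `P(Aa,Aa)=pq`, `P(Aa,aa)=pq²`, `P(aa,aa)=q³`, opposite homozygotes
   `0 → err`). Allele frequencies come from the pooled analysis panel
   with equal sample weight; `err = 0.001` is a genotyping-error floor.
   Expected per-site LOD is positive under true IBD1 and negative under
   independence (verified by simulation).
3. Segments must have ≥ 50 markers, span ≥ 100 kb, and score LOD > 0.
4. Within each population relation (all cross-population pairs), only the
   top half by LOD is kept (quantile cutoff with ties kept), and the
   surviving intervals are union-merged into the relation's
   representative IBD intervals.
5. Transmission along a pedigree chain (founder → F1 → F2) is the
   base-pair intersection of the *adjacent* relations, e.g.
   I(S,BS) ∩ I(BS,DBS); including the grandparent relation I(S,DBS) is
   deliberately off by default since transmission through the chain is
   what the design asks, and the grandparent signal is a subset of it in
   expectation.

Because the synthetic crosses draw gametes from genotyped founders, true
parent-offspring pairs exist in the panel; such pairs are IBD1 along
essentially the whole chromosome, so relation intervals are broad and the
*sweep scan provides the localization* — the same division of labour as
in real crossbred-line studies, where IBD yields tens of megabases and
the sweep intersection narrows them to a handful of genes.

## Candidate mining

Candidates are the base-pair intersection of the (multi-contrast) sweep
regions with the transmitted IBD intervals. Genes overlap a candidate if
their span (TSS→TES) shares ≥ 1 bp — no exon restriction and no minimum
overlap fraction (the bedtools default). Regions without genes are
retained with an empty gene list. With no pedigree available the sweep
regions themselves are annotated and the report flags the skip.

## Association module

Input is a per-population table of genotype counts (n_CC, n_CA, n_AA),
sample size and trait mean. Allele frequencies are recomputed exactly
from counts — reports round to 3 decimals, but the regression always uses
the exact values, which is what reproduces the packaged table's published
fit to printed precision. The HWE χ² compares observed genotype counts
with n·p², 2npq, n·q² and takes the p-value from the χ² upper tail with
**df = 2**; only df = 2 reproduces the reference table's printed P values
(for df = 2, P = exp(−χ²/2)). Monomorphic populations are marked
not-applicable for the test but stay in the regression. The regression is
plain unweighted OLS — weighting by population size changes the slope
substantially (≈ −2.3) and does not reproduce the reference fit, so it is
not used.

## Synthetic data

The generator emulates exactly the structure the estimators assume:

* **Divergence**: ancestral frequencies Uniform(0.05, 0.95); population
  frequencies Beta-distributed around them with variance parameter
  `divergence_fst` (Balding–Nichols; default 0.1). Founder haplotypes are
  i.i.d. per site — no background LD; LD arises only through
  crossbreeding. This is adequate for window statistics but understates
  the autocorrelation of real window scans.
* **Sweep**: haplotype homogenization — inside the sweep interval
  (default 300 kb on a 2-Mb chromosome) each target-population haplotype
  is replaced by one template with probability 1 − residual (residual
  0.05). This produces the diversity collapse and differentiation of a
  completed hard sweep without simulating selection dynamics.
* **Crosses**: each offspring draws one recombinant gamete from a random
  individual of each parent population; crossovers Poisson
  (`1e-8`/bp ≈ 1 cM/Mb) with uniform positions. Every transmitted
  founder-haplotype block and every gamete-donor relationship is recorded
  as truth IBD, giving exact base-level recall targets.
* **Population sizes** default to S = 20, BKX = 10, Y = 11, BS = 5,
  DBS = 20 — a realistic crossbred-line sampling design, so desk-scale
  runs carry comparable sampling noise.
* **INFO metrics**: passing records draw QD, FS, MQ and the rank sums
  inside the passing ranges; a configurable fraction of records receives
  exactly one violating metric and is truth-flagged (a record is also
  flagged if injected missingness pushes it over the 20 % ceiling). This
  makes filter adjudication exactly checkable.
* **Genes**: ten 30-kb four-exon models spaced along the chromosome, one
  centered on the sweep midpoint (the "causal" gene the pipeline should
  recover).
* **Count tables**: A-allele frequency Uniform(0, 0.9), genotype counts
  multinomial under HWE, trait mean linear in the realized sample
  frequency plus Gaussian noise — so the noiseless limit recovers the
  generating line exactly through the real fitting code.

What passing tests therefore show: the estimators are numerically correct
against independent oracles, calibrated on their own generative models,
and the integrated strategy recovers a planted signal at study-like
sample sizes. What they do not show: robustness to background LD,
ascertainment, genotyping error beyond the modeled missingness, or
population histories outside Balding–Nichols.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics everywhere;
  selection/keeping is always by ≥ cutoff so ties are kept.
* Missing genotypes are a sentinel (−1), reduce per-site called counts,
  and are never imputed.
* Empty inputs: quantile thresholds on empty/all-NaN values and
  regressions with < 3 points or constant X raise errors; empty segment
  sets filter to empty; an empty relation empties the transmission chain.
* Simulation problem sizes used by tests and the acceptance script —
  2-Mb chromosome, 4000 variants, 20 replicates — were chosen as the
  smallest design at which the windowed statistics have stable tails
  (≈ 20 windows per replicate) while the whole suite stays interactive.
* All generators are deterministic given the seed (single
  `numpy.random.Generator` with a fixed call order).

## Limitations

* Two-population F<sub>ST</sub> only (the r-population generalization is
  a straightforward extension of the component formulas).
* IBD detection is genotype-based; it cannot separate IBD1 from IBD2 and
  its physical resolution is limited by marker density and the
  opposite-homozygote rate — in particular, error-free parent-offspring
  pairs yield chromosome-length segments.
* The simplified region classifier uses one transcript per gene and does
  not annotate regulatory features.
* No FDR control across windows; the top-quantile rule is an outlier
  criterion, not a significance test.
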