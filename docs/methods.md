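# Methods

## Pipeline overview

`candeqtl` tests a small panel of candidate SNPs against genome-wide
transcript levels in a case/control cohort. The chain is:

1. **Probe QC.** A probe is excluded when its detection P-value exceeds
   `alpha` (default 0.05) in at least `fail_fraction` (default 25%) of
   samples. The comparison against the sample count is strict
   (`fails < fail_fraction · n` retains), so a probe failing in exactly
   the threshold fraction is dropped. `fail_fraction` is exposed because
   the opposite reading — keep probes detected in at least 25% of samples
   — is also in circulation; that rule is `fail_fraction=0.75`.
2. **Normalization.** Raw intensities are shifted by `log_offset`
   (default 1.0, guarding background-subtracted values ≤ 0), log2
   transformed, and quantile-normalized: every sample's values are
   replaced by the across-sample means of the order statistics, assigned
   by within-sample rank. A run of tied values receives the mean of the
   target entries spanning its ranks, which keeps the map deterministic
   and the transform idempotent. With a single sample the transform is the
   identity (after log2).
3. **Covariate residualization.** Each probe is regressed on intercept,
   age (years, continuous) and a 0/1 case indicator; the residuals are the
   phenotype for all downstream testing. Residualization happens once,
   before the scan and before permutation (two-stage design), rather than
   refitting covariates jointly with genotype: this keeps the permutation
   engine a pure relabeling of a fixed residual matrix. The nominal P of
   a joint model would differ slightly; the two-stage form is the
   documented contract. A covariate that is constant across samples is
   dropped with a warning instead of producing a singular design. Samples
   with missing covariates are rejected at load — no silent imputation.
4. **Association scan.** Simple OLS of residual on minor-allele dosage
   (additive, default) or carrier indicator (dominant). Missing genotypes
   are dropped pairwise. Per pair: slope, t statistic, two-sided P with
   n−2 df, r², and adjusted r² = 1 − (1−r²)(n−1)/(n−2) (one predictor).
   A genotype that is constant after missing-data removal yields a flagged
   degenerate record (β = 0, P = 1) so a monomorphic SNP never aborts a
   scan.
5. **Permutation-adjusted P.** B relabelings (default 10,000) of the
   residual matrix's sample labels; `perm_p` = (number of relabelings
   whose statistic ties or beats the observed) / B. Zero is reportable and
   the smallest nonzero value is 1/B; an `add_one` pseudocount
   ((count+1)/(B+1)) is available for strictly positive estimates.
6. **Annotation and reporting.** cis/trans against a 1 Mb window,
   per-SNP significant counts at 0.05/0.01/0.001 (strict `<`), cross-SNP
   overlap, and Fisher/EASE gene-set over-representation with BH FDR.

## Permutation engine

The nominal P of a simple regression is monotone in r² at fixed degrees of
freedom, so the engine compares r² directly and never evaluates the t
distribution inside the loop. Under the default `joint` scheme one
relabeling per iteration is shared by all pairs: for each SNP the permuted
residual rows are restricted to that SNP's non-missing samples and all
probe r² values are computed in one vectorized pass (centered cross-product
against the centered genotype vector). This is O(B · probes · samples) per
SNP and preserves transcript–transcript correlation in the permutation
null. The `per_pair` scheme draws independent relabelings per pair and is
provided for comparison; the two agree in distribution pair by pair.

Ties count against the observed pair (conservative, standard). Because a
relabeling that merely reorders samples within genotype groups reproduces
the observed r² exactly in exact arithmetic but not in floating point, the
comparison uses an absolute slack of 1e-9 on r²: `permuted ≥ observed −
1e-9` counts. Without the slack, summation-order noise breaks exact ties
arbitrarily and the Monte-Carlo estimate falls below the exact enumeration
value (verified against the n ≤ 8 full-enumeration oracle,
`exact_permutation_oracle`). A spurious extra count requires two distinct
labelings within 1e-9 in r², which has negligible probability for
continuous phenotypes.

## Synthetic-data generator

`SimulationConfig` defaults describe the cohort the pipeline was designed
around: 74 cases (ages uniform on 21–85) and 47 controls (ages uniform on
26–89), genotyped at seven ovarian-cancer risk SNPs. Published allele
frequencies are per-group; since the config carries one MAF per SNP, the
default pools them weighted by group size ((74·case + 47·control)/121),
with the per-group values retained in `CASE_CONTROL_MAFS`. Genotypes are
Hardy-Weinberg draws (dosage ~ Binomial(2, MAF)), independent across SNPs
and samples; the optional `ld_pairs` knob samples haplotypes at a given
allelic correlation r for SNPs that should travel together. Ages are
uniform within range — the underlying study reports only median and range,
and uniform is the simplest distribution consistent with the bounds; it is
a stand-in, not a claim about the real age distribution.

Expression is generated on the log2 scale directly (the analysis operates
on log2 intensities): probe baselines uniform on [6, 12], additive age and
status effects (defaults 0.005 per year and 0.1 for cases — small, plausible
log2-scale nuisance effects; the exact values are not critical since they
are removed by residualization), planted SNP effects, and Gaussian noise
(`noise_sd` = 1.0 log2 units). A planted effect is specified as the
fraction *f* of phenotype variance it should explain; the slope is
β = σ·sqrt(f / ((1−f)·2p(1−p))), which makes the population r² of the
genotype term exactly *f* under HWE. Detection P-values are two-point
(0.01 pass / 0.5 fail at rate `detection_miss_rate`, default 0) because
only the 0.05 threshold matters downstream.

What the generator does **not** emulate: bead-level measurement structure,
intensity-dependent noise, batch effects, probe cross-hybridization,
linkage beyond pairwise r, population structure, or relatedness. Passing
tests therefore demonstrate the statistical machinery is correct under the
stated model, not that the pipeline is robust to those artifacts.

One interaction worth knowing: quantile normalization maps values onto the
pooled order-statistic means, so with very few probes (tens) a planted
effect is visibly attenuated by the coarse rank grid; with hundreds of
probes the attenuation is negligible (the README example recovers a
planted 30% variance fraction as adjusted r² ≈ 0.32 with 400 probes).

## Numerical and design choices

* Coordinates are held 0-based half-open internally; SNP TSV positions are
  1-based and converted at load, BED is native. The cis window is closed
  (distance ≤ 1 Mb is cis) and the distance anchor is configurable:
  nearest gene-interval edge (default; 0 inside the gene) or interval
  start.
* Threshold counting uses strict `<`, matching the convention of labeling
  columns "P<0.05". Overlap percentages round to the nearest integer, ties
  away from zero.
* Enrichment: Fisher is the hypergeometric upper tail Pr[X ≥ count]; EASE
  subtracts one from the overlap cell first (count ≤ 1 gives P = 1). Sets
  are intersected with the user-supplied universe before testing; the
  recommended universe is all QC-passing genes. BH is used for the FDR
  column. Results from annotation-database-driven web services depend on
  the database version; this module reproduces the machinery, not any
  specific database's output.
* The adjusted-r² estimator at n = 121 is nearly unbiased for the planted
  variance fraction; the acceptance script's recovery study (1,000
  replicates) returns means within Monte-Carlo error of the target.
* Full-pipeline determinism: the same config and seed produce
  byte-identical output files (seeding uses `numpy.random.default_rng`
  with per-stage seed sequences, so stages are reproducible independently).

## Problem sizes

The test suite and acceptance script use desk-scale problems: the null
calibration study is 500 probes × 2 SNPs × 121 samples with B = 1,000
(about a second, vectorized), and the recovery study is 1,000 replicates
of a single 121-sample regression. A full 10,435-probe × 7-SNP scan at
B = 10,000 runs in minutes on one core under the joint scheme.

## Known limitations

* Permutation preserves exchangeability of samples; it does not account
  for relatedness or stratification (the design assumes unrelated,
  ancestry-matched subjects).
* The per-pair permutation scheme is O(B) relabelings per pair and is not
  intended for full-matrix scans.
* Probe-to-gene assignment is taken from the input annotation; no
  remapping against a transcriptome is attempted.
* No adaptive early stopping for permutations; B is fixed.
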