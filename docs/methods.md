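# Methods

## Model and statistic

`miract` infers miRNA regulatory activity from the joint behaviour of a
miRNA's predicted target set in matched miRNA/mRNA profiles.  The working
assumption is that an active miRNA destabilizes many of its targets at
once, producing weak but coordinated anticorrelation between the miRNA
and its target transcripts; conversely, co-transcription of a miRNA with
its targets produces coordinated positive correlation.  Both signs are
treated as evidence of regulation.

For miRNA *m*, genes are ranked by Spearman correlation with the miRNA
(descending), and a weighted running sum is computed over the ranked
list: position *i* holds

    S_i = Σ_{j ≤ i} ( w_j · |r_j|^α − b ),   b = (1/N) Σ_{targets} s_mj · |r_mj|^α

with w_j = s_mj at target genes and 0 elsewhere.  The enrichment score is
the signed value of S at its maximal |deviation|.  The weight s_mj is the
absolute total context score of the gene's longest 3'UTR isoform, so a
confidently predicted target moves the walk more than a marginal one, and
α (default 1) controls how strongly the correlation magnitude enters.

### Baseline convention

The decrement b is the *average over all N genes* of the target
contributions.  This is the unique convention under which the walk ends
exactly at zero (the same normalization GSEA uses), which in turn makes
positive and negative ES values symmetric, comparable quantities.  The
literal alternative — dividing by |S_m| — introduces a deterministic
negative drift of (1 − N/|S_m|)·Σ s|r| that dwarfs any signal; it is
implemented as `baseline="target_set"` purely for auditing.

### Permutation null and p-values

The null hypothesis is that target identity is unrelated to the
correlation ranking.  Each permutation round reassigns the target
memberships and their weights to uniformly random rank positions while
the sorted correlation profile stays fixed, and records the resulting ES.
This conditions on the observed correlation structure of the
transcriptome and is exactly the generative distribution of a target set
chosen independently of expression.

The empirical p-value is estimated separately for the two regions of the
null: for a positive observed ES, the proportion of *positive-region*
permutation scores at least as high; for a negative ES, the proportion of
negative-region scores at least as low (`denominator="region"`).  Region
normalization makes the p-value uniform under the null — verified in the
calibration test — because the observed score is exchangeable with the
same-region permutation scores.  The variant that divides by the total
number of permutations instead is available (`denominator="all"`) but is
anti-conservative in aggregate: a score beyond the 95th percentile of
*either* region then gets p < 0.05, doubling the nominal rate.  Raw
proportions may be exactly 0 (an observation more extreme than every
permutation); an observed ES of exactly 0 is defined to have p = 1.

p-values are adjusted jointly across all analyzed miRNAs by
Benjamini–Hochberg (step-up), and miRNAs with adjusted p below the FDR
threshold (default 0.1) are flagged as detected regulators.

### Determinism

Every source of randomness is seeded.  Each miRNA's permutation stream is
seeded by a SHA-256 hash of (master seed, miRNA id), so results are
bit-reproducible and independent of the number of miRNAs analyzed, their
processing order, and the worker count when parallelizing.  All
tie-breaks are deterministic: equal correlations rank by gene id; equal
|deviation| in the walk resolves to the earliest position; equal-length
3'UTR isoforms resolve by most-negative score, then isoform id.

### Degenerate inputs

Constant gene rows get correlation 0 with a warning (they can never enter
a leading edge since |r| = 0); a constant miRNA vector is an error.
Matrices with missing cells are rejected at load time rather than imputed
— the rank correlation assumes complete vectors.  Quantile normalization
requires ≥ 2 samples; batch correction requires ≥ 2 batches of ≥ 2
samples (a singleton batch leaves the effect inestimable without
shrinkage, which is out of scope).

## Leading edge and downstream statistics

The leading edge of a positive-ES miRNA is its targets at ranks
1..argmax; for negative ES, targets after the argmax (the mirror
convention, standard in GSEA — "before the peak" is only meaningful for
top-of-list enrichment).  A zero ES yields an empty leading edge.

Annotation enrichment uses the exact hypergeometric upper tail
P(X ≥ overlap) with the *measured* transcriptome (the N ranked genes) as
the universe — a smaller, honest background compared to the whole genome.
Bonferroni correction multiplies by the number of annotation sets with a
non-empty intersection with the universe (sets that cannot possibly
overlap are not counted as tests); categories with corrected p below
10⁻² are reported.  Cross-dataset concordance of two detected-regulator
lists uses the same tail test within the common universe of miRNAs
analyzed in both datasets.

## Preprocessing

Microarray miRNA intensities: asinh variance stabilization, then
mean-of-order-statistics quantile normalization (tied values receive the
mean of the reference values at their tied ranks); an additive
hybridization-batch effect is removed per feature by least squares
(equivalently, subtracting batch-mean deviations from the grand mean,
which preserves each feature's grand mean exactly); probes negative in
≥ 95% of arrays are discarded; technical replicates are averaged.
Sequencing-based miRNA counts use a detection filter instead: keep miRNAs
with more than 10 reads in at least 10% of samples.  The thresholds
follow the stated rules literally: "95% or more" and "at least 10%" are
inclusive (≥), "more than 10 reads" is strict (>).  The pipeline default
order is filter → normalize → batch-correct → average, configurable from
the CLI.  PCA-based outlier removal is not implemented; outliers are
dropped via an explicit sample-exclusion list.

## Synthetic data

The generator produces matched Gaussian matrices with planted signal:
for each planted regulator, a `fraction_responsive` subset of its targets
is replaced by `effect_size × regulator + N(0, noise_sd)`.  Because the
statistic is rank-based (invariant to monotone marginal transforms), this
Gaussian copula model exercises the method faithfully without simulating
platform-specific marginals.  Under it, a responsive target's population
Spearman correlation with its regulator is (6/π)·asin(ρ/2) with
ρ = e/√(e² + σ²); the defaults e = −1, σ = 1 give ≈ −0.69.

Defaults are the study conditions used throughout the validation suite:
1000 genes, 30 miRNAs, 50 samples, 50 targets per miRNA, 10 planted
regulators, 60% responsive targets, effect −1, unit noise.  Weights
default to a Beta(2, 6) draw clipped into (0, 1], mimicking the
small-|score| skew of sequence-prediction confidences; a uniform (0, 1]
option exists.  Planted effects are applied after all base profiles are
drawn, so the miRNA marginals of planted and null regulators are
exchangeable.

What the simulation does *not* emulate: read-count or probe-intensity
marginals, batch structure, cell-type mixture, ceRNA/sponge competition,
and correlated co-regulation beyond the planted blocks.  Passing tests
therefore demonstrate the statistical machinery (calibration, recovery,
reproducibility) — not robustness to every failure mode of real tissue
data, where confounding correlation structure can inflate scores for
non-regulating miRNAs.

## Known statistical limitations

- **Realized FDP variability.**  BH controls the *expected* false
  discovery proportion.  With only ~30 miRNAs tested and ~10 strong
  discoveries, nulls face an adaptive threshold near 0.1·11/30 ≈ 0.037,
  so the *realized* FDP of a single run fluctuates: about 5–8% of
  simulation replicates at the default conditions show FDP above 0.2 even
  though the expectation stays near 0.067 and null p-values are exactly
  uniform.  Pooled over replicates the FDP is ≈ 0.1.  This is inherent to
  FDR control at small test counts, not an implementation artefact.
- **Reversal antisymmetry has a tie exception.**  Reversing the ranked
  list negates the ES whenever the walk's extreme is uniquely attained.
  A single-target set whose target sits at the exact centre of an
  odd-length list makes the walk reversal-invariant with positive and
  negative extremes tied in magnitude; there only |ES| is preserved.  The
  property tests assert the tie-aware form.
- **Gene-gene correlation.**  The permutation null conditions on the
  observed expression and randomizes target identity only.  For real
  data, where a miRNA's predicted targets can be co-expressed for reasons
  unrelated to that miRNA, this null (like gene-permutation GSEA
  generally) does not account for inter-gene correlation within target
  sets.
- The empirical p-value resolution is 1/N_p within a region; reported
  zeros mean "beyond all permutations", and the optional
  (k+1)/(N_p+1)-style correction is off by default to keep the raw
  proportions the results tables report.

## Problem sizes in the validation suite

The suite validates the machinery at simulation scales chosen to keep the
full run near half a minute: oracle equivalence on 500 random instances
(N ≤ 50), exhaustive-enumeration checks at N ≤ 8, calibration on 25 null
replicates (200 genes × 20 miRNAs), and recovery on 20 planted replicates
at the default study conditions.  All scale linearly in n_perm × N per
miRNA, and the analysis of a 10⁴-gene transcriptome with a few hundred
miRNAs at N_p = 1000 completes in minutes on one CPU.
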