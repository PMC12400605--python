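# Methods

## Model and procedure

The analysis unit is the vector of population allele frequencies at each
biallelic SNP. For SNP *j* with ancestral frequency `π_j`, population
frequencies are modelled as a Gaussian perturbation with covariance
`π_j(1−π_j)·Ω` truncated (clipped) to valid frequencies, where the P×P
matrix Ω describes drift under shared population history. Observed counts
add binomial sampling noise at the per-population allele totals. Three
statistics are computed on standardized frequencies
`z_j = (p_j − π̂_j·1)/sqrt(π̂_j(1−π̂_j))`:

* differentiation `XtX_j = z_j' Ω̂⁻¹ z_j`;
* an empirical significance threshold from pseudo-observed data (PODs)
  simulated under the fitted null;
* a closed-form conjugate Bayes factor for linear association with a
  standardized population covariate, in deciban.

The reference analysis uses an MCMC tool for the same model family; this
package substitutes deterministic estimators — a moment/shrinkage estimator
for Ω and the closed-form BF — because they are exact, fast, and the POD
calibration absorbs scale differences in XtX. Scan runs are therefore
identical across replicates; consolidated runs differ only in POD seeds.

## Estimating Ω and π

π̂ is the per-SNP GLS mean `(1'Ω̂⁻¹p)/(1'Ω̂⁻¹1)`, iterated with the moment
estimate of Ω (two passes by default, identity start). Because π̂ is
estimated per SNP, the moment matrix `S = (1/J)Σ z z'` estimates the
*centred* covariance `M(Ω + D)M'`, where M is the GLS-centring projector
and D the diagonal binomial sampling variance (≈ 1/N_p standardized). Two
consequences matter:

1. **Centring.** The component of Ω along the all-ones direction is not
   identifiable; the estimator targets `MΩM'`. All downstream statistics
   (XtX, BF, PODs) operate in the centred contrast space, where this makes
   no difference. Unit tests assert recovery of the centred closed-form
   target, not of Ω itself.
2. **Sampling-noise subtraction.** The POD simulation re-applies binomial
   sampling on top of Ω̂, so Ω̂ must describe drift alone. The estimator
   subtracts `M·diag(d̂)·M'` with `d̂_p = mean_j p̂(1−p̂)/((N_p−1)π̂(1−π̂))`
   before shrinkage. Without this, sampling noise is counted twice, the POD
   threshold is inflated, and the neutral exceedance rate falls well below
   its nominal 1%.

Negative eigenvalues after subtraction are floored at 1e-6, and
off-diagonals are shrunk by `1−δ` (δ = 0.05) toward the diagonal, which
also restores strict positive definiteness. SNPs with π̂ outside
(1e-3, 1−1e-3) are excluded from the moment but still scored.

## POD calibration

PODs resample π from the empirical π̂ distribution, draw frequencies from
the truncated Gaussian under Ω̂, apply binomial sampling at the observed
sample sizes, and are scored exactly like data. The threshold is the
type-7 empirical quantile (q = 0.99 by default, n_pod = 100,000).

Generating from a truncated model whose covariance was itself estimated
from truncated data loses a few percent of variance (the truncation is
applied twice), which biases the raw threshold slightly low relative to
the data null. `pod_threshold` therefore supports a genomic-control-style
self-calibration: the POD XtX sample is rescaled so its 0.9 quantile
matches the observed genome-wide 0.9 quantile. The anchor sits near the
decision region but below the top few percent where truly selected loci
live, so it is robust to them. With calibration the neutral exceedance at
the default study conditions is 1.0 ± 0.1% across seeds. The χ²(P−1)
limit of XtX holds only when the drift scale is small relative to
π(1−π); at Ω = 0.01·I the POD 99% quantile matches the χ²(5) 0.99
quantile within Monte-Carlo error, while at Ω = I roughly a third of the
Gaussian draws hit the frequency bounds and the threshold is far lower.
This is a property of any generative model constrained to [0, 1], not of
the implementation.

## Bayes factor

Per SNP, with `y = Ω̂^(−1/2) z` and `x = Ω̂^(−1/2) c*` (c* standardized
with divisor P):

    BF = (1 + τ²S_xx)^(−1/2) · exp( τ² S_xy² / (2(1 + τ²S_xx)) )

with `S_xx = x'x`, `S_xy = x'y`, reported as 10·log10(BF). The prior
effect scale defaults to `τ = sqrt(0.1·P/S_xx)`, i.e. prior effect
variance equal to 0.1 of the unit whitened residual variance per
population — a weakly informative choice; it is a single global
hyperparameter exposed in the API. The closed form is verified against
numerical integration of the marginal likelihood on random instances
(rtol 1e-6).

## Synthetic data: what it emulates, and what it does not

Defaults (the study conditions of the end-to-end experiments): P = 6
populations on a latitudinal gradient, J = 20,000 SNPs over 10
chromosomes, 50 fully inbred individuals per population
(`selfing_f = 1`, dosages 0/2), π ~ Uniform(0.05, 0.95), Ω = compound
symmetry with σ² = 0.1 and ρ = 0.25 (an F_ST-scale drift variance typical
of strongly structured landrace groups, with modest shared-history
covariance), 1% differentiated loci with drift variance inflated by
λ = 5, 1% associated loci with a frequency-scale shift β = 0.3 per unit of
the standardized gradient (a standardized slope of 0.6–1.4 over the π
prior; clipping at the frequency bounds shrinks the realized mean
least-squares slope to ≈ 0.8·β). Frequencies are clipped, not resampled,
at (1e-4, 1−1e-4) — matching the truncated-Gaussian reading of the model
and keeping the generator deterministic.

Haplotype panels come from a founder-mosaic copy process: 8 founder
haplotypes, switch probability `1 − exp(−d/150 kb)` between adjacent SNPs,
per-site mutation rate 0.005, founder usage weighted per population along
the gradient so block frequencies follow it.

The generator does **not** emulate: recombination maps or coalescent
genealogies (LD exists only within the copy-process panels, not among the
frequency-model SNPs), site-frequency-spectrum shape beyond the uniform π
prior, missing data or genotyping error, linked selection, or admixed
individuals. Passing tests therefore demonstrate the correctness and
calibration of the statistics under the model's own assumptions, not
robustness to everything real genebank data contains.

### Power at the default conditions

For a locus whose drift covariance is inflated by λ, XtX ≈ λ·χ²(P−1)
under perfect calibration, so the detection ceiling at the 99% POD
threshold is `P(λχ²₅ > q99(χ²₅))` = 0.70 at λ = 5 — and binomial sampling
at n = 50 per population dilutes the effective inflation further; the
measured XtX power is ≈ 0.43. The association test is much stronger at
these conditions: ≈ 0.86 of planted associated loci exceed 10 dB while
≈ 0.03% of neutral loci do.

## Downstream rules and numerical choices

* Region calling: SNPs above threshold are merged while consecutive gaps
  are strictly below 50 kb; regions are padded ±5 kb, clipped to the
  chromosome; the peak is the maximum statistic (ties → smallest
  position). Coordinates are 1-based inclusive; a true BED export
  (0-based half-open) is provided.
* Overlaps between region sets require ≥ 1 shared bp; Venn counts report
  each side's hit count collapsed to the smaller side.
* LD is the squared Pearson correlation of dosages (equals haplotype r²
  for fully inbred lines; composite-LD caveat applies to heterozygous
  panels). Background LD is reported both as the mean interchromosomal r²
  and as the Breseghello–Sorrells statistic (squared type-7 95th
  percentile of √r² over unlinked pairs); the 3× network threshold uses
  the mean by default (configurable) because the cited reference reports
  the mean. Network clusters are connected components, filtered to those
  with an interchromosomal edge or an intra-chromosomal span ≥ 5 Mb.
* LD pruning is greedy left-to-right over the currently kept SNPs
  (windows of 10 kept SNPs capped at 500 kb; of a pair above threshold
  the lower-MAF member is dropped, ties → larger position), repeated to a
  fixed point so pruning is idempotent.
* Haplotype blocks use a transparent greedy Hamming clustering (most
  frequent string as consensus, ties lexicographic; absorption within 1
  mismatch; emitted at frequency ≥ 0.05) as a documented stand-in for
  window-based block software; comparisons downstream depend only on how
  blocks are used (group proportions, gradients, representation flags),
  not on boundary identity. Cultivar haplotypes are projected onto the
  source-panel consensus strings rather than re-blocked jointly, matching
  the direction of the germplasm comparison.
* Germplasm assignment is rule-driven from an editable CSV (ancestry
  ≥ 80%, maturity-group subdivision for the two northeastern groups,
  provincial split for the southern group; the earliest-maturity region
  exists only in scenario A). Unassigned accessions carry a reason code.
* GO enrichment is a local one-sided hypergeometric test with
  Benjamini–Hochberg control (FDR 0.05), sorted by (p, term) for
  determinism; the term universe defaults to all annotated genes supplied.
* Environmental variables use month-resolution day-weighted aggregation;
  accumulated temperature counts only months with mean ≥ 15 °C, prorated
  by days inside the window — the only month-resolution reading consistent
  with the shipped region table. Regional aggregation of climate input is
  unweighted over cultivated cells; climate input is tabular (per-region
  monthly summaries), not raster.
* Environmental PCA uses divisor-R standardization and unit-norm
  eigenvectors — pinned down by the self-consistency of the shipped
  table's printed scores (Σscore²/R equals the eigenvalue per axis) — with
  sign orientation fixed by named loadings (vegetative-phase mean
  temperature positive on PC1, reproductive accumulated temperature
  negative on PC2).

## Scenarios

The two scan scenarios share all populations but one: scenario A includes
the northernmost group, scenario B drops it (emulating overlapping
germplasm panels that differ in one northeastern group). Covariates are
re-standardized per scenario.

## Problem sizes

Default experiment sizes — J = 20,000 SNPs, 100,000 PODs, 50,000
background-LD pairs, 10,000 Monte-Carlo gene-set draws — were chosen so a
full run completes in seconds on a single core while keeping Monte-Carlo
error well inside the tolerances tested.

## Known limitations

* Ω is identified only up to the centred contrast space (see above);
  published Ω matrices from MCMC tools are not directly comparable
  entry-wise.
* The BF uses a single global τ rather than integrating over a prior
  grid; BF magnitudes shift with τ, though rankings are stable.
* The LD-network background on weakly structured synthetic panels is near
  the 1/n sampling floor, making the 3×-background threshold permissive
  there; on real structured panels background LD is an order of magnitude
  higher and the threshold is meaningful.
* Real-panel headline numbers (region counts on the USDA panels,
  background r² = 0.21, enrichment folds) require the original genotype
  collections and are out of scope for the synthetic experiments.
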