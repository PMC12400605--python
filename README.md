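# adaptscape

Landscape-genomics scans for local environmental adaptation in structured
crop germplasm — built around the analysis design used for genebank
collections of selfing crops such as soybean, where accessions are grouped
into regional populations and the units of analysis are population allele
frequencies rather than individual genotypes.

## Who this is for

Population geneticists and breeders who want to locate genomic regions where
traditional varieties (landraces) from different growing regions have
diverged more than shared history explains, or where allele frequencies
track an environmental gradient — and then to ask whether the haplotypes
carrying those putatively adaptive variants are present in modern breeding
material.

## The model

Let `p_pj` be the observed alternate-allele frequency of SNP *j* in
population *p* (of *P* populations), and `π_j` its ancestral frequency.
The null model treats the standardized frequency vector

    z_j = (p_j − π̂_j·1) / sqrt(π̂_j (1 − π̂_j))

as a draw with covariance **Ω**, the *P×P* allele-frequency covariance
matrix that captures shared demographic history (drift along the expansion
routes of the crop). On top of this null the package computes:

* **XtX** — a SNP-specific, structure-corrected analogue of F_ST:
  `XtX_j = z_j' Ω̂⁻¹ z_j`. Under neutrality and Ω̂-whitening this is
  approximately χ²(P−1) (one degree lost to the GLS estimate of π̂).
* **POD threshold** — significance is calibrated empirically: 100,000
  pseudo-observed SNPs are simulated from the fitted null (truncated
  Gaussian frequencies, binomial sampling at the observed sample sizes),
  scored identically, and the 99% quantile of their XtX is the cutoff.
* **Bayes factors (deciban)** for genotype–environment association: after
  whitening with Ω̂^(−1/2), a conjugate linear model of standardized
  frequency on a standardized population covariate gives a closed-form
  marginal-likelihood ratio, reported as `10·log10(BF)`; 10 dB is "strong"
  evidence.

The environmental covariates are the first two axes of a standardized PCA
over a region × variable table (latitude plus temperature, accumulated
heat ≥ 15 °C, diurnal range, precipitation and radiation for the vegetative
and reproductive windows). Downstream stages merge significant SNPs closer
than 50 kb into adaptation-signature regions (±5 kb padding), compare
regions across tests and scan scenarios, build threshold networks of
long-range LD among signature peaks (3× background LD), detect haplotype
blocks in signature regions and compare their frequencies across germplasm
groups and cultivar panels, intersect regions with gene models (GFF3) and
run hypergeometric GO enrichment.

A first-class synthetic-data generator simulates all of this structure —
covariance-structured population frequencies with planted differentiated
(λ-inflated) and environment-associated (β-shifted) loci, inbred genotypes,
founder-mosaic haplotype panels — together with a truth ledger, so every
stage is testable end to end without external data.

## Worked example

```python
from adaptscape import env_pca, load_builtin_env_table

pca = env_pca(load_builtin_env_table())
print((100 * pca.variance_fraction[:2]).round(1))   # [74.5 23.1]
print(pca.scores["PC1"].round(2).tolist())
# [-3.88, -2.03, -1.35, -0.17, 3.19, 4.24]
```

The built-in table characterizes six Chinese soybean growing regions; the
first axis (74.5% of variance) is the north–south temperature/latitude
gradient and orders the regions from the cool northeast (−3.88) to the
subtropical south (4.24). These scores are the scan covariates.

A full synthetic run from the shell:

```bash
adaptscape simulate --out simdat --n-snps 1500 --seed 3
adaptscape scan --vcf simdat/genotypes.vcf --pops simdat/populations.csv \
                --pod 5000 --seed 3 --out scan.tsv
# POD threshold (q=0.99): 14.945
adaptscape regions --scores scan.tsv --threshold 15 --out regions.tsv
# 26 regions
```

`scan.tsv` holds per-SNP XtX values; `regions.tsv` lists the called
signature regions (1-based inclusive, 5 kb padded) with their peak SNPs.
The library equivalent (`adaptscape.run_pipeline`) also runs both scan
scenarios, the LD-network and haplotype-block stages, and writes a summary
JSON including precision/recall against the generator's truth ledger.

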