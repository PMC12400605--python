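"""Analysis constants shared across the pipeline.

Every value here is a named, documented default of the published analysis
protocol this package implements; the pipeline configuration is required
(and tested) to agree with this registry.
"""

#: Minor-allele-frequency floor for the genome scan input.
MAF_SCAN = 0.01

#: Minor-allele-frequency floor for LD calculations.
MAF_LD = 0.05

#: Number of pseudo-observed (neutral) SNPs used to calibrate XtX.
POD_SIZE = 100_000

#: Empirical quantile of the POD XtX sample used as significance threshold.
POD_QUANTILE = 0.99

#: Bayes-factor threshold (deciban) for "strong evidence" of association.
BF_STRONG_DB = 10.0

#: Maximum gap (bp) between significant SNPs merged into one signature.
MERGE_DIST = 50_000

#: Padding (bp) added to each side of a called signature region.
PAD = 5_000

#: Edge threshold of the LD network, as a multiple of background LD.
LD_MULTIPLE = 3.0

#: Minimum intra-chromosomal span (bp) for a reported LD cluster.
MIN_CLUSTER_SPAN = 5_000_000

#: Permutations for the LD permutation t-test.
N_PERM = 1_000

#: Random SNPs per sample when estimating the neutral LD reference.
N_RANDOM_LD_SNPS = 1_000

#: Benjamini-Hochberg false discovery rate for GO enrichment.
FDR = 0.05

#: Number of independent scan runs consolidated per scenario.
N_RUNS = 5

#: Ancestry-coefficient threshold for assigning an accession to a group.
ANCESTRY_MIN = 0.80

#: Frequencies are kept strictly inside (EPS_FREQ, 1 - EPS_FREQ).
EPS_FREQ = 1e-4
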