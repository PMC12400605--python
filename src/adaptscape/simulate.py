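"""Synthetic data with the statistical structure the genome scan assumes.

The generator draws per-SNP population allele frequencies from a truncated
multivariate-Gaussian drift model: for SNP j with ancestral frequency
``pi_j`` the population frequency vector is

    alpha_j = clip( pi_j * 1 + L_j u_j , eps, 1 - eps ),   u_j ~ N(0, I_P)

where ``L_j`` is the Cholesky factor of ``pi_j (1 - pi_j) * lambda_j * Omega``
and ``Omega`` is the P x P drift covariance shared by all loci.  A configured
fraction of loci is *differentiated* (``lambda_j`` > 1, excess variance) and a
fraction is *associated* (a linear shift ``beta * c*`` on the frequency scale,
where ``c*`` is the standardized population covariate).  A truth ledger
records the class, beta and lambda of every simulated SNP.

Genotypes are drawn per individual from the population frequencies, with an
inbreeding coefficient controlling within-individual allele correlation
(default 1: fully inbred lines with dosages 0/2, the situation of a selfing
crop panel).  A separate founder-mosaic copy process generates haplotype
panels with local LD/haplotype-block structure and population-weighted founder
frequencies along a gradient, so the LD and haplotype-block modules have
detectable structure to recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import EPS_FREQ
from .io import GenotypeMatrix, write_vcf


def compound_symmetry(n_pops: int, sigma2: float = 0.1, rho: float = 0.25) -> np.ndarray:
    """Drift covariance sigma2 * ((1 - rho) I + rho J).

    ``sigma2`` is the per-population drift variance on the standardized
    frequency scale (the magnitude of an F_ST-like quantity) and ``rho`` the
    shared-history correlation between populations.
    """
    return sigma2 * ((1.0 - rho) * np.eye(n_pops) + rho * np.ones((n_pops, n_pops)))


def standardized_gradient(n_pops: int) -> np.ndarray:
    """Linear covariate over populations, zero mean / unit variance (divisor P)."""
    c = np.linspace(-1.0, 1.0, n_pops)
    return (c - c.mean()) / c.std()


@dataclass
class SimConfig:
    """Configuration of the synthetic dataset.

    Defaults give the study conditions of the end-to-end experiments: six
    populations along a latitudinal gradient, 20,000 SNPs, 50 inbred
    individuals per population, 1% differentiated loci (lambda = 5) and 1%
    covariate-associated loci (beta = 0.3 on the frequency scale, i.e. a
    standardized slope of at least 0.6 over the ancestral-frequency prior).
    """

    n_pops: int = 6
    n_snps: int = 20_000
    n_ind_per_pop: int = 50
    omega_spec: np.ndarray | None = None  # default: compound_symmetry(P, 0.1, 0.25)
    pi_prior: tuple[float, float] = (0.05, 0.95)
    frac_differentiated: float = 0.01
    frac_associated: float = 0.01
    lambda_diff: float = 5.0
    beta_assoc: float = 0.3
    covariate_values: np.ndarray | None = None  # default: standardized_gradient(P)
    selfing_f: float = 1.0
    chrom_layout: list[tuple[str, int, int]] | None = None
    block_len_mean: float = 150_000.0
    n_founders: int = 8
    mutation_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_snps, self.n_ind_per_pop) <= 0:
            raise ValueError("all counts must be positive")
        for name in ("frac_differentiated", "frac_associated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_differentiated + self.frac_associated > 1.0:
            raise ValueError("locus-class fractions sum to more than 1")
        if not 0.0 <= self.selfing_f <= 1.0:
            raise ValueError("selfing_f must be in [0, 1]")
        if self.block_len_mean <= 0:
            raise ValueError("block_len_mean must be positive")

    @property
    def omega(self) -> np.ndarray:
        om = (
            compound_symmetry(self.n_pops)
            if self.omega_spec is None
            else np.asarray(self.omega_spec, dtype=float)
        )
        if om.shape != (self.n_pops, self.n_pops):
            raise ValueError(f"omega_spec must be {self.n_pops} x {self.n_pops}")
        if not np.allclose(om, om.T):
            raise ValueError("omega_spec is not symmetric")
        ev = np.linalg.eigvalsh(om)
        if ev.min() <= 0:
            raise ValueError(f"omega_spec is not positive definite (eigenvalue {ev.min():g})")
        return om

    @property
    def covariate(self) -> np.ndarray:
        c = (
            standardized_gradient(self.n_pops)
            if self.covariate_values is None
            else np.asarray(self.covariate_values, dtype=float)
        )
        if c.shape != (self.n_pops,):
            raise ValueError(f"covariate_values must have length {self.n_pops}")
        if np.isclose(c.std(), 0.0):
            raise ValueError("covariate_values are constant")
        return (c - c.mean()) / c.std()

    @property
    def layout(self) -> list[tuple[str, int, int]]:
        """Chromosome layout; default spreads SNPs over up to 10 chromosomes."""
        if self.chrom_layout is not None:
            return self.chrom_layout
        n_chrom = min(10, max(2, self.n_snps // 500))
        base, extra = divmod(self.n_snps, n_chrom)
        out = []
        for i in range(n_chrom):
            n = base + (1 if i < extra else 0)
            out.append((f"chr{i + 1:02d}", n, max(n, 1) * 5_000))
        return out


@dataclass
class PopulationFrequencies:
    """Per-population alternate-allele frequencies with SNP metadata."""

    freqs: np.ndarray  # (n_pops, n_snps), strictly inside (eps, 1 - eps)
    snps: pd.DataFrame  # chrom, pos (1-based), ref, alt

    @property
    def n_pops(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]


def _snp_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms, pos = [], []
    for name, n, length in config.layout:
        p = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        chroms.extend([name] * n)
        pos.append(p)
    bases = np.array(list("ACGT"))
    n_tot = len(chroms)
    ref = rng.choice(bases, n_tot)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    return pd.DataFrame(
        {"chrom": chroms, "pos": np.concatenate(pos), "ref": ref, "alt": alt}
    )


def simulate_frequencies(config: SimConfig) -> tuple[PopulationFrequencies, pd.DataFrame]:
    """Draw population allele frequencies and the matching truth ledger.

    Returns ``(PopulationFrequencies, truth)`` where ``truth`` has one row
    per SNP with columns chrom, pos, class ('neutral', 'differentiated' or
    'associated'), beta and lambda.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    P, J = config.n_pops, config.n_snps
    omega = config.omega
    L = np.linalg.cholesky(omega)

    snps = _snp_positions(config, rng)
    pi = rng.uniform(*config.pi_prior, size=J)

    n_diff = int(round(config.frac_differentiated * J))
    n_assoc = int(round(config.frac_associated * J))
    c = config.covariate if n_assoc else np.zeros(P)
    classes = np.array(["neutral"] * J, dtype=object)
    special = rng.choice(J, size=n_diff + n_assoc, replace=False)
    classes[special[:n_diff]] = "differentiated"
    classes[special[n_diff:]] = "associated"
    lam = np.where(classes == "differentiated", config.lambda_diff, 1.0)
    beta = np.where(classes == "associated", config.beta_assoc, 0.0)

    u = rng.standard_normal((J, P))
    alpha = pi[:, None] + np.sqrt(pi * (1.0 - pi) * lam)[:, None] * (u @ L.T)
    if n_assoc:
        alpha += beta[:, None] * c
    alpha = np.clip(alpha, EPS_FREQ, 1.0 - EPS_FREQ)

    truth = snps[["chrom", "pos"]].copy()
    truth["class"] = classes
    truth["beta"] = beta
    truth["lambda"] = lam
    return PopulationFrequencies(freqs=alpha.T, snps=snps), truth


def simulate_genotypes(freqs: PopulationFrequencies, config: SimConfig) -> GenotypeMatrix:
    """Draw individual dosages from population frequencies.

    With ``selfing_f = 1`` each individual is fully inbred: dosage is
    2 * Bernoulli(alpha).  With ``selfing_f = f`` the two alleles of an
    individual are drawn with correlation f.
    """
    rng = np.random.default_rng(config.seed + 1)
    P, J, n = freqs.n_pops, freqs.n_snps, config.n_ind_per_pop
    f = config.selfing_f
    dosages = np.empty((J, P * n), dtype=np.int16)
    samples = []
    for p in range(P):
        a = freqs.freqs[p][:, None]  # (J, 1)
        first = rng.random((J, n)) < a
        if f >= 1.0:
            second = first
        else:
            copy = rng.random((J, n)) < f
            indep = rng.random((J, n)) < a
            second = np.where(copy, first, indep)
        dosages[:, p * n : (p + 1) * n] = first.astype(np.int16) + second.astype(np.int16)
        samples.extend(f"pop{p + 1}_i{i + 1}" for i in range(n))
    lengths = {name: length for name, _, length in config.layout}
    return GenotypeMatrix(
        dosages=dosages,
        chrom=freqs.snps["chrom"].to_numpy(),
        pos=freqs.snps["pos"].to_numpy(),
        ref=freqs.snps["ref"].to_numpy(),
        alt=freqs.snps["alt"].to_numpy(),
        samples=samples,
        chrom_lengths=lengths,
    )


def population_of_samples(gt: GenotypeMatrix) -> pd.DataFrame:
    """Accession -> population table for generator-made sample names."""
    pops = [s.split("_")[0] for s in gt.samples]
    return pd.DataFrame({"accession": gt.samples, "population": pops})


@dataclass
class HaplotypePanel:
    """Inbred haplotypes over one genomic region (founder-mosaic process)."""

    haplotypes: np.ndarray  # (n_haps, n_snps) 0/1 alleles
    chrom: str
    pos: np.ndarray
    populations: np.ndarray  # population label per haplotype
    founder_path: np.ndarray  # (n_haps, n_snps) founder index of each allele
    founders: np.ndarray  # (n_founders, n_snps)


def founder_gradient_weights(n_pops: int, n_founders: int, width: float = 0.2) -> np.ndarray:
    """Founder-usage weights placing founders along the population gradient.

    Founder f sits at position f/(F-1) in [0, 1]; population p at p/(P-1).
    Weights decay as a Gaussian kernel in that coordinate, so low-index
    founders dominate low-index (northern) populations and vice versa.
    """
    fx = np.linspace(0.0, 1.0, n_founders)
    px = np.linspace(0.0, 1.0, n_pops)
    w = np.exp(-((px[:, None] - fx[None, :]) ** 2) / (2.0 * width**2))
    return w / w.sum(axis=1, keepdims=True)


def simulate_haplotype_panel(
    config: SimConfig,
    n_snps: int = 200,
    founder_weights: np.ndarray | None = None,
    span_bp: int | None = None,
    snp_spacing: int = 5_000,
) -> HaplotypePanel:
    """Simulate an inbred haplotype panel for one region.

    Each sample haplotype is a mosaic of ``n_founders`` founder haplotypes:
    a Markov copy process switches founders between adjacent SNPs with
    probability ``1 - exp(-d / block_len_mean)`` for map distance d, then
    per-site mutations flip alleles at rate ``mutation_rate``.  Founder
    choice is population-weighted (see :func:`founder_gradient_weights`),
    which makes block frequencies follow the configured gradient.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founder haplotypes")
    rng = np.random.default_rng(config.seed + 2)
    P, F, n = config.n_pops, config.n_founders, config.n_ind_per_pop
    name = config.layout[0][0]
    span = span_bp if span_bp is not None else n_snps * snp_spacing
    pos = np.sort(rng.choice(np.arange(1, span + 1), n_snps, False))
    founders = (rng.random((F, n_snps)) < 0.5).astype(np.int8)
    if founder_weights is None:
        founder_weights = founder_gradient_weights(P, F)
    founder_weights = np.asarray(founder_weights, dtype=float)
    if founder_weights.shape != (P, F):
        raise ValueError(f"founder_weights must be {P} x {F}")

    d = np.diff(pos).astype(float)
    p_switch = 1.0 - np.exp(-d / config.block_len_mean)
    haps = np.empty((P * n, n_snps), dtype=np.int8)
    path = np.empty((P * n, n_snps), dtype=np.int16)
    pops = np.empty(P * n, dtype=object)
    for p in range(P):
        w = founder_weights[p]
        for i in range(n):
            k = p * n + i
            cur = rng.choice(F, p=w)
            switch = rng.random(n_snps - 1) < p_switch
            fpath = np.empty(n_snps, dtype=np.int16)
            fpath[0] = cur
            for s in range(1, n_snps):
                if switch[s - 1]:
                    cur = rng.choice(F, p=w)
                fpath[s] = cur
            path[k] = fpath
            haps[k] = founders[fpath, np.arange(n_snps)]
            pops[k] = f"pop{p + 1}"
    if config.mutation_rate > 0:
        flips = rng.random(haps.shape) < config.mutation_rate
        haps = np.where(flips, 1 - haps, haps).astype(np.int8)
    return HaplotypePanel(
        haplotypes=haps,
        chrom=name,
        pos=pos,
        populations=np.asarray(pops),
        founder_path=path,
        founders=founders,
    )


def panel_to_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """View an inbred haplotype panel as 0/2 dosages (one sample per haplotype)."""
    n = panel.haplotypes.shape[0]
    samples = [f"{panel.populations[k]}_i{k + 1}" for k in range(n)]
    return GenotypeMatrix(
        dosages=(2 * panel.haplotypes.T).astype(np.int16),
        chrom=np.array([panel.chrom] * len(panel.pos), dtype=object),
        pos=panel.pos,
        ref=np.array(["A"] * len(panel.pos), dtype=object),
        alt=np.array(["T"] * len(panel.pos), dtype=object),
        samples=samples,
        chrom_lengths={panel.chrom: int(panel.pos[-1]) + 1},
    )


def write_dataset(
    out_dir: str | Path,
    gt: GenotypeMatrix,
    truth: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a simulated dataset: VCF, population table, truth and covariates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": write_vcf(gt, out / "genotypes.vcf")}
    pops = population_of_samples(gt)
    pops.to_csv(out / "populations.csv", index=False)
    paths["populations"] = out / "populations.csv"
    if truth is not None:
        truth.to_csv(out / "truth.csv", index=False)
        paths["truth"] = out / "truth.csv"
    if covariates is not None:
        covariates.to_csv(out / "covariates.csv", index=False)
        paths["covariates"] = out / "covariates.csv"
    return paths
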