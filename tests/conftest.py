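import numpy as np
import pandas as pd
import pytest

from adaptscape.io import GenotypeMatrix
from adaptscape.scan import PopulationAlleleCounts
from adaptscape.simulate import (
    SimConfig,
    population_of_samples,
    simulate_frequencies,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_pops=4, n_snps=2_000, n_ind_per_pop=30, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    freqs, truth = simulate_frequencies(small_config)
    gt = simulate_genotypes(freqs, small_config)
    return freqs, truth, gt


@pytest.fixture(scope="session")
def small_gt(small_dataset) -> GenotypeMatrix:
    return small_dataset[2]


@pytest.fixture(scope="session")
def small_pops(small_gt) -> pd.DataFrame:
    return population_of_samples(small_gt)


def counts_from_frequencies(freqs: np.ndarray, totals: int = 200_000) -> PopulationAlleleCounts:
    """Allele counts that observe the given (P, J) frequencies near-exactly."""
    P, J = freqs.shape
    return PopulationAlleleCounts(
        counts=np.round(freqs * totals).astype(np.int64),
        totals=np.full((P, J), totals, dtype=np.int64),
        snps=pd.DataFrame(
            {
                "chrom": ["chr01"] * J,
                "pos": np.arange(1, J + 1),
                "ref": ["A"] * J,
                "alt": ["T"] * J,
            }
        ),
        populations=[f"pop{i + 1}" for i in range(P)],
    )


def toy_genotypes(dosage_rows, pos=None, chrom=None, samples=None) -> GenotypeMatrix:
    """GenotypeMatrix from a list of per-SNP dosage rows."""
    d = np.asarray(dosage_rows, dtype=np.int16)
    n_snps, n_samples = d.shape
    if pos is None:
        pos = np.arange(1, n_snps + 1) * 1_000
    if chrom is None:
        chrom = ["chr01"] * n_snps
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        dosages=d,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.array(["A"] * n_snps, dtype=object),
        alt=np.array(["T"] * n_snps, dtype=object),
        samples=list(samples),
        chrom_lengths={c: 10_000_000 for c in set(chrom)},
    )
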