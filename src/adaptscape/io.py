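"""Genotype container and format readers/writers (VCF v4.2, CSV/TSV tables)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of samples.

    ``dosages`` is an (n_snps, n_samples) integer array of alternate-allele
    dosages in {0, 1, 2}, with ``MISSING`` (-1) marking missing calls.
    Positions are 1-based and strictly increasing within a chromosome.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.pos)} SNPs x {len(self.samples)} samples"
            )

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return np.array([f"{c}:{p}" for c, p in zip(self.chrom, self.pos)])

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )

    def maf(self) -> np.ndarray:
        """Pooled minor-allele frequency per SNP over non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        p = d.mean(axis=1).filled(np.nan) / 2.0
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(n) for n in names]
        return replace(self, dosages=self.dosages[:, idx], samples=list(names))


def load_vcf_dosages(path: str | Path, maf_floor: float = 0.0) -> GenotypeMatrix:
    """Read biallelic SNP dosages from a VCF with GT calls.

    Multi-allelic records are skipped (count logged).  SNPs with pooled
    MAF below ``maf_floor`` are dropped after loading.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g = v.gt_types.astype(np.int16)
        g[g == 3] = MISSING
        rows.append(g)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
    lengths = {}
    for name in vcf.seqnames:
        try:
            lengths[name] = vcf.seqlens[vcf.seqnames.index(name)]
        except (AttributeError, IndexError):  # pragma: no cover - header w/o lengths
            pass
    vcf.close()
    if n_multi:
        log.info("skipped %d multi-allelic records in %s", n_multi, path)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    gt = GenotypeMatrix(
        dosages=np.vstack(rows),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        samples=samples,
        chrom_lengths=lengths,
    )
    if maf_floor > 0:
        keep = gt.maf() >= maf_floor
        log.info("MAF >= %g filter: %d -> %d SNPs", maf_floor, gt.n_snps, keep.sum())
        gt = gt.take_snps(np.flatnonzero(keep))
    return gt


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gt: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF v4.2 with GT genotypes."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=adaptscape\n")
            for name, length in gt.chrom_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(gt.samples)
                + "\n"
            )
            for j in range(gt.n_snps):
                calls = "\t".join(_GT_CODE[int(d)] for d in gt.dosages[j])
                fh.write(
                    f"{gt.chrom[j]}\t{gt.pos[j]}\t{gt.chrom[j]}:{gt.pos[j]}\t"
                    f"{gt.ref[j]}\t{gt.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    return path


def read_population_table(path: str | Path) -> pd.DataFrame:
    """Read an accession table with at least ``accession`` and ``population``."""
    df = pd.read_csv(path)
    missing = {"accession", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"population table {path} lacks columns {sorted(missing)}")
    return df
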