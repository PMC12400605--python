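"""Linkage disequilibrium: pairwise r2, background LD, networks, decay, pruning.

r2 is the squared Pearson correlation of dosage vectors; for fully inbred
lines this equals haplotype r2 (documented limitation for heterozygous
panels).  Background LD is estimated from random interchromosomal SNP pairs
and reported both as the mean r2 and as the Breseghello-Sorrells statistic
(the squared 95th percentile of sqrt(r2) over unlinked pairs).  The LD
network links signature-peak SNPs whose r2 exceeds a multiple (default 3) of
background; reported clusters are connected components with either an
interchromosomal edge or an intra-chromosomal edge spanning at least 5 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .constants import LD_MULTIPLE, MAF_LD, MIN_CLUSTER_SPAN, N_PERM
from .io import MISSING, GenotypeMatrix


@dataclass
class LDMatrix:
    r2: np.ndarray  # symmetric, diagonal 1
    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray


@dataclass
class BackgroundLD:
    mean_r2: float
    bs_p95: float  # Breseghello-Sorrells: (95th pct of sqrt(r2))^2
    n_pairs: int
    method: str = "interchromosomal"


def _standardized_rows(gt: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Rows standardized to zero mean / unit variance over non-missing calls.

    Missing calls are mean-imputed (zero after centring), which makes the
    per-pair product average a pairwise-complete correlation estimate when
    missingness is sparse.
    """
    d = gt.dosages[idx].astype(float)
    mask = d == MISSING
    d[mask] = np.nan
    mean = np.nanmean(d, axis=1, keepdims=True)
    sd = np.nanstd(d, axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = idx[np.flatnonzero(sd[:, 0] == 0)][0]
        raise ValueError(f"monomorphic SNP in set: {gt.chrom[bad]}:{gt.pos[bad]}")
    z = (d - mean) / sd
    z[np.isnan(z)] = 0.0
    return z


def pairwise_r2(
    gt: GenotypeMatrix, snp_index: np.ndarray, maf_floor: float = MAF_LD
) -> LDMatrix:
    """Squared Pearson correlation of dosages for a named SNP set."""
    idx = np.asarray(snp_index)
    maf = gt.maf()[idx]
    low = idx[maf < maf_floor]
    if len(low):
        raise ValueError(f"{len(low)} SNPs below the MAF {maf_floor} floor for LD")
    z = _standardized_rows(gt, idx)
    r = z @ z.T / z.shape[1]
    np.fill_diagonal(r, 1.0)
    return LDMatrix(
        r2=np.clip(r * r, 0.0, 1.0),
        chrom=gt.chrom[idx],
        pos=gt.pos[idx],
        ids=gt.snp_ids[idx],
    )


def summarize_unlinked_r2(r2_values: np.ndarray) -> tuple[float, float]:
    """Mean and Breseghello-Sorrells statistic of an unlinked-pair r2 sample.

    The BS statistic is the square of the (type-7 interpolated) 95th
    percentile of sqrt(r2).
    """
    r2 = np.asarray(r2_values, dtype=float)
    p95 = float(np.quantile(np.sqrt(r2), 0.95))
    return float(r2.mean()), p95 * p95


def background_ld(
    gt: GenotypeMatrix,
    n_pairs: int = 100_000,
    maf_floor: float = MAF_LD,
    seed: int = 0,
) -> BackgroundLD:
    """Background LD from random interchromosomal SNP pairs (MAF-filtered)."""
    if len(np.unique(gt.chrom)) < 2:
        raise ValueError("background LD needs at least two chromosomes")
    rng = np.random.default_rng(seed)
    eligible = np.flatnonzero(gt.maf() >= maf_floor)
    chroms = gt.chrom[eligible]
    a = rng.choice(len(eligible), size=2 * n_pairs)
    b = rng.choice(len(eligible), size=2 * n_pairs)
    keep = chroms[a] != chroms[b]
    a, b = a[keep][:n_pairs], b[keep][:n_pairs]
    if len(a) < n_pairs:  # pragma: no cover - tiny panels
        raise ValueError("could not sample enough interchromosomal pairs")
    uniq, inv = np.unique(np.r_[eligible[a], eligible[b]], return_inverse=True)
    z = _standardized_rows(gt, uniq)
    ia, ib = inv[: len(a)], inv[len(a) :]
    r = np.einsum("ij,ij->i", z[ia], z[ib]) / z.shape[1]
    r2 = np.clip(r * r, 0.0, 1.0)
    mean_r2, bs_p95 = summarize_unlinked_r2(r2)
    return BackgroundLD(mean_r2=mean_r2, bs_p95=bs_p95, n_pairs=len(r2))


def random_snp_r2_samples(
    gt: GenotypeMatrix,
    n_samples: int = 10,
    snps_per_sample: int = 1_000,
    maf_floor: float = MAF_LD,
    seed: int = 0,
    max_pairs: int = 20_000,
) -> list[np.ndarray]:
    """Neutral-reference r2 samples from random SNP draws.

    Emulates drawing repeated random SNP sets and recording their pairwise
    r2; pairs per sample are subsampled to ``max_pairs`` for tractability.
    """
    rng = np.random.default_rng(seed)
    eligible = np.flatnonzero(gt.maf() >= maf_floor)
    out = []
    for _ in range(n_samples):
        take = rng.choice(eligible, size=min(snps_per_sample, len(eligible)), replace=False)
        z = _standardized_rows(gt, take)
        m = len(take)
        ia = rng.integers(0, m, size=max_pairs)
        ib = rng.integers(0, m, size=max_pairs)
        ok = ia != ib
        r = np.einsum("ij,ij->i", z[ia[ok]], z[ib[ok]]) / z.shape[1]
        out.append(np.clip(r * r, 0.0, 1.0))
    return out


def permutation_ld_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = N_PERM,
    transform=np.cbrt,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided permutation t-test of mean transformed r2 (a vs b).

    Returns ``(t_obs, p)`` with p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1).
    The cube-root transform symmetrizes the skewed r2 distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = transform(np.asarray(a, dtype=float))
    b = transform(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    na = len(a)

    def tstat(x: np.ndarray, y: np.ndarray) -> float:
        va, vb = x.var(ddof=1) if len(x) > 1 else 0.0, y.var(ddof=1) if len(y) > 1 else 0.0
        se = np.sqrt(va / len(x) + vb / len(y))
        diff = x.mean() - y.mean()
        return 0.0 if se == 0 else diff / se

    t_obs = tstat(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(tstat(perm[:na], perm[na:])) >= abs(t_obs):
            count += 1
    return float(t_obs), (1 + count) / (n_perm + 1)


@dataclass
class LDNetwork:
    graph: nx.Graph
    threshold: float
    components: list[list[str]]
    clusters: list[dict]  # reported clusters (interchromosomal / long-span)


def build_ld_network(
    peaks: LDMatrix,
    background: BackgroundLD | float,
    multiple: float = LD_MULTIPLE,
    min_dist: int = MIN_CLUSTER_SPAN,
    background_stat: str = "mean",
) -> LDNetwork:
    """Threshold network over signature-peak SNPs.

    Edges connect peaks with r2 strictly above ``multiple`` times the
    background level (``background_stat``: 'mean' or 'bs_p95').  Reported
    clusters are connected components of >= 2 nodes containing an
    interchromosomal edge or an intra-chromosomal edge spanning
    >= ``min_dist`` bp.
    """
    if multiple <= 0:
        raise ValueError("multiple must be positive")
    if isinstance(background, BackgroundLD):
        base = background.mean_r2 if background_stat == "mean" else background.bs_p95
    else:
        base = float(background)
    threshold = multiple * base
    g = nx.Graph()
    n = len(peaks.ids)
    for i in range(n):
        g.add_node(peaks.ids[i], chrom=peaks.chrom[i], pos=int(peaks.pos[i]))
    for i in range(n):
        for j in range(i + 1, n):
            if peaks.r2[i, j] > threshold:
                g.add_edge(peaks.ids[i], peaks.ids[j], r2=float(peaks.r2[i, j]))
    components = [sorted(c) for c in nx.connected_components(g)]
    clusters = []
    for comp in components:
        if len(comp) < 2:
            continue
        inter = False
        max_span = 0
        for u, v in g.subgraph(comp).edges:
            if g.nodes[u]["chrom"] != g.nodes[v]["chrom"]:
                inter = True
            else:
                max_span = max(max_span, abs(g.nodes[u]["pos"] - g.nodes[v]["pos"]))
        if inter or max_span >= min_dist:
            clusters.append(
                {
                    "nodes": comp,
                    "interchromosomal": inter,
                    "max_intra_span": max_span,
                }
            )
    return LDNetwork(graph=g, threshold=threshold, components=components, clusters=clusters)


def ld_decay(
    gt: GenotypeMatrix,
    chrom: str,
    max_dist: int = 1_000_000,
    n_bins: int = 20,
    maf_floor: float = MAF_LD,
    max_pairs: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r2 per physical-distance bin for intra-chromosomal pairs."""
    idx = np.flatnonzero((gt.chrom == chrom) & (gt.maf() >= maf_floor))
    if len(idx) < 2:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"])
    pos = gt.pos[idx]
    rng = np.random.default_rng(seed)
    m = len(idx)
    if m * (m - 1) // 2 <= max_pairs:
        ia, ib = np.triu_indices(m, k=1)
    else:
        ia = rng.integers(0, m, size=2 * max_pairs)
        ib = rng.integers(0, m, size=2 * max_pairs)
        ok = ia < ib
        ia, ib = ia[ok][:max_pairs], ib[ok][:max_pairs]
    d = np.abs(pos[ia] - pos[ib])
    keep = (d > 0) & (d <= max_dist)
    ia, ib, d = ia[keep], ib[keep], d[keep]
    if len(d) == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"])
    z = _standardized_rows(gt, idx)
    r = np.einsum("ij,ij->i", z[ia], z[ib]) / z.shape[1]
    r2 = np.clip(r * r, 0.0, 1.0)
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            rows.append(
                {
                    "bin_lo": int(edges[b]),
                    "bin_hi": int(edges[b + 1]),
                    "mean_r2": float(r2[sel].mean()),
                    "n_pairs": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def ld_prune(
    gt: GenotypeMatrix,
    threshold: float,
    window_bp: int = 500_000,
    window_snps: int = 10,
    maf_floor: float = MAF_LD,
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns surviving SNP indices.

    Left to right over the *currently kept* SNPs of each chromosome: for
    the anchor SNP, up to ``window_snps - 1`` following kept SNPs within
    ``window_bp`` are examined; of any pair with r2 > threshold the member
    with the lower MAF is dropped (tie: the larger position).  Windows are
    formed over the kept set and passes repeat until no SNP is dropped, so
    pruning an already-pruned panel is a no-op.
    """
    maf = gt.maf()
    pos = gt.pos
    kept = maf >= maf_floor
    for chrom in pd.unique(gt.chrom):
        cidx = [int(i) for i in np.flatnonzero((gt.chrom == chrom) & kept)]
        if len(cidx) < 2:
            continue
        z = {}

        def zrow(i: int) -> np.ndarray:
            if i not in z:
                z[i] = _standardized_rows(gt, np.array([i]))[0]
            return z[i]

        alive = set(cidx)
        changed = True
        while changed:
            changed = False
            order = [i for i in cidx if i in alive]
            for a_pos, a in enumerate(order):
                if a not in alive:
                    continue
                companions = []
                for b in order[a_pos + 1 :]:
                    if b not in alive:
                        continue
                    if pos[b] - pos[a] > window_bp or len(companions) >= window_snps - 1:
                        break
                    companions.append(b)
                for b in companions:
                    if a not in alive:
                        break
                    if b not in alive:
                        continue
                    r = float(zrow(a) @ zrow(b)) / gt.n_samples
                    if r * r > threshold:
                        if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                            alive.discard(a)
                        else:
                            alive.discard(b)
                        changed = True
        kept[cidx] = [i in alive for i in cidx]
    return np.flatnonzero(kept)
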