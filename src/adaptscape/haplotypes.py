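"""Haplotype blocks within signature regions and group-frequency comparisons.

Blocks are found by a transparent greedy Hamming clustering of the inbred
haplotype strings over a region's SNPs: the most frequent remaining string
becomes a consensus (ties: lexicographically smallest), strings within a
mismatch budget are absorbed, and the cluster is emitted as a block if its
frequency reaches the minimum; everything left is pooled as "other".  This
deliberately simple algorithm stands in for window-based block software:
downstream comparisons operate on how blocks are *used* (per-group
proportions, latitudinal gradients, representation in cultivar panels), not
on algorithmic identity of the block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OTHER = "other"


@dataclass
class HaplotypeBlock:
    region_id: str
    block_id: str
    consensus: str  # allele string over the region's SNPs
    n_members: int
    member_index: np.ndarray  # haplotype row indices


def _hap_strings(haps: np.ndarray) -> np.ndarray:
    return np.array(["".join(map(str, row)) for row in haps])


def blocks_in_region(
    haplotypes: np.ndarray,
    region_id: str = "region",
    min_freq: float = 0.05,
    max_mismatch: int = 1,
) -> list[HaplotypeBlock]:
    """Greedy Hamming clustering of haplotype strings into blocks.

    ``haplotypes`` is an (n_haps, n_snps) 0/1 array (one haplotype per
    inbred accession, no missing calls).  Deterministic: candidate
    consensus order is by count, then lexicographic string.
    """
    haps = np.asarray(haplotypes)
    if haps.ndim != 2 or haps.shape[1] == 0:
        raise ValueError("region has no SNPs")
    n = haps.shape[0]
    strings = _hap_strings(haps)
    remaining = np.ones(n, dtype=bool)
    blocks: list[HaplotypeBlock] = []
    k = 0
    while remaining.any():
        uniq, counts = np.unique(strings[remaining], return_counts=True)
        order = np.lexsort((uniq, -counts))  # by count desc, then lexicographic
        consensus = uniq[order[0]]
        cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8) - ord("0")
        mism = (haps[remaining] != cons_arr).sum(axis=1)
        member_local = np.flatnonzero(remaining)[mism <= max_mismatch]
        freq = len(member_local) / n
        if freq < min_freq:
            break  # later candidates are rarer still; pool the rest as "other"
        k += 1
        blocks.append(
            HaplotypeBlock(
                region_id=region_id,
                block_id=f"{region_id}.B{k}",
                consensus=consensus,
                n_members=len(member_local),
                member_index=member_local,
            )
        )
        remaining[member_local] = False
    return blocks


def block_frequencies(
    blocks: list[HaplotypeBlock],
    groups: np.ndarray,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group block frequencies (rows: blocks plus "other"; columns: groups).

    ``groups`` assigns a group label to every haplotype row used for block
    calling.  Column sums equal 1; the "other" row absorbs haplotypes not in
    any block.  Empty groups yield a zero column.
    """
    groups = np.asarray(groups)
    if group_order is None:
        group_order = list(pd.unique(groups))
    n_in_group = {g: int((groups == g).sum()) for g in group_order}
    rows = {}
    assigned = np.zeros(len(groups), dtype=bool)
    for b in blocks:
        assigned[b.member_index] = True
        rows[b.block_id] = {
            g: ((groups[b.member_index] == g).sum() / n_in_group[g]) if n_in_group[g] else 0.0
            for g in group_order
        }
    rows[OTHER] = {
        g: ((groups[~assigned] == g).sum() / n_in_group[g]) if n_in_group[g] else 0.0
        for g in group_order
    }
    table = pd.DataFrame.from_dict(rows, orient="index")[group_order]
    table.index.name = "block"
    return table


def gradient_correlation(
    table: pd.DataFrame, group_latitudes: dict[str, float] | pd.Series
) -> pd.Series:
    """Pearson correlation of each block's frequencies with group latitude.

    Constant-frequency blocks get NaN (undefined correlation).
    """
    lats = pd.Series(group_latitudes)
    common = [g for g in table.columns if g in lats.index]
    if len(common) < 3:
        raise ValueError("need latitudes for at least 3 groups")
    lat = lats[common].to_numpy(dtype=float)
    out = {}
    for block, row in table[common].iterrows():
        f = row.to_numpy(dtype=float)
        if np.isclose(f.std(), 0.0):
            out[block] = np.nan
        else:
            out[block] = float(np.corrcoef(f, lat)[0, 1])
    return pd.Series(out, name="gradient_r")


def assign_to_blocks(
    blocks: list[HaplotypeBlock], haplotypes: np.ndarray, max_mismatch: int = 1
) -> np.ndarray:
    """Project external haplotypes onto existing block consensus strings.

    Each haplotype goes to the nearest consensus within ``max_mismatch``
    (ties: lowest block id), otherwise to "other".
    """
    if not blocks:
        raise ValueError("no blocks to assign to")
    haps = np.asarray(haplotypes)
    cons = np.vstack(
        [np.frombuffer(b.consensus.encode(), dtype=np.uint8) - ord("0") for b in blocks]
    )
    if haps.shape[1] != cons.shape[1]:
        raise ValueError("haplotype length does not match block consensus length")
    dists = (haps[:, None, :] != cons[None, :, :]).sum(axis=2)
    best = dists.argmin(axis=1)  # argmin takes the first (lowest block id) on ties
    labels = np.array([b.block_id for b in blocks], dtype=object)
    out = labels[best]
    out[dists[np.arange(len(haps)), best] > max_mismatch] = OTHER
    return out


def cultivar_frequencies(
    blocks: list[HaplotypeBlock],
    cultivar_haps: np.ndarray,
    panels: np.ndarray,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Block frequencies of cultivar panels, projected onto existing blocks."""
    if len(cultivar_haps) == 0:
        raise ValueError("empty cultivar panel")
    assigned = assign_to_blocks(blocks, cultivar_haps, max_mismatch)
    panels = np.asarray(panels)
    cols = list(pd.unique(panels))
    rows = [b.block_id for b in blocks] + [OTHER]
    out = pd.DataFrame(0.0, index=rows, columns=cols)
    for c in cols:
        sel = panels == c
        n = int(sel.sum())
        for r in rows:
            out.loc[r, c] = float((assigned[sel] == r).sum() / n) if n else 0.0
    out.index.name = "block"
    return out


def representation_report(
    china_table: pd.DataFrame,
    cultivar_table: pd.DataFrame,
    min_freq: float = 0.05,
    northern_groups: list[str] | None = None,
    fixation: float = 0.9,
) -> pd.DataFrame:
    """Flag blocks under- or over-represented in cultivar panels.

    For each block, its maximum frequency among the northern source groups
    (default: the first three columns of ``china_table``) is compared with
    its frequency in each cultivar panel: a block common in the north
    (>= 0.5) but below ``min_freq`` in a panel is "underrepresented"; a
    block at or above ``fixation`` in a panel is "selected" (near-fixation).
    """
    shared = [b for b in china_table.index if b != OTHER]
    missing = [b for b in shared if b not in cultivar_table.index]
    if missing:
        raise ValueError(f"block definitions missing from cultivar table: {missing}")
    if northern_groups is None:
        northern_groups = list(china_table.columns[:3])
    rows = []
    for b in shared:
        north_max = float(china_table.loc[b, northern_groups].max())
        for panel in cultivar_table.columns:
            f = float(cultivar_table.loc[b, panel])
            status = "-"
            if north_max >= 0.5 and f < min_freq:
                status = "underrepresented"
            elif f >= fixation:
                status = "selected"
            rows.append(
                {
                    "block": b,
                    "panel": panel,
                    "north_max_freq": north_max,
                    "panel_freq": f,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
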