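"""Adaptation-signature regions: merging significant SNPs, overlaps, classes.

Significant SNPs closer than the merge distance (default 50 kb, strict
inequality) are grouped into one signature; region bounds are the outermost
significant SNPs padded by 5 kb each side and clipped to the chromosome.
Coordinates are 1-based inclusive throughout; regions of one test/scenario
are pairwise disjoint by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import MERGE_DIST, PAD

REGION_COLUMNS = [
    "chrom", "start", "end", "peak_pos", "peak_value",
    "n_snps_supporting", "test", "scenario",
]


def call_signatures(
    scores: pd.DataFrame,
    stat: str,
    threshold: float,
    merge_dist: int = MERGE_DIST,
    pad: int = PAD,
    chrom_lengths: dict[str, int] | None = None,
    test: str = "",
    scenario: str = "",
) -> pd.DataFrame:
    """Merge passing SNPs into signature regions.

    ``scores`` needs columns chrom, pos and ``stat`` and must be sorted by
    (chrom, pos).  Consecutive passing SNPs on a chromosome are merged while
    their gap is strictly below ``merge_dist``; the peak is the passing SNP
    with the maximum statistic (ties: smallest position).
    """
    for col in ("chrom", "pos", stat):
        if col not in scores.columns:
            raise ValueError(f"scores table lacks column {col!r}")
    grouped = scores.groupby("chrom", sort=False)["pos"]
    if not all(g.is_monotonic_increasing for _, g in grouped):
        raise ValueError("scores must be sorted by (chrom, pos)")

    passing = scores.loc[scores[stat] > threshold, ["chrom", "pos", stat]]
    rows = []
    for chrom, grp in passing.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        val = grp[stat].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= merge_dist)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        clen = (chrom_lengths or {}).get(chrom)
        for a, b in zip(starts, ends):
            v = val[a : b + 1]
            peak = a + int(np.argmax(v))  # argmax takes the first (smallest pos) on ties
            lo = max(1, int(pos[a]) - pad)
            hi = int(pos[b]) + pad
            if clen is not None:
                hi = min(hi, clen)
            rows.append(
                {
                    "chrom": chrom,
                    "start": lo,
                    "end": hi,
                    "peak_pos": int(pos[peak]),
                    "peak_value": float(val[peak]),
                    "n_snps_supporting": int(b - a + 1),
                    "test": test,
                    "scenario": scenario,
                }
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def _check_disjoint(regions: pd.DataFrame, label: str) -> None:
    for chrom, grp in regions.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{label} regions overlap internally on {chrom}")


def _intersects_any(regions: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each region share >= 1 bp with any region in others."""
    hit = np.zeros(len(regions), dtype=bool)
    by_chrom = {c: g for c, g in others.groupby("chrom")}
    for i, (_, r) in enumerate(regions.iterrows()):
        g = by_chrom.get(r["chrom"])
        if g is None:
            continue
        hit[i] = bool(((g["start"] <= r["end"]) & (g["end"] >= r["start"])).any())
    return hit


def overlap_sets(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, int]:
    """Venn-style counts between two internally disjoint region sets.

    Two regions overlap iff their 1-based inclusive intervals share at
    least one bp on the same chromosome.  Each region contributes once;
    the shared count is the smaller of the per-side hit counts (a region
    may intersect several on the other side).
    """
    _check_disjoint(a, "A")
    _check_disjoint(b, "B")
    a_hit = int(_intersects_any(a, b).sum())
    b_hit = int(_intersects_any(b, a).sum())
    return {
        "a_only": len(a) - a_hit,
        "b_only": len(b) - b_hit,
        "overlap": min(a_hit, b_hit),
    }


def combine_tests(
    xtx_regions: pd.DataFrame, bf_regions: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Classify signature regions by the tests that support them.

    Regions from the differentiation scan and from each association
    covariate are merged (interval union); every merged region carries the
    set of supporting tests and a class: ``both`` (differentiation and at
    least one association), ``differentiation-only`` or ``association-only``.
    """
    pieces = []
    if len(xtx_regions):
        t = xtx_regions.copy()
        t["_src"] = "XtX"
        pieces.append(t)
    for name, df in bf_regions.items():
        if len(df):
            t = df.copy()
            t["_src"] = name
            pieces.append(t)
    if not pieces:
        return pd.DataFrame(columns=["chrom", "start", "end", "tests", "klass"])
    allr = pd.concat(pieces, ignore_index=True)
    rows = []
    for chrom, grp in allr.groupby("chrom"):
        g = grp.sort_values("start").reset_index(drop=True)
        cur_start, cur_end = int(g.loc[0, "start"]), int(g.loc[0, "end"])
        tests = {g.loc[0, "_src"]}
        for _, r in g.iloc[1:].iterrows():
            if r["start"] <= cur_end:  # >= 1 shared bp, inclusive coordinates
                cur_end = max(cur_end, int(r["end"]))
                tests.add(r["_src"])
            else:
                rows.append((chrom, cur_start, cur_end, sorted(tests)))
                cur_start, cur_end, tests = int(r["start"]), int(r["end"]), {r["_src"]}
        rows.append((chrom, cur_start, cur_end, sorted(tests)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "tests"])

    def klass(tests: list[str]) -> str:
        has_x = "XtX" in tests
        has_bf = any(t != "XtX" for t in tests)
        if has_x and has_bf:
            return "both"
        return "differentiation-only" if has_x else "association-only"

    out["klass"] = out["tests"].map(klass)
    return out


def to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """Export regions as true BED (0-based half-open)."""
    bed = regions[["chrom"]].copy()
    bed["start"] = regions["start"] - 1
    bed["end"] = regions["end"]
    name = regions["test"] if "test" in regions else pd.Series([""] * len(regions))
    bed["name"] = [
        f"{t}:{c}:{s}-{e}"
        for t, c, s, e in zip(name, regions["chrom"], regions["start"], regions["end"])
    ]
    return bed
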