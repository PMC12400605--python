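"""Germplasm-group assignment, gene intersection, GO enrichment, impact variants.

Accessions are assigned to germplasm groups and growing regions from their
ancestry coefficients (>= 80% with one ancestral group) plus passport rules:
the two northeastern groups are subdivided by maturity-group rating, the
southern group by provincial origin.  The rules are data (a packaged,
editable CSV), not code.  Candidate genes are gene models intersecting
signature regions (1-based inclusive, >= 1 shared bp); enrichment uses a
one-sided hypergeometric test with Benjamini-Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import ANCESTRY_MIN, FDR

#: Maturity-group ratings, earliest to latest.
MG_ORDER = ["000", "00", "0", "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
_MG_RANK = {m: i for i, m in enumerate(MG_ORDER)}


def load_builtin_group_rules() -> pd.DataFrame:
    with resources.files("adaptscape.data").joinpath("group_rules.csv").open() as fh:
        return pd.read_csv(fh, dtype=str).fillna("")


def assign_groups(
    q: pd.DataFrame,
    passports: pd.DataFrame,
    rules: pd.DataFrame | None = None,
    ancestry_min: float = ANCESTRY_MIN,
) -> pd.DataFrame:
    """Assign accessions to germplasm groups, regions and scenarios.

    ``q`` holds ancestry coefficients (rows: accessions; columns: ancestral
    groups; rows must sum to 1 within 1e-3).  ``passports`` needs columns
    ``accession``, ``maturity_group`` and ``province``.  Returns one row per
    accession with group/region/scenario or an ``unassigned_reason``.
    """
    if rules is None:
        rules = load_builtin_group_rules()
    sums = q.sum(axis=1)
    bad = q.index[np.abs(sums - 1.0) > 1e-3]
    if len(bad):
        raise ValueError(f"ancestry rows do not sum to 1: {list(bad[:5])}")
    pp = passports.set_index("accession")
    rows = []
    for acc in q.index:
        best = q.loc[acc].idxmax()
        frac = float(q.loc[acc, best])
        rec = {
            "accession": acc,
            "group": None,
            "region": None,
            "scenarios": "",
            "unassigned_reason": "",
        }
        if frac < ancestry_min:
            rec["unassigned_reason"] = "low_ancestry"
            rows.append(rec)
            continue
        cand = rules[rules["ancestry_group"] == best]
        if cand.empty:
            rec["unassigned_reason"] = "group_not_mapped"
            rows.append(rec)
            continue
        mg = str(pp.at[acc, "maturity_group"]) if acc in pp.index else ""
        province = str(pp.at[acc, "province"]) if acc in pp.index else ""
        matched = None
        for _, rule in cand.iterrows():
            if rule["mg_min"]:
                if mg not in _MG_RANK:
                    continue
                if not (_MG_RANK[rule["mg_min"]] <= _MG_RANK[mg] <= _MG_RANK[rule["mg_max"]]):
                    continue
            if rule["provinces"]:
                if province not in rule["provinces"].split(";"):
                    continue
            matched = rule
            break
        if matched is None:
            uses_mg = cand["mg_min"].astype(bool).any()
            if uses_mg and mg not in _MG_RANK:
                rec["unassigned_reason"] = "mg_missing"
            elif uses_mg:
                rec["unassigned_reason"] = "mg_out_of_range"
            else:
                rec["unassigned_reason"] = "province_not_listed"
            rows.append(rec)
            continue
        rec.update(
            group=best,
            region=int(matched["region"]),
            scenarios=matched["scenarios"],
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("accession")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str


def read_gene_models(gff_path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Gene models from a GFF3 file (in-memory gffutils database)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gid, feat.seqid, feat.start, feat.end, feat.strand))
    return genes


def genes_in_signatures(
    signatures: pd.DataFrame,
    genes: list[GeneModel],
    chrom_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Genes intersecting each signature region (>= 1 shared bp, inclusive)."""
    chrom_map = chrom_map or {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(chrom_map.get(g.chrom, g.chrom), []).append(g)
    rows = []
    for _, r in signatures.iterrows():
        for g in by_chrom.get(r["chrom"], []):
            if g.start <= r["end"] and g.end >= r["start"]:
                rows.append(
                    {
                        "chrom": r["chrom"],
                        "start": int(r["start"]),
                        "end": int(r["end"]),
                        "gene_id": g.gene_id,
                        "gene_start": g.start,
                        "gene_end": g.end,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "gene_start", "gene_end"])


def go_enrichment(
    query: set[str],
    universe: set[str],
    term_to_genes: dict[str, set[str]],
    fdr: float = FDR,
) -> pd.DataFrame:
    """One-sided hypergeometric GO enrichment with BH correction.

    For each term with K annotated genes in a universe of M, the p-value is
    the upper tail P(X >= k) of a hypergeometric draw of the n query genes.
    """
    from statsmodels.stats.multitest import multipletests

    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from universe: {sorted(stray)[:5]}")
    M, n = len(universe), len(query)
    rows = []
    for term, genes in term_to_genes.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "term_size": K, "overlap": k, "p": p})
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(out):
        _, qvals, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = qvals
        out["significant"] = out["q"] <= fdr
        out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = []
        out["significant"] = []
    return out


def gene_overlap_mc(
    n_query: int,
    target_size: int,
    universe_size: int,
    n_sims: int = 10_000,
    seed: int = 0,
    observed: int | None = None,
) -> tuple[float, float | None]:
    """Monte-Carlo overlap of a random gene set with a target set.

    Draws ``n_sims`` random ``n_query``-subsets of the universe and records
    the intersection size with a fixed target set.  Returns the mean overlap
    and, if ``observed`` is given, the one-sided p-value
    (1 + #{sim >= observed}) / (n_sims + 1).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_query > universe_size or target_size > universe_size:
        raise ValueError("query/target cannot exceed the universe")
    rng = np.random.default_rng(seed)
    is_target = np.zeros(universe_size, dtype=bool)
    is_target[:target_size] = True  # exchangeable under random sampling
    overlaps = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        take = rng.choice(universe_size, size=n_query, replace=False)
        overlaps[s] = int(is_target[take].sum())
    expected = float(overlaps.mean())
    if observed is None:
        return expected, None
    p = (1 + int((overlaps >= observed).sum())) / (n_sims + 1)
    return expected, p


def high_impact_variants(
    vcf_path: str | Path,
    signatures: pd.DataFrame,
    impacts: tuple[str, ...] = ("HIGH", "MODERATE"),
    ann_field: str = "ANN",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Variants with annotated functional impact inside signature regions.

    The VCF must carry an effect annotation: either a snpEff-style ``ANN``
    INFO field (impact is the third ``|``-separated entry) or a plain
    ``IMPACT`` INFO key.  Returns the per-region variant table and the
    panel-wide impact-class proportions.
    """
    from cyvcf2 import VCF

    regions = [
        (r["chrom"], int(r["start"]), int(r["end"])) for _, r in signatures.iterrows()
    ]
    vcf = VCF(str(vcf_path))
    counts: dict[str, int] = {}
    n_total = 0
    rows = []
    saw_annotation = False
    for v in vcf:
        ann = v.INFO.get(ann_field)
        impact = None
        if ann is not None:
            saw_annotation = True
            first = str(ann).split(",")[0].split("|")
            impact = first[2] if len(first) > 2 else None
        else:
            raw = v.INFO.get("IMPACT")
            if raw is not None:
                saw_annotation = True
                impact = str(raw)
        n_total += 1
        if impact:
            counts[impact] = counts.get(impact, 0) + 1
        if impact in impacts:
            for chrom, start, end in regions:
                if v.CHROM == chrom and start <= v.POS <= end:
                    rows.append(
                        {"chrom": v.CHROM, "pos": v.POS, "impact": impact,
                         "region_start": start, "region_end": end}
                    )
                    break
    vcf.close()
    if not saw_annotation:
        raise ValueError(
            f"no {ann_field}/IMPACT annotation in {vcf_path}; run an effect "
            "annotator (e.g. snpEff) first"
        )
    proportions = {k: v / n_total for k, v in counts.items()}
    table = pd.DataFrame(rows, columns=["chrom", "pos", "impact", "region_start", "region_end"])
    return table, proportions
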