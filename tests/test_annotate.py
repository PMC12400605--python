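"""Group assignment, gene intersection, GO enrichment, MC overlap, impacts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptscape.annotate import (
    GeneModel,
    assign_groups,
    gene_overlap_mc,
    genes_in_signatures,
    go_enrichment,
    high_impact_variants,
    load_builtin_group_rules,
    read_gene_models,
)


def q_matrix(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    groups = [f"K10.{i}" for i in range(1, 11)]
    out = pd.DataFrame(0.0, index=list(rows), columns=groups)
    for acc, fracs in rows.items():
        for g, f in fracs.items():
            out.loc[acc, g] = f
        out.loc[acc, "K10.1"] += 1.0 - out.loc[acc].sum()
    return out


class TestAssignGroups:
    def _passports(self, mg="I", province=""):
        return pd.DataFrame(
            {"accession": ["a1"], "maturity_group": [mg], "province": [province]}
        )

    def test_northeastern_group_mg_one_maps_to_region_two(self):
        q = q_matrix({"a1": {"K10.7": 0.85}})
        out = assign_groups(q, self._passports(mg="I"))
        assert out.loc["a1", "group"] == "K10.7"
        assert out.loc["a1", "region"] == 2
        assert out.loc["a1", "scenarios"] == "A"

    def test_low_ancestry_unassigned(self):
        q = q_matrix({"a1": {"K10.7": 0.60, "K10.5": 0.40}})
        out = assign_groups(q, self._passports())
        assert pd.isna(out.loc["a1", "region"])
        assert out.loc["a1", "unassigned_reason"] == "low_ancestry"

    def test_southern_group_province_split(self):
        q = q_matrix({"a1": {"K10.6": 0.92}})
        out = assign_groups(q, self._passports(province="Fujian"))
        assert out.loc["a1", "region"] == 6
        assert out.loc["a1", "scenarios"] == "AB"
        out2 = assign_groups(q, self._passports(province="Jiangsu"))
        assert out2.loc["a1", "region"] == 5

    def test_missing_mg_for_northeastern_group_reasoned(self):
        q = q_matrix({"a1": {"K10.8": 0.95}})
        out = assign_groups(q, self._passports(mg=""))
        assert out.loc["a1", "unassigned_reason"] == "mg_missing"

    def test_earliest_maturity_region1_only_in_scenario_a(self):
        rules = load_builtin_group_rules()
        q7 = q_matrix({"a1": {"K10.7": 0.9}})
        out = assign_groups(q7, self._passports(mg="000"))
        assert out.loc["a1", "region"] == 1 and out.loc["a1", "scenarios"] == "A"
        # the sibling northeastern group has no earliest-maturity rule
        assert not (
            (rules["ancestry_group"] == "K10.8") & (rules["mg_min"] == "000")
        ).any()
        q8 = q_matrix({"a1": {"K10.8": 0.9}})
        out8 = assign_groups(q8, self._passports(mg="000"))
        assert out8.loc["a1", "unassigned_reason"] == "mg_out_of_range"

    def test_bad_ancestry_rows_rejected(self):
        q = q_matrix({"a1": {"K10.7": 0.85}})
        q.loc["a1", "K10.1"] += 0.5
        with pytest.raises(ValueError, match="sum"):
            assign_groups(q, self._passports())

    @settings(max_examples=200, deadline=None)
    @given(
        best=st.sampled_from([f"K10.{i}" for i in range(1, 11)]),
        frac=st.floats(0.34, 1.0),
        mg=st.sampled_from(["000", "0", "I", "II", "III", "V", "X", ""]),
        province=st.sampled_from(["Fujian", "Jiangsu", "Gansu", ""]),
    )
    def test_totality_assigned_or_reasoned(self, best, frac, mg, province):
        q = q_matrix({"a1": {best: frac}})
        pp = pd.DataFrame(
            {"accession": ["a1"], "maturity_group": [mg], "province": [province]}
        )
        out = assign_groups(q, pp)
        row = out.loc["a1"]
        assigned = pd.notna(row["region"])
        assert assigned != bool(row["unassigned_reason"])


GFF = """##gff-version 3
chr01\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene1
chr01\tsrc\tgene\t500\t900\t.\t-\t.\tID=gene2
chr02\tsrc\tgene\t150\t260\t.\t+\t.\tID=gene3
"""


class TestGenes:
    def test_gff3_read_and_intersection(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(GFF)
        genes = read_gene_models(gff)
        assert [g.gene_id for g in genes] == ["gene1", "gene2", "gene3"]
        sigs = pd.DataFrame([{"chrom": "chr01", "start": 150, "end": 300}])
        hits = genes_in_signatures(sigs, genes)
        assert list(hits["gene_id"]) == ["gene1"]

    def test_inclusive_boundary(self):
        genes = [GeneModel("g", "chr01", 100, 200, "+")]
        inside = pd.DataFrame([{"chrom": "chr01", "start": 200, "end": 300}])
        outside = pd.DataFrame([{"chrom": "chr01", "start": 201, "end": 300}])
        assert len(genes_in_signatures(inside, genes)) == 1
        assert len(genes_in_signatures(outside, genes)) == 0

    def test_empty_annotation(self):
        sigs = pd.DataFrame([{"chrom": "chr01", "start": 1, "end": 10}])
        assert genes_in_signatures(sigs, []).empty


class TestGOEnrichment:
    def test_closed_form_hypergeometric(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        query = set(term)
        out = go_enrichment(query, universe, {"T": term})
        expected = 1 / math.comb(100, 10) * math.comb(10, 10) * math.comb(90, 0)
        assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)
        assert out.iloc[0]["significant"]

    def test_query_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        terms = {"T1": {"g0", "g1"}, "T2": {"g5"}}
        out = go_enrichment(set(universe), universe, terms)
        assert (out["p"] == 1.0).all()

    def test_zero_overlap_upper_tail_is_one(self):
        universe = {f"g{i}" for i in range(50)}
        out = go_enrichment({"g40"}, universe, {"T": {"g0", "g1"}})
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_bh_q_monotone_and_order_invariant(self):
        rng = np.random.default_rng(1)
        universe = {f"g{i}" for i in range(200)}
        terms = {
            f"T{k}": set(rng.choice(sorted(universe), 20, replace=False))
            for k in range(8)
        }
        query = set(rng.choice(sorted(universe), 40, replace=False))
        out = go_enrichment(query, universe, terms)
        assert (np.diff(out["q"]) >= -1e-12).all()
        shuffled = dict(reversed(list(terms.items())))
        out2 = go_enrichment(query, universe, shuffled)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), out2.reset_index(drop=True)
        )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            go_enrichment({"x"}, {"a"}, {"T": {"a"}})


class TestGeneOverlapMC:
    def test_mean_converges_to_hypergeometric_expectation(self):
        # law of large numbers at two simulation sizes
        n_query, target, universe = 300, 600, 6_000
        analytic = n_query * target / universe
        e_small, _ = gene_overlap_mc(n_query, target, universe, n_sims=300, seed=2)
        e_big, _ = gene_overlap_mc(n_query, target, universe, n_sims=6_000, seed=2)
        assert abs(e_big - analytic) < abs(e_small - analytic) + 0.2
        assert e_big == pytest.approx(analytic, abs=0.5)

    def test_target_equals_universe_trivial(self):
        e, p = gene_overlap_mc(10, 50, 50, n_sims=100, seed=3, observed=10)
        assert e == 10.0 and p == 1.0

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            gene_overlap_mc(10, 5, 8, n_sims=10)
        with pytest.raises(ValueError, match="n_sims"):
            gene_overlap_mc(1, 1, 10, n_sims=0)


def write_annotated_vcf(path, n_total=1_000, n_high=3, n_moderate=57):
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        "##contig=<ID=chr01,length=2000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i in range(n_total):
        if i < n_high:
            impact = "HIGH"
        elif i < n_high + n_moderate:
            impact = "MODERATE"
        else:
            impact = "LOW"
        pos = 1_000 + i * 100
        lines.append(
            f"chr01\t{pos}\t.\tA\tT\t.\tPASS\tANN=T|missense_variant|{impact}|gene{i}"
        )
    path.write_text("\n".join(lines) + "\n")


class TestHighImpactVariants:
    def test_panel_proportions_and_region_filter(self, tmp_path):
        vcf = tmp_path / "ann.vcf"
        write_annotated_vcf(vcf)
        sigs = pd.DataFrame([{"chrom": "chr01", "start": 1_000, "end": 1_500}])
        table, props = high_impact_variants(vcf, sigs)
        assert props["HIGH"] == pytest.approx(0.003)
        assert props["MODERATE"] == pytest.approx(0.057)
        # positions 1000..1500 hold the 3 HIGH and 3 of the MODERATE records
        assert len(table) == 6

    def test_region_without_annotated_variants_empty(self, tmp_path):
        vcf = tmp_path / "ann.vcf"
        write_annotated_vcf(vcf, n_total=10, n_high=1, n_moderate=1)
        sigs = pd.DataFrame([{"chrom": "chr01", "start": 900_000, "end": 900_100}])
        table, _ = high_impact_variants(vcf, sigs)
        assert table.empty

    def test_missing_annotation_field_instructs(self, tmp_path, small_gt):
        from adaptscape.io import write_vcf

        vcf = tmp_path / "plain.vcf"
        write_vcf(small_gt, vcf)
        sigs = pd.DataFrame([{"chrom": "chr01", "start": 1, "end": 10}])
        with pytest.raises(ValueError, match="annotator"):
            high_impact_variants(vcf, sigs)
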