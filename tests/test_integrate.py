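"""Selection regions, Venn overlaps, nonsynonymous tables, truth evaluation."""

import numpy as np
import pandas as pd
import pytest

from poolcross.conditions import Line
from poolcross.integrate import (
    SelectionRegion,
    nonsyn_table,
    select_regions,
    truth_eval,
    venn_counts,
)
from poolcross.tables import GeneAnnotation, GeneFamily


def traj_hits(rows):
    cols = [
        "locus_id",
        "line",
        "verdict",
        "band_lo",
        "effect",
        "f_F0",
        "f_F0_LD80",
        "f_F2",
        "f_F2_LD25",
        "f_F2_LD75",
    ]
    df = pd.DataFrame(rows, columns=["locus_id", "line", "verdict", "effect"])
    for c in cols:
        if c not in df.columns:
            df[c] = 0.5
    return df[cols]


def scan(locus_qs, line=Line.DELT, contrast="F0_contrast"):
    return pd.DataFrame(
        {
            "locus_id": list(locus_qs),
            "line": line.value,
            "contrast": contrast,
            "q_value": list(locus_qs.values()),
        }
    )


P450 = GeneAnnotation("cyp1", "cyp1", GeneFamily.P450, "chr1", 130_000, 140_000)
FAR_GENE = GeneAnnotation("cyp2", "cyp2", GeneFamily.P450, "chr1", 900_000, 910_000)
OTHER = GeneAnnotation("g_other", "g_other", GeneFamily.OTHER, "chr1", 130_000, 140_000)


class TestSelectRegions:
    def test_hit_near_candidate_gene_forms_region(self):
        hits = traj_hits([("chr1:100001", "Delt", "resistance-associated", "nonsynonymous")])
        s0 = scan({"chr1:100001": 0.01})
        s2 = scan({"chr1:100001": 0.01}, contrast="F2_contrast")
        regions = select_regions(hits, s0, s2, [P450], Line.DELT)
        assert len(regions) == 1
        assert regions[0].genes == ["cyp1"]  # 30 kb away, inside the 50 kb window
        assert not regions[0].anonymous

    def test_hit_far_from_genes_is_anonymous(self):
        hits = traj_hits([("chr1:100001", "Delt", "resistance-associated", "intergenic")])
        s0 = scan({"chr1:100001": 0.01})
        s2 = scan({"chr1:100001": 0.01}, contrast="F2_contrast")
        regions = select_regions(hits, s0, s2, [FAR_GENE], Line.DELT)
        assert len(regions) == 1 and regions[0].anonymous

    def test_requires_low_q_in_both_contrasts(self):
        hits = traj_hits([("chr1:100001", "Delt", "resistance-associated", "intergenic")])
        s0 = scan({"chr1:100001": 0.01})
        s2 = scan({"chr1:100001": 0.20}, contrast="F2_contrast")
        assert select_regions(hits, s0, s2, [P450], Line.DELT) == []

    def test_candidate_genes_exclude_family_other(self):
        hits = traj_hits([("chr1:100001", "Delt", "resistance-associated", "intergenic")])
        s0 = scan({"chr1:100001": 0.01})
        s2 = scan({"chr1:100001": 0.01}, contrast="F2_contrast")
        regions = select_regions(hits, s0, s2, [OTHER], Line.DELT)
        assert regions[0].anonymous

    def test_merging_is_idempotent_and_order_independent(self):
        loci = ["chr1:100001", "chr1:140001", "chr1:500001"]
        qmap = {l: 0.001 for l in loci}
        rows = [(l, "Delt", "resistance-associated", "intergenic") for l in loci]
        s0, s2 = scan(qmap), scan(qmap, contrast="F2_contrast")
        a = select_regions(traj_hits(rows), s0, s2, [], Line.DELT)
        b = select_regions(traj_hits(rows[::-1]), s0, s2, [], Line.DELT)
        assert len(a) == 2  # first two merge, third is separate
        assert [(r.chrom, r.start, r.end, tuple(sorted(r.loci))) for r in a] == [
            (r.chrom, r.start, r.end, tuple(sorted(r.loci))) for r in b
        ]
        assert a[0].min_q_f0 == pytest.approx(0.001)


class TestVenn:
    def test_example_sets(self):
        out = venn_counts(
            {Line.DELT: {"A", "B"}, Line.BEND: {"B"}, Line.FENI: {"C"}}
        )
        counts = dict(zip(out["members"], out["count"]))
        assert counts["Delt"] == 1
        assert counts["Delt&Bend"] == 1
        assert counts["Feni"] == 1
        assert counts["Delt&Bend&Feni"] == 0

    def test_identical_sets_all_in_triple_intersection(self):
        out = venn_counts({l: {"x", "y"} for l in Line if l is not Line.NONE})
        counts = dict(zip(out["members"], out["count"]))
        assert counts["Delt&Bend&Feni"] == 2
        assert sum(c for m, c in counts.items() if m != "Delt&Bend&Feni") == 0

    def test_empty_sets(self):
        out = venn_counts({})
        assert (out["count"] == 0).all()

    def test_totals_equal_union(self, rng):
        sets = {
            l: set(rng.choice(20, size=rng.integers(0, 10), replace=False).tolist())
            for l in (Line.DELT, Line.BEND, Line.FENI)
        }
        out = venn_counts(sets)
        assert out["count"].sum() == len(set.union(*sets.values()))


HOST = GeneAnnotation("vgsc", "vgsc", GeneFamily.TARGET, "chr1", 99_000, 101_000)


class TestNonsynTable:
    def test_filters_and_flags(self):
        hits = traj_hits(
            [
                ("chr1:100001", "Delt", "resistance-associated", "nonsynonymous"),
                ("chr1:100002", "Delt", "resistance-associated", "synonymous"),
                ("chr1:100003", "Feni", "deleterious", "frameshift"),
            ]
        )
        regions = {
            Line.DELT: [SelectionRegion("chr1", 50_000, 150_000, Line.DELT)],
            Line.FENI: [],
        }
        out = nonsyn_table(hits, [HOST], regions)
        assert set(out["locus_id"]) == {"chr1:100001", "chr1:100003"}
        delt = out[out["line"] == "Delt"].iloc[0]
        assert bool(delt["in_selection_region"])
        feni = out[out["line"] == "Feni"].iloc[0]
        assert feni["verdict"] == "deleterious"
        assert not bool(feni["in_selection_region"])

    def test_hits_outside_candidate_genes_dropped(self):
        hits = traj_hits([("chr5:1", "Delt", "resistance-associated", "nonsynonymous")])
        assert len(nonsyn_table(hits, [HOST], {})) == 0


def truth_frame(causal):
    rows = []
    for i, line in enumerate(["Delt", "Bend", "none", "none"]):
        rows.append(
            {
                "chrom": "chr1",
                "pos": i * 1000,
                "locus_class": "snp",
                "gene_id": "",
                "causal_line": line if causal else "none",
            }
        )
    rows.append(
        {
            "chrom": "chr1",
            "pos": 9000,
            "locus_class": "cnv_gene",
            "gene_id": "amp1",
            "causal_line": "Feni" if causal else "none",
        }
    )
    return pd.DataFrame(rows)


class TestTruthEval:
    def test_perfect_calls(self):
        truth = truth_frame(causal=True)
        traj = traj_hits(
            [
                ("chr1:1", "Delt", "resistance-associated", "nonsynonymous"),
                ("chr1:1001", "Bend", "resistance-associated", "nonsynonymous"),
                ("chr1:2001", "Delt", "none", "intergenic"),
                ("chr1:3001", "Delt", "none", "intergenic"),
            ]
        )
        report = truth_eval(truth, {Line.FENI: ["amp1"]}, traj, {})
        cnv = report[report["stream"] == "cnv"].iloc[0]
        assert cnv["sensitivity"] == 1.0 and cnv["false_positives"] == 0
        tr = report[report["stream"] == "trajectory"].iloc[0]
        assert tr["sensitivity"] == 1.0 and tr["false_positives"] == 0

    def test_empty_calls(self):
        truth = truth_frame(causal=True)
        traj = traj_hits([("chr1:2001", "Delt", "none", "intergenic")])
        report = truth_eval(truth, {}, traj, {})
        assert (report.set_index("stream")["sensitivity"][["cnv", "trajectory"]] == 0).all()

    def test_region_stream_counts_covered_causal_loci(self):
        truth = truth_frame(causal=True)
        traj = traj_hits([("chr1:1", "Delt", "resistance-associated", "nonsynonymous")])
        regions = {Line.DELT: [SelectionRegion("chr1", 0, 10_000, Line.DELT)]}
        report = truth_eval(truth, {}, traj, regions)
        reg = report[report["stream"] == "region"].iloc[0]
        assert reg["true_positives"] == 1
        assert reg["false_positives"] == 0
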