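"""Gene mapping, direction-matched expression tests, candidate assembly."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from lungdiverge.datamodel import DifferentialRegion, ExpressionMatrix
from lungdiverge.integration import (
    CandidateGene,
    concerted_gene_lists,
    integrate_methylation_expression,
    map_genes_to_regions,
    validate_vs_normal,
)
from lungdiverge.integration import test_region_genes as region_gene_test
from lungdiverge.methylation import DifferentialMethylProbe

from conftest import make_clinical

MB = 1_000_000


def make_region(start=10 * MB + 1, end=20 * MB, direction="gain",
                subtype="SqCC", chrom="chr1"):
    counts = {
        "AC": {"gain": 0, "neutral": 10, "loss": 0},
        "SqCC": {"gain": 8, "neutral": 2, "loss": 0},
    }
    if direction == "loss":
        counts = {
            "AC": {"gain": 0, "neutral": 2, "loss": 8},
            "SqCC": {"gain": 0, "neutral": 10, "loss": 0},
        }
        subtype = "AC" if subtype == "SqCC" else subtype
    return DifferentialRegion(
        chromosome=chrom, start=start, end=end, probe_ids=["x"],
        p=1e-5, q=1e-4, significant=True, direction=direction,
        assigned_subtype=subtype, freq_assigned=0.8, freq_other=0.0,
        counts=counts,
    )


def make_expression(rows: dict[str, tuple], samples: list[str], ann_extra=None):
    """rows: probe_id -> (symbol, chrom, start, end, values)."""
    ann_rows, data = [], {}
    for pid, (sym, chrom, start, end, values) in rows.items():
        ann_rows.append(
            {"probe_id": pid, "symbol": sym, "chromosome": chrom, "start": start, "end": end}
        )
        data[pid] = values
    ann = pd.DataFrame(ann_rows).set_index("probe_id")
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return ExpressionMatrix(ann, values.astype(float))


class TestGeneMapping:
    def test_overlap_rules(self):
        region = make_region()
        genes = pd.DataFrame(
            {
                "symbol": ["IN", "OUT", "SPAN"],
                "chromosome": ["chr1"] * 3,
                "start": [12 * MB, 20 * MB + 1, 19 * MB],
                "end": [13 * MB, 21 * MB, 22 * MB],
            },
            index=["g_in", "g_out", "g_span"],
        )
        out = map_genes_to_regions(genes, [region])
        (key,) = out.keys()
        assert set(out[key]) == {"g_in", "g_span"}  # 1 bp past end excluded

    def test_gene_spanning_two_regions_assigned_to_both(self):
        r1 = make_region(start=1, end=10 * MB)
        r2 = make_region(start=10 * MB + 1, end=20 * MB)
        genes = pd.DataFrame(
            {"symbol": ["SPAN"], "chromosome": ["chr1"],
             "start": [9 * MB], "end": [11 * MB]},
            index=["g0"],
        )
        out = map_genes_to_regions(genes, [r1, r2])
        assert all(v == ["g0"] for v in out.values())


class TestRegionGeneTest:
    def samples(self):
        ac = [f"a{i}" for i in range(10)]
        sq = [f"b{i}" for i in range(10)]
        return ac, sq, make_clinical({"AC": ac, "SqCC": sq})

    def test_perfect_separation_exact_p(self):
        ac, sq, clinical = self.samples()
        expr = make_expression(
            {"g0": ("GENE1", "chr1", 12 * MB, 13 * MB,
                    list(np.linspace(1.0, 2.0, 10)) + list(np.linspace(5.0, 6.0, 10)))},
            ac + sq,
        )
        out = region_gene_test(expr, clinical, make_region(), ["g0"], alpha=0.001)
        assert out[0].p == pytest.approx(1 / math.comb(20, 10))
        assert out[0].significant

    def test_opposite_direction_not_significant(self):
        ac, sq, clinical = self.samples()
        expr = make_expression(
            {"g0": ("GENE1", "chr1", 12 * MB, 13 * MB,
                    [5.0] * 10 + [1.0] * 10)},  # AC higher, region says SqCC gain
            ac + sq,
        )
        out = region_gene_test(expr, clinical, make_region(), ["g0"])
        assert out[0].p >= 0.5 and not out[0].significant

    def test_single_probe_q_equals_p(self):
        ac, sq, clinical = self.samples()
        expr = make_expression(
            {"g0": ("GENE1", "chr1", 12 * MB, 13 * MB,
                    list(np.linspace(0, 1, 10)) + list(np.linspace(2, 3, 10)))},
            ac + sq,
        )
        out = region_gene_test(expr, clinical, make_region(), ["g0"])
        assert out[0].q == pytest.approx(out[0].p)

    def test_multiple_probes_collapse_to_lowest_p(self):
        ac, sq, clinical = self.samples()
        expr = make_expression(
            {
                "g0": ("GENE1", "chr1", 12 * MB, 13 * MB,
                       list(np.linspace(1.0, 2.0, 10))
                       + list(np.linspace(5.0, 6.0, 10))),  # clean probe
                "g1": ("GENE1", "chr1", 12 * MB, 13 * MB,
                       list(np.linspace(0, 4, 20)[::2])
                       + list(np.linspace(0, 4, 20)[1::2])),  # interleaved probe
            },
            ac + sq,
        )
        out = region_gene_test(expr, clinical, make_region(), ["g0", "g1"])
        assert len(out) == 1
        assert out[0].probe_id == "g0"

    def test_empty_region_skipped(self):
        _, _, clinical = self.samples()
        expr = make_expression(
            {"g0": ("GENE1", "chr1", 1, 2, [0.0] * 20)},
            [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        assert region_gene_test(expr, clinical, make_region(), []) == []


class TestVsNormalValidation:
    def setup_candidates(self, tumor_vals, normal_vals, direction="up"):
        samples = [f"b{i}" for i in range(10)]
        normals = [f"n{i}" for i in range(6)]
        clinical = make_clinical({"SqCC": samples})
        expr_t = make_expression(
            {"g0": ("GENE1", "chr1", 1, 2, tumor_vals)}, samples
        )
        expr_n = make_expression(
            {"g0": ("GENE1", "chr1", 1, 2, normal_vals)}, normals
        )
        cand = CandidateGene(
            symbol="GENE1", subtype="SqCC", mechanism="copy_number",
            expected_direction=direction, link="r", subtype_p=1e-5,
            subtype_q=1e-4, pass_subtype=True,
        )
        return [cand], expr_t, clinical, expr_n

    def test_clear_overexpression_passes(self):
        cands, expr_t, clinical, expr_n = self.setup_candidates(
            list(np.linspace(7.8, 8.2, 10) + 2.0), list(np.linspace(7.8, 8.2, 6))
        )
        validate_vs_normal(cands, expr_t, clinical, expr_n, alpha=0.001)
        assert cands[0].pass_vs_normal and cands[0].fold_change > 1

    def test_fold_change_gate_blocks_wrong_direction(self):
        # expected up but tumors sit below normals: p(one-sided up) ~ 1
        cands, expr_t, clinical, expr_n = self.setup_candidates(
            list(np.linspace(5.8, 6.2, 10)), list(np.linspace(7.8, 8.2, 6))
        )
        validate_vs_normal(cands, expr_t, clinical, expr_n, alpha=0.001)
        assert not cands[0].pass_vs_normal

    def test_null_difference_fails(self):
        cands, expr_t, clinical, expr_n = self.setup_candidates(
            list(np.linspace(7.8, 8.2, 10)), list(np.linspace(7.8, 8.2, 6))
        )
        validate_vs_normal(cands, expr_t, clinical, expr_n, alpha=0.001)
        assert not cands[0].pass_vs_normal


class TestMethylationIntegration:
    def probe(self, direction="hypo", subtype="SqCC", significant=True):
        return DifferentialMethylProbe(
            probe_id="m0",
            counts={
                "AC": {"hyper": 0, "unchanged": 30, "hypo": 0},
                "SqCC": {"hyper": 0, "unchanged": 3, "hypo": 10},
            },
            p=1e-6, q=1e-5, significant=significant,
            dominant_subtype=subtype, direction=direction,
        )

    def run(self, tumor_sq_shift, normal_shift=0.0, direction="hypo"):
        ac = [f"a{i}" for i in range(10)]
        sq = [f"b{i}" for i in range(10)]
        normals = [f"n{i}" for i in range(6)]
        clinical = make_clinical({"AC": ac, "SqCC": sq})
        base = np.linspace(7.9, 8.1, 10)
        expr_t = make_expression(
            {"g0": ("GENE1", "chr1", 1, 2,
                    list(base) + list(base + tumor_sq_shift))},
            ac + sq,
        )
        expr_n = make_expression(
            {"g0": ("GENE1", "chr1", 1, 2, list(np.linspace(7.9, 8.1, 6) + normal_shift))},
            normals,
        )
        return integrate_methylation_expression(
            [self.probe(direction=direction)],
            pd.Series({"m0": "GENE1"}),
            expr_t, clinical, expr_n, alpha=0.05,
        )

    def test_hypomethylated_overexpressed_gene_retained(self):
        out = self.run(tumor_sq_shift=2.0)
        assert out[0].retained and out[0].expected_direction == "up"

    def test_unchanged_expression_dropped(self):
        out = self.run(tumor_sq_shift=0.0)
        assert not out[0].retained

    def test_discordant_direction_dropped(self):
        # hypo probe predicts up, but the gene is DOWN in SqCC
        out = self.run(tumor_sq_shift=-2.0)
        assert not out[0].retained


class TestConcertedLists:
    def cand(self, symbol, subtype, mechanism, direction):
        return CandidateGene(
            symbol=symbol, subtype=subtype, mechanism=mechanism,
            expected_direction=direction, link="L", subtype_p=1e-6,
            subtype_q=1e-5, vs_normal_p=1e-6, fold_change=2.0,
            pass_subtype=True, pass_vs_normal=True,
        )

    def test_disjoint_lists_concatenate(self):
        cn = [self.cand("A", "SqCC", "copy_number", "up")]
        meth = [self.cand("B", "SqCC", "methylation", "down")]
        out = concerted_gene_lists(cn, meth)
        assert out.concerted == {"AC": [], "SqCC": []}
        assert out.diametric == []
        assert sorted(out.union["symbol"]) == ["A", "B"]

    def test_same_direction_both_mechanisms_is_concerted(self):
        cn = [self.cand("BRF2", "SqCC", "copy_number", "up")]
        meth = [self.cand("BRF2", "SqCC", "methylation", "up")]
        out = concerted_gene_lists(cn, meth)
        assert out.concerted["SqCC"] == ["BRF2"]
        assert len(out.union) == 1

    def test_opposite_subtype_mechanisms_is_diametric(self):
        # up by hypomethylation in SqCC, down by loss in AC
        cn = [self.cand("PARP-LIKE", "AC", "copy_number", "down")]
        meth = [self.cand("PARP-LIKE", "SqCC", "methylation", "up")]
        out = concerted_gene_lists(cn, meth)
        assert out.diametric == ["PARP-LIKE"]

    def test_union_accounting_identity(self):
        cn = [
            self.cand("A", "SqCC", "copy_number", "up"),
            self.cand("B", "SqCC", "copy_number", "up"),
            self.cand("C", "AC", "copy_number", "down"),
        ]
        meth = [
            self.cand("B", "SqCC", "methylation", "up"),  # overlaps cn
            self.cand("D", "AC", "methylation", "down"),
        ]
        out = concerted_gene_lists(cn, meth)
        n_overlap = len(out.concerted["AC"]) + len(out.concerted["SqCC"])
        assert len(out.union) == len(cn) + len(meth) - n_overlap
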