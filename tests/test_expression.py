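"""FPKM, the NB Wald DE engine, the imprinting cascade and LOI calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scntomics.dmr import DMR
from scntomics.expression import (
    AllelicBands,
    CascadeParams,
    annotate_loi,
    call_allelic_status,
    call_loi,
    candidate_cascade,
    compute_fpkm,
    deg_flags,
    differential_expression,
    packaged_imprint_list,
    size_factors,
)


def nb_counts(rng, mean, disp, n):
    if disp <= 0:
        return rng.poisson(mean, size=n)
    shape = 1 / disp
    return rng.poisson(rng.gamma(shape, mean / shape, size=n))


class TestFpkm:
    def test_worked_example(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 1000}), pd.Series({"s1": 1_000_000}))
        assert fpkm.loc["g", "s1"] == pytest.approx(100.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g"])
        fpkm = compute_fpkm(counts, pd.Series({"g": 500}), pd.Series({"s1": 2_000_000}))
        assert fpkm.loc["g", "s1"] == 0.0

    def test_matches_formula_on_random_matrix(self, rng):
        genes = [f"g{i}" for i in range(20)]
        counts = pd.DataFrame(rng.integers(0, 500, (20, 4)), index=genes, columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 5000, 20), index=genes)
        libs = counts.sum(axis=0)
        fpkm = compute_fpkm(counts, lengths)
        for g in genes:
            for s in "abcd":
                expected = counts.loc[g, s] / (lengths[g] / 1e3) / (libs[s] / 1e6)
                assert fpkm.loc[g, s] == pytest.approx(expected)

    def test_scale_invariance_under_joint_library_rescaling(self, rng):
        genes = [f"g{i}" for i in range(10)]
        counts = pd.DataFrame(rng.integers(1, 500, (10, 3)), index=genes, columns=list("abc"))
        lengths = pd.Series(rng.integers(200, 5000, 10), index=genes)
        f1 = compute_fpkm(counts, lengths)
        # multiplying every count by 10 scales library sizes too: FPKM invariant
        f2 = compute_fpkm(counts * 10, lengths)
        pd.testing.assert_frame_equal(f1, f2)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            compute_fpkm(pd.DataFrame({"s": [1]}, index=["g"]), pd.Series({"g": 0}))


class TestDifferentialExpression:
    def make_groups(self, rng, n_genes=100, mean_b_factor=1.0, disp=0.1, n=3):
        genes = [f"g{i}" for i in range(n_genes)]
        ca = pd.DataFrame(
            np.vstack([nb_counts(rng, 100, disp, n) for _ in genes]), index=genes,
            columns=[f"a{i}" for i in range(n)],
        )
        cb = pd.DataFrame(
            np.vstack([nb_counts(rng, 100 * mean_b_factor, disp, n) for _ in genes]), index=genes,
            columns=[f"b{i}" for i in range(n)],
        )
        return ca, cb

    def test_identical_groups_log2fc_zero(self, rng):
        ca, _ = self.make_groups(rng)
        de = differential_expression(ca, ca.rename(columns=lambda c: "b" + c))
        assert np.allclose(de["log2FC"], 0.0)
        assert (de["p_value"] > 0.99).all()

    def test_size_factor_invariance_to_sample_scaling(self, rng):
        ca, cb = self.make_groups(rng)
        de1 = differential_expression(ca, cb)
        scaled = ca.copy()
        scaled["a0"] = scaled["a0"] * 2  # doubling one sample's depth
        de2 = differential_expression(scaled, cb)
        # normalization absorbs the doubling: fold changes are identical; the
        # extra depth may shift significance marginally, never conclusions
        np.testing.assert_allclose(de1["log2FC"], de2["log2FC"], atol=1e-9)
        np.testing.assert_allclose(de1["p_value"], de2["p_value"], rtol=0.05, atol=1e-12)

    def test_median_of_ratios_centers_at_one(self, rng):
        ca, cb = self.make_groups(rng)
        sf = size_factors(pd.concat([ca, cb], axis=1))
        assert np.abs(np.log(sf)).max() < 0.5

    def test_planted_fourfold_recovery(self, rng):
        # DE genes must be a minority or median-of-ratios normalization
        # (correctly) absorbs the shift as a depth difference
        ca_de, cb_de = self.make_groups(rng, n_genes=20, mean_b_factor=4.0)
        ca_null, cb_null = self.make_groups(rng, n_genes=180)
        ca = pd.concat([ca_de, ca_null.set_axis([f"n{i}" for i in range(180)])])
        cb = pd.concat([cb_de, cb_null.set_axis([f"n{i}" for i in range(180)])])
        de = deg_flags(differential_expression(ca, cb))
        planted = de.loc[ca_de.index]
        assert planted["is_deg"].mean() >= 0.9
        # median-of-ratios slightly shrinks the fold change when DE genes
        # are asymmetric; the recovered median stays near the planted 2
        assert 1.5 < planted["log2FC"].median() < 2.5

    def test_null_false_positive_control(self, rng):
        ca, cb = self.make_groups(rng, n_genes=500)
        de = deg_flags(differential_expression(ca, cb))
        assert de["is_deg"].mean() <= 0.02

    def test_all_zero_gene_excluded(self, rng):
        ca, cb = self.make_groups(rng, n_genes=10)
        ca.iloc[0] = 0
        cb.iloc[0] = 0
        de = differential_expression(ca, cb)
        assert de["excluded"].iloc[0] and not de["excluded"].iloc[1:].any()

    def test_single_replicate_rejected(self, rng):
        ca, cb = self.make_groups(rng)
        with pytest.raises(ValueError):
            differential_expression(ca[["a0"]], cb)


class TestAllelicStatus:
    @pytest.mark.parametrize(
        "fraction,n,expected",
        [
            (0.02, 100, "paternal"),
            (0.5, 100, "biallelic"),
            (0.97, 100, "maternal"),
            (0.22, 100, "not_evaluable"),  # between the mono and biallelic bands
            (0.5, 5, "not_evaluable"),  # below the informative-read floor
        ],
    )
    def test_band_logic(self, fraction, n, expected):
        assert call_allelic_status(fraction, n) == expected

    def test_monoallelic_simulation_calls_paternal(self):
        rng = np.random.default_rng(0)
        n = 50
        calls = [
            call_allelic_status(rng.binomial(n, 0.05) / n, n) for _ in range(500)
        ]
        assert calls.count("paternal") / len(calls) >= 0.99


class TestLoi:
    def test_expression_route(self):
        assert call_loi("paternal", "biallelic")
        assert call_loi("maternal", "biallelic")
        assert not call_loi("biallelic", "biallelic")
        assert not call_loi("paternal", "paternal")
        assert not call_loi("not_evaluable", "biallelic")

    def test_methylation_bias_route(self):
        assert call_loi("not_evaluable", "not_evaluable", meth_bias_control=0.8, meth_bias_test=0.05)
        assert not call_loi("not_evaluable", "not_evaluable", meth_bias_control=0.8, meth_bias_test=0.6)
        assert not call_loi("not_evaluable", "not_evaluable", meth_bias_control=0.1, meth_bias_test=0.0)

    def test_no_false_loi_when_fractions_share_distribution(self, rng):
        """LOI must not fire when control and test allelic fractions are
        drawn from the same (monoallelic) distribution."""
        n = 100
        false_calls = 0
        for _ in range(300):
            fc = rng.binomial(n, 0.05) / n
            ft = rng.binomial(n, 0.05) / n
            if call_loi(call_allelic_status(fc, n), call_allelic_status(ft, n)):
                false_calls += 1
        assert false_calls == 0


GENE_MODELS = pd.DataFrame(
    {
        "gene_id": ["imp1", "imp2", "imp3", "bg1"],
        "chrom": ["chr1"] * 4,
        "start": [1_000, 20_000, 40_000, 60_000],
        "end": [3_000, 22_000, 42_000, 62_000],
        "strand": ["+"] * 4,
        "exon_starts": ["1000", "20000", "40000", "60000"],
        "exon_ends": ["3000", "22000", "42000", "62000"],
    }
)


class TestCascade:
    def fpkm(self, values):
        return pd.Series(values, index=GENE_MODELS["gene_id"])

    def test_empty_imprint_list_empty_stages(self):
        res = candidate_cascade([], self.fpkm([5, 5, 5, 5]), self.fpkm([5, 5, 5, 5]), [], GENE_MODELS)
        assert not (res.stage1 | res.stage2 | res.stage3)

    def test_low_fpkm_excluded_at_stage1(self):
        res = candidate_cascade(
            ["imp1", "imp2"], self.fpkm([0.5, 5, 5, 5]), self.fpkm([9, 5, 5, 5]), [], GENE_MODELS
        )
        assert res.stage1 == {"imp2"}

    def test_stage_nesting_and_truth_recovery(self):
        # imp1: DMR-associated + 4-fold change -> stage 3
        # imp2: DMR-associated, no fold change -> stage 2 only
        # imp3: expressed, no DMR -> stage 1 only
        dmrs = [DMR("chr1", 1_500, 2_500, 30, 30, -0.4), DMR("chr1", 20_500, 21_500, 30, 30, -0.3)]
        res = candidate_cascade(
            ["imp1", "imp2", "imp3"],
            self.fpkm([10, 10, 10, 10]),
            self.fpkm([41, 11, 11, 11]),
            dmrs,
            GENE_MODELS,
            params=CascadeParams(dmr_window_bp=2_000),
        )
        assert res.stage3 <= res.stage2 <= res.stage1
        assert res.stage1 == {"imp1", "imp2", "imp3"}
        assert res.stage2 == {"imp1", "imp2"}
        assert res.stage3 == {"imp1"}
        assert res.calls["imp1"].stage == "fold_change_aberrant"

    def test_deg_route_intersects_imprint_list(self):
        dmrs = [DMR("chr1", 1_500, 2_500, 30, 30, -0.4)]
        de = pd.DataFrame(
            {
                "baseMean": [100.0, 100.0, 100.0, 100.0],
                "log2FC": [2.5, 0.1, 0.1, 3.0],
                "p_value": [1e-5, 0.5, 0.9, 1e-6],
                "dispersion": 0.1,
                "excluded": False,
            },
            index=GENE_MODELS["gene_id"],
        )
        res = candidate_cascade(
            ["imp1", "imp2"], self.fpkm([10] * 4), self.fpkm([12] * 4), dmrs, GENE_MODELS,
            de_results=de, params=CascadeParams(dmr_window_bp=2_000),
        )
        # bg1 is a DEG but not an imprint candidate; imp1 is DEG + DMR-assoc
        assert res.deg_route == {"imp1"}
        assert res.calls["imp1"].stage == "de_imprinted"

    def test_annotate_loi_combines_fractions(self):
        dmrs = [DMR("chr1", 1_500, 2_500, 30, 30, -0.4)]
        res = candidate_cascade(
            ["imp1"], self.fpkm([10] * 4), self.fpkm([45] * 4), dmrs, GENE_MODELS,
            params=CascadeParams(dmr_window_bp=2_000),
        )
        frac = pd.DataFrame(
            {"gene_id": ["imp1"], "n_maternal": [2], "n_paternal": [98], "maternal_fraction": [0.02], "evaluable": [True]}
        )
        frac_test = pd.DataFrame(
            {"gene_id": ["imp1"], "n_maternal": [51], "n_paternal": [49], "maternal_fraction": [0.51], "evaluable": [True]}
        )
        annotate_loi(res, frac, frac_test, AllelicBands())
        call = res.calls["imp1"]
        assert call.allelic_control == "paternal"
        assert call.allelic_test == "biallelic"
        assert call.loi


def test_packaged_imprint_list_structure():
    table = packaged_imprint_list()
    assert {"gene", "status", "expressed_allele"} <= set(table.columns)
    assert table["gene"].is_unique and len(table) >= 20
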