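"""Driver annotation, TMB, frequency matrix, integrative caller."""

import math

import numpy as np
import pandas as pd
import pytest

from hccsvr.driver_catalog import (annotate_drivers, call_expression_cnv_aberrations,
                                   compute_tmb, gene_copy_number, load_catalogue,
                                   mutation_frequency_matrix, oncoprint_matrix,
                                   round_half_up)


def variants_of(pairs):
    """(sample, gene) pairs -> minimal variant table."""
    return pd.DataFrame([{"sample": s, "gene": g, "chrom": "1", "pos": i + 1,
                          "ref": "C", "alt": "T", "variant_type": "SNV",
                          "effect": "missense"}
                         for i, (s, g) in enumerate(pairs)])


class TestCatalogueAndAnnotation:
    def test_packaged_catalogue_roles(self, catalogue):
        roles = catalogue.set_index("gene")["role"]
        assert roles["TP53"] == "TSG"
        assert roles["CTNNB1"] == "ONCOGENE"
        assert roles["ARID2"] == "TSG"
        assert roles["PREX2"] == "ONCOGENE"
        assert roles["KEAP1"] == "TSG"
        assert len(catalogue) >= 90

    def test_annotation_flags(self, catalogue):
        var = variants_of([("s1", "TP53"), ("s1", "NOT_A_GENE")])
        out = annotate_drivers(var, catalogue)
        assert out["is_driver"].tolist() == [True, False]
        assert out["driver_role"].tolist() == ["TSG", "NONE"]

    def test_empty_catalogue_zero_drivers(self):
        var = variants_of([("s1", "TP53")])
        empty = pd.DataFrame({"gene": [], "role": [], "source": []})
        assert annotate_drivers(var, empty)["is_driver"].sum() == 0


class TestTmb:
    def test_arithmetic_with_default_footprint(self):
        var = variants_of([("s1", f"G{i}") for i in range(348)])
        tmb = compute_tmb(var, 34.8)
        assert math.isclose(tmb["s1"], 10.0)

    def test_zero_mutations_and_bad_footprint(self):
        assert compute_tmb(pd.DataFrame(columns=["sample"])).empty
        with pytest.raises(ValueError):
            compute_tmb(variants_of([("s", "g")]), 0.0)


class TestFrequencyMatrix:
    def _clinical(self, n_pos=34, n_svr=35):
        samples = [f"p{i}" for i in range(n_pos)] + [f"v{i}" for i in range(n_svr)]
        return pd.DataFrame({"sample": samples,
                             "group": ["POS"] * n_pos + ["SVR"] * n_svr})

    def test_printed_percentages_from_cohort_margins(self):
        """The published frequency layer: 4/35=11.4%, 1/35=2.9%, 1/34=2.9%."""
        clin = self._clinical()
        pairs = ([(f"v{i}", "PREX2") for i in range(4)]
                 + [("v9", "ARID2")]
                 + [("p0", "PREX2")]
                 + [(f"p{i}", "ARID2") for i in range(6)])
        freq = mutation_frequency_matrix(variants_of(pairs), clin).set_index("gene")
        assert freq.loc["PREX2", "pct_SVR"] == 11.4
        assert freq.loc["PREX2", "pct_POS"] == 2.9
        assert freq.loc["ARID2", "pct_SVR"] == 2.9
        # 6/34 = 17.647...% -> 17.6 under half-up rounding at one decimal
        assert math.isclose(freq.loc["ARID2", "frac_POS"], 6 / 34)
        assert freq.loc["ARID2", "pct_POS"] == 17.6

    def test_sample_counts_once_per_gene(self):
        clin = self._clinical(2, 2)
        pairs = [("p0", "TP53"), ("p0", "TP53"), ("p1", "TP53")]
        freq = mutation_frequency_matrix(variants_of(pairs), clin).set_index("gene")
        assert freq.loc["TP53", "mut_POS"] == 2

    def test_recount_oracle_equality(self, small_bundle, catalogue):
        annotated = annotate_drivers(small_bundle.variants, catalogue)
        drivers = annotated[annotated["is_driver"]]
        freq = mutation_frequency_matrix(drivers, small_bundle.clinical)
        groups = small_bundle.clinical.set_index("sample")["group"]
        for _, row in freq.iterrows():
            for grp in groups.unique():
                direct = drivers.loc[
                    (drivers["gene"] == row["gene"])
                    & (drivers["sample"].map(groups) == grp), "sample"].nunique()
                assert row[f"mut_{grp}"] == direct
                assert row[f"mut_{grp}"] <= row[f"n_{grp}"]

    def test_missing_group_rejected(self):
        clin = self._clinical(1, 1)
        with pytest.raises(ValueError):
            mutation_frequency_matrix(variants_of([("zz", "TP53")]), clin)

    def test_zero_of_n_is_zero(self):
        freq = mutation_frequency_matrix(
            variants_of([("p0", "TP53")]), self._clinical(2, 2), genes=["TP53", "ARID2"])
        row = freq.set_index("gene").loc["ARID2"]
        assert row["pct_POS"] == 0.0 and row["pct_SVR"] == 0.0


def test_round_half_up_convention():
    assert round_half_up(11.42857 * 10 / 10, 1) == 11.4
    assert round_half_up(2.85, 1) == 2.9      # banker's rounding would give 2.8
    assert round_half_up(17.647058, 1) == 17.6
    assert round_half_up(0.05, 1) == 0.1


class TestIntegrativeCaller:
    def _inputs(self, fold, cn, role="ONCOGENE", gene="MYC"):
        tumor = pd.DataFrame({"s1": [math.log2(fold) + 5.0]}, index=[gene])
        normal = pd.DataFrame({"s1": [5.0]}, index=[gene])
        copy = pd.DataFrame({"s1": [cn]}, index=[gene])
        cat = pd.DataFrame({"gene": [gene], "role": [role], "source": ["x"]})
        return tumor, normal, copy, cat

    @pytest.mark.parametrize("fold,cn,expected", [
        (5.0, 2.5, 1),    # both boundaries inclusive
        (4.99, 2.5, 0),
        (5.0, 2.49, 0),
        (6.0, 2.0, 0),    # copy-number condition fails
        (100.0, 10.0, 1),
    ])
    def test_amplification_boundaries(self, fold, cn, expected):
        ab, _ = call_expression_cnv_aberrations(*self._inputs(fold, cn))
        assert len(ab) == expected
        if expected:
            assert ab.iloc[0]["call"] == "AMPLIFIED"

    @pytest.mark.parametrize("fold,cn,expected", [
        (0.2, 1.5, 1),    # five-fold decrease at the boundary
        (0.21, 1.5, 0),
        (0.2, 1.51, 0),
        (0.05, 1.0, 1),
    ])
    def test_deletion_boundaries(self, fold, cn, expected):
        ab, _ = call_expression_cnv_aberrations(
            *self._inputs(fold, cn, role="TSG", gene="RB1"))
        assert len(ab) == expected
        if expected:
            assert ab.iloc[0]["call"] == "DELETED"

    def test_role_gating(self):
        # a TSG with amplification-like numbers is not called
        ab, _ = call_expression_cnv_aberrations(*self._inputs(10.0, 3.0, role="TSG"))
        assert ab.empty

    def test_planted_recall_and_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(20)]
        cat = pd.DataFrame({"gene": genes,
                            "role": ["ONCOGENE" if i % 2 else "TSG" for i in range(20)],
                            "source": "x"})
        samples = [f"s{i}" for i in range(6)]
        normal = pd.DataFrame(5.0, index=genes, columns=samples)
        tumor = normal.copy()
        copy = pd.DataFrame(2.0, index=genes, columns=samples)
        planted = {("g1", "s0"): "AMPLIFIED", ("g3", "s2"): "AMPLIFIED",
                   ("g0", "s1"): "DELETED"}
        for (g, s), call in planted.items():
            if call == "AMPLIFIED":
                tumor.at[g, s] += 3.0   # 8-fold
                copy.at[g, s] = 3.0
            else:
                tumor.at[g, s] -= 3.0
                copy.at[g, s] = 1.2
        # a near-miss failing one threshold each
        tumor.at["g5", "s3"] += 3.0; copy.at["g5", "s3"] = 2.0     # CN too low
        tumor.at["g7", "s4"] += 1.0; copy.at["g7", "s4"] = 3.0     # fold too low
        ab, _ = call_expression_cnv_aberrations(tumor, normal, copy, cat)
        got = {(r["gene"], r["sample"]): r["call"] for _, r in ab.iterrows()}
        assert got == planted
        # permuting gene and sample order changes nothing
        perm = list(rng.permutation(genes))
        ab2, _ = call_expression_cnv_aberrations(
            tumor.loc[perm, ::-1], normal.loc[perm, ::-1], copy.loc[perm, ::-1], cat)
        got2 = {(r["gene"], r["sample"]): r["call"] for _, r in ab2.iterrows()}
        assert got2 == planted

    def test_missing_normal_skipped_with_warning(self):
        tumor, normal, copy, cat = self._inputs(10.0, 3.0)
        tumor["s2"] = 9.0
        copy["s2"] = 3.0
        with pytest.warns(UserWarning):
            ab, _ = call_expression_cnv_aberrations(tumor, normal, copy, cat)
        assert set(ab["sample"]) == {"s1"}

    def test_shortlist_rules(self):
        genes = ["gA", "gB", "gC"]
        cat = pd.DataFrame({"gene": genes, "role": "ONCOGENE", "source": "x"})
        samples = [f"d{i}" for i in range(8)] + [f"i{i}" for i in range(24)]
        clinical = pd.DataFrame({"sample": samples,
                                 "group": ["SVR_DAA"] * 8 + ["SVR_IFN"] * 24})
        normal = pd.DataFrame(5.0, index=genes, columns=samples)
        tumor = normal.copy()
        copy = pd.DataFrame(2.0, index=genes, columns=samples)
        # gA amplified in 6 IFN samples (recurrent >= 6, Fisher not small)
        for s in [f"i{i}" for i in range(6)]:
            tumor.at["gA", s] += 3.0; copy.at["gA", s] = 3.0
        # gB amplified in 4 of 8 DAA, none of IFN (Fisher p < 0.1)
        for s in [f"d{i}" for i in range(4)]:
            tumor.at["gB", s] += 3.0; copy.at["gB", s] = 3.0
        ab, shortlist = call_expression_cnv_aberrations(
            tumor, normal, copy, cat, clinical, ("SVR_DAA", "SVR_IFN"))
        listed = shortlist.set_index("gene")
        assert "gA" in listed.index and "recurrent" in listed.loc["gA", "reason"]
        assert "gB" in listed.index and "fisher" in listed.loc["gB", "reason"]
        assert "gC" not in listed.index


def test_gene_copy_number_midpoint_rule():
    coords = pd.DataFrame({"gene": ["g1", "g2"], "chrom": ["1", "1"],
                           "start": [100, 1000], "end": [199, 1099]})
    segments = pd.DataFrame({
        "sample": ["s1"] * 3,
        "chrom": ["1"] * 3,
        "start": [1, 140, 900], "end": [149, 500, 2000],
        "n_snvs": 10, "copy_number": [1.0, 3.0, 2.8],
        "p_value": 1e-5, "log2_mbaf_adj": 0.0,
    })
    cn = gene_copy_number(segments, coords)
    # g1 midpoint 149 lies in both [1,149] and [140,500]; earlier segment wins
    assert cn.loc["g1", "s1"] == 1.0
    assert cn.loc["g2", "s1"] == 2.8


def test_oncoprint_codes():
    drivers = variants_of([("s1", "TP53"), ("s2", "CTNNB1")])
    drivers["is_driver"] = True
    ab = pd.DataFrame([{"sample": "s1", "gene": "MYC", "role": "ONCOGENE",
                        "fold_change": 8.0, "copy_number": 3.0, "call": "AMPLIFIED"}])
    mat = oncoprint_matrix(drivers, ab, ["s1", "s2"])
    assert mat.loc["TP53", "s1"] == "missense"
    assert mat.loc["MYC", "s1"] == "AMP"
    assert mat.loc["TP53", "s2"] == ""
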