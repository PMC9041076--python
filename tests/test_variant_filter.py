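"""The ten-criterion filter against an independent rule-by-rule oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from hccsvr.variant_filter import (FilterThresholds, VariantCandidate,
                                   apply_filters, filter_cohort, mapq0_fisher)


def clean_variant(**overrides) -> VariantCandidate:
    base = dict(
        chrom="1", pos=1000, ref="C", alt="T", variant_type="SNV",
        quality_score=100.0, depth=120.0, vaf_tumor=30.0, vaf_normal=0.5,
        var_reads_fwd=10, var_reads_rev=12, avg_clipped_length=110.0,
        avg_pos_as_fraction=0.5, ref_mapq0=0, ref_mapq1=100,
        var_mapq0=0, var_mapq1=22, avg_read_len_ref=180.0, avg_read_len_var=175.0,
    )
    base.update(overrides)
    return VariantCandidate(**base)


def oracle_verdict(v: VariantCandidate, th: FilterThresholds) -> set[int]:
    """Independent re-statement of the ten elimination rules."""
    failed = set()
    snv = v.variant_type == "SNV"
    if v.quality_score < 50:
        failed.add(1)
    if v.depth < (20 if snv else 50):
        failed.add(2)
    if v.vaf_normal > (2.5 if snv else 0.0):
        failed.add(3)
    if not (v.var_reads_fwd > 0 and v.var_reads_rev > 0):
        failed.add(4)
    if v.avg_clipped_length < 90:
        failed.add(5)
    if v.avg_pos_as_fraction < 0.05:
        failed.add(6)
    if v.var_mapq0 > 0 and v.var_mapq1 / v.var_mapq0 < 0.8:
        failed.add(7)
    if abs(v.avg_read_len_ref - v.avg_read_len_var) > 80:
        failed.add(8)
    _, p = fisher_exact([[v.var_mapq0, v.var_mapq1], [v.ref_mapq0, v.ref_mapq1]],
                        alternative="greater")
    if p < 0.1:
        failed.add(9)
    if (v.chrom, v.pos, v.ref, v.alt) in th.blacklist:
        failed.add(10)
    return failed


class TestSingleCriteria:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            ({"quality_score": 49.0}, [1]),
            ({"variant_type": "INS", "depth": 49.0, "vaf_normal": 0.0}, [2]),
            ({"depth": 49.0}, []),  # depth 49 passes for SNVs
            ({"vaf_normal": 3.0}, [3]),
            ({"var_reads_rev": 0}, [4]),
            ({"avg_clipped_length": 89.0}, [5]),
            ({"avg_pos_as_fraction": 0.04}, [6]),
            ({"var_mapq0": 10, "var_mapq1": 5, "ref_mapq0": 80, "ref_mapq1": 40}, [7]),
            ({"avg_read_len_var": 99.0}, [8]),
            ({"var_mapq0": 5, "var_mapq1": 5, "ref_mapq0": 0, "ref_mapq1": 100}, [9]),
        ],
    )
    def test_each_rule_fires_alone(self, overrides, expected):
        verdict = apply_filters(clean_variant(**overrides))
        assert verdict.failed_criteria == expected
        assert verdict.passed == (not expected)

    def test_boundary_values_survive(self):
        """Strict inequalities: a variant sitting exactly on every cut-off passes."""
        v = clean_variant(
            quality_score=50.0, depth=20.0, vaf_normal=2.5,
            var_reads_fwd=3, var_reads_rev=3, avg_clipped_length=90.0,
            avg_pos_as_fraction=0.05, var_mapq0=5, var_mapq1=4,
            avg_read_len_ref=180.0, avg_read_len_var=100.0,
            ref_mapq0=50, ref_mapq1=40,
        )
        # mapq ratio 4/5 = 0.8 exactly; read-length diff exactly 80
        verdict = apply_filters(v)
        assert verdict.passed, verdict.failed_criteria

    def test_blacklist_membership(self):
        th = FilterThresholds(blacklist={("1", 1000, "C", "T")})
        assert apply_filters(clean_variant(), th).failed_criteria == [10]

    def test_missing_metric_is_named(self):
        v = clean_variant()
        v.depth = None
        with pytest.raises(ValueError, match="depth"):
            apply_filters(v)

    def test_unknown_variant_type(self):
        with pytest.raises(ValueError, match="variant_type"):
            apply_filters(clean_variant(variant_type="SV"))


class TestMapq0Fisher:
    def test_no_mapq0_variant_reads_gives_p_one(self):
        assert mapq0_fisher(3, 100, 0, 20) == 1.0

    def test_closed_form_extreme_table(self):
        # all 5 variant reads MAPQ0, all 10 reference reads MAPQ>=1:
        # p = 1 / C(15,5) = 1/3003
        p = mapq0_fisher(0, 10, 5, 0)
        assert math.isclose(p, 1.0 / 3003.0, rel_tol=0, abs_tol=1e-12)

    def test_balanced_table_not_enriched(self):
        assert mapq0_fisher(5, 5, 5, 5) > 0.1

    def test_all_zero_table_warns(self):
        with pytest.warns(UserWarning):
            assert mapq0_fisher(0, 0, 0, 0) == 1.0


def random_variant(rng: np.random.Generator) -> VariantCandidate:
    """Adversarial draws concentrated around the thresholds."""
    snv = rng.random() < 0.7
    return clean_variant(
        variant_type="SNV" if snv else ("INS" if rng.random() < 0.5 else "DEL"),
        quality_score=float(rng.uniform(30, 70)),
        depth=float(rng.uniform(5, 80)),
        vaf_normal=float(rng.uniform(0, 5)) if snv else float(rng.choice([0.0, 0.0, 0.5])),
        var_reads_fwd=int(rng.integers(0, 6)),
        var_reads_rev=int(rng.integers(0, 6)),
        avg_clipped_length=float(rng.uniform(70, 110)),
        avg_pos_as_fraction=float(rng.uniform(0, 0.15)),
        ref_mapq0=int(rng.integers(0, 10)),
        ref_mapq1=int(rng.integers(0, 60)),
        var_mapq0=int(rng.integers(0, 10)),
        var_mapq1=int(rng.integers(0, 15)),
        avg_read_len_ref=float(rng.uniform(100, 220)),
        avg_read_len_var=float(rng.uniform(100, 220)),
    )


def test_oracle_equivalence_on_random_variants(rng):
    """Verdicts on 1,200 randomized variants match the independent oracle."""
    th = FilterThresholds(blacklist={("1", 1000, "C", "T")} if rng.random() < 2 else set())
    for _ in range(1200):
        v = random_variant(rng)
        got = set(apply_filters(v, th).failed_criteria)
        assert got == oracle_verdict(v, th)


def test_relaxing_a_threshold_never_removes_passers(rng):
    """Monotonicity: loosening any single cut-off keeps passing variants passing."""
    relaxed = [
        FilterThresholds(min_quality=40),
        FilterThresholds(min_depth_snv=10, min_depth_indel=40),
        FilterThresholds(max_normal_vaf_snv=5.0, max_normal_vaf_indel=1.0),
        FilterThresholds(min_clipped_length=80),
        FilterThresholds(min_pos_fraction=0.01),
        FilterThresholds(min_mapq_ratio=0.5),
        FilterThresholds(max_len_diff=120),
        FilterThresholds(mapq0_fisher_alpha=0.01),
    ]
    strict = FilterThresholds()
    for _ in range(300):
        v = random_variant(rng)
        if apply_filters(v, strict).passed:
            for th in relaxed:
                assert apply_filters(v, th).passed


class TestFilterCohort:
    def test_empty_table(self):
        filtered, report = filter_cohort(pd.DataFrame())
        assert filtered.empty and report.empty

    def test_counts_conserve_and_attribution(self, small_bundle):
        filtered, report = filter_cohort(small_bundle.variants)
        assert report["n_input"].sum() == len(small_bundle.variants)
        assert report["n_kept"].sum() == len(filtered)
        # every variant may fail several criteria
        per_crit = report[[f"removed_c{i}" for i in range(1, 11)]].to_numpy().sum()
        assert per_crit >= report["n_removed"].sum()

    def test_sensitivity_and_specificity_against_truth(self, small_bundle):
        filtered, _ = filter_cohort(small_bundle.variants)
        kept = set(map(tuple, filtered[["sample", "chrom", "pos", "ref", "alt"]].values))
        truth = small_bundle.truth
        keys = truth[["sample", "chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
        is_kept = keys.isin(kept)
        somatic = truth["label"] == "somatic"
        assert (is_kept[somatic]).all()        # no true somatic call lost
        assert (~is_kept[~somatic]).all()      # every artifact removed

    def test_artifacts_attributed_to_injected_criterion(self, small_bundle):
        """Each artifact violates exactly the criterion it was built to violate."""
        variants, truth = small_bundle.variants, small_bundle.truth
        artifacts = truth[truth["label"] == "artifact"]
        for idx, t in artifacts.iterrows():
            row = variants.loc[idx]
            verdict = apply_filters(
                VariantCandidate(
                    chrom=str(row["chrom"]), pos=int(row["pos"]), ref=row["ref"],
                    alt=row["alt"], variant_type=row["variant_type"],
                    **{f: row[f] for f in (
                        "quality_score", "depth", "vaf_normal", "var_reads_fwd",
                        "var_reads_rev", "avg_clipped_length", "avg_pos_as_fraction",
                        "ref_mapq0", "ref_mapq1", "var_mapq0", "var_mapq1",
                        "avg_read_len_ref", "avg_read_len_var")},
                ))
            assert verdict.failed_criteria == [int(t["violated_criterion"])]
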