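"""Generator contracts: determinism, label bookkeeping, planted effects."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from hccsvr.cohortsim import (CohortConfig, default_gene_sets, gene_coordinates,
                              gene_universe, plant_expression_effect,
                              simulate_cohort, simulate_expression_only,
                              solve_latent_loading, write_bundle)
from hccsvr.exprsig import normalize_75th, score_signature


def _dir_checksums(path: Path) -> dict[str, str]:
    return {str(p.relative_to(path)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.rglob("*")) if p.is_file()}


class TestConfig:
    def test_default_strata(self):
        cfg = CohortConfig()
        assert cfg.stratum_sizes == {"HCV_POSITIVE": 34, "SVR_DAA": 8,
                                     "SVR_IFN": 24, "SVR_OTHER": 3}
        assert sum(cfg.stratum_sizes.values()) == 69

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_hcv_positive=-1)
        with pytest.raises(ValueError):
            CohortConfig(n_hcv_positive=0, n_svr_daa=0, n_svr_ifn=0, n_svr_other=0)
        with pytest.raises(ValueError):
            CohortConfig(signature_mixture={"Signature.1": 0.5})


class TestCohortStructure:
    def test_default_cohort_sizes(self, default_bundle):
        counts = default_bundle.clinical["group"].value_counts()
        assert len(default_bundle.clinical) == 69
        assert counts["HCV_POSITIVE"] == 34 and counts["SVR_DAA"] == 8
        assert counts["SVR_IFN"] == 24 and counts["SVR_OTHER"] == 3

    def test_planted_driver_margins(self, default_bundle):
        """Driver carriers per group equal round(prevalence x n)."""
        som = default_bundle.truth["label"].values == "somatic"
        var = default_bundle.variants[som]
        groups = default_bundle.clinical.set_index("sample")["group"]

        def carriers_of(gene):
            s = var.loc[var["gene"] == gene, "sample"].drop_duplicates()
            return s.map(groups).value_counts().to_dict()

        arid2 = carriers_of("ARID2")
        assert arid2.get("HCV_POSITIVE", 0) == 6
        assert arid2.get("SVR_DAA", 0) == 0 and arid2.get("SVR_IFN", 0) == 1
        prex2 = carriers_of("PREX2")
        assert prex2.get("HCV_POSITIVE", 0) == 1
        assert prex2.get("SVR_DAA", 0) == 1 and prex2.get("SVR_IFN", 0) == 3
        tp53 = carriers_of("TP53")
        assert tp53.get("SVR_DAA", 0) == 5 and tp53.get("SVR_IFN", 0) == 5

    def test_artifact_bookkeeping(self, default_bundle):
        truth = default_bundle.truth
        assert len(truth) == len(default_bundle.variants)
        artifacts = truth[truth["label"] == "artifact"]
        assert (artifacts["violated_criterion"].between(1, 9)).all()
        assert (truth.loc[truth["label"] == "somatic", "violated_criterion"] == 0).all()

    def test_zero_artifact_rate(self):
        cfg = CohortConfig(n_hcv_positive=3, n_svr_daa=2, n_svr_ifn=2, n_svr_other=0,
                           artifact_rate=0.0, n_true_variants=10.0, seed=5)
        bundle = simulate_cohort(cfg)
        assert (bundle.truth["label"] == "somatic").all()


class TestDeterminism:
    def test_same_seed_identical_checksums(self, tmp_path):
        cfg = dict(n_hcv_positive=4, n_svr_daa=2, n_svr_ifn=3, n_svr_other=0,
                   n_true_variants=15.0, artifact_rate=5.0)
        b1 = simulate_cohort(CohortConfig(seed=11, **cfg))
        b2 = simulate_cohort(CohortConfig(seed=11, **cfg))
        write_bundle(b1, tmp_path / "a")
        write_bundle(b2, tmp_path / "b")
        assert _dir_checksums(tmp_path / "a") == _dir_checksums(tmp_path / "b")

    def test_different_seed_different_variants(self):
        cfg = dict(n_hcv_positive=4, n_svr_daa=2, n_svr_ifn=3, n_svr_other=0,
                   n_true_variants=15.0, artifact_rate=5.0)
        b1 = simulate_cohort(CohortConfig(seed=11, **cfg))
        b2 = simulate_cohort(CohortConfig(seed=12, **cfg))
        assert not b1.variants["pos"].equals(b2.variants["pos"])


class TestExpressionPlanting:
    def test_zero_shift_is_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"),
                         columns=[f"s{i}" for i in range(4)])
        out = plant_expression_effect(m, ["a", "b"], ["s0"], 0.0)
        assert out.equals(m)

    def test_single_cell_shift(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"),
                         columns=[f"s{i}" for i in range(4)])
        out = plant_expression_effect(m, ["c"], ["s2"], 2.0)
        assert out.at["c", "s2"] == pytest.approx(m.at["c", "s2"] + 2.0)
        out.at["c", "s2"] = m.at["c", "s2"]
        assert out.equals(m)

    def test_unknown_genes_listed(self, rng):
        m = pd.DataFrame(rng.normal(size=(2, 2)), index=["a", "b"], columns=["x", "y"])
        with pytest.raises(ValueError, match="zz"):
            plant_expression_effect(m, ["a", "zz"], ["x"], 1.0)

    def test_effect_fidelity_within_three_se(self):
        """Planted +1 shift on the TP53-inactivation set is recovered to 3 SE."""
        cfg = CohortConfig(seed=21)
        raw, meta = simulate_expression_only(cfg)
        norm = normalize_75th(raw)
        sets = default_gene_sets()
        meta = meta.set_index("sample")
        tumors = meta[meta["tissue"] == "TUMOR"]
        scores, _ = score_signature(norm[tumors.index], sets["TP53_INACTIVATION"])
        daa = scores[tumors["group"] == "SVR_DAA"]
        ifn = scores[tumors["group"] == "SVR_IFN"]
        # score variance: latent loading^2 + noise/4 per sample
        sd = math.sqrt(daa.var(ddof=1) / len(daa) + ifn.var(ddof=1) / len(ifn))
        assert abs((daa.mean() - ifn.mean()) - 1.0) <= 3 * sd

    def test_downstream_score_difference_positive(self):
        cfg = CohortConfig(seed=22)
        raw, meta = simulate_expression_only(cfg)
        norm = normalize_75th(raw)
        meta = meta.set_index("sample")
        tumors = meta[meta["tissue"] == "TUMOR"]
        scores, _ = score_signature(norm[tumors.index],
                                    default_gene_sets()["TP53_INACTIVATION"])
        assert scores[tumors["group"] == "SVR_DAA"].mean() > \
            scores[tumors["group"] == "SVR_IFN"].mean()

    def test_immune_suppression_in_svr_normal_liver(self):
        raw, meta = simulate_expression_only(CohortConfig(seed=23))
        norm = normalize_75th(raw)
        meta = meta.set_index("sample")
        normals = meta[meta["tissue"] == "NORMAL"]
        scores, _ = score_signature(norm[normals.index],
                                    default_gene_sets()["CYTOLYTIC_ACTIVITY"])
        svr = scores[normals["group"].isin(["SVR_DAA", "SVR_IFN", "SVR_OTHER"])]
        pos = scores[normals["group"] == "HCV_POSITIVE"]
        assert svr.mean() < pos.mean() - 0.5


def test_latent_loading_solver():
    a = solve_latent_loading(0.9, 0.2, 0.08)
    corr = a * a / math.sqrt((a * a + 0.04) * (a * a + 0.0064))
    assert corr == pytest.approx(0.9, abs=1e-9)


def test_gene_universe_and_coordinates(catalogue):
    genes = gene_universe(catalogue)
    assert len(genes) == 2000
    assert len(set(genes)) == 2000
    sets = default_gene_sets()
    for members in sets.values():
        assert set(members) <= set(genes)
    coords = gene_coordinates(genes)
    assert (coords["start"] <= coords["end"]).all()
    assert set(coords["chrom"]) <= {str(c) for c in range(1, 23)}
    # genes on the same chromosome do not overlap
    for _, grp in coords.groupby("chrom"):
        g = grp.sort_values("start")
        assert (g["start"].values[1:] > g["end"].values[:-1]).all()
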