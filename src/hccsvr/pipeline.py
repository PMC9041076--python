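"""Configuration-driven orchestration: simulate -> filter -> drivers ->
signatures -> CNV -> expression -> statistics, with a consolidated report.

Each stage writes its tables before the next reads them; the run is
fully determined by the seed, and ``report.json`` records per-file
SHA-256 checksums so reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .cohortsim import CohortBundle, CohortConfig, simulate_cohort, write_bundle
from .cnv import classify_segments, compare_cnv_burden
from .cohort_stats import (classify_ihc, compare_frequencies,
                           ihc_mutation_concordance, km_logrank, mann_whitney)
from .driver_catalog import (annotate_drivers, call_expression_cnv_aberrations,
                             compute_tmb, gene_copy_number, load_catalogue,
                             mutation_frequency_matrix, oncoprint_matrix)
from .exprsig import (correlate_scores, linkage_to_newick, normalize_75th,
                      score_signature, tp53_inactivation_score, volcano,
                      ward_cluster)
from .mutsig import compare_signature_profiles, decompose_cohort, load_reference_signatures
from .variant_filter import FilterThresholds, filter_cohort

SVR_GROUPS = ("SVR_DAA", "SVR_IFN", "SVR_OTHER")


@dataclass
class RunConfig:
    """Paths, thresholds and options for one pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 1
    cohort: CohortConfig | None = None      # None -> defaults with `seed`
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    tmb_footprint_mb: float = 34.8
    weight_floor: float = 0.06
    genes_of_interest: tuple = ("ARID2", "PREX2", "KEAP1", "TP53", "CTNNB1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        thresholds = raw.pop("thresholds", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if cohort:
            cfg.cohort = CohortConfig(**cohort)
        if thresholds:
            cfg.thresholds = FilterThresholds(**thresholds)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a synthetic cohort; return the report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "sections": {}}

    # --- stage 1: cohort ---------------------------------------------------
    cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
    bundle = simulate_cohort(cohort_cfg)
    input_dir = out / "input"
    write_bundle(bundle, input_dir)
    clinical = bundle.clinical
    groups = clinical.set_index("sample")["group"]
    report["sections"]["cohort"] = {
        "n_tumors": int(len(clinical)),
        "strata": clinical["group"].value_counts().to_dict(),
    }

    # --- stage 2: variant filtering ----------------------------------------
    filtered, filt_report = filter_cohort(bundle.variants, config.thresholds)
    _write_tsv(filtered, out / "variants_filtered.tsv")
    _write_tsv(filt_report, out / "filter_report.tsv")
    truth = bundle.truth
    kept_keys = set(map(tuple, filtered[["sample", "chrom", "pos", "ref", "alt"]].values))
    truth_keys = truth[["sample", "chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
    is_kept = truth_keys.isin(kept_keys)
    is_somatic = truth["label"] == "somatic"
    tp = int((is_kept & is_somatic).sum())
    fn = int((~is_kept & is_somatic).sum())
    tn = int((~is_kept & ~is_somatic).sum())
    fp = int((is_kept & ~is_somatic).sum())
    report["sections"]["filter"] = {
        "n_candidates": int(len(bundle.variants)),
        "n_kept": int(len(filtered)),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
    }

    # --- stage 3: drivers, TMB, frequencies --------------------------------
    catalogue = load_catalogue()
    annotated = annotate_drivers(filtered, catalogue)
    drivers = annotated[annotated["is_driver"]]
    tmb = compute_tmb(filtered, config.tmb_footprint_mb)
    tmb.to_frame().reset_index().to_csv(out / "tmb.tsv", sep="\t", index=False,
                                        lineterminator="\n", float_format="%.6g")
    clin2 = clinical.copy()
    clin2["group2"] = np.where(clinical["group"].isin(SVR_GROUPS), "HCV_SVR", "HCV_POSITIVE")
    freq2 = mutation_frequency_matrix(
        drivers, clin2.rename(columns={"group": "group4", "group2": "group"}),
        genes=list(config.genes_of_interest))
    _write_tsv(freq2, out / "driver_frequency_hcv_vs_svr.tsv")
    freq4 = mutation_frequency_matrix(drivers, clinical, genes=list(config.genes_of_interest))
    _write_tsv(freq4, out / "driver_frequency_by_stratum.tsv")

    tests = []
    for _, row in freq2.iterrows():
        res = compare_frequencies(row["mut_HCV_SVR"], row["n_HCV_SVR"],
                                  row["mut_HCV_POSITIVE"], row["n_HCV_POSITIVE"])
        tests.append({"gene": row["gene"], "contrast": "SVR_vs_positive",
                      "test": res.test, "p": res.p,
                      "p_chi2": res.p_chi2, "p_fisher": res.p_fisher})
    for _, row in freq4.iterrows():
        res = compare_frequencies(row["mut_SVR_DAA"], row["n_SVR_DAA"],
                                  row["mut_SVR_IFN"], row["n_SVR_IFN"])
        tests.append({"gene": row["gene"], "contrast": "DAA_vs_IFN",
                      "test": res.test, "p": res.p,
                      "p_chi2": res.p_chi2, "p_fisher": res.p_fisher})
    _write_tsv(pd.DataFrame(tests), out / "driver_frequency_tests.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, tmb_p = mann_whitney(tmb.reindex(clin2.loc[clin2["group2"] == "HCV_POSITIVE", "sample"]).dropna(),
                                tmb.reindex(clin2.loc[clin2["group2"] == "HCV_SVR", "sample"]).dropna())
    report["sections"]["drivers"] = {
        "n_driver_mutations": int(len(drivers)),
        "median_tmb": float(tmb.median()),
        "tmb_positive_vs_svr_p": float(tmb_p),
    }

    # --- stage 4: mutational signatures ------------------------------------
    signatures = load_reference_signatures()
    exposures = decompose_cohort(filtered, signatures, config.weight_floor)
    exposures.reset_index().to_csv(out / "signature_exposures.tsv", sep="\t",
                                   index=False, lineterminator="\n", float_format="%.6g")
    sig_cmp = compare_signature_profiles(
        exposures, clin2.rename(columns={"group": "group4", "group2": "group"})[["sample", "group"]],
        ("HCV_POSITIVE", "HCV_SVR"))
    _write_tsv(sig_cmp, out / "signature_group_comparison.tsv")
    report["sections"]["mutsig"] = {
        "n_samples": int(len(exposures)),
        "mean_reconstruction_weight": float(exposures.sum(axis=1).mean()),
    }

    # --- stage 5: CNV -------------------------------------------------------
    calls = classify_segments(bundle.segments)
    _write_tsv(calls, out / "cnv_calls.tsv")
    counts, burden = compare_cnv_burden(calls, clinical, ("SVR_DAA", "SVR_IFN"))
    counts.reset_index().rename(columns={"index": "sample"}).to_csv(
        out / "cnv_burden_per_sample.tsv", sep="\t", index=False, lineterminator="\n")
    _write_tsv(burden, out / "cnv_burden_tests.tsv")
    del_p = float(burden.loc[burden["call"] == "LOSS", "p"].iloc[0])
    report["sections"]["cnv"] = {
        "n_segments": int(len(calls)),
        "n_non_neutral": int((calls["call"] != "NEUTRAL").sum()),
        "deletion_burden_daa_vs_ifn_p": del_p,
    }

    # --- stage 6: expression ------------------------------------------------
    norm = normalize_75th(bundle.expression_raw)
    meta = bundle.expression_meta.set_index("sample")
    tumor_cols = meta.index[meta["tissue"] == "TUMOR"]
    normal_cols = meta.index[meta["tissue"] == "NORMAL"]
    tumor = norm[tumor_cols]
    scores = {}
    for name, members in bundle.gene_sets.items():
        s, cov = score_signature(tumor, members, name=name)
        scores[name] = s
    score_df = pd.DataFrame(scores)
    score_df.insert(0, "group", meta.loc[score_df.index, "group"])
    score_df.reset_index().rename(columns={"index": "sample"}).to_csv(
        out / "signature_scores.tsv", sep="\t", index=False,
        lineterminator="\n", float_format="%.6g")

    tp53 = tp53_inactivation_score(tumor)
    patient_of = meta["patient_id"]
    grp_of = score_df["group"]
    daa = tp53[grp_of.reindex(tp53.index) == "SVR_DAA"]
    ifn = tp53[grp_of.reindex(tp53.index) == "SVR_IFN"]
    _, tp53_p = mann_whitney(daa.values, ifn.values)
    rho_cin, p_cin = correlate_scores(tp53, score_df["CIN_SIGNATURE"])
    rho_pi3k, p_pi3k = correlate_scores(tp53, score_df["PI3K_MTOR_CMAP_UP"])

    svr_tumors = [c for c in tumor_cols if groups.get(patient_of[c]) in ("SVR_DAA", "SVR_IFN")]
    mask = pd.Series({c: meta.loc[c, "group"] == "SVR_DAA" for c in svr_tumors})
    volc = volcano(tumor[svr_tumors], mask)
    _write_tsv(volc, out / "volcano_daa_vs_ifn.tsv")
    skp2_rank = int(volc.index[volc["gene"] == "SKP2"][0]) + 1 if (volc["gene"] == "SKP2").any() else -1

    Z, _ = ward_cluster(tumor)
    (out / "tumor_dendrogram.nwk").write_text(linkage_to_newick(Z, tumor.columns) + "\n")

    report["sections"]["expression"] = {
        "tp53_score_daa_vs_ifn_p": float(tp53_p),
        "tp53_cin_spearman_rho": float(rho_cin),
        "tp53_cin_spearman_p": float(p_cin),
        "tp53_pi3k_spearman_rho": float(rho_pi3k),
        "volcano_top_gene": str(volc.iloc[0]["gene"]),
        "skp2_rank": skp2_rank,
    }

    # --- stage 6b: integrative expression x CNV -----------------------------
    tumor_by_patient = tumor.rename(columns=patient_of.to_dict())
    normal_by_patient = norm[normal_cols].rename(columns=patient_of.to_dict())
    gene_cn = gene_copy_number(
        bundle.segments, bundle.gene_coords[bundle.gene_coords["gene"].isin(catalogue["gene"])])
    aberrations, shortlist = call_expression_cnv_aberrations(
        tumor_by_patient, normal_by_patient, gene_cn, catalogue,
        clinical, ("SVR_DAA", "SVR_IFN"))
    _write_tsv(aberrations, out / "expression_cnv_aberrations.tsv")
    _write_tsv(shortlist, out / "aberration_shortlist.tsv")
    onco = oncoprint_matrix(drivers, aberrations, clinical["sample"])
    onco.reset_index().rename(columns={"index": "gene"}).to_csv(
        out / "oncoprint.tsv", sep="\t", index=False, lineterminator="\n")
    report["sections"]["integrative"] = {
        "n_amplified": int((aberrations["call"] == "AMPLIFIED").sum()),
        "n_deleted": int((aberrations["call"] == "DELETED").sum()),
        "n_shortlisted": int(len(shortlist)),
    }

    # --- stage 7: clinical statistics ---------------------------------------
    ihc_calls = pd.Series(
        {r["sample"]: classify_ihc(r["ihc_p53_percent"], r["ihc_any_reaction"])
         for _, r in clinical.iterrows()})
    tp53_mut = pd.Series(
        {s: bool((drivers["gene"] == "TP53")[drivers["sample"] == s].any())
         for s in clinical["sample"]})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conc = ihc_mutation_concordance(ihc_calls, tp53_mut)
    aberrant_counts = {
        grp: int(sum(ihc_calls[s].aberrant for s in clinical.loc[clinical["group"] == grp, "sample"]))
        for grp in ("SVR_DAA", "SVR_IFN")
    }
    ihc_daa_ifn = compare_frequencies(
        aberrant_counts["SVR_DAA"], int((clinical["group"] == "SVR_DAA").sum()),
        aberrant_counts["SVR_IFN"], int((clinical["group"] == "SVR_IFN").sum()))
    curves, os_p = km_logrank(clin2["os_months"], clin2["os_event"], clin2["group2"])
    _write_tsv(curves, out / "km_os_curves.tsv")
    _, rfs_p = km_logrank(clin2["rfs_months"], clin2["rfs_event"], clin2["group2"])
    report["sections"]["stats"] = {
        "ihc_mutation_concordance_p": float(conc.p),
        "ihc_aberrant_daa_vs_ifn_p": float(ihc_daa_ifn.p),
        "os_logrank_p": float(os_p),
        "rfs_logrank_p": float(rfs_p),
    }

    # --- checksums -----------------------------------------------------------
    checksums = {p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()}
    checksums["tumor_dendrogram.nwk"] = _sha256(out / "tumor_dendrogram.nwk")
    for p in sorted((input_dir).rglob("*")):
        if p.is_file():
            checksums[str(p.relative_to(out))] = _sha256(p)
    report["checksums"] = checksums
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
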