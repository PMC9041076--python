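"""Expression layer: normalization, signature scores, TP53-inactivation
contrast, score correlations, volcano, clustering, integrative caller.

Scores every packaged gene set on 75th-percentile-normalized tumor
expression, contrasts the four-gene TP53-inactivation score between
SVR-DAA and SVR-IFN tumors, correlates it with the chromosomal-
instability and PI3K/mTOR scores, runs the DAA-vs-IFN volcano, and
calls integrative expression x copy-number amplifications/deletions.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hccsvr import io as hio
from hccsvr.cohort_stats import mann_whitney
from hccsvr.driver_catalog import (call_expression_cnv_aberrations,
                                   gene_copy_number, load_catalogue)
from hccsvr.exprsig import (correlate_scores, linkage_to_newick, normalize_75th,
                            score_signature, tp53_inactivation_score, volcano,
                            ward_cluster)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    raw = hio.read_expression_tsv(ROOT / "cohort" / "expression.tsv")
    meta = pd.read_csv(ROOT / "cohort" / "expression_meta.tsv", sep="\t",
                       index_col="sample")
    clinical = hio.read_clinical_csv(ROOT / "cohort" / "clinical.csv")
    gene_sets = hio.read_gmt(ROOT / "cohort" / "gene_sets.gmt")
    segments = hio.read_seg(ROOT / "cohort" / "segments.seg.tsv")
    coords = pd.read_csv(ROOT / "cohort" / "gene_coords.tsv", sep="\t",
                         dtype={"chrom": str})
    catalogue = load_catalogue()

    norm = normalize_75th(raw)
    tumor = norm[meta.index[meta["tissue"] == "TUMOR"]]
    normal = norm[meta.index[meta["tissue"] == "NORMAL"]]
    out = ROOT / "expression"
    out.mkdir(parents=True, exist_ok=True)

    scores = {name: score_signature(tumor, members, name=name)[0]
              for name, members in gene_sets.items()}
    score_df = pd.DataFrame(scores)
    score_df.insert(0, "group", meta.loc[score_df.index, "group"])
    score_df.reset_index(names="sample").to_csv(
        out / "scores.tsv", sep="\t", index=False, lineterminator="\n",
        float_format="%.6g")

    tp53 = tp53_inactivation_score(tumor)
    grp = score_df["group"]
    _, p = mann_whitney(tp53[grp == "SVR_DAA"].values, tp53[grp == "SVR_IFN"].values)
    print(f"TP53-inactivation score, DAA vs IFN tumors: Mann-Whitney p = {p:.4f}")

    rho, p_rho = correlate_scores(tp53, score_df["CIN_SIGNATURE"])
    print(f"TP53-inactivation x CIN: Spearman rho = {rho:.3f} (p = {p_rho:.2e})")
    rho2, p2 = correlate_scores(tp53, score_df["PI3K_MTOR_CMAP_UP"])
    print(f"TP53-inactivation x PI3K/mTOR: Spearman rho = {rho2:.3f} (p = {p2:.2e})")

    svr = meta.index[(meta["tissue"] == "TUMOR")
                     & meta["group"].isin(["SVR_DAA", "SVR_IFN"])]
    mask = pd.Series(meta.loc[svr, "group"] == "SVR_DAA", index=svr)
    volc = volcano(tumor[svr], mask)
    volc.to_csv(out / "volcano_daa_vs_ifn.tsv", sep="\t", index=False,
                lineterminator="\n", float_format="%.6g")
    skp2 = volc[volc["gene"] == "SKP2"].iloc[0]
    rank = int(volc.index[volc["gene"] == "SKP2"][0]) + 1
    print(f"SKP2 in DAA-vs-IFN volcano: log2FC = {skp2['log2_fc']:.2f}, "
          f"p = {skp2['p']:.2e} (rank {rank} of {len(volc)})")

    Z, _ = ward_cluster(tumor)
    (out / "tumor_dendrogram.nwk").write_text(linkage_to_newick(Z, tumor.columns) + "\n")

    patient_of = meta["patient_id"]
    gene_cn = gene_copy_number(segments, coords[coords["gene"].isin(catalogue["gene"])])
    ab, shortlist = call_expression_cnv_aberrations(
        tumor.rename(columns=patient_of.to_dict()),
        normal.rename(columns=patient_of.to_dict()),
        gene_cn, catalogue, clinical, ("SVR_DAA", "SVR_IFN"))
    ab.to_csv(out / "aberrations.tsv", sep="\t", index=False, lineterminator="\n",
              float_format="%.6g")
    shortlist.to_csv(out / "aberration_shortlist.tsv", sep="\t", index=False,
                     lineterminator="\n", float_format="%.6g")
    print(f"integrative caller: {(ab['call'] == 'AMPLIFIED').sum()} amplifications, "
          f"{(ab['call'] == 'DELETED').sum()} deletions; "
          f"{len(shortlist)} genes shortlisted")


if __name__ == "__main__":
    main()
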