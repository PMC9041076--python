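"""Driver-gene landscape: annotation, TMB, per-group mutation frequencies.

Compares driver mutation rates between HCV-positive and HCV-SVR tumors
and, within SVR, between the DAA and IFN strata (chi-squared without
continuity correction, Fisher's exact when expected counts are small).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hccsvr import io as hio
from hccsvr.cohort_stats import compare_frequencies
from hccsvr.driver_catalog import (annotate_drivers, compute_tmb, load_catalogue,
                                   mutation_frequency_matrix, oncoprint_matrix)

ROOT = Path(__file__).resolve().parents[1] / "results"
GENES = ["ARID2", "PREX2", "KEAP1", "TP53", "CTNNB1"]


def main() -> None:
    filtered = hio.read_variants_tsv(ROOT / "filtered" / "variants_filtered.tsv")
    clinical = hio.read_clinical_csv(ROOT / "cohort" / "clinical.csv")
    catalogue = load_catalogue()

    annotated = annotate_drivers(filtered, catalogue)
    drivers = annotated[annotated["is_driver"]]
    out = ROOT / "drivers"
    out.mkdir(parents=True, exist_ok=True)

    tmb = compute_tmb(filtered, footprint_mb=34.8)
    tmb.to_frame().reset_index().to_csv(out / "tmb.tsv", sep="\t", index=False,
                                        lineterminator="\n", float_format="%.4g")
    print(f"median TMB {tmb.median():.2f} mutations/Mb (34.8 Mb exonic footprint)")

    clin2 = clinical.copy()
    clin2["group"] = np.where(clinical["group"].str.startswith("SVR"),
                              "HCV_SVR", "HCV_POSITIVE")
    freq = mutation_frequency_matrix(drivers, clin2, genes=GENES)
    freq.to_csv(out / "frequency_hcv_vs_svr.tsv", sep="\t", index=False,
                lineterminator="\n", float_format="%.6g")
    print("\ngene  HCV-positive  HCV-SVR  p(chi2)  p(Fisher)")
    for _, row in freq.iterrows():
        res = compare_frequencies(int(row["mut_HCV_POSITIVE"]), int(row["n_HCV_POSITIVE"]),
                                  int(row["mut_HCV_SVR"]), int(row["n_HCV_SVR"]))
        print(f"{row['gene']:7s} {row['pct_HCV_POSITIVE']:5.1f}%   "
              f"{row['pct_HCV_SVR']:5.1f}%   {res.p_chi2:.3f}   {res.p_fisher:.3f}")

    freq4 = mutation_frequency_matrix(drivers, clinical, genes=GENES)
    freq4.to_csv(out / "frequency_by_stratum.tsv", sep="\t", index=False,
                 lineterminator="\n", float_format="%.6g")
    tp53 = freq4.set_index("gene").loc["TP53"]
    res = compare_frequencies(int(tp53["mut_SVR_DAA"]), int(tp53["n_SVR_DAA"]),
                              int(tp53["mut_SVR_IFN"]), int(tp53["n_SVR_IFN"]),
                              method="chi2")
    print(f"\nTP53 DAA {tp53['pct_SVR_DAA']}% vs IFN {tp53['pct_SVR_IFN']}%: "
          f"chi-squared p = {res.p:.3f}")

    onco = oncoprint_matrix(drivers, None, clinical["sample"])
    onco.reset_index().rename(columns={"index": "gene"}).to_csv(
        out / "oncoprint.tsv", sep="\t", index=False, lineterminator="\n")
    print(f"oncoprint matrix: {onco.shape[0]} genes x {onco.shape[1]} samples")


if __name__ == "__main__":
    main()
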