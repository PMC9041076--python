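"""Clinical statistics: p53 IHC classification and concordance, survival.

Classifies p53 immunostaining (mutant-pattern / null-type / wild-type),
tests its concordance with TP53 mutations and its DAA-vs-IFN contrast,
and estimates Kaplan-Meier overall/relapse-free survival with log-rank
tests between HCV-positive and HCV-SVR patients.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hccsvr import io as hio
from hccsvr.cohort_stats import (classify_ihc, compare_frequencies,
                                 ihc_mutation_concordance, km_logrank)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    clinical = hio.read_clinical_csv(ROOT / "cohort" / "clinical.csv")
    filtered = hio.read_variants_tsv(ROOT / "filtered" / "variants_filtered.tsv")
    out = ROOT / "stats"
    out.mkdir(parents=True, exist_ok=True)

    ihc = pd.Series({r["sample"]: classify_ihc(r["ihc_p53_percent"],
                                               r["ihc_any_reaction"])
                     for _, r in clinical.iterrows()})
    calls = pd.Series({s: c.call for s, c in ihc.items()}, name="ihc_call")
    calls.rename_axis("sample").reset_index().to_csv(
        out / "ihc_calls.tsv", sep="\t", index=False, lineterminator="\n")
    print("p53 IHC calls:", calls.value_counts().to_dict())

    tp53_mut = pd.Series({s: bool(((filtered["gene"] == "TP53")
                                   & (filtered["sample"] == s)).any())
                          for s in clinical["sample"]})
    conc = ihc_mutation_concordance(ihc, tp53_mut)
    print(f"aberrant p53 staining vs TP53 mutation: p = {conc.p:.4f} ({conc.test})")

    grp = clinical.set_index("sample")["group"]
    daa, ifn = grp[grp == "SVR_DAA"].index, grp[grp == "SVR_IFN"].index
    res = compare_frequencies(
        int(sum(ihc[s].aberrant for s in daa)), len(daa),
        int(sum(ihc[s].aberrant for s in ifn)), len(ifn))
    print(f"aberrant p53, DAA vs IFN: p = {res.p:.4f} ({res.test})")

    group2 = np.where(clinical["group"].str.startswith("SVR"),
                      "HCV_SVR", "HCV_POSITIVE")
    curves, p_os = km_logrank(clinical["os_months"], clinical["os_event"], group2)
    curves.to_csv(out / "km_os_curves.tsv", sep="\t", index=False,
                  lineterminator="\n", float_format="%.6g")
    _, p_rfs = km_logrank(clinical["rfs_months"], clinical["rfs_event"], group2)
    print(f"overall survival, HCV-positive vs SVR: log-rank p = {p_os:.3f}")
    print(f"relapse-free survival, HCV-positive vs SVR: log-rank p = {p_rfs:.3f}")


if __name__ == "__main__":
    main()
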