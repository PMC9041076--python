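"""Apply the ten-criterion somatic filter and audit it against truth labels.

Reads results/cohort/, writes results/filtered/ (passing variants plus a
per-sample removal report) and prints filter sensitivity/specificity
measured against the generator's per-variant labels.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hccsvr import io as hio
from hccsvr.variant_filter import FilterThresholds, filter_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    variants = hio.read_variants_tsv(ROOT / "cohort" / "variants.tsv")
    truth = pd.read_csv(ROOT / "cohort" / "truth_labels.tsv", sep="\t",
                        dtype={"chrom": str})
    filtered, report = filter_cohort(variants, FilterThresholds())

    out = ROOT / "filtered"
    out.mkdir(parents=True, exist_ok=True)
    hio.write_variants_tsv(filtered, out / "variants_filtered.tsv")
    report.to_csv(out / "filter_report.tsv", sep="\t", index=False, lineterminator="\n")

    kept = set(map(tuple, filtered[["sample", "chrom", "pos", "ref", "alt"]].values))
    keys = truth[["sample", "chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
    is_kept = keys.isin(kept)
    somatic = truth["label"] == "somatic"
    sens = (is_kept & somatic).sum() / somatic.sum()
    spec = (~is_kept & ~somatic).sum() / (~somatic).sum()
    print(f"kept {len(filtered)}/{len(variants)} candidates")
    print(f"sensitivity {sens:.4f}, specificity {spec:.4f} vs truth labels")
    removed = report[[f"removed_c{i}" for i in range(1, 11)]].sum()
    print("removals per criterion:", dict(removed[removed > 0].astype(int)))


if __name__ == "__main__":
    main()
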