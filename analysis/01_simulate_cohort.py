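"""Generate the synthetic study cohort (seed 1) and write every input table.

Emits, under results/cohort/: per-sample variant candidate tables (TSV +
minimal VCF), the raw expression matrix for 69 tumors and matched normal
liver, copy-number segment tables, the clinical covariate table, gene
sets, and per-variant truth labels.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hccsvr.cohortsim import CohortConfig, simulate_cohort, write_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = CohortConfig(seed=1)
    bundle = simulate_cohort(cfg)
    write_bundle(bundle, OUT)
    strata = bundle.clinical["group"].value_counts().to_dict()
    print(f"cohort: {len(bundle.clinical)} tumors, strata {strata}")
    labels = bundle.truth["label"].value_counts().to_dict()
    print(f"variant candidates: {len(bundle.variants)} "
          f"({labels.get('somatic', 0)} somatic, {labels.get('artifact', 0)} artifacts)")
    print(f"expression: {bundle.expression_raw.shape[0]} genes x "
          f"{bundle.expression_raw.shape[1]} samples; "
          f"segments: {len(bundle.segments)}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
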