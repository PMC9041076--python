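"""Ten-criterion somatic-mutation filter for tumor/normal exome calls.

Candidate somatic calls from a tumor/normal pair carry read-level QC
metrics (of the kind ``bam-readcount`` reports: clipped length, position
in read, mapping-quality class counts, read lengths).  A candidate is
eliminated when it fulfils at least one of ten criteria:

1.  quality score < 50
2.  depth of coverage < 20 (SNVs) / < 50 (indels)
3.  variant allele frequency in the matched control > 2.5% (SNVs) / > 0% (indels)
4.  variant reads observed on either forward or reverse strand but not both
5.  average clipped sequence length < 90
6.  variant located at the sequence end (avg_pos_as_fraction < 0.05)
7.  MAPQ1/MAPQ0 read ratio < 0.8 among variant-supporting reads
8.  difference between reference- and variant-read lengths > 80
9.  variant enriched in MAPQ0 reads (one-sided Fisher exact p < 0.1)
10. membership in a false-positive blacklist

All inequalities are strict exactly as written, so boundary values pass.
Every criterion is evaluated (no short-circuit) and each failure is
recorded, giving a per-variant audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "VariantCandidate",
    "FilterThresholds",
    "FilterVerdict",
    "apply_filters",
    "mapq0_fisher",
    "filter_cohort",
    "METRIC_FIELDS",
]

VARIANT_TYPES = ("SNV", "INS", "DEL")

#: metric fields every candidate must populate before filtering
METRIC_FIELDS = (
    "quality_score",
    "depth",
    "vaf_normal",
    "var_reads_fwd",
    "var_reads_rev",
    "avg_clipped_length",
    "avg_pos_as_fraction",
    "ref_mapq0",
    "ref_mapq1",
    "var_mapq0",
    "var_mapq1",
    "avg_read_len_ref",
    "avg_read_len_var",
)


@dataclass
class VariantCandidate:
    """One tumor/normal somatic candidate with read-level QC metrics.

    VAFs are percentages in [0, 100]; ``avg_pos_as_fraction`` is the mean
    relative position of the variant within its supporting reads, in
    [0, 1]; ``*_mapq0``/``*_mapq1`` count reads with mapping quality 0
    and >= 1 respectively.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    quality_score: float | None = None
    depth: float | None = None
    vaf_tumor: float | None = None
    vaf_normal: float | None = None
    var_reads_fwd: int | None = None
    var_reads_rev: int | None = None
    avg_clipped_length: float | None = None
    avg_pos_as_fraction: float | None = None
    ref_mapq0: int | None = None
    ref_mapq1: int | None = None
    var_mapq0: int | None = None
    var_mapq1: int | None = None
    avg_read_len_ref: float | None = None
    avg_read_len_var: float | None = None
    gene: str = ""
    effect: str = ""


@dataclass
class FilterThresholds:
    """Cut-offs for the ten elimination criteria (defaults as published)."""

    min_quality: float = 50.0
    min_depth_snv: float = 20.0
    min_depth_indel: float = 50.0
    max_normal_vaf_snv: float = 2.5  # percent
    max_normal_vaf_indel: float = 0.0
    min_clipped_length: float = 90.0
    min_pos_fraction: float = 0.05
    min_mapq_ratio: float = 0.8
    max_len_diff: float = 80.0
    mapq0_fisher_alpha: float = 0.1
    blacklist: set = field(default_factory=set)  # {(chrom, pos, ref, alt)}

    def __post_init__(self) -> None:
        if not 0.0 < self.mapq0_fisher_alpha < 1.0:
            raise ValueError("mapq0_fisher_alpha must lie in (0, 1)")


@dataclass
class FilterVerdict:
    passed: bool
    failed_criteria: list[int]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_criteria) == 0)


def mapq0_fisher(ref_mapq0: int, ref_mapq1: int, var_mapq0: int, var_mapq1: int) -> float:
    """One-sided Fisher exact p for MAPQ0 over-representation in variant reads.

    The 2x2 table has rows {reference reads, variant reads} and columns
    {MAPQ0, MAPQ>=1}.  Under the null, the variant reads are a uniform
    draw from all reads, so the variant-row MAPQ0 count is hypergeometric
    and the p-value is the upper tail P(X >= var_mapq0).
    """
    counts = (ref_mapq0, ref_mapq1, var_mapq0, var_mapq1)
    if any(c < 0 for c in counts):
        raise ValueError("read counts must be non-negative")
    total = sum(counts)
    if total == 0:
        warnings.warn("all-zero MAPQ table; returning p=1", stacklevel=2)
        return 1.0
    n_var = var_mapq0 + var_mapq1
    n_mapq0 = ref_mapq0 + var_mapq0
    # upper-tail survival at var_mapq0 - 1 gives P(X >= var_mapq0)
    return float(hypergeom.sf(var_mapq0 - 1, total, n_mapq0, n_var))


def _require(variant: VariantCandidate, fields: Iterable[str]) -> None:
    for name in fields:
        if getattr(variant, name) is None:
            raise ValueError(f"variant {variant.chrom}:{variant.pos} missing metric '{name}'")


def apply_filters(variant: VariantCandidate, thresholds: FilterThresholds | None = None) -> FilterVerdict:
    """Evaluate all ten elimination criteria; return the full failure set."""
    th = thresholds if thresholds is not None else FilterThresholds()
    if variant.variant_type not in VARIANT_TYPES:
        raise ValueError(f"unknown variant_type {variant.variant_type!r}")
    _require(variant, METRIC_FIELDS)
    is_snv = variant.variant_type == "SNV"

    failed: list[int] = []
    if variant.quality_score < th.min_quality:
        failed.append(1)
    min_depth = th.min_depth_snv if is_snv else th.min_depth_indel
    if variant.depth < min_depth:
        failed.append(2)
    max_nvaf = th.max_normal_vaf_snv if is_snv else th.max_normal_vaf_indel
    if variant.vaf_normal > max_nvaf:
        failed.append(3)
    if variant.var_reads_fwd == 0 or variant.var_reads_rev == 0:
        failed.append(4)
    if variant.avg_clipped_length < th.min_clipped_length:
        failed.append(5)
    if variant.avg_pos_as_fraction < th.min_pos_fraction:
        failed.append(6)
    # ratio undefined when no MAPQ0 variant reads: no MAPQ0 evidence, passes
    if variant.var_mapq0 > 0 and variant.var_mapq1 / variant.var_mapq0 < th.min_mapq_ratio:
        failed.append(7)
    if abs(variant.avg_read_len_ref - variant.avg_read_len_var) > th.max_len_diff:
        failed.append(8)
    p = mapq0_fisher(variant.ref_mapq0, variant.ref_mapq1, variant.var_mapq0, variant.var_mapq1)
    if p < th.mapq0_fisher_alpha:
        failed.append(9)
    if (variant.chrom, variant.pos, variant.ref, variant.alt) in th.blacklist:
        failed.append(10)
    return FilterVerdict(passed=not failed, failed_criteria=failed)


def _candidate_from_row(row: pd.Series) -> VariantCandidate:
    kwargs = {f: row[f] for f in METRIC_FIELDS if f in row}
    return VariantCandidate(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        variant_type=str(row["variant_type"]),
        vaf_tumor=row.get("vaf_tumor"),
        gene=str(row.get("gene", "")),
        effect=str(row.get("effect", "")),
        **kwargs,
    )


def filter_cohort(
    variants: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a cohort variant table (one row per candidate).

    Returns ``(filtered, report)``: ``filtered`` holds the passing rows,
    ``report`` a per-sample summary with kept/removed totals and a removal
    count per criterion.  A variant can fail several criteria, so the
    per-criterion counts may sum to more than the removed total.
    """
    th = thresholds if thresholds is not None else FilterThresholds()
    if variants.empty:
        report = pd.DataFrame(
            columns=["sample", "n_input", "n_kept", "n_removed"]
            + [f"removed_c{i}" for i in range(1, 11)]
        )
        return variants.copy(), report

    verdicts = [apply_filters(_candidate_from_row(row), th) for _, row in variants.iterrows()]
    passed = np.array([v.passed for v in verdicts])
    failed_lists = [v.failed_criteria for v in verdicts]

    annotated = variants.copy()
    annotated["passed"] = passed
    annotated["failed_criteria"] = [",".join(map(str, f)) for f in failed_lists]
    filtered = annotated[passed].drop(columns=["passed", "failed_criteria"]).reset_index(drop=True)

    rows = []
    sample_col = annotated["sample"] if "sample" in annotated else pd.Series(["all"] * len(annotated))
    for sample, grp in annotated.groupby(sample_col, sort=True):
        rec = {
            "sample": sample,
            "n_input": len(grp),
            "n_kept": int(grp["passed"].sum()),
            "n_removed": int((~grp["passed"]).sum()),
        }
        for i in range(1, 11):
            rec[f"removed_c{i}"] = int(
                grp["failed_criteria"].apply(lambda s, i=i: str(i) in s.split(",") if s else False).sum()
            )
        rows.append(rec)
    report = pd.DataFrame(rows)
    return filtered, report
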