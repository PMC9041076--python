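"""Cancer-gene catalogue, driver annotation, TMB, and the integrative
expression x copy-number aberration caller.

The catalogue maps gene symbols to roles (oncogene, tumor-suppressor,
other cancer gene).  Tumor mutation burden is passing somatic mutations
per megabase of sequenced footprint (default 34.8 Mb, the exonic
footprint of the exome design; the full amplicon footprint of 57.7 Mb is
available as an alternative denominator).  The integrative caller flags

* AMPLIFIED: oncogene with >= 5-fold expression increase over the
  matched normal and copy number >= 2.5
* DELETED:   TSG with >= 5-fold decrease (fold change <= 0.2) and copy
  number <= 1.5

and shortlists genes whose event rate differs between two strata at
Fisher p < 0.1 or with events in >= 6 samples overall.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import compare_frequencies
from .io import read_catalogue_tsv

__all__ = [
    "load_catalogue",
    "annotate_drivers",
    "compute_tmb",
    "mutation_frequency_matrix",
    "gene_copy_number",
    "call_expression_cnv_aberrations",
    "oncoprint_matrix",
    "round_half_up",
]

EXON_FOOTPRINT_MB = 34.8
GENOME_FOOTPRINT_MB = 57.7

FOLD_AMP = 5.0
FOLD_DEL = 0.2
CN_AMP = 2.5
CN_DEL = 1.5
SHORTLIST_ALPHA = 0.1
SHORTLIST_MIN_EVENTS = 6


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_catalogue(path: str | Path | None = None) -> pd.DataFrame:
    """Load the cancer-gene catalogue TSV (gene, role, source).

    The packaged fixture is a ~100-gene editable list carrying the usual
    hepatocellular-carcinoma drivers with their roles; supply a path to
    use a fuller catalogue.
    """
    if path is None:
        ref = resources.files("hccsvr").joinpath("data", "cancer_gene_catalogue.tsv")
        with resources.as_file(ref) as p:
            df = read_catalogue_tsv(p)
    else:
        df = read_catalogue_tsv(path)
    if df["gene"].duplicated().any():
        raise ValueError("catalogue gene symbols must be unique")
    bad = set(df["role"]) - {"ONCOGENE", "TSG", "OTHER_CANCER_GENE"}
    if bad:
        raise ValueError(f"unknown catalogue roles: {sorted(bad)}")
    return df


def annotate_drivers(variants: pd.DataFrame, catalogue: pd.DataFrame) -> pd.DataFrame:
    """Flag variants whose gene is in the catalogue; attach the role."""
    roles = catalogue.set_index("gene")["role"]
    out = variants.copy()
    out["driver_role"] = out["gene"].map(roles).fillna("NONE")
    out["is_driver"] = out["driver_role"] != "NONE"
    return out


def compute_tmb(variants: pd.DataFrame, footprint_mb: float = EXON_FOOTPRINT_MB) -> pd.Series:
    """Per-sample tumor mutation burden (mutations per megabase)."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be positive")
    if variants.empty:
        return pd.Series(dtype=float, name="tmb")
    counts = variants.groupby("sample").size()
    return (counts / footprint_mb).rename("tmb")


def mutation_frequency_matrix(
    variants: pd.DataFrame, clinical: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Gene x group table of (mutated samples, group size, percent).

    A sample counts once per gene regardless of mutation multiplicity.
    Percentages are half-up rounded to one decimal in the ``pct_*``
    columns; the raw fraction is kept alongside.
    """
    groups = clinical.set_index("sample")["group"]
    missing = set(variants["sample"]) - set(groups.index)
    if missing:
        raise ValueError(f"variants from samples without a group: {sorted(missing)[:5]}")
    group_sizes = groups.value_counts()
    if genes is None:
        genes = sorted(variants["gene"].dropna().unique())
    pairs = variants[["sample", "gene"]].drop_duplicates()
    pairs = pairs[pairs["gene"].isin(genes)]
    pairs["group"] = pairs["sample"].map(groups)
    counts = pairs.groupby(["gene", "group"]).size()
    rows = []
    for gene in genes:
        rec: dict = {"gene": gene}
        for grp in sorted(group_sizes.index):
            n = int(group_sizes[grp])
            mutated = int(counts.get((gene, grp), 0))
            frac = mutated / n
            rec[f"mut_{grp}"] = mutated
            rec[f"n_{grp}"] = n
            rec[f"frac_{grp}"] = frac
            rec[f"pct_{grp}"] = round_half_up(100.0 * frac, 1)
        rows.append(rec)
    return pd.DataFrame(rows)


def gene_copy_number(
    segments: pd.DataFrame, gene_coords: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample, per-gene copy number from the segment containing the
    gene midpoint (ties at segment boundaries resolve to the earlier
    segment).  Genes not covered by any segment get CN 2 (neutral).

    ``gene_coords`` needs columns gene, chrom, start, end (1-based
    inclusive).  Returns a genes x samples DataFrame.
    """
    coords = gene_coords.copy()
    coords["mid"] = (coords["start"] + coords["end"]) // 2
    samples = sorted(segments["sample"].unique())
    cn = pd.DataFrame(2.0, index=coords["gene"], columns=samples)
    for sample, seg in segments.groupby("sample"):
        for chrom, segc in seg.groupby("chrom"):
            segc = segc.sort_values(["start", "end"], kind="mergesort")
            sub = coords[coords["chrom"] == chrom]
            for _, g in sub.iterrows():
                hit = segc[(segc["start"] <= g["mid"]) & (g["mid"] <= segc["end"])]
                if len(hit):
                    cn.loc[g["gene"], sample] = float(hit.iloc[0]["copy_number"])
    return cn


def call_expression_cnv_aberrations(
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    copy_number: pd.DataFrame,
    catalogue: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    grouping: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrative expression x copy-number aberration calls.

    ``tumor_expr`` and ``normal_expr`` are genes x samples log2 matrices
    with matching sample ids (matched normal per patient); fold change is
    ``2**(tumor - normal)``.  ``copy_number`` is genes x samples.
    Returns ``(aberrations, shortlist)``; the shortlist compares the two
    strata in ``grouping`` with Fisher's exact test on sample counts and
    also keeps genes with >= 6 events overall.
    """
    roles = catalogue.set_index("gene")["role"]
    genes = [g for g in roles.index if g in tumor_expr.index and g in copy_number.index]
    samples = [s for s in tumor_expr.columns if s in copy_number.columns]
    skipped = [s for s in samples if s not in normal_expr.columns]
    if skipped:
        warnings.warn(f"samples without matched normal skipped: {skipped[:5]}", stacklevel=2)
        samples = [s for s in samples if s not in skipped]

    records = []
    for gene in genes:
        role = roles[gene]
        for sample in samples:
            fc = float(2.0 ** (tumor_expr.at[gene, sample] - normal_expr.at[gene, sample]))
            cn = float(copy_number.at[gene, sample])
            call = "NONE"
            # inclusive thresholds, robust to one-ulp log2/exp2 round-trips
            eps = 1e-9
            if role == "ONCOGENE" and fc >= FOLD_AMP - eps and cn >= CN_AMP - eps:
                call = "AMPLIFIED"
            elif role == "TSG" and fc <= FOLD_DEL + eps and cn <= CN_DEL + eps:
                call = "DELETED"
            if call != "NONE":
                records.append({"sample": sample, "gene": gene, "role": role,
                                "fold_change": fc, "copy_number": cn, "call": call})
    aberrations = pd.DataFrame(records, columns=["sample", "gene", "role",
                                                 "fold_change", "copy_number", "call"])

    shortlist = pd.DataFrame(columns=["gene", "events_total", "p_fisher", "reason"])
    if clinical is not None and grouping is not None:
        ga, gb = grouping
        groups = clinical.set_index("sample")["group"]
        in_a = [s for s in samples if groups.get(s) == ga]
        in_b = [s for s in samples if groups.get(s) == gb]
        rows = []
        event_samples = aberrations.groupby("gene")["sample"].apply(set) if len(aberrations) else pd.Series(dtype=object)
        for gene in genes:
            ev = event_samples.get(gene, set())
            total = len(ev)
            res = compare_frequencies(
                len(ev & set(in_a)), max(len(in_a), 1),
                len(ev & set(in_b)), max(len(in_b), 1),
                method="fisher",
            )
            reasons = []
            if res.p_fisher < SHORTLIST_ALPHA:
                reasons.append("fisher")
            if total >= SHORTLIST_MIN_EVENTS:
                reasons.append("recurrent")
            if reasons:
                rows.append({"gene": gene, "events_total": total,
                             "p_fisher": res.p_fisher, "reason": "+".join(reasons)})
        shortlist = pd.DataFrame(rows, columns=["gene", "events_total", "p_fisher", "reason"])
    return aberrations, shortlist


def oncoprint_matrix(
    driver_variants: pd.DataFrame,
    aberrations: pd.DataFrame | None,
    samples,
) -> pd.DataFrame:
    """Plain-text oncoprint: genes x samples with mutation/AMP/DEL codes.

    Cell codes join mutation effects and CNV events with ';'
    (e.g. ``missense;AMP``); empty string means no event.
    """
    cells: dict[tuple[str, str], list[str]] = {}
    muts = driver_variants[driver_variants.get("is_driver", True) == True]  # noqa: E712
    for _, row in muts.iterrows():
        key = (row["gene"], row["sample"])
        cells.setdefault(key, []).append(str(row.get("effect", "mut")) or "mut")
    if aberrations is not None:
        for _, row in aberrations.iterrows():
            code = "AMP" if row["call"] == "AMPLIFIED" else "DEL"
            cells.setdefault((row["gene"], row["sample"]), []).append(code)
    genes = sorted({g for g, _ in cells})
    mat = pd.DataFrame("", index=genes, columns=list(samples))
    for (gene, sample), codes in cells.items():
        if sample in mat.columns:
            mat.at[gene, sample] = ";".join(sorted(set(codes)))
    return mat
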