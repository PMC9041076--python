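"""Seeded synthetic cohort generator.

Emulates the data of a surgical hepatocellular-carcinoma cohort with
four HCV strata — HCV-positive tumors and tumors resected after a
sustained virological response achieved with direct-acting antivirals
(SVR-DAA), interferon (SVR-IFN) or otherwise (SVR-other) — emitting
every input the analysis pipeline reads: per-sample somatic variant
candidate tables with read-level QC metrics (true somatic calls plus
sequencing artifacts that each violate a known filter criterion),
a genes x samples expression matrix for tumors and matched normal liver,
copy-number segment tables, a clinical covariate table, and gene-set
definitions.

The defaults encode the cohort structure the pipeline is meant to
detect: stratum sizes 34/8/24/3; driver-gene mutation counts fixed at
their configured per-group prevalences (so cohort frequencies are
deterministic margins, not binomial draws); a TP53-inactivation and
chromosomal-instability expression program elevated in SVR-DAA tumors
and driven by a shared latent factor; PI3K/mTOR and SKP2 up-shifts in
SVR-DAA tumors; immune/interferon signatures suppressed in SVR
non-tumorous liver; and an excess of copy-number deletions in SVR-DAA
tumors.  Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as hio
from .driver_catalog import load_catalogue, round_half_up
from .mutsig import BASES, CONTEXT_LABELS, load_reference_signatures
from .variant_filter import FilterThresholds, VariantCandidate, apply_filters

GROUPS = ("HCV_POSITIVE", "SVR_DAA", "SVR_IFN", "SVR_OTHER")
TISSUES = ("TUMOR", "NORMAL")

N_GENES = 2000
CHROMOSOMES = [str(c) for c in range(1, 23)]
CHROM_LENGTH = 10_000_000  # synthetic per-chromosome coordinate space
GENE_LENGTH = 20_000

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# gene universe and gene sets

def default_gene_sets() -> dict[str, list[str]]:
    """Packaged gene-set definitions.

    The TP53-inactivation set is the literature four-gene set (CDC20,
    PLK1, CENPA, KIF2C).  The remaining sets are synthetic placeholders
    with documented sizes (the PI3K/mTOR set carries 134 genes including
    SKP2); their members are clearly marked with a ``syn`` infix.
    """
    sets = {
        "TP53_INACTIVATION": ["CDC20", "PLK1", "CENPA", "KIF2C"],
        "CIN_SIGNATURE": [f"CINsyn{i:02d}" for i in range(1, 26)],
        "PI3K_MTOR_CMAP_UP": ["SKP2"] + [f"PIMTsyn{i:03d}" for i in range(1, 134)],
        "CYTOLYTIC_ACTIVITY": ["GZMA", "PRF1"],
        "B_CELL_SIGNATURE": ["CD19", "MS4A1", "CD79A", "CD79B", "BLK"],
        "CD8_T_CELL": ["CD8A", "CD8B", "GZMK"],
        "NK_CELL": ["NCR1", "KLRD1", "NKG7"],
        "IFN_ALPHA_RESPONSE": [f"IFNAsyn{i:02d}" for i in range(1, 21)],
        "IFN_GAMMA_RESPONSE": [f"IFNGsyn{i:02d}" for i in range(1, 21)],
        "WNT_CTNNB1_UP": [f"WNTsyn{i:02d}" for i in range(1, 16)],
    }
    return sets

IMMUNE_SETS = ("CYTOLYTIC_ACTIVITY", "B_CELL_SIGNATURE", "IFN_ALPHA_RESPONSE",
               "IFN_GAMMA_RESPONSE")


def gene_universe(catalogue: pd.DataFrame | None = None,
                  gene_sets: dict[str, list[str]] | None = None,
                  n_genes: int = N_GENES) -> list[str]:
    """Ordered ~``n_genes`` gene symbols: set members, catalogue, filler."""
    if catalogue is None:
        catalogue = load_catalogue()
    if gene_sets is None:
        gene_sets = default_gene_sets()
    genes: list[str] = []
    seen = set()
    for members in gene_sets.values():
        for g in members:
            if g not in seen:
                genes.append(g)
                seen.add(g)
    for g in catalogue["gene"]:
        if g not in seen:
            genes.append(g)
            seen.add(g)
    i = 1
    while len(genes) < n_genes:
        g = f"GENE{i:04d}"
        if g not in seen:
            genes.append(g)
            seen.add(g)
        i += 1
    return genes


def gene_coordinates(genes: list[str]) -> pd.DataFrame:
    """Deterministic tiling of genes over 22 synthetic chromosomes."""
    per_chrom = math.ceil(len(genes) / len(CHROMOSOMES))
    spacing = CHROM_LENGTH // (per_chrom + 1)
    rows = []
    for i, gene in enumerate(genes):
        chrom = CHROMOSOMES[i // per_chrom]
        slot = i % per_chrom
        start = (slot + 1) * spacing
        rows.append({"gene": gene, "chrom": chrom, "start": start,
                     "end": start + GENE_LENGTH - 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration

def _default_driver_prevalence() -> dict[str, dict[str, float]]:
    # per-group fraction of samples carrying a mutation; counts are fixed
    # to round(fraction * n), so the defaults reproduce the planted
    # margins 6/34 vs 1/35 (ARID2), 1/34 vs 4/35 (PREX2, KEAP1), and a
    # DAA-enriched TP53 rate (5/8 vs 5/24); CTNNB1 is a common driver in
    # all strata.
    return {
        "HCV_POSITIVE": {"ARID2": 6 / 34, "PREX2": 1 / 34, "KEAP1": 1 / 34,
                         "TP53": 12 / 34, "CTNNB1": 10 / 34},
        "SVR_DAA": {"ARID2": 0.0, "PREX2": 1 / 8, "KEAP1": 1 / 8,
                    "TP53": 5 / 8, "CTNNB1": 2 / 8},
        "SVR_IFN": {"ARID2": 1 / 24, "PREX2": 3 / 24, "KEAP1": 3 / 24,
                    "TP53": 5 / 24, "CTNNB1": 8 / 24},
        "SVR_OTHER": {"ARID2": 0.0, "PREX2": 0.0, "KEAP1": 0.0,
                      "TP53": 1 / 3, "CTNNB1": 1 / 3},
    }


@dataclass
class ExpressionEffect:
    """A planted log2 shift on a gene set (or single gene) in one stratum."""
    target: str         # gene-set name or a single gene symbol
    group: str          # one of GROUPS, or "SVR_ANY"
    tissue: str         # TUMOR or NORMAL
    shift_log2: float


def _default_expression_effects() -> list[ExpressionEffect]:
    effects = [
        ExpressionEffect("TP53_INACTIVATION", "SVR_DAA", "TUMOR", 1.0),
        ExpressionEffect("CIN_SIGNATURE", "SVR_DAA", "TUMOR", 0.8),
        ExpressionEffect("PI3K_MTOR_CMAP_UP", "SVR_DAA", "TUMOR", 0.8),
        ExpressionEffect("SKP2", "SVR_DAA", "TUMOR", 2.0),
    ]
    effects += [ExpressionEffect(s, "SVR_ANY", "NORMAL", -1.0) for s in IMMUNE_SETS]
    return effects


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_hcv_positive: int = 34
    n_svr_daa: int = 8
    n_svr_ifn: int = 24
    n_svr_other: int = 3
    driver_prevalence: dict = field(default_factory=_default_driver_prevalence)
    artifact_rate: float = 25.0          # expected artifact variants per sample
    n_true_variants: float = 80.0        # mean true somatic variants per sample
    indel_fraction: float = 0.1
    expression_effects: list = field(default_factory=_default_expression_effects)
    expression_noise_sd: float = 0.4     # gene-wise Gaussian noise, log2 units
    score_correlation: float = 0.9       # latent TP53-inactivation x CIN coupling
    cnv_deletion_rate: dict = field(default_factory=lambda: {
        "HCV_POSITIVE": 3.0, "SVR_DAA": 6.0, "SVR_IFN": 1.5, "SVR_OTHER": 2.0})
    cnv_gain_rate: dict = field(default_factory=lambda: {
        "HCV_POSITIVE": 2.5, "SVR_DAA": 2.0, "SVR_IFN": 2.0, "SVR_OTHER": 2.0})
    cnv_loh_rate: float = 1.0
    signature_mixture: dict = field(default_factory=lambda: {
        "Signature.1": 0.5, "Signature.5": 0.3, "Signature.16": 0.2})
    survival_rate_per_month: float = 0.0025   # ~86% five-year overall survival
    censoring_fraction: float = 0.6
    seed: int = 1

    def __post_init__(self) -> None:
        counts = (self.n_hcv_positive, self.n_svr_daa, self.n_svr_ifn, self.n_svr_other)
        if any(c < 0 for c in counts):
            raise ValueError("stratum sizes must be non-negative")
        if sum(counts) <= 0:
            raise ValueError("total cohort size must be positive")
        w = sum(self.signature_mixture.values())
        if not math.isclose(w, 1.0, abs_tol=1e-6):
            raise ValueError("signature_mixture weights must sum to 1")
        for grp, genes in self.driver_prevalence.items():
            for gene, f in genes.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"prevalence {grp}/{gene} outside [0,1]")

    @property
    def stratum_sizes(self) -> dict[str, int]:
        return {"HCV_POSITIVE": self.n_hcv_positive, "SVR_DAA": self.n_svr_daa,
                "SVR_IFN": self.n_svr_ifn, "SVR_OTHER": self.n_svr_other}


@dataclass
class CohortBundle:
    """Everything one synthetic run emits, as in-memory tables."""

    clinical: pd.DataFrame
    variants: pd.DataFrame          # combined MAF-like candidate table
    truth: pd.DataFrame             # per-variant label + violated criterion
    expression_raw: pd.DataFrame    # genes x samples, linear intensities
    expression_meta: pd.DataFrame   # sample, patient_id, tissue, group
    segments: pd.DataFrame          # SEG-like table
    gene_sets: dict
    gene_coords: pd.DataFrame
    config: CohortConfig


# ---------------------------------------------------------------------------
# helpers

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float, high: float) -> float:
    """Truncated normal by resampling (bounds are guaranteed)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(min(max(mean, low), high))


def _clean_metrics(rng: np.random.Generator, is_snv: bool) -> dict:
    """Metrics that pass all ten criteria with comfortable margin."""
    var_reads = int(rng.integers(4, 60))
    fwd = int(rng.integers(1, var_reads))  # both strands occupied
    depth = _trunc_normal(rng, 150, 60, 60 if is_snv else 80, 500)
    return {
        "quality_score": _trunc_normal(rng, 120, 40, 55, 400),
        "depth": round(depth, 1),
        "vaf_tumor": round(_trunc_normal(rng, 30, 15, 5, 95), 2),
        "vaf_normal": round(_trunc_normal(rng, 0.5, 0.6, 0.0, 2.0), 2) if is_snv else 0.0,
        "var_reads_fwd": fwd,
        "var_reads_rev": var_reads - fwd,
        "avg_clipped_length": round(_trunc_normal(rng, 115, 12, 92, 160), 1),
        "avg_pos_as_fraction": round(_trunc_normal(rng, 0.5, 0.15, 0.08, 0.92), 3),
        "ref_mapq0": int(rng.integers(0, 3)),
        "ref_mapq1": int(rng.integers(50, 200)),
        "var_mapq0": 0,
        "var_mapq1": int(rng.integers(10, 80)),
        "avg_read_len_ref": round(_trunc_normal(rng, 180, 15, 130, 250), 1),
        "avg_read_len_var": 0.0,  # set below relative to ref
    }


def _finish_clean(rng: np.random.Generator, m: dict) -> dict:
    m["avg_read_len_var"] = round(m["avg_read_len_ref"] + _trunc_normal(rng, 0, 20, -60, 60), 1)
    return m


def _violate(rng: np.random.Generator, m: dict, criterion: int, is_snv: bool) -> dict:
    """Perturb clean metrics so exactly the given criterion fails."""
    m = dict(m)
    if criterion == 1:
        m["quality_score"] = round(rng.uniform(5, 49.5), 1)
    elif criterion == 2:
        m["depth"] = round(rng.uniform(2, 19.5 if is_snv else 49.5), 1)
    elif criterion == 3:
        m["vaf_normal"] = round(rng.uniform(3.0, 20.0), 2) if is_snv else round(rng.uniform(0.5, 5.0), 2)
    elif criterion == 4:
        total = m["var_reads_fwd"] + m["var_reads_rev"]
        if rng.random() < 0.5:
            m["var_reads_fwd"], m["var_reads_rev"] = total, 0
        else:
            m["var_reads_fwd"], m["var_reads_rev"] = 0, total
    elif criterion == 5:
        m["avg_clipped_length"] = round(rng.uniform(30, 89.0), 1)
    elif criterion == 6:
        m["avg_pos_as_fraction"] = round(rng.uniform(0.0, 0.045), 3)
    elif criterion == 7:
        # low MAPQ1/MAPQ0 ratio among variant reads, but the reference
        # reads are equally MAPQ0-rich so the Fisher test stays quiet
        m["ref_mapq0"], m["ref_mapq1"] = 80, 40
        m["var_mapq0"], m["var_mapq1"] = 10, int(rng.integers(2, 8))
    elif criterion == 8:
        m["avg_read_len_var"] = round(m["avg_read_len_ref"] - rng.uniform(85, 140), 1)
    elif criterion == 9:
        # variant reads enriched in MAPQ0 while the ratio stays >= 0.8
        m["ref_mapq0"], m["ref_mapq1"] = 0, int(rng.integers(100, 200))
        k = int(rng.integers(5, 10))
        m["var_mapq0"], m["var_mapq1"] = k, k
    else:
        raise ValueError(f"cannot inject criterion {criterion}")
    return m


def _draw_context(rng: np.random.Generator, context_probs: np.ndarray) -> tuple[str, str, str, str]:
    """Draw a 96-class and decode (ref, alt, 5', 3'), with random strand."""
    idx = int(rng.choice(96, p=context_probs))
    label = CONTEXT_LABELS[idx]
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    if rng.random() < 0.5:  # emit the purine-strand representation
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return ref, alt, five, three


def _planted_counts(prevalence: dict, sizes: dict) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for grp, genes in prevalence.items():
        n = sizes.get(grp, 0)
        out[grp] = {g: int(round_half_up(f * n, 0)) for g, f in genes.items()}
    return out


def solve_latent_loading(rho: float, se_a: float, se_b: float) -> float:
    """Latent-factor loading giving score correlation ``rho``.

    Two scores share a unit-variance latent factor with loading ``a`` and
    carry independent noises ``se_a``, ``se_b``; their correlation is
    a^2 / sqrt((a^2+se_a^2)(a^2+se_b^2)) = rho, solved for ``a``.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0,1)")
    def f(a: float) -> float:
        a2 = a * a
        return a2 / math.sqrt((a2 + se_a ** 2) * (a2 + se_b ** 2)) - rho
    return float(brentq(f, 1e-6, 100.0))


# ---------------------------------------------------------------------------
# expression

def plant_expression_effect(matrix: pd.DataFrame, genes, sample_mask,
                            shift_log2: float) -> pd.DataFrame:
    """Add ``shift_log2`` to the given genes in the masked samples.

    ``sample_mask`` is a boolean Series over the matrix columns or a list
    of column names.  Unknown genes raise an error listing them.
    """
    genes = list(genes)
    unknown = [g for g in genes if g not in matrix.index]
    if unknown:
        raise ValueError(f"genes absent from matrix: {unknown}")
    if isinstance(sample_mask, pd.Series):
        cols = [c for c in matrix.columns if bool(sample_mask.get(c, False))]
    else:
        cols = [c for c in sample_mask if c in matrix.columns]
    out = matrix.copy()
    if shift_log2 != 0 and cols:
        out.loc[genes, cols] = out.loc[genes, cols] + shift_log2
    return out


def _simulate_expression(config: CohortConfig, clinical: pd.DataFrame,
                         genes: list[str], gene_sets: dict,
                         rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 mean matrix with planted effects + latent factor, then noise.

    Returns (log2 matrix, sample metadata).  The raw linear matrix
    emitted in the bundle is 2**log2.
    """
    meta_rows = []
    for _, rec in clinical.iterrows():
        for tissue, suffix in (("TUMOR", "T"), ("NORMAL", "N")):
            meta_rows.append({"sample": f"{rec['patient_id']}_{suffix}",
                              "patient_id": rec["patient_id"],
                              "tissue": tissue, "group": rec["group"]})
    meta = pd.DataFrame(meta_rows)
    columns = list(meta["sample"])

    baseline = rng.normal(7.0, 1.5, size=len(genes))
    mean = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(columns))), index=genes, columns=columns
    )

    # shared latent factor couples the TP53-inactivation and CIN programs
    sd = config.expression_noise_sd
    tp53_set = gene_sets["TP53_INACTIVATION"]
    cin_set = gene_sets["CIN_SIGNATURE"]
    loading = solve_latent_loading(
        config.score_correlation,
        sd / math.sqrt(len(tp53_set)), sd / math.sqrt(len(cin_set)))
    tumor_cols = meta.loc[meta["tissue"] == "TUMOR", "sample"]
    factors = rng.normal(0.0, 1.0, size=len(tumor_cols))
    for g_list in (tp53_set, cin_set):
        for col, f in zip(tumor_cols, factors):
            mean.loc[g_list, col] = mean.loc[g_list, col] + loading * f

    # the PI3K/mTOR program rides the same latent factor with a weaker
    # loading plus a private factor, giving the moderate (~0.7)
    # correlation with the TP53-inactivation score seen in such tumors
    pi3k_set = gene_sets.get("PI3K_MTOR_CMAP_UP")
    if pi3k_set:
        private = rng.normal(0.0, 1.0, size=len(tumor_cols))
        for col, f, g in zip(tumor_cols, factors, private):
            mean.loc[pi3k_set, col] = mean.loc[pi3k_set, col] + 0.22 * f + 0.18 * g

    # planted group effects
    for eff in config.expression_effects:
        genes_in = gene_sets.get(eff.target, [eff.target])
        if eff.group == "SVR_ANY":
            in_group = meta["group"].isin(("SVR_DAA", "SVR_IFN", "SVR_OTHER"))
        else:
            in_group = meta["group"] == eff.group
        cols = meta.loc[in_group & (meta["tissue"] == eff.tissue), "sample"].tolist()
        mean = plant_expression_effect(mean, genes_in, cols, eff.shift_log2)

    noise = rng.normal(0.0, sd, size=mean.shape)
    log2 = mean + noise
    return log2, meta


# ---------------------------------------------------------------------------
# variants

def _simulate_variants(config: CohortConfig, clinical: pd.DataFrame,
                       coords: pd.DataFrame, gene_sets: dict,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    signatures = load_reference_signatures()
    context_probs = np.zeros(96)
    for sig, w in config.signature_mixture.items():
        context_probs += w * signatures[sig].values
    context_probs /= context_probs.sum()

    planted = _planted_counts(config.driver_prevalence, config.stratum_sizes)
    driver_genes = sorted({g for genes in config.driver_prevalence.values() for g in genes})
    passenger_pool = [g for g in coords["gene"] if g not in driver_genes]
    coord_map = coords.set_index("gene")

    # assign planted driver mutations to specific patients per group
    carrier: dict[str, list[str]] = {}
    for grp in GROUPS:
        patients = clinical.loc[clinical["group"] == grp, "patient_id"].tolist()
        for gene, k in planted.get(grp, {}).items():
            if k == 0 or not patients:
                continue
            chosen = rng.choice(patients, size=min(k, len(patients)), replace=False)
            for p in chosen:
                carrier.setdefault(p, []).append(gene)

    thresholds = FilterThresholds()
    rows, truth_rows = [], []

    def emit(patient: str, gene: str, is_driver: bool) -> None:
        is_indel = (not is_driver) and rng.random() < config.indel_fraction
        g = coord_map.loc[gene]
        pos = int(rng.integers(g["start"], g["end"] + 1))
        if is_indel:
            vtype = "INS" if rng.random() < 0.5 else "DEL"
            base = BASES[rng.integers(0, 4)]
            ins = BASES[rng.integers(0, 4)]
            ref, alt = (base, base + ins) if vtype == "INS" else (base + ins, base)
            five = three = ""
        else:
            vtype = "SNV"
            ref, alt, five, three = _draw_context(rng, context_probs)
        m = _finish_clean(rng, _clean_metrics(rng, vtype == "SNV"))
        effect = "missense"
        if is_driver:
            effect = "nonsense" if rng.random() < 0.3 else "missense"
        elif is_indel:
            effect = "frameshift"
        rows.append({"sample": patient, "chrom": g["chrom"], "pos": pos,
                     "ref": ref, "alt": alt, "variant_type": vtype,
                     "gene": gene, "effect": effect,
                     "context_5p": five, "context_3p": three, **m})
        truth_rows.append({"sample": patient, "chrom": g["chrom"], "pos": pos,
                           "ref": ref, "alt": alt, "label": "somatic",
                           "violated_criterion": 0, "is_driver": is_driver})

    for _, rec in clinical.iterrows():
        patient = rec["patient_id"]
        for gene in carrier.get(patient, []):
            emit(patient, gene, True)
        n_true = int(rng.poisson(config.n_true_variants))
        for _ in range(n_true):
            gene = passenger_pool[int(rng.integers(0, len(passenger_pool)))]
            emit(patient, gene, False)
        # artifacts, each violating exactly one criterion (1..9)
        n_art = int(rng.poisson(config.artifact_rate))
        for _ in range(n_art):
            criterion = int(rng.integers(1, 10))
            gene = passenger_pool[int(rng.integers(0, len(passenger_pool)))]
            g = coord_map.loc[gene]
            pos = int(rng.integers(g["start"], g["end"] + 1))
            ref, alt, five, three = _draw_context(rng, context_probs)
            for _attempt in range(50):
                m = _violate(rng, _finish_clean(rng, _clean_metrics(rng, True)), criterion, True)
                verdict = apply_filters(VariantCandidate(
                    chrom=str(g["chrom"]), pos=pos, ref=ref, alt=alt,
                    variant_type="SNV", **m), thresholds)
                if verdict.failed_criteria == [criterion]:
                    break
            rows.append({"sample": patient, "chrom": g["chrom"], "pos": pos,
                         "ref": ref, "alt": alt, "variant_type": "SNV",
                         "gene": gene, "effect": "missense",
                         "context_5p": five, "context_3p": three, **m})
            truth_rows.append({"sample": patient, "chrom": g["chrom"], "pos": pos,
                               "ref": ref, "alt": alt, "label": "artifact",
                               "violated_criterion": criterion, "is_driver": False})

    variants = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return variants, truth


# ---------------------------------------------------------------------------
# CNV segments

def _simulate_segments(config: CohortConfig, clinical: pd.DataFrame,
                       coords: pd.DataFrame, catalogue: pd.DataFrame,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, list[dict]]:
    """SEG table plus the list of planted gene-level events (for the
    integrative caller: each planted loss/gain also perturbs expression)."""
    tsgs = catalogue.loc[catalogue["role"] == "TSG", "gene"]
    oncs = catalogue.loc[catalogue["role"] == "ONCOGENE", "gene"]
    coord_map = coords.set_index("gene")
    tsgs = [g for g in tsgs if g in coord_map.index]
    oncs = [g for g in oncs if g in coord_map.index]

    rows, events = [], []
    for _, rec in clinical.iterrows():
        patient, grp = rec["patient_id"], rec["group"]
        planted: list[tuple[str, str]] = []  # (kind, gene)
        n_del = int(rng.poisson(config.cnv_deletion_rate.get(grp, 0.0)))
        n_gain = int(rng.poisson(config.cnv_gain_rate.get(grp, 0.0)))
        n_loh = int(rng.poisson(config.cnv_loh_rate))
        for g in rng.choice(tsgs, size=min(n_del, len(tsgs)), replace=False):
            planted.append(("LOSS", g))
        gain_pool = [g for g in oncs if g not in [x[1] for x in planted]]
        for g in rng.choice(gain_pool, size=min(n_gain, len(gain_pool)), replace=False):
            planted.append(("GAIN", g))
        loh_pool = [g for g in coords["gene"] if g not in [x[1] for x in planted]]
        for g in rng.choice(loh_pool, size=min(n_loh, len(loh_pool)), replace=False):
            planted.append(("CN_LOH", g))

        by_chrom: dict[str, list[tuple[str, int, int]]] = {}
        for kind, gene in planted:
            gc = coord_map.loc[gene]
            margin = int(rng.integers(50_000, 200_000))
            start = max(1, int(gc["start"]) - margin)
            end = min(CHROM_LENGTH, int(gc["end"]) + margin)
            by_chrom.setdefault(str(gc["chrom"]), []).append((kind, start, end))
            events.append({"sample": patient, "gene": gene, "kind": kind})

        for chrom in CHROMOSOMES:
            evs = sorted(by_chrom.get(chrom, []), key=lambda e: e[1])
            # drop overlapping events (rare): keep the first
            cleaned = []
            cursor = 0
            for kind, s, e in evs:
                if s > cursor:
                    cleaned.append((kind, s, e))
                    cursor = e
            bounds = [1]
            for kind, s, e in cleaned:
                bounds += [s, e]
            bounds.append(CHROM_LENGTH)
            # alternate neutral / event segments over the partition
            idx = 0
            segs = []
            if cleaned:
                pos = 1
                for kind, s, e in cleaned:
                    if s > pos:
                        segs.append(("NEUTRAL", pos, s - 1))
                    segs.append((kind, s, e))
                    pos = e + 1
                if pos <= CHROM_LENGTH:
                    segs.append(("NEUTRAL", pos, CHROM_LENGTH))
            else:
                segs = [("NEUTRAL", 1, CHROM_LENGTH)]
            for kind, s, e in segs:
                if kind == "NEUTRAL":
                    cn = float(rng.normal(2.0, 0.03))
                    p = float(rng.uniform(0.05, 1.0))
                    mbaf = float(rng.normal(-2.5, 0.3))
                elif kind == "LOSS":
                    cn = float(rng.uniform(1.0, 1.4))
                    p = float(10 ** -rng.uniform(3.5, 7.0))
                    mbaf = float(rng.normal(0.6, 0.1))
                elif kind == "GAIN":
                    cn = float(rng.uniform(2.6, 4.5))
                    p = float(10 ** -rng.uniform(3.5, 7.0))
                    mbaf = float(rng.normal(0.3, 0.05))
                else:  # CN_LOH
                    cn = float(rng.uniform(1.7, 2.3))
                    p = float(10 ** -rng.uniform(3.5, 7.0))
                    mbaf = float(rng.normal(0.5, 0.08))
                rows.append({"sample": patient, "chrom": chrom, "start": s,
                             "end": e, "n_snvs": int(rng.poisson(60) + 10),
                             "copy_number": round(cn, 3),
                             "p_value": float(f"{p:.3e}"),
                             "log2_mbaf_adj": round(mbaf, 3)})
                idx += 1
    return pd.DataFrame(rows), events


# ---------------------------------------------------------------------------
# clinical covariates

_STAGE_PROBS = {
    "HCV_POSITIVE": {"I": 21 / 34, "II": 9 / 34, "III": 4 / 34, "IV": 0.0},
    "SVR_DAA": {"I": 7 / 8, "II": 1 / 8, "III": 0.0, "IV": 0.0},
    "SVR_IFN": {"I": 22 / 24, "II": 1 / 24, "III": 1 / 24, "IV": 0.0},
    "SVR_OTHER": {"I": 1.0, "II": 0.0, "III": 0.0, "IV": 0.0},
}
_VP_PROBS = {
    "HCV_POSITIVE": {"Vp0": 24 / 34, "Vp1": 8 / 34, "Vp2": 0.0, "Vp3": 2 / 34},
    "SVR_DAA": {"Vp0": 3 / 8, "Vp1": 5 / 8, "Vp2": 0.0, "Vp3": 0.0},
    "SVR_IFN": {"Vp0": 20 / 24, "Vp1": 3 / 24, "Vp2": 1 / 24, "Vp3": 0.0},
    "SVR_OTHER": {"Vp0": 1.0, "Vp1": 0.0, "Vp2": 0.0, "Vp3": 0.0},
}
_LIVER_PROBS = {
    "HCV_POSITIVE": {"NL": 0.0, "CH_LF": 25 / 34, "LC": 9 / 34},
    "SVR_DAA": {"NL": 0.0, "CH_LF": 3 / 8, "LC": 5 / 8},
    "SVR_IFN": {"NL": 3 / 24, "CH_LF": 19 / 24, "LC": 2 / 24},
    "SVR_OTHER": {"NL": 1 / 3, "CH_LF": 2 / 3, "LC": 0.0},
}


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return str(rng.choice(keys, p=p))


def _simulate_clinical(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for grp in GROUPS:
        for _ in range(config.stratum_sizes[grp]):
            i += 1
            pid = f"P{i:03d}"
            followup = float(rng.uniform(6.0, 80.0))
            os_true = float(rng.exponential(1.0 / config.survival_rate_per_month))
            censor = rng.random() < config.censoring_fraction
            os_months = min(os_true, followup) if not censor else min(os_true, followup * 0.8)
            os_event = bool(os_true <= os_months + 1e-9)
            rfs_true = float(rng.exponential(1.0 / (2.5 * config.survival_rate_per_month)))
            rfs_months = min(rfs_true, os_months)
            rfs_event = bool(rfs_true <= os_months)
            rows.append({
                "patient_id": pid, "sample": pid, "group": grp,
                "stage": _draw_categorical(rng, _STAGE_PROBS[grp]),
                "portal_vein_invasion": _draw_categorical(rng, _VP_PROBS[grp]),
                "liver_background": _draw_categorical(rng, _LIVER_PROBS[grp]),
                "os_months": round(os_months, 2), "os_event": os_event,
                "rfs_months": round(rfs_months, 2), "rfs_event": rfs_event,
                "tumor_content": round(float(rng.uniform(0.3, 0.9)), 3),
            })
    return pd.DataFrame(rows)


def _assign_ihc(clinical: pd.DataFrame, carriers_tp53: set[str],
                rng: np.random.Generator) -> pd.DataFrame:
    """p53 staining concordant (with noise) with planted TP53 mutations."""
    pct, reaction = [], []
    for _, rec in clinical.iterrows():
        mutated = rec["patient_id"] in carriers_tp53
        r = rng.random()
        if mutated:
            if r < 0.65:
                pct.append(round(float(rng.uniform(40, 95)), 1)); reaction.append(True)
            elif r < 0.9:
                pct.append(0.0); reaction.append(False)       # null-type
            else:
                pct.append(round(float(rng.uniform(1, 20)), 1)); reaction.append(True)
        else:
            if r < 0.85:
                pct.append(round(float(rng.uniform(0, 15)), 1))
                reaction.append(pct[-1] > 0)
            elif r < 0.95:
                pct.append(round(float(rng.uniform(30, 60)), 1)); reaction.append(True)
            else:
                pct.append(0.0); reaction.append(False)
    out = clinical.copy()
    out["ihc_p53_percent"] = pct
    out["ihc_any_reaction"] = reaction
    return out


# ---------------------------------------------------------------------------
# top level

def simulate_cohort(config: CohortConfig | None = None) -> CohortBundle:
    """Generate the full synthetic cohort bundle from the config seed."""
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(config.seed)
    catalogue = load_catalogue()
    gene_sets = default_gene_sets()
    genes = gene_universe(catalogue, gene_sets)
    coords = gene_coordinates(genes)

    clinical = _simulate_clinical(config, rng)
    variants, truth = _simulate_variants(config, clinical, coords, gene_sets, rng)
    # truth rows align 1:1 with variant rows, in order
    somatic = truth["label"].values == "somatic" if len(truth) else np.array([], bool)
    tp53_carriers = (
        set(variants.loc[somatic & (variants["gene"].values == "TP53"), "sample"])
        if len(variants) else set()
    )
    clinical = _assign_ihc(clinical, tp53_carriers, rng)

    log2, meta = _simulate_expression(config, clinical, genes, gene_sets, rng)
    segments, cnv_events = _simulate_segments(config, clinical, coords, catalogue, rng)

    # planted CNV events perturb tumor expression so the integrative
    # expression x copy-number caller has true positives to find
    for ev in cnv_events:
        col = f"{ev['sample']}_T"
        if ev["kind"] == "LOSS":
            log2.at[ev["gene"], col] = log2.at[ev["gene"], col] - 3.0
        elif ev["kind"] == "GAIN":
            log2.at[ev["gene"], col] = log2.at[ev["gene"], col] + 3.0

    expression_raw = pd.DataFrame(
        np.power(2.0, log2.values), index=log2.index, columns=log2.columns)

    return CohortBundle(
        clinical=clinical, variants=variants, truth=truth,
        expression_raw=expression_raw, expression_meta=meta,
        segments=segments, gene_sets=gene_sets, gene_coords=coords,
        config=config,
    )


def simulate_expression_only(config: CohortConfig | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical + expression alone (raw linear matrix, sample metadata).

    A cheap path for replicated power studies over the expression layer;
    uses the same generative model as :func:`simulate_cohort` but skips
    variants and segments.
    """
    config = config if config is not None else CohortConfig()
    rng = np.random.default_rng(config.seed)
    catalogue = load_catalogue()
    gene_sets = default_gene_sets()
    genes = gene_universe(catalogue, gene_sets)
    clinical = _simulate_clinical(config, rng)
    log2, meta = _simulate_expression(config, clinical, genes, gene_sets, rng)
    raw = pd.DataFrame(np.power(2.0, log2.values), index=log2.index, columns=log2.columns)
    return raw, meta


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle table to ``out_dir`` in its flat-text format."""
    out = Path(out_dir)
    (out / "variants").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["variants"] = out / "variants.tsv"
    hio.write_variants_tsv(bundle.variants, paths["variants"])
    for sample, grp in bundle.variants.groupby("sample", sort=True):
        hio.write_variants_tsv(grp, out / "variants" / f"{sample}.tsv")
        hio.write_variants_vcf(grp, out / "variants" / f"{sample}.vcf", sample=str(sample))
    paths["truth"] = out / "truth_labels.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    paths["expression"] = out / "expression.tsv"
    hio.write_expression_tsv(bundle.expression_raw, paths["expression"])
    paths["expression_meta"] = out / "expression_meta.tsv"
    bundle.expression_meta.to_csv(paths["expression_meta"], sep="\t", index=False,
                                  lineterminator="\n")
    paths["segments"] = out / "segments.seg.tsv"
    hio.write_seg(bundle.segments, paths["segments"])
    paths["clinical"] = out / "clinical.csv"
    bundle.clinical.to_csv(paths["clinical"], index=False, lineterminator="\n")
    paths["gene_sets"] = out / "gene_sets.gmt"
    hio.write_gmt(bundle.gene_sets, paths["gene_sets"])
    paths["gene_coords"] = out / "gene_coords.tsv"
    bundle.gene_coords.to_csv(paths["gene_coords"], sep="\t", index=False,
                              lineterminator="\n")
    return paths


def simulate_snv_stream(n_snvs: int, cn_regions: list[tuple[int, int, float]],
                        seed: int, noise_sd: float = 0.25,
                        chrom: str = "1") -> pd.DataFrame:
    """Per-SNV log2 depth ratios + BAFs with planted copy-number regions.

    ``cn_regions`` lists (first_index, last_index, copy_number) spans over
    the SNV index range; everything else is copy-neutral.  Used to test
    the changepoint stage against ground truth.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_snvs, replace=False))
    cn = np.full(n_snvs, 2.0)
    for lo, hi, c in cn_regions:
        cn[lo:hi + 1] = c
    log2_ratio = rng.normal(np.log2(cn / 2.0), noise_sd)
    baf = np.clip(rng.normal(0.5, 0.04, size=n_snvs), 0.0, 1.0)
    for lo, hi, c in cn_regions:
        if c < 1.8 or c > 2.2:
            side = rng.random(hi + 1 - lo) < 0.5
            shift = np.where(side, 0.25, -0.25)
            baf[lo:hi + 1] = np.clip(0.5 + shift + rng.normal(0, 0.04, hi + 1 - lo), 0, 1)
    return pd.DataFrame({"chrom": chrom, "pos": pos,
                         "log2_ratio": log2_ratio, "baf": baf})
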