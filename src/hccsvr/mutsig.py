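"""96-context mutation spectra and non-negative signature decomposition.

Single-base substitutions are binned into the standard 96 pyrimidine-
centered trinucleotide classes (six substitutions C>A, C>G, C>T, T>A,
T>C, T>G crossed with the four 5' and four 3' flanking bases); purine-
reference mutations are reverse-complemented first.  A tumor's
normalized spectrum is then decomposed as a non-negative mixture of
reference signatures by iterative forward selection: at each step the
signature whose inclusion (with all weights re-optimized by bounded
golden-section line search) most reduces the squared reconstruction
error is added, stopping when the relative improvement falls below
1e-4.  Final weights below a floor (default 0.06, the convention of the
reference deconvolution tool) are zeroed and the remainder renormalized.

The packaged reference matrix is a deterministic SYNTHETIC stand-in with
the same shape and numbering (signatures 1..30 over 96 contexts) as the
COSMIC v2 catalogue, which cannot be redistributed here; supply your own
matrix via :func:`load_reference_signatures` to use the real catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cohort_stats import mann_whitney

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 96 class labels, e.g. "A[C>A]A", in canonical order
CONTEXT_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
_CLASS_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

N_CONTEXTS = 96
N_SIGNATURES = 30

_DEFAULT_MATRIX = "signatures_synthetic_cosmic_v2_like.tsv"


@dataclass
class SignatureExposure:
    """Non-negative signature weights for one sample."""

    weights: pd.Series  # indexed by signature name, in [0, 1]
    reconstruction_error: float

    @property
    def residual(self) -> float:
        return float(1.0 - self.weights.sum())


def context_class(ref: str, alt: str, five: str, three: str) -> int:
    """Map a substitution with flanks to its 96-class index.

    Purine-reference mutations are folded onto the opposite strand, so a
    mutation and its reverse complement land in the same class.
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    for b in (ref, alt, five, three):
        if b not in _COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r}")
    if ref in ("A", "G"):  # purine reference: reverse complement
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return _CLASS_INDEX[f"{five}[{ref}>{alt}]{three}"]


def build_spectrum(variants: pd.DataFrame) -> np.ndarray:
    """Count SNVs into the 96 trinucleotide classes.

    Expects columns ``ref``, ``alt``, ``context_5p``, ``context_3p``;
    rows with ``variant_type`` other than SNV are ignored, and variants
    with non-ACGT bases are skipped with a warning.
    """
    counts = np.zeros(N_CONTEXTS, dtype=float)
    if variants.empty:
        return counts
    snvs = variants
    if "variant_type" in variants.columns:
        snvs = variants[variants["variant_type"] == "SNV"]
    for _, row in snvs.iterrows():
        try:
            idx = context_class(row["ref"], row["alt"], row["context_5p"], row["context_3p"])
        except (ValueError, KeyError) as exc:
            warnings.warn(f"skipping variant at {row.get('chrom')}:{row.get('pos')}: {exc}",
                          stacklevel=2)
            continue
        counts[idx] += 1
    return counts


def synthesize_reference_signatures(
    n_signatures: int = N_SIGNATURES, seed: int = 20220217
) -> pd.DataFrame:
    """Deterministic SYNTHETIC reference-signature matrix (96 x n).

    Each column is a probability distribution over the 96 classes built
    from a sparse gamma draw with a handful of boosted characteristic
    peaks, giving mutually distinguishable signatures (pairwise cosine
    similarity well below 1).  This is a stand-in with the shape and
    numbering of the COSMIC v2 catalogue, not the catalogue itself.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(1, n_signatures + 1):
        w = rng.gamma(0.15, size=N_CONTEXTS)
        # disjoint characteristic peaks per signature keep the columns
        # mutually identifiable (pairwise cosine similarity stays low)
        peaks = [((k - 1) * 3 + off) % N_CONTEXTS for off in (0, 1, 2)]
        w[peaks] += rng.uniform(3.0, 6.0, size=3)
        cols[f"Signature.{k}"] = w / w.sum()
    return pd.DataFrame(cols, index=CONTEXT_LABELS)


def load_reference_signatures(path: str | Path | None = None) -> pd.DataFrame:
    """Load a 96 x K signature matrix (default: the packaged synthetic TSV)."""
    if path is None:
        ref = resources.files("hccsvr").joinpath("data", _DEFAULT_MATRIX)
        with resources.as_file(ref) as p:
            mat = pd.read_csv(p, sep="\t", index_col=0)
    else:
        mat = pd.read_csv(path, sep="\t", index_col=0)
    if list(mat.index) != CONTEXT_LABELS:
        raise ValueError("signature matrix rows must be the 96 canonical context labels")
    colsums = mat.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    if (mat.values < 0).any():
        raise ValueError("signature entries must be non-negative")
    return mat


def _optimize_support(
    m: np.ndarray, P: np.ndarray, support: list[int], w0: np.ndarray,
    inner_tol: float = 1e-8, max_sweeps: int = 200,
) -> np.ndarray:
    """Cyclic bounded golden-section line search over the supported weights."""
    w = w0.copy()
    def sse(wvec: np.ndarray) -> float:
        return float(((m - P @ wvec) ** 2).sum())
    err = sse(w)
    for _ in range(max_sweeps):
        for j in support:
            hi = min(1.0, 1.0 - w.sum() + w[j])
            if hi <= 0:
                w[j] = 0.0
                continue
            def f(x: float, j=j) -> float:
                trial = w.copy()
                trial[j] = x
                return sse(trial)
            res = minimize_scalar(f, bounds=(0.0, hi), method="bounded",
                                  options={"xatol": 1e-7})
            w[j] = float(res.x)
        new_err = sse(w)
        if err - new_err < inner_tol:
            break
        err = new_err
    return w


def decompose(
    spectrum: np.ndarray,
    signatures: pd.DataFrame,
    weight_floor: float = 0.06,
    rel_tol: float = 1e-4,
) -> SignatureExposure:
    """Forward-selection non-negative decomposition of a mutation spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (len(signatures.index),):
        raise ValueError("spectrum length must match signature matrix rows")
    total = spectrum.sum()
    if total <= 0:
        raise ValueError("cannot decompose an empty spectrum")
    m = spectrum / total
    P = signatures.values
    n_sig = P.shape[1]

    weights = np.zeros(n_sig)
    support: list[int] = []
    err = float((m ** 2).sum())
    while len(support) < n_sig:
        best_err, best_j, best_w = err, None, None
        for j in range(n_sig):
            if j in support:
                continue
            trial = _optimize_support(m, P, support + [j], weights)
            e = float(((m - P @ trial) ** 2).sum())
            if e < best_err - 1e-15:
                best_err, best_j, best_w = e, j, trial
        if best_j is None or (err - best_err) < rel_tol * err:
            break
        support.append(best_j)
        weights = best_w
        err = best_err

    original_sum = weights.sum()
    if weight_floor > 0 and original_sum > 0:
        keep = weights >= weight_floor
        floored = np.where(keep, weights, 0.0)
        kept_sum = floored.sum()
        if kept_sum > 0:
            # redistribute the floored mass over kept signatures; the kept
            # sum never exceeds the pre-floor sum, so this scales up to it
            floored *= original_sum / kept_sum
        weights = floored
    err = float(((m - P @ weights) ** 2).sum())
    return SignatureExposure(
        weights=pd.Series(weights, index=signatures.columns),
        reconstruction_error=err,
    )


def decompose_cohort(
    variants: pd.DataFrame, signatures: pd.DataFrame, weight_floor: float = 0.06
) -> pd.DataFrame:
    """Per-sample exposures (samples x signatures) for a cohort variant table."""
    rows = {}
    for sample, grp in variants.groupby("sample", sort=True):
        spec = build_spectrum(grp)
        if spec.sum() == 0:
            rows[sample] = pd.Series(0.0, index=signatures.columns)
        else:
            rows[sample] = decompose(spec, signatures, weight_floor).weights
    return pd.DataFrame(rows).T.rename_axis("sample")


def compare_signature_profiles(
    exposures: pd.DataFrame, clinical: pd.DataFrame, grouping: tuple[str, str]
) -> pd.DataFrame:
    """Per-signature group medians and Mann-Whitney p between two strata.

    ``exposures`` is samples x signatures; ``clinical`` must map
    ``sample`` to ``group``.  Degenerate groups (fewer than two samples)
    yield NA medians/p for every signature.
    """
    ga, gb = grouping
    groups = clinical.set_index("sample")["group"]
    sa = [s for s in exposures.index if groups.get(s) == ga]
    sb = [s for s in exposures.index if groups.get(s) == gb]
    rows = []
    for sig in exposures.columns:
        if len(sa) < 2 or len(sb) < 2:
            rows.append({"signature": sig, f"median_{ga}": np.nan,
                         f"median_{gb}": np.nan, "p": np.nan})
            continue
        xa = exposures.loc[sa, sig].values
        xb = exposures.loc[sb, sig].values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = mann_whitney(xa, xb)
        rows.append({"signature": sig,
                     f"median_{ga}": float(np.median(xa)),
                     f"median_{gb}": float(np.median(xb)),
                     "p": p})
    return pd.DataFrame(rows)
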