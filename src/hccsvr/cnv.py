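"""Copy-number segment classification and group burden comparison.

Segments carry a copy-number estimate, a segment test p-value and an
adjusted mirrored-BAF log ratio (log2_mbaf_adj, tracking allelic
imbalance).  Three CNV classes are called:

* GAIN:   p < 0.001 and copy number >= 2.5
* LOSS:   p < 0.001 and copy number <= 1.5
* CN-LOH: p < 0.001, 1.5 < copy number < 2.5, log2_mbaf_adj >= 0.2

Everything else is NEUTRAL.  At copy number exactly 1.5/2.5 the
gain/loss arms take precedence (their bounds are inclusive; the CN-LOH
band is open at both ends, so no segment can receive two labels).

A plain changepoint stage (:func:`segment_log_ratio`) is provided as
plumbing for turning per-SNV depth ratios and BAFs into segments; it is
a simple binary segmentation with per-segment one-sample t-tests, not a
reimplementation of joint depth/BAF segmentation models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import mann_whitney

__all__ = ["classify_segment", "classify_segments", "segment_log_ratio", "compare_cnv_burden"]

CALLS = ("GAIN", "LOSS", "CN_LOH", "NEUTRAL")

P_THRESHOLD = 0.001
CN_GAIN = 2.5
CN_LOSS = 1.5
MBAF_LOH = 0.2


def classify_segment(p_value: float, copy_number: float, log2_mbaf_adj: float) -> str:
    """Classify one segment into GAIN / LOSS / CN_LOH / NEUTRAL."""
    if p_value < P_THRESHOLD:
        if copy_number >= CN_GAIN:
            return "GAIN"
        if copy_number <= CN_LOSS:
            return "LOSS"
        if log2_mbaf_adj >= MBAF_LOH:
            return "CN_LOH"
    return "NEUTRAL"


def classify_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification; adds a ``call`` column."""
    out = segments.copy()
    sig = out["p_value"] < P_THRESHOLD
    gain = sig & (out["copy_number"] >= CN_GAIN)
    loss = sig & (out["copy_number"] <= CN_LOSS)
    loh = sig & ~gain & ~loss & (out["log2_mbaf_adj"] >= MBAF_LOH)
    call = np.where(gain, "GAIN", np.where(loss, "LOSS", np.where(loh, "CN_LOH", "NEUTRAL")))
    out["call"] = call
    return out


def _binary_segment(values: np.ndarray, start: int, end: int,
                    min_size: int, alpha: float, breaks: list[int]) -> None:
    """Recursive mean-shift binary segmentation on values[start:end]."""
    n = end - start
    if n < 2 * min_size:
        return
    seg = values[start:end]
    best_t, best_stat = None, 0.0
    for t in range(min_size, n - min_size + 1):
        left, right = seg[:t], seg[t:]
        pooled = np.sqrt(left.var(ddof=1) / len(left) + right.var(ddof=1) / len(right))
        if pooled == 0:
            continue
        stat = abs(left.mean() - right.mean()) / pooled
        if stat > best_stat:
            best_stat, best_t = stat, t
    if best_t is None:
        return
    # Welch-type significance gate on the candidate split
    df = n - 2
    p = 2 * stats.t.sf(best_stat, df)
    if p >= alpha:
        return
    breaks.append(start + best_t)
    _binary_segment(values, start, start + best_t, min_size, alpha, breaks)
    _binary_segment(values, start + best_t, end, min_size, alpha, breaks)


def segment_log_ratio(
    snvs: pd.DataFrame,
    min_snvs: int = 10,
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Segment per-SNV log2 depth ratios into copy-number segments.

    ``snvs`` needs columns ``chrom``, ``pos``, ``log2_ratio`` and ``baf``
    (tumor B-allele frequency of heterozygous sites), sorted by position
    within each chromosome.  Changepoints come from binary segmentation
    of the mean log2 depth ratio; each segment's p-value is a two-sided
    one-sample t-test of its log-ratios against 0; the mirrored-BAF
    statistic is ``log2(mean|BAF-0.5| / 0.25)``, which sits well below 0
    for balanced heterozygous segments and rises above 0.2 under clear
    allelic imbalance.  Fewer than ``min_snvs`` sites in a chromosome
    yields one segment.
    """
    required = {"chrom", "pos", "log2_ratio", "baf"}
    if not required.issubset(snvs.columns):
        raise ValueError(f"snvs table needs columns {sorted(required)}")
    rows = []
    for chrom, grp in snvs.groupby("chrom", sort=True):
        pos = grp["pos"].values
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"SNVs on chrom {chrom} are not sorted by position")
        values = grp["log2_ratio"].values.astype(float)
        baf = grp["baf"].values.astype(float)
        n = len(values)
        breaks: list[int] = []
        if n >= min_snvs:
            _binary_segment(values, 0, n, min_snvs, alpha, breaks)
        bounds = [0] + sorted(breaks) + [n]
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            seg = values[lo:hi]
            if len(seg) >= 2 and seg.std(ddof=1) > 0:
                _, p = stats.ttest_1samp(seg, 0.0)
            else:
                p = 1.0 if np.allclose(seg, 0) else 0.0
            mbaf = np.abs(baf[lo:hi] - 0.5).mean()
            rows.append({
                "chrom": chrom,
                "start": int(pos[lo]),
                "end": int(pos[hi - 1]),
                "n_snvs": hi - lo,
                "copy_number": float(2.0 * 2 ** seg.mean()),
                "p_value": float(p),
                "log2_mbaf_adj": float(np.log2(mbaf / 0.25 + 1e-9) if mbaf > 0 else -30.0),
            })
    return pd.DataFrame(rows)


def compare_cnv_burden(
    calls: pd.DataFrame, clinical: pd.DataFrame, grouping: tuple[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample CNV class counts and group comparisons.

    ``calls`` is a classified segment table (``sample``, ``call``);
    ``clinical`` maps ``sample`` to ``group``.  Returns the per-sample
    count table and a per-class comparison (Mann-Whitney on counts
    between the two named groups).
    """
    ga, gb = grouping
    groups = clinical.set_index("sample")["group"]
    unknown = set(calls["sample"]) - set(groups.index)
    if unknown:
        raise ValueError(f"samples without a clinical group: {sorted(unknown)[:5]}")
    counts = (
        calls[calls["call"] != "NEUTRAL"]
        .groupby(["sample", "call"]).size().unstack(fill_value=0)
        .reindex(columns=["GAIN", "LOSS", "CN_LOH"], fill_value=0)
        .reindex(index=sorted(groups.index), fill_value=0)
        .astype(int)
    )
    counts["group"] = groups.reindex(counts.index)
    rows = []
    for cls in ("GAIN", "LOSS", "CN_LOH"):
        xa = counts.loc[counts["group"] == ga, cls].values
        xb = counts.loc[counts["group"] == gb, cls].values
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"no samples for one of the groups {grouping}")
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            u, p = mann_whitney(xa, xb)
        rows.append({"call": cls, f"mean_{ga}": float(xa.mean()),
                     f"mean_{gb}": float(xb.mean()), "U": u, "p": p})
    return counts, pd.DataFrame(rows)
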