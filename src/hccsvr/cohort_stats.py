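"""Cohort-level statistics: contingency tests, rank tests, survival, p53 IHC.

Conventions follow common clinical-genomics practice: the chi-squared
test is computed without Yates continuity correction by default, the
two-sided Fisher exact p sums all tables (fixed margins) whose
probability does not exceed the observed table's, Mann-Whitney uses
average ranks with exact enumeration for small samples, and survival is
Kaplan-Meier with a log-rank test between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "ContingencyResult",
    "IhcCall",
    "compare_frequencies",
    "mann_whitney",
    "spearman",
    "km_logrank",
    "classify_ihc",
    "ihc_mutation_concordance",
]


@dataclass
class ContingencyResult:
    table: np.ndarray
    test: str  # CHI_SQUARED or FISHER (the one `method` selected)
    statistic: float
    p: float
    p_chi2: float
    p_fisher: float


@dataclass
class IhcCall:
    percent_positive: float
    call: str  # MUTANT_PATTERN | NULL_TYPE | WILD_TYPE

    @property
    def aberrant(self) -> bool:
        return self.call in ("MUTANT_PATTERN", "NULL_TYPE")


def compare_frequencies(
    mut_a: int, n_a: int, mut_b: int, n_b: int, method: str = "auto"
) -> ContingencyResult:
    """Compare two mutation frequencies on a 2x2 contingency table.

    ``method='auto'`` selects Fisher's exact test when any expected cell
    count is below 5, otherwise the chi-squared test (no continuity
    correction).  Both p-values are always computed and reported.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= mut_a <= n_a and 0 <= mut_b <= n_b):
        raise ValueError("mutated counts must lie in [0, n]")
    table = np.array([[mut_a, n_a - mut_a], [mut_b, n_b - mut_b]], dtype=int)

    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # degenerate margins: no evidence either way
        return ContingencyResult(table, "FISHER", 0.0, 1.0, 1.0, 1.0)

    if (table.sum(axis=0) > 0).all():
        chi2, p_chi2, _, expected = stats.chi2_contingency(table, correction=False)
    else:  # pragma: no cover - caught by degenerate branch above
        chi2, p_chi2, expected = np.nan, 1.0, np.zeros((2, 2))
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")

    if method == "auto":
        use_fisher = bool((expected < 5).any())
    elif method in ("fisher", "FISHER"):
        use_fisher = True
    elif method in ("chi2", "chi_squared", "CHI_SQUARED"):
        use_fisher = False
    else:
        raise ValueError(f"unknown method {method!r}")

    if use_fisher:
        return ContingencyResult(table, "FISHER", float(chi2), float(p_fisher),
                                 float(p_chi2), float(p_fisher))
    return ContingencyResult(table, "CHI_SQUARED", float(chi2), float(p_chi2),
                             float(p_chi2), float(p_fisher))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with average ranks for ties.

    Exact enumeration when the smaller sample has <= 20 observations and
    the data are tie-free; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all observations tied; p=1", stacklevel=2)
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def km_logrank(times, events, groups) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier curves per group plus the log-rank test p-value.

    Returns a long-format curve table (group, time, at_risk, survival,
    ci_lower, ci_upper) and the chi-squared log-rank p across groups.
    """
    df = pd.DataFrame({"time": np.asarray(times, float),
                       "event": np.asarray(events, bool),
                       "group": np.asarray(groups)})
    if (df["time"] < 0).any():
        raise ValueError("times must be non-negative")
    if df["group"].nunique() < 2:
        raise ValueError("need at least two groups")
    curves = []
    for g, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        surv = kmf.survival_function_
        ci = kmf.confidence_interval_
        at_risk = kmf.event_table["at_risk"]
        for t in surv.index:
            curves.append({
                "group": g,
                "time": float(t),
                "at_risk": int(at_risk.loc[t]) if t in at_risk.index else np.nan,
                "survival": float(surv.loc[t].iloc[0]),
                "ci_lower": float(ci.loc[t].iloc[0]),
                "ci_upper": float(ci.loc[t].iloc[1]),
            })
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return pd.DataFrame(curves), float(res.p_value)


def classify_ihc(percent_positive: float, any_immunoreaction: bool) -> IhcCall:
    """p53 immunohistochemistry call.

    MUTANT_PATTERN when >= 30% of cancer cells show distinct nuclear
    staining; NULL_TYPE when no immunoreaction is observed at all;
    WILD_TYPE otherwise.  Mutant-pattern and null-type together flag an
    aberrant p53 protein.
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must lie in [0, 100]")
    if percent_positive > 0 and not any_immunoreaction:
        raise ValueError("percent_positive > 0 contradicts any_immunoreaction=False")
    if percent_positive >= 30:
        return IhcCall(percent_positive, "MUTANT_PATTERN")
    if not any_immunoreaction:
        return IhcCall(percent_positive, "NULL_TYPE")
    return IhcCall(percent_positive, "WILD_TYPE")


def ihc_mutation_concordance(
    ihc_calls: pd.Series, mutation_flags: pd.Series
) -> ContingencyResult:
    """Concordance of aberrant p53 staining with TP53 mutation status.

    Inputs are indexed by sample; unpaired samples are dropped with a
    warning.  Builds the 2x2 of aberrant-vs-mutation and applies
    :func:`compare_frequencies`.
    """
    common = ihc_calls.index.intersection(mutation_flags.index)
    dropped = len(ihc_calls) + len(mutation_flags) - 2 * len(common)
    if dropped:
        warnings.warn(f"{dropped} unpaired samples excluded from concordance", stacklevel=2)
    aberrant = ihc_calls.loc[common].map(
        lambda c: c.aberrant if isinstance(c, IhcCall) else bool(c)
    ).astype(bool)
    mutated = mutation_flags.loc[common].astype(bool)
    return compare_frequencies(
        int((aberrant & mutated).sum()), int(mutated.sum()),
        int((aberrant & ~mutated).sum()), int((~mutated).sum()),
    )
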