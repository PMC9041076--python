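"""Expression normalization, gene-set signature scores, clustering, volcano.

Raw microarray intensities are log2-transformed and normalized so every
sample's 75th percentile is 0.  A signature score is the per-sample mean
of the normalized values of a gene set's members; the TP53-inactivation
score uses the fixed four-gene set CDC20, PLK1, CENPA, KIF2C, a
transcriptional readout of p53 pathway loss.  Group contrasts use
Mann-Whitney; per-gene volcano tables add Benjamini-Hochberg q-values;
hierarchical clustering is Ward linkage on gene-wise z-scored rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .cohort_stats import mann_whitney, spearman

__all__ = [
    "TP53_INACTIVATION_GENES",
    "normalize_75th",
    "score_signature",
    "tp53_inactivation_score",
    "correlate_scores",
    "volcano",
    "ward_cluster",
    "linkage_to_newick",
]

TP53_INACTIVATION_GENES = ("CDC20", "PLK1", "CENPA", "KIF2C")


def normalize_75th(raw: pd.DataFrame, already_log: bool = False) -> pd.DataFrame:
    """Log2-transform and shift each sample's 75th percentile to 0.

    ``raw`` is genes x samples of positive intensities (or log2 values
    when ``already_log``).  The operation is idempotent on its own
    output and invariant to per-sample scale factors.
    """
    if already_log:
        logm = raw.astype(float)
    else:
        vals = raw.values.astype(float)
        if (vals <= 0).any():
            gi, si = np.argwhere(vals <= 0)[0]
            raise ValueError(
                f"non-positive raw intensity at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
            )
        logm = pd.DataFrame(np.log2(vals), index=raw.index, columns=raw.columns)
    q75 = logm.quantile(0.75, axis=0)
    return logm.sub(q75, axis=1)


def score_signature(matrix: pd.DataFrame, genes, name: str = "") -> tuple[pd.Series, float]:
    """Mean normalized expression of the present member genes, per sample.

    Returns ``(scores, coverage)`` where coverage is the fraction of the
    set's genes present in the matrix.  Raises on zero overlap.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene set is empty")
    present = [g for g in genes if g in matrix.index]
    if not present:
        raise ValueError(f"no genes of set {name or genes} present in matrix")
    scores = matrix.loc[present].mean(axis=0)
    scores.name = name or "signature"
    return scores, len(present) / len(genes)


def tp53_inactivation_score(matrix: pd.DataFrame) -> pd.Series:
    """TP53-inactivation score: mean of CDC20, PLK1, CENPA and KIF2C."""
    missing = [g for g in TP53_INACTIVATION_GENES if g not in matrix.index]
    if missing:
        raise ValueError(f"TP53-inactivation genes absent from matrix: {missing}")
    scores, _ = score_signature(matrix, TP53_INACTIVATION_GENES, name="TP53_inactivation")
    return scores


def correlate_scores(score_a: pd.Series, score_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation between two per-sample scores."""
    common = score_a.index.intersection(score_b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    return spearman(score_a.loc[common].values, score_b.loc[common].values)


def volcano(matrix: pd.DataFrame, group_mask: pd.Series) -> pd.DataFrame:
    """Per-gene differential table between mask-true and mask-false samples.

    Fold change is the difference of group means on the log2 scale; the
    p-value is a two-sided Mann-Whitney per gene, with BH-adjusted
    q-values.  Rows are sorted by p ascending.
    """
    mask = group_mask.reindex(matrix.columns)
    if mask.isna().any():
        raise ValueError("group_mask must cover every sample column")
    mask = mask.astype(bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("need at least two samples per group")
    a = matrix.loc[:, mask.values].values
    b = matrix.loc[:, (~mask).values].values
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.empty(len(matrix.index))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(matrix.index)):
            _, pvals[i] = mann_whitney(a[i], b[i])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame({"gene": matrix.index, "log2_fc": log2fc, "p": pvals, "q": qvals})
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def ward_cluster(matrix: pd.DataFrame, n_clusters: int | None = None):
    """Ward-linkage clustering of samples on gene-wise z-scored rows.

    Returns ``(linkage, labels)``; ``labels`` is a per-sample Series when
    ``n_clusters`` is given, else None.  Constant genes are dropped
    before z-scoring.  Merge heights are invariant to sample order.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    sd = matrix.std(axis=1, ddof=0)
    usable = matrix.loc[sd > 0]
    z = usable.sub(usable.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    X = z.T.values  # samples x genes
    Z = hierarchy.ward(pdist(X, metric="euclidean"))
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        labels = pd.Series(flat, index=matrix.columns, name="cluster")
    return Z, labels


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
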