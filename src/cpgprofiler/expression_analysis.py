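"""ΔCt expression profiling: tertile classification, methylation–expression
correlation, and hierarchical clustering of transcript profiles.

All expression quantities are on the ΔCt scale (target Ct minus
reference-gene Ct), where *lower* ΔCt means *higher* transcript abundance.
Every correlation result therefore carries both orientations: the rho
computed against ΔCt and its negation, the rho against expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "ExpressionClassification",
    "CorrelationResult",
    "ClusterResult",
    "PAPER_PRESET_CUTOFFS",
    "tertile_cutoffs",
    "classify_expression",
    "classify_table",
    "spearman_methylation_expression",
    "cluster_expression",
]

# Published preset tertile boundaries on the ΔCt scale (33rd / 66th
# percentile of the original panel's ΔCt distribution, which is not
# re-derivable); treated as opaque constants in preset mode.
PAPER_PRESET_CUTOFFS = (9.083, 15.308)

_LABEL_RANK = {"low": 0, "intermediate": 1, "high": 2}


@dataclass
class ExpressionClassification:
    cutoff_low: float   # 33rd percentile of ΔCt
    cutoff_high: float  # 66th percentile of ΔCt
    labels: pd.DataFrame  # sample × transcript, {high, intermediate, low}


@dataclass
class CorrelationResult:
    rho_vs_dct: float
    rho_vs_expression: float  # = −rho_vs_dct
    p: float
    n: int
    orientation_note: str = (
        "rho computed against ΔCt; lower ΔCt = higher expression, so "
        "rho_vs_expression = -rho_vs_dct"
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix (complete, Euclidean)
    labels_at_k: pd.Series       # sample -> cluster id (1..k)
    newick: str
    distance: str = "euclidean"
    method: str = "complete"


def tertile_cutoffs(dct_values) -> tuple[float, float]:
    """33rd and 66th percentiles of the ΔCt distribution, by linear
    interpolation between order statistics (h = (n−1)p + 1)."""
    v = np.asarray(dct_values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise ValueError(f"need >= 3 finite ΔCt values for tertiles, got {len(v)}")
    lo, hi = np.percentile(v, [33, 66], method="linear")
    return float(lo), float(hi)


def classify_expression(dct: float, cutoffs: tuple[float, float]) -> str | float:
    """Tertile label for one ΔCt: high if ΔCt <= cutoff_low, low if
    ΔCt >= cutoff_high, intermediate strictly between (boundaries
    inclusive toward the extreme classes; high wins if the cutoffs
    coincide).  Missing ΔCt yields a missing label."""
    lo, hi = cutoffs
    if lo > hi:
        raise ValueError(f"cutoffs out of order: {cutoffs}")
    if dct is None or not np.isfinite(dct):
        return float("nan")
    if dct <= lo:
        return "high"
    if dct >= hi:
        return "low"
    return "intermediate"


def classify_table(dct_matrix: pd.DataFrame, cutoffs: tuple[float, float] | None = None) -> ExpressionClassification:
    """Classify every (sample, transcript) ΔCt; cutoffs default to the
    33rd/66th percentiles of the pooled finite values."""
    if cutoffs is None:
        cutoffs = tertile_cutoffs(dct_matrix.to_numpy().ravel())
    labels = dct_matrix.map(lambda x: classify_expression(x, cutoffs))
    return ExpressionClassification(cutoff_low=cutoffs[0], cutoff_high=cutoffs[1], labels=labels)


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_methylation_expression(
    mean_methylation, dct, exact_max_n: int = 9
) -> CorrelationResult:
    """Spearman rank correlation between per-sample promoter methylation and
    ΔCt (midrank ties); pairs with any missing value are dropped.

    Two-sided p by exact permutation enumeration when n <= ``exact_max_n``,
    else the t approximation t = rho·sqrt((n−2)/(1−rho²)).
    """
    x = np.asarray(mean_methylation, dtype=float)
    y = np.asarray(dct, dtype=float)
    if x.shape != y.shape:
        raise ValueError("methylation and ΔCt vectors must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    rho = _spearman_rho(x, y)
    if np.isnan(rho):
        p = 1.0
    elif n <= exact_max_n:
        ry = stats.rankdata(y, method="average")
        rx = stats.rankdata(x, method="average")
        rxc = rx - rx.mean()
        count = 0
        total = 0
        obs = abs(rho)
        for perm in permutations(ry):
            ryc = np.asarray(perm) - ry.mean()
            denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
            r = (rxc * ryc).sum() / denom if denom else 0.0
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho_vs_dct=rho, rho_vs_expression=-rho, p=float(min(1.0, p)), n=n)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def _fmt(node, parent_dist: float) -> str:
        length = max(0.0, parent_dist - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return _fmt(tree, tree.dist) + ";"


def cluster_expression(dct_matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Unsupervised hierarchical clustering of samples on raw ΔCt profiles
    (no transformation), Euclidean distance, complete linkage; the tree is
    cut at ``k`` clusters and serialised as Newick."""
    if dct_matrix.isna().any().any():
        missing = dct_matrix.isna().stack()
        cells = list(missing[missing].index[:5])
        raise ValueError(f"ΔCt matrix has missing cells (e.g. {cells}); impute or drop first")
    n = len(dct_matrix)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} samples")
    Z = hierarchy.linkage(dct_matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=dct_matrix.index, name="cluster")
    return ClusterResult(
        linkage=Z,
        labels_at_k=labels,
        newick=_linkage_to_newick(Z, [str(s) for s in dct_matrix.index]),
    )
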