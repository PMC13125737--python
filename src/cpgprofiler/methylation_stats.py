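"""Promoter methylation summaries: relative index, critical-CpG flags,
nonparametric group contrasts, and the demethylation (5-aza) contrast.

The central quantity is the *relative methylation index*: a CpG's percent
methylation divided by the mean promoter methylation of the same sample.
An index above 1 marks a CpG locally hypermethylated relative to its own
promoter; below 1, locally hypomethylated.  Because every sample is its own
denominator the index is invariant to sample-wide scaling, which removes
between-line differences in global promoter methylation before asking
which *positions* deviate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MethylationMatrix, ExpressionTable, ValidationError

__all__ = [
    "RelativeIndexTable",
    "promoter_mean_methylation",
    "relative_methylation_index",
    "flag_critical_cpgs",
    "group_compare",
    "mann_whitney_exact",
    "demethylation_contrast",
]


@dataclass
class RelativeIndexTable:
    """Per-(sample, CpG) relative methylation indices.

    ``indices``: DataFrame sample × CpG label; ``promoter_means``: the
    per-sample denominator (percent).  With complete data the row means of
    ``indices`` are exactly 1.
    """

    indices: pd.DataFrame
    promoter_means: pd.Series

    @property
    def cpg_labels(self) -> list[str]:
        return list(self.indices.columns)

    def median_index(self) -> pd.Series:
        """Median index per CpG across samples."""
        return self.indices.median(axis=0, skipna=True)


def promoter_mean_methylation(
    matrix: MethylationMatrix, sample: str | None = None, agg: str = "median"
) -> float | pd.Series:
    """Mean percent methylation over the promoter's CpGs for one sample (or
    all samples), after aggregating replicates (median by default).

    Missing CpGs are excluded pairwise; a sample with no usable value is an
    error.
    """
    per_cpg = matrix.aggregate(agg)
    means = per_cpg.mean(axis=1, skipna=True)
    empty = per_cpg.notna().sum(axis=1) == 0
    if sample is not None:
        if sample not in per_cpg.index:
            raise KeyError(f"sample {sample!r} not in matrix")
        if empty.loc[sample]:
            raise ValidationError(f"sample {sample!r}: all methylation values missing")
        return float(means.loc[sample])
    if empty.any():
        raise ValidationError(f"samples with all values missing: {list(means.index[empty])}")
    return means


def relative_methylation_index(matrix: MethylationMatrix, agg: str = "median") -> RelativeIndexTable:
    """Index[sample, CpG] = methylation[sample, CpG] / promoter mean of the
    sample, both computed from the same replicate-aggregated values so the
    per-sample mean of indices is exactly 1 on complete data.

    A sample whose promoter mean is 0 (fully unmethylated) gets missing
    indices with a warning, never infinities.
    """
    per_cpg = matrix.aggregate(agg)
    means = per_cpg.mean(axis=1, skipna=True)
    zero = means == 0
    if zero.any():
        warnings.warn(
            f"promoter mean is 0 for samples {list(means.index[zero])}; their indices are missing",
            stacklevel=2,
        )
        means = means.mask(zero)
    indices = per_cpg.div(means, axis=0)
    return RelativeIndexTable(indices=indices, promoter_means=means)


def flag_critical_cpgs(
    index_table: RelativeIndexTable,
    alpha: float = 0.05,
    test: str = "wilcoxon_one_sample",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Flag CpGs whose index distribution departs from 1 across the panel.

    Per CpG: two-sided one-sample Wilcoxon signed-rank of (index − 1)
    across samples; direction from the median index; ``neutral`` when
    p >= alpha or the CpG is untestable (< ``min_samples`` usable samples,
    or all indices exactly 1).  Benjamini–Hochberg q-values across the
    tested CpGs are reported alongside the raw p.

    Returns a DataFrame indexed by CpG label with columns
    ``direction`` ({high, low, neutral}), ``median_index``, ``n``, ``p``,
    ``q``, ``testable``.
    """
    if test != "wilcoxon_one_sample":
        raise ValueError("only the one-sample Wilcoxon panel test is implemented")
    rows = []
    for label in index_table.cpg_labels:
        x = index_table.indices[label].dropna().to_numpy()
        n = len(x)
        med = float(np.median(x)) if n else float("nan")
        p = float("nan")
        testable = n >= min_samples
        if testable:
            d = x - 1.0
            if np.all(d == 0):
                p = 1.0
            else:
                p = wilcoxon_signed_rank(d)
        rows.append({"cpg": label, "median_index": med, "n": n, "p": p, "testable": testable})
    out = pd.DataFrame(rows).set_index("cpg")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        from statsmodels.stats.multitest import multipletests

        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    direction = np.where(
        ~tested | (out["p"] >= alpha),
        "neutral",
        np.where(out["median_index"] > 1, "high", np.where(out["median_index"] < 1, "low", "neutral")),
    )
    out["direction"] = direction
    return out[["direction", "median_index", "n", "p", "q", "testable"]]


def wilcoxon_signed_rank(d: np.ndarray, exact_max_n: int = 13) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value for differences
    ``d`` (zeros dropped).

    Up to ``exact_max_n`` non-zero differences the full 2^n sign-flip
    distribution of the positive-rank sum is enumerated (midranks, so ties
    are handled exactly); beyond that the tie-corrected normal
    approximation of scipy is used.  The sign-flip distribution is
    symmetric about sum(ranks)/2, so the two-sided p is the probability of
    a deviation at least as large as observed.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    if n > exact_max_n:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(
                stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx").pvalue
            )
    ranks = stats.rankdata(np.abs(d), method="average")
    t_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    signs = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1  # all sign patterns
    t_all = signs @ ranks
    return float(np.mean(np.abs(t_all - mu) >= abs(t_obs - mu) - 1e-9))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by full enumeration of group
    assignments (midranks; handles ties).

    The permutation distribution of U is symmetric about n_a·n_b/2, so the
    two-sided p is the fraction of assignments at least as far from the
    centre as the observed U.
    """
    from itertools import combinations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n_a, n = len(a), len(pooled)
    centre = n_a * (n - n_a) / 2.0
    const = n_a * (n_a + 1) / 2.0
    u_obs = ranks[:n_a].sum() - const
    dev_obs = abs(u_obs - centre)
    count = 0
    total = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - const
        total += 1
        if abs(u - centre) >= dev_obs - 1e-9:
            count += 1
    return float(u_obs), count / total


def group_compare(*groups, test: str = "mann_whitney", exact_max_n: int = 8) -> tuple[float, float]:
    """Nonparametric comparison of independent groups.

    ``mann_whitney`` (two groups): exact enumeration when both group sizes
    are <= ``exact_max_n``, otherwise the normal approximation with tie and
    continuity correction.  ``kruskal_wallis`` (three or more groups):
    tie-corrected H with a chi-square p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney compares exactly two groups")
        a, b = groups
        if len(a) <= exact_max_n and len(b) <= exact_max_n:
            return mann_whitney_exact(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        if len(groups) < 3:
            raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney for two")
        if all(np.all(g == groups[0][0]) for g in groups):
            return 0.0, 1.0  # all-tie degenerate case: H = 0
        res = stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def demethylation_contrast(
    treated: MethylationMatrix,
    vehicle: MethylationMatrix,
    treated_expr: ExpressionTable | None = None,
    vehicle_expr: ExpressionTable | None = None,
    transcript: str | None = None,
) -> dict:
    """Per-CpG methylation change and expression change after a
    demethylating-agent treatment versus vehicle.

    Per CpG: difference of medians (treated − vehicle) over all
    (sample, replicate) values and a Mann–Whitney p.  With expression
    tables, ΔΔCt = median treated ΔCt − median vehicle ΔCt; negative ΔΔCt
    means re-expression.
    """
    if list(treated.cpg_labels) != list(vehicle.cpg_labels):
        raise ValidationError(
            f"CpG labels differ between conditions: {treated.cpg_labels} vs {vehicle.cpg_labels}"
        )
    rows = []
    for label in treated.cpg_labels:
        t = treated.data[label].dropna().to_numpy()
        v = vehicle.data[label].dropna().to_numpy()
        delta = float(np.median(t) - np.median(v))
        if len(t) >= 3 and len(v) >= 3:
            _, p = group_compare(t, v, test="mann_whitney")
        else:
            p = float("nan")
        rows.append({"cpg": label, "delta_methylation": delta, "p": p})
    result: dict = {"per_cpg": pd.DataFrame(rows).set_index("cpg")}
    if treated_expr is not None and vehicle_expr is not None:
        tcol = transcript or treated_expr.transcripts[0]
        t_dct = treated_expr.data[tcol].dropna().to_numpy()
        v_dct = vehicle_expr.data[tcol].dropna().to_numpy()
        ddct = float(np.median(t_dct) - np.median(v_dct))
        if len(t_dct) >= 3 and len(v_dct) >= 3:
            _, p_expr = group_compare(t_dct, v_dct, test="mann_whitney")
        else:
            p_expr = float("nan")
        result["ddct"] = ddct
        result["ddct_p"] = p_expr
        result["re_expressed"] = ddct < 0
    return result
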