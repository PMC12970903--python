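"""Permutation-based group comparison of AUC metrics, FDR, effect sizes,
and normality-gated correlation.

The group test is a two-sided label-permutation test on the difference of
group means. When the number of distinct label splits is small enough it is
run exhaustively (exact p); otherwise a Monte Carlo null with the
add-one correction p = (#{|null| >= |obs|} + 1) / (n_perm + 1) is used, so
p can never be exactly 0. Multiple comparisons are handled by
Benjamini-Hochberg step-up FDR, applied within metric families (the global
metrics form one family; each nodal metric forms a family across nodes).
Cohen's d with the pooled-SD denominator accompanies every comparison.

Correlations are gated by Shapiro-Wilk normality of both variables
(p > 0.05 for both -> Pearson, otherwise Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

_TIE_EPS = 1e-12    # guards >= comparisons of permuted vs observed differences


@dataclass
class ComparisonResult:
    metric_name: str
    node: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    observed_diff: float
    p_perm: float
    p_fdr: float
    cohen_d: float


@dataclass
class CorrelationResult:
    variable_x: str
    variable_y: str
    method: str
    r: float
    p: float
    normality_p_x: float
    normality_p_y: float


def permutation_test(values_a: np.ndarray, values_b: np.ndarray,
                     n_perm: int = 5000, seed: int | None = 0,
                     ) -> tuple[float, float]:
    """Two-sided permutation test on the difference of means.

    Returns ``(observed_diff, p)`` with ``observed_diff = mean(a) - mean(b)``.
    Exhaustive enumeration of all label splits is used automatically when
    their count does not exceed ``n_perm``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size

    n_splits = comb(n, na)
    if n_splits <= n_perm:
        # exact: every split equally likely under the null
        total_sum = pooled.sum()
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            diff = sa / na - (total_sum - sa) / (n - na)
            if abs(diff) >= abs(observed) - _TIE_EPS:
                count += 1
        return observed, count / n_splits

    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of uniforms = random permutations
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[order]
    diffs = shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1)
    count = int(np.sum(np.abs(diffs) >= abs(observed) - _TIE_EPS))
    return observed, (count + 1) / (n_perm + 1)


def fdr_bh(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def cohens_d(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (a minus b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    na, nb = a.size, b.size
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def gated_correlation(x: np.ndarray, y: np.ndarray,
                      name_x: str = "x", name_y: str = "y",
                      alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation if both variables pass Shapiro-Wilk normality
    (p > alpha), Spearman rank correlation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        const = name_x if np.ptp(x) == 0 else name_y
        raise ValueError(f"variable {const!r} is constant")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if sw_x > alpha and sw_y > alpha:
        method = "pearson"
        r, p = stats.pearsonr(x, y)
    else:
        method = "spearman"
        r, p = stats.spearmanr(x, y)
    return CorrelationResult(variable_x=name_x, variable_y=name_y,
                             method=method, r=float(r), p=float(p),
                             normality_p_x=float(sw_x),
                             normality_p_y=float(sw_y))


def compare_cohorts(auc_table: pd.DataFrame,
                    group_a: str = "expert",
                    group_b: str = "novice",
                    n_perm: int = 5000,
                    seed: int = 0,
                    fdr_mode: str = "within-family") -> pd.DataFrame:
    """Permutation-compare two groups on every (metric, node) AUC.

    ``auc_table`` is long-format with columns subject_id, group, metric,
    node ('' for global), auc. FDR families: ``within-family`` corrects the
    global metrics together and each nodal metric across its nodes;
    ``pooled`` corrects everything together.
    """
    if fdr_mode not in ("within-family", "pooled"):
        raise ValueError("fdr_mode must be 'within-family' or 'pooled'")
    table = auc_table.copy()
    table["node"] = table["node"].fillna("")
    rows = []
    ss = np.random.SeedSequence(seed)
    cells = sorted(set(zip(table["metric"], table["node"])))
    child_seeds = ss.spawn(len(cells))
    for (metric, node), child in zip(cells, child_seeds):
        sub = table[(table["metric"] == metric) & (table["node"] == node)]
        va = sub.loc[sub["group"] == group_a, "auc"].to_numpy(float)
        vb = sub.loc[sub["group"] == group_b, "auc"].to_numpy(float)
        if va.size == 0 or vb.size == 0:
            raise ValueError(f"metric {metric!r} node {node!r}: a group is empty")
        obs, p = permutation_test(va, vb, n_perm=n_perm,
                                  seed=child.generate_state(1)[0] % (2**31))
        rows.append({
            "metric": metric, "node": node,
            "mean_a": va.mean(), "sd_a": va.std(ddof=1),
            "mean_b": vb.mean(), "sd_b": vb.std(ddof=1),
            "observed_diff": obs, "p_perm": p,
            "cohen_d": cohens_d(va, vb),
        })
    result = pd.DataFrame(rows)
    result["p_fdr"] = np.nan
    if fdr_mode == "pooled":
        result["p_fdr"] = fdr_bh(result["p_perm"].to_numpy())
    else:
        families = np.where(result["node"] == "", "__global__", result["metric"])
        for fam in np.unique(families):
            mask = families == fam
            result.loc[mask, "p_fdr"] = fdr_bh(result.loc[mask, "p_perm"].to_numpy())
    return result
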