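"""Generic statistical kernel: rank tests, Fisher's exact test, BH
adjustment, per-gene score correlation and hypergeometric set enrichment.

All group comparisons are nonparametric, matching the pipeline's use of the
Wilcoxon rank-sum test for two groups and a Cuzick-type rank trend test for
ordered groups.  P values are two-sided unless an ``alternative`` is asked
for explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    direction: int  # sign of the first-group-minus-last-group median difference

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p value out of [0, 1]: {self.p_value}")


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> GroupComparisonResult:
    """Two-sided Wilcoxon / Mann-Whitney rank-sum test.

    ``mode='exact'`` enumerates all arrangements (requires total n <= 20 and
    no ties); ``'approx'`` uses the tie-corrected normal approximation with
    continuity correction; ``'auto'`` picks exact when admissible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 20 and not has_ties) else "approx"
    if mode == "exact":
        if pooled.size > 20:
            raise ValueError("exact mode requires total n <= 20")
        if has_ties:
            raise ValueError("exact mode requires no ties")
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    direction = int(np.sign(np.median(x) - np.median(y)))
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
        group_sizes=(x.size, y.size),
        direction=direction,
    )


def _cuzick_statistic(ranks: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(weights * ranks))


def trend_test(
    values, ordered_group_labels, mode: str = "auto", alternative: str = "two-sided"
) -> GroupComparisonResult:
    """Cuzick-type Wilcoxon rank trend test across >= 3 ordered groups.

    Group scores are equally spaced (1..G in label order).  The statistic is
    T = sum_i w_i R_i with mid-ranks R; under the permutation null
    E(T) = (N+1)/2 * sum w and Var(T) = N/(N-1) * s2_w * s2_R with the
    population variances of weights and ranks, giving a normal-approximation
    p.  For total n <= 8 (``mode='exact'`` or ``'auto'``) the permutation
    distribution is enumerated exactly.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(ordered_group_labels, pd.Series):
        ordered_group_labels = ordered_group_labels.to_numpy() if not isinstance(
            ordered_group_labels.dtype, pd.CategoricalDtype
        ) else pd.Categorical(ordered_group_labels)
    if isinstance(ordered_group_labels, pd.Categorical):
        cats = [c for c in ordered_group_labels.categories if (ordered_group_labels == c).any()]
        labels = np.asarray(ordered_group_labels.astype(object))
        groups = np.asarray(cats, dtype=object)
    else:
        labels = np.asarray(ordered_group_labels)
        groups = pd.unique(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels length mismatch")
    if len(groups) < 3:
        raise ValueError(
            "trend test needs >= 3 ordered groups (use wilcoxon_rank_sum for 2)"
        )
    level = {g: i + 1 for i, g in enumerate(groups)}
    w = np.array([level[g] for g in labels], dtype=float)
    n = values.size
    ranks = sps.rankdata(values)
    t_obs = _cuzick_statistic(ranks, w)
    e_t = (n + 1) / 2.0 * w.sum()

    if mode == "auto":
        mode = "exact" if n <= 8 else "approx"
    if mode == "exact":
        if n > 8:
            raise ValueError("exact trend test limited to total n <= 8")
        stats_null = np.array(
            [_cuzick_statistic(np.array(p), w) for p in permutations(ranks)]
        )
        if alternative == "two-sided":
            p = float(np.mean(np.abs(stats_null - e_t) >= abs(t_obs - e_t) - 1e-12))
        elif alternative == "increasing":
            p = float(np.mean(stats_null >= t_obs - 1e-12))
        elif alternative == "decreasing":
            p = float(np.mean(stats_null <= t_obs + 1e-12))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        z = t_obs - e_t
    else:
        var_w = np.sum((w - w.mean()) ** 2) / n
        var_r = np.sum((ranks - ranks.mean()) ** 2) / n  # tie-corrected by mid-ranks
        var_t = n * n / (n - 1.0) * var_w * var_r
        if var_t == 0:
            z, p = 0.0, 1.0
        else:
            z = (t_obs - e_t) / np.sqrt(var_t)
            if alternative == "two-sided":
                p = float(2.0 * sps.norm.sf(abs(z)))
            elif alternative == "increasing":
                p = float(sps.norm.sf(z))
            elif alternative == "decreasing":
                p = float(sps.norm.cdf(z))
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
    first, last = groups[0], groups[-1]
    direction = int(
        np.sign(np.median(values[labels == first]) - np.median(values[labels == last]))
    )
    sizes = tuple(int(np.sum(labels == g)) for g in groups)
    return GroupComparisonResult(
        statistic=float(z), p_value=min(p, 1.0), group_sizes=sizes, direction=direction
    )


def fisher_exact(table) -> GroupComparisonResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Two-sidedness is by the minimum-likelihood rule: the p value sums the
    hypergeometric probabilities of all tables (with the observed margins)
    no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        raise ValueError("Fisher's exact test requires positive margins")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    direction = int(np.sign(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]))
    return GroupComparisonResult(
        statistic=float(odds),
        p_value=min(float(p), 1.0),
        group_sizes=(int(t[0].sum()), int(t[1].sum())),
        direction=direction,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_genes_with_score(
    matrix: ExpressionMatrix, score: pd.Series, method: str = "spearman"
) -> pd.DataFrame:
    """Correlate every gene's expression with a per-sample score.

    Returns a per-gene DataFrame with columns ``r``, ``p`` and ``p_adj``
    (BH across genes).  Constant genes are reported with r = 0, p = 1 and
    logged.  Sample identifiers must match exactly (order-insensitive).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if set(score.index) != set(matrix.sample_ids):
        raise ValueError("score sample ids do not match the expression matrix")
    s = score.loc[matrix.sample_ids].to_numpy(dtype=float)
    n = s.size
    if n < 3:
        raise ValueError("correlation needs >= 3 samples")
    x = matrix.values  # genes x samples
    if method == "spearman":
        x = np.apply_along_axis(sps.rankdata, 1, x)
        s = sps.rankdata(s)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    ss = np.sqrt((sc**2).sum())
    const = sx == 0
    if const.any():
        logger.info("constant genes set to r=0, p=1: %d", int(const.sum()))
    denom = np.where(const, 1.0, sx * ss)
    r = np.clip((xc @ sc) / denom, -1.0, 1.0)
    r[const] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[const] = 1.0
    out = pd.DataFrame({"r": r, "p": p}, index=matrix.gene_ids)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def geneset_enrichment(selected, universe, target_set) -> GroupComparisonResult:
    """One-sided hypergeometric over-representation of ``target_set`` among
    ``selected`` genes drawn from ``universe``."""
    selected = set(selected)
    universe = set(universe)
    target = set(target_set)
    if not selected <= universe:
        extra = sorted(selected - universe)[:5]
        raise ValueError(f"selected genes outside the universe: {extra}")
    target_in = target & universe
    if not target_in:
        raise ValueError("target set does not intersect the universe")
    overlap = len(selected & target_in)
    M, K, n = len(universe), len(target_in), len(selected)
    p = float(sps.hypergeom.sf(overlap - 1, M, K, n))
    return GroupComparisonResult(
        statistic=float(overlap),
        p_value=min(p, 1.0),
        group_sizes=(n, K),
        direction=1 if overlap * M > K * n else (-1 if overlap * M < K * n else 0),
    )
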