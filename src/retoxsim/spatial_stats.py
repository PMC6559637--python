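"""Spatial correlation and binning statistics for hypoxia/thinning maps.

Per-eye 150 x 150 predictor maps (per-column minimum pO2, or drusen height)
are pooled with the matching follow-up thinning maps across eyes, and
summarized three ways: a pooled Pearson correlation, binned means with
standard errors, and a one-way ANOVA with Tukey's multiple-comparison test
across predictor bins.  Within-eye map points are spatially autocorrelated,
so every correlation report carries a non-independence caveat; no spatial
correction is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CorrelationReport",
    "BinSummary",
    "GroupComparison",
    "pooled_pearson",
    "bin_summary",
    "anova_tukey",
    "DEFAULT_O2_EDGES",
]

#: Oxygen bin edges in mmHg: five 10 mmHg-wide classes from "<10" (hypoxic)
#: to ">40" (well oxygenated).
DEFAULT_O2_EDGES = (10.0, 20.0, 30.0, 40.0)

NON_INDEPENDENCE_CAVEAT = (
    "pooled within-eye map points are spatially autocorrelated; "
    "p-values overstate independence"
)


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    n: int
    p: float
    grouping: str = "combined"
    caveat: str = NON_INDEPENDENCE_CAVEAT


@dataclass
class BinSummary:
    """Per-bin mean response, SEM, and count over a partition of the predictor."""

    bin_edges: np.ndarray  # interior edges; bins = (-inf, e0], (e0, e1], ..., (ek, inf)
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray
    groups: list  # raw response values per bin

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_dataframe(self) -> pd.DataFrame:
        lo = np.concatenate(([-np.inf], self.bin_edges))
        hi = np.concatenate((self.bin_edges, [np.inf]))
        return pd.DataFrame(
            {"bin_lo": lo, "bin_hi": hi, "mean": self.means, "sem": self.sems, "n": self.counts}
        )


@dataclass(frozen=True)
class GroupComparison:
    F: float
    p: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # columns group1, group2, p_adj


def _pool(pairs) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for x, y in pairs:
        x = np.asarray(getattr(x, "values", x), dtype=float)
        y = np.asarray(getattr(y, "values", y), dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired maps must have equal dims")
        m = np.isfinite(x) & np.isfinite(y)
        xs.append(x[m])
        ys.append(y[m])
    return np.concatenate(xs), np.concatenate(ys)


def pooled_pearson(pairs, grouping: str = "combined") -> CorrelationReport:
    """Pearson r over all unmasked points pooled across eyes.

    ``pairs`` is a sequence of (predictor map, response map) per eye; maps
    may be arrays or objects with a ``values`` attribute.  The p-value comes
    from the usual t transform and inherits the non-independence caveat.
    """
    x, y = _pool(pairs)
    if x.size <= 2:
        raise ValueError("need more than 2 pooled points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a pooled variable")
    res = stats.pearsonr(x, y)
    return CorrelationReport(r=float(res.statistic), n=int(x.size), p=float(res.pvalue), grouping=grouping)


def bin_summary(pairs, edges) -> BinSummary:
    """Bin the pooled response by the pooled predictor.

    ``edges`` are strictly increasing interior edges; k edges give k+1 bins
    with open outer bins.  Empty bins are reported with n = 0 and NaN mean,
    never dropped.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    x, y = _pool(pairs)
    which = np.digitize(x, edges)
    n_bins = edges.size + 1
    means = np.full(n_bins, np.nan)
    sems = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    groups = []
    for b in range(n_bins):
        g = y[which == b]
        groups.append(g)
        counts[b] = g.size
        if g.size:
            means[b] = g.mean()
            sems[b] = g.std(ddof=1) / np.sqrt(g.size) if g.size > 1 else 0.0
    return BinSummary(edges, means, sems, counts, groups)


def anova_tukey(bins: BinSummary) -> GroupComparison:
    """Classical one-way ANOVA plus Tukey HSD across the non-empty bins."""
    groups = [g for g in bins.groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups with n >= 2")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # identical constant groups: F is 0 by definition, scipy would warn
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        pairwise = pd.DataFrame(columns=["group1", "group2", "p_adj"])
    else:
        from itertools import combinations

        tk = pairwise_tukeyhsd(values, labels)
        g1, g2 = zip(*combinations(tk.groupsunique, 2))
        pairwise = pd.DataFrame({"group1": g1, "group2": g2, "p_adj": tk.pvalues})
    n = values.size
    k = len(groups)
    return GroupComparison(
        F=float(F), p=float(p), df_between=k - 1, df_within=n - k, pairwise=pairwise
    )
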