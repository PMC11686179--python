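"""Two-group Wilcoxon rank-sum tests with Benjamini-Hochberg correction,
Spearman correlations, and the per-comparison significance bookkeeping.

The rank-sum test enumerates the exact null distribution for small,
tie-free samples (n_x + n_y <= 12) and otherwise uses the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

EXACT_LIMIT = 12


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumeration of all rank assignments (no ties)."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n_x = len(x)
    w_obs = ranks[:n_x].sum()
    all_ranks = np.arange(1, len(combined) + 1)
    sums = np.array(
        [sum(c) for c in itertools.combinations(all_ranks, n_x)]
    )
    total = len(sums)
    p_low = np.count_nonzero(sums <= w_obs + 1e-12) / total
    p_high = np.count_nonzero(sums >= w_obs - 1e-12) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def _ranksum_normal(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n_x, n_y = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = ranks[:n_x].sum()
    mean = n_x * (n_x + n_y + 1) / 2.0
    n = n_x + n_y
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0  # degenerate: all observations tied
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * sps.norm.sf(z))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise StatsError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= EXACT_LIMIT and not has_ties:
        return _ranksum_exact(x, y)
    return _ranksum_normal(x, y)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Step-up BH adjusted values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

SPEARMAN_EXACT_LIMIT = 8


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho (Pearson correlation of mid-ranks) and two-sided p.

    Exact permutation p for n <= 8, t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise StatsError("spearman requires equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for constant vectors")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_LIMIT:
        rx_c = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
        ry_c = (ry - ry.mean()) / np.sqrt(((ry - ry.mean()) ** 2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = ry_c[perms] @ rx_c
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2)))
    return rho, p


# ---------------------------------------------------------------------------
# feature-level comparisons
# ---------------------------------------------------------------------------

@dataclass
class FeatureComparison:
    feature: str
    median_g1: float
    median_g2: float
    direction: int  # sign of median_g1 - median_g2
    p: float
    q: float

    @property
    def initially_significant(self) -> bool:
        return self.p < ALPHA

    @property
    def fdr_significant(self) -> bool:
        return self.q < ALPHA


def _comparison_frame(rows: List[FeatureComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "median_g1": [r.median_g1 for r in rows],
            "median_g2": [r.median_g2 for r in rows],
            "direction": [r.direction for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "initially_significant": [r.initially_significant for r in rows],
            "fdr_significant": [r.fdr_significant for r in rows],
        }
    )


def compare_two_groups(
    features: pd.DataFrame,
    group1_samples: Sequence[str],
    group2_samples: Sequence[str],
) -> pd.DataFrame:
    """One rank-sum test per feature column; BH across the feature family.

    ``features`` has samples as rows and features as columns. Constant
    features are skipped with p = 1.
    """
    g1 = [s for s in group1_samples if s in features.index]
    g2 = [s for s in group2_samples if s in features.index]
    if len(g1) < 2 or len(g2) < 2:
        raise StatsError("each group needs at least two samples")
    p_values: List[float] = []
    meta: List[Tuple[str, float, float, int]] = []
    for feature in features.columns:
        x = features.loc[g1, feature].to_numpy(dtype=float)
        y = features.loc[g2, feature].to_numpy(dtype=float)
        med1, med2 = float(np.median(x)), float(np.median(y))
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = rank_sum_test(x, y)
        p_values.append(p)
        meta.append((str(feature), med1, med2, int(np.sign(med1 - med2))))
    q_values = bh_adjust(p_values)
    rows = [
        FeatureComparison(f, m1, m2, d, p, q)
        for (f, m1, m2, d), p, q in zip(meta, p_values, q_values)
    ]
    return _comparison_frame(rows)


def compare_timepoints(
    features: pd.DataFrame,
    timepoint_of: Mapping[str, str],
    method: str = "pairwise",
) -> pd.DataFrame:
    """Time-course comparison across all time points.

    ``pairwise``: all pairwise rank-sum tests per feature, BH pooled over
    the feature x pair family, a feature flagged significant if any pair is
    (reported p/q are the per-feature minima). ``kruskal``: one omnibus
    Kruskal-Wallis test per feature, BH across features.
    """
    samples = [s for s in features.index if s in timepoint_of]
    groups: Dict[str, List[str]] = {}
    for s in samples:
        groups.setdefault(str(timepoint_of[s]), []).append(s)
    levels = sorted(groups)
    if len(levels) < 2:
        raise StatsError("need at least two time points")

    if method == "kruskal":
        p_values, meta = [], []
        for feature in features.columns:
            arrays = [
                features.loc[groups[g], feature].to_numpy(dtype=float)
                for g in levels
            ]
            flat = np.concatenate(arrays)
            if np.ptp(flat) == 0:
                p = 1.0
            else:
                p = float(sps.kruskal(*arrays).pvalue)
            p_values.append(p)
            meta.append(str(feature))
        q_values = bh_adjust(p_values)
        return pd.DataFrame(
            {
                "feature": meta,
                "p": p_values,
                "q": q_values,
                "initially_significant": [p < ALPHA for p in p_values],
                "fdr_significant": [q < ALPHA for q in q_values],
            }
        )

    if method != "pairwise":
        raise StatsError(f"unknown time-course method {method!r}")

    records: List[Tuple[str, str, float]] = []
    for feature in features.columns:
        for g1, g2 in itertools.combinations(levels, 2):
            x = features.loc[groups[g1], feature].to_numpy(dtype=float)
            y = features.loc[groups[g2], feature].to_numpy(dtype=float)
            if np.ptp(np.concatenate([x, y])) == 0:
                p = 1.0
            else:
                p = rank_sum_test(x, y)
            records.append((str(feature), f"{g1} vs {g2}", p))
    q_values = bh_adjust([p for _, _, p in records])
    long = pd.DataFrame(
        {
            "feature": [f for f, _, _ in records],
            "pair": [pair for _, pair, _ in records],
            "p": [p for _, _, p in records],
            "q": q_values,
        }
    )
    summary = (
        long.groupby("feature")
        .agg(p=("p", "min"), q=("q", "min"))
        .reset_index()
    )
    summary["initially_significant"] = summary["p"] < ALPHA
    summary["fdr_significant"] = summary["q"] < ALPHA
    summary.attrs["pairwise"] = long
    return summary


def compare_features(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    grouping: str,
    timecourse_method: str = "pairwise",
) -> pd.DataFrame:
    """Dispatch a comparison described by a grouping spec string.

    Two-group: ``"<column>:<group1>_vs_<group2>"`` with an optional
    ``"@<column>=<value>"`` sample subset, e.g.
    ``"delivery_mode:VD_vs_CSD@time_point=5 days"``. Time-course:
    ``"timepoints:<column>"``.
    """
    if grouping.startswith("timepoints:"):
        column = grouping.split(":", 1)[1]
        if column not in metadata.columns:
            raise StatsError(f"unknown metadata column {column!r}")
        return compare_timepoints(
            features, metadata[column].to_dict(), method=timecourse_method
        )
    subset = metadata
    head = grouping
    if "@" in grouping:
        head, condition = grouping.split("@", 1)
        col, _, value = condition.partition("=")
        if col not in metadata.columns:
            raise StatsError(f"unknown metadata column {col!r}")
        subset = metadata[metadata[col].astype(str) == value]
    column, _, spec = head.partition(":")
    if "_vs_" not in spec or column not in metadata.columns:
        raise StatsError(f"cannot parse grouping spec {grouping!r}")
    g1_label, g2_label = spec.split("_vs_", 1)
    g1 = subset.index[subset[column].astype(str) == g1_label]
    g2 = subset.index[subset[column].astype(str) == g2_label]
    return compare_two_groups(features, list(g1), list(g2))
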