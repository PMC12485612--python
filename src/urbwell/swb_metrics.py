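"""Stratified subjective well-being (SWB) metrics.

Post-level sentiment scores in [0, 1] inside each urbanization ring are
stratified into eight levels P1..P8 — the 10th through 80th percentiles
of the ring's score multiset (linear-interpolation percentiles, the
common "type 7" convention; recorded in output metadata).  Levels feed
three summaries:

* per-level mean / SD / Gini over zones (inequality profile),
* a disparity statistic per ring (default P8 - P1) and its trajectory,
* an OLS trend of each level across the gradient U1..UT, with the slope
  reported x100 as percentage points per gradient step.

The Gini coefficient G = sum_{j,k} |x_j - x_k| / (2 n^2 mu) is computed
via the sorted (Lorenz) form; the O(n^2) pairwise form lives in
``gini_pairwise`` and is used as the independent cross-check in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_QUANTILES: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
LEVEL_NAMES: tuple[str, ...] = tuple(f"P{k}" for k in range(1, 9))
PERCENTILE_METHOD = "linear"  # numpy's type-7 rule


def zone_percentiles(
    swb: np.ndarray,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    min_posts: int = 2,
) -> np.ndarray:
    """Level values P_i = percentile(swb, 100*i) for i in ``quantiles``.

    Linear interpolation between order statistics; output is monotone in
    i by construction.
    """
    swb = np.asarray(swb, dtype=float)
    if swb.size < min_posts:
        raise ValueError(f"need >= {min_posts} posts, got {swb.size}")
    if np.any((swb < 0) | (swb > 1)):
        raise ValueError("SWB scores must lie in [0, 1]")
    return np.percentile(swb, [100 * q for q in quantiles],
                         method=PERCENTILE_METHOD)


def stratify_posts(
    posts: pd.DataFrame,
    ring_of_post: np.ndarray,
    min_posts: int = 50,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> pd.DataFrame:
    """Per-ring level table ``ring, n_posts, P1..P8, ok``.

    Rings with fewer than ``min_posts`` posts are flagged ``ok = False``
    (the city-inclusion rule downstream requires 50 posts per ring).
    """
    df = posts.copy()
    df["ring"] = ring_of_post
    df = df[df["ring"] > 0]
    rows = []
    names = [f"P{k}" for k in range(1, len(quantiles) + 1)]
    for ring, grp in df.groupby("ring", sort=True):
        rec: dict = {"ring": int(ring), "n_posts": len(grp)}
        if len(grp) >= 2:
            levels = zone_percentiles(grp["swb"].to_numpy(), quantiles)
            rec.update(dict(zip(names, levels)))
        rec["ok"] = len(grp) >= min_posts
        rows.append(rec)
    return pd.DataFrame(rows)


def gini(values: np.ndarray) -> float:
    """Gini coefficient via the sorted-cumulative (Lorenz) identity.

    G = sum_i (2i - n - 1) x_(i) / (n^2 mu), i = 1..n ascending.
    Requires nonnegative values with positive mean; 0 for a constant
    vector, < 1 always.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    if np.any(x < 0):
        raise ValueError("Gini requires nonnegative values")
    mu = x.mean()
    if mu <= 0:
        raise ValueError("Gini requires positive mean")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * n * mu))


def gini_pairwise(values: np.ndarray) -> float:
    """O(n^2) mean-absolute-difference form; the oracle for ``gini``."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("Gini requires nonnegative values")
    mu = x.mean()
    if mu <= 0:
        raise ValueError("Gini requires positive mean")
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * x.size ** 2 * mu))


@dataclass
class TrendResult:
    level: str
    slope_pct: float  # percentage points per gradient step
    intercept: float
    p_value: float
    n_zones: int


def gradient_trend(
    level_values: np.ndarray,
    rings: np.ndarray | None = None,
    level: str = "",
) -> TrendResult:
    """OLS of a level value on the ring index t = 1..T.

    The slope is reported x100 as percentage points per gradient step
    (gradient steps are one per year, so this is also % per year); the
    p-value is the two-sided t-test on the slope.  A constant series
    returns slope 0 with p = 1 (no evidence of trend).
    """
    y = np.asarray(level_values, dtype=float)
    t = np.arange(1, y.size + 1) if rings is None else np.asarray(rings, float)
    keep = np.isfinite(y)
    y, t = y[keep], t[keep]
    if y.size < 3:
        raise ValueError("need >= 3 gradient steps with data")
    if np.allclose(y, y[0]):
        return TrendResult(level, 0.0, float(y[0]), 1.0, y.size)
    res = stats.linregress(t, y)
    return TrendResult(level, float(res.slope) * 100.0,
                       float(res.intercept), float(res.pvalue), y.size)


def relative_change(before: float, after: float) -> float:
    """Percent change (before -> after) relative to ``before``.

    relative_change(0.57, 0.50) = 12.28...% decrease (positive sign
    means a decrease).
    """
    if before == 0:
        raise ValueError("undefined relative change from 0")
    return (before - after) / before * 100.0


def inequality_profile(
    level_table: pd.DataFrame,
    level_names: tuple[str, ...] = LEVEL_NAMES,
    disparity=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inequality statistics over a zone x level table.

    Returns ``(per_level, per_ring)``: per-level mean, SD and Gini over
    zones, and the disparity statistic (default P8 - P1) per ring with
    the ring order preserved so its trajectory across the gradient can
    be inspected.
    """
    names = [n for n in level_names if n in level_table.columns]
    if len(level_table) < 2:
        raise ValueError("need >= 2 zones")
    if disparity is None:  # default gap statistic: top minus bottom level
        disparity = lambda row: row[names[-1]] - row[names[0]]
    per_level = pd.DataFrame({
        "level": names,
        "mean": [level_table[n].mean() for n in names],
        "sd": [level_table[n].std(ddof=1) for n in names],
        "gini": [gini(level_table[n].to_numpy()) for n in names],
    })
    per_ring = pd.DataFrame({
        "ring": level_table["ring"] if "ring" in level_table else
                np.arange(1, len(level_table) + 1),
        "disparity": level_table.apply(disparity, axis=1),
    })
    return per_level, per_ring
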