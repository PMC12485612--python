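"""Associating SWB levels with socioecological factors.

The analysis panel has one row per (city, ring) and columns P1..P8 plus
eleven candidate drivers — street ecology (SE, GN, GY, OP, CR),
vegetation (NDVI), air temperature (AT), road density (RD), population
density (POP, with "PD" accepted as an alias), public-service density
(PS) and GDP — min-max normalized to [0, 1] per analysis run.  Four
complementary views are computed:

* per-level Pearson correlations with two-sided p-values,
* forward/backward stepwise OLS (partial-F entry at ``alpha_enter``,
  t-test removal at ``alpha_remove``) per city x level, with factor
  importance counted as retention frequency across models,
* the Geodetector q-statistic q = 1 - SSW/SST over a stratification
  (continuous factors are quantile-binned first), single factors and
  pairwise interactions, significance by label permutation,
* a regression-discontinuity linearity check: two independent lines
  either side of a cutoff, delta = |left(c) - right(c)|; small delta
  supports a single linear relationship.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: the eleven candidate drivers, in registry order
FACTORS: tuple[str, ...] = (
    "SE", "NDVI", "AT", "RD", "POP", "PS", "GDP", "GN", "GY", "OP", "CR",
)
#: "PD" (population density) appears in some outputs as a synonym of POP
FACTOR_ALIASES: dict[str, str] = {"PD": "POP"}


def canonical_factor(name: str) -> str:
    return FACTOR_ALIASES.get(name, name)


def minmax_normalize(panel: pd.DataFrame,
                     columns: tuple[str, ...] = FACTORS) -> pd.DataFrame:
    """Min-max scale the given columns to [0, 1] (idempotent)."""
    out = panel.copy()
    for c in columns:
        if c not in out:
            continue
        lo, hi = out[c].min(), out[c].max()
        if hi > lo:
            out[c] = (out[c] - lo) / (hi - lo)
        else:
            out[c] = 0.0
    return out


# --------------------------------------------------------------------------
# correlations

def level_factor_correlation(
    panel: pd.DataFrame,
    level: str,
    factors: tuple[str, ...] = FACTORS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r of one SWB level against every factor.

    Zero-variance columns yield ``r = NaN`` with ``defined = False``
    rather than an error; stars mark p < alpha.
    """
    sub = panel[[level, *factors]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete rows")
    rows = []
    y = sub[level].to_numpy()
    for f in factors:
        x = sub[f].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"factor": f, "r": np.nan, "p": np.nan,
                         "defined": False, "significant": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"factor": f, "r": float(r), "p": float(p),
                     "defined": True, "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stepwise regression

class CollinearityError(ValueError):
    def __init__(self, pairs):
        self.pairs = pairs
        super().__init__(f"near-collinear candidate columns: {pairs}")


@dataclass
class StepwiseResult:
    level: str
    retained: list[str]
    coefficients: dict[str, float]   # includes "const"
    t_stats: dict[str, float]
    entry_f: dict[str, float]        # partial F at the step each entered
    r_squared: float
    model_p: float
    n_obs: int


def _check_collinearity(X: pd.DataFrame, cond_max: float = 1e10) -> None:
    Z = X.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    norms = np.linalg.norm(Z, axis=0)
    norms[norms == 0] = 1.0
    Z = Z / norms
    if np.linalg.cond(Z) <= cond_max:
        return
    corr = np.abs(np.corrcoef(Z, rowvar=False))
    pairs = [
        (X.columns[i], X.columns[j])
        for i, j in itertools.combinations(range(X.shape[1]), 2)
        if corr[i, j] > 0.9999
    ]
    raise CollinearityError(pairs or [("<condition number>", f"{cond_max:g}")])


def _partial_f(y, X_small: np.ndarray, X_big: np.ndarray) -> tuple[float, float]:
    """F statistic and p-value for adding the columns of X_big \\ X_small."""
    n = len(y)
    rss_s = sm.OLS(y, X_small).fit().ssr
    fit_b = sm.OLS(y, X_big).fit()
    rss_b = fit_b.ssr
    df_extra = X_big.shape[1] - X_small.shape[1]
    df_resid = n - X_big.shape[1]
    if df_resid <= 0:
        return np.nan, 1.0
    denom = rss_b / df_resid
    if denom <= 0:  # perfect fit: infinitely strong evidence
        return np.inf, 0.0
    F = (rss_s - rss_b) / df_extra / denom
    return float(F), float(stats.f.sf(F, df_extra, df_resid))


def stepwise_fit(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    level: str = "",
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward-selection / backward-elimination OLS.

    Each forward step adds the candidate with the largest partial F if
    its Bonferroni-adjusted p-value (over the candidates scanned that
    step) is below ``alpha_enter`` — so ``alpha_enter`` is the
    family-wise false-entry rate per step, not a per-candidate level.
    Each backward step drops the retained variable with the largest
    t-test p-value above ``alpha_remove``.  Iteration stops at a fixed
    point, with a no-revisit guard on retained sets so entry/removal
    cycles terminate.
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("need n rows > candidate count + 2")
    _check_collinearity(X)
    candidates = list(X.columns)
    retained: list[str] = []
    entry_f: dict[str, float] = {}
    seen: set[frozenset] = {frozenset()}

    def design(cols):
        return sm.add_constant(X[cols].to_numpy(dtype=float)) if cols \
            else np.ones((len(y), 1))

    sst = float(np.sum((y - y.mean()) ** 2))
    for _ in range(max_steps):
        changed = False
        # forward: best candidate by partial F; skip once the fit is
        # numerically perfect (F-tests on rounding error are meaningless)
        if retained and sm.OLS(y, design(retained)).fit().ssr <= 1e-10 * sst:
            break
        best, best_F, best_p, n_scanned = None, -np.inf, 1.0, 0
        for c in candidates:
            if c in retained:
                continue
            F, p = _partial_f(y, design(retained), design(retained + [c]))
            if np.isnan(F):
                continue
            n_scanned += 1
            if F > best_F:
                best, best_F, best_p = c, F, p
        # alpha_enter is a family-wise level per forward step: the best
        # of m partial-F tests is Bonferroni-adjusted before entry
        if best is not None and min(best_p * n_scanned, 1.0) < alpha_enter:
            trial = frozenset(retained + [best])
            if trial not in seen:
                retained.append(best)
                entry_f[best] = best_F
                seen.add(trial)
                changed = True
        # backward: worst retained variable by t-test p
        while retained:
            fit = sm.OLS(y, design(retained)).fit()
            pvals = fit.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if pvals[worst] <= alpha_remove:
                break
            trial = frozenset(r for i, r in enumerate(retained) if i != worst)
            if trial in seen:
                break
            retained.pop(worst)
            seen.add(trial)
            changed = True
        if not changed:
            break

    fit = sm.OLS(y, design(retained)).fit()
    names = ["const", *retained]
    return StepwiseResult(
        level=level,
        retained=list(retained),
        coefficients=dict(zip(names, map(float, fit.params))),
        t_stats=dict(zip(names, map(float, fit.tvalues))),
        entry_f=entry_f,
        r_squared=float(fit.rsquared) if retained else 0.0,
        model_p=float(fit.f_pvalue) if retained else 1.0,
        n_obs=len(y),
    )


def importance_frequency(results: list[StepwiseResult],
                         factors: tuple[str, ...] = FACTORS) -> pd.DataFrame:
    """Retention counts per factor across all fitted models.

    Sorted by count descending; ties broken alphabetically and flagged
    in the ``tied`` column.
    """
    if not results:
        raise ValueError("need at least one stepwise result")
    counts = {f: 0 for f in factors}
    for res in results:
        for v in res.retained:
            v = canonical_factor(v)
            if v in counts:
                counts[v] += 1
    df = pd.DataFrame({"factor": list(counts), "count": list(counts.values())})
    df = df.sort_values(["count", "factor"], ascending=[False, True],
                        ignore_index=True)
    dup = df["count"].duplicated(keep=False)
    df["tied"] = dup
    return df


# --------------------------------------------------------------------------
# Geodetector

@dataclass
class GeodetectorResult:
    factor: str
    q: float
    p_value: float | None = None
    significant: bool | None = None
    n_strata: int = 0


def quantile_bins(x: np.ndarray, k: int = 5) -> np.ndarray:
    """Equal-frequency discretization into <= k strata (integer labels)."""
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, k + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def _q_statistic(y: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero total variance: q undefined")
    ssw = 0.0
    strata = np.unique(labels)
    for h in strata:
        yh = y[labels == h]
        ssw += float(np.sum((yh - yh.mean()) ** 2))
    return 1.0 - ssw / sst, strata.size


def geodetector_q(
    y: np.ndarray,
    strata: np.ndarray,
    factor: str = "",
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    min_stratum: int = 2,
) -> GeodetectorResult:
    """q = 1 - SSW/SST for a stratification of y.

    Strata smaller than ``min_stratum`` are merged into their nearest
    (by label order) neighbour.  With ``n_permutations`` > 0 a
    permutation test of the labels gives the significance of q; pass a
    seeded Generator for reproducibility.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(strata).copy()
    # merge undersized strata forward into the next label
    uniq, counts = np.unique(labels, return_counts=True)
    order = list(uniq)
    for h, c in zip(uniq, counts):
        if c < min_stratum and len(order) > 1:
            i = order.index(h)
            target = order[i - 1] if i > 0 else order[1]
            labels[labels == h] = target
            order.remove(h)
    q, k = _q_statistic(y, labels)
    p = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        hits = 0
        for _ in range(n_permutations):
            qp, _ = _q_statistic(y, rng.permutation(labels))
            hits += qp >= q
        p = (hits + 1) / (n_permutations + 1)
    return GeodetectorResult(factor=factor, q=float(q), p_value=p,
                             significant=None if p is None else p < 0.05,
                             n_strata=k)


def interaction_strata(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Overlay of two stratifications: one stratum per label pair."""
    pairs = pd.Series(zip(np.asarray(a), np.asarray(b)))
    return pairs.astype("category").cat.codes.to_numpy()


def geodetector_matrix(
    panel: pd.DataFrame,
    level: str,
    factors: tuple[str, ...] = FACTORS,
    k: int = 5,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-factor and pairwise-interaction q values for one level."""
    y = panel[level].to_numpy(dtype=float)
    bins = {f: quantile_bins(panel[f].to_numpy(), k) for f in factors}
    rows = []
    for f in factors:
        res = geodetector_q(y, bins[f], factor=f,
                            n_permutations=n_permutations, rng=rng)
        rows.append({"factor_a": f, "factor_b": "", "q": res.q,
                     "p": res.p_value})
    for fa, fb in itertools.combinations(factors, 2):
        lab = interaction_strata(bins[fa], bins[fb])
        res = geodetector_q(y, lab, factor=f"{fa}x{fb}",
                            n_permutations=n_permutations, rng=rng)
        rows.append({"factor_a": fa, "factor_b": fb, "q": res.q,
                     "p": res.p_value})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# regression discontinuity

@dataclass
class RDResult:
    cutoff: float
    left: tuple[float, float]    # (slope, intercept)
    right: tuple[float, float]
    delta: float
    linear: bool = field(init=False)
    threshold: float = 0.05

    def __post_init__(self) -> None:
        self.linear = self.delta < self.threshold


def rd_check(
    y: np.ndarray,
    x: np.ndarray,
    cutoff: float | None = None,
    threshold: float = 0.05,
) -> RDResult:
    """Linearity check by regression discontinuity.

    Independent OLS lines are fitted strictly left (< cutoff) and right
    (>= cutoff) of the cutoff (default: midpoint of x); delta is the
    absolute gap between the two fitted lines evaluated at the cutoff.
    delta below ``threshold`` is taken as consistent with a single
    linear relationship.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if cutoff is None:
        cutoff = float((x.min() + x.max()) / 2)
    lx, ly = x[x < cutoff], y[x < cutoff]
    rx, ry = x[x >= cutoff], y[x >= cutoff]
    if lx.size < 3 or rx.size < 3:
        raise ValueError("need >= 3 points on each side of the cutoff")
    lfit = np.polyfit(lx, ly, 1)
    rfit = np.polyfit(rx, ry, 1)
    delta = abs(np.polyval(lfit, cutoff) - np.polyval(rfit, cutoff))
    res = RDResult(cutoff=cutoff, left=(float(lfit[0]), float(lfit[1])),
                   right=(float(rfit[0]), float(rfit[1])),
                   delta=float(delta))
    res.threshold = threshold
    res.linear = res.delta < threshold
    return res
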