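"""Inferential layer: Monte-Carlo permutation tests and the wind regressions.

The two-group comparison uses a standardized linear permutation statistic
(equivalent to a mean difference): T = sum of group A, standardized by its
exact mean and variance under the permutation null, with a two-sided
Monte-Carlo p-value from 9999 resamplings by default (exact enumeration is
used automatically when the number of arrangements is small).  The ordinary
least-squares models for ground/air speed on wind support and wind support
on route x direction are fitted with statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.special import comb

DEFAULT_RESAMPLES = 9999
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class PermutationResult:
    z: float
    p: float
    n_resamples: int
    seed: int | None
    exact: bool


@dataclass
class RegressionResult:
    f_statistic: float
    df: tuple[int, int]
    p: float
    r_squared: float
    coefficients: dict  # term -> (estimate, standard error)
    term_pvalues: dict


def permutation_test(group_a, group_b,
                     n_resamples: int = DEFAULT_RESAMPLES,
                     seed: int | None = None) -> PermutationResult:
    """Two-sided permutation test for a location difference between groups.

    The statistic is T = sum(group_a), standardized with its exact
    permutation-null moments: E[T] = n_a * mean(pooled) and
    Var[T] = n_a (N - n_a) / (N - 1) * var(pooled).  When the number of
    distinct arrangements C(N, n_a) is at most 20000 the null distribution
    is enumerated exhaustively; otherwise ``n_resamples`` Monte-Carlo draws
    are used and the raw proportion of |Z*| >= |Z| reported, floored at
    1 / n_resamples.  Zero pooled variance degenerates to Z = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    mean = pooled.mean()
    var = pooled.var(ddof=0)
    if var <= 0:
        return PermutationResult(z=0.0, p=1.0, n_resamples=0, seed=seed,
                                 exact=True)
    e_t = n_a * mean
    var_t = n_a * (n - n_a) / (n - 1) * var
    sd_t = np.sqrt(var_t)

    def z_of(t):
        return (t - e_t) / sd_t

    z_obs = float(z_of(a.sum()))
    if comb(n, n_a, exact=True) <= EXACT_ENUMERATION_LIMIT:
        sums = np.array([
            sum(c) for c in itertools.combinations(pooled, n_a)
        ])
        z_null = np.abs((sums - e_t) / sd_t)
        p = float(np.mean(z_null >= abs(z_obs) - 1e-12))
        return PermutationResult(z=z_obs, p=p, n_resamples=len(sums),
                                 seed=seed, exact=True)
    rng = np.random.default_rng(seed)
    # vectorised label permutations: random keys -> first n_a columns
    sums = np.empty(n_resamples)
    block = 2000
    for start in range(0, n_resamples, block):
        b = min(block, n_resamples - start)
        order = np.argsort(rng.random((b, n)), axis=1)[:, :n_a]
        sums[start:start + b] = pooled[order].sum(axis=1)
    z_null = np.abs((sums - e_t) / sd_t)
    p = float(np.mean(z_null >= abs(z_obs) - 1e-12))
    p = max(p, 1.0 / n_resamples)
    return PermutationResult(z=z_obs, p=p, n_resamples=n_resamples,
                             seed=seed, exact=False)


def _from_fit(fit) -> RegressionResult:
    terms = {
        name: (float(fit.params[name]), float(fit.bse[name]))
        for name in fit.params.index
    }
    pvals = {name: float(fit.pvalues[name]) for name in fit.params.index}
    df = (int(fit.df_model), int(fit.df_resid))
    f = float(fit.fvalue) if np.isfinite(fit.fvalue) else 0.0
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 1.0
    r2 = float(fit.rsquared) if np.isfinite(fit.rsquared) else 0.0
    return RegressionResult(f_statistic=f, df=df, p=p, r_squared=r2,
                            coefficients=terms, term_pvalues=pvals)


def fit_speed_wind(speeds, supports, response: str = "ground"
                   ) -> RegressionResult:
    """OLS of ground or air speed (km/h) on wind support (km/h).

    ``speeds`` and ``supports`` are paired sequences (or the columns of an
    annotated-leg table).  The slope is the change in speed per km/h of
    additional wind support.
    """
    speeds = np.asarray(speeds, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if len(speeds) != len(supports):
        raise ValueError("speeds and supports must be paired")
    if len(speeds) < 3:
        raise ValueError("need at least 3 paired observations")
    y = speeds if response == "ground" else speeds - supports
    if np.ptp(y) == 0 or np.ptp(supports) == 0:
        return RegressionResult(0.0, (1, len(y) - 2), 1.0, 0.0,
                                {"Intercept": (float(np.mean(y)), 0.0),
                                 "support": (0.0, 0.0)},
                                {"Intercept": 1.0, "support": 1.0})
    fit = smf.ols("y ~ support",
                  data=pd.DataFrame({"y": y, "support": supports})).fit()
    return _from_fit(fit)


def fit_wind_route_direction(supports, route, direction) -> RegressionResult:
    """OLS of wind support on route + direction + interaction.

    Reference levels are the eastern route and northward direction, so the
    route coefficient is the change when moving to the Himalayan route and
    the direction coefficient the change on southward migration.
    """
    df = pd.DataFrame({
        "support": np.asarray(supports, dtype=float),
        "route": pd.Categorical(route, categories=["eastern", "himalayan"]),
        "direction": pd.Categorical(direction,
                                    categories=["north", "south"]),
    })
    if df["route"].nunique() < 2 or df["direction"].nunique() < 2:
        raise ValueError("both factors need at least 2 levels present")
    if np.ptp(df["support"].to_numpy()) == 0:
        names = ["Intercept", "route[T.himalayan]", "direction[T.south]",
                 "route[T.himalayan]:direction[T.south]"]
        coefs = {n: (0.0, 0.0) for n in names}
        coefs["Intercept"] = (float(df["support"].iloc[0]), 0.0)
        return RegressionResult(0.0, (3, len(df) - 4), 1.0, 0.0, coefs,
                                {n: 1.0 for n in names})
    fit = smf.ols("support ~ route * direction", data=df).fit()
    return _from_fit(fit)


def correlate_durations(north_days, south_days,
                        exclude: np.ndarray | None = None
                        ) -> RegressionResult:
    """OLS of southward on northward migration duration per bird.

    ``exclude`` optionally masks flagged outlier birds before fitting.
    """
    x = np.asarray(north_days, dtype=float)
    y = np.asarray(south_days, dtype=float)
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        x, y = x[keep], y[keep]
    if np.ptp(y) == 0 and np.ptp(x) == 0:
        return RegressionResult(0.0, (1, max(len(x) - 2, 0)), 1.0, 1.0,
                                {"Intercept": (float(np.mean(y)), 0.0),
                                 "north": (0.0, 0.0)},
                                {"Intercept": 1.0, "north": 1.0})
    fit = smf.ols("south ~ north",
                  data=pd.DataFrame({"south": y, "north": x})).fit()
    return _from_fit(fit)
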