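"""Regression reports with 95 % confidence bands, one-way ANOVA with
Bonferroni post-tests, and extra-sum-of-squares model comparison.

The band on a least-squares fit is the pointwise CI of the *mean*
prediction, mean(x0) ± t(0.975, n-p) * se_mean(x0); for the nonlinear
Platt model the band uses first-order (delta-method) error propagation
through the parameter covariance.  Post-hoc pairwise comparisons use the
pooled ANOVA error term with the classic Bonferroni multiplier (raw p
times the number of pairs, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .growth import PlattLightResponse, platt_mu

__all__ = [
    "FitReport",
    "GroupComparison",
    "fit_with_band",
    "anova_bonferroni",
    "compare_fits",
]

SCHEMA_VERSION = 1


@dataclass
class FitReport:
    """A least-squares fit with its CI band on an evaluation grid."""

    model: str  # 'linear' | 'poly2' | 'platt'
    coefficients: dict
    ci95: dict
    r2: float
    n: int
    n_params: int
    ss_res: float
    grid: np.ndarray
    band_mean: np.ndarray
    band_half_width: np.ndarray
    schema_version: int = SCHEMA_VERSION


@dataclass
class GroupComparison:
    """One-way ANOVA + Bonferroni-adjusted all-pairs post tests."""

    levels: list
    means: dict
    sds: dict
    ns: dict
    f_stat: float
    p_anova: float
    pairs: dict = field(default_factory=dict)  # (a, b) -> dict(raw_p, adj_p, t)
    schema_version: int = SCHEMA_VERSION


def _poly_band(x, y, order, grid):
    n = x.size
    p = order + 1
    X = np.vander(x, p)
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: collinear polynomial terms up to order {order}"
        )
    fitted = X @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    dof = n - p
    s2 = ss_res / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.inv(X.T @ X)
    G = np.vander(np.asarray(grid, float), p)
    se_mean = np.sqrt(np.einsum("ij,jk,ik->i", G, XtX_inv, G) * s2)
    tcrit = stats.t.ppf(0.975, max(dof, 1))
    se_coef = np.sqrt(np.diag(XtX_inv) * s2)
    names = [f"c{order - k}" for k in range(p)]  # c0 = intercept last in vander
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return FitReport(
        model="linear" if order == 1 else f"poly{order}",
        coefficients=dict(zip(names, map(float, coef))),
        ci95={k: float(tcrit * s) for k, s in zip(names, se_coef)},
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        n=n,
        n_params=p,
        ss_res=ss_res,
        grid=np.asarray(grid, float),
        band_mean=G @ coef,
        band_half_width=tcrit * se_mean,
    )


def fit_with_band(x, y, model: str = "linear", grid=None) -> FitReport:
    """Least-squares fit with a 95 % CI band on the mean prediction.

    ``model`` is 'linear', 'poly2' (order-2 polynomial, the figure-style
    pooled-response curve) or 'platt'.
    """
    x = np.asarray(x, float).reshape(-1)
    y = np.asarray(y, float).reshape(-1)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.asarray(grid, float)

    if model == "linear":
        rep = _poly_band(x, y, 1, grid)
    elif model == "poly2":
        rep = _poly_band(x, y, 2, grid)
    elif model == "platt":
        est = PlattLightResponse().fit(x, y)
        popt = np.array([est.mu_s_, est.alpha_, est.beta_])
        n, p = x.size, 3
        if n <= p:
            raise ValueError("need n > number of parameters")
        ss_res = float(np.sum((y - est.predict(x)) ** 2))
        tcrit = stats.t.ppf(0.975, n - p)
        J = np.empty((grid.size, p))
        for k in range(p):
            h = max(abs(popt[k]) * 1e-6, 1e-12)
            up, dn = popt.copy(), popt.copy()
            up[k] += h
            dn[k] -= h
            J[:, k] = (platt_mu(grid, *up) - platt_mu(grid, *dn)) / (2 * h)
        se_mean = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", J, est.pcov_, J), 0, None))
        rep = FitReport(
            model="platt",
            coefficients=dict(mu_s=est.mu_s_, alpha=est.alpha_, beta=est.beta_,
                              mu_max=est.mu_max_, i_opt=est.i_opt_),
            ci95=est.ci95_,
            r2=est.r2_,
            n=n,
            n_params=p,
            ss_res=ss_res,
            grid=grid,
            band_mean=platt_mu(grid, *popt),
            band_half_width=tcrit * se_mean,
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    if x.size <= rep.n_params:
        raise ValueError("need n > number of parameters")
    return rep


def anova_bonferroni(groups: dict) -> GroupComparison:
    """One-way ANOVA with Bonferroni-adjusted all-pairs post-hoc t tests.

    ``groups`` maps level labels to 1-D samples (each n >= 2).  Post-hoc
    t statistics use the pooled ANOVA mean-square error with N - k
    degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, float).reshape(-1) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    levels = list(arrays)
    f_stat, p_anova = stats.f_oneway(*arrays.values())
    big_n = sum(v.size for v in arrays.values())
    k = len(arrays)
    mse = sum(np.sum((v - v.mean()) ** 2) for v in arrays.values()) / (big_n - k)
    m = k * (k - 1) // 2
    pairs = {}
    for a, b in combinations(levels, 2):
        va, vb = arrays[a], arrays[b]
        se = np.sqrt(mse * (1 / va.size + 1 / vb.size))
        t = (va.mean() - vb.mean()) / se if se > 0 else 0.0
        raw = 2 * stats.t.sf(abs(t), big_n - k)
        pairs[(a, b)] = dict(t=float(t), raw_p=float(raw),
                             adj_p=float(min(raw * m, 1.0)))
    return GroupComparison(
        levels=levels,
        means={k: float(v.mean()) for k, v in arrays.items()},
        sds={k: float(v.std(ddof=1)) for k, v in arrays.items()},
        ns={k: int(v.size) for k, v in arrays.items()},
        f_stat=float(f_stat),
        p_anova=float(p_anova),
        pairs=pairs,
    )


def compare_fits(fit_a: FitReport, fit_b: FitReport) -> dict:
    """Extra-sum-of-squares F test between nested fits on the same data.

    ``fit_a`` must be the simpler model nested in ``fit_b``.  The simpler
    model is preferred unless p < 0.05.
    """
    if fit_a.n != fit_b.n:
        raise ValueError("fits are not on the same data (different n)")
    if fit_b.n_params <= fit_a.n_params:
        raise ValueError("fit_a must be nested in (have fewer parameters than) fit_b")
    df1 = fit_b.n_params - fit_a.n_params
    df2 = fit_b.n - fit_b.n_params
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the complex model")
    num = max(fit_a.ss_res - fit_b.ss_res, 0.0) / df1
    den = fit_b.ss_res / df2
    f = num / den if den > 0 else (0.0 if num == 0 else np.inf)
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return dict(
        f_stat=float(f),
        p=p,
        df=(df1, df2),
        preferred=fit_b.model if p < 0.05 else fit_a.model,
        schema_version=SCHEMA_VERSION,
    )
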