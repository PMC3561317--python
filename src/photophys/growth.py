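"""Turbidostat growth-rate extraction and the Platt light-response fit.

A turbidostat trace is a sawtooth: optical density (OD680) rises
exponentially until a set-point triggers a 10 % volumetric dilution, which
drops OD by the same factor.  The specific growth rate mu (d-1) is the
exponential rate within each dilution cycle; the culture's rate is the
mean over the last cycles before harvest.

The light response of growth is fitted with the Platt photoinhibition
model

    mu(I) = mu_s * (1 - exp(-alpha*I/mu_s)) * exp(-beta*I/mu_s)

where alpha is the initial slope (d-1 per µmol photons m-2 s-1), beta the
photoinhibition parameter (same units) and mu_s a scale parameter.  The
curve maximum has the closed form

    mu_max = mu_s * [alpha/(alpha+beta)] * [beta/(alpha+beta)]**(beta/alpha)

attained at I_opt = (mu_s/alpha) * ln((alpha+beta)/beta); for beta = 0 the
curve saturates at mu_max = mu_s and has no finite optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)

__all__ = [
    "TurbidostatTrace",
    "DilutionCycle",
    "LightResponseFit",
    "segment_cycles",
    "fit_cycle_mu",
    "mean_growth_rate",
    "analyze_trace",
    "platt_mu",
    "platt_mu_max",
    "platt_i_opt",
    "PlattLightResponse",
    "fit_platt",
]


@dataclass
class TurbidostatTrace:
    """OD680 sawtooth time series; time in hours, strictly increasing."""

    time: np.ndarray
    od680: np.ndarray
    setpoint: float | None = None
    dilution_fraction: float = 0.10

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.od680 = np.asarray(self.od680, float)
        if self.time.shape != self.od680.shape:
            raise ValueError("time and od680 must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od680 <= 0):
            raise ValueError("od680 must be > 0")
        if not 0 < self.dilution_fraction < 1:
            raise ValueError("dilution_fraction must be in (0, 1)")


@dataclass
class DilutionCycle:
    """One exponential segment between dilutions (indices into the trace)."""

    start_index: int
    end_index: int
    mu: float | None = None  # d-1
    r2: float | None = None
    duration: float | None = None  # hours


@dataclass
class LightResponseFit:
    """Fitted Platt parameters with 95 % CI half-widths."""

    mu_s: float
    alpha: float
    beta: float
    mu_max: float
    i_opt: float
    ci95: dict = field(default_factory=dict)
    r2: float | None = None
    n: int | None = None


def segment_cycles(
    trace: TurbidostatTrace, drop_threshold: float = 0.05
) -> list[DilutionCycle]:
    """Split a sawtooth trace at dilution events.

    A new cycle starts after a sample-to-sample relative OD drop larger
    than ``drop_threshold`` (default 0.05 = half the 10 % dilution step,
    separating dilutions from noise).  Segments with fewer than 4 samples
    are discarded.
    """
    if not 0 < drop_threshold <= trace.dilution_fraction:
        raise ValueError("drop_threshold must be in (0, dilution_fraction]")
    if trace.time.size < 4:
        raise ValueError("need at least 4 samples")
    rel = np.diff(trace.od680) / trace.od680[:-1]
    drops = np.flatnonzero(rel < -drop_threshold)
    starts = np.concatenate([[0], drops + 1])
    ends = np.concatenate([drops, [trace.time.size - 1]])  # inclusive
    cycles = [
        DilutionCycle(int(s), int(e), duration=float(trace.time[e] - trace.time[s]))
        for s, e in zip(starts, ends)
        if e - s + 1 >= 4
    ]
    if not cycles:
        log.warning("no complete dilution cycles detected (>=4 samples each)")
    return cycles


def fit_cycle_mu(time_h: np.ndarray, od680: np.ndarray) -> tuple[float, float]:
    """Exponential growth rate of one cycle.

    Least squares on log OD (the exponential fit under multiplicative
    noise): od(t) = od0 * exp(mu*t).  Returns (mu in d-1, r^2).
    """
    t = np.asarray(time_h, float)
    od = np.asarray(od680, float)
    if t.size < 4:
        raise ValueError("need at least 4 points per cycle")
    if np.any(od <= 0):
        raise ValueError("od680 must be > 0")
    res = stats.linregress(t, np.log(od))
    if not np.isfinite(res.slope):
        raise RuntimeError("singular exponential fit")
    return float(res.slope * 24.0), float(res.rvalue**2)


def analyze_trace(
    trace: TurbidostatTrace, drop_threshold: float = 0.05
) -> list[DilutionCycle]:
    """Segment a trace and fit mu for every cycle."""
    cycles = segment_cycles(trace, drop_threshold)
    for c in cycles:
        sl = slice(c.start_index, c.end_index + 1)
        c.mu, c.r2 = fit_cycle_mu(trace.time[sl], trace.od680[sl])
    return cycles


def mean_growth_rate(
    cycles: list[DilutionCycle], n_last: int = 10
) -> tuple[float, float]:
    """Unweighted mean and SD of mu over the most recent cycles.

    The culture growth rate is the average over the final ``n_last``
    complete dilution cycles; if fewer are available all are used.
    """
    if not cycles:
        raise ValueError("empty cycle list")
    if n_last < 1:
        raise ValueError("n_last must be >= 1")
    mus = np.array([c.mu for c in cycles if c.mu is not None], float)
    if mus.size == 0:
        raise ValueError("cycles carry no fitted mu; run analyze_trace first")
    if n_last > mus.size:
        log.info("n_last=%d exceeds available cycles (%d); using all", n_last, mus.size)
    use = mus[-min(n_last, mus.size):]
    return float(use.mean()), float(use.std(ddof=1)) if use.size > 1 else 0.0


# ---------------------------------------------------------------- Platt fit


def platt_mu(i, mu_s, alpha, beta):
    """Platt photoinhibition curve mu(I)."""
    i = np.asarray(i, float)
    return mu_s * (1.0 - np.exp(-alpha * i / mu_s)) * np.exp(-beta * i / mu_s)


def platt_mu_max(mu_s: float, alpha: float, beta: float) -> float:
    """Closed-form maximum of the Platt curve (mu_s in the beta -> 0 limit)."""
    if beta <= 0:
        return float(mu_s)
    ab = alpha + beta
    return float(mu_s * (alpha / ab) * (beta / ab) ** (beta / alpha))


def platt_i_opt(mu_s: float, alpha: float, beta: float) -> float:
    """Irradiance of the curve maximum; infinite when beta = 0."""
    if beta <= 0:
        return float("inf")
    return float(mu_s / alpha * np.log((alpha + beta) / beta))


class PlattLightResponse(BaseEstimator, RegressorMixin):
    """Platt photoinhibition light-response curve, scikit-learn style.

    Fits mu(I) = mu_s*(1 - exp(-alpha*I/mu_s))*exp(-beta*I/mu_s) by
    nonlinear least squares.  Irradiances are taken per observation (each
    culture replicate at its actually measured light level), not averaged
    to nominal levels.

    Parameters
    ----------
    fit_beta : bool
        If False, beta is pinned to 0 (saturating curve without
        photoinhibition).

    Attributes
    ----------
    mu_s_, alpha_, beta_ : fitted parameters
    mu_max_ : closed-form curve maximum (d-1); may exceed every observed mu
    i_opt_ : irradiance of the maximum (µmol photons m-2 s-1)
    ci95_ : dict of 95 % CI half-widths for mu_s, alpha, beta and (by
        first-order error propagation) mu_max
    r2_, n_ : fit quality and sample size
    """

    def __init__(self, fit_beta: bool = True):
        self.fit_beta = fit_beta

    def fit(self, X, y):
        i = np.asarray(X, float).reshape(-1)
        mu = np.asarray(y, float).reshape(-1)
        if i.size != mu.size:
            raise ValueError("X and y must have the same length")
        if np.unique(i).size < 4:
            raise ValueError("need at least 4 distinct light levels")
        if np.allclose(mu, mu[0]):
            raise ValueError("degenerate fit: all growth rates identical")

        mu_s0 = max(mu.max(), 1e-6) * 1.2
        lo = i > 0
        alpha0 = max(np.median(mu[lo] / i[lo]), 1e-6) if lo.any() else 0.01
        p0 = [mu_s0, alpha0] + ([alpha0 * 0.05] if self.fit_beta else [])
        bounds = ([1e-9, 1e-9] + ([0.0] if self.fit_beta else []), np.inf)

        def model(ii, *p):
            return platt_mu(ii, p[0], p[1], p[2] if self.fit_beta else 0.0)

        try:
            popt, pcov = optimize.curve_fit(
                model, i, mu, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as err:
            resid = mu - model(i, *p0)
            raise RuntimeError(
                f"Platt fit did not converge (initial residual norm "
                f"{np.linalg.norm(resid):.3g})"
            ) from err

        self.mu_s_, self.alpha_ = float(popt[0]), float(popt[1])
        self.beta_ = float(popt[2]) if self.fit_beta else 0.0
        self.mu_max_ = platt_mu_max(self.mu_s_, self.alpha_, self.beta_)
        self.i_opt_ = platt_i_opt(self.mu_s_, self.alpha_, self.beta_)
        self.pcov_ = pcov
        self.n_ = int(mu.size)

        npar = len(popt)
        dof = max(self.n_ - npar, 1)
        tcrit = stats.t.ppf(0.975, dof)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        names = ["mu_s", "alpha"] + (["beta"] if self.fit_beta else [])
        self.ci95_ = {k: float(tcrit * s) for k, s in zip(names, se)}
        if not self.fit_beta:
            self.ci95_["beta"] = 0.0
        # mu_max CI by first-order propagation through the closed form
        grad = _num_grad(
            lambda p: platt_mu_max(p[0], p[1], p[2] if self.fit_beta else 0.0), popt
        )
        var = float(grad @ pcov @ grad)
        self.ci95_["mu_max"] = float(tcrit * np.sqrt(max(var, 0.0)))

        ss_res = float(np.sum((mu - model(i, *popt)) ** 2))
        ss_tot = float(np.sum((mu - mu.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, X):
        i = np.asarray(X, float).reshape(-1)
        return platt_mu(i, self.mu_s_, self.alpha_, self.beta_)


def _num_grad(f, p, rel=1e-6):
    p = np.asarray(p, float)
    g = np.zeros_like(p)
    for k in range(p.size):
        h = max(abs(p[k]) * rel, 1e-12)
        pp, pm = p.copy(), p.copy()
        pp[k] += h
        pm[k] -= h
        g[k] = (f(pp) - f(pm)) / (2 * h)
    return g


def fit_platt(light, mu, fit_beta: bool = True) -> LightResponseFit:
    """Fit the Platt model; thin wrapper over :class:`PlattLightResponse`."""
    est = PlattLightResponse(fit_beta=fit_beta).fit(light, mu)
    return LightResponseFit(
        mu_s=est.mu_s_,
        alpha=est.alpha_,
        beta=est.beta_,
        mu_max=est.mu_max_,
        i_opt=est.i_opt_,
        ci95=est.ci95_,
        r2=est.r2_,
        n=est.n_,
    )
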