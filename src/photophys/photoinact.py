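"""PSII photoinactivation cross-section from lincomycin light-shift series.

When chloroplast translation is blocked with lincomycin the PSII repair
cycle stops, and the loss of PSII photochemical yield under light follows
single-hit target theory: plotted against the cumulative incident photon
dose E (photons Å-2),

    Fv/Fm(E) = y0 * exp(-sigma_i * E)

where sigma_i (Å2 quanta-1) is the functional cross-section for
photoinactivation.  A slow rise of Fv/Fm after the shift back to growth
light is attributed to relaxation of non-photochemical quenching (NPQ);
its amplitude is used as an additive correction to the treatment-phase
yields before fitting.

Derived cost metrics: the first-order photoinactivation rate at a given
irradiance, k_pi = sigma_i * photon flux (s-1), and the photochemical
return-on-investment ratio sigma_PSII/sigma_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)

__all__ = [
    "AVOGADRO",
    "LightShiftSeries",
    "PhotoinactivationFit",
    "CostMetrics",
    "photon_dose",
    "photon_flux",
    "npq_correct",
    "PhotoinactivationDecay",
    "fit_sigma_i",
    "cost_metrics",
]

AVOGADRO = 6.02214076e23
_M2_TO_A2 = 1e20  # 1 m^2 = 1e20 Å^2


def photon_flux(irradiance: float) -> float:
    """Convert irradiance (µmol photons m-2 s-1) to photons Å-2 s-1."""
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    return irradiance * 1e-6 * AVOGADRO / _M2_TO_A2


def photon_dose(irradiance: float, duration: float) -> float:
    """Cumulative incident photons per area (photons Å-2).

    ``irradiance`` in µmol photons m-2 s-1, ``duration`` in seconds.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    return photon_flux(irradiance) * duration


@dataclass
class LightShiftSeries:
    """Fv/Fm time course through a high-light shift and recovery.

    time in minutes (samples at 0/15/30/60/90 treatment and 120/150
    recovery in the standard protocol); phase is 'treatment' or 'recovery'
    per sample; irradiances in µmol photons m-2 s-1.
    """

    time: np.ndarray
    fvfm: np.ndarray
    phase: np.ndarray  # 'treatment' | 'recovery'
    lincomycin: bool
    treatment_irradiance: float = 450.0
    growth_irradiance: float = 160.0
    npq_amplitude: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.fvfm = np.asarray(self.fvfm, float)
        self.phase = np.asarray(self.phase, object)
        if not (self.time.shape == self.fvfm.shape == self.phase.shape):
            raise ValueError("time, fvfm and phase must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any((self.fvfm < 0) | (self.fvfm >= 1)):
            raise ValueError("fvfm must lie in [0, 1)")
        tr = np.flatnonzero(self.phase == "treatment")
        rc = np.flatnonzero(self.phase == "recovery")
        if rc.size and tr.size and rc.min() < tr.max():
            raise ValueError("treatment phase must precede recovery")


@dataclass
class PhotoinactivationFit:
    """Fitted target-theory decay."""

    sigma_i: float  # Å2 quanta-1
    y0: float
    ci95: float
    r2: float
    npq_amplitude: float = 0.0


@dataclass
class CostMetrics:
    sigma_ratio: float  # sigma_PSII / sigma_i
    pi_rate: float  # s-1, sigma_i * photon flux


def npq_correct(series: LightShiftSeries) -> tuple[LightShiftSeries, float]:
    """Correct treatment-phase Fv/Fm for slow NPQ relaxation.

    In a lincomycin-treated flask no repair can occur, so any rise of
    Fv/Fm during the growth-light recovery phase is attributed to NPQ
    relaxation.  The amplitude (max recovery value minus the end-of-
    treatment value, clamped at 0) is added to every treatment-phase
    sample after t=0.  Returns the corrected series and the amplitude;
    amplitudes below 0.02 are logged as negligible.
    """
    rec = series.phase == "recovery"
    tre = series.phase == "treatment"
    if not rec.any():
        log.warning("no recovery samples; NPQ correction skipped")
        return replace(series, npq_amplitude=0.0), 0.0
    end_treatment = series.fvfm[tre][-1]
    amp = max(0.0, float(series.fvfm[rec].max() - end_treatment))
    if amp < 0.02:
        log.info("NPQ relaxation amplitude %.3f: negligible", amp)
    fv = series.fvfm.copy()
    fv[tre & (series.time > series.time[tre][0])] += amp
    corrected = replace(series, fvfm=np.clip(fv, 0, np.nextafter(1, 0)),
                        npq_amplitude=amp)
    return corrected, amp


class PhotoinactivationDecay(BaseEstimator, RegressorMixin):
    """Exponential target-theory decay fit, scikit-learn style.

    ``fit(X, y)`` takes cumulative photon dose (photons Å-2) as X and
    Fv/Fm as y; least squares of y0*exp(-sigma_i*E).  y0 is estimated
    rather than pinned to the t=0 measurement (robust to t=0 noise).

    Attributes
    ----------
    sigma_i_ : Å2 quanta-1 (0, with a warning, for non-decreasing series)
    y0_, ci95_, r2_ : companion fit quantities
    """

    def fit(self, X, y):
        dose = np.asarray(X, float).reshape(-1)
        fv = np.asarray(y, float).reshape(-1)
        if dose.size != fv.size:
            raise ValueError("dose and fvfm must have the same length")
        if dose.size < 4:
            raise ValueError("need at least 4 treatment-phase samples")

        # fit on a unit-scaled dose axis so the optimizer is indifferent to
        # the dose units carried in (per Å^2, per m^2, ...)
        scale = dose.max() if dose.max() > 0 else 1.0
        xs = dose / scale
        slope = stats.linregress(xs, np.log(np.clip(fv, 1e-9, None))).slope
        if slope >= 0:
            log.warning("Fv/Fm does not decrease with dose; sigma_i set to 0")
            self.sigma_i_, self.y0_ = 0.0, float(fv.mean())
            self.ci95_, self.r2_ = float("nan"), 0.0
            return self

        def model(e, y0, sig):
            return y0 * np.exp(-sig * e)

        popt, pcov = optimize.curve_fit(
            model, xs, fv, p0=[fv[0], -slope], bounds=([0, 0], np.inf), maxfev=20000
        )
        self.y0_, self.sigma_i_ = float(popt[0]), float(popt[1] / scale)
        dof = max(dose.size - 2, 1)
        tcrit = stats.t.ppf(0.975, dof)
        self.ci95_ = float(tcrit * np.sqrt(max(pcov[1, 1], 0.0)) / scale)
        res = fv - model(xs, *popt)
        ss_tot = float(np.sum((fv - fv.mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum(res**2)) / ss_tot if ss_tot > 0 else 1.0
        return self

    def predict(self, X):
        return self.y0_ * np.exp(-self.sigma_i_ * np.asarray(X, float).reshape(-1))


def fit_sigma_i(series: LightShiftSeries) -> PhotoinactivationFit:
    """Fit sigma_i from the treatment phase of a (corrected) series.

    The cumulative dose at each sample is irradiance * elapsed time via
    :func:`photon_dose`.  Apply :func:`npq_correct` first; the stored
    amplitude is carried into the result.
    """
    tre = series.phase == "treatment"
    t = series.time[tre]
    dose = np.array([photon_dose(series.treatment_irradiance, ti * 60.0) for ti in t])
    est = PhotoinactivationDecay().fit(dose, series.fvfm[tre])
    return PhotoinactivationFit(
        sigma_i=est.sigma_i_,
        y0=est.y0_,
        ci95=est.ci95_,
        r2=est.r2_,
        npq_amplitude=series.npq_amplitude or 0.0,
    )


def cost_metrics(sigma_psii: float, sigma_i: float, irradiance: float) -> CostMetrics:
    """Photochemical return ratio and photoinactivation rate at an irradiance."""
    if sigma_i <= 0:
        raise ValueError("sigma_i must be > 0 for the ratio to be defined")
    return CostMetrics(
        sigma_ratio=sigma_psii / sigma_i,
        pi_rate=sigma_i * photon_flux(irradiance),
    )
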