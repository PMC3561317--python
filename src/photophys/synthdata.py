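"""Seeded synthetic instrument data with known ground truth.

Emulates the study design of a pCO2 x growth-light factorial on a coastal
diatom in turbidostat culture: 2 pCO2 targets (390 / 750 ppm) x 5 growth
lights (30-380 µmol photons m-2 s-1) x 3 replicates, with every pipeline
input generated from explicit ground-truth parameters:

- OD680 turbidostat sawtooth: exponential rise to a set-point, 10 %
  dilution drop, multiplicative lognormal noise;
- single-turnover fluorescence induction curves (dark / growth light /
  high light) from the cumulative one-hit model, additive Gaussian noise;
- Fv/Fm light-shift time courses (±lincomycin) from first-order
  photoinactivation with optional repair and NPQ relaxation;
- carbonate samples consistent with a target pCO2 at a fixed alkalinity;
- per-cell biochemistry read back through the inverse assay equations.

The built-in cross-condition structure mirrors the study's headline
result: under the ambient arm the photoinactivation cross-section sigma_i
rises linearly with growth rate, under the elevated arm it is flat.

Randomness: one global seed expands into independent per-stream
generators via fixed spawn keys, so adding a new generator never perturbs
existing streams and a fixed (design, seed) pair regenerates identical
bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import carbonate as carb
from .fire import InductionCurve, induction_model
from .growth import TurbidostatTrace, platt_mu
from .photoinact import LightShiftSeries, photon_flux

__all__ = [
    "StudyDesign",
    "sim_turbidostat",
    "sim_induction",
    "sim_lightshift",
    "sim_carbonate",
    "sim_study",
    "write_dataset",
]

# stream ids for the counter-based seed expansion
_STREAMS = {
    "turbidostat": 1,
    "induction": 2,
    "lightshift": 3,
    "carbonate": 4,
    "biochem": 5,
    "light_offsets": 6,
}


def _rng(seed: int, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], *key))
    )


# ------------------------------------------------------------ ground truth

#: Platt growth-response truth per pCO2 arm (mu_s, alpha, beta); chosen so
#: the ambient arm peaks near 1.8 d-1 and the elevated arm near 2.3 d-1 at
#: growth-saturating light, converging under super-saturating light.
PLATT_TRUTH = {
    390: (3.410, 0.0308, 0.0080),
    750: (7.625, 0.0397, 0.0305),
}

#: MDA light response (attomol cell-1), Platt-shaped, ambient arm.
MDA_TRUTH = (46.0, 0.391, 0.1288)

SIGMA_I_AMBIENT = (5.8e-5, 1.9e-5)  # intercept, slope vs mu (Å2 quanta-1 per d-1)
SIGMA_I_ELEVATED = 7.0e-5  # flat


def sigma_psii_truth(light: float) -> float:
    """Dark-adapted sigma_PSII declining 322 -> 210 Å2 over 30 -> 380."""
    return 322.0 - 112.0 * (light - 30.0) / 350.0


def sigma_i_truth(pco2: int, mu: float) -> float:
    if pco2 == 390:
        a, b = SIGMA_I_AMBIENT
        return a + b * mu
    return SIGMA_I_ELEVATED


def qp_truth(light: float) -> float:
    """qP declining from ~0.89 at 30 to ~0.63 at saturating light."""
    return 0.63 + 0.26 * np.exp(-(light - 30.0) / 55.0)


def chl_truth(light: float) -> float:
    """Chl a pg cell-1, 0.22 at low light declining to ~0.08."""
    return 0.08 + 0.14 * np.exp(-(light - 30.0) / 100.0)


def mda_truth(pco2: int, light: float) -> float:
    base = platt_mu(light, *MDA_TRUTH)
    if pco2 == 750:  # elevated pCO2 raises MDA under low growth light
        base = base + 8.0 * np.exp(-(light - 30.0) / 60.0)
    return float(base)


def cn_truth(light: float) -> float:
    """Molar C:N, curved 5.1 -> 7.4 -> ~6.8 across the light gradient."""
    x = (np.log(light) - np.log(160.0)) / np.log(160.0 / 30.0)
    return 7.4 - 2.3 * x * x


@dataclass
class StudyDesign:
    """Factorial design and global seed for a full synthetic dataset."""

    pco2_levels: tuple[int, ...] = (390, 750)
    light_levels: tuple[float, ...] = (30.0, 80.0, 160.0, 240.0, 380.0)
    replicates: int = 3
    seed: int = 0
    noise: dict = field(
        default_factory=lambda: dict(
            od=0.01, fluor=0.01, fvfm=0.01, ph=0.02, dic=25.0, biochem=0.03
        )
    )


# ------------------------------------------------------------- generators


def sim_turbidostat(
    mu: float,
    setpoint: float = 0.40,
    dilution_fraction: float = 0.10,
    sample_dt: float = 1.0 / 60.0,
    n_cycles: int = 12,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> TurbidostatTrace:
    """Turbidostat OD680 sawtooth for a culture growing at ``mu`` (d-1).

    OD rises exponentially to the set-point and is instantaneously diluted
    by ``dilution_fraction``; the cycle period is ln(1/(1-f))/mu.  The
    default 1-minute sampling interval mirrors a photobioreactor's onboard
    OD logger.  Multiplicative lognormal noise of scale ``noise_sd``.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if not 0 < dilution_fraction < 1:
        raise ValueError("dilution_fraction must be in (0, 1)")
    mu_h = mu / 24.0
    period = np.log(1.0 / (1.0 - dilution_fraction)) / mu_h  # hours
    t = np.arange(0.0, n_cycles * period, sample_dt)
    od0 = setpoint * (1.0 - dilution_fraction)
    phase = np.mod(t, period)
    od = od0 * np.exp(mu_h * phase)
    if noise_sd > 0:
        rng = _rng(seed, "turbidostat")
        od = od * np.exp(rng.normal(0.0, noise_sd, od.size))
    return TurbidostatTrace(
        time=t, od680=od, setpoint=setpoint, dilution_fraction=dilution_fraction
    )


def sim_induction(
    f0: float = 280.0,
    fm: float = 700.0,
    sigma: float = 300.0,
    p: float = 0.0,
    flux: float = 250.0,
    duration_us: float = 80.0,
    n_points: int = 250,
    noise_sd: float = 0.0,
    seed: int = 0,
    state_label: str = "dark",
) -> InductionCurve:
    """Single-turnover fluorescence rise from the connectivity model.

    ``flux`` in photons Å-2 s-1; the default 250 samples mirror sub-µs
    digitization of the 80 µs flash; additive Gaussian noise with SD
    ``noise_sd * (fm - f0)``.  Warns (via the curve fit downstream) when
    sigma*flux*duration is too small to reach 95 % saturation.
    """
    if not fm > f0 > 0:
        raise ValueError("need fm > f0 > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = np.linspace(0.0, duration_us, n_points)
    dose = t * 1e-6 * flux
    f = induction_model(dose, f0, fm, sigma, p)
    if noise_sd > 0:
        rng = _rng(seed, "induction")
        f = f + rng.normal(0.0, noise_sd * (fm - f0), f.size)
        f = np.clip(f, 1e-6, None)
    return InductionCurve(
        time=t, fluorescence=f, excitation_flux=flux, state_label=state_label
    )


def sim_lightshift(
    sigma_i: float = 8.0e-5,
    k_rep: float = 0.0,
    npq_amp: float = 0.0,
    npq_relax_tau: float = 15.0,
    irradiance: float = 450.0,
    growth_irradiance: float = 160.0,
    times: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0, 90.0, 120.0, 150.0),
    lincomycin: bool = True,
    fvfm0: float = 0.65,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LightShiftSeries:
    """Fv/Fm time course through a high-light shift.

    Active PSII fraction A(t) obeys dA/dt = -k_pi*A + k_rep*(1-A) with
    k_pi = sigma_i * photon flux; lincomycin forces k_rep = 0.  During
    treatment the measured yield is fvfm0*A*(1-npq_amp) (no NPQ at the
    t=0, pre-shift sample); in recovery k_pi drops to its growth-light
    value and NPQ relaxes exponentially with ``npq_relax_tau`` (min).
    """
    if sigma_i < 0 or k_rep < 0 or npq_amp < 0:
        raise ValueError("rates and amplitudes must be >= 0")
    times = np.asarray(times, float)
    t_shift = 90.0  # min; end of the high-light treatment
    krep_eff = 0.0 if lincomycin else k_rep
    k_hi = sigma_i * photon_flux(irradiance) + krep_eff
    a_eq_hi = krep_eff / k_hi if k_hi > 0 else 1.0

    def a_of(t_min: float) -> float:
        tt = min(t_min, t_shift) * 60.0
        a = a_eq_hi + (1.0 - a_eq_hi) * np.exp(-k_hi * tt) if k_hi > 0 else 1.0
        if t_min > t_shift:
            k_lo = sigma_i * photon_flux(growth_irradiance) + krep_eff
            a_eq_lo = krep_eff / k_lo if k_lo > 0 else 1.0
            dt = (t_min - t_shift) * 60.0
            a = a_eq_lo + (a - a_eq_lo) * np.exp(-k_lo * dt) if k_lo > 0 else a
        return float(a)

    def npq_of(t_min: float) -> float:
        if t_min <= 0:
            return 0.0
        if t_min <= t_shift:
            return npq_amp
        return npq_amp * np.exp(-(t_min - t_shift) / npq_relax_tau)

    fv = np.array([fvfm0 * a_of(t) * (1.0 - npq_of(t)) for t in times])
    if noise_sd > 0:
        rng = _rng(seed, "lightshift")
        fv = fv + rng.normal(0.0, noise_sd, fv.size)
    fv = np.clip(fv, 0.0, np.nextafter(1.0, 0.0))
    phase = np.where(times <= t_shift, "treatment", "recovery").astype(object)
    return LightShiftSeries(
        time=times,
        fvfm=fv,
        phase=phase,
        lincomycin=lincomycin,
        treatment_irradiance=irradiance,
        growth_irradiance=growth_irradiance,
    )


def sim_carbonate(
    target_pco2: float,
    ta_base: float = 2300.0,
    ph_noise: float = 0.0,
    dic_noise: float = 0.0,
    n: int = 3,
    seed: int = 0,
    temperature: float = 18.0,
    salinity: float = 35.0,
    phosphate: float = 21.0,
    silicate: float = 52.5,
    formulation: str = "dm87",
) -> list[carb.CarbonateInput]:
    """Measured-style (pH, DIC) samples consistent with a target pCO2.

    Solves the equilibrium for the (pH, DIC) pair that yields exactly
    (ta_base, target_pco2), then perturbs the 'measured' pH and DIC with
    Gaussian noise.
    """
    if target_pco2 <= 0:
        raise ValueError("target_pco2 must be > 0")
    c = carb.equilibrium_constants(temperature, salinity, formulation)

    def dic_for(ph: float) -> float:
        h = 10.0**-ph
        f_co2 = h * h / (h * h + c.k1 * h + c.k1 * c.k2)
        return target_pco2 * c.k0 / f_co2  # µmol/kg

    def resid(ph: float) -> float:
        st = carb.speciate(ph, dic_for(ph), c, phosphate=phosphate, silicate=silicate)
        return carb.total_alkalinity(st, c) - ta_base

    ph_star = brentq(resid, 6.5, 9.5, xtol=1e-10)
    dic_star = dic_for(ph_star)
    rng = _rng(seed, "carbonate")
    out = []
    for _ in range(n):
        out.append(
            carb.CarbonateInput(
                temperature=temperature,
                salinity=salinity,
                ph_nbs=ph_star + (rng.normal(0, ph_noise) if ph_noise else 0.0),
                dic=dic_star + (rng.normal(0, dic_noise) if dic_noise else 0.0),
                phosphate=phosphate,
                silicate=silicate,
            )
        )
    return out


# ------------------------------------------------------------- full study


def sim_study(design: StudyDesign) -> dict:
    """Generate the full factorial dataset with a truth manifest.

    Returns a dict of DataFrames keyed 'trace', 'fire', 'lightshift',
    'carbonate', 'biochem' plus 'truth' (per culture ground-truth map);
    :func:`write_dataset` serializes the bundle to CSV + JSON.
    """
    noise = design.noise
    trace_rows, fire_rows, shift_rows, carb_rows, bio_rows = [], [], [], [], []
    truth: dict[str, dict] = {}
    fm_dark, f0_dark, fvfm0 = 800.0, 280.0, 0.65

    for ci, pco2 in enumerate(design.pco2_levels):
        # one carbonate sample per replicate culture in this arm
        carb_inputs = sim_carbonate(
            float(pco2),
            ph_noise=noise["ph"],
            dic_noise=noise["dic"],
            n=design.replicates * len(design.light_levels),
            seed=design.seed + ci,
        )
        for li, light in enumerate(design.light_levels):
            for rep in range(design.replicates):
                cid = f"p{pco2}_l{int(light)}_r{rep + 1}"
                key = (ci, li, rep)
                off = _rng(design.seed, "light_offsets", *key).normal(0.0, 0.02)
                light_actual = float(light * (1.0 + off))
                mu_true = float(platt_mu(light_actual, *PLATT_TRUTH[pco2]))
                sig_psii = sigma_psii_truth(light_actual)
                sig_i = sigma_i_truth(pco2, mu_true)

                trace = sim_turbidostat(
                    mu_true, n_cycles=14, noise_sd=noise["od"],
                    seed=_child(design.seed, 1, *key),
                )
                trace_rows.append(
                    pd.DataFrame(
                        dict(culture_id=cid, group=pco2, light=light_actual,
                             time_h=trace.time, od680=trace.od680)
                    )
                )

                qp_t = qp_truth(light_actual)
                fm_g = 0.98 * fm_dark
                fs_g = fm_g - qp_t * (fm_g - f0_dark)
                fm_h = 0.80 * fm_dark
                fs_h = fm_h - 0.30 * (fm_h - f0_dark)
                curves = {
                    "dark": (f0_dark, fm_dark, sig_psii),
                    "growth": (fs_g, fm_g, 0.97 * sig_psii),
                    "high": (fs_h, fm_h, (0.45 + 0.35 * light_actual / 380.0) * sig_psii),
                }
                for si, (state, (cf0, cfm, csig)) in enumerate(curves.items()):
                    cur = sim_induction(
                        f0=cf0, fm=cfm, sigma=csig, p=0.0,
                        noise_sd=noise["fluor"],
                        seed=_child(design.seed, 2, *key, si),
                        state_label=state,
                    )
                    fire_rows.append(
                        pd.DataFrame(
                            dict(curve_id=f"{cid}_{state}", culture_id=cid,
                                 group=pco2, light=light_actual, state=state,
                                 time_us=cur.time, fluorescence=cur.fluorescence,
                                 flux_photons_a2_s=cur.excitation_flux)
                        )
                    )

                for linco in (True, False):
                    series = sim_lightshift(
                        sigma_i=sig_i,
                        k_rep=8.0e-4,
                        npq_amp=0.02,
                        growth_irradiance=light_actual,
                        lincomycin=linco,
                        fvfm0=fvfm0,
                        noise_sd=noise["fvfm"],
                        seed=_child(design.seed, 3, *key, int(linco)),
                    )
                    shift_rows.append(
                        pd.DataFrame(
                            dict(culture_id=cid, group=pco2, light=light_actual,
                                 lincomycin=int(linco), time_min=series.time,
                                 phase=series.phase, fvfm=series.fvfm)
                        )
                    )

                ci_in = carb_inputs[li * design.replicates + rep]
                carb_rows.append(
                    dict(culture_id=cid, group=pco2, light=light_actual,
                         temp_c=ci_in.temperature, salinity=ci_in.salinity,
                         ph_nbs=ci_in.ph_nbs, dic_umol_kg=ci_in.dic,
                         po4_umol_l=ci_in.phosphate, si_umol_l=ci_in.silicate)
                )

                bio_rows.append(
                    _biochem_row(cid, pco2, light_actual,
                                 _rng(design.seed, "biochem", *key), noise["biochem"])
                )

                truth[cid] = dict(
                    group=pco2, light_nominal=float(light), light=light_actual,
                    mu=mu_true, sigma_psii=sig_psii,
                    sigma_prime=0.97 * sig_psii,
                    sigma_doubleprime=(0.45 + 0.35 * light_actual / 380.0) * sig_psii,
                    sigma_i=sig_i, k_rep=8.0e-4, npq_amp=0.02, qp=qp_t,
                    fvfm0=fvfm0,
                    chl_pg_cell=float(chl_truth(light_actual)),
                    mda_attomol_cell=mda_truth(pco2, light_actual),
                    protein_pg_cell=4.5,
                    c_pmol_cell=0.65,
                    cn_molar=float(cn_truth(light_actual)),
                )

    return dict(
        trace=pd.concat(trace_rows, ignore_index=True),
        fire=pd.concat(fire_rows, ignore_index=True),
        lightshift=pd.concat(shift_rows, ignore_index=True),
        carbonate=pd.DataFrame(carb_rows),
        biochem=pd.DataFrame(bio_rows),
        truth=truth,
    )


def _child(seed: int, stream: int, *key: int) -> int:
    """Deterministic sub-seed (< 2**31) from the global seed and a key."""
    ss = np.random.SeedSequence(seed, spawn_key=(100 + stream, *key))
    return int(ss.generate_state(1)[0] % (2**31))


def _biochem_row(cid, pco2, light, rng, cv):
    """Invert the assay equations so the analysis recovers the truth."""
    from . import biochem as bc

    chl = chl_truth(light) * (1 + rng.normal(0, cv))
    mda_v = mda_truth(pco2, light) * (1 + rng.normal(0, cv))
    cells_ml = 6.0e5 * (1 + rng.normal(0, cv))
    vol_chl, vol_mda = 50.0, 30.0
    extract_volume, dil = 0.4, 500.0 / 30.0

    conc_acet = chl * cells_ml * vol_chl / 1e6 / (extract_volume * dil)  # µg/mL
    a750 = 0.010
    a630 = a750 + 0.15 * conc_acet / bc.JH_A664
    a664 = a750 + (conc_acet - bc.JH_A630 * (a630 - a750)) / bc.JH_A664

    total_umol = mda_v * cells_ml * vol_mda / 1e12  # attomol -> µmol on filter
    conc_mix = total_umol * (0.35 / 0.8) / (0.7e-3)  # µmol/L in reaction mix
    a600 = 0.020
    a532 = a600 + conc_mix / bc.MDA_COEF

    c_pmol = 0.65 * (1 + rng.normal(0, cv))
    n_pmol = c_pmol / (cn_truth(light) * (1 + rng.normal(0, cv / 2)))
    return dict(
        culture_id=cid, group=pco2, light=light,
        cell_density_per_ml=cells_ml, vol_filtered_ml=vol_chl,
        vol_filtered_mda_ml=vol_mda, extract_vol_ml=extract_volume,
        dilution_factor=dil,
        a664=a664, a630=a630, a750=a750, a532=a532, a600=a600,
        protein_pg_cell=4.5 * (1 + rng.normal(0, cv)),
        c_pmol_cell=c_pmol, n_pmol_cell=n_pmol,
        rbcl_attomol_cell=3.2 + 7.8 * (light - 30.0) / 350.0,
        psba_attomol_cell=1.5 * (1.0 + 0.5 * light / 380.0),
        psbd_attomol_cell=1.5,
        petc_attomol_cell=1.0,
        psac_attomol_cell=2.5 - 1.3 * (light - 30.0) / 350.0,
    )


def write_dataset(bundle: dict, out_dir: str | Path) -> None:
    """Write a sim_study bundle to CSV files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = dict(trace="trace.csv", fire="fire.csv", lightshift="lightshift.csv",
                 carbonate="carbonate.csv", biochem="biochem.csv")
    for key, fname in names.items():
        bundle[key].to_csv(out / fname, index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle["truth"], fh, indent=1, sort_keys=True)
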