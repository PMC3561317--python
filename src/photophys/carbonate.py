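"""Seawater CO2-system speciation from a measured (pH_NBS, DIC) pair.

Solves the carbonic acid equilibrium at fixed temperature, salinity and
nutrient concentrations for free CO2 (CO2* including H2CO3), bicarbonate,
carbonate, pCO2 and total alkalinity, in the classic CO2SYS style used for
benchtop culture work: NBS-calibrated electrode pH, total DIC from an
infrared analyzer, and published equilibrium-constant formulations.

Two K1/K2 formulations are provided:

``"dm87"`` (default)
    Mehrbach-based constants as refit by Dickson & Millero (1987, combined
    Hansson + Mehrbach fit), applied with the hydrogen-ion term taken
    directly from the reported NBS pH.  This is the configuration that
    reproduces the reference dataset of culture carbonate conditions
    shipped with the package (see :func:`load_study_conditions`).
``"mehrbach"``
    The original Mehrbach et al. (1973) fit on the NBS scale (the GEOSECS
    formulation).

All other constants follow the Peng-era family: K0 from Weiss (1974), KB
from Lyman as used in GEOSECS, KW from Millero (1979) converted to the NBS
convention with the Takahashi activity coefficient fH, phosphoric and
silicic acid constants from Kester & Pytkowicz as adopted by Peng, and
total borate proportional to salinity (Culkin).  Pressure is fixed at the
surface and no fugacity correction is applied; pCO2 in µatm is reported as
ppm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CarbonateInput",
    "ConstantSet",
    "CarbonateState",
    "equilibrium_constants",
    "speciate",
    "total_alkalinity",
    "ph_from_ta_dic",
    "solve_sample",
    "process_dataframe",
    "treatment_summary",
    "load_study_conditions",
]

_T_RANGE = (0.0, 40.0)
_S_RANGE = (1.0, 45.0)
_PH_RANGE = (6.0, 10.0)


@dataclass(frozen=True)
class CarbonateInput:
    """One water sample's measured quantities.

    temperature in °C, salinity on the practical scale, pH on the NBS
    scale, DIC in µmol kg-1, phosphate and silicate in µmol L-1 (treated
    as µmol kg-1; the density correction is <0.3 % at S=35), pressure in
    dbar (surface cultures: 0).
    """

    temperature: float
    salinity: float
    ph_nbs: float
    dic: float
    phosphate: float = 0.0
    silicate: float = 0.0
    pressure: float = 0.0

    def __post_init__(self) -> None:
        _check_range("temperature", self.temperature, _T_RANGE)
        _check_range("salinity", self.salinity, _S_RANGE)
        _check_range("ph_nbs", self.ph_nbs, _PH_RANGE)
        if self.dic < 0:
            raise ValueError(f"dic must be >= 0, got {self.dic}")


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants evaluated at one (T, S), surface pressure.

    k0 in mol kg-1 atm-1; the dissociation constants are dimensioned for a
    hydrogen-ion term h = 10**(-pH_NBS); bt is total borate in mol kg-1;
    fh is the Takahashi activity coefficient used to convert the NBS
    hydrogen-ion activity to a free concentration.
    """

    temperature: float
    salinity: float
    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    kp1: float
    kp2: float
    kp3: float
    ksi: float
    bt: float
    fh: float
    formulation: str = "dm87"


@dataclass
class CarbonateState:
    """Speciated carbon system for one sample; species in µmol kg-1, pco2 in ppm."""

    input: CarbonateInput
    co2: float
    hco3: float
    co3: float
    pco2: float
    ta: float | None = None
    constants: ConstantSet | None = field(repr=False, default=None)


def _check_range(name: str, value: float, lo_hi: tuple[float, float]) -> None:
    lo, hi = lo_hi
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside the valid range [{lo}, {hi}]")


def equilibrium_constants(
    temperature: float, salinity: float, formulation: str = "dm87"
) -> ConstantSet:
    """Evaluate the full constant set at the given temperature and salinity.

    Parameters
    ----------
    temperature : float
        Water temperature in °C, in [0, 40].
    salinity : float
        Practical salinity, in [1, 45].
    formulation : {"dm87", "mehrbach"}
        Choice of K1/K2 fit (see module docstring).
    """
    _check_range("temperature", temperature, _T_RANGE)
    _check_range("salinity", salinity, _S_RANGE)
    tk = temperature + 273.15
    s = salinity

    # CO2 solubility, Weiss (1974), mol kg-1 atm-1
    lnk0 = (
        -60.2409
        + 93.4517 * (100.0 / tk)
        + 23.3585 * math.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    k0 = math.exp(lnk0)

    if formulation == "dm87":
        # Dickson & Millero (1987) refit of the Hansson + Mehrbach data
        pk1 = 845.0 / tk + 3.248 - 0.0098 * s + 0.000087 * s * s
        pk2 = 1377.3 / tk + 4.824 - 0.0185 * s + 0.000122 * s * s
    elif formulation == "mehrbach":
        # Mehrbach et al. (1973) original, NBS scale (GEOSECS)
        pk1 = (
            -13.7201
            + 0.031334 * tk
            + 3235.76 / tk
            + 1.3e-5 * s * tk
            - 0.1032 * math.sqrt(s)
        )
        pk2 = (
            5371.9645
            + 1.671221 * tk
            + 0.22913 * s
            + 18.3802 * math.log10(s)
            - 128375.28 / tk
            - 2194.3055 * math.log10(tk)
            - 8.0944e-4 * s * tk
            - 5617.11 * math.log10(s) / tk
            + 2.136 * s / tk
        )
    else:
        raise ValueError(f"unknown K1/K2 formulation: {formulation!r}")
    k1, k2 = 10.0**-pk1, 10.0**-pk2

    # Takahashi fH (GEOSECS): aH -> free hydrogen-ion concentration
    fh = 1.29 - 0.00204 * tk + (0.00046 - 0.00000148 * tk) * s * s
    # Borate, Lyman as used in GEOSECS (NBS convention)
    kb = 10.0 ** (-9.26 + 0.00886 * s + 0.01 * temperature)
    # Water, Millero (1979), converted with fH
    lnkw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * math.log(tk)
        + (-79.2447 + 3298.72 / tk + 12.0408 * math.log(tk)) * math.sqrt(s)
        - 0.019813 * s
    )
    kw = math.exp(lnkw) * fh
    # Phosphoric & silicic acid, Kester & Pytkowicz / Peng
    kp1 = 0.02
    kp2 = math.exp(-9.039 - 1450.0 / tk)
    kp3 = math.exp(4.466 - 7276.0 / tk)
    ksi = 4e-10
    # Total borate from salinity (Culkin), mol kg-1
    bt = 0.0004106 * s / 35.0

    return ConstantSet(
        temperature=temperature,
        salinity=salinity,
        k0=k0,
        k1=k1,
        k2=k2,
        kb=kb,
        kw=kw,
        kp1=kp1,
        kp2=kp2,
        kp3=kp3,
        ksi=ksi,
        bt=bt,
        fh=fh,
        formulation=formulation,
    )


def _fractions(h: float, c: ConstantSet) -> tuple[float, float, float]:
    """Mole fractions of (CO2*, HCO3-, CO3--) at hydrogen-ion term h."""
    d = h * h + c.k1 * h + c.k1 * c.k2
    return h * h / d, c.k1 * h / d, c.k1 * c.k2 / d


def speciate(
    ph_nbs: float,
    dic: float,
    constants: ConstantSet,
    *,
    phosphate: float = 0.0,
    silicate: float = 0.0,
) -> CarbonateState:
    """Partition DIC into CO2*, HCO3- and CO3-- at the measured pH.

    ``dic`` in µmol kg-1.  pCO2 (ppm, = µatm) follows from Henry's law,
    pCO2 = [CO2*]/K0.  The three species sum to DIC by construction.
    """
    if dic < 0:
        raise ValueError(f"dic must be >= 0, got {dic}")
    _check_range("ph_nbs", ph_nbs, _PH_RANGE)
    h = 10.0**-ph_nbs
    f_co2, f_hco3, f_co3 = _fractions(h, constants)
    co2 = dic * f_co2
    inp = CarbonateInput(
        temperature=constants.temperature,
        salinity=constants.salinity,
        ph_nbs=ph_nbs,
        dic=dic,
        phosphate=phosphate,
        silicate=silicate,
    )
    return CarbonateState(
        input=inp,
        co2=co2,
        hco3=dic * f_hco3,
        co3=dic * f_co3,
        pco2=co2 * 1e-6 / constants.k0 * 1e6,  # µmol/kg -> mol/kg -> atm -> µatm
        constants=constants,
    )


def total_alkalinity(state: CarbonateState, constants: ConstantSet | None = None) -> float:
    """Total alkalinity (µmol kg-1) of a speciated sample.

    TA = HCO3- + 2 CO3-- + B(OH)4- + OH- - H+(free) + phosphate alkalinity
    + silicate alkalinity.  The phosphate term follows the Peng convention
    (total phosphate added to the Dickson-style term, i.e. the zero proton
    level taken at H3PO4).
    """
    if constants is None:
        constants = state.constants
    if constants is None:
        raise ValueError("state carries no ConstantSet; pass `constants` explicitly")
    if state.hco3 is None:
        raise ValueError("state is not speciated")
    c = constants
    h = 10.0**-state.input.ph_nbs
    tp = state.input.phosphate  # µmol kg-1 (µmol/L taken 1:1)
    tsi = state.input.silicate

    balk = c.bt * 1e6 * c.kb / (c.kb + h)
    oh = c.kw / h * 1e6
    dpi = h**3 + c.kp1 * h * h + c.kp1 * c.kp2 * h + c.kp1 * c.kp2 * c.kp3
    palk = tp * (c.kp1 * c.kp2 * h + 2 * c.kp1 * c.kp2 * c.kp3 - h**3) / dpi + tp
    sialk = tsi * c.ksi / (c.ksi + h)
    hfree = h / c.fh * 1e6
    ta = state.hco3 + 2.0 * state.co3 + balk + oh + palk + sialk - hfree
    state.ta = ta
    return ta


def ph_from_ta_dic(
    ta: float,
    dic: float,
    constants: ConstantSet,
    *,
    phosphate: float = 0.0,
    silicate: float = 0.0,
) -> float:
    """Invert the alkalinity relation: find pH_NBS with the given TA and DIC.

    Bracketed root finding on pH in [4, 11]; the returned pH satisfies
    |TA(pH) - ta| well below 1e-3 µmol kg-1.
    """
    if ta <= 0 or dic <= 0:
        raise ValueError("ta and dic must be > 0")

    def resid(ph: float) -> float:
        st = speciate(ph, dic, constants, phosphate=phosphate, silicate=silicate)
        return total_alkalinity(st, constants) - ta

    # speciate() validates pH in [6, 10]; the bracket is clipped to that
    # domain (culture waters sit well inside it)
    lo, hi = 6.0 + 1e-9, 10.0 - 1e-9
    rlo, rhi = resid(lo), resid(hi)
    if rlo * rhi > 0:
        raise RuntimeError(
            f"no sign change in pH bracket [{lo:.2f}, {hi:.2f}]: "
            f"TA residuals ({rlo:.3g}, {rhi:.3g})"
        )
    return brentq(resid, lo, hi, xtol=1e-8)


def solve_sample(inp: CarbonateInput, formulation: str = "dm87") -> CarbonateState:
    """Full speciation + alkalinity for one measured sample."""
    c = equilibrium_constants(inp.temperature, inp.salinity, formulation)
    state = speciate(
        inp.ph_nbs, inp.dic, c, phosphate=inp.phosphate, silicate=inp.silicate
    )
    total_alkalinity(state, c)
    return state


_IN_COLS = ["temp_c", "salinity", "ph_nbs", "dic_umol_kg", "po4_umol_l", "si_umol_l"]


def process_dataframe(df: pd.DataFrame, formulation: str = "dm87") -> pd.DataFrame:
    """Speciate every row of an instrument-style table.

    Expects columns temp_c, salinity, ph_nbs, dic_umol_kg, po4_umol_l,
    si_umol_l (plus any pass-through columns such as group/light); returns
    a copy with ta_umol_kg, pco2_ppm, co2_umol_kg, hco3_umol_kg and
    co3_umol_kg appended.
    """
    missing = [c for c in _IN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing input columns: {missing}")
    out = df.copy()
    recs = []
    for _, row in df.iterrows():
        st = solve_sample(
            CarbonateInput(
                temperature=row["temp_c"],
                salinity=row["salinity"],
                ph_nbs=row["ph_nbs"],
                dic=row["dic_umol_kg"],
                phosphate=row["po4_umol_l"],
                silicate=row["si_umol_l"],
            ),
            formulation,
        )
        recs.append((st.ta, st.pco2, st.co2, st.hco3, st.co3))
    out[["ta_umol_kg", "pco2_ppm", "co2_umol_kg", "hco3_umol_kg", "co3_umol_kg"]] = recs
    return out


_SUMMARY_PARAMS = [
    "dic_umol_kg",
    "ph_nbs",
    "ta_umol_kg",
    "pco2_ppm",
    "co3_umol_kg",
    "hco3_umol_kg",
    "co2_umol_kg",
]


def treatment_summary(
    df: pd.DataFrame,
    group_col: str = "group",
    ambient: str | float = 390,
    elevated: str | float = 750,
) -> pd.DataFrame:
    """Per-treatment unweighted means and the elevated-vs-ambient contrast.

    Means are taken across light levels with equal weight.  The contrast is
    a percent change, 100*(elevated - ambient)/ambient, except for pH which
    is reported as a difference in pH units.
    """
    params = [p for p in _SUMMARY_PARAMS if p in df.columns]
    if not params:
        raise ValueError("no carbonate parameter columns found")
    groups = df.groupby(group_col)
    for g in (ambient, elevated):
        if g not in groups.groups:
            raise ValueError(f"treatment group {g!r} is empty or absent")
    means = groups[params].mean()
    amb, ele = means.loc[ambient], means.loc[elevated]
    change = 100.0 * (ele - amb) / amb
    if "ph_nbs" in params:
        change["ph_nbs"] = ele["ph_nbs"] - amb["ph_nbs"]  # difference in units
    out = means.T
    out.columns = [f"mean_{c}" for c in out.columns]
    out["change"] = change
    return out


def load_study_conditions() -> pd.DataFrame:
    """The reference dataset of culture carbonate conditions.

    Ten rows (5 growth-light levels x 2 pCO2 treatments) of measured
    (T, S, pH_NBS, DIC, nutrients) plus the originally reported derived
    values (TA, pCO2, CO3--, HCO3-, free CO2) for comparison; means only,
    reported uncertainties dropped.
    """
    with resources.files("photophys").joinpath(
        "data/study_carbonate_conditions.csv"
    ).open() as fh:
        return pd.read_csv(fh)
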