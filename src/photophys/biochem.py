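"""Per-cell biochemistry: chlorophyll a, MDA, C:N and composition ratios.

Raw spectrophotometer absorbances are converted to per-cell quantities
through the assay geometry (volume filtered, extract and aliquot volumes,
cell density).  Chlorophyll a uses the Jeffrey & Humphrey (1975)
90 %-acetone equation for chl a in the presence of c pigments;
malondialdehyde (MDA, the TBARS lipid-peroxidation proxy) uses the
A532-A600 difference times the 6.45 µM cm-1 coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "CultureSample",
    "CompositionResult",
    "chl_a_concentration",
    "chl_a",
    "mda_concentration",
    "mda",
    "cn_ratio",
    "composition_ratios",
    "subunit_ratios",
]

# Jeffrey & Humphrey (1975), chl a with c1+c2 pigments, 90% acetone, 1 cm path
JH_A664 = 11.47  # µg mL-1 per absorbance unit
JH_A630 = -0.40

MDA_COEF = 6.45  # µM per absorbance unit (1 cm path), i.e. 1/0.155 µM-1 cm-1


@dataclass
class CultureSample:
    """Assay geometry and raw readings for one culture harvest.

    Volumes in mL; cell_density in cells mL-1; absorbances blank-corrected
    instrument readings; protein_per_cell in pg; C/N contents in pmol.
    ``dilution_factor`` is the pigment-extraction dilution (aliquot of the
    protein extract into 90 % acetone, e.g. 500/30 for 30 µL into a final
    500 µL).
    """

    cell_density: float
    volume_filtered: float
    extract_volume: float = 0.4
    dilution_factor: float = 500.0 / 30.0
    a664: float | None = None
    a630: float | None = None
    a750: float | None = None
    a532: float | None = None
    a600: float | None = None
    protein_per_cell: float | None = None
    c_content: float | None = None
    n_content: float | None = None

    def __post_init__(self) -> None:
        for name in ("cell_density", "volume_filtered", "extract_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def chl_a_concentration(a664: float, a630: float, a750: float = 0.0) -> float:
    """Chl a in the measured extract, µg mL-1.

    Turbidity-corrected absorbances (A - A750) in the Jeffrey-Humphrey
    equation; a negative result is clamped to 0 with a warning.
    """
    if a664 < a750:
        raise ValueError("a664 must be >= a750 (turbidity blank)")
    conc = JH_A664 * (a664 - a750) + JH_A630 * (a630 - a750)
    if conc < 0:
        log.warning("negative chl a concentration %.4g clamped to 0", conc)
        conc = 0.0
    return conc


def chl_a(
    a664: float,
    a630: float,
    a750: float,
    *,
    extract_volume: float,
    dilution_factor: float,
    volume_filtered: float,
    cell_density: float,
) -> float:
    """Chlorophyll a per cell, pg cell-1.

    The measured acetone concentration is scaled back through the pigment
    dilution (``dilution_factor``) and the protein-extract volume to total
    chl on the filter, then divided by the number of cells filtered.
    """
    conc = chl_a_concentration(a664, a630, a750)  # µg/mL in the acetone
    total_ug = conc * extract_volume * dilution_factor
    cells = cell_density * volume_filtered
    return total_ug * 1e6 / cells  # µg -> pg


def mda_concentration(a532: float, a600: float) -> float:
    """MDA in the reaction mix, µmol L-1 = (A532 - A600) * 6.45."""
    if a532 < 0 or a600 < 0:
        raise ValueError("absorbances must be >= 0")
    diff = a532 - a600
    if diff < 0:
        log.warning("A532 < A600 (%.4g); MDA set to 0", diff)
        return 0.0
    return diff * MDA_COEF


def mda(
    a532: float,
    a600: float,
    *,
    volume_filtered: float,
    cell_density: float,
    homogenate_volume: float = 0.8,
    aliquot_volume: float = 0.35,
    reagent_volume: float = 0.35,
) -> float:
    """Malondialdehyde per cell, attomol cell-1.

    The reaction mix is ``aliquot_volume`` of TCA homogenate plus an equal
    ``reagent_volume`` of TBA reagent; amounts scale back through the
    homogenate volume to the cells filtered.
    """
    conc = mda_concentration(a532, a600)  # µmol/L in the mix
    mix_amount = conc * (aliquot_volume + reagent_volume) * 1e-3  # µmol
    total = mix_amount * homogenate_volume / aliquot_volume
    cells = cell_density * volume_filtered
    return total * 1e12 / cells  # µmol -> attomol


def cn_ratio(c: float, n: float) -> float:
    """Molar carbon-to-nitrogen ratio from per-cell contents (pmol cell-1)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    return c / n


@dataclass
class CompositionResult:
    chl_per_cell: float  # pg cell-1
    mda_per_cell: float | None = None  # attomol cell-1
    chl_protein_ratio: float | None = None  # mass ratio
    cn_molar: float | None = None


def composition_ratios(
    sample: CultureSample, chl_pg_cell: float, mda_attomol_cell: float | None = None
) -> CompositionResult:
    """Bundle per-cell quantities and the Chl a : protein mass ratio.

    The ratio is computed from paired same-extract values, so a common
    extraction-efficiency factor cancels; it is omitted (None) when the
    sample carries no protein measurement.
    """
    ratio = None
    if sample.protein_per_cell is not None:
        if sample.protein_per_cell <= 0:
            raise ValueError("protein_per_cell must be > 0")
        ratio = chl_pg_cell / sample.protein_per_cell
    cn = None
    if sample.c_content is not None and sample.n_content is not None:
        cn = cn_ratio(sample.c_content, sample.n_content)
    return CompositionResult(
        chl_per_cell=chl_pg_cell,
        mda_per_cell=mda_attomol_cell,
        chl_protein_ratio=ratio,
        cn_molar=cn,
    )


def subunit_ratios(
    rbcl: float | None = None,
    psba: float | None = None,
    psbd: float | None = None,
    petc: float | None = None,
    psac: float | None = None,
) -> dict:
    """Molar ratios among photosynthetic complex subunits (vs PsbD).

    Inputs are pre-quantified attomol cell-1 values; returns RbcL:PsbD
    (RUBISCO:PSII proxy), PsbA:PsbD (repair-cycle proxy) and PsaC:PsbD
    (PSI:PSII proxy) where the operands are available.
    """
    if psbd is None or psbd <= 0:
        raise ValueError("psbd must be provided and > 0")
    out = {}
    if rbcl is not None:
        out["rbcl_psbd"] = rbcl / psbd
    if psba is not None:
        out["psba_psbd"] = psba / psbd
    if psac is not None:
        out["psac_psbd"] = psac / psbd
    return out
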