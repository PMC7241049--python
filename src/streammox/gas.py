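"""Headspace-equilibration gas chemistry.

Dissolved CH4 and CO2 are measured by equilibrating a water sample with an
N2 headspace in a syringe, transferring the headspace to a second syringe and
topping it up with N2, then reading the mixing ratio on a gas analyser. This
module provides the forward model (dissolved concentration → observed ppmv)
and its exact inverse, built on temperature-dependent Henry's law solubility
for freshwater.

Solubility uses the dimensionless-to-molar Henry constants from the Sander
compilation of Henry's law coefficients (H_cp at 298.15 K plus a van 't Hoff
temperature coefficient), valid here for 0–40 °C freshwater; ionic-strength
corrections are deliberately omitted and CO2 is treated as free dissolved CO2
only (no carbonate speciation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HENRY_COEFFICIENTS",
    "HeadspaceMeasurement",
    "henry_constant",
    "simulate_headspace",
    "dissolved_from_headspace",
    "ch4_co2_ratio",
]

R_L_ATM = 0.082057366  # L atm mol⁻¹ K⁻¹

# H_cp in mol L⁻¹ atm⁻¹ at 298.15 K and van 't Hoff slope d ln(H)/d(1/T) in K.
# Sander's compilation, converted from mol m⁻³ Pa⁻¹ (CH4 1.4e-5, CO2 3.3e-4).
HENRY_COEFFICIENTS: dict[str, dict[str, float]] = {
    "CH4": {"h_cp_298": 1.4e-3, "vant_hoff_K": 1900.0, "t_min": 0.0, "t_max": 40.0},
    "CO2": {"h_cp_298": 3.3e-2, "vant_hoff_K": 2400.0, "t_min": 0.0, "t_max": 40.0},
}


@dataclass
class HeadspaceMeasurement:
    """One headspace-equilibration measurement.

    ``water_volume`` mL of sample is shaken with ``headspace_volume`` mL of
    ultrapure N2; the equilibrated headspace is then diluted with N2 to
    ``post_transfer_dilution_volume`` mL before analysis. Defaults follow the
    30 mL + 30 mL → 50 mL syringe protocol.
    """

    mixing_ratio: float  # ppmv as read by the analyser
    analyte: str = "CH4"
    water_volume: float = 30.0
    headspace_volume: float = 30.0
    post_transfer_dilution_volume: float = 50.0
    temperature: float = 20.0
    ambient_pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        for name in ("water_volume", "headspace_volume",
                     "post_transfer_dilution_volume", "ambient_pressure"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.post_transfer_dilution_volume < self.headspace_volume:
            raise ValueError("dilution volume must be >= headspace volume")
        if self.mixing_ratio < 0:
            raise ValueError("mixing ratio must be >= 0")


def henry_constant(analyte: str, temperature_c: float) -> float:
    """Henry solubility H_cp in mol L⁻¹ atm⁻¹ at ``temperature_c`` (°C)."""
    try:
        coef = HENRY_COEFFICIENTS[analyte]
    except KeyError:
        raise ValueError(f"no solubility coefficients for analyte {analyte!r}") from None
    if not coef["t_min"] <= temperature_c <= coef["t_max"]:
        raise ValueError(
            f"temperature {temperature_c} °C outside validity "
            f"[{coef['t_min']}, {coef['t_max']}] for {analyte}"
        )
    t_k = temperature_c + 273.15
    return coef["h_cp_298"] * np.exp(coef["vant_hoff_K"] * (1.0 / t_k - 1.0 / 298.15))


def equilibrium_headspace_pressure(
    c_w: float,
    analyte: str,
    water_volume: float,
    headspace_volume: float,
    temperature: float,
) -> float:
    """Partial pressure (atm) in the headspace after equilibrating a sample.

    Two-phase closed mass balance: the dissolved amount C_w·V_w partitions
    between water (Henry's law, C_aq = 10⁶·H·p µM) and gas (ideal gas).
    """
    if c_w < 0:
        raise ValueError("dissolved concentration must be >= 0")
    h = henry_constant(analyte, temperature)
    t_k = temperature + 273.15
    # amounts in nmol; volumes mL: water term 1e6·H·p·V_w, gas term 1e6·p·V_hs/(R·T)
    return c_w * water_volume / (1e6 * (h * water_volume + headspace_volume / (R_L_ATM * t_k)))


def simulate_headspace(
    c_w: float,
    analyte: str = "CH4",
    water_volume: float = 30.0,
    headspace_volume: float = 30.0,
    post_transfer_dilution_volume: float = 50.0,
    temperature: float = 20.0,
    ambient_pressure: float = 1.0,
) -> float:
    """Forward model: dissolved concentration (µM) → observed mixing ratio (ppmv).

    Deterministic and strictly increasing (linear) in ``c_w``.
    """
    p = equilibrium_headspace_pressure(
        c_w, analyte, water_volume, headspace_volume, temperature
    )
    dilution = headspace_volume / post_transfer_dilution_volume
    return p / ambient_pressure * dilution * 1e6


def dissolved_from_headspace(m: HeadspaceMeasurement) -> float:
    """Invert the headspace protocol: observed ppmv → µM in the original water.

    Exact algebraic inverse of :func:`simulate_headspace` (the two-phase
    equilibrium is linear in concentration at fixed geometry).
    """
    unit = simulate_headspace(
        1.0,
        analyte=m.analyte,
        water_volume=m.water_volume,
        headspace_volume=m.headspace_volume,
        post_transfer_dilution_volume=m.post_transfer_dilution_volume,
        temperature=m.temperature,
        ambient_pressure=m.ambient_pressure,
    )
    return m.mixing_ratio / unit


def ch4_co2_ratio(site) -> float:
    """Streamwater CH4:CO2 ratio, a proxy for in-situ CH4 production."""
    if site.co2_stream <= 0:
        raise ValueError(f"site {site.site_id}: CO2 must be positive for the ratio")
    return site.ch4_stream / site.co2_stream
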