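"""Temperature/salinity-dependent N2O solubility and headspace conversion.

Implements the seawater N2O solubility fit of Weiss & Price (1980,
Mar. Chem. 8, 347-359): the concentration solubility K0 in
mol L-1 atm-1,

    ln K0 = a1 + a2 (100/T) + a3 ln(T/100)
            + S [b1 + b2 (T/100) + b3 (T/100)^2]

with T in kelvin and S in practical salinity units, together with their
seawater vapor-pressure fit used for the moist-air correction at a total
pressure of 1 atm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibrationSetup",
    "solubility_function",
    "water_vapor_pressure",
    "headspace_to_dissolved",
]

# Weiss & Price (1980) N2O fit, mol L-1 atm-1
_A1, _A2, _A3 = -62.7062, 97.3066, 24.1406
_B1, _B2, _B3 = -0.058420, 0.033193, -0.0051313

# seawater vapor pressure fit (atm)
_V1, _V2, _V3, _V4 = 24.4543, -67.4509, -4.8489, -0.000544

R_L_ATM = 0.0820573660809596  # gas constant, L atm K-1 mol-1

T_RANGE = (-2.0, 40.0)  # deg C
S_RANGE = (0.0, 42.0)  # PSU


@dataclass
class EquilibrationSetup:
    """A closed headspace equilibration at 1 atm total pressure."""

    temperature: float  # deg C
    salinity: float  # PSU
    water_volume: float  # mL
    headspace_volume: float  # mL
    headspace_mole_fraction: float  # ppmv N2O in the (dry) headspace gas

    def __post_init__(self):
        if not self.water_volume > 0:
            raise ValueError(f"water_volume must be > 0, got {self.water_volume}")
        if not self.headspace_volume > 0:
            raise ValueError(
                f"headspace_volume must be > 0, got {self.headspace_volume}"
            )
        _check_range(self.temperature, self.salinity)
        if self.headspace_mole_fraction < 0:
            raise ValueError("headspace_mole_fraction must be >= 0")


def _check_range(temperature: float, salinity: float) -> None:
    if not T_RANGE[0] <= temperature <= T_RANGE[1]:
        raise ValueError(
            f"temperature {temperature} degC outside validity range {T_RANGE}"
        )
    if not S_RANGE[0] <= salinity <= S_RANGE[1]:
        raise ValueError(f"salinity {salinity} outside validity range {S_RANGE}")


def solubility_function(temperature: float, salinity: float) -> float:
    """N2O concentration solubility K0 in mol L-1 atm-1.

    Strictly positive and strictly decreasing in both temperature and
    salinity over the fit's validity range (-2..40 degC, 0..42 PSU).
    """
    _check_range(temperature, salinity)
    t = temperature + 273.15
    t100 = t / 100.0
    ln_k0 = (
        _A1
        + _A2 / t100
        + _A3 * np.log(t100)
        + salinity * (_B1 + _B2 * t100 + _B3 * t100 * t100)
    )
    return float(np.exp(ln_k0))


def water_vapor_pressure(temperature: float, salinity: float) -> float:
    """Vapor pressure of seawater in atm."""
    _check_range(temperature, salinity)
    t = temperature + 273.15
    t100 = t / 100.0
    return float(np.exp(_V1 + _V2 / t100 + _V3 * np.log(t100) + _V4 * salinity * t))


def headspace_to_dissolved(setup: EquilibrationSetup) -> float:
    """Original dissolved N2O (nmol L-1) from an equilibrated headspace.

    At equilibrium the water holds ``K0 * p`` and the headspace holds
    ``p * V_hs / (R T)`` moles, with the N2O partial pressure
    ``p = x * (1 atm - p_H2O)`` for dry mole fraction ``x``.  The
    original concentration is the total divided by the water volume
    (all N2O was initially dissolved); the result is exactly linear in
    the headspace mole fraction.
    """
    k0 = solubility_function(setup.temperature, setup.salinity)
    t = setup.temperature + 273.15
    p_n2o = setup.headspace_mole_fraction * 1e-6 * (
        1.0 - water_vapor_pressure(setup.temperature, setup.salinity)
    )  # atm
    v_w = setup.water_volume / 1000.0  # L
    v_hs = setup.headspace_volume / 1000.0  # L
    mol_dissolved = k0 * p_n2o * v_w
    mol_headspace = p_n2o * v_hs / (R_L_ATM * t)
    return (mol_dissolved + mol_headspace) / v_w * 1e9  # nmol L-1
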