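"""Four-equilibrium ion-binding model of the phosphatidylcholine surface.

The zwitterionic PC head group exposes a phosphate (A- = -PO(-)) and a
trimethylammonium (B+ = -N(+)(CH3)3) site.  Four mass-action equilibria are
assumed, with association constants relating areal site concentrations
(mol m^-2) to volumetric ion concentrations (mol m^-3):

    A- + H+  <=> AH      K_AH  = a_AH  / (a_A-  a_H)
    A- + Na+ <=> ANa     K_ANa = a_ANa / (a_A-  a_Na)
    B+ + OH- <=> BOH     K_BOH = a_BOH / (a_B+  a_OH)
    B+ + X-  <=> BX      K_BX  = a_BX  / (a_B+  a_X)

Site conservation a_A- + a_AH + a_ANa = a_B+ + a_BOH + a_BX = C_PC gives the
closed-form net surface charge density

    δ(pH)/F = C_PC/(1 + K_BOH a_OH + K_BX a_X)
            - C_PC/(1 + K_AH a_H + K_ANa a_Na),

which is strictly decreasing in pH for positive constants, so the
isoelectric point (δ = 0) is unique when it exists.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.optimize import bisect

from .constants import ANGSTROM, AVOGADRO, FARADAY
from .exceptions import DomainError, NoIsoelectricPointError
from .types import (
    BindingConstants,
    Electrolyte,
    Medium,
    Membrane,
    ProtolyticState,
    SpeciationResult,
)

__all__ = [
    "surface_concentration",
    "protolytic_state",
    "speciation",
    "model_charge_density",
    "isoelectric_point",
]

ArrayLike = Union[float, np.ndarray]


def surface_concentration(area_per_lipid: float) -> float:
    """Surface concentration of PC, C_PC = 1/(A N_A), in mol m^-2.

    ``area_per_lipid`` is in Å² (70 Å² for a PC molecule in a bilayer).
    """
    if not area_per_lipid > 0:
        raise DomainError("area_per_lipid must be positive")
    return 1.0 / (area_per_lipid * ANGSTROM**2 * AVOGADRO)


def protolytic_state(pH: float, medium: Medium = Medium()) -> ProtolyticState:
    """Bulk H+/OH- concentrations (mol m^-3) at a given pH.

    pH is defined on the mol L^-1 scale, so a_H = 10^(3-pH) mol m^-3 and
    a_OH = K_W / a_H with K_W in (mol m^-3)^2.
    """
    if not 0.0 <= pH <= 14.0:
        raise DomainError(f"pH must lie in [0, 14], got {pH!r}")
    a_H = 10.0 ** (3.0 - pH)
    return ProtolyticState(pH=pH, a_H=a_H, a_OH=medium.water_ion_product / a_H)


def speciation(
    state: ProtolyticState,
    electrolyte: Electrolyte,
    constants: BindingConstants,
    membrane: Membrane = Membrane(),
) -> SpeciationResult:
    """Surface speciation of both head-group sites by mass action.

    Free-site concentrations follow from conservation:
    a_A- = C_PC/(1 + K_AH a_H + K_ANa a_Na) and
    a_B+ = C_PC/(1 + K_BOH a_OH + K_BX a_X); the bound forms are the
    corresponding mass-action products.  delta = (a_B+ - a_A-) F.
    """
    c_pc = membrane.surface_concentration
    a_na = electrolyte.cation_concentration
    a_x = electrolyte.anion_concentration
    a_aminus = c_pc / (1.0 + constants.K_AH * state.a_H + constants.K_ANa * a_na)
    a_bplus = c_pc / (1.0 + constants.K_BOH * state.a_OH + constants.K_BX * a_x)
    return SpeciationResult(
        a_Aminus=a_aminus,
        a_AH=constants.K_AH * a_aminus * state.a_H,
        a_ANa=constants.K_ANa * a_aminus * a_na,
        a_Bplus=a_bplus,
        a_BOH=constants.K_BOH * a_bplus * state.a_OH,
        a_BX=constants.K_BX * a_bplus * a_x,
        delta=(a_bplus - a_aminus) * FARADAY,
    )


def model_charge_density(
    pH: ArrayLike,
    electrolyte: Electrolyte,
    constants: BindingConstants,
    membrane: Membrane = Membrane(),
    medium: Medium = Medium(),
) -> ArrayLike:
    """Net surface charge density δ(pH) in C m^-2 (vectorized in pH)."""
    pH = np.asarray(pH, dtype=float)
    a_h = 10.0 ** (3.0 - pH)
    a_oh = medium.water_ion_product / a_h
    c_pc = membrane.surface_concentration
    pos = c_pc / (
        1.0 + constants.K_BOH * a_oh + constants.K_BX * electrolyte.anion_concentration
    )
    neg = c_pc / (
        1.0 + constants.K_AH * a_h + constants.K_ANa * electrolyte.cation_concentration
    )
    out = FARADAY * (pos - neg)
    return float(out) if out.ndim == 0 else out


def isoelectric_point(
    electrolyte: Electrolyte,
    constants: BindingConstants,
    membrane: Membrane = Membrane(),
    medium: Medium = Medium(),
    tol: float = 1e-13,
) -> float:
    """pH at which δ(pH) = 0, by bisection on [0, 14].

    δ(pH) is strictly decreasing for positive constants, so the root is
    unique.  Raises :class:`NoIsoelectricPointError` when δ does not change
    sign on [0, 14].
    """

    def f(pH: float) -> float:
        return model_charge_density(pH, electrolyte, constants, membrane, medium)

    lo, hi = f(0.0), f(14.0)
    if lo == 0.0 and hi != 0.0:
        return 0.0
    if hi == 0.0 and lo != 0.0:
        return 14.0
    if np.sign(lo) == np.sign(hi):
        raise NoIsoelectricPointError(
            "model charge density does not change sign on pH in [0, 14] "
            f"(δ(0) = {lo:.3e}, δ(14) = {hi:.3e} C m^-2)"
        )
    return float(bisect(f, 0.0, 14.0, xtol=tol))
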