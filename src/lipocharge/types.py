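"""Core domain containers: medium, electrolyte, membrane, binding constants,
titration curves and fit results.

Unit conventions are SI throughout: volumetric ion concentrations in
mol m^-3 (so 155 mM = 155 mol m^-3), surface concentrations in mol m^-2,
charge density in C m^-2, zeta potential in V, mobility in m^2 V^-1 s^-1.
Association constants are in m^3 mol^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import ANGSTROM, AVOGADRO
from .exceptions import DomainError

#: Crystallographic (Pauling-type) anion radii in Å, shipped as metadata for
#: the Hofmeister size–affinity relation.
ANION_RADII_ANGSTROM = {
    "NaCl": 1.81,
    "NaBr": 1.95,
    "NaNO3": 1.89,
    "NaI": 2.16,
}


def _require_positive(name: str, value: float) -> None:
    if not (np.isfinite(value) and value > 0):
        raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class Medium:
    """Aqueous solvent context.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.
    relative_permittivity : float
        Relative permittivity of the electrolyte (dimensionless).
    viscosity : float
        Dynamic viscosity, Pa s.
    water_ion_product : float
        Ionic product of water K_W in (mol m^-3)^2; 1e-8 corresponds to the
        familiar 1e-14 mol^2 L^-2 at 25 °C.
    """

    temperature: float = 298.15
    relative_permittivity: float = 78.36
    viscosity: float = 8.903e-4
    water_ion_product: float = 1.0e-8

    def __post_init__(self) -> None:
        for name in ("temperature", "relative_permittivity", "viscosity", "water_ion_product"):
            _require_positive(name, getattr(self, name))

    @property
    def permittivity(self) -> float:
        """Absolute permittivity ε ε₀ in F m^-1."""
        from .constants import VACUUM_PERMITTIVITY

        return self.relative_permittivity * VACUUM_PERMITTIVITY


@dataclass(frozen=True)
class Electrolyte:
    """A 1:1 sodium salt at a given bulk concentration.

    concentration is in mol m^-3; for a 1:1 salt the cation and anion bulk
    concentrations both equal it.  anion_radius (Å) is optional metadata,
    auto-filled for the four salts of the study design.
    """

    salt: str = "NaCl"
    concentration: float = 155.0
    anion_radius: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("concentration", self.concentration)
        if self.anion_radius is None and self.salt in ANION_RADII_ANGSTROM:
            object.__setattr__(self, "anion_radius", ANION_RADII_ANGSTROM[self.salt])

    @property
    def cation_concentration(self) -> float:
        """Bulk Na+ concentration a_Na, mol m^-3."""
        return self.concentration

    @property
    def anion_concentration(self) -> float:
        """Bulk X- concentration a_X, mol m^-3."""
        return self.concentration


@dataclass(frozen=True)
class Membrane:
    """Phosphatidylcholine membrane described by its area per lipid (Å²)."""

    area_per_lipid: float = 70.0

    def __post_init__(self) -> None:
        _require_positive("area_per_lipid", self.area_per_lipid)

    @property
    def surface_concentration(self) -> float:
        """Surface concentration of PC, C_PC = 1/(A N_A) in mol m^-2."""
        return 1.0 / (self.area_per_lipid * ANGSTROM**2 * AVOGADRO)


@dataclass(frozen=True)
class BindingConstants:
    """The four ion–lipid association constants, m^3 mol^-1.

    K_AH and K_ANa bind H+ and Na+ to the phosphate group (A- = -PO(-));
    K_BOH and K_BX bind OH- and the salt anion X- to the trimethylammonium
    group (B+ = -N(+)(CH3)3).
    """

    K_AH: float
    K_ANa: float
    K_BOH: float
    K_BX: float

    def __post_init__(self) -> None:
        for name in ("K_AH", "K_ANa", "K_BOH", "K_BX"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise DomainError(f"{name} must be finite and non-negative, got {v!r}")

    def as_array(self) -> np.ndarray:
        """(K_AH, K_ANa, K_BOH, K_BX) as a float array."""
        return np.array([self.K_AH, self.K_ANa, self.K_BOH, self.K_BX], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "BindingConstants":
        k_ah, k_ana, k_boh, k_bx = values
        return cls(K_AH=float(k_ah), K_ANa=float(k_ana), K_BOH=float(k_boh), K_BX=float(k_bx))

    def to_presentation_units(self) -> dict:
        """Constants on the conventional reporting scales
        (K_ANa, K_BX in 10^-1; K_AH in 10^2; K_BOH in 10^9 m^3 mol^-1)."""
        return {
            "K_ANa_1e-1": self.K_ANa / 1e-1,
            "K_AH_1e2": self.K_AH / 1e2,
            "K_BOH_1e9": self.K_BOH / 1e9,
            "K_BX_1e-1": self.K_BX / 1e-1,
        }


@dataclass(frozen=True)
class ProtolyticState:
    """Bulk H+/OH- concentrations at a given pH, mol m^-3."""

    pH: float
    a_H: float
    a_OH: float


@dataclass(frozen=True)
class MobilityPoint:
    """A single electrophoretic-mobility observation.

    mobility in m^2 V^-1 s^-1 (signed); zeta, if present, must share its
    sign.  particle_radius (m) is optional metadata for the thin-double-layer
    check.
    """

    pH: float
    mobility: float
    particle_radius: Optional[float] = None
    zeta: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise DomainError(f"pH must lie in [0, 14], got {self.pH!r}")
        if self.zeta is not None and self.mobility * self.zeta < 0:
            raise DomainError("mobility and zeta must have the same sign (or both be zero)")


@dataclass(frozen=True)
class SpeciationResult:
    """Surface speciation of the two PC head groups, mol m^-2 each, and the
    resulting net charge density delta in C m^-2."""

    a_Aminus: float
    a_AH: float
    a_ANa: float
    a_Bplus: float
    a_BOH: float
    a_BX: float
    delta: float


@dataclass
class TitrationCurve:
    """Ordered (pH, sigma, sd) observations of surface charge density.

    pH strictly increasing within [0, 14]; sigma in C m^-2; sd optional
    per-point standard deviation (same units).
    """

    pH: np.ndarray
    sigma: np.ndarray
    sd: Optional[np.ndarray] = None
    electrolyte: Electrolyte = field(default_factory=Electrolyte)
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.pH.shape:
                raise DomainError("sd must have the same shape as pH")
        if self.pH.shape != self.sigma.shape or self.pH.ndim != 1:
            raise DomainError("pH and sigma must be 1-d arrays of equal length")
        if self.pH.size and (self.pH.min() < 0 or self.pH.max() > 14):
            raise DomainError("all pH values must lie in [0, 14]")
        if self.pH.size > 1 and not np.all(np.diff(self.pH) > 0):
            raise DomainError("pH must be strictly increasing")
        if self.provenance not in ("experimental", "synthetic"):
            raise DomainError("provenance must be 'experimental' or 'synthetic'")

    def __len__(self) -> int:
        return self.pH.size

    def restrict(self, pH_max: float) -> "TitrationCurve":
        """Sub-curve with points at pH <= pH_max."""
        keep = self.pH <= pH_max + 1e-12
        return TitrationCurve(
            pH=self.pH[keep],
            sigma=self.sigma[keep],
            sd=None if self.sd is None else self.sd[keep],
            electrolyte=self.electrolyte,
            provenance=self.provenance,
        )

    def to_frame(self):
        """pandas DataFrame with columns pH, sigma[, sd]."""
        import pandas as pd

        data = {"pH": self.pH, "sigma": self.sigma}
        if self.sd is not None:
            data["sd"] = self.sd
        return pd.DataFrame(data)


@dataclass(frozen=True)
class LinearFit:
    """OLS line fitted to one asymptotic branch transform."""

    branch: str  # "acid" | "base"
    slope: float
    intercept: float
    window: tuple
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.branch not in ("acid", "base"):
            raise DomainError("branch must be 'acid' or 'base'")
        if self.n_points < 2:
            raise DomainError("a linear fit needs at least 2 points")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise DomainError("r_squared must lie in [0, 1]")


@dataclass
class EstimationResult:
    """Estimated binding constants plus fit diagnostics."""

    constants: BindingConstants
    method: str  # "linearized" | "nonlinear" | "linearized+nonlinear"
    rmse: float
    windows: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    n_points: int = 0
    excluded_points: int = 0

    def __post_init__(self) -> None:
        if self.rmse < 0 or not math.isfinite(self.rmse):
            raise DomainError("rmse must be finite and non-negative")

    def to_dict(self, salt: Optional[str] = None) -> dict:
        """JSON-ready summary (constants in SI m^3 mol^-1)."""
        out = {
            "salt": salt,
            "method": self.method,
            "K_AH": self.constants.K_AH,
            "K_ANa": self.constants.K_ANa,
            "K_BOH": self.constants.K_BOH,
            "K_BX": self.constants.K_BX,
            "windows": self.windows,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "excluded_points": self.excluded_points,
        }
        out.update({k: v for k, v in self.diagnostics.items() if k not in out})
        return out
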