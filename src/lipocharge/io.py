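"""File I/O and run configuration.

Accepted CSV schemas (comma delimiter, dot decimal, UTF-8, case-insensitive
headers, ``sd`` column optional):

    pH,mobility,sd   mobility in m^2 V^-1 s^-1 (scientific notation accepted)
    pH,zeta,sd       zeta potential in mV
    pH,sigma,sd      surface charge density in C m^-2

Mobility and zeta inputs are converted to σ through the Smoluchowski
parallel-plate relations using the configured electrolyte and medium.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import electrokinetics as ek
from .estimation import DEFAULT_ACID_WINDOW, DEFAULT_BASE_WINDOW, DEFAULT_EXCLUDE_ABOVE
from .exceptions import DomainError, DuplicatePHWarning, FormatError
from .types import Electrolyte, EstimationResult, Medium, Membrane, TitrationCurve

__all__ = ["RunConfig", "read_titration_csv", "write_titration_csv", "result_to_json"]

_SCHEMAS = ("sigma", "zeta", "mobility")


@dataclass
class RunConfig:
    """Configuration shared by the CLI and the readers.

    Units: temperature K, viscosity Pa s, concentration mol m^-3, area Å²,
    zeta mV (in files), mobility m^2 V^-1 s^-1, sigma C m^-2.
    """

    salt: str = "NaCl"
    concentration: float = 155.0
    temperature: float = 298.15
    viscosity: float = 8.903e-4
    relative_permittivity: float = 78.36
    water_ion_product: float = 1.0e-8
    area_per_lipid: float = 70.0
    acid_window: Tuple[float, float] = DEFAULT_ACID_WINDOW
    base_window: Tuple[float, float] = DEFAULT_BASE_WINDOW
    exclude_above: float = DEFAULT_EXCLUDE_ABOVE
    henry_factor: float = 1.5
    plate_spacing: Optional[float] = None  # m; default: Debye length
    method: str = "linearized+nonlinear"
    weighted: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.acid_window = tuple(self.acid_window)
        self.base_window = tuple(self.base_window)
        for name in (
            "concentration", "temperature", "viscosity",
            "relative_permittivity", "water_ion_product", "area_per_lipid",
            "henry_factor",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        for win in (self.acid_window, self.base_window):
            if not (0 <= win[0] < win[1] <= 14):
                raise DomainError(f"window {win} must be increasing within [0, 14]")
        if self.acid_window[1] > self.base_window[0]:
            raise DomainError("acid and base windows must not overlap")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        """Load from YAML or JSON (same schema)."""
        path = Path(path)
        with path.open() as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls(**(data or {}))

    def medium(self) -> Medium:
        return Medium(
            temperature=self.temperature,
            relative_permittivity=self.relative_permittivity,
            viscosity=self.viscosity,
            water_ion_product=self.water_ion_product,
        )

    def electrolyte(self) -> Electrolyte:
        return Electrolyte(salt=self.salt, concentration=self.concentration)

    def membrane(self) -> Membrane:
        return Membrane(area_per_lipid=self.area_per_lipid)

    def spacing(self) -> float:
        return (
            self.plate_spacing
            if self.plate_spacing is not None
            else ek.debye_length(self.electrolyte(), self.medium())
        )

    def to_dict(self) -> dict:
        return asdict(self)


def read_titration_csv(
    path: Union[str, Path], config: RunConfig = None
) -> TitrationCurve:
    """Read a titration CSV, auto-dispatching on the observable column.

    Mobility and zeta (mV) columns are converted to surface charge density;
    duplicate pH rows are averaged with a :class:`DuplicatePHWarning`; rows
    are sorted by pH.
    """
    config = config or RunConfig()
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if "ph" not in lower:
        raise FormatError(
            "missing 'pH' column; accepted schemas: pH,sigma[,sd] | pH,zeta[,sd] | pH,mobility[,sd]"
        )
    kind = next((k for k in _SCHEMAS if k in lower), None)
    if kind is None:
        raise FormatError(
            f"no observable column among {_SCHEMAS}; accepted schemas: "
            "pH,sigma[,sd] | pH,zeta[,sd] | pH,mobility[,sd]"
        )
    out = pd.DataFrame(
        {
            "pH": df[lower["ph"]].astype(float),
            "value": df[lower[kind]].astype(float),
        }
    )
    if "sd" in lower:
        out["sd"] = df[lower["sd"]].astype(float)
    if out["pH"].duplicated().any():
        warnings.warn("duplicate pH values averaged", DuplicatePHWarning)
        out = out.groupby("pH", as_index=False).mean()
    out = out.sort_values("pH", kind="stable").reset_index(drop=True)

    medium = config.medium()
    value = out["value"].to_numpy()
    sd = out["sd"].to_numpy() if "sd" in out else None
    if kind == "sigma":
        sigma, sigma_sd = value, sd
    elif kind == "zeta":
        d = config.spacing()
        sigma = np.asarray(ek.charge_density_from_zeta(value * 1e-3, medium, d))
        sigma_sd = None if sd is None else np.abs(
            np.asarray(ek.charge_density_from_zeta(sd * 1e-3, medium, d))
        )
    else:  # mobility
        d = config.spacing()
        sigma = np.asarray(ek.charge_density_from_mobility(value, medium, d))
        sigma_sd = None if sd is None else np.abs(
            np.asarray(ek.charge_density_from_mobility(sd, medium, d))
        )
    return TitrationCurve(
        pH=out["pH"].to_numpy(),
        sigma=sigma,
        sd=sigma_sd,
        electrolyte=config.electrolyte(),
        provenance="experimental",
    )


def write_titration_csv(
    curve_or_frame, path: Union[str, Path], observable: str = "sigma"
) -> None:
    """Write a curve (or a pH/mobility DataFrame) in the accepted dialect."""
    if isinstance(curve_or_frame, TitrationCurve):
        df = curve_or_frame.to_frame().rename(columns={"sigma": observable})
    else:
        df = curve_or_frame
    df.to_csv(path, index=False, float_format="%.10e")


def result_to_json(
    result: EstimationResult,
    salt: Optional[str] = None,
    path: Optional[Union[str, Path]] = None,
) -> dict:
    """Serialize an estimation result (constants in SI m^3 mol^-1)."""
    payload = result.to_dict(salt=salt)
    payload["presentation_units"] = result.constants.to_presentation_units()
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return payload
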