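"""Synthetic titration data with the statistical structure of the
microelectrophoresis study design: 155 mol m^-3 1:1 sodium salts, pH grid
2–9.5 in 0.3-unit steps, three replicates reported as mean ± sample SD,
i.i.d. Gaussian measurement noise.

Noise is homoscedastic either in σ (charge-density-level generation) or in µ
(instrument-level generation); Gaussian is the minimal assumption for data
reported as mean ± SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .electrokinetics import debye_length
from .equilibrium import model_charge_density
from .exceptions import DomainError
from .types import BindingConstants, Electrolyte, Medium, Membrane, TitrationCurve

__all__ = [
    "DEFAULT_PH_GRID",
    "SyntheticSpec",
    "generate_titration",
    "generate_mobility_series",
    "reference_constants",
    "liposome_metadata",
]

#: The study's measurement grid: pH 2.0–9.5 every 0.3 units (26 points).
DEFAULT_PH_GRID = np.round(np.arange(2.0, 9.5 + 1e-9, 0.3), 10)

#: Default per-replicate measurement noise, C m^-2 (~4% of the low-pH NaCl
#: signal of ≈1.4e-2 C m^-2, the magnitude class of visible error bars).
DEFAULT_NOISE_SD = 5e-4


def reference_constants(salt: Optional[str] = None):
    """Published association constants (SI m^3 mol^-1) for egg-PC membranes
    in the four 155 mM sodium salts.  Returns a dict of
    :class:`BindingConstants` or a single entry when ``salt`` is given."""
    with resources.files("lipocharge.data").joinpath("reference_constants.json").open() as fh:
        raw = json.load(fh)
    table = {s: BindingConstants(**vals) for s, vals in raw.items()}
    return table if salt is None else table[salt]


def liposome_metadata() -> dict:
    """Reference dynamic-light-scattering characterization (bimodal size
    distribution, PDI, zeta potential) of the PC liposome preparations.
    Documentation metadata only: it motivates the thin-double-layer
    (f(κa) = 1.5) treatment but does not enter any computation."""
    with resources.files("lipocharge.data").joinpath("liposome_dls_reference.json").open() as fh:
        return json.load(fh)


@dataclass
class SyntheticSpec:
    """Specification of a synthetic titration experiment."""

    constants: BindingConstants
    electrolyte: Electrolyte = field(default_factory=Electrolyte)
    membrane: Membrane = field(default_factory=Membrane)
    medium: Medium = field(default_factory=Medium)
    pH_grid: np.ndarray = field(default_factory=lambda: DEFAULT_PH_GRID.copy())
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.pH_grid = np.asarray(self.pH_grid, dtype=float)
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be at least 1")
        if self.pH_grid.size and (self.pH_grid.min() < 0 or self.pH_grid.max() > 14):
            raise DomainError("pH grid must lie within [0, 14]")
        if self.pH_grid.size > 1 and not np.all(np.diff(self.pH_grid) > 0):
            raise DomainError("pH grid must be strictly increasing")

    @classmethod
    def for_salt(cls, salt: str, **kwargs) -> "SyntheticSpec":
        """Spec using the published constants for one of the four study salts."""
        return cls(
            constants=reference_constants(salt),
            electrolyte=Electrolyte(salt=salt),
            **kwargs,
        )


def _true_sigma(spec: SyntheticSpec) -> np.ndarray:
    return np.atleast_1d(
        model_charge_density(
            spec.pH_grid, spec.electrolyte, spec.constants, spec.membrane, spec.medium
        )
    )


def generate_titration(spec: SyntheticSpec) -> TitrationCurve:
    """Synthetic σ(pH) curve: per grid point, ``n_replicates`` draws of
    δ_true + N(0, noise_sd²); the curve stores the replicate mean and sample
    SD.  Identical seeds give identical output; noise_sd = 0 reproduces the
    model exactly (SD = 0)."""
    truth = _true_sigma(spec)
    if spec.noise_sd == 0.0:
        mean, sd = truth.copy(), np.zeros_like(truth)
    else:
        rng = np.random.default_rng(spec.seed)
        reps = truth[None, :] + rng.normal(
            0.0, spec.noise_sd, (spec.n_replicates, truth.size)
        )
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if spec.n_replicates > 1 else np.zeros_like(mean)
    return TitrationCurve(
        pH=spec.pH_grid.copy(),
        sigma=mean,
        sd=sd,
        electrolyte=spec.electrolyte,
        provenance="synthetic",
    )


def generate_mobility_series(
    spec: SyntheticSpec, noise_sd_mobility: Optional[float] = None
) -> pd.DataFrame:
    """Instrument-level synthetic data: mobility records (pH, mobility, sd).

    The true σ is mapped to mobility through the parallel-plate relation
    µ = δ d / η with d the Debye length of the spec's electrolyte, and
    Gaussian noise is applied in mobility space.  When ``noise_sd_mobility``
    is omitted, the spec's σ-space noise is propagated linearly
    (noise_µ = noise_σ · d/η)."""
    d = debye_length(spec.electrolyte, spec.medium)
    factor = d / spec.medium.viscosity  # sigma -> mobility
    mu_true = _true_sigma(spec) * factor
    if noise_sd_mobility is None:
        noise_sd_mobility = spec.noise_sd * factor
    if noise_sd_mobility == 0.0:
        mean, sd = mu_true.copy(), np.zeros_like(mu_true)
    else:
        rng = np.random.default_rng(spec.seed)
        reps = mu_true[None, :] + rng.normal(
            0.0, noise_sd_mobility, (spec.n_replicates, mu_true.size)
        )
        mean = reps.mean(axis=0)
        sd = (
            reps.std(axis=0, ddof=1)
            if spec.n_replicates > 1
            else np.zeros_like(mean)
        )
    return pd.DataFrame({"pH": spec.pH_grid, "mobility": mean, "sd": sd})
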