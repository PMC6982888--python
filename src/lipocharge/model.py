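"""scikit-learn style estimators.

:class:`IonBindingModel` regresses a surface-charge-density titration curve
onto the four ion–lipid association constants and predicts σ(pH);
:class:`MobilityToChargeDensity` is a stateless transformer converting raw
electrophoretic observables (mobility or zeta) to σ.  Both compose with
sklearn pipelines and model selection.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import electrokinetics as ek
from .equilibrium import isoelectric_point, model_charge_density
from .estimation import (
    DEFAULT_ACID_WINDOW,
    DEFAULT_BASE_WINDOW,
    DEFAULT_EXCLUDE_ABOVE,
    _curve_rmse,
    _linearized_estimate,
    fit_nonlinear,
)
from .exceptions import DomainError, InsufficientDataError, LipochargeError
from .types import BindingConstants, Electrolyte, EstimationResult, Medium, Membrane, TitrationCurve

__all__ = ["IonBindingModel", "MobilityToChargeDensity"]


def _as_ph_array(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise DomainError("X must be a single pH column")
        X = X[:, 0]
    if X.ndim != 1:
        raise DomainError("X must be 1-d or a single-column 2-d array of pH values")
    return X


class IonBindingModel(RegressorMixin, BaseEstimator):
    """Four-equilibrium ion-binding model of a PC membrane, fitted to a
    σ(pH) titration curve.

    Parameters
    ----------
    salt, concentration : electrolyte (1:1 sodium salt, mol m^-3).
    area_per_lipid : membrane area per PC molecule, Å².
    temperature, viscosity, relative_permittivity, water_ion_product :
        medium constants (K, Pa s, –, (mol m^-3)^2).
    method : "linearized", "nonlinear" or "linearized+nonlinear" (default);
        the combined route uses the asymptotic-regression estimate to
        initialize the nonlinear refit.
    acid_window, base_window : pH windows for the two branch regressions.
    exclude_above : points with pH above this are dropped before fitting.
    weighted : use 1/sd² weights when per-point SDs are supplied to fit.
    init : optional :class:`BindingConstants` overriding the nonlinear
        initialization.

    Attributes
    ----------
    constants_ : BindingConstants
        The fitted association constants (m^3 mol^-1).
    result_ : EstimationResult
        Full fit record (method, windows, rmse, diagnostics).
    rmse_ : float
        Root-mean-square residual of the fitted curve, C m^-2.

    Examples
    --------
    >>> from lipocharge import IonBindingModel, synthetic
    >>> spec = synthetic.SyntheticSpec.for_salt("NaBr", noise_sd=0.0)
    >>> curve = synthetic.generate_titration(spec)
    >>> est = IonBindingModel(salt="NaBr").fit(curve.pH, curve.sigma)
    >>> round(est.constants_.K_BX, 3)
    0.133
    """

    def __init__(
        self,
        salt: str = "NaCl",
        concentration: float = 155.0,
        area_per_lipid: float = 70.0,
        temperature: float = 298.15,
        viscosity: float = 8.903e-4,
        relative_permittivity: float = 78.36,
        water_ion_product: float = 1.0e-8,
        method: str = "linearized+nonlinear",
        acid_window: Tuple[float, float] = DEFAULT_ACID_WINDOW,
        base_window: Tuple[float, float] = DEFAULT_BASE_WINDOW,
        exclude_above: float = DEFAULT_EXCLUDE_ABOVE,
        weighted: bool = False,
        init: Optional[BindingConstants] = None,
    ):
        self.salt = salt
        self.concentration = concentration
        self.area_per_lipid = area_per_lipid
        self.temperature = temperature
        self.viscosity = viscosity
        self.relative_permittivity = relative_permittivity
        self.water_ion_product = water_ion_product
        self.method = method
        self.acid_window = acid_window
        self.base_window = base_window
        self.exclude_above = exclude_above
        self.weighted = weighted
        self.init = init

    # -- context objects ----------------------------------------------------
    def _medium(self) -> Medium:
        return Medium(
            temperature=self.temperature,
            relative_permittivity=self.relative_permittivity,
            viscosity=self.viscosity,
            water_ion_product=self.water_ion_product,
        )

    def _electrolyte(self) -> Electrolyte:
        return Electrolyte(salt=self.salt, concentration=self.concentration)

    def _membrane(self) -> Membrane:
        return Membrane(area_per_lipid=self.area_per_lipid)

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y, sd: Optional[np.ndarray] = None) -> "IonBindingModel":
        """Fit the binding constants to observations (pH, σ).

        X : array of pH values, shape (n,) or (n, 1).
        y : surface charge densities, C m^-2.
        sd : optional per-point standard deviations (used when weighted=True).
        """
        if self.method not in ("linearized", "nonlinear", "linearized+nonlinear"):
            raise DomainError(f"unknown method {self.method!r}")
        pH = _as_ph_array(X)
        y = np.asarray(y, dtype=float)
        if pH.shape != y.shape:
            raise DomainError("X and y must have matching lengths")
        order = np.argsort(pH, kind="stable")
        pH, y = pH[order], y[order]
        if sd is not None:
            sd = np.asarray(sd, dtype=float)[order]
        curve = TitrationCurve(
            pH=pH, sigma=y, sd=sd, electrolyte=self._electrolyte(), provenance="experimental"
        )

        medium, membrane = self._medium(), self._membrane()
        n_total = len(curve)
        curve = curve.restrict(self.exclude_above)
        excluded = n_total - len(curve)
        if len(curve) < 4:
            raise InsufficientDataError(
                f"need at least 4 points at pH <= {self.exclude_above}, have {len(curve)}"
            )

        windows = {"acid": tuple(self.acid_window), "base": tuple(self.base_window)}
        diagnostics: dict = {}
        lin_constants = None
        if self.method in ("linearized", "linearized+nonlinear"):
            try:
                lin_constants, lin_diag = _linearized_estimate(
                    curve, membrane, medium, self.acid_window, self.base_window, self.weighted
                )
                diagnostics["linearized"] = {
                    "K": lin_constants.as_array().tolist(),
                    "root_selection": lin_diag.get("root_selection"),
                    "intercept_fallback": lin_diag.get("intercept_fallback"),
                    "acid_r_squared": lin_diag["acid_fit"].r_squared,
                    "base_r_squared": lin_diag["base_fit"].r_squared,
                }
            except LipochargeError:
                if self.method == "linearized":
                    raise
                # noisy data can break the asymptotic route; the nonlinear
                # refit then starts from a generic initialization instead
                diagnostics["linearized"] = {"failed": True}
        if self.method == "linearized":
            constants = lin_constants
            result = EstimationResult(
                constants=constants,
                method="linearized",
                rmse=_curve_rmse(curve, constants, membrane, medium),
                windows=windows,
                diagnostics=diagnostics,
                n_points=len(curve),
                excluded_points=excluded,
            )
        else:
            init = self.init
            if init is None and self.method == "linearized+nonlinear":
                init = lin_constants
            nl = fit_nonlinear(curve, membrane, medium, init=init, weighted=self.weighted)
            diagnostics["nonlinear"] = nl.diagnostics
            result = EstimationResult(
                constants=nl.constants,
                method=self.method,
                rmse=nl.rmse,
                windows=windows,
                diagnostics=diagnostics,
                n_points=len(curve),
                excluded_points=excluded,
            )

        self.constants_ = result.constants
        self.result_ = result
        self.rmse_ = result.rmse
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Model σ(pH) at the fitted constants, C m^-2."""
        check_is_fitted(self, "constants_")
        pH = _as_ph_array(X)
        return np.atleast_1d(
            model_charge_density(
                pH, self._electrolyte(), self.constants_, self._membrane(), self._medium()
            )
        )

    def isoelectric_point(self) -> float:
        """pH of zero net surface charge at the fitted constants."""
        check_is_fitted(self, "constants_")
        return isoelectric_point(
            self._electrolyte(), self.constants_, self._membrane(), self._medium()
        )


class MobilityToChargeDensity(TransformerMixin, BaseEstimator):
    """Convert electrophoretic mobility (m^2 V^-1 s^-1) or zeta potential (V)
    to surface charge density (C m^-2) in the Smoluchowski regime.

    ``plate_spacing`` (the condenser spacing d, m) defaults to the Debye
    length of the configured electrolyte.  Stateless: ``fit`` only records
    the derived spacing.
    """

    def __init__(
        self,
        input: str = "mobility",
        salt: str = "NaCl",
        concentration: float = 155.0,
        temperature: float = 298.15,
        viscosity: float = 8.903e-4,
        relative_permittivity: float = 78.36,
        water_ion_product: float = 1.0e-8,
        henry_factor: float = 1.5,
        plate_spacing: Optional[float] = None,
    ):
        self.input = input
        self.salt = salt
        self.concentration = concentration
        self.temperature = temperature
        self.viscosity = viscosity
        self.relative_permittivity = relative_permittivity
        self.water_ion_product = water_ion_product
        self.henry_factor = henry_factor
        self.plate_spacing = plate_spacing

    def _medium(self) -> Medium:
        return Medium(
            temperature=self.temperature,
            relative_permittivity=self.relative_permittivity,
            viscosity=self.viscosity,
            water_ion_product=self.water_ion_product,
        )

    def _spacing(self) -> float:
        if self.plate_spacing is not None:
            return self.plate_spacing
        return ek.debye_length(
            Electrolyte(salt=self.salt, concentration=self.concentration), self._medium()
        )

    def fit(self, X=None, y=None) -> "MobilityToChargeDensity":
        if self.input not in ("mobility", "zeta"):
            raise DomainError("input must be 'mobility' or 'zeta'")
        self.plate_spacing_ = self._spacing()
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "plate_spacing_")
        X = np.asarray(X, dtype=float)
        medium = self._medium()
        if self.input == "mobility":
            return np.asarray(
                ek.charge_density_from_mobility(X, medium, self.plate_spacing_)
            )
        return np.asarray(ek.charge_density_from_zeta(X, medium, self.plate_spacing_))

    def inverse_transform(self, sigma) -> np.ndarray:
        check_is_fitted(self, "plate_spacing_")
        sigma = np.asarray(sigma, dtype=float)
        medium = self._medium()
        if self.input == "mobility":
            return sigma * self.plate_spacing_ / medium.viscosity
        return sigma * self.plate_spacing_ / medium.permittivity
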