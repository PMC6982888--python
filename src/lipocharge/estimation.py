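"""Estimation of the four ion–lipid association constants from a σ(pH)
titration curve.

Two routes are provided:

1. **Linearized (asymptotic) route** — the historical procedure.  At high
   H+ concentration (acid branch) and low H+ concentration (base branch) the
   closed-form σ(pH) model linearizes, to first order, as

       acid:  δ a_H / F  ≈  [C_PC/(1+K_BX a_X)] a_H
                           - [C_PC K_BOH K_W/(1+K_BX a_X)^2 + C_PC/K_AH]
       base:  δ /(F a_H) ≈ -[C_PC/(1+K_ANa a_Na)] (1/a_H)
                           + [C_PC K_AH/(1+K_ANa a_Na)^2 + C_PC/(K_BOH K_W)]

   OLS slopes of the two branches give K_BX and K_ANa directly; the two
   intercept equations are then solved simultaneously for (K_AH, K_BOH),
   which reduces to a quadratic.  The asymptotic truncation biases this
   route; the bias is characterized in the tests and documented in the
   methods note.

2. **Nonlinear route** — direct least-squares refit of the closed-form model
   over log10-parameterized constants, initialized from the linearized
   estimate.  On noiseless model data this recovers the generating constants
   to machine precision.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import spearmanr

from .constants import FARADAY
from .equilibrium import model_charge_density
from .exceptions import (
    ConvergenceFailureError,
    DomainError,
    InsufficientDataError,
    NonPhysicalRootError,
    SignConventionError,
    TieWarning,
)
from .types import (
    BindingConstants,
    Electrolyte,
    EstimationResult,
    LinearFit,
    Medium,
    Membrane,
    TitrationCurve,
)

__all__ = [
    "DEFAULT_ACID_WINDOW",
    "DEFAULT_BASE_WINDOW",
    "DEFAULT_EXCLUDE_ABOVE",
    "transform_acid_branch",
    "transform_base_branch",
    "fit_linear_window",
    "linear_coefficients",
    "constants_from_linear_fits",
    "fit_nonlinear",
    "estimate_constants",
    "theoretical_curve",
    "rank_hofmeister",
]

#: Default pH windows for the two branch regressions.  The acid window is
#: deliberately short: the acid-branch expansion parameter
#: K_BOH K_W/(a_H (1+K_BX a_X)) grows quickly with pH, and for constants of
#: the magnitudes seen on PC membranes the K_BX truncation bias stays small
#: only over the lowest grid points (calibrated on noiseless model curves;
#: see the methods note).  Both windows are configurable.
DEFAULT_ACID_WINDOW = (2.0, 2.3)
DEFAULT_BASE_WINDOW = (5.5, 8.0)

#: Points above this pH are excluded from fitting by default (experimental
#: scatter grows there and the model is not meant to describe that region).
DEFAULT_EXCLUDE_ABOVE = 8.0

_WINDOW_EPS = 1e-9


def transform_acid_branch(
    curve: TitrationCurve, medium: Medium = Medium()
) -> Tuple[np.ndarray, np.ndarray]:
    """Acid-branch coordinates (x, y) = (a_H, δ a_H / F) for every point."""
    if len(curve) == 0:
        raise InsufficientDataError("empty curve")
    a_h = 10.0 ** (3.0 - curve.pH)
    return a_h, curve.sigma * a_h / FARADAY


def transform_base_branch(
    curve: TitrationCurve, medium: Medium = Medium()
) -> Tuple[np.ndarray, np.ndarray]:
    """Base-branch coordinates (x, y) = (1/a_H, δ /(F a_H)) for every point."""
    if len(curve) == 0:
        raise InsufficientDataError("empty curve")
    a_h = 10.0 ** (3.0 - curve.pH)
    return 1.0 / a_h, curve.sigma / (FARADAY * a_h)


def fit_linear_window(
    x: np.ndarray,
    y: np.ndarray,
    pH: np.ndarray,
    window: Tuple[float, float],
    branch: str,
    weights: Optional[np.ndarray] = None,
) -> LinearFit:
    """Ordinary (optionally weighted) least-squares line over points whose pH
    lies inside ``window``.  Exact for collinear input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pH = np.asarray(pH, dtype=float)
    lo, hi = window
    mask = (pH >= lo - _WINDOW_EPS) & (pH <= hi + _WINDOW_EPS)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"{branch} branch: need >= 2 points with pH in [{lo}, {hi}], found {int(mask.sum())}"
        )
    xw, yw = x[mask], y[mask]
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[mask])
    else:
        w = np.ones_like(xw)
    design = np.column_stack([xw, np.ones_like(xw)]) * w[:, None]
    coef, *_ = np.linalg.lstsq(design, yw * w, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    fitted = slope * xw + intercept
    ss_res = float(np.sum((w * (yw - fitted)) ** 2))
    ss_tot = float(np.sum((w * (yw - np.average(yw, weights=w**2))) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return LinearFit(
        branch=branch,
        slope=slope,
        intercept=intercept,
        window=(lo, hi),
        n_points=int(mask.sum()),
        r_squared=r2,
    )


def linear_coefficients(
    constants: BindingConstants,
    electrolyte: Electrolyte,
    membrane: Membrane = Membrane(),
    medium: Medium = Medium(),
) -> Tuple[float, float, float, float]:
    """Analytic asymptote coefficients (acid slope, acid intercept, base
    slope, base intercept) implied by a set of constants.  The algebraic
    inverse of :func:`constants_from_linear_fits`."""
    c_pc = membrane.surface_concentration
    a_na = electrolyte.cation_concentration
    a_x = electrolyte.anion_concentration
    kw = medium.water_ion_product
    db = 1.0 + constants.K_BX * a_x
    da = 1.0 + constants.K_ANa * a_na
    acid_slope = c_pc / db
    acid_intercept = -(c_pc * constants.K_BOH * kw / db**2 + c_pc / constants.K_AH)
    base_slope = -c_pc / da
    base_intercept = c_pc * constants.K_AH / da**2 + c_pc / (constants.K_BOH * kw)
    return acid_slope, acid_intercept, base_slope, base_intercept


def _intercept_candidates(
    alpha: float, i_b: float, c_pc: float, p: float, q: float
) -> list:
    """Positive (K_AH, v = K_BOH K_W) pairs solving the two intercept
    equations  alpha = C v/P + C/u  and  i_b = C u/Q + C/v.

    Eliminating v yields the quadratic
    C P alpha u^2 - (C^2 P - C^2 Q + i_b Q P alpha) u + i_b Q P C = 0.
    Both roots can be physically admissible: the two solutions reproduce the
    same asymptote lines and always straddle the threshold
    u v = sqrt(P Q); disambiguation is the caller's job.
    """
    a2 = c_pc * p * alpha
    a1 = -(c_pc**2) * p + c_pc**2 * q - i_b * q * p * alpha
    a0 = i_b * q * p * c_pc
    if a2 == 0.0:
        roots = [] if a1 == 0.0 else [-a0 / a1]
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc < 0.0:
            # numerically marginal discriminant -> treat as a double root
            if disc > -1e-12 * a1 * a1:
                disc = 0.0
            else:
                return []
        sq = np.sqrt(disc)
        roots = [(-a1 + sq) / (2.0 * a2), (-a1 - sq) / (2.0 * a2)]
    pairs = []
    for u in roots:
        if u > 0.0 and np.isfinite(u):
            v = p * (alpha - c_pc / u) / c_pc
            if v > 0.0 and np.isfinite(v):
                pairs.append((float(u), float(v)))
    return pairs


def _intercept_least_squares(
    alpha: float, i_b: float, c_pc: float, p: float, q: float
) -> Tuple[float, float]:
    """Best positive (K_AH, v) compromise when the intercept system is
    inconsistent (no exact positive solution): minimize the two relative
    equation residuals over log10(K_AH), log10(v)."""

    def residuals(t):
        u, v = 10.0 ** t[0], 10.0 ** t[1]
        return [
            (alpha - (c_pc * v / p + c_pc / u)) / abs(alpha),
            (i_b - (c_pc * u / q + c_pc / v)) / abs(i_b),
        ]

    best = None
    for u0, v0 in ((1e2, 1e1), (1e1, 1e2), (1e3, 1e0)):
        sol = least_squares(residuals, [np.log10(u0), np.log10(v0)], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise NonPhysicalRootError("intercept system admits no positive solution")
    return float(10.0 ** best.x[0]), float(10.0 ** best.x[1])


def constants_from_linear_fits(
    acid: LinearFit,
    base: LinearFit,
    membrane: Membrane = Membrane(),
    electrolyte: Electrolyte = Electrolyte(),
    medium: Medium = Medium(),
    curve: Optional[TitrationCurve] = None,
    allow_fallback: bool = False,
    root_selection: str = "strong_association",
) -> Tuple[BindingConstants, dict]:
    """Binding constants from the two branch fits.

    Slopes give K_BX and K_ANa directly; (K_AH, K_BOH) come from the
    simultaneous solution of the two intercept equations (a quadratic in
    K_AH).  The quadratic generically has two positive root pairs that
    reproduce the same asymptote lines; by default the strong
    protolytic-association branch (larger K_AH root) is returned — the
    physical regime for PC membranes, where H+ and OH- bind orders of
    magnitude more strongly than Na+ and X-.  With
    ``root_selection="curve_rmse"`` (requires ``curve``) the pair whose full
    model better reproduces the curve is chosen instead.

    Raises :class:`SignConventionError` for slope signs inconsistent with
    the model and :class:`NonPhysicalRootError` when no positive pair exists
    (unless ``allow_fallback`` enables a least-squares compromise).
    """
    if root_selection not in ("strong_association", "curve_rmse"):
        raise DomainError(f"unknown root_selection {root_selection!r}")
    if root_selection == "curve_rmse" and (curve is None or len(curve) == 0):
        raise DomainError("root_selection='curve_rmse' requires a source curve")
    if acid.slope <= 0:
        raise SignConventionError("acid-branch slope must be positive")
    if base.slope >= 0:
        raise SignConventionError("base-branch slope must be negative")
    c_pc = membrane.surface_concentration
    a_na = electrolyte.cation_concentration
    a_x = electrolyte.anion_concentration
    kw = medium.water_ion_product

    k_bx = (c_pc / acid.slope - 1.0) / a_x
    k_ana = (-c_pc / base.slope - 1.0) / a_na
    for name, val in (("K_BX", k_bx), ("K_ANa", k_ana)):
        if val < -1e-9 * c_pc:
            raise NonPhysicalRootError(f"slope-derived {name} is negative ({val:.3e})")
    k_bx = max(k_bx, 0.0)
    k_ana = max(k_ana, 0.0)

    p = (1.0 + k_bx * a_x) ** 2
    q = (1.0 + k_ana * a_na) ** 2
    alpha = -acid.intercept
    diagnostics: dict = {"intercept_fallback": False}
    if alpha <= 0:
        pairs = []
    else:
        pairs = _intercept_candidates(alpha, base.intercept, c_pc, p, q)

    if not pairs:
        if not allow_fallback or alpha <= 0 or base.intercept <= 0:
            raise NonPhysicalRootError(
                "no positive (K_AH, K_BOH) pair solves the intercept equations"
            )
        k_ah, v = _intercept_least_squares(alpha, base.intercept, c_pc, p, q)
        diagnostics["intercept_fallback"] = True
        diagnostics["root_selection"] = "least_squares"
    elif len(pairs) == 1:
        k_ah, v = pairs[0]
        diagnostics["root_selection"] = "unique"
    elif root_selection == "curve_rmse":
        def sse(pair):
            cand = BindingConstants(K_AH=pair[0], K_ANa=k_ana, K_BOH=pair[1] / kw, K_BX=k_bx)
            resid = model_charge_density(curve.pH, electrolyte, cand, membrane, medium) - curve.sigma
            return float(np.sum(resid**2))

        k_ah, v = min(pairs, key=sse)
        diagnostics["root_selection"] = "curve_rmse"
    else:
        k_ah, v = max(pairs, key=lambda pr: pr[0])
        diagnostics["root_selection"] = "strong_association"

    constants = BindingConstants(K_AH=k_ah, K_ANa=k_ana, K_BOH=v / kw, K_BX=k_bx)
    return constants, diagnostics


def _curve_rmse(
    curve: TitrationCurve,
    constants: BindingConstants,
    membrane: Membrane,
    medium: Medium,
) -> float:
    resid = (
        model_charge_density(curve.pH, curve.electrolyte, constants, membrane, medium)
        - curve.sigma
    )
    return float(np.sqrt(np.mean(resid**2)))


def fit_nonlinear(
    curve: TitrationCurve,
    membrane: Membrane = Membrane(),
    medium: Medium = Medium(),
    init: Optional[BindingConstants] = None,
    weighted: bool = False,
) -> EstimationResult:
    """Direct least-squares refit of the closed-form σ(pH) model.

    The four constants are parameterized as log10(K) (enforcing positivity)
    and refined by Levenberg–Marquardt.  ``init`` defaults to the linearized
    estimate; a generic starting point is used if that route fails.
    Deterministic given the data and the initialization.
    """
    if len(curve) < 5:
        raise InsufficientDataError("nonlinear fit needs at least 5 points")
    if init is None:
        try:
            init = _linearized_estimate(curve, membrane, medium)[0]
        except (InsufficientDataError, NonPhysicalRootError, SignConventionError):
            init = BindingConstants(K_AH=1e2, K_ANa=2e-1, K_BOH=3e9, K_BX=1e-1)

    k0 = np.clip(init.as_array(), 1e-12, None)
    electrolyte = curve.electrolyte
    if weighted and curve.sd is not None and np.all(curve.sd > 0):
        w = 1.0 / curve.sd
    else:
        w = np.ones_like(curve.sigma)

    a_h = 10.0 ** (3.0 - curve.pH)
    a_oh = medium.water_ion_product / a_h
    a_na = electrolyte.cation_concentration
    a_x = electrolyte.anion_concentration
    c_pc = membrane.surface_concentration

    def residuals(t):
        # clip the log-parameters so LM exploration cannot overflow 10**t
        k_ah, k_ana, k_boh, k_bx = 10.0 ** np.clip(t, -30.0, 30.0)
        sigma = FARADAY * (
            c_pc / (1.0 + k_boh * a_oh + k_bx * a_x)
            - c_pc / (1.0 + k_ah * a_h + k_ana * a_na)
        )
        return w * (sigma - curve.sigma)

    sol = least_squares(
        residuals, np.log10(k0), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=2000,
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise ConvergenceFailureError(
            f"nonlinear refit did not converge (status {sol.status}: {sol.message})",
            diagnostics={"status": sol.status, "nfev": sol.nfev, "cost": sol.cost},
        )
    constants = BindingConstants.from_array(10.0 ** np.clip(sol.x, -30.0, 30.0))
    return EstimationResult(
        constants=constants,
        method="nonlinear",
        rmse=_curve_rmse(curve, constants, membrane, medium),
        windows={},
        diagnostics={
            "nfev": int(sol.nfev),
            "status": int(sol.status),
            "init": init.as_array().tolist(),
            "weighted": bool(weighted and curve.sd is not None),
        },
        n_points=len(curve),
    )


def _linearized_estimate(
    curve: TitrationCurve,
    membrane: Membrane,
    medium: Medium,
    acid_window: Tuple[float, float] = DEFAULT_ACID_WINDOW,
    base_window: Tuple[float, float] = DEFAULT_BASE_WINDOW,
    weighted: bool = False,
) -> Tuple[BindingConstants, dict]:
    """Full linearized pipeline on an (already filtered) curve."""
    xa, ya = transform_acid_branch(curve, medium)
    xb, yb = transform_base_branch(curve, medium)
    weights = None
    if weighted and curve.sd is not None and np.all(curve.sd > 0):
        weights = 1.0 / curve.sd**2
    acid = fit_linear_window(xa, ya, curve.pH, acid_window, "acid", weights)
    base = fit_linear_window(xb, yb, curve.pH, base_window, "base", weights)
    constants, diag = constants_from_linear_fits(
        acid, base, membrane, curve.electrolyte, medium, curve=curve, allow_fallback=True
    )
    diag = dict(diag)
    diag["acid_fit"] = acid
    diag["base_fit"] = base
    return constants, diag


def estimate_constants(
    curve: TitrationCurve,
    membrane: Membrane = Membrane(),
    medium: Medium = Medium(),
    method: str = "linearized+nonlinear",
    acid_window: Tuple[float, float] = DEFAULT_ACID_WINDOW,
    base_window: Tuple[float, float] = DEFAULT_BASE_WINDOW,
    exclude_above: float = DEFAULT_EXCLUDE_ABOVE,
    weighted: bool = False,
    init: Optional[BindingConstants] = None,
) -> EstimationResult:
    """Estimate the four binding constants from a titration curve.

    Thin functional wrapper over :class:`lipocharge.model.IonBindingModel`;
    see that class for the orchestration details.
    """
    from .model import IonBindingModel

    est = IonBindingModel(
        salt=curve.electrolyte.salt,
        concentration=curve.electrolyte.concentration,
        area_per_lipid=membrane.area_per_lipid,
        temperature=medium.temperature,
        viscosity=medium.viscosity,
        relative_permittivity=medium.relative_permittivity,
        water_ion_product=medium.water_ion_product,
        method=method,
        acid_window=acid_window,
        base_window=base_window,
        exclude_above=exclude_above,
        weighted=weighted,
        init=init,
    )
    est.fit(curve.pH.reshape(-1, 1), curve.sigma, sd=curve.sd)
    return est.result_


def theoretical_curve(
    constants: BindingConstants,
    electrolyte: Electrolyte,
    membrane: Membrane = Membrane(),
    medium: Medium = Medium(),
    pH_grid: Union[Sequence[float], np.ndarray] = None,
) -> TitrationCurve:
    """Model σ(pH) evaluated on a pH grid, as a synthetic-provenance curve."""
    if pH_grid is None:
        pH_grid = np.round(np.arange(2.0, 9.5 + 1e-9, 0.3), 10)
    pH_grid = np.asarray(pH_grid, dtype=float)
    if pH_grid.size and (pH_grid.min() < 0 or pH_grid.max() > 14):
        raise DomainError("pH grid must lie within [0, 14]")
    sigma = model_charge_density(pH_grid, electrolyte, constants, membrane, medium)
    return TitrationCurve(
        pH=pH_grid,
        sigma=np.atleast_1d(sigma),
        sd=None,
        electrolyte=electrolyte,
        provenance="synthetic",
    )


def rank_hofmeister(
    results: Mapping[str, BindingConstants],
    radii: Optional[Mapping[str, float]] = None,
) -> dict:
    """Rank salts by anion-binding strength (descending K_BX).

    Ties keep input order and set a warning flag.  If anion radii (Å) are
    supplied, the Spearman rank correlation between radius and K_BX is
    reported (the Hofmeister size–affinity relation).
    """
    if len(results) < 2:
        raise InsufficientDataError("ranking needs at least 2 salts")
    salts = list(results)
    k_bx = {s: results[s].K_BX for s in salts}
    order = sorted(salts, key=lambda s: -k_bx[s])  # stable: ties keep input order
    values = [k_bx[s] for s in salts]
    tie = len(set(values)) < len(values)
    if tie:
        warnings.warn("equal K_BX values; ranking kept input order", TieWarning)
    out = {
        "order": order,
        "K_BX": k_bx,
        "tie": tie,
    }
    if radii is not None:
        common = [s for s in salts if s in radii]
        if len(common) >= 2:
            rho, _ = spearmanr([radii[s] for s in common], [k_bx[s] for s in common])
            out["spearman_radius_K_BX"] = float(rho)
            out["radii"] = {s: radii[s] for s in common}
    return out
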