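"""Saturation-exponential calibration, inversion and error budget.

The calibration model is I(C) = A * (1 - exp(-B * C)) with A the
saturation fluorescence (ERF) and B the sensitivity (mL/ng).  The full
fit identifies both parameters by nonlinear least squares on nonzero
concentrations.  The production strategy freezes B from prior
calibration runs and re-identifies A in every run from a few
high-concentration controls plus the (0, 0) anchor; a sample
concentration then follows from the closed-form inversion

    C_x = (k / (B * D)) * ln(A / (A - I_x))

with dilution factor D and molecular-mass ratio k.  Uncertainty is
propagated in quadrature through the inversion; the negative control
sets the limit of detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "QuantInput",
    "QuantResult",
    "FitError",
    "SaturationError",
    "saturation_model",
    "fit_full",
    "fit_A_fixed_B",
    "invert_concentration",
    "propagate_error",
    "detection_limit",
    "quantify",
]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


class SaturationError(ValueError):
    """Sample fluorescence at or above the calibration asymptote."""


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # ng/mL, in-channel
    fluorescence: float   # ERF, background-subtracted

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class CalibrationFit:
    A: float               # ERF
    A_uncertainty: float
    B: float               # mL/ng
    B_uncertainty: float
    residual_norm: float = 0.0
    n_points: int = 0
    B_fixed: bool = False

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be > 0")
        if self.A_uncertainty < 0 or self.B_uncertainty < 0:
            raise ValueError("uncertainties must be >= 0")


@dataclass(frozen=True)
class QuantInput:
    I_x: float                 # ERF, background-subtracted sample signal
    dilution: float = 0.1      # D
    mass_ratio: float = 1.6    # k
    I_x_uncertainty: float = 0.0

    def __post_init__(self):
        if not (0 < self.dilution <= 1):
            raise ValueError("dilution must be in (0, 1]")
        if self.mass_ratio <= 0:
            raise ValueError("mass_ratio must be > 0")


@dataclass(frozen=True)
class QuantResult:
    C_x: float                  # ng/mL
    C_x_uncertainty: float
    contributions: dict         # absolute ng/mL per parameter
    in_range: bool
    c_min: float                # ng/mL, limit of detection
    saturated: bool = False


def saturation_model(A: float, B: float, C):
    """I(C) = A * (1 - exp(-B * C)); monotone in C with asymptote A."""
    return A * (1.0 - np.exp(-B * np.asarray(C, dtype=float))) \
        if not np.isscalar(C) else A * (1.0 - math.exp(-B * C))


def _jacobian(A, B, C):
    e = np.exp(-B * C)
    return np.column_stack([1.0 - e, A * C * e])


def _covariance(A, B, C, I):
    resid = I - A * (1.0 - np.exp(-B * C))
    ssr = float(resid @ resid)
    dof = len(C) - 2
    J = _jacobian(A, B, C)
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return math.sqrt(ssr), float("nan"), float("nan")
    if dof > 0:
        cov = cov * (ssr / dof)
        dA, dB = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
    else:
        dA = dB = 0.0  # exact interpolation, no residual information
    return math.sqrt(ssr), dA, dB


def fit_full(points: list[CalibrationPoint]) -> CalibrationFit:
    """Two-parameter least squares, excluding zero-concentration data."""
    pts = [p for p in points if p.concentration > 0]
    C = np.array([p.concentration for p in pts])
    I = np.array([p.fluorescence for p in pts])
    if len(np.unique(C)) < 2:
        raise ValueError("need >= 2 distinct nonzero concentrations")
    A0 = 1.1 * float(I.max())
    order = np.argsort(C)
    c1, i1 = C[order[0]], I[order[0]]
    frac = min(max(i1 / A0, 1e-6), 1 - 1e-6)
    B0 = -math.log(1.0 - frac) / c1
    try:
        with warnings.catch_warnings():
            # covariance is recomputed analytically below
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                lambda c, a, b: a * (1.0 - np.exp(-b * c)),
                C, I, p0=[A0, B0], maxfev=20000,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            )
    except RuntimeError as exc:
        raise FitError(f"saturation-model fit did not converge: {exc}") from exc
    A, B = float(popt[0]), float(popt[1])
    rnorm, dA, dB = _covariance(A, B, C, I)
    return CalibrationFit(A, dA, B, dB, rnorm, len(C))


def fit_A_fixed_B(points: list[CalibrationPoint], B_known: float,
                  B_uncertainty: float = 0.0,
                  include_origin: bool = True) -> CalibrationFit:
    """One-parameter least squares for A with B frozen.

    The model is linear in A, so the optimum is closed-form:
    A = sum(f * I) / sum(f^2) with f = 1 - exp(-B * C).  The origin,
    when appended, is an ordinary (0, 0) data point contributing only to
    the residual degrees of freedom.
    """
    if B_known <= 0:
        raise ValueError("B_known must be > 0")
    C = np.array([p.concentration for p in points], dtype=float)
    I = np.array([p.fluorescence for p in points], dtype=float)
    if not np.any(C > 0):
        raise ValueError("need at least one nonzero-concentration point")
    if include_origin:
        C = np.append(C, 0.0)
        I = np.append(I, 0.0)
    f = 1.0 - np.exp(-B_known * C)
    denom = float(f @ f)
    A = float(f @ I) / denom
    if A <= 0:
        raise FitError("fixed-B fit produced a non-positive asymptote")
    resid = I - A * f
    ssr = float(resid @ resid)
    dof = len(C) - 1
    dA = math.sqrt((ssr / dof) / denom) if dof > 0 else 0.0
    return CalibrationFit(A, dA, B_known, B_uncertainty,
                          math.sqrt(ssr), len(C), B_fixed=True)


def invert_concentration(fit: CalibrationFit, inp: QuantInput,
                         allow_negative: bool = False) -> float:
    """Closed-form inversion C_x = (k / (B D)) * ln(A / (A - I_x))."""
    if inp.I_x >= fit.A:
        raise SaturationError(
            f"I_x = {inp.I_x:g} ERF is at or above the asymptote "
            f"A = {fit.A:g} ERF; concentration unresolvable")
    if inp.I_x < 0 and not allow_negative:
        raise ValueError("negative I_x (enable allow_negative to tolerate)")
    scale = inp.mass_ratio / (fit.B * inp.dilution)
    return scale * math.log(fit.A / (fit.A - inp.I_x))


def propagate_error(fit: CalibrationFit, inp: QuantInput,
                    allow_negative: bool = False) -> tuple[float, dict]:
    """Quadrature error of the inverted concentration.

    Partials of the inversion: dC/dA = -(k/(BD)) * I_x / (A (A - I_x)),
    dC/dB = -C_x / B, dC/dI_x = (k/(BD)) / (A - I_x).  Returns the
    total and the absolute per-parameter contributions (ng/mL).
    """
    C_x = invert_concentration(fit, inp, allow_negative=allow_negative)
    scale = inp.mass_ratio / (fit.B * inp.dilution)
    dC_dA = -scale * inp.I_x / (fit.A * (fit.A - inp.I_x))
    dC_dB = -C_x / fit.B
    dC_dI = scale / (fit.A - inp.I_x)
    contrib = {
        "A": abs(dC_dA) * fit.A_uncertainty,
        "B": abs(dC_dB) * fit.B_uncertainty,
        "I_x": abs(dC_dI) * inp.I_x_uncertainty,
    }
    total = math.sqrt(sum(v * v for v in contrib.values()))
    return total, contrib


def detection_limit(fit: CalibrationFit, negative_control_I: float,
                    dilution: float = 0.1, mass_ratio: float = 1.6) -> float:
    """LOD: inversion of the negative-control fluorescence (ng/mL).

    A negative control at or above the asymptote makes every measurement
    unresolvable; the LOD is then +inf.
    """
    if negative_control_I <= 0:
        return 0.0
    if negative_control_I >= fit.A:
        return float("inf")
    inp = QuantInput(negative_control_I, dilution, mass_ratio)
    return invert_concentration(fit, inp)


def quantify(fit: CalibrationFit, inp: QuantInput,
             negative_control_I: float = 0.0,
             allow_negative: bool = True) -> QuantResult:
    """Full quantification of one sample: inversion, error budget, LOD."""
    c_min = detection_limit(fit, negative_control_I, inp.dilution,
                            inp.mass_ratio)
    if inp.I_x >= fit.A:
        return QuantResult(float("nan"), float("nan"), {}, False, c_min,
                           saturated=True)
    C_x = invert_concentration(fit, inp, allow_negative=allow_negative)
    dC_x, contrib = propagate_error(fit, inp, allow_negative=allow_negative)
    in_range = C_x >= c_min
    return QuantResult(C_x, dC_x, contrib, in_range, c_min)
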