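"""Heater temperature calibration and extrapolation.

The target container temperature is not read out during collections; only
heater current and voltage are.  Before the run, a pyrometer calibrates
temperature against applied current up to a nominal maximum, but collections
exceed it, so temperature must be extrapolated.  Two physically motivated
models capture resistive + radiative power dissipation:

    power model:    P = a·T + b·T⁴
    current model:  I = (α·T + β·T⁴) / (T + τ)

Both are fitted to the calibration points and inverted by root finding; the
quoted temperature is the mean of the two model predictions with a 1σ
uncertainty of half their absolute difference.  Fitting and inversion are
done in kelvin (the radiative T⁴ term requires an absolute scale); every
public interface speaks °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit, nnls

__all__ = [
    "CalibrationPoint",
    "CalibModels",
    "CalibrationError",
    "fit_models",
    "predict_temperature",
    "combine_temperatures",
]

_T0_K = 273.15
_BRACKET_K = (300.0, 4000.0)   # beyond tantalum's melting point; failure
                               # outside means a bad fit, not extrapolation


class CalibrationError(RuntimeError):
    """Underdetermined, singular, or non-convergent calibration fit."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One pyrometer reading: applied current (A), voltage (V), temperature (°C)."""

    applied_current: float
    voltage: float
    temperature: float

    def __post_init__(self):
        if self.applied_current <= 0 or self.power <= 0:
            raise CalibrationError("current and power must be > 0")
        if self.temperature <= 0:
            raise CalibrationError("temperature must be > 0 °C")

    @property
    def power(self) -> float:
        return self.applied_current * self.voltage


@dataclass(frozen=True)
class CalibModels:
    """Fitted parameter sets of the two extrapolation models.

    ``power_params`` = (a, b) with P in W, T in K; ``current_params`` =
    (α, β, τ) with I in A, T in K.  Residuals are model − data in the
    respective observable's units, one per calibration point.
    """

    power_params: tuple[float, float]
    current_params: tuple[float, float, float]
    power_residuals: tuple[float, ...]
    current_residuals: tuple[float, ...]
    temperature_range_c: tuple[float, float]
    current_range_a: tuple[float, float]

    def power_of_T(self, t_kelvin: float) -> float:
        a, b = self.power_params
        return a * t_kelvin + b * t_kelvin**4

    def current_of_T(self, t_kelvin: float) -> float:
        alpha, beta, tau = self.current_params
        return (alpha * t_kelvin + beta * t_kelvin**4) / (t_kelvin + tau)


def fit_models(points: list[CalibrationPoint]) -> CalibModels:
    """Fit the power and current extrapolation models to calibration points.

    The power model is linear in the (T, T⁴) basis and solved by
    non-negative least squares (a, b > 0 is physical: resistive + radiative);
    the current model by bounded nonlinear least squares, unweighted.
    """
    if len(points) < 3:
        raise CalibrationError(
            f"need at least 3 calibration points, got {len(points)}"
        )
    t_k = np.array([p.temperature + _T0_K for p in points])
    power = np.array([p.power for p in points])
    current = np.array([p.applied_current for p in points])
    if np.ptp(t_k) <= 0:
        raise CalibrationError("calibration points must span a temperature range")

    design = np.column_stack([t_k, t_k**4])
    (a, b), _ = nnls(design, power)
    if a <= 0 or b <= 0:
        raise CalibrationError(
            f"unphysical power-model coefficients a={a:.3g}, b={b:.3g}"
        )
    power_resid = design @ (a, b) - power

    def current_model(T, alpha, beta, tau):
        return (alpha * T + beta * T**4) / (T + tau)

    # start from the power fit: I ≈ P/V with V ≈ (T+τ₀)/k is equivalent to
    # α ∝ a, β ∝ b; scale by a least-squares match at τ₀
    tau0 = 300.0
    scale = float(
        np.sum(current * current_model(t_k, a, b, tau0))
        / np.sum(current_model(t_k, a, b, tau0) ** 2)
    )
    try:
        popt, _ = curve_fit(
            current_model, t_k, current,
            p0=[max(a * scale, 1e-12), max(b * scale, 1e-20), tau0],
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, 1e5]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise CalibrationError(f"current-model fit did not converge: {exc}") from exc
    alpha, beta, tau = map(float, popt)
    if alpha <= 0 or beta <= 0:
        raise CalibrationError(
            f"unphysical current-model coefficients α={alpha:.3g}, β={beta:.3g}"
        )
    current_resid = current_model(t_k, *popt) - current

    return CalibModels(
        power_params=(float(a), float(b)),
        current_params=(alpha, beta, tau),
        power_residuals=tuple(float(r) for r in power_resid),
        current_residuals=tuple(float(r) for r in current_resid),
        temperature_range_c=(float(t_k.min() - _T0_K), float(t_k.max() - _T0_K)),
        current_range_a=(float(current.min()), float(current.max())),
    )


def _invert(f, target: float, label: str) -> float:
    lo, hi = _BRACKET_K
    flo, fhi = f(lo) - target, f(hi) - target
    if flo * fhi > 0:
        raise CalibrationError(
            f"{label} model has no root in [{lo}, {hi}] K for target {target:.4g}; "
            "fit likely invalid"
        )
    return brentq(lambda T: f(T) - target, lo, hi, xtol=1e-9)


def predict_temperature(
    models: CalibModels, current: float, power: float
) -> tuple[float, float]:
    """Temperature (°C) and 1σ from the two-model combination rule.

    Each monotone model is inverted for T by bracketed root finding; the
    estimate is the mean of the two solutions and σ is half their absolute
    difference (the models' disagreement is the dominant extrapolation
    uncertainty).
    """
    t_power = _invert(models.power_of_T, power, "power")
    t_current = _invert(models.current_of_T, current, "current")
    mean_k, sigma = combine_temperatures(t_power, t_current)
    return mean_k - _T0_K, sigma


def combine_temperatures(t1: float, t2: float) -> tuple[float, float]:
    """Two-model combination rule: mean, and half the absolute difference as 1σ.

    Symmetric in argument order; works on any common temperature scale.
    """
    return 0.5 * (t1 + t2), 0.5 * abs(t1 - t2)
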