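"""Release-rate fitting of the background-subtracted ion current.

At constant target temperature the release of ²²⁵Ac from the source surface
follows the general solution of the diffusion/effusion problem: the ion
current is a series of decaying exponentials plus a constant,

    I(t) = Σᵢ φᵢ·exp(−λᵢ·t) + c,

where the slowest rate λ₁ is the effective release rate (half-time ln2/λ₁)
and c absorbs a slowly-vaporizing component (e.g. a target cold spot).
Terms are added one at a time and a candidate term is discarded — and the
series truncated — when two fitted rates agree within a configurable
relative threshold, which renders the extra term redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .beam_current import CurrentTrace

__all__ = ["ReleaseFit", "ReleaseFitError", "fit_release", "half_time"]

#: two fitted rates closer than this (relative) make a term redundant
RATE_DISTINCTION = 0.10


class ReleaseFitError(RuntimeError):
    """Release fit did not converge or input is degenerate."""


@dataclass(frozen=True)
class ReleaseFit:
    """Accepted exponential-series model of one constant-temperature window.

    Rates are per hour; amplitudes share the trace's current units.  ``stderr``
    holds 1σ errors in the order (φ₁…φₙ, λ₁…λₙ, c); ``covariance`` the full
    parameter covariance in the same order.
    """

    amplitudes: tuple[float, ...]
    rates_per_h: tuple[float, ...]
    constant: float
    stderr: tuple[float, ...]
    covariance: np.ndarray
    n_terms: int
    window: tuple[float, float]
    target_temperature_c: float | None = None

    @property
    def lambda1(self) -> float:
        """Slowest (release) rate, 1/h."""
        return min(self.rates_per_h)

    @property
    def lambda1_stderr(self) -> float:
        k = self.rates_per_h.index(self.lambda1)
        return self.stderr[self.n_terms + k]

    @property
    def half_time_h(self) -> float:
        return half_time(self.lambda1)

    def as_dict(self) -> dict:
        return {
            "phi": list(self.amplitudes),
            "lambda_per_h": list(self.rates_per_h),
            "c": self.constant,
            "stderr": list(self.stderr),
            "half_time_h": self.half_time_h,
            "n_terms": self.n_terms,
            "window": list(self.window),
            "target_temperature_C": self.target_temperature_c,
        }


def _model(t, *params):
    n = (len(params) - 1) // 2
    phis, lams, c = params[:n], params[n:2 * n], params[-1]
    out = np.full_like(t, c, dtype=float)
    for phi, lam in zip(phis, lams):
        out += phi * np.exp(-lam * t)
    return out


def _fit_n(t_h, y, n, p0):
    """Fit an n-term model in normalized current units (the picoampere-scale
    amplitudes would otherwise sit below the optimizer's step tolerances)."""
    scale = float(np.max(np.abs(y))) or 1.0
    p0s = list(np.asarray(p0, float))
    for k in list(range(n)) + [-1]:
        p0s[k] = p0s[k] / scale
    lower = [-np.inf] * n + [1e-9] * n + [-np.inf]
    upper = [np.inf] * (2 * n + 1)
    popt, pcov = curve_fit(
        _model, t_h, y / scale, p0=p0s, bounds=(lower, upper), maxfev=50000
    )
    for k in list(range(n)) + [2 * n]:
        popt[k] *= scale
        pcov[k, :] *= scale
        pcov[:, k] *= scale
    resid = y - _model(t_h, *popt)
    return popt, pcov, float(np.sum(resid**2))


def fit_release(
    segment: CurrentTrace,
    max_terms: int = 3,
    rate_distinction: float = RATE_DISTINCTION,
    target_temperature_c: float | None = None,
) -> ReleaseFit:
    """Fit Σφᵢ·exp(−λᵢt) + c to a background-subtracted constant-temperature
    current segment.

    Starts with one term and adds terms while the fitted rates remain
    mutually distinguishable (relative separation ≥ ``rate_distinction``);
    the first redundant term ends the search and the previous model is kept.
    Initial values: c from the final 10% of samples, λ and φ from a
    log-linear fit of (signal − c).
    """
    if len(segment) < 10:
        raise ReleaseFitError(f"need >= 10 samples, got {len(segment)}")
    t = segment.time_s
    y = segment.current_a
    t_h = (t - t[0]) / 3600.0

    n_tail = max(len(y) // 10, 2)
    c0 = float(np.mean(y[-n_tail:]))
    resid0 = y - c0
    pos = resid0 > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t_h[pos], np.log(resid0[pos]), 1)
        lam0 = max(-float(slope), 1e-3)
        phi0 = float(np.exp(intercept))
    else:
        lam0 = max(1.0 / max(t_h[-1], 1e-6), 1e-3)
        phi0 = float(max(y[0] - c0, np.ptp(y), 1e-15))

    try:
        popt, pcov, ssr = _fit_n(t_h, y, 1, [phi0, lam0, c0])
    except RuntimeError as exc:
        raise ReleaseFitError(
            f"single-term fit did not converge (rms residual of initial model "
            f"{np.std(y - _model(t_h, phi0, lam0, c0)):.3g}): {exc}"
        ) from exc

    best = (1, popt, pcov)
    for n in range(2, max_terms + 1):
        phis = list(popt[: n - 1]) + [popt[: n - 1][-1] * 0.3]
        lams = list(popt[n - 1 : 2 * (n - 1)])
        lams = lams + [lams[-1] * 5.0]
        p0 = phis + lams + [popt[-1]]
        try:
            cand, cand_cov, cand_ssr = _fit_n(t_h, y, n, p0)
        except RuntimeError:
            break
        rates = np.sort(cand[n : 2 * n])
        redundant = any(
            (b - a) < rate_distinction * b for a, b in zip(rates, rates[1:])
        )
        # a term whose amplitude is consistent with zero is redundant too:
        # the rate criterion alone is blind to the φ→0 degeneracy
        amp_err = np.sqrt(np.clip(np.diag(cand_cov)[:n], 0.0, None))
        amp_floor = 1e-6 * float(np.max(np.abs(y)))
        insignificant = bool(
            np.any(~np.isfinite(amp_err))
            or np.any(np.abs(cand[:n]) <= np.maximum(2.0 * amp_err, amp_floor))
        )
        if redundant or insignificant:
            break
        best = (n, cand, cand_cov)
        popt = cand

    n, popt, pcov = best
    stderr = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0.0, None)))
    return ReleaseFit(
        amplitudes=tuple(float(p) for p in popt[:n]),
        rates_per_h=tuple(float(p) for p in popt[n : 2 * n]),
        constant=float(popt[-1]),
        stderr=stderr,
        covariance=pcov,
        n_terms=n,
        window=(float(t[0]), float(t[-1])),
        target_temperature_c=target_temperature_c,
    )


def half_time(rate_per_h: float) -> float:
    """Release half-time ln(2)/λ in hours."""
    if rate_per_h <= 0:
        raise ValueError(f"rate must be > 0, got {rate_per_h}")
    return math.log(2.0) / rate_per_h
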