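"""End-of-collection (EOC) activity by back-extrapolation.

The ²²⁵Ac activity of a collected sample at the end-of-collection instant
t_f is inferred from spectroscopy measurements of chain members (²¹³Bi,
²²¹Fr, ²⁰⁹Tl …) taken days later.  Every predicted activity is linear in the
single unknown scale A_Ac(t_f): the decay-chain evolution supplies, per
measurement, the activity of that nuclide at that time per unit parent
activity at t_f.  The fit is therefore a one-parameter weighted linear least
squares with a closed-form solution; σ comes from the curvature of the
weighted residual sum and χ² is reported as a consistency diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .nuclear_data import ActivityState, DecayChain, evolve
from .spectroscopy import TimedActivity

__all__ = ["EOCEstimate", "EOCError", "estimate_eoc", "decay_to"]


class EOCError(ValueError):
    """Empty or degenerate back-extrapolation input."""


@dataclass(frozen=True)
class EOCEstimate:
    sample_id: str
    t_f: float        # s
    activity: float   # Bq, A_Ac(t_f)
    sigma: float      # Bq
    chi2: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "t_f": self.t_f,
            "activity_Bq": self.activity,
            "sigma_Bq": self.sigma,
            "chi2": self.chi2,
            "n_points": self.n_points,
        }


def _template_state(chain: DecayChain, t_f: float, initial_composition: str) -> ActivityState:
    if initial_composition == "pure-parent":
        return ActivityState.pure(chain, chain.root.name, activity_bq=1.0, timestamp=t_f)
    if initial_composition == "equilibrium":
        return ActivityState.equilibrium(chain, chain.root.name, 1.0, timestamp=t_f)
    raise EOCError(
        f"initial_composition must be 'pure-parent' or 'equilibrium', "
        f"got {initial_composition!r}"
    )


def estimate_eoc(
    measurements: list[TimedActivity],
    chain: DecayChain,
    t_f: float,
    initial_composition: str = "equilibrium",
    sample_id: str = "",
) -> EOCEstimate:
    """Weighted least-squares scale fit of A_Ac(t_f) to later activities.

    ``initial_composition`` fixes the daughter inventory at t_f: "equilibrium"
    (daughters grown in during the multi-hour collection; the default) or
    "pure-parent".  Since every measured probe re-equilibrates within hours,
    the choice is immaterial for measurements taken days after t_f.

    Measurements with σ=0 are treated as exact: if any are present the fit
    uses only those, unweighted.
    """
    if not measurements:
        raise EOCError("no measurements to fit")
    for m in measurements:
        if m.timestamp < t_f:
            raise EOCError(
                f"measurement at t={m.timestamp} precedes t_f={t_f}"
            )
        if m.nuclide not in chain:
            raise EOCError(f"nuclide {m.nuclide!r} not in chain")

    template = _template_state(chain, t_f, initial_composition)

    exact = [m for m in measurements if m.sigma == 0.0]
    fit_set = exact if exact else list(measurements)
    unweighted = bool(exact)

    # predicted activity per unit A_Ac(t_f), per measurement
    cache: dict[float, ActivityState] = {}
    g, y, w = [], [], []
    for m in fit_set:
        dt = m.timestamp - t_f
        if dt not in cache:
            cache[dt] = evolve(template, dt, chain)
        g.append(cache[dt].activity(m.nuclide))
        y.append(m.activity)
        w.append(1.0 if unweighted else 1.0 / m.sigma**2)

    swg2 = sum(wi * gi * gi for wi, gi in zip(w, g))
    if swg2 <= 0.0:
        raise EOCError("all weights (or all predictions) vanish; cannot fit")
    a_hat = sum(wi * yi * gi for wi, yi, gi in zip(w, y, g)) / swg2
    chi2 = sum(wi * (yi - a_hat * gi) ** 2 for wi, yi, gi in zip(w, y, g))
    sigma = 0.0 if unweighted else 1.0 / math.sqrt(swg2)
    return EOCEstimate(sample_id, t_f, a_hat, sigma, chi2, len(fit_set))


def decay_to(activity: float, nuclide, t_from: float, t_to: float) -> float:
    """Radioactive decay law: A(t_to) = A(t_from) · 2^(−Δt/t½).

    Used to refresh a loaded-source activity from its reference assay.
    ``nuclide`` is a :class:`~ac225rims.nuclear_data.Nuclide` or a half-life
    in seconds.  Δt may be negative (back-correction).
    """
    half_life_s = nuclide if isinstance(nuclide, (int, float)) else nuclide.half_life_s
    if half_life_s is None or half_life_s <= 0:
        raise ValueError("nuclide must be unstable (half-life > 0)")
    return activity * 2.0 ** (-(t_to - t_from) / half_life_s)
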