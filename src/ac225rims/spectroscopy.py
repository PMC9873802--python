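"""Count rates → activities: gamma singles, γ–γ coincidence, alpha counting.

Each estimator returns a :class:`TimedActivity` — one nuclide's activity with
a Poisson-propagated uncertainty at one instant — which is the currency of
the end-of-collection back-extrapolation.

The γ–γ coincidence estimator for the ²⁰⁹Tl 465/1567 keV cascade is the
workhorse for weak samples: the activity is the quotient of the product of
the two gate singles rates to the true-coincidence rate (up to branching
intensity factors), so both detector efficiencies — and with them the
geometry changes caused by alpha-recoil relocation of the daughters — cancel
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .nuclear_data import DecayChain

__all__ = [
    "CountMeasurement",
    "CoincidenceMeasurement",
    "TimedActivity",
    "SpectroscopyError",
    "SaturationError",
    "deadtime_correct",
    "singles_activity",
    "coincidence_activity",
    "alpha_activity",
]


class SpectroscopyError(ValueError):
    """Invalid or indeterminate counting measurement."""


class SaturationError(SpectroscopyError):
    """Observed rate at or beyond the non-paralyzable dead-time limit."""


@dataclass(frozen=True)
class TimedActivity:
    """Activity of one nuclide at one timestamp (seconds), with 1σ error."""

    nuclide: str
    timestamp: float
    activity: float           # Bq
    sigma: float              # Bq
    method: str               # "singles" | "coincidence" | "alpha"
    flag: str | None = None   # e.g. "negative-net", "indeterminate"

    def __post_init__(self):
        if self.sigma < 0:
            raise SpectroscopyError("sigma must be >= 0")


@dataclass(frozen=True)
class CountMeasurement:
    """One peak-area measurement from a gamma (or alpha) spectrum.

    ``gross_counts`` and ``background_counts`` share ``live_time`` (scale the
    background beforehand if it was measured over a different period).  The
    dead-time constant is the per-event τ of a non-paralyzable counter.
    """

    mid_time: float           # s
    live_time: float          # s
    gross_counts: float
    background_counts: float
    deadtime_constant: float  # s per recorded event
    detector_efficiency: float
    nuclide: str
    energy_kev: float
    intensity: float          # photons per decay

    def __post_init__(self):
        if self.live_time <= 0:
            raise SpectroscopyError("live_time must be > 0")
        if self.gross_counts < 0 or self.background_counts < 0:
            raise SpectroscopyError("counts must be >= 0")
        if not 0.0 < self.detector_efficiency <= 1.0:
            raise SpectroscopyError("detector efficiency must be in (0, 1]")


@dataclass(frozen=True)
class CoincidenceMeasurement:
    """Gate singles and coincidence rates for a two-gamma cascade.

    ``gate_intensities`` are the absolute emission intensities (per decay) of
    the two gated lines; ``cascade_intensity`` is the probability per decay
    that both are emitted in cascade.
    """

    mid_time: float
    live_time: float
    singles_rate_1: float     # counts/s in gate 1
    singles_rate_2: float     # counts/s in gate 2
    coincidence_rate: float   # counts/s
    window: float             # coincidence window, s
    gate_intensities: tuple[float, float]
    cascade_intensity: float
    nuclide: str = "Tl-209"

    def __post_init__(self):
        if min(self.singles_rate_1, self.singles_rate_2, self.coincidence_rate) < 0:
            raise SpectroscopyError("rates must be >= 0")
        if self.window <= 0:
            raise SpectroscopyError("window must be > 0")


def deadtime_correct(rate: float, deadtime_constant: float) -> float:
    """True event rate from an observed rate, non-paralyzable model.

    r_true = r_obs / (1 − r_obs·τ); requires r_obs·τ < 1.
    """
    if rate < 0:
        raise SpectroscopyError("rate must be >= 0")
    loss = rate * deadtime_constant
    if loss >= 1.0:
        raise SaturationError(
            f"observed rate {rate}/s at dead time {deadtime_constant}s is saturated"
        )
    return rate / (1.0 - loss)


def singles_activity(meas: CountMeasurement) -> TimedActivity:
    """Activity from a single gamma (or alpha) peak area.

    A = (dead-time-corrected gross rate − background rate) / (ε · I), with
    Poisson errors on gross and background counts propagated through the
    same expression.  A negative net rate is clamped to zero activity and
    flagged; its σ is still the counting error.
    """
    rate_gross = meas.gross_counts / meas.live_time
    rate_bkg = meas.background_counts / meas.live_time
    corrected = deadtime_correct(rate_gross, meas.deadtime_constant)
    net = corrected - rate_bkg

    denom = meas.detector_efficiency * meas.intensity
    if denom <= 0:
        raise SpectroscopyError("efficiency × intensity must be > 0")

    # d(corrected)/d(rate_gross) = 1/(1 − rτ)²
    dcorr = 1.0 / (1.0 - rate_gross * meas.deadtime_constant) ** 2
    var_net = (
        (math.sqrt(meas.gross_counts) / meas.live_time * dcorr) ** 2
        + (math.sqrt(meas.background_counts) / meas.live_time) ** 2
    )
    sigma = math.sqrt(var_net) / denom

    if net < 0:
        return TimedActivity(
            meas.nuclide, meas.mid_time, 0.0, sigma, "singles", flag="negative-net"
        )
    return TimedActivity(meas.nuclide, meas.mid_time, net / denom, sigma, "singles")


def coincidence_activity(
    meas: CoincidenceMeasurement, *, subtract_accidentals: bool = True
) -> TimedActivity:
    """Efficiency-free activity from a γ–γ cascade.

    Accidental coincidences 2·τ_w·R₁·R₂ are subtracted from the coincidence
    rate (optional); then A = (R₁·R₂ / R_c,true) · I_c / (I₁·I₂).  Both
    detector efficiencies cancel.  Uncertainty from Poisson statistics of the
    three counted rates over the live time, correlations neglected.
    """
    r1, r2, rc = meas.singles_rate_1, meas.singles_rate_2, meas.coincidence_rate
    accidental = 2.0 * meas.window * r1 * r2 if subtract_accidentals else 0.0
    rc_true = rc - accidental
    if rc_true <= 0:
        raise SpectroscopyError(
            f"true coincidence rate non-positive ({rc_true:.3g}/s): "
            "activity indeterminate"
        )
    i1, i2 = meas.gate_intensities
    if min(i1, i2, meas.cascade_intensity) <= 0:
        raise SpectroscopyError("gate/cascade intensities must be > 0")
    flag = None
    if rc_true > min(r1, r2):
        flag = "coincidence-exceeds-singles"

    a = (r1 * r2 / rc_true) * meas.cascade_intensity / (i1 * i2)

    t = meas.live_time
    rel_var = 0.0
    if r1 > 0:
        rel_var += 1.0 / (r1 * t)
    if r2 > 0:
        rel_var += 1.0 / (r2 * t)
    rel_var += rc / (rc_true**2 * t)   # σ(R_c)=√(R_c/t), scaled by ∂A/∂R_c
    sigma = a * math.sqrt(rel_var)
    return TimedActivity(meas.nuclide, meas.mid_time, a, sigma, "coincidence", flag=flag)


def alpha_activity(
    peak_counts: dict[str, float],
    live_time: float,
    geometry: float,
    retention: dict[str, float],
    chain: DecayChain,
    mid_time: float = 0.0,
) -> list[TimedActivity]:
    """Activities from alpha peak areas on a surface-deposited sample.

    Alpha decay kicks each recoiling daughter with ~100 keV, so a fraction of
    every generation leaves the counting geometry.  The effective solid angle
    for the n-th chain member is geometry × Π(retention of its ancestors);
    per-decay retention fractions are configuration.
    """
    if not 0.0 < geometry <= 0.5:
        raise SpectroscopyError("geometry must be in (0, 0.5] (2π maximum)")
    if live_time <= 0:
        raise SpectroscopyError("live_time must be > 0")
    order = [n for n in chain.names if n in peak_counts]
    root = chain.root.name
    out: list[TimedActivity] = []
    for name in order:
        # cumulative retention: product over ancestors along the chain order
        ancestors = [
            anc for anc in chain.names
            if anc != name
            and chain.is_reachable(anc, name) and chain.is_reachable(root, anc)
        ]
        missing = [anc for anc in ancestors if anc not in retention]
        if missing:
            raise SpectroscopyError(
                f"missing retention entry for ancestors {missing} of {name}"
            )
        cum = 1.0
        for anc in ancestors:
            cum *= retention[anc]
        counts = peak_counts[name]
        denom = live_time * geometry * cum
        if denom == 0.0:
            out.append(
                TimedActivity(name, mid_time, 0.0, math.inf, "alpha",
                              flag="indeterminate")
            )
            continue
        a = counts / denom
        sigma = math.sqrt(counts) / denom
        out.append(TimedActivity(name, mid_time, a, sigma, "alpha"))
    return out
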