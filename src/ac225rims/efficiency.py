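"""The efficiency calculus of a mass-separation collection.

The total collection efficiency factorizes over the physical sub-processes

    ε_T = ε_diff · ε_eff · ε_ion · ε_sep · ε_trans,

(diffusion out of the source matrix, effusion to the ion source, ionization,
mass-separator acceptance, beam transport).  The measured quantities are:

* ε_T      = Σ A_f(t_f) / A_t(t_i)  — summed end-of-collection activities of
  the samples collected from one source over the activity loaded into it;
* ε_op     = ΣA_collected / (ΣA_collected + ΣA_loss) — the fraction of the
  ionized beam not forfeited to mass scans and laser-optimization periods;
* ε_trans  = foil current / Faraday-cup current;
* ε_ion    = ε_T / (ε_trans · ε_op · ε_sep) — deduced, with ε_sep taken as
  unity (separator acceptance losses negligible).

All operations propagate 1σ uncertainties to first order assuming
uncorrelated inputs; a Monte-Carlo propagation is provided for audit.
Values are fractions in [0, 1] unless flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Measured",
    "EfficiencyBreakdown",
    "EfficiencyError",
    "collection_efficiency",
    "operational_efficiency",
    "ionization_efficiency",
    "transport_efficiency",
    "propagate_mc",
]

Measured = tuple[float, float]   # (value, 1σ)


class EfficiencyError(ValueError):
    """Degenerate input to an efficiency ratio."""


@dataclass(frozen=True)
class EfficiencyTerm:
    value: float
    sigma: float
    provenance: str   # "measured" | "derived" | "assumed-unity" | "unknown"


@dataclass
class EfficiencyBreakdown:
    """The ε-terms of the factorization with uncertainty and provenance.

    Terms left ``unknown`` (ε_diff, ε_eff unless supplied) are excluded from
    the product-consistency check.
    """

    eps_diff: EfficiencyTerm = EfficiencyTerm(float("nan"), float("nan"), "unknown")
    eps_eff: EfficiencyTerm = EfficiencyTerm(float("nan"), float("nan"), "unknown")
    eps_ion: EfficiencyTerm = EfficiencyTerm(float("nan"), float("nan"), "unknown")
    eps_sep: EfficiencyTerm = EfficiencyTerm(1.0, 0.0, "assumed-unity")
    eps_trans: EfficiencyTerm = EfficiencyTerm(float("nan"), float("nan"), "unknown")
    eps_op: EfficiencyTerm = EfficiencyTerm(float("nan"), float("nan"), "unknown")
    eps_T: EfficiencyTerm = EfficiencyTerm(float("nan"), float("nan"), "unknown")

    def as_dict(self) -> dict:
        def num(x):
            return None if math.isnan(x) else x

        return {
            name: {
                "value": num(term.value),
                "sigma": num(term.sigma),
                "provenance": term.provenance,
            }
            for name, term in vars(self).items()
        }

    def product_consistency(self) -> tuple[float, float] | None:
        """(ε_T − Π known terms, combined σ) over non-unknown factors, or
        None when ε_T or every factor is unknown."""
        factors = [
            t for t in (self.eps_diff, self.eps_eff, self.eps_ion,
                        self.eps_sep, self.eps_trans)
            if t.provenance != "unknown"
        ]
        if self.eps_T.provenance == "unknown" or not factors:
            return None
        prod = math.prod(t.value for t in factors)
        rel = math.sqrt(
            sum((t.sigma / t.value) ** 2 for t in factors if t.value != 0)
        )
        sigma = math.hypot(self.eps_T.sigma, prod * rel)
        return self.eps_T.value - prod, sigma


def collection_efficiency(
    eoc_activities: Sequence[Measured], loaded_activity: Measured
) -> Measured:
    """ε_T = Σ A_f(t_f) / A_t(t_i) with first-order propagation.

    By the convention the printed results follow, A_t is *not* decay-corrected
    from collection start to t_f; pass a corrected value explicitly for the
    decay-corrected variant.
    """
    a_t, s_t = loaded_activity
    if a_t <= 0:
        raise EfficiencyError(f"loaded activity must be > 0, got {a_t}")
    total = sum(a for a, _ in eoc_activities)
    var_num = sum(s**2 for _, s in eoc_activities)
    eps = total / a_t
    sigma = math.sqrt(var_num / a_t**2 + (total * s_t / a_t**2) ** 2)
    return eps, sigma


def operational_efficiency(
    collected: Sequence[Measured], losses: Sequence[Measured]
) -> Measured:
    """ε_op = ΣA_collected / (ΣA_collected + ΣA_loss) with propagation."""
    if not collected:
        raise EfficiencyError("need at least one collected activity")
    c = sum(a for a, _ in collected)
    l = sum(a for a, _ in losses)
    if c + l <= 0:
        raise EfficiencyError("collected + lost activity must be > 0")
    var_c = sum(s**2 for _, s in collected)
    var_l = sum(s**2 for _, s in losses)
    denom2 = (c + l) ** 2
    eps = c / (c + l)
    sigma = math.sqrt((l / denom2) ** 2 * var_c + (c / denom2) ** 2 * var_l)
    return eps, sigma


def ionization_efficiency(
    eps_T: Measured,
    eps_trans: Measured,
    eps_op: Measured,
    eps_sep: Measured = (1.0, 0.0),
) -> Measured:
    """ε_ion = ε_T / (ε_trans · ε_op · ε_sep) with relative-quadrature σ."""
    for name, (v, _) in (
        ("eps_trans", eps_trans), ("eps_op", eps_op), ("eps_sep", eps_sep),
    ):
        if v <= 0:
            raise EfficiencyError(f"{name} must be > 0, got {v}")
    value = eps_T[0] / (eps_trans[0] * eps_op[0] * eps_sep[0])
    rel = 0.0
    for v, s in (eps_T, eps_trans, eps_op, eps_sep):
        if v != 0:
            rel += (s / v) ** 2
    return value, abs(value) * math.sqrt(rel)


def transport_efficiency(
    current_on_foil: Measured, current_on_fc: Measured
) -> tuple[float, float, bool]:
    """ε_trans = I_foil / I_FC; third element flags an unphysical value > 1
    (indicates residual background in one of the readings)."""
    i_fc, s_fc = current_on_fc
    if i_fc <= 0:
        raise EfficiencyError(f"Faraday-cup current must be > 0, got {i_fc}")
    i_f, s_f = current_on_foil
    eps = i_f / i_fc
    rel = (s_f / i_f) ** 2 if i_f != 0 else 0.0
    rel += (s_fc / i_fc) ** 2
    return eps, abs(eps) * math.sqrt(rel), eps > 1.0


def propagate_mc(
    func: Callable[..., float],
    inputs: Sequence[Measured],
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> Measured:
    """Monte-Carlo audit of first-order propagation.

    Draws each input from an independent Gaussian and returns the sample mean
    and sd of ``func(*draws)``; draws for which ``func`` raises are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.column_stack(
        [rng.normal(v, s, size=n) for v, s in inputs]
    )
    vals = np.empty(n)
    ok = np.ones(n, bool)
    for k in range(n):
        try:
            vals[k] = func(*draws[k])
        except Exception:
            ok[k] = False
    vals = vals[ok]
    if len(vals) == 0:
        raise EfficiencyError("every Monte-Carlo draw failed")
    return float(np.mean(vals)), float(np.std(vals, ddof=1))
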