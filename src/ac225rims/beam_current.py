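"""Implanted-beam-current trace: background, integration, gap losses.

The picoammeter on the collection foil records the implanted ion current
together with instrument state: whether the upstream Faraday cup blocks the
beam (pure-background readings), whether the ionization lasers are on, and
whether the sample is nominally collecting.  Alpha recoil from the implanted
activity ejects charge from the foil, producing a slowly growing *negative*
background that is modelled by a sigmoid fitted to the beam-blocked samples
and subtracted everywhere.

The net current is converted to an equivalent activity at a reference time
(normally end of collection) by decay-weighted trapezoidal integration, and
activity forfeited to separator operations (mass scans, laser optimization)
is estimated by Monte-Carlo resampling of current recorded at the same
heater setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._time import to_seconds
from .nuclear_data import Nuclide

__all__ = [
    "E_CHARGE",
    "CurrentTrace",
    "BackgroundModel",
    "ActivityLoss",
    "BeamCurrentError",
    "fit_background",
    "subtract_background",
    "integrate_to_activity",
    "estimate_gap_loss",
]

E_CHARGE = 1.602176634e-19  # C

_COLUMNS = ["time_s", "current_a", "fc_in", "laser_on", "collecting", "heater_current_a"]


class BeamCurrentError(RuntimeError):
    """Trace malformed, fit failed, or estimation impossible."""


@dataclass
class CurrentTrace:
    """Time-stamped ion-current samples with instrument-state flags.

    Backed by a DataFrame with columns ``time_s`` (s, strictly increasing),
    ``current_a`` (A; may be negative — recoil background), boolean
    ``fc_in``/``laser_on``/``collecting``, and ``heater_current_a`` (A).
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise BeamCurrentError(f"trace missing columns {missing}")
        t = self.data["time_s"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise BeamCurrentError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time_s(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(float)

    @property
    def current_a(self) -> np.ndarray:
        return self.data["current_a"].to_numpy(float)

    def window(self, t0: float, t1: float) -> "CurrentTrace":
        m = (self.data["time_s"] >= t0) & (self.data["time_s"] <= t1)
        return CurrentTrace(self.data.loc[m].reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        """Read the trace dialect {time_iso, current_A, fc_in, laser_on,
        collecting, heater_current_A}."""
        raw = pd.read_csv(path)
        df = pd.DataFrame(
            {
                "time_s": [to_seconds(t) for t in raw["time_iso"]],
                "current_a": raw["current_A"].astype(float),
                "fc_in": raw["fc_in"].astype(int).astype(bool),
                "laser_on": raw["laser_on"].astype(int).astype(bool),
                "collecting": raw["collecting"].astype(int).astype(bool),
                "heater_current_a": raw["heater_current_A"].astype(float),
            }
        )
        return cls(df)

    def to_csv(self, path) -> None:
        from ._time import to_iso

        out = pd.DataFrame(
            {
                "time_iso": [to_iso(t) for t in self.data["time_s"]],
                "current_A": self.data["current_a"],
                "fc_in": self.data["fc_in"].astype(int),
                "laser_on": self.data["laser_on"].astype(int),
                "collecting": self.data["collecting"].astype(int),
                "heater_current_A": self.data["heater_current_a"],
            }
        )
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class BackgroundModel:
    """Sigmoid recoil background b(t) = b₀ + (b₁−b₀)/(1+exp(−(t−t₀)/w))."""

    b0: float
    b1: float
    t0: float
    w: float

    def __post_init__(self):
        if self.w <= 0:
            raise BeamCurrentError("sigmoid width w must be > 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return self.b0 + (self.b1 - self.b0) / (1.0 + np.exp(-(t - self.t0) / self.w))


@dataclass(frozen=True)
class ActivityLoss:
    """Equivalent EOC activity forfeited during a non-collection interval."""

    label: str                    # "mass_scan" | "laser_optimization" | ...
    interval: tuple[float, float]
    activity: float               # Bq
    sigma: float                  # Bq (nan when indeterminate)

    def __post_init__(self):
        if self.activity < 0:
            raise BeamCurrentError("loss activity must be >= 0")


def fit_background(trace: CurrentTrace) -> BackgroundModel:
    """Fit the sigmoid background to beam-blocked (Faraday-cup-in) samples.

    A constant pool of blocked readings degenerates gracefully to a flat
    sigmoid b₀ = b₁.
    """
    blocked = trace.data[trace.data["fc_in"]]
    if len(blocked) < 4:
        raise BeamCurrentError(
            f"need >= 4 beam-blocked samples to fit the background, "
            f"got {len(blocked)}"
        )
    t = blocked["time_s"].to_numpy(float)
    i = blocked["current_a"].to_numpy(float)
    span = t.max() - t.min()

    if np.ptp(i) == 0.0 or span == 0.0:
        return BackgroundModel(float(i[0]), float(i[0]), float(t.mean()), max(span, 1.0))

    def sigmoid(tt, b0, b1, t0, w):
        return b0 + (b1 - b0) / (1.0 + np.exp(-(tt - t0) / w))

    n4 = max(len(i) // 4, 1)
    p0 = [float(i[:n4].mean()), float(i[-n4:].mean()), float(t.mean()), span / 10.0]
    try:
        popt, _ = curve_fit(
            sigmoid, t, i, p0=p0,
            bounds=([-np.inf, -np.inf, t.min() - span, 1e-9],
                    [np.inf, np.inf, t.max() + span, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise BeamCurrentError(f"background fit did not converge: {exc}") from exc
    return BackgroundModel(*map(float, popt))


def subtract_background(trace: CurrentTrace, model: BackgroundModel) -> CurrentTrace:
    """Per-sample current minus b(t); no clipping, flags preserved."""
    df = trace.data.copy()
    df["current_a"] = df["current_a"] - model(df["time_s"].to_numpy(float))
    return CurrentTrace(df)


def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True as (start, stop) index pairs (stop exclusive)."""
    out = []
    start = None
    for k, flag in enumerate(mask):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            out.append((start, k))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def integrate_to_activity(
    trace: CurrentTrace,
    nuclide: Nuclide,
    charge_state: int = 1,
    t_ref: float | None = None,
    only_collecting: bool = False,
    noise_sigma_a: float | None = None,
) -> tuple[float, float]:
    """Equivalent activity at ``t_ref`` of the ions delivered by the trace.

    Atom rate r(t) = I(t)/(q·e); equivalent activity
    A(t_ref) = λ · ∫ r(t)·exp(−λ(t_ref−t)) dt, trapezoidal on the irregular
    timestamps.  Faraday-cup-in samples are excluded (integration restarts at
    each contiguous run); negative net samples contribute as-is — they are
    unbiased noise.  σ comes from the per-sample current noise (estimated
    from first differences unless given) propagated through the trapezoid
    weights.
    """
    if nuclide.stable:
        raise BeamCurrentError("equivalent activity requires an unstable nuclide")
    if charge_state < 1:
        raise BeamCurrentError("charge state must be >= 1")
    if len(trace) == 0:
        return 0.0, 0.0

    mask = (~trace.data["fc_in"]).to_numpy()
    if only_collecting:
        mask &= trace.data["collecting"].to_numpy()
    t = trace.time_s
    i = trace.current_a
    if t_ref is None:
        t_ref = float(t[-1])
    elif t_ref < t[-1]:
        raise BeamCurrentError("t_ref must be at or after the last sample")

    lam = nuclide.lam
    qe = charge_state * E_CHARGE
    total = 0.0
    var = 0.0
    weights = np.zeros(len(t))
    for lo, hi in _segments(mask):
        if hi - lo < 2:
            continue
        ts, is_ = t[lo:hi], i[lo:hi]
        decay = np.exp(-lam * (t_ref - ts))
        f = is_ / qe * decay
        dt = np.diff(ts)
        total += float(np.sum(0.5 * dt * (f[:-1] + f[1:])))
        # trapezoid weight per sample, for noise propagation
        wseg = np.zeros(hi - lo)
        wseg[:-1] += 0.5 * dt
        wseg[1:] += 0.5 * dt
        weights[lo:hi] = wseg * decay / qe

    if noise_sigma_a is None:
        sel = i[mask]
        noise_sigma_a = (
            float(np.median(np.abs(np.diff(sel))) / 0.6745 / math.sqrt(2.0))
            if len(sel) > 3 else 0.0
        )
    var = float(np.sum((weights * noise_sigma_a) ** 2))
    activity = lam * total
    sigma = lam * math.sqrt(var)
    return activity, sigma


def estimate_gap_loss(
    trace: CurrentTrace,
    gap: tuple[float, float],
    nuclide: Nuclide,
    label: str = "gap",
    charge_state: int = 1,
    t_ref: float | None = None,
    heater_tolerance_a: float = 5.0,
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ActivityLoss:
    """Monte-Carlo estimate of activity lost during a non-collection gap.

    The gap is filled by bootstrap-resampling currents from "donor" samples —
    collecting, beam-on readings whose heater current matches the gap's
    within ``heater_tolerance_a`` (heater current proxies temperature, which
    is itself derived and uncertain) — then integrated to equivalent activity
    at ``t_ref``.  Mean and sd over ``n_resamples`` draws are reported; a
    single resample leaves σ indeterminate (NaN).
    """
    t0, t1 = gap
    if not t1 > t0:
        raise BeamCurrentError("gap interval must have positive length")
    df = trace.data
    in_gap = (df["time_s"] >= t0) & (df["time_s"] <= t1)
    if in_gap.any():
        heater = float(df.loc[in_gap, "heater_current_a"].mean())
    else:
        k = int(np.searchsorted(trace.time_s, 0.5 * (t0 + t1)))
        heater = float(df["heater_current_a"].iloc[min(k, len(df) - 1)])

    donors_mask = (
        df["collecting"] & ~df["fc_in"] & ~in_gap
        & (np.abs(df["heater_current_a"] - heater) <= heater_tolerance_a)
    )
    donors = df.loc[donors_mask, "current_a"].to_numpy(float)
    if len(donors) == 0:
        raise BeamCurrentError(
            f"no donor samples within ±{heater_tolerance_a} A of heater "
            f"{heater:.1f} A; widen the tolerance"
        )

    times = trace.time_s
    dts = np.diff(times)
    step = float(np.median(dts)) if len(dts) else 60.0
    grid = np.arange(t0, t1 + 0.5 * step, step)
    if t_ref is None:
        t_ref = float(times[-1])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = nuclide.lam
    qe = charge_state * E_CHARGE
    decay = np.exp(-lam * (t_ref - grid))
    # trapezoid weights on the regular gap grid
    w = np.full(len(grid), step)
    w[0] = w[-1] = 0.5 * step

    draws = np.empty(n_resamples)
    for k in range(n_resamples):
        cur = rng.choice(donors, size=len(grid), replace=True)
        draws[k] = lam * float(np.sum(w * cur / qe * decay))
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1)) if n_resamples > 1 else float("nan")
    return ActivityLoss(label, (t0, t1), max(mean, 0.0), sd)
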