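"""Synthetic campaign generator with known ground truth.

Every input the analysis consumes can be generated here, statistically
faithful to the real campaign's regime: ~10 MBq of ²²⁵Ac loaded, ~10% total
collection efficiency, a ~20 h collection at pA-scale implanted currents,
and decay-spectroscopy measurements days later.  The noise structure is the
minimal one the analysis assumes — Gaussian on the picoammeter, Poisson on
counts, Gaussian on the pyrometer — with the instrument artefacts that the
cleaning stages must handle: Faraday-cup background-only intervals, laser-off
dips, a mass-scan gap, and a recoil background that drifts negative as
implanted activity accumulates.

All generators are pure functions of (truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beam_current import E_CHARGE, BackgroundModel, CurrentTrace
from .nuclear_data import ActivityState, DecayChain, evolve

__all__ = [
    "CampaignTruth",
    "generate_current_trace",
    "generate_count_data",
    "generate_calibration_points",
    "implanted_eoc_activity",
]

PA = 1e-12  # ampere


@dataclass(frozen=True)
class CampaignTruth:
    """Ground truth of one synthetic collection campaign.

    Defaults reproduce the real campaign's regime; times are seconds on the
    campaign axis with collection starting at t = 0.
    """

    # source & efficiency partition
    loaded_activity_bq: float = 10.11e6
    eps_ion: float = 0.151
    eps_trans: float = 0.87
    eps_sep: float = 1.0

    # release model at constant target temperature (current units: A)
    release_phi_a: tuple[float, ...] = (10.0 * PA,)
    release_lambda_per_h: tuple[float, ...] = (0.34,)
    release_constant_a: float = 0.5 * PA

    # recoil background sigmoid (A) and picoammeter noise
    background_b0_a: float = 0.0
    background_b1_a: float = -0.05 * PA
    background_t0_s: float = 36000.0
    background_w_s: float = 7200.0
    current_noise_a: float = 0.5 * PA

    # schedule
    collection_span_s: float = 72000.0       # 20 h
    sample_dt_s: float = 60.0
    fc_intervals: tuple[tuple[float, float], ...] = (
        (7200.0, 7800.0), (21600.0, 22200.0), (43200.0, 43800.0),
        (57600.0, 58200.0), (68400.0, 69000.0),
    )
    laser_off_intervals: tuple[tuple[float, float], ...] = (
        (14400.0, 14700.0), (50400.0, 50700.0),
    )
    mass_scan_interval: tuple[float, float] = (28800.0, 32400.0)
    heater_current_a: float = 602.0

    # spectroscopy campaign (measurement mid-times, s after EOC)
    measurement_times_s: tuple[float, ...] = tuple(
        d * 86400.0 for d in (3.0, 5.0, 7.0, 10.0, 14.0, 20.0)
    )
    live_time_s: float = 21600.0             # ~6 h spectra
    detector_efficiency: float = 0.01        # HPGe at the 440 keV line
    coincidence_efficiencies: tuple[float, float] = (0.012, 0.004)
    deadtime_s: float = 2e-6
    coincidence_window_s: float = 200e-9
    alpha_geometry: float = 0.25
    alpha_retention: float = 0.6             # per alpha decay, recoil escape

    charge_state: int = 1

    def signal_current(self, t_s: np.ndarray) -> np.ndarray:
        """Noise-free implanted signal current (A) at campaign time t."""
        t_h = np.asarray(t_s, float) / 3600.0
        out = np.full_like(t_h, self.release_constant_a)
        for phi, lam in zip(self.release_phi_a, self.release_lambda_per_h):
            out = out + phi * np.exp(-lam * t_h)
        return out

    @property
    def background_model(self) -> BackgroundModel:
        return BackgroundModel(
            self.background_b0_a, self.background_b1_a,
            self.background_t0_s, self.background_w_s,
        )

    @property
    def eoc_time_s(self) -> float:
        return self.collection_span_s


def _in_any(t: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(len(t), bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def generate_current_trace(
    truth: CampaignTruth, seed: int | np.random.Generator = 0
) -> CurrentTrace:
    """Synthesize the picoammeter trace of one collection.

    Signal follows the release model; Faraday-cup-in intervals read
    background only; laser-off dips suppress the (laser-dominated) signal to
    10%; the mass-scan interval is beam-off-foil (collecting = False, and the
    cup blocks the foil).  The sigmoid recoil background and Gaussian noise
    are added everywhere.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, truth.collection_span_s + 0.5 * truth.sample_dt_s,
                  truth.sample_dt_s)
    signal = truth.signal_current(t)

    fc_in = _in_any(t, truth.fc_intervals) | _in_any(t, [truth.mass_scan_interval])
    laser_on = ~_in_any(t, truth.laser_off_intervals)
    collecting = ~fc_in

    current = signal.copy()
    current[~laser_on] *= 0.10          # surface-ionization remnant
    current[fc_in] = 0.0                # beam blocked upstream of the foil
    current = current + truth.background_model(t)
    if truth.current_noise_a > 0:
        current = current + rng.normal(0.0, truth.current_noise_a, len(t))

    df = pd.DataFrame(
        {
            "time_s": t,
            "current_a": current,
            "fc_in": fc_in,
            "laser_on": laser_on,
            "collecting": collecting,
            "heater_current_a": np.full(len(t), truth.heater_current_a),
        }
    )
    return CurrentTrace(df)


def implanted_eoc_activity(truth: CampaignTruth, chain: DecayChain) -> float:
    """Noise-free ²²⁵Ac activity on the foil at end of collection (Bq).

    Decay-weighted integral of the signal atom rate over the collecting
    intervals (trapezoid on the sampling grid), i.e. the generator's
    bookkeeping counterpart of ``integrate_to_activity``.
    """
    lam = chain["Ac-225"].lam
    t = np.arange(0.0, truth.collection_span_s + 0.5 * truth.sample_dt_s,
                  truth.sample_dt_s)
    rate = truth.signal_current(t) / (truth.charge_state * E_CHARGE)
    off = _in_any(t, truth.fc_intervals) | _in_any(t, [truth.mass_scan_interval])
    rate[off] = 0.0
    rate[_in_any(t, truth.laser_off_intervals)] *= 0.10
    weight = np.exp(-lam * (truth.eoc_time_s - t))
    atoms = float(np.trapezoid(rate * weight, t))
    return lam * atoms


def generate_count_data(
    truth: CampaignTruth,
    chain: DecayChain,
    seed: int | np.random.Generator = 0,
    sample_id: str = "synthetic",
    eoc_activity_bq: float | None = None,
) -> pd.DataFrame:
    """Poisson-sampled spectroscopy rows for the post-collection campaign.

    The implanted inventory at EOC (parent plus equilibrated daughters) is
    evolved to each measurement time; expected counts pass through the
    non-paralyzable dead-time distortion before Poisson sampling.  Emits the
    counts-CSV dialect: singles rows for the ²¹³Bi 440 keV and ²²¹Fr 218 keV
    lines, a γ–γ coincidence row for the ²⁰⁹Tl 465/1567 keV cascade, and an
    alpha row for ²²⁵Ac.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_f = implanted_eoc_activity(truth, chain) if eoc_activity_bq is None else eoc_activity_bq
    state_f = ActivityState.equilibrium(chain, "Ac-225", a_f, timestamp=truth.eoc_time_s)

    def line(nuclide: str, kev: float) -> float:
        for g in chain[nuclide].gamma_lines:
            if abs(g.energy_kev - kev) < 1.0:
                return g.intensity
        raise KeyError(f"{nuclide} has no line at {kev} keV")

    i_440 = line("Bi-213", 440.45)
    i_218 = line("Fr-221", 218.12)
    i_465 = line("Tl-209", 465.13)
    i_1567 = line("Tl-209", 1567.09)
    i_cascade = i_465 * i_1567   # both cascade gammas emitted, near-independent

    rows = []
    live = truth.live_time_s
    tau = truth.deadtime_s
    for dt in truth.measurement_times_s:
        mid = truth.eoc_time_s + dt
        state = evolve(state_f, dt, chain)

        for nuclide, intensity in (("Bi-213", i_440), ("Fr-221", i_218)):
            a = state.activity(nuclide)
            true_rate = a * truth.detector_efficiency * intensity
            observed = true_rate / (1.0 + true_rate * tau)   # non-paralyzable
            gross = rng.poisson(observed * live)
            rows.append(
                {
                    "sample_id": sample_id, "method": "singles",
                    "nuclide": nuclide, "mid_time_s": mid,
                    "live_time_s": live, "gross": gross, "background": 0.0,
                    "deadtime_s": tau,
                    "efficiency": truth.detector_efficiency,
                    "intensity": intensity,
                }
            )

        a_tl = state.activity("Tl-209")
        e1, e2 = truth.coincidence_efficiencies
        r1 = a_tl * e1 * i_465
        r2 = a_tl * e2 * i_1567
        rc = a_tl * e1 * e2 * i_cascade + 2.0 * truth.coincidence_window_s * r1 * r2
        rows.append(
            {
                "sample_id": sample_id, "method": "coincidence",
                "nuclide": "Tl-209", "mid_time_s": mid, "live_time_s": live,
                "singles1_rate": rng.poisson(r1 * live) / live,
                "singles2_rate": rng.poisson(r2 * live) / live,
                "coincidence_rate": rng.poisson(rc * live) / live,
                "window_s": truth.coincidence_window_s,
                "i1": i_465, "i2": i_1567, "ic": i_cascade,
            }
        )

        a_ac = state.activity("Ac-225")
        expected = a_ac * truth.alpha_geometry * live
        rows.append(
            {
                "sample_id": sample_id, "method": "alpha",
                "nuclide": "Ac-225", "mid_time_s": mid, "live_time_s": live,
                "gross": rng.poisson(expected), "background": 0.0,
                "deadtime_s": 0.0, "efficiency": truth.alpha_geometry,
                "intensity": 1.0,
            }
        )
    return pd.DataFrame(rows)


def generate_calibration_points(
    a: float,
    b: float,
    current_range_a: tuple[float, float] = (300.0, 625.0),
    n_points: int = 12,
    noise_sd_c: float = 5.0,
    seed: int | np.random.Generator = 0,
    tau_k: float = 300.0,
    voltage_scale: float = 120.0,
) -> pd.DataFrame:
    """Pyrometer calibration points from a resistive+radiative truth.

    Truth: P(T) = a·T + b·T⁴ (T in kelvin) with a voltage law
    V(T) = (T + τ)/k — resistance rising linearly with temperature — so the
    companion current model I = k·(aT + bT⁴)/(T + τ) is exactly consistent.
    Points are laid out uniformly over ``current_range_a`` and the pyrometer
    reading gets additive Gaussian noise.  Columns: current_A, voltage_V,
    temperature_C.
    """
    if a <= 0 or b <= 0:
        raise ValueError("power-model coefficients must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = voltage_scale

    def current_of_T(T):
        return k * (a * T + b * T**4) / (T + tau_k)

    from scipy.optimize import brentq

    currents = np.linspace(*current_range_a, n_points)
    t_hi = 6000.0
    while current_of_T(t_hi) < currents.max() and t_hi < 1e7:
        t_hi *= 2.0
    temps_k = np.array(
        [brentq(lambda T: current_of_T(T) - i, 1.0, t_hi) for i in currents]
    )
    volts = (temps_k + tau_k) / k
    temps_c = temps_k - 273.15
    if noise_sd_c > 0:
        temps_c = temps_c + rng.normal(0.0, noise_sd_c, n_points)
    return pd.DataFrame(
        {"current_A": currents, "voltage_V": volts, "temperature_C": temps_c}
    )
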