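"""Campaign orchestration: config → stage outputs → one JSON report.

A campaign couples every stage of the analysis: spectroscopy turns count
rates into activities; the end-of-collection extrapolation turns those into
A_f(t_f) per sample; the beam-current stage cleans the trace and prices the
mass-scan / laser-optimization gaps in equivalent EOC activity; the
efficiency calculus combines everything into ε_T, ε_op, ε_trans and ε_ion;
and the release fit extracts λ₁ on a constant-temperature window.  The
result is a single report holding every intermediate quantity, its σ and its
provenance, plus a log of every analysis default, so the headline numbers
can be re-derived from the report alone.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field

import pandas as pd

from ._time import to_seconds
from .beam_current import (
    CurrentTrace,
    estimate_gap_loss,
    fit_background,
    integrate_to_activity,
    subtract_background,
)
from .efficiency import (
    EfficiencyBreakdown,
    EfficiencyTerm,
    collection_efficiency,
    ionization_efficiency,
    operational_efficiency,
    transport_efficiency,
)
from .eoc_extrapolation import decay_to, estimate_eoc
from .nuclear_data import DecayChain, build_ac225_chain
from .release_kinetics import fit_release
from .spectroscopy import (
    CoincidenceMeasurement,
    CountMeasurement,
    TimedActivity,
    coincidence_activity,
    singles_activity,
)

__all__ = [
    "CampaignConfig",
    "SampleSpec",
    "SourceSpec",
    "LossSpec",
    "ConfigError",
    "load_counts_csv",
    "run_campaign",
]

log = logging.getLogger("ac225rims")


class ConfigError(ValueError):
    """Invalid or incomplete campaign configuration."""


@dataclass(frozen=True)
class SourceSpec:
    """A loaded ²²⁵Ac source: reference assay and collection start."""

    source_id: str
    activity_bq: float
    sigma_bq: float
    reference_time_s: float
    t_i_s: float            # collection start


@dataclass(frozen=True)
class SampleSpec:
    """One collected foil: which source fed it and when collection ended."""

    sample_id: str
    source_id: str
    t_f_s: float


@dataclass(frozen=True)
class LossSpec:
    label: str
    start_s: float
    end_s: float


@dataclass
class CampaignConfig:
    sources: list[SourceSpec]
    samples: list[SampleSpec]
    counts_csv: str | None = None
    trace_csv: str | None = None
    calibration_csv: str | None = None
    losses: list[LossSpec] = field(default_factory=list)
    release_window_s: tuple[float, float] | None = None
    transport_foil: tuple[float, float] | None = None   # (A, σ)
    transport_fc: tuple[float, float] | None = None
    # analysis options (each a default the published analysis left unstated)
    charge_state: int = 1
    initial_composition: str = "equilibrium"
    subtract_accidentals: bool = True
    decay_correct_loaded: bool = False
    heater_tolerance_a: float = 5.0
    n_resamples: int = 1000
    seed: int = 0

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate sample_id")
        known = {s.source_id for s in self.sources}
        for s in self.samples:
            if s.source_id not in known:
                raise ConfigError(
                    f"sample {s.sample_id} references unknown source {s.source_id}"
                )
        by_source = {s.source_id: s for s in self.sources}
        for s in self.samples:
            if not by_source[s.source_id].t_i_s < s.t_f_s:
                raise ConfigError(f"sample {s.sample_id}: t_i must precede t_f")
        for path in (self.counts_csv, self.trace_csv, self.calibration_csv):
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"input file not found: {path}")

    @classmethod
    def from_json(cls, path) -> "CampaignConfig":
        with open(path) as fh:
            raw = json.load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            if p is None:
                return None
            return p if os.path.isabs(p) else os.path.join(base, p)

        def t(x):
            return to_seconds(x)

        sources = [
            SourceSpec(
                s["source_id"], float(s["activity_bq"]), float(s["sigma_bq"]),
                t(s["reference_time"]), t(s["t_i"]),
            )
            for s in raw.get("sources", [])
        ]
        samples = [
            SampleSpec(s["sample_id"], s["source_id"], t(s["t_f"]))
            for s in raw.get("samples", [])
        ]
        losses = [
            LossSpec(l["label"], t(l["start"]), t(l["end"]))
            for l in raw.get("losses", [])
        ]
        opts = raw.get("options", {})
        window = raw.get("release_window")
        transport = raw.get("transport", {})
        return cls(
            sources=sources,
            samples=samples,
            counts_csv=resolve(raw.get("counts_csv")),
            trace_csv=resolve(raw.get("trace_csv")),
            calibration_csv=resolve(raw.get("calibration_csv")),
            losses=losses,
            release_window_s=tuple(t(x) for x in window) if window else None,
            transport_foil=tuple(transport["foil"]) if "foil" in transport else None,
            transport_fc=tuple(transport["faraday_cup"]) if "faraday_cup" in transport else None,
            **{
                k: opts[k]
                for k in (
                    "charge_state", "initial_composition", "subtract_accidentals",
                    "decay_correct_loaded", "heater_tolerance_a", "n_resamples",
                    "seed",
                )
                if k in opts
            },
        )


def load_counts_csv(
    source, subtract_accidentals: bool = True
) -> dict[str, list[TimedActivity]]:
    """Counts CSV (or DataFrame) → TimedActivity lists keyed by sample_id.

    Singles and alpha rows need {mid_time_s|mid_time_iso, live_time_s, gross,
    background, deadtime_s, efficiency, intensity}; coincidence rows the gate
    columns {singles1_rate, singles2_rate, coincidence_rate, window_s, i1,
    i2, ic}.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    out: dict[str, list[TimedActivity]] = {}
    for _, row in df.iterrows():
        mid = (
            float(row["mid_time_s"])
            if "mid_time_s" in row and pd.notna(row.get("mid_time_s"))
            else to_seconds(row["mid_time_iso"])
        )
        method = row["method"]
        if method in ("singles", "alpha"):
            meas = CountMeasurement(
                mid_time=mid,
                live_time=float(row["live_time_s"]),
                gross_counts=float(row["gross"]),
                background_counts=float(row["background"]),
                deadtime_constant=float(row["deadtime_s"]),
                detector_efficiency=float(row["efficiency"]),
                nuclide=row["nuclide"],
                energy_kev=float(row.get("energy_keV", 0.0) or 0.0),
                intensity=float(row["intensity"]),
            )
            act = singles_activity(meas)
            if method == "alpha":
                act = TimedActivity(
                    act.nuclide, act.timestamp, act.activity, act.sigma,
                    "alpha", act.flag,
                )
        elif method == "coincidence":
            meas = CoincidenceMeasurement(
                mid_time=mid,
                live_time=float(row["live_time_s"]),
                singles_rate_1=float(row["singles1_rate"]),
                singles_rate_2=float(row["singles2_rate"]),
                coincidence_rate=float(row["coincidence_rate"]),
                window=float(row["window_s"]),
                gate_intensities=(float(row["i1"]), float(row["i2"])),
                cascade_intensity=float(row["ic"]),
                nuclide=row["nuclide"],
            )
            act = coincidence_activity(meas, subtract_accidentals=subtract_accidentals)
        else:
            raise ConfigError(f"unknown counts method {method!r}")
        out.setdefault(str(row["sample_id"]), []).append(act)
    return out


def _stage(name):
    log.info("stage: %s", name)


def run_campaign(config: CampaignConfig, chain: DecayChain | None = None) -> dict:
    """Execute the full analysis chain and return the campaign report.

    Stage order: spectroscopy → EOC extrapolation → beam current
    (background, integration, gap losses) → efficiencies → release fit.
    Deterministic for fixed inputs and seed.  Any stage failure raises with
    the stage name attached.
    """
    chain = chain or build_ac225_chain()
    report: dict = {
        "options": {
            "charge_state": config.charge_state,
            "deadtime_model": "non-paralyzable",
            "initial_composition": config.initial_composition,
            "subtract_accidentals": config.subtract_accidentals,
            "decay_correct_loaded": config.decay_correct_loaded,
            "heater_tolerance_a": config.heater_tolerance_a,
            "n_resamples": config.n_resamples,
            "seed": config.seed,
        },
        "samples": {},
        "sources": {},
        "losses": [],
        "efficiencies": {},
    }
    for key, val in report["options"].items():
        log.info("analysis default %s = %r", key, val)

    sources = {s.source_id: s for s in config.sources}
    t_f_by_sample = {s.sample_id: s.t_f_s for s in config.samples}

    # --- spectroscopy + EOC -------------------------------------------------
    eoc_by_sample: dict[str, tuple[float, float]] = {}
    if config.counts_csv is not None:
        _stage("spectroscopy")
        try:
            activities = load_counts_csv(
                config.counts_csv, config.subtract_accidentals
            )
        except Exception as exc:
            raise RuntimeError(f"[spectroscopy] {exc}") from exc
        _stage("eoc_extrapolation")
        for sample in config.samples:
            acts = activities.get(sample.sample_id)
            if not acts:
                continue
            try:
                est = estimate_eoc(
                    acts, chain, sample.t_f_s,
                    initial_composition=config.initial_composition,
                    sample_id=sample.sample_id,
                )
            except Exception as exc:
                raise RuntimeError(f"[eoc_extrapolation] {sample.sample_id}: {exc}") from exc
            eoc_by_sample[sample.sample_id] = (est.activity, est.sigma)
            report["samples"][sample.sample_id] = {
                "eoc": est.as_dict(),
                "n_activities": len(acts),
            }

    # --- beam current -------------------------------------------------------
    trace_net = None
    if config.trace_csv is not None:
        _stage("beam_current")
        try:
            trace = CurrentTrace.from_csv(config.trace_csv)
            background = fit_background(trace)
            trace_net = subtract_background(trace, background)
            t_ref = float(trace_net.time_s[-1])
            act, sig = integrate_to_activity(
                trace_net, chain["Ac-225"], config.charge_state, t_ref
            )
            report["beam_current"] = {
                "background": asdict(background),
                "integrated_eoc_activity_Bq": act,
                "integrated_eoc_sigma_Bq": sig,
                "t_ref_s": t_ref,
            }
            for k, loss_spec in enumerate(config.losses):
                loss = estimate_gap_loss(
                    trace_net, (loss_spec.start_s, loss_spec.end_s),
                    chain["Ac-225"], label=loss_spec.label,
                    charge_state=config.charge_state, t_ref=t_ref,
                    heater_tolerance_a=config.heater_tolerance_a,
                    n_resamples=config.n_resamples,
                    seed=config.seed + k,
                )
                report["losses"].append(
                    {
                        "label": loss.label,
                        "interval_s": list(loss.interval),
                        "activity_Bq": loss.activity,
                        "sigma_Bq": loss.sigma,
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"[beam_current] {exc}") from exc

    # --- efficiencies -------------------------------------------------------
    _stage("efficiency")
    try:
        for source in config.sources:
            coll = [
                eoc_by_sample[s.sample_id]
                for s in config.samples
                if s.source_id == source.source_id and s.sample_id in eoc_by_sample
            ]
            if not coll:
                continue
            loaded = (source.activity_bq, source.sigma_bq)
            if config.decay_correct_loaded:
                a_i = decay_to(
                    source.activity_bq, chain.root,
                    source.reference_time_s, source.t_i_s,
                )
                loaded = (a_i, source.sigma_bq * a_i / source.activity_bq)
            eps, sig = collection_efficiency(coll, loaded)
            report["sources"][source.source_id] = {
                "loaded_activity_Bq": loaded[0],
                "loaded_sigma_Bq": loaded[1],
                "eps_T": eps,
                "eps_T_sigma": sig,
            }

        collected = [v for v in eoc_by_sample.values()]
        losses = [(l["activity_Bq"], l["sigma_Bq"]) for l in report["losses"]]
        if collected and losses:
            eps_op, s_op = operational_efficiency(collected, losses)
            report["efficiencies"]["eps_op"] = {"value": eps_op, "sigma": s_op}

        if config.transport_foil and config.transport_fc:
            eps_tr, s_tr, flagged = transport_efficiency(
                tuple(config.transport_foil), tuple(config.transport_fc)
            )
            report["efficiencies"]["eps_trans"] = {
                "value": eps_tr, "sigma": s_tr, "flagged_gt1": flagged,
            }

        eff = report["efficiencies"]
        srcs = report["sources"]
        if srcs and "eps_op" in eff and "eps_trans" in eff:
            sid = next(iter(srcs))
            eps_ion, s_ion = ionization_efficiency(
                (srcs[sid]["eps_T"], srcs[sid]["eps_T_sigma"]),
                (eff["eps_trans"]["value"], eff["eps_trans"]["sigma"]),
                (eff["eps_op"]["value"], eff["eps_op"]["sigma"]),
            )
            eff["eps_ion"] = {
                "value": eps_ion, "sigma": s_ion, "eps_sep": "assumed-unity",
                "from_source": sid,
            }
            report["efficiency_breakdown"] = EfficiencyBreakdown(
                eps_ion=EfficiencyTerm(eps_ion, s_ion, "derived"),
                eps_trans=EfficiencyTerm(
                    eff["eps_trans"]["value"], eff["eps_trans"]["sigma"], "measured"
                ),
                eps_op=EfficiencyTerm(
                    eff["eps_op"]["value"], eff["eps_op"]["sigma"], "measured"
                ),
                eps_T=EfficiencyTerm(
                    srcs[sid]["eps_T"], srcs[sid]["eps_T_sigma"], "measured"
                ),
            ).as_dict()
    except Exception as exc:
        raise RuntimeError(f"[efficiency] {exc}") from exc

    # --- release kinetics ---------------------------------------------------
    if trace_net is not None and config.release_window_s is not None:
        _stage("release_kinetics")
        try:
            t0, t1 = config.release_window_s
            seg = trace_net.window(t0, t1)
            keep = (~seg.data["fc_in"]) & seg.data["laser_on"]
            seg = CurrentTrace(seg.data[keep].reset_index(drop=True))
            fit = fit_release(seg)
            report["release"] = fit.as_dict()
        except Exception as exc:
            raise RuntimeError(f"[release_kinetics] {exc}") from exc

    return report
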