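"""Per-session orchestration into a CouplingReport, and cohort contrasts.

``run_coupling_analysis`` composes the evoked, rhythm and sync stages;
any stage whose preconditions the session cannot meet yields a null field
with the reason recorded, rather than an error.  ``condition_contrast``
extracts one scalar per report and applies the normality-gated two-sample
comparison; pairing is an explicit input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import evoked as ev
from . import rhythm as rh
from . import sync as sy
from .stats import TestResult, compare_groups
from .types import CouplingReport, Session, ValidationError

__all__ = ["AnalysisConfig", "run_coupling_analysis", "condition_contrast", "report_scalar"]


@dataclass
class AnalysisConfig:
    psth_bin_width: float = 0.001   # s
    psth_window: float = None       # s; default: the protocol's isi
    merge_gap: int = 2
    n_phase_bins: int = 150
    bands: tuple = ("slow", "intermediate")
    max_lag: float = 0.2            # s, cross-correlogram search range
    precession_band: str = "intermediate"


def _main_train(session: Session, region: str):
    kind = "MUA" if region == "LC" else "SU"
    trains = session.trains(region, kind) or session.trains(region)
    return trains[0] if trains else None


def run_coupling_analysis(session: Session, config: AnalysisConfig = None) -> CouplingReport:
    """Full per-session analysis; deterministic given session + config."""
    cfg = config or AnalysisConfig()
    report = CouplingReport(condition=session.condition)
    reasons = report.reasons

    trains = {r: _main_train(session, r) for r in ("LC", "TCC")}

    # --- evoked components per region -------------------------------------
    stim = [e for e in session.events if e.label in ("cutaneous", "meningeal")]
    if not stim:
        reasons["evoked"] = "no electrical stimulation train"
    else:
        train_ev = stim[0]
        window = cfg.psth_window or train_ev.isi
        evoked_table = {}
        for region, tr in trains.items():
            if tr is None or len(tr) == 0:
                evoked_table[region] = None
                reasons[f"evoked.{region}"] = "no spikes"
                continue
            psth = ev.build_psth(tr, train_ev, window, cfg.psth_bin_width)
            comps = ev.extract_components(psth, region, cfg.merge_gap)
            evoked_table[region] = [asdict_component(c) for c in comps]
        report.evoked = evoked_table
        # LC/TCC evoked ratio
        lc_comps = [c for c in (evoked_table.get("LC") or []) if c["kind"] == "early"]
        tcc_tr = trains["TCC"]
        if lc_comps and tcc_tr is not None:
            counts = ev.tcc_train_counts(tcc_tr, train_ev)
            early = ev.EvokedComponent(**lc_comps[0])
            report.lc_tcc_ratio = ev.lc_tcc_evoked_ratio(early, counts["A_total"])
            if report.lc_tcc_ratio is None:
                reasons["lc_tcc_ratio"] = "zero TCC A-response or undefined LC magnitude"
        else:
            reasons["lc_tcc_ratio"] = "no LC early component"

    # --- oscillation periods and phase -----------------------------------
    rates = {}
    periods = {}
    for region, tr in trains.items():
        if tr is None or len(tr) < 10:
            reasons[f"periods.{region}"] = "too few spikes"
            continue
        periods[region] = {}
        for band in cfg.bands:
            width, fs_out = rh.MEAN_FREQ_DEFAULTS[band]
            try:
                rate = rates.setdefault(
                    (region, band),
                    rh.mean_frequency(tr, width, fs_out, duration=session.duration),
                )
                periods[region][band] = rh.estimate_period(rate, band)
            except (ValidationError, rh.PeriodEstimationError) as exc:
                periods[region][band] = None
                reasons[f"periods.{region}.{band}"] = str(exc)
    report.periods = periods or None

    # preferred phases against the LC reference rhythm
    band = cfg.precession_band
    try:
        lc_tr, tcc_tr = trains["LC"], trains["TCC"]
        if lc_tr is None or tcc_tr is None:
            raise ValidationError("missing spike train in one region")
        width, fs_out = rh.MEAN_FREQ_DEFAULTS[band]
        lc_rate = rates.get((("LC"), band)) or rh.mean_frequency(
            lc_tr, width, fs_out, duration=session.duration
        )
        phase = rh.instantaneous_phase(lc_rate, band)
        hists = {
            "LC": rh.phase_histogram(lc_tr, phase, cfg.n_phase_bins),
            "TCC": rh.phase_histogram(tcc_tr, phase, cfg.n_phase_bins),
        }
        report.preferred_phase = {r: {band: h.preferred} for r, h in hists.items()}
        report.precession = rh.precession(hists["TCC"], hists["LC"])
    except ValidationError as exc:
        reasons["precession"] = str(exc)

    # --- MUA delta synchronization ----------------------------------------
    report.delta_ratio = {}
    for region, tr in trains.items():
        if tr is None or len(tr) < 10:
            report.delta_ratio[region] = None
            reasons[f"delta_ratio.{region}"] = "too few spikes"
            continue
        width, fs_out = rh.MEAN_FREQ_DEFAULTS["delta"]
        rate50 = rh.mean_frequency(tr, width, fs_out, duration=session.duration)
        try:
            report.delta_ratio[region] = sy.delta_power_ratio(rate50)
        except ValidationError as exc:
            report.delta_ratio[region] = None
            reasons[f"delta_ratio.{region}"] = str(exc)

    # --- LFP measures ------------------------------------------------------
    if "LC" not in session.lfp or "TCC" not in session.lfp:
        reasons["lfp_lag"] = reasons["r2max"] = "no LFP"
    else:
        try:
            report.lfp_lag = sy.crosscorrelogram_lag(
                session.lfp["LC"], session.lfp["TCC"], cfg.max_lag
            )
        except ValidationError as exc:
            reasons["lfp_lag"] = str(exc)
        try:
            lfp50 = sy.decimate_lfp(session.lfp["LC"])
            spec = sy.spectrogram(lfp50)
            band_power = sy.delta_band_timecourse(spec)
            lc_tr = trains["LC"]
            if lc_tr is None:
                raise ValidationError("no LC train for the slow rate")
            width, fs_out = rh.MEAN_FREQ_DEFAULTS["slow"]
            slow_rate = rh.mean_frequency(lc_tr, width, fs_out, duration=session.duration)
            r2 = sy.sliding_r2(band_power, slow_rate)
            report.r2max = min(r2["r2max"], 1.0)
        except ValidationError as exc:
            reasons["r2max"] = str(exc)
    return report


def asdict_component(c: ev.EvokedComponent) -> dict:
    return {
        "kind": c.kind,
        "bin_run": tuple(c.bin_run),
        "time_to_peak": c.time_to_peak,
        "magnitude": c.magnitude,
        "total_spikes": c.total_spikes,
    }


def report_scalar(report: CouplingReport, name: str):
    """Extract a named scalar from a report.

    Dotted paths address nested fields, e.g. ``periods.LC.slow``,
    ``delta_ratio.LC``, ``evoked.LC.late.magnitude``."""
    parts = name.split(".")
    if parts[0] == "evoked" and len(parts) == 4:
        comps = (report.evoked or {}).get(parts[1]) or []
        match = [c for c in comps if c["kind"] == parts[2]]
        return match[0][parts[3]] if match else None
    obj = report
    for p in parts:
        if obj is None:
            return None
        if isinstance(obj, dict):
            obj = obj.get(p)
        else:
            obj = getattr(obj, p, None)
    return obj


def condition_contrast(reports: list, field_name: str, conditions: tuple,
                       paired: bool = False) -> TestResult:
    """Compare one scalar report field between two conditions.

    Reports missing the field are excluded (their count is raised as a
    warning through the returned result only implicitly: they simply do
    not contribute)."""
    groups = []
    for cond in conditions:
        vals = [
            report_scalar(r, field_name)
            for r in reports
            if r.condition == cond
        ]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if len(vals) < 3:
            raise ValidationError(
                f"condition {cond!r}: only {len(vals)} usable values for {field_name!r}"
            )
        groups.append(np.asarray(vals, dtype=float))
    return compare_groups(groups[0], groups[1], paired=paired)
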