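"""End-to-end orchestration: simulate → track → analyze → fit → classify.

One :func:`run_pipeline` call reproduces the whole assay workflow for a drug
panel under a single seed: synthetic recordings per cell, optional spectral
tracking (so the analysis consumes tracked rather than direct traces),
transient analysis per concentration period, per-cell vehicle-normalised
effects, Hill/margin fitting, AC/CE incidence, pro-arrhythmia calls and
panel scoring. The full configuration is echoed into the report, and a given
config + seed regenerates a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fixtures import (
    baseline_population_model,
    load_baseline_population,
    load_effect_profiles,
    load_panel,
)
from .pharm import fit_hill, margin, percent_change
from .risk import classify_drug, decompose_variability, incidence, score_panel
from .synthgen import (
    PacingProtocol,
    sample_population,
    simulate_cell,
    synthesize_intensity_stack,
)
from .tracking import track_stack
from .traces import write_trace
from .transients import AnalysisConfig, analyze_recording

__all__ = ["RunConfig", "Report", "run_pipeline", "simulate_drug_cells", "analyze_cells"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to regenerate a run (fully echoed into the report)."""

    seed: int = 0
    drugs: tuple[str, ...] | None = None  # None = whole packaged panel
    n_cells: int | None = None  # None = per-drug panel replicate counts
    vehicle_duration: float = 30.0
    period_duration: float = 30.0
    frequency: float = 1.0
    sample_rate: float = 240.0
    noise_sd: float = 0.005
    use_tracking: bool = False
    threshold_fold: float = 10.0
    classification_rule: str = "le"
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str | None = None
    write_intermediates: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drugs"] = list(self.drugs) if self.drugs is not None else None
        return d


@dataclass
class Report:
    """Run output: per-drug results, panel confusion summary, variability."""

    config: dict
    version: str
    drugs: dict[str, dict]
    confusion: dict | None
    variability: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def simulate_drug_cells(entry, profile, config: RunConfig, rng: np.random.Generator):
    """Simulate one drug's replicate cells (kinetics drawn per heart/cell)."""
    n_cells = config.n_cells if config.n_cells is not None else entry.n_cells
    n_hearts = min(entry.n_hearts, n_cells)
    per_heart = int(np.ceil(n_cells / n_hearts))
    population = baseline_population_model(
        n_hearts=n_hearts, cells_per_heart=per_heart, noise_sd=config.noise_sd
    )
    means = {
        k: v["mean"] for k, v in load_baseline_population()["parameters"].items()
    }
    protocol = PacingProtocol(
        frequency=config.frequency,
        sample_rate=config.sample_rate,
        vehicle_duration=config.vehicle_duration,
        period_duration=config.period_duration,
    )
    draws = sample_population(means, population, rng=rng)[:n_cells]
    cells = []
    for cell_id, (heart_id, kin) in enumerate(draws):
        cells.append(
            simulate_cell(
                kin,
                profile,
                protocol,
                population,
                concentrations=list(entry.concentrations),
                rng=rng,
                heart_id=heart_id,
                cell_id=cell_id,
            )
        )
    return cells


def analyze_cells(cells, config: RunConfig, rng: np.random.Generator):
    """Run (optional) tracking plus transient analysis on simulated cells."""
    analysis = dataclasses.replace(config.analysis, noise_sd=config.noise_sd)
    out = []
    for cell in cells:
        trace = cell.trace
        if config.use_tracking:
            stack = synthesize_intensity_stack(trace, rng=rng)
            tracked = track_stack(stack)
            trace = dataclasses.replace(
                tracked, stimulus_times=cell.trace.stimulus_times
            )
        periods = [(p.name, p.concentration, p.start_s, p.end_s) for p in cell.truth]
        out.append(analyze_recording(trace, periods, analysis))
    return out


def _drug_result(entry, results, config: RunConfig) -> dict:
    """Collapse per-cell period analyses into the per-drug report record."""
    # vehicle-normalised per-cell effects
    pct_short, pct_tr90 = {}, {}
    for cell_res in results:
        vehicle = cell_res[0]
        for per in cell_res[1:]:
            if per.params.censored.get("tr90", False) or vehicle.params.censored.get("tr90", False):
                tr90_change = None
            else:
                tr90_change = percent_change(per.params, vehicle.params, "tr90")
            short_change = (
                percent_change(per.params, vehicle.params, "frac_shortening")
                if vehicle.params.frac_shortening > 0
                else None
            )
            pct_short.setdefault(per.concentration, []).append(short_change)
            pct_tr90.setdefault(per.concentration, []).append(tr90_change)

    concs = sorted(pct_short)
    mean_remaining = []
    for c in concs:
        vals = [100.0 + v for v in pct_short[c] if v is not None]
        mean_remaining.append(float(np.mean(vals)) if vals else float("nan"))
    fit = fit_hill(concs, mean_remaining) if len(concs) >= 3 else None
    saf = margin(fit, entry.fetpc) if fit is not None else None

    fold_by_conc = dict(zip(entry.concentrations, entry.fold_labels))
    incidence_ac, incidence_ce, mean_tr90 = {}, {}, {}
    for c in concs:
        fold = fold_by_conc.get(c, c / entry.fetpc)
        period_events = [
            per.events
            for cell_res in results
            for per in cell_res
            if per.concentration == c
        ]
        incidence_ac[fold] = incidence(period_events, "AC")
        incidence_ce[fold] = incidence(period_events, "CE")
        tr90_vals = [v for v in pct_tr90[c] if v is not None]
        mean_tr90[fold] = float(np.mean(tr90_vals)) if tr90_vals else None

    call = classify_drug(
        entry, incidence_ac, threshold_fold=config.threshold_fold, rule=config.classification_rule
    )
    return {
        "clinical_tdp": entry.clinical_tdp,
        "fetpc_um": entry.fetpc,
        "concentrations_um": list(entry.concentrations),
        "fold_labels": [float(f) for f in entry.fold_labels],
        "mean_pct_change_tr90_by_fold": {f"{k:g}": v for k, v in mean_tr90.items()},
        "ac_incidence_by_fold": {f"{k:g}": v for k, v in incidence_ac.items()},
        "ce_incidence_by_fold": {f"{k:g}": v for k, v in incidence_ce.items()},
        "hill": None
        if fit is None
        else {
            "ic50_um": fit.ic50,
            "hill_slope": fit.hill_slope,
            "censored": fit.censored,
            "fit_rms": fit.fit_rms,
        },
        "margin": None
        if saf is None
        else {
            "ratio": saf.ratio,
            "ratio_rounded": saf.ratio_rounded,
            "is_lower_bound": saf.is_lower_bound,
            "inotropy_call": saf.inotropy_call,
        },
        "risk_call": call.predicted,
    }


def run_pipeline(config: RunConfig) -> Report:
    """Execute the full workflow for the configured drugs; returns the report.

    Any stage error propagates wrapped with the drug/stage context.
    """
    panel = {e.name: e for e in load_panel()}
    profiles = load_effect_profiles()
    names = list(config.drugs) if config.drugs is not None else list(panel)
    unknown = [n for n in names if n not in panel]
    if unknown:
        raise ValueError(f"drugs not in the panel: {unknown}")

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(names))
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    drug_reports: dict[str, dict] = {}
    calls = []
    baseline_by_drug_heart: dict[str, dict[int, list]] = {}
    cell_rows: list[dict] = []
    for name, child in zip(names, children):
        rng = np.random.default_rng(child)
        entry, profile = panel[name], profiles[name]
        try:
            cells = simulate_drug_cells(entry, profile, config, rng)
            if out_dir is not None and config.write_intermediates:
                tdir = out_dir / "traces"
                tdir.mkdir(exist_ok=True)
                for cell in cells:
                    write_trace(
                        cell.trace,
                        tdir / f"{name.replace('/', '_').replace(',', '')}_cell{cell.cell_id}.csv",
                        extra={"periods": [p.to_dict() for p in cell.truth],
                               "heart_id": cell.heart_id},
                    )
            results = analyze_cells(cells, config, rng)
        except Exception as exc:  # noqa: BLE001 - annotate with stage context
            raise RuntimeError(f"pipeline failed for {name!r}: {exc}") from exc
        drug_reports[name] = _drug_result(entry, results, config)
        for cell, cell_res in zip(cells, results):
            for per in cell_res:
                row = {
                    "drug": name,
                    "heart": cell.heart_id,
                    "cell": cell.cell_id,
                    "period": per.name,
                    "concentration_um": per.concentration,
                    "n_averaged": per.n_averaged,
                    "n_ac_beats": len(per.events.ac_beats),
                    "n_ce_beats": len(per.events.ce_beats),
                }
                row.update(per.params.as_dict())
                cell_rows.append(row)
        by_heart: dict[int, list] = {}
        for cell, cell_res in zip(cells, results):
            by_heart.setdefault(cell.heart_id, []).append(
                cell_res[0].params.frac_shortening
            )
        baseline_by_drug_heart[name] = by_heart
        calls.append(
            classify_drug(
                entry,
                {float(k): v for k, v in drug_reports[name]["ac_incidence_by_fold"].items()},
                threshold_fold=config.threshold_fold,
                rule=config.classification_rule,
            )
        )

    confusion = None
    if calls:
        cs = score_panel(calls, list(panel.values()))
        confusion = dataclasses.asdict(cs)

    # baseline variability of fractional shortening across all simulated hearts
    pooled_by_heart: dict[str, list] = {}
    for name, by_heart in baseline_by_drug_heart.items():
        for heart, vals in by_heart.items():
            pooled_by_heart[f"{name}:{heart}"] = vals
    multi = {k: v for k, v in pooled_by_heart.items() if len(v) >= 2}
    variability = {}
    if multi:
        dec = decompose_variability(multi)
        variability = dataclasses.asdict(dec)

    if out_dir is not None and config.write_intermediates and cell_rows:
        pd.DataFrame(cell_rows).to_csv(
            out_dir / "cells.tsv", sep="\t", index=False, float_format="%.6g"
        )

    report = Report(
        config=config.to_dict(),
        version=__version__,
        drugs=drug_reports,
        confusion=confusion,
        variability=variability,
    )
    if out_dir is not None:
        (out_dir / "report.json").write_text(report.to_json())
    return report
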