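"""Packaged reference tables: drug panel, baseline population, effect profiles.

These transcribe the published validation study's design tables — the
33-drug panel with clinical torsades-de-pointes (TdP) labels, fETPCs and the
four test concentrations per drug; the baseline contractility-parameter
distribution of 189 cells from 11 donor hearts; the reported per-drug IC50s
and safety margins; and the per-drug assay outcome at the 10× fETPC decision
point. The drug *effect profiles* additionally parameterise the synthetic
generator; where the source only reports incidences, the per-beat/per-stimulus
probabilities behind them are plausibility values, not published numbers.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .risk import DrugPanelEntry
from .synthgen import DrugEffectProfile, PopulationModel, TwitchKinetics

__all__ = [
    "load_panel",
    "load_panel_frame",
    "load_baseline_population",
    "baseline_kinetics",
    "baseline_population_model",
    "load_effect_profiles",
    "load_reported_potency",
    "load_assay_outcomes",
]


def _fixture_path(name: str):
    return resources.files("cardiotwitch.data").joinpath(name)


@lru_cache(maxsize=None)
def load_panel_frame() -> pd.DataFrame:
    """The drug panel as a DataFrame (one row per drug)."""
    with resources.as_file(_fixture_path("panel.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_panel() -> list[DrugPanelEntry]:
    """The 33-drug panel: 23 clinical TdP positives, 10 negatives."""
    df = load_panel_frame()
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            DrugPanelEntry(
                name=row.drug,
                clinical_tdp=row.clinical_tdp,
                fetpc=float(row.fetpc_um),
                concentrations=(row.conc1_um, row.conc2_um, row.conc3_um, row.conc4_um),
                fold_labels=(row.fold1, row.fold2, row.fold3, row.fold4),
                n_cells=int(row.n_cells),
                n_hearts=int(row.n_hearts),
                cipa_flag=bool(row.cipa),
            )
        )
    return entries


@lru_cache(maxsize=None)
def load_baseline_population() -> dict:
    """Baseline population statistics (means, spreads, bounds, skew family)."""
    return json.loads(_fixture_path("baseline_population.json").read_text())


def baseline_kinetics() -> TwitchKinetics:
    """The population-mean twitch (resting 1.78 µm, 4.31% shortening,
    TPeak 168 ms, TR90 337 ms)."""
    p = load_baseline_population()["parameters"]
    return TwitchKinetics(
        baseline_sl=p["baseline_sl"]["mean"],
        frac_shortening=p["frac_shortening"]["mean"],
        t_peak=p["t_peak"]["mean"],
        tr90=p["tr90"]["mean"],
    )


def baseline_population_model(
    n_hearts: int | None = None,
    cells_per_heart: int | None = None,
    seed: int = 0,
    noise_sd: float = 0.005,
    intra_fraction: float | None = None,
) -> PopulationModel:
    """Population model reproducing the baseline study's variance structure.

    The intra-heart (cell-level) share of the total SD defaults to the
    fixture's 0.9; heart-level SD takes up the remainder in quadrature.
    """
    fix = load_baseline_population()
    frac = fix["intra_heart_fraction"] if intra_fraction is None else intra_fraction
    cell_sd, heart_sd = {}, {}
    for name, stats in fix["parameters"].items():
        total = stats["total_sd"]
        cell_sd[name] = frac * total
        heart_sd[name] = float(np.sqrt(max(total**2 - cell_sd[name] ** 2, 0.0)))
    return PopulationModel(
        heart_level_sd=heart_sd,
        cell_level_sd=cell_sd,
        noise_sd=noise_sd,
        n_hearts=n_hearts if n_hearts is not None else fix["n_hearts"],
        cells_per_heart=cells_per_heart if cells_per_heart is not None else 17,
        seed=seed,
    )


@lru_cache(maxsize=None)
def _raw_profiles() -> dict:
    return json.loads(_fixture_path("effect_profiles.json").read_text())


def load_effect_profiles() -> dict[str, DrugEffectProfile]:
    """Per-drug generator profiles keyed by drug name.

    Fold-indexed fixture maps are re-keyed to the actual test concentrations
    using each drug's panel grid (the grid is taken from the panel table,
    never recomputed from the fETPC).
    """
    raw = _raw_profiles()
    out: dict[str, DrugEffectProfile] = {}
    for entry in load_panel():
        prof = raw[entry.name]
        fold_to_conc = {f"{f:g}": c for f, c in zip(entry.fold_labels, entry.concentrations)}

        def by_conc(fold_map: dict[str, float], transform=lambda v: v) -> dict[float, float]:
            return {
                fold_to_conc[f]: transform(v) for f, v in fold_map.items() if f in fold_to_conc
            }

        out[entry.name] = DrugEffectProfile(
            drug_name=entry.name,
            hill_ic50=prof["hill_ic50_um"],
            hill_slope=prof["hill_slope"],
            tr90_multiplier_by_conc=by_conc(
                prof["tr90_pct_by_fold"], lambda pct: 1.0 + pct / 100.0
            ),
            ac_prob_by_conc=by_conc(prof["ac_prob_by_fold"]),
            ce_prob_by_conc=by_conc(prof["ce_prob_by_fold"]),
        )
    return out


@lru_cache(maxsize=None)
def load_reported_potency() -> pd.DataFrame:
    """Published shortening IC50s and IC50/fETPC margins (censored fits as
    '>top' bounds). ``printed_ratio`` is the value as printed; recomputation
    from IC50 and fETPC is the job of :func:`cardiotwitch.pharm.margin`."""
    with resources.as_file(_fixture_path("reported_potency.tsv")) as p:
        return pd.read_csv(p, sep="\t")


@lru_cache(maxsize=None)
def load_assay_outcomes() -> pd.DataFrame:
    """Per-drug AC-based assay call at the 10× fETPC decision point.

    One false negative among the clinical positives (astemizole), none among
    the negatives — the worked-example input for panel scoring.
    """
    with resources.as_file(_fixture_path("assay_outcomes.tsv")) as p:
        return pd.read_csv(p, sep="\t")
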