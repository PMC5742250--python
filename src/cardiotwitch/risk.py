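"""Drug-level pro-arrhythmia calls, panel scoring and variability decomposition.

The pro-arrhythmia marker is the aftercontraction (AC): a drug is called
positive when AC incidence (fraction of cells showing at least one event in a
period) is non-zero at any period at or below a fold-of-fETPC threshold
(default 10×). CE events inform margin reporting but do not enter the
classifier. Panel-level performance against clinical torsades-de-pointes
labels is summarised as a confusion matrix with rounded-percent sensitivity
and specificity.

Variability is decomposed the way multi-donor myocyte studies report it:
intra-heart variability is the mean of per-heart standard deviations, total
variability the SD of all cells pooled; their ratio approaches 1 when donors
are interchangeable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .transients import EventCalls

__all__ = [
    "DrugPanelEntry",
    "RiskCall",
    "ConfusionSummary",
    "VariabilityDecomposition",
    "incidence",
    "classify_drug",
    "score_panel",
    "decompose_variability",
]


@dataclass(frozen=True)
class DrugPanelEntry:
    """One row of the reference-drug panel."""

    name: str
    clinical_tdp: str  # "positive" | "negative"
    fetpc: float  # µM
    concentrations: tuple[float, ...]  # 4 ascending test concentrations, µM
    fold_labels: tuple[float, ...] = ()  # printed multiples of the fETPC
    n_cells: int = 0
    n_hearts: int = 1
    cipa_flag: bool = False

    def __post_init__(self) -> None:
        if self.clinical_tdp not in ("positive", "negative"):
            raise ValueError("clinical_tdp must be 'positive' or 'negative'")
        if self.fetpc <= 0:
            raise ValueError("fETPC must be positive")
        if len(self.concentrations) != 4:
            raise ValueError("panel entries carry exactly 4 test concentrations")

    def folds(self) -> tuple[float, ...]:
        """Raw concentration/fETPC multiples."""
        return tuple(c / self.fetpc for c in self.concentrations)


@dataclass
class RiskCall:
    """Per-drug pro-arrhythmia prediction at a fold-of-fETPC threshold."""

    drug: str
    predicted: str  # "positive" | "negative"
    threshold_fold: float
    evidence: dict[float, float] = field(default_factory=dict)  # fold -> AC incidence %


@dataclass
class ConfusionSummary:
    """Panel-level confusion counts and rounded performance percentages."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # %, rounded half-up to integer
    specificity: float

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "ConfusionSummary":
        sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        rnd = lambda v: float(math.floor(v + 0.5)) if np.isfinite(v) else v
        return cls(tp=tp, fn=fn, tn=tn, fp=fp, sensitivity=rnd(sens), specificity=rnd(spec))


@dataclass
class VariabilityDecomposition:
    """Intra-heart vs. total (pooled) spread of a parameter."""

    intra_heart_sd: float  # mean of per-heart SDs
    total_sd: float  # SD of all cells pooled
    fraction: float  # intra / total
    n_hearts: int
    n_cells: int


def incidence(cells: list[EventCalls], event: str) -> float:
    """Percent of cells showing at least one event of the given kind.

    ``event`` is ``"AC"`` or ``"CE"``. The raw (unrounded) percentage is
    returned; reports round half-up to an integer (1 of 6 → 17%).
    """
    if not cells:
        raise ValueError("need at least one cell")
    if event == "AC":
        hits = sum(1 for c in cells if c.cell_has_ac)
    elif event == "CE":
        hits = sum(1 for c in cells if c.cell_has_ce)
    else:
        raise ValueError("event must be 'AC' or 'CE'")
    return 100.0 * hits / len(cells)


def classify_drug(
    entry: DrugPanelEntry,
    incidence_by_fold: dict[float, float],
    threshold_fold: float = 10.0,
    rule: str = "le",
) -> RiskCall:
    """Pro-arrhythmia call: positive iff AC incidence > 0 at any period within
    the fold threshold.

    ``incidence_by_fold`` maps a period's fold-of-fETPC (the printed multiple)
    to its AC incidence in percent. ``rule='le'`` counts every period at or
    below the threshold (an AC appearing already at the fETPC is a positive);
    ``rule='eq'`` restricts to the threshold period alone. Periods above the
    threshold contribute margin information only, never the call.
    """
    if rule not in ("le", "eq"):
        raise ValueError("rule must be 'le' or 'eq'")
    eligible = {
        f: v
        for f, v in incidence_by_fold.items()
        if (f <= threshold_fold if rule == "le" else f == threshold_fold)
    }
    if not eligible:
        raise ValueError(
            f"{entry.name}: no period at{' or below' if rule == 'le' else ''} "
            f"{threshold_fold}-fold fETPC — panel misconfigured"
        )
    positive = any(v > 0 for v in eligible.values())
    return RiskCall(
        drug=entry.name,
        predicted="positive" if positive else "negative",
        threshold_fold=threshold_fold,
        evidence=dict(sorted(incidence_by_fold.items())),
    )


def score_panel(calls: list[RiskCall], panel: list[DrugPanelEntry]) -> ConfusionSummary:
    """Confusion matrix of predicted vs. clinical TdP labels for a panel."""
    labels = {e.name: e.clinical_tdp for e in panel}
    tp = fn = tn = fp = 0
    for call in calls:
        if call.drug not in labels:
            raise ValueError(f"drug {call.drug!r} not in the panel")
        truth = labels[call.drug]
        if truth == "positive":
            if call.predicted == "positive":
                tp += 1
            else:
                fn += 1
        else:
            if call.predicted == "negative":
                tn += 1
            else:
                fp += 1
    return ConfusionSummary.from_counts(tp, fn, tn, fp)


def decompose_variability(values_by_heart: dict | list) -> VariabilityDecomposition:
    """Intra-heart (mean of per-heart SDs) vs. total (pooled SD) variability.

    Hearts with fewer than two cells have no defined SD and are excluded from
    the intra-heart average (with a warning); their cells still count toward
    the pooled total. With a single heart the two statistics coincide exactly.
    """
    if isinstance(values_by_heart, dict):
        groups = [np.asarray(v, dtype=float) for v in values_by_heart.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_heart]
    if not groups:
        raise ValueError("need at least one heart")
    per_heart_sds = []
    for g in groups:
        if g.size < 2:
            warnings.warn("heart with a single cell excluded from intra-heart SD", stacklevel=2)
            continue
        per_heart_sds.append(g.std(ddof=1))
    if not per_heart_sds:
        raise ValueError("no heart has >= 2 cells; intra-heart SD undefined")
    pooled = np.concatenate(groups)
    intra = float(np.mean(per_heart_sds))
    total = float(pooled.std(ddof=1))
    return VariabilityDecomposition(
        intra_heart_sd=intra,
        total_sd=total,
        fraction=intra / total if total > 0 else float("nan"),
        n_hearts=len(groups),
        n_cells=int(pooled.size),
    )
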