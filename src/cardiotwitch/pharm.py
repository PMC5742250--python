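"""Concentration–effect assembly, Hill potency fitting and safety margins.

Treatment effects are expressed per cell relative to its own vehicle baseline
period. Sarcomere-shortening concentration–effect data are fitted with a Hill
curve constrained between 100% (no effect) and 0%,

``R(c) = 100 · [1 − c^h / (c^h + IC50^h)]``,  h ∈ [0.3, 5],

to estimate the IC50 (concentration halving shortening). Four-point curves
cannot support free top/bottom parameters, so both are fixed. A fit is
censored — reported as a "greater-than" bound at the top tested concentration
— when the fitted IC50 exceeds the top concentration or the observed maximal
inhibition never reaches 50%. Potency is interpreted clinically as the margin
IC50/fETPC (free effective therapeutic plasma concentration); printed
multiples follow the panel convention of rounding to an integer at ≥ 1 and to
one decimal below 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import ttest_rel

from .transients import TransientParams

__all__ = [
    "ConcentrationPeriod",
    "HillFitResult",
    "SafetyMargin",
    "PairedTestResult",
    "percent_change",
    "hill_response",
    "fit_hill",
    "margin",
    "paired_compare",
    "fold_multiple",
    "round_fold",
]


@dataclass
class ConcentrationPeriod:
    """One drug-exposure period of one cell, normalised to its vehicle."""

    concentration: float  # µM
    fold_fetpc: float  # raw multiple of the fETPC
    fold_fetpc_rounded: float
    params: TransientParams | None = None
    pct_change: dict[str, float] = field(default_factory=dict)


def round_fold(x: float) -> float:
    """Panel rounding convention: integer at ≥ 1, one decimal below 1.

    Uses round-half-up (the convention the printed multiples follow, e.g.
    8.5 → 9), not banker's rounding.
    """
    if x >= 1.0:
        return float(math.floor(x + 0.5))
    return math.floor(x * 10.0 + 0.5) / 10.0


def fold_multiple(concentration: float, fetpc: float) -> tuple[float, float]:
    """(raw, rounded) multiple of the fETPC for a test concentration."""
    if fetpc <= 0:
        raise ValueError("fETPC must be positive")
    raw = concentration / fetpc
    return raw, round_fold(raw)


def percent_change(
    treated: TransientParams | float,
    vehicle: TransientParams | float,
    parameter: str | None = None,
) -> float:
    """Percent change of a parameter vs. the same cell's vehicle period.

    Returns ``nan`` (with a warning) when the vehicle value is zero.
    """
    if parameter is not None:
        treated = getattr(treated, parameter)
        vehicle = getattr(vehicle, parameter)
    vehicle = float(vehicle)
    treated = float(treated)
    if vehicle == 0.0:
        warnings.warn("vehicle value is zero; percent change undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (treated - vehicle) / vehicle


def hill_response(conc, ic50: float, slope: float):
    """Remaining response (% of vehicle) under Hill inhibition."""
    c = np.asarray(conc, dtype=float)
    ch = np.power(c, slope, where=c > 0, out=np.zeros_like(c))
    return 100.0 * (1.0 - ch / (ch + ic50**slope))


@dataclass
class HillFitResult:
    """IC50/slope estimate for one drug's shortening concentration–effect data."""

    ic50: float  # µM (point estimate even when censored)
    hill_slope: float
    censored: bool  # True: report "IC50 > top_conc"
    fit_rms: float  # % of vehicle scale
    top_conc: float
    n_points: int
    warning: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.censored:
            return f"IC50 > {self.top_conc:g} µM (no 50% inhibition observed)"
        return f"IC50 = {self.ic50:.3g} µM (h = {self.hill_slope:.2f})"


_HILL_SLOPE_BOUNDS = (0.3, 5.0)


def fit_hill(
    concs,
    responses,
    weights=None,
) -> HillFitResult:
    """Least-squares Hill fit of shortening responses (% of vehicle).

    Multi-start over log-spaced IC50 initialisations guards against the local
    minima of 4-point curves. Non-monotone data (responses rising with
    concentration beyond noise) get a best-effort fit plus a warning flag.
    """
    concs = np.asarray(concs, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if concs.size < 3:
        raise ValueError("need at least 3 concentrations to fit a Hill curve")
    if concs.size != responses.size:
        raise ValueError("concs and responses must have equal length")
    order = np.argsort(concs)
    concs, responses = concs[order], responses[order]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[order]
    sigma = None if weights is None else 1.0 / np.sqrt(weights)

    top = float(concs.max())
    lo, hi = float(concs.min()) * 1e-4, top * 1e4
    best: tuple[float, np.ndarray] | None = None
    for ic0 in np.geomspace(max(lo * 10, 1e-12), hi / 10, 11):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    hill_response,
                    concs,
                    responses,
                    p0=[ic0, 1.0],
                    bounds=([lo, _HILL_SLOPE_BOUNDS[0]], [hi, _HILL_SLOPE_BOUNDS[1]]),
                    sigma=sigma,
                    maxfev=10000,
                )
        except RuntimeError:
            continue
        sse = float(np.sum((hill_response(concs, *popt) - responses) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:  # pragma: no cover - bounds make this unreachable in practice
        raise RuntimeError("Hill fit failed from every initialisation")
    sse, (ic50, slope) = best

    max_inhibition = 100.0 - float(responses.min())
    censored = bool(ic50 > top or max_inhibition < 50.0)
    warning = None
    diffs = np.diff(responses)
    # a genuine reversal: responses rising with concentration by more than a
    # noise-sized fraction of the observed response range
    if np.any(diffs > max(10.0, 0.3 * float(np.ptp(responses)))):
        warning = "non-monotone concentration-effect data; best-effort fit"
    return HillFitResult(
        ic50=float(ic50),
        hill_slope=float(slope),
        censored=censored,
        fit_rms=float(np.sqrt(sse / concs.size)),
        top_conc=top,
        n_points=int(concs.size),
        warning=warning,
    )


@dataclass
class SafetyMargin:
    """IC50/fETPC multiple and the inotropy call derived from it."""

    ratio: float  # raw IC50/fETPC (top_conc/fETPC bound when censored)
    ratio_rounded: float
    is_lower_bound: bool  # censored fits: true margin exceeds `ratio`
    inotropy_call: str  # "negative inotrope" | "no effect"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        prefix = ">" if self.is_lower_bound else ""
        return f"{prefix}{self.ratio_rounded:g}× fETPC ({self.inotropy_call})"


def margin(fit: HillFitResult, fetpc: float) -> SafetyMargin:
    """Safety margin of a fitted (possibly censored) IC50 over the fETPC."""
    if fetpc <= 0:
        raise ValueError("fETPC must be positive")
    if fit.censored:
        ratio = fit.top_conc / fetpc
        call = "no effect"
    else:
        ratio = fit.ic50 / fetpc
        call = "negative inotrope"
    return SafetyMargin(
        ratio=float(ratio),
        ratio_rounded=round_fold(ratio),
        is_lower_bound=fit.censored,
        inotropy_call=call,
    )


@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    significant: bool
    degenerate: bool
    n: int


def paired_compare(treated, vehicle, alpha: float = 0.05) -> PairedTestResult:
    """Two-sided paired Student's t-test on per-cell values.

    Zero within-pair variance (all differences identical) is flagged
    degenerate: the t statistic is undefined or infinite there.
    """
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    if treated.size != vehicle.size or treated.size < 2:
        raise ValueError("need >= 2 paired values")
    diffs = treated - vehicle
    if np.ptp(diffs) < 1e-12:
        return PairedTestResult(
            statistic=float("nan"),
            pvalue=float("nan"),
            significant=False,
            degenerate=True,
            n=treated.size,
        )
    res = ttest_rel(treated, vehicle)
    return PairedTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        degenerate=False,
        n=treated.size,
    )
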