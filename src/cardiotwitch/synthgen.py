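"""Synthetic paced-cardiomyocyte recordings with known ground truth.

The generator emulates the statistical structure of 1 Hz field-stimulated
adult ventricular cardiomyocyte recordings sampled at 240 Hz: a population of
twitch kinetics with heart-level and cell-level variance components,
concentration-dependent Hill suppression of fractional shortening, relaxation
(TR90) prolongation, stochastic aftercontractions (AC) and contractility
escapes (CE), additive white measurement noise on sarcomere length, and —
optionally — the striated optical-intensity line profiles from which sarcomere
length is recovered spectrally.

Twitch waveform model
---------------------
One beat of sarcomere length is

``sl(t) = baseline − A · φ(t)``,  A = baseline · frac_shortening,

where the normalized shape ``φ`` is a raised-cosine contraction limb
``φ(t) = (½ − ½cos(πt/t_peak))^shape`` for ``t ≤ t_peak`` joined to a
biexponential relaxation evaluated on a warped time axis,

``φ(t_peak + τ) = w·exp(−q(τ)/τ₁) + (1−w)·exp(−q(τ)/(ρ·τ₁))``,
``q(τ) = τ²/(τ + c)``,

with ``w = relax_biexp_ratio``, ``ρ = relax_tau_ratio`` and smoothing constant
``c = 20 ms``. The warp gives the twitch a rounded minimum (zero slope on both
sides of the peak), matching real transients and keeping quadratic-vertex peak
localisation unbiased. The fast time constant ``τ₁`` is solved numerically so
the waveform recovers 90% of its amplitude exactly ``tr90`` ms after the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .traces import IntensityFrameStack, SarcomereLengthTrace

__all__ = [
    "TwitchKinetics",
    "DrugEffectProfile",
    "PacingProtocol",
    "PopulationModel",
    "PeriodTruth",
    "SimulatedCell",
    "InfeasibleKineticsError",
    "make_twitch",
    "twitch_shape",
    "relaxation_residual",
    "tr90_from_taus",
    "sample_population",
    "simulate_cell",
    "synthesize_intensity_stack",
    "striation_profile",
]

#: smoothing constant of the relaxation time warp, seconds
PEAK_SMOOTH_S = 0.020
#: fraction of amplitude still un-recovered at TR90, by definition
TR90_RESIDUAL = 0.10


class InfeasibleKineticsError(ValueError):
    """Raised when a twitch cannot fit inside one pacing interval."""


@dataclass(frozen=True)
class TwitchKinetics:
    """Descriptors of one twitch: resting length, amplitude and timing.

    Parameters
    ----------
    baseline_sl
        Resting (diastolic) sarcomere length, µm; physiological Z-band spacing
        is ~1.6–2.2 µm, the accepted band here is [1.4, 2.4].
    frac_shortening
        Fractional sarcomere shortening at the twitch peak (0–0.25 as a
        fraction, i.e. 0.0431 for 4.31%).
    t_peak
        Time from stimulus to peak shortening, ms.
    tr90
        Time from peak to 90% amplitude recovery, ms.
    contraction_shape
        Exponent of the raised-cosine contraction limb (higher = later, sharper
        descent); 2.0 reproduces the reported contraction velocities.
    relax_biexp_ratio
        Weight of the fast exponential in the biexponential relaxation.
    relax_tau_ratio
        Ratio of slow to fast relaxation time constants.
    """

    baseline_sl: float
    frac_shortening: float
    t_peak: float
    tr90: float
    contraction_shape: float = 2.0
    relax_biexp_ratio: float = 0.7
    relax_tau_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not (1.4 <= self.baseline_sl <= 2.4):
            raise ValueError(f"baseline_sl {self.baseline_sl} outside [1.4, 2.4] µm")
        if not (0.0 <= self.frac_shortening < 0.25):
            raise ValueError("frac_shortening must be in [0, 0.25)")
        if self.t_peak <= 0 or self.tr90 <= 0:
            raise ValueError("t_peak and tr90 must be positive")
        if not (0.0 < self.relax_biexp_ratio <= 1.0):
            raise ValueError("relax_biexp_ratio must be in (0, 1]")
        if self.relax_tau_ratio < 1.0:
            raise ValueError("relax_tau_ratio must be >= 1")

    @classmethod
    def from_relaxation_taus(
        cls,
        baseline_sl: float,
        frac_shortening: float,
        t_peak: float,
        tau1: float,
        tau2: float,
        weight: float = 0.7,
        **kwargs,
    ) -> "TwitchKinetics":
        """Build kinetics from explicit relaxation time constants (ms).

        ``tr90`` is derived from the closed form of the relaxation model, so a
        waveform built from the result reproduces the biexponential's own 90%
        recovery time.
        """
        if tau2 < tau1:
            tau1, tau2, weight = tau2, tau1, 1.0 - weight
        tr90 = tr90_from_taus(tau1, tau2, weight)
        return cls(
            baseline_sl,
            frac_shortening,
            t_peak,
            tr90,
            relax_biexp_ratio=weight,
            relax_tau_ratio=tau2 / tau1,
            **kwargs,
        )


def relaxation_residual(tau_s, tau1_s, weight=0.7, tau_ratio=3.0, smooth_s=PEAK_SMOOTH_S):
    """Un-recovered amplitude fraction ``φ`` at time ``tau_s`` after the peak."""
    tau = np.asarray(tau_s, dtype=float)
    q = tau * tau / (tau + smooth_s)
    return weight * np.exp(-q / tau1_s) + (1.0 - weight) * np.exp(-q / (tau_ratio * tau1_s))


def _solve_tau1(tr90_s: float, weight: float, tau_ratio: float) -> float:
    f = lambda tau: relaxation_residual(tr90_s, tau, weight, tau_ratio) - TR90_RESIDUAL
    return brentq(f, 1e-5, 20.0 * tr90_s)


def tr90_from_taus(tau1: float, tau2: float, weight: float = 0.7) -> float:
    """Closed-form 90% recovery time (ms) of the warped biexponential relaxation."""
    tau1_s, tau2_s = tau1 / 1e3, tau2 / 1e3
    f = lambda s: (
        weight * math.exp(-(s * s / (s + PEAK_SMOOTH_S)) / tau1_s)
        + (1 - weight) * math.exp(-(s * s / (s + PEAK_SMOOTH_S)) / tau2_s)
        - TR90_RESIDUAL
    )
    return brentq(f, 1e-5, 100.0 * tau2_s) * 1e3


def twitch_shape(t_s, t_peak_ms, tr90_ms, shape=2.0, weight=0.7, tau_ratio=3.0):
    """Normalized twitch shape φ(t) ∈ [0, 1] (1 at the peak), zero for t < 0."""
    t = np.asarray(t_s, dtype=float)
    tp = t_peak_ms / 1e3
    tau1 = _solve_tau1(tr90_ms / 1e3, weight, tau_ratio)
    phi = np.zeros_like(t)
    rising = (t >= 0) & (t <= tp)
    phi[rising] = (0.5 - 0.5 * np.cos(np.pi * t[rising] / tp)) ** shape
    falling = t > tp
    phi[falling] = relaxation_residual(t[falling] - tp, tau1, weight, tau_ratio)
    return phi


def make_twitch(
    kinetics: TwitchKinetics, sample_rate: float, interval_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """One noiseless beat of sarcomere length over a pacing interval.

    Returns ``(t, sl)`` with ``t`` starting at the stimulus (0 s).

    Raises
    ------
    InfeasibleKineticsError
        If ``t_peak + tr90`` does not fit inside the pacing interval.
    """
    if (kinetics.t_peak + kinetics.tr90) / 1e3 >= interval_s:
        raise InfeasibleKineticsError(
            f"t_peak + tr90 = {kinetics.t_peak + kinetics.tr90:.0f} ms "
            f">= pacing interval {interval_s * 1e3:.0f} ms"
        )
    n = int(round(interval_s * sample_rate))
    t = np.arange(n) / sample_rate
    amplitude = kinetics.baseline_sl * kinetics.frac_shortening
    if amplitude == 0.0:
        return t, np.full(n, kinetics.baseline_sl)
    phi = twitch_shape(
        t,
        kinetics.t_peak,
        kinetics.tr90,
        kinetics.contraction_shape,
        kinetics.relax_biexp_ratio,
        kinetics.relax_tau_ratio,
    )
    return t, kinetics.baseline_sl - amplitude * phi


@dataclass(frozen=True)
class DrugEffectProfile:
    """Concentration-indexed drug effect used to drive the generator.

    All maps are keyed by test concentration in µM. Hill suppression of twitch
    amplitude uses ``1 − c^h/(c^h + IC50^h)``; ``hill_ic50=None`` means no
    inotropic effect at any tested concentration. TR90 multipliers are
    fractions (1.26 = +26%); AC probabilities are per beat, CE probabilities
    per stimulus.
    """

    drug_name: str
    hill_ic50: float | None = None
    hill_slope: float = 1.0
    tr90_multiplier_by_conc: dict[float, float] = field(default_factory=dict)
    ac_prob_by_conc: dict[float, float] = field(default_factory=dict)
    ce_prob_by_conc: dict[float, float] = field(default_factory=dict)
    #: AC amplitude as a fraction of twitch amplitude, drawn uniformly
    ac_amplitude_range: tuple[float, float] = (0.15, 0.5)
    #: AC onset window: [peak + onset_factor·TR90, next stimulus − onset_guard_s]
    ac_onset_factor: float = 1.05
    ac_onset_guard_s: float = 0.10

    def __post_init__(self) -> None:
        if self.hill_ic50 is not None and self.hill_ic50 <= 0:
            raise ValueError("hill_ic50 must be positive")
        for m in (self.ac_prob_by_conc, self.ce_prob_by_conc):
            for c, p in m.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"probability {p} at {c} µM outside [0, 1]")

    def amplitude_scale(self, conc: float) -> float:
        """Hill fraction of vehicle twitch amplitude remaining at ``conc``."""
        if self.hill_ic50 is None or conc <= 0:
            return 1.0
        ch = conc**self.hill_slope
        return 1.0 - ch / (ch + self.hill_ic50**self.hill_slope)

    def tr90_multiplier(self, conc: float) -> float:
        return self.tr90_multiplier_by_conc.get(conc, 1.0)

    def ac_prob(self, conc: float) -> float:
        return self.ac_prob_by_conc.get(conc, 0.0)

    def ce_prob(self, conc: float) -> float:
        return self.ce_prob_by_conc.get(conc, 0.0)

    @classmethod
    def null(cls, drug_name: str = "vehicle") -> "DrugEffectProfile":
        return cls(drug_name=drug_name)


@dataclass(frozen=True)
class PacingProtocol:
    """Field-stimulation and acquisition protocol (1 Hz pacing, 240 Hz video)."""

    frequency: float = 1.0
    sample_rate: float = 240.0
    vehicle_duration: float = 120.0
    period_duration: float = 250.0
    n_periods: int = 4

    def __post_init__(self) -> None:
        if self.sample_rate < 10 * self.frequency:
            raise ValueError("sample_rate must be at least 10x pacing frequency")

    @property
    def interval_s(self) -> float:
        return 1.0 / self.frequency


@dataclass(frozen=True)
class PopulationModel:
    """Hierarchical (heart → cell) population spread plus measurement noise.

    ``heart_level_sd`` / ``cell_level_sd`` map a kinetics parameter name
    (``baseline_sl``, ``frac_shortening``, ``t_peak``, ``tr90``) to its spread;
    for lognormal parameters these are natural-scale SDs converted internally.
    ``effect_log_sd`` is the SD of the log response factor that scales each
    cell's drug effect (TR90 increment and IC50 shift).
    """

    heart_level_sd: dict[str, float] = field(default_factory=dict)
    cell_level_sd: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.005
    n_hearts: int = 1
    cells_per_heart: int = 1
    seed: int = 0
    effect_log_sd: float = 0.2

    def __post_init__(self) -> None:
        for m in (self.heart_level_sd, self.cell_level_sd):
            if any(v < 0 for v in m.values()):
                raise ValueError("spreads must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PeriodTruth:
    """Ground truth for one concentration period of a simulated cell."""

    name: str
    concentration: float
    start_s: float
    end_s: float
    n_beats: int
    kinetics: TwitchKinetics
    ac_beats: list[tuple[int, float, float]] = field(default_factory=list)  # (beat, onset_s, amp_um)
    ce_beats: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        k = self.kinetics
        return {
            "name": self.name,
            "concentration_um": self.concentration,
            "start_s": self.start_s,
            "end_s": self.end_s,
            "n_beats": self.n_beats,
            "kinetics": {
                "baseline_sl": k.baseline_sl,
                "frac_shortening": k.frac_shortening,
                "t_peak": k.t_peak,
                "tr90": k.tr90,
            },
            "ac_beats": [[int(b), float(o), float(a)] for b, o, a in self.ac_beats],
            "ce_beats": [int(b) for b in self.ce_beats],
        }


@dataclass
class SimulatedCell:
    """A simulated recording plus its per-period ground truth."""

    trace: SarcomereLengthTrace
    truth: list[PeriodTruth]
    heart_id: int = 0
    cell_id: int = 0

    def periods(self) -> list[tuple[str, float, float, float]]:
        """(name, concentration, start_s, end_s) per period, for the analyzer."""
        return [(p.name, p.concentration, p.start_s, p.end_s) for p in self.truth]


# Population statistics: which parameters are drawn lognormally. Table-style
# baseline distributions are right-skewed for shortening and the timing
# parameters (mean > median) and near-symmetric for resting length.
_LOGNORMAL_PARAMS = frozenset({"frac_shortening", "t_peak", "tr90"})
_PARAM_BOUNDS = {
    "baseline_sl": (1.45, 2.1),
    "frac_shortening": (0.010, 0.14),
    "t_peak": (90.0, 360.0),
    "tr90": (170.0, 720.0),
}


def sample_population(
    means: dict[str, float],
    model: PopulationModel,
    rng: np.random.Generator | None = None,
    interval_s: float = 1.0,
    match_population_mean: bool = True,
) -> list[tuple[int, TwitchKinetics]]:
    """Draw ``n_hearts × cells_per_heart`` twitch kinetics.

    Heart means are drawn around the population mean with ``heart_level_sd``,
    cells around their heart mean with ``cell_level_sd`` (both in log space for
    the right-skewed parameters, so the population mean is preserved on the
    natural scale). Draws outside physiological bounds, or infeasible for the
    pacing interval, are resampled.

    With ``match_population_mean`` (default) the realized draws are recentred
    so the simulated cohort's empirical mean equals the configured mean: the
    target statistics describe *this* study's cells, not a superpopulation, so
    the emulator reproduces them rather than scattering around them (with few
    hearts the free-draw pooled mean would wander by ±5% run to run). Spread
    and the heart/cell variance split are unaffected.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    params = ["baseline_sl", "frac_shortening", "t_peak", "tr90"]
    out: list[tuple[int, TwitchKinetics]] = []
    for heart in range(model.n_hearts):
        heart_shift: dict[str, float] = {}
        for p in params:
            mu, h_sd = means[p], model.heart_level_sd.get(p, 0.0)
            if p in _LOGNORMAL_PARAMS:
                sigma = _natural_to_log_sd(mu, h_sd)
                heart_shift[p] = rng.normal(0.0, sigma) - 0.5 * sigma**2
            else:
                heart_shift[p] = rng.normal(0.0, h_sd)
        for _ in range(model.cells_per_heart):
            for _attempt in range(200):
                draw: dict[str, float] = {}
                ok = True
                for p in params:
                    mu, c_sd = means[p], model.cell_level_sd.get(p, 0.0)
                    if p in _LOGNORMAL_PARAMS:
                        sigma = _natural_to_log_sd(mu, c_sd)
                        val = mu * math.exp(
                            heart_shift[p] + rng.normal(0.0, sigma) - 0.5 * sigma**2
                        )
                    else:
                        val = mu + heart_shift[p] + rng.normal(0.0, c_sd)
                    lo, hi = _PARAM_BOUNDS[p]
                    if not (lo <= val <= hi):
                        ok = False
                        break
                    draw[p] = val
                if ok and (draw["t_peak"] + draw["tr90"]) / 1e3 < interval_s - 0.05:
                    out.append((heart, draw))
                    break
            else:  # pragma: no cover - pathological configuration
                raise RuntimeError("could not draw feasible kinetics in 200 attempts")
    if match_population_mean and len(out) > 1:
        for p in params:
            vals = np.array([draw[p] for _, draw in out])
            lo, hi = _PARAM_BOUNDS[p]
            if p in _LOGNORMAL_PARAMS:
                scale = means[p] / vals.mean()
                for _, draw in out:
                    draw[p] = float(np.clip(draw[p] * scale, lo, hi))
            else:
                shift = means[p] - vals.mean()
                for _, draw in out:
                    draw[p] = float(np.clip(draw[p] + shift, lo, hi))
        for _, draw in out:  # recentring may nudge a draw past feasibility
            max_tr90 = (interval_s - 0.05) * 1e3 - draw["t_peak"]
            draw["tr90"] = min(draw["tr90"], max_tr90)
    return [(heart, TwitchKinetics(**draw)) for heart, draw in out]


def _natural_to_log_sd(mean: float, sd: float) -> float:
    """SD of log X for a lognormal with given natural-scale mean and SD."""
    if sd == 0.0:
        return 0.0
    return math.sqrt(math.log1p((sd / mean) ** 2))


# aftercontraction mini-twitch kinetics (ms); amplitude is scaled per event
_AC_T_PEAK = 50.0
_AC_TR90 = 110.0


def simulate_cell(
    kinetics: TwitchKinetics,
    profile: DrugEffectProfile,
    protocol: PacingProtocol,
    population: PopulationModel,
    concentrations: list[float] | None = None,
    rng: np.random.Generator | None = None,
    heart_id: int = 0,
    cell_id: int = 0,
) -> SimulatedCell:
    """Simulate one cell through a vehicle period and ascending concentrations.

    Per concentration period the twitch amplitude is scaled by the Hill
    fraction, TR90 by the profile's multiplier (both modulated by the cell's
    response factor), ACs are injected per beat as a delayed scaled copy of the
    twitch during late relaxation, CEs as absent twitches, and Gaussian noise
    of ``population.noise_sd`` is added pointwise.
    """
    rng = np.random.default_rng(population.seed) if rng is None else rng
    concentrations = list(concentrations or [])
    fs, interval = protocol.sample_rate, protocol.interval_s
    spb = int(round(interval * fs))  # samples per beat

    # cell-specific response factor, shared across periods (a cell that
    # responds strongly at one concentration responds strongly at all)
    effect_factor = math.exp(rng.normal(0.0, population.effect_log_sd))
    ic50_cell = None if profile.hill_ic50 is None else profile.hill_ic50 / effect_factor

    periods: list[tuple[str, float, int]] = [
        ("vehicle", 0.0, int(round(protocol.vehicle_duration * protocol.frequency)))
    ]
    for c in concentrations:
        periods.append((f"{c:g}uM", c, int(round(protocol.period_duration * protocol.frequency))))

    chunks: list[np.ndarray] = []
    stim_times: list[float] = []
    truth: list[PeriodTruth] = []
    t0 = 0.0
    for name, conc, n_beats in periods:
        if conc > 0 and ic50_cell is not None:
            ch = conc**profile.hill_slope
            amp_scale = 1.0 - ch / (ch + ic50_cell**profile.hill_slope)
        else:
            amp_scale = 1.0
        tr90_eff = kinetics.tr90 * (1.0 + (profile.tr90_multiplier(conc) - 1.0) * effect_factor)
        tr90_eff = min(tr90_eff, (interval - 0.06) * 1e3 - kinetics.t_peak)
        eff = replace(
            kinetics,
            frac_shortening=kinetics.frac_shortening * amp_scale,
            tr90=tr90_eff,
        )
        _, beat_wave = make_twitch(eff, fs, interval)
        amplitude = eff.baseline_sl * eff.frac_shortening

        p_ac, p_ce = profile.ac_prob(conc), profile.ce_prob(conc)
        ptruth = PeriodTruth(name, conc, t0, t0 + n_beats * interval, n_beats, eff)
        ac_window_lo = (kinetics.t_peak + profile.ac_onset_factor * tr90_eff) / 1e3
        ac_window_hi = interval - profile.ac_onset_guard_s
        for b in range(n_beats):
            stim_times.append(t0 + b * interval)
            if p_ce > 0 and rng.random() < p_ce:
                chunks.append(np.full(spb, eff.baseline_sl))
                ptruth.ce_beats.append(b)
                continue
            beat = beat_wave.copy()
            if p_ac > 0 and ac_window_hi > ac_window_lo and rng.random() < p_ac:
                onset = rng.uniform(ac_window_lo, ac_window_hi)
                ac_amp = amplitude * rng.uniform(*profile.ac_amplitude_range)
                tb = np.arange(spb) / fs
                beat = beat - ac_amp * twitch_shape(tb - onset, _AC_T_PEAK, _AC_TR90)
                ptruth.ac_beats.append((b, onset, ac_amp))
            chunks.append(beat)
        truth.append(ptruth)
        t0 += n_beats * interval

    sl = np.concatenate(chunks)
    if population.noise_sd > 0:
        sl = sl + rng.normal(0.0, population.noise_sd, sl.size)
    time = np.arange(sl.size) / fs
    trace = SarcomereLengthTrace(time, sl, np.asarray(stim_times), fs)
    return SimulatedCell(trace=trace, truth=truth, heart_id=heart_id, cell_id=cell_id)


def striation_profile(
    x_um: np.ndarray,
    period_um: float,
    contrast: float = 0.5,
    kind: str = "cosine",
    band_width_um: float = 0.25,
    phase: float = 0.0,
) -> np.ndarray:
    """Idealised bright/dark striation intensity at positions ``x_um``.

    ``kind='cosine'`` is a pure sinusoidal grating; ``kind='comb'`` is a train
    of Gaussian Z-band peaks of width ``band_width_um`` at the given spatial
    period (a closer caricature of real Z-band images).
    """
    x = np.asarray(x_um, dtype=float)
    if kind == "cosine":
        return 1.0 + contrast * np.cos(2.0 * np.pi * x / period_um + phase)
    if kind == "comb":
        offset = phase / (2.0 * np.pi) * period_um
        d = np.mod(x - offset + period_um / 2.0, period_um) - period_um / 2.0
        return 1.0 + contrast * (
            np.exp(-0.5 * (d / band_width_um) ** 2) / (band_width_um * math.sqrt(2 * math.pi)) * period_um / 4.0
        )
    raise ValueError(f"unknown striation kind {kind!r}")


def synthesize_intensity_stack(
    trace: SarcomereLengthTrace,
    roi_length_um: float = 30.0,
    pixel_pitch_um: float = 0.05,
    band_contrast: float = 0.5,
    noise_sd: float = 0.03,
    kind: str = "cosine",
    rng: np.random.Generator | None = None,
) -> IntensityFrameStack:
    """Render a trace as per-frame 1-D striation profiles.

    Each frame's spatial period equals the trace's sarcomere length at that
    sample. The ROI must span ≥ 10 × the maximum sarcomere length so the
    spectral estimator downstream has enough periods to work with.
    """
    max_sl = float(np.nanmax(trace.sl))
    if roi_length_um < 10.0 * max_sl:
        raise ValueError(
            f"ROI of {roi_length_um} µm too short: need >= 10 sarcomere periods "
            f"({10 * max_sl:.1f} µm) for reliable spectral estimation"
        )
    rng = np.random.default_rng(0) if rng is None else rng
    x = np.arange(int(round(roi_length_um / pixel_pitch_um))) * pixel_pitch_um
    phase = rng.uniform(0.0, 2.0 * np.pi)
    if kind == "cosine":
        frames = 1.0 + band_contrast * np.cos(
            2.0 * np.pi * x[None, :] / trace.sl[:, None] + phase
        )
    else:
        frames = np.stack(
            [striation_profile(x, sl, band_contrast, kind, phase=phase) for sl in trace.sl]
        )
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return IntensityFrameStack(
        frames=frames,
        pixel_pitch=pixel_pitch_um,
        frame_rate=trace.sample_rate,
        stimulus_times=trace.stimulus_times,
    )
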