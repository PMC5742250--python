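"""Beat segmentation, event detection and twitch-parameter extraction.

A paced recording is cut into beats at the stimulus timestamps. Per period,
beats are screened for contractility escapes (CE: the stimulus fails to evoke
a twitch) and aftercontractions (AC: a secondary shortening — slope reversal —
during late relaxation, the mechanical counterpart of an early
afterdepolarization). Event-free-or-not, the steady-state beats are averaged
into a representative transient, five polynomial segments are fitted to its
phases, and the twitch descriptors are read off the fitted curve: resting
sarcomere length, peak, fractional shortening, contraction/relaxation
velocity, time to peak, and TR70/TR80/TR90 (time from peak to 70/80/90%
amplitude recovery).

TR70/80/90 are peak-referenced by default — time-to-peak plus TR90 then adds
up to the full twitch duration — with a stimulus-referenced variant available
through ``trx_reference="stimulus"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import SarcomereLengthTrace

__all__ = [
    "Beat",
    "ACCall",
    "EventCalls",
    "RepresentativeTransient",
    "TransientParams",
    "PhaseFit",
    "AnalysisConfig",
    "PeriodResult",
    "PacingError",
    "segment_beats",
    "detect_ce",
    "detect_ac",
    "average_representative",
    "fit_phases",
    "analyze_recording",
    "estimate_noise_sd",
    "moving_average",
]


class PacingError(ValueError):
    """Raised for unusable stimulus trains (irregular, empty, out of range)."""


@dataclass
class Beat:
    """One inter-stimulus window of a trace."""

    index: int
    stimulus_time: float
    time: np.ndarray  # seconds, relative to stimulus
    sl: np.ndarray
    baseline_sl: float  # median of the 50 ms pre-stimulus
    amplitude: float  # baseline − smoothed minimum
    sample_rate: float


@dataclass(frozen=True)
class ACCall:
    """A detected aftercontraction within one beat."""

    onset_s: float  # relative to the stimulus
    onset_from_peak_s: float
    amplitude: float  # µm, trend-compensated secondary-deflection depth


@dataclass
class EventCalls:
    """Per-period AC/CE calls for one cell."""

    ac_beats: list[tuple[int, ACCall]] = field(default_factory=list)
    ce_beats: list[int] = field(default_factory=list)

    @property
    def cell_has_ac(self) -> bool:
        return len(self.ac_beats) > 0

    @property
    def cell_has_ce(self) -> bool:
        return len(self.ce_beats) > 0


@dataclass
class RepresentativeTransient:
    """Average of steady-state twitch-bearing beats of one period."""

    time: np.ndarray
    mean_waveform: np.ndarray
    n_averaged: int
    sample_rate: float
    low_confidence: bool = False


@dataclass
class PhaseFit:
    """One fitted polynomial segment of the representative transient."""

    name: str
    t_start: float
    t_end: float
    order: int
    coeffs: np.ndarray  # numpy polyval convention (highest power first)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.polyval(self.coeffs, t)


@dataclass
class TransientParams:
    """The twitch descriptor set extracted from a representative transient.

    Times are ms, lengths µm, velocities µm/s (contraction negative),
    fractional shortening in percent. ``nan`` with the corresponding censored
    flag set means the recovery level was not reached before the next
    stimulus.
    """

    sarcomere_length: float
    peak: float
    frac_shortening: float
    contraction_velocity: float
    relaxation_velocity: float
    t_peak: float
    tr70: float
    tr80: float
    tr90: float
    censored: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "sarcomere_length": self.sarcomere_length,
            "peak": self.peak,
            "frac_shortening": self.frac_shortening,
            "contraction_velocity": self.contraction_velocity,
            "relaxation_velocity": self.relaxation_velocity,
            "t_peak": self.t_peak,
            "tr70": self.tr70,
            "tr80": self.tr80,
            "tr90": self.tr90,
        }


@dataclass(frozen=True)
class AnalysisConfig:
    """Detector thresholds and averaging options (all CLI-overridable)."""

    smooth_ms: float = 25.0
    n_average: int = 15
    min_beats_for_average: int = 5
    #: CE: amplitude below max(floor × vehicle median amplitude, ce_k × noise)
    ce_amplitude_floor: float = 0.1
    ce_k: float = 3.0
    #: AC: secondary deflection above max(fraction × twitch amplitude, ac_k × noise)
    ac_min_amp_fraction: float = 0.05
    ac_k: float = 4.0
    ac_min_run_samples: int = 3
    noise_sd: float | None = None  # None = estimate from pre-stimulus windows
    trx_reference: str = "peak"  # or "stimulus"
    pacing_tolerance: float = 0.1


def moving_average(y: np.ndarray, width_samples: int) -> np.ndarray:
    """Centered moving average with edge-replication (no zero-pad edge dips)."""
    w = max(1, int(width_samples)) | 1  # force odd
    if w == 1 or y.size < 3:
        return np.asarray(y, dtype=float)
    kernel = np.ones(w) / w
    padded = np.pad(np.asarray(y, dtype=float), (w // 2, w // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: y.size]


def _smooth_width(smooth_ms: float, fs: float) -> int:
    return max(3, int(round(smooth_ms / 1e3 * fs)) | 1)


def estimate_noise_sd(beats: list[Beat], window_ms: float = 50.0) -> float:
    """Measurement-noise SD from detrended pre-minimum baseline windows."""
    resid = []
    for b in beats[: min(len(beats), 20)]:
        n = max(4, int(round(window_ms / 1e3 * b.sample_rate)))
        seg = b.sl[:n] if b.sl.size >= n else b.sl
        if seg.size >= 4:
            t = np.arange(seg.size)
            resid.append(seg - np.polyval(np.polyfit(t, seg, 1), t))
    if not resid:
        return 0.0
    return float(np.concatenate(resid).std())


def segment_beats(
    trace: SarcomereLengthTrace,
    stimulus_times: np.ndarray | None = None,
    pacing_tolerance: float = 0.1,
    smooth_ms: float = 25.0,
) -> list[Beat]:
    """Cut a trace into one Beat per stimulus.

    The last stimulus is dropped if its window would be truncated. Pacing
    irregular by more than ``pacing_tolerance`` (fractional deviation of any
    inter-stimulus interval from the median) is an error. The pre-stimulus
    baseline is the median of the 50 ms before the stimulus; for the first
    beat (nothing precedes it) the first 10 ms of its own window are used.
    """
    stims = np.asarray(
        trace.stimulus_times if stimulus_times is None else stimulus_times, dtype=float
    )
    if stims.size < 2:
        raise PacingError("need at least 2 stimuli to segment beats")
    if stims.min() < trace.time[0] - 1e-9 or stims.max() > trace.time[-1] + 1e-9:
        raise PacingError("stimulus times outside the trace span")
    intervals = np.diff(stims)
    interval = float(np.median(intervals))
    if np.any(np.abs(intervals - interval) > pacing_tolerance * interval):
        raise PacingError("pacing irregular by more than "
                          f"{100 * pacing_tolerance:.0f}% of the median interval")
    fs = trace.sample_rate
    spb = int(round(interval * fs))
    t0 = trace.time[0]
    pre = int(round(0.050 * fs))
    width = _smooth_width(smooth_ms, fs)
    beats: list[Beat] = []
    for i, s in enumerate(stims):
        start = int(round((s - t0) * fs))
        stop = start + spb
        if stop > trace.sl.size:
            break  # truncated final window: drop
        window = trace.sl[start:stop]
        if np.any(~np.isfinite(window)):
            window = window.copy()
            good = np.isfinite(window)
            if good.sum() < 0.8 * window.size:
                continue  # too many flagged samples to trust this beat
            window[~good] = np.interp(
                np.flatnonzero(~good), np.flatnonzero(good), window[good]
            )
        if start >= pre:
            baseline = float(np.median(trace.sl[start - pre : start]))
        else:
            baseline = float(np.median(window[: max(2, int(round(0.010 * fs)))]))
        smoothed = moving_average(window, width)
        amplitude = baseline - float(smoothed.min())
        beats.append(
            Beat(
                index=i,
                stimulus_time=float(s),
                time=np.arange(spb) / fs,
                sl=window,
                baseline_sl=baseline,
                amplitude=amplitude,
                sample_rate=fs,
            )
        )
    if not beats:
        raise PacingError("no complete beats inside the trace")
    return beats


def detect_ce(
    beat: Beat,
    noise_sd: float,
    vehicle_median_amplitude: float | None = None,
    amplitude_floor: float = 0.1,
    k: float = 3.0,
) -> bool:
    """True iff the stimulus evoked no contraction transient.

    The beat counts as an escape when its amplitude is below
    ``max(amplitude_floor × vehicle median amplitude, k × noise_sd)``; without
    a vehicle reference only the noise criterion applies.
    """
    threshold = k * noise_sd
    if vehicle_median_amplitude is not None:
        threshold = max(threshold, amplitude_floor * vehicle_median_amplitude)
    return beat.amplitude < threshold


def detect_ac(
    beat: Beat,
    noise_sd: float,
    smooth_ms: float = 25.0,
    min_amp_fraction: float = 0.05,
    k: float = 4.0,
    min_run_samples: int = 3,
) -> ACCall | None:
    """Find the earliest aftercontraction of a twitch-bearing beat, if any.

    The smoothed signal is scanned from peak + TR50 (50% recovery) to the end
    of the window for a derivative reversal — relaxation (lengthening) turning
    into a secondary shortening and back. The deflection amplitude is measured
    against a local linear extrapolation of the preceding relaxation, so the
    underlying recovery does not mask shallow events, and must exceed
    ``max(min_amp_fraction × twitch amplitude, k × noise_sd)``.
    """
    fs = beat.sample_rate
    s = moving_average(beat.sl, _smooth_width(smooth_ms, fs))
    # twitch peak restricted to the first 70% of the window so a large late AC
    # can never masquerade as the primary twitch
    search_end = max(3, int(0.7 * s.size))
    p = int(np.argmin(s[:search_end]))
    amplitude = beat.baseline_sl - s[p]
    if amplitude <= 0:
        return None
    lev50 = s[p] + 0.5 * amplitude
    after = np.flatnonzero(s[p + 1 :] >= lev50)
    if after.size == 0:
        return None
    i50 = p + 1 + int(after[0])
    threshold = max(min_amp_fraction * amplitude, k * noise_sd)
    deriv = np.gradient(s)
    i, n = i50, s.size - 1
    trend_w = max(3, int(round(0.060 * fs)))
    while i < n:
        if deriv[i] >= 0:
            i += 1
            continue
        j = i
        while j < n and deriv[j] < 0:
            j += 1
        if j - i >= min_run_samples:
            k_min = i + int(np.argmin(s[i : j + 1]))
            # reference: last pre-dip sample extrapolated along the local
            # relaxation slope (clamped non-negative — relaxation never
            # re-shortens), so ongoing recovery does not mask the deflection
            i0 = max(p, i - trend_w)
            if i - i0 >= 3:
                tt = np.arange(i0, i) / fs
                slope = float(np.polyfit(tt, s[i0:i], 1)[0])
            else:
                slope = 0.0
            ref = s[i - 1] + max(slope, 0.0) * (k_min - (i - 1)) / fs
            deflection = float(ref - s[k_min])
            if deflection >= threshold:
                onset = i / fs
                return ACCall(
                    onset_s=onset,
                    onset_from_peak_s=onset - p / fs,
                    amplitude=deflection,
                )
        i = j + 1
    return None


def average_representative(
    beats: list[Beat],
    ce_flags: list[bool] | None = None,
    n: int = 15,
    min_beats: int = 5,
) -> RepresentativeTransient:
    """Average the last ``n`` steady-state twitch-bearing beats of a period.

    CE beats carry no transient and are excluded; AC-bearing beats are kept
    (events are determined from the non-averaged beats, not from this mean).
    Fewer than ``min_beats`` usable beats flags the result low-confidence.
    """
    if not beats:
        raise ValueError("no beats to average")
    if ce_flags is None:
        ce_flags = [False] * len(beats)
    usable = [b for b, ce in zip(beats, ce_flags) if not ce]
    chosen = usable[-n:] if len(usable) > n else usable
    n_averaged = len(chosen)
    if not chosen:
        # every stimulus escaped (or the twitch is fully suppressed): the
        # period's representative is the flat mean of what was recorded
        chosen = beats[-n:]
        n_averaged = 0
    spb = min(b.sl.size for b in chosen)
    mean = np.mean([b.sl[:spb] for b in chosen], axis=0)
    fs = chosen[0].sample_rate
    return RepresentativeTransient(
        time=np.arange(spb) / fs,
        mean_waveform=mean,
        n_averaged=n_averaged,
        sample_rate=fs,
        low_confidence=n_averaged < min_beats,
    )


# polynomial order per phase: baseline, contraction, peak, fast relaxation,
# late relaxation/return
_PHASE_ORDERS = (1, 3, 2, 3, 3)
# peak-neighbourhood half width and how far past the raw 90% crossing the
# late-relaxation fit extends (both ms); calibrated on noiseless waveforms so
# the quadratic vertex and the cubic's TR90 root stay within one 240 Hz sample
_SEG3_HALF_MS = 12.0
_SEG5_MARGIN_MS = 100.0


def fit_phases(
    rep: RepresentativeTransient,
    noise_sd: float = 0.0,
    smooth_ms: float = 25.0,
    trx_reference: str = "peak",
    min_amplitude: float = 1e-4,
) -> tuple[list[PhaseFit], TransientParams]:
    """Fit five polynomial segments to a representative transient and read the
    twitch descriptors off the fitted curve.

    Phases (derivative-based breakpoints, no manual input): (1) pre-contraction
    baseline up to contraction onset, (2) contraction limb, (3) peak
    neighbourhood (±20 ms, quadratic — its vertex gives peak value and time to
    peak), (4) fast relaxation to the 50% recovery point, (5) late relaxation
    from 50% recovery to 95% recovery (capped 50 ms past the raw 90% crossing
    so the fit is not pulled by late-diastole events). TR70/80/90 come from
    root-finding on segments 4–5; a level never reached before the next
    stimulus is censored, not extrapolated.
    """
    t, y, fs = rep.time, rep.mean_waveform, rep.sample_rate
    s = moving_average(y, _smooth_width(smooth_ms, fs))
    n = y.size

    search_end = max(3, int(0.7 * n))
    p = int(np.argmin(s[:search_end]))
    base0 = float(np.median(y[: max(2, int(round(0.030 * fs)))]))
    amp0 = base0 - s[p]
    effective_noise = noise_sd / np.sqrt(max(rep.n_averaged, 1))
    if amp0 < max(min_amplitude, 3.0 * effective_noise) or p < 2:
        params = TransientParams(
            sarcomere_length=base0,
            peak=base0,
            frac_shortening=0.0,
            contraction_velocity=0.0,
            relaxation_velocity=0.0,
            t_peak=float("nan"),
            tr70=float("nan"),
            tr80=float("nan"),
            tr90=float("nan"),
            censored={"t_peak": True, "tr70": True, "tr80": True, "tr90": True},
        )
        return [], params

    # contraction onset: first sustained descent before the peak
    deriv = np.gradient(s)
    descent_thr = 0.05 * deriv[:p].min()
    onset_idx = 1
    for i in range(1, p):
        if deriv[i] <= descent_thr and deriv[min(i + 1, p)] <= descent_thr:
            onset_idx = i
            break
    half_w = max(2, int(round(_SEG3_HALF_MS / 1e3 * fs)))
    p_lo, p_hi = max(onset_idx + 1, p - half_w), min(n - 1, p + half_w)

    def _fit(name: str, i0: int, i1: int, order: int) -> PhaseFit:
        i1 = max(i1, i0 + order + 1)
        i1 = min(i1, n - 1)
        i0 = min(i0, i1 - order - 1) if i1 - i0 < order + 1 else i0
        i0 = max(i0, 0)
        coeffs = np.polyfit(t[i0 : i1 + 1], y[i0 : i1 + 1], order)
        return PhaseFit(name, t[i0], t[i1], order, coeffs)

    fit1 = _fit("baseline", 0, max(onset_idx, 2), _PHASE_ORDERS[0])
    fit2 = _fit("contraction", onset_idx, p_lo, _PHASE_ORDERS[1])
    fit3 = _fit("peak", p_lo, p_hi, _PHASE_ORDERS[2])

    # peak value/time from the quadratic vertex (clamped to the segment)
    a2, b2 = fit3.coeffs[0], fit3.coeffs[1]
    if a2 > 0:
        t_pk = float(np.clip(-b2 / (2.0 * a2), fit3.t_start, fit3.t_end))
    else:
        t_pk = t[p]
    peak_val = float(np.polyval(fit3.coeffs, t_pk))

    sarcomere_length = float(np.polyval(fit1.coeffs, 0.5 * (fit1.t_start + fit1.t_end)))
    amplitude = sarcomere_length - peak_val
    frac_shortening = 100.0 * amplitude / sarcomere_length

    # raw recovery crossings locate the phase-4/5 breakpoints
    def _raw_crossing(frac_recovered: float) -> int | None:
        level = peak_val + frac_recovered * amplitude
        after = np.flatnonzero(s[p:] >= level)
        return p + int(after[0]) if after.size else None

    i50 = _raw_crossing(0.50)
    i90 = _raw_crossing(0.90)
    i95 = _raw_crossing(0.95)
    end4 = i50 if i50 is not None else n - 1
    if i95 is not None and i90 is not None:
        end5 = min(i95, i90 + int(round(_SEG5_MARGIN_MS / 1e3 * fs)))
    elif i90 is not None:
        end5 = min(n - 1, i90 + int(round(_SEG5_MARGIN_MS / 1e3 * fs)))
    else:
        end5 = n - 1
    fit4 = _fit("fast_relaxation", p_hi, end4, _PHASE_ORDERS[3])
    fit5 = _fit("late_relaxation", end4, max(end5, end4 + 5), _PHASE_ORDERS[4])

    def _poly_crossing(fit: PhaseFit, level: float) -> float | None:
        c = fit.coeffs.copy()
        c[-1] -= level
        roots = np.roots(c)
        real = roots[np.abs(roots.imag) < 1e-9].real
        inside = real[(real >= fit.t_start - 1e-9) & (real <= fit.t_end + 1e-9)]
        return float(inside.min()) if inside.size else None

    censored: dict[str, bool] = {}
    trx: dict[str, float] = {}
    for pct, name in ((0.70, "tr70"), (0.80, "tr80"), (0.90, "tr90")):
        level = peak_val + pct * amplitude
        cross = _poly_crossing(fit4, level)
        if cross is None:
            cross = _poly_crossing(fit5, level)
        if cross is None:
            raw = _raw_crossing(pct)
            cross = t[raw] if raw is not None else None
        if cross is None:
            trx[name] = float("nan")
            censored[name] = True
        else:
            ref = t_pk if trx_reference == "peak" else 0.0
            trx[name] = (cross - ref) * 1e3
            censored[name] = False

    # extremal derivatives of the contraction / fast-relaxation fits
    d2 = np.polyder(fit2.coeffs)
    grid2 = np.linspace(fit2.t_start, fit2.t_end, 200)
    contraction_velocity = float(np.polyval(d2, grid2).min())
    d4 = np.polyder(fit4.coeffs)
    grid4 = np.linspace(fit4.t_start, fit4.t_end, 200)
    relaxation_velocity = float(np.polyval(d4, grid4).max())

    params = TransientParams(
        sarcomere_length=sarcomere_length,
        peak=peak_val,
        frac_shortening=frac_shortening,
        contraction_velocity=contraction_velocity,
        relaxation_velocity=relaxation_velocity,
        t_peak=t_pk * 1e3,
        tr70=trx["tr70"],
        tr80=trx["tr80"],
        tr90=trx["tr90"],
        censored=censored,
    )
    return [fit1, fit2, fit3, fit4, fit5], params


@dataclass
class PeriodResult:
    """Analysis output for one concentration period of one cell."""

    name: str
    concentration: float
    params: TransientParams
    events: EventCalls
    n_averaged: int
    n_beats: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "concentration_um": self.concentration,
            "params": self.params.as_dict(),
            "censored": dict(self.params.censored),
            "n_ac_beats": len(self.events.ac_beats),
            "n_ce_beats": len(self.events.ce_beats),
            "cell_has_ac": self.events.cell_has_ac,
            "cell_has_ce": self.events.cell_has_ce,
            "n_averaged": self.n_averaged,
            "n_beats": self.n_beats,
            "flags": list(self.flags),
        }


def analyze_recording(
    trace: SarcomereLengthTrace,
    periods: list[tuple[str, float, float, float]],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[PeriodResult]:
    """Full per-cell analysis: segment, detect events, average, fit.

    ``periods`` is a list of ``(name, concentration_um, start_s, end_s)``; the
    first is taken as the vehicle baseline whose median amplitude anchors the
    CE criterion. Events are determined from every non-averaged beat of each
    period; parameters come from the representative average of its last
    ``config.n_average`` twitch-bearing beats.
    """
    beats = segment_beats(
        trace, pacing_tolerance=config.pacing_tolerance, smooth_ms=config.smooth_ms
    )
    noise_sd = config.noise_sd if config.noise_sd is not None else estimate_noise_sd(beats)

    results: list[PeriodResult] = []
    vehicle_median_amp: float | None = None
    for name, conc, start, end in periods:
        in_period = [b for b in beats if start - 1e-9 <= b.stimulus_time < end - 1e-9]
        if not in_period:
            continue
        flags: list[str] = []
        if vehicle_median_amp is None and results == []:
            vehicle_median_amp = float(np.median([b.amplitude for b in in_period]))
        ce_flags = [
            detect_ce(
                b,
                noise_sd,
                vehicle_median_amplitude=vehicle_median_amp,
                amplitude_floor=config.ce_amplitude_floor,
                k=config.ce_k,
            )
            for b in in_period
        ]
        events = EventCalls()
        for b, is_ce in zip(in_period, ce_flags):
            if is_ce:
                events.ce_beats.append(b.index)
                continue
            call = detect_ac(
                b,
                noise_sd,
                smooth_ms=config.smooth_ms,
                min_amp_fraction=config.ac_min_amp_fraction,
                k=config.ac_k,
                min_run_samples=config.ac_min_run_samples,
            )
            if call is not None:
                events.ac_beats.append((b.index, call))
        rep = average_representative(
            in_period, ce_flags, n=config.n_average, min_beats=config.min_beats_for_average
        )
        if rep.low_confidence:
            flags.append("low_confidence_average")
        _, params = fit_phases(
            rep,
            noise_sd=noise_sd,
            smooth_ms=config.smooth_ms,
            trx_reference=config.trx_reference,
        )
        if any(params.censored.values()):
            flags.append("censored_recovery")
        results.append(
            PeriodResult(
                name=name,
                concentration=conc,
                params=params,
                events=events,
                n_averaged=rep.n_averaged,
                n_beats=len(in_period),
                flags=flags,
            )
        )
    return results
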