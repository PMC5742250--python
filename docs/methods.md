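# Methods

This note documents the models, defaults and numerical choices behind
`cardiotwitch`, and the limits of what its synthetic-data results demonstrate.

## Twitch waveform model

One beat of sarcomere length is `sl(t) = baseline − A·φ(t)` with
`A = baseline × frac_shortening` and a normalized shape `φ` built from two
pieces:

* **contraction limb** (`0 ≤ t ≤ t_peak`): `φ = (½ − ½cos(πt/t_peak))^p`,
  with shape exponent `p = 2` by default. This rises smoothly from zero
  slope at the stimulus to zero slope at the peak; `p = 2` reproduces peak
  contraction velocities near −0.9 µm/s for the population-mean twitch,
  matching the reported distribution.
* **relaxation** (`t > t_peak`): a biexponential evaluated on the warped
  time axis `q(τ) = τ²/(τ + c)`, `c = 20 ms`:
  `φ = w·exp(−q/τ₁) + (1−w)·exp(−q/(ρτ₁))` with fast-weight `w = 0.7` and
  time-constant ratio `ρ = 3`. The warp gives the minimum zero slope on both
  sides — real transients have rounded peaks, and without it the
  quadratic-vertex peak localisation in the analysis stage is biased early
  by more than one 240 Hz sample. `τ₁` is solved by bracketed root-finding
  so that exactly 10% of the amplitude remains `tr90` ms after the peak.

Infeasible descriptor sets (`t_peak + tr90` ≥ pacing interval) raise rather
than silently distort. Each simulated beat is generated independently within
its stimulus window; the small residual a slow relaxation would carry into
the next diastole is truncated at the window edge (a ≲1% of amplitude
discontinuity for the slowest cells).

## Population model

Baseline descriptors are drawn hierarchically: heart effect ~ population,
cell ~ heart. Fractional shortening, TPeak and TR90 are drawn lognormally —
their recorded distributions are right-skewed (mean > median), and the
lognormal parameterised by the recorded mean and SD reproduces the recorded
medians within ~5% — while resting sarcomere length is normal. Draws are
rejected outside physiological bounds (e.g. TR90 ∈ [170, 720] ms) or when
infeasible for the pacing interval; this truncation costs roughly 7% of the
nominal SD for the most skewed parameter.

The intra-heart share of the total SD defaults to 0.9 (cell-level SD =
0.9 × total; heart-level takes the quadrature remainder), matching the
observation that within-heart variability accounts for ~90% of the total.

**Mean matching.** The realized cohort is recentred (multiplicatively in log
space for the skewed parameters) so its empirical mean equals the configured
population mean. The statistics being emulated describe a specific recorded
cohort, and with only ~11 heart effects a free draw of the pooled mean
wanders by ±5% run to run, which would swamp any analysis-accuracy signal in
a population-recovery comparison. Spread and the heart/cell split are
untouched. `sample_population(..., match_population_mean=False)` restores
free draws (used by the variance-decomposition tests).

**Drug-response heterogeneity.** Each cell draws one lognormal response
factor (σ_log = 0.2) applied to both its IC50 and its TR90 increment, so a
strongly responding cell responds strongly at every concentration. This puts
a ~5-percentage-point SD on a 26% TR90 effect — deliberately below the ±7
s.e.m. reported for 6-cell experiments, because that published spread also
contains measurement noise, which the generator adds separately
(white Gaussian on sarcomere length, default SD 0.005 µm ≈ 6.5% of the mean
twitch amplitude; the noise floor of the real instrument is not published
and this value keeps baseline periods free of false event calls at the
default detector thresholds).

**Events.** ACs are injected as scaled mini-twitches (amplitude a uniform
0.15–0.5 fraction of the twitch, 50 ms to peak, 110 ms TR90) with onset
uniform in [peak + 1.05·TR90, next stimulus − 100 ms]. Placing onsets after
the 90% recovery point mirrors the observation that these events sit in the
late relaxation phase, and keeps the 15-beat averaged transient's recovery
times meaningful even at 50% per-beat AC probability — events straddling the
70–90% recovery region would systematically inflate the averaged TR90. CEs
replace the whole beat with flat baseline. All probabilities are per beat
(AC) or per stimulus (CE); the per-drug values in the packaged effect
profiles are plausibility settings chosen so cell-level incidences land in
the reported ranges under 30-beat periods — they are free parameters of the
generator, not published rates.

## Striation rendering and spectral tracking

Frames are 1-D profiles `1 + contrast·cos(2πx/SL(t) + φ₀)` (or a Gaussian
Z-band comb) over a 30 µm ROI at 50 nm/px, optionally with white intensity
noise. The tracker detrends each profile (mean + linear ramp, removing
illumination gradients without touching band frequencies), applies a Hann
taper, zero-pads ×4, and takes the dominant rFFT magnitude peak inside the
1.4–2.4 µm band — wide enough to bracket the physiological 1.6–2.2 µm range,
narrow enough to exclude harmonics and shading. The peak is refined by
three-point quadratic interpolation of the log-magnitude; per-frame accuracy
on clean profiles is well under 1 nm and ~4 nm RMS at the default noise.
Frames whose peak prominence (peak/median in-band magnitude) falls below 4
are flagged `nan`, never interpolated; traces with >20% flagged frames are
rejected outright. A width-3 median filter removes isolated outliers. The
estimate requires ≥8 periods in the ROI.

## Transient analysis

Beats are cut at the stimulus timestamps (pacing irregular by >10% is an
error; a truncated final window is dropped). The pre-stimulus baseline is
the median of the preceding 50 ms. Event detection runs on every
non-averaged beat of a period:

* **CE**: amplitude below `max(0.1 × vehicle median amplitude, 3 × noise SD)`.
  Note one consequence: when a strong negative inotrope suppresses the
  twitch below this floor, the detector reports CE even though excitability
  was never modelled as lost — the assay's visual distinction between "tiny
  twitch" and "no twitch" has no amplitude-rule equivalent. CE is excluded
  from the risk classifier, so drug calls are unaffected.
* **AC**: on the 25 ms-smoothed beat, scan from peak + TR50 to the next
  stimulus for a derivative reversal (relaxation → secondary shortening →
  recovery) sustained ≥3 samples. The deflection is measured against the
  last pre-dip sample extrapolated along the local relaxation slope
  (clamped non-negative), so ongoing recovery does not mask shallow events,
  and must exceed `max(0.05 × twitch amplitude, 4 × noise SD)`. At the
  default noise this floor is 20 nm — large relative to a small AC, which is
  the price of zero false calls on clean baselines; the floor scales down
  directly with the noise level.

The representative transient averages the last 15 twitch-bearing beats of a
period (CE beats excluded, AC beats included — events are determined from
the non-averaged beats); fewer than 5 usable beats flags low confidence, and
a fully suppressed period falls back to the flat mean with `n_averaged = 0`.

**Five-phase fitting.** Segments and polynomial orders: pre-contraction
baseline (order 1) to the contraction onset (first sustained descent of the
smoothed derivative); contraction limb (order 3); peak neighbourhood ±12 ms
(order 2 — its vertex gives peak value and TPeak); fast relaxation to the
raw 50% recovery crossing (order 3); late relaxation from there to
min(95% recovery, raw 90% crossing + 100 ms) (order 3). TR70/80/90 come
from root-finding on the phase-4/5 polynomials against levels referenced to
the fitted baseline and peak; a level not reached before the next stimulus
is censored (`nan` + flag), never extrapolated. The ±12 ms peak window and
the late-segment cap were calibrated on noiseless waveforms across the
kinetics range: a ±20 ms window biases the vertex up to −8 ms at extreme
shapes, and a cubic fitted to the full diastolic tail misses TR90 by ~9 ms,
versus ≤4.4 ms (under one 240 Hz sample) for the chosen domains. TR70/80/90
are peak-referenced by default (TPeak + TR90 = full twitch duration);
`trx_reference="stimulus"` switches the convention.

Accuracy at the defaults: noiseless extraction is within one sample for all
timing parameters; at 0.005 µm noise the per-cell TR90 estimate carries
σ ≈ 15–25 ms (the 90% recovery crossing is shallow, so timing noise is
residual noise divided by a small slope — a floor no 15-beat average can
beat), while pooled means over a cohort remain accurate to a few ms. The
<5 ms per-cell round-trip regime is reached at ≤0.001 µm noise.

## Concentration–effect and risk

Effects are percent change from the same cell's vehicle period. Hill fits
fix top = 100 and bottom = 0 (four-point curves cannot support free
asymptotes), bound the slope to [0.3, 5], and multi-start over 11 log-spaced
IC50 initialisations; censoring (`IC50 > top concentration`) triggers when
the fitted IC50 exceeds the top tested concentration or observed inhibition
never reaches 50%. In a 500-replicate simulation at 10% relative response
noise on a four-point grid, the median |IC50 bias| is ~12%.

Margins are IC50/fETPC, rounded by the panel convention (integer at ≥1,
one decimal below 1, half-up). A drug is called pro-arrhythmia-positive when
cell-level AC incidence is non-zero at any period at or below the 10× fETPC
threshold (threshold and ≤-vs-= rule are configurable); CE informs margins
but not the call. Sensitivity/specificity are rounded-percent confusion
rates against clinical TdP labels. Variability decomposes as intra-heart
(mean of per-heart SDs, hearts with <2 cells excluded with a warning) versus
total (pooled SD).

Known transcription inconsistencies in the packaged reference tables are
surfaced, not repaired: three top-row fold labels are nominal decade labels
rather than arithmetic ratios, and several printed IC50/fETPC margins
(verapamil most visibly: 0.04/0.045 ≈ 0.9, printed 2) do not re-derive from
their own printed inputs. The fixtures store the printed values alongside
the recomputed ones.

## Problem sizes and determinism

The study-level recomputations run the baseline cohort at its full size
(189 cells, 11 hearts) but with 16 s vehicle recordings — one beat more than
the 15-beat average needs — and the dofetilide experiment at its published
size (6 cells) with 30-beat periods; these keep the full
simulate→render→track→analyze chain at minutes on one CPU. Every stochastic
stage consumes an explicit `numpy` Generator; the pipeline derives
per-drug/per-cell streams from a single root seed via `SeedSequence`, and a
fixed config + seed regenerates byte-identical reports.

## What passing tests do and do not show

The generator shares its waveform family with the analyzer's assumptions, so
round-trip accuracy bounds the analysis error under the model, not under
real optics: no motion or rotation artifacts, no photobleaching, no
baseline drift, no beat-to-beat kinetic memory (alternans), stationary
noise, and AC morphology that is a scaled twitch rather than a genuine
electro-mechanical event. Classification results on the synthetic panel
demonstrate that the decision logic reproduces the published outcome pattern
given effect profiles consistent with the published summaries — they are not
an independent validation of the assay's clinical predictivity.
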