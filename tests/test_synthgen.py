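"""Generator contracts: waveform descriptors, event injection, population structure."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from cardiotwitch.fixtures import load_baseline_population, baseline_population_model
from cardiotwitch.synthgen import (
    DrugEffectProfile,
    InfeasibleKineticsError,
    PacingProtocol,
    PopulationModel,
    TwitchKinetics,
    make_twitch,
    sample_population,
    simulate_cell,
    synthesize_intensity_stack,
)

FS = 240.0


def _extract_descriptors(t, y, baseline):
    """Sample-level TPeak/TR90/amplitude read directly off a waveform."""
    i = int(np.argmin(y))
    amplitude = baseline - y[i]
    level = baseline - 0.1 * amplitude
    after = np.flatnonzero((np.arange(y.size) > i) & (y >= level))
    t90 = np.interp(level, [y[after[0] - 1], y[after[0]]], [t[after[0] - 1], t[after[0]]])
    return t[i] * 1e3, (t90 - t[i]) * 1e3, amplitude


@pytest.mark.parametrize(
    "baseline,frac,t_peak,tr90",
    [
        (1.78, 0.0431, 168.0, 337.0),  # population-mean twitch
        (1.60, 0.10, 120.0, 250.0),
        (2.10, 0.02, 220.0, 500.0),
    ],
)
def test_make_twitch_reproduces_configured_descriptors(baseline, frac, t_peak, tr90):
    kin = TwitchKinetics(baseline, frac, t_peak, tr90)
    t, y = make_twitch(kin, FS)
    tpk, tr90_meas, amplitude = _extract_descriptors(t, y, baseline)
    one_sample_ms = 1e3 / FS
    assert abs(tpk - t_peak) <= one_sample_ms
    assert abs(tr90_meas - tr90) <= one_sample_ms
    assert abs(amplitude - baseline * frac) <= 1e-3 * baseline * frac


def test_zero_shortening_gives_flat_line():
    kin = TwitchKinetics(1.78, 0.0, 168.0, 337.0)
    _, y = make_twitch(kin, FS)
    assert np.allclose(y, 1.78)


def test_infeasible_kinetics_raises():
    kin = TwitchKinetics(1.78, 0.04, 400.0, 650.0)
    with pytest.raises(InfeasibleKineticsError):
        make_twitch(kin, FS, interval_s=1.0)


def test_biexponential_relaxation_matches_analytic_root():
    """TR90 of a τ1=60/τ2=200 ms mixture: analytic root vs. waveform extraction."""
    tau1, tau2, w, c = 0.060, 0.200, 0.7, 0.020
    # independent oracle: root of the relaxation's closed form
    resid = lambda s: w * np.exp(-(s * s / (s + c)) / tau1) + (1 - w) * np.exp(
        -(s * s / (s + c)) / tau2
    ) - 0.10
    tr90_oracle = brentq(resid, 1e-5, 5.0) * 1e3
    kin = TwitchKinetics.from_relaxation_taus(1.78, 0.0431, 168.0, 60.0, 200.0, 0.7)
    assert abs(kin.tr90 - tr90_oracle) < 1e-6  # closed form self-consistency
    t, y = make_twitch(kin, FS)
    _, tr90_meas, _ = _extract_descriptors(t, y, 1.78)
    assert abs(tr90_meas - tr90_oracle) <= 1e3 / FS


class TestSimulateCell:
    def test_null_profile_identical_to_zero_effect_profile(
        self, table_kinetics, short_protocol, quiet_population
    ):
        concs = [0.1, 1.0]
        zero = DrugEffectProfile(
            drug_name="inert",
            tr90_multiplier_by_conc={0.1: 1.0, 1.0: 1.0},
            ac_prob_by_conc={0.1: 0.0},
            ce_prob_by_conc={1.0: 0.0},
        )
        a = simulate_cell(
            table_kinetics, DrugEffectProfile.null(), short_protocol, quiet_population,
            concs, rng=np.random.default_rng(7),
        )
        b = simulate_cell(
            table_kinetics, zero, short_protocol, quiet_population,
            concs, rng=np.random.default_rng(7),
        )
        np.testing.assert_array_equal(a.trace.sl, b.trace.sl)

    def test_seed_determinism(self, table_kinetics, short_protocol, quiet_population):
        profile = DrugEffectProfile(
            drug_name="x", hill_ic50=1.0, ac_prob_by_conc={1.0: 0.3}
        )
        runs = [
            simulate_cell(
                table_kinetics, profile, short_protocol, quiet_population,
                [1.0], rng=np.random.default_rng(123),
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].trace.sl, runs[1].trace.sl)
        assert [p.to_dict() for p in runs[0].truth] == [p.to_dict() for p in runs[1].truth]

    def test_verapamil_like_full_suppression_without_events(
        self, table_kinetics, short_protocol, quiet_population
    ):
        profile = DrugEffectProfile(drug_name="verapamil", hill_ic50=0.04, hill_slope=1.0)
        cell = simulate_cell(
            table_kinetics, profile, short_protocol, quiet_population,
            [10.0], rng=np.random.default_rng(0),
        )
        top = cell.truth[-1]
        vehicle_amp = table_kinetics.baseline_sl * table_kinetics.frac_shortening
        assert top.kinetics.frac_shortening < 0.01 * table_kinetics.frac_shortening
        assert vehicle_amp * (top.kinetics.frac_shortening / table_kinetics.frac_shortening) < 0.01 * vehicle_amp
        assert top.ac_beats == [] and top.ce_beats == []

    def test_injected_ac_count_within_binomial_bounds(self, table_kinetics):
        protocol = PacingProtocol(vehicle_duration=0.0, period_duration=240.0)
        population = PopulationModel(noise_sd=0.005, seed=0, effect_log_sd=0.0)
        profile = DrugEffectProfile(drug_name="x", ac_prob_by_conc={1.0: 0.5})
        cell = simulate_cell(
            table_kinetics, profile, protocol, population, [1.0],
            rng=np.random.default_rng(11),
        )
        n_ac = len(cell.truth[-1].ac_beats)
        lo, hi = binom.ppf([0.005, 0.995], 240, 0.5)
        assert lo <= n_ac <= hi

    def test_amplitude_monotone_in_concentration(self, table_kinetics, short_protocol):
        population = PopulationModel(noise_sd=0.0, seed=0, effect_log_sd=0.0)
        profile = DrugEffectProfile(drug_name="x", hill_ic50=0.5, hill_slope=1.2)
        cell = simulate_cell(
            table_kinetics, profile, short_protocol, population,
            [0.1, 0.5, 2.0, 10.0], rng=np.random.default_rng(0),
        )
        amplitudes = [p.kinetics.frac_shortening for p in cell.truth]
        assert all(a >= b - 1e-12 for a, b in zip(amplitudes, amplitudes[1:]))

    def test_vehicle_purity_no_events_in_truth(self, vehicle_cell):
        assert all(p.ac_beats == [] and p.ce_beats == [] for p in vehicle_cell.truth)


class TestPopulation:
    def test_pooled_sd_matches_cell_level_sd_without_heart_variance(self):
        """With no heart-level variance the pooled spread is the cell-level SD.

        The SD of a 189-draw right-skewed sample fluctuates by several percent
        seed to seed, so the comparison averages the SD over three replicate
        cohorts (the physiological-bounds truncation itself costs ~7%).
        """
        fix = load_baseline_population()
        means = {k: v["mean"] for k, v in fix["parameters"].items()}
        total_sd = {k: v["total_sd"] for k, v in fix["parameters"].items()}
        model = PopulationModel(
            heart_level_sd={k: 0.0 for k in means},
            cell_level_sd=total_sd,
            n_hearts=1,
            cells_per_heart=189,
            seed=3,
        )
        sds = {p: [] for p in ("tr90", "frac_shortening", "t_peak")}
        for seed in (3, 4, 5):
            draws = sample_population(means, model, rng=np.random.default_rng(seed))
            for param in sds:
                sds[param].append(np.std([getattr(k, param) for _, k in draws]))
        for param, vals in sds.items():
            assert np.mean(vals) == pytest.approx(total_sd[param], rel=0.10)

    def test_population_mean_matching(self):
        fix = load_baseline_population()
        means = {k: v["mean"] for k, v in fix["parameters"].items()}
        model = baseline_population_model(n_hearts=11, cells_per_heart=18, seed=9)
        draws = sample_population(means, model, rng=np.random.default_rng(9))
        tr90 = np.array([k.tr90 for _, k in draws])
        assert tr90.mean() == pytest.approx(means["tr90"], abs=2.0)

    def test_draws_respect_feasibility(self):
        fix = load_baseline_population()
        means = {k: v["mean"] for k, v in fix["parameters"].items()}
        model = baseline_population_model(n_hearts=5, cells_per_heart=10, seed=2)
        for _, kin in sample_population(means, model, rng=np.random.default_rng(2)):
            assert kin.t_peak + kin.tr90 < 950.0


class TestIntensityStack:
    def test_constant_trace_gives_constant_period_frames(self, table_kinetics):
        from cardiotwitch.traces import SarcomereLengthTrace

        trace = SarcomereLengthTrace(
            time=np.arange(10) / FS,
            sl=np.full(10, 1.80),
            stimulus_times=np.array([0.0]),
            sample_rate=FS,
        )
        stack = synthesize_intensity_stack(trace, noise_sd=0.0)
        # every frame identical and periodic with period 1.80 µm
        assert np.abs(stack.frames - stack.frames[0]).max() < 1e-12
        x = np.arange(stack.frames.shape[1]) * stack.pixel_pitch
        shift = int(round(1.80 / stack.pixel_pitch))
        prof = stack.frames[0]
        np.testing.assert_allclose(prof[shift:], prof[:-shift], atol=1e-6)

    def test_roi_too_short_raises(self, vehicle_cell):
        with pytest.raises(ValueError, match="ROI"):
            synthesize_intensity_stack(vehicle_cell.trace, roi_length_um=10.0)

    def test_zero_contrast_gives_flat_frames(self, vehicle_cell):
        stack = synthesize_intensity_stack(
            vehicle_cell.trace, band_contrast=0.0, noise_sd=0.0
        )
        assert np.ptp(stack.frames) < 1e-12
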